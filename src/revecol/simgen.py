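"""Synthetic community generator.

Plants, with machine-readable ground truth, the evolutionary events a
reverse-ecology analysis of a clonal, epithelium-attached bacterial lineage
must recover:

* two clonal populations (A and B) whose genomes lie at a raw pairwise
  distance of ``d_between`` across populations and ``d_within`` within them;
* a pangenome in which ``core_fraction`` of genes are present in every
  genome, blocks of genes are unique to (and fixed within) one population,
  and the remaining flexible genes are missing from two or more genomes;
* a recently imported segment, identical in every population-A genome
  (hence SNP-free within A) and strongly diverged from population B;
* a duplicated two-variant gene whose 3' tail has been homogenized between
  the two copies carried by population B (gene-conversion signature);
* negative-binomial transcript counts with planted population-biased genes,
  and covariates (SCFA-like concentrations) linearly coupled to population-A
  abundance.

Substitutions are planted uniformly at random, sites independent, with no
indels; gene gain/loss is realised as deletion of whole gene spans, so all
genomes remain colinear on the ancestral coordinate system and every
downstream oracle stays exact.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import decode, plant_substitutions, random_sequence, revcomp
from .config import ConfigError, SimConfig

# rng stream constants fanned out from the top-level seed
_STREAM_GENOMES, _STREAM_READS, _STREAM_COUNTS, _STREAM_COVARIATES = 0, 1, 2, 3

CLASS_CORE = "core"
CLASS_FLEXIBLE = "flexible"
CLASS_POP_A = "pop_specific_A"
CLASS_POP_B = "pop_specific_B"


def _rng(config: SimConfig, stream: int, seed=None) -> np.random.Generator:
    if seed is not None:
        return np.random.default_rng(seed)
    return np.random.default_rng([config.seed, stream])


@dataclass
class SimulatedCommunity:
    """Genomes, annotations and ground truth emitted by :func:`simulate_populations`."""

    config: SimConfig
    genome_names: list[str]
    genomes: dict[str, np.ndarray]          # post-deletion sequences (uint8 0..3)
    genomes_anc: dict[str, np.ndarray]      # full-length, ancestor coordinates
    keep_masks: dict[str, np.ndarray]       # ancestor columns retained per genome
    gene_table: pd.DataFrame                # gene_id, idx, anc_start, anc_end, strand, class
    presence: pd.DataFrame                  # genes x genomes boolean
    annotations: pd.DataFrame               # genome, gene_id, start/end (1-based), strand
    truth_populations: dict[str, str]
    truth_sweep_region: dict
    dup_genes: tuple[str, str]
    truth_de_genes: dict[str, float] = field(default_factory=dict)

    # -- accessors -----------------------------------------------------------
    @property
    def truth_gene_classes(self) -> pd.Series:
        return self.gene_table.set_index("gene_id")["gene_class"]

    def population(self, name: str) -> str:
        return self.truth_populations[name]

    def reference(self, pop: str) -> str:
        """First genome of a population, used as that population's reference."""
        for name in self.genome_names:
            if self.truth_populations[name] == pop:
                return name
        raise KeyError(pop)

    def members(self, pop: str) -> list[str]:
        return [g for g in self.genome_names if self.truth_populations[g] == pop]

    def gene_seq(self, genome: str, gene_id: str) -> np.ndarray:
        """Strand-adjusted gene sequence extracted from the emitted genome."""
        row = self.annotations[
            (self.annotations.genome == genome) & (self.annotations.gene_id == gene_id)
        ]
        if row.empty:
            raise KeyError(f"{gene_id} absent from {genome}")
        r = row.iloc[0]
        seq = self.genomes[genome][r.start - 1 : r.end]
        return revcomp(seq) if r.strand == "-" else seq

    def genes_of(self, genome: str) -> pd.DataFrame:
        return self.annotations[self.annotations.genome == genome].reset_index(drop=True)

    # -- alignment over shared (core) columns --------------------------------
    def core_columns(self) -> np.ndarray:
        mask = np.ones(self.config.genome_length, dtype=bool)
        for m in self.keep_masks.values():
            mask &= m
        return mask

    def core_alignment(self) -> tuple[list[str], np.ndarray, np.ndarray]:
        """Gap-free alignment over ancestor columns present in all genomes.

        Returns (genome names, n x m uint8 matrix, ancestor positions of columns).
        """
        mask = self.core_columns()
        pos = np.flatnonzero(mask)
        mat = np.stack([self.genomes_anc[g][mask] for g in self.genome_names])
        return list(self.genome_names), mat, pos

    # -- output --------------------------------------------------------------
    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name in self.genome_names:
                fh.write(f">{name}\n")
                s = decode(self.genomes[name])
                for i in range(0, len(s), 80):
                    fh.write(s[i : i + 80] + "\n")

    def write_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for name in self.genome_names:
                fh.write(f"##sequence-region {name} 1 {len(self.genomes[name])}\n")
            for r in self.annotations.itertuples():
                attrs = f"ID={r.genome}:{r.gene_id};locus_tag={r.gene_id}"
                fh.write(
                    f"{r.genome}\trevecol_sim\tgene\t{r.start}\t{r.end}\t.\t{r.strand}\t.\t{attrs}\n"
                )

    def write_truth(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        pd.Series(self.truth_populations, name="population").rename_axis("genome").to_csv(
            outdir / "populations.tsv", sep="\t"
        )
        self.gene_table.to_csv(outdir / "gene_classes.tsv", sep="\t", index=False)
        self.presence.astype(int).to_csv(outdir / "presence.tsv", sep="\t")
        pd.DataFrame([self.truth_sweep_region]).to_csv(
            outdir / "sweep_region.tsv", sep="\t", index=False
        )
        if self.truth_de_genes:
            pd.Series(self.truth_de_genes, name="log2fc").rename_axis("gene_id").to_csv(
                outdir / "de_genes.tsv", sep="\t"
            )


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _layout_genes(config: SimConfig, rng: np.random.Generator):
    """Place n_genes non-overlapping gene slots on the ancestral coordinate
    system. Returns (starts, ends, strands, dup_idx pair)."""
    n, mean = config.n_genes, config.gene_length_mean
    lengths = rng.normal(mean, 0.15 * mean, size=n)
    lengths = np.clip(lengths, max(90, int(0.6 * mean)), int(1.5 * mean))
    lengths = (np.round(lengths / 3).astype(int) * 3).clip(min=90)
    # two slots host the duplicated two-variant gene
    dup1 = int(0.55 * n)
    dup2 = int(0.70 * n)
    lengths[[dup1, dup2]] = config.dup_gene_length
    margin = 100
    spare = config.genome_length - 2 * margin - int(lengths.sum())
    gap = spare // max(n - 1, 1)
    if gap < 10:
        raise ConfigError(
            "genome_length too small for n_genes x gene_length_mean "
            f"(needs >= {2 * margin + int(lengths.sum()) + 10 * (n - 1)} bp)"
        )
    starts = margin + np.concatenate([[0], np.cumsum(lengths[:-1] + gap)])
    ends = starts + lengths
    strands = np.where(rng.random(n) < 0.5, "+", "-")
    strands[[dup1, dup2]] = "+"  # keeps the 3' tail a plain suffix in genome coords
    return starts.astype(int), ends.astype(int), strands, (dup1, dup2)


def _assign_classes(config: SimConfig, rng: np.random.Generator,
                    starts, ends, dup_idx, sweep_interval):
    """Choose gene classes and the genes x genomes presence matrix."""
    n = config.n_genes
    n_genomes = config.n_genomes_a + config.n_genomes_b
    idx_a = np.arange(config.n_genomes_a)
    idx_b = np.arange(config.n_genomes_a, n_genomes)

    forced_core = set(dup_idx)
    s0, e0 = sweep_interval
    forced_core |= set(np.flatnonzero((ends > s0) & (starts < e0)))

    n_core = round(config.core_fraction * n)
    n_flex = n - n_core
    classes = np.full(n, CLASS_CORE, dtype=object)
    available = np.ones(n, dtype=bool)
    available[list(forced_core)] = False

    def carve_blocks(total, label):
        placed = 0
        guard = 0
        while placed < total:
            block = min(config.pop_specific_block, total - placed)
            s = int(rng.integers(0, n - block + 1))
            if available[s : s + block].all():
                classes[s : s + block] = label
                available[s : s + block] = False
                placed += block
            guard += 1
            if guard > 100 * n:
                raise ConfigError("n_pop_specific: could not place gene blocks; too crowded")

    carve_blocks(config.n_pop_specific_a, CLASS_POP_A)
    carve_blocks(config.n_pop_specific_b, CLASS_POP_B)

    n_other = n_flex - config.n_pop_specific_a - config.n_pop_specific_b
    pool = np.flatnonzero(available)
    other = rng.choice(pool, size=n_other, replace=False)
    classes[other] = CLASS_FLEXIBLE

    presence = np.ones((n, n_genomes), dtype=bool)
    for i in np.flatnonzero(classes == CLASS_POP_A):
        presence[i, idx_b] = False
    for i in np.flatnonzero(classes == CLASS_POP_B):
        presence[i, idx_a] = False
    max_missing = min(config.flexible_max_missing, n_genomes - 1)
    for i in np.flatnonzero(classes == CLASS_FLEXIBLE):
        while True:
            k = int(rng.integers(2, max(max_missing, 2) + 1))
            missing = rng.choice(n_genomes, size=k, replace=False)
            row = np.ones(n_genomes, dtype=bool)
            row[missing] = False
            # avoid accidentally re-creating a population-specific pattern
            if row[idx_a].all() and not row[idx_b].any():
                continue
            if row[idx_b].all() and not row[idx_a].any():
                continue
            presence[i] = row
            break
    return classes, presence


def simulate_populations(config: SimConfig, seed=None) -> SimulatedCommunity:
    """Generate the two-population community with all planted events.

    Deterministic for a fixed ``config.seed``. The stem between the two
    population ancestors carries ``d_between - d_within`` substitutions/site,
    and each genome another ``d_within / 2`` from its population ancestor, so
    expected pairwise distances are ``d_within`` within and ``d_between``
    between populations.
    """
    config.validate()
    rng = _rng(config, _STREAM_GENOMES, seed)
    L = config.genome_length

    starts, ends, strands, dup_idx = _layout_genes(config, rng)
    gene_ids = [f"gene_{i + 1:05d}" for i in range(config.n_genes)]

    # sweep interval on ancestor coordinates, away from genome edges
    s0 = int(0.30 * L)
    sweep_interval = (s0, s0 + config.sweep_region_length)

    classes, presence = _assign_classes(config, rng, starts, ends, dup_idx, sweep_interval)

    ancestor = random_sequence(L, rng)
    # ancestral duplication: the second variant is a diverged copy of the first
    d1, d2 = dup_idx
    dup_subs = round(config.dup_copy_divergence * config.dup_gene_length)
    ancestor[starts[d2]:ends[d2]] = plant_substitutions(
        ancestor[starts[d1]:ends[d1]], dup_subs, rng
    )

    # stem split between population ancestors
    m_stem = round((config.d_between - config.d_within) * L)
    stem_sites = rng.choice(L, size=m_stem, replace=False)
    to_a = rng.random(m_stem) < 0.5
    anc_a = plant_substitutions(ancestor, int(to_a.sum()), rng, positions=stem_sites[to_a])
    anc_b = plant_substitutions(ancestor, int((~to_a).sum()), rng, positions=stem_sites[~to_a])

    names = [f"A{i + 1:02d}" for i in range(config.n_genomes_a)] + [
        f"B{i + 1:02d}" for i in range(config.n_genomes_b)
    ]
    pops = {n: ("A" if n.startswith("A") else "B") for n in names}

    m_within = round(config.d_within / 2 * L)
    genomes_anc: dict[str, np.ndarray] = {}
    for name in names:
        base = anc_a if pops[name] == "A" else anc_b
        genomes_anc[name] = plant_substitutions(base, m_within, rng)

    # imported segment: one draw, written identically into every A genome
    sw_s, sw_e = sweep_interval
    sweep_subs = round(config.sweep_region_divergence * (sw_e - sw_s))
    sweep_seq = plant_substitutions(anc_b[sw_s:sw_e], sweep_subs, rng)
    for name in names:
        if pops[name] == "A":
            genomes_anc[name][sw_s:sw_e] = sweep_seq

    # gene-conversion: homogenize the 3' tail of the two variants within B
    tail = config.dup_homogenized_tail
    if tail > 0:
        for name in names:
            if pops[name] == "B":
                g = genomes_anc[name]
                g[ends[d2] - tail : ends[d2]] = g[ends[d1] - tail : ends[d1]]

    # gene loss as deletion of gene spans; build per-genome sequences + coords
    genomes: dict[str, np.ndarray] = {}
    keep_masks: dict[str, np.ndarray] = {}
    ann_rows = []
    for gi, name in enumerate(names):
        keep = np.ones(L, dtype=bool)
        absent = np.flatnonzero(~presence[:, gi])
        for i in absent:
            keep[starts[i]:ends[i]] = False
        keep_masks[name] = keep
        genomes[name] = genomes_anc[name][keep]
        del_before = np.concatenate([[0], np.cumsum(~keep)])
        for i in np.flatnonzero(presence[:, gi]):
            ns = int(starts[i] - del_before[starts[i]])
            ne = int(ends[i] - del_before[ends[i]])
            ann_rows.append((name, gene_ids[i], ns + 1, ne, strands[i]))

    annotations = pd.DataFrame(
        ann_rows, columns=["genome", "gene_id", "start", "end", "strand"]
    )

    gene_table = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "order_index": np.arange(config.n_genes),
            "anc_start": starts,
            "anc_end": ends,
            "strand": strands,
            "gene_class": classes,
        }
    )
    presence_df = pd.DataFrame(presence, index=gene_ids, columns=names)

    # sweep interval expressed on the A reference genome's own coordinates
    ref_a = names[0]
    del_before = np.concatenate([[0], np.cumsum(~keep_masks[ref_a])])
    truth_sweep = {
        "reference": ref_a,
        "start": int(sw_s - del_before[sw_s]),
        "end": int(sw_e - del_before[sw_e]),
        "anc_start": int(sw_s),
        "anc_end": int(sw_e),
        "divergence_vs_b": config.sweep_region_divergence,
    }

    return SimulatedCommunity(
        config=config,
        genome_names=names,
        genomes=genomes,
        genomes_anc=genomes_anc,
        keep_masks=keep_masks,
        gene_table=gene_table,
        presence=presence_df,
        annotations=annotations,
        truth_populations=pops,
        truth_sweep_region=truth_sweep,
        dup_genes=(gene_ids[d1], gene_ids[d2]),
    )


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Dense read batch: all reads share one length (Illumina-like)."""

    seqs: np.ndarray          # n_reads x read_length uint8
    source: np.ndarray        # index into genome_names
    pos: np.ndarray           # 0-based start on the source genome
    strand: np.ndarray        # 0 = forward, 1 = reverse
    genome_names: list[str]

    def __len__(self) -> int:
        return len(self.seqs)

    @property
    def read_length(self) -> int:
        return self.seqs.shape[1]

    def names(self) -> list[str]:
        return [f"read_{i:08d}" for i in range(len(self))]

    def to_fastq(self, path) -> None:
        qual = "I" * self.read_length
        with open(path, "w") as fh:
            for i in range(len(self)):
                fh.write(f"@read_{i:08d}\n{decode(self.seqs[i])}\n+\n{qual}\n")


def simulate_reads(
    community: SimulatedCommunity,
    source_mix: dict[str, float] | None = None,
    config: SimConfig | None = None,
    seed=None,
) -> ReadSet:
    """Draw uniform shotgun reads from weighted genomes.

    Read count per genome ≈ depth * weight * genome_length / read_length;
    per-base substitution errors at ``error_rate``; strands uniform.
    """
    config = config or community.config
    rng = _rng(config, _STREAM_READS, seed)
    if source_mix is None:
        source_mix = {name: 1.0 for name in community.genome_names}
    weights = np.array([source_mix.get(n, 0.0) for n in community.genome_names], float)
    if (weights < 0).any():
        raise ValueError("source_mix weights must be >= 0")
    if not (weights > 0).any():
        raise ValueError("source_mix must contain at least one positive weight")

    rl = config.read_length
    chunks_seq, chunks_src, chunks_pos, chunks_strand = [], [], [], []
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    for gi, name in enumerate(community.genome_names):
        if weights[gi] == 0:
            continue
        g = community.genomes[name]
        n_reads = int(round(config.depth * weights[gi] * len(g) / rl))
        if n_reads == 0:
            continue
        pos = rng.integers(0, len(g) - rl + 1, size=n_reads)
        seqs = g[pos[:, None] + np.arange(rl)]
        strand = rng.integers(0, 2, size=n_reads, dtype=np.int8)
        rev = np.flatnonzero(strand == 1)
        seqs[rev] = comp[seqs[rev]][:, ::-1]
        if config.error_rate > 0:
            for lo in range(0, n_reads, 200_000):
                hi = min(lo + 200_000, n_reads)
                mask = rng.random((hi - lo, rl)) < config.error_rate
                ii, jj = np.nonzero(mask)
                offs = rng.integers(1, 4, size=len(ii), dtype=np.uint8)
                seqs[lo + ii, jj] = (seqs[lo + ii, jj] + offs) % 4
        chunks_seq.append(seqs)
        chunks_src.append(np.full(n_reads, gi, dtype=np.int32))
        chunks_pos.append(pos.astype(np.int64))
        chunks_strand.append(strand)

    return ReadSet(
        seqs=np.concatenate(chunks_seq),
        source=np.concatenate(chunks_src),
        pos=np.concatenate(chunks_pos),
        strand=np.concatenate(chunks_strand),
        genome_names=list(community.genome_names),
    )


# ---------------------------------------------------------------------------
# transcript counts and covariates
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    counts: pd.DataFrame            # genes x samples, integer
    design: pd.Series               # sample -> population context ("A"/"B")
    size_factors: pd.Series         # planted library-size factors
    truth_log2fc: pd.Series         # planted effect per gene (0 = null)
    baseline_mean: pd.Series


def simulate_counts(
    community: SimulatedCommunity, config: SimConfig | None = None, seed=None
) -> CountMatrix:
    """Negative-binomial transcript counts over the community's genes.

    ``n_de_genes`` core genes receive a planted log2 fold change of
    ``±de_log2fc`` (half in each direction) between the two population
    contexts; everything else is null. Library size factors are log-normal
    and recorded in the output.
    """
    config = config or community.config
    if config.nb_dispersion <= 0:
        raise ConfigError(f"nb_dispersion must be > 0, got {config.nb_dispersion}")
    if config.n_samples < 2:
        raise ConfigError("n_samples must be >= 2 per population context")
    rng = _rng(config, _STREAM_COUNTS, seed)

    genes = list(community.gene_table.gene_id)
    n_genes = len(genes)
    samples = [f"A_{i + 1}" for i in range(config.n_samples)] + [
        f"B_{i + 1}" for i in range(config.n_samples)
    ]
    design = pd.Series(
        ["A"] * config.n_samples + ["B"] * config.n_samples, index=samples, name="population"
    )

    base = rng.lognormal(config.nb_mean_log, config.nb_mean_sd, size=n_genes)
    lfc = np.zeros(n_genes)
    core_idx = np.flatnonzero((community.gene_table.gene_class == CLASS_CORE).to_numpy())
    n_de = min(config.n_de_genes, len(core_idx))
    de_idx = rng.choice(core_idx, size=n_de, replace=False)
    signs = np.where(np.arange(n_de) % 2 == 0, 1.0, -1.0)
    lfc[de_idx] = signs * config.de_log2fc

    sf = rng.lognormal(0.0, 0.3, size=len(samples))
    is_a = (design == "A").to_numpy()
    mu = base[:, None] * np.where(is_a[None, :], 2.0 ** lfc[:, None], 1.0) * sf[None, :]
    disp = config.nb_dispersion
    counts = rng.negative_binomial(1.0 / disp, 1.0 / (1.0 + disp * mu))

    truth = pd.Series(lfc, index=genes, name="log2fc")
    community.truth_de_genes = {g: float(v) for g, v in truth[truth != 0].items()}
    return CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        design=design,
        size_factors=pd.Series(sf, index=samples, name="size_factor"),
        truth_log2fc=truth,
        baseline_mean=pd.Series(base, index=genes, name="baseline_mean"),
    )


def simulate_abundances(
    config: SimConfig, seed=None, n_samples: int | None = None
) -> pd.DataFrame:
    """Log-normal dPCR-like copy numbers for populations A and B per sample."""
    rng = _rng(config, _STREAM_COVARIATES, seed)
    n = n_samples or config.n_cov_samples
    idx = [f"sample_{i + 1:03d}" for i in range(n)]
    return pd.DataFrame(
        {
            "A_copies": rng.lognormal(10.0, 1.0, size=n),
            "B_copies": rng.lognormal(9.0, 1.0, size=n),
        },
        index=pd.Index(idx, name="sample"),
    )


def simulate_covariates(
    abundances: pd.DataFrame, config: SimConfig | None = None, seed=None,
    noise_sd: float | None = None,
) -> tuple[pd.DataFrame, dict]:
    """SCFA-like covariates linearly coupled to population-A abundance.

    Covariate 1 (acetate-like) increases with A abundance, covariate 2
    (propionate-like) decreases; both get Gaussian noise. Returns the
    covariate table and the planted slopes (in covariate units per standard
    deviation of log A abundance).
    """
    config = config or SimConfig()
    if len(abundances) < 3:
        raise ValueError("need at least 3 samples to simulate covariates")
    rng = _rng(config, _STREAM_COVARIATES + 100, seed)
    sd = config.covariate_noise_sd if noise_sd is None else noise_sd
    a = np.log(abundances["A_copies"].to_numpy())
    z = (a - a.mean()) / a.std() if a.std() > 0 else np.zeros_like(a)
    eff = config.covariate_effect
    cov1 = 60.0 + 8.0 * (eff * z + rng.normal(0, sd, size=len(z)))
    cov2 = 25.0 + 5.0 * (-eff * z + rng.normal(0, sd, size=len(z)))
    table = pd.DataFrame(
        {"covariate_1": cov1, "covariate_2": cov2}, index=abundances.index
    )
    truth = {"covariate_1_slope": 8.0 * eff, "covariate_2_slope": -5.0 * eff}
    return table, truth
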