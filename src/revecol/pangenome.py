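"""Pangenome classification, gene identity profiles, NG86 dN/dS and
identity distributions.

Gene presence follows the double 70% rule used for nucleotide-level ORF
comparisons: a gene is present in a target genome when its best hit reaches
both 70% identity and 70% query coverage. Classes follow the convention for
a two-population isolate collection: *core* genes occur in every genome,
*flexible* genes are missing from two or more genomes, and the
*population-specific* subset of flexible genes is fixed in all genomes of
one population while absent from every genome of the other. Genes missing
from exactly one genome sit between the published definitions and are
reported separately as *near_core*.
"""
from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from ._seq import encode, revcomp
from .align import KmerIndex, map_query

CLASS_ORDER = ["core", "near_core", "flexible", "population_specific"]


# ---------------------------------------------------------------------------
# gene matching and classification
# ---------------------------------------------------------------------------

def extract_gene_seqs(genes: pd.DataFrame, ref_seq) -> dict[str, np.ndarray]:
    """Strand-adjusted gene sequences from 1-based inclusive coordinates."""
    ref = encode(ref_seq)
    out = {}
    for r in genes.itertuples():
        if r.start < 1 or r.end > len(ref) or r.start > r.end:
            raise ValueError(f"gene {r.gene_id} coordinates outside reference")
        s = ref[r.start - 1 : r.end]
        out[r.gene_id] = revcomp(s) if getattr(r, "strand", "+") == "-" else s
    return out


def match_genes(
    genes: pd.DataFrame,
    ref_seq,
    target_genomes: dict[str, np.ndarray | str],
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
) -> pd.DataFrame:
    """Best hit of each reference gene in each target genome (both strands).

    Returns one row per (gene, target) with identity%, coverage%, location
    and a ``present`` flag applying the double-threshold rule. Genes with no
    seed hit in a target are recorded as absent with NaN identity.
    """
    seqs = extract_gene_seqs(genes, ref_seq)
    rows = []
    for target, tseq in target_genomes.items():
        idx = KmerIndex(encode(tseq))
        for gene_id, q in seqs.items():
            hit = map_query(q, idx)
            if hit is None:
                rows.append((gene_id, target, np.nan, np.nan, -1, -1, ".", False))
                continue
            ident = 100.0 * hit.identity
            cov = 100.0 * hit.coverage
            present = bool(ident >= min_identity and cov >= min_coverage)
            rows.append((gene_id, target, ident, cov, hit.start, hit.end, hit.strand, present))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "target", "identity", "coverage", "t_start", "t_end",
                 "strand", "present"],
    )


def build_gene_catalog(
    annotations: pd.DataFrame, primary: str, secondary: str
) -> pd.DataFrame:
    """Non-redundant gene catalog from two reference genomes' annotations.

    Takes all genes of the primary reference plus those genes of the
    secondary reference not already in the catalog (shared locus tags mark
    orthologues, as emitted by the annotation step). The catalog keeps each
    gene's source genome so sequences are extracted from the genome that
    actually carries them.
    """
    a = annotations[annotations.genome == primary]
    b = annotations[annotations.genome == secondary]
    extra = b[~b.gene_id.isin(set(a.gene_id))]
    return pd.concat([a, extra], ignore_index=True)


def match_gene_catalog(
    catalog: pd.DataFrame,
    genomes: dict[str, np.ndarray | str],
    min_identity: float = 70.0,
    min_coverage: float = 70.0,
) -> pd.DataFrame:
    """Best hits of every catalog gene (extracted from its source genome)
    in every genome; same columns and thresholds as :func:`match_genes`."""
    parts = []
    for src, genes in catalog.groupby("genome"):
        parts.append(
            match_genes(genes.reset_index(drop=True), genomes[src], genomes,
                        min_identity, min_coverage)
        )
    return pd.concat(parts, ignore_index=True)


def classify_pangenome(
    matches: pd.DataFrame,
    populations: dict[str, str],
) -> pd.DataFrame:
    """Classify genes from a presence table over both populations' genomes.

    ``populations`` maps every target genome to its population label; each
    population needs at least 2 genomes. Output columns: gene_id, gene_class
    (core / near_core / flexible / population_specific), population (owner
    for population-specific genes), n_present, n_genomes, presence (ordered
    0/1 string over sorted genome names).
    """
    pops: dict[str, list[str]] = {}
    for g, p in populations.items():
        pops.setdefault(p, []).append(g)
    for p, members in pops.items():
        if len(members) < 2:
            raise ValueError(f"population {p!r} has {len(members)} genome(s); need >= 2")

    genomes = sorted(populations)
    pres = (
        matches[matches.target.isin(genomes)]
        .pivot_table(index="gene_id", columns="target", values="present",
                     aggfunc="any", fill_value=False)
        .reindex(columns=genomes, fill_value=False)
        .astype(bool)
    )
    missing_targets = set(genomes) - set(matches.target.unique())
    if missing_targets:
        raise ValueError(f"matches lack targets: {sorted(missing_targets)}")

    rows = []
    for gene_id, row in pres.iterrows():
        n_missing = int((~row).sum())
        owner = None
        if n_missing == 0:
            cls = "core"
        elif n_missing == 1:
            cls = "near_core"
        else:
            cls = "flexible"
            for p, members in pops.items():
                others = [g for g in genomes if g not in members]
                if row[members].all() and not row[others].any():
                    cls = "population_specific"
                    owner = p
                    break
        rows.append((gene_id, cls, owner, int(row.sum()), len(genomes),
                     "".join("1" if v else "0" for v in row)))
    return pd.DataFrame(
        rows, columns=["gene_id", "gene_class", "population", "n_present",
                       "n_genomes", "presence"],
    )


def core_fraction(classes: pd.DataFrame) -> float:
    """Core genes as a fraction of all classified genes."""
    return float((classes.gene_class == "core").mean())


def identity_profile(
    genes: pd.DataFrame, ref_seq, genome_b, min_identity: float = 70.0,
    min_coverage: float = 70.0,
) -> pd.DataFrame:
    """Per-gene best-hit identity in a second genome, in reference gene order.

    Genes absent under the 70/70 rule keep NaN identity (they plot on the
    axis line). ``genes`` must carry an ``order_index`` column or will be
    ordered by start coordinate.
    """
    m = match_genes(genes, ref_seq, {"target": genome_b}, min_identity, min_coverage)
    m = m.set_index("gene_id")
    g = genes.copy()
    if "order_index" not in g.columns:
        g = g.sort_values("start").reset_index(drop=True)
        g["order_index"] = np.arange(len(g))
    g = g.sort_values("order_index")
    ident = m.loc[g.gene_id, "identity"].to_numpy()
    present = m.loc[g.gene_id, "present"].to_numpy()
    ident = np.where(present, ident, np.nan)
    return pd.DataFrame(
        {"order_index": g.order_index.to_numpy(), "gene_id": g.gene_id.to_numpy(),
         "identity": ident, "present": present}
    )


# ---------------------------------------------------------------------------
# NG86 dN/dS
# ---------------------------------------------------------------------------

_CODON_TABLE: dict[str, str] = {}


def _codon_table() -> dict[str, str]:
    if not _CODON_TABLE:
        from Bio.Data.CodonTable import standard_dna_table

        _CODON_TABLE.update(standard_dna_table.forward_table)
        for stop in standard_dna_table.stop_codons:
            _CODON_TABLE[stop] = "*"
    return _CODON_TABLE


def _syn_sites(codon: str) -> float:
    """Synonymous site count of one codon (Nei–Gojobori counting).

    Each of the nine single-base neighbours contributes 1/3 of a site;
    changes producing a stop codon count as nonsynonymous.
    """
    table = _codon_table()
    if table.get(codon, "*") == "*":
        return 0.0
    syn = 0
    for i in range(3):
        for b in "ACGT":
            if b == codon[i]:
                continue
            alt = codon[:i] + b + codon[i + 1 :]
            if table[alt] != "*" and table[alt] == table[codon]:
                syn += 1
    return syn / 3.0


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences between two codons, averaged
    over all mutational pathways with equal weight; steps through stop
    codons count as nonsynonymous."""
    table = _codon_table()
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    sd = nd = 0.0
    n_paths = 0
    for order in permutations(diff_pos):
        cur = c1
        for i in order:
            nxt = cur[:i] + c2[i] + cur[i + 1 :]
            if table[nxt] != "*" and table[cur] != "*" and table[nxt] == table[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        n_paths += 1
    return sd / n_paths, nd / n_paths


@dataclass
class DnDsResult:
    dn: float
    ds: float
    ratio: float | None          # None when dS == 0
    pn: float
    ps: float
    n_sites: float
    s_sites: float
    n_codons_used: int


def compute_dnds(gene_a, gene_b) -> DnDsResult:
    """NG86 dN/dS of two aligned same-length in-frame CDSs.

    Synonymous/nonsynonymous sites counted per codon, differences averaged
    over mutational pathways, Jukes–Cantor correction applied to pN and pS.
    Codon pairs involving a stop codon are excluded from sites and
    differences. Raises on length mismatch or frame violation.
    """
    a = gene_a if isinstance(gene_a, str) else "".join("ACGT"[int(x)] for x in np.asarray(gene_a))
    b = gene_b if isinstance(gene_b, str) else "".join("ACGT"[int(x)] for x in np.asarray(gene_b))
    if len(a) != len(b):
        raise ValueError(f"CDS lengths differ: {len(a)} vs {len(b)}")
    if len(a) % 3 != 0 or len(a) == 0:
        raise ValueError(f"CDS length {len(a)} is not a positive multiple of 3")
    table = _codon_table()
    s_sites = n_sites = sd = nd = 0.0
    used = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if table.get(ca, "*") == "*" or table.get(cb, "*") == "*":
            continue
        used += 1
        s_sites += (_syn_sites(ca) + _syn_sites(cb)) / 2.0
        n_sites += 3.0 - (_syn_sites(ca) + _syn_sites(cb)) / 2.0
        d_s, d_n = _pathway_differences(ca, cb)
        sd += d_s
        nd += d_n
    if used == 0:
        raise ValueError("no usable (stop-free) codons in the alignment")
    ps = sd / s_sites if s_sites > 0 else 0.0
    pn = nd / n_sites if n_sites > 0 else 0.0

    def jc(p: float) -> float:
        if p >= 0.75:
            return float("nan")
        return -0.75 * np.log(1.0 - 4.0 * p / 3.0)

    ds, dn = jc(ps), jc(pn)
    ratio = None if ds == 0 or np.isnan(ds) else dn / ds
    return DnDsResult(dn=dn, ds=ds, ratio=ratio, pn=pn, ps=ps,
                      n_sites=n_sites, s_sites=s_sites, n_codons_used=used)


def dnds_table(
    genes_a: dict[str, np.ndarray | str], genes_b: dict[str, np.ndarray | str]
) -> pd.DataFrame:
    """Per-gene dN/dS for orthologue pairs whose alignments have identical
    length and a valid reading frame; other pairs are skipped with a reason."""
    rows = []
    for gid in genes_a:
        if gid not in genes_b:
            continue
        a, b = genes_a[gid], genes_b[gid]
        if len(a) != len(b) or len(a) % 3 != 0:
            rows.append((gid, np.nan, np.nan, np.nan, "length_or_frame"))
            continue
        try:
            r = compute_dnds(a, b)
        except ValueError:
            rows.append((gid, np.nan, np.nan, np.nan, "no_usable_codons"))
            continue
        rows.append((gid, r.dn, r.ds, np.nan if r.ratio is None else r.ratio,
                     "ok" if r.ratio is not None else "ds_zero"))
    return pd.DataFrame(rows, columns=["gene_id", "dn", "ds", "ratio", "status"])


# ---------------------------------------------------------------------------
# identity distributions (hidden-population check)
# ---------------------------------------------------------------------------

@dataclass
class IdentityDistribution:
    histogram: pd.DataFrame       # bin_left, bin_right, count
    modes: list[float]            # identity at detected modes (%)
    n_modes: int

    @property
    def is_multimodal(self) -> bool:
        return self.n_modes >= 2


def identity_distribution(
    identities, bin_width: float = 0.5, min_prominence_frac: float = 0.10,
) -> IdentityDistribution:
    """Binned distribution of pairwise identities with simple mode detection.

    A hidden extra population produces a second inter-population mode; the
    summary flags multimodality via peak finding on the (lightly smoothed)
    histogram. Raises on empty input.
    """
    vals = np.asarray(pd.Series(identities).dropna(), dtype=float)
    if len(vals) == 0:
        raise ValueError("identity_distribution: empty input")
    lo = np.floor(vals.min() / bin_width) * bin_width
    hi = np.ceil(vals.max() / bin_width) * bin_width + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(vals, bins=edges)
    if len(counts) >= 3:
        smooth = np.convolve(counts, np.ones(3) / 3.0, mode="same")
    else:
        smooth = counts.astype(float)
    pad = np.concatenate([[0.0], smooth, [0.0]])  # peaks at the ends count too
    peaks, _ = find_peaks(pad, prominence=max(1.0, min_prominence_frac * smooth.max()),
                          distance=2)
    centers = (edges[:-1] + edges[1:]) / 2.0
    modes = [float(centers[p - 1]) for p in peaks]
    hist = pd.DataFrame({"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts})
    return IdentityDistribution(histogram=hist, modes=modes, n_modes=len(modes))
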