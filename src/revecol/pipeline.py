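"""Pipeline orchestration: simulate -> demarcate -> pangenome -> sweep ->
windows -> DE -> quant as one reproducible run with a manifest.

One top-level seed fans out to per-stage streams (the simulator documents
its stream constants), so any stage can be re-run in isolation and
deterministic stages reproduce byte-identical outputs. The manifest records
the config snapshot, seed, per-file SHA-256 digests and stage timings;
resuming against outputs whose digests no longer match is refused.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .anipop import ani_matrix, cluster_genomes, demarcate_populations
from .config import SimConfig
from .diffexpr import pair_orthologues, differential_test_pairs
from .divwin import build_nj_tree, window_distances, within_between_summary
from .pangenome import (build_gene_catalog, classify_pangenome, dnds_table,
                        extract_gene_seqs, identity_distribution,
                        identity_profile, match_gene_catalog)
from .quant import correlate
from .simgen import (simulate_abundances, simulate_counts, simulate_covariates,
                     simulate_populations, simulate_reads)
from .sweepscan import (call_snps, competitive_assign, cross_identity_profile,
                        largest_snp_free_region, snp_density_windows, write_vcf)

log = logging.getLogger("revecol")

STAGES = ["simulate", "ani", "pangenome", "sweep", "windows", "de", "quant"]
_DEPS = {
    "ani": ["simulate"],
    "pangenome": ["simulate", "ani"],
    "sweep": ["simulate", "ani"],
    "windows": ["simulate", "ani"],
    "de": ["simulate", "ani"],
    "quant": ["simulate"],
}


class DependencyError(RuntimeError):
    pass


class IntegrityError(RuntimeError):
    pass


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


def run_pipeline(
    config: SimConfig | str | Path,
    outdir: str | Path,
    stages: list[str] | None = None,
    seed: int | None = None,
    write_reads: bool = False,
) -> dict:
    """Execute the requested stages in dependency order; returns the manifest.

    Upstream results needed by a requested stage are recomputed in memory
    (deterministically from config + seed) without rewriting their files
    unless the stage itself was requested. An existing manifest whose file
    digests no longer match the on-disk outputs aborts the run.
    """
    if not isinstance(config, SimConfig):
        config = SimConfig.from_yaml(config)
    if seed is not None:
        config = config.with_(seed=seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    requested = list(STAGES) if stages in (None, ["all"], "all") else list(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    requested = [s for s in STAGES if s in requested]

    manifest_path = outdir / "manifest.json"
    if manifest_path.exists():
        old = json.loads(manifest_path.read_text())
        for stage, info in old.get("stages", {}).items():
            for rel, digest in info.get("files", {}).items():
                p = outdir / rel
                if p.exists() and _sha256(p) != digest:
                    raise IntegrityError(
                        f"digest mismatch for {rel} (stage {stage}); refusing to resume"
                    )

    manifest = {"version": __version__, "seed": config.seed,
                "config": config.to_dict(), "stages": {}}
    ctx: dict = {}

    def record(stage: str, files: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "files": {str(p.relative_to(outdir)): _sha256(p) for p in files},
            "seconds": round(time.perf_counter() - t0, 3),
        }

    needed = set(requested)
    for s in requested:
        needed.update(_DEPS.get(s, []))

    for stage in STAGES:
        if stage not in needed:
            continue
        emit = stage in requested
        t0 = time.perf_counter()
        log.info("stage %s (outputs %s)", stage, "written" if emit else "in-memory")
        files: list[Path] = []

        if stage == "simulate":
            community = simulate_populations(config)
            ctx["community"] = community
            if emit:
                fa, gff = outdir / "genomes.fasta", outdir / "genes.gff3"
                community.write_fasta(fa)
                community.write_gff3(gff)
                community.write_truth(outdir / "truth")
                files = [fa, gff] + sorted((outdir / "truth").glob("*.tsv"))

        elif stage == "ani":
            community = ctx["community"]
            ani = ani_matrix(community.genomes)
            clusters = cluster_genomes(ani)
            pops = demarcate_populations(clusters, ani)
            ctx.update(ani=ani, clusters=clusters, pops=pops)
            if pops.n_populations < 2:
                log.warning("demarcation found %d candidate population(s)", pops.n_populations)
            if emit:
                f1, f2, f3, f4 = (outdir / n for n in
                                  ("ani_matrix.tsv", "ani_long.tsv", "clusters.tsv",
                                   "populations.tsv"))
                ani.to_square_tsv(f1)
                ani.to_long_tsv(f2)
                pd.Series(clusters.labels, name="cluster").rename_axis("genome").to_csv(
                    f3, sep="\t")
                pd.Series(pops.labels, name="population").rename_axis("genome").to_csv(
                    f4, sep="\t")
                files = [f1, f2, f3, f4]

        elif stage == "pangenome":
            community, pops = ctx["community"], ctx["pops"]
            ref_a = community.reference("A")
            ref_b = community.reference("B")
            genes_a = community.genes_of(ref_a)
            catalog = build_gene_catalog(community.annotations, ref_a, ref_b)
            matches = match_gene_catalog(catalog, community.genomes)
            pop_map = {g: p for g, p in pops.labels.items() if p is not None}
            classes = classify_pangenome(matches, pop_map)
            profile = identity_profile(
                genes_a.assign(order_index=np.arange(len(genes_a))),
                community.genomes[ref_a], community.genomes[ref_b])
            seqs_a = extract_gene_seqs(genes_a, community.genomes[ref_a])
            seqs_b = extract_gene_seqs(community.genes_of(ref_b), community.genomes[ref_b])
            dnds = dnds_table(seqs_a, seqs_b)
            hist = identity_distribution(profile.identity.dropna())
            ctx.update(matches=matches, classes=classes)
            if emit:
                f1, f2, f3, f4 = (outdir / n for n in
                                  ("gene_classes.tsv", "identity_profile.tsv",
                                   "dnds.tsv", "identity_hist.tsv"))
                classes.to_csv(f1, sep="\t", index=False)
                profile.to_csv(f2, sep="\t", index=False)
                dnds.to_csv(f3, sep="\t", index=False)
                hist.histogram.to_csv(f4, sep="\t", index=False)
                files = [f1, f2, f3, f4]

        elif stage == "sweep":
            community = ctx["community"]
            reads = simulate_reads(community)
            ref_a = community.reference("A")
            ref_b = community.reference("B")
            refs = {ref_a: community.genomes[ref_a], ref_b: community.genomes[ref_b]}
            assign = competitive_assign(reads, refs)
            snps = call_snps(assign, reads, ref_a, refs[ref_a])
            density = snp_density_windows(snps.table, len(refs[ref_a]))
            region, gaps = largest_snp_free_region(
                snps.table, len(refs[ref_a]), coverage_mask=snps.coverage >= snps.params["min_depth"])
            track = cross_identity_profile((region.start, region.end),
                                           refs[ref_a], refs[ref_b])
            ctx.update(reads=reads, assign=assign, snps=snps, sweep_region=region)
            if emit:
                f1 = outdir / "snps.vcf"
                write_vcf(snps, f1, reference_length=len(refs[ref_a]))
                f2, f3, f4 = (outdir / n for n in
                              ("snp_density.bed", "snp_free_regions.tsv",
                               "identity_track.bed"))
                density.assign(reference=ref_a)[
                    ["reference", "start", "end", "pct_snps"]
                ].to_csv(f2, sep="\t", index=False, header=False)
                gaps.to_csv(f3, sep="\t", index=False)
                track.assign(reference=ref_a)[
                    ["reference", "start", "end", "identity", "smoothed"]
                ].to_csv(f4, sep="\t", index=False, header=False)
                files = [f1, f2, f3, f4]
                if write_reads:
                    fq = outdir / "reads.fastq"
                    reads.to_fastq(fq)
                    files.append(fq)

        elif stage == "windows":
            community, pops = ctx["community"], ctx["pops"]
            ids, mat, _pos = community.core_alignment()
            wds = window_distances((ids, mat), window=2500, model="raw_p")
            pop_map = {g: p for g, p in pops.labels.items() if p is not None}
            table, summary = within_between_summary(wds, pop_map)
            # segment trees of the duplicated two-variant gene
            v1, v2 = community.dup_genes
            ref_a, ref_b = community.reference("A"), community.reference("B")
            seg_seqs = {}
            for g, tag in ((ref_a, "A"), (ref_b, "B")):
                for gid, vtag in ((v1, "V1"), (v2, "V2")):
                    seg_seqs[f"{tag}_{vtag}"] = community.gene_seq(g, gid)
            head = {k: v[:1000] for k, v in seg_seqs.items()}
            tail = {k: v[-community.config.dup_homogenized_tail:] for k, v in seg_seqs.items()}
            tree_head = build_nj_tree(head)
            tree_tail = build_nj_tree(tail)
            ctx.update(window_summary=summary)
            if emit:
                f1, f2, f3 = (outdir / n for n in
                              ("window_distances.tsv", "window_summary.tsv", "trees.nwk"))
                table.to_csv(f1, sep="\t", index=False)
                pd.Series(summary).to_csv(f2, sep="\t", header=False)
                Path(f3).write_text(
                    f"# first 1000 bp\n{tree_head}\n# last "
                    f"{community.config.dup_homogenized_tail} bp\n{tree_tail}\n")
                files = [f1, f2, f3]

        elif stage == "de":
            community = ctx["community"]
            ref_a, ref_b = community.reference("A"), community.reference("B")
            seqs_a = extract_gene_seqs(community.genes_of(ref_a), community.genomes[ref_a])
            seqs_b = extract_gene_seqs(community.genes_of(ref_b), community.genomes[ref_b])
            pairs = pair_orthologues(seqs_a, seqs_b)
            cm = simulate_counts(community)
            de = differential_test_pairs(cm.counts, cm.design, pairs)
            ctx.update(pairs=pairs, de=de)
            if emit:
                f1, f2 = outdir / "de_results.tsv", outdir / "excluded_pairs.tsv"
                de.table.rename_axis("gene_id").to_csv(f1, sep="\t")
                pairs[~pairs.comparable].to_csv(f2, sep="\t", index=False)
                files = [f1, f2]

        elif stage == "quant":
            community = ctx["community"]
            abund = simulate_abundances(community.config)
            covars, _truth = simulate_covariates(abund, community.config)
            corr = correlate(abund, covars)
            ctx.update(correlations=corr)
            if emit:
                f1 = outdir / "correlations.tsv"
                corr.to_csv(f1, sep="\t", index=False)
                files = [f1]

        if emit:
            record(stage, files, t0)

    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest
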