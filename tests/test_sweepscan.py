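"""Competitive assignment, SNP calling, window tracks and SNP-free regions."""
import numpy as np
import pandas as pd
import pytest

from revecol import simulate_populations, simulate_reads
from revecol._seq import random_sequence
from revecol.sweepscan import (call_snps, competitive_assign,
                               cross_identity_profile, largest_snp_free_region,
                               read_vcf, snp_density_windows, write_vcf)

from conftest import toy_config


@pytest.fixture(scope="module")
def two_refs():
    rng = np.random.default_rng(9)
    a = rng.integers(0, 4, 20_000, dtype=np.uint8)
    b = a.copy()
    pos = rng.choice(len(b), size=int(0.034 * len(b)), replace=False)
    b[pos] = (b[pos] + rng.integers(1, 4, len(pos))) % 4
    return {"refA": a, "refB": b}


def _reads_from(ref, positions, rl=150, edits=()):
    seqs = np.stack([ref[p:p + rl] for p in positions]).copy()
    for (row, col, delta) in edits:
        seqs[row, col] = (seqs[row, col] + delta) % 4
    return seqs


def test_read_matching_one_reference_is_assigned_there(two_refs):
    reads = _reads_from(two_refs["refA"], [1000, 5000, 9000])
    asn = competitive_assign(reads, two_refs)
    assert [asn.ref_names[w] for w in asn.winner] == ["refA"] * 3


def test_equidistant_read_is_tie_and_discarded():
    rng = np.random.default_rng(1)
    a = rng.integers(0, 4, 10_000, dtype=np.uint8)
    refs = {"refA": a, "refB": a.copy()}  # identical references
    reads = _reads_from(a, [2000])
    asn = competitive_assign(reads, refs)
    assert asn.winner[0] == -1
    assert asn.n_ties == 1
    snps = call_snps(asn, reads, "refA", a)
    assert snps.coverage.sum() == 0  # ties never enter pileups


def test_score_arithmetic_one_vs_five_mismatches(two_refs):
    # read from refA with 1 planted error: ~1 mismatch to A, ~1+divergence to B
    reads = _reads_from(two_refs["refA"], [3000], edits=[(0, 70, 1)])
    asn = competitive_assign(reads, two_refs)
    rl = reads.shape[1]
    i_a = asn.ref_names.index("refA")
    assert asn.winner[0] == i_a
    assert asn.scores[0, i_a] == rl - 2  # match - mismatch scoring
    assert asn.scores[0, 1 - i_a] < rl - 2


def test_conservation_assigned_plus_ties_plus_unassigned(two_refs, toy_community):
    cfg = toy_community.config.with_(depth=1.0)
    reads = simulate_reads(toy_community, config=cfg)
    refs = {n: toy_community.genomes[n]
            for n in (toy_community.reference("A"), toy_community.reference("B"))}
    asn = competitive_assign(reads, refs)
    counts = asn.counts()
    assert counts.sum() == len(reads)


def test_fewer_than_two_references_rejected(two_refs):
    with pytest.raises(ValueError):
        competitive_assign(_reads_from(two_refs["refA"], [0]), {"refA": two_refs["refA"]})
    with pytest.raises(ValueError, match="empty"):
        competitive_assign(np.empty((0, 150), dtype=np.uint8), two_refs)


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

def _pileup_case(two_refs, n_reads, alt_rows, pos=4000, col=75):
    """n_reads stacked on one locus; alt_rows carry an alternate base at
    reference position pos+col."""
    edits = [(r, col, 1) for r in alt_rows]
    reads = _reads_from(two_refs["refA"], [pos] * n_reads, edits=edits)
    asn = competitive_assign(reads, two_refs)
    return call_snps(asn, reads, "refA", two_refs["refA"])


def test_concordant_pileup_has_no_snps(two_refs):
    snps = _pileup_case(two_refs, 20, alt_rows=[])
    assert len(snps.table) == 0


def test_balanced_biallelic_site_is_called(two_refs):
    snps = _pileup_case(two_refs, 20, alt_rows=range(10))
    assert len(snps.table) == 1
    row = snps.table.iloc[0]
    assert row.pos == 4000 + 75 + 1  # 1-based
    assert row.depth == 20
    assert row.af == pytest.approx(0.5)


def test_rare_alternate_below_min_af_not_called(two_refs):
    snps = _pileup_case(two_refs, 100, alt_rows=[0])
    assert len(snps.table) == 0


def test_low_depth_site_not_called(two_refs):
    snps = _pileup_case(two_refs, 6, alt_rows=range(3))  # depth 6 < 10
    assert len(snps.table) == 0


def test_missing_reference_raises(two_refs):
    reads = _reads_from(two_refs["refA"], [0])
    asn = competitive_assign(reads, two_refs)
    with pytest.raises(ValueError, match="absent"):
        call_snps(asn, reads, "refC", two_refs["refA"])


# ---------------------------------------------------------------------------
# windows and gaps
# ---------------------------------------------------------------------------

def test_density_zero_without_snps():
    track = snp_density_windows(pd.DataFrame({"pos": []}), 5000)
    assert (track.pct_snps == 0).all()


def test_density_arithmetic_and_partial_window():
    snps = pd.DataFrame({"pos": np.arange(1, 11)})  # 10 SNPs in window 0
    track = snp_density_windows(snps, 2500, window=1000)
    assert track.pct_snps.iloc[0] == pytest.approx(1.0)
    assert track.end.iloc[-1] == 2500
    assert track.start.iloc[-1] == 2000  # 500 bp wide, normalised by 500
    snps2 = pd.DataFrame({"pos": [2001]})
    t2 = snp_density_windows(snps2, 2500, window=1000)
    assert t2.pct_snps.iloc[-1] == pytest.approx(100.0 / 500)


def test_largest_gap_between_snps():
    snps = pd.DataFrame({"pos": [100, 9000]})
    region, gaps = largest_snp_free_region(snps, 20_000)
    assert (region.start, region.end, region.length) == (9000, 20_000, 11_000)
    assert gaps.length.tolist() == [11_000, 8899, 99]


def test_empty_snp_table_whole_reference():
    region, _ = largest_snp_free_region(pd.DataFrame({"pos": []}), 7777)
    assert (region.start, region.end) == (0, 7777)


def test_uncovered_stretches_break_gaps():
    snps = pd.DataFrame({"pos": [100]})
    cov = np.ones(10_000, dtype=bool)
    cov[6000:6050] = False  # uncovered stretch must not count as SNP-free
    region, _ = largest_snp_free_region(snps, 10_000, coverage_mask=cov)
    assert (region.start, region.end) == (100, 6000)


def test_vcf_round_trip_exact(tmp_path, two_refs):
    snps = _pileup_case(two_refs, 20, alt_rows=range(10))
    path = tmp_path / "x.vcf"
    write_vcf(snps, path, reference_length=len(two_refs["refA"]))
    back = read_vcf(path)
    assert back.pos.tolist() == snps.table.pos.tolist()
    assert back.ref.tolist() == snps.table.ref.tolist()
    assert back.alt.tolist() == snps.table.alt.tolist()
    assert back.depth.tolist() == snps.table.depth.tolist()
    np.testing.assert_allclose(back.af, snps.table.af, rtol=1e-5)
    # header declares the caller's thresholds
    head = path.read_text().splitlines()[1]
    assert "min_depth=10" in head and "min_af=0.1" in head


# ---------------------------------------------------------------------------
# cross-population identity track
# ---------------------------------------------------------------------------

def test_identity_track_flat_for_identical_region(two_refs):
    a = two_refs["refA"]
    track = cross_identity_profile((2000, 6000), a, a, smooth_k=1,
                                   genomewide_identity=100.0)
    assert (track.identity == 100.0).all()
    assert (track.smoothed == track.identity).all()


def test_identity_track_shows_planted_import_drop(toy_community):
    c = toy_community
    t = c.truth_sweep_region
    ref_a = c.genomes[t["reference"]]
    ref_b = c.genomes[c.reference("B")]
    flank = 3000
    lo, hi = t["start"] - flank, t["end"] + flank
    track = cross_identity_profile((lo, hi), ref_a, ref_b, genomewide_identity=96.6)
    inside = track[(track.start >= t["start"]) & (track.end <= t["end"])]
    outside = track[(track.end <= t["start"]) | (track.start >= t["end"])]
    assert inside.identity.mean() == pytest.approx(85.0, abs=2.0)
    assert outside.identity.mean() > 95.0
    assert inside.breakpoint.all()


def test_unalignable_region_raises(rng):
    a = random_sequence(10_000, rng)
    b = random_sequence(10_000, rng)
    with pytest.raises(ValueError, match="aligned"):
        cross_identity_profile((0, 3000), a, b, genomewide_identity=100.0)


# ---------------------------------------------------------------------------
# end-to-end sweep recovery (reduced scale)
# ---------------------------------------------------------------------------

def test_sweep_recovery_end_to_end():
    hits = 0
    for seed in (61, 62):
        cfg = toy_config(seed=seed, depth=25.0)
        c = simulate_populations(cfg)
        reads = simulate_reads(c)
        ref_a, ref_b = c.reference("A"), c.reference("B")
        asn = competitive_assign(reads, {ref_a: c.genomes[ref_a],
                                         ref_b: c.genomes[ref_b]})
        snps = call_snps(asn, reads, ref_a, c.genomes[ref_a])
        region, _ = largest_snp_free_region(
            snps.table, len(c.genomes[ref_a]),
            coverage_mask=snps.coverage >= 10)
        t = c.truth_sweep_region
        inter = max(0, min(region.end, t["end"]) - max(region.start, t["start"]))
        if (inter / max(region.length, t["end"] - t["start"])) >= 0.8:
            hits += 1
    assert hits == 2
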