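"""Construction audits and calibration of the synthetic community generator."""
import numpy as np
import pandas as pd
import pytest

from revecol import ConfigError, SimConfig, simulate_populations, simulate_reads
from revecol.simgen import (simulate_abundances, simulate_counts,
                            simulate_covariates)
from revecol._seq import p_distance

from conftest import toy_config


# ---------------------------------------------------------------------------
# configuration validation
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "field,value,needle",
    [
        ("d_within", 0.05, "d_within"),          # exceeds d_between
        ("core_fraction", 0.0, "core_fraction"),
        ("sweep_region_length", 10**9, "sweep_region_length"),
        ("nb_dispersion", 0.0, "nb_dispersion"),
        ("error_rate", 1.5, "error_rate"),
        ("dup_homogenized_tail", 5000, "dup_homogenized_tail"),
    ],
)
def test_config_validation_names_offending_field(field, value, needle):
    with pytest.raises(ConfigError, match=needle):
        SimConfig(**{field: value}).validate()


def test_zero_mutation_config_gives_identical_genomes():
    cfg = toy_config(
        d_between=0.0, d_within=0.0, core_fraction=1.0,
        n_pop_specific_a=0, n_pop_specific_b=0, sweep_region_length=0,
        dup_copy_divergence=0.0, dup_homogenized_tail=0,
    )
    c = simulate_populations(cfg)
    ref = c.genomes[c.genome_names[0]]
    for name in c.genome_names[1:]:
        assert np.array_equal(c.genomes[name], ref)


# ---------------------------------------------------------------------------
# planted structure audits
# ---------------------------------------------------------------------------

def test_determinism_same_seed_same_genomes():
    a = simulate_populations(toy_config())
    b = simulate_populations(toy_config())
    for name in a.genome_names:
        assert np.array_equal(a.genomes[name], b.genomes[name])
    pd.testing.assert_frame_equal(a.annotations, b.annotations)


def test_pop_specific_genes_present_absent_exactly_as_planted(toy_community):
    c = toy_community
    ann = c.annotations
    a_members = set(c.members("A"))
    b_members = set(c.members("B"))
    ps_a = c.truth_gene_classes[c.truth_gene_classes == "pop_specific_A"].index
    assert len(ps_a) == c.config.n_pop_specific_a
    for gid in ps_a:
        carriers = set(ann[ann.gene_id == gid].genome)
        assert carriers == a_members
    ps_b = c.truth_gene_classes[c.truth_gene_classes == "pop_specific_B"].index
    for gid in ps_b:
        carriers = set(ann[ann.gene_id == gid].genome)
        assert carriers == b_members


def test_truth_and_fasta_agree_for_planted_genes(toy_community):
    """Extracting a core gene's coordinates from every genome yields nearly
    identical sequences (within-population substitutions only)."""
    c = toy_community
    core = c.truth_gene_classes[c.truth_gene_classes == "core"].index[:5]
    for gid in core:
        seqs = [c.gene_seq(g, gid) for g in c.genome_names]
        L = len(seqs[0])
        for s in seqs[1:]:
            assert len(s) == L
            assert (seqs[0] != s).mean() < 0.08  # d_between + margin


def test_annotations_non_overlapping_within_genome(toy_community):
    for g, sub in toy_community.annotations.groupby("genome"):
        sub = sub.sort_values("start")
        assert (sub.start.to_numpy()[1:] > sub.end.to_numpy()[:-1]).all()


def test_sweep_region_identical_across_population_a(toy_community):
    c = toy_community
    s, e = c.truth_sweep_region["anc_start"], c.truth_sweep_region["anc_end"]
    a_members = c.members("A")
    ref = c.genomes_anc[a_members[0]][s:e]
    for g in a_members[1:]:
        assert np.array_equal(c.genomes_anc[g][s:e], ref)
    # and strongly diverged from population B at the same coordinates
    b_seg = c.genomes_anc[c.members("B")[0]][s:e]
    assert abs((ref != b_seg).mean() - c.config.sweep_region_divergence) < 0.02


def test_sweep_region_genome_coordinates_consistent(toy_community):
    c = toy_community
    t = c.truth_sweep_region
    ref = c.genomes[t["reference"]][t["start"]:t["end"]]
    anc = c.genomes_anc[t["reference"]][t["anc_start"]:t["anc_end"]]
    assert np.array_equal(ref, anc)


def test_divergence_calibration_over_replicates():
    """Mean between-population p-distance within 3 relative % of d_between
    over 10 replicate seeds (gap-free shared columns)."""
    vals = []
    for seed in range(10):
        cfg = toy_config(seed=100 + seed, genome_length=50_000, n_genes=150,
                         n_pop_specific_a=5, n_pop_specific_b=5,
                         sweep_region_length=0)
        c = simulate_populations(cfg)
        ids, mat, _ = c.core_alignment()
        pops = np.array([c.truth_populations[g] for g in ids])
        ia, ib = np.flatnonzero(pops == "A"), np.flatnonzero(pops == "B")
        d = np.mean([p_distance(mat[i], mat[j]) for i in ia for j in ib])
        vals.append(d)
    mean_d = float(np.mean(vals))
    assert abs(mean_d - 0.034) / 0.034 < 0.03


def test_dup_gene_tail_homogenized_within_population_b(toy_community):
    c = toy_community
    v1, v2 = c.dup_genes
    tail = c.config.dup_homogenized_tail
    for g in c.members("B"):
        s1, s2 = c.gene_seq(g, v1), c.gene_seq(g, v2)
        assert np.array_equal(s1[-tail:], s2[-tail:])
    # in population A the two variants' tails stay diverged
    ga = c.members("A")[0]
    s1, s2 = c.gene_seq(ga, v1), c.gene_seq(ga, v2)
    assert (s1[-tail:] != s2[-tail:]).mean() > 0.05


# ---------------------------------------------------------------------------
# reads
# ---------------------------------------------------------------------------

def test_error_free_reads_are_exact_substrings(toy_community):
    cfg = toy_community.config.with_(depth=2.0, error_rate=0.0)
    reads = simulate_reads(toy_community, config=cfg)
    comp = np.array([3, 2, 1, 0, 4], dtype=np.uint8)
    for i in range(0, len(reads), max(1, len(reads) // 50)):
        g = toy_community.genomes[reads.genome_names[reads.source[i]]]
        sub = g[reads.pos[i] : reads.pos[i] + reads.read_length]
        r = reads.seqs[i]
        if reads.strand[i] == 1:
            r = comp[r][::-1]
        assert np.array_equal(r, sub)


def test_read_count_arithmetic(toy_community):
    cfg = toy_community.config.with_(depth=50.0, read_length=100)
    name = toy_community.genome_names[0]
    reads = simulate_reads(toy_community, source_mix={name: 1.0}, config=cfg)
    expected = 50.0 * len(toy_community.genomes[name]) / 100
    assert abs(len(reads) - expected) <= 1


def test_reads_deterministic_under_seed(tmp_path, toy_community):
    cfg = toy_community.config.with_(depth=0.5)
    r1 = simulate_reads(toy_community, config=cfg)
    r2 = simulate_reads(toy_community, config=cfg)
    assert np.array_equal(r1.seqs, r2.seqs)
    f1, f2 = tmp_path / "a.fastq", tmp_path / "b.fastq"
    r1.to_fastq(f1)
    r2.to_fastq(f2)
    assert f1.read_bytes() == f2.read_bytes()


def test_reads_reject_degenerate_weights(toy_community):
    with pytest.raises(ValueError):
        simulate_reads(toy_community, source_mix={g: 0.0 for g in toy_community.genome_names})
    with pytest.raises(ValueError):
        simulate_reads(toy_community, source_mix={toy_community.genome_names[0]: -1.0})


# ---------------------------------------------------------------------------
# counts and covariates
# ---------------------------------------------------------------------------

def test_counts_no_de_genes_means_all_null(toy_community):
    cfg = toy_community.config.with_(n_de_genes=0)
    cm = simulate_counts(toy_community, config=cfg)
    assert (cm.truth_log2fc == 0).all()


def test_counts_planted_fold_change_recovered():
    """Monte-Carlo: with planted log2FC=2 the size-factor-corrected group
    mean ratio approaches 4."""
    cfg = toy_config(seed=21, n_de_genes=10, de_log2fc=2.0, n_samples=150)
    c = simulate_populations(cfg)
    cm = simulate_counts(c)
    q = cm.counts / cm.size_factors
    is_a = cm.design == "A"
    ratio = q.loc[:, is_a.values].mean(axis=1) / q.loc[:, (~is_a).values].mean(axis=1)
    up = cm.truth_log2fc[cm.truth_log2fc == 2.0].index
    assert len(up) > 0
    assert np.allclose(ratio[up], 4.0, rtol=0.15)


def test_counts_poisson_limit_small_dispersion():
    cfg = toy_config(seed=22, nb_dispersion=1e-6, n_samples=300, n_de_genes=0,
                     nb_mean_sd=0.0)
    c = simulate_populations(cfg)
    cm = simulate_counts(c)
    q = cm.counts / cm.size_factors  # remove planted library-size variation
    ratio = q.var(axis=1) / q.mean(axis=1)
    assert 0.7 < ratio.median() < 1.4


def test_covariates_noise_free_perfect_correlation():
    cfg = SimConfig(seed=5)
    ab = simulate_abundances(cfg)
    cov, truth = simulate_covariates(ab, cfg, noise_sd=0.0)
    la = np.log(ab.A_copies)
    assert np.corrcoef(la, cov.covariate_1)[0, 1] == pytest.approx(1.0)
    assert np.corrcoef(la, cov.covariate_2)[0, 1] == pytest.approx(-1.0)
    assert truth["covariate_1_slope"] > 0 > truth["covariate_2_slope"]


def test_covariates_null_slope_gives_weak_correlation():
    cfg = SimConfig(seed=6, covariate_effect=0.0)
    ab = simulate_abundances(cfg)
    cov, _ = simulate_covariates(ab, cfg)
    la = np.log(ab.A_copies)
    for col in cov.columns:
        assert abs(np.corrcoef(la, cov[col])[0, 1]) < 0.3  # ~3 sigma at n=94


def test_covariates_require_three_samples():
    cfg = SimConfig()
    ab = simulate_abundances(cfg).iloc[:2]
    with pytest.raises(ValueError):
        simulate_covariates(ab, cfg)
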