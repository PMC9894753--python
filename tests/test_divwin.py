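"""Windowed distances, JC69 and neighbor-joining trees."""
import numpy as np
import pytest

from revecol import simulate_populations
from revecol._seq import GAP, encode, random_sequence
from revecol.divwin import (build_nj_tree, jc69_distance,
                            nj_tree_from_distances, window_distances,
                            within_between_summary)

from conftest import toy_config


def test_jc69_closed_form_at_p_0034():
    assert jc69_distance(0.034) == pytest.approx(
        -0.75 * np.log(1 - 4 * 0.034 / 3), abs=1e-12
    )
    assert jc69_distance(0.034) == pytest.approx(0.0348, abs=1e-4)


def test_jc69_undefined_at_saturation():
    assert np.isnan(jc69_distance(0.75))
    assert np.isnan(jc69_distance(0.9))


def test_identical_rows_zero_distance(rng):
    s = random_sequence(6000, rng)
    wds = window_distances({"a": s, "b": s.copy(), "c": s.copy()}, window=2500)
    assert np.allclose(wds.distances, 0.0)
    assert wds.n_windows == 3


def test_window_larger_than_alignment_gives_single_window(rng):
    s = random_sequence(1000, rng)
    wds = window_distances({"a": s, "b": s.copy()}, window=5000)
    assert wds.n_windows == 1
    assert wds.windows.end.iloc[0] == 1000


def test_gap_columns_excluded(rng):
    a = random_sequence(1000, rng)
    b = a.copy()
    b[:100] = GAP
    b[500] = (b[500] + 1) % 4
    wds = window_distances({"a": a, "b": b}, window=1000)
    assert wds.pair("a", "b")[0] == pytest.approx(1 / 900)


def test_saturated_pair_is_nan_under_jc69(rng):
    a = random_sequence(400, rng)
    b = (a + 1) % 4  # p = 1
    with pytest.warns(UserWarning, match="JC69"):
        wds = window_distances({"a": a, "b": b}, window=400, model="jc69")
    assert np.isnan(wds.pair("a", "b")[0])


def test_concatenated_windows_reproduce_whole_alignment_p(rng):
    """Weighted (by non-gap columns) mean of per-window p equals the
    whole-alignment p-distance exactly."""
    a = random_sequence(5234, rng)
    b = a.copy()
    pos = rng.choice(len(b), 300, replace=False)
    b[pos] = (b[pos] + rng.integers(1, 4, 300)) % 4
    b[rng.choice(len(b), 80, replace=False)] = GAP
    wds = window_distances({"a": a, "b": b}, window=1000)
    # recompute weights: non-gap columns per window
    both = (a != GAP) & (b != GAP)
    weights = np.add.reduceat(both, np.arange(0, len(a), 1000)).astype(float)
    p_windows = wds.pair("a", "b")
    whole = ((a != b) & both).sum() / both.sum()
    assert np.nansum(p_windows * weights) / weights.sum() == pytest.approx(whole, abs=1e-12)


def test_within_between_summary_on_toy_community(toy_community):
    c = toy_community
    ids, mat, pos = c.core_alignment()
    wds = window_distances((ids, mat), window=2500)
    pops = {g: c.truth_populations[g] for g in ids}
    table, summary = within_between_summary(wds, pops)
    # windows overlapping the planted import spike; exclude them from means
    t = c.truth_sweep_region
    in_sweep = np.array([
        ((pos[s:e] >= t["anc_start"]) & (pos[s:e] < t["anc_end"])).any()
        for s, e in zip(wds.windows.start, wds.windows.end)
    ])
    clean = table[~in_sweep]
    assert clean.between.mean() == pytest.approx(0.034, abs=0.002)
    assert clean.within_A.mean() == pytest.approx(0.003, abs=0.001)
    assert clean.within_B.mean() == pytest.approx(0.003, abs=0.001)
    spike = table[in_sweep]
    assert spike.between.max() > 0.08  # planted import at 0.15 vs B
    assert spike.within_A.max() <= clean.within_A.mean() + 0.003  # swept clean


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def _tips_of_smallest_clade_with(newick, *names):
    from io import StringIO

    from Bio import Phylo

    tree = Phylo.read(StringIO(newick), "newick")
    best = None
    for clade in tree.find_clades():
        tips = {t.name for t in clade.get_terminals()}
        if set(names) <= tips and (best is None or len(tips) < len(best)):
            best = tips
    return best


def test_identical_pair_gets_zero_terminal_branches(rng):
    s = random_sequence(900, rng)
    t = s.copy()
    u = s.copy()
    pos = rng.choice(900, 90, replace=False)
    u[pos] = (u[pos] + 1) % 4
    nwk = build_nj_tree({"a": s, "b": t, "c": u})
    assert "a:0," in nwk or "a:0)" in nwk or "(a:0" in nwk
    assert "b:0" in nwk


def test_four_taxon_topology_recovered(rng):
    root = random_sequence(2000, rng)

    def mutate(x, n):
        y = x.copy()
        pos = rng.choice(len(y), n, replace=False)
        y[pos] = (y[pos] + rng.integers(1, 4, n)) % 4
        return y

    left = mutate(root, 200)
    right = mutate(root, 200)
    seqs = {"a1": mutate(left, 20), "a2": mutate(left, 20),
            "b1": mutate(right, 20), "b2": mutate(right, 20)}
    nwk = build_nj_tree(seqs)
    assert _tips_of_smallest_clade_with(nwk, "a1", "a2") == {"a1", "a2"}


def test_star_distances_equal_branch_lengths():
    ids = list("abcd")
    d = np.full((4, 4), 0.2)
    np.fill_diagonal(d, 0.0)
    nwk = nj_tree_from_distances(ids, d)
    import re

    lengths = [float(x) for x in re.findall(r":([0-9.]+)", nwk)]
    terminal = [l for l in lengths if l > 0]
    assert all(abs(l - 0.1) < 1e-9 for l in terminal)


def test_fewer_than_three_sequences_rejected(rng):
    s = random_sequence(300, rng)
    with pytest.raises(ValueError):
        build_nj_tree({"a": s, "b": s.copy()})


def test_nj_matches_scikit_bio_topology():
    """Independent oracle: on an additive (tree-derived) distance matrix our
    NJ and scikit-bio's NJ recover the same unrooted topology."""
    import skbio

    # unrooted tree ((a:1,b:2):1.5,(c:1,d:1):0.5,(e:2,f:1):1.0) as path lengths
    ids = list("abcdef")
    up = {"a": 1.0, "b": 2.0, "c": 1.0, "d": 1.0, "e": 2.0, "f": 1.0}
    stem = {"a": 1.5, "b": 1.5, "c": 0.5, "d": 0.5, "e": 1.0, "f": 1.0}
    group = {"a": 0, "b": 0, "c": 1, "d": 1, "e": 2, "f": 2}
    d = np.zeros((6, 6))
    for i, x in enumerate(ids):
        for j, y in enumerate(ids):
            if i == j:
                continue
            if group[x] == group[y]:
                d[i, j] = up[x] + up[y]
            else:
                d[i, j] = up[x] + stem[x] + stem[y] + up[y]
    def bipartitions(tree, all_tips):
        out = set()
        for node in tree.non_tips(include_self=False):
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(all_tips) - 1:
                other = frozenset(all_tips) - side
                out.add(min(side, other, key=sorted))
        return out

    ours = skbio.TreeNode.read([nj_tree_from_distances(ids, d)])
    theirs = skbio.tree.nj(skbio.DistanceMatrix(d, ids))
    assert bipartitions(ours, ids) == bipartitions(theirs, ids)
    # cherries recovered exactly
    for pair in ("ab", "cd", "ef"):
        tips = _tips_of_smallest_clade_with(nj_tree_from_distances(ids, d), *pair)
        assert tips == set(pair)


def test_segment_tree_discordance_from_gene_conversion():
    """The 3' homogenized tail groups B's two variants as sisters while the
    5' segment groups variants by the ancestral duplication, in >= 4/5 seeds."""
    tail_ok = head_ok = 0
    n_seeds = 5
    for seed in range(70, 70 + n_seeds):
        cfg = toy_config(seed=seed)
        c = simulate_populations(cfg)
        v1, v2 = c.dup_genes
        seqs = {}
        for g, tag in ((c.reference("A"), "A"), (c.reference("B"), "B")):
            for gid, vt in ((v1, "V1"), (v2, "V2")):
                seqs[f"{tag}_{vt}"] = c.gene_seq(g, gid)
        head = build_nj_tree({k: v[:1000] for k, v in seqs.items()})
        tail = build_nj_tree({k: v[-cfg.dup_homogenized_tail:] for k, v in seqs.items()})
        if _tips_of_smallest_clade_with(tail, "B_V1", "B_V2") == {"B_V1", "B_V2"}:
            tail_ok += 1
        if _tips_of_smallest_clade_with(head, "A_V1", "B_V1") == {"A_V1", "B_V1"}:
            head_ok += 1
    assert tail_ok >= 4
    assert head_ok >= 4
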