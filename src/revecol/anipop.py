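"""Genome relatedness, clustering and population demarcation.

ANI here is a transparent fragment-mean estimator: the query genome is tiled
into non-overlapping fragments (default 1 kb), each fragment is placed at its
best location in the target, fragments at >= 70% identity are retained, and
ANI is the mean retained identity with the retained fraction reported
alongside. Populations are demarcated the way microdiverse clusters are
recognised in practice: complete-linkage clusters whose members stay within a
maximum pairwise divergence (default 0.4%), each needing at least two
members; pairs of candidate populations are then characterised by their
between-cluster ANI.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from ._seq import encode, revcomp
from .align import KmerIndex, _diagonal_hit, map_batch, revcomp_batch


@dataclass
class ANIResult:
    """One directional fragment-based comparison (query tiled, target searched)."""

    ani: float                 # % mean identity of retained fragments (nan if none)
    aligned_fraction: float    # retained fragments / total fragments
    n_fragments: int
    n_retained: int

    @property
    def defined(self) -> bool:
        return self.n_retained > 0


_ANOMALY_WIN = 100       # sliding window (bp) for the non-homology detector
_ANOMALY_MIN_MATCH = 45  # a clean fragment at >= 70% identity essentially


def _anomalous_run(match_mask: np.ndarray) -> np.ndarray:
    """True for fragments containing a >= _ANOMALY_WIN stretch matching at a
    rate only random sequence would produce.

    Under pure substitution divergence at any retainable identity (>= 70%)
    the chance of a 100 bp window with <= 45 matches is negligible; such a
    run means part of the fragment is non-homologous to its placement (it
    spans a gene gained/lost or a rearrangement breakpoint), so the fragment
    would measure gene content rather than sequence divergence.
    """
    n, fl = match_mask.shape
    if fl <= _ANOMALY_WIN:
        return match_mask.sum(axis=1) <= _ANOMALY_MIN_MATCH * fl / _ANOMALY_WIN
    cs = np.cumsum(match_mask, axis=1, dtype=np.int32)
    win = cs[:, _ANOMALY_WIN - 1 :].copy()
    win[:, 1:] -= cs[:, : fl - _ANOMALY_WIN]
    return win.min(axis=1) <= _ANOMALY_MIN_MATCH


def compute_ani(
    genome_a,
    genome_b,
    fragment_length: int = 1000,
    min_fragment_identity: float = 70.0,
    index_b: KmerIndex | None = None,
) -> ANIResult:
    """Directional ANI of ``genome_a`` against ``genome_b``.

    ``genome_a`` is tiled into non-overlapping full fragments (a trailing
    partial fragment is dropped); each fragment is placed at its best seeded
    location in ``genome_b`` (either strand) and scored ungapped, so
    fragment identity measures substitution divergence. Fragments that are
    only part-homologous at their placement — e.g. spanning a gene gained
    or lost, detected as a window of random-level matching — are excluded
    from retention rather than scored, because they would drag the mean
    toward gene content instead of sequence divergence. Fragments with
    identity >= ``min_fragment_identity`` are retained; ANI is their mean
    identity, undefined (NaN) when nothing is retained.
    """
    a = encode(genome_a)
    b = encode(genome_b)
    if len(a) < fragment_length or len(b) < fragment_length:
        raise ValueError("both sequences must be at least one fragment long")
    n_frag = len(a) // fragment_length
    frags = a[: n_frag * fragment_length].reshape(n_frag, fragment_length)
    idx = index_b if index_b is not None else KmerIndex(b)

    s_fwd, m_fwd = map_batch(frags, idx)
    s_rev, m_rev = map_batch(revcomp_batch(frags), idx)
    use_rev = m_rev > m_fwd
    matches = np.where(use_rev, m_rev, m_fwd)
    starts = np.where(use_rev, s_rev, s_fwd)

    # fragments the quick pass could not seed: let all their k-mers vote
    oriented = frags.copy()
    if use_rev.any():
        oriented[use_rev] = revcomp_batch(frags[use_rev])
    for i in np.flatnonzero(matches < 0):
        best = None
        for fr in (frags[i], revcomp(frags[i])):
            d = _diagonal_hit(fr, idx)
            if d is None:
                continue
            st = int(np.clip(d, 0, max(len(b) - fragment_length, 0)))
            m = int((idx.seq[st : st + fragment_length] == fr).sum())
            if best is None or m > best[2]:
                best = (st, fr, m)
        if best is not None:
            starts[i], oriented[i], matches[i] = best

    seeded = matches >= 0
    identity = np.where(seeded, 100.0 * matches / fragment_length, np.nan)
    excluded = np.zeros(n_frag, dtype=bool)
    idx_seeded = np.flatnonzero(seeded)
    if len(idx_seeded):
        win = idx.seq[starts[idx_seeded, None] + np.arange(fragment_length)]
        excluded[idx_seeded] = _anomalous_run(win == oriented[idx_seeded])

    retained = seeded & ~excluded & (identity >= min_fragment_identity)
    n_ret = int(retained.sum())
    ani = float(identity[retained].mean()) if n_ret else float("nan")
    return ANIResult(ani, n_ret / n_frag, n_frag, n_ret)


@dataclass
class ANIMatrix:
    """Symmetric ANI summary over a genome set (mean of the two directions)."""

    ids: list[str]
    matrix: pd.DataFrame          # % ANI, diagonal 100
    aligned_fraction: pd.DataFrame
    directional: pd.DataFrame     # long form: query, target, ani, aligned_fraction

    def undefined_pairs(self) -> list[tuple[str, str]]:
        m = self.matrix.to_numpy()
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if np.isnan(m[i, j]):
                    out.append((self.ids[i], self.ids[j]))
        return out

    def mean_between(self, group_a: list[str], group_b: list[str]) -> float:
        return float(self.matrix.loc[group_a, group_b].to_numpy().mean())

    def mean_within_divergence(self, group: list[str]) -> float:
        """Mean pairwise (1 - ANI/100) within a group of >= 2 genomes."""
        sub = self.matrix.loc[group, group].to_numpy()
        iu = np.triu_indices(len(group), k=1)
        return float((1.0 - sub[iu] / 100.0).mean())

    def to_long_tsv(self, path) -> None:
        self.directional.to_csv(path, sep="\t", index=False)

    def to_square_tsv(self, path) -> None:
        self.matrix.to_csv(path, sep="\t")


def ani_matrix(
    genomes: dict[str, np.ndarray | str],
    fragment_length: int = 1000,
    min_fragment_identity: float = 70.0,
) -> ANIMatrix:
    """All-vs-all directional ANI; the symmetric matrix averages both directions."""
    ids = list(genomes)
    enc = {g: encode(genomes[g]) for g in ids}
    indexes = {g: KmerIndex(enc[g]) for g in ids}
    n = len(ids)
    ani_dir = np.full((n, n), np.nan)
    af_dir = np.full((n, n), np.nan)
    rows = []
    for i, qa in enumerate(ids):
        for j, tb in enumerate(ids):
            if i == j:
                ani_dir[i, j], af_dir[i, j] = 100.0, 1.0
                continue
            r = compute_ani(enc[qa], enc[tb], fragment_length, min_fragment_identity,
                            index_b=indexes[tb])
            ani_dir[i, j] = r.ani
            af_dir[i, j] = r.aligned_fraction
            rows.append((qa, tb, r.ani, r.aligned_fraction, r.n_fragments, r.n_retained))
    sym = (ani_dir + ani_dir.T) / 2.0
    af = (af_dir + af_dir.T) / 2.0
    np.fill_diagonal(sym, 100.0)
    np.fill_diagonal(af, 1.0)
    return ANIMatrix(
        ids=ids,
        matrix=pd.DataFrame(sym, index=ids, columns=ids),
        aligned_fraction=pd.DataFrame(af, index=ids, columns=ids),
        directional=pd.DataFrame(
            rows, columns=["query", "target", "ani", "aligned_fraction",
                           "n_fragments", "n_retained"],
        ),
    )


@dataclass
class ClusterResult:
    ids: list[str]
    linkage: np.ndarray                 # scipy linkage matrix (complete)
    cut: float                          # distance cut (percentage points)
    labels: dict[str, int]              # genome -> flat cluster id at `cut`

    def clusters(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for g, c in self.labels.items():
            out.setdefault(c, []).append(g)
        return out

    def cut_at(self, cut: float) -> dict[str, int]:
        flat = fcluster(self.linkage, t=cut, criterion="distance")
        return dict(zip(self.ids, (int(c) for c in flat)))


def cluster_genomes(ani: ANIMatrix, cut: float = 5.0) -> ClusterResult:
    """Complete-linkage clustering on distance 100 - ANI with a flat cut
    (default 5 percentage points, i.e. 95% ANI). Undefined ANI entries are a
    hard error listing the offending pairs."""
    bad = ani.undefined_pairs()
    if bad:
        raise ValueError(f"ANI undefined for pairs: {bad}")
    dist = 100.0 - ani.matrix.to_numpy()
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # guard tiny asymmetries
    z = linkage(squareform(dist, checks=False), method="complete")
    flat = fcluster(z, t=cut, criterion="distance")
    return ClusterResult(ids=list(ani.ids), linkage=z, cut=cut,
                         labels=dict(zip(ani.ids, (int(c) for c in flat))))


@dataclass
class PopulationAssignment:
    """Demarcated candidate populations plus diagnostics."""

    labels: dict[str, str | None]       # genome -> population name (None = unassigned)
    populations: pd.DataFrame           # name, n_members, mean_within_divergence
    between_ani: pd.DataFrame           # pop_i, pop_j, mean_ani
    flags: list[str] = field(default_factory=list)

    @property
    def n_populations(self) -> int:
        return len(self.populations)

    def members(self, name: str) -> list[str]:
        return [g for g, p in self.labels.items() if p == name]


def demarcate_populations(
    clusters: ClusterResult,
    ani: ANIMatrix,
    within_divergence_max: float = 0.004,
    min_members: int = 2,
) -> PopulationAssignment:
    """Demarcate candidate populations from microdiverse clusters.

    The dendrogram is re-cut at a complete-linkage height of
    ``2 * 100 * within_divergence_max`` percentage points — complete linkage
    bounds the *maximum* pairwise distance, and individual pairs scatter
    around the mean the criterion is stated on — and each resulting cluster
    must then satisfy mean within divergence <= ``within_divergence_max``
    and size >= ``min_members``. Under-sampled clusters are flagged, never
    merged.
    """
    fine = clusters.cut_at(2.0 * 100.0 * within_divergence_max)
    groups: dict[int, list[str]] = {}
    for g, c in fine.items():
        groups.setdefault(c, []).append(g)

    flags: list[str] = []
    candidates = []
    for members in groups.values():
        members = sorted(members)
        if len(members) < min_members:
            flags.append(
                f"cluster {{{', '.join(members)}}} has {len(members)} member(s) "
                f"< min_members={min_members}; flagged, not merged"
            )
            continue
        wd = ani.mean_within_divergence(members)
        if wd > within_divergence_max:
            flags.append(
                f"cluster {{{', '.join(members)}}} rejected: mean within divergence "
                f"{wd:.4f} > {within_divergence_max}"
            )
            continue
        candidates.append((members, wd))

    candidates.sort(key=lambda t: (-len(t[0]), t[0][0]))
    labels: dict[str, str | None] = {g: None for g in clusters.ids}
    pop_rows = []
    for i, (members, wd) in enumerate(candidates):
        name = f"P{i + 1}"
        for g in members:
            labels[g] = name
        pop_rows.append((name, len(members), wd))
    populations = pd.DataFrame(
        pop_rows, columns=["population", "n_members", "mean_within_divergence"]
    )

    between_rows = []
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            between_rows.append(
                (f"P{i + 1}", f"P{j + 1}",
                 ani.mean_between(candidates[i][0], candidates[j][0]))
            )
    between = pd.DataFrame(between_rows, columns=["pop_i", "pop_j", "mean_ani"])

    if not candidates:
        flags.append("no candidate populations: all clusters under-sampled or too diverse")
    return PopulationAssignment(labels=labels, populations=populations,
                                between_ani=between, flags=flags)
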