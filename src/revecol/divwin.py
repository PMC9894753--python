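"""Windowed divergence, JC69 correction and distance-based (NJ) trees.

Distances are direct pairwise model distances (raw p or Jukes–Cantor
corrected) computed per fixed window of a gap-aware multiple alignment; the
within/between-population summary averages them over the demarcated groups.
Trees are neighbor-joining with deterministic lowest-index tie-breaking —
the claims made downstream are about distances and topology classes, so a
self-contained distance method is preferred over ML inference.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import GAP, encode


def jc69_distance(p: float | np.ndarray):
    """Jukes–Cantor correction d = -(3/4) ln(1 - (4/3) p); NaN for p >= 0.75."""
    p = np.asarray(p, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(p < 0.75, -0.75 * np.log(1.0 - 4.0 * p / 3.0), np.nan)
    return d if d.ndim else float(d)


@dataclass
class WindowDistanceSet:
    ids: list[str]
    windows: pd.DataFrame        # start, end (0-based half-open columns)
    distances: np.ndarray        # n_windows x n x n (model distances)
    model: str                   # "raw_p" or "jc69"

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def pair(self, a: str, b: str) -> np.ndarray:
        i, j = self.ids.index(a), self.ids.index(b)
        return self.distances[:, i, j]


def _as_matrix(alignment) -> tuple[list[str], np.ndarray]:
    if isinstance(alignment, tuple) and len(alignment) == 2:
        ids, mat = alignment
        return list(ids), np.asarray(mat, dtype=np.uint8)
    if isinstance(alignment, dict):
        ids = list(alignment)
        mat = np.stack([encode(alignment[g]) for g in ids])
        return ids, mat
    raise TypeError("alignment must be (ids, matrix) or a dict of sequences")


def window_distances(alignment, window: int = 2500, model: str = "raw_p") -> WindowDistanceSet:
    """Pairwise distances per fixed window of an equal-length alignment.

    p-distances are computed over non-gap columns of each window; with
    ``model='jc69'`` the correction is applied and pairs with p >= 0.75 get
    NaN with a warning. A window larger than the alignment yields a single
    window spanning all columns.
    """
    if model not in ("raw_p", "jc69"):
        raise ValueError(f"unknown model {model!r}")
    if window < 1:
        raise ValueError("window must be >= 1")
    ids, mat = _as_matrix(alignment)
    n, m = mat.shape
    if n < 2:
        raise ValueError("need >= 2 aligned sequences")
    starts = np.arange(0, m, window)
    ends = np.minimum(starts + window, m)
    nw = len(starts)
    dists = np.zeros((nw, n, n), dtype=float)
    valid_any = mat != GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = valid_any[i] & valid_any[j]
            diff = (mat[i] != mat[j]) & both
            nvalid = np.add.reduceat(both, starts).astype(float)
            ndiff = np.add.reduceat(diff, starts).astype(float)
            with np.errstate(invalid="ignore", divide="ignore"):
                p = np.where(nvalid > 0, ndiff / nvalid, np.nan)
            dists[:, i, j] = dists[:, j, i] = p
    if model == "jc69":
        if np.nanmax(dists) >= 0.75:
            warnings.warn("p-distance >= 0.75 in some windows; JC69 undefined there")
        dists = jc69_distance(dists)
    windows = pd.DataFrame({"start": starts, "end": ends})
    return WindowDistanceSet(ids=ids, windows=windows, distances=dists, model=model)


def within_between_summary(
    wds: WindowDistanceSet, populations: dict[str, str]
) -> tuple[pd.DataFrame, dict]:
    """Per-window mean within-population and between-population distances.

    ``populations`` maps genome id to one of exactly two labels. Returns the
    per-window table and a summary with genome-wide means and the
    coefficient of variation of the between-population track (stability of
    the long branches across the genome).
    """
    labels = sorted(set(populations.get(g) for g in wds.ids) - {None})
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 population labels, got {labels}")
    pa, pb = labels
    ia = [i for i, g in enumerate(wds.ids) if populations.get(g) == pa]
    ib = [i for i, g in enumerate(wds.ids) if populations.get(g) == pb]

    def mean_within(idx):
        if len(idx) < 2:
            return np.full(wds.n_windows, np.nan)
        pairs = [(i, j) for k, i in enumerate(idx) for j in idx[k + 1:]]
        return np.nanmean([wds.distances[:, i, j] for i, j in pairs], axis=0)

    between = np.nanmean(
        [wds.distances[:, i, j] for i in ia for j in ib], axis=0
    )
    table = pd.DataFrame(
        {"start": wds.windows.start, "end": wds.windows.end,
         f"within_{pa}": mean_within(ia), f"within_{pb}": mean_within(ib),
         "between": between}
    )
    bt = table.between.to_numpy()
    bt = bt[~np.isnan(bt)]
    summary = {
        f"mean_within_{pa}": float(np.nanmean(table[f"within_{pa}"])),
        f"mean_within_{pb}": float(np.nanmean(table[f"within_{pb}"])),
        "mean_between": float(bt.mean()) if len(bt) else float("nan"),
        "between_cv": float(bt.std(ddof=1) / bt.mean()) if len(bt) > 1 else float("nan"),
    }
    return table, summary


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree_from_distances(ids: list[str], dist: np.ndarray) -> str:
    """Neighbor joining on a distance matrix; returns newick with branch lengths.

    Deterministic: among minimal-Q pairs the lexicographically lowest index
    pair is joined. Negative branch-length estimates are clamped to zero.
    """
    n = len(ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 sequences")
    D = np.asarray(dist, dtype=float).copy()
    nodes = [f"{name}" for name in ids]
    active = list(range(n))
    while len(active) > 2:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        flat = np.argmin(q)
        bi, bj = divmod(flat, m)  # argmin returns first minimum -> lowest index pair
        if bi > bj:
            bi, bj = bj, bi
        i, j = active[bi], active[bj]
        dij = D[i, j]
        li = 0.5 * dij + (r[bi] - r[bj]) / (2.0 * (m - 2))
        lj = dij - li
        li = li if li > 0 else 0.0
        lj = lj if lj > 0 else 0.0
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        du = 0.5 * (D[i, active] + D[j, active] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, active] = du
        D[active, -1] = du
        D[-1, -1] = 0.0
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]
    i, j = active
    half = max(D[i, j] / 2.0, 0.0)
    return f"({nodes[i]}:{half:.10g},{nodes[j]}:{half:.10g});"


def build_nj_tree(seqs: dict[str, np.ndarray | str], model: str = "jc69") -> str:
    """NJ tree of aligned equal-length sequences on JC69 (or raw p) distances."""
    ids = list(seqs)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs >= 3 sequences")
    mat = np.stack([encode(seqs[g]) for g in ids])
    n = len(ids)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] != GAP) & (mat[j] != GAP)
            p = ((mat[i] != mat[j]) & both).sum() / max(both.sum(), 1)
            d = jc69_distance(p) if model == "jc69" else p
            D[i, j] = D[j, i] = d
    return nj_tree_from_distances(ids, D)
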