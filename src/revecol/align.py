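"""Shared alignment engine: k-mer-seeded best-location search.

Fragment ANI, gene matching and competitive read assignment all use the same
kernel: seed candidate locations with exact shared k-mers (default k=15),
score the implied diagonal with an ungapped comparison, and — for single
queries — refine with a banded edlib alignment so small indels do not break
the identity estimate. Ties between equally supported locations are broken
by the leftmost position in the target.
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np

from ._seq import decode, kmer_codes, revcomp

_COMP = np.array([3, 2, 1, 0, 4], dtype=np.uint8)


class KmerIndex:
    """Exact k-mer index over one encoded reference sequence."""

    def __init__(self, seq: np.ndarray, k: int = 15):
        self.seq = np.ascontiguousarray(seq, dtype=np.uint8)
        self.k = k
        codes = kmer_codes(self.seq, k)
        order = np.argsort(codes, kind="stable")  # ties keep ascending position
        sc = codes[order]
        first = np.ones(len(sc), dtype=bool)
        first[1:] = sc[1:] != sc[:-1]
        self.codes = sc[first]
        self.pos = order[first].astype(np.int64)

    def __len__(self) -> int:
        return len(self.seq)

    def lookup(self, query_codes: np.ndarray) -> np.ndarray:
        """Leftmost reference position of each code, -1 when absent."""
        i = np.searchsorted(self.codes, query_codes)
        ok = (i < len(self.codes)) & (query_codes >= 0)
        ok[ok] &= self.codes[i[ok]] == query_codes[ok]
        out = np.full(len(query_codes), -1, dtype=np.int64)
        out[ok] = self.pos[i[ok]]
        return out


def _batch_codes(seqs: np.ndarray, offset: int, k: int) -> np.ndarray:
    a = seqs[:, offset : offset + k].astype(np.int64)
    codes = np.zeros(len(seqs), dtype=np.int64)
    bad = np.zeros(len(seqs), dtype=bool)
    for j in range(k):
        codes = codes * 4 + np.where(a[:, j] > 3, 0, a[:, j])
        bad |= a[:, j] > 3
    codes[bad] = -1
    return codes


def _count_matches(seqs: np.ndarray, ref: np.ndarray, starts: np.ndarray,
                   chunk: int = 400_000) -> np.ndarray:
    n, rl = seqs.shape
    out = np.empty(n, dtype=np.int32)
    ar = np.arange(rl)
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        win = ref[starts[lo:hi, None] + ar]
        out[lo:hi] = (win == seqs[lo:hi]).sum(axis=1, dtype=np.int32)
    return out


def map_batch(seqs: np.ndarray, index: KmerIndex, max_rounds: int = 4) -> tuple[np.ndarray, np.ndarray]:
    """Best ungapped location for a dense batch of equal-length queries.

    Returns (start, matches); start = -1 and matches = -1 for queries with no
    usable seed. Queries are re-seeded from up to ``max_rounds`` different
    k-mer offsets until their match count looks consistent with a true
    homologous placement (>= 90% identity) or offsets are exhausted.
    """
    n, rl = seqs.shape
    k = index.k
    L = len(index.seq)
    if rl < k or L < rl:
        raise ValueError("queries must be >= k and <= reference length")
    span = rl - k
    n_off = min(max_rounds, span + 1) if span > 0 else 1
    offsets = np.unique(np.linspace(0, span, n_off).astype(int))
    best_start = np.full(n, -1, dtype=np.int64)
    best_matches = np.full(n, -1, dtype=np.int32)
    accept = rl - max(1, int(np.ceil(0.10 * rl)))
    active = np.arange(n)
    for off in offsets:
        if len(active) == 0:
            break
        codes = _batch_codes(seqs[active], int(off), k)
        pos = index.lookup(codes)
        found = pos >= 0
        rows = active[found]
        if len(rows):
            starts = np.clip(pos[found] - off, 0, L - rl)
            m = _count_matches(seqs[rows], index.seq, starts)
            upd = m > best_matches[rows]
            best_matches[rows[upd]] = m[upd]
            best_start[rows[upd]] = starts[upd]
        active = active[best_matches[active] < accept]
    return best_start, best_matches


@dataclass
class QueryHit:
    start: int           # 0-based on target
    end: int             # half-open
    matches: int
    identity: float      # fraction in [0,1], matches / query length
    coverage: float      # aligned query span / query length
    strand: str          # "+" or "-"


def _diagonal_hit(q: np.ndarray, index: KmerIndex, max_seeds: int = 512):
    nk = len(q) - index.k + 1
    if nk <= 0:
        return None
    stride = max(1, nk // max_seeds)
    qpos = np.arange(0, nk, stride)
    codes = kmer_codes(q, index.k)[qpos]
    pos = index.lookup(codes)
    ok = pos >= 0
    if not ok.any():
        return None
    diags = pos[ok] - qpos[ok]
    vals, counts = np.unique(diags, return_counts=True)
    best = vals[counts == counts.max()].min()  # leftmost on tie
    return int(best)


def map_query(q: np.ndarray, index: KmerIndex, both_strands: bool = True,
              refine_below: float = 0.995, band_extra: int = 32) -> QueryHit | None:
    """Best location of one variable-length query in the indexed target.

    Seeds with shared k-mers voting on a diagonal, scores the diagonal
    ungapped, and refines with an edlib infix alignment in a window around
    the candidate when the ungapped identity falls below ``refine_below``
    (rescues small indels). Returns ``None`` when no seed exists on either
    strand.
    """
    L = len(index.seq)
    ql = len(q)
    best: QueryHit | None = None
    strands = [("+", q), ("-", revcomp(q))] if both_strands else [("+", q)]
    for strand, qs in strands:
        diag = _diagonal_hit(qs, index)
        if diag is None:
            continue
        start = int(np.clip(diag, 0, max(L - ql, 0)))
        end = min(start + ql, L)
        span = end - start
        matches = int((index.seq[start:end] == qs[:span]).sum())
        identity = matches / ql
        coverage = span / ql
        if identity < refine_below:
            lo = max(0, diag - band_extra)
            hi = min(L, diag + ql + band_extra)
            res = edlib.align(decode(qs), decode(index.seq[lo:hi]), mode="HW", task="locations")
            if res["editDistance"] >= 0:
                e_matches = ql - res["editDistance"]
                if e_matches > matches:
                    s, e = res["locations"][0]
                    start, end = lo + s, lo + e + 1
                    matches = e_matches
                    identity = max(0.0, matches / ql)
                    coverage = min(1.0, (end - start) / ql)
        hit = QueryHit(start, end, matches, identity, coverage, strand)
        if best is None or hit.matches > best.matches:
            best = hit
    return best


def revcomp_batch(seqs: np.ndarray) -> np.ndarray:
    return _COMP[seqs][:, ::-1]
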