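"""Competitive read assignment, SNP calling and sweep-region scanning.

Reads are assigned competitively: each read is scored against every
reference (both strands, match +1 / mismatch -1 on the best seeded
diagonal); the highest-scoring reference wins and equal best scores are
ties, which are discarded from all pileups rather than placed arbitrarily —
conservative for SNP-free-region detection, since random placement would
manufacture false intra-population polymorphism.

The SNP caller is native and fully parameterised (min depth 10, minor-allele
fraction 0.1 by default), with the thresholds declared in the emitted VCF
header.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._seq import BASES, decode, encode
from .align import KmerIndex, map_batch, map_query, revcomp_batch
from .anipop import compute_ani
from .simgen import ReadSet


# ---------------------------------------------------------------------------
# competitive assignment
# ---------------------------------------------------------------------------

@dataclass
class ReadAssignmentSet:
    """Per-read competitive mapping outcome against >= 2 references."""

    ref_names: list[str]
    winner: np.ndarray          # index into ref_names; -1 = tie, -2 = unassigned
    scores: np.ndarray          # n_reads x n_refs (match - mismatch; min int32)
    starts: np.ndarray          # n_reads x n_refs best start (-1 no seed)
    strands: np.ndarray         # n_reads x n_refs, 0 forward / 1 reverse
    read_length: int

    def __len__(self) -> int:
        return len(self.winner)

    @property
    def n_ties(self) -> int:
        return int((self.winner == -1).sum())

    @property
    def n_unassigned(self) -> int:
        return int((self.winner == -2).sum())

    def counts(self) -> pd.Series:
        vals = {name: int((self.winner == i).sum()) for i, name in enumerate(self.ref_names)}
        vals["tie"] = self.n_ties
        vals["unassigned"] = self.n_unassigned
        return pd.Series(vals, name="reads")

    def runner_up(self) -> np.ndarray:
        part = np.sort(self.scores, axis=1)
        return part[:, -2]

    def to_frame(self) -> pd.DataFrame:
        win = np.array(["tie"] * len(self), dtype=object)
        for i, name in enumerate(self.ref_names):
            win[self.winner == i] = name
        win[self.winner == -2] = "unassigned"
        return pd.DataFrame(
            {"read": [f"read_{i:08d}" for i in range(len(self))],
             "winner": win,
             "best_score": self.scores.max(axis=1),
             "runner_up_score": self.runner_up(),
             "tie": self.winner == -1}
        )


def competitive_assign(
    reads: ReadSet | np.ndarray,
    references: dict[str, np.ndarray | str],
    min_identity: float = 0.80,
) -> ReadAssignmentSet:
    """Assign each read to its best-scoring reference.

    Reads whose best alignment anywhere falls below ``min_identity`` (or that
    have no seed) are reported unassigned; exact score ties are flagged and
    excluded from downstream pileups.
    """
    if len(references) < 2:
        raise ValueError("competitive assignment needs >= 2 references")
    seqs = reads.seqs if isinstance(reads, ReadSet) else np.asarray(reads, dtype=np.uint8)
    if len(seqs) == 0:
        raise ValueError("empty read set")
    n, rl = seqs.shape
    names = list(references)
    n_ref = len(names)
    scores = np.full((n, n_ref), np.iinfo(np.int32).min, dtype=np.int64)
    starts = np.full((n, n_ref), -1, dtype=np.int64)
    strands = np.zeros((n, n_ref), dtype=np.int8)
    rc = revcomp_batch(seqs)
    accept = rl - max(1, int(np.ceil(0.10 * rl)))
    for j, name in enumerate(names):
        idx = KmerIndex(encode(references[name]))
        s_f, m_f = map_batch(seqs, idx)
        # reverse strand only for reads the forward pass could not place well
        need = np.flatnonzero(m_f < accept)
        s_r = np.full(n, -1, dtype=np.int64)
        m_r = np.full(n, -1, dtype=np.int32)
        if len(need):
            s_r[need], m_r[need] = map_batch(rc[need], idx)
        use_r = m_r > m_f
        m = np.where(use_r, m_r, m_f)
        s = np.where(use_r, s_r, s_f)
        ok = m >= 0
        scores[ok, j] = 2 * m[ok] - rl
        starts[:, j] = s
        strands[:, j] = use_r.astype(np.int8)

    order = np.argsort(scores, axis=1)
    best = order[:, -1]
    best_sc = scores[np.arange(n), best]
    second_sc = scores[np.arange(n), order[:, -2]]
    winner = best.astype(np.int64)
    winner[best_sc == second_sc] = -1
    min_score = 2 * int(np.ceil(min_identity * rl)) - rl
    winner[best_sc < min_score] = -2
    return ReadAssignmentSet(names, winner, scores, starts, strands, rl)


# ---------------------------------------------------------------------------
# SNP calling
# ---------------------------------------------------------------------------

@dataclass
class SNPCallResult:
    reference: str
    table: pd.DataFrame          # pos (1-based), ref, alt, depth, af
    coverage: np.ndarray         # per-position assigned-read depth
    params: dict = field(default_factory=dict)

    def positions(self) -> np.ndarray:
        return self.table.pos.to_numpy()


def call_snps(
    assignments: ReadAssignmentSet,
    reads: ReadSet | np.ndarray,
    reference: str,
    reference_seq,
    min_depth: int = 10,
    min_af: float = 0.1,
    mode: str = "polymorphism",
) -> SNPCallResult:
    """Call SNPs from the pileup of reads competitively assigned to one reference.

    ``mode='polymorphism'`` (used for intra-population diversity scans)
    requires the minor-allele fraction to lie in [min_af, 1 - min_af];
    ``mode='reference'`` requires the non-reference allele fraction to reach
    min_af. Both require depth >= min_depth.
    """
    if reference not in assignments.ref_names:
        raise ValueError(f"reference {reference!r} absent from assignments")
    j = assignments.ref_names.index(reference)
    ref = encode(reference_seq)
    L = len(ref)
    rl = assignments.read_length
    seqs = reads.seqs if isinstance(reads, ReadSet) else np.asarray(reads, dtype=np.uint8)
    sel = np.flatnonzero(assignments.winner == j)

    cov_diff = np.zeros(L + 1, dtype=np.int64)
    starts = assignments.starts[sel, j]
    np.add.at(cov_diff, starts, 1)
    np.add.at(cov_diff, np.minimum(starts + rl, L), -1)
    coverage = np.cumsum(cov_diff[:-1])

    base_counts = np.zeros((4, L), dtype=np.int64)
    ar = np.arange(rl)
    chunk = 400_000
    for lo in range(0, len(sel), chunk):
        rows = sel[lo : lo + chunk]
        sub = seqs[rows]
        flip = assignments.strands[rows, j] == 1
        if flip.any():
            sub = sub.copy()
            sub[flip] = revcomp_batch(sub[flip])
        st = assignments.starts[rows, j]
        win = ref[st[:, None] + ar]
        ii, jj = np.nonzero(sub != win)
        pos = st[ii] + jj
        np.add.at(base_counts, (sub[ii, jj], pos), 1)

    nonref_total = base_counts.sum(axis=0)
    cand = np.flatnonzero(nonref_total > 0)
    depth = coverage[cand]
    counts = base_counts[:, cand]
    alt = counts.argmax(axis=0).astype(np.uint8)
    alt_n = counts.max(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        af = np.where(depth > 0, alt_n / depth, 0.0)
    if mode == "polymorphism":
        keep = (depth >= min_depth) & (af >= min_af) & (af <= 1.0 - min_af)
    elif mode == "reference":
        keep = (depth >= min_depth) & (af >= min_af)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    cand, depth, alt, af = cand[keep], depth[keep], alt[keep], af[keep]
    table = pd.DataFrame(
        {"pos": cand + 1,
         "ref": [chr(BASES[b]) for b in ref[cand]],
         "alt": [chr(BASES[b]) for b in alt],
         "depth": depth,
         "af": af}
    ).sort_values("pos").reset_index(drop=True)
    params = {"min_depth": min_depth, "min_af": min_af, "mode": mode}
    return SNPCallResult(reference=reference, table=table, coverage=coverage, params=params)


# ---------------------------------------------------------------------------
# window tracks and SNP-free regions
# ---------------------------------------------------------------------------

def snp_density_windows(
    snps: pd.DataFrame, reference_length: int, window: int = 1000
) -> pd.DataFrame:
    """Percentage of positions that are SNPs per fixed window (BED-style
    0-based half-open coordinates); a trailing partial window is normalised
    by its true width."""
    if window < 1:
        raise ValueError("window must be >= 1")
    n_win = int(np.ceil(reference_length / window))
    counts = np.zeros(n_win, dtype=np.int64)
    if len(snps):
        idx = (snps.pos.to_numpy() - 1) // window
        np.add.at(counts, idx, 1)
    start = np.arange(n_win) * window
    end = np.minimum(start + window, reference_length)
    width = end - start
    return pd.DataFrame(
        {"start": start, "end": end, "n_snps": counts,
         "pct_snps": 100.0 * counts / width}
    )


@dataclass
class SnpFreeRegion:
    start: int   # 0-based half-open
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def largest_snp_free_region(
    snps: pd.DataFrame,
    reference_length: int,
    coverage_mask: np.ndarray | None = None,
) -> tuple[SnpFreeRegion, pd.DataFrame]:
    """Largest interval containing no SNP (and, optionally, no uncovered
    position), plus the full ranked gap list.

    Sequence ends bound the intervals; with ``coverage_mask`` given (True =
    adequately covered), uncovered stretches break intervals so they cannot
    masquerade as SNP-free. Ties go to the leftmost interval.
    """
    breaker = np.zeros(reference_length, dtype=bool)
    if len(snps):
        breaker[snps.pos.to_numpy() - 1] = True
    if coverage_mask is not None:
        breaker |= ~np.asarray(coverage_mask, dtype=bool)
    padded = np.concatenate([[True], breaker, [True]])
    edges = np.diff(padded.astype(np.int8))
    run_starts = np.flatnonzero(edges == -1)
    run_ends = np.flatnonzero(edges == 1)
    if len(run_starts) == 0:
        empty = pd.DataFrame(columns=["start", "end", "length"])
        return SnpFreeRegion(0, 0), empty
    lengths = run_ends - run_starts
    gaps = pd.DataFrame({"start": run_starts, "end": run_ends, "length": lengths})
    gaps = gaps.sort_values(["length", "start"], ascending=[False, True]).reset_index(drop=True)
    top = gaps.iloc[0]
    return SnpFreeRegion(int(top.start), int(top.end)), gaps


def cross_identity_profile(
    region: tuple[int, int],
    genome_a,
    genome_b,
    window: int = 1000,
    smooth_k: int = 3,
    breakpoint_delta: float = 5.0,
    genomewide_identity: float | None = None,
) -> pd.DataFrame:
    """Windowed alignment identity of a region of genome A against genome B.

    The region (0-based half-open on A) is located in B, identity is computed
    per window and smoothed with a centered moving average over ``smooth_k``
    windows; windows whose smoothed identity drops more than
    ``breakpoint_delta`` points below the genome-wide mean identity are
    flagged as breakpoints. Raises when the region cannot be located in B.
    """
    import edlib

    a = encode(genome_a)
    b = encode(genome_b)
    s, e = region
    seg = a[s:e]
    idx_b = KmerIndex(b)
    hit = map_query(seg, idx_b)
    if hit is None:
        raise ValueError("region could not be aligned to the second genome")
    if genomewide_identity is None:
        genomewide_identity = compute_ani(a, b, fragment_length=min(1000, len(seg))).ani
    off = hit.start - (0 if hit.strand == "+" else 0)
    rows = []
    for ws in range(0, len(seg), window):
        we = min(ws + window, len(seg))
        bs = off + ws
        be = min(off + we, len(b))
        if be <= bs:
            ident = np.nan
        else:
            res = edlib.align(decode(seg[ws:we]), decode(b[bs:be]), mode="NW")
            ident = 100.0 * (1.0 - res["editDistance"] / (we - ws))
        rows.append((s + ws, s + we, ident))
    track = pd.DataFrame(rows, columns=["start", "end", "identity"])
    k = max(1, int(smooth_k))
    track["smoothed"] = (
        track.identity.rolling(window=k, center=True, min_periods=1).mean()
    )
    track["breakpoint"] = track.smoothed < (genomewide_identity - breakpoint_delta)
    return track


# ---------------------------------------------------------------------------
# VCF round-trip
# ---------------------------------------------------------------------------

def write_vcf(result: SNPCallResult, path, reference_length: int | None = None) -> None:
    """Plain-text VCF with the caller's thresholds declared in the header."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##source=revecol call_snps mode={result.params.get('mode')} "
                 f"min_depth={result.params.get('min_depth')} "
                 f"min_af={result.params.get('min_af')}\n")
        if reference_length is not None:
            fh.write(f"##contig=<ID={result.reference},length={reference_length}>\n")
        else:
            fh.write(f"##contig=<ID={result.reference}>\n")
        fh.write('##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write('##INFO=<ID=AF,Number=1,Type=Float,Description="Alternate allele fraction">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for r in result.table.itertuples():
            fh.write(f"{result.reference}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                     f"DP={r.depth};AF={r.af:.6g}\n")


def read_vcf(path) -> pd.DataFrame:
    """Read a VCF written by :func:`write_vcf` back into a SNP table."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, pos, _id, ref, alt, _q, _f, info = line.rstrip("\n").split("\t")[:8]
            fields = dict(kv.split("=") for kv in info.split(";") if "=" in kv)
            rows.append((chrom, int(pos), ref, alt, int(fields.get("DP", 0)),
                         float(fields.get("AF", np.nan))))
    return pd.DataFrame(rows, columns=["reference", "pos", "ref", "alt", "depth", "af"])
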