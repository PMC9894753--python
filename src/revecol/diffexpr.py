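"""Identity-gated orthologue pairing and cross-population NB differential
expression.

Cross-population expression comparisons are only meaningful for gene pairs
that competitive mapping can separate (not too similar) yet that remain
true orthologues (not too divergent): pairs are tested only when their
global alignment identity lies in (80%, 97.5%]. The test itself is a
self-contained negative-binomial Wald test — median-of-ratios size factors,
method-of-moments dispersion shrunk toward a fitted mean–dispersion trend,
two-sided Wald p-values on the log2 fold change with Benjamini–Hochberg
correction — standing in for heavier external DE machinery, with the same
decision surface (log2FC, adjusted p).
"""
from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._seq import decode, encode
from .align import KmerIndex, map_query


# ---------------------------------------------------------------------------
# orthologue pairing
# ---------------------------------------------------------------------------

def _global_identity(a: np.ndarray, b: np.ndarray) -> float:
    """Global alignment identity over the shorter sequence (%), via edit distance."""
    d = edlib.align(decode(a), decode(b), mode="NW")["editDistance"]
    short = min(len(a), len(b))
    return 100.0 * max(0.0, 1.0 - d / short)


def pair_orthologues(
    genes_a: dict[str, np.ndarray | str],
    genes_b: dict[str, np.ndarray | str],
    min_id: float = 80.0,
    max_id: float = 97.5,
) -> pd.DataFrame:
    """Reciprocal-best-hit orthologue pairs with the identity gate applied.

    Returns one row per reciprocal pair: gene_a, gene_b, identity,
    comparable, reason (``ok`` / ``too_similar`` / ``too_divergent``).
    Excluded pairs are retained with their reason.
    """
    enc_a = {g: encode(s) for g, s in genes_a.items()}
    enc_b = {g: encode(s) for g, s in genes_b.items()}

    def best_hits(queries, targets):
        names = list(targets)
        bounds = np.cumsum([0] + [len(targets[t]) + 50 for t in names])
        cat = np.full(bounds[-1], 4, dtype=np.uint8)
        for t, name in enumerate(names):
            cat[bounds[t] : bounds[t] + len(targets[name])] = targets[name]
        idx = KmerIndex(cat)
        out = {}
        for q, seq in queries.items():
            hit = map_query(seq, idx)
            if hit is None:
                continue
            t = int(np.searchsorted(bounds, hit.start, side="right") - 1)
            out[q] = names[t]
        return out

    a2b = best_hits(enc_a, enc_b)
    b2a = best_hits(enc_b, enc_a)
    rows = []
    for ga, gb in a2b.items():
        if b2a.get(gb) != ga:
            continue
        ident = _global_identity(enc_a[ga], enc_b[gb])
        if ident > max_id:
            reason, comparable = "too_similar", False
        elif ident <= min_id:
            reason, comparable = "too_divergent", False
        else:
            reason, comparable = "ok", True
        rows.append((ga, gb, ident, comparable, reason))
    return pd.DataFrame(
        rows, columns=["gene_a", "gene_b", "identity", "comparable", "reason"]
    )


# ---------------------------------------------------------------------------
# read counting
# ---------------------------------------------------------------------------

def count_expression(
    assignments, annotations: pd.DataFrame, reference: str, reference_length: int
) -> pd.Series:
    """Per-gene read counts for one reference from competitive assignments.

    A read counts toward exactly one gene — the one it overlaps longest
    (leftmost gene on ties); reads overlapping no gene are dropped.
    ``annotations`` uses 1-based inclusive start/end for one reference.
    """
    ann = annotations.sort_values("start").reset_index(drop=True)
    if len(ann) and int(ann.end.max()) > reference_length:
        raise ValueError("annotation coordinates exceed reference length")
    if reference not in assignments.ref_names:
        raise ValueError(f"reference {reference!r} absent from assignments")
    j = assignments.ref_names.index(reference)
    sel = assignments.winner == j
    starts = assignments.starts[sel, j]
    rl = assignments.read_length
    g_start = ann.start.to_numpy() - 1
    g_end = ann.end.to_numpy()
    n_genes = len(ann)
    counts = np.zeros(n_genes, dtype=np.int64)
    if n_genes and len(starts):
        first = np.searchsorted(g_end, starts, side="right")
        best_gene = np.full(len(starts), -1, dtype=np.int64)
        best_ov = np.zeros(len(starts), dtype=np.int64)
        for delta in range(3):  # a short read spans at most a few gene slots
            gi = first + delta
            ok = gi < n_genes
            ov = np.zeros(len(starts), dtype=np.int64)
            ov[ok] = (np.minimum(g_end[gi[ok]], starts[ok] + rl)
                      - np.maximum(g_start[gi[ok]], starts[ok]))
            upd = ok & (ov > best_ov)  # strict: ties stay with the leftmost gene
            best_gene[upd] = gi[upd]
            best_ov[upd] = ov[upd]
        hit = best_gene >= 0
        np.add.at(counts, best_gene[hit], 1)
    return pd.Series(counts, index=ann.gene_id, name="count")


# ---------------------------------------------------------------------------
# NB Wald test
# ---------------------------------------------------------------------------

def size_factors_median_of_ratios(counts: pd.DataFrame) -> pd.Series:
    """DESeq-style size factors: per-sample median ratio to the per-gene
    geometric mean, over genes expressed in all samples."""
    logc = np.log(counts.where(counts > 0))
    loggm = logc.mean(axis=1)
    use = np.isfinite(loggm)
    if not use.any():
        raise ValueError("no gene has positive counts in all samples")
    ratios = logc.loc[use].sub(loggm[use], axis=0)
    return np.exp(ratios.median(axis=0)).rename("size_factor")


@dataclass
class DEResult:
    table: pd.DataFrame            # pair/gene, baseMean, log2FC, lfcSE, pvalue, padj, status
    size_factors: pd.Series
    alpha: float

    def significant(self) -> pd.DataFrame:
        return self.table[(self.table.status == "tested") & (self.table.padj < self.alpha)]


def nb_differential_test(
    counts: pd.DataFrame,
    design: pd.Series,
    alpha: float = 1e-5,
    shrink_weight: float = 0.5,
    pseudocount: float = 0.5,
) -> DEResult:
    """Two-sided NB Wald test of population A vs B expression per gene.

    * size factors by median-of-ratios;
    * per-gene dispersion by method-of-moments on normalized counts (pooled
      within-group), shrunk in log space toward a 1/mu + constant trend
      fitted across genes;
    * Wald statistic log2FC / SE with the delta-method SE, referred to the
      standard normal (the trend-shrunken dispersion pools information
      across genes, as in standard NB-Wald DE practice);
    * Benjamini–Hochberg adjustment across tested genes; all-zero genes are
      excluded and reported with status ``all_zero``.
    """
    design = design.reindex(counts.columns)
    groups = sorted(design.dropna().unique())
    if len(groups) != 2:
        raise ValueError(f"design must have exactly 2 groups, got {groups}")
    ga, gb = groups
    cols_a = design.index[design == ga]
    cols_b = design.index[design == gb]
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("each group needs >= 2 samples")

    sf = size_factors_median_of_ratios(counts)
    q = counts / sf
    qa, qb = q[cols_a], q[cols_b]
    na, nb = len(cols_a), len(cols_b)

    base_mean = q.mean(axis=1)
    mean_a = qa.mean(axis=1)
    mean_b = qb.mean(axis=1)
    nonzero = counts.sum(axis=1) > 0

    # method-of-moments dispersion from pooled within-group moments
    var_w = (qa.var(axis=1, ddof=1) * (na - 1) + qb.var(axis=1, ddof=1) * (nb - 1)) / (
        na + nb - 2
    )
    mu_w = (mean_a * na + mean_b * nb) / (na + nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        disp_mom = ((var_w - mu_w) / mu_w**2).clip(lower=1e-8)

    # mean-dispersion trend: alpha(mu) = a1/mu + a0 (gamma-GLM-style, via
    # least squares on genes with informative estimates)
    fit_mask = nonzero & np.isfinite(disp_mom) & (mu_w > 0) & (disp_mom > 1e-7)
    if fit_mask.sum() >= 10:
        X = np.column_stack([np.ones(fit_mask.sum()), 1.0 / mu_w[fit_mask]])
        coef, *_ = np.linalg.lstsq(X, disp_mom[fit_mask], rcond=None)
        a0, a1 = max(coef[0], 1e-8), max(coef[1], 0.0)
    else:
        a0, a1 = max(np.nanmedian(disp_mom[nonzero]) if nonzero.any() else 0.01, 1e-8), 0.0
    with np.errstate(divide="ignore"):
        disp_trend = (a0 + a1 / mu_w).clip(lower=1e-8)
        disp = np.exp(
            (1 - shrink_weight) * np.log(disp_mom.fillna(disp_trend))
            + shrink_weight * np.log(disp_trend)
        )

    log2fc = np.log2((mean_a + pseudocount) / (mean_b + pseudocount))
    inv_sf_a = (1.0 / sf[cols_a]).sum()
    inv_sf_b = (1.0 / sf[cols_b]).sum()
    var_mean_a = (mean_a * inv_sf_a / na**2) + disp * mean_a**2 / na
    var_mean_b = (mean_b * inv_sf_b / nb**2) + disp * mean_b**2 / nb
    ln2sq = np.log(2.0) ** 2
    se = np.sqrt(
        var_mean_a / ((mean_a + pseudocount) ** 2 * ln2sq)
        + var_mean_b / ((mean_b + pseudocount) ** 2 * ln2sq)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        wald = log2fc / se
    pvals = 2.0 * stats.norm.sf(np.abs(wald))

    table = pd.DataFrame(
        {"baseMean": base_mean, "log2FC": log2fc, "lfcSE": se,
         "pvalue": pvals, "padj": np.nan, "status": "tested"},
        index=counts.index,
    )
    table.loc[~nonzero, "status"] = "all_zero"
    table.loc[~nonzero, ["log2FC", "lfcSE", "pvalue"]] = np.nan
    tested = table.status == "tested"
    if tested.any():
        table.loc[tested, "padj"] = multipletests(
            table.loc[tested, "pvalue"].to_numpy(), method="fdr_bh"
        )[1]
    return DEResult(table=table, size_factors=sf, alpha=alpha)


def differential_test_pairs(
    counts: pd.DataFrame,
    design: pd.Series,
    pairs: pd.DataFrame,
    alpha: float = 1e-5,
    **kw,
) -> DEResult:
    """NB test restricted to comparable orthologue pairs.

    ``pairs`` comes from :func:`pair_orthologues`; counts are indexed by the
    A-side gene id. Non-comparable pairs never enter the test or the BH
    correction.
    """
    keep = pairs[pairs.comparable].gene_a
    sub = counts.loc[counts.index.intersection(keep)]
    return nb_differential_test(sub, design, alpha=alpha, **kw)
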