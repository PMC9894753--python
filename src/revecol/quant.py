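"""Abundance arithmetic and population–covariate statistics.

Reads-per-kilobase abundance with the usual genome-quality gate
(completeness > 50%, contamination < 10%), paired fold changes relative to
an untreated control, and plain two-tailed Pearson correlations between
population abundances and covariates (e.g. rumen SCFA concentrations) — no
multiplicity correction by default, mirroring how small correlation panels
are conventionally reported; a BH option exists.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


def reads_per_kilobase(
    mapped_read_counts: pd.DataFrame,
    unit_lengths: pd.Series,
    quality: pd.DataFrame | None = None,
    min_completeness: float = 50.0,
    max_contamination: float = 10.0,
) -> tuple[pd.DataFrame, list[str]]:
    """RPK table (units x samples) with the quality filter applied.

    ``mapped_read_counts`` is units x samples; ``quality`` (optional) carries
    ``completeness`` and ``contamination`` per unit. Returns the RPK table
    ranked by median RPK (descending) and the list of excluded units.
    Raises on non-positive unit lengths.
    """
    lengths = unit_lengths.reindex(mapped_read_counts.index)
    if (lengths <= 0).any() or lengths.isna().any():
        bad = lengths.index[(lengths <= 0) | lengths.isna()].tolist()
        raise ValueError(f"unit length must be > 0; offending units: {bad}")
    excluded: list[str] = []
    keep = mapped_read_counts.index
    if quality is not None:
        q = quality.reindex(keep)
        ok = (q.completeness > min_completeness) & (q.contamination < max_contamination)
        excluded = keep[~ok.fillna(False)].tolist()
        keep = keep[ok.fillna(False)]
    rpk = mapped_read_counts.loc[keep].div(lengths[keep] / 1000.0, axis=0)
    order = rpk.median(axis=1).sort_values(ascending=False).index
    return rpk.loc[order], excluded


@dataclass
class FoldChangeResult:
    mean: float
    sd: float
    folds: np.ndarray
    n: int
    excluded: list[int]          # replicate indices with zero control


def fold_change(treatment, control) -> FoldChangeResult:
    """Per-replicate fold change treatment/control; mean ± sd over replicates.

    Replicates with a zero control value are flagged and excluded with a
    warning rather than producing infinities.
    """
    t = np.asarray(treatment, dtype=float)
    c = np.asarray(control, dtype=float)
    if t.shape != c.shape:
        raise ValueError("treatment and control must be paired (same length)")
    bad = np.flatnonzero(c == 0)
    if len(bad):
        import warnings

        warnings.warn(f"control is zero in replicates {bad.tolist()}; excluded")
    ok = c != 0
    folds = t[ok] / c[ok]
    return FoldChangeResult(
        mean=float(folds.mean()) if len(folds) else float("nan"),
        sd=float(folds.std(ddof=1)) if len(folds) > 1 else 0.0,
        folds=folds,
        n=int(ok.sum()),
        excluded=bad.tolist(),
    )


def correlate(
    abundances: pd.DataFrame,
    covariates: pd.DataFrame,
    alpha: float = 0.05,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Pearson correlations of every (unit, covariate) pair, two-tailed p.

    Rows are samples in both tables (aligned on index). Zero-variance
    variables yield NaN flagged ``undefined``; n < 3 is an error. With
    ``bh_correct`` the significance flag uses BH-adjusted p-values (off by
    default).
    """
    common = abundances.index.intersection(covariates.index)
    if len(common) < 3:
        raise ValueError(f"need >= 3 paired samples, got {len(common)}")
    a = abundances.loc[common]
    c = covariates.loc[common]
    rows = []
    for unit in a.columns:
        for cov in c.columns:
            x, y = a[unit].to_numpy(float), c[cov].to_numpy(float)
            mask = np.isfinite(x) & np.isfinite(y)
            n = int(mask.sum())
            if n < 3 or x[mask].std() == 0 or y[mask].std() == 0:
                rows.append((unit, cov, np.nan, np.nan, n, "undefined"))
                continue
            r, p = stats.pearsonr(x[mask], y[mask])
            rows.append((unit, cov, float(r), float(p), n, "ok"))
    out = pd.DataFrame(rows, columns=["unit", "covariate", "r", "p", "n", "status"])
    ok = out.status == "ok"
    if bh_correct and ok.any():
        out.loc[ok, "p_adj"] = multipletests(out.loc[ok, "p"], method="fdr_bh")[1]
        out["significant"] = ok & (out.get("p_adj", pd.Series(index=out.index)) < alpha)
    else:
        out["significant"] = ok & (out.p < alpha)
    return out
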