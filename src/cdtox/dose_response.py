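"""Per-gene linear regression of expression on Cd2+ concentration.

Each exposure block (1-day: 0/9/27/45 uM; 13-day: 0/4.5/9/27 uM) is a
single-replicate dose series, so the per-gene model is ordinary least squares
of (raw or log2) signal on dose, with the two-sided slope t test on
n - 2 residual degrees of freedom.  With n = 4 samples the design is
deliberately minimal: selection is by raw P value at a strict cutoff, and BH
q values are reported alongside (at this sample size they rarely clear 0.05,
as expected).

Degenerate fits are handled rather than rejected: a response with zero
variance reports slope 0, direction "flat" and P = 1; an exactly linear
(zero-residual) response reports P = 0 with ``perfect_fit`` set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import ExpressionStudy, filter_present

__all__ = [
    "fit_dose_regression",
    "select_genes",
    "GeneListSelection",
    "pvalue_histogram",
    "bh_fdr",
]

SCALES = ("raw", "log2")

# residual sum of squares below this fraction of the response variance is a
# numerically perfect fit (reachable at n=4 with noise-free simulated data)
_PERFECT_FIT_RTOL = 1e-12


def fit_dose_regression(
    study: ExpressionStudy,
    block: float,
    scale: str = "raw",
    apply_present_filter: bool = True,
) -> pd.DataFrame:
    """OLS of expression on dose for every (present) probe of one block.

    Parameters
    ----------
    study : ExpressionStudy
        The full study; samples with ``time_days == block`` are used.
    block : exposure duration in days selecting the block (1 or 13).
    scale : "raw" fits the signal as-is; "log2" fits log2(signal + 1).
    apply_present_filter : drop probes Absent/Marginal in every sample first.

    Returns
    -------
    DataFrame indexed by probe with columns ``slope``, ``intercept``, ``t``,
    ``p``, ``df``, ``direction`` (positive/negative/flat) and ``perfect_fit``,
    sorted by ascending P within each direction group.
    """
    if scale not in SCALES:
        raise ValueError(f"scale must be one of {SCALES}, got {scale!r}")
    if apply_present_filter:
        study = filter_present(study)
    sub = study.block(block)
    x = sub.design["dose_uM"].to_numpy(dtype=float)
    if len(np.unique(x)) < 3:
        raise ValueError(
            f"block {block} has {len(np.unique(x))} distinct doses; need >= 3"
        )
    if np.ptp(x) == 0:
        raise ValueError(f"block {block} has zero dose variance")

    Y = sub.signal.to_numpy(dtype=float)
    if scale == "log2":
        Y = np.log2(Y + 1.0)
    n = len(x)
    df = n - 2
    xc = x - x.mean()
    sxx = float(xc @ xc)
    yc = Y - Y.mean(axis=1, keepdims=True)
    syy = np.einsum("ij,ij->i", yc, yc)
    sxy = yc @ xc
    slope = sxy / sxx
    intercept = Y.mean(axis=1) - slope * x.mean()
    rss = syy - slope * sxy
    # guard tiny negative values from cancellation
    rss = np.maximum(rss, 0.0)

    flat = syy == 0.0
    perfect = (~flat) & (rss <= _PERFECT_FIT_RTOL * syy)

    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df / sxx)
        t = slope / se
    p = 2.0 * stats.t.sf(np.abs(t), df)

    slope = np.where(flat, 0.0, slope)
    t = np.where(flat, 0.0, t)
    p = np.where(flat, 1.0, p)
    with np.errstate(invalid="ignore"):
        t = np.where(perfect, np.sign(slope) * np.inf, t)
    p = np.where(perfect, 0.0, p)

    direction = np.where(slope > 0, "positive", np.where(slope < 0, "negative", "flat"))
    out = pd.DataFrame(
        {
            "slope": slope,
            "intercept": intercept,
            "t": t,
            "p": p,
            "df": df,
            "direction": direction,
            "perfect_fit": perfect,
        },
        index=sub.signal.index.rename("probe"),
    )
    order = pd.Categorical(out["direction"], categories=["positive", "negative", "flat"])
    return out.assign(_d=order).sort_values(["_d", "p"], kind="stable").drop(columns="_d")


@dataclass(frozen=True)
class GeneListSelection:
    """Probes/genes passing a strict P-value cutoff in one direction."""

    cutoff: float
    direction: str | None          # "positive", "negative" or None (both)
    ids: tuple[str, ...]
    n_selected: int
    n_universe: int


def select_genes(
    results: pd.DataFrame,
    cutoff: float,
    direction: str | None = None,
) -> GeneListSelection:
    """Select results with P strictly below ``cutoff``, optionally one-sided.

    ``direction`` of "positive"/"negative" keeps only slopes of that sign;
    a P equal to the cutoff is excluded (strict inequality).
    """
    if not (0 < cutoff <= 1):
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    if direction not in (None, "positive", "negative"):
        raise ValueError(f"bad direction {direction!r}")
    if len(results) == 0:
        return GeneListSelection(cutoff, direction, (), 0, 0)
    mask = results["p"] < cutoff
    if direction is not None:
        mask &= results["direction"] == direction
    picked = results.index[mask]
    return GeneListSelection(
        cutoff=cutoff,
        direction=direction,
        ids=tuple(picked),
        n_selected=int(mask.sum()),
        n_universe=len(results),
    )


def pvalue_histogram(pvalues, n_bins: int = 20) -> pd.DataFrame:
    """Counts of P values over equal-width bins on [0, 1].

    Accepts a results DataFrame (uses its ``p`` column) or an array of P
    values.  The counts always sum to the number of inputs (P = 1 falls in
    the last bin).
    """
    if n_bins < 2:
        raise ValueError(f"n_bins must be >= 2, got {n_bins}")
    if isinstance(pvalues, pd.DataFrame):
        pvalues = pvalues["p"].to_numpy()
    p = np.asarray(pvalues, dtype=float)
    counts, edges = np.histogram(p, bins=n_bins, range=(0.0, 1.0))
    return pd.DataFrame({"bin_left": edges[:-1], "count": counts})


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q values, in the input order."""
    if isinstance(pvalues, pd.DataFrame):
        pvalues = pvalues["p"].to_numpy()
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("bh_fdr needs at least one P value")
    return multipletests(p, method="fdr_bh")[1]
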