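"""Hypergeometric tail machinery for enrichment and list-overlap tests.

Both tests ask the same question: when ``K`` of ``M`` universe genes are
marked (regression-significant, or members of the first list) and ``n`` genes
are drawn without replacement (a pathway, or the second list), is the observed
number of marked draws ``r`` larger than chance?  The P value used throughout
is the strictly-greater upper tail

    P(X > r) = sum_{k=r+1}^{min(K, n)} C(K, k) C(M-K, n-k) / C(M, n)

computed in the log domain so it is stable for universes of ~30,000 genes and
tail probabilities far below float underflow of individual ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .dose_response import bh_fdr

__all__ = [
    "hypergeom_logpmf",
    "hypergeom_tail_gt",
    "enrich_gene_sets",
    "overlap_significance",
    "OverlapResult",
]


def _validate(M: int, K: int, n: int, r: int) -> None:
    for name, v in (("M", M), ("K", K), ("n", n), ("r", r)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    if not (0 <= K <= M):
        raise ValueError(f"need 0 <= K <= M, got K={K}, M={M}")
    if not (0 <= n <= M):
        raise ValueError(f"need 0 <= n <= M, got n={n}, M={M}")
    if not (0 <= r <= min(K, n)):
        raise ValueError(f"need 0 <= r <= min(K, n)={min(K, n)}, got r={r}")


def _logC(a, b):
    """log C(a, b) via log-gamma; a, b may be arrays with 0 <= b <= a."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def hypergeom_logpmf(k, M: int, K: int, n: int):
    """log P(X = k) for X ~ Hypergeometric(M, K, n); -inf outside support."""
    k = np.asarray(k, dtype=float)
    lo, hi = max(0, n - (M - K)), min(K, n)
    out = np.full(k.shape, -np.inf)
    ok = (k >= lo) & (k <= hi)
    if np.any(ok):
        kk = k[ok]
        out[ok] = _logC(K, kk) + _logC(M - K, n - kk) - _logC(M, n)
    return out if out.shape else float(out)


def hypergeom_tail_gt(M: int, K: int, n: int, r: int) -> float:
    """Strictly-greater hypergeometric upper tail P(X > r).

    Parameters
    ----------
    M : universe size (genes present in the study).
    K : marked genes (the significant set / first list).
    n : draw size (pathway size within the universe / second list).
    r : observed marked draws (intersection size).

    Returns 0.0 when the tail beyond ``r`` is empty (``r == min(K, n)``).
    """
    _validate(M, K, n, r)
    M, K, n, r = int(M), int(K), int(n), int(r)
    hi = min(K, n)
    if r >= hi:
        return 0.0
    ks = np.arange(r + 1, hi + 1)
    logp = hypergeom_logpmf(ks, M, K, n)
    logp = logp[np.isfinite(logp)]
    if logp.size == 0:
        return 0.0
    return float(min(1.0, np.exp(logsumexp(logp))))


@dataclass(frozen=True)
class OverlapResult:
    """Cross-timepoint list-overlap test summary."""

    M: int          # universe (present genes)
    K: int          # |list A|
    n: int          # |list B|
    r: int          # |A & B|
    expected: float  # K * n / M under independence
    p: float        # P(X > r)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def overlap_significance(
    list_a: Iterable[str], list_b: Iterable[str], universe: Iterable[str]
) -> OverlapResult:
    """Test whether two gene lists share more members than chance.

    Both lists must be subsets of the universe.  Models the overlap count of
    random lists of the same sizes as hypergeometric and returns the
    strictly-greater tail at the observed overlap, plus the expected overlap
    K*n/M.
    """
    uni = set(universe)
    a, b = set(list_a), set(list_b)
    if not a <= uni:
        raise ValueError(f"list A has {len(a - uni)} genes outside the universe")
    if not b <= uni:
        raise ValueError(f"list B has {len(b - uni)} genes outside the universe")
    M, K, n, r = len(uni), len(a), len(b), len(a & b)
    return OverlapResult(
        M=M, K=K, n=n, r=r,
        expected=K * n / M if M else 0.0,
        p=hypergeom_tail_gt(M, K, n, r),
    )


def enrich_gene_sets(
    selection: Sequence[str],
    universe: Sequence[str],
    sets,
) -> pd.DataFrame:
    """Rank-based over-representation test of gene sets in a significant list.

    For each set, with universe size M, significant-list size K, set size
    within the universe n and significant set members r, the set's P value is
    the strictly-greater tail P(X > r).  Sets with no member in the universe
    are skipped (and logged); results are sorted by P with BH q values
    appended.

    Parameters
    ----------
    selection : the regression-significant genes (subset of ``universe``).
    universe : all analyzed genes (gene level, after probe collapsing).
    sets : a GeneSetCollection (or any iterable of (name, (desc, members))).
    """
    import logging

    log = logging.getLogger(__name__)
    uni = set(universe)
    sel = set(selection)
    if not sel <= uni:
        raise ValueError(
            f"selection has {len(sel - uni)} genes outside the universe"
        )
    M, K = len(uni), len(sel)
    rows = []
    for name, (_desc, members) in sets:
        in_uni = uni.intersection(members)
        n = len(in_uni)
        if n == 0:
            log.info("gene set %r has no member in the universe; skipped", name)
            continue
        r = len(sel.intersection(in_uni))
        rows.append((name, n, r, hypergeom_tail_gt(M, K, n, r)))
    out = pd.DataFrame(rows, columns=["set", "n", "r", "p"]).set_index("set")
    if len(out):
        out = out.sort_values("p", kind="stable")
        out["q"] = bh_fdr(out["p"].to_numpy())
    else:
        out["q"] = pd.Series(dtype=float)
    return out
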