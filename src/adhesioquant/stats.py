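"""Robust outlier identification (ROUT) and group summaries.

ROUT combines a robust fit with a false-discovery-rate test on residuals.
For univariate group measurements the model is a constant, so the robust fit
reduces to a Lorentzian-loss M-estimate of the center:

1. center: iteratively reweighted mean with Lorentzian weights
   ``w = 1 / (1 + (res / RSDR)^2)``, initialized at the median;
2. scale: RSDR, the robust standard deviation of residuals — the 68.27th
   percentile of absolute residuals times ``n / (n - K)`` (K = 1 fitted
   parameter);
3. detection: residuals are tested largest-first with t statistics
   ``|res| / RSDR`` against stepwise two-sided levels
   ``alpha_i = Q * (n - i + 1) / n``; flagging stops at the first
   non-significant rank, so the flag set is always a suffix of the
   residual-magnitude ordering.

Q is the maximum desired false-discovery rate among flagged points
(default 1%).  Standard hypothesis tests (normality batteries, omnibus
comparisons) are delegated to scipy and are not re-implemented here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = ["RoutParams", "OutlierResult", "rout_outliers", "group_summary"]


@dataclass(frozen=True)
class RoutParams:
    Q: float = 0.01
    max_fraction_removed: float = 0.3

    def __post_init__(self) -> None:
        if not (0 < self.Q < 1):
            raise ValueError("Q must lie in (0, 1)")
        if not (0 < self.max_fraction_removed <= 1):
            raise ValueError("max_fraction_removed must lie in (0, 1]")


@dataclass
class OutlierResult:
    kept: np.ndarray
    flagged: np.ndarray
    flagged_idx: np.ndarray     # indices into the input array
    center: float
    rsdr: float

    @property
    def n_flagged(self) -> int:
        return len(self.flagged_idx)


def _rsdr(residuals: np.ndarray, n_params: int = 1) -> float:
    """Robust SD of residuals: P68.27 of |res|, df-corrected by n/(n-K)."""
    n = len(residuals)
    if n <= n_params:
        return 0.0
    p68 = float(np.percentile(np.abs(residuals), 68.27))
    return p68 * n / (n - n_params)


def _robust_center(x: np.ndarray, max_iter: int = 200, tol: float = 1e-12) -> float:
    """Lorentzian-loss M-estimate of location, median-initialized."""
    c = float(np.median(x))
    scale0 = float(np.median(np.abs(x - c)))
    if scale0 == 0:
        return c
    for _ in range(max_iter):
        res = x - c
        s = _rsdr(res)
        if s == 0:
            break
        w = 1.0 / (1.0 + (res / s) ** 2)
        c_new = float(np.sum(w * x) / np.sum(w))
        if abs(c_new - c) <= tol * max(scale0, abs(c)):
            c = c_new
            break
        c = c_new
    return c


def rout_outliers(values, params: RoutParams | None = None) -> OutlierResult:
    """Identify outliers in a univariate sample with the ROUT procedure.

    Returns kept and flagged values; with fewer than 3 finite values or a
    degenerate (all-identical) sample, nothing is flagged.  Never flags more
    than ``max_fraction_removed`` of the sample.
    """
    params = params or RoutParams()
    x = np.asarray(values, dtype=float)
    if x.ndim != 1:
        x = x.ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    n = len(x)
    empty = np.array([], dtype=int)
    if n < 3:
        warnings.warn("fewer than 3 values; outlier removal skipped", stacklevel=2)
        return OutlierResult(x.copy(), x[empty], empty,
                             float(np.median(x)) if n else math.nan, 0.0)
    center = _robust_center(x)
    res = x - center
    rsdr = _rsdr(res)
    if rsdr == 0:
        return OutlierResult(x.copy(), x[empty], empty, center, 0.0)

    order = np.argsort(-np.abs(res), kind="stable")  # largest residual first
    tvals = np.abs(res[order]) / rsdr
    pvals = 2.0 * sps.t.sf(tvals, df=n - 1)
    max_flag = int(math.floor(params.max_fraction_removed * n))
    n_flag = 0
    for i in range(n):
        if i >= max_flag:
            break
        alpha_i = params.Q * (n - i) / n  # i is 0-based: rank 1 gets alpha = Q
        if pvals[i] < alpha_i:
            n_flag = i + 1
        else:
            break
    flagged_idx = np.sort(order[:n_flag])
    keep_mask = np.ones(n, dtype=bool)
    keep_mask[flagged_idx] = False
    return OutlierResult(x[keep_mask], x[flagged_idx], flagged_idx, center, rsdr)


def group_summary(
    groups: dict[str, "np.ndarray | list[float]"],
    rout: RoutParams | None = None,
    zero_exempt_fraction: float = 0.5,
) -> pd.DataFrame:
    """Per-group n, mean and SEM, with an optional ROUT pass per group.

    When ``rout`` is given, each group is outlier-filtered first — except
    groups in which more than ``zero_exempt_fraction`` of values are exactly
    zero, which are never filtered (a heavy spike at zero is structure, not
    contamination).  SEM is SD/sqrt(n) (sample SD); a single-value group
    reports SEM as missing.
    """
    rows = []
    for name, vals in groups.items():
        x = np.asarray(vals, dtype=float)
        if x.size == 0:
            raise ValueError(f"group '{name}' is empty")
        n_removed = 0
        if rout is not None:
            frac_zero = float(np.mean(x == 0))
            if frac_zero <= zero_exempt_fraction and x.size >= 3:
                result = rout_outliers(x, rout)
                n_removed = result.n_flagged
                x = result.kept
        n = int(x.size)
        mean = float(x.mean())
        sem = float(x.std(ddof=1) / math.sqrt(n)) if n > 1 else math.nan
        rows.append((name, n, mean, sem, n_removed))
    return pd.DataFrame(rows, columns=["group", "n", "mean", "sem", "n_outliers_removed"])
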