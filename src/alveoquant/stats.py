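"""Statistical layer of the decremental-PEEP analysis.

Per response (ASdim, ASnum) and ROI, an ordinary least-squares regression of
the pooled per-slice observations on the applied PEEP tests whether the
metric tracks the distending pressure.  Regression pairs are compared with
an extra-sum-of-squares F-test, paired continuous variables with the
Wilcoxon signed-rank test, and families of comparisons are Bonferroni
corrected at a family-wise alpha of 0.05.

The regressor defaults to the *measured* end-expiratory pressure ladder
(12.4, 9.6, 6.8, 4.1, 1.1 cmH2O) rather than the nominal dial settings
(12, 9, 6, 3, 0): measured pressures are what the parenchyma actually saw,
and the reference subpleural ASdim slope of 0.41 voxel/cmH2O is recovered
under this reading.  Both options are exposed.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

log = logging.getLogger(__name__)

RESPONSE_COLUMN = {"ASdim": "asdim_vox", "ASnum": "asnum_per_mm3"}


@dataclass(frozen=True)
class StudyConfig:
    """Defaults of the decremental-PEEP study design."""

    peep_nominal: tuple[float, ...] = (12.0, 9.0, 6.0, 3.0, 0.0)
    peep_measured: tuple[float, ...] = (12.4, 9.6, 6.8, 4.1, 1.1)
    alpha: float = 0.05
    regressor: str = "measured"  # or "nominal"
    n_slices: int = 40
    voxel_side_um: float = 47.7

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if len(self.peep_nominal) != len(self.peep_measured):
            raise ValueError("nominal and measured PEEP ladders differ in length")
        if self.regressor not in ("measured", "nominal"):
            raise ValueError("regressor must be 'measured' or 'nominal'")

    @property
    def regressor_column(self) -> str:
        return "peep_measured" if self.regressor == "measured" else "peep_nominal"


@dataclass
class RegressionResult:
    """One fitted PEEP regression: the machine twin of a results-table row."""

    response: str
    roi: str
    m: float  # slope, response units per cmH2O
    k: float  # intercept, response units
    r_squared: float
    p_value: float  # two-sided p of the slope
    n: int
    n_dropped: int = 0  # observations with undefined response
    m_stderr: float = float("nan")  # standard error of the slope


def _extract_xy(
    table: pd.DataFrame, response: str, roi: str, regressor: str
) -> tuple[np.ndarray, np.ndarray, int]:
    if response not in RESPONSE_COLUMN:
        raise ValueError(f"unknown response {response!r}")
    xcol = "peep_measured" if regressor == "measured" else "peep_nominal"
    sub = table[table["roi"] == roi]
    y = sub[RESPONSE_COLUMN[response]].to_numpy(dtype=float)
    x = sub[xcol].to_numpy(dtype=float)
    ok = np.isfinite(y) & np.isfinite(x)
    return x[ok], y[ok], int(len(y) - ok.sum())


def fit_peep_regression(
    table: pd.DataFrame,
    response: str,
    roi: str,
    regressor: str = "measured",
) -> RegressionResult:
    """OLS of one response on the applied PEEP over pooled per-slice data.

    Observations with undefined response (no airspace counted) are dropped
    and their number logged and reported.
    """
    x, y, n_drop = _extract_xy(table, response, roi, regressor)
    if n_drop:
        log.info("%s/%s: dropped %d observations with undefined response", response, roi, n_drop)
    if len(x) < 3:
        raise ValueError("need at least 3 observations with a defined response")
    if np.ptp(x) == 0:
        raise ValueError("all observations share one PEEP value; no regressor variance")
    if np.ptp(y) == 0:
        # perfectly constant response (e.g. a fully de-aerated stack):
        # a flat line fits exactly and carries no evidence of a trend
        return RegressionResult(
            response=response, roi=roi, m=0.0, k=float(y[0]), r_squared=0.0,
            p_value=1.0, n=int(len(x)), n_dropped=n_drop, m_stderr=0.0,
        )
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        response=response,
        roi=roi,
        m=float(fit.params[1]),
        k=float(fit.params[0]),
        r_squared=float(fit.rsquared),
        p_value=float(fit.pvalues[1]),
        n=int(len(x)),
        n_dropped=n_drop,
        m_stderr=float(fit.bse[1]),
    )


def _rss_line(x: np.ndarray, y: np.ndarray) -> float:
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    return float(fit.ssr)


def compare_regressions_ftest(
    fit_a: RegressionResult,
    fit_b: RegressionResult,
    table_a: pd.DataFrame,
    table_b: pd.DataFrame,
    alpha: float = 0.05,
    require_significant: bool = True,
) -> tuple[float, float]:
    """Extra-sum-of-squares F-test: do two PEEP regressions share one line?

    The reduced model fits a common (slope, intercept) to the concatenated
    data; the full model fits each dataset its own line.  Only regressions
    that are themselves significant are meaningfully comparable, so by
    default both inputs must have slope p <= alpha.
    """
    if require_significant and (fit_a.p_value > alpha or fit_b.p_value > alpha):
        raise ValueError("both regressions must be significant to be compared")
    regressor = "measured"
    xa, ya, _ = _extract_xy(table_a, fit_a.response, fit_a.roi, regressor)
    xb, yb, _ = _extract_xy(table_b, fit_b.response, fit_b.roi, regressor)
    n = len(xa) + len(xb)
    if n - 4 < 1:
        raise ValueError("insufficient degrees of freedom for the F-test")
    rss_full = _rss_line(xa, ya) + _rss_line(xb, yb)
    rss_common = _rss_line(np.r_[xa, xb], np.r_[ya, yb])
    if rss_full <= 0:
        # both lines exact: any difference in the common fit is infinite F
        f_stat = np.inf if rss_common > 1e-12 else 0.0
    else:
        f_stat = ((rss_common - rss_full) / 2.0) / (rss_full / (n - 4))
        f_stat = max(f_stat, 0.0)
    p = float(sps.f.sf(f_stat, 2, n - 4)) if np.isfinite(f_stat) else 0.0
    return float(f_stat), p


@dataclass
class WilcoxonResult:
    p_value: float
    statistic: float  # W+: rank sum of positive differences
    n_used: int
    n_zero: int
    degenerate: bool = False
    method: str = "exact"


def wilcoxon_signed_rank(pairs, exact_max_n: int = 15) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired observations.

    Zero differences are dropped (and counted).  For up to ``exact_max_n``
    non-zero pairs the p-value is computed from the exhaustive 2^n sign-flip
    permutation distribution of the positive-rank sum (midranks, so ties are
    handled exactly); above that, a normal approximation whose variance uses
    the midrank sum-of-squares (tie-corrected) is used.  If every difference
    is zero the test is degenerate and p = 1.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or len(arr) < 1:
        raise ValueError("pairs must be an (n, 2) array with n >= 1")
    d = arr[:, 0] - arr[:, 1]
    nz = d != 0
    n_zero = int((~nz).sum())
    d = d[nz]
    n = len(d)
    if n == 0:
        return WilcoxonResult(1.0, 0.0, 0, n_zero, degenerate=True, method="degenerate")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    mu = ranks.sum() / 2.0
    if n <= exact_max_n:
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        w_all = signs @ ranks
        p = float(np.mean(np.abs(w_all - mu) >= abs(w_pos - mu) - 1e-9))
        return WilcoxonResult(min(p, 1.0), w_pos, n, n_zero, method="exact")
    sigma = np.sqrt((ranks**2).sum() / 4.0)
    z = (w_pos - mu) / sigma
    p = float(2.0 * sps.norm.sf(abs(z)))
    return WilcoxonResult(min(p, 1.0), w_pos, n, n_zero, method="normal")


@dataclass
class BonferroniResult:
    threshold: float
    decisions: list[bool] = field(default_factory=list)
    m: int = 0


def bonferroni(p_values, alpha: float = 0.05) -> BonferroniResult:
    """Bonferroni control of a family of m tests.

    The family-wise threshold is ``alpha / m``; a test is declared
    significant when its p-value is less than or *equal to* the threshold
    (boundary cases reject).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if ((p < 0) | (p > 1) | ~np.isfinite(p)).any():
        raise ValueError("p-values must lie in [0, 1]")
    thr = alpha / p.size
    return BonferroniResult(
        threshold=thr, decisions=[bool(v) for v in p <= thr], m=int(p.size)
    )
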