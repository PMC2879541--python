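"""Critical-sample-size (N_crit) goodness of fit and diagnostic plot surfaces.

N_crit rescales the chi-square goodness-of-fit statistic into the sample size
at which a lack of fit of the observed magnitude would become detectable at
the 5% level:

    N_crit = chi2_{k-m-1; 0.95} / D,      D = sum_i (r_i - p_i)^2 / p_i,

with k bins, m = 3 estimated parameters, r_i the sample proportion and p_i
the fitted skew-Laplace probability of bin i.  Large N_crit means good fit;
the working classification is

    N_crit > 900        excellent
    500 < N_crit <= 900 satisfactory
    250 < N_crit <= 500 acceptable
    0 <= N_crit <= 250  unacceptable

Binning is standardized to 40 intervals, as homogeneous as possible:
interior edges sit at the i/40 empirical quantiles and the outer bins are
open-ended, so every fitted bin probability is positive and sums to one.
Duplicate edges from heavily tied (quantized-channel) data are merged and
the realized bin count recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Any

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy import stats

from .distributions import SkewLaplaceParams, sl_cdf, sl_loglinear, sl_quantile
from .fitting import FitResult

__all__ = [
    "BinnedSample",
    "GofResult",
    "DEFAULT_BINS",
    "DEFAULT_THRESHOLDS",
    "N_PARAMS",
    "bin_sample",
    "critical_sample_size",
    "n_crit",
    "classify_fit",
    "qq_surface",
    "logfreq_surface",
]

DEFAULT_BINS = 40
#: Number of estimated skew-Laplace parameters (mu, alpha, beta).
N_PARAMS = 3
#: Upper bounds of the unacceptable / acceptable / satisfactory classes.
DEFAULT_THRESHOLDS = (250.0, 500.0, 900.0)

FIT_CLASSES = ("excellent", "satisfactory", "acceptable", "unacceptable")


@dataclass(frozen=True)
class BinnedSample:
    """Equal-count (or equal-width) binning of one sample.

    ``edges`` are the k-1 interior boundaries; the outermost bins extend to
    -inf and +inf.  ``merged`` is True when duplicate quantile edges were
    collapsed, reducing k below the requested count.
    """

    edges: NDArray[np.float64]
    counts: NDArray[np.int64]
    proportions: NDArray[np.float64]
    n: int
    requested_k: int
    merged: bool = False

    @property
    def k(self) -> int:
        return int(self.counts.size)


@dataclass(frozen=True)
class GofResult:
    """N_crit verdict for one fitted sample on one scale."""

    n_crit: float
    discrepancy: float
    chi2_crit: float
    df: int
    k: int
    m: int
    fit_class: str
    scale: str

    def to_dict(self) -> dict[str, Any]:
        return {
            "n_crit": "inf" if np.isinf(self.n_crit) else float(self.n_crit),
            "discrepancy": float(self.discrepancy),
            "chi2_crit": float(self.chi2_crit),
            "df": int(self.df),
            "k": int(self.k),
            "m": int(self.m),
            "fit_class": self.fit_class,
            "scale": self.scale,
        }


def bin_sample(data: ArrayLike, k: int = DEFAULT_BINS, *, equal_width: bool = False) -> BinnedSample:
    """Bin a sample into ``k`` intervals, as homogeneous as possible.

    Default dialect places interior edges at the i/k empirical quantiles so
    counts are near-equal; ``equal_width=True`` instead splits the data range
    evenly (instrument-channel style).  Outer bins are open-ended either way.
    """
    x = np.asarray(data, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("data must be finite")
    n = x.size
    if n < k:
        raise ValueError(f"need at least k={k} events, got {n}")
    if equal_width:
        edges = np.linspace(x.min(), x.max(), k + 1)[1:-1]
    else:
        edges = np.quantile(x, np.arange(1, k) / k)
    uniq = np.unique(edges)
    merged = uniq.size < edges.size
    # bin i is (e_{i-1}, e_i]; searchsorted(side="left") sends x == e_i to bin i
    idx = np.searchsorted(uniq, x, side="left")
    counts = np.bincount(idx, minlength=uniq.size + 1).astype(np.int64)
    return BinnedSample(
        edges=uniq,
        counts=counts,
        proportions=counts / n,
        n=int(n),
        requested_k=int(k),
        merged=merged,
    )


def critical_sample_size(discrepancy: float, k: int, m: int = N_PARAMS) -> tuple[float, float, int]:
    """(N_crit, chi-square critical value, df) for a given binned discrepancy.

    df = k - m - 1 and the critical value is the 0.95 chi-square quantile.
    A zero discrepancy (perfect fit) yields N_crit = +inf.
    """
    df = int(k) - int(m) - 1
    if df < 1:
        raise ValueError(f"k={k} leaves no degrees of freedom with m={m}")
    chi2_crit = float(stats.chi2.ppf(0.95, df))
    if discrepancy < 0:
        raise ValueError("discrepancy must be >= 0")
    ncrit = np.inf if discrepancy == 0.0 else chi2_crit / discrepancy
    return float(ncrit), chi2_crit, df


def n_crit(binned: BinnedSample, fit: FitResult,
           thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS) -> GofResult:
    """N_crit of a binned sample against its fitted skew-Laplace law.

    Bin probabilities come from the fitted CDF at the interior edges, with 0
    and 1 at the open ends, so they are positive and sum to one exactly.
    """
    F = np.asarray(sl_cdf(binned.edges, fit.params), dtype=float)
    p = np.diff(np.concatenate(([0.0], F, [1.0])))
    if np.any(p <= 0.0):
        raise ValueError("fitted bin probability vanished; check edges/params")
    r = binned.proportions
    D = float(np.sum((r - p) ** 2 / p))
    ncrit, chi2_crit, df = critical_sample_size(D, binned.k, N_PARAMS)
    return GofResult(
        n_crit=ncrit,
        discrepancy=D,
        chi2_crit=chi2_crit,
        df=df,
        k=binned.k,
        m=N_PARAMS,
        fit_class=classify_fit(ncrit, thresholds),
        scale=fit.scale,
    )


def classify_fit(n_crit_value: float,
                 thresholds: tuple[float, float, float] = DEFAULT_THRESHOLDS) -> str:
    """Four-class verdict from an N_crit value.

    Boundaries belong to the lower class: exactly 900 is satisfactory,
    exactly 500 acceptable, exactly 250 unacceptable.
    """
    v = float(n_crit_value)
    if np.isnan(v) or v < 0.0:
        raise ValueError("n_crit must be >= 0")
    t_unacc, t_acc, t_sat = thresholds
    if v > t_sat:
        return "excellent"
    if v > t_acc:
        return "satisfactory"
    if v > t_unacc:
        return "acceptable"
    return "unacceptable"


def qq_surface(data: ArrayLike, fit: FitResult) -> NDArray[np.float64]:
    """Quantile-quantile pairs (empirical quantile, fitted model quantile).

    Uses plotting positions p_j = (j - 0.5)/n.  When the model holds the
    points hug the identity line.  Pass data already on the fitting scale
    (ln-transformed for a log-scale fit).
    """
    x = np.sort(np.asarray(data, dtype=float).ravel())
    n = x.size
    p = (np.arange(1, n + 1) - 0.5) / n
    model_q = np.asarray(sl_quantile(p, fit.params))
    return np.column_stack([x, model_q])


def logfreq_surface(binned: BinnedSample, fit: FitResult) -> dict[str, Any]:
    """Log-frequency plot surface: ln density of interior bins plus the two fitted lines.

    Open-ended outer bins have no midpoint and are excluded; interior bins
    with zero count are skipped and flagged in ``skipped_empty``.
    Returns midpoints, ln(proportion / width), the (intercept, slope) pairs
    of the fitted left/right lines, and the skipped-bin flag.
    """
    e = binned.edges
    widths = np.diff(e)
    mids = 0.5 * (e[:-1] + e[1:])
    props = binned.proportions[1:-1]
    keep = props > 0.0
    left_line, right_line = sl_loglinear(fit.params)
    return {
        "midpoints": mids[keep],
        "log_density": np.log(props[keep] / widths[keep]),
        "left_line": left_line,
        "right_line": right_line,
        "skipped_empty": bool(np.any(~keep)),
    }
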