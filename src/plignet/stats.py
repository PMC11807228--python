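"""Evaluation statistics for affinity prediction.

Per-series metrics (Pearson correlation, Kendall's tau-a, RMSE), weighted
means over congeneric series, bias-corrected and accelerated (BCa)
bootstrap confidence intervals, a paired bootstrap significance test for
comparing two methods on the same complexes, and pK <-> free-energy
conversions.

Kendall's tau is the tau-a variant: (n_c - n_d) / (n(n-1)/2), where tied
pairs count as neither concordant nor discordant but remain in the
denominator.  The paired bootstrap test resamples complexes with the same
indices for both methods, computes the per-draw metric difference
Delta_rho_b, and reports P as the fraction of draws with Delta_rho_b < 0
(P < 0.05 significant).  Free energies use Delta_G = RT ln K with
R = 1.987e-3 kcal/(K mol) and T = 297 K, i.e. Delta_G = -ln(10) RT pK.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
from scipy import stats as sp_stats

R_GAS_KCAL = 1.987e-3  # kcal / (K mol)
TEMPERATURE_K = 297.0
_LN10_RT = np.log(10.0) * R_GAS_KCAL * TEMPERATURE_K


class UndefinedMetricError(ValueError):
    """A metric has no defined value on this input (e.g. zero variance)."""


@dataclass
class SeriesPredictions:
    """Paired experimental (x) and predicted (y) affinities for one series."""

    series_id: str
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-d arrays of equal length")

    @property
    def n(self) -> int:
        return self.x.size


@dataclass
class MetricReport:
    metric: str
    value: float
    ci_low: float
    ci_high: float
    n: int


# ---------------------------------------------------------------------------
# point metrics
# ---------------------------------------------------------------------------

def pcc(x, y) -> float:
    """Pearson product-moment correlation; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 2:
        raise UndefinedMetricError("PCC needs at least two paired values")
    dx = x - x.mean()
    dy = y - y.mean()
    denom = np.sqrt((dx * dx).sum() * (dy * dy).sum())
    if denom == 0:
        raise UndefinedMetricError("PCC undefined: zero variance")
    return float((dx * dy).sum() / denom)


def kendall_tau(x, y) -> float:
    """Kendall's tau-a: (concordant - discordant) / all C(n,2) pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n or n < 2:
        raise UndefinedMetricError("Kendall tau needs at least two pairs")
    i, j = np.triu_indices(n, k=1)
    s = np.sign(x[j] - x[i]) * np.sign(y[j] - y[i])
    return float(s.sum() / (0.5 * n * (n - 1)))


def rmse(x, y) -> float:
    """Root mean square error, in the units of the inputs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or x.shape != y.shape:
        raise ValueError("rmse needs equal-length non-empty inputs")
    return float(np.sqrt(np.mean((y - x) ** 2)))


def weighted_mean_metric(
    series_list: Sequence[SeriesPredictions],
    metric: Callable[[np.ndarray, np.ndarray], float],
) -> float:
    """Mean of a per-series metric weighted by relative series size.

    Series on which the metric is undefined are excluded with a warning and
    the weights are renormalised over the remainder.
    """
    values, weights = [], []
    for s in series_list:
        try:
            values.append(metric(s.x, s.y))
            weights.append(s.n)
        except UndefinedMetricError:
            warnings.warn(
                f"metric undefined for series {s.series_id!r}; excluded"
            )
    if not values:
        raise UndefinedMetricError("metric undefined for every series")
    w = np.array(weights, dtype=float)
    return float(np.dot(np.array(values), w / w.sum()))


# ---------------------------------------------------------------------------
# bootstrap machinery
# ---------------------------------------------------------------------------

def bca_ci(
    x,
    y,
    metric: Callable[[np.ndarray, np.ndarray], float] = pcc,
    B: int = 10_000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> tuple[float, float]:
    """95% (by default) BCa bootstrap interval for a paired-sample metric.

    Pairs (x_i, y_i) are resampled together.  Falls back to the plain
    percentile interval (with a warning) when the bootstrap distribution is
    degenerate and the BCa correction is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2:
        raise UndefinedMetricError("bootstrap CI needs n >= 2")
    rng = np.random.default_rng(seed)

    def stat(xs, ys):
        try:
            return metric(xs, ys)
        except UndefinedMetricError:
            return np.nan

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sp_stats.bootstrap(
                (x, y), stat, paired=True, vectorized=False,
                n_resamples=B, confidence_level=level, method="BCa",
                random_state=rng,
            )
            lo, hi = float(res.confidence_interval.low), float(
                res.confidence_interval.high
            )
        except Exception:
            lo, hi = np.nan, np.nan
    if not (np.isfinite(lo) and np.isfinite(hi)):
        warnings.warn(
            "degenerate bootstrap distribution; falling back to percentile CI"
        )
        res = sp_stats.bootstrap(
            (x, y), stat, paired=True, vectorized=False,
            n_resamples=B, confidence_level=level, method="percentile",
            random_state=np.random.default_rng(seed),
        )
        lo, hi = float(res.confidence_interval.low), float(
            res.confidence_interval.high
        )
        if not np.isfinite(lo) or not np.isfinite(hi):
            value = stat(x, y)
            lo = hi = float(value)
    return lo, hi


def metric_report(
    x, y,
    metric: Callable[[np.ndarray, np.ndarray], float] = pcc,
    name: str = "pcc",
    B: int = 10_000,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> MetricReport:
    lo, hi = bca_ci(x, y, metric, B=B, level=level, seed=seed)
    return MetricReport(name, metric(np.asarray(x), np.asarray(y)), lo, hi,
                        n=len(np.asarray(x)))


@dataclass
class PairedTestResult:
    p_value: float
    fraction_negative: float
    degenerate: bool
    B: int
    n_undefined: int
    seed: Optional[int] = None


def paired_bootstrap_test(
    y1,
    y2,
    x,
    metric: Callable[[np.ndarray, np.ndarray], float] = pcc,
    B: int = 10_000,
    seed: Optional[int] = None,
) -> PairedTestResult:
    """One-sided paired bootstrap test of H0: metric(M1) <= metric(M2).

    The same resampled complex indices are applied to both methods in each
    draw b; Delta_rho_b = rho_b(M1) - rho_b(M2); P is the fraction of draws
    with Delta_rho_b < 0.  When every draw gives Delta_rho_b = 0 (e.g.
    identical predictions) the test is flagged degenerate and P is reported
    as 1.0, with the literal fraction-negative preserved in the result.
    Aborts if the metric is undefined in more than 10% of draws.
    """
    x = np.asarray(x, dtype=float)
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    n = x.size
    if y1.size != n or y2.size != n or n < 2:
        raise ValueError("paired test needs equal-length inputs, n >= 2")
    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    n_undef = 0
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            deltas[b] = metric(x[idx], y1[idx]) - metric(x[idx], y2[idx])
        except UndefinedMetricError:
            deltas[b] = np.nan
            n_undef += 1
    if n_undef > 0.1 * B:
        raise RuntimeError(
            f"metric undefined in {n_undef}/{B} bootstrap draws; "
            "input too degenerate for this test"
        )
    valid = deltas[~np.isnan(deltas)]
    frac_neg = float((valid < 0).sum() / valid.size)
    degenerate = bool(np.all(valid == 0))
    return PairedTestResult(
        p_value=1.0 if degenerate else frac_neg,
        fraction_negative=frac_neg,
        degenerate=degenerate,
        B=B,
        n_undefined=n_undef,
        seed=seed,
    )


def paired_bootstrap_test_weighted(
    series1: Sequence[SeriesPredictions],
    series2: Sequence[SeriesPredictions],
    metric: Callable[[np.ndarray, np.ndarray], float] = pcc,
    B: int = 10_000,
    seed: Optional[int] = None,
) -> PairedTestResult:
    """Paired test on the weighted-mean metric across congeneric series.

    Resampling is within each series (the bootstrap unit is a complex in
    its series); the weighted mean is recomputed per draw with the same
    indices for both methods.
    """
    if len(series1) != len(series2):
        raise ValueError("both methods need the same series")
    for s1, s2 in zip(series1, series2):
        if s1.n != s2.n or not np.allclose(s1.x, s2.x):
            raise ValueError("series must pair the same experimental values")
    rng = np.random.default_rng(seed)
    deltas = np.empty(B)
    n_undef = 0
    for b in range(B):
        idx = [rng.integers(0, s.n, size=s.n) for s in series1]
        try:
            m1 = weighted_mean_metric(
                [SeriesPredictions(s.series_id, s.x[i], s.y[i])
                 for s, i in zip(series1, idx)], metric)
            m2 = weighted_mean_metric(
                [SeriesPredictions(s.series_id, s.x[i], s.y[i])
                 for s, i in zip(series2, idx)], metric)
            deltas[b] = m1 - m2
        except UndefinedMetricError:
            deltas[b] = np.nan
            n_undef += 1
    if n_undef > 0.1 * B:
        raise RuntimeError(
            f"metric undefined in {n_undef}/{B} bootstrap draws"
        )
    valid = deltas[~np.isnan(deltas)]
    frac_neg = float((valid < 0).sum() / valid.size)
    degenerate = bool(np.all(valid == 0))
    return PairedTestResult(
        p_value=1.0 if degenerate else frac_neg,
        fraction_negative=frac_neg,
        degenerate=degenerate,
        B=B,
        n_undefined=n_undef,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# unit conversions
# ---------------------------------------------------------------------------

def k_to_dg(K) -> float:
    """Delta_G = RT ln K (K in molar, Delta_G in kcal/mol)."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("binding constant must be positive")
    out = R_GAS_KCAL * TEMPERATURE_K * np.log(K)
    return float(out) if out.ndim == 0 else out


def dg_to_pk(dg) -> float:
    """pK = -(1/ln 10) Delta_G / (RT)."""
    out = -np.asarray(dg, dtype=float) / _LN10_RT
    return float(out) if out.ndim == 0 else out


def pk_to_dg(pk) -> float:
    """Delta_G = -ln(10) RT pK."""
    out = -_LN10_RT * np.asarray(pk, dtype=float)
    return float(out) if out.ndim == 0 else out


def k_to_pk(K) -> float:
    """pK = -log10 K (K in molar)."""
    K = np.asarray(K, dtype=float)
    if np.any(K <= 0):
        raise ValueError("binding constant must be positive")
    out = -np.log10(K)
    return float(out) if out.ndim == 0 else out


_CONVERSIONS = {
    "k_to_dg": k_to_dg,
    "dg_to_pk": dg_to_pk,
    "pk_to_dg": pk_to_dg,
    "k_to_pk": k_to_pk,
}


def convert_affinity(value, direction: str):
    """Dispatch the free-energy/pK conversions by name."""
    try:
        fn = _CONVERSIONS[direction]
    except KeyError:
        raise ValueError(
            f"unknown direction {direction!r}; one of {sorted(_CONVERSIONS)}"
        ) from None
    return fn(value)
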