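"""Power-law estimation of the radius scaling exponent from diameter lists.

The branch-count relation n = (r0/r)**alpha implies that the diameter of a
randomly selected branch has tail function P(d >= x) = (xm/x)**alpha above
a cutoff xm.  To suppress within-scale noise the data are binned
logarithmically by powers of a base lambda (default 2): diameter d falls in
bin k = floor(log_lambda(d/xm)).  Integrating the tail over bin k gives a
geometric probability mass function on the bin index,

    Pr(k) = (1 - lambda**(-alpha)) * lambda**(-alpha*k),

whose exponent is the same alpha as the tail slope — the convention used
throughout this package is the *cumulative*-distribution exponent, which is
one less than the density exponent.  Maximizing the binned likelihood has
the closed form

    alpha_hat = ln(1 + N/S) / ln(lambda),   N = total count, S = sum k*n_k.

Data below xm are excluded: small diameters are unreliable (measurement
error, or censorship such as an artist's choice not to paint a branch) and
their curvature on the log-log tail plot biases the fit.  Confidence
intervals come from a nonparametric bootstrap over the retained diameters.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .samples import DiameterSample

__all__ = [
    "LogBinnedCounts",
    "PowerLawFit",
    "TailCurve",
    "ThresholdDiagnostic",
    "InsufficientDataError",
    "DegenerateSampleError",
    "log_bin",
    "fit_alpha",
    "bootstrap_ci",
    "fit_power_law",
    "tail_curve",
    "tail_slope",
    "threshold_diagnostic",
    "choose_xm",
]

log = logging.getLogger(__name__)

# relative guard so values intended to sit on a bin boundary, but perturbed
# by float arithmetic, land in the upper bin as the half-open convention says
_BOUNDARY_EPS = 1e-12


class InsufficientDataError(ValueError):
    """No usable observations remain after the cutoff."""


class DegenerateSampleError(ValueError):
    """All retained diameters fall in the first bin; alpha is unbounded."""


@dataclass(frozen=True)
class LogBinnedCounts:
    """Counts of diameters in logarithmic bins [xm*lambda^k, xm*lambda^(k+1))."""

    xm: float
    lambda_base: float
    counts: dict[int, int]
    n_excluded_below_xm: int

    @property
    def n_used(self) -> int:
        return sum(self.counts.values())

    @property
    def index_weight(self) -> int:
        """S = sum over observations of their bin index k."""
        return sum(k * c for k, c in self.counts.items())


@dataclass(frozen=True)
class PowerLawFit:
    """Fitted cumulative-distribution exponent with its provenance."""

    alpha_hat: float
    xm: float
    lambda_base: float
    n_used: int
    n_excluded: int
    log_likelihood: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float | None = None

    def __post_init__(self) -> None:
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.alpha_hat <= self.ci_high):
                raise ValueError("confidence interval must bracket alpha_hat")


@dataclass(frozen=True)
class TailCurve:
    """Exceedance curve: percentage of the sample >= d at each distinct d."""

    diameters: np.ndarray
    percentages: np.ndarray

    @property
    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.diameters.tolist(), self.percentages.tolist()))


@dataclass(frozen=True)
class ThresholdDiagnostic:
    """Slope-match check of the cutoff: tail slope at xm versus -alpha_hat."""

    available: bool
    local_slope: float | None
    alpha_hat: float
    mismatch: float | None
    flagged: bool
    max_mismatch_ratio: float


def _bin_indices(diameters: np.ndarray, xm: float, lambda_base: float) -> np.ndarray:
    """Bin index for every diameter; negative indices mean below the cutoff."""
    t = np.log(diameters / xm) / math.log(lambda_base)
    return np.floor(t + _BOUNDARY_EPS * np.maximum(1.0, np.abs(t))).astype(np.int64)


def log_bin(sample: DiameterSample, xm: float,
            lambda_base: float = 2.0) -> LogBinnedCounts:
    """Assign diameters >= xm to bins [xm*lambda^k, xm*lambda^(k+1)).

    Boundary values go to the upper bin.  Diameters below xm are counted as
    excluded, not binned.
    """
    if xm <= 0:
        raise ValueError("xm must be positive")
    if lambda_base <= 1:
        raise ValueError("lambda_base must exceed 1")
    k = _bin_indices(sample.diameters, xm, lambda_base)
    kept = k[k >= 0]
    n_excluded = int(k.size - kept.size)
    if kept.size == 0:
        raise InsufficientDataError(
            f"no diameters at or above the cutoff xm={xm!r}")
    values, freq = np.unique(kept, return_counts=True)
    counts = {int(v): int(c) for v, c in zip(values, freq)}
    return LogBinnedCounts(xm=xm, lambda_base=lambda_base, counts=counts,
                           n_excluded_below_xm=n_excluded)


def _alpha_mle(n_total: float, index_weight: float, lambda_base: float) -> float:
    return math.log1p(n_total / index_weight) / math.log(lambda_base)


def binned_log_likelihood(binned: LogBinnedCounts, alpha: float) -> float:
    """Log-likelihood of the geometric bin-index model at a given alpha."""
    lam = binned.lambda_base
    return (binned.n_used * math.log1p(-lam ** (-alpha))
            - alpha * math.log(lam) * binned.index_weight)


def fit_alpha(binned: LogBinnedCounts) -> PowerLawFit:
    """Closed-form maximum-likelihood exponent from log-binned counts.

    Raises :class:`DegenerateSampleError` when every observation sits in
    bin 0, where the likelihood increases without bound in alpha.
    """
    n = binned.n_used
    s = binned.index_weight
    if n == 0:
        raise InsufficientDataError("no binned observations")
    if s == 0:
        raise DegenerateSampleError(
            "all diameters fall within one bin of the cutoff; "
            "alpha is unbounded above")
    alpha_hat = _alpha_mle(n, s, binned.lambda_base)
    return PowerLawFit(alpha_hat=alpha_hat, xm=binned.xm,
                       lambda_base=binned.lambda_base, n_used=n,
                       n_excluded=binned.n_excluded_below_xm,
                       log_likelihood=binned_log_likelihood(binned, alpha_hat))


def bootstrap_ci(sample: DiameterSample, xm: float, lambda_base: float = 2.0,
                 n_boot: int = 10_000, seed: int = 0,
                 level: float = 0.95,
                 max_redraw_rounds: int = 1000) -> tuple[float, float]:
    """Percentile bootstrap interval for the fitted exponent.

    Resamples the diameters at or above xm with replacement (size equal to
    the retained count), refits alpha on each resample, and returns the
    percentile interval at the requested level.  Degenerate resamples with
    all mass in bin 0 are redrawn, up to a capped number of rounds, and the
    redraw count is logged.
    """
    if n_boot < 1000:
        raise ValueError("n_boot must be at least 1000 for a stable interval")
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    k = _bin_indices(sample.diameters, xm, lambda_base)
    k = k[k >= 0]
    if k.size == 0:
        raise InsufficientDataError(f"no diameters at or above xm={xm!r}")
    kvals, freq = np.unique(k, return_counts=True)
    if kvals.size == 1 and kvals[0] == 0:
        raise DegenerateSampleError("sample is degenerate at this cutoff")
    n = int(k.size)
    rng = np.random.Generator(np.random.PCG64(seed))
    probs = freq / n
    # iid resampling of n diameters is equivalent to a multinomial draw over
    # the distinct bin indices, which is what alpha_hat depends on
    table = rng.multinomial(n, probs, size=n_boot)
    s = table @ kvals
    n_degenerate = 0
    for _ in range(max_redraw_rounds):
        bad = s == 0
        n_bad = int(bad.sum())
        if n_bad == 0:
            break
        n_degenerate += n_bad
        s[bad] = rng.multinomial(n, probs, size=n_bad) @ kvals
    else:
        raise DegenerateSampleError(
            "could not draw non-degenerate bootstrap resamples")
    if n_degenerate:
        log.info("bootstrap: redrew %d degenerate resamples", n_degenerate)
    alphas = np.log1p(n / s) / math.log(lambda_base)
    tail = (1.0 - level) / 2.0
    lo, hi = np.quantile(alphas, [tail, 1.0 - tail])
    return float(lo), float(hi)


def fit_power_law(sample: DiameterSample, xm: float, lambda_base: float = 2.0,
                  n_boot: int = 10_000, seed: int = 0,
                  level: float = 0.95) -> PowerLawFit:
    """Bin, fit, and bootstrap in one call; the workhorse of the pipeline."""
    binned = log_bin(sample, xm, lambda_base)
    fit = fit_alpha(binned)
    lo, hi = bootstrap_ci(sample, xm, lambda_base, n_boot=n_boot,
                          seed=seed, level=level)
    # the point estimate can fall marginally outside the percentile interval
    # on tiny samples; widen to keep the bracket invariant
    lo, hi = min(lo, fit.alpha_hat), max(hi, fit.alpha_hat)
    return PowerLawFit(alpha_hat=fit.alpha_hat, xm=xm, lambda_base=lambda_base,
                       n_used=fit.n_used, n_excluded=fit.n_excluded,
                       log_likelihood=fit.log_likelihood,
                       ci_low=lo, ci_high=hi, ci_level=level)


def tail_curve(sample: DiameterSample) -> TailCurve:
    """Exceedance percentages at every distinct diameter, sorted ascending.

    On a log-log plot this curve is approximately straight with slope
    -alpha for self-similar data.
    """
    d = np.sort(np.unique(sample.diameters))
    n = len(sample)
    counts_ge = n - np.searchsorted(np.sort(sample.diameters), d, side="left")
    return TailCurve(diameters=d, percentages=100.0 * counts_ge / n)


def tail_slope(curve: TailCurve, xm: float = 0.0,
               x_max: float = math.inf) -> float:
    """OLS slope of log-percentage against log-diameter over [xm, x_max)."""
    mask = (curve.diameters >= xm * (1.0 - _BOUNDARY_EPS)) \
        & (curve.diameters < x_max)
    x = np.log(curve.diameters[mask])
    y = np.log(curve.percentages[mask])
    if x.size < 2:
        raise InsufficientDataError("need at least two points for a slope")
    return float(np.polyfit(x, y, 1)[0])


def threshold_diagnostic(sample: DiameterSample, fit: PowerLawFit,
                         max_mismatch_ratio: float = 0.25) -> ThresholdDiagnostic:
    """Check that the tail slope just above the cutoff matches -alpha_hat.

    A cutoff that excludes too little of the small-diameter curvature shows
    up as a local slope shallower than the fitted exponent.  The local
    slope is measured on the tail curve within the first bin
    [xm, xm*lambda); with fewer than three distinct diameters there the
    diagnostic is reported unavailable rather than failing.
    """
    curve = tail_curve(sample)
    lo = fit.xm * (1.0 - _BOUNDARY_EPS)
    hi = fit.xm * fit.lambda_base * (1.0 - _BOUNDARY_EPS)
    in_bin = (curve.diameters >= lo) & (curve.diameters < hi)
    if int(in_bin.sum()) < 3:
        return ThresholdDiagnostic(available=False, local_slope=None,
                                   alpha_hat=fit.alpha_hat, mismatch=None,
                                   flagged=False,
                                   max_mismatch_ratio=max_mismatch_ratio)
    slope = tail_slope(curve, xm=fit.xm, x_max=fit.xm * fit.lambda_base)
    mismatch = abs(slope / (-fit.alpha_hat) - 1.0)
    return ThresholdDiagnostic(available=True, local_slope=slope,
                               alpha_hat=fit.alpha_hat, mismatch=mismatch,
                               flagged=mismatch > max_mismatch_ratio,
                               max_mismatch_ratio=max_mismatch_ratio)


def choose_xm(sample: DiameterSample, lambda_base: float = 2.0,
              max_mismatch_ratio: float = 0.25) -> float:
    """Smallest cutoff whose threshold diagnostic passes.

    Convenience only, and non-canonical: the cutoff is properly a
    per-dataset judgement made by inspecting the work and the tail plot.
    Candidates are the distinct observed diameters small enough to leave at
    least one full bin of spread above them.
    """
    d = np.sort(np.unique(sample.diameters))
    for candidate in d:
        if d[-1] < candidate * lambda_base:
            break
        try:
            fit = fit_alpha(log_bin(sample, float(candidate), lambda_base))
        except (InsufficientDataError, DegenerateSampleError):
            continue
        diag = threshold_diagnostic(sample, fit, max_mismatch_ratio)
        if diag.available and not diag.flagged:
            return float(candidate)
    raise InsufficientDataError(
        "no candidate cutoff passes the slope-match diagnostic")
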