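"""Calibration of the decay distributions and the binarization threshold.

Reacted (bit-1) spots show normalized decays modelled as a Gaussian truncated
to [0, 1]; unreacted (bit-0) spots should decay by exactly 0, so their small
positive decays are modelled as a half-normal — fit by mirroring the sample
about zero and fitting a zero-mean Gaussian, whose MLE has the closed form
sigma^2 = mean(x^2).  The binarization threshold is the Bayes decision
boundary between the two fitted densities (or the count-minimizing cut on
labelled samples in empirical mode).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.stats import halfnorm, norm, truncnorm

__all__ = [
    "DecaySample",
    "FitResult",
    "DegenerateSampleError",
    "fit_bit1",
    "fit_bit0",
    "optimal_threshold",
    "empirical_threshold",
    "misclassification_report",
]


class DegenerateSampleError(ValueError):
    """Sample has no usable variation (e.g. all values identical at a bound)."""


@dataclass(frozen=True)
class DecaySample:
    values: np.ndarray
    label: str  # 'bit1' | 'bit0'

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if self.label not in ("bit1", "bit0"):
            raise ValueError("label must be 'bit1' or 'bit0'")
        if np.any(v < 0) or np.any(v > 1):
            raise ValueError("normalized decays must lie in [0, 1]")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FitResult:
    """Fitted decay distribution for one bit class.

    For ``truncated_gaussian`` the (mu, sigma) are the parameters of the
    untruncated parent Gaussian; mu may lie outside [0, 1] when truncation is
    strongly active.  For ``halfnormal_mirrored`` mu is fixed at 0.
    """

    mu: float
    sigma: float
    family: str  # 'truncated_gaussian' | 'halfnormal_mirrored'
    loglik: float
    n: int

    def __post_init__(self):
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")

    def cdf(self, x) -> np.ndarray:
        if self.family == "truncated_gaussian":
            a = (0.0 - self.mu) / self.sigma
            b = (1.0 - self.mu) / self.sigma
            return truncnorm.cdf(x, a, b, loc=self.mu, scale=self.sigma)
        return halfnorm.cdf(x, scale=self.sigma)


def _trunc_negll(theta: np.ndarray, x: np.ndarray) -> float:
    mu, log_sigma = theta
    sigma = np.exp(log_sigma)
    z = (x - mu) / sigma
    mass = norm.cdf((1.0 - mu) / sigma) - norm.cdf((0.0 - mu) / sigma)
    if mass <= 0:
        return np.inf
    return float(-(norm.logpdf(z) - log_sigma - np.log(mass)).sum())


def fit_bit1(sample, tol: float = 1e-10) -> FitResult:
    """Maximum-likelihood truncated-Gaussian fit on [0, 1].

    Quasi-Newton minimization of the exact truncated log-likelihood in
    (mu, log sigma), started from the sample moments.
    """
    x = sample.values if isinstance(sample, DecaySample) else np.asarray(sample, float)
    if len(x) < 10:
        raise ValueError("need at least 10 values to fit")
    if np.std(x) == 0:
        raise DegenerateSampleError("bit-1 sample has zero variance")
    x0 = np.array([x.mean(), np.log(max(x.std(), 1e-3))])
    res = optimize.minimize(
        _trunc_negll, x0, args=(x,), method="L-BFGS-B", tol=tol,
        bounds=[(-2.0, 3.0), (np.log(1e-4), np.log(5.0))],
    )
    mu, sigma = res.x[0], float(np.exp(res.x[1]))
    return FitResult(float(mu), sigma, "truncated_gaussian", float(-res.fun), len(x))


def fit_bit0(sample) -> FitResult:
    """Half-normal fit via the mirrored-sample construction.

    Pooling the sample with its negation and fitting a zero-mean Gaussian
    gives the closed form sigma = sqrt(mean(x^2)), which is also the direct
    half-normal MLE.
    """
    x = sample.values if isinstance(sample, DecaySample) else np.asarray(sample, float)
    if len(x) < 10:
        raise ValueError("need at least 10 values to fit")
    if np.any(x < 0):
        raise ValueError("bit-0 decays must be non-negative")
    sigma = float(np.sqrt(np.mean(x**2)))
    if sigma == 0:
        raise DegenerateSampleError("bit-0 sample is identically zero")
    loglik = float(halfnorm.logpdf(x, scale=sigma).sum())
    return FitResult(0.0, sigma, "halfnormal_mirrored", loglik, len(x))


def optimal_threshold(
    fit1: FitResult, fit0: FitResult, prior1: float = 0.5
) -> float:
    """Threshold minimizing the expected misclassification risk

        prior1 * P(bit1 decay <= t) + (1 - prior1) * P(bit0 decay > t)

    by bounded 1-D minimization over t in (0, 1).
    """
    if not (0 < prior1 < 1):
        raise ValueError("prior1 must lie in (0, 1)")

    def risk(t):
        return prior1 * fit1.cdf(t) + (1 - prior1) * (1.0 - fit0.cdf(t))

    res = optimize.minimize_scalar(risk, bounds=(0.0, 1.0), method="bounded",
                                   options={"xatol": 1e-8})
    return float(res.x)


def empirical_threshold(sample1, sample0) -> float:
    """Count-based threshold: the cut with the fewest false binarized digits.

    Scans midpoints between adjacent pooled sample values; among minimizers
    the widest-gap midpoint is returned, so a perfectly separable pair of
    samples yields the midpoint of the separating gap.
    """
    v1 = np.asarray(sample1.values if isinstance(sample1, DecaySample) else sample1, float)
    v0 = np.asarray(sample0.values if isinstance(sample0, DecaySample) else sample0, float)
    pooled = np.unique(np.concatenate([v0, v1]))
    cuts = (pooled[:-1] + pooled[1:]) / 2.0
    if len(cuts) == 0:
        return float(pooled[0])
    errors = np.array([(v1 <= t).sum() + (v0 > t).sum() for t in cuts])
    gaps = pooled[1:] - pooled[:-1]
    best = errors.min()
    candidates = np.flatnonzero(errors == best)
    return float(cuts[candidates[np.argmax(gaps[candidates])]])


def misclassification_report(
    sample1, sample0, threshold: float
) -> dict[str, float]:
    """False-0 / false-1 counts and rates at a given threshold."""
    v1 = np.asarray(sample1.values if isinstance(sample1, DecaySample) else sample1, float)
    v0 = np.asarray(sample0.values if isinstance(sample0, DecaySample) else sample0, float)
    false0 = int((v1 <= threshold).sum())  # bit 1 read as 0
    false1 = int((v0 > threshold).sum())  # bit 0 read as 1
    return {
        "threshold": float(threshold),
        "false0": false0,
        "false1": false1,
        "n1": len(v1),
        "n0": len(v0),
        "false0_rate": false0 / len(v1) if len(v1) else 0.0,
        "false1_rate": false1 / len(v0) if len(v0) else 0.0,
        "total_errors": false0 + false1,
    }
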