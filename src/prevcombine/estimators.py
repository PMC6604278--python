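"""Prevalence estimators that combine two error-prone case indicators.

Four estimators, all sharing one calling convention: ``fit(X)`` where the
first two columns of ``X`` are the binary case indicators from the two
sources and any remaining columns are person-level covariates (used only by
the latent-class PSSA estimator).  Fitted attributes follow scikit-learn
conventions (``prevalence_``, ``ci_low_``, ``ci_high_``, ``n_``).

* OR  — case if flagged by either source (upper envelope).
* AND — case if flagged by both sources (lower envelope).
* RSSA — each source's observed prevalence is de-biased with the
  Rogan–Gladen correction using externally supplied (published) sensitivity
  and specificity, then the two corrected estimates are averaged.
* PSSA — Bayesian latent-class model fit by Gibbs sampling (see
  :mod:`prevcombine.pssa`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import ndtri
from sklearn.base import BaseEstimator

from .simulate import AccuracySpec, ObservedSources

__all__ = [
    "PrevalenceEstimate",
    "AssumedAccuracyPair",
    "PUBLISHED_AHR_ACCURACY",
    "PUBLISHED_EMR_ACCURACY",
    "default_assumed_accuracy",
    "rogan_gladen",
    "wald_ci",
    "bootstrap_percentile_ci",
    "estimate_source",
    "estimate_or",
    "estimate_and",
    "estimate_rssa",
    "OrEstimator",
    "AndEstimator",
    "RssaEstimator",
]

# Average published sensitivity/specificity of hypertension case definitions
# from Canadian validation studies: administrative health records and
# primary-care electronic medical records.
PUBLISHED_AHR_ACCURACY = AccuracySpec(sensitivity=0.72, specificity=0.95)
PUBLISHED_EMR_ACCURACY = AccuracySpec(sensitivity=0.87, specificity=0.90)


@dataclass(frozen=True)
class AssumedAccuracyPair:
    """Assumed accuracy of each source, as used by the RSSA correction."""

    source1: AccuracySpec = PUBLISHED_AHR_ACCURACY
    source2: AccuracySpec = PUBLISHED_EMR_ACCURACY


def default_assumed_accuracy() -> AssumedAccuracyPair:
    return AssumedAccuracyPair()


@dataclass(frozen=True)
class PrevalenceEstimate:
    method: str
    point: float
    ci_low: float
    ci_high: float
    ci_method: str
    n: int


def _as_sources(X) -> ObservedSources:
    if isinstance(X, ObservedSources):
        return X
    arr = np.asarray(X)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("X must be 2-D with the two source indicators as columns 0-1")
    if arr.shape[0] == 0:
        raise ValueError("empty input")
    return ObservedSources(y1=arr[:, 0], y2=arr[:, 1])


def wald_ci(p: float, n: int, level: float = 0.95) -> tuple[float, float]:
    """Normal-approximation binomial interval, truncated to [0, 1]."""
    if n < 1:
        raise ValueError("n must be at least 1")
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    z = float(ndtri(0.5 + level / 2.0))
    half = z * np.sqrt(p * (1.0 - p) / n)
    return (max(p - half, 0.0), min(p + half, 1.0))


def rogan_gladen(obs_prev: float, acc: AccuracySpec) -> float:
    """(obs + Sp - 1) / (Sn + Sp - 1), truncated to [0, 1].

    De-biases an observed prevalence for known misclassification: the
    numerator removes the false-positive floor 1 - Sp, the denominator
    rescales by the Youden index.
    """
    if acc.youden <= 0:
        raise ValueError("accuracy must have positive Youden index")
    est = (obs_prev + acc.specificity - 1.0) / acc.youden
    return float(min(max(est, 0.0), 1.0))


def bootstrap_percentile_ci(
    estimator,
    sources: ObservedSources,
    B: int = 999,
    level: float = 0.95,
    seed: int | np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap over individuals (rows), preserving (y1, y2) pairing."""
    if B < 1:
        raise ValueError("B must be at least 1")
    rng = np.random.default_rng(seed)
    n = sources.n
    stats = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        try:
            stats[b] = estimator(ObservedSources(sources.y1[idx], sources.y2[idx]))
        except Exception as exc:  # pragma: no cover - defensive
            raise RuntimeError(f"estimator failed on bootstrap resample {b}") from exc
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(stats, [alpha, 1.0 - alpha])
    return (float(lo), float(hi))


# -- point estimators (used standalone and inside bootstrap loops) ----------


def _point_or(sources: ObservedSources) -> float:
    return float(np.mean((sources.y1 == 1) | (sources.y2 == 1)))


def _point_and(sources: ObservedSources) -> float:
    return float(np.mean((sources.y1 == 1) & (sources.y2 == 1)))


def _point_rssa(
    sources: ObservedSources,
    assumed: AssumedAccuracyPair,
    combination: str = "mean",
) -> float:
    c1 = rogan_gladen(float(sources.y1.mean()), assumed.source1)
    c2 = rogan_gladen(float(sources.y2.mean()), assumed.source2)
    if combination == "mean":
        return 0.5 * (c1 + c2)
    if combination == "inverse_variance":
        # delta-method variance of the Rogan-Gladen corrector: p(1-p)/(n*J^2)
        ws = []
        for p, acc in ((float(sources.y1.mean()), assumed.source1),
                       (float(sources.y2.mean()), assumed.source2)):
            v = max(p * (1.0 - p), 1e-12) / (sources.n * acc.youden**2)
            ws.append(1.0 / v)
        return float((ws[0] * c1 + ws[1] * c2) / (ws[0] + ws[1]))
    raise ValueError("combination must be 'mean' or 'inverse_variance'")


def estimate_source(X, which: int = 1, level: float = 0.95) -> PrevalenceEstimate:
    """Naive single-source prevalence with Wald interval."""
    sources = _as_sources(X)
    y = sources.y1 if which == 1 else sources.y2
    p = float(y.mean())
    lo, hi = wald_ci(p, sources.n, level)
    return PrevalenceEstimate(f"source{which}", p, lo, hi, "wald", sources.n)


def estimate_or(X, level: float = 0.95) -> PrevalenceEstimate:
    sources = _as_sources(X)
    p = _point_or(sources)
    lo, hi = wald_ci(p, sources.n, level)
    return PrevalenceEstimate("OR", p, lo, hi, "wald", sources.n)


def estimate_and(X, level: float = 0.95) -> PrevalenceEstimate:
    sources = _as_sources(X)
    p = _point_and(sources)
    lo, hi = wald_ci(p, sources.n, level)
    return PrevalenceEstimate("AND", p, lo, hi, "wald", sources.n)


def estimate_rssa(
    X,
    assumed: AssumedAccuracyPair | None = None,
    combination: str = "mean",
    level: float = 0.95,
    B: int = 999,
    seed: int | np.random.Generator | None = None,
    ci: bool = True,
) -> PrevalenceEstimate:
    sources = _as_sources(X)
    assumed = assumed or default_assumed_accuracy()
    p = _point_rssa(sources, assumed, combination)
    if ci:
        lo, hi = bootstrap_percentile_ci(
            lambda s: _point_rssa(s, assumed, combination), sources, B, level, seed
        )
        lo, hi = min(lo, p), max(hi, p)
    else:
        lo = hi = p
    return PrevalenceEstimate("RSSA", p, lo, hi, "percentile_bootstrap", sources.n)


# -- scikit-learn estimator classes -----------------------------------------


class _RulePrevalenceEstimator(BaseEstimator):
    """Shared fit plumbing for the rule-based estimators."""

    _method = ""

    def __init__(self, level: float = 0.95):
        self.level = level

    def _estimate(self, sources: ObservedSources) -> PrevalenceEstimate:
        raise NotImplementedError

    def fit(self, X, y=None):
        sources = _as_sources(X)
        est = self._estimate(sources)
        self.estimate_ = est
        self.prevalence_ = est.point
        self.ci_low_ = est.ci_low
        self.ci_high_ = est.ci_high
        self.n_ = est.n
        return self


class OrEstimator(_RulePrevalenceEstimator):
    """Prevalence of being flagged by either source."""

    _method = "OR"

    def _estimate(self, sources):
        return estimate_or(sources, self.level)


class AndEstimator(_RulePrevalenceEstimator):
    """Prevalence of being flagged by both sources."""

    _method = "AND"

    def _estimate(self, sources):
        return estimate_and(sources, self.level)


class RssaEstimator(_RulePrevalenceEstimator):
    """Rogan-Gladen-corrected per-source prevalences, averaged.

    Parameters
    ----------
    assumed : AssumedAccuracyPair, default published hypertension values
        (Sn, Sp) = (0.72, 0.95) for source 1 and (0.87, 0.90) for source 2.
    combination : "mean" (default) or "inverse_variance".
    ci : attach a percentile-bootstrap interval (B resamples) when True.
    """

    _method = "RSSA"

    def __init__(
        self,
        assumed: AssumedAccuracyPair | None = None,
        combination: str = "mean",
        level: float = 0.95,
        B: int = 999,
        ci: bool = True,
        random_state: int | None = None,
    ):
        super().__init__(level=level)
        self.assumed = assumed
        self.combination = combination
        self.B = B
        self.ci = ci
        self.random_state = random_state

    def _estimate(self, sources):
        return estimate_rssa(
            sources,
            assumed=self.assumed,
            combination=self.combination,
            level=self.level,
            B=self.B,
            seed=self.random_state,
            ci=self.ci,
        )
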