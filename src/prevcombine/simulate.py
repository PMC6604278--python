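"""Synthetic two-source cohort generator.

A population of n individuals is simulated in three stages:

1. **Markers** — binary disease markers with specified marginal prevalences
   and a specified latent (tetrachoric-scale) correlation structure, drawn
   through a Gaussian copula: a multivariate normal vector is dichotomized
   column-wise at the (1 - prevalence) quantile.
2. **Truth** — true disease status D is Bernoulli with probability
   expit(b0 + x·beta); the intercept b0 is calibrated by root-finding so the
   population mean probability hits the target prevalence.
3. **Observed sources** — each source j reports Y_j = 1 with probability
   Sn_j when D = 1 and 1 - Sp_j when D = 0.  Within each stratum of D the
   two sources' error draws may be correlated through a shared Gaussian
   copula, which is how between-source dependence beyond the
   conditional-independence bound is induced.

The generating sensitivities/specificities are calibrated per simulation
condition so that (i) each source's marginal prevalence matches its target
exactly and (ii) the tetrachoric correlation between the two sources matches
the target.  Both sources share a single positive-predictive-value parameter
psi (Sn_j = psi * obs_j / prev, remaining observed positives are false
positives), and psi is solved so that *conditionally independent* sources
already exhibit the target correlation; only when the target falls outside
the attainable conditional-independence range is a residual within-stratum
error correlation added.  This mirrors administrative case definitions,
whose dominant error is under-ascertainment (missed cases) rather than
false positives.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit, ndtri

from ._bvn import orthant_prob

__all__ = [
    "SimulationCondition",
    "MarkerPanel",
    "DiseaseModel",
    "AccuracySpec",
    "DependenceSpec",
    "ObservedSources",
    "FeasibilityError",
    "build_marker_correlation",
    "nearest_positive_definite",
    "generate_markers",
    "calibrate_intercept",
    "generate_truth",
    "solve_sensitivity",
    "calibrate_accuracy",
    "apply_misclassification",
    "default_coefficients",
    "resolve_marker_prevalences",
    "simulate_condition",
    "condition_seed",
    "implied_cells",
    "tetrachoric_target_cell",
]


class FeasibilityError(ValueError):
    """Requested condition admits no valid generating distribution."""


def _check_proportion(name: str, value: float, open_interval: bool = True) -> None:
    lo_ok = value > 0.0 if open_interval else value >= 0.0
    hi_ok = value < 1.0 if open_interval else value <= 1.0
    if not (lo_ok and hi_ok):
        raise ValueError(f"{name} must lie in (0, 1), got {value}")


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of the simulation design.

    Parameters
    ----------
    true_prev : target population disease prevalence.
    obs_prev_1, obs_prev_2 : target marginal prevalence of each observed source.
    source_corr : target tetrachoric correlation between the two sources.
    n_markers : number of binary disease markers.
    marker_corr_mean : mean pairwise latent correlation amongst markers.
    marker_corr_pattern : "exchangeable" or "unstructured".
    population_size : individuals per replication.
    marker_prevalences : optional explicit marker prevalences; drawn from
        U[0.05, 0.35] on a condition-derived seed when omitted.
    """

    true_prev: float
    obs_prev_1: float
    obs_prev_2: float
    source_corr: float
    n_markers: int = 16
    marker_corr_mean: float = 0.0
    marker_corr_pattern: str = "exchangeable"
    population_size: int = 10_000
    marker_prevalences: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        _check_proportion("true_prev", self.true_prev)
        _check_proportion("obs_prev_1", self.obs_prev_1)
        _check_proportion("obs_prev_2", self.obs_prev_2)
        if not -1.0 < self.source_corr < 1.0:
            raise ValueError("source_corr must lie in (-1, 1)")
        if self.n_markers < 1:
            raise ValueError("n_markers must be a positive integer")
        if not 0.0 <= self.marker_corr_mean < 1.0:
            raise ValueError("marker_corr_mean must lie in [0, 1)")
        if self.marker_corr_pattern not in ("exchangeable", "unstructured"):
            raise ValueError("marker_corr_pattern must be 'exchangeable' or 'unstructured'")
        if self.population_size < 1:
            raise ValueError("population_size must be positive")
        if self.marker_prevalences is not None:
            if len(self.marker_prevalences) != self.n_markers:
                raise ValueError("marker_prevalences length must equal n_markers")
            for p in self.marker_prevalences:
                _check_proportion("marker prevalence", p)

    def canonical_key(self) -> str:
        mp = "auto" if self.marker_prevalences is None else ",".join(
            f"{p:.6f}" for p in self.marker_prevalences
        )
        return (
            f"{self.true_prev:.6f}|{self.obs_prev_1:.6f}|{self.obs_prev_2:.6f}|"
            f"{self.source_corr:.6f}|{self.n_markers}|{self.marker_corr_mean:.6f}|"
            f"{self.marker_corr_pattern}|{self.population_size}|{mp}"
        )


@dataclass(frozen=True)
class MarkerPanel:
    """Binary marker matrix with the targets it was generated to meet."""

    values: np.ndarray  # (n, n_markers) of {0, 1}
    target_prevalences: np.ndarray
    target_corr: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_markers(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DiseaseModel:
    """Logistic model for true status: P(D=1|x) = expit(intercept + x @ coefficients)."""

    intercept: float
    coefficients: np.ndarray

    def __post_init__(self) -> None:
        coef = np.asarray(self.coefficients, dtype=float)
        object.__setattr__(self, "coefficients", coef)
        if not np.isfinite(self.intercept) or not np.all(np.isfinite(coef)):
            raise ValueError("disease model parameters must be finite")

    def probabilities(self, panel: MarkerPanel) -> np.ndarray:
        if panel.n_markers != self.coefficients.shape[0]:
            raise ValueError("model dimension does not match marker panel")
        return expit(self.intercept + panel.values @ self.coefficients)


@dataclass(frozen=True)
class AccuracySpec:
    """Sensitivity/specificity pair of one source; Youden index must be positive."""

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not 0.0 < self.sensitivity <= 1.0:
            raise ValueError("sensitivity must lie in (0, 1]")
        if not 0.0 < self.specificity <= 1.0:
            raise ValueError("specificity must lie in (0, 1]")
        if self.sensitivity + self.specificity <= 1.0:
            raise ValueError(
                "sensitivity + specificity must exceed 1 (positive Youden index)"
            )

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class DependenceSpec:
    """Within-stratum Gaussian-copula correlation of the two sources' error draws."""

    error_corr_diseased: float = 0.0
    error_corr_nondiseased: float = 0.0

    def __post_init__(self) -> None:
        for r in (self.error_corr_diseased, self.error_corr_nondiseased):
            if not -1.0 < r < 1.0:
                raise ValueError("error correlations must lie in (-1, 1)")


@dataclass(frozen=True)
class ObservedSources:
    """Per-person binary case indicators from the two sources."""

    y1: np.ndarray
    y2: np.ndarray

    def __post_init__(self) -> None:
        y1 = np.asarray(self.y1, dtype=np.int8)
        y2 = np.asarray(self.y2, dtype=np.int8)
        if y1.shape != y2.shape or y1.ndim != 1:
            raise ValueError("y1 and y2 must be 1-D arrays of equal length")
        for arr in (y1, y2):
            if not np.isin(arr, (0, 1)).all():
                raise ValueError("source indicators must be binary")
        object.__setattr__(self, "y1", y1)
        object.__setattr__(self, "y2", y2)

    @property
    def n(self) -> int:
        return self.y1.shape[0]


# ---------------------------------------------------------------------------
# markers


def nearest_positive_definite(a: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Nearest correlation-like positive-definite matrix (Higham-style projection).

    Alternates eigenvalue clipping with unit-diagonal restoration; adequate for
    the mildly indefinite matrices produced by random off-diagonal fills.
    """
    x = np.asarray(a, dtype=float).copy()
    for _ in range(100):
        w, v = np.linalg.eigh((x + x.T) / 2.0)
        if w.min() > eps:
            break
        w = np.clip(w, eps, None)
        x = (v * w) @ v.T
        d = np.sqrt(np.diag(x))
        x = x / np.outer(d, d)
        np.fill_diagonal(x, 1.0)
    return x


def build_marker_correlation(
    pattern: str, corr_mean: float, n_markers: int, seed: int | None = None
) -> np.ndarray:
    """Latent correlation matrix amongst markers.

    "exchangeable": every off-diagonal equals ``corr_mean``.  "unstructured":
    off-diagonals are drawn uniformly on
    [max(0, corr_mean - 0.15), min(0.95, corr_mean + 0.15)], then projected to
    the nearest positive-definite correlation matrix; the realized mean
    off-diagonal is required to land within 0.01 of ``corr_mean``.
    """
    if n_markers < 2:
        raise ValueError("n_markers must be at least 2")
    if not 0.0 <= corr_mean < 1.0:
        raise ValueError("corr_mean must lie in [0, 1)")
    if pattern == "exchangeable":
        if corr_mean < -1.0 / (n_markers - 1):
            raise FeasibilityError("exchangeable correlation below PD bound")
        mat = np.full((n_markers, n_markers), corr_mean)
        np.fill_diagonal(mat, 1.0)
        return mat
    if pattern != "unstructured":
        raise ValueError("pattern must be 'exchangeable' or 'unstructured'")
    rng = np.random.default_rng(seed)
    lo = max(0.0, corr_mean - 0.15)
    hi = min(0.95, corr_mean + 0.15)
    for _ in range(50):
        off = rng.uniform(lo, hi, size=n_markers * (n_markers - 1) // 2)
        # center the draw so its mean equals corr_mean before projection
        off = np.clip(off - off.mean() + corr_mean, 0.0, 0.97)
        mat = np.eye(n_markers)
        iu = np.triu_indices(n_markers, 1)
        mat[iu] = off
        mat = mat + mat.T - np.diag(np.diag(mat))
        np.fill_diagonal(mat, 1.0)
        mat = nearest_positive_definite(mat)
        if abs(mat[iu].mean() - corr_mean) <= 0.01:
            return mat
    raise FeasibilityError("could not construct unstructured correlation matrix")


def generate_markers(
    n: int,
    prevalences: np.ndarray,
    corr: np.ndarray,
    seed: int | np.random.Generator | None = None,
) -> MarkerPanel:
    """Gaussian-copula binary markers with given marginals and latent correlation."""
    prevalences = np.asarray(prevalences, dtype=float)
    corr = np.asarray(corr, dtype=float)
    k = prevalences.shape[0]
    if corr.shape != (k, k):
        raise ValueError("prevalences and correlation matrix dimensions differ")
    rng = np.random.default_rng(seed)
    if np.allclose(corr, np.eye(k)):
        z = rng.standard_normal((n, k))
    else:
        try:
            chol = np.linalg.cholesky(corr)
        except np.linalg.LinAlgError:
            chol = np.linalg.cholesky(nearest_positive_definite(corr))
        z = rng.standard_normal((n, k)) @ chol.T
    thresholds = ndtri(1.0 - prevalences)
    values = (z > thresholds).astype(np.int8)
    return MarkerPanel(values=values, target_prevalences=prevalences, target_corr=corr)


# ---------------------------------------------------------------------------
# truth


def calibrate_intercept(
    coefficients: np.ndarray,
    panel: MarkerPanel,
    target_prev: float,
    tol: float = 1e-10,
) -> float:
    """Intercept b0 with mean expit(b0 + x·beta) equal to target_prev.

    The population mean is strictly increasing and continuous in b0 with range
    (0, 1), so a bracketing root-find always succeeds.
    """
    _check_proportion("target_prev", target_prev)
    if panel.n == 0:
        raise ValueError("marker panel is empty")
    coefficients = np.asarray(coefficients, dtype=float)
    lin = panel.values @ coefficients

    def gap(b0: float) -> float:
        return float(expit(b0 + lin).mean() - target_prev)

    lo, hi = -40.0, 40.0
    while gap(lo) > 0:
        lo *= 2
    while gap(hi) < 0:
        hi *= 2
    return float(brentq(gap, lo, hi, xtol=tol))


def generate_truth(
    panel: MarkerPanel,
    model: DiseaseModel,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Bernoulli true disease status per individual under the logistic model."""
    rng = np.random.default_rng(seed)
    p = model.probabilities(panel)
    return (rng.random(panel.n) < p).astype(np.int8)


# ---------------------------------------------------------------------------
# accuracy calibration


def solve_sensitivity(obs_prev: float, true_prev: float, specificity: float) -> float:
    """Sensitivity satisfying Sn*prev + (1-Sp)(1-prev) = obs_prev for fixed Sp."""
    sn = (obs_prev - (1.0 - specificity) * (1.0 - true_prev)) / true_prev
    if not 0.0 < sn <= 1.0:
        raise FeasibilityError(
            f"specificity {specificity} cannot produce observed prevalence "
            f"{obs_prev} at true prevalence {true_prev} (implied sensitivity {sn:.4f})"
        )
    return float(sn)


def _acc_from_ppv(obs: float, prev: float, psi: float, sn_cap: float) -> AccuracySpec:
    sn = min(psi * obs / prev, sn_cap)
    fp = (obs - sn * prev) / (1.0 - prev)
    return AccuracySpec(sensitivity=sn, specificity=1.0 - fp)


def implied_cells(
    true_prev: float, acc1: AccuracySpec, acc2: AccuracySpec, dep: DependenceSpec
) -> np.ndarray:
    """Exact 2x2 joint probabilities [[p00, p01], [p10, p11]] of (Y1, Y2)."""
    p11 = true_prev * orthant_prob(
        acc1.sensitivity, acc2.sensitivity, dep.error_corr_diseased
    ) + (1 - true_prev) * orthant_prob(
        1 - acc1.specificity, 1 - acc2.specificity, dep.error_corr_nondiseased
    )
    m1 = acc1.sensitivity * true_prev + (1 - acc1.specificity) * (1 - true_prev)
    m2 = acc2.sensitivity * true_prev + (1 - acc2.specificity) * (1 - true_prev)
    p10, p01 = m1 - p11, m2 - p11
    return np.array([[1.0 - m1 - m2 + p11, p01], [p10, p11]])


def tetrachoric_target_cell(obs_prev_1: float, obs_prev_2: float, rho: float) -> float:
    """Joint positive cell that a tetrachoric correlation rho implies for fixed margins."""
    return orthant_prob(obs_prev_1, obs_prev_2, rho)


def _tetrachoric_of_cell(p1: float, p2: float, p11: float) -> float:
    lo, hi = -0.99999, 0.99999
    f = lambda r: orthant_prob(p1, p2, r) - p11
    if f(lo) > 0 or f(hi) < 0:
        return 1.0 if f(hi) < 0 else -1.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def calibrate_accuracy(
    condition: SimulationCondition,
    sn_cap: float = 0.95,
    youden_floor: float = 0.02,
    specificity_override: tuple[float, float] | None = None,
) -> tuple[AccuracySpec, AccuracySpec, DependenceSpec]:
    """Generating accuracies and error dependence for a simulation condition.

    Both sources share one positive-predictive-value parameter psi; psi is
    solved so that conditionally independent sources already carry the target
    tetrachoric correlation.  If the target lies outside the attainable
    conditional-independence range, psi is clamped to the boundary and the
    remaining gap is closed by a shared within-stratum error correlation,
    found by monotone root search.  ``specificity_override`` bypasses the psi
    closure (both generating specificities fixed, sensitivities solved from
    the marginal constraint) — the mechanism for studying misspecified
    accuracy assumptions.
    """
    prev, o1, o2 = condition.true_prev, condition.obs_prev_1, condition.obs_prev_2
    rho = condition.source_corr
    p11_star = tetrachoric_target_cell(o1, o2, rho)

    if specificity_override is not None:
        acc1 = AccuracySpec(solve_sensitivity(o1, prev, specificity_override[0]),
                            specificity_override[0])
        acc2 = AccuracySpec(solve_sensitivity(o2, prev, specificity_override[1]),
                            specificity_override[1])
        return acc1, acc2, _solve_residual_dependence(prev, acc1, acc2, o1, o2, p11_star)

    # psi range: lower bound from the Youden floor of the worse source,
    # upper bound from PPV=1 (or the sensitivity cap binding).
    def min_youden(psi: float) -> float:
        return min(
            _acc_from_ppv(o, prev, psi, sn_cap).sensitivity
            + _acc_from_ppv(o, prev, psi, sn_cap).specificity
            - 1.0
            for o in (o1, o2)
        )

    psi_hi = 1.0
    psi_eps = prev + 1e-6
    if min_youden(psi_eps) >= youden_floor:
        psi_lo = psi_eps
    elif min_youden(psi_hi) < youden_floor:
        raise FeasibilityError("no accuracy specification satisfies the Youden floor")
    else:
        psi_lo = brentq(lambda p: min_youden(p) - youden_floor, psi_eps, psi_hi)

    def ci_p11(psi: float) -> float:
        a1 = _acc_from_ppv(o1, prev, psi, sn_cap)
        a2 = _acc_from_ppv(o2, prev, psi, sn_cap)
        return prev * a1.sensitivity * a2.sensitivity + (1 - prev) * (
            1 - a1.specificity
        ) * (1 - a2.specificity)

    tet_lo = _tetrachoric_of_cell(o1, o2, ci_p11(psi_lo))
    tet_hi = _tetrachoric_of_cell(o1, o2, ci_p11(psi_hi))
    if tet_lo <= rho <= tet_hi:
        psi = float(
            brentq(
                lambda p: _tetrachoric_of_cell(o1, o2, ci_p11(p)) - rho,
                psi_lo,
                psi_hi,
                xtol=1e-10,
            )
        )
        acc1 = _acc_from_ppv(o1, prev, psi, sn_cap)
        acc2 = _acc_from_ppv(o2, prev, psi, sn_cap)
        return acc1, acc2, DependenceSpec(0.0, 0.0)

    psi = psi_hi if rho > tet_hi else psi_lo
    acc1 = _acc_from_ppv(o1, prev, psi, sn_cap)
    acc2 = _acc_from_ppv(o2, prev, psi, sn_cap)
    return acc1, acc2, _solve_residual_dependence(prev, acc1, acc2, o1, o2, p11_star)


def _solve_residual_dependence(
    prev: float,
    acc1: AccuracySpec,
    acc2: AccuracySpec,
    o1: float,
    o2: float,
    p11_star: float,
) -> DependenceSpec:
    """Shared within-stratum error correlation r hitting the target joint cell."""

    def p11_of_r(r: float) -> float:
        dep = DependenceSpec(r, r)
        return float(implied_cells(prev, acc1, acc2, dep)[1, 1])

    lo, hi = -0.99999, 0.99999
    f_lo, f_hi = p11_of_r(lo) - p11_star, p11_of_r(hi) - p11_star
    if f_lo > 0 or f_hi < 0:
        tet_min = _tetrachoric_of_cell(o1, o2, p11_of_r(lo))
        tet_max = _tetrachoric_of_cell(o1, o2, p11_of_r(hi))
        raise FeasibilityError(
            "requested source correlation unattainable with these accuracies; "
            f"attainable tetrachoric range is [{tet_min:.3f}, {tet_max:.3f}]"
        )
    r = float(brentq(lambda r: p11_of_r(r) - p11_star, lo, hi, xtol=1e-10))
    return DependenceSpec(r, r)


# ---------------------------------------------------------------------------
# observation


def apply_misclassification(
    truth: np.ndarray,
    acc1: AccuracySpec,
    acc2: AccuracySpec,
    dep: DependenceSpec = DependenceSpec(),
    seed: int | np.random.Generator | None = None,
) -> ObservedSources:
    """Error-prone source indicators given true status.

    Marginally each source follows the conditional-Bernoulli scheme
    (probability Sn given D=1, probability 1-Sp given D=0).  The two sources'
    uniform draws are coupled through a bivariate Gaussian copula with
    stratum-specific correlation, so conditional independence (correlation 0)
    and strong agreement are both reachable without disturbing the marginals.
    """
    truth = np.asarray(truth)
    rng = np.random.default_rng(seed)
    n = truth.shape[0]
    z = rng.standard_normal((n, 2))
    r = np.where(truth == 1, dep.error_corr_diseased, dep.error_corr_nondiseased)
    z2 = r * z[:, 0] + np.sqrt(1.0 - r * r) * z[:, 1]
    z1 = z[:, 0]

    p1 = np.where(truth == 1, acc1.sensitivity, 1.0 - acc1.specificity)
    p2 = np.where(truth == 1, acc2.sensitivity, 1.0 - acc2.specificity)
    y1 = (z1 < ndtri(p1)).astype(np.int8)
    y2 = (z2 < ndtri(p2)).astype(np.int8)
    return ObservedSources(y1=y1, y2=y2)


# ---------------------------------------------------------------------------
# condition-level plumbing


def condition_seed(condition: SimulationCondition, base_seed: int = 0) -> int:
    """Stable per-condition seed: base seed combined with a CRC of the fields."""
    h = zlib.crc32(condition.canonical_key().encode())
    return int((base_seed + h) % (2**31 - 1))


def resolve_marker_prevalences(condition: SimulationCondition) -> np.ndarray:
    """Marker prevalences for a condition; drawn once from U[0.05, 0.35] if unset."""
    if condition.marker_prevalences is not None:
        return np.asarray(condition.marker_prevalences, dtype=float)
    key = replace(condition, marker_prevalences=None)
    rng = np.random.default_rng(condition_seed(key) ^ 0x5EED)
    return rng.uniform(0.05, 0.35, size=condition.n_markers)


def default_coefficients(n_markers: int) -> np.ndarray:
    """Log odds ratios equally spaced between log(1.5) and log(2.5)."""
    return np.log(np.linspace(1.5, 2.5, n_markers))


def simulate_condition(
    condition: SimulationCondition,
    seed: int | np.random.Generator | None = None,
    coefficients: np.ndarray | None = None,
    accuracies: tuple[AccuracySpec, AccuracySpec, DependenceSpec] | None = None,
) -> tuple[MarkerPanel, np.ndarray, ObservedSources]:
    """One replication: markers, true status, and both observed sources."""
    rng = np.random.default_rng(seed)
    prevalences = resolve_marker_prevalences(condition)
    corr = build_marker_correlation(
        condition.marker_corr_pattern,
        condition.marker_corr_mean,
        condition.n_markers,
        seed=condition_seed(condition) ^ 0xC0FF,
    )
    panel = generate_markers(condition.population_size, prevalences, corr, seed=rng)
    coefficients = (
        default_coefficients(condition.n_markers) if coefficients is None else coefficients
    )
    b0 = calibrate_intercept(coefficients, panel, condition.true_prev)
    model = DiseaseModel(intercept=b0, coefficients=coefficients)
    truth = generate_truth(panel, model, seed=rng)
    acc1, acc2, dep = accuracies if accuracies is not None else calibrate_accuracy(condition)
    sources = apply_misclassification(truth, acc1, acc2, dep, seed=rng)
    return panel, truth, sources
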