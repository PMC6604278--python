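"""Simulation-study evaluation: replication loops, bias/error summaries,
and the tetrachoric association diagnostic.

Per-method performance over R replications of a condition is summarized by

* percent absolute relative bias, RB = 100 * |prev_T - mean(est)| / prev_T;
* mean squared error, MSE = var(est) + |prev_T - mean(est)|^2, reported on
  the x100 scale; the variance uses the population (divide-by-R) convention
  so the plug-in decomposition MSE = variance + squared bias holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import ndtri

from ._bvn import orthant_prob
from .estimators import (
    AssumedAccuracyPair,
    _point_and,
    _point_or,
    _point_rssa,
    default_assumed_accuracy,
)
from .pssa import PssaFitSpec, PssaPriors, fit_pssa, posterior_prevalence
from .simulate import (
    FeasibilityError,
    SimulationCondition,
    calibrate_accuracy,
    condition_seed,
    simulate_condition,
)

__all__ = [
    "ConditionResult",
    "GridResult",
    "TetrachoricResult",
    "relative_bias",
    "mean_squared_error",
    "run_condition",
    "run_grid",
    "tetrachoric_correlation",
    "DEFAULT_METHODS",
]

DEFAULT_METHODS = ("source1", "source2", "OR", "AND", "RSSA", "PSSA")


def relative_bias(estimates: np.ndarray, true_prev: float) -> float:
    """Percent absolute relative bias of the mean estimate."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("empty estimates")
    if true_prev <= 0:
        raise ValueError("true_prev must be positive")
    return float(100.0 * abs(true_prev - estimates.mean()) / true_prev)


def mean_squared_error(
    estimates: np.ndarray, true_prev: float, scale: float = 100.0, ddof: int = 0
) -> float:
    """Variance-plus-squared-bias error of the estimates, reported x100."""
    estimates = np.asarray(estimates, dtype=float)
    if estimates.size == 0:
        raise ValueError("empty estimates")
    var = estimates.var(ddof=ddof) if estimates.size > ddof else 0.0
    return float(scale * (var + (true_prev - estimates.mean()) ** 2))


@dataclass
class ConditionResult:
    condition: SimulationCondition
    estimates: dict[str, np.ndarray]
    rb: dict[str, float]
    mse: dict[str, float]
    n_replications: int
    pssa_nonconverged: int = 0
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        c = self.condition
        rows = [
            {
                "true_prev": c.true_prev,
                "obs_prev_1": c.obs_prev_1,
                "obs_prev_2": c.obs_prev_2,
                "source_corr": c.source_corr,
                "n_markers": c.n_markers,
                "marker_corr_mean": c.marker_corr_mean,
                "marker_corr_pattern": c.marker_corr_pattern,
                "method": m,
                "rb": self.rb[m],
                "mse": self.mse[m],
                "n_replications": self.n_replications,
            }
            for m in self.estimates
        ]
        return pd.DataFrame(rows)


@dataclass
class GridResult:
    results: list[ConditionResult]
    errors: list[tuple[SimulationCondition, str]] = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        if not self.results:
            return pd.DataFrame()
        return pd.concat([r.to_frame() for r in self.results], ignore_index=True)

    def to_wide(self) -> pd.DataFrame:
        """One row per condition, method RB/MSE side by side (report layout)."""
        tidy = self.to_frame()
        if tidy.empty:
            return tidy
        idx = [
            "true_prev",
            "obs_prev_1",
            "obs_prev_2",
            "source_corr",
            "marker_corr_mean",
            "n_markers",
        ]
        wide = tidy.pivot_table(index=idx, columns="method", values=["rb", "mse"])
        wide.columns = [f"{a}_{b}" for a, b in wide.columns]
        return wide.reset_index()


def run_condition(
    condition: SimulationCondition,
    reps: int = 500,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    assumed: AssumedAccuracyPair | None = None,
    pssa_spec: PssaFitSpec | None = None,
    pssa_priors: PssaPriors | None = None,
    seed: int = 0,
    accuracies=None,
) -> ConditionResult:
    """Replicate one condition and summarize per-method RB and MSE.

    Each replication draws a fresh population, applies every requested
    method, and records its point estimate.  PSSA runs one chain per
    replication with reduced iterations by default (2,000 with 500 burn-in);
    replications whose split-chain PSRF on prevalence exceeds 1.2 are counted
    in ``pssa_nonconverged`` but their estimates are retained.
    """
    unknown = set(methods) - set(DEFAULT_METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    assumed = assumed or default_assumed_accuracy()
    if accuracies is None:
        accuracies = calibrate_accuracy(condition)  # may raise FeasibilityError
    if pssa_spec is None:
        pssa_spec = PssaFitSpec(n_iterations=2_000, burn_in=500, n_chains=1)

    cseed = condition_seed(condition, seed)
    estimates = {m: np.empty(reps) for m in methods}
    nonconv = 0
    for r in range(reps):
        ss = np.random.SeedSequence((cseed, r))
        sim_rng, pssa_seed = np.random.default_rng(ss), int(
            np.random.SeedSequence((cseed, r, 7)).generate_state(1)[0] % (2**31)
        )
        panel, truth, sources = simulate_condition(
            condition, seed=sim_rng, accuracies=accuracies
        )
        for m in methods:
            if m == "source1":
                estimates[m][r] = sources.y1.mean()
            elif m == "source2":
                estimates[m][r] = sources.y2.mean()
            elif m == "OR":
                estimates[m][r] = _point_or(sources)
            elif m == "AND":
                estimates[m][r] = _point_and(sources)
            elif m == "RSSA":
                estimates[m][r] = _point_rssa(sources, assumed)
            elif m == "PSSA":
                spec = PssaFitSpec(
                    n_iterations=pssa_spec.n_iterations,
                    burn_in=pssa_spec.burn_in,
                    n_chains=pssa_spec.n_chains,
                    seed=pssa_seed,
                )
                draws = fit_pssa(sources, panel, pssa_priors, spec)
                estimates[m][r] = posterior_prevalence(draws).point
                if draws.psrf.get("prevalence", 1.0) > 1.2:
                    nonconv += 1

    rb = {m: relative_bias(estimates[m], condition.true_prev) for m in methods}
    mse = {m: mean_squared_error(estimates[m], condition.true_prev) for m in methods}
    return ConditionResult(
        condition=condition,
        estimates=estimates,
        rb=rb,
        mse=mse,
        n_replications=reps,
        pssa_nonconverged=nonconv,
        seed=cseed,
    )


def run_grid(
    conditions: list[SimulationCondition],
    reps: int = 500,
    methods: tuple[str, ...] = DEFAULT_METHODS,
    seed: int = 0,
    **kwargs,
) -> GridResult:
    """Run a list of conditions with independent per-condition seeds.

    A condition that fails (e.g. infeasible calibration) is recorded in
    ``errors`` and the run continues.
    """
    if not conditions:
        raise ValueError("conditions list is empty")
    results, errors = [], []
    for cond in conditions:
        try:
            results.append(
                run_condition(cond, reps=reps, methods=methods, seed=seed, **kwargs)
            )
        except (FeasibilityError, ValueError) as exc:
            errors.append((cond, str(exc)))
    return GridResult(
        results=results,
        errors=errors,
        metadata={"base_seed": seed, "reps": reps, "methods": list(methods)},
    )


@dataclass(frozen=True)
class TetrachoricResult:
    rho: float
    ci_low: float
    ci_high: float
    boundary: bool = False


def tetrachoric_correlation(
    y1: np.ndarray, y2: np.ndarray, level: float = 0.95
) -> TetrachoricResult:
    """Maximum-likelihood tetrachoric correlation of two binary variables.

    Thresholds are fixed at the normal quantiles of the margins and the
    latent correlation maximizes the 2x2 multinomial likelihood (the
    standard two-step estimator).  The interval comes from the observed
    Fisher information of the profile likelihood; an empty off-diagonal
    cell returns +/-1 with ``boundary=True``.
    """
    y1 = np.asarray(y1).astype(int)
    y2 = np.asarray(y2).astype(int)
    if y1.shape != y2.shape:
        raise ValueError("inputs must have equal length")
    p1, p2 = y1.mean(), y2.mean()
    if p1 in (0.0, 1.0) or p2 in (0.0, 1.0):
        raise ValueError("degenerate margin: each variable needs both 0s and 1s")
    n = y1.shape[0]
    n11 = int(np.sum((y1 == 1) & (y2 == 1)))
    n10 = int(np.sum((y1 == 1) & (y2 == 0)))
    n01 = int(np.sum((y1 == 0) & (y2 == 1)))
    n00 = n - n11 - n10 - n01
    if (n10 == 0 or n01 == 0) and n11 > 0 and n00 > 0:
        return TetrachoricResult(1.0, 1.0, 1.0, boundary=True)
    if n11 == 0 and n10 > 0 and n01 > 0:
        return TetrachoricResult(-1.0, -1.0, -1.0, boundary=True)

    def negll(r: float) -> float:
        p11 = orthant_prob(p1, p2, r)
        p11 = min(max(p11, 1e-12), min(p1, p2) - 1e-12)
        a = p1 - p11
        b = p2 - p11
        c = 1.0 - p1 - p2 + p11
        return -(
            n11 * np.log(p11) + n10 * np.log(a) + n01 * np.log(b) + n00 * np.log(c)
        )

    res = minimize_scalar(negll, bounds=(-0.999, 0.999), method="bounded",
                          options={"xatol": 1e-8})
    rho = float(res.x)
    # observed information by central difference of the negative log-likelihood
    h = 1e-4
    info = (negll(rho + h) - 2 * negll(rho) + negll(rho - h)) / h**2
    if info > 0:
        se = 1.0 / np.sqrt(info)
        z = float(ndtri(0.5 + level / 2.0))
        lo, hi = max(rho - z * se, -1.0), min(rho + z * se, 1.0)
    else:  # flat likelihood; fall back to the full range
        lo, hi = -1.0, 1.0
    return TetrachoricResult(rho, float(lo), float(hi))
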