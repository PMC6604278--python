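"""Bayesian latent-class prevalence estimator (PSSA).

True disease status D_i is unobserved.  An outcome model links covariates
(disease markers) to D through a probit regression, and a reporting model
links D to each source's observed indicator through that source's
sensitivity and specificity:

    D_i | x_i           ~ Bernoulli( Phi(x_i' alpha) )
    Y_ij | D_i = 1      ~ Bernoulli( Sn_j )
    Y_ij | D_i = 0      ~ Bernoulli( 1 - Sp_j )

with Y_i1, Y_i2 conditionally independent given D_i.  Priors: diffuse normal
on the probit coefficients, Beta on each sensitivity/specificity.  The
posterior is explored by Gibbs sampling:

1. each D_i from its Bernoulli full conditional (outcome odds times the two
   reporting likelihood ratios);
2. alpha by Albert-Chib truncated-normal data augmentation for the probit
   model given the current D;
3. each Sn_j, Sp_j from conjugate Beta full conditionals given D and Y,
   with a label-switching guard rejecting draws implying Sn + Sp < 1.

The per-iteration population prevalence is the mean of the sampled latent
statuses, so the reported posterior is over the *realized* prevalence of
the cohort in hand.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.special import log_ndtr, ndtr, ndtri
from sklearn.base import BaseEstimator

from .estimators import PrevalenceEstimate, _as_sources
from .simulate import ObservedSources

__all__ = [
    "PssaPriors",
    "PssaFitSpec",
    "PosteriorDraws",
    "fit_pssa",
    "posterior_prevalence",
    "gelman_rubin_psrf",
    "split_chain_psrf",
    "compute_dic",
    "chains_to_frame",
    "PssaEstimator",
]


@dataclass(frozen=True)
class PssaPriors:
    """Priors: N(coef_mean, coef_sd^2) per probit coefficient; Beta for accuracy.

    The Beta(2, 1) defaults put increasing density toward 1 for every
    sensitivity/specificity, which together with the label-switching guard
    selects the substantively meaningful mode (informative tests).
    """

    coef_mean: float = 0.0
    coef_sd: float = 10.0
    sn_a: float = 2.0
    sn_b: float = 1.0
    sp_a: float = 2.0
    sp_b: float = 1.0

    def __post_init__(self) -> None:
        if self.coef_sd <= 0:
            raise ValueError("coef_sd must be positive")
        for v in (self.sn_a, self.sn_b, self.sp_a, self.sp_b):
            if v <= 0:
                raise ValueError("Beta prior parameters must be positive")


@dataclass(frozen=True)
class PssaFitSpec:
    """Gibbs run length: total iterations, burn-in discarded, chain count."""

    n_iterations: int = 10_000
    burn_in: int = 500
    n_chains: int = 2
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.n_chains < 1:
            raise ValueError("n_chains must be at least 1")


@dataclass
class PosteriorDraws:
    """Retained post-burn-in Gibbs output (axis 0 indexes chains)."""

    prevalence: np.ndarray  # (n_chains, n_kept)
    coefs: np.ndarray  # (n_chains, n_kept, p)
    sensitivity: np.ndarray  # (n_chains, n_kept, 2)
    specificity: np.ndarray  # (n_chains, n_kept, 2)
    burn_in: int
    psrf: dict[str, float] = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.prevalence.shape[0]

    @property
    def prevalence_flat(self) -> np.ndarray:
        return self.prevalence.reshape(-1)


def _sample_truncnorm(eta: np.ndarray, sign: np.ndarray, rng) -> np.ndarray:
    """z ~ N(eta, 1) truncated to z > 0 where sign=+1, z <= 0 where sign=-1.

    One fully vectorized inverse-CDF pass: with w = Phi(sign * eta) the
    truncated draw is eta - sign * Phi^{-1}(u * w), which evaluates ndtri on
    the small tail probability and stays accurate for |eta| up to ~35.
    """
    u = np.clip(rng.random(eta.shape[0]), 1e-15, 1.0 - 1e-15)
    w = ndtr(sign * eta)
    return eta - sign * ndtri(np.clip(u * w, 1e-300, 1.0))


def _design(markers) -> np.ndarray:
    if markers is None:
        x = np.empty((0, 0))
    else:
        x = np.asarray(getattr(markers, "values", markers), dtype=float)
        if x.ndim == 1:
            x = x[:, None]
    return x


def _run_chain(
    y1: np.ndarray,
    y2: np.ndarray,
    X: np.ndarray,
    priors: PssaPriors,
    spec: PssaFitSpec,
    rng: np.random.Generator,
):
    n, p = X.shape
    kept = spec.n_iterations - spec.burn_in
    prev_out = np.empty(kept)
    coef_out = np.empty((kept, p))
    sn_out = np.empty((kept, 2))
    sp_out = np.empty((kept, 2))

    # fixed posterior covariance factor for the probit coefficients
    prior_prec = 1.0 / priors.coef_sd**2
    P = X.T @ X + prior_prec * np.eye(p)
    cf = cho_factor(P, lower=True)
    L = np.linalg.cholesky(np.linalg.inv(P))
    prior_shift = prior_prec * priors.coef_mean * np.ones(p)

    ys = (y1, y2)
    ysum = (float(y1.sum()), float(y2.sum()))
    d = ((y1 + y2) >= 1).astype(float)  # initialize from the OR rule
    alpha = np.zeros(p)
    sn = np.array([0.8, 0.8])
    sp = np.array([0.95, 0.95])
    Xt = np.ascontiguousarray(X.T)

    for it in range(spec.n_iterations):
        eta = X @ alpha
        # -- latent status full conditional ---------------------------------
        # reporting log-likelihood ratio is affine in y_j: B_j + (A_j - B_j) y_j
        llr = 0.0
        for j in range(2):
            a_j = np.log(sn[j]) - np.log(1.0 - sp[j])
            b_j = np.log(1.0 - sn[j]) - np.log(sp[j])
            llr = llr + (b_j + (a_j - b_j) * ys[j])
        lr = np.exp(np.clip(llr, -690.0, 690.0))
        phi = ndtr(eta)
        pd1 = phi * lr / (phi * lr + (1.0 - phi))
        d = (rng.random(n) < pd1).astype(float)

        # -- probit coefficients via truncated-normal augmentation ----------
        z = _sample_truncnorm(eta, 2.0 * d - 1.0, rng)
        mean = cho_solve(cf, Xt @ z + prior_shift)
        alpha = mean + L @ rng.standard_normal(p)

        # -- reporting model: conjugate Beta updates with orientation guard --
        n1 = float(d.sum())
        n0 = n - n1
        for j in range(2):
            tp = float(d @ ys[j])
            fp = ysum[j] - tp
            for _ in range(100):
                sn_j = rng.beta(priors.sn_a + tp, priors.sn_b + (n1 - tp))
                sp_j = rng.beta(priors.sp_a + (n0 - fp), priors.sp_b + fp)
                if sn_j + sp_j > 1.0:
                    sn[j], sp[j] = sn_j, sp_j
                    break
            # else: keep previous draw (prior-dominated degenerate case)

        if it >= spec.burn_in:
            k = it - spec.burn_in
            prev_out[k] = d.mean()
            coef_out[k] = alpha
            sn_out[k] = sn
            sp_out[k] = sp

    return prev_out, coef_out, sn_out, sp_out


def fit_pssa(
    sources,
    markers=None,
    priors: PssaPriors | None = None,
    spec: PssaFitSpec | None = None,
) -> PosteriorDraws:
    """Fit the latent-class model by Gibbs sampling.

    Parameters
    ----------
    sources : ObservedSources or (n, 2) binary array.
    markers : MarkerPanel or (n, k) array of covariates; an intercept column
        is always added internally.  ``None`` fits an intercept-only outcome
        model.
    """
    sources = _as_sources(sources)
    priors = priors or PssaPriors()
    spec = spec or PssaFitSpec()
    y1 = sources.y1.astype(float)
    y2 = sources.y2.astype(float)
    both_degenerate = (y1.sum() + y2.sum() == 0) or (
        (1 - y1).sum() + (1 - y2).sum() == 0
    )
    if both_degenerate:
        raise ValueError("both sources are degenerate (all zero or all one)")

    Xm = _design(markers)
    if Xm.shape[0] not in (0, sources.n):
        raise ValueError("markers are not aligned with sources")
    if Xm.size:
        const = Xm.std(axis=0) == 0
        if const.any():
            import warnings

            warnings.warn(
                "constant marker column(s) detected; their coefficients are "
                "prior-dominated",
                RuntimeWarning,
            )
        X = np.column_stack([np.ones(sources.n), Xm])
    else:
        X = np.ones((sources.n, 1))

    ss = np.random.SeedSequence(spec.seed)
    children = ss.spawn(spec.n_chains)
    prev, coef, sn, sp = [], [], [], []
    for child in children:
        rng = np.random.default_rng(child)
        out = _run_chain(y1, y2, X, priors, spec, rng)
        prev.append(out[0])
        coef.append(out[1])
        sn.append(out[2])
        sp.append(out[3])

    draws = PosteriorDraws(
        prevalence=np.stack(prev),
        coefs=np.stack(coef),
        sensitivity=np.stack(sn),
        specificity=np.stack(sp),
        burn_in=spec.burn_in,
    )
    draws.psrf = _psrf_table(draws)
    return draws


def _psrf_table(draws: PosteriorDraws) -> dict[str, float]:
    def psrf_of(mat: np.ndarray) -> float:
        if mat.shape[0] >= 2:
            return gelman_rubin_psrf(mat)
        return split_chain_psrf(mat[0])

    table = {"prevalence": psrf_of(draws.prevalence)}
    for j in range(draws.coefs.shape[2]):
        table[f"coef_{j}"] = psrf_of(draws.coefs[:, :, j])
    for j in range(2):
        table[f"sn_{j + 1}"] = psrf_of(draws.sensitivity[:, :, j])
        table[f"sp_{j + 1}"] = psrf_of(draws.specificity[:, :, j])
    return table


def gelman_rubin_psrf(chains: np.ndarray) -> float:
    """Potential scale reduction factor from >= 2 chains of one scalar."""
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2 or chains.shape[0] < 2:
        raise ValueError("need at least two chains (rows)")
    m, n = chains.shape
    if n < 10:
        raise ValueError("chains must have length >= 10")
    means = chains.mean(axis=1)
    w = chains.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def split_chain_psrf(chain: np.ndarray) -> float:
    """PSRF of one chain split into halves (single-chain stationarity check)."""
    chain = np.asarray(chain, dtype=float)
    half = chain.shape[0] // 2
    return gelman_rubin_psrf(np.stack([chain[:half], chain[half : 2 * half]]))


def posterior_prevalence(
    draws: PosteriorDraws, level: float = 0.95
) -> PrevalenceEstimate:
    """Posterior mean prevalence with central posterior interval."""
    chain = draws.prevalence_flat
    if chain.size == 0:
        raise ValueError("empty prevalence chain")
    alpha = (1.0 - level) / 2.0
    lo, hi = np.quantile(chain, [alpha, 1.0 - alpha])
    return PrevalenceEstimate(
        "PSSA", float(chain.mean()), float(lo), float(hi), "posterior", chain.size
    )


def _observed_loglik(
    y1: np.ndarray,
    y2: np.ndarray,
    X: np.ndarray,
    alpha: np.ndarray,
    sn: np.ndarray,
    sp: np.ndarray,
) -> float:
    """Log-likelihood of (y1, y2) with the latent status summed out."""
    eta = X @ alpha
    lp1 = log_ndtr(eta)
    lp0 = log_ndtr(-eta)
    for j, y in enumerate((y1, y2)):
        lp1 = lp1 + np.where(y == 1, np.log(sn[j]), np.log(1 - sn[j]))
        lp0 = lp0 + np.where(y == 1, np.log(1 - sp[j]), np.log(sp[j]))
    return float(np.logaddexp(lp1, lp0).sum())


def compute_dic(
    draws: PosteriorDraws, sources, markers=None, max_draws: int = 500
) -> float:
    """Deviance information criterion on the marginalized likelihood.

    DIC = Dbar + pD where Dbar is the posterior mean deviance and
    pD = Dbar - D(posterior means).  Draws are thinned to at most
    ``max_draws`` for the Dbar average.
    """
    sources = _as_sources(sources)
    y1 = sources.y1.astype(float)
    y2 = sources.y2.astype(float)
    Xm = _design(markers)
    X = (
        np.column_stack([np.ones(sources.n), Xm])
        if Xm.size
        else np.ones((sources.n, 1))
    )

    coefs = draws.coefs.reshape(-1, draws.coefs.shape[2])
    sn = draws.sensitivity.reshape(-1, 2)
    sp = draws.specificity.reshape(-1, 2)
    total = coefs.shape[0]
    step = max(total // max_draws, 1)
    idx = np.arange(0, total, step)
    devs = np.empty(idx.shape[0])
    for i, k in enumerate(idx):
        ll = _observed_loglik(y1, y2, X, coefs[k], sn[k], sp[k])
        if not np.isfinite(ll):
            raise FloatingPointError(f"non-finite deviance at retained draw {k}")
        devs[i] = -2.0 * ll
    dbar = devs.mean()
    dhat = -2.0 * _observed_loglik(
        y1, y2, X, coefs.mean(axis=0), sn.mean(axis=0), sp.mean(axis=0)
    )
    return float(2.0 * dbar - dhat)


def chains_to_frame(draws: PosteriorDraws) -> pd.DataFrame:
    """Long-format chain export: chain, iteration, parameter, value."""
    rows = []
    names = (
        [("prevalence", draws.prevalence[:, :, None])]
        + [("coefs", draws.coefs)]
        + [("sn", draws.sensitivity), ("sp", draws.specificity)]
    )
    for label, arr in names:
        for c in range(arr.shape[0]):
            for j in range(arr.shape[2]):
                name = label if arr.shape[2] == 1 and label == "prevalence" else f"{label}_{j}"
                rows.append(
                    pd.DataFrame(
                        {
                            "chain": c,
                            "iteration": np.arange(arr.shape[1]) + draws.burn_in,
                            "parameter": name,
                            "value": arr[c, :, j],
                        }
                    )
                )
    return pd.concat(rows, ignore_index=True)


class PssaEstimator(BaseEstimator):
    """scikit-learn wrapper around :func:`fit_pssa`.

    ``fit(X)`` takes the two source indicator columns first and treats all
    remaining columns as outcome-model covariates.
    """

    def __init__(
        self,
        n_iterations: int = 10_000,
        burn_in: int = 500,
        n_chains: int = 2,
        priors: PssaPriors | None = None,
        level: float = 0.95,
        random_state: int | None = None,
    ):
        self.n_iterations = n_iterations
        self.burn_in = burn_in
        self.n_chains = n_chains
        self.priors = priors
        self.level = level
        self.random_state = random_state

    def fit(self, X, y=None):
        arr = np.asarray(X)
        sources = _as_sources(arr[:, :2])
        markers = arr[:, 2:] if arr.shape[1] > 2 else None
        spec = PssaFitSpec(
            n_iterations=self.n_iterations,
            burn_in=self.burn_in,
            n_chains=self.n_chains,
            seed=self.random_state,
        )
        self.draws_ = fit_pssa(sources, markers, self.priors, spec)
        est = posterior_prevalence(self.draws_, self.level)
        self.estimate_ = est
        self.prevalence_ = est.point
        self.ci_low_ = est.ci_low
        self.ci_high_ = est.ci_high
        self.n_ = sources.n
        self.psrf_ = self.draws_.psrf
        self.sensitivity_ = self.draws_.sensitivity.reshape(-1, 2).mean(axis=0)
        self.specificity_ = self.draws_.specificity.reshape(-1, 2).mean(axis=0)
        self._sources = sources
        self._markers = markers
        return self

    def dic(self) -> float:
        return compute_dic(self.draws_, self._sources, self._markers)
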