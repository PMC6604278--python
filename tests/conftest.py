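import numpy as np
import pytest

import prevcombine as pc


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def flagship_condition():
    """The design cell matching the applied example's characteristics."""
    return pc.SimulationCondition(
        true_prev=0.20,
        obs_prev_1=0.18,
        obs_prev_2=0.15,
        source_corr=0.85,
        n_markers=16,
        marker_corr_mean=0.20,
        population_size=10_000,
    )


@pytest.fixture(scope="session")
def small_latent_class_data():
    """Data generated from the latent-class model itself (probit truth,
    conditionally independent sources with known accuracy)."""
    gen = np.random.default_rng(7)
    n = 4_000
    X = gen.standard_normal((n, 3))
    alpha = np.array([-1.1, 0.5, 0.4, 0.3])
    from scipy.special import ndtr

    p = ndtr(alpha[0] + X @ alpha[1:])
    truth = (gen.random(n) < p).astype(np.int8)
    acc1 = pc.AccuracySpec(0.80, 0.97)
    acc2 = pc.AccuracySpec(0.65, 0.98)
    sources = pc.apply_misclassification(truth, acc1, acc2, pc.DependenceSpec(), seed=gen)
    return {
        "X": X,
        "alpha": alpha,
        "truth": truth,
        "sources": sources,
        "acc": (acc1, acc2),
    }


@pytest.fixture(scope="session")
def small_pssa_fit(small_latent_class_data):
    d = small_latent_class_data
    spec = pc.PssaFitSpec(n_iterations=1_200, burn_in=300, n_chains=2, seed=42)
    return pc.fit_pssa(d["sources"], d["X"], spec=spec)
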