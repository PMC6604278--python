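"""Configuration, person-level table I/O, and the linked-cohort fixture
generator.

The fixture emulates a two-source linked cohort: each person carries a
binary case flag from an administrative-records source and one from an
electronic-medical-records source (high tetrachoric agreement, one source
over-capturing and one under-capturing the true prevalence), plus a block of
socio-demographic and comorbidity covariates generated through the same
Gaussian-copula machinery as the simulation markers.  No real data is
resampled; everything is synthetic.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .estimators import (
    AssumedAccuracyPair,
    PrevalenceEstimate,
    estimate_and,
    estimate_or,
    estimate_rssa,
    estimate_source,
)
from .pssa import PssaFitSpec, fit_pssa, posterior_prevalence
from .simulate import (
    AccuracySpec,
    SimulationCondition,
    apply_misclassification,
    calibrate_accuracy,
    generate_markers,
)

__all__ = [
    "RunConfig",
    "CohortFixtureSpec",
    "load_config",
    "save_config",
    "generate_fixture_dataset",
    "estimate_all",
    "write_population",
    "read_population",
    "run_manifest",
]

_CONFIG_DEFAULTS = {
    "mode": None,
    "input_path": None,
    "output_dir": ".",
    "methods": ["source1", "source2", "OR", "AND", "RSSA", "PSSA"],
    "reps": 500,
    "bootstrap_samples": 999,
    "iterations": 10_000,
    "burn_in": 500,
    "chains": 2,
    "seed": 0,
    "assumed_accuracy": {
        "source1": {"sensitivity": 0.72, "specificity": 0.95},
        "source2": {"sensitivity": 0.87, "specificity": 0.90},
    },
    "grid": None,
    "fixture": None,
}

_GRID_KEYS = {
    "true_prev",
    "obs_prev_1",
    "obs_prev_2",
    "source_corr",
    "n_markers",
    "marker_corr_mean",
    "marker_corr_pattern",
    "population_size",
}


@dataclass
class RunConfig:
    mode: str
    input_path: str | None = None
    output_dir: str = "."
    methods: list[str] = field(
        default_factory=lambda: ["source1", "source2", "OR", "AND", "RSSA", "PSSA"]
    )
    reps: int = 500
    bootstrap_samples: int = 999
    iterations: int = 10_000
    burn_in: int = 500
    chains: int = 2
    seed: int = 0
    assumed_accuracy: dict = field(
        default_factory=lambda: _CONFIG_DEFAULTS["assumed_accuracy"].copy()
    )
    grid: dict | None = None
    fixture: dict | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "estimate", "fixture"):
            raise ValueError(f"mode must be simulate/estimate/fixture, got {self.mode!r}")
        if self.mode == "estimate" and not self.input_path:
            raise ValueError("estimate mode requires input_path")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        for name in ("reps", "bootstrap_samples", "chains"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        if self.grid is not None:
            unknown = set(self.grid) - _GRID_KEYS
            if unknown:
                raise ValueError(f"unknown grid keys: {sorted(unknown)}")

    def assumed_pair(self) -> AssumedAccuracyPair:
        a = self.assumed_accuracy
        return AssumedAccuracyPair(
            source1=AccuracySpec(**a["source1"]), source2=AccuracySpec(**a["source2"])
        )

    def pssa_spec(self) -> PssaFitSpec:
        return PssaFitSpec(
            n_iterations=self.iterations,
            burn_in=self.burn_in,
            n_chains=self.chains,
            seed=self.seed,
        )

    def conditions(self) -> list[SimulationCondition]:
        """Expand the factor grid (each key scalar or list) into conditions."""
        if not self.grid:
            raise ValueError("config has no simulation grid")
        grid = {k: v if isinstance(v, list) else [v] for k, v in self.grid.items()}
        # observed prevalences pair up positionally rather than crossing
        pairs = list(zip(grid.pop("obs_prev_1"), grid.pop("obs_prev_2")))
        keys = sorted(grid)
        out = []

        def recurse(i: int, acc: dict):
            if i == len(keys):
                for o1, o2 in pairs:
                    out.append(
                        SimulationCondition(obs_prev_1=o1, obs_prev_2=o2, **acc)
                    )
                return
            for v in grid[keys[i]]:
                recurse(i + 1, {**acc, keys[i]: v})

        recurse(0, {})
        return out


def load_config(path: str | Path) -> RunConfig:
    """Read and validate a YAML run configuration; unknown keys are rejected."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    unknown = set(raw) - set(_CONFIG_DEFAULTS)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    merged = {**{k: v for k, v in _CONFIG_DEFAULTS.items() if k != "mode"}, **raw}
    return RunConfig(**merged)


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(config), sort_keys=True))


@dataclass(frozen=True)
class CohortFixtureSpec:
    """Synthetic linked-cohort recipe.

    Defaults emulate a primary-care cohort in which the administrative source
    over-captures and the EMR source under-captures a true prevalence of
    0.25, with tetrachoric agreement 0.90 between the sources, and a
    covariate block (sex, three age groups, binary comorbidity flags with a
    mild exchangeable correlation).
    """

    n: int = 68_877
    target_prev: float = 0.25
    obs_prev_1: float = 0.309
    obs_prev_2: float = 0.249
    source_corr: float = 0.90
    covariate_prevalences: dict = field(
        default_factory=lambda: {
            "female": 0.567,
            "urban": 0.552,
            "copd": 0.019,
            "diabetes": 0.093,
            "depression": 0.160,
            "obesity": 0.221,
            "dementia": 0.016,
        }
    )
    covariate_corr: float = 0.1
    age_group_probs: tuple[float, float, float] = (0.479, 0.381, 0.140)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.target_prev, self.obs_prev_1, self.obs_prev_2):
            if not 0.0 < p < 1.0:
                raise ValueError("proportions must lie in (0, 1)")
        if not -1.0 < self.source_corr < 1.0:
            raise ValueError("source_corr must lie in (-1, 1)")
        if abs(sum(self.age_group_probs) - 1.0) > 1e-9:
            raise ValueError("age_group_probs must sum to 1")


def generate_fixture_dataset(spec: CohortFixtureSpec) -> pd.DataFrame:
    """Person-level synthetic cohort table.

    Columns: id, y_source1, y_source2, female, age_group, then the binary
    comorbidity flags.  The flags drive the true-status model, so PSSA has
    informative markers to work with; the two sources are calibrated so
    their marginal prevalences and tetrachoric correlation hit the spec.
    """
    rng = np.random.default_rng(spec.seed)
    names = list(spec.covariate_prevalences)
    prevs = np.array([spec.covariate_prevalences[k] for k in names])
    k = len(names)
    corr = np.full((k, k), spec.covariate_corr)
    np.fill_diagonal(corr, 1.0)
    panel = generate_markers(spec.n, prevs, corr, seed=rng)

    age = rng.choice(3, size=spec.n, p=np.asarray(spec.age_group_probs))

    cond = SimulationCondition(
        true_prev=spec.target_prev,
        obs_prev_1=spec.obs_prev_1,
        obs_prev_2=spec.obs_prev_2,
        source_corr=spec.source_corr,
        n_markers=k,
        population_size=spec.n,
        marker_prevalences=tuple(prevs),
    )
    acc1, acc2, dep = calibrate_accuracy(cond)

    # true status: logistic in the flags plus a strong age gradient
    from .simulate import DiseaseModel, calibrate_intercept, generate_truth

    coefs = np.log(np.linspace(1.5, 2.5, k))
    age_effect = np.array([0.0, 1.2, 2.4])[age]
    lin_extra = age_effect - age_effect.mean()
    # absorb the age effect by calibrating on the shifted linear predictor
    from scipy.optimize import brentq
    from scipy.special import expit

    lin = panel.values @ coefs + lin_extra
    b0 = float(
        brentq(lambda b: expit(b + lin).mean() - spec.target_prev, -40, 40, xtol=1e-10)
    )
    p_true = expit(b0 + lin)
    truth = (rng.random(spec.n) < p_true).astype(np.int8)
    sources = apply_misclassification(truth, acc1, acc2, dep, seed=rng)

    frame = pd.DataFrame(
        {
            "id": np.arange(1, spec.n + 1),
            "y_source1": sources.y1,
            "y_source2": sources.y2,
            "female": panel.values[:, names.index("female")]
            if "female" in names
            else rng.integers(0, 2, spec.n),
            "age_group": age,
        }
    )
    for j, name in enumerate(names):
        if name == "female":
            continue
        frame[name] = panel.values[:, j]
    return frame


def write_population(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, index=False)


def read_population(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    required = {"y_source1", "y_source2"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    return frame


def _estimate_table(
    frame: pd.DataFrame,
    config: RunConfig,
    covariate_cols: list[str],
) -> list[PrevalenceEstimate]:
    y = frame[["y_source1", "y_source2"]].to_numpy()
    out = []
    methods = config.methods
    if "source1" in methods:
        out.append(estimate_source(y, which=1))
    if "source2" in methods:
        out.append(estimate_source(y, which=2))
    if "OR" in methods:
        out.append(estimate_or(y))
    if "AND" in methods:
        out.append(estimate_and(y))
    if "RSSA" in methods:
        out.append(
            estimate_rssa(
                y,
                assumed=config.assumed_pair(),
                B=config.bootstrap_samples,
                seed=config.seed,
            )
        )
    if "PSSA" in methods:
        X = pd.get_dummies(
            frame[covariate_cols], columns=[c for c in covariate_cols if frame[c].nunique() > 2]
        ).to_numpy(dtype=float)
        draws = fit_pssa(y, X, spec=config.pssa_spec())
        out.append(posterior_prevalence(draws))
    return out


def estimate_all(
    frame: pd.DataFrame,
    config: RunConfig,
    stratify_by: str | None = None,
) -> pd.DataFrame:
    """Per-method prevalence estimates, overall and optionally stratified."""
    covariate_cols = [
        c for c in frame.columns if c not in ("id", "y_source1", "y_source2")
    ]
    if "PSSA" in config.methods and not covariate_cols:
        raise ValueError("PSSA requested but the table has no covariate columns")
    rows = []
    for est in _estimate_table(frame, config, covariate_cols):
        rows.append({"stratum": "overall", **asdict(est)})
    if stratify_by is not None:
        if stratify_by not in frame.columns:
            raise ValueError(f"stratification column {stratify_by!r} not present")
        strat_covs = [c for c in covariate_cols if c != stratify_by]
        for value, sub in frame.groupby(stratify_by):
            sub_cfg = config
            for est in _estimate_table(sub.reset_index(drop=True), sub_cfg, strat_covs):
                rows.append({"stratum": f"{stratify_by}={value}", **asdict(est)})
    return pd.DataFrame(rows)


def run_manifest(config: RunConfig, extra: dict | None = None) -> dict:
    """Reproducibility manifest: config hash, seed, and package versions."""
    import prevcombine

    payload = json.dumps(asdict(config), sort_keys=True).encode()
    return {
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "seed": config.seed,
        "prevcombine_version": prevcombine.__version__,
        "numpy_version": np.__version__,
        **(extra or {}),
    }
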