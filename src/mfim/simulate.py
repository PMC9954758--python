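"""Synthetic dyslexia cohorts with the threshold/interactive generative law.

The generator emulates the statistical structure the analysis assumes, so every
pipeline stage is testable without restricted clinical data:

* five positively correlated cognitive factors (multivariate normal z-scores);
* a latent multifactor index ``MFi = sum_i w_i f_i``;
* latent reading ``MFi + gamma * min(0, MFi - tau) + noise`` — efficient above
  the threshold ``tau``, difficulties proportional to the shortfall below it
  (a hinge, the minimal piecewise-linear reading of the threshold idea);
* six observed reading components (text/word/nonword for accuracy and speed),
  each the latent reading plus independent component noise;
* diagnosis-based ascertainment: keep children with at least one reading
  z-score at or below the cutoff (default -2);
* missing-completely-at-random predictor deletion leaving exactly
  ``n_complete`` children with every predictor.

All randomness flows from a single integer seed through named substreams
(one per stage) so stages are individually reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable

__all__ = [
    "SimulationConfig",
    "SyntheticCohort",
    "ACCURACY_COMPONENTS",
    "SPEED_COMPONENTS",
    "READING_COMPONENTS",
    "DEFAULT_FACTORS",
    "sample_factors",
    "reading_from_factors",
    "apply_diagnosis_filter",
    "inject_missingness",
    "generate_cohort",
]

DEFAULT_FACTORS = (
    "iq",
    "phonological_awareness",
    "ran_speed",
    "visual_search_speed",
    "memory",
)

#: illustrative correlation weights; phonological awareness carries the largest
#: weight, then RAN, per the field's usual ordering of reading predictors
DEFAULT_WEIGHTS = {
    "iq": 0.25,
    "phonological_awareness": 0.35,
    "ran_speed": 0.30,
    "visual_search_speed": 0.20,
    "memory": 0.20,
}

ACCURACY_COMPONENTS = ("text_accuracy", "word_accuracy", "nonword_accuracy")
SPEED_COMPONENTS = ("text_speed", "word_speed", "nonword_speed")
READING_COMPONENTS = ACCURACY_COMPONENTS + SPEED_COMPONENTS

_STAGES = ("factors", "reading", "missingness")


def _stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Named substream for one generation stage, derived from the master seed."""
    key = _STAGES.index(stage)
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


def exchangeable_correlation(k: int, rho: float = 0.3) -> np.ndarray:
    """Unit-diagonal matrix with constant off-diagonal correlation *rho*."""
    r = np.full((k, k), rho, dtype=float)
    np.fill_diagonal(r, 1.0)
    return r


@dataclass
class SimulationConfig:
    """Everything needed to generate one synthetic cohort.

    Defaults mirror the cohort structure the pipeline targets: 266 referred
    children of whom 55 carry every predictor, mildly positively correlated
    factors, and a hinge amplification below the reading threshold.  ``tau``,
    ``gamma`` and the correlation structure are illustrative, not population
    estimates.
    """

    n_total: int = 266
    n_complete: int = 55
    factor_names: tuple[str, ...] = DEFAULT_FACTORS
    factor_correlation: np.ndarray | None = None
    true_weights: dict[str, float] | None = None
    tau: float = 0.5
    gamma: float = 1.5
    noise_sd: float = 0.6
    component_noise_sd: float = 0.4
    diagnosis_cutoff: float = -2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.factor_names = tuple(self.factor_names)
        k = len(self.factor_names)
        if self.factor_correlation is None:
            self.factor_correlation = exchangeable_correlation(k)
        self.factor_correlation = np.asarray(self.factor_correlation, dtype=float)
        if self.true_weights is None:
            if set(self.factor_names) == set(DEFAULT_WEIGHTS):
                self.true_weights = {f: DEFAULT_WEIGHTS[f] for f in self.factor_names}
            else:
                self.true_weights = {f: 1.0 / k for f in self.factor_names}
        if self.factor_correlation.shape != (k, k):
            raise ValueError("factor_correlation shape does not match factor_names")
        if not np.allclose(np.diag(self.factor_correlation), 1.0):
            raise ValueError("factor_correlation must have unit diagonal")
        if set(self.true_weights) != set(self.factor_names):
            raise ValueError("true_weights keys must match factor_names")
        if any(w < 0 for w in self.true_weights.values()):
            raise ValueError("true_weights must be nonnegative")
        if self.gamma < 0:
            raise ValueError("gamma must be nonnegative")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.component_noise_sd < 0:
            raise ValueError("component_noise_sd must be nonnegative")
        if not 0 < self.n_complete <= self.n_total:
            raise ValueError("need 0 < n_complete <= n_total")

    @property
    def weight_array(self) -> np.ndarray:
        return np.array([self.true_weights[f] for f in self.factor_names])

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.factor_correlation)
        except np.linalg.LinAlgError as exc:
            raise ValueError("factor_correlation is not positive definite") from exc

    def to_yaml(self, path: str | Path) -> None:
        doc = {
            "n_total": self.n_total,
            "n_complete": self.n_complete,
            "factor_names": list(self.factor_names),
            "factor_correlation": self.factor_correlation.tolist(),
            "true_weights": {k: float(v) for k, v in self.true_weights.items()},
            "tau": self.tau,
            "gamma": self.gamma,
            "noise_sd": self.noise_sd,
            "component_noise_sd": self.component_noise_sd,
            "diagnosis_cutoff": self.diagnosis_cutoff,
            "seed": self.seed,
        }
        Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "SimulationConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        doc.update(overrides)
        if "factor_names" in doc:
            doc["factor_names"] = tuple(doc["factor_names"])
        if doc.get("factor_correlation") is not None:
            doc["factor_correlation"] = np.asarray(doc["factor_correlation"], dtype=float)
        return cls(**doc)


@dataclass
class SyntheticCohort:
    """A generated cohort plus the ground truth that produced it."""

    table: CohortTable
    config: SimulationConfig
    latent_mfi: pd.Series

    def write_truth(self, path: str | Path) -> None:
        """Structured-text truth record (config + per-child latent MFi)."""
        doc = {
            "latent_mfi": {str(k): float(v) for k, v in self.latent_mfi.items()},
        }
        cfg_path = Path(path)
        self.config.to_yaml(cfg_path.with_suffix(".config.yaml"))
        cfg_path.write_text(yaml.safe_dump(doc, sort_keys=True))


def sample_factors(
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Draw n_total children from a zero-mean MVN with the configured correlations."""
    rng = rng if rng is not None else _stage_rng(config.seed, "factors")
    chol = config.cholesky()
    z = rng.standard_normal((config.n_total, len(config.factor_names))) @ chol.T
    ids = [f"c{i + 1:04d}" for i in range(config.n_total)]
    return pd.DataFrame(z, index=pd.Index(ids, name="child_id"),
                        columns=list(config.factor_names))


def reading_from_factors(
    factors: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[pd.DataFrame, pd.Series]:
    """Observed reading components and the latent MFi behind them.

    Latent reading is ``MFi + gamma * min(0, MFi - tau) + N(0, noise_sd)``; each
    of the six observed components adds independent N(0, component_noise_sd).
    With ``gamma = 0`` the model is purely additive.
    """
    rng = rng if rng is not None else _stage_rng(config.seed, "reading")
    w = config.weight_array
    mfi = pd.Series(factors.to_numpy() @ w, index=factors.index, name="mfi")
    hinge = np.minimum(0.0, mfi.to_numpy() - config.tau)
    latent = mfi.to_numpy() + config.gamma * hinge + rng.normal(
        0.0, config.noise_sd, size=len(factors)
    )
    comps = {
        name: latent + rng.normal(0.0, config.component_noise_sd, size=len(factors))
        for name in READING_COMPONENTS
    }
    return pd.DataFrame(comps, index=factors.index), mfi


def apply_diagnosis_filter(
    table: pd.DataFrame,
    cutoff: float = -2.0,
    reading_columns: Sequence[str] = READING_COMPONENTS,
) -> pd.DataFrame:
    """Retain children with at least one reading z-score at or below *cutoff*."""
    missing = [c for c in reading_columns if c not in table.columns]
    if missing:
        raise KeyError(f"reading columns absent from table: {missing}")
    keep = table[list(reading_columns)].min(axis=1) <= cutoff
    return table.loc[keep]


def inject_missingness(
    table: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """MCAR predictor deletion leaving exactly ``n_complete`` fully observed children.

    Reading columns are never deleted.  Every non-complete child loses a random
    nonempty subset of predictors (each with probability 1/2, redrawn until
    nonempty).
    """
    rng = rng if rng is not None else _stage_rng(config.seed, "missingness")
    n = len(table)
    if config.n_complete > n:
        raise ValueError(
            f"n_complete={config.n_complete} exceeds cohort size {n} after filtering"
        )
    predictors = [c for c in config.factor_names if c in table.columns]
    out = table.copy()
    order = rng.permutation(n)
    incomplete_rows = order[config.n_complete:]
    for i in incomplete_rows:
        mask = rng.random(len(predictors)) < 0.5
        while not mask.any():
            mask = rng.random(len(predictors)) < 0.5
        cols = [p for p, m in zip(predictors, mask) if m]
        out.iloc[i, [out.columns.get_loc(c) for c in cols]] = np.nan
    return out


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Full generation pipeline: factors -> reading -> ascertainment -> missingness."""
    factors = sample_factors(config)
    components, mfi = reading_from_factors(factors, config)
    full = pd.concat([factors, components], axis=1)
    kept = apply_diagnosis_filter(full, config.diagnosis_cutoff)
    observed = inject_missingness(kept, config)
    return SyntheticCohort(
        table=CohortTable(observed),
        config=config,
        latent_mfi=mfi.loc[kept.index],
    )
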