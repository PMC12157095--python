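"""Balanced longitudinal data simulation with known residual correlation.

Outcomes follow ``y_i = X_i beta + eps_i`` with ``eps_i`` multivariate normal
and covariance ``sigma2 * D^{1/2} R D^{1/2}``, where ``R`` comes from a
:class:`~covselect.corrstruct.CorrelationStructure` and ``D = diag(delta_t^2)``
holds optional per-occasion variance multipliers.  This is both the numeric
validation device for the selection method and the test-fixture generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .corrstruct import CorrelationStructure, build_correlation_matrix

__all__ = [
    "CovariateSpec",
    "SimulationDesign",
    "LongitudinalDataset",
    "MissingDataError",
    "default_covariates",
    "simulate_dataset",
    "write_dataset",
    "read_dataset",
]

MISSING_DATA_GUIDANCE = (
    "missing values detected; this tool requires complete data — impute or "
    "otherwise resolve missingness (e.g. multiple imputation) before loading"
)


class MissingDataError(ValueError):
    pass


@dataclass(frozen=True)
class CovariateSpec:
    """One covariate column: how it is drawn and its fixed-effect coefficient.

    ``generator`` is one of ``intercept``, ``time``, ``binary`` (subject-level
    Bernoulli(param)), ``normal`` (subject-level N(param[0], param[1]^2)), or
    ``uniform`` (subject-level U(param[0], param[1])).
    """

    name: str
    generator: str
    beta: float
    param: tuple[float, ...] = ()

    def to_dict(self):
        return {"name": self.name, "generator": self.generator,
                "beta": self.beta, "param": list(self.param)}

    @classmethod
    def from_dict(cls, d):
        return cls(d["name"], d["generator"], float(d["beta"]),
                   tuple(d.get("param", ())))


def default_covariates() -> tuple[CovariateSpec, ...]:
    """Stand-in covariate battery: intercept, linear time, a binary group and
    a continuous subject-level covariate.  Effect sizes are placeholders, not
    taken from any published cohort; all are configurable via
    :class:`SimulationDesign`."""
    return (
        CovariateSpec("intercept", "intercept", beta=10.0),
        CovariateSpec("time_effect", "time", beta=-0.5),
        CovariateSpec("group", "binary", beta=2.0, param=(0.5,)),
        CovariateSpec("age", "normal", beta=0.05, param=(40.0, 10.0)),
    )


@dataclass(frozen=True)
class SimulationDesign:
    n_subjects: int
    times: tuple[float, ...]
    structure: CorrelationStructure
    sigma2: float = 1.0
    fixed_effects: tuple[CovariateSpec, ...] = field(default_factory=default_covariates)
    variance_weights: tuple[float, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        if len(self.times) < 2:
            raise ValueError("need at least 2 occasions")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be >= 0")
        if self.variance_weights is not None:
            w = tuple(float(x) for x in self.variance_weights)
            if len(w) != len(self.times):
                raise ValueError("variance_weights must have one entry per occasion")
            if abs(w[0] - 1.0) > 1e-12:
                raise ValueError("variance_weights[0] must equal 1 (reference occasion)")
            if any(x <= 0 for x in w):
                raise ValueError("variance_weights must be > 0")
            object.__setattr__(self, "variance_weights", w)

    def to_dict(self):
        return {
            "n_subjects": self.n_subjects,
            "times": list(self.times),
            "structure": self.structure.to_dict(),
            "sigma2": self.sigma2,
            "fixed_effects": [c.to_dict() for c in self.fixed_effects],
            "variance_weights": (list(self.variance_weights)
                                 if self.variance_weights is not None else None),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d):
        return cls(
            n_subjects=int(d["n_subjects"]),
            times=tuple(d["times"]),
            structure=CorrelationStructure.from_dict(d["structure"]),
            sigma2=float(d.get("sigma2", 1.0)),
            fixed_effects=tuple(CovariateSpec.from_dict(c)
                                for c in d.get("fixed_effects", [])) or default_covariates(),
            variance_weights=(tuple(d["variance_weights"])
                              if d.get("variance_weights") else None),
            seed=int(d.get("seed", 0)),
        )


@dataclass
class LongitudinalDataset:
    """Long-format repeated-measures table plus a role map.

    Every (subject, time) pair is unique and no cell is missing; for
    discrete-structure analyses the design must additionally be balanced
    (every subject seen at every occasion).
    """

    data: pd.DataFrame
    subject: str = "subject"
    time: str = "time"
    outcome: str = "outcome"

    def __post_init__(self):
        df = self.data
        for col in (self.subject, self.time, self.outcome):
            if col not in df.columns:
                raise ValueError(f"role column {col!r} not found in data")
        if df.isna().any().any():
            raise MissingDataError(MISSING_DATA_GUIDANCE)
        if df.duplicated(subset=[self.subject, self.time]).any():
            dup = df[df.duplicated(subset=[self.subject, self.time], keep=False)]
            raise ValueError(
                f"duplicated (subject, time) pairs: "
                f"{dup[[self.subject, self.time]].head().to_dict('records')}"
            )
        for col in (self.time, self.outcome):
            if not pd.api.types.is_numeric_dtype(df[col]):
                raise ValueError(f"column {col!r} must be numeric")
        self.data = df.sort_values([self.subject, self.time], kind="mergesort") \
                      .reset_index(drop=True)

    @property
    def n_subjects(self) -> int:
        return self.data[self.subject].nunique()

    @property
    def subjects(self) -> np.ndarray:
        return self.data[self.subject].unique()

    @property
    def occasions(self) -> np.ndarray:
        return np.sort(self.data[self.time].unique())

    @property
    def covariate_names(self) -> list[str]:
        roles = {self.subject, self.time, self.outcome}
        return [c for c in self.data.columns if c not in roles]

    def is_balanced(self) -> bool:
        occ = self.occasions
        counts = self.data.groupby(self.subject, sort=False)[self.time] \
                          .apply(lambda s: len(s) == len(occ) and
                                 np.array_equal(np.sort(s.to_numpy()), occ))
        return bool(counts.all())

    def require_balanced(self):
        if not self.is_balanced():
            raise ValueError(
                "unbalanced design: not every subject is observed at every "
                "occasion; use a continuous-time correlation structure or "
                "complete the data first"
            )

    def outcome_matrix(self) -> np.ndarray:
        """n_subjects x T outcome matrix (balanced data only)."""
        self.require_balanced()
        T = len(self.occasions)
        return self.data[self.outcome].to_numpy().reshape(self.n_subjects, T)


def _draw_covariates(spec: CovariateSpec, rng, times):
    T = len(times)
    if spec.generator == "intercept":
        return np.ones(T)
    if spec.generator == "time":
        return np.asarray(times, dtype=float)
    if spec.generator == "binary":
        p = spec.param[0] if spec.param else 0.5
        return np.full(T, float(rng.random() < p))
    if spec.generator == "normal":
        mu, sd = (spec.param + (0.0, 1.0))[:2]
        return np.full(T, rng.normal(mu, sd))
    if spec.generator == "uniform":
        lo, hi = (spec.param + (0.0, 1.0))[:2]
        return np.full(T, rng.uniform(lo, hi))
    raise ValueError(f"unknown covariate generator {spec.generator!r}")


def simulate_dataset(design: SimulationDesign) -> LongitudinalDataset:
    """Draw a balanced longitudinal dataset from the design.

    Each subject gets an independent random stream derived from the root seed
    and the subject index, so increasing ``n_subjects`` extends the dataset
    without reshuffling earlier subjects.  The residual covariance is
    assembled as ``sigma2 * D^{1/2} R D^{1/2}`` and Cholesky-factored; a
    non-positive-definite assembly is an error, never regularized.
    """
    times = np.asarray(design.times, dtype=float)
    T = len(times)
    R = build_correlation_matrix(design.structure, times).values
    delta = (np.asarray(design.variance_weights, dtype=float)
             if design.variance_weights is not None else np.ones(T))
    cov = design.sigma2 * (delta[:, None] * R * delta[None, :])
    if design.sigma2 > 0:
        L = np.linalg.cholesky(cov)  # raises LinAlgError if not PD
    else:
        L = np.zeros((T, T))

    rows = []
    for i in range(design.n_subjects):
        rng = np.random.default_rng(np.random.SeedSequence(
            entropy=design.seed, spawn_key=(i,)))
        cols = {}
        eta = np.zeros(T)
        for spec in design.fixed_effects:
            x = _draw_covariates(spec, rng, times)
            eta += spec.beta * x
            if spec.generator != "intercept":
                cols[spec.name] = x
        eps = L @ rng.standard_normal(T)
        y = eta + eps
        for t_idx in range(T):
            row = {"subject": i + 1, "time": times[t_idx], "outcome": y[t_idx]}
            row.update({k: v[t_idx] for k, v in cols.items()})
            rows.append(row)
    df = pd.DataFrame(rows)
    return LongitudinalDataset(df)


def write_dataset(dataset: LongitudinalDataset, path) -> None:
    """Write the long-format table to CSV (full float precision)."""
    dataset.data.to_csv(path, index=False, float_format="%.17g")


def read_dataset(path, subject="subject", time="time", outcome="outcome") -> LongitudinalDataset:
    """Read a long-format CSV and validate it against the dataset invariants.

    Missing cells, duplicate (subject, time) rows, absent role columns and
    non-numeric outcome/time are all hard errors.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in (subject, time, outcome):
        if col not in df.columns:
            raise ValueError(f"role column {col!r} not found in {path.name} "
                             f"(columns: {list(df.columns)})")
    return LongitudinalDataset(df, subject=subject, time=time, outcome=outcome)
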