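"""Parametric surrogate family: predictor encoding, polynomial least squares
and the standardized multivariate mean squared error.

The surrogate problem is y = psi(x) + eps with y the 6-month outcome triple
and x a 9-vector of numeric regressors (baseline BMI, age, sex, the three
diet-level multipliers and the three physical-activity factors).  The
parametric family defines psi as a multivariate polynomial of total degree d
in the standardized features; each output is fitted by ordinary least
squares on the same monomial basis.  Model quality is summarised by a single
pooled scalar: the mean of the squared errors after z-scoring each output by
its training statistics, so a training-mean predictor scores exactly 1.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_design import AnthropometricProfile, SubjectSpec
from .energy_model import LEVEL_MULTIPLIERS
from .synthetic_simulator import OUTCOME_NAMES

__all__ = [
    "PREDICTOR_NAMES",
    "IMPORTANCE_ORDER",
    "Standardization",
    "ParametricFit",
    "encode_predictors",
    "predictor_frame",
    "design_matrices",
    "monomial_exponents",
    "fit_parametric",
    "predict_parametric",
    "standardized_mse",
]

#: Regressor order of the 9-dimensional predictor vector.
PREDICTOR_NAMES = (
    "bmi0", "age", "sex", "carb_mult", "protein_mult", "fat_mult",
    "n_pa", "d_pa", "i_pa",
)

#: Conventional reporting order for importance tables/matrices:
#: anthropometrics and diet first, physical activity last.
IMPORTANCE_ORDER = (
    "bmi0", "carb_mult", "age", "protein_mult", "fat_mult", "sex",
    "n_pa", "d_pa", "i_pa",
)


@dataclass(frozen=True)
class Standardization:
    """Per-column mean/sd (population sd, ddof=0; zero sds replaced by 1)."""

    mean: np.ndarray
    sd: np.ndarray

    @classmethod
    def fit(cls, X: np.ndarray) -> "Standardization":
        X = np.asarray(X, dtype=float)
        mean = X.mean(axis=0)
        sd = X.std(axis=0)
        sd = np.where(sd == 0, 1.0, sd)
        return cls(mean=mean, sd=sd)

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd

    def inverse(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(Z, dtype=float) * self.sd + self.mean


def encode_predictors(
    spec: SubjectSpec, profile: AnthropometricProfile
) -> np.ndarray:
    """Deterministic 9-vector of numeric regressors for one subject.

    Sedentary subjects get ``n_pa = d_pa = i_pa = 0``; sex encodes female as
    0 and male as 1; diet levels map to their gram multipliers 0.8/1.0/1.5.
    """
    return np.array(
        [
            profile.bmi0,
            float(spec.age),
            1.0 if spec.sex == "male" else 0.0,
            LEVEL_MULTIPLIERS[spec.carb_level],
            LEVEL_MULTIPLIERS[spec.protein_level],
            LEVEL_MULTIPLIERS[spec.fat_level],
            float(spec.sessions_per_week),
            float(spec.session_duration or 0),
            float(spec.session_intensity or 0),
        ]
    )


def predictor_frame(dataset: pd.DataFrame) -> pd.DataFrame:
    """Numeric predictor columns derived from a design/dataset table."""
    return pd.DataFrame(
        {
            "bmi0": dataset["bmi0"].astype(float),
            "age": dataset["age"].astype(float),
            "sex": (dataset["sex"] == "male").astype(float),
            "carb_mult": dataset["carb"].map(LEVEL_MULTIPLIERS).astype(float),
            "protein_mult": dataset["protein"].map(LEVEL_MULTIPLIERS).astype(float),
            "fat_mult": dataset["fat"].map(LEVEL_MULTIPLIERS).astype(float),
            "n_pa": dataset["n_pa"].astype(float),
            "d_pa": dataset["d_pa"].fillna(0).astype(float),
            "i_pa": dataset["i_pa"].fillna(0).astype(float),
        },
        index=dataset.index,
    )


def design_matrices(dataset: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """(X, Y) numpy matrices for fitting: predictors and the outcome triple."""
    X = predictor_frame(dataset).to_numpy()
    Y = dataset[list(OUTCOME_NAMES)].to_numpy(dtype=float)
    return X, Y


def monomial_exponents(n_features: int, degree: int) -> list[tuple[int, ...]]:
    """Exponent tuples of all monomials with total degree <= degree.

    Ordered by total degree, then lexicographically; the first entry is the
    intercept (all-zero exponents).
    """
    exps: list[tuple[int, ...]] = []
    for d in range(degree + 1):
        for combo in itertools.combinations_with_replacement(range(n_features), d):
            e = [0] * n_features
            for idx in combo:
                e[idx] += 1
            exps.append(tuple(e))
    # dedupe while keeping order (combinations_with_replacement is unique)
    return exps


def _expand(Z: np.ndarray, exponents: list[tuple[int, ...]]) -> np.ndarray:
    n = Z.shape[0]
    B = np.empty((n, len(exponents)))
    for j, exp in enumerate(exponents):
        col = np.ones(n)
        for f, e in enumerate(exp):
            if e:
                col = col * Z[:, f] ** e
        B[:, j] = col
    return B


@dataclass(frozen=True)
class ParametricFit:
    """A fitted polynomial surrogate of total degree ``degree``.

    Coefficients live in standardized feature/output space; the
    standardization statistics required to round-trip to original units are
    stored alongside.
    """

    degree: int
    exponents: list[tuple[int, ...]]
    coef: np.ndarray            # (n_monomials, n_outputs)
    x_stats: Standardization
    y_stats: Standardization
    rank: int

    def to_json(self, path) -> None:
        payload = {
            "degree": self.degree,
            "exponents": [list(e) for e in self.exponents],
            "coef": self.coef.tolist(),
            "x_mean": self.x_stats.mean.tolist(),
            "x_sd": self.x_stats.sd.tolist(),
            "y_mean": self.y_stats.mean.tolist(),
            "y_sd": self.y_stats.sd.tolist(),
            "rank": self.rank,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "ParametricFit":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            degree=d["degree"],
            exponents=[tuple(e) for e in d["exponents"]],
            coef=np.asarray(d["coef"], dtype=float),
            x_stats=Standardization(
                np.asarray(d["x_mean"]), np.asarray(d["x_sd"])
            ),
            y_stats=Standardization(
                np.asarray(d["y_mean"]), np.asarray(d["y_sd"])
            ),
            rank=d["rank"],
        )


def fit_parametric(X: np.ndarray, Y: np.ndarray, degree: int) -> ParametricFit:
    """Least-squares polynomial fit of total degree ``degree`` per output.

    Features are z-scored before the monomial expansion (conditioning);
    outputs are z-scored by their training statistics.  A rank-deficient
    basis triggers a warning and is solved by the minimum-norm solution.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if degree < 0:
        raise ValueError("degree must be >= 0")
    x_stats = Standardization.fit(X)
    y_stats = Standardization.fit(Y)
    exps = monomial_exponents(X.shape[1], degree)
    if X.shape[0] < len(exps):
        warnings.warn(
            f"{X.shape[0]} rows < {len(exps)} basis monomials: "
            "system is underdetermined; using the least-norm solution",
            stacklevel=2,
        )
    B = _expand(x_stats.transform(X), exps)
    coef, _, rank, _ = np.linalg.lstsq(B, y_stats.transform(Y), rcond=None)
    if rank < len(exps):
        warnings.warn(
            f"monomial basis is rank deficient (rank {rank} < {len(exps)}); "
            "coefficients are the least-norm solution",
            stacklevel=2,
        )
    return ParametricFit(
        degree=degree, exponents=exps, coef=coef,
        x_stats=x_stats, y_stats=y_stats, rank=int(rank),
    )


def predict_parametric(fit: ParametricFit, X: np.ndarray) -> np.ndarray:
    """Evaluate a fit; predictions are returned in original output units."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    B = _expand(fit.x_stats.transform(X), fit.exponents)
    return fit.y_stats.inverse(B @ fit.coef)


def standardized_mse(
    Y: np.ndarray, Y_hat: np.ndarray, y_stats: Standardization
) -> float:
    """Pooled standardized MSE: mean over all n x q z-scored squared errors.

    Each output is scaled by its *training* standard deviation, making the
    single scalar comparable across outputs and models; predicting the
    training mean scores exactly 1 in sample.
    """
    Y = np.asarray(Y, dtype=float)
    Y_hat = np.asarray(Y_hat, dtype=float)
    if Y.shape != Y_hat.shape:
        raise ValueError("Y and Y_hat must have the same shape")
    if Y.ndim == 1:
        Y = Y[:, None]
        Y_hat = Y_hat[:, None]
    z = (Y - Y_hat) / y_stats.sd
    return float(np.mean(z**2))
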