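"""End-to-end study orchestration.

Runs the whole pipeline behind one entry point: enumerate (or subsample) the
factorial design, simulate 6-month outcomes, split into a 2/3 train and 1/3
test partition, fit the five surrogate models (linear, polynomial degrees
2-4, multivariate random forest), compute the pooled standardized in/out-of-
sample MSE table, the Pearson correlation matrix, true-vs-predicted
diagnostics, the permutation/pairwise importance tables and the minimal-
depth matrix, and export everything as CSV/JSON (optionally with scatter
plots).  A single integer seed makes the full chain reproducible.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort_design import enumerate_design
from .importance import depth_matrix, importance_table, pairwise_table
from .random_forest import Forest, ForestParams, fit_forest, predict_forest
from .surrogate_models import (
    IMPORTANCE_ORDER,
    ParametricFit,
    Standardization,
    design_matrices,
    fit_parametric,
    predict_parametric,
    standardized_mse,
)
from .synthetic_simulator import (
    OUTCOME_NAMES,
    ResponseSurfaceParams,
    generate_dataset,
)

__all__ = [
    "StudyConfig",
    "ComparisonReport",
    "StudyResult",
    "split_dataset",
    "correlation_matrix",
    "build_dataset",
    "run_model_comparison",
    "run_full_study",
    "export_report",
]

MODEL_NAMES = ("linear", "poly2", "poly3", "poly4", "rf")


@dataclass(frozen=True)
class StudyConfig:
    """Desk-scale defaults: a 5,000-subject subsample of the 46,170-cell
    design, 100 trees, 2/3 train split, seed 1."""

    seed: int = 1
    n_subjects: int | None = 5000      # None -> the full design
    train_fraction: float = 2.0 / 3.0
    degrees: tuple[int, ...] = (1, 2, 3, 4)
    forest: ForestParams = field(default_factory=ForestParams)
    surface: ResponseSurfaceParams = field(default_factory=ResponseSurfaceParams)
    n_reps_single: int = 5
    n_reps_pairs: int = 3

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs: dict = {}
        for key in ("seed", "n_subjects", "train_fraction", "n_reps_single",
                    "n_reps_pairs"):
            if key in raw:
                kwargs[key] = raw[key]
        if "degrees" in raw:
            kwargs["degrees"] = tuple(raw["degrees"])
        if "forest" in raw:
            kwargs["forest"] = ForestParams(**raw["forest"])
        if "surface" in raw:
            kwargs["surface"] = ResponseSurfaceParams(**raw["surface"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_subjects": self.n_subjects,
            "train_fraction": self.train_fraction,
            "degrees": list(self.degrees),
            "forest": {
                "n_trees": self.forest.n_trees,
                "mtry": self.forest.mtry,
                "min_leaf": self.forest.min_leaf,
                "max_depth": self.forest.max_depth,
                "bootstrap": self.forest.bootstrap,
            },
            "n_reps_single": self.n_reps_single,
            "n_reps_pairs": self.n_reps_pairs,
        }


def _child_seeds(seed: int, k: int = 5) -> np.ndarray:
    """Derive independent sub-stream seeds (< 2**31) from the master seed."""
    return np.random.default_rng(seed).integers(0, 2**31 - 1, size=k)


def split_dataset(
    data: pd.DataFrame, train_fraction: float = 2.0 / 3.0, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Uniform random disjoint/exhaustive partition into train and test.

    The train set takes ``round(train_fraction * m)`` rows (30,780 of the
    full 46,170-row design at the default 2/3); reproducible per seed.
    """
    m = len(data)
    if m < 3:
        raise ValueError("need at least 3 rows to split")
    n_train = int(round(train_fraction * m))
    perm = np.random.default_rng(seed).permutation(m)
    train_idx = np.sort(perm[:n_train])
    test_idx = np.sort(perm[n_train:])
    return data.iloc[train_idx], data.iloc[test_idx]


def correlation_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Sample Pearson correlation matrix of the numeric columns.

    rho_ij = [(m-1) s_i s_j]^-1 * sum_k (x_i^k - mu_i)(x_j^k - mu_j), with
    sample (ddof=1) standard deviations.  Zero-variance columns yield NaN
    entries and a warning rather than a silent 0.
    """
    num = table.select_dtypes(include=[np.number]).astype(float)
    if len(num) < 2:
        raise ValueError("need at least 2 rows")
    X = num.to_numpy()
    m = X.shape[0]
    mu = X.mean(axis=0)
    s = X.std(axis=0, ddof=1)
    zero = s == 0
    if zero.any():
        bad = list(num.columns[zero])
        warnings.warn(
            f"zero-variance columns {bad}: correlation undefined (NaN)",
            stacklevel=2,
        )
    centered = X - mu
    cov = centered.T @ centered / (m - 1)
    denom = np.outer(s, s)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, cov / np.where(denom == 0, 1, denom), np.nan)
    np.fill_diagonal(rho, np.where(zero, np.nan, 1.0))
    return pd.DataFrame(rho, index=num.columns, columns=num.columns)


def build_dataset(config: StudyConfig) -> pd.DataFrame:
    """Enumerate the design, subsample it if requested, simulate outcomes."""
    sub_seed, noise_seed, *_ = _child_seeds(config.seed)
    specs = enumerate_design()
    if config.n_subjects is not None and config.n_subjects < len(specs):
        keep = np.sort(
            np.random.default_rng(sub_seed).choice(
                len(specs), size=config.n_subjects, replace=False
            )
        )
        specs = [specs[i] for i in keep]
    return generate_dataset(specs, params=config.surface, seed=int(noise_seed))


@dataclass
class ComparisonReport:
    """Surrogate-model comparison on one shared train/test split."""

    mse: pd.DataFrame                     # model, mse_in, mse_out
    n_train: int
    n_test: int
    seed: int
    y_stats: Standardization              # training-output z-scoring stats
    fits: Mapping[str, ParametricFit | Forest]
    predictions: pd.DataFrame             # long: model, output, y_true, y_pred


def run_model_comparison(
    data: pd.DataFrame, config: StudyConfig | None = None
) -> ComparisonReport:
    """Fit all five surrogates on the same split and tabulate pooled MSEs.

    All models share one output standardization (training statistics), so
    the in/out-of-sample MSE scalars are directly comparable across models.
    """
    config = StudyConfig() if config is None else config
    _, _, split_seed, forest_seed, _ = _child_seeds(config.seed)
    train, test = split_dataset(data, config.train_fraction, seed=int(split_seed))
    X_tr, Y_tr = design_matrices(train)
    X_te, Y_te = design_matrices(test)
    y_stats = Standardization.fit(Y_tr)

    fits: dict[str, ParametricFit | Forest] = {}
    rows = []
    pred_rows = []
    for d in config.degrees:
        name = "linear" if d == 1 else f"poly{d}"
        fit = fit_parametric(X_tr, Y_tr, degree=d)
        fits[name] = fit
        hat_in = predict_parametric(fit, X_tr)
        hat_out = predict_parametric(fit, X_te)
        rows.append(
            {
                "model": name,
                "mse_in": standardized_mse(Y_tr, hat_in, y_stats),
                "mse_out": standardized_mse(Y_te, hat_out, y_stats),
            }
        )
        pred_rows.append((name, hat_out))

    forest = fit_forest(X_tr, Y_tr, params=config.forest, seed=int(forest_seed))
    fits["rf"] = forest
    hat_in = predict_forest(forest, X_tr)
    hat_out = predict_forest(forest, X_te)
    rows.append(
        {
            "model": "rf",
            "mse_in": standardized_mse(Y_tr, hat_in, y_stats),
            "mse_out": standardized_mse(Y_te, hat_out, y_stats),
        }
    )
    pred_rows.append(("rf", hat_out))

    long_rows = []
    for name, hat in pred_rows:
        for j, out_name in enumerate(OUTCOME_NAMES):
            long_rows.append(
                pd.DataFrame(
                    {
                        "model": name,
                        "output": out_name,
                        "y_true": Y_te[:, j],
                        "y_pred": hat[:, j],
                    }
                )
            )
    return ComparisonReport(
        mse=pd.DataFrame(rows),
        n_train=len(train),
        n_test=len(test),
        seed=config.seed,
        y_stats=y_stats,
        fits=fits,
        predictions=pd.concat(long_rows, ignore_index=True),
    )


@dataclass
class StudyResult:
    config: StudyConfig
    dataset: pd.DataFrame
    comparison: ComparisonReport
    correlations: pd.DataFrame
    importance_single: pd.DataFrame
    importance_pairs: pd.DataFrame
    depth: pd.DataFrame


def run_full_study(config: StudyConfig | None = None) -> StudyResult:
    """Design -> simulate -> split -> fit -> evaluate -> importance."""
    config = StudyConfig() if config is None else config
    *_, imp_seed = _child_seeds(config.seed)
    data = build_dataset(config)
    report = run_model_comparison(data, config)

    _, _, split_seed, _, _ = _child_seeds(config.seed)
    train, test = split_dataset(data, config.train_fraction, seed=int(split_seed))
    X_te, Y_te = design_matrices(test)
    forest: Forest = report.fits["rf"]  # type: ignore[assignment]

    single = importance_table(
        forest, X_te, Y_te,
        seed=int(imp_seed), n_reps=config.n_reps_single, y_stats=report.y_stats,
    )
    pairs = pairwise_table(
        forest, X_te, Y_te,
        seed=int(imp_seed) + 1, n_reps=config.n_reps_pairs, y_stats=report.y_stats,
    )
    depth = depth_matrix(forest).to_frame(order=IMPORTANCE_ORDER)

    num_cols = [
        "bmi0", "age", "n_pa", "d_pa", "i_pa", "height_m", "weight_kg",
        *OUTCOME_NAMES,
    ]
    corr = correlation_matrix(data[num_cols])
    return StudyResult(
        config=config,
        dataset=data,
        comparison=report,
        correlations=corr,
        importance_single=single,
        importance_pairs=pairs,
        depth=depth,
    )


def export_report(result: StudyResult, out_dir, plots: bool = False) -> list[Path]:
    """Write the canonical CSV/JSON outputs (optionally PNG diagnostics).

    Reruns with the same config and seed produce byte-identical CSV/JSON.
    Emits six CSV files (model comparison, correlations, single and pairwise
    importance, depth matrix, true-vs-predicted pairs) plus metadata.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _write_csv(df: pd.DataFrame, name: str, index: bool = False) -> None:
        path = out / name
        df.to_csv(path, index=index)
        written.append(path)

    _write_csv(result.comparison.mse, "model_comparison.csv")
    _write_csv(result.correlations, "correlations.csv", index=True)
    _write_csv(result.importance_single, "importance_single.csv")
    _write_csv(result.importance_pairs, "importance_pairs.csv")
    _write_csv(result.depth, "depth_matrix.csv", index=True)
    _write_csv(result.comparison.predictions, "predictions.csv")

    meta = {
        "package": "t2demu",
        "version": __version__,
        "config": result.config.to_dict(),
        "n_rows": len(result.dataset),
        "n_train": result.comparison.n_train,
        "n_test": result.comparison.n_test,
    }
    meta_path = out / "metadata.json"
    with open(meta_path, "w") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)
    written.append(meta_path)

    if plots:
        written.extend(_diagnostic_plots(result, out))
    return written


def _diagnostic_plots(result: StudyResult, out: Path) -> list[Path]:
    """True-vs-predicted scatter grid per model/output (PNG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    preds = result.comparison.predictions
    models = preds["model"].unique()
    fig, axes = plt.subplots(
        len(models), len(OUTCOME_NAMES),
        figsize=(3 * len(OUTCOME_NAMES), 2.5 * len(models)),
        squeeze=False,
    )
    for r, model in enumerate(models):
        for c, out_name in enumerate(OUTCOME_NAMES):
            sub = preds[(preds["model"] == model) & (preds["output"] == out_name)]
            ax = axes[r][c]
            ax.scatter(sub["y_true"], sub["y_pred"], s=2, alpha=0.3)
            lims = [sub["y_true"].min(), sub["y_true"].max()]
            ax.plot(lims, lims, lw=0.8, color="orange")
            ax.set_title(f"{model}: {out_name}", fontsize=8)
    fig.tight_layout()
    path = out / "true_vs_predicted.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    written.append(path)
    return written
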