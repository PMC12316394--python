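"""Locally 3D-monotone power estimation with gradient-boosted trees.

Per-N P-spline surfaces guarantee monotonicity in detection rate and
|logFC| but not across N, and the per-N fits can cross where both
predictors are near zero.  For those local regions this module fits a
gradient-boosted tree ensemble on (pi, |beta|, N) with hard
monotone-increasing constraints on all three features: any candidate
split that would break monotonicity is never accepted, so the fitted
step-surface is exactly monotone along every axis.

Records are pooled over all N, filtered to the region, split 80/10/10
into train/validation/test (seeded).  Tree depth and learning rate are
chosen by validation RMSE with early stopping (squared-error objective);
the test-split RMSE is computed once afterwards and reported, never used
for selection.  XGBoost is the default backend; LightGBM is available as
an independent cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import ValidationError

__all__ = ["GBTSurface", "fit_gbt", "predict_gbt", "crosscheck_backends"]

FEATURES = ["pi_g", "abs_beta_g", "N"]
MONOTONE = (1, 1, 1)
DEFAULT_DEPTHS = (2, 3, 4, 5, 6)
DEFAULT_LEARNING_RATES = (0.05, 0.1, 0.3)
MAX_TREES = 500
PATIENCE = 20


@dataclass
class GBTSurface:
    """A fitted monotone tree ensemble over (pi, |beta|, N) for one region."""

    model: object
    backend: str
    region: tuple[tuple[float, float], tuple[float, float]]
    n_range: tuple[int, int]
    hyperparams: dict
    split_seed: int
    rmse_validation: float
    rmse_test: float
    fit_info: dict = field(default_factory=dict)

    def predict(self, pi, abs_beta, N, return_flag: bool = False):
        """Predicted power, clamped to [0, 1]; flags region extrapolation."""
        scalar = np.ndim(pi) == 0 and np.ndim(abs_beta) == 0 and np.ndim(N) == 0
        pi = np.atleast_1d(np.asarray(pi, dtype=float))
        ab = np.atleast_1d(np.asarray(abs_beta, dtype=float))
        n = np.atleast_1d(np.asarray(N, dtype=float))
        pi, ab, n = np.broadcast_arrays(pi, ab, n)
        X = np.column_stack([pi, ab, n])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            val = np.clip(self.model.predict(X), 0.0, 1.0)
        (plo, phi), (blo, bhi) = self.region
        flag = (
            (pi < plo) | (pi > phi) | (ab < blo) | (ab > bhi)
            | (n < self.n_range[0]) | (n > self.n_range[1])
        )
        if scalar:
            return (float(val[0]), bool(flag[0])) if return_flag else float(val[0])
        return (val, flag) if return_flag else val


def _region_filter(records: pd.DataFrame, region) -> pd.DataFrame:
    if region is None:
        return records
    (plo, phi), (blo, bhi) = region
    m = (
        records["pi_g"].between(plo, phi)
        & records["abs_beta_g"].between(blo, bhi)
    )
    return records.loc[m]


def _split_801010(
    n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(round(0.8 * n))
    n_val = int(round(0.1 * n))
    return perm[:n_train], perm[n_train : n_train + n_val], perm[n_train + n_val :]


def _fit_one_xgb(Xtr, ytr, Xval, yval, depth, lr, seed):
    import xgboost as xgb

    model = xgb.XGBRegressor(
        objective="reg:squarederror",
        n_estimators=MAX_TREES,
        max_depth=depth,
        learning_rate=lr,
        monotone_constraints=str(MONOTONE),
        early_stopping_rounds=PATIENCE,
        random_state=seed,
        verbosity=0,
    )
    model.fit(Xtr, ytr, eval_set=[(Xval, yval)], verbose=False)
    pred = model.predict(Xval)
    return model, float(np.sqrt(np.mean((pred - yval) ** 2)))


def _fit_one_lgb(Xtr, ytr, Xval, yval, depth, lr, seed):
    import lightgbm as lgb

    model = lgb.LGBMRegressor(
        objective="regression",
        n_estimators=MAX_TREES,
        max_depth=depth,
        num_leaves=2**depth,
        learning_rate=lr,
        monotone_constraints=list(MONOTONE),
        random_state=seed,
        verbosity=-1,
        min_child_samples=5,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        model.fit(
            Xtr,
            ytr,
            eval_set=[(Xval, yval)],
            callbacks=[lgb.early_stopping(PATIENCE, verbose=False)],
        )
        pred = model.predict(Xval)
    return model, float(np.sqrt(np.mean((pred - yval) ** 2)))


def fit_gbt(
    records: pd.DataFrame,
    region: tuple[tuple[float, float], tuple[float, float]] | None = None,
    hyper_grid: dict | None = None,
    seed: int = 0,
    backend: str = "xgboost",
) -> GBTSurface:
    """Fit the monotone GBT power model on records pooled over all N.

    ``records`` is a power table with at least ``pi_g, abs_beta_g, N,
    power``; ``region`` is ``((pi_lo, pi_hi), (beta_lo, beta_hi))``,
    typically the bounding box from crossing detection (None = all records).
    ``hyper_grid`` may override ``{"max_depth": ..., "learning_rate": ...}``.
    Requires >= 50 records in the region and >= 2 distinct N values (with
    one N the constraint along N would be vacuous).
    """
    sub = _region_filter(records, region).reset_index(drop=True)
    if len(sub) < 50:
        raise ValidationError(
            f"need >= 50 records in the region to fit, got {len(sub)}"
        )
    n_values = sorted(set(int(v) for v in sub["N"]))
    if len(n_values) < 2:
        raise ValidationError(
            "need >= 2 distinct N values (monotonicity in N is unverifiable "
            "from a single sample size)"
        )
    X = sub[FEATURES].to_numpy(dtype=float)
    y = sub["power"].to_numpy(dtype=float)
    tr, va, te = _split_801010(len(sub), seed)
    Xtr, ytr = X[tr], y[tr]
    Xval, yval = X[va], y[va]
    Xte, yte = X[te], y[te]

    grid = hyper_grid or {}
    depths = tuple(grid.get("max_depth", DEFAULT_DEPTHS))
    rates = tuple(grid.get("learning_rate", DEFAULT_LEARNING_RATES))
    fit_one = {"xgboost": _fit_one_xgb, "lightgbm": _fit_one_lgb}[backend]

    best = None
    selection_log = []
    for depth in depths:
        for lr in rates:
            model, rmse_val = fit_one(Xtr, ytr, Xval, yval, depth, lr, seed)
            selection_log.append(
                {"max_depth": depth, "learning_rate": lr, "rmse_val": rmse_val}
            )
            if best is None or rmse_val < best["rmse_val"]:
                best = {
                    "model": model,
                    "rmse_val": rmse_val,
                    "max_depth": depth,
                    "learning_rate": lr,
                }
    assert best is not None
    # test error measured exactly once, after selection is final
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        pred_te = best["model"].predict(Xte)
    rmse_test = float(np.sqrt(np.mean((pred_te - yte) ** 2))) if len(te) else float("nan")

    if region is None:
        region = (
            (float(sub["pi_g"].min()), float(sub["pi_g"].max())),
            (float(sub["abs_beta_g"].min()), float(sub["abs_beta_g"].max())),
        )
    return GBTSurface(
        model=best["model"],
        backend=backend,
        region=region,
        n_range=(n_values[0], n_values[-1]),
        hyperparams={
            "max_depth": best["max_depth"],
            "learning_rate": best["learning_rate"],
            "n_trees_max": MAX_TREES,
            "early_stopping_rounds": PATIENCE,
        },
        split_seed=seed,
        rmse_validation=best["rmse_val"],
        rmse_test=rmse_test,
        fit_info={
            "selection_log": selection_log,
            "n_records": len(sub),
            "n_values": n_values,
            "split_sizes": (len(tr), len(va), len(te)),
        },
    )


def predict_gbt(
    surface: GBTSurface, pi: float, abs_beta: float, N: int, return_flag: bool = False
):
    """Functional alias for :meth:`GBTSurface.predict` on a single query."""
    return surface.predict(pi, abs_beta, N, return_flag=return_flag)


def monotonicity_violations(
    surface: GBTSurface, n_pi: int = 21, n_beta: int = 21, n_N: int = 5
) -> int:
    """Count axis-aligned forward-difference violations on a 3D grid."""
    (plo, phi), (blo, bhi) = surface.region
    pis = np.linspace(plo, phi, n_pi)
    abs_ = np.linspace(blo, bhi, n_beta)
    ns = np.linspace(surface.n_range[0], surface.n_range[1], n_N)
    P, A, Nn = np.meshgrid(pis, abs_, ns, indexing="ij")
    vals = surface.predict(P.ravel(), A.ravel(), Nn.ravel()).reshape(P.shape)
    viol = 0
    for axis in range(3):
        viol += int(np.sum(np.diff(vals, axis=axis) < 0))
    return viol


def crosscheck_backends(
    records: pd.DataFrame,
    region: tuple[tuple[float, float], tuple[float, float]] | None = None,
    seed: int = 0,
    grid_size: int = 15,
) -> dict:
    """Fit XGBoost and LightGBM with equivalent settings and compare.

    Returns a report dict with the max/mean absolute prediction difference
    on a grid over the region plus per-feature importances.  If the second
    backend cannot be imported the report is marked ``single_backend``.
    """
    sub = _region_filter(records, region)
    if len(sub) == 0:
        raise ValidationError("no records in the requested region")
    primary = fit_gbt(records, region=region, seed=seed, backend="xgboost")
    report: dict = {
        "single_backend": False,
        "xgboost": {
            "rmse_validation": primary.rmse_validation,
            "rmse_test": primary.rmse_test,
            "feature_importance": dict(
                zip(FEATURES, np.asarray(primary.model.feature_importances_, dtype=float))
            ),
        },
    }
    try:
        secondary = fit_gbt(records, region=region, seed=seed, backend="lightgbm")
    except ImportError:
        report["single_backend"] = True
        return report
    (plo, phi), (blo, bhi) = primary.region
    pis = np.linspace(plo, phi, grid_size)
    abs_ = np.linspace(blo, bhi, grid_size)
    ns = np.array(sorted(set(int(v) for v in sub["N"])), dtype=float)
    P, A, Nn = np.meshgrid(pis, abs_, ns, indexing="ij")
    p1 = primary.predict(P.ravel(), A.ravel(), Nn.ravel())
    p2 = secondary.predict(P.ravel(), A.ravel(), Nn.ravel())
    diff = np.abs(np.asarray(p1) - np.asarray(p2))
    report["lightgbm"] = {
        "rmse_validation": secondary.rmse_validation,
        "rmse_test": secondary.rmse_test,
        "feature_importance": dict(
            zip(FEATURES, np.asarray(secondary.model.feature_importances_, dtype=float))
        ),
    }
    report["max_abs_diff"] = float(diff.max())
    report["mean_abs_diff"] = float(diff.mean())
    return report


def gbt_sidecar_json(surface: GBTSurface, path: str | Path | None = None) -> str:
    """JSON sidecar describing a saved model artifact."""
    payload = {
        "backend": surface.backend,
        "region": surface.region,
        "n_range": surface.n_range,
        "monotone_constraints": list(MONOTONE),
        "hyperparams": surface.hyperparams,
        "split_seed": surface.split_seed,
        "rmse_validation": surface.rmse_validation,
        "rmse_test": surface.rmse_test,
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text
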