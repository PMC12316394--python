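"""Monotone bivariate P-spline power surfaces.

For a fixed number of replicates N, statistical power can be assumed
non-decreasing in both the gene detection rate pi and the absolute log
fold change |beta|.  This module fits a tensor-product quadratic B-spline
surface m(pi, |beta|) under that double monotone-increasing shape
constraint, in the style of shape-constrained additive models (SCAM):

* the tensor coefficient grid theta (q1 x q2) is reparameterized as a
  double cumulative sum of exponentiated working parameters,
  ``theta = (T1 kron T2) e(gamma)`` with ``e = [gamma_1, exp(gamma_2), ...]``
  and T lower-triangular matrices of ones — every increment of theta along
  either grid axis is then a sum of non-negative terms, so the fitted
  surface is non-decreasing in both inputs by construction;
* the objective is penalized least squares on the observed power values,
  with independent second-order difference penalties along the two working
  parameter grid axes (the classic P-spline double penalty) weighted by
  smoothing parameters lambda1, lambda2;
* the objective is minimized by a damped Newton-Raphson iteration
  (analytic gradient and Hessian, step-halving), and (lambda1, lambda2)
  are chosen by generalized cross-validation (GCV) over a log-spaced grid.

Predictions are clamped to [0, 1]; queries outside the fitted predictor
range are clamped to the boundary and flagged as extrapolation.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import BSpline

from .dataio import ValidationError

__all__ = [
    "SplineSurface",
    "make_knots",
    "build_basis",
    "fit_scam2d",
    "predict_power",
    "detect_crossings",
    "compare_surfaces",
    "CrossingReport",
    "surface_to_json",
    "surface_from_json",
]

DEGREE = 2  # quadratic splines
GAMMA_MAX = 50.0  # cap on working parameters; exp(50) already dwarfs any power scale
DEFAULT_LAMBDA_GRID = tuple(10.0**k for k in range(-4, 3, 2))  # 1e-4 .. 1e2


# ---------------------------------------------------------------------------
# B-spline plumbing
# ---------------------------------------------------------------------------


def make_knots(lo: float, hi: float, q: int, degree: int = DEGREE) -> np.ndarray:
    """Clamped, equally spaced knot vector giving ``q`` basis functions."""
    if q < degree + 1:
        raise ValidationError(f"need q >= degree+1 ({degree + 1}), got {q}")
    if not hi > lo:
        raise ValidationError(f"empty knot range [{lo}, {hi}]")
    inner = np.linspace(lo, hi, q - degree + 1)
    return np.concatenate([[lo] * degree, inner, [hi] * degree])


def build_basis(x: np.ndarray, knots: np.ndarray, degree: int = DEGREE) -> np.ndarray:
    """Dense B-spline design matrix: rows = points, columns = basis functions.

    ``x`` must lie inside the knot span ``[knots[degree], knots[-degree-1]]``;
    callers wanting boundary behaviour must clamp first.
    """
    x = np.asarray(x, dtype=float)
    knots = np.asarray(knots, dtype=float)
    lo, hi = knots[degree], knots[-degree - 1]
    if np.any(x < lo) or np.any(x > hi):
        raise ValidationError(
            f"evaluation points outside knot range [{lo}, {hi}]"
        )
    return BSpline.design_matrix(x, knots, degree, extrapolate=True).toarray()


def _second_diff_penalty(q1: int, q2: int, axis: int) -> np.ndarray:
    """Second-order difference penalty along one axis of the working grid.

    The first working parameter is the surface level (a power value) while
    all others are log-increments; difference rows touching it would mix
    units and bias increments away from zero, so they are dropped.
    """
    q = q1 if axis == 0 else q2
    d = np.diff(np.eye(q), n=2, axis=0)
    if axis == 0:
        D = np.kron(d, np.eye(q2))
    else:
        D = np.kron(np.eye(q1), d)
    D = D[D[:, 0] == 0]
    return D.T @ D


def _constraint_matrix(q1: int, q2: int) -> np.ndarray:
    """Double cumulative-sum matrix: theta_{jk} = sum_{l<=j, m<=k} e_{lm}."""
    t1 = np.tril(np.ones((q1, q1)))
    t2 = np.tril(np.ones((q2, q2)))
    return np.kron(t1, t2)


def _row_tensor(b1: np.ndarray, b2: np.ndarray) -> np.ndarray:
    """Row-wise Kronecker product (tensor-product design matrix)."""
    n = b1.shape[0]
    return (b1[:, :, None] * b2[:, None, :]).reshape(n, -1)


# ---------------------------------------------------------------------------
# surface container
# ---------------------------------------------------------------------------


@dataclass
class SplineSurface:
    """A fitted double-monotone tensor P-spline power surface for one N."""

    degree: int
    knots1: np.ndarray
    knots2: np.ndarray
    gamma: np.ndarray  # tensor coefficients theta, length q1*q2 (row-major)
    lambda1: float
    lambda2: float
    N: int | None
    pi_range: tuple[float, float]
    beta_range: tuple[float, float]
    fit_info: dict = field(default_factory=dict)

    @property
    def q1(self) -> int:
        return len(self.knots1) - self.degree - 1

    @property
    def q2(self) -> int:
        return len(self.knots2) - self.degree - 1

    def predict(
        self, pi, abs_beta, return_flag: bool = False
    ):
        """Predicted power at (pi, |beta|), clamped to [0, 1].

        Out-of-range inputs are clamped to the fitted boundary; with
        ``return_flag=True`` a boolean extrapolation indicator (per point)
        is returned alongside the values.
        """
        pi = np.asarray(pi, dtype=float)
        ab = np.asarray(abs_beta, dtype=float)
        pi_b, ab_b = np.broadcast_arrays(pi, ab)
        scalar = pi_b.ndim == 0
        pi_f = np.atleast_1d(pi_b).astype(float)
        ab_f = np.atleast_1d(ab_b).astype(float)
        flag = (
            (pi_f < self.pi_range[0])
            | (pi_f > self.pi_range[1])
            | (ab_f < self.beta_range[0])
            | (ab_f > self.beta_range[1])
        )
        pi_c = np.clip(pi_f, *self.pi_range)
        ab_c = np.clip(ab_f, *self.beta_range)
        X = _row_tensor(
            build_basis(pi_c, self.knots1, self.degree),
            build_basis(ab_c, self.knots2, self.degree),
        )
        val = np.clip(X @ self.gamma, 0.0, 1.0)
        if scalar:
            val, flag = val[0], bool(flag[0])
        if return_flag:
            return val, flag
        return val


def predict_power(
    surface: SplineSurface, pi: float, abs_beta: float, return_flag: bool = False
):
    """Functional alias for :meth:`SplineSurface.predict` on a single query."""
    return surface.predict(pi, abs_beta, return_flag=return_flag)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _unpack_records(records) -> tuple[np.ndarray, np.ndarray, np.ndarray, int | None]:
    """Accept a power-table DataFrame or an (x1, x2, y) triple."""
    if hasattr(records, "columns"):
        x1 = records["pi_g"].to_numpy(dtype=float)
        x2 = records["abs_beta_g"].to_numpy(dtype=float)
        y = records["power"].to_numpy(dtype=float)
        Ns = set(records["N"].tolist()) if "N" in records.columns else set()
        if len(Ns) > 1:
            raise ValidationError(
                f"records span several N values {sorted(Ns)}; fit one surface per N"
            )
        N = int(next(iter(Ns))) if Ns else None
        return x1, x2, y, N
    x1, x2, y = (np.asarray(a, dtype=float) for a in records)
    return x1, x2, y, None


def _exp_map(gamma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """e(gamma) and its elementwise derivative (first entry is identity)."""
    e = np.empty_like(gamma)
    e[0] = gamma[0]
    e[1:] = np.exp(np.minimum(gamma[1:], GAMMA_MAX))
    d = e.copy()
    d[0] = 1.0
    return e, d


def _newton_fit(
    XS: np.ndarray,
    y: np.ndarray,
    S_pen: np.ndarray,
    gamma0: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 200,
    max_halvings: int = 30,
) -> tuple[np.ndarray, bool, int, float]:
    """Damped Newton-Raphson on the penalized least-squares objective."""
    G = XS.T @ XS
    gamma = gamma0.copy()

    def objective(g):
        e, _ = _exp_map(g)
        r = XS @ e - y
        return r @ r + g @ S_pen @ g

    def _directions(g):
        e, d = _exp_map(g)
        r = XS @ e - y
        xtr = XS.T @ r
        grad = 2.0 * xtr * d + 2.0 * S_pen @ g
        H_gn = 2.0 * (d[:, None] * G * d[None, :]) + 2.0 * S_pen
        H = H_gn.copy()
        curv = xtr * e
        curv[0] = 0.0
        H[np.diag_indices_from(H)] += 2.0 * curv
        eye = 1e-10 * np.eye(len(g))
        steps = []
        for mat in (H, H_gn):  # full Newton, then Gauss-Newton (always PSD)
            try:
                s = np.linalg.solve(mat + eye, -grad)
                if np.all(np.isfinite(s)):
                    steps.append(s)
            except np.linalg.LinAlgError:
                pass
        gn = np.linalg.norm(grad)
        if gn > 0:
            steps.append(-grad / gn)  # last resort: normalized steepest descent
        return steps

    def _line_search(g, step, f):
        t = 1.0
        for _ in range(max_halvings + 1):
            cand = np.minimum(g + t * step, GAMMA_MAX)
            new_f = objective(cand)
            if np.isfinite(new_f) and new_f < f:
                return cand, new_f
            t *= 0.5
        return None, f

    f = objective(gamma)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        accepted = None
        for step in _directions(gamma):
            accepted, new_f = _line_search(gamma, step, f)
            if accepted is not None:
                break
        if accepted is None:
            converged = True  # no descent direction left: a (numerical) optimum
            break
        gamma = accepted
        if abs(f - new_f) <= tol * (abs(f) + tol):
            f = new_f
            converged = True
            break
        f = new_f
    return gamma, converged, it, f


def _initial_gamma(q1: int, q2: int, y: np.ndarray) -> np.ndarray:
    """Start from a gently increasing bilinear ramp spanning the data range."""
    lo = float(np.min(y))
    rng = max(float(np.ptp(y)), 1e-3)
    g = np.full((q1, q2), -20.0)  # exp(-20): negligible interior increments
    g[0, 0] = lo
    if q1 > 1:
        g[1:, 0] = np.log(0.5 * rng / (q1 - 1))
    if q2 > 1:
        g[0, 1:] = np.log(0.5 * rng / (q2 - 1))
    return g.ravel()


def fit_scam2d(
    records,
    q1: int = 10,
    q2: int = 10,
    lambda_grid: Sequence[float] | None = None,
    N: int | None = None,
    beta_max: float | None = None,
) -> SplineSurface:
    """Fit the double-monotone tensor P-spline to one N's power records.

    ``records`` is either the power table (DataFrame with columns
    ``pi_g, abs_beta_g, power`` and a single ``N``) or a ``(pi, abs_beta,
    power)`` triple of arrays.  Knots are equally spaced over the observed
    predictor ranges (``beta_max`` widens the second axis if given);
    ``lambda_grid`` values are tried for both penalties with GCV deciding.

    Raises if fewer than 20 records or either predictor is constant.  On
    Newton non-convergence the best surface found is returned with
    ``fit_info["converged"] = False`` and a warning.
    """
    x1, x2, y, rec_N = _unpack_records(records)
    if N is None:
        N = rec_N
    n = len(y)
    if n < 20:
        raise ValidationError(f"need >= 20 records to fit a surface, got {n}")
    if np.ptp(x1) == 0 or np.ptp(x2) == 0:
        raise ValidationError("both predictors must be non-constant")

    hi2 = float(max(x2.max(), beta_max) if beta_max is not None else x2.max())
    knots1 = make_knots(float(x1.min()), float(x1.max()), q1)
    knots2 = make_knots(float(x2.min()), hi2, q2)
    X = _row_tensor(build_basis(x1, knots1), build_basis(x2, knots2))
    if np.linalg.matrix_rank(X.T @ X) == 0:
        raise ValidationError("rank-deficient design")
    Sigma = _constraint_matrix(q1, q2)
    XS = X @ Sigma
    S1 = _second_diff_penalty(q1, q2, axis=0)
    S2 = _second_diff_penalty(q1, q2, axis=1)

    grid = tuple(lambda_grid) if lambda_grid is not None else DEFAULT_LAMBDA_GRID
    gamma0 = _initial_gamma(q1, q2, y)
    best = None
    gcv_table = []
    warm = gamma0
    for l1 in grid:
        for l2 in grid:
            S_pen = l1 * S1 + l2 * S2
            gamma, conv, iters, fval = _newton_fit(XS, y, S_pen, warm)
            warm = gamma
            e, d = _exp_map(gamma)
            resid = XS @ e - y
            rss = float(resid @ resid)
            Xt = XS * d[None, :]
            A = Xt.T @ Xt + S_pen
            try:
                edf = float(np.trace(np.linalg.solve(A, Xt.T @ Xt)))
            except np.linalg.LinAlgError:
                edf = float(len(gamma))
            denom = max(n - edf, 1e-8)
            gcv = n * rss / denom**2
            gcv_table.append(
                {"lambda1": l1, "lambda2": l2, "gcv": gcv, "rss": rss, "edf": edf}
            )
            if best is None or gcv < best["gcv"]:
                best = {
                    "lambda1": l1,
                    "lambda2": l2,
                    "gcv": gcv,
                    "gamma": gamma,
                    "converged": conv,
                    "iterations": iters,
                    "objective": fval,
                    "rss": rss,
                    "edf": edf,
                }
    assert best is not None
    if not best["converged"]:
        warnings.warn(
            "Newton-Raphson did not converge for the GCV-selected penalties; "
            "returning the best surface found",
            RuntimeWarning,
        )
    e, _ = _exp_map(best["gamma"])
    theta = Sigma @ e
    return SplineSurface(
        degree=DEGREE,
        knots1=knots1,
        knots2=knots2,
        gamma=theta,
        lambda1=best["lambda1"],
        lambda2=best["lambda2"],
        N=N,
        pi_range=(float(x1.min()), float(x1.max())),
        beta_range=(float(x2.min()), hi2),
        fit_info={
            "converged": bool(best["converged"]),
            "iterations": int(best["iterations"]),
            "objective": float(best["objective"]),
            "rss": float(best["rss"]),
            "edf": float(best["edf"]),
            "gcv": float(best["gcv"]),
            "gcv_table": gcv_table,
            "n_records": n,
        },
    )


# ---------------------------------------------------------------------------
# diagnostics across surfaces
# ---------------------------------------------------------------------------


@dataclass
class CrossingReport:
    """Grid cells where predicted power decreases as N increases."""

    pi_grid: np.ndarray
    beta_grid: np.ndarray
    cells: list  # (i, j, N_low, N_high) tuples with power(N_high) < power(N_low)
    mask: np.ndarray  # bool (len(pi_grid), len(beta_grid)): any violating pair

    @property
    def has_crossings(self) -> bool:
        return bool(self.mask.any())

    @property
    def bounding_box(self) -> tuple[tuple[float, float], tuple[float, float]] | None:
        """(pi_range, beta_range) enclosing all violating cells, or None."""
        if not self.has_crossings:
            return None
        ii, jj = np.nonzero(self.mask)
        return (
            (float(self.pi_grid[ii.min()]), float(self.pi_grid[ii.max()])),
            (float(self.beta_grid[jj.min()]), float(self.beta_grid[jj.max()])),
        )


def _default_grid(surfaces: Sequence[SplineSurface], num: int = 41):
    lo1 = max(s.pi_range[0] for s in surfaces)
    hi1 = min(s.pi_range[1] for s in surfaces)
    lo2 = max(s.beta_range[0] for s in surfaces)
    hi2 = min(s.beta_range[1] for s in surfaces)
    return np.linspace(lo1, hi1, num), np.linspace(lo2, hi2, num)


def detect_crossings(
    surfaces: Sequence[SplineSurface],
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> CrossingReport:
    """Find where per-N surfaces violate monotonicity in N.

    ``surfaces`` must be ordered by strictly increasing N.  Every adjacent
    pair is compared on the evaluation grid; a cell where the larger-N
    surface predicts strictly lower power is a crossing.  The report's
    bounding box is the region to hand to the boosted 3D-monotone fit.
    """
    if len(surfaces) < 2:
        raise ValidationError("need at least 2 surfaces to detect crossings")
    Ns = [s.N for s in surfaces]
    if any(a is None for a in Ns) or any(b <= a for a, b in zip(Ns, Ns[1:])):
        raise ValidationError(f"surfaces must have strictly increasing N, got {Ns}")
    if grid is None:
        grid = _default_grid(surfaces)
    pi_grid, beta_grid = (np.asarray(g, dtype=float) for g in grid)
    P, Bm = np.meshgrid(pi_grid, beta_grid, indexing="ij")
    preds = [s.predict(P.ravel(), Bm.ravel()).reshape(P.shape) for s in surfaces]
    mask = np.zeros(P.shape, dtype=bool)
    cells = []
    for (n_lo, p_lo), (n_hi, p_hi) in zip(
        zip(Ns, preds), zip(Ns[1:], preds[1:])
    ):
        bad = p_hi < p_lo
        mask |= bad
        for i, j in zip(*np.nonzero(bad)):
            cells.append((int(i), int(j), int(n_lo), int(n_hi)))
    return CrossingReport(pi_grid=pi_grid, beta_grid=beta_grid, cells=cells, mask=mask)


def compare_surfaces(
    a: SplineSurface,
    b: SplineSurface,
    grid: tuple[np.ndarray, np.ndarray] | None = None,
) -> np.ndarray:
    """Element-wise relative difference ``|P_a - P_b| / P_b`` on a grid.

    Cells where the reference surface ``b`` predicts exactly zero power are
    undefined and returned as NaN (never infinity).
    """
    if grid is None:
        grid = _default_grid([a, b])
    pi_grid, beta_grid = (np.asarray(g, dtype=float) for g in grid)
    P, Bm = np.meshgrid(pi_grid, beta_grid, indexing="ij")
    pa = a.predict(P.ravel(), Bm.ravel()).reshape(P.shape)
    pb = b.predict(P.ravel(), Bm.ravel()).reshape(P.shape)
    out = np.full(P.shape, np.nan)
    ok = pb != 0
    out[ok] = np.abs(pa[ok] - pb[ok]) / pb[ok]
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

SCHEMA_VERSION = 1


def surface_to_json(surface: SplineSurface, path: str | Path | None = None) -> str:
    payload = {
        "schema_version": SCHEMA_VERSION,
        "degree": surface.degree,
        "knots1": surface.knots1.tolist(),
        "knots2": surface.knots2.tolist(),
        "gamma": surface.gamma.tolist(),
        "lambda1": surface.lambda1,
        "lambda2": surface.lambda2,
        "N": surface.N,
        "pi_range": list(surface.pi_range),
        "beta_range": list(surface.beta_range),
        "fit_info": {
            k: v for k, v in surface.fit_info.items() if k != "gcv_table"
        },
    }
    text = json.dumps(payload, indent=2)
    if path is not None:
        Path(path).write_text(text)
    return text


def surface_from_json(source: str | Path) -> SplineSurface:
    text = Path(source).read_text() if Path(str(source)).exists() else str(source)
    d = json.loads(text)
    return SplineSurface(
        degree=int(d["degree"]),
        knots1=np.asarray(d["knots1"], dtype=float),
        knots2=np.asarray(d["knots2"], dtype=float),
        gamma=np.asarray(d["gamma"], dtype=float),
        lambda1=float(d["lambda1"]),
        lambda2=float(d["lambda2"]),
        N=None if d["N"] is None else int(d["N"]),
        pi_range=tuple(d["pi_range"]),
        beta_range=tuple(d["beta_range"]),
        fit_info=d.get("fit_info", {}),
    )
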