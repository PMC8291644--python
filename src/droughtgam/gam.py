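"""Penalized logistic regression with a low-rank spherical spline smoother.

The model is

    logit P(y=1) = b0 + X b + b_d x_d + delta_survey + s(lat, lon)

where ``s`` is a knot-based radial smoother: basis functions
``eta(c) = c^2 log(c)`` of the chord distance ``c`` to each knot on the
unit sphere, penalized by the knot-knot Gram matrix.  Only the spline
weights are penalized; the smoothing parameter is chosen by AIC
(deviance + 2*edf) over a log-spaced grid.  Fitting is by penalized
iteratively reweighted least squares with step-halving.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from sklearn.cluster import KMeans

from .geo import unit_vectors, chord_sq_matrix
from .simulate import OUTCOME_COLUMNS

logger = logging.getLogger(__name__)

DEFAULT_LAMBDA_GRID = np.logspace(-4, 6, 20)

#: covariate -> None (binary 0/1 column) or tuple of levels (first = reference)
DEFAULT_COVARIATES: dict = {
    "married": None,
    "literate": None,
    "rural": None,
    "age_band": ("<20", "20-29", "30-39", "40-49"),
    "births_band": ("0-2", "3-4", ">4"),
    "partner_education": ("none", "primary", "secondary", "higher"),
    "partner_age_band": ("<20", "20-29", "30-39", "40-49", ">49"),
    "hh_size_band": ("1-3", "4-5", ">5"),
}

DROUGHT_CATEGORY_LEVELS = ("moderate", "severe", "extreme")


class ConvergenceError(RuntimeError):
    """PIRLS failed to reach the gradient tolerance within the iteration cap."""


class SeparationError(RuntimeError):
    """Coefficients diverging: (quasi-)perfect separation detected."""


@dataclass
class DesignMatrix:
    """Fixed-effect design for one outcome, plus per-row coordinates."""

    X: np.ndarray
    y: np.ndarray
    column_names: list
    coords: np.ndarray  # (n, 2) lat, lon
    outcome: str
    drought_columns: list = field(default_factory=list)
    references: dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]


@dataclass
class SplineBasis:
    knots: np.ndarray  # (K, 2) lat, lon
    basis: np.ndarray  # (n, K)
    penalty: np.ndarray  # (K, K) raw Gram matrix, symmetric

    @property
    def n_knots(self) -> int:
        return self.knots.shape[0]


@dataclass
class FittedModel:
    coefficients: np.ndarray
    column_names: list
    n_fixed: int
    covariance: np.ndarray
    lam: float
    edf: float
    deviance: float
    aic: float
    fitted: np.ndarray
    y: np.ndarray
    model_matrix: np.ndarray  # fixed columns then spline basis columns
    basis: SplineBasis | None
    convergence_info: dict

    @property
    def n_spline(self) -> int:
        return self.coefficients.size - self.n_fixed

    def coefficient(self, name: str) -> float:
        return float(self.coefficients[self.column_names.index(name)])

    def wald_p_value(self, name: str) -> float:
        """Two-sided normal p-value for one fixed-effect coefficient."""
        from scipy.stats import norm

        j = self.column_names.index(name)
        se = float(np.sqrt(self.covariance[j, j]))
        if se == 0:
            return 1.0
        return float(2.0 * norm.sf(abs(self.coefficients[j]) / se))


def build_design(
    records: pd.DataFrame,
    outcome_name: str,
    covariate_spec: Mapping | None = None,
    drought: str = "category",
) -> DesignMatrix:
    """Dummy-encode a respondent table into a full-rank design matrix.

    Reference levels (dropped): first listed level of each categorical
    covariate, drought = none/normal, survey = first id in sorted order.
    ``drought`` selects ``"category"`` (three dummies from
    ``drought_category``) or ``"binary"`` (one dummy from
    ``drought_binary``).  All-constant dummy columns are dropped with a
    warning; a rank-deficient result is an error.
    """
    if outcome_name not in OUTCOME_COLUMNS:
        raise ValueError(f"outcome must be one of {OUTCOME_COLUMNS}, got {outcome_name!r}")
    spec = DEFAULT_COVARIATES if covariate_spec is None else covariate_spec

    y = records[outcome_name].to_numpy(dtype=float)
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    references: dict = {}

    for name, levels in spec.items():
        if levels is None:
            cols.append(records[name].to_numpy(dtype=float))
            names.append(name)
        else:
            vals = records[name].to_numpy()
            present = [lev for lev in levels if (vals == lev).any()]
            if not present:
                raise ValueError(f"covariate {name!r} has no listed level present")
            # reference = first listed level present in the data (an absent
            # reference would make the dummies sum to the intercept)
            references[name] = present[0]
            if present[0] != levels[0]:
                logger.warning("covariate %r: reference level %r absent, using %r",
                               name, levels[0], present[0])
            for lev in present[1:]:
                cols.append((vals == lev).astype(float))
                names.append(f"{name}[{lev}]")

    drought_columns: list[str] = []
    if drought == "category":
        references["drought"] = "none"
        vals = records["drought_category"].to_numpy()
        for lev in DROUGHT_CATEGORY_LEVELS:
            cols.append((vals == lev).astype(float))
            names.append(f"drought[{lev}]")
            drought_columns.append(f"drought[{lev}]")
    elif drought == "binary":
        references["drought"] = "normal"
        vals = records["drought_binary"].to_numpy()
        cols.append((vals == "drought").astype(float))
        names.append("drought[drought]")
        drought_columns.append("drought[drought]")
    else:
        raise ValueError("drought must be 'category' or 'binary'")

    surveys = sorted(pd.unique(records["survey_id"]))
    references["survey"] = surveys[0] if surveys else None
    svals = records["survey_id"].to_numpy()
    for s in surveys[1:]:
        cols.append((svals == s).astype(float))
        names.append(f"survey[{s}]")

    X = np.column_stack(cols)
    keep = np.ones(X.shape[1], dtype=bool)
    for j in range(1, X.shape[1]):
        if np.all(X[:, j] == X[0, j]):
            keep[j] = False
            logger.warning("dropping constant design column %r", names[j])
            if names[j] in drought_columns:
                logger.warning("drought term %r is unidentifiable in this data", names[j])
    X = X[:, keep]
    names = [nm for nm, k in zip(names, keep) if k]
    drought_columns = [c for c in drought_columns if c in names]

    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank-deficient after reference-level drops")

    coords = records[["latitude", "longitude"]].to_numpy(dtype=float)
    return DesignMatrix(
        X=X,
        y=y,
        column_names=names,
        coords=coords,
        outcome=outcome_name,
        drought_columns=drought_columns,
        references=references,
    )


def _to_latlon(u: np.ndarray) -> np.ndarray:
    u = u / np.linalg.norm(u, axis=1, keepdims=True)
    lat = np.degrees(np.arcsin(np.clip(u[:, 2], -1.0, 1.0)))
    lon = np.degrees(np.arctan2(u[:, 1], u[:, 0]))
    return np.column_stack([lat, lon])


def make_knots(coords: np.ndarray, K: int, seed: int = 0) -> np.ndarray:
    """K knot locations by k-means on the unit-sphere embedding of the
    distinct coordinate points; centroids are renormalized to the sphere.

    K = 0 gives an empty set; K equal to the number of distinct points
    returns those points; K larger is an error.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    distinct = np.unique(coords, axis=0)
    if K == 0:
        return np.empty((0, 2))
    if K > distinct.shape[0]:
        raise ValueError(
            f"K={K} exceeds the {distinct.shape[0]} distinct coordinate points; choose a smaller K"
        )
    if K == distinct.shape[0]:
        return distinct
    u = unit_vectors(distinct[:, 0], distinct[:, 1])
    km = KMeans(n_clusters=K, random_state=seed, n_init=4).fit(u)
    return _to_latlon(km.cluster_centers_)


def _eta(c2: np.ndarray) -> np.ndarray:
    """Thin-plate radial function of chord distance, eta(c) = c^2 log c,
    continuous at 0 with eta(0) = 0.  Takes squared chords."""
    out = np.zeros_like(c2)
    pos = c2 > 0
    # c^2 log c = 0.5 * c^2 * log(c^2)
    out[pos] = 0.5 * c2[pos] * np.log(c2[pos])
    return out


def spline_basis(coords: np.ndarray, knots: np.ndarray) -> SplineBasis:
    """Radial basis and Gram penalty from chord distances on the sphere."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 2)
    knots = np.asarray(knots, dtype=float).reshape(-1, 2)
    if knots.shape[0] < 1:
        raise ValueError("at least one knot is required")
    uk = unit_vectors(knots[:, 0], knots[:, 1])
    kk = chord_sq_matrix(uk, uk)
    off_diag = kk[~np.eye(len(kk), dtype=bool)]
    if off_diag.size and np.min(off_diag) <= 1e-24:
        raise ValueError("duplicate knots")
    uc = unit_vectors(coords[:, 0], coords[:, 1])
    basis = _eta(chord_sq_matrix(uc, uk))
    penalty = _eta(kk)
    penalty = 0.5 * (penalty + penalty.T)
    return SplineBasis(knots=knots, basis=basis, penalty=penalty)


def _psd_clip(S: np.ndarray) -> np.ndarray:
    """Positive-definite surrogate of the raw thin-plate Gram matrix.

    The Gram matrix is only conditionally positive definite: it carries
    one large negative eigenvalue along a constant-like direction that is
    redundant with the explicit intercept.  Flipping eigenvalue signs
    (with a tiny floor) keeps the wiggliness penalty on the positive
    subspace intact while ensuring every spline direction is penalized,
    so lambda -> infinity recovers the no-spline fit.
    """
    w, V = np.linalg.eigh(S)
    w = np.abs(w)
    w = np.maximum(w, 1e-10 * (w.max() if w.size else 1.0))
    return (V * w) @ V.T


def _deviance(y: np.ndarray, mu: np.ndarray) -> float:
    eps = 1e-12
    mu = np.clip(mu, eps, 1 - eps)
    return float(-2.0 * np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))


def _pirls(
    A: np.ndarray,
    y: np.ndarray,
    P: np.ndarray,
    theta0: np.ndarray | None,
    max_iter: int,
    tol: float,
):
    """Penalized IRLS for Bernoulli log-likelihood minus (1/2) theta' P theta.

    Returns (theta, mu, info).  Raises SeparationError when coefficients
    diverge and ConvergenceError at the iteration cap.
    """
    n, p = A.shape
    theta = np.zeros(p) if theta0 is None else theta0.copy()
    eta = A @ theta
    mu = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
    pen_dev = _deviance(y, mu) + float(theta @ P @ theta)

    def _check_separation(theta, eta):
        if np.max(np.abs(theta)) > 1e4 or np.max(np.abs(eta)) > 30.0:
            raise SeparationError("coefficients diverging; data may be perfectly separated")

    for it in range(max_iter):
        w = np.clip(mu * (1 - mu), 1e-10, None)
        grad = A.T @ (y - mu) - P @ theta
        if np.linalg.norm(grad) < tol:
            _check_separation(theta, A @ theta)
            return theta, mu, {"iterations": it, "grad_norm": float(np.linalg.norm(grad))}
        H = (A.T * w) @ A + P
        try:
            c, low = cho_factor(H)
            step = cho_solve((c, low), grad)
        except np.linalg.LinAlgError:
            step = np.linalg.solve(H + 1e-8 * np.eye(p), grad)
        # a vanishing Newton step means the remaining gradient is pure
        # floating-point noise from the penalty term (huge lambda)
        if np.linalg.norm(step) < 1e-12 * (1.0 + np.linalg.norm(theta)):
            _check_separation(theta, A @ theta)
            return theta, mu, {"iterations": it, "grad_norm": float(np.linalg.norm(grad))}
        # step-halving on penalized deviance increase
        alpha = 1.0
        for _ in range(40):
            cand = theta + alpha * step
            eta = A @ cand
            mu_c = 1.0 / (1.0 + np.exp(-np.clip(eta, -35, 35)))
            cand_dev = _deviance(y, mu_c) + float(cand @ P @ cand)
            if cand_dev <= pen_dev + 1e-12:
                break
            alpha *= 0.5
        theta, mu, pen_dev = cand, mu_c, cand_dev
        _check_separation(theta, eta)

    grad = A.T @ (y - mu) - P @ theta
    if np.linalg.norm(grad) < tol:
        return theta, mu, {"iterations": max_iter, "grad_norm": float(np.linalg.norm(grad))}
    raise ConvergenceError(
        f"PIRLS did not converge in {max_iter} iterations (|grad| = {np.linalg.norm(grad):.3e})"
    )


def fit_penalized_logistic(
    design: DesignMatrix,
    basis: SplineBasis | None = None,
    lambda_grid: Sequence[float] | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
) -> FittedModel:
    """Fit the model, selecting the smoothing parameter by AIC.

    With ``basis=None`` this is an ordinary logistic MLE.  Otherwise each
    lambda in the grid is fitted by PIRLS (warm-started along the grid);
    the fit minimizing ``deviance + 2*edf`` wins.  Effective degrees of
    freedom is the trace of the influence matrix
    ``(A'WA + lambda*S)^{-1} A'WA`` at the optimum; the covariance is the
    inverse penalized information.
    """
    y = design.y
    if y.min() == y.max():
        raise ValueError("response has a single class")
    if basis is None or basis.n_knots == 0:
        A = design.X
        S = None
        grid = [0.0]
    else:
        A = np.hstack([design.X, basis.basis])
        S = _psd_clip(basis.penalty)
        grid = list(DEFAULT_LAMBDA_GRID if lambda_grid is None else lambda_grid)

    n_fixed = design.n_columns
    p = A.shape[1]
    best = None
    theta_warm = None
    failures: list[tuple[float, Exception]] = []
    for lam in grid:
        P = np.zeros((p, p))
        if S is not None and lam > 0:
            P[n_fixed:, n_fixed:] = lam * S
        try:
            theta, mu, info = _pirls(A, y, P, theta_warm, max_iter, tol)
        except (ConvergenceError, SeparationError) as exc:
            # a near-interpolating spline at a rough lambda can effectively
            # separate single clusters; skip that lambda, keep the grid
            if len(grid) == 1:
                raise
            logger.info("lambda %.3g failed (%s); skipped", lam, exc)
            failures.append((lam, exc))
            theta_warm = None
            continue
        theta_warm = theta
        w = np.clip(mu * (1 - mu), 1e-10, None)
        AtWA = (A.T * w) @ A
        H = AtWA + P
        Hinv = np.linalg.inv(H)
        edf = float(np.trace(Hinv @ AtWA))
        dev = _deviance(y, mu)
        aic = dev + 2.0 * edf
        if best is None or aic < best["aic"]:
            best = {
                "lam": lam, "theta": theta, "mu": mu, "edf": edf, "dev": dev,
                "aic": aic, "cov": Hinv, "info": info,
            }

    if best is None:
        raise failures[-1][1] if failures else ConvergenceError("no lambda converged")
    names = list(design.column_names)
    if S is not None:
        names += [f"spline[{j}]" for j in range(basis.n_knots)]
    return FittedModel(
        coefficients=best["theta"],
        column_names=names,
        n_fixed=n_fixed,
        covariance=best["cov"],
        lam=float(best["lam"]),
        edf=best["edf"],
        deviance=best["dev"],
        aic=best["aic"],
        fitted=best["mu"],
        y=y,
        model_matrix=A,
        basis=basis,
        convergence_info=best["info"],
    )


def model_residuals(model: FittedModel, kind: str = "pearson") -> np.ndarray:
    """Pearson residuals (y - p)/sqrt(p(1-p)); deviance residuals behind a flag."""
    y, mu = model.y, np.clip(model.fitted, 1e-12, 1 - 1e-12)
    if kind == "pearson":
        return (y - mu) / np.sqrt(mu * (1 - mu))
    if kind == "deviance":
        d = -2.0 * (y * np.log(mu) + (1 - y) * np.log(1 - mu))
        return np.sign(y - mu) * np.sqrt(np.clip(d, 0.0, None))
    raise ValueError("kind must be 'pearson' or 'deviance'")
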