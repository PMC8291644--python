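"""Average marginal effects of drought, uncertainty, and subgroup tables.

The AME of a drought level is the mean over respondents of the change in
fitted probability when that respondent's drought dummies are toggled
counterfactually from the reference (no drought) to the level, holding
everything else — covariates, survey effects and the spatial term — at
observed values.  Reported in percentage points.

Uncertainty comes from simulating coefficient vectors from the Gaussian
approximation at the optimum and recomputing the AME per draw; the
two-sided p-value uses the normal approximation ame/se.  Familywise
control is plain Bonferroni (alpha/m).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from . import gam
from .moran import WeightSpec
from .selection import knot_escalation

logger = logging.getLogger(__name__)

SUBGROUP_COLUMNS = {
    "wealth": "wealth_quintile",
    "employment": "employment",
    "water_source": "water_source",
    "urbanization": "rural",
}


@dataclass
class AMEResult:
    outcome: str
    level: str
    ame: float  # percentage points
    se: float | None = None
    p_value: float | None = None
    p_adjusted_threshold: float | None = None
    significant: bool | None = None


def _level_column(level: str) -> str:
    return f"drought[{level}]"


def _counterfactual_eta(model: gam.FittedModel, design: gam.DesignMatrix,
                        level: str | None, theta: np.ndarray) -> np.ndarray:
    """Linear predictor with every row's drought dummies set to ``level``
    (None = reference), all other columns at observed values."""
    eta = model.model_matrix @ theta
    # subtract observed drought contributions, add the counterfactual one
    for name in design.drought_columns:
        j = model.column_names.index(name)
        eta = eta - model.model_matrix[:, j] * theta[j]
    if level is not None:
        col = _level_column(level)
        if col not in model.column_names:
            raise ValueError(f"drought level {level!r} absent from the model")
        eta = eta + theta[model.column_names.index(col)]
    return eta


def _ame_from_theta(model, design, level, theta) -> float:
    p1 = 1.0 / (1.0 + np.exp(-np.clip(_counterfactual_eta(model, design, level, theta), -35, 35)))
    p0 = 1.0 / (1.0 + np.exp(-np.clip(_counterfactual_eta(model, design, None, theta), -35, 35)))
    return 100.0 * float(np.mean(p1 - p0))


def average_marginal_effect(model: gam.FittedModel, design: gam.DesignMatrix,
                            level: str) -> AMEResult:
    """Point estimate of the AME of ``level`` vs the no-drought reference."""
    if _level_column(level) not in model.column_names:
        raise ValueError(f"drought level {level!r} absent from the model")
    ame = _ame_from_theta(model, design, level, model.coefficients)
    return AMEResult(outcome=design.outcome, level=level, ame=ame)


def ame_uncertainty(model: gam.FittedModel, design: gam.DesignMatrix, level: str,
                    n_draws: int = 1000, seed=None) -> tuple[float, float]:
    """(se, two-sided p) for the AME by coefficient simulation.

    Draws from N(theta_hat, covariance); the covariance must be positive
    definite (singular -> error).
    """
    cov = model.covariance
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.trace(cov) / len(cov) * np.eye(len(cov)))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular coefficient covariance") from exc
    rng = np.random.default_rng(seed)
    draws = model.coefficients[None, :] + rng.standard_normal((n_draws, len(cov))) @ chol.T
    # vectorized over draws: adjust the linear predictor column-by-column
    A = model.model_matrix
    eta0 = A @ draws.T  # (n, B)
    for name in design.drought_columns:
        j = model.column_names.index(name)
        eta0 = eta0 - A[:, j][:, None] * draws[:, j][None, :]
    eta1 = eta0 + draws[:, model.column_names.index(_level_column(level))][None, :]
    p1 = 1.0 / (1.0 + np.exp(-np.clip(eta1, -35, 35)))
    p0 = 1.0 / (1.0 + np.exp(-np.clip(eta0, -35, 35)))
    ames = 100.0 * np.mean(p1 - p0, axis=0)
    se = float(ames.std(ddof=1))
    ame = _ame_from_theta(model, design, level, model.coefficients)
    p = 1.0 if se == 0 else float(2.0 * norm.sf(abs(ame) / se))
    return se, p


def bonferroni_threshold(alpha: float, m: int) -> float:
    """Per-test threshold alpha/m controlling the familywise error rate."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if m < 1 or int(m) != m:
        raise ValueError("m must be a positive integer")
    return alpha / m


def ame_table(model: gam.FittedModel, design: gam.DesignMatrix, levels=("moderate", "severe", "extreme"),
              alpha: float = 0.05, m: int = 12, n_draws: int = 1000, seed=None) -> pd.DataFrame:
    """AMEs for the requested drought levels with Bonferroni flags."""
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    rng = np.random.default_rng(seed)
    for level in levels:
        if _level_column(level) not in model.column_names:
            logger.warning("level %r absent from model; skipped", level)
            continue
        res = average_marginal_effect(model, design, level)
        se, p = ame_uncertainty(model, design, level, n_draws=n_draws, seed=rng)
        rows.append({
            "outcome": design.outcome, "level": level, "ame": res.ame, "se": se,
            "p_value": p, "p_adjusted_threshold": threshold, "significant": p < threshold,
        })
    return pd.DataFrame(rows)


def wealth_quintiles(wealth_index) -> np.ndarray:
    """Pooled (across-survey) quintile labels 1..5 from a numeric wealth
    index; cuts at the 20/40/60/80 empirical percentiles, ties assigned to
    the lower quintile."""
    x = np.asarray(wealth_index, dtype=float)
    if np.unique(x).size < 5:
        raise ValueError("need at least 5 distinct wealth values")
    cuts = np.quantile(x, [0.2, 0.4, 0.6, 0.8])
    return (np.searchsorted(cuts, x, side="left") + 1).astype(int)


def subgroup_analysis(
    records: pd.DataFrame,
    grouping: str,
    weight_spec: WeightSpec | None = None,
    ladder=(0, 25, 50),
    outcomes=("controlling", "emotional", "physical", "sexual"),
    alpha: float = 0.05,
    m: int = 4,
    min_rows: int = 200,
    n_draws: int = 1000,
    seed: int = 0,
    lambda_grid=None,
) -> pd.DataFrame:
    """Per-category, per-outcome binary-drought AMEs (Table-style layout).

    For each category of the grouping variable the full pipeline runs on
    that subset: design with a single binary drought dummy, knot
    escalation, then AME of drought vs normal, Bonferroni-corrected for
    ``m`` hypotheses.  Subgroups lacking both outcome classes, both
    drought states, or ``min_rows`` rows are skipped with a logged reason.
    """
    if grouping not in SUBGROUP_COLUMNS:
        raise ValueError(f"unknown grouping {grouping!r}; choose from {sorted(SUBGROUP_COLUMNS)}")
    col = SUBGROUP_COLUMNS[grouping]
    if grouping == "urbanization":
        cat_series = np.where(records[col].astype(int) == 1, "rural", "urban")
    else:
        cat_series = records[col].astype(str).to_numpy()
    threshold = bonferroni_threshold(alpha, m)
    rows = []
    rng = np.random.default_rng(seed)
    for category in pd.unique(cat_series):
        sub = records[cat_series == category]
        reason = None
        if len(sub) < min_rows:
            reason = f"only {len(sub)} rows"
        elif sub["drought_binary"].nunique() < 2:
            reason = "single drought state"
        for outcome in outcomes:
            if reason is None and sub[outcome].nunique() < 2:
                row_reason = f"outcome {outcome} has a single class"
            else:
                row_reason = reason
            if row_reason is not None:
                rows.append({"grouping": grouping, "category": category, "outcome": outcome,
                             "ame": np.nan, "se": np.nan, "p_value": np.nan,
                             "significant": None, "selected_knots": None, "skipped": row_reason})
                continue
            design = gam.build_design(sub, outcome, drought="binary")
            if weight_spec is not None:
                # weight_spec acts as a template; coords are per-subset
                sub_spec = WeightSpec(
                    coords=design.coords, scheme=weight_spec.scheme,
                    band_km=weight_spec.band_km, k=weight_spec.k,
                    row_standardized=weight_spec.row_standardized,
                    min_distance_km=weight_spec.min_distance_km,
                )
            else:
                sub_spec = None
            sel = knot_escalation(design, ladder=ladder, alpha=0.05,
                                  weight_spec=sub_spec, seed=seed, lambda_grid=lambda_grid)
            model = sel.selected_model
            ame = average_marginal_effect(model, design, "drought")
            se, p = ame_uncertainty(model, design, "drought", n_draws=n_draws, seed=rng)
            rows.append({"grouping": grouping, "category": category, "outcome": outcome,
                         "ame": ame.ame, "se": se, "p_value": p,
                         "significant": bool(p < threshold),
                         "selected_knots": sel.selected_knots, "skipped": None})
    return pd.DataFrame(rows)
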