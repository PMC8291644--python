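"""Knot-ladder model selection driven by residual Moran's I.

Models of increasing spatial flexibility are fitted along a ladder of
knot counts; the first rung whose Pearson residuals show no significant
spatial autocorrelation (two-sided Moran test at ``alpha``) is selected.
Selection depends only on the Moran p-value, never on AIC; AIC is
recorded per rung for the naive-vs-spatial comparison.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import gam
from .moran import MoranResult, WeightSpec, moran_test

logger = logging.getLogger(__name__)

DEFAULT_LADDER = (0, 50, 100, 500, 1000, 1500)


@dataclass
class RungRecord:
    knots: int
    aic: float | None
    moran_I: float | None
    moran_p: float | None
    error: str | None = None


@dataclass
class SelectionResult:
    ladder: tuple
    per_rung: list  # RungRecord, in ladder order, attempted rungs only
    selected_knots: int | None
    selected_model: gam.FittedModel | None
    exhausted: bool
    alpha: float
    models: dict = field(default_factory=dict)  # knots -> FittedModel (rung 0 + selected kept)

    def rung(self, knots: int) -> RungRecord:
        for r in self.per_rung:
            if r.knots == knots:
                return r
        raise KeyError(f"rung {knots} was not attempted")


def default_weight_spec(coords: np.ndarray) -> WeightSpec:
    return WeightSpec(coords=coords)


def knot_escalation(
    design: gam.DesignMatrix,
    ladder=DEFAULT_LADDER,
    alpha: float = 0.05,
    weight_spec: WeightSpec | None = None,
    seed: int = 0,
    lambda_grid=None,
    block_size: int = 512,
) -> SelectionResult:
    """Fit each rung in order, stopping at the first with Moran p >= alpha.

    Rungs exceeding the number of distinct coordinate points are skipped
    with a warning.  If no rung passes, the final fitted rung is returned
    with ``exhausted=True``.  Per-rung fit errors are recorded and the
    escalation continues.
    """
    ladder = tuple(ladder)
    if any(b <= a for a, b in zip(ladder, ladder[1:])):
        raise ValueError("ladder must be strictly increasing")
    coords = design.coords
    n_distinct = np.unique(coords, axis=0).shape[0]
    spec = weight_spec if weight_spec is not None else default_weight_spec(coords)

    per_rung: list[RungRecord] = []
    models: dict[int, gam.FittedModel] = {}
    selected = None
    last_fitted = None
    for K in ladder:
        if K > n_distinct:
            logger.warning("skipping rung %d: only %d distinct coordinates", K, n_distinct)
            continue
        try:
            basis = None if K == 0 else gam.spline_basis(coords, gam.make_knots(coords, K, seed))
            model = gam.fit_penalized_logistic(design, basis, lambda_grid=lambda_grid)
            resid = gam.model_residuals(model)
            mres: MoranResult = moran_test(resid, spec, block_size=block_size)
            per_rung.append(RungRecord(knots=K, aic=model.aic, moran_I=mres.I, moran_p=mres.p_value))
            last_fitted = (K, model)
            if K == 0:
                models[0] = model
            if mres.p_value >= alpha:
                selected = (K, model)
                models[K] = model
                break
        except (gam.ConvergenceError, gam.SeparationError, ValueError) as exc:
            logger.warning("rung %d failed: %s", K, exc)
            per_rung.append(RungRecord(knots=K, aic=None, moran_I=None, moran_p=None, error=str(exc)))
    exhausted = selected is None
    if exhausted and last_fitted is not None:
        selected = last_fitted
        models[selected[0]] = selected[1]
        logger.warning("ladder exhausted: no rung passed the Moran criterion; returning rung %d",
                       selected[0])
    return SelectionResult(
        ladder=ladder,
        per_rung=per_rung,
        selected_knots=None if selected is None else selected[0],
        selected_model=None if selected is None else selected[1],
        exhausted=exhausted,
        alpha=alpha,
        models=models,
    )


def compare_spatial_vs_naive(selection: SelectionResult, m: int = 12, alpha: float = 0.05) -> dict:
    """Naive (rung 0) vs selected spatial model: AIC difference, drought
    coefficients and Wald p-values under each, and how many drought terms
    are significant at the Bonferroni threshold alpha/m."""
    if 0 not in selection.models:
        raise ValueError("selection does not contain the rung-0 (no-spline) model")
    if selection.selected_model is None:
        raise ValueError("selection has no selected model")
    naive = selection.models[0]
    spatial = selection.selected_model
    threshold = alpha / m
    out = {
        "aic_naive": naive.aic,
        "aic_spatial": spatial.aic,
        "aic_difference": naive.aic - spatial.aic,
        "selected_knots": selection.selected_knots,
        "exhausted": selection.exhausted,
        "bonferroni_threshold": threshold,
        "drought_terms": {},
    }
    for name in [c for c in naive.column_names if c.startswith("drought[")]:
        rec = {}
        for label, model in (("naive", naive), ("spatial", spatial)):
            if name in model.column_names:
                p = model.wald_p_value(name)
                rec[label] = {
                    "coefficient": model.coefficient(name),
                    "p_value": p,
                    "significant": bool(p < threshold),
                }
            else:
                rec[label] = None
        out["drought_terms"][name] = rec
    for label, model in (("naive", naive), ("spatial", spatial)):
        out[f"n_significant_{label}"] = sum(
            1 for rec in out["drought_terms"].values()
            if rec[label] is not None and rec[label]["significant"]
        )
    return out
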