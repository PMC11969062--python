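"""Response surfaces over two climate axes, masked to the observed hull.

A fitted marginality model predicts a metric anywhere in centered-scaled
climate space, but only the region actually covered by sites is meaningful.
``predict_surface`` evaluates the fitted mean surface on a grid over two
model variables (all other predictors held at baseline: 0 for centered
numerics, the reference level for categoricals) and masks grid nodes outside
the convex hull of the observed site climates (closed hull: boundary points
count as inside). ``marginal_effect`` returns one-dimensional slices with
pointwise 95% Wald confidence bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .marginality_model import FitResult, _expand_terms

__all__ = ["SurfaceGrid", "predict_surface", "marginal_effect"]


@dataclass
class SurfaceGrid:
    """Prediction grid for one metric over two climate variables."""

    x_variable: str
    y_variable: str
    x_values: np.ndarray
    y_values: np.ndarray
    predictions: np.ndarray      # shape (len(y_values), len(x_values))
    inside_hull: np.ndarray      # same shape, boolean
    baseline: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per grid node (x, y, prediction, inside_hull)."""
        xx, yy = np.meshgrid(self.x_values, self.y_values)
        return pd.DataFrame({
            self.x_variable: xx.ravel(),
            self.y_variable: yy.ravel(),
            "prediction": self.predictions.ravel(),
            "inside_hull": self.inside_hull.ravel(),
        })


def _base_variables(fit: FitResult) -> list[str]:
    out = []
    for term in fit.spec.mean_terms:
        if term.endswith("^2"):
            out.append(term[:-2])
        elif ":" in term:
            out.extend(term.split(":"))
        else:
            out.append(term)
    seen = []
    for v in out:
        if v not in seen:
            seen.append(v)
    return seen


def _prediction_matrix(fit: FitResult, points: pd.DataFrame) -> np.ndarray:
    """Mean design rows for arbitrary predictor values, consistent with the
    training design (same term expansion, same categorical coding)."""
    if fit.spec is None or fit.design is None:
        raise ValueError("fit carries no spec/design; use fit_model")
    cat_levels = fit.design.cat_levels
    table = points.copy()
    for var in _base_variables(fit):
        if var in cat_levels:
            if var not in table.columns:
                table[var] = cat_levels[var][0]  # reference level
            table[var] = table[var].astype(object)
        elif var not in table.columns:
            table[var] = 0.0  # baseline of a centered, scaled predictor
    X, _ = _expand_terms(fit.spec.mean_terms, table, dict(cat_levels),
                         list(fit.design.dropped_terms))
    missing = [c for c in fit.x_columns if c not in X.columns]
    if missing:
        raise ValueError(f"cannot reconstruct design columns: {missing}")
    return X[fit.x_columns].to_numpy(float)


def predict_surface(
    fit: FitResult,
    x_variable: str,
    y_variable: str,
    observed_points,
    n_grid: int = 101,
    baseline: dict | None = None,
) -> SurfaceGrid:
    """Evaluate the fitted mean surface over a 2-D grid, hull-masked.

    ``observed_points`` is an (n, 2) array (or DataFrame with the two
    variables as columns) of observed site climates defining both the grid
    extent (no padding) and the convex hull mask. Other predictors sit at
    ``baseline`` (default 0 / reference level). Requires at least three
    non-collinear observed points for the hull.
    """
    if not fit.converged:
        raise ValueError("cannot build a surface from a non-converged fit")
    if isinstance(observed_points, pd.DataFrame):
        pts = observed_points[[x_variable, y_variable]].to_numpy(float)
    else:
        pts = np.asarray(observed_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("observed_points must be (n, 2)")
    try:
        tri = Delaunay(pts)
    except (QhullError, ValueError) as exc:
        raise ValueError(
            "convex hull undefined: need >= 3 non-collinear observed points"
        ) from exc

    x_values = np.linspace(pts[:, 0].min(), pts[:, 0].max(), n_grid)
    y_values = np.linspace(pts[:, 1].min(), pts[:, 1].max(), n_grid)
    xx, yy = np.meshgrid(x_values, y_values)

    grid = pd.DataFrame({x_variable: xx.ravel(), y_variable: yy.ravel()})
    for var, value in (baseline or {}).items():
        grid[var] = value
    X = _prediction_matrix(fit, grid)
    predictions = (X @ fit.beta).reshape(xx.shape)
    inside = tri.find_simplex(np.column_stack([xx.ravel(), yy.ravel()])) >= 0
    return SurfaceGrid(
        x_variable=x_variable, y_variable=y_variable,
        x_values=x_values, y_values=y_values,
        predictions=predictions, inside_hull=inside.reshape(xx.shape),
        baseline=dict(baseline or {}),
    )


def marginal_effect(
    fit: FitResult,
    x_variable: str,
    x_values,
    at: dict | None = None,
    level: float = 0.95,
) -> pd.DataFrame:
    """Marginal-effect slice: prediction ± Wald band along one variable.

    ``at`` fixes other predictors (e.g. ``{"ap": -1.0}``); everything else
    stays at baseline. The band is prediction ± z_{level}·SE from the mean
    coefficient covariance.
    """
    from scipy.stats import norm

    x_values = np.asarray(x_values, dtype=float)
    grid = pd.DataFrame({x_variable: x_values})
    for var, value in (at or {}).items():
        grid[var] = value
    X = _prediction_matrix(fit, grid)
    pred = X @ fit.beta
    se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.beta_cov(), X))
    zcrit = norm.ppf(0.5 + level / 2.0)
    return pd.DataFrame({
        x_variable: x_values,
        "prediction": pred,
        "lo": pred - zcrit * se,
        "hi": pred + zcrit * se,
        "se": se,
    })
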