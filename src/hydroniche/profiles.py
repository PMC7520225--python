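"""Continuous depth profiles from discrete proportional uptake.

Replicate uptake proportions exist only at the injection depths; the soil
water model needs a continuous per-cm root-activity density over the whole
0-125 cm column, and the ecology question ("do trees and grasses root
differently?") is a model-selection problem.  This module provides:

* :func:`fit_profile` -- maximum-likelihood fit of a cubic B-spline in depth
  under a beta likelihood with a logit link (proportions are bounded [0,1]
  responses), returning a normalized per-cm density plus logLik/df/AIC;
* :func:`compare_pooling` -- "all together" (one shared curve) versus
  "all separate" (independent curve per growth form) by AIC, with every
  candidate within 2 AIC of the best reported as supported;
* grid utilities: stratum totals to per-cm values, a 15-cm running average,
  and D50 (the depth above which half of the mass lies).

Depth grids are cell-based: a density of length n covers n contiguous 1-cm
cells with edges 0..n cm, and "density[i]" is the per-cm value over
[i, i+1) cm.  D50 is interpolated linearly within its crossing centimeter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.special import expit, logit
from statsmodels.othermod.betareg import BetaModel

__all__ = [
    "SmoothProfile",
    "ModelComparison",
    "FitError",
    "spline_design",
    "fit_profile",
    "fit_intercept_only",
    "compare_pooling",
    "per_cm",
    "running_mean_15",
    "depth50",
]

DEPTH_DOMAIN = (0.0, 125.0)
SPLINE_DEGREE = 3


class FitError(RuntimeError):
    """Raised when the beta-likelihood optimizer fails after restarts."""


def spline_design(x, knots: int, interior: np.ndarray, domain=DEPTH_DOMAIN):
    """Cubic B-spline design matrix with ``knots`` basis functions.

    ``interior`` holds the ``knots - (degree + 1)`` interior knot positions
    (empty for knots == 4).
    """
    lo, hi = domain
    t = np.concatenate(
        [
            np.repeat(lo, SPLINE_DEGREE + 1),
            np.asarray(interior, dtype=float),
            np.repeat(hi, SPLINE_DEGREE + 1),
        ]
    )
    x = np.clip(np.asarray(x, dtype=float), lo, hi - 1e-9)
    return BSpline.design_matrix(x, t, SPLINE_DEGREE).toarray()


def interior_knots(depths, knots: int, domain=DEPTH_DOMAIN) -> np.ndarray:
    """Interior knots at quantiles of the observed injection depths."""
    n_interior = knots - (SPLINE_DEGREE + 1)
    if n_interior < 0:
        raise ValueError(f"need at least {SPLINE_DEGREE + 1} knots, got {knots}")
    if n_interior == 0:
        return np.empty(0)
    qs = np.linspace(0, 1, n_interior + 2)[1:-1]
    uniq = np.unique(np.asarray(depths, dtype=float))
    pts = np.quantile(uniq, qs)
    lo, hi = domain
    return np.clip(pts, lo + 1e-6, hi - 1e-6)


@dataclass
class SmoothProfile:
    """A fitted continuous uptake/root density over the depth domain."""

    depth_grid_cm: np.ndarray  # cell centers
    density_per_cm: np.ndarray  # nonnegative, sums to 1 over 1-cm cells
    knots: int
    interior_knots: np.ndarray
    coef: np.ndarray
    loglik: float
    df: float
    aic: float

    def __post_init__(self):
        if np.any(self.density_per_cm < 0):
            raise ValueError("density must be nonnegative")
        if abs(self.density_per_cm.sum() - 1.0) > 1e-6:
            raise ValueError("density must integrate to 1 over the grid")

    @property
    def d50_cm(self) -> float:
        return depth50(self.density_per_cm)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"depth_cm": self.depth_grid_cm, "density_per_cm": self.density_per_cm}
        )


def _compress(y: np.ndarray) -> np.ndarray:
    """Pull exact 0/1 proportions off the boundary: y' = (y(N-1)+0.5)/N."""
    n = y.size
    return (y * (n - 1) + 0.5) / n


def _fit_beta(endog: np.ndarray, exog: np.ndarray):
    """ML beta regression (logit mean link, constant precision) with restarts."""
    model = BetaModel(endog, exog, exog_precision=np.ones((endog.size, 1)))
    # start from a least-squares fit on the logit scale
    z = logit(np.clip(endog, 1e-6, 1 - 1e-6))
    coef0, *_ = np.linalg.lstsq(exog, z, rcond=None)
    starts = [
        np.concatenate([coef0, [1.0]]),
        np.concatenate([np.zeros(exog.shape[1]), [0.0]]),
    ]
    last_exc = None
    for sp in starts:
        for method in ("bfgs", "nm"):
            try:
                res = model.fit(
                    start_params=sp, method=method, maxiter=2000, disp=False
                )
            except Exception as exc:  # singular hessians etc.
                last_exc = exc
                continue
            if np.isfinite(res.llf):
                return res
    raise FitError(f"beta regression did not converge: {last_exc}")


def fit_profile(
    replicates: pd.DataFrame,
    knots: int = 4,
    domain=DEPTH_DOMAIN,
    value_column: str = "proportion",
    depth_column: str = "depth_cm",
    _compressed: bool = False,
) -> SmoothProfile:
    """Fit a smooth per-cm uptake density to replicate proportions.

    ``replicates`` needs a depth column and a proportion column (values in
    [0, 1]; exact boundary values are compressed before fitting).  The knot
    count is the spline basis dimension: 4 gives a plain cubic, each extra
    knot adds one interior knot at a depth quantile.  The basis spans the
    observed depth range (where the injections are); over the rest of
    ``domain`` the fitted curve is extended by constant continuation on the
    logit scale before renormalizing to a per-cm density.  ``df`` counts
    the spline coefficients plus the beta precision parameter; AIC is
    ``2 df - 2 logLik``.
    """
    depths = replicates[depth_column].to_numpy(dtype=float)
    y = replicates[value_column].to_numpy(dtype=float)
    if not _compressed and np.any((y < 0) | (y > 1)):
        raise ValueError("responses must lie in [0, 1]")
    if np.unique(depths).size < 3:
        raise ValueError("need >= 3 distinct depths to fit a profile")
    if np.unique(depths).size < knots:
        raise ValueError(
            f"{knots}-knot basis needs >= {knots} distinct depths, "
            f"got {np.unique(depths).size}"
        )
    span = (float(depths.min()), float(depths.max()))
    interior = interior_knots(depths, knots, span)
    X = spline_design(depths, knots, interior, span)
    res = _fit_beta(y if _compressed else _compress(y), X)

    coef = np.asarray(res.params[: knots])
    lo, hi = domain
    centers = np.arange(lo, hi) + 0.5
    clamped = np.clip(centers, span[0], span[1])
    mu = expit(spline_design(clamped, knots, interior, span) @ coef)
    density = mu / mu.sum()
    df = knots + 1  # coefficients + one dispersion
    llf = float(res.llf)
    return SmoothProfile(
        depth_grid_cm=centers,
        density_per_cm=density,
        knots=knots,
        interior_knots=interior,
        coef=coef,
        loglik=llf,
        df=df,
        aic=2.0 * df - 2.0 * llf,
    )


def fit_intercept_only(values: np.ndarray) -> float:
    """logLik of the intercept-only beta model (nesting baseline)."""
    y = _compress(np.asarray(values, dtype=float))
    res = _fit_beta(y, np.ones((y.size, 1)))
    return float(res.llf)


@dataclass
class ModelComparison:
    """AIC comparison of pooled vs growth-form-specific profile models."""

    candidates: pd.DataFrame = field(repr=False)
    selected: list[str] = field(default_factory=list)
    profiles: dict = field(default_factory=dict, repr=False)

    @property
    def top(self) -> str:
        return str(self.candidates["model"].iloc[0])


def compare_pooling(
    tree_replicates: pd.DataFrame,
    grass_replicates: pd.DataFrame,
    knots: int = 4,
    domain=DEPTH_DOMAIN,
) -> ModelComparison:
    """Fit "all together" and "all separate" profile models and compare AIC.

    "All together" ignores growth form and fits one curve to the combined
    replicates; "all separate" is a single joint beta likelihood with an
    independent spline per growth form and one shared precision
    (df = 2 knots + 1 versus knots + 1).  Responses are boundary-compressed
    once on the combined data so the two likelihoods are comparable.
    Candidates within 2 AIC of the best are reported as supported.
    """
    combined = pd.concat([tree_replicates, grass_replicates], ignore_index=True)
    combined = combined.reset_index(drop=True)
    y_all = combined["proportion"].to_numpy(dtype=float)
    if np.any((y_all < 0) | (y_all > 1)):
        raise ValueError("responses must lie in [0, 1]")
    combined = combined.assign(proportion=_compress(y_all))
    n_tree = len(tree_replicates)
    tree_c = combined.iloc[:n_tree]
    grass_c = combined.iloc[n_tree:]

    together = fit_profile(combined, knots=knots, domain=domain, _compressed=True)
    tree = fit_profile(tree_c, knots=knots, domain=domain, _compressed=True)
    grass = fit_profile(grass_c, knots=knots, domain=domain, _compressed=True)

    # joint "all separate": block design, one shared beta precision
    is_tree = np.arange(len(combined)) < n_tree
    depths = combined["depth_cm"].to_numpy(dtype=float)
    Xs = []
    for mask, prof in ((is_tree, tree), (~is_tree, grass)):
        lohi = (float(depths[mask].min()), float(depths[mask].max()))
        B = spline_design(
            np.clip(depths, *lohi), knots, prof.interior_knots, lohi
        )
        Xs.append(B * mask[:, None])
    X_sep = np.hstack(Xs)
    res_sep = _fit_beta(combined["proportion"].to_numpy(), X_sep)
    ll_sep = float(res_sep.llf)
    df_sep = 2 * knots + 1

    rows = [
        {
            "model": "all_together",
            "logLik": together.loglik,
            "df": together.df,
            "AIC": together.aic,
        },
        {
            "model": "all_separate",
            "logLik": ll_sep,
            "df": df_sep,
            "AIC": 2.0 * df_sep - 2.0 * ll_sep,
        },
    ]
    table = pd.DataFrame(rows)
    best_ll = table["logLik"].max()
    best_aic = table["AIC"].min()
    table["dlogLik"] = best_ll - table["logLik"]
    table["dAIC"] = table["AIC"] - best_aic
    table = table.sort_values("AIC", kind="stable").reset_index(drop=True)
    selected = table.loc[table["dAIC"] < 2.0, "model"].tolist()
    return ModelComparison(
        candidates=table[["model", "logLik", "AIC", "dlogLik", "dAIC", "df"]],
        selected=selected,
        profiles={"all_together": together, "tree": tree, "grass": grass},
    )


def per_cm(strata_values, strata_bounds):
    """Convert per-stratum totals to per-cm values.

    ``strata_bounds`` are the n+1 contiguous edges (cm) of n strata; each
    stratum's value is divided by its thickness (e.g. 20 mm over the
    20-30 cm stratum becomes 2 mm per cm).
    """
    values = np.asarray(strata_values, dtype=float)
    bounds = np.asarray(strata_bounds, dtype=float)
    if bounds.size != values.size + 1:
        raise ValueError("need n+1 bounds for n strata")
    thickness = np.diff(bounds)
    if np.any(thickness <= 0):
        raise ValueError("strata must be contiguous with positive thickness")
    return values / thickness


def running_mean_15(values, window: int = 15):
    """Centered running average over a 1-cm grid, truncated at the edges.

    Near the top and bottom of the domain the window is shortened to what
    fits and the average renormalized over the cells actually present.
    """
    v = np.asarray(values, dtype=float)
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd cell count")
    kernel = np.ones(window)
    num = np.convolve(v, kernel, mode="same")
    cnt = np.convolve(np.ones_like(v), kernel, mode="same")
    return num / cnt


def depth50(density, dz: float = 1.0) -> float:
    """Depth (cm) above which half of the mass lies.

    ``density`` gives per-cm values over contiguous cells starting at the
    surface.  The crossing is located by linear interpolation inside the
    crossing cell; if the cumulative sits exactly at half over a flat
    stretch the shallowest crossing is reported.
    """
    d = np.asarray(density, dtype=float)
    if np.any(d < 0):
        raise ValueError("density must be nonnegative")
    total = d.sum() * dz
    if total <= 0:
        raise ValueError("density integrates to zero; D50 undefined")
    target = 0.5 * total
    cum = np.cumsum(d) * dz
    i = int(np.searchsorted(cum, target))  # first cell whose upper edge >= target
    below = cum[i - 1] if i > 0 else 0.0
    if d[i] <= 0:  # flat stretch exactly at half: report shallowest crossing
        return float(i * dz)
    return float(i * dz + (target - below) / d[i])
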