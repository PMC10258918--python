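"""Capillary-number analysis of boundary fractality.

The moving cell-cell interface is treated like the interface of two
partially miscible fluids.  With viscosity analogue ``mu`` (held constant,
playing the role of the move probability), interfacial-tension analogue
``sigma = a_l / a_d`` and boundary velocity ``V``, the capillary number is
``Ca = mu * V / sigma``.  Assuming a locally linear fractality-vs-Ca law
``f = -m * Ca + b`` together with the two boundary conditions

    f -> 1        as V -> V_max   (fresh, straight contact line)
    f -> f_final  as V -> 0       (equilibrated boundary)

yields ``f_final = m * mu * V_max / sigma + 1`` and
``-df/dV = m * mu / sigma`` — both inversely proportional to sigma.  The
module fits those inverse laws, ``y = A / (sigma + B) + C``, by non-linear
least squares, and compares the inverse family against linear, quadratic
and exponential-decay alternatives by residual norm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import CellfractError, FitError, UndefinedSlopeError

__all__ = [
    "CapillaryModel",
    "InverseFit",
    "sigma_from_params",
    "capillary_number",
    "fractality_velocity_slope",
    "fit_inverse",
    "compare_fit_families",
    "predict_f_final",
]

DEFAULT_MU = 1.0  # nominal viscosity analogue; only ratios matter


@dataclass(frozen=True)
class CapillaryModel:
    """One condition's fluid-analogy summary."""

    sigma: float
    f_final: float
    v_max: float = np.nan
    mu: float = DEFAULT_MU
    m: float = np.nan  # local slope constant of f = -m Ca + b
    b_lin: float = np.nan

    @property
    def ca_max(self) -> float:
        return capillary_number(self.mu, self.v_max, self.sigma)


@dataclass(frozen=True)
class InverseFit:
    """Fitted coefficients of y = A / (sigma + B) + C (or a rival family)."""

    A: float
    B: float
    C: float
    residual_norm: float  # squared 2-norm of residuals
    family: str = "inverse"

    def __call__(self, sigma) -> np.ndarray:
        return predict_f_final(sigma, self)


def sigma_from_params(a_l: float, a_d: float) -> float:
    """Interfacial-tension analogue of a simulation condition.

    ``sigma = a_l / a_d``: the lower the unlike-affinity ``a_d``, the
    stronger the mutual repulsion and the higher the effective tension.
    """
    if a_d <= 0:
        raise CellfractError(f"a_d must be > 0, got {a_d}")
    return a_l / a_d


def capillary_number(mu: float, v: float, sigma: float) -> float:
    """Ca = mu * V / sigma, the ratio of viscous to interfacial forces."""
    if sigma <= 0:
        raise CellfractError(f"sigma must be > 0, got {sigma}")
    return mu * v / sigma


def fractality_velocity_slope(
    f_series: np.ndarray, v_series: np.ndarray
) -> float:
    """Least-squares slope df/dV over aligned fractality/velocity series.

    Expected negative: fractality grows as the boundary slows.  The
    magnitude ``-df/dV`` is the quantity compared across conditions.
    Raises :class:`UndefinedSlopeError` when every velocity is equal.
    """
    f = np.asarray(f_series, float)
    v = np.asarray(v_series, float)
    if f.shape != v.shape or f.size < 3:
        raise CellfractError("need >= 3 aligned (f, V) samples")
    if np.ptp(v) == 0:
        raise UndefinedSlopeError("slope undefined: zero velocity variance")
    slope, _ = np.polyfit(v, f, 1)
    return float(slope)


def _residuals(model, params, x, y):
    return model(x, *params) - y


def _inverse_model(s, A, B, C):
    return A / (s + B) + C


def fit_inverse(
    sigmas: np.ndarray,
    ys: np.ndarray,
    fix_C: float | None = None,
) -> InverseFit:
    """Fit ``y = A / (sigma + B) + C`` by non-linear least squares.

    The fit is initialisation-sensitive, so a small multi-start grid is
    tried (A and B over {0.1, 1, 10}, C over {min(y), 1} when free) and the
    lowest final residual wins.  ``fix_C`` pins the offset — used with
    ``fix_C=1`` for the f_final law, whose boundary condition forces
    f -> 1 as sigma -> infinity.  B is kept above ``-min(sigma)`` so the
    pole stays outside the data range.
    """
    s = np.asarray(sigmas, float)
    y = np.asarray(ys, float)
    if s.size < 3 or s.size != y.size:
        raise CellfractError("need >= 3 (sigma, y) pairs")
    b_floor = -float(s.min()) + 1e-9

    best = None
    c_starts = [1.0] if fix_C is not None else [float(y.min()), 1.0]
    for a0 in (0.1, 1.0, 10.0):
        for b0 in (0.1, 1.0, 10.0):
            for c0 in c_starts:
                if fix_C is not None:
                    fun = lambda p: _inverse_model(s, p[0], p[1], fix_C) - y
                    x0 = [a0, b0]
                    bounds = ([-np.inf, b_floor], [np.inf, np.inf])
                else:
                    fun = lambda p: _inverse_model(s, p[0], p[1], p[2]) - y
                    x0 = [a0, b0, c0]
                    bounds = ([-np.inf, b_floor, -np.inf], [np.inf, np.inf, np.inf])
                try:
                    res = least_squares(fun, x0, bounds=bounds, xtol=1e-14, ftol=1e-14)
                except Exception:
                    continue
                if not res.success:
                    continue
                cost = float(np.sum(res.fun**2))
                if best is None or cost < best[0]:
                    best = (cost, res.x)
    if best is None:
        raise FitError("inverse fit failed to converge from every start")
    cost, p = best
    if fix_C is not None:
        return InverseFit(float(p[0]), float(p[1]), float(fix_C), cost)
    return InverseFit(float(p[0]), float(p[1]), float(p[2]), cost)


def _fit_poly(s, y, deg):
    coef = np.polyfit(s, y, deg)
    resid = np.polyval(coef, s) - y
    return coef, float(np.sum(resid**2))


def _fit_exp_decay(s, y):
    """A * exp(-sigma / B) + C, multi-start on the decay length B."""
    best = None
    for b0 in (0.5, 1.0, 5.0, 20.0):
        for a0 in (float(np.ptp(y)) or 1.0, 1.0):
            x0 = [a0, b0, float(y.min())]
            fun = lambda p: p[0] * np.exp(-s / p[1]) + p[2] - y
            try:
                res = least_squares(fun, x0, bounds=([-np.inf, 1e-9, -np.inf], np.inf))
            except Exception:
                continue
            if not res.success:
                continue
            cost = float(np.sum(res.fun**2))
            if best is None or cost < best[0]:
                best = (cost, res.x)
    if best is None:
        raise FitError("exponential-decay fit failed to converge")
    return best[1], best[0]


def compare_fit_families(sigmas: np.ndarray, ys: np.ndarray):
    """Residual norms of inverse, linear, quadratic and exp-decay fits.

    Returns a pandas DataFrame with one row per family (non-convergent
    families flagged rather than dropped) and ``best = True`` on the
    family with the lowest residual norm.
    """
    import pandas as pd

    s = np.asarray(sigmas, float)
    y = np.asarray(ys, float)
    if s.size < 4:
        raise CellfractError("family comparison needs >= 4 points")
    rows = []
    try:
        inv = fit_inverse(s, y)
        rows.append({"family": "inverse", "residual_norm": inv.residual_norm, "converged": True})
    except FitError:
        rows.append({"family": "inverse", "residual_norm": np.nan, "converged": False})
    for name, deg in (("linear", 1), ("quadratic", 2)):
        _, rn = _fit_poly(s, y, deg)
        rows.append({"family": name, "residual_norm": rn, "converged": True})
    try:
        _, rn = _fit_exp_decay(s, y)
        rows.append({"family": "exp_decay", "residual_norm": rn, "converged": True})
    except FitError:
        rows.append({"family": "exp_decay", "residual_norm": np.nan, "converged": False})
    table = pd.DataFrame(rows)
    table["best"] = table["residual_norm"] == table["residual_norm"].min()
    return table


def predict_f_final(sigma, fit: InverseFit) -> np.ndarray:
    """Evaluate the fitted inverse law; decreasing in sigma when A > 0."""
    return _inverse_model(np.asarray(sigma, float), fit.A, fit.B, fit.C)
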