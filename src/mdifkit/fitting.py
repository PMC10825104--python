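"""Standalone kinetic fitting and macroparameter quantification.

Weighted nonlinear least-squares fitting of single TACs to the irreversible
2TCM against a given input function (measured AIF, MDIF or IDIF), Patlak
graphical analysis with conversion to CMRGlu, error-propagation coefficient
of variation of Ki, windowed goodness-of-fit, and input-function comparison
statistics (windowed AUC ratios, percent error / percent difference).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .kinetics import TAC, MicroParams, TimeGrid, twotcm_forward

__all__ = [
    "WeightVector",
    "FitResult",
    "PatlakResult",
    "CmrgluConfig",
    "CurveComparison",
    "STANDALONE_UPPER",
    "STANDALONE_LOWER",
    "STANDALONE_START",
    "make_weights",
    "fit_standalone",
    "patlak",
    "cmrglu_from_ki",
    "ki_gradient",
    "cv_ki",
    "compare_curves",
    "percent_error",
    "percent_difference",
]

# Standalone-fit boxes (K1, k2, k3, Vb): wider than the SIME boxes and with
# no distribution-volume constraint.
STANDALONE_UPPER = (0.5, 0.5, 0.2, 1.0)
STANDALONE_LOWER = (0.0, 0.0, 0.0, 0.0)
STANDALONE_START = (0.1, 0.15, 0.05, 0.05)

#: Default AUC comparison windows, minutes.
DEFAULT_AUC_WINDOWS = ((0.0, 5.0), (5.0, 10.0), (10.0, 30.0), (30.0, 60.0))


@dataclass(frozen=True)
class WeightVector:
    """Per-frame fit weights, normalized so max(w) = 1."""

    w: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.w, float)
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("weights must be finite and >= 0")
        if w.max() <= 0:
            raise ValueError("all-zero weight vector")
        w = w / w.max()
        w.setflags(write=False)
        object.__setattr__(self, "w", w)


def make_weights(grid: TimeGrid, wb_tac: TAC) -> WeightVector:
    """Inverse-variance weights: frame duration over whole-brain activity.

    w_i is proportional to dt_i / C_wb(t_i), with frames where the
    whole-brain activity is non-positive given zero weight, normalized to a
    maximum of 1.
    """
    if wb_tac.grid != grid:
        raise ValueError("weight grid must match the whole-brain TAC grid")
    v = wb_tac.values
    raw = np.where(v > 0, grid.frame_duration / np.where(v > 0, v, 1.0), 0.0)
    return WeightVector(raw)


@dataclass
class FitResult:
    """Output of the standalone weighted 2TCM fit."""

    params: MicroParams
    wrss: float
    wrss_0_3min: float
    wrss_0_60min: float
    covariance: np.ndarray  # 3x3, (K1, k2, k3) block
    cv_ki: float  # percent
    fitted_curve: TAC
    converged: bool = True


def _fit_residuals(x, tac, cp, cb, sqw):
    p = MicroParams(*x)
    model = twotcm_forward(p, cp, cb)
    return sqw * (model.values - tac.values)


def fit_standalone(
    tac: TAC,
    cp: TAC,
    cb: TAC | None = None,
    weights: WeightVector | None = None,
    R: float = 1.0,
    start=STANDALONE_START,
) -> FitResult:
    """Weighted NLLS fit of one TAC to the irreversible 2TCM.

    ``cp`` is the plasma input (measured AIF, MDIF, or IDIF); the
    whole-blood curve defaults to ``R * cp``. Bounds are 0..(0.5, 0.5, 0.2,
    1.0) for (K1, k2, k3, Vb) with no distribution-volume constraint. The
    reported covariance is the (K1, k2, k3) block of (J^T J)^{-1} WRSS / T,
    and cv_ki propagates it through the gradient of Ki.
    """
    if cp.grid != tac.grid:
        raise ValueError("tac and cp must share one TimeGrid")
    if cb is None:
        cb = cp.with_values(R * cp.values)
    if weights is None:
        weights = WeightVector(np.ones(len(tac.grid)))
    sqw = np.sqrt(weights.w)
    res = least_squares(
        _fit_residuals,
        np.asarray(start, float),
        bounds=(STANDALONE_LOWER, STANDALONE_UPPER),
        args=(tac, cp, cb, sqw),
        method="trf",
        ftol=1e-12,
        xtol=1e-12,
        gtol=1e-12,
        max_nfev=2000,
    )
    params = MicroParams(*res.x)
    fitted = twotcm_forward(params, cp, cb, label=f"fit({tac.label})")
    r = sqw * (fitted.values - tac.values)
    wrss = float(np.sum(r**2))
    mid = tac.t
    wrss_3 = float(np.sum(r[mid <= 3.0] ** 2))
    wrss_60 = float(np.sum(r[mid <= 60.0] ** 2))
    T = len(tac.grid)
    J = res.jac[:, :3]
    JtJ = J.T @ J
    try:
        gamma = np.linalg.inv(JtJ) * wrss / T
    except np.linalg.LinAlgError:
        gamma = np.full((3, 3), np.nan)
    cv = cv_ki(params, gamma)
    return FitResult(
        params=params,
        wrss=wrss,
        wrss_0_3min=wrss_3,
        wrss_0_60min=wrss_60,
        covariance=gamma,
        cv_ki=cv,
        fitted_curve=fitted,
        converged=bool(res.status > 0),
    )


# ---------------------------------------------------------------------------
# Variance of Ki by error propagation
# ---------------------------------------------------------------------------


def ki_gradient(params: MicroParams) -> np.ndarray:
    """Gradient of Ki = K1 k3 / (k2 + k3) with respect to (K1, k2, k3)."""
    kf = params.kf
    if kf == 0:
        raise ZeroDivisionError("Ki gradient undefined at k2 = k3 = 0")
    return np.array(
        [
            params.k3 / kf,
            -params.K1 * params.k3 / kf**2,
            params.K1 * params.k2 / kf**2,
        ]
    )


def cv_ki(params: MicroParams, covariance: np.ndarray) -> float:
    """Coefficient of variation of Ki, percent: 100 sqrt(g Γ g^T) / Ki."""
    ki = params.Ki
    if ki <= 0 or not np.all(np.isfinite(covariance)):
        return float("nan")
    g = ki_gradient(params)
    var = float(g @ covariance @ g)
    return 100.0 * math.sqrt(max(var, 0.0)) / ki


# ---------------------------------------------------------------------------
# Patlak graphical analysis and CMRGlu
# ---------------------------------------------------------------------------


@dataclass
class PatlakResult:
    """Patlak slope (reported as mL/100 g/min) and intercept."""

    Ki: float  # slope * 100, mL/100 g/min
    intercept: float  # mL/g
    t_star: float
    points_used: int
    cmrglu: float | None = None  # umol/100 g/min

    @property
    def slope(self) -> float:
        """Raw slope, mL/g/min."""
        return self.Ki / 100.0


@dataclass(frozen=True)
class CmrgluConfig:
    """Constants converting net FDG clearance to glucose consumption."""

    lumped_constant: float = 0.52
    plasma_glucose: float = 5.0  # umol/mL

    def __post_init__(self):
        if self.lumped_constant <= 0 or self.plasma_glucose <= 0:
            raise ValueError("lumped constant and plasma glucose must be > 0")


def patlak(
    tac: TAC,
    cp: TAC,
    t_star: float = 20.0,
    cmrglu: CmrgluConfig | None = None,
) -> PatlakResult:
    """Patlak graphical analysis for irreversible tracers.

    Ordinary least squares of C(t)/Cp(t) against int_0^t Cp / Cp(t) over
    frames with mid-time beyond ``t_star``. The plasma running integral is
    trapezoidal on the input grid with the left edge closed at (0, 0). The
    slope estimates the net clearance Ki and is reported times 100
    (mL/100 g/min); pass a :class:`CmrgluConfig` to also convert to CMRGlu.
    """
    if cp.grid != tac.grid:
        raise ValueError("tac and cp must share one TimeGrid")
    t = tac.t
    sel = t > t_star
    if np.count_nonzero(sel) < 3:
        raise ValueError(f"need >= 3 frames beyond t* = {t_star} min")
    if np.any(cp.values[sel] <= 0):
        raise ValueError("plasma input must be positive beyond t*")
    t0 = np.concatenate([[0.0], t]) if t[0] > 0 else t
    c0 = np.concatenate([[0.0], cp.values]) if t[0] > 0 else cp.values
    integral = np.interp(t, t0, _cumtrapz(t0, c0))
    x = integral[sel] / cp.values[sel]
    y = tac.values[sel] / cp.values[sel]
    slope, intercept = np.polyfit(x, y, 1)
    value = None
    if cmrglu is not None:
        value = cmrglu_from_ki(100.0 * slope, cmrglu)
    return PatlakResult(
        Ki=100.0 * float(slope),
        intercept=float(intercept),
        t_star=t_star,
        points_used=int(np.count_nonzero(sel)),
        cmrglu=value,
    )


def _cumtrapz(t, c):
    out = np.zeros_like(c)
    out[1:] = np.cumsum(0.5 * (c[1:] + c[:-1]) * np.diff(t))
    return out


def cmrglu_from_ki(ki: float, cfg: CmrgluConfig) -> float:
    """CMRGlu (umol/100 g/min) = Ki (mL/100 g/min) * glucose / lumped constant."""
    return ki * cfg.plasma_glucose / cfg.lumped_constant


# ---------------------------------------------------------------------------
# Input-function comparison statistics
# ---------------------------------------------------------------------------


def percent_error(observed: float, expected: float) -> float:
    """100 (m - m_hat) / m_hat."""
    return 100.0 * (observed - expected) / expected


def percent_difference(m1: float, m2: float) -> float:
    """100 |m1 - m2| / mean(m1, m2)."""
    return 100.0 * abs(m1 - m2) / ((m1 + m2) / 2.0)


@dataclass
class CurveComparison:
    windows: tuple
    auc_ratios: dict[str, float]
    auc_1: float
    auc_2: float
    percent_difference: float


def _window_auc(tac: TAC, lo: float, hi: float) -> float:
    """Trapezoidal AUC of the mid-time-sampled curve over [lo, hi].

    The curve is linearly interpolated at the window edges (and through
    (0, 0) before the first mid-time).
    """
    t = tac.t
    v = tac.values
    if t[0] > 0:
        t = np.concatenate([[0.0], t])
        v = np.concatenate([[0.0], v])
    inside = (t > lo) & (t < hi)
    ts = np.concatenate([[lo], t[inside], [hi]])
    vs = np.interp(ts, t, v)
    return float(np.trapezoid(vs, ts))


def compare_curves(c1: TAC, c2: TAC, windows=DEFAULT_AUC_WINDOWS) -> CurveComparison:
    """Windowed AUC ratios (c1/c2) plus the overall AUC percent difference."""
    if c1.grid != c2.grid:
        raise ValueError("curves must share one TimeGrid")
    ratios = {}
    for lo, hi in windows:
        a1 = _window_auc(c1, lo, hi)
        a2 = _window_auc(c2, lo, hi)
        ratios[f"{lo:g}-{hi:g}"] = a1 / a2 if a2 != 0 else float("nan")
    lo = min(w[0] for w in windows)
    hi = max(w[1] for w in windows)
    a1 = _window_auc(c1, lo, hi)
    a2 = _window_auc(c2, lo, hi)
    return CurveComparison(
        windows=tuple(windows),
        auc_ratios=ratios,
        auc_1=a1,
        auc_2=a2,
        percent_difference=percent_difference(a1, a2),
    )
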