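"""Simultaneous estimation (SIME) of the input function.

Two estimators share one cost function: the sum over regions of squared
residuals between each measured TAC and its 2TCM fit driven by the
candidate input function, plus squared residuals at the late blood-sample
anchors,

    RSS = sum_j sum_i (Cj_fit(t_i) - Cj(t_i))^2 + sum_k w_k (Cp(t_k) - C_k)^2.

* MDIF mode: the candidate input is the closed-form inversion of the
  whole-brain TAC, parameterized by the four whole-brain rate constants
  (K1, k2, k3, Vb) -> 4n + 4 free parameters for n regions.
* IDIF mode: the candidate input is the Feng tri-exponential with 7 free
  parameters (A1..A3, lambda1..3, delay) -> 4n + 7; anchor residuals carry
  an extra weight of 10 and the delay is boxed to +/-10 s around an initial
  estimate from the whole-brain TAC rise.

Tissue parameters are box-bounded (upper 0.2 mL/g/min, 0.4, 0.2 1/min,
0.10 mL/g; lower 0.01 on all) and constrained to a distribution volume
below unity (K1 < k2 + k3). The constraint is enforced smoothly by fitting
the ratio s = K1/(k2 + k3) in (0.01, 0.999); the K1 box itself is kept by a
hinge penalty residual, which is inactive at any interior solution.
Optimization is bound-constrained nonlinear least squares (trust-region
reflective) with a seeded Latin-hypercube multi-start.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .kinetics import TAC, FengParams, MdifModel, MicroParams, feng_value, mdif_from_wb, twotcm_forward

logger = logging.getLogger(__name__)

__all__ = [
    "AnchorSample",
    "SimeProblem",
    "SimeResult",
    "TISSUE_UPPER",
    "TISSUE_LOWER",
    "IDIF_UPPER",
    "estimate_delay",
    "fit_sime_mdif",
    "fit_sime_idif",
]

# Tissue-parameter boxes (K1, k2, k3, Vb), literature-based.
TISSUE_UPPER = (0.2, 0.4, 0.2, 0.10)
TISSUE_LOWER = (0.01, 0.01, 0.01, 0.01)

# Input-model boxes for IDIF mode (A1, A2, A3, lam1, lam2, lam3).
IDIF_UPPER = (4000.0, 100.0, 50.0, 25.0, 1.0, 0.1)
IDIF_LOWER = (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

#: Ratio s = K1/(k2+k3) box enforcing distribution volume < 1.
S_BOUNDS = (0.01, 0.999)

#: Hinge-penalty weight keeping K1 inside its own box under the s-parameterization.
K1_PENALTY = 1e3

#: Default anchor weights by mode.
ANCHOR_WEIGHT = {"mdif": 1.0, "idif": 10.0}


@dataclass(frozen=True)
class AnchorSample:
    """A late blood sample anchoring the input-function scale."""

    time: float  # minutes, mid-draw
    concentration: float  # plasma activity, kBq/mL (or a.u.)
    weight: float = 1.0

    def __post_init__(self):
        if self.concentration <= 0:
            raise ValueError("anchor concentration must be > 0")
        if self.weight < 0:
            raise ValueError("anchor weight must be >= 0")


@dataclass
class SimeProblem:
    """One simultaneous-estimation problem."""

    wb_tac: TAC
    region_tacs: list[TAC]
    anchors: list[AnchorSample]
    R: float = 1.0
    mode: str = "mdif"

    def __post_init__(self):
        if self.mode not in ("mdif", "idif"):
            raise ValueError(f"mode must be 'mdif' or 'idif', got {self.mode!r}")
        if len(self.region_tacs) < 2:
            raise ValueError("SIME needs at least 2 region TACs")
        if not self.anchors:
            raise ValueError("SIME needs at least 1 anchor sample")
        for tac in self.region_tacs:
            if tac.grid != self.wb_tac.grid:
                raise ValueError("all TACs must share one TimeGrid")
        t_end = self.wb_tac.grid.frame_end[-1]
        for a in self.anchors:
            if not (0 <= a.time <= t_end):
                raise ValueError(f"anchor at {a.time} min outside scan window [0, {t_end}]")

    @property
    def n_regions(self) -> int:
        return len(self.region_tacs)


@dataclass
class SimeResult:
    """Joint fit output: input-function parameters, regional kinetics, diagnostics."""

    mode: str
    region_params: list[MicroParams]
    input_function: TAC
    cost: float
    anchor_residuals: list[float]  # percent difference per anchor
    converged: bool
    n_parameters: int
    wb_params: MicroParams | None = None  # mdif mode
    feng: FengParams | None = None  # idif mode
    start_costs: list[float] = field(default_factory=list)
    region_labels: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "cost": self.cost,
            "converged": self.converged,
            "n_parameters": self.n_parameters,
            "anchor_residuals_pct": self.anchor_residuals,
            "region_params": [
                {"label": lbl, "K1": p.K1, "k2": p.k2, "k3": p.k3, "Vb": p.Vb, "Ki": p.Ki}
                for lbl, p in zip(
                    self.region_labels
                    or [f"region{i + 1}" for i in range(len(self.region_params))],
                    self.region_params,
                )
            ],
            "input_function": {
                "t_min": self.input_function.t.tolist(),
                "value": self.input_function.values.tolist(),
            },
        }
        if self.wb_params is not None:
            p = self.wb_params
            d["wb_params"] = {"K1": p.K1, "k2": p.k2, "k3": p.k3, "Vb": p.Vb, "Ki": p.Ki}
        if self.feng is not None:
            d["feng_params"] = dict(
                zip(("A1", "A2", "A3", "lam1", "lam2", "lam3", "delay"), self.feng.as_array())
            )
        return d


# ---------------------------------------------------------------------------
# Delay estimation from the whole-brain rise
# ---------------------------------------------------------------------------


def estimate_delay(wb_tac: TAC) -> float:
    """Arrival time of tracer in the brain, from the whole-brain TAC rise.

    Returns the time at which the curve first exceeds 5% of its maximum
    within the first two minutes, with linear back-interpolation to the
    crossing. Raises on a flat curve.
    """
    t = wb_tac.t
    v = wb_tac.values
    early = v[t <= 2.0]
    if early.size == 0:
        early = v[:1]
    peak = float(np.max(early))
    if peak <= 0:
        raise ValueError("whole-brain TAC has no early rise; cannot estimate delay")
    thr = 0.05 * peak
    idx = np.argmax(v > thr)
    if v[idx] <= thr:
        raise ValueError("whole-brain TAC never exceeds 5% of its early peak")
    if idx == 0:
        # crossing inside the first frame: interpolate from (0, 0)
        t0, v0 = 0.0, 0.0
    else:
        t0, v0 = t[idx - 1], v[idx - 1]
    frac = (thr - v0) / (v[idx] - v0)
    return float(max(0.0, t0 + frac * (t[idx] - t0)))


# ---------------------------------------------------------------------------
# Parameter packing
# ---------------------------------------------------------------------------


def _tissue_to_vector(p: MicroParams) -> np.ndarray:
    s = p.K1 / p.kf
    return np.array([s, p.k2, p.k3, p.Vb])


def _tissue_from_vector(x) -> MicroParams:
    s, k2, k3, vb = x
    return MicroParams(K1=s * (k2 + k3), k2=k2, k3=k3, Vb=vb)


def _tissue_bounds():
    lo = np.array([S_BOUNDS[0], TISSUE_LOWER[1], TISSUE_LOWER[2], TISSUE_LOWER[3]])
    hi = np.array([S_BOUNDS[1], TISSUE_UPPER[1], TISSUE_UPPER[2], TISSUE_UPPER[3]])
    return lo, hi


def _k1_penalty(params: MicroParams) -> float:
    return K1_PENALTY * (
        max(0.0, params.K1 - TISSUE_UPPER[0]) + max(0.0, TISSUE_LOWER[0] - params.K1)
    )


# ---------------------------------------------------------------------------
# Cost functions
# ---------------------------------------------------------------------------


def _residuals(problem: SimeProblem, cp: TAC, tissue_sets: list[MicroParams], anchor_w: float):
    res = []
    for tac, p in zip(problem.region_tacs, tissue_sets):
        fit = twotcm_forward(p, cp, R=problem.R)
        res.append(fit.values - tac.values)
    anchor_t = np.array([a.time for a in problem.anchors])
    anchor_c = np.array([a.concentration for a in problem.anchors])
    cp_at = cp.interp(anchor_t)
    res.append(math.sqrt(anchor_w) * (cp_at - anchor_c))
    res.append(np.array([_k1_penalty(p) for p in tissue_sets]))
    return np.concatenate(res)


def _mdif_unpack(x, problem):
    wb = _tissue_from_vector(x[:4])
    tissue = [_tissue_from_vector(x[4 + 4 * j : 8 + 4 * j]) for j in range(problem.n_regions)]
    return wb, tissue


def _mdif_residuals(x, problem, anchor_w):
    wb, tissue = _mdif_unpack(x, problem)
    cp = mdif_from_wb(MdifModel(wb, problem.R), problem.wb_tac)
    res = _residuals(problem, cp, tissue, anchor_w)
    return np.append(res, _k1_penalty(wb))


def _idif_unpack(x, problem):
    feng = FengParams(*x[:7])
    tissue = [_tissue_from_vector(x[7 + 4 * j : 11 + 4 * j]) for j in range(problem.n_regions)]
    return feng, tissue


def _idif_residuals(x, problem, anchor_w):
    feng, tissue = _idif_unpack(x, problem)
    grid = problem.wb_tac.grid
    cp = TAC(grid, feng_value(feng, grid.mid_time), "IDIF")
    return _residuals(problem, cp, tissue, anchor_w)


# ---------------------------------------------------------------------------
# Multi-start driver
# ---------------------------------------------------------------------------


def _multistart(fun, lo, hi, n_starts, seed, max_nfev):
    """Latin-hypercube starts plus the geometric box midpoint; best cost wins."""
    d = lo.size
    if n_starts > 0:
        sampler = qmc.LatinHypercube(d=d, seed=seed)
        unit = sampler.random(n=n_starts)
        starts = lo + unit * (hi - lo)
    else:
        starts = np.empty((0, d))
    lo_pos = np.where(lo > 0, lo, 1e-3 * (hi - lo) + lo)
    mid = np.sqrt(lo_pos * hi)
    starts = np.vstack([mid, starts])
    best = None
    costs = []
    for x0 in starts:
        try:
            r = least_squares(
                fun,
                np.clip(x0, lo, hi),
                bounds=(lo, hi),
                method="trf",
                ftol=1e-9,
                xtol=1e-9,
                gtol=1e-10,
                max_nfev=max_nfev,
            )
        except Exception as exc:  # numerical blow-up in one start is not fatal
            logger.warning("SIME start failed: %s", exc)
            costs.append(float("inf"))
            continue
        costs.append(2.0 * r.cost)  # least_squares cost = 0.5 * RSS
        if best is None or r.cost < best.cost:
            best = r
    if best is None:
        raise RuntimeError("all SIME starts failed")
    return best, costs


def _finish(problem, best, costs, cp, tissue, n_params, wb=None, feng=None):
    anchor_pct = []
    for a in problem.anchors:
        est = float(cp.interp(a.time))
        anchor_pct.append(100.0 * abs(est - a.concentration) / ((est + a.concentration) / 2.0))
    return SimeResult(
        mode=problem.mode,
        wb_params=wb,
        feng=feng,
        region_params=tissue,
        input_function=cp,
        cost=2.0 * best.cost,
        anchor_residuals=anchor_pct,
        converged=bool(best.status > 0),
        n_parameters=n_params,
        start_costs=costs,
        region_labels=[t.label for t in problem.region_tacs],
    )


def fit_sime_mdif(
    problem: SimeProblem,
    n_starts: int = 8,
    seed: int = 0,
    max_nfev: int = 2000,
) -> SimeResult:
    """Joint MDIF estimation: 4 whole-brain + 4 per-region parameters.

    The candidate input function is the closed-form whole-brain inversion;
    its four parameters and the regional rate constants are fit together
    against all region TACs and the anchor samples. Returns the best
    solution over ``n_starts`` Latin-hypercube starts plus the box midpoint.
    """
    if problem.mode != "mdif":
        raise ValueError("problem.mode must be 'mdif'")
    anchor_w = ANCHOR_WEIGHT["mdif"]
    lo_t, hi_t = _tissue_bounds()
    lo = np.concatenate([lo_t] * (problem.n_regions + 1))
    hi = np.concatenate([hi_t] * (problem.n_regions + 1))
    best, costs = _multistart(
        lambda x: _mdif_residuals(x, problem, anchor_w), lo, hi, n_starts, seed, max_nfev
    )
    wb, tissue = _mdif_unpack(best.x, problem)
    cp = mdif_from_wb(MdifModel(wb, problem.R), problem.wb_tac)
    n_params = 4 * problem.n_regions + 4
    return _finish(problem, best, costs, cp, tissue, n_params, wb=wb)


def fit_sime_idif(
    problem: SimeProblem,
    n_starts: int = 8,
    seed: int = 0,
    max_nfev: int = 2000,
    anchor_weight: float | None = None,
) -> SimeResult:
    """Joint exponential-IDIF estimation: 7 input + 4 per-region parameters.

    Anchor residuals are weighted (default 10). The delay is boxed to
    +/-10 s around an initial estimate from the whole-brain TAC rise.
    """
    if problem.mode != "idif":
        raise ValueError("problem.mode must be 'idif'")
    anchor_w = ANCHOR_WEIGHT["idif"] if anchor_weight is None else anchor_weight
    delay0 = estimate_delay(problem.wb_tac)
    d_lo = max(0.0, delay0 - 10.0 / 60.0)
    d_hi = delay0 + 10.0 / 60.0
    lo_t, hi_t = _tissue_bounds()
    lo = np.concatenate([np.array(IDIF_LOWER + (d_lo,)), np.tile(lo_t, problem.n_regions)])
    hi = np.concatenate([np.array(IDIF_UPPER + (d_hi,)), np.tile(hi_t, problem.n_regions)])
    best, costs = _multistart(
        lambda x: _idif_residuals(x, problem, anchor_w), lo, hi, n_starts, seed, max_nfev
    )
    feng, tissue = _idif_unpack(best.x, problem)
    grid = problem.wb_tac.grid
    cp = TAC(grid, feng_value(feng, grid.mid_time), "IDIF")
    n_params = 4 * problem.n_regions + 7
    return _finish(problem, best, costs, cp, tissue, n_params, feng=feng)
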