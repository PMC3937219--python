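"""Directions of mutational phenotype jumps on the fitness surface.

Works on the (FlhA, FghA) plane at a reference plasmid copy number,
conventionally on the relative-expression scale with the ancestor at
(100, 100).  Each mutation's displacement is compared against three
reference directions anchored at the ancestor:

* the local fitness gradient (steepest ascent for the ancestor),
* the direct vector to the global optimum of the corrected surface,
* the (-1, -1) diagonal of equal proportional decrease in both
  enzymes, the direction a single-transcript cassette is naively
  expected to move along.

Because FghA is a pure cost dimension in the model, the global optimum
in FghA always sits on the domain's lower bound; this boundary hit is
reported explicitly rather than hidden.  Angles are computed from unit
vectors, so they are invariant to uniform rescaling of both axes for
the diagonal and optimum references, while the gradient direction is
scale-covariant (documented, and asserted in tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, minimize_scalar

from .landscape import (LandscapeParameters, NoInteriorOptimum,
                        landscape_fitness, optimal_flha)

__all__ = ["DirectionReport", "OptimumReport", "gradient_at",
           "global_optimum", "direction_report", "flank_analysis",
           "DEFAULT_DOMAIN"]

#: default phenotype domain on the relative-expression scale
DEFAULT_DOMAIN = ((1.0, 150.0), (1.0, 150.0))

REFERENCE_LABELS = ("gradient", "optimum", "diagonal")


def gradient_at(point, params: LandscapeParameters, p_ref: float
                ) -> np.ndarray:
    """Analytic gradient (dW/dE_FlhA, dW/dE_FghA) at a phenotype point.

    In the unclamped region the FlhA component is
    Vmax*Eh/(Eh+E_A)^2 - cA and the FghA component is -cG everywhere
    (linear cost).  Where the net benefit is clamped at zero the
    benefit term contributes no gradient; a warning is issued and only
    the cost gradients remain.
    """
    e_a, e_g = float(point[0]), float(point[1])
    if e_a < 0 or e_g < 0 or p_ref <= 0:
        raise ValueError("phenotypes must be non-negative, p_ref positive")
    benefit = params.vmax * e_a / (params.eh + e_a) - params.ft
    d_benefit = params.vmax * params.eh / (params.eh + e_a) ** 2
    if benefit < 0:
        warnings.warn("point lies in the clamped (zero-benefit) region; "
                      "benefit gradient is zero there", stacklevel=2)
        d_benefit = 0.0
    return np.array([d_benefit - params.cost_flha, -params.cost_fgha])


@dataclass(frozen=True)
class OptimumReport:
    """Location of the surface maximum over a bounded domain."""

    point: tuple[float, float]
    fitness: float
    flha_on_boundary: bool
    fgha_on_boundary: bool


def global_optimum(params: LandscapeParameters,
                   domain=DEFAULT_DOMAIN,
                   p_ref: float = 1.0,
                   *,
                   clamp: bool = True) -> OptimumReport:
    """Argmax of the corrected surface over a rectangular domain.

    FghA only ever costs, so its optimum is the domain's lower bound
    whenever cG > 0 (flagged as a boundary hit).  The FlhA coordinate
    is the closed-form stationary point when it lies inside the
    domain, otherwise the nearer bound.
    """
    (a_lo, a_hi), (g_lo, g_hi) = domain
    if not (0 < a_lo < a_hi and 0 < g_lo < g_hi):
        raise ValueError("domain bounds must be positive and ordered")

    g_star = g_lo
    g_boundary = True  # FghA only ever costs: the optimum is a bound
    try:
        a_star = optimal_flha(params)
        a_boundary = not (a_lo <= a_star <= a_hi)
        a_star = float(np.clip(a_star, a_lo, a_hi))
    except NoInteriorOptimum:
        # monotone in FlhA over the domain: pick the better bound
        lo_w = landscape_fitness(a_lo, g_star, p_ref, params, clamp=clamp)
        hi_w = landscape_fitness(a_hi, g_star, p_ref, params, clamp=clamp)
        a_star = a_lo if lo_w >= hi_w else a_hi
        a_boundary = True
    # refine numerically in case the clamp moves the argmax off the
    # closed form (it cannot raise it, but keeps the report honest)
    res = minimize_scalar(
        lambda x: -landscape_fitness(x, g_star, p_ref, params, clamp=clamp),
        bounds=(a_lo, a_hi), method="bounded",
        options={"xatol": 1e-8})
    if -res.fun > landscape_fitness(a_star, g_star, p_ref, params,
                                    clamp=clamp) + 1e-12:
        a_star = float(res.x)
        a_boundary = not (a_lo + 1e-6 < a_star < a_hi - 1e-6)
    w_star = float(landscape_fitness(a_star, g_star, p_ref, params,
                                     clamp=clamp))
    return OptimumReport(point=(float(a_star), float(g_star)),
                         fitness=w_star,
                         flha_on_boundary=bool(a_boundary),
                         fgha_on_boundary=bool(g_boundary))


@dataclass(frozen=True)
class DirectionReport:
    """Angles of one mutation's phenotype displacement to the references."""

    mutation_id: str
    displacement: tuple[float, float]
    angle_to_gradient: float
    angle_to_optimum: float
    angle_to_diagonal: float
    nearest_reference: str

    def as_dict(self) -> dict:
        d = dict(self.__dict__)
        d["displacement_flha"], d["displacement_fgha"] = d.pop("displacement")
        return d


def _angle_deg(u: np.ndarray, v: np.ndarray) -> float:
    cu = u / np.linalg.norm(u)
    cv = v / np.linalg.norm(v)
    return float(np.degrees(np.arccos(np.clip(cu @ cv, -1.0, 1.0))))


def direction_report(ancestor, mutant, params: LandscapeParameters,
                     domain=DEFAULT_DOMAIN, p_ref: float = 1.0,
                     mutation_id: str = "") -> DirectionReport:
    """Compare a mutant's displacement to gradient/optimum/diagonal vectors.

    All vectors are anchored at the ancestor phenotype; angles are in
    degrees in [0, 180] and the nearest reference is the one with the
    smallest angle.
    """
    anc = np.asarray(ancestor, dtype=float)
    mut = np.asarray(mutant, dtype=float)
    disp = mut - anc
    if np.allclose(disp, 0):
        raise ValueError("mutant phenotype equals ancestor: no displacement")
    grad = gradient_at(anc, params, p_ref)
    if np.allclose(grad, 0):
        raise ValueError("zero gradient at ancestor; direction undefined")
    opt = np.asarray(global_optimum(params, domain, p_ref).point)
    to_opt = opt - anc
    if np.allclose(to_opt, 0):
        raise ValueError("ancestor already at the optimum")
    diagonal = np.array([-1.0, -1.0])

    angles = {
        "gradient": _angle_deg(disp, grad),
        "optimum": _angle_deg(disp, to_opt),
        "diagonal": _angle_deg(disp, diagonal),
    }
    nearest = min(angles, key=angles.get)
    return DirectionReport(mutation_id=mutation_id,
                           displacement=(float(disp[0]), float(disp[1])),
                           angle_to_gradient=angles["gradient"],
                           angle_to_optimum=angles["optimum"],
                           angle_to_diagonal=angles["diagonal"],
                           nearest_reference=nearest)


def flank_analysis(strains: pd.DataFrame, params: LandscapeParameters,
                   axis: str = "flha", *,
                   clamp: bool = True,
                   expression_cols: tuple[str, str] = ("flha_obs", "fgha_obs"),
                   copy_col: str = "copy_obs",
                   at_tol: float = 1e-6) -> pd.DataFrame:
    """Which side of the axis optimum each strain sits on, and its margin.

    For each strain, the fitness profile along the chosen enzyme axis
    (the other enzyme and copy number held at the strain's own values)
    is examined: the strain is "below" or "above" the profile's
    argmax, and its margin is the distance, in expression units, from
    its level down to the "cliff" where predicted fitness falls below
    1 on the low-expression side.  Strains already below fitness 1 on
    the low flank get a non-positive margin; equal-fitness strains on
    opposite flanks reveal the asymmetry of the surface (the
    low-expression one has the smaller margin).
    """
    if axis not in ("flha", "fgha"):
        raise ValueError("axis must be 'flha' or 'fgha'")
    a_col, g_col = expression_cols
    rows = []
    for _, r in strains.iterrows():
        e_a, e_g, p = float(r[a_col]), float(r[g_col]), float(r[copy_col])
        if axis == "flha":
            level = e_a

            def w_at(x):
                return landscape_fitness(x, e_g, p, params, clamp=clamp)
        else:
            level = e_g

            def w_at(x):
                return landscape_fitness(e_a, x, p, params, clamp=clamp)

        hi = max(level * 10, 1e3)
        res = minimize_scalar(lambda x: -w_at(x), bounds=(1e-9, hi),
                              method="bounded", options={"xatol": 1e-6})
        x_opt, w_opt = float(res.x), float(-res.fun)
        if abs(level - x_opt) <= at_tol * max(1.0, x_opt):
            side = "at optimum"
        else:
            side = "below" if level < x_opt else "above"

        if w_opt < 1.0:
            cliff = np.nan
            margin = -np.inf  # whole profile below fitness 1
        elif w_at(1e-12) >= 1.0:
            cliff = 0.0
            margin = level
        else:
            cliff = float(brentq(lambda x: w_at(x) - 1.0, 1e-12, x_opt))
            margin = level - cliff
        rows.append({"strain": r.get("strain", ""), "axis": axis,
                     "level": level, "axis_optimum": x_opt,
                     "side_of_optimum": side, "fitness": float(w_at(level)),
                     "cliff_level": cliff, "margin_to_cliff": margin})
    return pd.DataFrame(rows)
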