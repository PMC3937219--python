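"""Benefit-cost fitness landscape over enzyme expression levels.

Fitness of a strain is modelled as the metabolic benefit of the first
pathway enzyme (FlhA, S-hydroxymethyl-glutathione dehydrogenase) minus
linear expression costs for both enzymes and a per-plasmid maintenance
cost:

    W(E_A, E_G, P) = max(0, Vmax * E_A / (Eh + E_A) - Ft)
                     - cA * E_A - cG * E_G - cP * P

where ``E_A`` and ``E_G`` are FlhA and FghA levels, ``P`` is plasmid
copy number, ``Vmax`` the saturating pathway benefit, ``Eh`` the
half-maximal FlhA level, and ``Ft`` a flux threshold capturing the
right-shift of the benefit curve (fitness approaches zero while enzyme
is still measurable, plausibly from formaldehyde toxicity at low
dehydrogenase levels).  Only FlhA enters the benefit term: over the
perturbation range FghA behaves as a low-control enzyme whose reduction
is purely cost relief.  The ``max(0, .)`` clamp keeps the net benefit
non-negative; an unclamped variant is available via ``clamp=False``.

The model has exactly six free parameters.  It is fit to the training
partition of a strain table (ancestor, single mutants, and an
inducible-promoter dilution series) by bounded nonlinear least squares
with multistart, and evaluated out of sample on the combination
strains.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, fields
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "PARAM_NAMES",
    "LandscapeParameters",
    "LandscapeFit",
    "NoInteriorOptimum",
    "landscape_fitness",
    "optimal_flha",
    "fit_landscape",
    "corrected_surface",
    "DEFAULT_BOUNDS",
]

#: canonical parameter order used everywhere arrays are exchanged
PARAM_NAMES = ("vmax", "eh", "ft", "cost_flha", "cost_fgha", "cost_copy")


class NoInteriorOptimum(ValueError):
    """The unclamped surface has no stationary point inside the domain."""


@dataclass(frozen=True)
class LandscapeParameters:
    """The six constants of the benefit-cost fitness model.

    Parameters
    ----------
    vmax
        Maximal pathway benefit (fitness units, > 0).
    eh
        FlhA level giving half-maximal benefit (expression units, > 0).
    ft
        Flux threshold subtracted from the benefit (fitness units, >= 0).
    cost_flha, cost_fgha
        Linear expression cost per unit of FlhA / FghA (>= 0).
    cost_copy
        Maintenance cost per plasmid copy (>= 0).
    """

    vmax: float
    eh: float
    ft: float = 0.0
    cost_flha: float = 0.0
    cost_fgha: float = 0.0
    cost_copy: float = 0.0

    def __post_init__(self) -> None:
        if not (self.vmax > 0 and self.eh > 0):
            raise ValueError("vmax and eh must be positive")
        for name in ("ft", "cost_flha", "cost_fgha", "cost_copy"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, theta: Sequence[float]) -> "LandscapeParameters":
        theta = np.asarray(theta, dtype=float)
        if theta.shape != (len(PARAM_NAMES),):
            raise ValueError(f"expected {len(PARAM_NAMES)} parameters")
        return cls(**dict(zip(PARAM_NAMES, theta)))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LandscapeParameters":
        with open(path) as fh:
            return cls(**json.load(fh))


def landscape_fitness(e_flha, e_fgha, copies, params: LandscapeParameters, *,
                      clamp: bool = True):
    """Evaluate the benefit-cost model.

    Accepts scalars or broadcastable arrays.  Negative phenotype values
    are rejected: expression levels and copy numbers are physical
    quantities.
    """
    e_flha = np.asarray(e_flha, dtype=float)
    e_fgha = np.asarray(e_fgha, dtype=float)
    copies = np.asarray(copies, dtype=float)
    if np.any(e_flha < 0) or np.any(e_fgha < 0) or np.any(copies < 0):
        raise ValueError("expression levels and copy number must be >= 0")
    benefit = params.vmax * e_flha / (params.eh + e_flha) - params.ft
    if clamp:
        benefit = np.maximum(0.0, benefit)
    w = (benefit
         - params.cost_flha * e_flha
         - params.cost_fgha * e_fgha
         - params.cost_copy * copies)
    if w.ndim == 0:
        return float(w)
    return w


def optimal_flha(params: LandscapeParameters) -> float:
    """Closed-form FlhA level maximizing W in the FlhA direction.

    Setting dW/dE_A = Vmax*Eh/(Eh+E_A)^2 - cA = 0 gives
    E_A* = sqrt(Vmax*Eh/cA) - Eh.  Requires a strictly positive FlhA
    cost and Vmax*Eh/cA >= Eh^2, otherwise the optimum sits on a domain
    boundary and :class:`NoInteriorOptimum` is raised.
    """
    if params.cost_flha <= 0:
        raise NoInteriorOptimum(
            "cost_flha = 0: fitness is non-decreasing in FlhA, optimum is at "
            "the domain boundary")
    e_star = np.sqrt(params.vmax * params.eh / params.cost_flha) - params.eh
    if e_star < 0:
        raise NoInteriorOptimum(
            "FlhA cost so large that the optimum is at zero expression")
    return float(e_star)


# log10-space box constraints for the multistart fit; wide enough to cover
# both the mU scale and the relative (ancestor = 100) scale
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "vmax": (0.1, 50.0),
    "eh": (0.5, 2000.0),
    "ft": (1e-4, 10.0),
    "cost_flha": (1e-6, 0.5),
    "cost_fgha": (1e-6, 0.5),
    "cost_copy": (1e-6, 1.0),
}

# strain-table column conventions (shared with fitscape.synthetic)
OBS_COLS = ("flha_obs", "fgha_obs", "copy_obs", "fitness_obs")
TRUE_COLS = ("flha_true", "fgha_true", "copy_true", "fitness_true")


@dataclass
class LandscapeFit:
    """Result of a multistart landscape fit."""

    parameters: LandscapeParameters
    training_residuals: pd.DataFrame
    oos_r2: float | None
    n_starts: int
    n_converged: int
    best_cost: float
    seed: int
    clamp: bool = True

    def predict(self, e_flha, e_fgha, copies):
        return landscape_fitness(e_flha, e_fgha, copies, self.parameters,
                                 clamp=self.clamp)


def _phenotype_columns(use_observed: bool) -> tuple[str, str, str, str]:
    return OBS_COLS if use_observed else TRUE_COLS


def fit_landscape(strains: pd.DataFrame,
                  bounds: Mapping[str, tuple[float, float]] | None = None,
                  n_starts: int = 200,
                  seed: int = 0,
                  *,
                  clamp: bool = True,
                  use_observed: bool = True) -> LandscapeFit:
    """Fit the six-parameter model to the training partition of a strain table.

    The training set is every row with ``partition == "fit"`` (ancestor,
    single mutants, inducible series); rows flagged ``"predict"``
    (mutation combinations) are scored out of sample with the fitted
    parameters, without refitting.  Optimization is bounded nonlinear
    least squares on the fitness scale, run from ``n_starts``
    log-uniform draws inside the parameter box; deterministic given
    ``seed``.
    """
    box = dict(DEFAULT_BOUNDS)
    if bounds:
        box.update(bounds)
    fcol_a, fcol_g, fcol_p, fcol_w = _phenotype_columns(use_observed)
    for col in ("partition", fcol_a, fcol_g, fcol_p, fcol_w):
        if col not in strains.columns:
            raise ValueError(f"strain table missing required column {col!r}")

    train = strains[strains["partition"] == "fit"]
    if len(train) < len(PARAM_NAMES) + 1:
        raise ValueError(
            f"training partition has {len(train)} records; need at least "
            f"{len(PARAM_NAMES) + 1} to fit {len(PARAM_NAMES)} parameters")

    ea = train[fcol_a].to_numpy(float)
    eg = train[fcol_g].to_numpy(float)
    pp = train[fcol_p].to_numpy(float)
    w_obs = train[fcol_w].to_numpy(float)

    lo = np.log10([box[n][0] for n in PARAM_NAMES])
    hi = np.log10([box[n][1] for n in PARAM_NAMES])

    def residuals(log_theta: np.ndarray) -> np.ndarray:
        p = LandscapeParameters.from_array(10.0 ** log_theta)
        return landscape_fitness(ea, eg, pp, p, clamp=clamp) - w_obs

    rng = np.random.default_rng(seed)
    starts = rng.uniform(lo, hi, size=(n_starts, len(PARAM_NAMES)))
    best = None
    n_converged = 0
    for x0 in starts:
        try:
            sol = least_squares(residuals, x0, bounds=(lo, hi),
                                method="trf", xtol=1e-14, ftol=1e-14,
                                gtol=1e-12)
        except Exception:  # a bad start may degenerate; count it as failed
            continue
        if not sol.success:
            continue
        n_converged += 1
        if best is None or sol.cost < best.cost:
            best = sol
    if best is None:
        raise RuntimeError(
            f"none of {n_starts} starts converged; check bounds and data")

    params = LandscapeParameters.from_array(10.0 ** best.x)
    resid = pd.DataFrame({
        "strain": train.get("strain", pd.RangeIndex(len(train))),
        "fitness_obs": w_obs,
        "fitness_pred": landscape_fitness(ea, eg, pp, params, clamp=clamp),
    })
    resid["residual"] = resid["fitness_obs"] - resid["fitness_pred"]

    oos_r2 = None
    test = strains[strains["partition"] == "predict"]
    if len(test):
        w_t = test[fcol_w].to_numpy(float)
        w_hat = landscape_fitness(test[fcol_a].to_numpy(float),
                                  test[fcol_g].to_numpy(float),
                                  test[fcol_p].to_numpy(float),
                                  params, clamp=clamp)
        ss_res = float(np.sum((w_t - w_hat) ** 2))
        ss_tot = float(np.sum((w_t - w_t.mean()) ** 2))
        oos_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")

    return LandscapeFit(parameters=params, training_residuals=resid,
                        oos_r2=oos_r2, n_starts=n_starts,
                        n_converged=n_converged, best_cost=float(best.cost),
                        seed=seed, clamp=clamp)


def corrected_surface(params: LandscapeParameters,
                      p_ref: float,
                      flha_grid: Sequence[float],
                      fgha_grid: Sequence[float],
                      *,
                      clamp: bool = True):
    """Fitness surface over (FlhA, FghA) at a reference copy number.

    The model is four-dimensional (two enzymes plus plasmid copy
    number); projecting every strain to a common reference copy number
    ``p_ref`` removes the plasmid-cost dimension so the surface can be
    drawn over the two enzyme axes alone.

    Returns ``(F, G, W, peak)`` where ``F``/``G`` are the meshgrid
    coordinate arrays, ``W`` the fitness grid, and ``peak`` a dict with
    the grid maximum's location and value.
    """
    if p_ref <= 0:
        raise ValueError("p_ref must be positive")
    flha = np.asarray(flha_grid, dtype=float)
    fgha = np.asarray(fgha_grid, dtype=float)
    if flha.size == 0 or fgha.size == 0:
        raise ValueError("empty surface grid")
    if np.any(flha < 0) or np.any(fgha < 0):
        raise ValueError("grid bounds must be non-negative")
    F, G = np.meshgrid(flha, fgha, indexing="ij")
    W = landscape_fitness(F, G, np.full_like(F, p_ref), params, clamp=clamp)
    i, j = np.unravel_index(np.argmax(W), W.shape)
    peak = {"flha": float(F[i, j]), "fgha": float(G[i, j]),
            "fitness": float(W[i, j])}
    return F, G, W, peak
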