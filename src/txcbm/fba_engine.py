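"""Flux balance analysis and flux variability analysis over a HiGHS LP backend.

All programs in this package share the steady-state polytope

    { v : S v = 0,  lb <= v <= ub }

with optional point fixes (lb_j = ub_j = value).  ``fba`` optimizes a single
reaction flux; ``fva`` reports per-reaction flux ranges at (near-)optimal
objective, flagging substitutable reactions whose range shows interchangeable
alternative routes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog

from .model_core import MetabolicModel, stoichiometric_matrix

#: |v| below this is treated as numerically zero (solver-noise squelch)
ZERO_FLUX_TOL = 1e-6
#: mass-balance residual allowed on an optimal solution
MASS_BALANCE_TOL = 1e-6
#: bound violation allowed on an optimal solution
BOUND_TOL = 1e-9


class InfeasibleProblemError(RuntimeError):
    """LP infeasible or unbounded where a solution was required."""


@dataclass
class FluxDistribution:
    fluxes: dict[str, float]
    objective_value: float | None
    status: str  # optimal | infeasible | unbounded
    biomass_flux: float | None = None

    def __getitem__(self, rid: str) -> float:
        return self.fluxes[rid]

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {"reaction_id": list(self.fluxes), "flux": list(self.fluxes.values())}
        ).set_index("reaction_id")


@dataclass
class FvaRange:
    ranges: dict[str, tuple[float, float]]
    substitutable: dict[str, bool] = field(default_factory=dict)

    def __getitem__(self, rid: str) -> tuple[float, float]:
        return self.ranges[rid]


_STATUS = {0: "optimal", 1: "iteration limit", 2: "infeasible", 3: "unbounded", 4: "numerical"}


def _solve_lp(c, A_eq, b_eq, bounds):
    res = linprog(c, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    status = _STATUS.get(res.status, "numerical")
    return res, status


def _effective_bounds(
    model: MetabolicModel, fixed: dict[str, float] | None
) -> list[tuple[float, float]]:
    fixed = fixed or {}
    bounds = []
    for rxn in model.reactions:
        if rxn.id in fixed:
            v = float(fixed[rxn.id])
            if v < rxn.lower_bound - BOUND_TOL or v > rxn.upper_bound + BOUND_TOL:
                raise ValueError(
                    f"fixed flux {v} for {rxn.id} outside bounds {rxn.bounds}"
                )
            bounds.append((v, v))
        else:
            bounds.append((rxn.lower_bound, rxn.upper_bound))
    unknown = set(fixed) - set(model.reaction_ids)
    if unknown:
        raise KeyError(f"fixed fluxes name unknown reactions: {sorted(unknown)}")
    return bounds


def check_solution(model: MetabolicModel, fluxes: dict[str, float],
                   bounds: list[tuple[float, float]] | None = None) -> None:
    """Assert mass balance and bound feasibility of a solved flux vector."""
    S = stoichiometric_matrix(model)
    v = np.array([fluxes[r] for r in model.reaction_ids])
    residual = np.abs(S @ v).max() if len(v) else 0.0
    if residual > MASS_BALANCE_TOL:
        raise AssertionError(f"mass-balance residual {residual:.3e} > {MASS_BALANCE_TOL}")
    if bounds is None:
        bounds = [r.bounds for r in model.reactions]
    for (lo, hi), x, rid in zip(bounds, v, model.reaction_ids):
        if x < lo - 1e-7 or x > hi + 1e-7:
            raise AssertionError(f"flux {x} of {rid} violates bounds [{lo}, {hi}]")


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    fixed: dict[str, float] | None = None,
    sense: str = "max",
    bounds_override: list[tuple[float, float]] | None = None,
) -> FluxDistribution:
    """Solve the flux LP optimizing ``objective_id`` (default: biomass).

    ``fixed`` pins named reactions to exact fluxes (e.g. the measured sucrose
    uptake rate).  Infeasible/unbounded problems are reported in ``status``,
    never as silent zeros.
    """
    model.validate()
    if objective_id is None:
        objective_id = model.biomass_reaction_id
    if objective_id is None:
        raise ValueError("no objective reaction given and model has no biomass id")
    rids = model.reaction_ids
    j_obj = rids.index(objective_id)

    S = stoichiometric_matrix(model, sparse_format=True)
    bounds = bounds_override if bounds_override is not None else _effective_bounds(model, fixed)
    c = np.zeros(len(rids))
    c[j_obj] = -1.0 if sense == "max" else 1.0

    res, status = _solve_lp(c, S, np.zeros(S.shape[0]), bounds)
    if status != "optimal":
        return FluxDistribution(fluxes={}, objective_value=None, status=status)
    fluxes = dict(zip(rids, res.x.tolist()))
    check_solution(model, fluxes, bounds)
    biomass = (
        fluxes.get(model.biomass_reaction_id) if model.biomass_reaction_id else None
    )
    return FluxDistribution(
        fluxes=fluxes,
        objective_value=float(fluxes[objective_id]),
        status="optimal",
        biomass_flux=biomass,
    )


def fva(
    model: MetabolicModel,
    fixed: dict[str, float] | None = None,
    fraction_of_optimum: float = 1.0,
    objective_id: str | None = None,
) -> FvaRange:
    """Per-reaction flux min/max at ``fraction_of_optimum`` of the FBA optimum.

    A reaction is flagged *substitutable* when its range at the fixed optimum
    still has width (it can be switched on/off or reversed while an alternative
    route carries the difference): range spans zero, or touches zero with
    positive width.
    """
    model.validate()
    if objective_id is None:
        objective_id = model.biomass_reaction_id
    base = fba(model, objective_id=objective_id, fixed=fixed)
    if not base.optimal:
        raise InfeasibleProblemError(f"FVA base problem {base.status}")

    rids = model.reaction_ids
    S = stoichiometric_matrix(model, sparse_format=True)
    bounds = _effective_bounds(model, fixed)
    j_obj = rids.index(objective_id)
    # hold the objective at >= fraction * optimum via its bound
    lo, hi = bounds[j_obj]
    target = fraction_of_optimum * base.objective_value
    bounds[j_obj] = (max(lo, target), hi) if base.objective_value >= 0 else (lo, min(hi, target))

    ranges: dict[str, tuple[float, float]] = {}
    subst: dict[str, bool] = {}
    b_eq = np.zeros(S.shape[0])
    for j, rid in enumerate(rids):
        c = np.zeros(len(rids))
        c[j] = 1.0
        res_min, st_min = _solve_lp(c, S, b_eq, bounds)
        res_max, st_max = _solve_lp(-c, S, b_eq, bounds)
        if st_min != "optimal" or st_max != "optimal":
            raise InfeasibleProblemError(f"FVA subproblem for {rid}: {st_min}/{st_max}")
        vmin, vmax = float(res_min.x[j]), float(res_max.x[j])
        ranges[rid] = (vmin, vmax)
        width = vmax - vmin
        spans_zero = vmin < -ZERO_FLUX_TOL < ZERO_FLUX_TOL < vmax
        touches_zero = min(abs(vmin), abs(vmax)) <= ZERO_FLUX_TOL and width > ZERO_FLUX_TOL
        subst[rid] = bool(spans_zero or touches_zero)
    return FvaRange(ranges=ranges, substitutable=subst)
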