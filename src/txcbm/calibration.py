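"""Growth-associated maintenance (S_GAM) calibration and sensitivity analysis.

S_GAM is the ATP-consumption coefficient inside the biomass reaction
(mmol_ATP·gDW⁻¹).  Raising it makes each unit of biomass more expensive in
ATP, so the predicted growth rate v_p is non-increasing in S_GAM; calibration
bisects on S_GAM until the signed percent error ε = 100·(v_p − v_o)/v_o
against the observed growth rate v_o vanishes, and the sensitivity scan maps
the S_GAM interval keeping |ε| within a stated band (±20 % by default).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

from .fba_engine import fba
from .integration import HpcofConfig, eflux, gimme, hpcof
from .model_core import MetabolicModel
from .transcriptome import ReactionExpression


@dataclass
class SensitivityPoint:
    s_gam: float
    v_p: float | None  # predicted growth, day⁻¹; None when infeasible
    v_o: float
    epsilon: float | None
    status: str = "optimal"


class BracketingError(ValueError):
    """The requested observed growth is not straddled by the S_GAM bracket."""


def percent_error(v_p: float, v_o: float) -> float:
    """Signed percent error ε = (v_p − v_o)/v_o × 100."""
    if v_o == 0:
        raise ZeroDivisionError("percent error undefined for v_o = 0")
    return (v_p - v_o) / v_o * 100.0


def _predict_growth(
    model: MetabolicModel,
    method: str,
    rxn_expr: ReactionExpression | None,
    hpcof_config: HpcofConfig | None = None,
) -> tuple[float | None, str]:
    """Predicted biomass flux for one method; growth is never fixed here."""
    fixed = {}
    if model.substrate_uptake_id is not None and model.uptake_rate is not None:
        fixed[model.substrate_uptake_id] = model.uptake_rate
    if method == "fba":
        dist = fba(model, fixed=fixed)
        if not dist.optimal:
            return None, dist.status
        return dist.biomass_flux, "optimal"
    if rxn_expr is None:
        raise ValueError(f"method {method!r} needs reaction expression")
    if method == "gimme":
        # growth is the quantity being predicted: use the fraction-of-optimum
        # variant at the full optimum rather than a fixed rate
        res = gimme(model, rxn_expr, growth=None, fraction_of_optimum=1.0)
        return res.fluxes.biomass_flux, "optimal"
    if method == "eflux":
        res = eflux(model, rxn_expr)
        return res.fluxes.biomass_flux, "optimal"
    if method == "hpcof":
        res = hpcof(model, rxn_expr, config=hpcof_config)
        return res.fluxes.biomass_flux, "optimal"
    raise ValueError(f"unknown method {method!r}")


def sgam_scan(
    model: MetabolicModel,
    method: str,
    rxn_expr: ReactionExpression | None,
    grid: list[float],
    v_o: float,
    hpcof_config: HpcofConfig | None = None,
) -> list[SensitivityPoint]:
    """Re-solve the model across a grid of S_GAM values.

    Each point rewrites the biomass ATP-maintenance coefficient, re-runs the
    chosen method, and records (v_p, ε).  Infeasible points are recorded with
    their status, never dropped.  Results are sorted by S_GAM.
    """
    if any(s <= 0 for s in grid):
        raise ValueError("S_GAM grid values must be positive")
    points = []
    for s in sorted(grid):
        m = copy.deepcopy(model)
        m.set_gam(s)
        try:
            v_p, status = _predict_growth(m, method, rxn_expr, hpcof_config)
        except RuntimeError as exc:
            v_p, status = None, str(exc)
        eps = percent_error(v_p, v_o) if v_p is not None else None
        points.append(SensitivityPoint(s_gam=s, v_p=v_p, v_o=v_o, epsilon=eps, status=status))
    return points


def calibrate_sgam(
    model: MetabolicModel,
    method: str,
    rxn_expr: ReactionExpression | None,
    v_o: float,
    bracket: tuple[float, float],
    tol_eps: float = 0.1,
    max_iter: int = 200,
    hpcof_config: HpcofConfig | None = None,
) -> tuple[float, float]:
    """Bisect on S_GAM until |ε| ≤ tol_eps (percent); returns (S_GAM, final ε).

    Requires ε(lo) ≥ 0 ≥ ε(hi): growth is monotone non-increasing in S_GAM, so
    the bracket must straddle the observed rate.
    """
    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError(f"invalid bracket {bracket}")

    def eps_at(s: float) -> float:
        m = copy.deepcopy(model)
        m.set_gam(s)
        v_p, status = _predict_growth(m, method, rxn_expr, hpcof_config)
        if v_p is None:
            raise BracketingError(f"model infeasible at S_GAM={s} ({status})")
        return percent_error(v_p, v_o)

    e_lo, e_hi = eps_at(lo), eps_at(hi)
    if not (e_lo >= 0 >= e_hi):
        raise BracketingError(
            f"bracket does not straddle the observed growth: ε({lo})={e_lo:.3g}, "
            f"ε({hi})={e_hi:.3g}"
        )
    for _ in range(max_iter):
        if abs(e_lo) <= tol_eps:
            return lo, e_lo
        if abs(e_hi) <= tol_eps:
            return hi, e_hi
        mid = 0.5 * (lo + hi)
        e_mid = eps_at(mid)
        if abs(e_mid) <= tol_eps:
            return mid, e_mid
        if e_mid >= 0:
            lo, e_lo = mid, e_mid
        else:
            hi, e_hi = mid, e_mid
    return mid, e_mid


def sensitivity_range(
    scan: list[SensitivityPoint], eps_max: float = 20.0
) -> tuple[float, float]:
    """Widest contiguous S_GAM interval with |ε| ≤ eps_max.

    Interval endpoints falling between grid points are located by linear
    interpolation of ε over S_GAM.
    """
    pts = sorted((p for p in scan if p.epsilon is not None), key=lambda p: p.s_gam)
    if not pts:
        raise ValueError("scan contains no feasible points")
    inside = [abs(p.epsilon) <= eps_max for p in pts]
    if not any(inside):
        raise ValueError(f"no scan point within |ε| ≤ {eps_max}")

    def crossing(p0: SensitivityPoint, p1: SensitivityPoint, level: float) -> float:
        # linear interpolation of |ε| between adjacent grid points
        e0, e1 = abs(p0.epsilon), abs(p1.epsilon)
        if e1 == e0:
            return p1.s_gam
        t = (level - e0) / (e1 - e0)
        return p0.s_gam + t * (p1.s_gam - p0.s_gam)

    # widest run of in-band points
    best = (0, -1, -1)
    i = 0
    while i < len(pts):
        if inside[i]:
            j = i
            while j + 1 < len(pts) and inside[j + 1]:
                j += 1
            if j - i >= best[0]:
                best = (j - i, i, j)
            i = j + 1
        else:
            i += 1
    _, i, j = best
    lo = pts[i].s_gam
    hi = pts[j].s_gam
    if i > 0 and not inside[i - 1]:
        lo = crossing(pts[i], pts[i - 1], eps_max)
    if j < len(pts) - 1 and not inside[j + 1]:
        hi = crossing(pts[j], pts[j + 1], eps_max)
    return (min(lo, hi), max(lo, hi))
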