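"""Transcriptome-integration programs: GIMME, E-Flux, and HPCOF.

All three confine the steady-state flux polytope of a
:class:`~txcbm.model_core.MetabolicModel` with per-reaction expression ranks
``x_j`` in [0, 1] (see :mod:`txcbm.transcriptome`):

* **GIMME** — minimize ``Σ c_j |v_j|`` with penalty
  ``c_j = max(x_threshold − x_j, 0)`` at fixed growth and uptake: flux through
  reactions expressed below the threshold is squeezed out unless feasibility
  forces it (such reactions are reported as *recovered*).
* **E-Flux** — scale each gene-associated reaction's bounds by its rank and
  maximize biomass: expression caps enzymatic capacity.
* **HPCOF** — minimize ``Σ φ(v_j − x̃_j) + w‖v‖₁`` (Huber penalty φ plus an
  ℓ₁ regularizer) so fluxes track expression-derived targets robustly; the
  convex program has a unique optimum up to solver tolerance.

GIMME and E-Flux are linear programs (HiGHS); HPCOF is solved as a smooth
convex program on split variables ``v = p − q`` (p, q ≥ 0), which makes both
``‖v‖₁`` and the C¹ Huber term differentiable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import LinearConstraint, linprog, minimize

from .fba_engine import (
    ZERO_FLUX_TOL,
    FluxDistribution,
    InfeasibleProblemError,
    _effective_bounds,
    check_solution,
    fba,
)
from .model_core import MetabolicModel, stoichiometric_matrix
from .transcriptome import ReactionExpression


@dataclass
class GimmePenalty:
    penalties: dict[str, float]
    threshold: float  # x_threshold in rank units [0, 1]

    def __getitem__(self, rid: str) -> float:
        return self.penalties[rid]


@dataclass
class HpcofConfig:
    """Tunables of the Huber-penalty program.

    ``flux_scale`` maps ranks onto flux-unit targets ``x̃_j = rank_j · scale``;
    the string ``"uptake"`` uses the model's fixed substrate-uptake rate so
    targets and fluxes are commensurate.  ``bound_policy`` chooses the flux
    bounds: ``"eflux"`` scales the original bounds by the rank (always feasible
    with a fixed uptake), ``"expression"`` caps fluxes at ``x̃_j`` directly
    (the literal program; fluxes then live on the rank scale).
    """

    huber_delta: float = 1.0
    l1_weight: float = 1.0
    flux_scale: float | str = "uptake"
    bound_policy: str = "eflux"

    def __post_init__(self) -> None:
        if self.huber_delta <= 0:
            raise ValueError(f"huber_delta must be > 0, got {self.huber_delta}")
        if self.l1_weight < 0:
            raise ValueError(f"l1_weight must be >= 0, got {self.l1_weight}")
        if self.bound_policy not in ("eflux", "expression"):
            raise ValueError(f"unknown bound_policy {self.bound_policy!r}")


@dataclass
class IntegrationResult:
    fluxes: FluxDistribution
    objective: float | None
    recovered_reactions: list[str] = field(default_factory=list)
    method: str = ""


def gimme_penalties(
    rxn_expr: ReactionExpression, threshold_percentile: float
) -> GimmePenalty:
    """Penalty scores c_j = max(x_threshold − x_j, 0); 0 for gene-free reactions."""
    if not 0 < threshold_percentile < 100:
        raise ValueError("threshold percentile must lie in (0, 100)")
    x_thr = threshold_percentile / 100.0
    pen = {}
    for rid, has in rxn_expr.has_genes.items():
        if has:
            pen[rid] = max(x_thr - rxn_expr.rank[rid], 0.0)
        else:
            pen[rid] = 0.0
    return GimmePenalty(penalties=pen, threshold=x_thr)


def _independent_rows(S: np.ndarray, rtol: float = 1e-10) -> np.ndarray:
    """Row-reduce S to a full-row-rank submatrix (same null space).

    Conserved moieties (e.g. ATP + ADP) make rows of S linearly dependent,
    which degrades equality-constrained solvers; S v = 0 is unchanged by
    dropping dependent rows.
    """
    if S.shape[0] == 0:
        return S
    from scipy.linalg import qr

    _, R, piv = qr(S.T, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    if diag.size == 0 or diag[0] == 0:
        return S[:0]
    rank = int(np.sum(diag > rtol * diag[0]))
    return S[np.sort(piv[:rank])]


def _split_caps(bounds: list[tuple[float, float]]) -> list[tuple[float, float, float, float]]:
    """Per reaction: (p_lo, p_hi, q_lo, q_hi) for the split v = p − q."""
    caps = []
    for lo, hi in bounds:
        p_lo, p_hi = max(lo, 0.0), max(hi, 0.0)
        q_lo, q_hi = max(-hi, 0.0), max(-lo, 0.0)
        caps.append((p_lo, p_hi, q_lo, q_hi))
    return caps


def gimme(
    model: MetabolicModel,
    rxn_expr: ReactionExpression,
    threshold_percentile: float = 50.0,
    growth: float | None = None,
    uptake: float | None = None,
    fraction_of_optimum: float | None = None,
    tol: float = ZERO_FLUX_TOL,
) -> IntegrationResult:
    """GIMME: minimize penalty-weighted total flux at the measured growth rate.

    By default both biomass (``growth``) and substrate uptake (``uptake``,
    falling back to the model's recorded rate) are pinned to their measured
    values.  Alternatively pass ``fraction_of_optimum`` (and ``growth=None``)
    for the canonical variant that requires biomass ≥ fraction · FBA optimum.

    Penalized reactions that still carry flux (feasibility demands them) are
    returned in ``recovered_reactions``.
    """
    model.validate()
    if model.biomass_reaction_id is None:
        raise ValueError("GIMME needs a biomass reaction")
    penalty = gimme_penalties(rxn_expr, threshold_percentile)

    fixed: dict[str, float] = {}
    if uptake is None:
        uptake = model.uptake_rate
    if uptake is not None and model.substrate_uptake_id is not None:
        fixed[model.substrate_uptake_id] = uptake
    if growth is not None:
        fixed[model.biomass_reaction_id] = growth

    bounds = _effective_bounds(model, fixed)
    rids = model.reaction_ids
    j_bio = rids.index(model.biomass_reaction_id)
    if growth is None and fraction_of_optimum is not None:
        base = fba(model, fixed=fixed)
        if not base.optimal:
            raise InfeasibleProblemError(f"GIMME pre-solve {base.status}")
        bounds[j_bio] = (fraction_of_optimum * base.objective_value, bounds[j_bio][1])

    n = len(rids)
    S = stoichiometric_matrix(model, sparse_format=True)
    from scipy import sparse

    # variables [p; q], v = p − q
    A_eq = sparse.hstack([S, -S]).tocsr()
    caps = _split_caps(bounds)
    lp_bounds = [(p_lo, p_hi) for p_lo, p_hi, _, _ in caps] + [
        (q_lo, q_hi) for _, _, q_lo, q_hi in caps
    ]
    c_vec = np.array([penalty[r] for r in rids])
    c = np.concatenate([c_vec, c_vec])

    res = linprog(c, A_eq=A_eq, b_eq=np.zeros(S.shape[0]), bounds=lp_bounds, method="highs")
    if res.status == 2:
        raise InfeasibleProblemError(
            "GIMME infeasible at the requested growth/uptake fixes"
        )
    if res.status != 0:
        raise InfeasibleProblemError(f"GIMME solver status {res.status}: {res.message}")
    p, q = res.x[:n], res.x[n:]
    v = p - q
    fluxes = dict(zip(rids, v.tolist()))
    check_solution(model, fluxes, bounds)
    objective = float(c_vec @ np.abs(v))
    recovered = [r for r in rids if penalty[r] > 0 and abs(fluxes[r]) > tol]
    dist = FluxDistribution(
        fluxes=fluxes,
        objective_value=objective,
        status="optimal",
        biomass_flux=fluxes[model.biomass_reaction_id],
    )
    return IntegrationResult(dist, objective, recovered, method="gimme")


def eflux_bounds(
    model: MetabolicModel, rxn_expr: ReactionExpression
) -> list[tuple[float, float]]:
    """Rank-scaled bounds: [0, x_j·ub] irreversible, [−x_j·|lb|, x_j·ub] reversible.

    Reactions without gene associations keep their original bounds
    (constraint-free).
    """
    bounds = []
    for rxn in model.reactions:
        if rxn_expr.has_genes.get(rxn.id, False):
            x = rxn_expr.rank[rxn.id]
            if rxn.reversible:
                bounds.append((-x * abs(rxn.lower_bound), x * rxn.upper_bound))
            else:
                bounds.append((0.0, x * rxn.upper_bound))
        else:
            bounds.append(rxn.bounds)
    return bounds


def eflux(
    model: MetabolicModel,
    rxn_expr: ReactionExpression,
    uptake: float | None = None,
) -> IntegrationResult:
    """E-Flux: maximize biomass under rank-scaled flux bounds at fixed uptake."""
    model.validate()
    if model.biomass_reaction_id is None:
        raise ValueError("E-Flux needs a biomass reaction")
    bounds = eflux_bounds(model, rxn_expr)
    if uptake is None:
        uptake = model.uptake_rate
    rids = model.reaction_ids
    if uptake is not None and model.substrate_uptake_id is not None:
        bounds[rids.index(model.substrate_uptake_id)] = (uptake, uptake)
    dist = fba(model, bounds_override=bounds)
    if not dist.optimal:
        raise InfeasibleProblemError(f"E-Flux LP {dist.status}")
    return IntegrationResult(dist, dist.objective_value, [], method="eflux")


def huber(u: float, delta: float = 1.0):
    """Huber penalty φ(u): u² inside |u| ≤ delta, 2·delta·|u| − delta² outside.

    Continuous, convex, C¹; with delta = 1 this is the printed piecewise form
    (u² for |u| ≤ 1, 2|u| − 1 beyond).
    """
    if delta <= 0:
        raise ValueError(f"huber delta must be > 0, got {delta}")
    u = np.asarray(u, dtype=float)
    out = np.where(np.abs(u) <= delta, u * u, 2.0 * delta * np.abs(u) - delta * delta)
    return float(out) if out.ndim == 0 else out


def _huber_grad(u: np.ndarray, delta: float) -> np.ndarray:
    return np.where(np.abs(u) <= delta, 2.0 * u, 2.0 * delta * np.sign(u))


def hpcof_targets(
    model: MetabolicModel,
    rxn_expr: ReactionExpression,
    config: HpcofConfig,
    uptake: float | None = None,
) -> dict[str, float]:
    """Expression targets x̃_j = rank_j · flux_scale for gene-associated reactions."""
    scale = config.flux_scale
    if scale == "uptake":
        scale = uptake if uptake is not None else model.uptake_rate
        if scale is None:
            raise ValueError(
                "flux_scale='uptake' but no uptake rate is fixed or recorded"
            )
    return {
        rid: rxn_expr.rank[rid] * float(scale)
        for rid, has in rxn_expr.has_genes.items()
        if has
    }


def hpcof(
    model: MetabolicModel,
    rxn_expr: ReactionExpression,
    config: HpcofConfig | None = None,
    uptake: float | None = None,
) -> IntegrationResult:
    """HPCOF: min Σ φ(v_j − x̃_j) + w‖v‖₁ over the expression-bounded polytope.

    Growth is *not* fixed — the biomass flux emerges from the optimization and
    is matched to observation via S_GAM calibration.  Uptake defaults to the
    model's recorded rate (the program collapses to v = 0 without any driving
    fix).  The split-variable formulation is solved with a trust-region
    method; the objective is convex, so the optimum is global.
    """
    model.validate()
    config = config or HpcofConfig()
    if uptake is None:
        uptake = model.uptake_rate

    rids = model.reaction_ids
    n = len(rids)
    targets = hpcof_targets(model, rxn_expr, config, uptake=uptake)

    if config.bound_policy == "eflux":
        bounds = eflux_bounds(model, rxn_expr)
    else:  # literal expression caps
        bounds = []
        for rxn in model.reactions:
            if rxn_expr.has_genes.get(rxn.id, False):
                x = targets[rxn.id]
                bounds.append((-x, x) if rxn.reversible else (0.0, x))
            else:
                bounds.append(rxn.bounds)
    if uptake is not None and model.substrate_uptake_id is not None:
        j_up = rids.index(model.substrate_uptake_id)
        lo, hi = bounds[j_up]
        if uptake < lo - 1e-9 or uptake > hi + 1e-9:
            raise InfeasibleProblemError(
                f"fixed uptake {uptake} incompatible with expression bounds [{lo}, {hi}]"
            )
        bounds[j_up] = (uptake, uptake)

    S = stoichiometric_matrix(model)
    S_red = _independent_rows(S)
    caps = _split_caps(bounds)
    lb_pq = np.array([c[0] for c in caps] + [c[2] for c in caps])
    ub_pq = np.array([c[1] for c in caps] + [c[3] for c in caps])

    # feasible start from a zero-objective LP on the same polytope
    from scipy import sparse

    A_split = np.hstack([S_red, -S_red])
    res0 = linprog(
        np.zeros(2 * n),
        A_eq=sparse.csr_matrix(A_split),
        b_eq=np.zeros(S_red.shape[0]),
        bounds=list(zip(lb_pq, ub_pq)),
        method="highs",
    )
    if res0.status == 2:
        raise InfeasibleProblemError("HPCOF polytope is empty under the given bounds")
    if res0.status != 0:
        raise InfeasibleProblemError(f"HPCOF feasibility LP status {res0.status}")

    # Exact smooth reformulation: φ_δ(u) = min_z (u − z)² + 2δ|z|, so with
    # z = a − b (a, b ≥ 0) the program becomes a convex QP with constant
    # Hessian — no kinks left for the trust-region solver.
    target_idx = np.array([j for j, rid in enumerate(rids) if rid in targets], dtype=int)
    t_vec = np.array([targets[rids[j]] for j in target_idx])
    m = len(target_idx)
    w = config.l1_weight
    delta = config.huber_delta

    sel = np.zeros((m, n))
    sel[np.arange(m), target_idx] = 1.0  # picks targeted v components

    def unpack(x):
        return x[:n], x[n: 2 * n], x[2 * n: 2 * n + m], x[2 * n + m:]

    def residual(x):
        p, q, a, b = unpack(x)
        return sel @ (p - q) - t_vec - (a - b)

    def objective(x: np.ndarray) -> float:
        p, q, a, b = unpack(x)
        r = residual(x)
        return float(r @ r + 2.0 * delta * np.sum(a + b) + w * np.sum(p + q))

    def gradient(x: np.ndarray) -> np.ndarray:
        p, q, a, b = unpack(x)
        r = residual(x)
        g_v = 2.0 * (sel.T @ r)
        return np.concatenate(
            [g_v + w, -g_v + w, -2.0 * r + 2.0 * delta, 2.0 * r + 2.0 * delta]
        )

    J = np.hstack([sel, -sel, -np.eye(m), np.eye(m)])  # r = J x − t_vec
    H_const = 2.0 * (J.T @ J)

    def hessian(x: np.ndarray) -> np.ndarray:
        return H_const

    aux_cap = float(np.max(np.abs(t_vec), initial=1.0) + np.max(ub_pq) + 1.0)
    lb = np.concatenate([lb_pq, np.zeros(2 * m)])
    ub = np.concatenate([ub_pq, np.full(2 * m, aux_cap)])
    x0 = np.concatenate([res0.x, np.zeros(2 * m)])

    A_eq_full = np.hstack([A_split, np.zeros((A_split.shape[0], 2 * m))])

    def run_slsqp(start):
        return minimize(
            objective,
            start,
            jac=gradient,
            bounds=list(zip(lb, ub)),
            constraints=[{"type": "eq", "fun": lambda x: A_eq_full @ x,
                          "jac": lambda x: A_eq_full}],
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-12},
        )

    def feasible(x):
        return (
            np.abs(A_eq_full @ x).max() < 1e-8
            and (x >= lb - 1e-8).all()
            and (x <= ub + 1e-8).all()
        )

    # SLSQP is fast and accurate but its line search occasionally stalls on
    # degenerate vertices; cascade to the trust-region solver (exact constant
    # Hessian) and, if its status is inconclusive, re-polish with SLSQP from
    # its iterate.  Accept only converged AND feasible solutions.
    res = run_slsqp(x0)
    ok = res.success and feasible(res.x)
    if not ok:
        import warnings

        constraint = LinearConstraint(A_eq_full, 0.0, 0.0)
        with warnings.catch_warnings():
            # rank-deficient working sets trigger a harmless SVD-fallback note
            warnings.simplefilter("ignore", UserWarning)
            res_tc = minimize(
                objective,
                x0,
                jac=gradient,
                hess=hessian,
                bounds=list(zip(lb, ub)),
                constraints=[constraint],
                method="trust-constr",
                options={"gtol": 1e-10, "xtol": 1e-13, "maxiter": 5000, "verbose": 0},
            )
        if (res_tc.success or res_tc.status in (1, 2)) and feasible(res_tc.x):
            res = res_tc
            ok = True
        else:
            res = run_slsqp(np.clip(res_tc.x, lb, ub))
            ok = res.success and feasible(res.x)
    if not ok:
        raise InfeasibleProblemError(
            f"HPCOF solver did not converge: {res.message}"
        )
    p, q = res.x[:n], res.x[n: 2 * n]
    v = p - q
    v[np.abs(v) < 1e-12] = 0.0
    fluxes = dict(zip(rids, v.tolist()))
    check_solution(model, fluxes, bounds)
    obj = float(np.sum(huber(v[target_idx] - t_vec, delta)) + w * np.abs(v).sum())
    dist = FluxDistribution(
        fluxes=fluxes,
        objective_value=obj,
        status="optimal",
        biomass_flux=fluxes.get(model.biomass_reaction_id),
    )
    return IntegrationResult(dist, obj, [], method="hpcof")
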