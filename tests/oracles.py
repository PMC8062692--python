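"""Independent oracles kept deliberately separate from the implementation.

Each oracle re-derives an expected value through a different route than the
code under test: a differently-encoded LP, a brute-force grid search, or
rejection-style sampling of feasible points.
"""

import numpy as np
from scipy.optimize import linprog

from txcbm.model_core import stoichiometric_matrix


def gimme_lp_oracle(model, penalties, fixed):
    """Penalty-weighted |flux| minimum via an epigraph LP (t_j >= ±v_j).

    A different encoding from the implementation's forward/backward split:
    variables [v; t] with t_j >= v_j, t_j >= -v_j and objective c·t.
    """
    rids = model.reaction_ids
    n = len(rids)
    S = stoichiometric_matrix(model)
    bounds = []
    for r in model.reactions:
        if r.id in fixed:
            bounds.append((fixed[r.id], fixed[r.id]))
        else:
            bounds.append(r.bounds)
    big = max(abs(b) for bb in bounds for b in bb) + 1.0
    var_bounds = bounds + [(0.0, big)] * n
    A_eq = np.hstack([S, np.zeros((S.shape[0], n))])
    eye = np.eye(n)
    A_ub = np.vstack([np.hstack([eye, -eye]), np.hstack([-eye, -eye])])
    c = np.concatenate([np.zeros(n), np.array([penalties[r] for r in rids])])
    res = linprog(
        c,
        A_ub=A_ub,
        b_ub=np.zeros(2 * n),
        A_eq=A_eq,
        b_eq=np.zeros(S.shape[0]),
        bounds=var_bounds,
        method="highs",
    )
    assert res.status == 0, res.message
    return float(res.fun)


def hpcof_grid_oracle(targets, l1_weight, t_max, step=1e-4, delta=1.0):
    """1-D grid search for a single-degree-of-freedom flux t in [0, t_max].

    Objective: sum of Huber penalties to each target plus l1_weight·(#reactions)·t.
    """

    def phi(u):
        return u * u if abs(u) <= delta else 2 * delta * abs(u) - delta ** 2

    ts = np.arange(0.0, t_max + step, step)
    best_t, best_f = 0.0, np.inf
    for t in ts:
        f = sum(phi(t - x) for x in targets) + l1_weight * len(targets) * t
        if f < best_f:
            best_t, best_f = t, f
    return best_t, best_f


def random_feasible_points(model, bounds, n_points, seed):
    """Feasible flux vectors: convex combinations of random-objective LP vertices."""
    rng = np.random.default_rng(seed)
    S = stoichiometric_matrix(model)
    vertices = []
    for _ in range(max(8, n_points // 10)):
        c = rng.normal(size=len(model.reactions))
        res = linprog(c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=bounds,
                      method="highs")
        if res.status == 0:
            vertices.append(res.x)
    assert vertices, "no feasible vertex found"
    V = np.array(vertices)
    points = []
    for _ in range(n_points):
        w = rng.dirichlet(np.ones(len(V)))
        points.append(w @ V)
    return points


def confusion_brute(pairs):
    """Counts from explicit (predicted_active, truth_active) pairs."""
    tp = sum(1 for p, t in pairs if p and t)
    fp = sum(1 for p, t in pairs if p and not t)
    fn = sum(1 for p, t in pairs if not p and t)
    tn = sum(1 for p, t in pairs if not p and not t)
    return tp, fp, tn, fn
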