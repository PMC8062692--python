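import numpy as np
import pytest

from conftest import build_model, chain_model, parallel_model, ranks
from oracles import gimme_lp_oracle, hpcof_grid_oracle, random_feasible_points
from txcbm.fba_engine import InfeasibleProblemError, fba
from txcbm.integration import (
    HpcofConfig,
    eflux,
    eflux_bounds,
    gimme,
    gimme_penalties,
    hpcof,
    huber,
)
from txcbm.model_core import stoichiometric_matrix


class TestGimmePenalties:
    def test_rule(self):
        model = parallel_model()
        rx = ranks(model, {"p1": 0.9, "p2": 0.1})
        pen = gimme_penalties(rx, 50.0)
        assert pen["p1"] == 0.0
        assert pen["p2"] == pytest.approx(0.4)
        assert pen["uptake"] == 0.0  # no genes, no penalty

    def test_threshold_domain(self):
        model = parallel_model()
        rx = ranks(model, {"p1": 0.5})
        with pytest.raises(ValueError):
            gimme_penalties(rx, 0.0)
        with pytest.raises(ValueError):
            gimme_penalties(rx, 100.0)


class TestGimme:
    def test_parallel_routes_through_expressed_path(self):
        model = parallel_model(uptake_cap=10.0)
        rx = ranks(model, {"p1": 0.9, "p2": 0.1})
        res = gimme(model, rx, 50.0, growth=10.0, uptake=10.0)
        assert res.objective == pytest.approx(0.0, abs=1e-9)
        assert res.fluxes["p1"] == pytest.approx(10.0)
        assert res.fluxes["p2"] == pytest.approx(0.0, abs=1e-9)
        assert res.recovered_reactions == []

    def test_threshold_below_all_ranks_degenerate(self):
        model = parallel_model(uptake_cap=10.0)
        rx = ranks(model, {"p1": 0.9, "p2": 0.8})
        res = gimme(model, rx, 50.0, growth=10.0, uptake=10.0)
        assert res.objective == pytest.approx(0.0, abs=1e-12)

    def test_essential_low_expression_reaction_recovered(self):
        model = chain_model(uptake_cap=10.0, genes=True)
        rx = ranks(model, {"r1": 0.1})
        res = gimme(model, rx, 50.0, growth=4.0, uptake=4.0)
        assert res.recovered_reactions == ["r1"]
        assert res.fluxes["r1"] == pytest.approx(4.0)
        # removing the reaction makes the demanded growth infeasible
        model.reaction("r1").upper_bound = 0.0
        with pytest.raises(InfeasibleProblemError):
            gimme(model, rx, 50.0, growth=4.0, uptake=4.0)

    def test_infeasible_growth_is_an_error(self):
        model = chain_model(uptake_cap=10.0, genes=True)
        rx = ranks(model, {"r1": 0.9})
        with pytest.raises(InfeasibleProblemError):
            gimme(model, rx, 50.0, growth=20.0, uptake=10.0)

    @pytest.mark.parametrize("case_seed", range(6))
    def test_matches_independent_lp_oracle(self, case_seed):
        """Objective equals a differently-encoded epigraph LP on <= 8 reactions."""
        rng = np.random.default_rng(case_seed)
        model = build_model(
            {"A": "cytosol", "B": "cytosol", "C": "cytosol"},
            [
                {"id": "uptake", "stoich": {"A": 1.0}, "ub": 10,
                 "category": "transport_exchange"},
                {"id": "p1", "stoich": {"A": -1.0, "B": 1.0}, "genes": ["g1"]},
                {"id": "p2", "stoich": {"A": -1.0, "B": 1.0}, "genes": ["g2"]},
                {"id": "r3", "stoich": {"B": -1.0, "C": 1.0}, "genes": ["g3"],
                 "reversible": True, "lb": -50.0, "ub": 50.0},
                {"id": "leak", "stoich": {"A": -1.0, "C": 1.0}, "genes": ["g4"]},
                {"id": "biomass", "stoich": {"C": -1.0}, "category": "auxiliary"},
            ],
            biomass="biomass",
            uptake="uptake",
        )
        rx = ranks(model, {r: float(rng.random()) for r in ("p1", "p2", "r3", "leak")})
        growth = float(rng.uniform(1.0, 9.0))
        res = gimme(model, rx, 50.0, growth=growth, uptake=growth)
        pen = gimme_penalties(rx, 50.0).penalties
        expected = gimme_lp_oracle(
            model, pen, {"biomass": growth, "uptake": growth}
        )
        assert res.objective == pytest.approx(expected, abs=1e-8)

    def test_bundle_oracle_match(self, bundle):
        model, _, _, rx = bundle
        res = gimme(model, rx, 50.0, growth=4.5, uptake=10.0)
        pen = gimme_penalties(rx, 50.0).penalties
        expected = gimme_lp_oracle(
            model, pen, {"R_biomass": 4.5, "EX_suc": 10.0}
        )
        assert res.objective == pytest.approx(expected, abs=1e-7)


class TestEflux:
    def chain3(self, uptake_cap):
        return build_model(
            {"A": "cytosol", "B": "cytosol", "C": "cytosol"},
            [
                {"id": "uptake", "stoich": {"A": 1.0}, "ub": uptake_cap,
                 "category": "transport_exchange"},
                {"id": "r1", "stoich": {"A": -1.0, "B": 1.0}, "genes": ["g1"]},
                {"id": "r2", "stoich": {"B": -1.0, "C": 1.0}, "genes": ["g2"]},
                {"id": "biomass", "stoich": {"C": -1.0}, "category": "auxiliary"},
            ],
            biomass="biomass",
            uptake="uptake",
        )

    def test_uptake_binds(self):
        model = self.chain3(uptake_cap=10.0)
        rx = ranks(model, {"r1": 0.8, "r2": 0.2})
        res = eflux(model, rx, uptake=10.0)
        assert res.fluxes.biomass_flux == pytest.approx(10.0)

    def test_scaled_bound_binds(self):
        model = self.chain3(uptake_cap=1000.0)
        rx = ranks(model, {"r1": 0.8, "r2": 0.2})
        res = eflux(model, rx)  # no fix: bound min(0.2*1000) limits
        assert res.fluxes.biomass_flux == pytest.approx(200.0)

    def test_zero_rank_blocks_growth(self):
        model = self.chain3(uptake_cap=10.0)
        rx = ranks(model, {"r1": 0.8, "r2": 0.0})
        res = eflux(model, rx)
        assert res.fluxes.status == "optimal"
        assert res.fluxes.biomass_flux == pytest.approx(0.0, abs=1e-9)

    def test_non_gene_reactions_keep_bounds(self):
        model = self.chain3(uptake_cap=10.0)
        rx = ranks(model, {"r1": 0.5, "r2": 0.5})
        bounds = eflux_bounds(model, rx)
        j = model.reaction_ids.index("uptake")
        assert bounds[j] == (0.0, 10.0)

    def test_raising_a_rank_never_decreases_biomass(self):
        model = self.chain3(uptake_cap=1000.0)
        base = ranks(model, {"r1": 0.4, "r2": 0.2})
        low = eflux(model, base).fluxes.biomass_flux
        for rid in ("r1", "r2"):
            bumped = {"r1": 0.4, "r2": 0.2}
            bumped[rid] = min(1.0, bumped[rid] + 0.3)
            high = eflux(model, ranks(model, bumped)).fluxes.biomass_flux
            assert high >= low - 1e-9


class TestHuber:
    @pytest.mark.parametrize(
        "u,expected", [(0.0, 0.0), (0.5, 0.25), (-3.0, 5.0), (1.0, 1.0), (2.0, 3.0)]
    )
    def test_printed_piecewise_values(self, u, expected):
        assert huber(u) == pytest.approx(expected)

    def test_continuity_at_knee(self):
        eps = 1e-9
        assert huber(1.0 - eps) == pytest.approx(huber(1.0 + eps), abs=1e-6)

    def test_scaled_delta(self):
        assert huber(0.5, delta=2.0) == pytest.approx(0.25)
        assert huber(5.0, delta=2.0) == pytest.approx(2 * 2 * 5 - 4)

    def test_invalid_delta(self):
        with pytest.raises(ValueError):
            huber(1.0, delta=0.0)

    def test_convexity_spot(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.normal(0, 3, 2)
            lam = rng.random()
            assert huber(lam * a + (1 - lam) * b) <= lam * huber(a) + (
                1 - lam
            ) * huber(b) + 1e-12


def one_dof_model():
    """exchange -> A -> sink; a single flux t runs the whole chain."""
    return build_model(
        {"A": "cytosol"},
        [
            {"id": "ex", "stoich": {"A": 1.0}, "genes": ["ga"]},
            {"id": "sink", "stoich": {"A": -1.0}, "genes": ["gb"]},
        ],
    )


class TestHpcof:
    def test_one_dof_matches_grid_oracle(self):
        model = one_dof_model()
        rx = ranks(model, {"ex": 0.8, "sink": 0.3})
        cfg = HpcofConfig(flux_scale=1.0, bound_policy="expression")
        res = hpcof(model, rx, config=cfg)
        t_star, f_star = hpcof_grid_oracle([0.8, 0.3], l1_weight=1.0, t_max=0.3)
        assert res.fluxes["ex"] == pytest.approx(t_star, abs=1e-3)
        assert res.objective == pytest.approx(f_star, abs=1e-3)

    def test_zero_targets_force_zero_flux(self):
        model = one_dof_model()
        rx = ranks(model, {"ex": 0.0, "sink": 0.0})
        cfg = HpcofConfig(flux_scale=1.0, bound_policy="expression")
        res = hpcof(model, rx, config=cfg)
        assert res.fluxes["ex"] == pytest.approx(0.0, abs=1e-9)
        assert res.fluxes["sink"] == pytest.approx(0.0, abs=1e-9)

    def test_dominates_random_feasible_points(self, bundle):
        model, _, _, rx = bundle
        cfg = HpcofConfig()
        res = hpcof(model, rx, uptake=10.0)
        bounds = eflux_bounds(model, rx)
        j = model.reaction_ids.index("EX_suc")
        bounds[j] = (10.0, 10.0)
        targets = {
            rid: rx.rank[rid] * 10.0 for rid, h in rx.has_genes.items() if h
        }
        rids = model.reaction_ids

        def objective(v):
            tot = sum(
                huber(v[j] - targets[r])
                for j, r in enumerate(rids)
                if r in targets
            )
            return tot + np.abs(v).sum()

        v_star = np.array([res.fluxes[r] for r in rids])
        f_star = objective(v_star)
        assert f_star == pytest.approx(res.objective, rel=1e-6)
        for pt in random_feasible_points(model, bounds, n_points=100, seed=42):
            assert f_star <= objective(pt) + 1e-6

    def test_mass_balance_and_bounds(self, bundle):
        model, _, _, rx = bundle
        res = hpcof(model, rx, uptake=10.0)
        S = stoichiometric_matrix(model)
        v = np.array([res.fluxes[r] for r in model.reaction_ids])
        assert np.abs(S @ v).max() <= 1e-6
        bounds = eflux_bounds(model, rx)
        for (lo, hi), rid in zip(bounds, model.reaction_ids):
            if rid == "EX_suc":
                lo, hi = 10.0, 10.0
            assert lo - 1e-7 <= res.fluxes[rid] <= hi + 1e-7

    def test_infeasible_expression_caps_error(self):
        model = chain_model(uptake_cap=10.0, genes=True)
        model.uptake_rate = 10.0
        rx = ranks(model, {"r1": 0.3})
        cfg = HpcofConfig(flux_scale=1.0, bound_policy="expression")
        with pytest.raises(InfeasibleProblemError):
            hpcof(model, rx, config=cfg, uptake=10.0)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            HpcofConfig(huber_delta=0.0)
        with pytest.raises(ValueError):
            HpcofConfig(l1_weight=-1.0)
        with pytest.raises(ValueError):
            HpcofConfig(bound_policy="other")


class TestGimmeFractionVariant:
    def test_fraction_of_optimum(self):
        model = parallel_model(uptake_cap=10.0)
        model.uptake_rate = 10.0
        rx = ranks(model, {"p1": 0.9, "p2": 0.1})
        res = gimme(model, rx, 50.0, growth=None, uptake=10.0,
                    fraction_of_optimum=1.0)
        assert res.fluxes.biomass_flux == pytest.approx(10.0)
        assert res.fluxes["p1"] == pytest.approx(10.0)
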