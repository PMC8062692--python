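import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import ranks
from oracles import confusion_brute
from txcbm.evaluation import (
    ActivityCall,
    ConfusionSummary,
    OmicsEvidence,
    activity_from_expression,
    activity_from_flux,
    confusion,
    core_overlap,
    evaluated_reactions,
    multiomics_counts,
    multiomics_verify,
    ssd,
)
from txcbm.fba_engine import FluxDistribution


def dist(fluxes):
    return FluxDistribution(fluxes=fluxes, objective_value=None, status="optimal")


class TestActivityCalls:
    def test_flux_calls(self):
        call = activity_from_flux(dist({"a": 0.0, "b": 1e-12, "c": 0.0548}))
        assert call.calls == {"a": False, "b": False, "c": True}

    def test_non_optimal_rejected(self):
        bad = FluxDistribution(fluxes={}, objective_value=None, status="infeasible")
        with pytest.raises(ValueError):
            activity_from_flux(bad)

    def test_expression_calls_strict_boundary(self, bundle):
        model = bundle[0]
        rx = ranks(model, {"R_inv": 0.9, "R_pyk": 0.5, "R_ala": 0.2})
        call = activity_from_expression(rx, 50.0)
        assert call.calls["R_inv"] is True
        assert call.calls["R_pyk"] is False  # strict > at the threshold
        assert call.calls["R_ala"] is False
        assert "EX_suc" not in call.calls  # no genes -> excluded


class TestConfusion:
    def test_printed_counts_ratio(self):
        cm = ConfusionSummary(TP=155, TN=23, FN=141, FP=11)
        assert cm.n == 330
        assert cm.ACC == pytest.approx(178 / 330)

    def test_perfect_agreement(self):
        pred = ActivityCall({"a": True, "b": False}, source="flux")
        truth = ActivityCall({"a": True, "b": False}, source="expression")
        cm = confusion(pred, truth)
        assert (cm.ACC, cm.FP, cm.FN) == (1.0, 0, 0)

    def test_all_active_prediction(self):
        pred = ActivityCall({f"r{i}": True for i in range(10)}, source="flux")
        truth = ActivityCall(
            {f"r{i}": i < 5 for i in range(10)}, source="expression"
        )
        cm = confusion(pred, truth)
        assert cm.SEN == 1.0
        assert cm.SPC == 0.0
        assert cm.ACC == 0.5
        assert math.isnan(cm.NPV)  # no negative predictions at all

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.tuples(st.booleans(), st.booleans()), min_size=1, max_size=500))
    def test_identities_on_random_call_pairs(self, pairs):
        pred = ActivityCall({f"r{i}": p for i, (p, _) in enumerate(pairs)}, "flux")
        truth = ActivityCall({f"r{i}": t for i, (_, t) in enumerate(pairs)}, "expression")
        cm = confusion(pred, truth)
        tp, fp, tn, fn = confusion_brute(pairs)
        assert (cm.TP, cm.FP, cm.TN, cm.FN) == (tp, fp, tn, fn)
        assert cm.n == len(pairs)
        if not math.isnan(cm.ACC):
            assert cm.ACC == pytest.approx((tp + tn) / len(pairs))
        for value in (cm.SEN, cm.SPC, cm.PPV, cm.NPV):
            assert math.isnan(value) or 0.0 <= value <= 1.0


class TestSsd:
    def test_identical_ranks_zero(self):
        assert ssd({"a": 0.2, "b": 0.8}, {"a": 0.2, "b": 0.8}).total == 0.0

    def test_hand_arithmetic(self):
        res = ssd({"a": 0.2, "b": 0.8}, {"a": 0.4, "b": 0.4})
        assert res.per_reaction["a"] == pytest.approx(0.04)
        assert res.per_reaction["b"] == pytest.approx(0.16)
        assert res.total == pytest.approx(0.20)

    def test_symmetry(self):
        x = {"a": 0.1, "b": 0.9, "c": 0.3}
        y = {"a": 0.5, "b": 0.2, "c": 0.8}
        assert ssd(x, y).total == pytest.approx(ssd(y, x).total)

    def test_out_of_range_rank_rejected(self):
        with pytest.raises(ValueError):
            ssd({"a": 1.5}, {"a": 0.2})

    def test_monotone_under_rank_replacement(self):
        rng = np.random.default_rng(3)
        keys = [f"r{i}" for i in range(20)]
        flux = {k: float(rng.random()) for k in keys}
        expr = {k: float(rng.random()) for k in keys}
        total = ssd(flux, expr).total
        for k in keys:
            flux[k] = expr[k]
            new_total = ssd(flux, expr).total
            assert new_total <= total + 1e-12
            total = new_total
        assert total == pytest.approx(0.0, abs=1e-12)


class TestCoreOverlap:
    def call(self, active, universe):
        return ActivityCall({r: r in active for r in universe}, source="flux")

    def test_identical_calls(self):
        u = ["a", "b", "c"]
        c = self.call({"a", "b"}, u)
        out = core_overlap({"m1": c, "m2": c})
        assert out["core"] == {"a", "b"}
        assert out["only_m1"] == set() and out["only_m2"] == set()

    def test_disjoint_sets(self):
        u = ["a", "b"]
        out = core_overlap(
            {"m1": self.call({"a"}, u), "m2": self.call({"b"}, u)}
        )
        assert out["core"] == set()
        assert out["only_m1"] == {"a"}

    def test_partition_matches_set_algebra(self):
        u = [f"r{i}" for i in range(30)]
        rng = np.random.default_rng(11)
        sets = {
            m: {r for r in u if rng.random() < 0.5} for m in ("x", "y", "z")
        }
        out = core_overlap({m: self.call(s, u) for m, s in sets.items()})
        assert out["core"] == sets["x"] & sets["y"] & sets["z"]
        assert out["only_x"] == sets["x"] - (sets["y"] | sets["z"])

    def test_overlap_shrinks_with_methods(self):
        u = [f"r{i}" for i in range(30)]
        rng = np.random.default_rng(12)
        sets = {m: {r for r in u if rng.random() < 0.7} for m in ("a", "b", "c")}
        two = core_overlap({m: self.call(sets[m], u) for m in ("a", "b")})
        three = core_overlap({m: self.call(sets[m], u) for m in ("a", "b", "c")})
        assert three["core"] <= two["core"]


class TestMultiomics:
    def test_fully_supported_reaction_integrated(self, bundle):
        model = bundle[0]
        rxn = model.reaction("R_inv")
        evidence = OmicsEvidence(
            transcript_genes=set(rxn.genes),
            protein_genes=set(rxn.genes),
            metabolites={"suc_c", "g6p_c"},
        )
        call = ActivityCall({"R_inv": True}, source="flux")
        table = multiomics_verify(model, call, evidence)
        assert bool(table.loc["R_inv", "integrated"])

    def test_inactive_prediction_not_integrated(self, bundle):
        model = bundle[0]
        rxn = model.reaction("R_inv")
        evidence = OmicsEvidence(set(rxn.genes), set(rxn.genes), {"suc_c"})
        call = ActivityCall({"R_inv": False}, source="flux")
        table = multiomics_verify(model, call, evidence)
        assert not bool(table.loc["R_inv", "integrated"])

    def test_counts_match_brute_force(self, bundle):
        model, truth, _, _ = bundle
        rng = np.random.default_rng(7)
        universe = evaluated_reactions(model)
        call = ActivityCall(
            {r: bool(rng.random() < 0.7) for r in universe}, source="flux"
        )
        genes = sorted({g for r in universe for g in model.reaction(r).genes})
        tr = {g for g in genes if rng.random() < 0.8}
        pr = {g for g in genes if rng.random() < 0.6}
        mets = {m for m in model.metabolite_ids if rng.random() < 0.5}
        evidence = OmicsEvidence(tr, pr, mets)
        table = multiomics_verify(model, call, evidence)
        counts = multiomics_counts(table)
        from txcbm.evaluation import DEFAULT_CURRENCY

        def base(mid):
            stem, _, tag = mid.rpartition("_")
            return stem if stem and len(tag) <= 2 else mid

        expected_integrated = 0
        for r in universe:
            rxn = model.reaction(r)
            ok = (
                call[r]
                and bool(set(rxn.genes) & tr)
                and bool(set(rxn.genes) & pr)
                and bool({m for m in rxn.stoichiometry
                          if base(m) not in DEFAULT_CURRENCY} & mets)
            )
            expected_integrated += ok
        assert counts["integrated"] == expected_integrated
        assert counts["integrated"] <= min(
            counts["transcript"], counts["protein"], counts["metabolite"]
        )
        assert counts["integrated"] <= counts["n"]

    def test_empty_layer_warns_not_errors(self, bundle):
        model = bundle[0]
        call = ActivityCall({"R_inv": True}, source="flux")
        table = multiomics_verify(model, call, OmicsEvidence())
        assert multiomics_counts(table)["integrated"] == 0
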