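"""Consistency evaluation of flux predictions against expression and omics data.

The evaluation universe follows the model's category partition: confusion
indices and rank-SSD are computed over gene-associated *biochemical* reactions
(transport/exchange and auxiliary reactions carry no expression evidence and
are excluded).

Activity calls: a reaction is flux-active when |v_j| exceeds a numeric
tolerance, expression-active when its rank strictly exceeds a percentile
threshold.  Calls from the two sources meet in a confusion matrix with the
usual ACC/SEN/SPC/PPV/NPV indices, and quantitatively in the sum of squared
differences between percentile-ranked |fluxes| and percentile-ranked
expression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fba_engine import ZERO_FLUX_TOL, FluxDistribution
from .model_core import MetabolicModel
from .transcriptome import ReactionExpression, percentile_rank

#: metabolites ignored in metabolite-evidence matching (would trivially verify
#: nearly every reaction); matched on the id stripped of a compartment suffix
DEFAULT_CURRENCY = frozenset(
    {"atp", "adp", "amp", "nad", "nadh", "nadp", "nadph", "pi", "ppi",
     "h2o", "h", "co2", "o2", "coa"}
)


@dataclass
class ActivityCall:
    calls: dict[str, bool]  # reaction-id -> active?
    source: str  # "flux" | "expression" | "truth"
    threshold: float | None = None

    def active_set(self) -> set[str]:
        return {r for r, a in self.calls.items() if a}

    def __getitem__(self, rid: str) -> bool:
        return self.calls[rid]


@dataclass
class ConfusionSummary:
    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def n(self) -> int:
        return self.TP + self.FP + self.TN + self.FN

    def _ratio(self, num: int, den: int) -> float:
        return num / den if den else math.nan

    @property
    def ACC(self) -> float:
        return self._ratio(self.TP + self.TN, self.n)

    @property
    def SEN(self) -> float:
        return self._ratio(self.TP, self.TP + self.FN)

    @property
    def SPC(self) -> float:
        return self._ratio(self.TN, self.TN + self.FP)

    @property
    def PPV(self) -> float:
        return self._ratio(self.TP, self.TP + self.FP)

    @property
    def NPV(self) -> float:
        return self._ratio(self.TN, self.TN + self.FN)

    def as_dict(self) -> dict[str, float]:
        return {
            "TP": self.TP, "FP": self.FP, "TN": self.TN, "FN": self.FN, "n": self.n,
            "ACC": self.ACC, "SEN": self.SEN, "SPC": self.SPC,
            "PPV": self.PPV, "NPV": self.NPV,
        }


@dataclass
class SsdResult:
    per_reaction: dict[str, float]
    total: float


@dataclass
class OmicsEvidence:
    transcript_genes: set[str] = field(default_factory=set)
    protein_genes: set[str] = field(default_factory=set)
    metabolites: set[str] = field(default_factory=set)


def evaluated_reactions(model: MetabolicModel) -> list[str]:
    """Gene-associated biochemical reactions — the confusion/SSD universe."""
    return [
        r.id for r in model.reactions if r.category == "biochemical" and r.genes
    ]


def activity_from_flux(
    fluxes: FluxDistribution, tol: float = ZERO_FLUX_TOL, subset: list[str] | None = None
) -> ActivityCall:
    """Active iff |v_j| > tol (squelches solver noise)."""
    if not fluxes.optimal:
        raise ValueError(f"activity calls need an optimal solution, got {fluxes.status}")
    rids = subset if subset is not None else list(fluxes.fluxes)
    return ActivityCall(
        calls={r: abs(fluxes.fluxes[r]) > tol for r in rids},
        source="flux",
        threshold=tol,
    )


def activity_from_expression(
    rxn_expr: ReactionExpression,
    threshold_percentile: float = 50.0,
    subset: list[str] | None = None,
) -> ActivityCall:
    """Active iff rank_j strictly exceeds the percentile threshold.

    Reactions without gene associations are excluded from the calls.
    """
    thr = threshold_percentile / 100.0
    rids = subset if subset is not None else list(rxn_expr.has_genes)
    calls = {
        r: rxn_expr.rank[r] > thr
        for r in rids
        if rxn_expr.has_genes.get(r, False)
    }
    return ActivityCall(calls=calls, source="expression", threshold=thr)


def confusion(pred: ActivityCall, truth: ActivityCall) -> ConfusionSummary:
    """Confusion counts over the shared reaction set.

    Convention: *positive* = active.  TP: both active; FN: prediction inactive
    where the reference is active; FP: prediction active where the reference is
    inactive.
    """
    shared = set(pred.calls) & set(truth.calls)
    if not shared:
        raise ValueError("prediction and reference share no reactions")
    tp = fp = tn = fn = 0
    for r in shared:
        if pred[r] and truth[r]:
            tp += 1
        elif pred[r] and not truth[r]:
            fp += 1
        elif not pred[r] and truth[r]:
            fn += 1
        else:
            tn += 1
    return ConfusionSummary(TP=tp, FP=fp, TN=tn, FN=fn)


def ssd(flux_ranks: dict[str, float], expr_ranks: dict[str, float]) -> SsdResult:
    """Sum over the shared set of (flux rank − expression rank)²."""
    shared = sorted(set(flux_ranks) & set(expr_ranks))
    if not shared:
        raise ValueError("rank vectors share no reactions")
    per = {}
    for r in shared:
        vr, zr = flux_ranks[r], expr_ranks[r]
        for name, x in (("flux", vr), ("expression", zr)):
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name} rank of {r} outside [0, 1]: {x}")
        per[r] = (vr - zr) ** 2
    return SsdResult(per_reaction=per, total=float(sum(per.values())))


def flux_ranks(fluxes: FluxDistribution, subset: list[str]) -> dict[str, float]:
    """Percentile ranks of |v_j| over ``subset`` (flux side of the SSD)."""
    mags = [abs(fluxes.fluxes[r]) for r in subset]
    return dict(zip(subset, percentile_rank(mags).tolist()))


def ssd_for(
    model: MetabolicModel,
    fluxes: FluxDistribution,
    rxn_expr: ReactionExpression,
    subset: list[str] | None = None,
) -> SsdResult:
    """Convenience: SSD of a solution against expression over the evaluated universe."""
    if subset is None:
        subset = [r for r in evaluated_reactions(model) if rxn_expr.has_genes.get(r)]
    vr = flux_ranks(fluxes, subset)
    zr = {r: rxn_expr.rank[r] for r in subset}
    return ssd(vr, zr)


def core_overlap(results: dict[str, ActivityCall]) -> dict[str, set[str]]:
    """Venn partition of per-method active sets.

    Returns the intersection under ``"core"`` plus one ``"only_<method>"``
    exclusive set per method.
    """
    if len(results) < 2:
        raise ValueError("core overlap needs at least two methods")
    actives = {m: c.active_set() for m, c in results.items()}
    core = set.intersection(*actives.values())
    out = {"core": core}
    for m, a in actives.items():
        others = set.union(*(v for k, v in actives.items() if k != m)) if len(actives) > 1 else set()
        out[f"only_{m}"] = a - others
    return out


def multiomics_verify(
    model: MetabolicModel,
    flux_act: ActivityCall,
    evidence: OmicsEvidence,
    currency: frozenset[str] = DEFAULT_CURRENCY,
) -> pd.DataFrame:
    """Per-reaction verification against transcript, protein and metabolite layers.

    A reaction is layer-verified when any associated gene (transcript/protein
    layers) or any non-currency substrate/product (metabolite layer) appears in
    the evidence set; *integrated-verified* additionally requires the flux
    prediction to be active.  Currency metabolites are matched after stripping
    a trailing ``_<compartment>`` tag.
    """
    import logging

    logger = logging.getLogger("txcbm")
    for layer, ids in (
        ("transcript", evidence.transcript_genes),
        ("protein", evidence.protein_genes),
        ("metabolite", evidence.metabolites),
    ):
        if not ids:
            logger.warning("empty %s evidence layer: its counts will be 0", layer)

    def base_id(mid: str) -> str:
        stem, _, tag = mid.rpartition("_")
        return stem if stem and len(tag) <= 2 else mid

    rows = []
    for rid in flux_act.calls:
        rxn = model.reaction(rid)
        genes = set(rxn.genes)
        mets = {m for m in rxn.stoichiometry if base_id(m) not in currency}
        t = bool(genes & evidence.transcript_genes)
        p = bool(genes & evidence.protein_genes)
        m = bool(mets & evidence.metabolites)
        active = flux_act[rid]
        rows.append(
            {
                "reaction_id": rid,
                "flux_active": active,
                "transcript": t,
                "protein": p,
                "metabolite": m,
                "integrated": active and t and p and m,
            }
        )
    return pd.DataFrame(rows).set_index("reaction_id")


def multiomics_counts(table: pd.DataFrame) -> dict[str, int]:
    active = table[table["flux_active"]]
    return {
        "transcript": int((active["transcript"]).sum()),
        "protein": int((active["protein"]).sum()),
        "metabolite": int((active["metabolite"]).sum()),
        "integrated": int((active["integrated"]).sum()),
        "flux_active": int(table["flux_active"].sum()),
        "n": int(len(table)),
    }
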