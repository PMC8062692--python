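"""Desk-scale synthetic networks, expression tables and omics evidence.

The generator emulates the structure of a compartmentalized storage-root
carbon-metabolism model at toy scale, with a known ground truth so every
pipeline stage is testable without external downloads:

* sucrose-like substrate uptake feeding a cytosolic glycolysis-like chain,
* an oxidative-PPP-like branch that loses CO₂ (strictly less carbon-efficient
  than the chain, so plain FBA avoids it even when its genes are expressed),
* a mitochondrial TCA-like cycle producing ATP,
* substitutable parallel isozyme pairs (one member expressed, one silent),
* a blocked side reaction (dead-end product),
* a plastidic starch route and a biomass reaction carrying the tunable
  S_GAM ATP-maintenance coefficient, plus a non-gene maintenance ATPase that
  lets surplus carbon be respired at a fixed growth rate.

Ground truth marks the reactions (and their genes) that carry flux in the
designed physiological state; expression is drawn log-normal with a strong
active/silent separation and replicate noise on the FPKM scale.

With the default spec the maximum attainable growth has the closed form
``g_max = 6·u / (S_GAM + 5.375)`` (u the sucrose uptake rate): each biomass
unit costs 1 starch + 0.3 pyruvate + 0.2 alanine + 0.1 pentose phosphate +
(S_GAM + 1) ATP, and ATP comes from the pyruvate-kinase step and the cycle at
2 ATP per pyruvate respired.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import OmicsEvidence
from .fba_engine import fba
from .model_core import MetabolicModel, Metabolite, Reaction
from .transcriptome import ExpressionMatrix


@dataclass
class NetworkSpec:
    """Sizes and conditions of the generated network.

    Chain/branch/cycle counts are reaction counts of each motif; the defaults
    give 23 gene-associated biochemical reactions (20 active, 3 silent).
    Uptake and observed growth are the fixed study conditions of the bundle.
    """

    n_chain: int = 6
    n_branch: int = 3
    n_cycle: int = 5
    n_parallel_pairs: int = 2
    compartments: tuple[str, ...] = ("cytosol", "plastid", "mitochondrion")
    uptake_rate: float = 10.0
    observed_growth: float = 4.5
    s_gam: float = 6.0

    def validate(self) -> None:
        if self.n_chain < 3:
            raise ValueError("n_chain must be >= 3")
        if self.n_branch < 2:
            raise ValueError("n_branch must be >= 2")
        if self.n_cycle < 3:
            raise ValueError("n_cycle must be >= 3")
        if not 0 <= self.n_parallel_pairs <= 2:
            raise ValueError("n_parallel_pairs must be 0, 1 or 2")
        if self.uptake_rate <= 0 or self.s_gam <= 0:
            raise ValueError("uptake_rate and s_gam must be positive")


@dataclass
class ExpressionParams:
    active_log_mean: float = float(np.log(50.0))
    inactive_log_mean: float = float(np.log(0.5))
    log_sd: float = 0.4
    replicate_cv: float = 0.10
    cross_dataset_sd: float = 0.05
    high_cv_fraction: float = 0.1
    high_cv_sd: float = 0.6


@dataclass
class SyntheticTruth:
    seed: int
    active_reactions: set[str]
    active_genes: set[str]
    gene_map: dict[str, list[str]]  # reaction -> genes
    expression_params: ExpressionParams = field(default_factory=ExpressionParams)
    network_spec: NetworkSpec = field(default_factory=NetworkSpec)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "active_reactions": sorted(self.active_reactions),
            "active_genes": sorted(self.active_genes),
            "gene_map": {k: self.gene_map[k] for k in sorted(self.gene_map)},
        }


def generate_network(
    spec: NetworkSpec | None = None, seed: int = 0
) -> tuple[MetabolicModel, SyntheticTruth]:
    """Build the 3-compartment toy model and its ground-truth activity."""
    spec = spec or NetworkSpec()
    spec.validate()
    rng = np.random.default_rng(seed)

    mets: list[Metabolite] = []
    rxns: list[Reaction] = []

    def met(mid: str, comp: str) -> str:
        mets.append(Metabolite(id=mid, name=mid, compartment=comp))
        return mid

    # metabolites -----------------------------------------------------------
    suc_e = met("suc_e", "external")
    co2_e = met("co2_e", "external")
    biomass_e = met("biomass_e", "external")
    suc_c = met("suc_c", "cytosol")
    g6p_c = met("g6p_c", "cytosol")
    chain_mets = [met(f"gly{i}_c", "cytosol") for i in range(1, spec.n_chain)]
    pep_c = met("pep_c", "cytosol")
    branch_mets = [met(f"ppp{i}_c", "cytosol") for i in range(1, spec.n_branch - 1)]
    r5p_c = met("r5p_c", "cytosol")
    pyr_c = met("pyr_c", "cytosol")
    ala_c = met("ala_c", "cytosol")
    atp_c = met("atp_c", "cytosol")
    adp_c = met("adp_c", "cytosol")
    deadend_c = met("deadend_c", "cytosol")
    g6p_p = met("g6p_p", "plastid")
    adpg_p = met("adpg_p", "plastid")
    starch_p = met("starch_p", "plastid")
    pyr_m = met("pyr_m", "mitochondrion")
    acc_m = met("acc_m", "mitochondrion")
    cyc_mets = [met(f"tca{i}_m", "mitochondrion") for i in range(1, spec.n_cycle)]
    oaa_m = met("oaa_m", "mitochondrion")

    # reactions -------------------------------------------------------------
    active: set[str] = set()

    def rxn(rid, stoich, category="biochemical", pathway=None, genes=True,
            is_active=True, reversible=False, name=""):
        rxns.append(
            Reaction(
                id=rid, name=name or rid, stoichiometry=stoich,
                reversible=reversible, category=category, pathway=pathway,
                genes=["__pending__"] if genes else [],
            )
        )
        if is_active:
            active.add(rid)
        return rid

    rxn("EX_suc", {suc_e: 1.0}, category="transport_exchange", genes=False,
        name="sucrose supply")
    rxn("T_suc", {suc_e: -1.0, suc_c: 1.0}, category="transport_exchange", genes=False)
    rxn("R_inv", {suc_c: -1.0, g6p_c: 2.0}, pathway="SSP",
        name="invertase + hexokinase (lumped)")

    # glycolysis-like chain g6p -> ... -> pep, all 1:1
    chain_nodes = [g6p_c] + chain_mets + [pep_c]
    for i in range(spec.n_chain):
        rxn(f"R_chain{i + 1}", {chain_nodes[i]: -1.0, chain_nodes[i + 1]: 1.0},
            pathway="RES")
    rxn("R_pyk", {pep_c: -1.0, adp_c: -1.0, pyr_c: 1.0, atp_c: 1.0}, pathway="RES",
        name="pyruvate kinase")

    # PPP-like branch: an oxidative entry losing CO2 (0.8 carbon yield) feeds a
    # pentose-phosphate pool (r5p, a biomass precursor), and a return step
    # reconverges into the chain — so the branch is essential in truth while
    # the return leg is carbon-wasteful and avoided by plain FBA
    branch_nodes = [g6p_c] + branch_mets + [r5p_c]
    for i in range(spec.n_branch - 1):
        stoich = {branch_nodes[i]: -1.0, branch_nodes[i + 1]: 1.0}
        if i == 0:
            stoich[branch_nodes[i + 1]] = 0.8
            stoich[co2_e] = 0.2
        rxn(f"R_ppp{i + 1}", stoich, pathway="PPP",
            name="oxidative branch entry (lumped)" if i == 0 else "")
    rxn(f"R_ppp{spec.n_branch}", {r5p_c: -1.0, chain_nodes[2]: 1.0}, pathway="PPP",
        name="non-oxidative return to the chain (lumped)")

    # mitochondrial entry + cycle; the closing step regenerates the cycle
    # carrier and pays out 2 ATP
    rxn("T_pyr", {pyr_c: -1.0, pyr_m: 1.0}, category="transport_exchange", genes=False)
    rxn("R_pdh", {pyr_m: -1.0, acc_m: 1.0, co2_e: 1.0}, pathway="RES",
        name="pyruvate dehydrogenase (lumped)")
    cyc_nodes = [acc_m] + cyc_mets
    rxn("R_tca1", {acc_m: -1.0, oaa_m: -1.0, cyc_nodes[1]: 1.0},
        pathway="RES", name="citrate synthase (lumped)")
    for i in range(1, spec.n_cycle - 1):
        rxn(f"R_tca{i + 1}", {cyc_nodes[i]: -1.0, cyc_nodes[i + 1]: 1.0, co2_e: 1.0},
            pathway="RES")
    rxn(f"R_tca{spec.n_cycle}",
        {cyc_nodes[-1]: -1.0, adp_c: -2.0, oaa_m: 1.0, atp_c: 2.0, co2_e: 1.0},
        pathway="RES", name="cycle closing + substrate phosphorylation (lumped)")

    rxn("R_ala", {pyr_c: -1.0, ala_c: 1.0}, pathway="AMI", name="alanine biosynthesis (lumped)")

    rxn("T_g6p", {g6p_c: -1.0, g6p_p: 1.0}, category="transport_exchange", genes=False)
    rxn("R_agp", {g6p_p: -1.0, atp_c: -1.0, adpg_p: 1.0, adp_c: 1.0}, pathway="SSP",
        name="ADP-glucose pyrophosphorylase (lumped)")
    rxn("R_ss1", {adpg_p: -1.0, starch_p: 1.0}, pathway="SSP", name="starch synthase")

    # silent members: parallel isozymes and a dead-end side reaction
    if spec.n_parallel_pairs >= 1:
        rxn("R_chain1_alt", {g6p_c: -1.0, chain_nodes[1]: 1.0}, pathway="RES",
            is_active=False, name="silent isozyme of R_chain1")
    if spec.n_parallel_pairs >= 2:
        rxn("R_ss2", {adpg_p: -1.0, starch_p: 1.0}, pathway="SSP",
            is_active=False, name="silent starch synthase isozyme")
    rxn("R_side", {g6p_c: -1.0, deadend_c: 1.0}, pathway="CEL",
        is_active=False, name="silent side reaction (dead-end product)")

    # maintenance ATPase: non-gene overflow valve for surplus carbon/ATP
    rxn("R_atpase", {atp_c: -1.0, adp_c: 1.0}, category="auxiliary", genes=False,
        name="maintenance ATP hydrolysis")

    rxn("R_biomass",
        {starch_p: -1.0, pyr_c: -0.3, ala_c: -0.2, r5p_c: -0.1,
         atp_c: -spec.s_gam, adp_c: spec.s_gam, biomass_e: 1.0},
        category="auxiliary", genes=False, name="biomass")
    rxn("EX_biomass", {biomass_e: -1.0}, category="transport_exchange", genes=False)
    rxn("EX_co2", {co2_e: -1.0}, category="transport_exchange", genes=False)

    # gene assignment: 1–3 dedicated genes per biochemical reaction ---------
    gene_map: dict[str, list[str]] = {}
    counter = 1
    for r in rxns:
        if r.genes == ["__pending__"]:
            k = int(rng.integers(1, 4))
            r.genes = [f"G{counter + i:04d}" for i in range(k)]
            gene_map[r.id] = list(r.genes)
            counter += k

    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="R_biomass",
        substrate_uptake_id="EX_suc",
        uptake_rate=spec.uptake_rate,
        gam_metabolite_ids={"consumed": [atp_c], "released": [adp_c]},
        id=f"synthetic_{seed}",
    )
    model.validate()

    dist = fba(model, fixed={"EX_suc": spec.uptake_rate})
    if not dist.optimal or dist.biomass_flux <= 1e-9:
        raise RuntimeError(
            f"generated network cannot grow (status {dist.status}, "
            f"biomass {dist.biomass_flux}); spec: {spec}"
        )
    if dist.biomass_flux < spec.observed_growth - 1e-9:
        raise RuntimeError(
            f"observed growth {spec.observed_growth} exceeds the attainable "
            f"maximum {dist.biomass_flux:.4f}; adjust the spec"
        )

    active_genes = {g for rid in active for g in gene_map.get(rid, [])}
    truth = SyntheticTruth(
        seed=seed,
        active_reactions=active,
        active_genes=active_genes,
        gene_map=gene_map,
        network_spec=spec,
    )
    return model, truth


def max_growth_closed_form(spec: NetworkSpec) -> float:
    """Analytic FBA optimum of the default topology.

    Per biomass unit: 1 g6p to starch, 0.125 g6p to pentose phosphate
    (0.1 r5p at the 0.8-carbon oxidative yield), and (S_GAM + 2)/3 g6p down
    the chain to cover pyruvate and ATP demands, against 2 g6p per substrate
    unit: g_max = 6·u / (S_GAM + 5.375).
    """
    return 6.0 * spec.uptake_rate / (spec.s_gam + 5.375)


def generate_expression(
    truth: SyntheticTruth,
    n_datasets: int = 3,
    n_replicates: int = 3,
    seed: int = 0,
    params: ExpressionParams | None = None,
) -> list[ExpressionMatrix]:
    """Draw FPKM-like bimodal expression for the truth's genes.

    Active genes are log-normal around ``active_log_mean``, silent genes around
    ``inactive_log_mean`` (well separated by default).  A gene-level effect is
    shared across datasets; per-dataset factors keep the cross-dataset CV small
    except for a ``high_cv_fraction`` of genes given large dataset-to-dataset
    swings to exercise the consensus filter; replicates add multiplicative
    noise at ``replicate_cv``.
    """
    if n_datasets < 1 or n_replicates < 1:
        raise ValueError("need at least one dataset and one replicate")
    params = params or truth.expression_params
    rng = np.random.default_rng(seed)

    genes = sorted({g for gs in truth.gene_map.values() for g in gs})
    is_active = np.array([g in truth.active_genes for g in genes])
    base_log = np.where(is_active, params.active_log_mean, params.inactive_log_mean)
    gene_effect = rng.normal(0.0, params.log_sd, size=len(genes))
    high_cv = rng.random(len(genes)) < params.high_cv_fraction
    ds_sd = np.where(high_cv, params.high_cv_sd, params.cross_dataset_sd)

    datasets = []
    for d in range(n_datasets):
        ds_effect = rng.normal(0.0, ds_sd)
        cols = {}
        for r in range(n_replicates):
            noise = rng.normal(0.0, max(params.replicate_cv, 1e-12), size=len(genes))
            fpkm = np.exp(base_log + gene_effect + ds_effect + noise)
            cols[f"d{d + 1}_r{r + 1}"] = fpkm
        df = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
        datasets.append(ExpressionMatrix(df))
    return datasets


def generate_omics(
    truth: SyntheticTruth,
    protein_dropout: float = 0.2,
    metabolite_dropout: float = 0.3,
    seed: int = 0,
    model: MetabolicModel | None = None,
) -> OmicsEvidence:
    """Evidence layers derived from the truth, thinned by dropout.

    Transcript evidence is the active gene set; protein evidence is that set
    thinned by ``protein_dropout``; metabolite evidence is the set of
    metabolites touched by active reactions thinned by ``metabolite_dropout``.
    """
    for name, frac in (("protein_dropout", protein_dropout),
                       ("metabolite_dropout", metabolite_dropout)):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {frac}")
    rng = np.random.default_rng(seed)
    transcript = set(truth.active_genes)
    proteins = {g for g in sorted(transcript) if rng.random() >= protein_dropout}

    if model is not None:
        touched = sorted(
            {m for rid in truth.active_reactions
             for m in model.reaction(rid).stoichiometry}
        )
    else:
        touched = []
    metabolites = {m for m in touched if rng.random() >= metabolite_dropout}
    return OmicsEvidence(
        transcript_genes=transcript,
        protein_genes=proteins,
        metabolites=metabolites,
    )


def linear_toy_model(uptake: float = 10.0, atp_yield: float = 2.0,
                     s_gam: float = 4.0) -> MetabolicModel:
    """Minimal chain for analytic S_GAM calibration.

    Substrate is respired to ``atp_yield`` ATP per unit; biomass costs S_GAM
    ATP and nothing else, so growth is exactly
    ``v_bio = atp_yield · uptake / S_GAM`` and the S_GAM hitting an observed
    rate v_o is ``atp_yield · uptake / v_o``.
    """
    mets = [
        Metabolite("s_e", compartment="external"),
        Metabolite("s_c", compartment="cytosol"),
        Metabolite("atp_c", compartment="cytosol"),
        Metabolite("adp_c", compartment="cytosol"),
        Metabolite("biomass_e", compartment="external"),
    ]
    rxns = [
        Reaction("EX_s", stoichiometry={"s_e": 1.0}, category="transport_exchange"),
        Reaction("T_s", stoichiometry={"s_e": -1.0, "s_c": 1.0},
                 category="transport_exchange"),
        Reaction("R_resp", stoichiometry={"s_c": -1.0, "adp_c": -atp_yield,
                                          "atp_c": atp_yield},
                 genes=["Gtoy1"]),
        Reaction("R_biomass", stoichiometry={"atp_c": -s_gam, "adp_c": s_gam,
                                             "biomass_e": 1.0},
                 category="auxiliary"),
        Reaction("EX_biomass", stoichiometry={"biomass_e": -1.0},
                 category="transport_exchange"),
    ]
    return MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id="R_biomass",
        substrate_uptake_id="EX_s",
        uptake_rate=uptake,
        gam_metabolite_ids={"consumed": ["atp_c"], "released": ["adp_c"]},
        id="linear_toy",
    )
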