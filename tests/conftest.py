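import pytest

from txcbm.model_core import MetabolicModel, Metabolite, Reaction
from txcbm.synthetic_data import generate_expression, generate_network
from txcbm.transcriptome import ReactionExpression, reaction_expression

#: canonical seed of the pinned synthetic bundle used across the suite
BUNDLE_SEED = 17


def build_model(
    metabolites,
    reactions,
    biomass=None,
    uptake=None,
    uptake_rate=None,
    gam=None,
):
    """Compact toy-model builder.

    ``metabolites``: {id: compartment}; ``reactions``: list of dicts with keys
    id, stoich and optional lb/ub/reversible/genes/category/pathway.
    """
    mets = [Metabolite(id=m, compartment=c) for m, c in metabolites.items()]
    rxns = [
        Reaction(
            id=r["id"],
            stoichiometry=r["stoich"],
            lower_bound=r.get("lb"),
            upper_bound=r.get("ub"),
            reversible=r.get("reversible", False),
            genes=r.get("genes", []),
            category=r.get("category", "biochemical"),
            pathway=r.get("pathway"),
        )
        for r in reactions
    ]
    model = MetabolicModel(
        metabolites=mets,
        reactions=rxns,
        biomass_reaction_id=biomass,
        substrate_uptake_id=uptake,
        uptake_rate=uptake_rate,
        gam_metabolite_ids=gam or {},
    )
    model.validate()
    return model


def chain_model(uptake_cap=10.0, genes=False):
    """uptake -> A -> B -> biomass, biomass consumes 1 B."""
    return build_model(
        {"A": "cytosol", "B": "cytosol"},
        [
            {"id": "uptake", "stoich": {"A": 1.0}, "ub": uptake_cap,
             "category": "transport_exchange"},
            {"id": "r1", "stoich": {"A": -1.0, "B": 1.0},
             "genes": ["g1"] if genes else []},
            {"id": "biomass", "stoich": {"B": -1.0}, "category": "auxiliary"},
        ],
        biomass="biomass",
        uptake="uptake",
    )


def parallel_model(uptake_cap=10.0):
    """uptake -> A, two equivalent routes A -> B, B -> biomass."""
    return build_model(
        {"A": "cytosol", "B": "cytosol"},
        [
            {"id": "uptake", "stoich": {"A": 1.0}, "ub": uptake_cap,
             "category": "transport_exchange"},
            {"id": "p1", "stoich": {"A": -1.0, "B": 1.0}, "genes": ["g1"]},
            {"id": "p2", "stoich": {"A": -1.0, "B": 1.0}, "genes": ["g2"]},
            {"id": "biomass", "stoich": {"B": -1.0}, "category": "auxiliary"},
        ],
        biomass="biomass",
        uptake="uptake",
    )


def ranks(model, values):
    """ReactionExpression with explicit per-reaction ranks (raw = rank)."""
    rx = ReactionExpression()
    for rxn in model.reactions:
        has = rxn.id in values
        rx.has_genes[rxn.id] = has
        if has:
            rx.raw[rxn.id] = float(values[rxn.id])
            rx.rank[rxn.id] = float(values[rxn.id])
    return rx


@pytest.fixture(scope="session")
def bundle():
    """The pinned default synthetic bundle (model, truth, reaction expression)."""
    model, truth = generate_network(seed=BUNDLE_SEED)
    expr = generate_expression(truth, seed=BUNDLE_SEED + 1)
    rxn_expr = reaction_expression(model, expr[0])
    return model, truth, expr, rxn_expr
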