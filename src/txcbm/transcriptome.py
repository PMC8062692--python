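"""FPKM ingestion, cross-dataset consensus, and reaction-level expression ranks.

Expression enters the flux programs as a percentile rank ``x_j`` in [0, 1] per
reaction.  A reaction linked to several genes takes the expression of its
highest-expressed gene (isozyme semantics: any one expressed enzyme suffices),
and ranks are computed across all gene-associated reactions of the model so
that datasets with different FPKM scales become comparable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import MetabolicModel

logger = logging.getLogger("txcbm")


class ExpressionError(ValueError):
    pass


@dataclass
class ExpressionMatrix:
    """Gene × sample FPKM table (non-negative, unique gene ids)."""

    values: pd.DataFrame  # index: gene ids; columns: sample ids

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ExpressionError(f"duplicate gene ids: {dup}")
        if not np.issubdtype(self.values.to_numpy().dtype, np.number):
            raise ExpressionError("non-numeric expression values")
        if (self.values.to_numpy() < 0).any():
            bad = self.values.index[(self.values < 0).any(axis=1)].tolist()
            raise ExpressionError(f"negative FPKM values for genes: {bad}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def gene_means(self) -> pd.Series:
        """Per-gene mean FPKM across samples (replicate aggregation)."""
        return self.values.mean(axis=1)


@dataclass
class ReactionExpression:
    """Per-reaction aggregated FPKM and percentile rank.

    ``rank`` is defined only for reactions with gene associations; it is the
    mid-rank percentile of ``raw`` among all gene-associated reactions.
    """

    raw: dict[str, float] = field(default_factory=dict)
    rank: dict[str, float] = field(default_factory=dict)
    has_genes: dict[str, bool] = field(default_factory=dict)
    threshold_registry: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rids = list(self.has_genes)
        return pd.DataFrame(
            {
                "reaction_id": rids,
                "raw": [self.raw.get(r, np.nan) for r in rids],
                "rank": [self.rank.get(r, np.nan) for r in rids],
                "has_genes": [self.has_genes[r] for r in rids],
            }
        ).set_index("reaction_id")


def load_fpkm(path: str, sep: str | None = None) -> ExpressionMatrix:
    """Read a TSV/CSV with a gene-id column followed by numeric sample columns."""
    if sep is None:
        sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[1] < 1:
        raise ExpressionError(f"{path}: no sample columns")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ExpressionError(f"{path}: non-numeric expression cell ({exc})") from exc
    df.index = df.index.astype(str)
    return ExpressionMatrix(df)


def write_fpkm(expr: ExpressionMatrix, path: str) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene_id")


def coefficient_of_variation(values) -> float:
    """CV in percent: 100 · sd / mean, with the sample (n−1) standard deviation."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise ValueError("CV needs at least two values")
    mean = arr.mean()
    if mean == 0:
        raise ZeroDivisionError("CV undefined: mean expression is zero")
    return 100.0 * arr.std(ddof=1) / mean


def consensus_genes(
    datasets: list[ExpressionMatrix],
    expressed_min: float = 1.0,
    cv_threshold: float = 25.0,
) -> set[str]:
    """Genes concurrently expressed in every dataset with stable expression.

    A gene is kept when its replicate-mean FPKM exceeds ``expressed_min`` in
    every dataset AND the coefficient of variation of those dataset means is
    below ``cv_threshold`` percent.
    """
    if len(datasets) < 2:
        raise ValueError("consensus needs at least two datasets")
    universe = set(datasets[0].genes)
    for ds in datasets[1:]:
        universe &= set(ds.genes)
    if not universe:
        raise ExpressionError("datasets share no genes")
    means = pd.DataFrame({i: ds.gene_means() for i, ds in enumerate(datasets)}).loc[
        sorted(universe)
    ]
    expressed = (means > expressed_min).all(axis=1)
    kept = set()
    for gene in means.index[expressed]:
        if coefficient_of_variation(means.loc[gene]) < cv_threshold:
            kept.add(gene)
    return kept


def percentile_rank(values) -> np.ndarray:
    """Mid-rank percentile in [0, 1): (count below + half the ties) / n.

    Ties share a rank; the mapping is non-decreasing in the input value.
    """
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("percentile rank of an empty sequence")
    if not np.isfinite(arr).all():
        raise ValueError("percentile rank requires finite values")
    n = arr.size
    below = (arr[None, :] < arr[:, None]).sum(axis=1)
    ties_excl_self = (arr[None, :] == arr[:, None]).sum(axis=1) - 1
    return (below + 0.5 * ties_excl_self) / n


def reaction_expression(
    model: MetabolicModel,
    expr: ExpressionMatrix,
    sample_agg: str = "mean",
) -> ReactionExpression:
    """Map gene expression onto reactions as max-gene aggregated FPKM + ranks.

    Aggregation per reaction is the MAX over its genes of the sample-aggregated
    FPKM; genes absent from the table count as 0 FPKM (with a warning).  Ranks
    are percentile ranks of the aggregated values over all gene-associated
    reactions.
    """
    if sample_agg == "mean":
        gene_level = expr.values.mean(axis=1)
    elif sample_agg == "median":
        gene_level = expr.values.median(axis=1)
    else:
        raise ValueError(f"unknown sample aggregation {sample_agg!r}")
    gene_level = gene_level.to_dict()

    model_genes = set(model.genes())
    if model_genes and not (model_genes & set(gene_level)):
        raise ExpressionError("no overlap between model genes and expression genes")
    missing = sorted(model_genes - set(gene_level))
    if missing:
        logger.warning(
            "%d model genes absent from expression table (treated as 0 FPKM): %s%s",
            len(missing), ", ".join(missing[:5]), "…" if len(missing) > 5 else "",
        )

    out = ReactionExpression()
    gene_rids = []
    raws = []
    for rxn in model.reactions:
        has = bool(rxn.genes)
        out.has_genes[rxn.id] = has
        if has:
            raw = max(gene_level.get(g, 0.0) for g in rxn.genes)
            out.raw[rxn.id] = float(raw)
            gene_rids.append(rxn.id)
            raws.append(raw)
    if gene_rids:
        ranks = percentile_rank(raws)
        out.rank = dict(zip(gene_rids, ranks.tolist()))
    return out


def write_reaction_expression(rxn_expr: ReactionExpression, path: str) -> None:
    rxn_expr.to_frame().to_csv(path, sep="\t")
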