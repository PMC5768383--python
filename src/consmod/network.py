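"""Correlation, soft-threshold adjacency, topological overlap, and the
consensus dissimilarity clustered downstream.

Per cohort the chain is Pearson correlation -> adjacency
(``|r|^beta`` unsigned, ``((1+r)/2)^beta`` signed) -> topological overlap
(TOM). The two cohorts' TOMs are combined elementwise (min by default)
into a consensus similarity, and ``d = 1 - consensusTOM`` is the
dissimilarity handed to average-linkage clustering. ``beta=1`` with the
``tom=False`` shortcut in higher layers recovers plain ``1 - |r|``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionStudy

logger = logging.getLogger(__name__)


def _check_square(df: pd.DataFrame, what: str) -> None:
    if df.shape[0] != df.shape[1] or not df.index.equals(df.columns):
        raise ValueError(f"{what} must be square with matching gene index/columns")


@dataclass
class AdjacencyMatrix:
    """Gene x gene soft-threshold adjacency, a_ij in [0, 1], diagonal 1."""

    values: pd.DataFrame
    beta: float
    mode: str

    @property
    def connectivity(self) -> pd.Series:
        a = self.values.to_numpy(copy=True)
        np.fill_diagonal(a, 0.0)
        return pd.Series(a.sum(axis=1), index=self.values.index, name="k")


@dataclass
class TOMMatrix:
    """Gene x gene topological overlap, values in [0, 1], diagonal 1."""

    values: pd.DataFrame
    beta: float
    mode: str


@dataclass
class DissimilarityMatrix:
    """Gene x gene dissimilarity d_ij in [0, 1] with zero diagonal."""

    values: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)


def correlation_matrix(study: ExpressionStudy, genes: list[str] | None = None) -> pd.DataFrame:
    """Pearson correlation of genes across all samples of the study.

    Constant genes (zero variance) get correlation 0 to every other gene,
    with a logged warning, so they become isolated network nodes rather
    than NaNs.
    """
    if study.n_samples < 3:
        raise ValueError(
            f"study {study.name!r} has {study.n_samples} samples; >= 3 required"
        )
    sub = study.values if genes is None else study.subset_genes(genes).values
    x = sub.to_numpy()
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "study %s: %d constant gene(s) given zero correlation: %s",
            study.name, int(constant.sum()), list(sub.index[constant][:5]),
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        cor = np.corrcoef(x)
    cor[constant, :] = 0.0
    cor[:, constant] = 0.0
    np.fill_diagonal(cor, 1.0)
    cor = np.clip(cor, -1.0, 1.0)
    return pd.DataFrame(cor, index=sub.index, columns=sub.index)


def adjacency(cor: pd.DataFrame, beta: float = 6.0, mode: str = "unsigned") -> AdjacencyMatrix:
    """Soft-threshold a correlation matrix into an adjacency in [0, 1]."""
    if beta < 1:
        raise ValueError(f"beta must be >= 1, got {beta}")
    if mode == "unsigned":
        a = np.abs(cor.to_numpy()) ** beta
    elif mode == "signed":
        a = ((1.0 + cor.to_numpy()) / 2.0) ** beta
    else:
        raise ValueError(f"mode must be 'unsigned' or 'signed', got {mode!r}")
    np.fill_diagonal(a, 1.0)
    return AdjacencyMatrix(pd.DataFrame(a, index=cor.index, columns=cor.columns), beta, mode)


def topological_overlap(adj: AdjacencyMatrix) -> TOMMatrix:
    """Topological overlap: similarity by direct links plus shared neighbours.

    ``TOM_ij = (L_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)`` with
    ``L_ij = sum_{u != i,j} a_iu a_uj`` and ``k_i = sum_{u != i} a_iu``;
    the diagonal is 1 by convention. A zero denominator (two isolated,
    unconnected nodes) yields TOM 0.
    """
    _check_square(adj.values, "adjacency")
    a = adj.values.to_numpy(copy=True)
    np.fill_diagonal(a, 0.0)
    l = a @ a  # zero diagonal of a removes the u=i and u=j terms
    k = a.sum(axis=1)
    denom = np.minimum.outer(k, k) + 1.0 - a
    with np.errstate(invalid="ignore", divide="ignore"):
        tom = (l + a) / denom
    zero_denom = denom <= 0
    if zero_denom.any():
        logger.warning("TOM: %d pair(s) with zero denominator set to 0", int(zero_denom.sum()))
        tom[zero_denom] = 0.0
    np.fill_diagonal(tom, 1.0)
    tom = np.clip(tom, 0.0, 1.0)
    return TOMMatrix(
        pd.DataFrame(tom, index=adj.values.index, columns=adj.values.columns),
        adj.beta, adj.mode,
    )


def consensus_dissimilarity(
    tom_a: TOMMatrix | pd.DataFrame,
    tom_b: TOMMatrix | pd.DataFrame,
    combiner: str = "min",
) -> DissimilarityMatrix:
    """Combine two cohorts' TOMs and convert to a clustering dissimilarity.

    ``min`` (default) is the conservative consensus — a gene pair is only
    as similar as it is in its *less* similar cohort; ``mean`` is offered
    for sensitivity analysis. ``d = 1 - consensusTOM`` with a zero diagonal.
    """
    ta = tom_a.values if isinstance(tom_a, TOMMatrix) else tom_a
    tb = tom_b.values if isinstance(tom_b, TOMMatrix) else tom_b
    if not ta.index.equals(tb.index):
        diff = sorted(set(ta.index).symmetric_difference(tb.index))
        raise ValueError(f"gene sets differ between cohort TOMs: {diff[:10]}")
    if combiner == "min":
        cons = np.minimum(ta.to_numpy(), tb.to_numpy())
    elif combiner == "mean":
        cons = (ta.to_numpy() + tb.to_numpy()) / 2.0
    else:
        raise ValueError(f"combiner must be 'min' or 'mean', got {combiner!r}")
    d = 1.0 - cons
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 1.0)
    return DissimilarityMatrix(pd.DataFrame(d, index=ta.index, columns=ta.columns))


def cohort_tom(
    study: ExpressionStudy,
    genes: list[str] | None = None,
    beta: float = 6.0,
    mode: str = "unsigned",
    tom: bool = True,
) -> TOMMatrix:
    """Correlation -> adjacency -> TOM for one cohort in one call.

    With ``tom=False`` the adjacency itself is returned as the similarity
    (so ``beta=1, tom=False`` gives plain ``|r|``).
    """
    adj = adjacency(correlation_matrix(study, genes), beta=beta, mode=mode)
    if tom:
        return topological_overlap(adj)
    return TOMMatrix(adj.values, beta, mode)
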