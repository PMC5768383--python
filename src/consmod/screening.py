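"""Differential-expression screening and hub-gene selection.

Per cohort, each gene is tested cancer vs normal with a two-sided
Mann-Whitney U test; the significant sets of the two cohorts are
intersected into the common-gene list, and a consensus-connectivity
filter keeps the genes that are hubs of the co-expression network in
*both* cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import ExpressionStudy
from .network import adjacency, correlation_matrix

#: exact enumeration is used when the smaller group has at most this many
#: samples and the gene has no tied values; beyond that the tie-corrected
#: normal approximation with continuity correction takes over
EXACT_CUTOVER = 8


@dataclass
class DEResult:
    """Per-gene Mann-Whitney statistics for one cohort."""

    table: pd.DataFrame  # index gene_id; columns U, p_value [, p_adjusted]
    alpha: float
    cohort: str = "study"

    @property
    def significant(self) -> list[str]:
        col = "p_adjusted" if "p_adjusted" in self.table.columns else "p_value"
        return list(self.table.index[self.table[col] < self.alpha])

    def p_value(self, gene: str) -> float:
        return float(self.table.loc[gene, "p_value"])


@dataclass
class ScreenSummary:
    """Sizes of the per-cohort significant sets and their intersection."""

    n_sig_a: int
    n_sig_b: int
    n_common: int
    rate_a: float = field(init=False)
    rate_b: float = field(init=False)

    def __post_init__(self) -> None:
        self.rate_a = self.n_common / self.n_sig_a if self.n_sig_a else 0.0
        self.rate_b = self.n_common / self.n_sig_b if self.n_sig_b else 0.0


def mann_whitney_de(
    study: ExpressionStudy,
    alpha: float = 0.05,
    fdr: str | None = None,
) -> DEResult:
    """Two-sided Mann-Whitney U test of cancer vs normal for every gene.

    The exact null distribution is enumerated when ``min(n1, n2) <= 8``
    and the gene has no ties; otherwise the normal approximation with tie
    and continuity corrections is used. ``fdr="bh"`` adds a
    Benjamini-Hochberg adjusted column and bases significance on it.
    """
    cancer = study.samples_in_group("cancer")
    normal = study.samples_in_group("normal")
    if len(cancer) < 2 or len(normal) < 2:
        raise ValueError(
            f"study {study.name!r}: each group needs >= 2 samples "
            f"(cancer={len(cancer)}, normal={len(normal)})"
        )
    xc = study.values[cancer].to_numpy()
    xn = study.values[normal].to_numpy()

    small = min(len(cancer), len(normal)) <= EXACT_CUTOVER
    u_stats = np.empty(study.n_genes)
    p_vals = np.empty(study.n_genes)
    for i in range(study.n_genes):
        a, b = xc[i], xn[i]
        has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
        method = "exact" if small and not has_ties else "asymptotic"
        res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
        u_stats[i], p_vals[i] = res.statistic, min(res.pvalue, 1.0)

    table = pd.DataFrame({"U": u_stats, "p_value": p_vals}, index=study.values.index)
    if fdr == "bh":
        table["p_adjusted"] = multipletests(p_vals, method="fdr_bh")[1]
    elif fdr is not None:
        raise ValueError(f"unknown fdr method {fdr!r}")
    return DEResult(table, alpha=alpha, cohort=study.name)


def common_de_genes(de_a: DEResult, de_b: DEResult) -> tuple[list[str], ScreenSummary]:
    """Intersect the two cohorts' significant sets, in cohort-A order."""
    universe_a, universe_b = set(de_a.table.index), set(de_b.table.index)
    if not universe_a & universe_b:
        raise ValueError("gene universes of the two DE results are disjoint")
    sig_b = set(de_b.significant)
    common = [g for g in de_a.significant if g in sig_b]
    summary = ScreenSummary(
        n_sig_a=len(de_a.significant), n_sig_b=len(de_b.significant), n_common=len(common)
    )
    return common, summary


def consensus_connectivity(
    study_a: ExpressionStudy,
    study_b: ExpressionStudy,
    genes: list[str],
    beta: float = 6.0,
    mode: str = "unsigned",
) -> pd.Series:
    """Per-gene min-over-cohorts soft-threshold connectivity.

    Connectivity is ``k_i = sum_{j != i} a_ij`` of the soft-threshold
    adjacency; the consensus value is the elementwise minimum of the two
    cohorts' connectivities, so a hub must be a hub in both.
    """
    ks = []
    for study in (study_a, study_b):
        adj = adjacency(correlation_matrix(study, genes), beta=beta, mode=mode)
        a = adj.values.to_numpy(copy=True)
        np.fill_diagonal(a, 0.0)
        ks.append(a.sum(axis=1))
    return pd.Series(np.minimum(*ks), index=genes, name="consensus_connectivity")


def consensus_connectivity_filter(
    study_a: ExpressionStudy,
    study_b: ExpressionStudy,
    genes: list[str],
    n_keep: int,
    beta: float = 6.0,
    mode: str = "unsigned",
) -> list[str]:
    """Keep the ``n_keep`` genes with the largest consensus connectivity.

    Ties are broken by lexicographic gene id, so the selection does not
    depend on the order of ``genes``. The result preserves the input order
    of the selected genes.
    """
    if n_keep > len(genes):
        raise ValueError(f"n_keep={n_keep} exceeds the {len(genes)} candidate genes")
    k = consensus_connectivity(study_a, study_b, genes, beta=beta, mode=mode)
    ranked = sorted(genes, key=lambda g: (-k[g], g))
    keep = set(ranked[:n_keep])
    return [g for g in genes if g in keep]
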