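"""Module eigengenes and per-cohort eigengene networks.

The eigengene of a module is the first principal component of its
standardized expression submatrix — a sample-length profile
``E = C1 g1 + C2 g2 + ... + Cn gn`` summarising the module, where the
``C_k`` are the PC1 gene weights. Eigengenes of one cohort are correlated
pairwise into an eigengene network, whose dissimilarity ``1 - cor`` can
itself be clustered to reveal meta-module branches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionStudy
from .modules import Dendrogram, ModuleAssignment, average_linkage_tree


@dataclass
class Eigengene:
    """First principal component of one module in one cohort.

    ``vector`` is the unit-norm sample-length eigengene, sign-oriented so
    it correlates positively with the module's mean standardized profile;
    ``loadings`` are the C_k gene weights in member-gene order;
    ``variance_explained`` is the leading eigenvalue over the trace of the
    module's gene-gene correlation matrix.
    """

    module: str
    cohort: str
    vector: pd.Series
    loadings: pd.Series
    variance_explained: float


@dataclass
class EigengeneSet:
    """All module eigengenes of one cohort, on a shared sample set."""

    cohort: str
    eigengenes: dict[str, Eigengene]

    @property
    def modules(self) -> list[str]:
        return list(self.eigengenes)

    def matrix(self) -> pd.DataFrame:
        """Samples x modules eigengene matrix."""
        return pd.DataFrame({m: e.vector for m, e in self.eigengenes.items()})

    def correlation(self) -> pd.DataFrame:
        """Module x module Pearson correlation of the eigengenes."""
        mat = self.matrix()
        cor = np.atleast_2d(np.corrcoef(mat.to_numpy().T))
        cor = np.clip(cor, -1.0, 1.0)
        np.fill_diagonal(cor, 1.0)
        return pd.DataFrame(cor, index=mat.columns, columns=mat.columns)

    def __getitem__(self, module: str) -> Eigengene:
        return self.eigengenes[module]


@dataclass
class EigengeneNetwork:
    """Correlation network among one cohort's module eigengenes."""

    cohort: str
    correlation: pd.DataFrame
    dissimilarity: pd.DataFrame
    dendrogram: Dendrogram


def module_eigengene(
    study: ExpressionStudy,
    member_genes: list[str],
    module: str = "module",
    drop_constant: bool = False,
) -> Eigengene:
    """Eigengene of one module: PC1 of the standardized member genes.

    Genes are z-scored across samples before the decomposition so the
    eigengene is scale-free across probes. Constant genes cannot be
    standardized and raise, unless ``drop_constant`` removes them (with at
    least 2 members required afterwards).
    """
    if len(member_genes) < 2:
        raise ValueError(f"module {module!r}: needs >= 2 member genes")
    if study.n_samples < 3:
        raise ValueError(f"study {study.name!r}: needs >= 3 samples")
    sub = study.subset_genes(member_genes).values
    x = sub.to_numpy(dtype=float)
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = list(sub.index[sd == 0])
        if not drop_constant:
            raise ValueError(
                f"module {module!r}: constant gene(s) cannot be standardized: {bad}"
            )
        keep = sd > 0
        if keep.sum() < 2:
            raise ValueError(f"module {module!r}: < 2 non-constant genes remain")
        sub, x, sd = sub[keep], x[keep], sd[keep]
    z = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]

    u, s, vt = np.linalg.svd(z, full_matrices=False)
    e = vt[0]  # unit-norm sample direction
    weights = u[:, 0]
    mean_profile = z.mean(axis=0)
    if float(e @ mean_profile) < 0:
        e, weights = -e, -weights
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return Eigengene(
        module=module,
        cohort=study.name,
        vector=pd.Series(e, index=sub.columns, name=module),
        loadings=pd.Series(weights, index=sub.index, name=module),
        variance_explained=var_explained,
    )


def eigengene_set(
    study: ExpressionStudy,
    assignment: ModuleAssignment,
    drop_constant: bool = False,
) -> EigengeneSet:
    """Eigengenes of every non-grey module of one cohort."""
    eigs = {
        color: module_eigengene(study, assignment.members(color), color, drop_constant)
        for color in assignment.colors
    }
    return EigengeneSet(study.name, eigs)


def eigengene_network(eigs: EigengeneSet) -> EigengeneNetwork:
    """Correlation network and meta-module dendrogram of one cohort's
    eigengenes.

    Requires >= 2 modules on a common sample set; dissimilarity is
    ``1 - cor`` clustered by average linkage.
    """
    modules = eigs.modules
    if len(modules) < 2:
        raise ValueError(f"cohort {eigs.cohort!r}: needs >= 2 modules, got {len(modules)}")
    samples = [tuple(e.vector.index) for e in eigs.eigengenes.values()]
    if len(set(samples)) != 1:
        raise ValueError(f"cohort {eigs.cohort!r}: eigengenes have mismatched sample sets")
    cor = eigs.correlation()
    dissim = 1.0 - cor
    np.fill_diagonal(dissim.values, 0.0)
    tree = average_linkage_tree(dissim)
    return EigengeneNetwork(eigs.cohort, cor, dissim, tree)
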