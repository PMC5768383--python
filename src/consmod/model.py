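"""Two-cohort consensus-module analysis as a fit-able model.

:class:`ConsensusModuleModel` is built from two :class:`ExpressionStudy`
objects and the pipeline's tuning parameters; ``fit()`` runs the full
chain — optional Mann-Whitney screening and hub filtering, per-cohort
topological overlap, consensus dissimilarity, average-linkage clustering
with a static height cut, module eigengenes, eigengene networks, and the
cross-cohort preservation statistic — and returns a
:class:`ConsensusModuleResults` carrying every intermediate product plus
a ``summary()`` table.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import screening as scr
from .eigengenes import EigengeneNetwork, EigengeneSet, eigengene_network, eigengene_set
from .io import ExpressionStudy, write_matrix, write_module_assignment
from .modules import Dendrogram, ModuleAssignment, average_linkage_tree, static_cut
from .network import DissimilarityMatrix, TOMMatrix, cohort_tom, consensus_dissimilarity
from .preservation import PreservationResult, preservation_matrix
from .simulate import SimulationConfig, simulate_pair, uniform_factor_cor

#: condition for the degradation-trend harness: many 4-gene modules with
#: equicorrelated factors, at the default (paper-scale) cohort sizes
TREND_CONFIG = SimulationConfig(module_sizes=(4,) * 100, n_genes=440)


@dataclass
class ConsensusModuleModel:
    """Consensus co-expression module analysis of two expression cohorts.

    Parameters
    ----------
    study_a, study_b : ExpressionStudy
        The two cohorts; gene universes must overlap.
    screen : bool
        Run per-cohort Mann-Whitney screening and keep only genes
        significant in both cohorts (default True).
    alpha : float
        Two-sided significance threshold for the screening (default 0.05).
    fdr : {None, "bh"}
        Optional Benjamini-Hochberg adjustment before thresholding.
    n_hub : int or None
        Keep this many top consensus-connectivity hub genes before
        clustering (None keeps all; values larger than the available gene
        count are clamped).
    beta : float
        Soft-threshold power for the adjacency (default 6, unsigned).
    mode : {"unsigned", "signed"}
        Adjacency type.
    tom : bool
        Use topological overlap as the similarity (default); False
        clusters on the consensus adjacency itself, so ``beta=1,
        tom=False`` gives plain ``1 - |r|``.
    combiner : {"min", "mean"}
        Cross-cohort consensus combiner (default the conservative min).
    height : float
        Static cut height on the dissimilarity dendrogram (default 0.95).
    min_size : int
        Minimum module size; smaller branches go grey (default 25).
    """

    study_a: ExpressionStudy
    study_b: ExpressionStudy
    screen: bool = True
    alpha: float = 0.05
    fdr: str | None = None
    n_hub: int | None = 977
    beta: float = 6.0
    mode: str = "unsigned"
    tom: bool = True
    combiner: str = "min"
    height: float = 0.95
    min_size: int = 25
    drop_constant: bool = False

    def __post_init__(self) -> None:
        shared = set(self.study_a.gene_ids) & set(self.study_b.gene_ids)
        if not shared:
            raise ValueError("the two studies share no gene ids")

    @classmethod
    def from_tsv(
        cls,
        expr_a: str | Path,
        meta_a: str | Path,
        expr_b: str | Path,
        meta_b: str | Path,
        name_a: str = "A",
        name_b: str = "B",
        **params,
    ) -> "ConsensusModuleModel":
        """Build the model straight from expression + metadata TSV files."""
        from .io import read_expression_tsv

        return cls(
            read_expression_tsv(expr_a, meta_a, name=name_a),
            read_expression_tsv(expr_b, meta_b, name=name_b),
            **params,
        )

    @classmethod
    def from_simulation(
        cls, config: SimulationConfig | None = None, **params
    ) -> tuple["ConsensusModuleModel", "object"]:
        """Simulate a planted-module cohort pair and wrap it in a model.

        Returns ``(model, truth)`` so detected modules can be scored
        against the planted labels.
        """
        study_a, study_b, truth = simulate_pair(config or SimulationConfig())
        return cls(study_a, study_b, **params), truth

    # -- pipeline --------------------------------------------------------
    def fit(self) -> "ConsensusModuleResults":
        """Run the full consensus-module pipeline."""
        shared = [g for g in self.study_a.gene_ids if g in set(self.study_b.gene_ids)]

        de_a = de_b = screen_summary = None
        genes = shared
        if self.screen:
            de_a = scr.mann_whitney_de(self.study_a, alpha=self.alpha, fdr=self.fdr)
            de_b = scr.mann_whitney_de(self.study_b, alpha=self.alpha, fdr=self.fdr)
            common, screen_summary = scr.common_de_genes(de_a, de_b)
            genes = [g for g in common if g in set(shared)]
        if len(genes) < 2:
            raise ValueError(
                f"only {len(genes)} gene(s) survive screening; nothing to cluster"
            )

        if self.n_hub is not None and self.n_hub < len(genes):
            genes = scr.consensus_connectivity_filter(
                self.study_a, self.study_b, genes, n_keep=self.n_hub,
                beta=self.beta, mode=self.mode,
            )

        tom_a = cohort_tom(self.study_a, genes, beta=self.beta, mode=self.mode, tom=self.tom)
        tom_b = cohort_tom(self.study_b, genes, beta=self.beta, mode=self.mode, tom=self.tom)
        dissim = consensus_dissimilarity(tom_a, tom_b, combiner=self.combiner)
        tree = average_linkage_tree(dissim)
        assignment = static_cut(tree, height=self.height, min_size=self.min_size)

        eigs_a = eigs_b = net_a = net_b = preservation = None
        if assignment.colors:
            eigs_a = eigengene_set(self.study_a, assignment, self.drop_constant)
            eigs_b = eigengene_set(self.study_b, assignment, self.drop_constant)
            preservation = preservation_matrix(eigs_a, eigs_b)
            if len(assignment.colors) >= 2:
                net_a = eigengene_network(eigs_a)
                net_b = eigengene_network(eigs_b)

        return ConsensusModuleResults(
            model=self,
            genes=genes,
            de_a=de_a,
            de_b=de_b,
            screen_summary=screen_summary,
            tom_a=tom_a,
            tom_b=tom_b,
            dissimilarity=dissim,
            tree=tree,
            modules=assignment,
            eigengenes_a=eigs_a,
            eigengenes_b=eigs_b,
            eigengene_network_a=net_a,
            eigengene_network_b=net_b,
            preservation=preservation,
        )

    @staticmethod
    def overall_preservation_for(
        rewire_fraction: float,
        seed: int,
        config: SimulationConfig | None = None,
        factor_rho: float = 0.3,
        beta: float = 6.0,
        mode: str = "unsigned",
        height: float = 0.95,
        min_size: int = 3,
    ) -> float:
        """Overall D of one simulated pair at one degradation level.

        The standard ``run_pipeline`` callable for
        :func:`consmod.preservation.preservation_trend`. The harness is
        designed for *sensitivity to intermediate degradation*: module
        eigengenes of large modules are still estimable from the genes
        left intact until rewiring is nearly total, so the default
        condition plants many small (4-gene) modules, where re-drawing
        half the members materially corrupts the eigengene, and gives
        every factor pair a uniform correlation (``factor_rho``) so each
        module pair carries relational signal that degradation erodes.
        Modules are defined on the reference cohort A's own topological
        overlap — the standard reference/test design for preservation —
        and the two cohorts' eigengene networks are then compared.
        (Detecting on the *degraded consensus* instead would, by
        construction, destroy the modules themselves as rewiring grows,
        leaving nothing to evaluate.)
        """
        from dataclasses import replace

        base = config or TREND_CONFIG
        cfg = replace(base, rewire_fraction=rewire_fraction, seed=seed)
        factor_cor = uniform_factor_cor(len(cfg.module_sizes), rho=factor_rho)
        study_a, study_b, _ = simulate_pair(cfg, factor_cor=factor_cor)

        tom_a = cohort_tom(study_a, beta=beta, mode=mode)
        d = 1.0 - tom_a.values.to_numpy()
        np.fill_diagonal(d, 0.0)
        dissim = DissimilarityMatrix(
            pd.DataFrame(d, index=tom_a.values.index, columns=tom_a.values.columns)
        )
        assignment = static_cut(
            average_linkage_tree(dissim), height=height, min_size=min_size
        )
        if not assignment.colors:
            raise RuntimeError(
                f"no modules detected in reference cohort at "
                f"rewire={rewire_fraction}, seed={seed}"
            )
        eigs_a = eigengene_set(study_a, assignment)
        eigs_b = eigengene_set(study_b, assignment)
        return preservation_matrix(eigs_a, eigs_b).overall


@dataclass
class ConsensusModuleResults:
    """Everything the fitted pipeline produced."""

    model: ConsensusModuleModel
    genes: list[str]
    de_a: scr.DEResult | None
    de_b: scr.DEResult | None
    screen_summary: scr.ScreenSummary | None
    tom_a: TOMMatrix
    tom_b: TOMMatrix
    dissimilarity: DissimilarityMatrix
    tree: Dendrogram
    modules: ModuleAssignment
    eigengenes_a: EigengeneSet | None
    eigengenes_b: EigengeneSet | None
    eigengene_network_a: EigengeneNetwork | None
    eigengene_network_b: EigengeneNetwork | None
    preservation: PreservationResult | None
    _summary_cache: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def module_sizes(self) -> dict[str, int]:
        return self.modules.sizes

    def summary(self) -> str:
        """Human-readable account of the fit, one row per module."""
        m = self.model
        lines = [
            "Consensus co-expression module analysis",
            "=" * 55,
            f"Cohorts: {m.study_a.name} ({m.study_a.n_samples} samples), "
            f"{m.study_b.name} ({m.study_b.n_samples} samples)",
            f"Genes clustered: {len(self.genes)}",
        ]
        if self.screen_summary is not None:
            s = self.screen_summary
            lines.append(
                f"Screening (alpha={m.alpha}): {s.n_sig_a} sig in A, {s.n_sig_b} sig in B, "
                f"{s.n_common} common (rates {s.rate_a:.3f} / {s.rate_b:.3f})"
            )
        lines.append(
            f"Network: beta={m.beta} ({m.mode}), "
            f"{'TOM' if m.tom else 'adjacency'} similarity, combiner={m.combiner}"
        )
        lines.append(f"Cut: height={m.height}, min module size={m.min_size}")
        lines.append("")
        lines.append(self.module_table().to_string(index=False))
        if self.preservation is not None:
            lines.append("")
            lines.append(
                f"Overall preservation D = {self.preservation.overall:.6g} "
                f"(rounded {self.preservation.overall_rounded:.2f})"
            )
        return "\n".join(lines)

    def module_table(self) -> pd.DataFrame:
        """Per-module size, variance explained per cohort, and D_i."""
        rows = []
        sizes = self.modules.sizes
        per_d = self.preservation.per_module if self.preservation is not None else None
        for color in self.modules.colors:
            row = {"module": color, "n_genes": sizes[color]}
            if self.eigengenes_a is not None:
                row[f"var_expl_{self.model.study_a.name}"] = round(
                    self.eigengenes_a[color].variance_explained, 4
                )
                row[f"var_expl_{self.model.study_b.name}"] = round(
                    self.eigengenes_b[color].variance_explained, 4
                )
            if per_d is not None:
                row["D"] = round(float(per_d[color]), 4)
            rows.append(row)
        if "grey" in sizes:
            rows.append({"module": "grey", "n_genes": sizes["grey"]})
        return pd.DataFrame(rows)

    # -- persistence -----------------------------------------------------
    def save(self, directory: str | Path, save_matrices: bool = False) -> dict[str, Path]:
        """Write the standard output files under ``directory``."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        paths["modules"] = write_module_assignment(
            self.modules.assignment, directory / "modules.tsv"
        )
        paths["dendrogram"] = self.tree.to_json(directory / "dendrogram.json")
        if save_matrices:
            paths["tom_a"] = write_matrix(self.tom_a.values, directory / "tom_a.tsv")
            paths["tom_b"] = write_matrix(self.tom_b.values, directory / "tom_b.tsv")
            paths["consensus_dissim"] = write_matrix(
                self.dissimilarity.values, directory / "consensus_dissim.tsv"
            )
        for eigs, label in ((self.eigengenes_a, "a"), (self.eigengenes_b, "b")):
            if eigs is None:
                continue
            p = directory / f"eigengenes_{label}.tsv"
            eigs.matrix().rename_axis("sample_id").to_csv(p, sep="\t")
            paths[f"eigengenes_{label}"] = p
        for net, label in ((self.eigengene_network_a, "a"), (self.eigengene_network_b, "b")):
            if net is None:
                continue
            p = directory / f"eigengene_network_{label}.tsv"
            net.correlation.rename_axis("module").to_csv(p, sep="\t")
            paths[f"eigengene_network_{label}"] = p
        if self.eigengenes_a is not None:
            var = {
                self.model.study_a.name: {
                    c: self.eigengenes_a[c].variance_explained for c in self.modules.colors
                },
                self.model.study_b.name: {
                    c: self.eigengenes_b[c].variance_explained for c in self.modules.colors
                },
            }
            p = directory / "var_explained.json"
            p.write_text(json.dumps(var, indent=1))
            paths["var_explained"] = p
        if self.preservation is not None:
            p = directory / "preservation.tsv"
            self.preservation.matrix.rename_axis("module").to_csv(p, sep="\t")
            paths["preservation"] = p
            summary = {
                "per_module_D": {
                    c: float(v) for c, v in self.preservation.per_module.items()
                },
                "overall_D": self.preservation.overall,
                "overall_D_rounded": self.preservation.overall_rounded,
            }
            p = directory / "preservation_summary.json"
            p.write_text(json.dumps(summary, indent=1))
            paths["preservation_summary"] = p
        return paths

    # -- plotting --------------------------------------------------------
    def plot_dendrogram(self, ax=None):
        """Gene dendrogram with the cut height marked."""
        import matplotlib.pyplot as plt
        from scipy.cluster.hierarchy import dendrogram as scipy_dendrogram

        if ax is None:
            _, ax = plt.subplots(figsize=(10, 4))
        scipy_dendrogram(self.tree.linkage, no_labels=True, ax=ax, color_threshold=0.0)
        ax.axhline(self.model.height, color="red", linestyle="--", linewidth=1)
        ax.set_ylabel("consensus dissimilarity")
        return ax

    def plot_preservation(self, ax=None):
        """Bar chart of per-module preservation D_i, bars in module colours."""
        import matplotlib.pyplot as plt

        if self.preservation is None:
            raise ValueError("no preservation result to plot")
        if ax is None:
            _, ax = plt.subplots(figsize=(6, 4))
        d = self.preservation.per_module
        ax.bar(range(len(d)), d.to_numpy(), color=list(d.index), edgecolor="black")
        ax.set_xticks(range(len(d)), list(d.index), rotation=45, ha="right")
        ax.set_ylim(0, 1.05)
        ax.set_ylabel("preservation D")
        return ax
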