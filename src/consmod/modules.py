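"""Module detection: average-linkage clustering and the static height cut.

Genes are clustered by average linkage (UPGMA) on the consensus
dissimilarity; the tree is cut at a fixed merge height (default 0.95 on
the dissimilarity scale), branches below the cut become candidate
modules, candidates smaller than ``min_size`` (default 25) are relabelled
grey, and surviving modules are named by the standard colour palette in
decreasing-size order (turquoise = largest).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .network import DissimilarityMatrix

GREY = "grey"

#: colour order follows the convention of the co-expression-module
#: literature: modules are named by decreasing size down this list
COLOR_PALETTE = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
)


@dataclass
class Dendrogram:
    """An agglomerative merge tree over genes.

    ``linkage`` is the standard (n-1) x 4 merge table (children ids,
    merge height, cluster size); heights are non-decreasing for average
    linkage on a proper dissimilarity.
    """

    linkage: np.ndarray
    gene_ids: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    @property
    def max_height(self) -> float:
        return float(self.heights[-1]) if len(self.linkage) else 0.0

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "gene_ids": self.gene_ids,
            "merges": [[int(a), int(b)] for a, b in self.linkage[:, :2]],
            "heights": [float(h) for h in self.heights],
            "sizes": [int(s) for s in self.linkage[:, 3]],
        }
        path.write_text(json.dumps(payload, indent=1))
        return path


@dataclass
class ModuleAssignment:
    """Gene -> colour label partition; ``grey`` collects unassigned genes."""

    assignment: dict[str, str]
    color_order: list[str] = field(default_factory=list)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.assignment)

    @property
    def colors(self) -> list[str]:
        """Non-grey module colours, largest module first."""
        return list(self.color_order)

    @property
    def sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for label in self.assignment.values():
            out[label] = out.get(label, 0) + 1
        return out

    def members(self, color: str) -> list[str]:
        return [g for g, c in self.assignment.items() if c == color]

    def labels(self, genes: list[str] | None = None) -> list[str]:
        genes = genes if genes is not None else self.gene_ids
        return [self.assignment[g] for g in genes]

    def __getitem__(self, gene: str) -> str:
        return self.assignment[gene]


def average_linkage_tree(dissim: DissimilarityMatrix | pd.DataFrame) -> Dendrogram:
    """UPGMA merge tree of a gene x gene dissimilarity.

    Deterministic for a given input; exact average linkage (every merge
    height is the mean pairwise dissimilarity between the merged clusters).
    """
    df = dissim.values if isinstance(dissim, DissimilarityMatrix) else dissim
    n = df.shape[0]
    if n < 2:
        raise ValueError(f"need >= 2 genes to cluster, got {n}")
    d = df.to_numpy(dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("dissimilarity matrix is not symmetric")
    condensed = squareform(d, checks=False)
    z = linkage(condensed, method="average")
    return Dendrogram(z, list(df.index))


def cut_tree_at_height(tree: Dendrogram, height: float) -> list[list[str]]:
    """Branches of the tree merged at heights <= ``height``, as gene lists.

    Candidate clusters are returned in order of their first gene.
    """
    if height <= 0:
        raise ValueError(f"cut height must be > 0, got {height}")
    flat = fcluster(tree.linkage, t=height, criterion="distance")
    clusters: dict[int, list[str]] = {}
    for gene, cid in zip(tree.gene_ids, flat):
        clusters.setdefault(int(cid), []).append(gene)
    order = sorted(clusters, key=lambda cid: tree.gene_ids.index(clusters[cid][0]))
    return [clusters[cid] for cid in order]


def assign_colors(candidates: list[list[str]]) -> ModuleAssignment:
    """Name candidate modules by decreasing size down the colour palette.

    Ties are broken by first-gene input order. If candidates outnumber the
    palette, extra modules are labelled ``module_<k>``.
    """
    indexed = sorted(range(len(candidates)), key=lambda i: (-len(candidates[i]), i))
    assignment: dict[str, str] = {}
    order: list[str] = []
    for rank, i in enumerate(indexed):
        color = (
            COLOR_PALETTE[rank]
            if rank < len(COLOR_PALETTE)
            else f"module_{rank + 1}"
        )
        order.append(color)
        for g in candidates[i]:
            assignment[g] = color
    return ModuleAssignment(assignment, order)


def static_cut(tree: Dendrogram, height: float = 0.95, min_size: int = 25) -> ModuleAssignment:
    """Fixed-height cut with a minimum module size.

    Branches merged below ``height`` become candidate modules; candidates
    with fewer than ``min_size`` genes are relabelled grey; the rest are
    coloured by :func:`assign_colors`. Every input gene receives exactly
    one label.
    """
    if min_size < 1:
        raise ValueError(f"min_size must be >= 1, got {min_size}")
    candidates = cut_tree_at_height(tree, height)
    kept = [c for c in candidates if len(c) >= min_size]
    grey_genes = [g for c in candidates if len(c) < min_size for g in c]
    colored = assign_colors(kept)
    assignment = {g: colored.assignment[g] for g in tree.gene_ids if g in colored.assignment}
    for g in grey_genes:
        assignment[g] = GREY
    # restore input gene order
    assignment = {g: assignment[g] for g in tree.gene_ids}
    return ModuleAssignment(assignment, colored.color_order)
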