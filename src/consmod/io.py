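"""Expression matrix and metadata I/O.

The on-disk dialect is plain TSV. An expression file has a ``gene_id``
first column (``ID_REF`` is accepted for series-matrix-style exports) and
one column per sample of log-scale intensities. A metadata file has
columns ``sample_id`` and ``group`` with group values ``cancer`` or
``normal``. Metadata order is authoritative: the loaded study's samples
follow the metadata file, and matrix columns absent from the metadata are
dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("cancer", "normal")

#: significant digits used by the TSV writers; 17 makes float64 round-trips
#: exact, comfortably beyond the 12-digit contract
TSV_PRECISION = 17


@dataclass
class ExpressionStudy:
    """A genes x samples matrix of log-scale intensities with group labels.

    Parameters
    ----------
    values : DataFrame
        Rows indexed by unique gene ids, columns by unique sample ids.
    group : mapping
        ``sample_id -> "cancer" | "normal"`` covering every sample.
    name : str
        Cohort label, e.g. ``"HNC"`` or ``"CC"``.
    """

    values: pd.DataFrame
    group: dict[str, str] = field(default_factory=dict)
    name: str = "study"

    def __post_init__(self) -> None:
        self.values = pd.DataFrame(self.values).astype(float)
        if self.values.index.duplicated().any():
            dups = sorted(self.values.index[self.values.index.duplicated()].unique())
            raise ValueError(f"duplicate gene ids: {dups}")
        if self.values.columns.duplicated().any():
            dups = sorted(self.values.columns[self.values.columns.duplicated()].unique())
            raise ValueError(f"duplicate sample ids: {dups}")
        missing = [s for s in self.values.columns if s not in self.group]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        bad = {s: g for s, g in self.group.items() if g not in GROUPS}
        if bad:
            raise ValueError(f"group labels must be one of {GROUPS}, got {bad}")
        if self.values.isna().any().any():
            rows = list(self.values.index[self.values.isna().any(axis=1)][:5])
            raise ValueError(
                f"missing values in expression matrix (first offending genes: {rows}); "
                "load with impute='row-median' to fill them"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        return [s for s in self.sample_ids if self.group[s] == group]

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionStudy":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from study {self.name!r}: {missing[:10]}")
        return ExpressionStudy(self.values.loc[genes], dict(self.group), self.name)


def read_expression_tsv(
    path: str | Path,
    metadata_path: str | Path,
    name: str | None = None,
    impute: str | None = None,
) -> ExpressionStudy:
    """Load an expression TSV plus its sample metadata.

    Samples are restricted to, and ordered by, the metadata file. A sample
    listed in the metadata but absent from the matrix is an error; a matrix
    column absent from the metadata is dropped with a warning.

    Parameters
    ----------
    impute : {None, "row-median"}
        Off by default: missing cells raise. ``"row-median"`` fills each
        gene's missing cells with that gene's median over observed samples.
    """
    path, metadata_path = Path(path), Path(metadata_path)
    mat = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if mat.index.name not in (None, "gene_id", "ID_REF"):
        raise ValueError(
            f"{path}: first column must be 'gene_id' (or 'ID_REF'), got {mat.index.name!r}"
        )
    mat.index = mat.index.astype(str)
    mat.index.name = "gene_id"
    if mat.index.duplicated().any():
        dups = sorted(mat.index[mat.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicated gene rows: {dups}")

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in meta.columns:
            raise ValueError(f"{metadata_path}: missing required column {col!r}")

    absent = [s for s in meta["sample_id"] if s not in mat.columns]
    if absent:
        raise ValueError(f"samples in metadata missing from {path}: {absent}")
    extra = [s for s in mat.columns if s not in set(meta["sample_id"])]
    if extra:
        logger.warning("dropping %d matrix sample(s) absent from metadata: %s", len(extra), extra)
    mat = mat[list(meta["sample_id"])]

    non_numeric = mat.apply(pd.to_numeric, errors="coerce")
    introduced = non_numeric.isna() & mat.notna()
    if introduced.any().any():
        r, c = np.argwhere(introduced.values)[0]
        raise ValueError(
            f"{path}: non-numeric value {mat.iat[r, c]!r} at gene {mat.index[r]!r}, "
            f"sample {mat.columns[c]!r}"
        )
    mat = non_numeric

    if impute == "row-median":
        mat = mat.apply(lambda row: row.fillna(row.median()), axis=1)
    elif impute is not None:
        raise ValueError(f"unknown impute method {impute!r}")

    group = dict(zip(meta["sample_id"], meta["group"]))
    return ExpressionStudy(mat, group, name or path.stem)


def collapse_probes(
    study: ExpressionStudy,
    probe_to_gene: Mapping[str, str],
    method: str = "max_mean",
) -> ExpressionStudy:
    """Collapse probe-level rows to one row per gene symbol.

    ``max_mean`` (the co-expression-network convention) keeps, for each
    gene, the probe with the highest mean expression; ``mean`` averages all
    of a gene's probes column-wise. Probes missing from the mapping are
    dropped. Output genes are ordered by first appearance of their probes.
    """
    if not probe_to_gene:
        raise ValueError("empty probe-to-gene mapping")
    if method not in ("max_mean", "mean"):
        raise ValueError(f"method must be 'max_mean' or 'mean', got {method!r}")

    mapped = [p for p in study.gene_ids if p in probe_to_gene]
    order: list[str] = []
    seen: set[str] = set()
    for p in mapped:
        g = probe_to_gene[p]
        if g not in seen:
            seen.add(g)
            order.append(g)

    rows = {}
    sub = study.values.loc[mapped]
    genes_of = pd.Series([probe_to_gene[p] for p in mapped], index=sub.index)
    for gene, block in sub.groupby(genes_of, sort=False):
        if method == "max_mean":
            rows[gene] = block.loc[block.mean(axis=1).idxmax()]
        else:
            rows[gene] = block.mean(axis=0)
    out = pd.DataFrame([rows[g] for g in order], index=pd.Index(order, name="gene_id"))
    return ExpressionStudy(out, dict(study.group), study.name)


# -- writers -----------------------------------------------------------------

def _float_fmt(x: float) -> str:
    return f"{x:.{TSV_PRECISION}g}"


def write_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    """Write a DataFrame as TSV, lossless to 12 significant digits."""
    path = Path(path)
    if str(path) == "":
        raise ValueError("empty output path")
    df = pd.DataFrame(matrix)
    if df.index.name is None:
        df = df.rename_axis("gene_id")
    df.to_csv(path, sep="\t", float_format=f"%.{TSV_PRECISION}g")
    return path


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    df.index = df.index.astype(str)
    return df


def write_module_assignment(assignment: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(
        {"gene_id": list(assignment.keys()), "module": list(assignment.values())}
    )
    df.to_csv(path, sep="\t", index=False)
    return path


def read_module_assignment(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["gene_id", "module"]:
        raise ValueError(f"{path}: expected columns gene_id, module, got {list(df.columns)}")
    return dict(zip(df["gene_id"], df["module"]))


def write_metadata(group: Mapping[str, str], path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"sample_id": list(group.keys()), "group": list(group.values())}).to_csv(
        path, sep="\t", index=False
    )
    return path
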