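"""Per-module over-representation against user-supplied gene sets.

For each (module, term) pair a 2x2 table is formed on a background
universe and scored with the one-sided hypergeometric (Fisher) upper
tail; the EASE score is the same tail with the overlap decremented by
one — a conservative variant that cannot call a single-gene overlap
significant. Benjamini-Hochberg adjustment is applied within each module
across terms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


@dataclass
class GeneSetCollection:
    """Named gene sets, e.g. parsed from a GMT file."""

    sets: dict[str, set[str]]
    source: str = ""

    @property
    def names(self) -> list[str]:
        return list(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> set[str]:
        return self.sets[name]


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: per line, set name, description, then members.

    Duplicate members within a set are counted once; duplicate set names
    or structurally short lines are errors reported with line numbers.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    lines = path.read_text().splitlines()
    if not any(line.strip() for line in lines):
        raise ValueError(f"{path}: empty GMT file")
    for lineno, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(
                f"{path}:{lineno}: GMT line needs name, description and >= 1 member"
            )
        name = fields[0]
        if name in sets:
            raise ValueError(f"{path}:{lineno}: duplicate set name {name!r}")
        members = {g for g in fields[2:] if g}
        if not members:
            raise ValueError(f"{path}:{lineno}: set {name!r} has no members")
        sets[name] = members
    return GeneSetCollection(sets, source=str(path))


def _fisher_upper_tail(k: int, n_background: int, n_term: int, n_module: int) -> float:
    """P(overlap >= k) under the hypergeometric null."""
    if k <= 0:
        return 1.0
    return float(min(1.0, hypergeom.sf(k - 1, n_background, n_term, n_module)))


def ease_enrichment(
    module_genes: Iterable[str],
    background_genes: Iterable[str],
    collection: GeneSetCollection,
    module: str = "module",
) -> pd.DataFrame:
    """Score every term of the collection against one module.

    Term sets are intersected with the background universe before the 2x2
    table is built. Returns one row per term with overlap count, sizes,
    Fisher p, EASE p (overlap decremented by one; p = 1 when k <= 1) and
    the BH-adjusted EASE p across the collection's terms.
    """
    module_set = set(module_genes)
    background = set(background_genes)
    absent = sorted(module_set - background)
    if absent:
        raise ValueError(f"module genes absent from background: {absent[:10]}")
    n_bg, n_mod = len(background), len(module_set)

    rows = []
    for name in collection.names:
        term = collection[name] & background
        k = len(module_set & term)
        p_fisher = _fisher_upper_tail(k, n_bg, len(term), n_mod)
        p_ease = _fisher_upper_tail(k - 1, n_bg, len(term), n_mod)
        rows.append(
            {
                "module": module,
                "term": name,
                "overlap": k,
                "module_size": n_mod,
                "term_size": len(term),
                "background_size": n_bg,
                "p_fisher": p_fisher,
                "p_ease": p_ease,
            }
        )
    table = pd.DataFrame(rows)
    table["p_bh"] = multipletests(table["p_ease"].to_numpy(), method="fdr_bh")[1]
    return table


def enrich_modules(
    assignment: Mapping[str, str],
    collection: GeneSetCollection,
    background_genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """EASE enrichment of every non-grey module; BH within each module.

    The default background is the set of genes actually clustered (every
    gene carrying a label, grey included).
    """
    background = set(background_genes) if background_genes is not None else set(assignment)
    tables = []
    modules = sorted({c for c in assignment.values() if c != "grey"})
    for color in modules:
        members = [g for g, c in assignment.items() if c == color]
        tables.append(ease_enrichment(members, background, collection, module=color))
    if not tables:
        return pd.DataFrame(
            columns=[
                "module", "term", "overlap", "module_size", "term_size",
                "background_size", "p_fisher", "p_ease", "p_bh",
            ]
        )
    return pd.concat(tables, ignore_index=True)
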