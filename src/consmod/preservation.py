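"""Eigengene-network preservation between two cohorts.

For modules i and j with eigengenes E in cohorts A and B,

    preserv_ij(A, B) = 1 - |cor(Ei(A), Ej(A)) - cor(Ei(B), Ej(B))| / 2

is 1 when the two modules relate identically in both cohorts and 0 when
their eigengene correlations are maximally discrepant (+1 vs -1). The
per-module index D_i averages preserv_ij over j != i, and the overall
index D averages the D_i — equivalently the mean off-diagonal of the
preservation matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .eigengenes import EigengeneSet


@dataclass
class PreservationResult:
    """Pairwise preservation matrix with per-module and overall indices."""

    matrix: pd.DataFrame  # module x module, P_ii = 1
    cohort_a: str
    cohort_b: str

    @property
    def modules(self) -> list[str]:
        return list(self.matrix.index)

    @property
    def per_module(self) -> pd.Series:
        """D_i: mean preservation of module i with every other module."""
        p = self.matrix.to_numpy()
        n = p.shape[0]
        if n == 1:
            return pd.Series([1.0], index=self.matrix.index, name="D")
        off = p.sum(axis=1) - np.diag(p)
        return pd.Series(off / (n - 1), index=self.matrix.index, name="D")

    @property
    def overall(self) -> float:
        """Overall D: unweighted mean of the per-module indices."""
        return overall_preservation(self.per_module.to_numpy())

    @property
    def overall_rounded(self) -> float:
        return round(self.overall, 2)


def preservation_matrix(eigs_a: EigengeneSet, eigs_b: EigengeneSet) -> PreservationResult:
    """Pairwise preservation of the eigengene networks of two cohorts.

    Both cohorts must carry the same module colours; each cohort's
    eigengene correlations are computed on that cohort's own samples.
    """
    only_a = set(eigs_a.modules) - set(eigs_b.modules)
    only_b = set(eigs_b.modules) - set(eigs_a.modules)
    if only_a or only_b:
        raise ValueError(
            f"modules present in one cohort only: "
            f"{sorted(only_a)} (A), {sorted(only_b)} (B)"
        )
    modules = eigs_a.modules
    cor_a = eigs_a.correlation().loc[modules, modules].to_numpy()
    cor_b = eigs_b.correlation().loc[modules, modules].to_numpy()
    p = 1.0 - np.abs(cor_a - cor_b) / 2.0
    np.fill_diagonal(p, 1.0)
    return PreservationResult(
        pd.DataFrame(p, index=modules, columns=modules),
        cohort_a=eigs_a.cohort,
        cohort_b=eigs_b.cohort,
    )


def overall_preservation(per_module_d: Sequence[float]) -> float:
    """Unweighted mean of the per-module preservation indices."""
    d = np.asarray(per_module_d, dtype=float)
    if d.size == 0:
        raise ValueError("no per-module preservation values given")
    return float(d.mean())


def preservation_trend(
    rewire_levels: Sequence[float],
    seeds: Sequence[int],
    run_pipeline: Callable[[float, int], float],
) -> pd.DataFrame:
    """Mean overall preservation at each cross-cohort degradation level.

    ``run_pipeline(rewire_fraction, seed)`` must run the full analysis and
    return the overall D; the standard callable is
    ``ConsensusModuleModel.overall_preservation_for`` (see ``model``).
    Returns a table of (rewire_fraction, mean_D, n_runs) plus the Spearman
    correlation between level and mean D in ``.attrs["spearman_rho"]``.
    """
    if len(rewire_levels) < 2:
        raise ValueError("need >= 2 rewire levels")
    if len(seeds) < 3:
        raise ValueError("need >= 3 seeds per level")
    rows = []
    for level in rewire_levels:
        ds = []
        for seed in seeds:
            try:
                d = run_pipeline(level, seed)
            except Exception as exc:  # noqa: BLE001 - annotate failing cell
                raise RuntimeError(
                    f"pipeline failed at rewire={level}, seed={seed}: {exc}"
                ) from exc
            ds.append(d)
        rows.append({"rewire_fraction": level, "mean_D": float(np.mean(ds)), "n_runs": len(ds)})
    table = pd.DataFrame(rows)
    rho = spearmanr(table["rewire_fraction"], table["mean_D"]).statistic
    table.attrs["spearman_rho"] = float(rho)
    return table
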