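"""Synthetic paired expression cohorts with planted co-expression modules.

The generator emulates the structure of a two-cohort microarray study:
two studies of unequal size (defaults mirror 13 cancer / 14 normal and
8 / 8 samples), genes organised into latent-factor modules shared across
cohorts, additive cancer-vs-normal shifts for a subset of module genes,
and i.i.d. background noise genes.

Each module ``m`` has one latent factor ``u_m`` drawn per sample; a member
gene is ``noise_sd * (loading * u_m + sqrt(1 - loading^2) * eps)`` around a
constant baseline, so the population correlation between two members is
``loading**2``. A ``rewire_fraction`` of each module's genes are re-drawn
as background noise in cohort B only, degrading cross-cohort preservation
from 1 down towards the background level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import ExpressionStudy, write_matrix, write_metadata

BACKGROUND = "background"

#: baseline log2 intensity around which genes fluctuate
BASELINE = 8.0


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the paired-cohort generator.

    Defaults plant eight 40-gene modules among 400 genes at loading 0.9 —
    the scale at which the downstream pipeline is exercised — with half the
    module genes shifted by one intensity unit in cancer samples.
    """

    n_genes: int = 400
    module_sizes: tuple[int, ...] = (40,) * 8
    n_cancer_a: int = 13
    n_normal_a: int = 14
    n_cancer_b: int = 8
    n_normal_b: int = 8
    factor_loading: float = 0.9
    de_fraction: float = 0.5
    de_effect: float = 1.0
    noise_sd: float = 1.0
    rewire_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError(f"n_genes must be >= 0, got {self.n_genes}")
        sizes = tuple(int(s) for s in self.module_sizes)
        object.__setattr__(self, "module_sizes", sizes)
        if any(s < 2 for s in sizes):
            raise ValueError(f"module_sizes entries must be >= 2, got {sizes}")
        if sum(sizes) > self.n_genes:
            raise ValueError(
                f"module_sizes sum to {sum(sizes)} > n_genes={self.n_genes}"
            )
        for name in ("n_cancer_a", "n_normal_a", "n_cancer_b", "n_normal_b"):
            if getattr(self, name) < 2:
                raise ValueError(f"{name} must be >= 2, got {getattr(self, name)}")
        if not 0.0 < self.factor_loading <= 1.0:
            raise ValueError(f"factor_loading must be in (0, 1], got {self.factor_loading}")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError(f"de_fraction must be in [0, 1], got {self.de_fraction}")
        if self.de_effect < 0:
            raise ValueError(f"de_effect must be >= 0, got {self.de_effect}")
        if self.noise_sd <= 0:
            raise ValueError(f"noise_sd must be > 0, got {self.noise_sd}")
        if not 0.0 <= self.rewire_fraction <= 1.0:
            raise ValueError(
                f"rewire_fraction must be in [0, 1], got {self.rewire_fraction}"
            )


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated pair.

    ``module`` maps every generated gene to its planted module label
    (``"module_1"``, ... ) or ``"background"``; ``is_de_a``/``is_de_b``
    flag genes carrying a cancer-vs-normal shift in each cohort;
    ``rewired`` names the genes degraded to background in cohort B.
    """

    module: dict[str, str]
    is_de_a: dict[str, bool]
    is_de_b: dict[str, bool]
    rewired: set[str] = field(default_factory=set)
    rewire_fraction: float = 0.0

    def labels(self, genes: list[str]) -> list[str]:
        return [self.module[g] for g in genes]


def _sample_cohort(
    rng: np.random.Generator,
    cfg: SimulationConfig,
    n_cancer: int,
    n_normal: int,
    module_of: np.ndarray,
    de_mask: np.ndarray,
    rewired_mask: np.ndarray,
    factor_cor: np.ndarray | None,
) -> np.ndarray:
    """Draw one cohort's genes x samples matrix.

    ``module_of`` holds the module index per gene (-1 = background);
    rewired genes are treated as background. ``factor_cor`` optionally
    correlates the module factors (used to design eigengene meta-branches).
    """
    n_samples = n_cancer + n_normal
    n_modules = int(module_of.max()) + 1 if module_of.size and module_of.max() >= 0 else 0
    if n_modules:
        if factor_cor is None:
            factors = rng.standard_normal((n_modules, n_samples))
        else:
            chol = np.linalg.cholesky(factor_cor)
            factors = chol @ rng.standard_normal((n_modules, n_samples))
    lam = cfg.factor_loading
    resid = np.sqrt(1.0 - lam**2)

    x = np.empty((len(module_of), n_samples))
    for i, m in enumerate(module_of):
        eps = rng.standard_normal(n_samples)
        if m >= 0 and not rewired_mask[i]:
            x[i] = lam * factors[m] + resid * eps
        else:
            x[i] = eps
    x = BASELINE + cfg.noise_sd * x
    x[np.ix_(de_mask, np.arange(n_cancer))] += cfg.de_effect
    return x


def uniform_factor_cor(n_modules: int, rho: float) -> np.ndarray:
    """Equicorrelated module factors: every pair of factors correlates rho.

    Gives every module pair a non-trivial eigengene relationship, so
    cross-cohort degradation has relational structure to erode.
    """
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"factor correlation must be in [0, 1), got {rho}")
    cor = np.full((n_modules, n_modules), rho)
    np.fill_diagonal(cor, 1.0)
    return cor


def meta_branch_factor_cor(n_modules: int, within: float = 0.8) -> np.ndarray:
    """Module-factor correlation with two meta-branches.

    The first half of the modules and the second half each form a branch;
    factors correlate ``within`` inside a branch and 0 across, giving the
    eigengene network a two-branch structure worth preserving.
    """
    if not 0.0 <= within < 1.0:
        raise ValueError(f"within-branch correlation must be in [0, 1), got {within}")
    cor = np.eye(n_modules)
    half = n_modules // 2
    for branch in (range(half), range(half, n_modules)):
        for i in branch:
            for j in branch:
                if i != j:
                    cor[i, j] = within
    return cor


def simulate_pair(
    config: SimulationConfig,
    factor_cor: np.ndarray | None = None,
) -> tuple[ExpressionStudy, ExpressionStudy, SyntheticTruth]:
    """Generate two cohorts sharing planted modules, plus the ground truth.

    Cohort B reuses cohort A's module memberships, but a ``rewire_fraction``
    of each module's genes are re-drawn as pure noise in B. Reproducible
    under a fixed ``config.seed``.

    Parameters
    ----------
    factor_cor : array, optional
        Module-factor correlation matrix (n_modules x n_modules), applied
        in both cohorts; identity if omitted.
    """
    cfg = config
    # two streams: gene-level structure (DE flags, rewire order) and data
    # draws. The rewired set at fraction f is the first round(f*size) genes
    # of a per-module permutation, so rewired sets are nested in f and the
    # data stream is untouched by f — runs at different rewire levels under
    # one seed share every other random draw (common random numbers).
    rng_structure = np.random.default_rng([cfg.seed, 0])
    rng = np.random.default_rng([cfg.seed, 1])

    genes = [f"g{i + 1:04d}" for i in range(cfg.n_genes)]
    module_of = np.full(cfg.n_genes, -1, dtype=int)
    pos = 0
    for m, size in enumerate(cfg.module_sizes):
        module_of[pos : pos + size] = m
        pos += size

    de_mask = np.zeros(cfg.n_genes, dtype=bool)
    rewired_mask = np.zeros(cfg.n_genes, dtype=bool)
    for m, size in enumerate(cfg.module_sizes):
        members = np.flatnonzero(module_of == m)
        n_de = int(round(cfg.de_fraction * size))
        if n_de:
            de_mask[rng_structure.choice(members, size=n_de, replace=False)] = True
        rewire_order = rng_structure.permutation(members)
        n_rw = int(round(cfg.rewire_fraction * size))
        if n_rw:
            rewired_mask[rewire_order[:n_rw]] = True

    def _sample_names(prefix: str, n_cancer: int, n_normal: int) -> tuple[list[str], dict[str, str]]:
        ids = [f"{prefix}_c{i + 1}" for i in range(n_cancer)]
        ids += [f"{prefix}_n{i + 1}" for i in range(n_normal)]
        groups = {s: ("cancer" if s.split("_")[1].startswith("c") else "normal") for s in ids}
        return ids, groups

    xa = _sample_cohort(
        rng, cfg, cfg.n_cancer_a, cfg.n_normal_a, module_of, de_mask,
        np.zeros(cfg.n_genes, dtype=bool), factor_cor,
    )
    xb = _sample_cohort(
        rng, cfg, cfg.n_cancer_b, cfg.n_normal_b, module_of, de_mask,
        rewired_mask, factor_cor,
    )

    ids_a, groups_a = _sample_names("A", cfg.n_cancer_a, cfg.n_normal_a)
    ids_b, groups_b = _sample_names("B", cfg.n_cancer_b, cfg.n_normal_b)
    study_a = ExpressionStudy(pd.DataFrame(xa, index=genes, columns=ids_a), groups_a, "A")
    study_b = ExpressionStudy(pd.DataFrame(xb, index=genes, columns=ids_b), groups_b, "B")

    module_label = {
        g: (f"module_{module_of[i] + 1}" if module_of[i] >= 0 else BACKGROUND)
        for i, g in enumerate(genes)
    }
    truth = SyntheticTruth(
        module=module_label,
        is_de_a={g: bool(de_mask[i]) for i, g in enumerate(genes)},
        is_de_b={g: bool(de_mask[i]) for i, g in enumerate(genes)},
        rewired={g for i, g in enumerate(genes) if rewired_mask[i]},
        rewire_fraction=cfg.rewire_fraction,
    )
    return study_a, study_b, truth


def write_fixture(
    study_a: ExpressionStudy,
    study_b: ExpressionStudy,
    truth: SyntheticTruth,
    directory: str | Path,
) -> dict[str, Path]:
    """Write a simulated pair as the TSV fixture layout the readers accept."""
    if str(directory) == "":
        raise ValueError("empty fixture directory")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr_a": write_matrix(study_a.values, directory / "expr_a.tsv"),
        "expr_b": write_matrix(study_b.values, directory / "expr_b.tsv"),
        "meta_a": write_metadata(study_a.group, directory / "meta_a.tsv"),
        "meta_b": write_metadata(study_b.group, directory / "meta_b.tsv"),
    }
    genes = study_a.gene_ids
    truth_df = pd.DataFrame(
        {
            "gene_id": genes,
            "module": [truth.module[g] for g in genes],
            "is_de_a": [int(truth.is_de_a[g]) for g in genes],
            "is_de_b": [int(truth.is_de_b[g]) for g in genes],
        }
    )
    truth_path = directory / "truth.tsv"
    truth_df.to_csv(truth_path, sep="\t", index=False)
    paths["truth"] = truth_path
    return paths
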