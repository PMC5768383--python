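"""Module eigengenes (PC1 summaries) and eigengene networks."""

import numpy as np
import pytest

from consmod import (
    SimulationConfig,
    eigengene_network,
    eigengene_set,
    module_eigengene,
    simulate_pair,
)
from consmod.modules import ModuleAssignment

from conftest import make_study


class TestModuleEigengene:
    def test_identical_genes_explain_everything(self, rng):
        profile = rng.normal(size=12)
        study = make_study(np.tile(profile, (5, 1)))
        eig = module_eigengene(study, study.gene_ids)
        assert eig.variance_explained == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        expected = z / np.linalg.norm(z)
        np.testing.assert_allclose(eig.vector.to_numpy(), expected, atol=1e-10)

    def test_two_independent_genes_split_variance(self, rng):
        study = make_study(rng.normal(size=(2, 1000)))
        eig = module_eigengene(study, study.gene_ids)
        assert eig.variance_explained == pytest.approx(0.5, abs=0.05)

    def test_matches_eigendecomposition_of_correlation(self, rng):
        """SVD route vs an independent eigensolver on the correlation
        matrix: variance explained and the eigengene direction agree."""
        x = rng.normal(size=(10, 20))
        study = make_study(x)
        eig = module_eigengene(study, study.gene_ids)

        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        cor = z @ z.T / z.shape[1]
        evals, evecs = np.linalg.eigh(cor)
        assert eig.variance_explained == pytest.approx(
            evals[-1] / evals.sum(), abs=1e-10
        )
        e_from_eig = z.T @ evecs[:, -1]
        e_from_eig /= np.linalg.norm(e_from_eig)
        dot = abs(float(e_from_eig @ eig.vector.to_numpy()))
        assert dot == pytest.approx(1.0, abs=1e-10)

    def test_unit_norm_and_sign_convention(self, rng):
        x = rng.normal(size=(6, 15)) + rng.normal(size=15)
        study = make_study(x)
        eig = module_eigengene(study, study.gene_ids)
        assert np.linalg.norm(eig.vector) == pytest.approx(1.0)
        z = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        assert float(np.corrcoef(eig.vector, z.mean(axis=0))[0, 1]) >= 0

    def test_gene_order_invariance(self, rng):
        study = make_study(rng.normal(size=(8, 15)))
        genes = study.gene_ids
        e1 = module_eigengene(study, genes)
        e2 = module_eigengene(study, genes[::-1])
        np.testing.assert_allclose(e1.vector, e2.vector, atol=1e-10)
        assert e1.variance_explained == pytest.approx(e2.variance_explained)

    def test_global_sign_flip_is_unobservable(self, rng):
        x = rng.normal(size=(5, 12)) + 2 * rng.normal(size=12)
        e1 = module_eigengene(make_study(x), [f"g{i+1}" for i in range(5)])
        e2 = module_eigengene(make_study(-x), [f"g{i+1}" for i in range(5)])
        np.testing.assert_allclose(np.abs(e1.vector), np.abs(e2.vector), atol=1e-10)
        assert e1.variance_explained == pytest.approx(e2.variance_explained)

    def test_noise_genes_dilute_variance_explained(self, rng):
        """Appending i.i.d. noise genes never raises variance explained,
        checked in expectation over seeds."""
        diffs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            base = r.normal(size=30)
            module = 0.9 * base + 0.44 * r.normal(size=(6, 30))
            noisy = np.vstack([module, r.normal(size=(4, 30))])
            s_small = make_study(module)
            s_big = make_study(noisy)
            v_small = module_eigengene(s_small, s_small.gene_ids).variance_explained
            v_big = module_eigengene(s_big, s_big.gene_ids).variance_explained
            diffs.append(v_big - v_small)
        assert np.mean(diffs) < 0

    def test_constant_gene_raises_unless_dropped(self, rng):
        x = rng.normal(size=(3, 10))
        x[1] = 5.0
        study = make_study(x)
        with pytest.raises(ValueError, match="g2"):
            module_eigengene(study, study.gene_ids)
        eig = module_eigengene(study, study.gene_ids, drop_constant=True)
        assert set(eig.loadings.index) == {"g1", "g3"}

    def test_too_small_module_errors(self, rng):
        study = make_study(rng.normal(size=(3, 10)))
        with pytest.raises(ValueError, match=">= 2"):
            module_eigengene(study, ["g1"])


class TestEigengeneNetwork:
    def _planted_sets(self, seed=3):
        cfg = SimulationConfig(n_genes=160, module_sizes=(40, 40, 40, 40), seed=seed)
        study_a, study_b, truth = simulate_pair(cfg)
        assignment = ModuleAssignment(
            {g: m for g, m in truth.module.items() if m != "background"},
            [f"module_{i+1}" for i in range(4)],
        )
        return study_a, study_b, assignment

    def test_duplicated_module_gives_correlation_one(self, rng):
        x = rng.normal(size=(6, 20)) + rng.normal(size=20)
        study = make_study(np.vstack([x, x]), name="dup")
        assignment = ModuleAssignment(
            {**{f"g{i+1}": "turquoise" for i in range(6)},
             **{f"g{i+7}": "blue" for i in range(6)}},
            ["turquoise", "blue"],
        )
        eigs = eigengene_set(study, assignment)
        net = eigengene_network(eigs)
        assert net.correlation.loc["turquoise", "blue"] == pytest.approx(1.0)

    def test_independent_modules_near_zero_correlation(self):
        study_a, _, assignment = self._planted_sets()
        net = eigengene_network(eigengene_set(study_a, assignment))
        off = net.correlation.to_numpy()[~np.eye(4, dtype=bool)]
        # null scale ~ 1/sqrt(n_samples - 1) with 27 samples
        assert np.abs(off).mean() < 0.35

    def test_designed_meta_branches_recovered(self):
        """Factors correlated 0.8 within two designed branches: the
        eigengene dendrogram splits modules into those branches."""
        from consmod.simulate import simulate_pair as sim

        cfg = SimulationConfig(
            n_genes=320, module_sizes=(40,) * 8, seed=5,
            n_cancer_a=50, n_normal_a=50, de_effect=0.0,
        )
        factor_cor = np.eye(8)
        for branch in ([0, 1, 2, 3], [4, 5, 6, 7]):
            for i in branch:
                for j in branch:
                    if i != j:
                        factor_cor[i, j] = 0.8
        study_a, _, truth = sim(cfg, factor_cor=factor_cor)
        assignment = ModuleAssignment(
            {g: m for g, m in truth.module.items() if m != "background"},
            [f"module_{i+1}" for i in range(8)],
        )
        net = eigengene_network(eigengene_set(study_a, assignment))
        # cut the module dendrogram into two branches and compare
        from consmod.modules import cut_tree_at_height

        heights = net.dendrogram.heights
        mid = (heights[-2] + heights[-1]) / 2
        clusters = cut_tree_at_height(net.dendrogram, mid)
        assert len(clusters) == 2
        got = {frozenset(c) for c in clusters}
        want = {
            frozenset(f"module_{i+1}" for i in (0, 1, 2, 3)),
            frozenset(f"module_{i+1}" for i in (4, 5, 6, 7)),
        }
        assert got == want

    def test_single_module_network_errors(self, rng):
        study = make_study(rng.normal(size=(4, 12)))
        assignment = ModuleAssignment(
            {g: "turquoise" for g in study.gene_ids}, ["turquoise"]
        )
        with pytest.raises(ValueError, match=">= 2 modules"):
            eigengene_network(eigengene_set(study, assignment))
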