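"""Mann-Whitney screening, common genes, and hub-gene selection."""

import itertools

import numpy as np
import pytest

from consmod import common_de_genes, consensus_connectivity_filter, mann_whitney_de
from consmod.network import adjacency, correlation_matrix
from consmod.screening import DEResult, ScreenSummary

from conftest import make_study


def exact_mw_p_two_sided(x, y):
    """Two-sided Mann-Whitney p by full enumeration of label assignments.

    Independent oracle: for tie-free data, enumerate every C(n1+n2, n1)
    split of the pooled values, compute U for each, and count splits whose
    U is at least as far from the null mean n1*n2/2 as the observed one.
    """
    pooled = list(x) + list(y)
    n1 = len(x)
    idx = range(len(pooled))

    def u_of(indices):
        xs = [pooled[i] for i in indices]
        ys = [pooled[i] for i in idx if i not in set(indices)]
        return sum(1 for a in xs for b in ys if a > b)

    observed = u_of(tuple(range(n1)))
    mean_u = n1 * (len(pooled) - n1) / 2
    dev = abs(observed - mean_u)
    count = total = 0
    for combo in itertools.combinations(idx, n1):
        total += 1
        if abs(u_of(combo) - mean_u) >= dev - 1e-12:
            count += 1
    return count / total


def _two_group_study(x, y):
    n1, n2 = len(x), len(y)
    values = np.array([list(x) + list(y)])
    groups = {f"s{i+1}": ("cancer" if i < n1 else "normal") for i in range(n1 + n2)}
    return make_study(values, groups=groups)


class TestMannWhitney:
    def test_textbook_example_u0_p_point1(self):
        """cancer=(1,2,3) vs normal=(4,5,6): U=0, exact two-sided p=0.1."""
        study = _two_group_study([1, 2, 3], [4, 5, 6])
        res = mann_whitney_de(study)
        assert res.table["U"].iloc[0] == 0.0
        assert res.table["p_value"].iloc[0] == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        study = _two_group_study([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        res = mann_whitney_de(study)
        assert res.table["p_value"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_symmetry(self, rng):
        x = rng.normal(size=(20, 12))
        half = {f"s{i+1}": ("cancer" if i < 6 else "normal") for i in range(12)}
        flipped = {s: ("normal" if g == "cancer" else "cancer") for s, g in half.items()}
        p1 = mann_whitney_de(make_study(x, groups=half)).table["p_value"]
        p2 = mann_whitney_de(make_study(x, groups=flipped)).table["p_value"]
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    def test_exact_matches_enumeration(self, rng):
        """Exact p equals full-enumeration p for tie-free small groups."""
        for _ in range(30):
            n1, n2 = rng.integers(2, 6, size=2)
            x = rng.normal(size=n1)
            y = rng.normal(size=n2)
            res = mann_whitney_de(_two_group_study(x, y))
            expected = exact_mw_p_two_sided(x, y)
            assert res.table["p_value"].iloc[0] == pytest.approx(expected, abs=1e-10)

    def test_exact_and_normal_approx_agree_at_cutover(self, rng):
        """At min(n)=8 without ties the two p-value routes agree closely."""
        from scipy.stats import mannwhitneyu

        worst = 0.0
        for _ in range(200):
            x = rng.normal(size=8)
            y = rng.normal(size=10)
            p_exact = mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
            p_approx = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
            worst = max(worst, abs(p_exact - p_approx))
        assert worst < 0.01

    def test_small_group_errors(self):
        study = _two_group_study([1.0], [2.0, 3.0])
        with pytest.raises(ValueError, match="2 samples"):
            mann_whitney_de(study)

    def test_alpha_monotonicity(self, rng):
        x = rng.normal(size=(50, 13))
        x[:10, :6] += 1.5
        groups = {f"s{i+1}": ("cancer" if i < 6 else "normal") for i in range(13)}
        study = make_study(x, groups=groups)
        sig_small = set(mann_whitney_de(study, alpha=0.01).significant)
        sig_large = set(mann_whitney_de(study, alpha=0.1).significant)
        assert sig_small <= sig_large

    def test_bh_adjustment_is_used_for_significance(self, rng):
        x = rng.normal(size=(40, 16))
        groups = {f"s{i+1}": ("cancer" if i < 8 else "normal") for i in range(16)}
        study = make_study(x, groups=groups)
        res = mann_whitney_de(study, alpha=0.05, fdr="bh")
        assert "p_adjusted" in res.table.columns
        assert (res.table["p_adjusted"] >= res.table["p_value"] - 1e-15).all()


class TestCommonGenes:
    def _de(self, pvals, alpha=0.05, cohort="x"):
        import pandas as pd

        table = pd.DataFrame(
            {"U": np.zeros(len(pvals)), "p_value": list(pvals.values())},
            index=list(pvals.keys()),
        )
        return DEResult(table, alpha=alpha, cohort=cohort)

    def test_intersection_and_rates(self):
        de_a = self._de({"g1": 0.01, "g2": 0.02, "g3": 0.03, "g4": 0.9})
        de_b = self._de({"g2": 0.01, "g3": 0.02, "g4": 0.03, "g1": 0.9})
        common, summary = common_de_genes(de_a, de_b)
        assert common == ["g2", "g3"]
        assert summary.n_common == 2
        assert summary.rate_a == pytest.approx(2 / 3)
        assert summary.rate_b == pytest.approx(2 / 3)

    def test_empty_b_gives_zero_rates(self):
        de_a = self._de({"g1": 0.01, "g2": 0.9})
        de_b = self._de({"g1": 0.5, "g2": 0.9})
        common, summary = common_de_genes(de_a, de_b)
        assert common == []
        assert (summary.rate_a, summary.rate_b) == (0.0, 0.0)

    def test_identical_sets_rates_one(self):
        de = self._de({"g1": 0.01, "g2": 0.02})
        _, summary = common_de_genes(de, de)
        assert (summary.rate_a, summary.rate_b) == (1.0, 1.0)

    def test_disjoint_universes_error(self):
        de_a = self._de({"g1": 0.01})
        de_b = self._de({"h1": 0.01})
        with pytest.raises(ValueError, match="disjoint"):
            common_de_genes(de_a, de_b)

    def test_summary_invariant(self):
        s = ScreenSummary(n_sig_a=10, n_sig_b=5, n_common=4)
        assert s.n_common <= min(s.n_sig_a, s.n_sig_b)
        assert s.rate_a == 0.4 and s.rate_b == 0.8


class TestConnectivityFilter:
    def _paired_studies(self, rng, n_genes=30, n_samples=20):
        a = make_study(rng.normal(size=(n_genes, n_samples)), name="A")
        b = make_study(rng.normal(size=(n_genes, n_samples)), name="B")
        return a, b

    def test_keep_all_returns_input(self, rng):
        a, b = self._paired_studies(rng)
        genes = a.gene_ids
        assert consensus_connectivity_filter(a, b, genes, n_keep=len(genes)) == genes

    def test_correlated_triple_beats_noise(self, rng):
        base = rng.normal(size=20)
        x = np.vstack(
            [base, base * 1.01 + 1e-3, base * 0.99 - 1e-3, *rng.normal(size=(3, 20))]
        )
        a = make_study(x, name="A")
        b = make_study(x + rng.normal(scale=1e-3, size=x.shape), name="B")
        kept = consensus_connectivity_filter(a, b, a.gene_ids, n_keep=3)
        assert kept == ["g1", "g2", "g3"]

    def test_matches_brute_force_min_ranking(self, rng):
        """Top-10 of 30 genes equals a direct min-connectivity recomputation."""
        a, b = self._paired_studies(rng)
        genes = a.gene_ids
        ks = []
        for study in (a, b):
            cor = correlation_matrix(study, genes)
            adj = adjacency(cor, beta=6.0).values.to_numpy()
            np.fill_diagonal(adj, 0.0)
            ks.append(adj.sum(axis=1))
        consensus = np.minimum(*ks)
        expected = set(
            sorted(genes, key=lambda g: (-consensus[genes.index(g)], g))[:10]
        )
        got = consensus_connectivity_filter(a, b, genes, n_keep=10)
        assert set(got) == expected

    def test_invariant_to_gene_input_order(self, rng):
        a, b = self._paired_studies(rng)
        genes = a.gene_ids
        fwd = consensus_connectivity_filter(a, b, genes, n_keep=10)
        rev = consensus_connectivity_filter(a, b, genes[::-1], n_keep=10)
        assert set(fwd) == set(rev)

    def test_n_keep_too_large_errors(self, rng):
        a, b = self._paired_studies(rng)
        with pytest.raises(ValueError, match="n_keep"):
            consensus_connectivity_filter(a, b, a.gene_ids, n_keep=31)
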