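"""Spearman correlation, significance, clustering, and association labels."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from fibercoip import (
    ExpressionMatrix,
    ExprSimConfig,
    associate,
    cluster_expression,
    correlation_pvalue,
    permutation_pvalue,
    simulate_expression,
    spearman_rho,
)


def _rank_pearson_oracle(x, y):
    """Brute force: explicit average ranks, then Pearson on the ranks."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


class TestSpearmanRho:
    def test_identity_and_reversal(self):
        x = [3.0, 1.0, 4.0, 1.5, 5.0]
        assert spearman_rho(x, x) == pytest.approx(1.0)
        assert spearman_rho(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_closed_form_example(self):
        # sum of squared rank differences is 4: 1 - 6*4/(5*24) = 0.8
        assert spearman_rho([1, 2, 3, 4, 5], [2, 1, 4, 3, 5]) == pytest.approx(0.8)

    def test_constant_vector_undefined(self):
        assert spearman_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0]) is None

    def test_length_mismatch_and_short_input(self):
        with pytest.raises(ValueError):
            spearman_rho([1, 2, 3], [1, 2])
        with pytest.raises(ValueError):
            spearman_rho([1, 2], [2, 1])

    @given(
        st.lists(st.integers(0, 20), min_size=4, max_size=30),
        st.data(),
    )
    def test_matches_rank_pearson_oracle_with_ties(self, x, data):
        y = data.draw(st.lists(st.integers(0, 20), min_size=len(x), max_size=len(x)))
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        assert spearman_rho(x, y) == pytest.approx(_rank_pearson_oracle(x, y), abs=1e-12)

    @given(st.lists(st.floats(0.1, 50), min_size=4, max_size=20, unique=True), st.data())
    def test_invariant_under_monotone_transforms(self, x, data):
        y = data.draw(
            st.lists(st.floats(0.1, 50), min_size=len(x), max_size=len(x), unique=True)
        )
        base = spearman_rho(x, y)
        assert spearman_rho(np.log(x), y) == pytest.approx(base, abs=1e-12)
        assert spearman_rho(x, np.asarray(y) ** 3) == pytest.approx(base, abs=1e-12)


class TestCorrelationPvalue:
    def test_null_rho_gives_p_one(self):
        assert correlation_pvalue(0.0, 10) == pytest.approx(1.0)

    def test_t_transform_example(self):
        # t = 0.8 * sqrt(3 / 0.36) = 2.309 on 3 df
        assert correlation_pvalue(0.8, 5) == pytest.approx(0.104, abs=1e-3)

    def test_perfect_correlation_flagged(self):
        with pytest.warns(UserWarning, match="perfect correlation"):
            assert correlation_pvalue(1.0, 10) == 0.0

    @given(
        st.floats(0.0, 0.95).map(lambda r: round(r, 3)),
        st.floats(0.0, 0.95).map(lambda r: round(r, 3)),
    )
    def test_decreasing_in_absolute_rho(self, r1, r2):
        lo, hi = sorted((r1, r2))
        if lo == hi:
            return
        assert correlation_pvalue(hi, 20) < correlation_pvalue(lo, 20)
        assert correlation_pvalue(-hi, 20) == pytest.approx(correlation_pvalue(hi, 20))

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            correlation_pvalue(0.5, 3)

    def test_permutation_pvalue_tracks_t_approximation(self):
        rng = np.random.default_rng(11)
        latent = rng.standard_normal(30)
        x = latent + 0.5 * rng.standard_normal(30)
        y = latent + 0.5 * rng.standard_normal(30)
        p_perm = permutation_pvalue(x, y, n_permutations=999, seed=5)
        p_t = correlation_pvalue(spearman_rho(x, y), 30)
        assert p_perm < 0.05 and p_t < 0.05


class TestClusterExpression:
    def test_recovers_planted_modules(self):
        matrix, truth = simulate_expression(ExprSimConfig(n_background=0, seed=3))
        clusters = cluster_expression(matrix, k=2)
        for module in ("cesa_module", "cals_module"):
            members = [g for g, m in truth.module_of.items() if m == module]
            assert len({clusters[g] for g in members}) == 1
        assert len(set(clusters.values())) == 2

    def test_k_one_and_k_equals_genes(self):
        matrix, _ = simulate_expression(ExprSimConfig(n_background=0, seed=3))
        assert set(cluster_expression(matrix, k=1).values()) == {1}
        n = len(matrix.gene_ids)
        assert len(set(cluster_expression(matrix, k=n).values())) == n

    def test_duplicated_rows_cluster_together(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(20)
        other = rng.standard_normal(20)
        matrix = ExpressionMatrix(
            ["a_dup1", "a_dup2", "b"], [f"t{i}" for i in range(20)],
            np.vstack([base, base, other]),
        )
        clusters = cluster_expression(matrix, k=2)
        assert clusters["a_dup1"] == clusters["a_dup2"]

    def test_invalid_inputs(self):
        matrix, _ = simulate_expression(ExprSimConfig(n_background=0, seed=3))
        with pytest.raises(ValueError):
            cluster_expression(matrix, k=100)
        const = ExpressionMatrix(
            ["flat", "var"], ["t1", "t2", "t3"], [[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]]
        )
        with pytest.raises(ValueError, match="flat"):
            cluster_expression(const, k=2)

    def test_deterministic_under_row_permutation(self):
        matrix, _ = simulate_expression(ExprSimConfig(seed=9))
        clusters = cluster_expression(matrix, k=2)
        perm = np.random.default_rng(1).permutation(len(matrix.gene_ids))
        shuffled = ExpressionMatrix(
            [matrix.gene_ids[i] for i in perm], matrix.tissue_ids, matrix.values[perm]
        )
        assert cluster_expression(shuffled, k=2) == clusters


@pytest.fixture(scope="module")
def planted():
    matrix, truth = simulate_expression(ExprSimConfig(n_background=2, seed=17))
    cesa_refs = [g for g, m in truth.module_of.items() if m == "cesa_module"][:3]
    cals_refs = [g for g, m in truth.module_of.items() if m == "cals_module"][:3]
    return matrix, truth, cesa_refs, cals_refs


class TestAssociate:
    def test_module_member_labelled_with_its_module(self, planted):
        matrix, truth, cesa_refs, cals_refs = planted
        candidate = [
            g for g, m in truth.module_of.items()
            if m == "cesa_module" and g not in cesa_refs
        ][0]
        labels = associate([candidate], cesa_refs, cals_refs, matrix)
        assert labels[candidate].label == "cesa_associated"
        assert all(rho > 0 and p < 0.05 for _r, rho, p in labels[candidate].supporting)

    def test_background_noise_gene_labelled_none(self, planted):
        matrix, truth, cesa_refs, cals_refs = planted
        noise_gene = [g for g, m in truth.module_of.items() if m == "background"][0]
        labels = associate([noise_gene], cesa_refs, cals_refs, matrix)
        assert labels[noise_gene].label == "none"

    def test_candidate_identical_to_reference_profile(self, planted):
        matrix, truth, cesa_refs, cals_refs = planted
        ref = cals_refs[0]
        clone = ExpressionMatrix(
            matrix.gene_ids + ["cals_clone"],
            matrix.tissue_ids,
            np.vstack([matrix.values, matrix.row(ref)]),
        )
        labels = associate(["cals_clone"], cesa_refs, cals_refs, clone)
        assert labels["cals_clone"].label == "cals_associated"

    def test_null_candidates_rarely_labelled(self):
        """White-noise candidates pass the per-reference test at ~alpha rate,
        so the majority vote labels them 'none' nearly always."""
        matrix, truth = simulate_expression(
            ExprSimConfig(module_sizes=(5, 5), n_background=40, seed=23)
        )
        cesa_refs = [g for g, m in truth.module_of.items() if m == "cesa_module"]
        cals_refs = [g for g, m in truth.module_of.items() if m == "cals_module"]
        background = [g for g, m in truth.module_of.items() if m == "background"]
        labels = associate(background, cesa_refs, cals_refs, matrix)
        none_rate = sum(lab.label == "none" for lab in labels.values()) / len(background)
        assert none_rate >= 0.95

    def test_empty_and_missing_references_rejected(self, planted):
        matrix, _truth, cesa_refs, cals_refs = planted
        with pytest.raises(ValueError):
            associate(["bg_g01"], [], cals_refs, matrix)
        with pytest.raises(KeyError):
            associate(["bg_g01"], ["ghost_gene"], cals_refs, matrix)
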