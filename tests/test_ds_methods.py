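"""Unit and property tests for the six differential-splicing detectors.

Derived expected values are frozen from independent straight-line
evaluations of the defining formulas (see the oracle helpers below); the
implementation under test never feeds the oracle.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from exonsplice.core_model import ScenarioSpec
from exonsplice.ds_methods import (
    anosva_pvalue,
    arh_score,
    condition_profile,
    exon_probability_distribution,
    klas_intermediate,
    klas_score,
    midas_pvalue,
    pac_score,
    run_method,
    splicing_index,
)
from exonsplice.permutation import PermutationConfig
from exonsplice.simulator import SimulationConfig, simulate_scenario

from conftest import make_block, make_dataset


def block_from_profiles(profile_c1, profile_c2, reps=2):
    """Block whose per-condition exon means equal the given profiles
    exactly (each condition's samples replicate its profile)."""
    profile_c1 = np.asarray(profile_c1, dtype=float)
    profile_c2 = np.asarray(profile_c2, dtype=float)
    m = np.column_stack([profile_c1] * reps + [profile_c2] * reps)
    return make_block(m, reps, reps)


class TestConditionProfile:
    def test_single_exon_mean(self):
        b = make_block([[4.0, 6.0, 5.0, 5.0]], 2, 2)
        np.testing.assert_allclose(condition_profile(b, "c1"), [5.0])

    def test_constant_matrix_identity(self):
        b = make_block(np.full((4, 6), 7.0), 3, 3)
        prof = condition_profile(b, "c2")
        np.testing.assert_array_equal(prof, np.full(4, 7.0))
        assert prof.mean() == 7.0

    def test_gene_value_is_mean_of_exon_means(self):
        b = block_from_profiles([6.0, 7.0, 8.0], [6.0, 7.0, 8.0])
        assert condition_profile(b, "c1").mean() == pytest.approx(7.0)

    def test_unknown_condition_rejected(self):
        b = make_block(np.zeros((2, 4)), 2, 2)
        with pytest.raises(KeyError, match="c9"):
            condition_profile(b, "c9")


class TestExonProbabilityDistribution:
    def test_equal_deviations_give_uniform(self):
        np.testing.assert_allclose(exon_probability_distribution(np.zeros(4)), np.full(4, 0.25))

    def test_one_log2_unit_doubles_weight(self):
        np.testing.assert_allclose(
            exon_probability_distribution(np.array([1.0, 0.0])), [2 / 3, 1 / 3]
        )

    @given(
        d=st.lists(st.floats(-30, 30), min_size=2, max_size=12),
        k=st.floats(-100, 100),
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_shift_invariance_positivity_and_normalization(self, d, k):
        d = np.asarray(d)
        p = exon_probability_distribution(d)
        assert (p > 0).all()
        assert p.sum() == pytest.approx(1.0)
        np.testing.assert_allclose(p, exon_probability_distribution(d + k), atol=1e-12)

    def test_single_exon_rejected(self):
        with pytest.raises(ValueError, match=">= 2 exons"):
            exon_probability_distribution(np.array([1.0]))


def klas_oracle(profile_c1, profile_c2):
    """Straight-line evaluation of the KLAS definition with Q = 1."""
    d1 = [x - sum(profile_c1) / len(profile_c1) for x in profile_c1]
    d2 = [x - sum(profile_c2) / len(profile_c2) for x in profile_c2]
    w1 = [2.0**d for d in d1]
    w2 = [2.0**d for d in d2]
    p1 = [w / sum(w1) for w in w1]
    p2 = [w / sum(w2) for w in w2]
    return sum(a * math.log2(a / b) for a, b in zip(p1, p2)) + sum(
        b * math.log2(b / a) for a, b in zip(p1, p2)
    )


class TestKlas:
    def test_identical_profiles_score_zero(self):
        b = block_from_profiles([8.0, 7.0, 9.0], [8.0, 7.0, 9.0])
        assert klas_score(b) == pytest.approx(0.0, abs=1e-12)

    def test_symmetric_under_condition_swap(self, rng):
        m = rng.normal(8, 1, size=(6, 8))
        b = make_block(m, 4, 4)
        swapped = make_block(np.hstack([m[:, 4:], m[:, :4]]), 4, 4)
        assert klas_score(b) == pytest.approx(klas_score(swapped), rel=1e-12)

    def test_location_invariance(self, noisy_block):
        shifted = make_block(noisy_block.matrix + 3.7, 4, 4)
        assert klas_score(noisy_block) == pytest.approx(klas_score(shifted), rel=1e-10)

    def test_three_exon_worked_value_matches_oracle(self):
        # c1 means (8,8,8) vs c2 means (8,8,6) with Q forced to 1:
        # p1 = (1/3,1/3,1/3), p2 = (4/9,4/9,1/9); symmetrized KL = 4/9.
        b = block_from_profiles([8.0, 8.0, 8.0], [8.0, 8.0, 6.0])
        expected = 4.0 / 9.0
        assert klas_oracle([8, 8, 8], [8, 8, 6]) == pytest.approx(expected, rel=1e-12)
        assert klas_score(b, q_mode="fixed_1") == pytest.approx(expected, rel=1e-10)

    def test_nonnegative_with_positive_q(self, rng):
        for _ in range(50):
            b = make_block(rng.normal(8, 1, size=(rng.integers(2, 9), 8)), 4, 4)
            for q_mode in ("quotient_linear", "fixed_1"):
                assert klas_score(b, q_mode=q_mode) >= 0

    def test_intermediates_are_consistent(self, noisy_block):
        inter = klas_intermediate(noisy_block)
        assert inter.p_c1.sum() == pytest.approx(1.0)
        assert inter.p_c2.sum() == pytest.approx(1.0)
        assert (inter.p_c1 > 0).all() and (inter.p_c2 > 0).all()
        assert inter.q_c1 >= 1.0 and inter.q_c2 >= 1.0  # quotient of ordered positive quantiles
        assert np.isfinite(inter.kl)
        assert inter.kl == pytest.approx(klas_score(noisy_block))

    def test_fewer_than_two_exons_rejected(self):
        b = make_block([[1.0, 2.0, 3.0, 4.0]], 2, 2)
        with pytest.raises(ValueError, match=">= 2 exons"):
            klas_score(b)


class TestSplicingIndex:
    def test_identical_conditions_zero(self):
        b = block_from_profiles([8, 7, 9], [8, 7, 9])
        si, score = splicing_index(b)
        np.testing.assert_allclose(si, 0.0, atol=1e-12)
        assert score == 0.0

    def test_compensated_twofold_drop_gives_si_one(self):
        # exon 4 down one log2 unit in c2; others raised to keep the gene
        # level unchanged, so SI of the spliced exon is exactly 1
        c1 = np.array([8.0, 8.0, 8.0, 8.0, 8.0])
        c2 = c1 + 1.0 / 4.0
        c2[3] = c1[3] - 1.0
        b = block_from_profiles(c1, c2)
        si, score = splicing_index(b)
        assert si[3] == pytest.approx(1.0)
        assert score == pytest.approx(1.0)

    def test_antisymmetry_under_condition_swap(self, rng):
        m = rng.normal(8, 1, size=(5, 8))
        si, score = splicing_index(make_block(m, 4, 4))
        si_swapped, score_swapped = splicing_index(make_block(np.hstack([m[:, 4:], m[:, :4]]), 4, 4))
        np.testing.assert_allclose(si, -si_swapped, atol=1e-12)
        assert score == pytest.approx(score_swapped)


def arh_oracle(si_values):
    """Direct evaluation of the ARH definition from per-exon SI values."""
    med = float(np.median(si_values))
    s = [v - med for v in si_values]
    w = [2.0**v for v in s]
    q = [x / sum(w) for x in w]
    entropy = -sum(x * math.log2(x) for x in q)
    q75, q25 = np.quantile(s, [0.75, 0.25])
    return (q75 - q25) * (1 - entropy / math.log2(len(s)))


class TestArh:
    def test_uniform_deviations_score_zero(self):
        b = block_from_profiles([8, 7, 9, 6], [8, 7, 9, 6])
        assert arh_score(b) == pytest.approx(0.0, abs=1e-12)

    def test_four_exon_worked_value_matches_oracle(self):
        # constructed so SI = (-0.5,-0.5,-0.5,1.5), i.e. s = (0,0,0,2):
        # score = IQR(s) * (1 - H(softmax2(s))/2) = 0.5*(1-(log2(7)-8/7)/2)
        b = block_from_profiles([8.0, 8.0, 8.0, 8.0], [8.0, 8.0, 8.0, 6.0])
        si, _ = splicing_index(b)
        np.testing.assert_allclose(si, [-0.5, -0.5, -0.5, 1.5])
        expected = 0.0838755551998847
        assert arh_oracle(si) == pytest.approx(expected, rel=1e-12)
        assert arh_score(b) == pytest.approx(expected, rel=1e-10)

    def test_location_invariance(self, noisy_block):
        shifted = make_block(noisy_block.matrix - 2.2, 4, 4)
        assert arh_score(noisy_block) == pytest.approx(arh_score(shifted), rel=1e-10)


def ttest_oracle(a, b):
    """Closed-form pooled two-sample t-test, p from the t distribution."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = a.size, b.size
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / na + 1 / nb))
    return 2 * stats.t.sf(abs(t), na + nb - 2)


class TestMidas:
    def test_identical_groups_with_spread_give_p_one(self):
        half = np.array([[1.0, 1.2, 0.8], [-1.0, -1.2, -0.8]])
        b = make_block(np.hstack([half, half]), 3, 3)
        p, gene_p = midas_pvalue(b)
        np.testing.assert_allclose(p, 1.0)
        assert gene_p == 1.0

    def test_toy_exon_p_matches_t_distribution_oracle(self):
        # rows sum to zero per column, so gene-level normalization is a
        # no-op and the exon-level values are exactly as printed
        c1 = np.array([[1.0, 1.1, 0.9], [-1.0, -1.1, -0.9]])
        c2 = np.array([[-1.0, -0.9, -1.1], [1.0, 0.9, 1.1]])
        b = make_block(np.hstack([c1, c2]), 3, 3)
        p, gene_p = midas_pvalue(b)
        expected = ttest_oracle(c1[0], c2[0])
        assert p[0] == pytest.approx(expected, rel=1e-10)
        assert gene_p == pytest.approx(min(1.0, 2 * p.min()), rel=1e-12)

    def test_bonferroni_bounds(self, rng):
        for _ in range(20):
            b = make_block(rng.normal(7, 1, size=(6, 10)), 5, 5)
            p, gene_p = midas_pvalue(b)
            assert gene_p <= 1.0
            assert gene_p <= 6 * p.min() + 1e-12


def anova_oracle_2x2x3(x):
    """Classical two-way ANOVA interaction test by hand sums of squares.

    ``x`` is 2 exons x 6 samples (3 per condition), a balanced 2x2 design
    with 3 replicates per cell.
    """
    cells = {(e, c): x[e, 3 * c : 3 * c + 3] for e in range(2) for c in range(2)}
    grand = x.mean()
    exon_means = x.mean(axis=1)
    cond_means = [x[:, :3].mean(), x[:, 3:].mean()]
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in cells.values())
    ss_inter = sum(
        3 * (cells[e, c].mean() - exon_means[e] - cond_means[c] + grand) ** 2
        for e in range(2)
        for c in range(2)
    )
    f = (ss_inter / 1) / (ss_within / 8)  # df: (2-1)(2-1)=1, 12-4=8
    return f, stats.f.sf(f, 1, 8)


class TestAnosva:
    def test_additive_data_with_pure_within_cell_noise_gives_p_one(self):
        # cell means exactly additive; a +/-d pattern inside every cell adds
        # residual variance but no interaction, so the interaction SS is 0
        exon = np.array([0.0, 1.0, 2.0])
        cond = np.array([0.0, 0.5])
        cells = exon[:, None] + cond[None, :] + 7.0
        m = np.zeros((3, 4))
        m[:, :2] = cells[:, [0]] + np.array([-0.3, 0.3])
        m[:, 2:] = cells[:, [1]] + np.array([-0.3, 0.3])
        b = make_block(m, 2, 2)
        assert anosva_pvalue(b) == pytest.approx(1.0)

    def test_2x2x3_toy_matches_hand_sums_of_squares(self):
        x = np.array(
            [
                [7.1, 7.3, 6.9, 7.8, 8.1, 8.0],
                [6.2, 6.0, 6.4, 5.1, 5.0, 5.3],
            ]
        )
        b = make_block(x, 3, 3)
        _, p_oracle = anova_oracle_2x2x3(x)
        assert anosva_pvalue(b) == pytest.approx(p_oracle, rel=1e-10)

    def test_matches_statsmodels_interaction_anova(self, rng):
        import pandas as pd
        import statsmodels.formula.api as smf
        from statsmodels.stats.anova import anova_lm

        for n1, n2 in ((4, 4), (5, 2)):
            x = rng.normal(7, 1, size=(4, n1 + n2))
            b = make_block(x, n1, n2)
            long = pd.DataFrame(
                {
                    "y": x.ravel(),
                    "exon": np.repeat([f"e{i}" for i in range(4)], n1 + n2),
                    "cond": (["c1"] * n1 + ["c2"] * n2) * 4,
                }
            )
            fit = smf.ols("y ~ C(exon) * C(cond)", data=long).fit()
            expected = anova_lm(fit, typ=2).loc["C(exon):C(cond)", "PR(>F)"]
            assert anosva_pvalue(b) == pytest.approx(expected, rel=1e-8)

    def test_invariances(self, rng):
        x = rng.normal(7, 1, size=(5, 9))
        b = make_block(x, 5, 4)
        p = anosva_pvalue(b)
        assert anosva_pvalue(make_block(x + 11.0, 5, 4)) == pytest.approx(p, rel=1e-9)
        assert anosva_pvalue(make_block(x[::-1], 5, 4)) == pytest.approx(p, rel=1e-9)
        swapped = make_block(np.hstack([x[:, 5:], x[:, :5]]), 4, 5)
        assert anosva_pvalue(swapped) == pytest.approx(p, rel=1e-9)

    def test_single_sample_group_rejected(self):
        b = make_block(np.arange(12.0).reshape(4, 3), 2, 1)
        with pytest.raises(ValueError, match="2 samples per condition"):
            anosva_pvalue(b)


def pearson_oracle(x, y):
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


class TestPac:
    def test_affine_exons_score_zero(self):
        g = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        m = np.vstack([1.0 + 2.0 * g, -3.0 + 0.5 * g, 0.2 + 1.0 * g])
        b = make_block(m, 3, 3)
        assert pac_score(b) == pytest.approx(0.0, abs=1e-12)

    def test_antiproportional_exon_scores_two(self):
        g = np.array([5.0, 6.0, 7.0, 8.0, 9.0, 10.0])
        m = np.vstack([3.0 * g, 3.0 * g, -1.0 * g])  # column means still rise with g
        b = make_block(m, 3, 3)
        assert pac_score(b) == pytest.approx(2.0, abs=1e-12)

    def test_two_exon_toy_matches_covariance_oracle(self):
        m = np.array(
            [
                [7.0, 7.4, 6.8, 7.9, 8.2, 7.5],
                [6.1, 6.6, 6.0, 5.2, 5.9, 4.9],
            ]
        )
        b = make_block(m, 3, 3)
        gene = m.mean(axis=0)
        expected = 1.0 - min(pearson_oracle(m[0], gene), pearson_oracle(m[1], gene))
        assert pac_score(b) == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_exon_is_skipped(self, rng):
        m = rng.normal(7, 1, size=(3, 6))
        m[1] = 4.0
        b = make_block(m, 3, 3)
        keep = np.array([0, 2])
        gene = m.mean(axis=0)
        expected = 1.0 - min(pearson_oracle(m[i], gene) for i in keep)
        assert pac_score(b) == pytest.approx(expected, rel=1e-12)


@pytest.fixture(scope="module")
def simulated():
    spec = ScenarioSpec("high", 10, 100, (15, 15))
    cfg = SimulationConfig(seed=7, n_tp=10, n_tn=10)
    return simulate_scenario(spec, cfg)


class TestRunMethod:
    def test_score_method_yields_scores_and_pvalues(self, simulated):
        ds, _ = simulated
        res = run_method(ds, "klas", perm_config=PermutationConfig(n_perm=50, seed=1))
        assert np.isfinite(res.score).all()
        assert np.isfinite(res.p_value).all()
        assert len(res.gene_ids) == 20

    def test_pvalue_native_method_has_no_scores(self, simulated):
        ds, _ = simulated
        res = run_method(ds, "midas")
        assert res.score is None
        assert np.isfinite(res.p_value).all()

    def test_determinism_with_same_permutation_seed(self, simulated):
        ds, _ = simulated
        pc = PermutationConfig(n_perm=50, seed=9)
        r1 = run_method(ds, "arh", perm_config=pc)
        r2 = run_method(ds, "arh", perm_config=pc)
        np.testing.assert_array_equal(r1.score, r2.score)
        np.testing.assert_array_equal(r1.p_value, r2.p_value)

    def test_unknown_method_lists_valid_names(self, simulated):
        ds, _ = simulated
        with pytest.raises(ValueError, match="klas"):
            run_method(ds, "firma")

    def test_single_exon_gene_skipped_with_reason(self):
        b1 = make_block(np.random.default_rng(0).normal(8, 1, (1, 8)), 4, 4, gene_id="solo")
        b2 = make_block(np.random.default_rng(1).normal(8, 1, (4, 8)), 4, 4, gene_id="multi")
        ds = make_dataset([b1, b2])
        res = run_method(ds, "klas")
        assert "solo" in res.skipped and "exons" in res.skipped["solo"]
        assert np.isnan(res.score[0]) and np.isfinite(res.score[1])
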