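"""Per-study odds ratios and fixed/random pooling against hand oracles."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from genemeta import (
    EffectEstimate,
    heterogeneity,
    pool_fixed_iv,
    pool_fixed_mh,
    pool_random_dl,
    study_effect,
)
from genemeta.effect_pooling import CorrectionPolicy
from genemeta.errors import (
    DegenerateInputError,
    InsufficientStudiesError,
    ZeroCellError,
)
from genemeta.genetic_models import TwoByTwoTable


def brute_force_pool(effects, random=False):
    """Independent scalar-loop implementation of the pooling formulas,
    kept deliberately free of the package's vectorised code path."""
    k = len(effects)
    w = [1.0 / e.var for e in effects]
    mean = sum(wi * e.log_or for wi, e in zip(w, effects)) / sum(w)
    q = sum(wi * (e.log_or - mean) ** 2 for wi, e in zip(w, effects))
    tau2 = 0.0
    if random:
        denom = sum(w) - sum(wi ** 2 for wi in w) / sum(w)
        tau2 = max(0.0, (q - (k - 1)) / denom)
        w = [1.0 / (e.var + tau2) for e in effects]
        mean = sum(wi * e.log_or for wi, e in zip(w, effects)) / sum(w)
    se = sum(w) ** -0.5
    return mean, se, tau2, q


class TestStudyEffect:
    def test_wang_dominant(self):
        est = study_effect(TwoByTwoTable(81, 20, 32, 16))
        assert est.odds_ratio == pytest.approx(2.025, abs=5e-4)
        assert est.var == pytest.approx(1 / 81 + 1 / 20 + 1 / 32 + 1 / 16,
                                        rel=1e-12)

    def test_lang_dominant(self):
        est = study_effect(TwoByTwoTable(108, 6, 135, 4))
        assert est.odds_ratio == pytest.approx(432 / 810, rel=1e-9)

    def test_symmetric_table_is_null(self):
        est = study_effect(TwoByTwoTable(10, 10, 10, 10))
        assert est.log_or == 0.0
        assert est.odds_ratio == 1.0

    def test_ci_brackets_or(self):
        est = study_effect(TwoByTwoTable(81, 20, 32, 16))
        assert est.ci_low < est.odds_ratio < est.ci_high
        assert est.ci_low == pytest.approx(
            math.exp(est.log_or - 1.959964 * est.se))

    def test_zero_cell_policies(self):
        zero = TwoByTwoTable(5, 0, 7, 3)
        with pytest.raises(ZeroCellError):
            study_effect(zero, CorrectionPolicy.NONE)
        corrected = study_effect(zero, CorrectionPolicy.ADD_HALF_IF_ZERO)
        assert corrected.log_or == pytest.approx(
            math.log(5.5 * 3.5 / (0.5 * 7.5)))
        # no zero cell: add_half_if_zero leaves the table alone
        clean = study_effect(TwoByTwoTable(5, 1, 7, 3),
                             CorrectionPolicy.ADD_HALF_IF_ZERO)
        assert clean.log_or == pytest.approx(math.log(15 / 7))

    def test_always_half_applies_unconditionally(self):
        est = study_effect(TwoByTwoTable(5, 1, 7, 3), CorrectionPolicy.ALWAYS_HALF)
        assert est.log_or == pytest.approx(math.log(5.5 * 3.5 / (1.5 * 7.5)))

    def test_empty_arm_errors_under_every_policy(self):
        for policy in CorrectionPolicy:
            with pytest.raises(DegenerateInputError):
                study_effect(TwoByTwoTable(0, 0, 7, 3), policy)


class TestFixedIV:
    def test_single_study_identity(self):
        est = study_effect(TwoByTwoTable(81, 20, 32, 16))
        pooled = pool_fixed_iv([est])
        assert pooled.pooled_log_or == pytest.approx(est.log_or)
        assert pooled.se == pytest.approx(est.se)

    def test_all_eight_cohorts(self, fixture_effects):
        pooled = pool_fixed_iv(fixture_effects)
        assert pooled.odds_ratio == pytest.approx(1.23, abs=0.01)

    def test_asian_stratum(self, asian_effects):
        pooled = pool_fixed_iv(asian_effects)
        assert pooled.odds_ratio == pytest.approx(1.25, abs=0.01)
        assert pooled.ci_low == pytest.approx(1.01, abs=0.01)
        assert pooled.ci_high == pytest.approx(1.54, abs=0.01)
        assert pooled.p == pytest.approx(0.044, abs=0.003)

    def test_empty_input_errors(self):
        with pytest.raises(InsufficientStudiesError):
            pool_fixed_iv([])


class TestFixedMH:
    def test_single_table_equals_crude_or(self):
        table = TwoByTwoTable(81, 20, 32, 16)
        pooled = pool_fixed_mh([table])
        assert pooled.odds_ratio == pytest.approx(81 * 16 / (20 * 32), rel=1e-9)

    def test_replication_invariance(self):
        table = TwoByTwoTable(81, 20, 32, 16)
        one = pool_fixed_mh([table])
        two = pool_fixed_mh([table, table])
        assert two.odds_ratio == pytest.approx(one.odds_ratio, rel=1e-12)

    def test_fixture_hand_sums(self, fixture_tables):
        pooled = pool_fixed_mh(fixture_tables)
        r_sum = sum(t.a * t.d / t.n() for t in fixture_tables)
        s_sum = sum(t.b * t.c / t.n() for t in fixture_tables)
        assert r_sum == pytest.approx(138.148, abs=0.001)
        assert s_sum == pytest.approx(111.865, abs=0.001)
        assert pooled.odds_ratio == pytest.approx(1.235, abs=0.001)

    def test_agrees_with_iv_on_fixture(self, fixture_tables, fixture_effects):
        mh = pool_fixed_mh(fixture_tables)
        iv = pool_fixed_iv(fixture_effects)
        assert mh.odds_ratio == pytest.approx(iv.odds_ratio, rel=0.01)


class TestRandomDL:
    def test_needs_two_studies(self):
        est = study_effect(TwoByTwoTable(81, 20, 32, 16))
        with pytest.raises(InsufficientStudiesError):
            pool_random_dl([est])

    def test_no_heterogeneity_collapses_to_common_value(self):
        a = EffectEstimate("a", 0.3, 0.05)
        b = EffectEstimate("b", 0.3, 0.05)
        pooled = pool_random_dl([a, b])
        assert pooled.tau2 == 0.0
        assert pooled.pooled_log_or == pytest.approx(0.3)

    def test_fixture_equals_fixed_when_q_below_df(self, fixture_effects):
        fixed = pool_fixed_iv(fixture_effects)
        random = pool_random_dl(fixture_effects)
        assert random.tau2 == 0.0
        assert random.pooled_log_or == fixed.pooled_log_or
        assert random.se == fixed.se

    def test_asian_stratum(self, asian_effects):
        pooled = pool_random_dl(asian_effects)
        assert pooled.odds_ratio == pytest.approx(1.25, abs=0.01)
        assert pooled.ci_low == pytest.approx(1.001, abs=0.005)
        assert pooled.p == pytest.approx(0.049, abs=0.003)


class TestHeterogeneity:
    def test_identical_studies(self):
        effects = [EffectEstimate(f"s{i}", 0.2, 0.04) for i in range(4)]
        result = heterogeneity(effects)
        assert result.q == pytest.approx(0.0, abs=1e-12)
        assert result.i2 == 0.0
        assert result.p_q == pytest.approx(1.0)

    def test_fixture_i2_truncates_to_zero(self, fixture_effects):
        result = heterogeneity(fixture_effects)
        assert result.q < result.df
        assert result.i2 == 0.0

    def test_asian_stratum(self, asian_effects):
        result = heterogeneity(asian_effects)
        assert result.i2 == pytest.approx(5.6, abs=0.5)
        assert result.p_q == pytest.approx(0.35, abs=0.02)

    def test_needs_two_studies(self):
        with pytest.raises(InsufficientStudiesError):
            heterogeneity([EffectEstimate("a", 0.1, 0.1)])


effect_lists = st.lists(
    st.builds(
        EffectEstimate,
        study_label=st.just("s"),
        log_or=st.floats(-2, 2, allow_nan=False),
        var=st.floats(0.01, 1.0, allow_nan=False),
    ),
    min_size=2, max_size=6,
)


class TestPoolingProperties:
    @given(effects=effect_lists)
    def test_matches_brute_force_oracle(self, effects):
        mean, se, _, _ = brute_force_pool(effects)
        pooled = pool_fixed_iv(effects)
        assert pooled.pooled_log_or == pytest.approx(mean, rel=1e-9, abs=1e-12)
        assert pooled.se == pytest.approx(se, rel=1e-9)
        mean_r, se_r, tau2, _ = brute_force_pool(effects, random=True)
        random = pool_random_dl(effects)
        assert random.pooled_log_or == pytest.approx(mean_r, rel=1e-9, abs=1e-12)
        assert random.tau2 == pytest.approx(tau2, rel=1e-9, abs=1e-12)

    @given(effects=effect_lists, seed=st.integers(0, 2**16))
    def test_order_invariance(self, effects, seed):
        rng = np.random.default_rng(seed)
        shuffled = list(effects)
        rng.shuffle(shuffled)
        assert pool_fixed_iv(shuffled).pooled_log_or == pytest.approx(
            pool_fixed_iv(effects).pooled_log_or, rel=1e-12, abs=1e-12)
        assert pool_random_dl(shuffled).pooled_log_or == pytest.approx(
            pool_random_dl(effects).pooled_log_or, rel=1e-12, abs=1e-12)

    @given(effects=effect_lists)
    def test_random_ci_never_narrower_than_fixed(self, effects):
        fixed = pool_fixed_iv(effects)
        random = pool_random_dl(effects)
        assert random.se >= fixed.se - 1e-12

    def test_z_and_p_consistency(self, fixture_effects):
        pooled = pool_fixed_iv(fixture_effects)
        assert pooled.p == pytest.approx(
            2 * stats.norm.sf(abs(pooled.pooled_log_or / pooled.se)))
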