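"""Statistical battery against exact/brute-force oracles and simulations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st
from scipy import stats

from aortaflow.cohort_stats import (
    build_reports,
    fisher_exact,
    fmt_count_pct,
    fmt_mean_sd,
    fmt_p,
    icc_absolute_agreement,
    map_bp,
    mcnemar_exact,
    paired_t,
    pearson_r,
    unpaired_t,
)


def fisher_oracle(a, b, c, d):
    """Two-sided Fisher p by direct hypergeometric enumeration."""
    n, r, cc = a + b + c + d, a + b, a + c
    support = np.arange(max(0, r + cc - n), min(r, cc) + 1)
    pmf = stats.hypergeom.pmf(support, n, r, cc)
    p_obs = stats.hypergeom.pmf(a, n, r, cc)
    return float(pmf[pmf <= p_obs * (1 + 1e-9)].sum())


def exact_mean_sample(mean, sd, n, seed):
    """A sample with exactly the requested mean (approximate SD)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, sd, n)
    return x - x.mean() + mean


class TestMAP:
    def test_native_group_blood_pressures(self):
        assert map_bp(114, 66) == pytest.approx(82.0)

    def test_operated_group_rounds_to_84(self):
        assert map_bp(117, 67) == pytest.approx(83.6667, abs=1e-3)
        assert round(map_bp(117, 67)) == 84

    def test_degenerate_pressures_rejected(self):
        with pytest.raises(ValueError):
            map_bp(120, 120)
        with pytest.raises(ValueError):
            map_bp(80, 90)


class TestPairedT:
    def test_identical_vectors_undefined(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        res = paired_t(x, x)
        assert res.estimate == 0.0 and not res.defined

    def test_constant_nonzero_differences_undefined(self):
        res = paired_t(np.zeros(4), np.ones(4))
        assert res.estimate == 1.0 and not res.defined

    def test_ci_coverage_of_true_effect(self):
        """95% CI covers the true change 0.5 in ~95% of replicates."""
        rng = np.random.default_rng(10)
        hits = 0
        n_rep = 1000
        for _ in range(n_rep):
            before = rng.normal(0, 1, 20)
            after = before + rng.normal(0.5, 1, 20)
            res = paired_t(before, after)
            hits += res.ci_low <= 0.5 <= res.ci_high
        assert 0.93 <= hits / n_rep <= 0.97


class TestUnpairedT:
    def test_difference_is_mean_b_minus_mean_a(self):
        a = exact_mean_sample(29.2, 2.6, 26, 1)
        b = exact_mean_sample(31.8, 2.4, 20, 2)
        res = unpaired_t(a, b)
        assert res.estimate == pytest.approx(2.6, abs=1e-9)
        assert res.ci_low < 2.6 < res.ci_high

    def test_identical_groups_p_one(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=12)
        res = unpaired_t(x, x.copy())
        assert res.estimate == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_power_against_unit_effect(self):
        """n=50 per arm vs a 1 SD shift: rejections ~99% of the time."""
        rng = np.random.default_rng(4)
        rejections = sum(
            unpaired_t(rng.normal(0, 1, 50), rng.normal(1, 1, 50)).p < 0.05
            for _ in range(500)
        )
        assert rejections / 500 > 0.97

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(0, 1, 15), rng.normal(0.4, 1.3, 11)
        res = unpaired_t(a, b)
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert res.p == pytest.approx(ref.pvalue)


class TestFisher:
    def test_sex_difference_table_significant(self):
        """18/26 vs 5/20 female: the groups differ at p < 0.05."""
        p = fisher_exact(18, 8, 5, 15)
        assert p < 0.05
        assert p == pytest.approx(fisher_oracle(18, 8, 5, 15), abs=1e-10)

    def test_balanced_table_p_one(self):
        assert fisher_exact(5, 5, 5, 5) == pytest.approx(1.0)

    def test_perfect_separation_equals_enumeration(self):
        # only the two extreme tables are as improbable as the observed one,
        # so p = 2 / C(20, 10)
        p = fisher_exact(10, 0, 0, 10)
        assert p == pytest.approx(fisher_oracle(10, 0, 0, 10), abs=1e-12)
        assert p == pytest.approx(2.0 * stats.hypergeom.pmf(10, 20, 10, 10), abs=1e-12)

    def test_random_tables_match_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            a, b, c, d = rng.integers(0, 12, 4)
            if (a + b == 0 or c + d == 0) and (a + c == 0 or b + d == 0):
                continue
            assert fisher_exact(a, b, c, d) == pytest.approx(
                fisher_oracle(a, b, c, d), abs=1e-9
            )

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact(-1, 2, 3, 4)

    @settings(deadline=None, max_examples=80, derandomize=True)
    @given(st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    def test_agrees_with_enumeration_property(self, a, b, c, d):
        assume(not ((a + b == 0 or c + d == 0) and (a + c == 0 or b + d == 0)))
        p = fisher_exact(a, b, c, d)
        assert 0.0 < p <= 1.0 + 1e-12
        assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-9)


class TestMcNemar:
    def test_no_discordant_pairs_is_na(self):
        assert mcnemar_exact(0, 0) is None

    def test_single_discordant_pair(self):
        assert mcnemar_exact(1, 0) == pytest.approx(1.0)

    def test_eight_vs_one(self):
        """2 * sum_{k<=1} C(9,k) / 2^9 = 0.0390625."""
        assert mcnemar_exact(8, 1) == pytest.approx(0.0390625, abs=1e-12)

    @pytest.mark.parametrize("b", [1, 3, 7])
    def test_symmetric_discordance_p_one(self, b):
        assert mcnemar_exact(b, b) == pytest.approx(1.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 30), st.integers(0, 30))
    def test_valid_symmetric_probability(self, b, c):
        p = mcnemar_exact(b, c)
        if b + c == 0:
            assert p is None
        else:
            assert 0.0 < p <= 1.0
            assert p == pytest.approx(mcnemar_exact(c, b))
            if b == c:
                assert p == pytest.approx(1.0)


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        r, p = pearson_r(x, 2 * x + 1)
        assert r == pytest.approx(1.0)
        r, _ = pearson_r(x, -x)
        assert r == pytest.approx(-1.0)

    def test_sampling_mean_near_population_rho(self):
        """Bivariate normal rho=0.59 at n=19 (the PWV-age analysis shape)."""
        rng = np.random.default_rng(7)
        rho = 0.59
        rs = []
        for _ in range(1000):
            x = rng.normal(size=19)
            y = rho * x + np.sqrt(1 - rho**2) * rng.normal(size=19)
            rs.append(pearson_r(x, y)[0])
        assert np.mean(rs) == pytest.approx(rho, abs=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestICC:
    def test_duplicated_ratings_give_one(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=30)
        res = icc_absolute_agreement(np.column_stack([x, x]))
        assert res.icc == pytest.approx(1.0)

    def test_dominant_noise_gives_low_icc(self):
        rng = np.random.default_rng(9)
        x = rng.normal(0, 1.0, 60)
        noisy = x + rng.normal(0, 8.0, 60)
        res = icc_absolute_agreement(np.column_stack([x, noisy]))
        assert res.icc < 0.2

    def test_closed_form_variance_ratio(self):
        """Subject SD 1, error SD 0.17 -> ICC ~ 1/(1+0.17^2) ~ 0.971."""
        rng = np.random.default_rng(11)
        subj = rng.normal(0, 1.0, 200)
        ratings = subj[:, None] + rng.normal(0, 0.17, (200, 2))
        res = icc_absolute_agreement(ratings)
        assert res.icc == pytest.approx(1 / (1 + 0.17**2), abs=0.01)
        assert res.ci_low < res.icc < res.ci_high

    def test_matches_pingouin_reference(self):
        """Independent cross-check of value and CI against pingouin ICC2."""
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(12)
        ratings = rng.normal(0, 1, (25, 2)) + rng.normal(0, 1, 25)[:, None]
        res = icc_absolute_agreement(ratings)
        df = pd.DataFrame({
            "subject": np.repeat(np.arange(25), 2),
            "rater": np.tile(["a", "b"], 25),
            "score": ratings.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subject", raters="rater",
                                 ratings="score").set_index("Type").loc["ICC(A,1)"]
        ci_col = "CI95%" if "CI95%" in ref.index else "CI95"
        assert res.icc == pytest.approx(ref["ICC"], abs=1e-9)
        assert res.ci_low == pytest.approx(ref[ci_col][0], abs=0.01)
        assert res.ci_high == pytest.approx(ref[ci_col][1], abs=0.01)

    def test_shifting_one_rater_decreases_agreement(self):
        """Absolute agreement (unlike consistency) penalizes a rater offset."""
        rng = np.random.default_rng(13)
        x = rng.normal(0, 1.0, 50)
        ratings = np.column_stack([x, x + rng.normal(0, 0.1, 50)])
        base = icc_absolute_agreement(ratings).icc
        shifted = ratings.copy()
        shifted[:, 1] += 1.5
        assert icc_absolute_agreement(shifted).icc < base

    def test_zero_between_subject_variance_rejected(self):
        with pytest.raises(ValueError, match="between-subject"):
            icc_absolute_agreement(np.ones((10, 2)))


class TestFormatting:
    @pytest.mark.parametrize("count,total,expected", [
        (12, 26, "12 (46%)"),
        (20, 20, "20 (100%)"),
        (0, 26, "0 (0%)"),
        (1, 8, "1 (13%)"),  # 12.5 rounds half away from zero
    ])
    def test_count_pct_cells(self, count, total, expected):
        assert fmt_count_pct(count, total) == expected

    def test_p_formatting(self):
        assert fmt_p(0.0391) == "0.039"
        assert fmt_p(0.0004) == "<0.001"
        assert fmt_p(None) == "NA"
        assert fmt_p(float("nan")) == "NA"

    def test_mean_sd(self):
        assert fmt_mean_sd(np.array([1.0, 2.0, 3.0]), 1) == "2.0 ± 1.0"


class TestBuildReports:
    @pytest.fixture()
    def cohort_table(self):
        rng = np.random.default_rng(14)
        rows = []
        for i in range(8):
            group = "native" if i < 4 else "rr"
            base_v = rng.normal(0.6, 0.05)
            for session in ("baseline", "follow_up"):
                rows.append({
                    "subject": f"P{i}", "session": session, "group": group,
                    "sbp": rng.normal(115, 10), "dbp": rng.normal(66, 8),
                    "hr": rng.normal(61, 9), "female": bool(i % 2),
                    "vel_inner_DAo": base_v + rng.normal(0, 0.02),
                    "wss_inner_DAo": rng.normal(1.0, 0.2),
                    "pwv": rng.normal(8, 1.5),
                    "flag_elevated_velocity_inner_DAo": bool(rng.random() < 0.5),
                })
        return pd.DataFrame(rows)

    def test_reports_written_with_expected_structure(self, tmp_path, cohort_table):
        tables = build_reports(cohort_table, tmp_path)
        for name in ("table1", "table2", "table3", "table4"):
            assert (tmp_path / f"{name}.csv").exists()
        assert "MAP (mmHg)" in tables["table1"]["characteristic"].to_numpy()
        assert {"vel_inner_DAo", "wss_inner_DAo", "pwv"} <= set(tables["table3"]["metric"])
        t4 = tables["table4"]
        assert t4["metric"].iloc[0] == "elevated_velocity_inner_DAo"
        assert "(" in t4["V1"].iloc[0]  # n (%) cells

    def test_missing_required_column_rejected(self, tmp_path, cohort_table):
        with pytest.raises(ValueError, match="required column"):
            build_reports(cohort_table.drop(columns=["group"]), tmp_path)
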