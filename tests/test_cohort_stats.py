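"""Repeated-measures ANOVA, sphericity, Pearson screen."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import ocumetrics.cohort_stats as cs
from ocumetrics.synthetic import CohortSimParams, generate_cohort, metric_column


def ss_oracle(data) -> tuple[float, float, float, float]:
    """Independent sum-of-squares decomposition by explicit loops."""
    n, k = len(data), len(data[0])
    grand = sum(data[i][j] for i in range(n) for j in range(k)) / (n * k)
    ss_time = sum(
        n * (sum(data[i][j] for i in range(n)) / n - grand) ** 2 for j in range(k)
    )
    ss_subj = sum(
        k * (sum(data[i][j] for j in range(k)) / k - grand) ** 2 for i in range(n)
    )
    ss_total = sum((data[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_time - ss_subj
    f = (ss_time / (k - 1)) / (ss_err / ((n - 1) * (k - 1)))
    p = float(stats.f.sf(f, k - 1, (n - 1) * (k - 1)))
    return ss_time, ss_err, f, p


def spherical_data(n: int, k: int, seed: int = 0) -> np.ndarray:
    """Data whose sample contrast covariance is exactly the identity."""
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n, k))
    x = x - x.mean(axis=0)
    cov = np.cov(x, rowvar=False, ddof=1)
    vals, vecs = np.linalg.eigh(cov)
    white = x @ vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T
    return white + rng.standard_normal(n)[:, None]  # subject offsets keep W


class TestRMAnova:
    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            data = rng.normal(size=(4, 3)) + rng.normal(size=(4, 1))
            res = cs.rm_anova(data)
            ss_time, ss_err, f, p = ss_oracle(data.tolist())
            assert res.ss_time == pytest.approx(ss_time, abs=1e-8)
            assert res.ss_error == pytest.approx(ss_err, abs=1e-8)
            assert res.f_stat == pytest.approx(f, abs=1e-8)
            if not res.correction_applied:
                assert res.p_value == pytest.approx(p, abs=1e-8)

    def test_matches_pingouin_reference(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        data = rng.normal(size=(12, 4)) + rng.normal(size=(12, 1)) + np.array([0, 0.5, 0.7, 0.6])
        res = cs.rm_anova(data)
        long = pd.DataFrame(
            {
                "y": data.ravel(),
                "subj": np.repeat(np.arange(12), 4),
                "time": np.tile(np.arange(4), 12),
            }
        )
        ref = pg.rm_anova(data=long, dv="y", within="time", subject="subj", correction=True)
        assert res.f_stat == pytest.approx(float(ref["F"][0]), abs=1e-9)
        assert res.epsilon == pytest.approx(float(ref["eps"][0]), abs=1e-9)

    def test_constant_subjects_give_zero_f(self):
        data = np.tile(np.arange(1.0, 6.0)[:, None], (1, 4))  # constant across time
        res = cs.rm_anova(data)
        assert res.f_stat == 0.0
        assert res.p_value == 1.0
        assert res.ss_time == pytest.approx(0.0, abs=1e-12)

    def test_detects_jump_effect_in_generated_cohorts(self):
        detected = 0
        for seed in range(20):
            frame = generate_cohort(CohortSimParams(n_eyes=46, seed=seed))
            cols = [metric_column("vad", "SVP", tp) for tp in ("T0", "T1", "T2", "T3")]
            res = cs.rm_anova(frame[cols].to_numpy())
            detected += res.p_value < 0.001
        assert detected >= 19  # jump effect is large relative to visit noise

    def test_shift_and_subject_offset_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.normal(size=(10, 4))
        base = cs.rm_anova(data)
        shifted = cs.rm_anova(data + 7.5)
        offset = cs.rm_anova(data + rng.normal(size=(10, 1)))
        assert shifted.f_stat == pytest.approx(base.f_stat, rel=1e-9)
        assert offset.f_stat == pytest.approx(base.f_stat, rel=1e-9)

    def test_gg_corrected_p_not_smaller(self):
        rng = np.random.default_rng(3)
        # strongly non-spherical (one contrast direction dominates) plus a
        # real time effect so F sits in the rejection region
        base = rng.normal(size=(20, 1)) * np.array([0.0, 3.0, 0.0, 0.2])
        data = base + 0.3 * rng.normal(size=(20, 4)) + np.array([0.0, 3.0, 1.0, 2.0])
        res = cs.rm_anova(data)
        assert res.f_stat > 1.0 and res.correction_applied
        p_uncorrected = float(stats.f.sf(res.f_stat, 3.0, 57.0))
        assert res.p_value >= p_uncorrected
        assert res.df_num < 3.0

    def test_missing_cells_rejected(self):
        data = np.ones((5, 4))
        data[2, 1] = np.nan
        with pytest.raises(cs.StatsInputError):
            cs.rm_anova(data)


class TestSphericity:
    def test_exact_spherical_data_gives_unit_w(self):
        data = spherical_data(30, 4, seed=1)
        res = cs.mauchly_test(data)
        assert res.w_stat == pytest.approx(1.0, abs=1e-6)
        assert cs.gg_epsilon(data) == pytest.approx(1.0, abs=1e-6)

    def test_two_timepoints_trivially_spherical(self):
        res = cs.mauchly_test(np.random.default_rng(0).normal(size=(8, 2)))
        assert not res.applicable and res.p_value == 1.0

    def test_w_matches_determinant_oracle(self):
        rng = np.random.default_rng(4)
        data = rng.normal(size=(15, 4)) * np.array([1.0, 2.0, 0.5, 1.5])
        res = cs.mauchly_test(data)
        c = cs._contrast_matrix(4)
        t = c @ np.cov(data, rowvar=False, ddof=1) @ c.T
        w_oracle = np.linalg.det(t) / (np.trace(t) / 3) ** 3
        assert res.w_stat == pytest.approx(w_oracle, abs=1e-10)

    def test_epsilon_near_lower_bound_for_rank_one_covariance(self):
        rng = np.random.default_rng(5)
        dominant = rng.normal(size=(40, 1)) * np.array([0.0, 5.0, 0.0, 0.0])
        data = dominant + 0.05 * rng.normal(size=(40, 4))
        eps = cs.gg_epsilon(data)
        assert 1.0 / 3.0 <= eps < 0.40

    def test_epsilon_clamped_to_valid_range(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            data = rng.normal(size=(8, 4)) * rng.uniform(0.2, 3.0, size=4)
            eps = cs.gg_epsilon(data)
            assert 1.0 / 3.0 <= eps <= 1.0


class TestPearson:
    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        assert cs.pearson_corr(x, 2 * x + 1).r == pytest.approx(1.0)
        assert cs.pearson_corr(x, -x).r == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=10)
        y = 0.4 * x + rng.normal(size=10)
        res = cs.pearson_corr(x, y)
        r_oracle = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        t = r_oracle * np.sqrt(8 / (1 - r_oracle**2))
        p_oracle = float(2 * stats.t.sf(abs(t), 8))
        assert res.r == pytest.approx(r_oracle, abs=1e-12)
        assert res.p_value == pytest.approx(p_oracle, abs=1e-10)

    def test_constant_input_rejected(self):
        with pytest.raises(cs.StatsInputError):
            cs.pearson_corr(np.ones(5), np.arange(5.0))

    def test_affine_invariance_of_magnitude(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=30)
        y = 0.5 * x + rng.normal(size=30)
        base = cs.pearson_corr(x, y)
        scaled = cs.pearson_corr(3.0 * x + 2.0, y)
        flipped = cs.pearson_corr(-x, y)
        assert scaled.r == pytest.approx(base.r, abs=1e-12)
        assert flipped.r == pytest.approx(-base.r, abs=1e-12)


class TestCohortTables:
    def test_delta_metrics_basics(self):
        frame = generate_cohort(CohortSimParams(n_eyes=8, seed=0))
        zero = cs.delta_metrics(frame, "T0", "T0")
        assert (zero.drop(columns="iop_change") == 0).all().all()
        d = cs.delta_metrics(frame, "T0", "T3")
        col = metric_column("vad", "SVP", "T3")
        expected = frame[col] - frame[metric_column("vad", "SVP", "T0")]
        assert np.allclose(d["d_vad_SVP"], expected)
        shuffled = cs.delta_metrics(frame.sample(frac=1, random_state=1), "T0", "T3")
        assert np.allclose(shuffled.sort_index()["d_vad_SVP"], d.sort_index()["d_vad_SVP"])

    def test_unknown_timepoint_rejected(self):
        frame = generate_cohort(CohortSimParams(n_eyes=8, seed=0))
        with pytest.raises(cs.StatsInputError):
            cs.delta_metrics(frame, "T0", "T9")

    def test_screen_recovers_injected_correlation(self):
        frame = generate_cohort(CohortSimParams(n_eyes=200, target_correlation=0.5, seed=1))
        table = cs.correlation_screen(frame)
        cell = table[
            (table.metric == "vad") & (table.plexus == "SVP") & (table.predictor == "nuclear_opacity")
        ].iloc[0]
        assert 0.38 < cell.r < 0.62  # Fisher-z 95% interval at n = 200

    def test_screen_flags_deterministic_dependence(self):
        frame = generate_cohort(CohortSimParams(n_eyes=40, seed=2))
        frame = frame.copy()
        frame["vad_SVP_T3"] = frame["vad_SVP_T0"] + 0.001 * frame["nuclear_opacity"]
        table = cs.correlation_screen(frame)
        cell = table[
            (table.metric == "vad") & (table.plexus == "SVP") & (table.predictor == "nuclear_opacity")
        ].iloc[0]
        assert cell.r == pytest.approx(1.0, abs=1e-9)
        assert cell.significant

    def test_null_correlation_stays_small(self):
        small = 0
        for seed in range(20):
            frame = generate_cohort(CohortSimParams(n_eyes=46, target_correlation=0.0, seed=seed))
            table = cs.correlation_screen(frame)
            cell = table[
                (table.metric == "bvt")
                & (table.plexus == "DCP")
                & (table.predictor == "nuclear_opacity")
            ].iloc[0]
            small += abs(cell.r) < 0.3
        assert small >= 18

    def test_anova_table_schema(self):
        frame = generate_cohort(CohortSimParams(n_eyes=20, seed=3))
        table = cs.anova_table(frame)
        assert len(table) == 27  # 9 metrics x 3 plexuses
        assert {"f_stat", "p_value", "epsilon", "mean_T0", "sd_T3"} <= set(table.columns)
        assert (table["f_stat"] >= 0).all()

    def test_duplicate_eyes_rejected(self):
        frame = generate_cohort(CohortSimParams(n_eyes=8, seed=0))
        doubled = pd.concat([frame, frame])
        with pytest.raises(cs.StatsInputError):
            cs.validate_cohort(doubled)
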