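"""Cohort-level statistics: clinical table, paired tests, correlations."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tempobind import (
    Condition,
    IntegrationMode,
    ObserverParams,
    SessionConfig,
    TrialSlot,
    compare_correlations,
    compare_observed_predicted,
    correlate,
    fit_subject,
    group_report,
    load_table1,
    mle_threshold,
    pooled_bimodal_fit,
    simulate_dataset,
    table1_frame,
)
from tempobind.cohort_analysis import (
    DegenerateVarianceError,
    SubjectMismatchError,
    UndefinedCorrelationError,
)


class TestTable1:
    def test_shape_and_first_record(self):
        records = load_table1()
        assert len(records) == 32
        dy01 = records[0]
        assert dy01.code == "DY01"
        assert dy01.age_months == pytest.approx(84.53)
        assert dy01.decode_time_s == 358
        assert dy01.comprehension_time_s == 302

    def test_missing_values(self):
        records = load_table1()
        assert sum(r.decode_time_s is None for r in records) == 6
        assert sum(r.comprehension_time_s is None for r in records) == 6
        assert sum(r.raven_iq is None for r in records) == 1
        # missing rows are the last six (DY27-DY32)
        assert all(r.decode_time_s is None for r in records[26:])

    def test_mean_age_rounds_to_ten_years(self):
        frame = table1_frame()
        assert round(frame["age_months"].mean() / 12) == 10


class TestCompareObservedPredicted:
    def test_identical_vectors(self):
        res = compare_observed_predicted([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t_statistic == 0.0 and res.cohen_d == 0.0 and res.p_value == 1.0

    def test_constant_nonzero_difference_rejected(self):
        with pytest.raises(DegenerateVarianceError):
            compare_observed_predicted([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])

    def test_matches_textbook_formulas(self, rng):
        """Independent oracle: recompute t, p and d from first principles."""
        obs = rng.normal(10, 2, 25)
        pred = obs + rng.normal(0.5, 1, 25)
        res = compare_observed_predicted(obs, pred)
        diff = obs - pred
        t_manual = diff.mean() / (diff.std(ddof=1) / np.sqrt(25))
        p_manual = 2 * stats.t.sf(abs(t_manual), 24)
        assert res.t_statistic == pytest.approx(t_manual, abs=1e-10)
        assert res.p_value == pytest.approx(p_manual, abs=1e-10)
        assert res.cohen_d == pytest.approx(diff.mean() / diff.std(ddof=1), abs=1e-10)
        assert res.df == 24

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            compare_observed_predicted([1.0, 2.0], [1.0, 2.0, 3.0])


class TestCorrelate:
    def test_perfect_linear(self, rng):
        x = rng.uniform(0, 10, 20)
        res = correlate(x, 2 * x + 1, n_boot=200, n_perm=500, rng=rng)
        assert res.pearson_r == pytest.approx(1.0)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(res.pearson_r**2, abs=1e-12)

    def test_listwise_deletion(self, rng):
        x = np.array([1.0, 2, 3, np.nan, 5, 6, 7, 8])
        y = np.array([2.0, 1, 4, 5, np.nan, 7, 6, 9])
        res = correlate(x, y, n_boot=200, n_perm=500, rng=rng)
        assert res.n == 6

    def test_constant_vector_rejected(self, rng):
        with pytest.raises(UndefinedCorrelationError):
            correlate(np.ones(10), np.arange(10.0), rng=rng)

    def test_ci_brackets_rho_and_is_ordered(self, rng):
        x = rng.normal(size=32)
        y = 0.6 * x + rng.normal(size=32)
        res = correlate(x, y, rng=rng)
        assert res.rho_ci_low < res.spearman_rho < res.rho_ci_high

    def test_permutation_p_calibration(self):
        """Under independence the permutation test rejects at close to its
        nominal 5% level (500 seeded replicates, n=32)."""
        rng = np.random.default_rng(99)
        rejections = 0
        for _ in range(500):
            x = rng.normal(size=32)
            y = rng.normal(size=32)
            res = correlate(x, y, n_boot=50, n_perm=2000, rng=rng)
            rejections += res.p_two_sided < 0.05
        assert 0.03 <= rejections / 500 <= 0.07


class TestCompareCorrelations:
    def test_equal_correlations(self):
        z, p = compare_correlations(0.5, 30, 0.5, 40)
        assert z == 0.0 and p == 1.0

    def test_matches_fisher_formula(self):
        z, p = compare_correlations(0.8, 50, 0.2, 50)
        z_manual = (np.arctanh(0.8) - np.arctanh(0.2)) / np.sqrt(1 / 47 + 1 / 47)
        assert z == pytest.approx(z_manual, abs=1e-12)
        assert p == pytest.approx(2 * stats.norm.sf(abs(z_manual)), abs=1e-12)

    def test_antisymmetry(self):
        z1, p1 = compare_correlations(0.7, 40, 0.1, 35)
        z2, p2 = compare_correlations(0.1, 35, 0.7, 40)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_r(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 30, 0.2, 30)


def _uniform_slots(n_per_condition, rng):
    slots, i = [], 0
    for cond in Condition:
        for _ in range(n_per_condition):
            slots.append(TrialSlot(trial_index=i, condition=cond,
                                   delta=cond.delta, is_easy=False,
                                   probe_nominal=float(rng.uniform(50, 950))))
            i += 1
    return slots


class TestPooledFit:
    def test_pooling_merges_all_bimodal_trials(self, rng):
        obs = ObserverParams(sigma_a=150, sigma_v=150)
        records = simulate_dataset(obs, _uniform_slots(30, rng), rng)
        est = pooled_bimodal_fit(records, rng=rng, n_boot=20)
        assert est.n_trials == 90
        assert est.condition == "AV_pooled"

    def test_pooling_equals_concatenated_fit(self, rng):
        """Pooling is trial concatenation: fitting the merged records gives
        the same estimate as the pooled fit."""
        from tempobind import fit_cumulative_gaussian

        obs = ObserverParams(sigma_a=150, sigma_v=150)
        records = simulate_dataset(obs, _uniform_slots(40, rng), rng)
        bimodal = [r for r in records if r.condition.is_bimodal]
        est_pool = pooled_bimodal_fit(records, rng=np.random.default_rng(0), n_boot=10)
        est_cat = fit_cumulative_gaussian(bimodal)
        assert est_pool.pse == pytest.approx(est_cat.pse)
        assert est_pool.sigma == pytest.approx(est_cat.sigma)

    def test_mle_observer_pooled_threshold_matches_prediction(self, rng):
        obs = ObserverParams(sigma_a=200, sigma_v=300, mode=IntegrationMode.MLE)
        records = simulate_dataset(obs, _uniform_slots(700, rng), rng)
        est = pooled_bimodal_fit(records, rng=rng, n_boot=100)
        assert est.sigma == pytest.approx(
            mle_threshold(300, 200), abs=3 * est.se_sigma)

    def test_no_bimodal_trials(self, rng):
        obs = ObserverParams(sigma_a=150, sigma_v=150)
        slots = [s for s in _uniform_slots(20, rng) if not s.condition.is_bimodal]
        records = simulate_dataset(obs, slots, rng)
        with pytest.raises(ValueError):
            pooled_bimodal_fit(records)


def _simulate_group_fits(mode, group, n_subjects, rng, sigma=180.0,
                         n_per_condition=100):
    """Uniform-probe sessions for identical observers of a given mode,
    fitted per subject."""
    fit_rows, preds = [], {}
    from tempobind import predict_from_unisensory

    for i in range(n_subjects):
        obs = ObserverParams(sigma_a=sigma, sigma_v=sigma, lapse=0.02, mode=mode)
        subject_id = f"{group}-{i:02d}"
        records = simulate_dataset(obs, _uniform_slots(n_per_condition, rng),
                                   rng, subject_id=subject_id)
        fits = fit_subject(records, n_boot=0, rng=rng)
        preds[subject_id] = predict_from_unisensory(
            sigma_v=fits["V"].sigma, sigma_a=fits["A"].sigma)
        for key, est in fits.items():
            fit_rows.append({
                "subject_id": subject_id, "group": group, "condition": key,
                "pse_ms": est.pse, "sigma_ms": est.sigma,
                "se_pse_ms": est.se_pse, "se_sigma_ms": est.se_sigma,
                "n_trials": est.n_trials, "converged": est.converged})
    from tempobind import predictions_to_frame

    preds_frame = predictions_to_frame(preds)
    preds_frame.insert(1, "group", group)
    return pd.DataFrame(fit_rows), preds_frame


class TestGroupReport:
    def test_identical_groups_have_zero_differences(self, rng):
        fits_a, preds_a = _simulate_group_fits(
            IntegrationMode.MLE, "g1", 6, np.random.default_rng(1))
        fits_b = fits_a.copy()
        fits_b["group"] = "g2"
        fits_b["subject_id"] = fits_b["subject_id"].str.replace("g1", "g2")
        preds_b = preds_a.copy()
        preds_b["group"] = "g2"
        preds_b["subject_id"] = preds_b["subject_id"].str.replace("g1", "g2")
        report = group_report(pd.concat([fits_a, fits_b]),
                              pd.concat([preds_a, preds_b]))
        assert report["groups"]["g1"] == report["groups"]["g2"]
        assert report["tests"]["g1"] == report["tests"]["g2"]

    def test_subject_mismatch_raises(self, rng):
        fits, preds = _simulate_group_fits(
            IntegrationMode.MLE, "g1", 4, np.random.default_rng(2))
        with pytest.raises(SubjectMismatchError):
            group_report(fits, preds[preds["subject_id"] != "g1-00"])

    def test_mode_contrast_in_group_means(self):
        """Audio-dominant cohorts show pooled bimodal thresholds above the
        optimal prediction; optimally integrating cohorts sit within one
        group standard error of it."""
        fits_dom, preds_dom = _simulate_group_fits(
            IntegrationMode.AUDIO_DOMINANT, "dominant", 12,
            np.random.default_rng(31), n_per_condition=300)
        fits_mle, preds_mle = _simulate_group_fits(
            IntegrationMode.MLE, "optimal", 12,
            np.random.default_rng(32), n_per_condition=300)
        report = group_report(pd.concat([fits_dom, fits_mle]),
                              pd.concat([preds_dom, preds_mle]))
        dom = report["tests"]["dominant"]["pooled_sigma_vs_prediction"]
        opt = report["tests"]["optimal"]["pooled_sigma_vs_prediction"]
        assert dom["mean_difference"] > 0
        assert dom["p_value"] < 0.05
        se_opt = report["groups"]["optimal"]["AV_pooled"]["sigma_se"]
        assert abs(opt["mean_difference"]) <= se_opt

    def test_correlations_with_metadata(self):
        """Audio fits joined to the clinical covariates produce correlation
        entries with listwise-deleted n."""
        rng = np.random.default_rng(5)
        fits, preds = _simulate_group_fits(IntegrationMode.MLE, "dy", 8, rng)
        meta = table1_frame().head(8).rename(columns={"code": "subject_id"})
        meta["subject_id"] = [f"dy-{i:02d}" for i in range(8)]
        report = group_report(fits, preds, metadata=meta,
                              corr_rng=np.random.default_rng(0))
        corrs = report["correlations"]["dy"]
        assert "audio_sigma_ms_vs_age_months" in corrs
        assert corrs["audio_sigma_ms_vs_age_months"]["n"] == 8
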