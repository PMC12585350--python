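"""ROI-wise OLS, permutation maxT FWER, tau association."""

import numpy as np
import pytest
from scipy import stats as sps

import stepgrad as sg
from stepgrad.stats import fwer_maxT, roi_group_regression, tau_association

from conftest import make_atlas


def build_cohort(groups, ages=None, sexes=None, apoe=None, taus=None, n_rois=2):
    """Minimal cohort with given covariates; connectomes are placeholders."""
    atlas = make_atlas(n_rois)
    zero = np.zeros((n_rois, n_rois))
    subs = []
    for i, g in enumerate(groups):
        subs.append(
            sg.SubjectRecord(
                subject_id=f"s{i}",
                group=g,
                age=70.0 if ages is None else ages[i],
                sex="F" if sexes is None else sexes[i],
                apoe4_carrier=False if apoe is None else apoe[i],
                functional=sg.Connectome("functional", zero, atlas),
                structural=sg.Connectome("structural", zero, atlas),
                tau_suvr=None if taus is None else taus[i],
            )
        )
    return sg.CohortTable(subjects=subs, atlas=atlas)


class TestGroupRegression:
    def test_hand_computed_two_group_example(self):
        """y=(1,2,3,4), groups (A,A,B,B), no covariates -> coef 2, t 2.828."""
        cohort = build_cohort(["A-CN", "A-CN", "CI", "CI"])
        values = np.array([[1.0], [2.0], [3.0], [4.0]])
        res = roi_group_regression(values, cohort, ("A-CN", "CI"), covariates=())
        assert res.loc[0, "coef"] == pytest.approx(2.0)
        assert res.loc[0, "t"] == pytest.approx(2.828, abs=5e-4)

    def test_matches_statsmodels_with_covariates(self, rng):
        import statsmodels.api as sm

        n = 24
        groups = ["A-CN"] * 12 + ["CI"] * 12
        ages = rng.uniform(55, 85, n)
        sexes = rng.choice(["F", "M"], n)
        apoe = rng.random(n) < 0.4
        cohort = build_cohort(groups, ages, list(sexes), list(apoe))
        values = rng.standard_normal((n, 5))
        res = roi_group_regression(values, cohort, ("A-CN", "CI"))
        X = sm.add_constant(
            np.column_stack(
                [
                    (np.arange(n) >= 12).astype(float),
                    ages,
                    (sexes == "M").astype(float),
                    apoe.astype(float),
                ]
            )
        )
        for r in range(5):
            fit = sm.OLS(values[:, r], X).fit()
            assert res.loc[r, "t"] == pytest.approx(fit.tvalues[1], abs=1e-8)
            assert res.loc[r, "p"] == pytest.approx(fit.pvalues[1], abs=1e-8)

    def test_matches_closed_form_two_sample_t(self, rng):
        values = rng.standard_normal((20, 3))
        cohort = build_cohort(["A-CN"] * 10 + ["CI"] * 10)
        res = roi_group_regression(values, cohort, ("A-CN", "CI"), covariates=())
        for r in range(3):
            t_ref = sps.ttest_ind(values[10:, r], values[:10, r], equal_var=True)
            assert res.loc[r, "t"] == pytest.approx(t_ref.statistic, abs=1e-10)

    def test_rank_deficient_design_names_column(self):
        cohort = build_cohort(
            ["A-CN"] * 5 + ["CI"] * 5, sexes=["F"] * 10  # single-sex: sex column constant
        )
        with pytest.raises(ValueError, match="sex"):
            roi_group_regression(np.zeros((10, 2)), cohort, ("A-CN", "CI"))

    def test_row_count_mismatch(self):
        cohort = build_cohort(["A-CN"] * 3 + ["CI"] * 3)
        with pytest.raises(ValueError, match="rows"):
            roi_group_regression(np.zeros((5, 2)), cohort, ("A-CN", "CI"), covariates=())


class TestFwerMaxT:
    def _cohort(self, n_per=8, rng=None):
        rng = rng or np.random.default_rng(0)
        groups = ["A-CN"] * n_per + ["CI"] * n_per
        ages = rng.uniform(55, 85, 2 * n_per)
        sexes = list(rng.choice(["F", "M"], 2 * n_per))
        apoe = list(rng.random(2 * n_per) < 0.4)
        return build_cohort(groups, ages, sexes, apoe)

    def test_extreme_effect_reaches_floor(self, rng):
        cohort = self._cohort(rng=rng)
        values = rng.standard_normal((16, 4)) * 0.01
        values[8:, 0] += 100.0  # overwhelming group effect at ROI 0
        p = fwer_maxT(values, cohort, ("A-CN", "CI"), n_perm=200, rng_seed=1)
        assert p[0] == pytest.approx(1.0 / 201.0)
        assert np.all(p >= 1.0 / 201.0)

    def test_monotone_in_observed_t(self, rng):
        cohort = self._cohort(rng=rng)
        values = rng.standard_normal((16, 6))
        res = roi_group_regression(values, cohort, ("A-CN", "CI"))
        p = fwer_maxT(values, cohort, ("A-CN", "CI"), n_perm=300, rng_seed=2)
        order = np.argsort(-np.abs(res["t"].to_numpy()))
        assert np.all(np.diff(p[order]) >= 0)

    def test_reproducible_from_seed(self, rng):
        cohort = self._cohort(rng=rng)
        values = rng.standard_normal((16, 4))
        p1 = fwer_maxT(values, cohort, ("A-CN", "CI"), n_perm=150, rng_seed=7)
        p2 = fwer_maxT(values, cohort, ("A-CN", "CI"), n_perm=150, rng_seed=7)
        np.testing.assert_array_equal(p1, p2)

    def test_low_n_perm_warns(self, rng):
        cohort = self._cohort(rng=rng)
        with pytest.warns(RuntimeWarning, match="n_perm"):
            fwer_maxT(rng.standard_normal((16, 2)), cohort, ("A-CN", "CI"), n_perm=50)


class TestTauAssociation:
    def test_degenerate_identical_subjects_all_flagged(self):
        n_sub, n_roi = 8, 4
        taus = [np.full(n_roi, 1.2)] * n_sub
        cohort = build_cohort(
            ["CI"] * n_sub,
            ages=np.linspace(60, 80, n_sub),
            sexes=["F", "M"] * 4,
            apoe=[True, True, False, False] * 2,
            taus=taus,
            n_rois=n_roi,
        )
        same_map = np.ones(n_roi)
        maps = {s.subject_id: same_map for s in cohort.subjects}
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            res = tau_association(
                cohort, maps, "CI", reference_group="CI", n_perm=100
            )
        assert res["zero_variance"].all()
        assert res["slope"].isna().all()

    def test_recovers_known_slope_without_noise(self, rng):
        n_ref, n_ana, n_roi = 6, 12, 5
        ref_maps = rng.standard_normal((n_ref, n_roi))
        ana_maps = rng.standard_normal((n_ana, n_roi))
        delta = ana_maps - ref_maps.mean(axis=0)
        slope = 0.7
        taus = [1.0 + slope * delta[i] for i in range(n_ana)]
        cohort = build_cohort(
            ["A-CN"] * n_ref + ["CI"] * n_ana,
            ages=np.linspace(55, 85, n_ref + n_ana),
            sexes=["F", "M"] * ((n_ref + n_ana) // 2),
            apoe=([True, True, False] * (n_ref + n_ana))[: n_ref + n_ana],
            taus=[np.full(n_roi, 1.0)] * n_ref + taus,
            n_rois=n_roi,
        )
        maps = {}
        for i, s in enumerate(cohort.subjects[:n_ref]):
            maps[s.subject_id] = ref_maps[i]
        for i, s in enumerate(cohort.subjects[n_ref:]):
            maps[s.subject_id] = ana_maps[i]
        res = tau_association(cohort, maps, "CI", n_perm=200, rng_seed=0)
        np.testing.assert_allclose(res["slope"], slope, atol=1e-10)
        assert res["significant"].all()

    def test_missing_tau_subjects_dropped_from_reference_mean(self, rng):
        n_roi = 3
        maps = {}
        taus = []
        groups = ["A-CN"] * 4 + ["CI"] * 8
        for i in range(12):
            maps[f"s{i}"] = rng.standard_normal(n_roi)
            taus.append(rng.standard_normal(n_roi) + 1.0)
        taus[0] = None  # first reference subject has no tau
        cohort = build_cohort(
            groups,
            ages=np.linspace(60, 80, 12),
            sexes=["F", "M"] * 6,
            apoe=([True, True, False] * 4),
            taus=taus,
            n_rois=n_roi,
        )
        res = tau_association(cohort, maps, "CI", n_perm=100, rng_seed=0)
        # reference mean over subjects s1..s3 only; re-derive the slope by hand
        ref_mean = np.mean([maps[f"s{i}"] for i in range(1, 4)], axis=0)
        import statsmodels.api as sm

        ana = cohort.group_subjects("CI")
        r = 1
        x = np.array([maps[s.subject_id][r] - ref_mean[r] for s in ana])
        cov = cohort.covariate_frame(ana)
        X = sm.add_constant(
            np.column_stack([cov["age"], cov["sex"], cov["apoe4"], x])
        )
        fit = sm.OLS([s.tau_suvr[r] for s in ana], X).fit()
        assert res.loc[r, "slope"] == pytest.approx(fit.params[-1], abs=1e-10)
        assert res.loc[r, "t"] == pytest.approx(fit.tvalues[-1], abs=1e-8)

    def test_empty_reference_rejected(self):
        cohort = build_cohort(["CI"] * 6, taus=[np.ones(2)] * 6)
        maps = {s.subject_id: np.ones(2) for s in cohort.subjects}
        with pytest.raises(ValueError, match="reference group"):
            tau_association(cohort, maps, "CI", reference_group="A-CN")
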