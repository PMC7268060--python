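import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erdpipe.modeling import (
    compute_plc,
    fit_plc_regression,
    fit_stage1,
    fit_stage2,
    fit_subgroup_contralesional,
    lrt_compare,
    median_split,
    per_subject_ols,
)
from erdpipe.synthetic import CohortSpec, simulate_cohort


def _traj(subjects, intercepts, slopes):
    return pd.DataFrame(dict(subject=subjects, intercept=intercepts,
                             slope=slopes))


def _outcomes(subjects, deltas):
    return pd.DataFrame(dict(subject=subjects, delta=deltas))


@pytest.fixture(scope="module")
def cohort22():
    spec = CohortSpec(n_subjects=22, sessions_per_subject=17, sigma_eps=8,
                      seed=42)
    return simulate_cohort(spec)


@pytest.fixture(scope="module")
def fits22(cohort22):
    ipsi = fit_stage1(cohort22.erd, "ipsilesional", "alpha")
    contra = fit_stage1(cohort22.erd, "contralesional", "alpha")
    return ipsi, contra


class TestFitStage1:
    def test_noiseless_limit_exact(self):
        spec = CohortSpec(n_subjects=6, sessions_per_subject=8, sigma_eps=0,
                          sd_b0=0, sd_b1=0, beta0=-30, beta1=-0.5, seed=0)
        c = simulate_cohort(spec)
        f = fit_stage1(c.erd, "ipsilesional", "alpha")
        assert f.beta0 == pytest.approx(-30.0, abs=1e-6)
        assert f.beta1 == pytest.approx(-0.5, abs=1e-6)

    def test_subject_coefficients_track_ols(self, cohort22, fits22):
        ipsi, _ = fits22
        erd = cohort22.erd
        ols = per_subject_ols(erd[(erd.hemisphere == "ipsilesional")])
        merged = ipsi.subjects.merge(ols, on="subject", suffixes=("_lmm", "_ols"))
        r_int = np.corrcoef(merged.intercept_lmm, merged.intercept_ols)[0, 1]
        r_slp = np.corrcoef(merged.slope_lmm, merged.slope_ols)[0, 1]
        assert r_int > 0.9 and r_slp > 0.9

    def test_shrinkage_reduces_variance(self, cohort22, fits22):
        ipsi, _ = fits22
        erd = cohort22.erd
        ols = per_subject_ols(erd[(erd.hemisphere == "ipsilesional")])
        assert ipsi.subjects.intercept.var() <= ols.intercept.var() + 1e-9
        assert ipsi.subjects.slope.var() <= ols.slope.var() + 1e-9

    def test_mean_subject_coefficients_near_fixed_effects(self, fits22):
        ipsi, _ = fits22
        assert ipsi.subjects.intercept.mean() == pytest.approx(ipsi.beta0,
                                                               abs=1.0)
        assert ipsi.subjects.slope.mean() == pytest.approx(ipsi.beta1,
                                                           abs=0.1)

    def test_too_few_subjects_rejected(self):
        erd = pd.DataFrame(dict(subject=["A"] * 3, session=[0, 1, 2],
                                erd_percent=[-30, -31, -32]))
        with pytest.raises(ValueError, match="2 subjects"):
            fit_stage1(erd)

    def test_unbalanced_sessions_accepted(self):
        rng = np.random.default_rng(0)
        rows = []
        for i, n_sess in enumerate([5, 9, 13, 17, 8, 11]):
            b0, b1 = rng.normal(-30, 5), rng.normal(-0.5, 0.3)
            for j in sorted(rng.choice(20, size=n_sess, replace=False)):
                rows.append(dict(subject=f"S{i}", session=int(j),
                                 erd_percent=b0 + b1 * j + rng.normal(0, 3)))
        f = fit_stage1(pd.DataFrame(rows))
        assert np.isfinite(f.beta0) and np.isfinite(f.beta1)
        assert len(f.subjects) == 6


class TestFitStage2:
    def test_df_identity_22_subjects(self, cohort22, fits22):
        ipsi, _ = fits22
        r = fit_stage2(ipsi.subjects, cohort22.outcomes)
        assert (r.df1, r.df2) == (3, 18)
        assert r.n == 22

    def test_df2_identity_generic(self):
        rng = np.random.default_rng(1)
        for n in (8, 13, 30):
            subs = [f"S{i}" for i in range(n)]
            traj = _traj(subs, rng.normal(-30, 10, n), rng.normal(-0.5, 0.4, n))
            out = _outcomes(subs, rng.normal(0, 3, n))
            r = fit_stage2(traj, out)
            assert r.df2 == n - r.df1 - 1

    def test_adjusted_r2_below_r2(self, cohort22, fits22):
        ipsi, _ = fits22
        r = fit_stage2(ipsi.subjects, cohort22.outcomes)
        assert r.adj_r2 <= r.r2

    def test_planted_gamma3_sign_recovered(self):
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(10_000 + seed)
            I = rng.normal(-30, 10, 22)
            S = rng.normal(-0.5, 0.4, 22)
            delta = 2 + 0.05 * I - 4 * S - 0.15 * I * S + rng.normal(0, 0.5, 22)
            subs = [f"S{i:02d}" for i in range(22)]
            r = fit_stage2(_traj(subs, I, S), _outcomes(subs, delta))
            hits += r.coefficients["gamma3"] < 0
        assert hits / 50 >= 0.9

    def test_too_few_subjects_rejected(self):
        subs = list("ABCDE")
        with pytest.raises(ValueError, match="more than 5"):
            fit_stage2(_traj(subs, range(5), range(5)),
                       _outcomes(subs, range(5)))

    def test_missing_outcome_rejected(self, fits22, cohort22):
        ipsi, _ = fits22
        with pytest.raises(ValueError, match="no outcome"):
            fit_stage2(ipsi.subjects, cohort22.outcomes.iloc[:-1])


class TestMedianSplit:
    def test_example_four_subjects(self):
        traj = _traj(list("ABCD"), [-50, -40, -30, -20], [0] * 4)
        strong, weak = median_split(traj)
        assert sorted(strong.intercept) == [-50, -40]
        assert sorted(weak.intercept) == [-30, -20]

    def test_n22_even_split(self, fits22):
        ipsi, _ = fits22
        strong, weak = median_split(ipsi.subjects)
        assert len(strong) == len(weak) == 11
        assert strong.intercept.max() <= weak.intercept.min()

    def test_ties_resolved_deterministically(self):
        traj = _traj(list("ABCDEF"), [-30, -30, -30, -30, -20, -40], [0] * 6)
        s1, w1 = median_split(traj)
        s2, w2 = median_split(traj)
        pd.testing.assert_frame_equal(s1, s2)
        assert len(s1) == 3 and len(w1) == 3

    def test_too_small_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            median_split(_traj(list("ABC"), [1, 2, 3], [0] * 3))


class TestSubgroupRegression:
    def test_df_for_11_subjects(self):
        rng = np.random.default_rng(2)
        subs = [f"S{i}" for i in range(11)]
        traj = _traj(subs, rng.normal(size=11), rng.normal(size=11))
        out = _outcomes(subs, rng.normal(size=11))
        r = fit_subgroup_contralesional(traj, out)
        assert (r.df1, r.df2) == (1, 9)

    def test_constant_outcome_zero_slope(self):
        subs = [f"S{i}" for i in range(8)]
        traj = _traj(subs, np.zeros(8), np.linspace(-1, 1, 8))
        r = fit_subgroup_contralesional(traj, _outcomes(subs, [3.0] * 8))
        assert r.coefficients["slope"] == pytest.approx(0.0, abs=1e-10)
        assert r.fvalue == 0.0

    def test_planted_weak_only_relation(self):
        # plant a slope-outcome relation in the weak subgroup only and
        # recover the qualitative significance pattern
        rng = np.random.default_rng(3)
        subs = [f"S{i:02d}" for i in range(22)]
        initial = np.sort(rng.normal(-30, 10, 22))
        contra_slope = rng.normal(-0.3, 0.5, 22)
        traj_ipsi = _traj(subs, initial, rng.normal(-0.5, 0.4, 22))
        traj_contra = _traj(subs, rng.normal(-30, 10, 22), contra_slope)
        strong, weak = median_split(traj_ipsi)
        delta = np.where(np.isin(subs, weak.subject),
                         4.0 * contra_slope + rng.normal(0, 0.3, 22),
                         rng.normal(0, 1.0, 22))
        out = _outcomes(subs, delta)
        r_weak = fit_subgroup_contralesional(
            traj_contra[traj_contra.subject.isin(weak.subject)], out)
        r_strong = fit_subgroup_contralesional(
            traj_contra[traj_contra.subject.isin(strong.subject)], out)
        assert r_weak.pvalue < 0.05
        assert r_strong.pvalue > 0.05
        assert r_weak.coefficients["slope"] > 0

    def test_too_small_subgroup_rejected(self):
        with pytest.raises(ValueError, match="at least 3"):
            fit_subgroup_contralesional(
                _traj(["A", "B"], [0, 1], [0, 1]),
                _outcomes(["A", "B"], [0, 1]))


class TestPlc:
    def test_sign_convention(self):
        ipsi = _traj(["A"], [-30], [-0.5])     # lesioned-side slope S_L
        contra = _traj(["A"], [-30], [-0.2])   # healthy-side slope S_H
        plc = compute_plc(ipsi, contra)
        assert plc.plc.iloc[0] == pytest.approx(0.3)

    def test_equal_slopes_zero(self):
        ipsi = _traj(["A"], [-30], [-0.4])
        contra = _traj(["A"], [-30], [-0.4])
        assert compute_plc(ipsi, contra).plc.iloc[0] == 0.0

    def test_antisymmetric_under_swap(self):
        rng = np.random.default_rng(4)
        subs = list("ABCDE")
        a = _traj(subs, rng.normal(size=5), rng.normal(size=5))
        b = _traj(subs, rng.normal(size=5), rng.normal(size=5))
        fwd = compute_plc(a, b).plc.to_numpy()
        rev = compute_plc(b, a).plc.to_numpy()
        np.testing.assert_allclose(fwd, -rev)

    @given(st.floats(-5, 5, allow_nan=False), st.floats(-5, 5, allow_nan=False),
           st.floats(-10, 10, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_translation_invariance(self, s_h, s_l, c):
        base = compute_plc(_traj(["A"], [0], [s_l]),
                           _traj(["A"], [0], [s_h])).plc.iloc[0]
        shifted = compute_plc(_traj(["A"], [0], [s_l + c]),
                              _traj(["A"], [0], [s_h + c])).plc.iloc[0]
        assert shifted == pytest.approx(base, abs=1e-9)

    def test_missing_hemisphere_rejected(self):
        with pytest.raises(ValueError, match="missing hemisphere"):
            compute_plc(_traj(["A", "B"], [0, 0], [0, 0]),
                        _traj(["A"], [0], [0]))


class TestPlcRegression:
    def test_df_22_subjects(self):
        rng = np.random.default_rng(5)
        subs = [f"S{i}" for i in range(22)]
        plc = pd.DataFrame(dict(subject=subs, plc=rng.normal(size=22)))
        r = fit_plc_regression(plc, _outcomes(subs, rng.normal(size=22)))
        assert (r.df1, r.df2) == (1, 20)

    def test_planted_relation_recovered(self):
        rng = np.random.default_rng(6)
        subs = [f"S{i}" for i in range(22)]
        vals = rng.normal(0, 0.5, 22)
        plc = pd.DataFrame(dict(subject=subs, plc=vals))
        out = _outcomes(subs, 6.0 * vals + rng.normal(0, 0.3, 22))
        r = fit_plc_regression(plc, out)
        assert r.coefficients["plc"] > 0
        assert r.r2 > 0.8

    def test_degenerate_design_rejected(self):
        subs = list("ABCD")
        plc = pd.DataFrame(dict(subject=subs, plc=[0.5] * 4))
        with pytest.raises(ValueError, match="degenerate"):
            fit_plc_regression(plc, _outcomes(subs, [1, 2, 3, 4]))


class TestLrt:
    @pytest.fixture(scope="class")
    def ml_fits(self, cohort22):
        full = fit_stage1(cohort22.erd, "ipsilesional", "alpha", reml=False)
        reduced = fit_stage1(cohort22.erd, "ipsilesional", "alpha",
                             reml=False, random_slopes=False)
        return full, reduced

    def test_identical_models_null(self, ml_fits):
        full, _ = ml_fits
        r = lrt_compare(full, full)
        assert r.chi2 == 0.0 and r.pvalue == 1.0 and r.df == 0

    def test_random_slope_improves_fit_when_planted(self, ml_fits):
        # generator has sd_b1 > 0, so the slope model should win clearly
        full, reduced = ml_fits
        r = lrt_compare(full, reduced)
        assert r.df == 2
        assert r.chi2 > 0
        assert r.pvalue < 0.05

    def test_chi2_657_on_2df(self):
        from scipy import stats

        p = float(stats.chi2.sf(6.57, 2))
        assert p == pytest.approx(0.0374, abs=5e-4)
        assert round(p, 2) == round(0.038, 2)

    def test_non_nested_rejected(self, ml_fits):
        full, reduced = ml_fits
        with pytest.raises(ValueError, match="more parameters"):
            lrt_compare(reduced, full)

    def test_objective_mismatch_rejected(self, cohort22, ml_fits):
        full, _ = ml_fits
        reml_fit = fit_stage1(cohort22.erd, "ipsilesional", "alpha", reml=True)
        with pytest.raises(ValueError, match="objective"):
            lrt_compare(reml_fit, full)

    def test_power_grows_with_slope_variance(self):
        # rejection of the intercept-only model becomes near-certain as the
        # random-slope SD grows
        rejections = {0.05: 0, 1.5: 0}
        for sd_b1, _ in rejections.items():
            hits = 0
            for seed in range(5):
                spec = CohortSpec(n_subjects=16, sessions_per_subject=12,
                                  sd_b1=sd_b1, sigma_eps=6, seed=300 + seed)
                c = simulate_cohort(spec)
                full = fit_stage1(c.erd, "ipsilesional", "alpha", reml=False)
                red = fit_stage1(c.erd, "ipsilesional", "alpha", reml=False,
                                 random_slopes=False)
                hits += lrt_compare(full, red).pvalue < 0.05
            rejections[sd_b1] = hits
        assert rejections[1.5] == 5
        assert rejections[0.05] <= 2


class TestTwoStageProperty:
    def test_sign_pattern_recovery(self):
        ok = 0
        n_seeds = 60
        for seed in range(n_seeds):
            spec = CohortSpec(n_subjects=22, sessions_per_subject=17,
                              sigma_eps=3, sigma_out=0.25,
                              gamma=(2, 0.05, -4, -0.15), seed=seed)
            c = simulate_cohort(spec)
            f = fit_stage1(c.erd, "ipsilesional", "alpha")
            r = fit_stage2(f.subjects, c.outcomes)
            g = r.coefficients
            ok += ((g["gamma0"] > 0) and (g["gamma1"] > 0)
                   and (g["gamma2"] < 0) and (g["gamma3"] < 0))
        assert ok / n_seeds >= 0.9
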