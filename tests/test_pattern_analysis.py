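"""ROI selection, correlations, Fisher z, decorrelation, PSC, suppression bins."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import brentq

from adaptdecorr import encoding_sim as enc
from adaptdecorr import pattern_analysis as pa


def _make_betas(values, run_adaptor):
    return enc.BetaPatterns(
        values=np.asarray(values, dtype=float),
        run_adaptor=np.asarray(run_adaptor, dtype="<U1"),
        noise_sd=0.0,
    )


def _patterns_with_correlation(rng, n_vox, rho):
    """Two zero-mean patterns with population correlation rho (exact by construction)."""
    x = rng.standard_normal(n_vox)
    z = rng.standard_normal(n_vox)
    x = (x - x.mean()) / x.std()
    z = z - z.mean()
    z -= (z @ x) / (x @ x) * x  # orthogonalise
    z /= z.std()
    y = rho * x + np.sqrt(1 - rho**2) * z
    return x, y


class TestROISelection:
    def test_top_k_matches_argsort_oracle(self):
        rng = np.random.default_rng(0)
        contrast = rng.normal(size=500)
        parcel = np.zeros(500, dtype=bool)
        parcel[rng.choice(500, 300, replace=False)] = True
        roi = pa.select_roi(contrast, parcel, k=100)
        in_parcel = np.flatnonzero(parcel)
        expected = set(in_parcel[np.argsort(-contrast[in_parcel], kind="stable")[:100]])
        assert set(roi.indices) == expected
        assert contrast[roi.indices].min() >= contrast[np.setdiff1d(in_parcel, roi.indices)].max()

    def test_whole_parcel_when_k_equals_size(self):
        parcel = np.zeros(50, dtype=bool)
        parcel[10:30] = True
        roi = pa.select_roi(np.arange(50, dtype=float), parcel, k=20)
        assert np.array_equal(roi.indices, np.arange(10, 30))

    def test_tie_break_deterministic(self):
        contrast = np.ones(40)
        parcel = np.ones(40, dtype=bool)
        r1 = pa.select_roi(contrast, parcel, k=10)
        r2 = pa.select_roi(contrast, parcel, k=10)
        assert np.array_equal(r1.indices, r2.indices)
        assert np.array_equal(r1.indices, np.arange(10))  # ties -> lowest indices

    def test_rank_invariance_under_affine_map(self):
        rng = np.random.default_rng(1)
        contrast = rng.normal(size=80)
        parcel = np.ones(80, dtype=bool)
        r1 = pa.select_roi(contrast, parcel, k=25)
        r2 = pa.select_roi(3.5 * contrast + 11.0, parcel, k=25)
        assert np.array_equal(r1.indices, r2.indices)

    def test_small_parcel_rejected(self):
        with pytest.raises(ValueError):
            pa.select_roi(np.arange(10.0), np.ones(10, dtype=bool), k=11)


class TestCorrelationAndFisher:
    def test_self_and_affine(self):
        x = np.array([1.0, 5.0, 2.0, 4.0])
        assert pa.pattern_correlation(x, x) == pytest.approx(1.0)
        assert pa.pattern_correlation(x, 2 * x + 7) == pytest.approx(1.0)
        assert pa.pattern_correlation(np.array([1.0, 2, 3, 4]), np.array([4.0, 3, 2, 1])) == pytest.approx(-1.0)

    def test_constant_pattern_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            pa.pattern_correlation(np.ones(5), np.arange(5.0))

    def test_fisher_values_against_bisection_oracle(self):
        # independent route: invert tanh by bisection instead of calling atanh
        for r in (0.0, 0.5, -0.8, 0.95):
            z_oracle = 0.0 if r == 0 else brentq(lambda z: np.tanh(z) - r, -10, 10, xtol=1e-14)
            assert pa.fisher_z(r) == pytest.approx(z_oracle, abs=1e-12)
        assert pa.fisher_z(0.5) == pytest.approx(0.549306, abs=1e-6)

    def test_fisher_odd_symmetry_and_roundtrip(self):
        grid = np.linspace(-0.99, 0.99, 21)
        assert np.allclose(pa.fisher_z(-grid), -pa.fisher_z(grid))
        assert np.allclose(pa.inverse_fisher(pa.fisher_z(grid)), grid)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pa.fisher_z(1.0)


class TestDecorrelation:
    def test_known_correlations_give_exact_delta(self):
        # every run: r(pair) = 0.6 when unadapted, 0.4 when adapted
        rng = np.random.default_rng(3)
        n_vox = 400
        runs = []
        adaptors = ["A", "B", "A", "B"]
        for cls in adaptors:
            conds = {}
            for pair_cls, rho in (("A", 0.4 if cls == "A" else 0.6), ("B", 0.4 if cls == "B" else 0.6)):
                x, y = _patterns_with_correlation(rng, n_vox, rho)
                conds[pair_cls + "1"], conds[pair_cls + "2"] = x, y
            runs.append([conds[c] for c in enc.CONDITIONS])
        betas = _make_betas([runs], [adaptors])
        res = pa.decorrelation(betas, np.arange(n_vox))
        row = res.per_subject.iloc[0]
        assert row["r_adapted"] == pytest.approx(0.4, abs=1e-9)
        assert row["r_unadapted"] == pytest.approx(0.6, abs=1e-9)
        assert row["delta_r"] == pytest.approx(0.2, abs=1e-9)

    def test_condition_invariant_patterns_give_zero_delta(self):
        rng = np.random.default_rng(4)
        pair_a = _patterns_with_correlation(rng, 60, 0.5)
        pair_b = _patterns_with_correlation(rng, 60, 0.3)
        run = [pair_a[0], pair_a[1], pair_b[0], pair_b[1]]
        betas = _make_betas([[run, run]], [["A", "B"]])
        res = pa.decorrelation(betas, np.arange(60))
        assert res.per_subject["delta_r"].iloc[0] == pytest.approx(0.0, abs=1e-12)

    def test_missing_adaptor_class_rejected(self):
        rng = np.random.default_rng(5)
        run = [rng.standard_normal(20) for _ in range(4)]
        betas = _make_betas([[run, run]], [["A", "A"]])
        with pytest.raises(ValueError, match="missing"):
            pa.decorrelation(betas, np.arange(20))

    def test_fisher_route_not_naive_average(self):
        # two runs with r = 0.9 and 0.1: the z-route average differs from the
        # naive mean by construction; the implementation must take the z-route
        rng = np.random.default_rng(6)
        runs = []
        run_adaptors = ["A", "B"]
        for i, rho_unadapted in enumerate((0.9, 0.1)):
            conds = {}
            cls = run_adaptors[i]
            other = "B" if cls == "A" else "A"
            xa, ya = _patterns_with_correlation(rng, 300, 0.5)
            xu, yu = _patterns_with_correlation(rng, 300, rho_unadapted)
            conds[cls + "1"], conds[cls + "2"] = xa, ya
            conds[other + "1"], conds[other + "2"] = xu, yu
            runs.append([conds[c] for c in enc.CONDITIONS])
        betas = _make_betas([runs], [run_adaptors])
        res = pa.decorrelation(betas, np.arange(300))
        z_route = np.tanh((np.arctanh(0.9) + np.arctanh(0.1)) / 2)
        naive = 0.5
        assert abs(z_route - naive) > 0.01
        assert res.per_subject["r_unadapted"].iloc[0] == pytest.approx(z_route, abs=1e-9)

    def test_delta_invariant_under_common_affine_rescaling(self, graded_cohort):
        betas, _ = graded_cohort
        res1 = pa.decorrelation(betas, np.arange(betas.n_voxels))
        scaled = enc.BetaPatterns(
            values=3.0 * betas.values + 2.0,
            run_adaptor=betas.run_adaptor,
            noise_sd=betas.noise_sd,
        )
        res2 = pa.decorrelation(scaled, np.arange(betas.n_voxels))
        assert np.allclose(res1.delta_r, res2.delta_r, atol=1e-12)

    def test_most_subjects_decorrelate_under_default_mechanism(self, graded_cohort):
        from conftest import roi_delta_r

        betas, extras = graded_cohort
        drs = roi_delta_r(betas, extras["localizers"], k=100)
        assert (drs > 0).sum() >= 9


class TestPSC:
    def test_beta_equal_baseline_is_100(self):
        rng = np.random.default_rng(7)
        run = [np.full(20, 2.0) + 0 * rng.standard_normal(20) for _ in range(4)]
        betas = _make_betas([[run, run]], [["A", "B"]])
        psc = pa.percent_signal_change(betas, np.full(20, 2.0), np.arange(20))
        assert np.allclose(psc["psc"], 100.0)

    def test_zero_betas_zero_psc(self):
        run = [np.zeros(20) for _ in range(4)]
        betas = _make_betas([[run, run]], [["A", "B"]])
        psc = pa.percent_signal_change(betas, np.ones(20), np.arange(20))
        assert np.allclose(psc["psc"], 0.0)

    def test_nonpositive_baseline_rejected(self):
        run = [np.ones(20) for _ in range(4)]
        betas = _make_betas([[run, run]], [["A", "B"]])
        with pytest.raises(ValueError):
            pa.percent_signal_change(betas, np.zeros(20), np.arange(20))

    def test_suppressive_cohort_direction(self, graded_cohort):
        betas, _ = graded_cohort
        psc = pa.percent_signal_change(betas, np.ones(betas.n_voxels), np.arange(betas.n_voxels))
        means = psc.groupby("condition")["psc"].mean()
        assert means["adapted"] < means["unadapted"]


class TestScalingFactors:
    def test_identical_conditions_give_unity(self):
        rng = np.random.default_rng(8)
        run = [rng.uniform(0.5, 1.5, 30) for _ in range(4)]
        betas = _make_betas([[run, run]], [["A", "B"]])
        prof = pa.scaling_factors(betas, np.arange(30))[0]
        assert np.allclose(prof.scaling_factor, 1.0)

    def test_uniform_scaling_recovered(self):
        rng = np.random.default_rng(9)
        base = [rng.uniform(0.5, 1.5, 30) for _ in range(4)]
        run_a = [0.82 * base[0], 0.82 * base[1], base[2], base[3]]  # A adapted
        run_b = [base[0], base[1], 0.82 * base[2], 0.82 * base[3]]  # B adapted
        betas = _make_betas([[run_a, run_b]], [["A", "B"]])
        prof = pa.scaling_factors(betas, np.arange(30))[0]
        assert np.allclose(prof.scaling_factor, 0.82)

    def test_subset_ordering(self, graded_cohort):
        betas, _ = graded_cohort
        prof = pa.scaling_factors(betas, np.arange(betas.n_voxels), k=50)[0]
        sf = prof.scaling_factor
        assert np.nanmean(sf[prof.lowest_k]) <= np.nanmean(sf) <= np.nanmean(sf[prof.highest_k])


class TestBinnedDecorrelation:
    def test_small_bins_excluded(self):
        rng = np.random.default_rng(10)
        n_vox = 40
        run = [rng.uniform(0.5, 1.5, n_vox) + 0.05 * rng.standard_normal(n_vox) for _ in range(4)]
        betas = _make_betas([[run, run]] * 8, [["A", "B"]] * 8)
        profiles = pa.scaling_factors(betas, np.arange(n_vox))
        # force 9 voxels into one bin, the rest into another
        for p in profiles:
            p.scaling_factor[:] = 0.95
            p.scaling_factor[:9] = 0.85
        table = pa.binned_decorrelation(profiles, betas, np.array([0.8, 0.9, 1.0]))
        assert set(table["bin"]) == {1}  # the 9-voxel bin never appears

    def test_single_bin_equals_whole_roi(self, graded_cohort):
        betas, _ = graded_cohort
        roi = np.arange(betas.n_voxels)
        profiles = pa.scaling_factors(betas, roi)
        table = pa.binned_decorrelation(profiles, betas, np.array([0.0, 10.0]))
        whole = pa.decorrelation(betas, roi)
        assert table["mean_delta_r"].iloc[0] == pytest.approx(whole.delta_r.mean(), abs=1e-12)

    def test_all_bins_excluded_raises(self):
        rng = np.random.default_rng(11)
        run = [rng.uniform(0.5, 1.5, 30) for _ in range(4)]
        betas = _make_betas([[run, run]], [["A", "B"]])
        profiles = pa.scaling_factors(betas, np.arange(30))
        with pytest.raises(ValueError, match="no admissible bins"):
            pa.binned_decorrelation(profiles, betas, np.array([5.0, 6.0]))

    def test_default_cohort_bins_decorrelate(self, graded_cohort):
        # decorrelation is present across the suppression range, including the
        # most-suppressed admissible bin (significant paired test)
        betas, _ = graded_cohort
        roi = np.arange(betas.n_voxels)
        profiles = pa.scaling_factors(betas, roi)
        table = pa.binned_decorrelation(profiles, betas)
        inc = table[table["included"]]
        assert len(inc) >= 2
        assert (inc["n_subjects"] >= 7).all()
        assert (inc["mean_delta_r"] > 0).all()
        most_suppressed = inc.sort_values("bin_lo").iloc[0]
        assert most_suppressed["p"] < 0.05 and most_suppressed["t"] > 0


def test_paired_t_type_one_error_calibrated():
    """Null paired data rejected at ~5% over 10,000 replicates."""
    rng = np.random.default_rng(12)
    n = 10
    rejections = 0
    reps = 10_000
    for _ in range(reps):
        x = rng.standard_normal(n)
        y = rng.standard_normal(n)
        if pa.paired_t(x, y)["p"] < 0.05:
            rejections += 1
    assert abs(rejections / reps - 0.05) < 0.01


def test_null_cohort_decorrelation_test_calibrated(stimulus_set, small_grid):
    """With no adaptation, the cohort paired test on delta_r rejects at ~alpha.

    1000 synthetic cohorts are drawn analytically: condition amplitudes are
    identical across run types (mode none), so betas are amplitude + noise.
    """
    from scipy import stats

    subj = enc.build_subject(0, 11, small_grid, stimuli=stimulus_set,
                             mode=enc.AdaptationMode("none", 0.0), n_units=200)
    amp = subj.probe_amplitude_maps("A")[:, :100]  # (4, 100), same for all runs
    rng = np.random.default_rng(13)
    n_cohorts, n_sub, n_runs, n_vox = 1000, 10, 8, amp.shape[1]
    rejections = 0
    chunk = 100
    for start in range(0, n_cohorts, chunk):
        noise = rng.normal(0, 0.06, size=(chunk, n_sub, n_runs, 4, n_vox))
        x = amp[None, None, None] + noise
        xc = x - x.mean(axis=-1, keepdims=True)
        norm = np.sqrt((xc**2).sum(axis=-1))
        r_a = (xc[..., 0, :] * xc[..., 1, :]).sum(-1) / (norm[..., 0] * norm[..., 1])
        r_b = (xc[..., 2, :] * xc[..., 3, :]).sum(-1) / (norm[..., 2] * norm[..., 3])
        z_a, z_b = np.arctanh(r_a), np.arctanh(r_b)  # (chunk, n_sub, n_runs)
        # alternate run adaptor classes A,B,A,B...: label z-values accordingly
        a_runs = np.arange(n_runs) % 2 == 0
        z_ad = (z_a[..., a_runs].mean(-1) + z_b[..., ~a_runs].mean(-1)) / 2
        z_un = (z_a[..., ~a_runs].mean(-1) + z_b[..., a_runs].mean(-1)) / 2
        d = z_un - z_ad  # (chunk, n_sub)
        t = d.mean(1) / (d.std(1, ddof=1) / np.sqrt(n_sub))
        p = 2 * stats.t.sf(np.abs(t), df=n_sub - 1)
        rejections += int((p < 0.05).sum())
    rate = rejections / n_cohorts
    se = np.sqrt(0.05 * 0.95 / n_cohorts)
    assert abs(rate - 0.05) <= max(2 * se, 0.015)
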