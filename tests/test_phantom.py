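"""Phantom generators: geometry, AIF, simulators, cohort, biomarkers."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from svdquant.phantom import (Labels, PhantomSpec, generate_biomarker_panel,
                              generate_cohort, generate_phantom_masks,
                              make_class_library, make_truth_maps,
                              randomize_arms, simulate_aif,
                              simulate_dce_study, simulate_pet_study)
from svdquant.phantom.cohort import ARM_ACTIVE, ARM_PLACEBO
from svdquant.schedules import FrameSchedule


class TestFrameSchedule:
    def test_default_covers_75_minutes_in_55_frames(self):
        s = FrameSchedule.geometric()
        assert s.n_frames == 55
        assert s.total_s == pytest.approx(75 * 60)
        assert np.all(np.diff(s.duration_s) > 0)

    def test_contiguity_enforced(self):
        with pytest.raises(ValueError):
            FrameSchedule(np.array([0.0, 20.0]), np.array([10.0, 10.0]))


class TestMasks:
    def test_no_blobs_requested_means_no_wmh(self):
        spec = PhantomSpec(n_wmh_blobs=0)
        vol = generate_phantom_masks(spec)
        assert not np.any(vol.labels == Labels.WMH)

    def test_same_seed_same_volume(self):
        spec = PhantomSpec(seed=5)
        a = generate_phantom_masks(spec)
        b = generate_phantom_masks(spec)
        assert np.array_equal(a.labels, b.labels)

    def test_different_seed_differs(self):
        a = generate_phantom_masks(PhantomSpec(seed=1))
        b = generate_phantom_masks(PhantomSpec(seed=2))
        assert not np.array_equal(a.labels, b.labels)

    def test_wmh_count_consistent_with_sphere_volumes(self):
        # independent oracle: expected blob volume = (4/3) pi E[r^3] for
        # radii ~ U(2, 4): E[r^3] = (4^4 - 2^4) / (4 * (4 - 2)) = 30
        spec = PhantomSpec(n_wmh_blobs=3, seed=9)
        vol = generate_phantom_masks(spec)
        count = int(np.sum(vol.labels == Labels.WMH))
        expected = 3 * (4.0 / 3.0) * np.pi * 30.0
        assert 0.5 * expected <= count <= 1.5 * expected

    def test_sss_roi_nonempty_and_tubular(self):
        vol = generate_phantom_masks(PhantomSpec())
        sss = vol.labels == Labels.SSS
        assert sss.sum() > 0
        # tube spans a contiguous range of slices along z
        zs = np.unique(np.argwhere(sss)[:, 2])
        assert np.array_equal(zs, np.arange(zs.min(), zs.max() + 1))

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            PhantomSpec(hct=1.5)
        with pytest.raises(ValueError):
            PhantomSpec(hotspot_fraction=1.5)


class TestAif:
    def test_zero_at_injection(self):
        wb, cp, _ = simulate_aif(np.array([0.0, 1.0, 5.0]), 0.025, 0.45)
        assert wb[0] == 0.0 and cp[0] == 0.0

    def test_dose_linearity(self):
        t = np.linspace(0, 8, 9)
        _, cp1, _ = simulate_aif(t, 0.025, 0.45)
        _, cp2, _ = simulate_aif(t, 0.050, 0.45)
        assert np.allclose(cp2, 2.0 * cp1, rtol=1e-12)

    def test_plasma_is_whole_blood_over_one_minus_hct(self):
        t = np.linspace(0, 8, 9)
        wb, cp, _ = simulate_aif(t, 0.025, 0.45)
        assert np.allclose(cp, wb / 0.55, rtol=1e-12)

    def test_closed_form_integral_matches_dense_trapezoid(self):
        # the analytic running integral is the oracle for Patlak forward
        t = np.linspace(0, 8, 20001)
        _, cp, model = simulate_aif(t, 0.025, 0.45)
        dense = np.concatenate([[0.0], np.cumsum(
            0.5 * (cp[1:] + cp[:-1]) * np.diff(t))])
        assert np.max(np.abs(dense - model.plasma_integral(t))) < 1e-7

    def test_invalid_hct_rejected(self):
        with pytest.raises(ValueError):
            simulate_aif(np.array([0.0, 1.0]), 0.025, 1.2)


class TestDceSimulator:
    def test_no_leakage_no_vascular_term_means_static_signal(self):
        spec = PhantomSpec(noise_sd_dce=0.0, noise_sd_pet=0.0, n_wmh_blobs=0,
                           hotspot_fraction=0.0)
        rng = np.random.default_rng(0)
        masks = generate_phantom_masks(spec)
        truth = make_truth_maps(masks, spec, rng)
        zero = np.zeros(masks.shape)
        dce = simulate_dce_study(masks, zero, zero, truth.t1_ms, spec, rng)
        tissue = masks.labels == Labels.WM
        for c in range(1, dce.signals.shape[0]):
            assert np.allclose(dce.signals[c][:, tissue],
                               dce.signals[0][:, tissue], rtol=1e-12)

    def test_sss_voxels_carry_whole_blood_concentration(self, clean_phantom):
        # blood T1 shortening in the sinus follows C_wb, not the tissue model
        from svdquant.dce_patlak import concentration_from_t1
        masks, dce = clean_phantom["masks"], clean_phantom["dce"]
        from svdquant.t1_mapping import fit_vfa_t1
        fits = [fit_vfa_t1(np.moveaxis(dce.signals[c], 0, -1),
                           dce.flip_angles_deg, dce.tr_ms) for c in (0, 4)]
        sss = masks.mask(Labels.SSS)
        conc = concentration_from_t1(fits[1].t1_ms[sss], fits[0].t1_ms[sss])
        wb = dce.aif_model.whole_blood(dce.cycle_times_min[3])
        assert conc.mean() == pytest.approx(wb, rel=1e-6)

    def test_negative_truth_t1_rejected(self):
        spec = PhantomSpec(noise_sd_dce=0.0)
        rng = np.random.default_rng(0)
        masks = generate_phantom_masks(spec)
        truth = make_truth_maps(masks, spec, rng)
        bad = truth.t1_ms.copy()
        bad[masks.labels > 0] = -1.0
        with pytest.raises(ValueError):
            simulate_dce_study(masks, truth.ki, truth.vp, bad, spec, rng)


class TestPetSimulator:
    def test_pure_reference_voxel_equals_white_curve(self, clean_phantom, schedule):
        spec, masks, lib = (clean_phantom[k] for k in ("spec", "masks", "library"))
        rng = np.random.default_rng(0)
        shape = masks.shape
        ones, zeros = np.ones(shape), np.zeros(shape)
        pet = simulate_pet_study(masks, ones, 0.1 * ones, zeros, zeros,
                                 lib, schedule, spec, rng)
        wm = masks.labels == Labels.WM
        idx = np.argwhere(wm)[0]
        tac = pet.tacs[:, idx[0], idx[1], idx[2]]
        assert np.allclose(tac, lib.white, rtol=1e-9)

    def test_pure_vascular_voxel_equals_blood_curve(self, clean_phantom, schedule):
        spec, masks, lib = (clean_phantom[k] for k in ("spec", "masks", "library"))
        rng = np.random.default_rng(0)
        shape = masks.shape
        ones = np.ones(shape)
        pet = simulate_pet_study(masks, ones, 0.1 * ones, np.zeros(shape),
                                 ones, lib, schedule, spec, rng)
        wm = masks.labels == Labels.WM
        idx = np.argwhere(wm)[0]
        tac = pet.tacs[:, idx[0], idx[1], idx[2]]
        assert np.allclose(tac, lib.blood, rtol=1e-9)

    def test_bp_below_minus_one_rejected(self, clean_phantom, schedule):
        spec, masks, lib = (clean_phantom[k] for k in ("spec", "masks", "library"))
        rng = np.random.default_rng(0)
        shape = masks.shape
        ones = np.ones(shape)
        with pytest.raises(ValueError):
            simulate_pet_study(masks, ones, 0.1 * ones, -1.5 * ones,
                               np.zeros(shape), lib, schedule, spec, rng)

    def test_library_classes_independent_and_nonnegative(self, clean_phantom):
        lib = clean_phantom["library"]
        assert np.all(lib.class_tacs >= 0)
        assert np.linalg.matrix_rank(lib.class_tacs) == 4


class TestRandomization:
    def test_n44_complete_blocks_gives_22_per_arm(self):
        for seed in range(5):
            arms = randomize_arms(44, seed=seed)
            assert np.sum(arms == ARM_ACTIVE) == 22

    def test_prefix_imbalance_never_exceeds_two(self):
        for seed in range(20):
            arms = randomize_arms(101, seed=seed)
            run = np.cumsum(np.where(arms == ARM_ACTIVE, 1, -1))
            assert np.max(np.abs(run)) <= 2

    def test_first_allocation_is_balanced_across_seeds(self):
        first = [randomize_arms(4, seed=s)[0] == ARM_ACTIVE for s in range(1000)]
        assert abs(np.mean(first) - 0.5) < 0.04


class TestCohort:
    def test_arm_counts_follow_block_randomization(self):
        df = generate_cohort(44, seed=7)
        assert (df.arm == ARM_ACTIVE).sum() == 22
        assert (df.arm == ARM_PLACEBO).sum() == 22

    def test_active_arm_age_mean_matches_target_over_reps(self):
        means = [generate_cohort(44, seed=s)
                 .query("arm == @ARM_ACTIVE")["age_years"].mean()
                 for s in range(200)]
        mc_se = np.std(means) / np.sqrt(len(means))
        assert abs(np.mean(means) - 73.0) < 4 * mc_se + 0.05

    def test_wmh_volume_lognormal_moments(self):
        rows = pd.concat([generate_cohort(44, seed=s) for s in range(100)])
        act = rows[rows.arm == ARM_ACTIVE]["wmh_volume_cc"]
        assert act.mean() == pytest.approx(31.2, rel=0.1)
        assert act.std() == pytest.approx(22.6, rel=0.2)

    def test_perfect_qalb_correlation_when_rho_one(self):
        from svdquant.trial_stats import qalb, qalb_validation
        df = generate_cohort(44, seed=3, qalb_rho=1.0)
        lp = df.dropna(subset=["csf_albumin_mg_L"])
        ratios = qalb(lp["csf_albumin_mg_L"], lp["serum_albumin_g_L"])
        out = qalb_validation(ratios, lp["true_mean_ki"])
        assert out["pearson_r"] == pytest.approx(1.0, abs=1e-9)

    def test_minimum_size_enforced(self):
        with pytest.raises(ValueError):
            generate_cohort(1)


class TestBiomarkers:
    def test_rank_one_panel_explains_everything(self):
        from svdquant.trial_stats import pca_treatment
        cohort = generate_cohort(30, seed=0)
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(30, 1))
        load = rng.normal(size=(1, 20))
        X = pd.DataFrame(scores @ load, columns=[f"P{i:03d}" for i in range(20)])
        X.insert(0, "subject_id", cohort.subject_id.to_numpy())
        pca, _ = pca_treatment(X, X, cohort, k=1,
                               protein_cols=[c for c in X if c.startswith("P0") or c.startswith("P1")])
        assert pca.variance_share[0] == pytest.approx(1.0, abs=1e-9)

    def test_first_three_pc_share_near_target(self):
        from svdquant.trial_stats import pca_treatment
        shares = []
        for s in range(10):
            cohort = generate_cohort(44, seed=s)
            base, follow = generate_biomarker_panel(cohort, seed=s)
            prot = [c for c in base.columns if c.startswith("P")]
            pca, _ = pca_treatment(base, follow, cohort, protein_cols=prot)
            shares.append(float(np.sum(pca.variance_share[:3])))
        assert abs(np.mean(shares) - 0.45) < 0.10

    def test_null_panel_rarely_flags_proteins(self):
        from svdquant.trial_stats import biomarker_analysis
        n_sig = []
        for s in range(12):
            cohort = generate_cohort(44, seed=s)
            base, follow = generate_biomarker_panel(cohort, seed=s,
                                                    treatment_effects=1.0)
            prot = [c for c in base.columns if c.startswith("P")]
            res = biomarker_analysis(base, follow, cohort, m=92,
                                     protein_cols=prot)
            n_sig.append(int(res.bonferroni_significant.sum()))
        assert np.mean([n == 0 for n in n_sig]) >= 0.95 - 1e-9

    def test_validates_factor_count(self):
        cohort = generate_cohort(10, seed=0)
        with pytest.raises(ValueError):
            generate_biomarker_panel(cohort, k_factors=92)


class TestDeterminism:
    def test_identical_spec_and_seed_bitwise_identical(self, schedule):
        spec = PhantomSpec(seed=13)
        outs = []
        for _ in range(2):
            rng = np.random.default_rng(13)
            masks = generate_phantom_masks(spec)
            truth = make_truth_maps(masks, spec, rng)
            lib = make_class_library(spec, schedule, rng, n_control=500)
            dce = simulate_dce_study(masks, truth.ki, truth.vp, truth.t1_ms,
                                     spec, rng)
            outs.append((masks.labels, truth.ki, lib.control_ki_values,
                         dce.signals))
        for a, b in zip(*outs):
            assert np.array_equal(a, b)
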