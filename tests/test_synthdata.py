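"""Synthetic cohort generator: parcellation, AR sampling, motion, behavior."""

import json
from pathlib import Path

import numpy as np
import pytest

from fct.parcellation import make_parcellation
from fct.synthdata import (
    CohortConfig,
    build_cohort,
    make_ar_modes,
    sample_similarity_kernel,
    sample_subject_ar,
    simulate_behavior,
    simulate_motion,
    simulate_run,
    spectral_radius,
    true_variance_explained,
)
from fct.timeseries import CensorMask, compute_censor_mask, dynamic_fc, run_passes_qc


class TestParcellation:
    def test_contiguous_assignment(self):
        p = make_parcellation(8, {"A": 4, "B": 4})
        assert p.networks == ("A",) * 4 + ("B",) * 4
        assert p.roi_ids[0] == "ROI001"

    def test_full_scale_layout(self):
        sizes = {
            "VIS": 61, "SM": 77, "D-Att": 46, "Sal": 47,
            "Lim": 26, "FP": 52, "DMN": 91, "Sub": 19,
        }
        assert sum(v for k, v in sizes.items() if k != "Sub") == 400
        p = make_parcellation(419, sizes)
        assert p.n_roi == 419
        assert len(p.label_order()) == 8

    def test_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            make_parcellation(8, {"A": 4, "B": 3})

    def test_single_network_rejected(self):
        with pytest.raises(ValueError):
            make_parcellation(4, {"A": 4})

    def test_subnetwork_split(self):
        p = make_parcellation(8, {"A": 4, "B": 4}, subnetworks_per_network=2)
        assert p.subnetworks == ("A-1", "A-1", "A-2", "A-2", "B-1", "B-1", "B-2", "B-2")


class TestSampleSubjectAR:
    BASE = np.array([[0.5, 0.1], [0.0, 0.4]])

    def test_zero_scale_returns_rescaled_base(self):
        a = sample_subject_ar(self.BASE, 0.0, 0.8, seed=0)
        assert spectral_radius(a) == pytest.approx(0.8, abs=1e-10)
        assert np.allclose(a, self.BASE * (0.8 / 0.5), atol=1e-12)

    def test_two_seeds_differ_but_share_radius(self):
        a1 = sample_subject_ar(self.BASE, 0.3, 0.85, seed=1)
        a2 = sample_subject_ar(self.BASE, 0.3, 0.85, seed=2)
        assert not np.allclose(a1, a2)
        for a in (a1, a2):
            assert spectral_radius(a) == pytest.approx(0.85, abs=1e-10)

    def test_nonstationary_radius_rejected(self):
        with pytest.raises(ValueError):
            sample_subject_ar(self.BASE, 0.1, 1.0, seed=0)

    def test_deterministic_given_seed(self):
        assert np.array_equal(
            sample_subject_ar(self.BASE, 0.3, 0.85, seed=5),
            sample_subject_ar(self.BASE, 0.3, 0.85, seed=5),
        )


class TestSimulateRun:
    def test_noiseless_recursion_exact(self, rng):
        a = np.array([[0.5, 0.2], [0.1, 0.6]])
        x0 = np.array([1.0, -1.0])
        run = simulate_run(a, 0.0, 5, burn_in=0, seed=0, x0=x0)
        expected = []
        x = x0
        for _ in range(5):
            x = a @ x
            expected.append(x)
        assert np.allclose(run.data, expected, atol=1e-14)

    def test_unstable_matrix_rejected(self):
        with pytest.raises(ValueError):
            simulate_run(np.eye(3) * 1.01, 1.0, 10)

    def test_stationary_variance_bounded(self):
        a = np.diag([0.9, 0.5])
        run = simulate_run(a, 1.0, 5000, seed=1)
        v = run.data.var(axis=0)
        # analytic stationary variances 1/(1-a^2)
        assert v[0] == pytest.approx(1 / (1 - 0.81), rel=0.15)
        assert v[1] == pytest.approx(1 / (1 - 0.25), rel=0.15)

    def test_fit_error_shrinks_with_length(self):
        parc = make_parcellation(20, {"A": 10, "B": 10})
        base = make_ar_modes(parc, 1, seed=0)[0]
        a = sample_subject_ar(np.eye(20) * 0.7 + base, 0.2, 0.9, seed=3)
        errs = {}
        for t in (1200, 4800):
            run = simulate_run(a, 1.0, t, seed=4)
            fit = dynamic_fc([(run, CensorMask(keep=np.ones(t, bool)))])
            errs[t] = np.linalg.norm(fit.A - a) / np.linalg.norm(a)
        assert errs[4800] < errs[1200]
        assert errs[4800] < 0.2


class TestSimulateMotion:
    def test_zero_target_is_spotless(self):
        fd, dv = simulate_motion(500, 0.0, seed=0)
        assert fd.max() < 0.2 and dv.max() < 75
        assert compute_censor_mask(fd, dv).keep.all()

    def test_target_fraction_achieved(self):
        for seed in range(3):
            fd, dv = simulate_motion(1200, 0.2, seed=seed)
            frac = compute_censor_mask(fd, dv).censored_fraction
            assert 0.15 <= frac <= 0.25

    def test_heavy_motion_run_fails_qc(self):
        fd, dv = simulate_motion(1200, 0.7, seed=1)
        assert not run_passes_qc(compute_censor_mask(fd, dv))

    def test_infeasible_target_rejected(self):
        # at 12 frames a single spike censors far more than 10% (frame
        # expansion plus the minimum-segment rule), so the target cannot
        # be approached
        with pytest.raises(ValueError):
            simulate_motion(12, 0.1, seed=0)

    def test_invalid_target_rejected(self):
        with pytest.raises(ValueError):
            simulate_motion(100, 1.0, seed=0)


class TestSimulateBehavior:
    def test_true_m_from_traces(self):
        q = 5
        m, m_i = true_variance_explained([0.4 * np.eye(q)], 0.6 * np.eye(q))
        assert m == pytest.approx(0.4, abs=1e-15)
        assert np.allclose(m_i, 0.4)

    def test_null_signal_fits_near_zero(self):
        from fct.vcm import fit_vcm

        f = sample_similarity_kernel(150, seed=0)
        y, m_true, _ = simulate_behavior([f], [np.zeros((8, 8))], np.eye(8), seed=1)
        assert m_true == 0.0
        assert fit_vcm(y, [f]).M < 0.12

    def test_pure_signal_gram_structure(self):
        f = sample_similarity_kernel(60, seed=2)
        q = 200
        y, _, _ = simulate_behavior([f], [np.eye(q)], np.zeros((q, q)), seed=3)
        gram = y @ y.T / q
        # per-subject Gram of a pure-signal draw concentrates around F
        assert np.corrcoef(gram.ravel(), f.ravel())[0, 1] > 0.9

    def test_matrix_normal_covariance_converges(self):
        # empirical covariance of Vec(C) over 2000 draws vs Sigma_c (x) F
        n, q = 4, 2
        f = np.array(
            [
                [1.0, 0.6, 0.3, 0.1],
                [0.6, 1.0, 0.4, 0.2],
                [0.3, 0.4, 1.0, 0.5],
                [0.1, 0.2, 0.5, 1.0],
            ]
        )
        sc = np.array([[1.0, 0.4], [0.4, 0.8]])
        reps = 2000
        draws = np.empty((reps, n * q))
        for r in range(reps):
            y, _, _ = simulate_behavior([f], [sc], np.zeros((q, q)), seed=r)
            draws[r] = y.flatten(order="F")  # stack columns: Vec(C)
        emp = np.cov(draws, rowvar=False)
        target = np.kron(sc, f)
        # entrywise 3-standard-error band for a covariance of gaussians
        se = np.sqrt(
            (np.outer(np.diag(target), np.diag(target)) + target**2) / reps
        )
        assert np.all(np.abs(emp - target) < 3.5 * se + 1e-12)

    def test_non_psd_kernel_rejected(self):
        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        with pytest.raises(ValueError):
            simulate_behavior([bad], [np.eye(2)], np.eye(2), seed=0)

    def test_dimension_mismatch_rejected(self):
        f = sample_similarity_kernel(10, seed=1)
        with pytest.raises(ValueError):
            simulate_behavior([f], [np.eye(2)], np.eye(3), seed=0)


class TestBuildCohort:
    def test_ground_truth_m_matches_trace_formula(self, small_cohort):
        gt = small_cohort.ground_truth
        m, m_i = true_variance_explained(gt.sigma_c_list, gt.sigma_e)
        assert gt.M == pytest.approx(m, abs=1e-15)
        assert np.allclose(gt.M_i, m_i)

    def test_every_subject_ar_is_stationary(self, small_cohort):
        for a in small_cohort.ground_truth.subject_A:
            assert spectral_radius(a) < 1.0

    def test_fitted_r2_in_calibration_band(self, small_cohort):
        assert 0.55 <= small_cohort.mean_r2 <= 0.85

    def test_zero_subjects_rejected(self):
        with pytest.raises(ValueError):
            build_cohort(CohortConfig(n_subjects=0))

    def test_bundle_roundtrip_and_determinism(self, tmp_path):
        from fct.io import load_cohort

        cfg = CohortConfig(
            n_subjects=6, n_runs=1, n_frames=250, n_task=2, n_self=2,
            n_unclassified=1, seed=11,
        )
        d1, d2 = tmp_path / "a", tmp_path / "b"
        build_cohort(cfg, out_dir=d1)
        build_cohort(cfg, out_dir=d2)
        assert (d1 / "behavior.csv").read_bytes() == (d2 / "behavior.csv").read_bytes()
        assert (d1 / "ground_truth.json").read_bytes() == (d2 / "ground_truth.json").read_bytes()

        loaded = load_cohort(d1)
        assert loaded.subject_ids == [f"sub-{i:03d}" for i in range(1, 7)]
        direct = build_cohort(cfg)
        sid = loaded.subject_ids[0]
        assert np.allclose(
            loaded.runs[sid][0].data, direct.runs[sid][0].data, atol=1e-9
        )
        assert json.loads((d1 / "manifest.json").read_text())["config"]["seed"] == 11


class TestSampleSimilarityKernel:
    def test_unit_diagonal_and_psd(self):
        f = sample_similarity_kernel(30, seed=0)
        assert np.allclose(np.diag(f), 1.0)
        assert np.linalg.eigvalsh(f).min() > -1e-10

    def test_shared_component_raises_offdiagonal(self):
        f = sample_similarity_kernel(30, seed=0, shared_scale=2.0, n_factors=0)
        tri = f[np.triu_indices(30, 1)]
        assert tri.mean() > 0.5
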