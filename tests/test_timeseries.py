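"""Censoring rules, nuisance regression, and static/dynamic FC estimation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fct.timeseries import (
    CensorMask,
    DegenerateDataError,
    RunTimeSeries,
    ar_pairs,
    compute_censor_mask,
    dynamic_fc,
    regress_nuisance,
    run_passes_qc,
    static_fc,
)


def clean_run(data, run_id="run-1"):
    n = data.shape[0]
    return RunTimeSeries(data=data, fd=np.zeros(n), dvars=np.zeros(n), run_id=run_id)


def full_mask(n):
    return CensorMask(keep=np.ones(n, dtype=bool))


class TestCensorMask:
    def test_all_clean_keeps_everything(self):
        m = compute_censor_mask(np.full(10, 0.1), np.full(10, 50.0))
        assert m.keep.all()
        assert m.segments == [(0, 10)]

    def test_single_spike_with_expansion_and_segment_cleanup(self):
        # 10 frames, FD spike at frame 4 (1-based): frames 3-6 censored by
        # 1-before/2-after expansion; remainders {1-2} and {7-10} are both
        # shorter than 5 frames and are removed entirely
        fd = np.full(10, 0.1)
        fd[3] = 0.25
        m = compute_censor_mask(fd, np.full(10, 50.0))
        assert not m.keep.any()
        assert m.segments == []

    def test_thresholds_are_strict_inequalities(self):
        m = compute_censor_mask(np.full(10, 0.2), np.full(10, 75.0))
        assert m.keep.all()

    def test_dvars_triggers_too(self):
        dv = np.full(20, 50.0)
        dv[10] = 75.5
        m = compute_censor_mask(np.full(20, 0.1), dv)
        assert not m.keep[9:13].any()
        assert m.keep[:9].all() and m.keep[13:].all()

    def test_expansion_clipped_at_run_boundaries(self):
        fd = np.full(12, 0.1)
        fd[0] = 0.3
        m = compute_censor_mask(fd, np.full(12, 50.0))
        # frames 0-2 censored (no frame before 0 to expand into)
        assert not m.keep[:3].any() and m.keep[3:].all()

    def test_short_segment_between_spikes_removed(self):
        fd = np.full(20, 0.1)
        fd[[5, 12]] = 0.3                 # censored: 4-7 and 11-14
        m = compute_censor_mask(fd, np.full(20, 50.0))
        assert not m.keep[8:11].any()     # 3-frame island removed
        assert m.keep[15:].all()          # trailing 5-frame segment kept
        assert not m.keep[:4].any()       # leading 4-frame segment removed

    def test_empty_traces_rejected(self):
        with pytest.raises(ValueError):
            compute_censor_mask(np.array([]), np.array([]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_raising_fd_threshold_never_censors_more(self, seed):
        r = np.random.default_rng(seed)
        fd = r.uniform(0, 0.4, size=60)
        dv = r.uniform(0, 100, size=60)
        strict = compute_censor_mask(fd, dv, fd_thresh=0.2)
        loose = compute_censor_mask(fd, dv, fd_thresh=0.3)
        # every frame kept under the stricter threshold is kept under the looser one
        assert np.all(loose.keep[strict.keep])

    def test_deterministic(self):
        r = np.random.default_rng(3)
        fd, dv = r.uniform(0, 0.4, 50), r.uniform(0, 100, 50)
        a = compute_censor_mask(fd, dv)
        b = compute_censor_mask(fd, dv)
        assert np.array_equal(a.keep, b.keep)


class TestRunQC:
    @pytest.mark.parametrize(
        "censored,expected",
        [(0, True), (50, True), (51, False), (100, False)],
    )
    def test_discard_rule_is_strict(self, censored, expected):
        keep = np.ones(100, dtype=bool)
        keep[:censored] = False
        assert run_passes_qc(CensorMask(keep=keep)) is expected


class TestRegressNuisance:
    def test_linear_ramp_removed(self, rng):
        n = 50
        ramp = np.linspace(0, 1, n)[:, None] * rng.uniform(1, 3, size=6)[None, :]
        out = regress_nuisance(clean_run(ramp), full_mask(n), regress_global=False)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_global_regressor_absorbs_shared_signal(self, rng):
        n = 80
        shared = rng.standard_normal(n)
        data = np.tile(shared[:, None], (1, 5))
        out = regress_nuisance(clean_run(data), full_mask(n), regress_global=True)
        assert np.allclose(out.data, 0.0, atol=1e-10)

    def test_spikes_at_censored_frames_do_not_move_coefficients(self, rng):
        n = 100
        data = rng.standard_normal((n, 4)) + np.linspace(0, 2, n)[:, None]
        keep = np.ones(n, dtype=bool)
        keep[40:45] = False
        mask = CensorMask(keep=keep)
        spiked = data.copy()
        spiked[40:45] += 50.0
        a = regress_nuisance(clean_run(data), mask, regress_global=False)
        b = regress_nuisance(clean_run(spiked), mask, regress_global=False)
        assert np.allclose(a.data[keep], b.data[keep], atol=1e-8)

    def test_too_few_kept_frames(self, rng):
        data = rng.standard_normal((10, 3))
        keep = np.zeros(10, dtype=bool)
        keep[:2] = True
        with pytest.raises(DegenerateDataError):
            regress_nuisance(clean_run(data), CensorMask(keep=keep))


class TestStaticFC:
    def test_two_identical_runs_return_that_matrix(self, rng):
        data = rng.standard_normal((200, 5))
        runs = [
            (clean_run(data, "run-1"), full_mask(200)),
            (clean_run(data, "run-2"), full_mask(200)),
        ]
        single = static_fc(runs[:1]).matrix
        double = static_fc(runs).matrix
        assert np.allclose(single, double, atol=1e-12)
        assert np.allclose(single, np.corrcoef(data.T), atol=1e-10)

    def test_fisher_average_of_two_correlations(self):
        # two 2-ROI runs engineered to have r = 0.5 and r = 0.9;
        # the averaged value must be tanh((atanh(.5)+atanh(.9))/2) ~ 0.766
        def run_with_corr(r, seed):
            g = np.random.default_rng(seed)
            x = g.standard_normal((4000, 2))
            x -= x.mean(0)
            # whiten the sample exactly, then recolor to correlation r
            x = x @ np.linalg.inv(np.linalg.cholesky(np.cov(x.T))).T
            c = np.array([[1.0, r], [r, 1.0]])
            return x @ np.linalg.cholesky(c).T

        ra, rb = run_with_corr(0.5, 0), run_with_corr(0.9, 1)
        out = static_fc(
            [(clean_run(ra), full_mask(4000)), (clean_run(rb), full_mask(4000))]
        ).matrix
        expected = np.tanh((np.arctanh(0.5) + np.arctanh(0.9)) / 2.0)
        assert out[0, 1] == pytest.approx(expected, abs=1e-6)

    def test_symmetric_unit_diagonal(self, rng):
        data = rng.standard_normal((100, 8))
        out = static_fc([(clean_run(data), full_mask(100))]).matrix
        assert np.array_equal(out, out.T)
        assert np.array_equal(np.diag(out), np.ones(8))
        assert np.all(np.abs(out) <= 1.0 + 1e-12)

    def test_constant_roi_rejected(self):
        data = np.ones((50, 3))
        with pytest.raises(DegenerateDataError):
            static_fc([(clean_run(data), full_mask(50))])


def pairlist_lstsq(segments_data):
    """Oracle: explicit least squares over an enumerated pair list."""
    xp = np.vstack([d[:-1] for d in segments_data])
    xn = np.vstack([d[1:] for d in segments_data])
    at, *_ = np.linalg.lstsq(xp, xn, rcond=None)
    return at.T


class TestDynamicFC:
    def test_noiseless_recursion_recovered_exactly(self, rng):
        r = 6
        a = rng.standard_normal((r, r))
        a *= 0.8 / np.max(np.abs(np.linalg.eigvals(a)))
        segs = []
        for s in range(3):
            x = rng.standard_normal(r)
            rows = [x]
            for _ in range(19):
                rows.append(a @ rows[-1])
            segs.append(np.array(rows))
        data = np.vstack(segs)
        runs = [(clean_run(d, f"run-{i}"), full_mask(20)) for i, d in enumerate(segs)]
        fit = dynamic_fc(runs)
        assert np.allclose(fit.A, a, atol=1e-9)
        assert fit.r2 > 1 - 1e-9

    def test_run_boundary_pair_excluded(self, rng):
        data = rng.standard_normal((100, 3))
        whole = [(clean_run(data), full_mask(100))]
        split = [
            (clean_run(data[:60], "run-1"), full_mask(60)),
            (clean_run(data[60:], "run-2"), full_mask(40)),
        ]
        fit_split = dynamic_fc(split)
        oracle = pairlist_lstsq([data[:60], data[60:]])
        assert np.allclose(fit_split.A, oracle, atol=1e-12)
        # and the boundary pair genuinely matters: whole-run fit differs
        assert not np.allclose(dynamic_fc(whole).A, fit_split.A, atol=1e-12)

    def test_matches_pairlist_oracle_under_censoring(self, rng):
        data = rng.standard_normal((120, 4))
        keep = np.ones(120, dtype=bool)
        keep[30:40] = False
        keep[80:84] = False
        mask = CensorMask(keep=keep)
        fit = dynamic_fc([(clean_run(data), mask)])
        oracle = pairlist_lstsq([data[s:e] for s, e in mask.segments])
        assert np.allclose(fit.A, oracle, atol=1e-12)
        assert fit.n_pairs == sum(e - s - 1 for s, e in mask.segments)

    def test_white_noise_gives_near_zero_A(self):
        g = np.random.default_rng(0)
        data = g.standard_normal((10_000, 4))
        fit = dynamic_fc([(clean_run(data), full_mask(10_000))])
        assert np.linalg.norm(fit.A, "fro") < 0.05
        assert abs(fit.r2) < 0.02

    def test_refit_on_resimulated_data_preserves_r2(self, rng):
        # simulate from a fitted model; the refit r2 should sit near the
        # original fit's r2 (model self-consistency)
        from fct.synthdata import simulate_run

        r = 8
        a = rng.standard_normal((r, r))
        a *= 0.85 / np.max(np.abs(np.linalg.eigvals(a)))
        run = simulate_run(a, 1.0, 3000, seed=5)
        fit = dynamic_fc([(run, full_mask(3000))])
        run2 = simulate_run(fit.A, fit.resid_cov, 3000, seed=6)
        fit2 = dynamic_fc([(run2, full_mask(3000))])
        assert fit2.r2 == pytest.approx(fit.r2, abs=0.05)

    def test_too_few_pairs_rejected(self, rng):
        data = rng.standard_normal((5, 10))
        with pytest.raises(DegenerateDataError):
            dynamic_fc([(clean_run(data), full_mask(5))])

    def test_ar_pairs_skips_short_segments(self):
        keep = np.zeros(10, dtype=bool)
        keep[2] = True          # singleton segment: no pairs
        keep[5:8] = True
        data = np.arange(20, dtype=float).reshape(10, 2)
        mask = CensorMask(keep=keep)
        xp, xn = ar_pairs([(clean_run(data), mask)])
        assert xp.shape[0] == 2  # only pairs (5,6) and (6,7)
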