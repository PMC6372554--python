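"""QC and signal conditioning: FD, exclusion rules, regression, filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from modcoupling import (
    MetaboliteRecord,
    apply_qc,
    crlb_filter,
    csf_correct,
    detrend_bandpass,
    framewise_displacement,
    friston24,
    motion_exclusion,
    nuisance_regress,
)


class TestFramewiseDisplacement:
    def test_constant_trace_is_zero(self):
        motion = np.tile([0.3, -0.1, 0.2, 0.5, -0.4, 0.1], (20, 1))
        np.testing.assert_array_equal(
            framewise_displacement(motion), np.zeros(20)
        )

    def test_pure_translation_step(self):
        motion = np.zeros((3, 6))
        motion[1:, 0] = 3.0  # 3 mm step on x between volumes 0 and 1
        fd = framewise_displacement(motion)
        assert fd[0] == 0.0
        assert fd[1] == pytest.approx(3.0)
        assert fd[2] == pytest.approx(0.0)

    def test_rotation_step_against_monte_carlo_sphere_oracle(self, rng):
        """Oracle: RMS displacement of 10,000 points sampled uniformly in an
        80 mm ball under a 1-degree single-axis rotation."""
        motion = np.zeros((2, 6))
        motion[1, 3] = 1.0  # 1 degree about x
        fd = framewise_displacement(motion, head_radius_mm=80.0)[1]

        directions = rng.normal(size=(10_000, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        radii = 80.0 * rng.uniform(size=(10_000, 1)) ** (1 / 3)
        points = directions * radii
        rot = Rotation.from_euler("xyz", [1.0, 0.0, 0.0], degrees=True)
        displaced = rot.apply(points) - points
        oracle = np.sqrt(np.mean(np.sum(displaced**2, axis=1)))
        assert fd == pytest.approx(oracle, rel=0.03)

    def test_rejects_nonfinite(self):
        motion = np.zeros((5, 6))
        motion[2, 1] = np.nan
        with pytest.raises(ValueError, match="finite"):
            framewise_displacement(motion)


class TestMotionExclusion:
    def test_all_zero_cohort_included(self):
        traces = {f"s{i}": np.zeros((10, 6)) for i in range(4)}
        report = motion_exclusion(traces, {f"s{i}": "g" for i in range(4)})
        assert all(report.included.values())

    def test_absolute_rules_and_fd_rule(self, rng):
        # 9 quiet subjects, one over-translation subject, one high-FD subject
        traces = {}
        for i in range(9):
            t = np.zeros((60, 6))
            t[:, 0] = 0.001 * rng.normal(size=60).cumsum()
            traces[f"quiet{i}"] = t
        big = np.zeros((60, 6))
        big[30:, 1] = 3.1  # translation rule, but a single small FD step
        traces["big_trans"] = big
        jitter = np.zeros((60, 6))
        jitter[:, 2] = 0.4 * np.arange(60) % 2  # 0.4 mm every volume
        traces["high_fd"] = jitter
        groups = {sid: "g" for sid in traces}
        report = motion_exclusion(traces, groups)
        assert report.records["big_trans"]["reasons"] == ["max_translation_mm"]
        assert report.records["high_fd"]["reasons"] == ["mean_fd"]
        assert report.n_included() == 9

    def test_fd_statistics_exclude_absolute_rule_failures(self):
        """The over-limit subject's huge FD must not inflate the group mean,
        i.e. absolute rules are applied before the FD rule."""
        quiet = {f"q{i}": np.zeros((40, 6)) for i in range(5)}
        wild = np.zeros((40, 6))
        wild[::2, 0] = 4.0  # violates translation rule with enormous FD
        traces = {**quiet, "wild": wild}
        report = motion_exclusion(traces, {sid: "g" for sid in traces})
        assert not report.records["wild"]["included"]
        # quiet subjects all at FD 0 -> limit is 0, none excluded
        assert report.n_included() == 5

    def test_paper_style_recruitment_counts(self, default_cohort):
        """24 recruited patients (3 motion, 1 MRS failure) and 29 controls
        (3 motion) reduce to 20 / 26 after QC."""
        report = apply_qc(default_cohort)
        assert report.n_included("patient") == 20
        assert report.n_included("control") == 26
        excluded = {sid for sid, r in report.records.items()
                    if not r["included"]}
        planted = {s.subject_id for s in default_cohort.subjects
                   if s.truth["motion_outlier"] or s.truth["crlb_outlier"]}
        assert excluded == planted


class TestFriston24:
    def test_zero_motion_gives_zero_design(self):
        assert np.all(friston24(np.zeros((10, 6))) == 0.0)

    def test_lag_square_and_shape(self, rng):
        motion = rng.normal(size=(30, 6))
        design = friston24(motion)
        assert design.shape == (30, 24)
        np.testing.assert_array_equal(design[:, :6], motion)
        assert np.all(design[0, 6:12] == 0.0)
        np.testing.assert_array_equal(design[1:, 6:12], motion[:-1])
        np.testing.assert_array_equal(design[:, 12:18], motion**2)
        np.testing.assert_array_equal(design[1:, 18:24], motion[:-1] ** 2)


class TestNuisanceRegress:
    def test_no_regressors_demeans(self, rng):
        ts = rng.normal(size=(40, 3)) + 5.0
        out = nuisance_regress(ts)
        np.testing.assert_allclose(out, ts - ts.mean(axis=0), atol=1e-10)

    def test_region_equal_to_regressor_vanishes(self, rng):
        reg = rng.normal(size=(40, 1))
        ts = np.hstack([reg, rng.normal(size=(40, 2))])
        out = nuisance_regress(ts, reg)
        np.testing.assert_allclose(out[:, 0], 0.0, atol=1e-10)

    def test_matches_pseudoinverse_oracle(self, rng):
        ts = rng.normal(size=(50, 7))
        reg = rng.normal(size=(50, 5))
        design = np.hstack([np.ones((50, 1)), reg])
        oracle = ts - design @ np.linalg.pinv(design) @ ts
        np.testing.assert_allclose(nuisance_regress(ts, reg), oracle,
                                   atol=1e-10)

    def test_residuals_orthogonal_and_idempotent(self, rng):
        ts = rng.normal(size=(60, 4))
        reg = rng.normal(size=(60, 3))
        out = nuisance_regress(ts, reg)
        gram = np.abs(reg.T @ out)
        assert gram.max() <= 1e-8 * np.abs(ts).max() * 60
        np.testing.assert_allclose(nuisance_regress(out, reg), out, atol=1e-9)

    def test_rank_deficiency_reports_columns(self, rng):
        reg = rng.normal(size=(30, 2))
        reg = np.hstack([reg, reg[:, :1]])  # duplicate column
        with pytest.raises(np.linalg.LinAlgError, match="columns"):
            nuisance_regress(rng.normal(size=(30, 2)), reg)


class TestDetrendBandpass:
    def test_linear_ramp_removed(self):
        ts = np.outer(np.arange(64, dtype=float), [1.0, -2.0]) + 3.0
        out = detrend_bandpass(ts, tr_s=2.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-9)

    def test_in_band_sinusoid_preserved(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.05 * t)  # exact FFT bin at T=200, TR=2
        out = detrend_bandpass(sig[:, None], tr_s=2.0)
        in_amp = np.abs(np.fft.rfft(sig))[20]
        out_amp = np.abs(np.fft.rfft(out[:, 0]))[20]
        assert out_amp == pytest.approx(in_amp, rel=0.01)

    def test_out_of_band_sinusoid_attenuated(self):
        t = np.arange(200) * 2.0
        sig = np.sin(2 * np.pi * 0.2 * t)
        out = detrend_bandpass(sig[:, None], tr_s=2.0)
        assert np.max(np.abs(out)) <= 0.01 * np.max(np.abs(sig))

    @given(st.floats(-3, 3), st.floats(-3, 3))
    def test_linearity(self, a, b):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(64, 2))
        y = rng.normal(size=(64, 2))
        lhs = detrend_bandpass(a * x + b * y, 2.0)
        rhs = a * detrend_bandpass(x, 2.0) + b * detrend_bandpass(y, 2.0)
        np.testing.assert_allclose(lhs, rhs, atol=1e-10)

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            detrend_bandpass(np.zeros((32, 1)), tr_s=2.0, low_hz=0.01,
                             high_hz=0.3)


def _rec(crlb, conc=8.0, f_csf=0.1):
    return MetaboliteRecord("NAA", conc, crlb, 0.6, 1.0 - 0.6 - f_csf, f_csf)


class TestMetaboliteQC:
    def test_strict_crlb_boundary(self):
        kept, dropped = crlb_filter([_rec(19.9), _rec(20.0)])
        assert [r.crlb for r in kept] == [19.9]
        assert [r.crlb for r in dropped] == [20.0]

    def test_empty_and_counts(self):
        assert crlb_filter([]) == ([], [])
        records = [_rec(c) for c in (5, 12, 19, 20, 35)]
        kept, dropped = crlb_filter(records)
        assert len(kept) == 3 and len(dropped) == 2

    def test_csf_correction(self, rng):
        assert csf_correct(_rec(5, conc=7.5, f_csf=0.0)) == 7.5
        assert csf_correct(_rec(5, conc=8.0, f_csf=0.2)) == pytest.approx(10.0)
        for _ in range(20):
            f = rng.uniform(0.0, 0.3)
            c = rng.uniform(1.0, 12.0)
            assert csf_correct(_rec(5, conc=c, f_csf=f)) == \
                pytest.approx(c / (1 - f))

    def test_tissue_fraction_validation(self):
        with pytest.raises(ValueError, match="sum to 1"):
            MetaboliteRecord("NAA", 8.0, 5.0, 0.5, 0.5, 0.5)
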