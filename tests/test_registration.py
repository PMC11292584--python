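"""Rigid sub-sample registration: precision, consistency, correlation."""

import numpy as np
import pytest

from pdus import (
    DisplacementTrace,
    EnsembleStack,
    GroundTruthSpec,
    apply_registration,
    estimate_displacements,
    interframe_correlation,
    register_ensemble,
    simulate_ensemble,
)
from pdus.registration import translate_frame


def _static_frame(geom, seed=4, snr_db=None):
    """One speckle frame, optionally with additive noise at a given SNR."""
    spec = GroundTruthSpec(
        clutter_power_db=0.0, blood_power_db=-np.inf, noise_power_db=-np.inf,
        respiration_amplitude_mm=0.0, axial_drift_mm_per_s=0.0, seed=seed,
    )
    frame = simulate_ensemble(spec, geom, n_frames=2).frames[0]
    if snr_db is None:
        return frame, None
    sigma = np.sqrt(np.mean(frame**2) / 10 ** (snr_db / 10))
    return frame, sigma


class TestEstimate:
    def test_identical_frames_give_zero_trace(self, static_ensemble):
        frames = np.repeat(static_ensemble.frames[:1], 4, axis=0)
        ens = EnsembleStack(frames=frames, geometry=static_ensemble.geometry)
        tr = estimate_displacements(ens)
        assert np.all(tr.axial_mm == 0.0)
        assert np.all(tr.lateral_mm == 0.0)

    def test_integer_sample_shift_recovered_exactly(self, geom):
        frame, _ = _static_frame(geom)
        shifted = np.roll(frame, 2, axis=0)  # +2 axial samples
        ens = EnsembleStack(frames=np.stack([frame, shifted]), geometry=geom)
        tr = estimate_displacements(ens)
        assert tr.axial_mm[1] == pytest.approx(2 * geom.axial_spacing_mm, abs=1e-4)
        assert tr.lateral_mm[1] == pytest.approx(0.0, abs=1e-4)

    @pytest.mark.parametrize("shift_mm", [(0.005, 0.0), (0.0, 0.012), (0.012, 0.02)])
    def test_subsample_precision_within_1_um_at_15_db_snr(self, geom, shift_mm, rng):
        # shift-equivariance: injected sub-sample shifts <= 0.02 mm recovered
        # to <= 1 um with noise at 15 dB echo SNR
        d_ax, d_lat = shift_mm
        frame, sigma = _static_frame(geom, snr_db=15.0)
        moved = translate_frame(
            frame, d_ax / geom.axial_spacing_mm, d_lat / geom.line_pitch_mm
        )
        f0 = frame + rng.normal(0, sigma, frame.shape)
        f1 = moved + rng.normal(0, sigma, frame.shape)
        ens = EnsembleStack(frames=np.stack([f0, f1]), geometry=geom)
        tr = estimate_displacements(ens)
        assert abs(tr.axial_mm[1] - d_ax) < 1e-3
        assert abs(tr.lateral_mm[1] - d_lat) < 1e-3

    def test_respiration_amplitude_recovered(self, moving_ensemble):
        # 0.010 mm periodic lateral translation -> recovered within 0.001 mm
        tr = estimate_displacements(moving_ensemble)
        amplitude = (tr.lateral_mm.max() - tr.lateral_mm.min()) / 2
        assert amplitude == pytest.approx(0.010, abs=0.001)

    def test_all_zero_frames_fail(self, geom):
        ens = EnsembleStack(frames=np.zeros((3, 16, 8)), geometry=geom)
        with pytest.raises(ValueError, match="constant"):
            estimate_displacements(ens)


class TestApply:
    def test_zero_trace_is_identity(self, static_ensemble):
        tr = DisplacementTrace(
            axial_mm=np.zeros(static_ensemble.n_frames),
            lateral_mm=np.zeros(static_ensemble.n_frames),
        )
        out = apply_registration(static_ensemble, tr)
        np.testing.assert_array_equal(out.frames, static_ensemble.frames)

    def test_shift_then_unshift_round_trip(self, geom):
        frame, _ = _static_frame(geom, seed=6)
        # band-limit the oracle input: physical RF has no energy at the
        # folding frequency; what a cropped frame carries there is artifact
        spec = np.fft.fft2(frame)
        spec[frame.shape[0] // 2, :] = 0.0
        spec[:, frame.shape[1] // 2] = 0.0
        frame = np.fft.ifft2(spec).real
        d_ax, d_lat = 1.3, 0.7  # pixels
        back = translate_frame(translate_frame(frame, d_ax, d_lat), -d_ax, -d_lat)
        interior = (slice(4, -4), slice(2, -2))
        err = np.linalg.norm(back[interior] - frame[interior]) / np.linalg.norm(
            frame[interior]
        )
        assert err < 1e-6

    def test_inverse_consistency(self, moving_ensemble):
        reg, tr = register_ensemble(moving_ensemble)
        residual = estimate_displacements(reg)
        assert np.max(np.abs(residual.axial_mm)) < 2e-3
        assert np.max(np.abs(residual.lateral_mm)) < 2e-3

    def test_mismatched_trace_length_fails(self, static_ensemble):
        tr = DisplacementTrace(axial_mm=np.zeros(3), lateral_mm=np.zeros(3))
        with pytest.raises(ValueError, match="length"):
            apply_registration(static_ensemble, tr)

    def test_displacement_beyond_10_percent_fov_fails(self, static_ensemble):
        n = static_ensemble.n_frames
        ax = np.zeros(n)
        ax[1] = 0.2 * static_ensemble.geometry.axial_extent_mm
        tr = DisplacementTrace(axial_mm=ax, lateral_mm=np.zeros(n))
        with pytest.raises(ValueError, match="rigid"):
            apply_registration(static_ensemble, tr)

    def test_trace_must_start_at_origin(self):
        with pytest.raises(ValueError, match="frame 1"):
            DisplacementTrace(axial_mm=np.array([0.1, 0.0]),
                              lateral_mm=np.zeros(2))


class TestCorrelation:
    def test_identical_frames_correlate_perfectly(self, static_ensemble):
        frames = np.repeat(static_ensemble.frames[:1], 3, axis=0)
        ens = EnsembleStack(frames=frames, geometry=static_ensemble.geometry)
        assert interframe_correlation(ens) == pytest.approx(1.0)

    def test_independent_noise_frames_decorrelate(self, small_geom, rng):
        frames = rng.standard_normal((4, small_geom.n_axial_samples,
                                      small_geom.n_lines))
        ens = EnsembleStack(frames=frames, geometry=small_geom)
        assert abs(interframe_correlation(ens)) < 0.05

    def test_constant_frames_fail(self, small_geom):
        ens = EnsembleStack(frames=np.ones((3, 16, 8)), geometry=small_geom)
        with pytest.raises(ValueError):
            interframe_correlation(ens)

    def test_registration_does_not_reduce_correlation(self, moving_ensemble, rois):
        reg, _ = register_ensemble(moving_ensemble)
        for roi in rois:
            before = interframe_correlation(moving_ensemble, roi)
            after = interframe_correlation(reg, roi)
            assert after >= before - 0.005
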