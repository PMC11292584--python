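"""Acquisition geometry, IQ→RF conversion, and slow-time ensemble assembly.

A 12-s recording holds 96 Doppler frames at 8 fps; each Doppler frame is a
burst of 17 echo frames acquired in color-flow mode at 1000 fps.  Taking the
first echo frame of every Doppler frame yields a slow-time sequence sampled
at 8 Hz, which is partitioned into six 16-frame ensembles of 2 s each — the
atomic unit of clutter filtering and power estimation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import resample

log = logging.getLogger(__name__)

DEFAULT_ENSEMBLE_LEN = 16


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Scanner geometry and sampling parameters.

    Defaults describe a 24 MHz linear-array acquisition: RF sampled at 4x
    the carrier, 0.05 mm line pitch, Doppler frames at 8 fps with 17 echo
    frames each at 1000 fps, 96 Doppler frames per 12-s recording.
    PSF widths are full-width-half-maximum values of the two-way
    (pulse-echo) point-spread function.
    """

    transmit_freq_hz: float = 24e6
    sound_speed_m_per_s: float = 1540.0
    axial_sample_freq_hz: float = 96e6
    line_pitch_mm: float = 0.05
    doppler_frame_rate_hz: float = 8.0
    echo_frames_per_doppler_frame: int = 17
    intra_frame_rate_hz: float = 1000.0
    n_doppler_frames: int = 96
    psf_axial_mm: float = 0.10
    psf_lateral_mm: float = 0.15
    n_axial_samples: int = 300
    n_lines: int = 72

    def __post_init__(self) -> None:
        if self.transmit_freq_hz <= 0:
            raise ValueError("transmit_freq_hz must be positive")
        if self.sound_speed_m_per_s <= 0:
            raise ValueError("sound_speed_m_per_s must be positive")
        for name in ("axial_sample_freq_hz", "line_pitch_mm",
                     "doppler_frame_rate_hz", "intra_frame_rate_hz",
                     "psf_axial_mm", "psf_lateral_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("echo_frames_per_doppler_frame", "n_doppler_frames",
                     "n_axial_samples", "n_lines"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def axial_spacing_mm(self) -> float:
        """Axial sample spacing: c / (2 fs), pulse-echo distance."""
        return self.sound_speed_m_per_s / (2.0 * self.axial_sample_freq_hz) * 1e3

    @property
    def axial_extent_mm(self) -> float:
        return self.n_axial_samples * self.axial_spacing_mm

    @property
    def lateral_extent_mm(self) -> float:
        return self.n_lines * self.line_pitch_mm

    @property
    def recording_duration_s(self) -> float:
        return self.n_doppler_frames / self.doppler_frame_rate_hz


#: geometry shrunk to a ~1.2 x 1.2 mm field; same sampling physics, cheaper
#: to simulate — convenient for quick experiments
def small_geometry(**overrides) -> AcquisitionGeometry:
    params = dict(n_axial_samples=150, n_lines=24)
    params.update(overrides)
    return AcquisitionGeometry(**params)


@dataclass(frozen=True)
class ROI:
    """Rectangular region of interest in field coordinates (mm).

    ``axial_mm``/``lateral_mm`` locate the near/left corner; the paper-style
    analysis uses three ~1 mm^2 regions in the gracilis muscle.
    """

    axial_mm: float
    lateral_mm: float
    height_mm: float = 1.0
    width_mm: float = 1.0

    def __post_init__(self) -> None:
        if self.height_mm <= 0 or self.width_mm <= 0:
            raise ValueError("ROI height and width must be positive")

    def to_slices(self, geom: AcquisitionGeometry) -> tuple[slice, slice]:
        a0 = int(round(self.axial_mm / geom.axial_spacing_mm))
        a1 = int(round((self.axial_mm + self.height_mm) / geom.axial_spacing_mm))
        l0 = int(round(self.lateral_mm / geom.line_pitch_mm))
        l1 = int(round((self.lateral_mm + self.width_mm) / geom.line_pitch_mm))
        if a0 < 0 or l0 < 0 or a1 > geom.n_axial_samples or l1 > geom.n_lines:
            raise ValueError(f"ROI {self} lies outside the imaged field")
        if a1 <= a0 or l1 <= l0:
            raise ValueError(f"ROI {self} is empty at this sampling")
        return slice(a0, a1), slice(l0, l1)

    @property
    def area_mm2(self) -> float:
        return self.height_mm * self.width_mm


def default_rois(geom: AcquisitionGeometry) -> list[ROI]:
    """Three 1 mm^2 ROIs, centered axially and spread laterally.

    Falls back to a single centered ROI covering ~60% of a small field.
    """
    ax0 = (geom.axial_extent_mm - 1.0) / 2.0
    if geom.lateral_extent_mm >= 3.5 and geom.axial_extent_mm >= 1.2:
        gap = (geom.lateral_extent_mm - 3.0) / 4.0
        return [
            ROI(ax0, gap + i * (1.0 + gap), 1.0, 1.0) for i in range(3)
        ]
    h = 0.6 * geom.axial_extent_mm
    w = 0.6 * geom.lateral_extent_mm
    return [ROI((geom.axial_extent_mm - h) / 2, (geom.lateral_extent_mm - w) / 2, h, w)]


@dataclass
class EnsembleStack:
    """One slow-time ensemble: 16 RF echo frames spanning 2 s at 8 fps."""

    frames: np.ndarray  # (n_frames, n_axial, n_lines), real RF samples
    geometry: AcquisitionGeometry
    slow_time_rate_hz: float = 8.0
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, axial, lateral) array")
        if self.frames.shape[0] < 2:
            raise ValueError("an ensemble needs at least 2 frames")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.slow_time_rate_hz

    def copy_with(self, frames: np.ndarray, **prov) -> "EnsembleStack":
        return EnsembleStack(
            frames=frames,
            geometry=self.geometry,
            slow_time_rate_hz=self.slow_time_rate_hz,
            provenance={**self.provenance, **prov},
        )


@dataclass
class DopplerRecording:
    """A full recording: Doppler frames x echo frames, plus geometry/ROIs.

    ``doppler_frames`` has shape (n_doppler, n_echo_per_frame, axial,
    lateral); real RF when ``is_rf`` else complex baseband IQ, in which case
    ``demodulation_freq_hz`` must be supplied before RF conversion.
    """

    doppler_frames: np.ndarray
    geometry: AcquisitionGeometry
    roi_set: list[ROI] = field(default_factory=list)
    is_rf: bool = True
    demodulation_freq_hz: float | None = None
    iq_sample_freq_hz: float | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.doppler_frames = np.asarray(self.doppler_frames)
        if self.doppler_frames.ndim != 4:
            raise ValueError(
                "doppler_frames must be (n_doppler, n_echo, axial, lateral)"
            )
        for roi in self.roi_set:
            roi.to_slices(self.geometry)  # validates bounds


# ----------------------------------------------------------------------
# IQ <-> RF conversion

def iq_to_rf(
    iq_frame: np.ndarray,
    iq_sample_freq_hz: float,
    demodulation_freq_hz: float | None,
    rf_sample_freq_hz: float | None = None,
) -> np.ndarray:
    """Convert a complex-baseband IQ frame to real RF along the axial axis.

    The baseband signal is spectrally zero-padded (FFT resampling) to
    ``rf_sample_freq_hz`` (default: at least 4x the demodulation
    frequency), remodulated onto the carrier, and the real part taken:
    ``rf(t) = Re{iq(t) exp(2 pi i f_d t)}``, so a constant IQ value ``c``
    becomes a carrier of amplitude ``|c|``.

    Raises if the demodulation frequency is missing — there is no safe
    default for vendor data.
    """
    if demodulation_freq_hz is None:
        raise ValueError(
            "demodulation frequency is required for IQ->RF conversion; "
            "refusing to guess a carrier"
        )
    if iq_sample_freq_hz <= 0:
        raise ValueError("iq_sample_freq_hz must be positive")
    iq = np.asarray(iq_frame, dtype=complex)
    if iq.ndim != 2:
        raise ValueError("iq_frame must be 2-D (axial x lateral)")
    if rf_sample_freq_hz is None:
        rf_sample_freq_hz = max(iq_sample_freq_hz, 4.0 * demodulation_freq_hz)
    n_in = iq.shape[0]
    n_out = int(round(n_in * rf_sample_freq_hz / iq_sample_freq_hz))
    if n_out != n_in:
        iq = resample(iq, n_out, axis=0)
    t = np.arange(n_out)[:, None] / rf_sample_freq_hz
    return np.real(iq * np.exp(2j * np.pi * demodulation_freq_hz * t))


def rf_to_iq(
    rf_frame: np.ndarray,
    rf_sample_freq_hz: float,
    demodulation_freq_hz: float,
    iq_sample_freq_hz: float | None = None,
) -> np.ndarray:
    """Demodulate real RF back to complex baseband (inverse of `iq_to_rf`).

    Mixes down by the carrier, brick-wall low-passes at half the output
    sample rate, and FFT-resamples to ``iq_sample_freq_hz``.
    """
    rf = np.asarray(rf_frame, dtype=float)
    if iq_sample_freq_hz is None:
        iq_sample_freq_hz = rf_sample_freq_hz
    n = rf.shape[0]
    t = np.arange(n)[:, None] / rf_sample_freq_hz
    base = 2.0 * rf * np.exp(-2j * np.pi * demodulation_freq_hz * t)
    # brick-wall low-pass at the baseband Nyquist of the output rate
    spec = np.fft.fft(base, axis=0)
    freqs = np.fft.fftfreq(n, 1.0 / rf_sample_freq_hz)
    spec[np.abs(freqs) > iq_sample_freq_hz / 2.0, :] = 0.0
    base = np.fft.ifft(spec, axis=0)
    n_out = int(round(n * iq_sample_freq_hz / rf_sample_freq_hz))
    if n_out != n:
        base = resample(base, n_out, axis=0)
    return base


# ----------------------------------------------------------------------
# Ensemble assembly

def assemble_ensembles(
    rec: DopplerRecording,
    ensemble_len: int = DEFAULT_ENSEMBLE_LEN,
    echo_index: int = 0,
) -> list[EnsembleStack]:
    """Partition a recording into slow-time ensembles.

    Selects echo frame ``echo_index`` (default: the first) from each Doppler
    frame and groups consecutive runs of ``ensemble_len`` into ensembles at
    the Doppler frame rate.  A 96-frame recording yields six 16-frame
    ensembles.  Short recordings yield as many complete ensembles as
    possible (with a warning); none at all is an error.
    """
    n_dop, n_echo = rec.doppler_frames.shape[:2]
    if not (0 <= echo_index < n_echo):
        raise ValueError(f"echo_index {echo_index} out of range [0, {n_echo})")
    n_ens = n_dop // ensemble_len
    if n_ens == 0:
        raise ValueError(
            f"recording has {n_dop} Doppler frames; "
            f"need at least {ensemble_len} for one ensemble"
        )
    if n_dop % ensemble_len:
        warnings.warn(
            f"recording has {n_dop} Doppler frames; using {n_ens} complete "
            f"ensembles of {ensemble_len} and discarding the remainder",
            stacklevel=2,
        )
    slow = rec.doppler_frames[:, echo_index]  # (n_dop, axial, lateral)
    if not rec.is_rf:
        fs = rec.iq_sample_freq_hz or rec.geometry.axial_sample_freq_hz
        slow = np.stack(
            [iq_to_rf(f, fs, rec.demodulation_freq_hz) for f in slow]
        )
    out = []
    for k in range(n_ens):
        frames = slow[k * ensemble_len:(k + 1) * ensemble_len]
        out.append(
            EnsembleStack(
                frames=np.array(frames, dtype=float),
                geometry=rec.geometry,
                slow_time_rate_hz=rec.geometry.doppler_frame_rate_hz,
                provenance={
                    "recording_id": rec.recording_id,
                    "ensemble_index": k + 1,
                    "echo_index": echo_index,
                },
            )
        )
    return out


# ----------------------------------------------------------------------
# Analytic acquisition relations

def doppler_resolution_hz(
    rate_hz: float = 8.0, ensemble_len: int = DEFAULT_ENSEMBLE_LEN
) -> float:
    """Doppler frequency resolution of a slow-time ensemble: rate / length.

    16 frames at 8 fps (a 2-s ensemble) give 0.5 Hz bins.
    """
    return rate_hz / ensemble_len


def nyquist_band_hz(rate_hz: float = 8.0) -> float:
    """Half-width of the slow-time Doppler band: +/- rate/2 (4 Hz at 8 fps)."""
    return rate_hz / 2.0


def velocity_resolution_mm_per_s(
    freq_resolution_hz: float = 0.5,
    transmit_freq_hz: float = 24e6,
    sound_speed_m_per_s: float = 1540.0,
) -> float:
    """Axial velocity step per Doppler bin: v = f_D c / (2 f0).

    0.5 Hz bins at 24 MHz in soft tissue resolve ~0.016 mm/s.
    """
    return freq_resolution_hz * sound_speed_m_per_s / (2.0 * transmit_freq_hz) * 1e3


def ensembles_per_recording(
    n_doppler_frames: int = 96, ensemble_len: int = DEFAULT_ENSEMBLE_LEN
) -> int:
    """Complete slow-time ensembles per recording (96 frames -> 6)."""
    return n_doppler_frames // ensemble_len


def round_trip_attenuation_db(
    attenuation_db_per_cm_mhz: float = 0.5,
    depth_cm: float = 0.2,
    freq_mhz: float = 24.0,
) -> float:
    """Two-way attenuation loss: alpha x 2 depth x f (~5 dB at 2 mm, 24 MHz)."""
    return attenuation_db_per_cm_mhz * 2.0 * depth_cm * freq_mhz
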