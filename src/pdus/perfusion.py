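"""Doppler spectra, power-Doppler (PD-US) estimation, and perfusion profiles.

After clutter filtering, the mean squared echo amplitude over an ROI and a
2-s ensemble is the PD-US estimate: a relative perfusion index.  Six
sequential ensembles are averaged per 12-s recording, powers are averaged
on the linear scale within a mouse, normalized by the pre-ligation baseline
of the same limb, and expressed in dB.  Group curves average the per-mouse
dB values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .acquisition import ROI, EnsembleStack
from .clutterfilter import FilterConfig, SingularSpectrum, casorati, svd_filter
from .schedule import SCHEDULE_LABELS


def db_to_fraction(db: float | np.ndarray) -> float | np.ndarray:
    """dB re baseline -> linear fraction of baseline (-5 dB -> ~0.316)."""
    return 10.0 ** (np.asarray(db, dtype=float) / 10.0)


def fraction_to_db(fraction: float | np.ndarray) -> float | np.ndarray:
    """Linear fraction of baseline -> dB (0.5 -> ~-3.01 dB)."""
    fraction = np.asarray(fraction, dtype=float)
    if np.any(fraction <= 0):
        raise ValueError("fractions must be positive to convert to dB")
    return 10.0 * np.log10(fraction)


@dataclass
class DopplerSpectrum:
    """Spatially averaged slow-time power spectral density.

    With 16 samples at 8 Hz the grid spans -4 ... +3.5 Hz in 0.5 Hz steps
    (the -4 Hz bin is the shared Nyquist bin).  Normalized so that
    sum(psd) * df equals the mean signal power (Parseval).
    """

    freq_hz: np.ndarray
    psd: np.ndarray
    df_hz: float
    stage: str = "original"

    def __post_init__(self) -> None:
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freq_hz.shape != self.psd.shape:
            raise ValueError("frequency grid and PSD must align")
        if np.any(self.psd < -1e-12):
            raise ValueError("PSD must be non-negative")

    @property
    def total_power(self) -> float:
        """Integral of the PSD = mean signal power (Parseval)."""
        return float(np.sum(self.psd) * self.df_hz)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"freq_hz": self.freq_hz, "psd": self.psd, "stage": self.stage}
        )


def doppler_psd(
    M: np.ndarray, rate_hz: float = 8.0, stage: str = "original"
) -> DopplerSpectrum:
    """Slow-time periodogram of a Casorati matrix, averaged over space.

    No taper and no mean removal: with 16 samples a window would widen the
    0.5 Hz bins, and the 0 Hz bin is part of the filtered spectrum.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[1] < 2:
        raise ValueError("need a space x time matrix with >= 2 time samples")
    n = M.shape[1]
    df = rate_hz / n
    spec = np.fft.fft(M, axis=1)
    # mean over space of |X_k|^2 / n^2; divided by df so the sum integrates
    # to the mean power per sample
    psd = np.mean(np.abs(spec) ** 2, axis=0) / (n**2 * df)
    freqs = np.fft.fftshift(np.fft.fftfreq(n, d=1.0 / rate_hz))
    return DopplerSpectrum(
        freq_hz=freqs, psd=np.fft.fftshift(psd), df_hz=df, stage=stage
    )


def pdus_power(M: np.ndarray) -> float:
    """Mean squared sample value over space and time (linear power)."""
    M = np.asarray(M, dtype=float)
    if M.size == 0:
        raise ValueError("empty matrix has no power")
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix entries must be finite")
    return float(np.mean(M**2))


@dataclass
class PDUSEstimate:
    """PD-US estimate for one recording: per-ensemble powers and their mean."""

    ensemble_powers: np.ndarray  # linear, one per (ensemble x ROI) mean
    power_linear: float
    se_linear: float

    @classmethod
    def from_powers(cls, powers: Sequence[float]) -> "PDUSEstimate":
        p = np.asarray(powers, dtype=float)
        if p.size == 0:
            raise ValueError("no powers to aggregate")
        if np.any(p < 0):
            raise ValueError("linear powers must be non-negative")
        se = float(np.std(p, ddof=1) / np.sqrt(p.size)) if p.size > 1 else np.nan
        return cls(ensemble_powers=p, power_linear=float(np.mean(p)), se_linear=se)


def process_ensemble(
    ens: EnsembleStack,
    rois: Sequence[ROI],
    cfg: FilterConfig = FilterConfig(),
    register: bool = True,
) -> tuple[list[float], list[SingularSpectrum]]:
    """Clutter-filter one ensemble and return per-ROI linear powers.

    Optionally registers frames to frame 1 first.  Filtering operates on
    the ROI-restricted Casorati matrix (the default) or on the full frame.
    """
    from .registration import register_ensemble

    if register:
        ens, _ = register_ensemble(ens)
    powers, spectra = [], []
    if cfg.roi_restricted:
        for roi in rois:
            M = casorati(ens, roi)
            filt, ss = svd_filter(M, cfg)
            powers.append(pdus_power(filt))
            spectra.append(ss)
    else:
        M = casorati(ens, None)
        filt, ss = svd_filter(M, cfg)
        frames = filt.T.reshape(ens.n_frames, *ens.frame_shape)
        for roi in rois:
            sa, sl = roi.to_slices(ens.geometry)
            powers.append(pdus_power(frames[:, sa, sl]))
        spectra.append(ss)
    return powers, spectra


def pdus_estimate(
    ensembles: Sequence[EnsembleStack],
    rois: Sequence[ROI],
    cfg: FilterConfig = FilterConfig(),
    register: bool = True,
) -> PDUSEstimate:
    """PD-US estimate for one recording: mean over ensembles x ROIs."""
    powers: list[float] = []
    for ens in ensembles:
        p, _ = process_ensemble(ens, rois, cfg, register=register)
        powers.extend(p)
    return PDUSEstimate.from_powers(powers)


def pdus_image_db(
    ens: EnsembleStack,
    cfg: FilterConfig = FilterConfig(),
    dynamic_range_db: float = 40.0,
) -> np.ndarray:
    """Per-pixel filtered power map in dB below the maximum (display only)."""
    M = casorati(ens, None)
    filt, _ = svd_filter(M, cfg)
    power = np.mean(filt**2, axis=1).reshape(ens.frame_shape)
    peak = float(power.max())
    if peak == 0.0:
        raise ValueError("zero-power image")
    img = 10.0 * np.log10(np.maximum(power / peak, 10 ** (-dynamic_range_db / 10)))
    return img


# ----------------------------------------------------------------------
# Profiles

@dataclass
class PerfusionProfile:
    """Baseline-normalized PD-US values (dB) of one limb over the schedule."""

    labels: list[str]
    values_db: np.ndarray
    se_db: np.ndarray | None = None
    mouse_id: str = ""
    limb: str = "ischemic"
    group: str = ""
    sex: str = ""

    def __post_init__(self) -> None:
        self.values_db = np.asarray(self.values_db, dtype=float)
        if len(self.labels) != self.values_db.size:
            raise ValueError("labels and values must align")
        order = [SCHEDULE_LABELS.index(lab) for lab in self.labels]
        if order != sorted(order):
            raise ValueError("schedule labels must be in chronological order")
        if "pre" in self.labels and self.value("pre") != 0.0:
            raise ValueError("profile must be 0 dB at the pre-ligation baseline")
        if self.se_db is not None:
            self.se_db = np.asarray(self.se_db, dtype=float)
            if self.se_db.shape != self.values_db.shape:
                raise ValueError("se must align with values")

    def value(self, label: str) -> float:
        try:
            return float(self.values_db[self.labels.index(label)])
        except ValueError:
            raise KeyError(f"label {label!r} not in profile") from None

    def has(self, label: str) -> bool:
        return label in self.labels

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "mouse_id": self.mouse_id,
                "group": self.group,
                "sex": self.sex,
                "limb": self.limb,
                "time_label": self.labels,
                "pdus_db": self.values_db,
            }
        )
        if self.se_db is not None:
            df["se_db"] = self.se_db
        return df


def normalize_profile(
    powers: Mapping[str, float],
    se: Mapping[str, float] | None = None,
    mouse_id: str = "",
    limb: str = "ischemic",
    group: str = "",
    sex: str = "",
) -> PerfusionProfile:
    """Convert raw linear powers per schedule point to a dB profile.

    value(t) = 10 log10(power(t) / power(pre)); the baseline maps to 0 dB
    exactly, and any constant processing offset (e.g. a registration-induced
    PSD floor change) cancels.
    """
    if "pre" not in powers:
        raise ValueError("a pre-ligation baseline power is required")
    baseline = float(powers["pre"])
    if baseline <= 0:
        raise ValueError("baseline power must be positive")
    labels = [lab for lab in SCHEDULE_LABELS if lab in powers]
    values = np.array(
        [10.0 * np.log10(float(powers[lab]) / baseline) for lab in labels]
    )
    se_arr = None
    if se is not None:
        # delta-method: se_dB = 10/ln(10) * se_linear / power
        se_arr = np.array(
            [
                10.0 / np.log(10.0) * float(se.get(lab, np.nan)) / float(powers[lab])
                for lab in labels
            ]
        )
    return PerfusionProfile(
        labels=labels, values_db=values, se_db=se_arr,
        mouse_id=mouse_id, limb=limb, group=group, sex=sex,
    )


def cohort_average(
    profiles: Sequence[PerfusionProfile], group: str | None = None
) -> pd.DataFrame:
    """Group mean curve: per-point mean dB, se = sd/sqrt(n), and n.

    n may vary by time point (attrition, missing data).  With a single
    mouse the se is reported as missing.
    """
    if group is not None:
        profiles = [p for p in profiles if p.group == group]
    if not profiles:
        raise ValueError("no profiles to average")
    rows = []
    for lab in SCHEDULE_LABELS:
        vals = np.array([p.value(lab) for p in profiles if p.has(lab)])
        if vals.size == 0:
            continue
        se = float(np.std(vals, ddof=1) / np.sqrt(vals.size)) if vals.size > 1 else np.nan
        rows.append(
            {
                "time_label": lab,
                "mean_db": float(np.mean(vals)),
                "se_db": se,
                "n": int(vals.size),
            }
        )
    return pd.DataFrame(rows)


def profiles_to_tidy(profiles: Sequence[PerfusionProfile]) -> pd.DataFrame:
    """Concatenate profiles into one long-format table."""
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
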