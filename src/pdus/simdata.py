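"""Synthetic RF echo ensembles and synthetic cohorts with known ground truth.

The signal model follows the physics assumed by the analysis pipeline:

* **tissue clutter** — a dense random point-scatterer field that moves
  rigidly in the scan plane (periodic lateral respiration motion plus a slow
  axial drift), typically ~40 dB stronger than blood echoes;
* **blood echoes** — diffuse scatterers performing an uncorrelated random
  walk at capillary speeds (< 2 mm/s), whose echo power tracks the true
  perfusion curve;
* **electronic noise** — additive white Gaussian noise setting the echo SNR
  (~15 dB under typical scanning conditions).

Frames are synthesized by summing Gaussian-modulated pulse-echo point
responses over scatterers: axially a Gaussian envelope modulated at the
two-way carrier (2 f0 / c cycles per unit depth), laterally a Gaussian beam
profile.  Component powers are normalized per-realization over the whole
ensemble so that the mean blood power at baseline is exactly the requested
linear power; ROI estimates then fluctuate around the target with ordinary
speckle statistics.

Profile- and cohort-level generators emulate the phenomenology of the
ischemic hindlimb study: a perfusion decline after ligation, a transient
spike at 20 min, a minimum of several dB below baseline at day 1-2, and a
polynomial (in log-time) recovery crossing baseline at the recovery time T.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .acquisition import AcquisitionGeometry, EnsembleStack
from .schedule import (
    SCHEDULE_LABELS,
    SCHEDULE_MINUTES,
    schedule_index,
    schedule_minutes,
)

_FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def _db_to_linear(db: float) -> float:
    """dB -> linear power; -inf maps to exactly zero."""
    if db == -np.inf:
        return 0.0
    return 10.0 ** (db / 10.0)


@dataclass(frozen=True)
class GroundTruthSpec:
    """Physical ground truth for one simulated acquisition.

    Powers are linear-scale ratios expressed in dB relative to the baseline
    blood echo power (0 dB).  ``-inf`` disables a component.  The default
    clutter-to-blood ratio is 40 dB and the default noise level puts the
    echo SNR (tissue+blood over noise) at ~15 dB.
    """

    clutter_power_db: float = 40.0
    blood_power_db: float = 0.0
    noise_power_db: float = 25.0
    respiration_amplitude_mm: float = 0.010
    respiration_period_s: float = 0.4
    axial_drift_mm_per_s: float = 0.002
    blood_speed_mm_per_s: float = 1.0
    scatterer_density_per_mm2: float = 150.0
    perfusion_curve: Mapping[str, float] | Callable[[str], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("clutter_power_db", "blood_power_db", "noise_power_db"):
            v = getattr(self, name)
            if np.isnan(v) or v == np.inf:
                raise ValueError(f"{name} must be finite or -inf, got {v}")
        if self.respiration_amplitude_mm < 0:
            raise ValueError("respiration_amplitude_mm must be >= 0")
        if self.respiration_period_s <= 0:
            raise ValueError("respiration_period_s must be positive")
        if self.blood_speed_mm_per_s < 0:
            raise ValueError("blood_speed_mm_per_s must be >= 0")
        if self.scatterer_density_per_mm2 <= 0:
            raise ValueError("scatterer_density_per_mm2 must be positive")
        if self.perfusion_db("pre") != 0.0:
            raise ValueError("perfusion_curve must be 0 dB at 'pre' (baseline)")

    def perfusion_db(self, t: str) -> float:
        """True relative blood power (dB re baseline) at a schedule time."""
        if self.perfusion_curve is None:
            return 0.0
        if callable(self.perfusion_curve):
            return float(self.perfusion_curve(t))
        return float(self.perfusion_curve.get(t, 0.0))

    @property
    def echo_snr_db(self) -> float:
        """Echo SNR: (clutter + blood) power over noise power, in dB."""
        sig = _db_to_linear(self.clutter_power_db) + _db_to_linear(self.blood_power_db)
        return 10.0 * np.log10(sig / _db_to_linear(self.noise_power_db))


def _render_frames(
    axial_mm: np.ndarray,
    lateral_mm: np.ndarray,
    positions: np.ndarray,  # (n_frames, n_scat, 2): (axial, lateral) in mm
    amplitudes: np.ndarray,  # (n_scat,)
    geom: AcquisitionGeometry,
) -> np.ndarray:
    """Sum Gaussian-modulated point responses over scatterers, per frame.

    The per-frame image is a separable outer-product sum, computed as one
    matrix product: frames[f] = (A_f * amp) @ L_f^T where A_f holds the
    modulated axial pulse of every scatterer and L_f the lateral beam
    profile.
    """
    sig_ax = geom.psf_axial_mm * _FWHM_TO_SIGMA
    sig_lat = geom.psf_lateral_mm * _FWHM_TO_SIGMA
    # two-way carrier: 2 f0 / c cycles per mm of depth
    k_mm = 2.0 * geom.transmit_freq_hz / geom.sound_speed_m_per_s * 1e-3
    n_frames = positions.shape[0]
    out = np.empty((n_frames, axial_mm.size, lateral_mm.size))
    for f in range(n_frames):
        dz = axial_mm[:, None] - positions[f, :, 0][None, :]  # (n_ax, n_scat)
        dx = lateral_mm[:, None] - positions[f, :, 1][None, :]  # (n_lat, n_scat)
        ax = np.exp(-0.5 * (dz / sig_ax) ** 2) * np.cos(2.0 * np.pi * k_mm * dz)
        lat = np.exp(-0.5 * (dx / sig_lat) ** 2)
        out[f] = (ax * amplitudes[None, :]) @ lat.T
    return out


def _normalize_power(frames: np.ndarray, target_linear: float) -> np.ndarray:
    """Scale a component so its ensemble-mean power equals the target."""
    if target_linear == 0.0:
        return np.zeros_like(frames)
    p = np.mean(frames**2)
    if p == 0.0:
        raise RuntimeError("degenerate scatterer field: zero rendered power")
    return frames * math.sqrt(target_linear / p)


def simulate_ensemble(
    spec: GroundTruthSpec,
    geom: AcquisitionGeometry,
    t: str = "pre",
    n_frames: int = 16,
    rng: np.random.Generator | None = None,
) -> EnsembleStack:
    """Simulate one slow-time RF ensemble at a schedule time.

    Tissue scatterers translate rigidly (respiration sinusoid laterally,
    drift axially); blood scatterers random-walk with per-frame Gaussian
    steps whose RMS magnitude matches ``blood_speed_mm_per_s``; blood power
    is scaled by the perfusion curve at ``t``; white noise is added last.
    Deterministic given ``spec.seed`` and ``t``.
    """
    if t not in SCHEDULE_MINUTES:
        raise ValueError(f"t={t!r} is not a schedule time")
    if n_frames < 2:
        raise ValueError("need at least 2 frames")
    if rng is None:
        rng = np.random.default_rng(
            np.random.SeedSequence([int(spec.seed), schedule_index(t)])
        )

    axial = (np.arange(geom.n_axial_samples) + 0.5) * geom.axial_spacing_mm
    lateral = (np.arange(geom.n_lines) + 0.5) * geom.line_pitch_mm
    margin = 3.0 * max(geom.psf_axial_mm, geom.psf_lateral_mm) + 0.1
    area = (geom.axial_extent_mm + 2 * margin) * (geom.lateral_extent_mm + 2 * margin)
    n_scat = max(int(round(spec.scatterer_density_per_mm2 * area)), 1)
    times = np.arange(n_frames) / geom.doppler_frame_rate_hz

    clutter_lin = _db_to_linear(spec.clutter_power_db)
    blood_lin = _db_to_linear(spec.blood_power_db + spec.perfusion_db(t))
    noise_lin = _db_to_linear(spec.noise_power_db)

    def draw_positions() -> np.ndarray:
        pos = np.empty((n_scat, 2))
        pos[:, 0] = rng.uniform(-margin, geom.axial_extent_mm + margin, n_scat)
        pos[:, 1] = rng.uniform(-margin, geom.lateral_extent_mm + margin, n_scat)
        return pos

    frames = np.zeros((n_frames, geom.n_axial_samples, geom.n_lines))

    if clutter_lin > 0.0:
        base = draw_positions()
        amps = rng.standard_normal(n_scat)
        shift_ax = spec.axial_drift_mm_per_s * times
        shift_lat = spec.respiration_amplitude_mm * np.sin(
            2.0 * np.pi * times / spec.respiration_period_s
        )
        pos = np.repeat(base[None], n_frames, axis=0)
        pos[:, :, 0] += shift_ax[:, None]
        pos[:, :, 1] += shift_lat[:, None]
        clutter = _render_frames(axial, lateral, pos, amps, geom)
        frames += _normalize_power(clutter, clutter_lin)

    if blood_lin > 0.0:
        base = draw_positions()
        amps = rng.standard_normal(n_scat)
        # per-frame Gaussian steps; RMS 2-D step magnitude = speed * dt
        step_rms = spec.blood_speed_mm_per_s / geom.doppler_frame_rate_hz
        steps = rng.normal(
            0.0, step_rms / math.sqrt(2.0), size=(n_frames, n_scat, 2)
        )
        steps[0] = 0.0
        pos = base[None] + np.cumsum(steps, axis=0)
        blood = _render_frames(axial, lateral, pos, amps, geom)
        frames += _normalize_power(blood, blood_lin)

    if noise_lin > 0.0:
        frames += rng.normal(0.0, math.sqrt(noise_lin), size=frames.shape)

    return EnsembleStack(
        frames=frames,
        geometry=geom,
        slow_time_rate_hz=geom.doppler_frame_rate_hz,
        provenance={
            "simulated": True,
            "t": t,
            "seed": int(spec.seed),
            "true_clutter_db": spec.clutter_power_db,
            "true_blood_db": spec.blood_power_db + spec.perfusion_db(t),
            "true_noise_db": spec.noise_power_db,
        },
    )


# ----------------------------------------------------------------------
# Profile-level simulation

def ischemic_truth_curve(
    p_max_db: float, p_min_db: float, t_recovery_days: float
) -> dict[str, float]:
    """True perfusion curve (dB re baseline) over the schedule.

    Construction (all fits are exact by design, enabling closed-loop
    estimator tests):

    * acute phase: a quadratic in log10(minutes) through 0 dB at the
      baseline abscissa (1 min), declining to 60% of ``p_min_db`` at 60 min;
      the 20-min value sits ``p_max_db`` above that trend;
    * recovery phase: a parabola in log10(days) with its vertex at day 1
      (value ``p_min_db``) rising through 0 dB at ``t_recovery_days``; weeks
      3-4 are capped at +0.5 dB (the fit only uses days 1-14).
    """
    if not (1.0 < t_recovery_days <= 28.0):
        raise ValueError("t_recovery_days must lie in (1, 28] days")
    if p_min_db >= 0:
        raise ValueError("p_min_db must be negative")
    if not np.isfinite(p_max_db):
        raise ValueError("p_max_db must be finite")

    s = 0.6 * p_min_db / math.log10(60.0) ** 2
    u_t = math.log10(t_recovery_days)
    a = -p_min_db / u_t**2

    curve: dict[str, float] = {"pre": 0.0}
    for label in ("10 m", "20 m", "30 m", "60 m"):
        u = math.log10(schedule_minutes(label))
        curve[label] = s * u**2
    curve["20 m"] += p_max_db
    for label in ("1 d", "2 d", "3 d", "1 w", "2 w", "3 w", "4 w"):
        u = math.log10(schedule_minutes(label) / 1440.0)
        v = p_min_db + a * u**2
        if label in ("3 w", "4 w"):
            v = min(v, 0.5)
        curve[label] = v
    return curve


def simulate_mouse_profile(
    p_max_db: float,
    p_min_db: float,
    t_recovery_days: float,
    noise_sd_db: float = 0.5,
    seed: int = 0,
    mouse_id: str = "sim",
    group: str = "",
    sex: str = "",
):
    """One ischemic-limb perfusion profile with known (P_max, P_min, T).

    Gaussian measurement noise of sd ``noise_sd_db`` is added to every
    post-ligation point; the pre-ligation baseline is 0 dB by construction.
    """
    from .perfusion import PerfusionProfile

    curve = ischemic_truth_curve(p_max_db, p_min_db, t_recovery_days)
    rng = np.random.default_rng(seed)
    values = np.array([curve[lab] for lab in SCHEDULE_LABELS])
    noise = rng.normal(0.0, noise_sd_db, size=values.size)
    noise[0] = 0.0  # baseline defines the reference
    return PerfusionProfile(
        labels=list(SCHEDULE_LABELS),
        values_db=values + noise,
        mouse_id=mouse_id,
        limb="ischemic",
        group=group,
        sex=sex,
    )


def simulate_control_profile(
    noise_sd_db: float = 0.5,
    seed: int = 0,
    mouse_id: str = "sim",
    group: str = "",
    sex: str = "",
):
    """A control-limb profile: flat 0 dB truth plus measurement noise."""
    from .perfusion import PerfusionProfile

    rng = np.random.default_rng(seed)
    values = rng.normal(0.0, noise_sd_db, size=len(SCHEDULE_LABELS))
    values[0] = 0.0
    return PerfusionProfile(
        labels=list(SCHEDULE_LABELS),
        values_db=values,
        mouse_id=mouse_id,
        limb="control",
        group=group,
        sex=sex,
    )


# ----------------------------------------------------------------------
# Cohort-level simulation

#: per-group default (P_max dB, P_min dB, T days) means, emulating the
#: healthy/diabetic x sedentary/exercised phenomenology: diabetic groups
#: recover later and spike less
DEFAULT_PARAM_MEANS: dict[str, tuple[float, float, float]] = {
    "HS": (3.0, -6.5, 6.0),
    "HE": (3.0, -6.0, 5.5),
    "DS": (2.0, -5.5, 9.5),
    "DE": (2.2, -5.5, 8.5),
}
DEFAULT_PARAM_SDS: tuple[float, float, float] = (0.5, 0.8, 1.5)

#: baseline age (months) and weight (g) by group; diabetic mice are heavier
DEFAULT_COVARIATES: dict[str, tuple[float, float]] = {
    "HS": (10.0, 34.0),
    "HE": (14.0, 39.0),
    "DS": (18.0, 57.0),
    "DE": (9.0, 48.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Specification of a synthetic cohort of mice.

    ``groups`` pairs a treatment label (HS, HE, DS, DE) with a sex; each
    group draws per-mouse (P_max, P_min, T) from Gaussian spreads around the
    group means, truncated to physical ranges.
    """

    groups: Sequence[tuple[str, str]] = (
        ("HS", "M"), ("HE", "M"), ("DS", "M"), ("DE", "M"),
        ("HS", "F"), ("HE", "F"), ("DS", "F"), ("DE", "F"),
    )
    n_per_group: int = 5
    param_means: Mapping[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PARAM_MEANS)
    )
    param_sds: tuple[float, float, float] = DEFAULT_PARAM_SDS
    noise_sd_db: float = 0.5
    covariate_means: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.groups) == 0:
            raise ValueError("cohort needs at least one group")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        for g, _ in self.groups:
            if g not in self.param_means:
                raise ValueError(f"no parameter means for group {g!r}")
            t_mean = self.param_means[g][2]
            if not (1.0 < t_mean <= 28.0):
                raise ValueError(f"group {g!r} mean T must be in (1, 28] days")


@dataclass
class CohortResult:
    """Simulated cohort: profiles, mouse records, and true parameters."""

    profiles: list
    records: pd.DataFrame  # mouse_id, group, sex, age_months, weight_g
    true_params: pd.DataFrame  # per-mouse drawn (p_max, p_min, t) truth

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table: one row per mouse x schedule point."""
        rows = []
        rec = self.records.set_index("mouse_id")
        for p in self.profiles:
            for lab, v in zip(p.labels, p.values_db):
                rows.append(
                    {
                        "mouse_id": p.mouse_id,
                        "group": p.group,
                        "sex": p.sex,
                        "age_months": rec.loc[p.mouse_id, "age_months"],
                        "weight_g": rec.loc[p.mouse_id, "weight_g"],
                        "time_label": lab,
                        "pdus_db": v,
                    }
                )
        return pd.DataFrame(rows)


def simulate_cohort(cs: CohortSpec) -> CohortResult:
    """Draw per-mouse parameters per group and synthesize their profiles."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cs.seed), 0xC0F0]))
    profiles, records, truths = [], [], []
    for g_label, sex in cs.groups:
        means = np.asarray(cs.param_means[g_label], dtype=float)
        sds = np.asarray(cs.param_sds, dtype=float)
        age_m, weight_m = cs.covariate_means.get(g_label, (12.0, 40.0))
        for i in range(cs.n_per_group):
            draw = rng.normal(means, sds)
            p_max = max(draw[0], 0.0)
            p_min = min(draw[1], -0.5)
            t_rec = float(np.clip(draw[2], 1.5, 28.0))
            mid = f"{g_label}-{sex}-{i + 1:02d}"
            prof_seed = int(rng.integers(0, 2**31 - 1))
            profiles.append(
                simulate_mouse_profile(
                    p_max, p_min, t_rec,
                    noise_sd_db=cs.noise_sd_db,
                    seed=prof_seed,
                    mouse_id=mid, group=g_label, sex=sex,
                )
            )
            records.append(
                {
                    "mouse_id": mid,
                    "group": g_label,
                    "sex": sex,
                    "age_months": max(rng.normal(age_m, 1.0), 2.0),
                    "weight_g": max(rng.normal(weight_m, 3.0), 15.0),
                }
            )
            truths.append(
                {"mouse_id": mid, "group": g_label, "sex": sex,
                 "p_max_db": p_max, "p_min_db": p_min, "t_days": t_rec}
            )
    return CohortResult(
        profiles=profiles,
        records=pd.DataFrame(records),
        true_params=pd.DataFrame(truths),
    )
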