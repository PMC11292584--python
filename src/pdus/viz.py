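"""Diagnostic plot hooks (matplotlib).

Layouts mirror the figures an analyst wants while tuning the pipeline: a
displacement trace per ensemble, Doppler spectra at successive processing
stages, singular spectra with and without registration, perfusion profiles
on log-time axes, and PD-US power maps.
"""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")  # headless-safe
import matplotlib.pyplot as plt
import numpy as np

from .clutterfilter import SingularSpectrum
from .perfusion import DopplerSpectrum, PerfusionProfile
from .registration import DisplacementTrace
from .schedule import SCHEDULE_LABELS


def plot_displacement_trace(trace: DisplacementTrace, ax=None):
    """Axial (blue) and lateral (red) displacement vs slow time."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    t = trace.time_s
    ax.plot(t, trace.axial_mm * 1e3, "o-", color="tab:blue", label="axial")
    ax.plot(t, trace.lateral_mm * 1e3, "s-", color="tab:red", label="lateral")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("displacement (µm)")
    ax.legend(frameon=False)
    return ax


def plot_doppler_spectra(spectra: Sequence[DopplerSpectrum], ax=None, log=True):
    """Overlay Doppler PSDs at different processing stages."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for sp in spectra:
        y = 10 * np.log10(np.maximum(sp.psd, 1e-300)) if log else sp.psd
        ax.plot(sp.freq_hz, y, label=sp.stage)
    ax.set_xlabel("Doppler frequency (Hz)")
    ax.set_ylabel("PSD (dB)" if log else "PSD")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_singular_spectra(
    spectra: dict[str, SingularSpectrum], ax=None, normalized=True
):
    """Singular spectra keyed by label (e.g. original vs registered)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    for label, ss in spectra.items():
        y = ss.normalized if normalized else ss.values
        ax.semilogy(np.arange(1, y.size + 1), y, "o-", label=label)
    ax.set_xlabel("singular value rank")
    ax.set_ylabel("energy fraction" if normalized else "singular value")
    ax.legend(frameon=False)
    return ax


def plot_profiles(profiles: Sequence[PerfusionProfile], ax=None):
    """Perfusion profiles over the schedule (categorical time axis)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3.5))
    for p in profiles:
        x = [SCHEDULE_LABELS.index(lab) for lab in p.labels]
        label = p.mouse_id or p.group
        ax.plot(x, p.values_db, "o-", label=label)
        if p.se_db is not None:
            ax.errorbar(x, p.values_db, yerr=p.se_db, fmt="none", alpha=0.5)
    ax.axhline(0.0, color="gray", lw=0.8)
    ax.set_xticks(range(len(SCHEDULE_LABELS)))
    ax.set_xticklabels(SCHEDULE_LABELS, rotation=45)
    ax.set_ylabel("PD-US (dB re baseline)")
    ax.legend(frameon=False, fontsize=8)
    return ax


def plot_pdus_image(image_db: np.ndarray, geom, ax=None):
    """PD-US power map in dB with physical axes."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(
        image_db,
        extent=(0, geom.lateral_extent_mm, geom.axial_extent_mm, 0),
        cmap="hot",
        aspect="equal",
    )
    plt.colorbar(im, ax=ax, label="power (dB re max)")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    return ax
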