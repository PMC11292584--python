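"""Endothelial-function indices from cuff-occlusion recordings.

After a 5-min pressure-cuff occlusion of the hindlimb, two indices separate
conduit- from resistance-vessel endothelial function:

* **FMD** (flow-mediated dilation) — fractional increase of the femoral
  artery diameter at peak hyperemia: (Da - Db)/Db.  Normal murine values
  run 0.13-0.14; smaller values indicate conduit-vessel dysfunction.
* **RH** (reactive hyperemia) index — dB ratio of peak post-release PD-US
  power to the pre-cuff baseline: 10 log10(PDUSa/PDUSb).  Normal values run
  3.9-5.2 dB; smaller values indicate resistance-vessel dysfunction.

The peak is searched within a configurable window after cuff release
(default 5 min, measurements every minute); the baseline is the average of
pre-cuff samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: lower edges of the normal ranges; the boundary itself counts as normal
FMD_NORMAL_MIN = 0.13
RH_NORMAL_MIN_DB = 3.9

DEFAULT_PEAK_WINDOW_MIN = 5.0


@dataclass
class EndothelialIndices:
    """FMD and RH for one mouse, with the inputs that produced them."""

    fmd: float
    rh_db: float
    d_b_mm: float
    d_a_mm: float
    pdus_b: float
    pdus_a: float

    def __post_init__(self) -> None:
        if self.d_b_mm <= 0:
            raise ValueError("baseline diameter must be positive")
        if self.pdus_b <= 0:
            raise ValueError("baseline power must be positive")
        if self.fmd < -1:
            raise ValueError("FMD below -1 is non-physical")


def _baseline_and_peak(
    time_min: np.ndarray,
    values: np.ndarray,
    release_time_min: float,
    window_min: float,
) -> tuple[float, float]:
    time_min = np.asarray(time_min, dtype=float)
    values = np.asarray(values, dtype=float)
    if time_min.shape != values.shape or time_min.size == 0:
        raise ValueError("time and value series must align and be non-empty")
    pre = values[time_min < release_time_min]
    if pre.size == 0:
        raise ValueError("no pre-release baseline samples")
    in_window = (time_min >= release_time_min) & (
        time_min <= release_time_min + window_min
    )
    post = values[in_window]
    if post.size == 0:
        raise ValueError("no post-release samples inside the search window")
    return float(np.mean(pre)), float(np.max(post))


def compute_fmd(
    time_min: np.ndarray,
    diameter_mm: np.ndarray,
    release_time_min: float = 0.0,
    window_min: float = DEFAULT_PEAK_WINDOW_MIN,
) -> float:
    """Flow-mediated dilation: (Da - Db)/Db.

    Db averages samples before cuff release; Da is the largest diameter in
    the post-release window.  Dimensionless and invariant to the diameter
    unit.
    """
    diameter_mm = np.asarray(diameter_mm, dtype=float)
    if np.any(diameter_mm <= 0):
        raise ValueError("diameters must be positive")
    d_b, d_a = _baseline_and_peak(time_min, diameter_mm, release_time_min, window_min)
    return (d_a - d_b) / d_b


def compute_rh(
    time_min: np.ndarray,
    pdus_power: np.ndarray,
    release_time_min: float = 0.0,
    window_min: float = DEFAULT_PEAK_WINDOW_MIN,
) -> float:
    """Reactive hyperemia index: 10 log10(peak post-release / baseline), dB."""
    pdus_power = np.asarray(pdus_power, dtype=float)
    if np.any(pdus_power <= 0):
        raise ValueError("PD-US powers must be positive")
    p_b, p_a = _baseline_and_peak(time_min, pdus_power, release_time_min, window_min)
    return 10.0 * np.log10(p_a / p_b)


def indices_from_series(
    time_min,
    diameter_mm,
    pdus_power,
    release_time_min: float = 0.0,
    window_min: float = DEFAULT_PEAK_WINDOW_MIN,
) -> EndothelialIndices:
    """Compute both indices from simultaneous diameter and power series."""
    diameter_mm = np.asarray(diameter_mm, dtype=float)
    pdus_power = np.asarray(pdus_power, dtype=float)
    if np.any(diameter_mm <= 0) or np.any(pdus_power <= 0):
        raise ValueError("diameters and powers must be positive")
    d_b, d_a = _baseline_and_peak(time_min, diameter_mm, release_time_min, window_min)
    p_b, p_a = _baseline_and_peak(time_min, pdus_power, release_time_min, window_min)
    return EndothelialIndices(
        fmd=(d_a - d_b) / d_b,
        rh_db=10.0 * np.log10(p_a / p_b),
        d_b_mm=d_b, d_a_mm=d_a, pdus_b=p_b, pdus_a=p_a,
    )


def classify_endothelial(
    e: EndothelialIndices,
    fmd_normal_min: float = FMD_NORMAL_MIN,
    rh_normal_min_db: float = RH_NORMAL_MIN_DB,
) -> dict[str, str]:
    """Classify each index as normal or reduced.

    The lower edge of the normal range is inclusive: FMD >= 0.13 and
    RH >= 3.9 dB count as normal.
    """
    return {
        "conduit": "normal" if e.fmd >= fmd_normal_min else "reduced",
        "resistance": "normal" if e.rh_db >= rh_normal_min_db else "reduced",
    }


def coefficient_of_variation(values) -> float:
    """100 * sample sd / |mean|, in percent (reproducibility metric)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("CV needs at least 2 values")
    mean = float(np.mean(values))
    if mean == 0.0:
        raise ValueError("CV undefined for zero mean")
    return 100.0 * float(np.std(values, ddof=1)) / abs(mean)
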