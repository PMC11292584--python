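"""Ischemic-response parameters: the 20-min spike P_max, the perfusion
minimum P_min, and the recovery time T.

Following femoral ligation, perfusion declines over 1-2 days and then
recovers to baseline within four weeks.  Three parameters summarize each
mouse's profile:

* ``P_max`` — the transient perfusion spike 20 min after ligation,
  measured as the dB excess of the 20-min point above a second-order
  polynomial through the pre, 10-, 30-, and 60-min points;
* ``P_min`` — the minimum measured (not fitted) dB value over the 28 days;
* ``T`` — the day at which a second-order polynomial through the day
  1, 2, 3, 7, and 14 points crosses 0 dB from below.

Both fits use a log10(time) abscissa, consistent with the log-time axes on
which the profiles are linear-looking; the pre-ligation point is assigned
1 min so it occupies a finite abscissa.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .perfusion import PerfusionProfile
from .schedule import (
    PMAX_SPIKE_LABEL,
    PMAX_TREND_LABELS,
    RECOVERY_FIT_LABELS,
    schedule_minutes,
)

#: abscissa (minutes) assigned to the pre-ligation baseline in the acute fit
PRE_ABSCISSA_MIN = 1.0

#: admissible recovery-time window (days); crossings outside are censored
RECOVERY_WINDOW_DAYS = (1.0, 28.0)


@dataclass
class IschemicParams:
    """The (P_max, P_min, T) triplet characterizing one perfusion profile."""

    p_max_db: float
    p_min_db: float
    t_recovery_days: float
    censored: bool = False
    p_max_sd_db: float = np.nan
    diagnostics: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "p_max_db": self.p_max_db,
            "p_min_db": self.p_min_db,
            "t_days": self.t_recovery_days,
            "censored": self.censored,
        }


def _fit_quadratic(u: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares quadratic coefficients (highest power first)."""
    return np.polyfit(u, y, 2)


def estimate_pmax(profile: PerfusionProfile) -> tuple[float, float, dict]:
    """20-min perfusion spike above the acute trend.

    Fits the pre (at 1 min), 10-, 30-, and 60-min points to a quadratic in
    log10(minutes); P_max is the measured 20-min value minus the fit value
    there.  The uncertainty is the sd of the 20-min measurements when the
    profile carries per-point errors, else NaN.

    Returns (p_max_db, p_max_sd_db, diagnostics).
    """
    required = (*PMAX_TREND_LABELS, PMAX_SPIKE_LABEL)
    missing = [lab for lab in required if not profile.has(lab)]
    if missing:
        raise ValueError(f"profile lacks required acute points: {missing}")
    u = np.array(
        [
            math.log10(PRE_ABSCISSA_MIN if lab == "pre" else schedule_minutes(lab))
            for lab in PMAX_TREND_LABELS
        ]
    )
    y = np.array([profile.value(lab) for lab in PMAX_TREND_LABELS])
    coeffs = _fit_quadratic(u, y)
    u20 = math.log10(schedule_minutes(PMAX_SPIKE_LABEL))
    trend_at_20 = float(np.polyval(coeffs, u20))
    measured = profile.value(PMAX_SPIKE_LABEL)
    p_max = measured - trend_at_20
    sd = np.nan
    if profile.se_db is not None:
        sd = float(profile.se_db[profile.labels.index(PMAX_SPIKE_LABEL)])
    diagnostics = {
        "coefficients": coeffs,
        "trend_at_20min_db": trend_at_20,
        "residuals": y - np.polyval(coeffs, u),
    }
    return float(p_max), sd, diagnostics


def estimate_recovery_time(profile: PerfusionProfile) -> tuple[float, bool, dict]:
    """Day at which the recovery fit crosses 0 dB from below.

    Fits days 1, 2, 3, 7, 14 to a quadratic in log10(days) and selects the
    upward 0-dB crossing (positive slope at the root) within (1, 28] days;
    the earlier qualifying crossing wins ties.  Censored when no such
    crossing exists.  A degenerate all-baseline profile reports the day-1
    boundary with a warning.

    Returns (t_days, censored, diagnostics).
    """
    present = [lab for lab in RECOVERY_FIT_LABELS if profile.has(lab)]
    if len(present) < 3:
        raise ValueError(
            f"recovery fit needs >= 3 of {RECOVERY_FIT_LABELS}; have {present}"
        )
    u = np.array([math.log10(schedule_minutes(lab) / 1440.0) for lab in present])
    y = np.array([profile.value(lab) for lab in present])
    lo, hi = RECOVERY_WINDOW_DAYS
    scale = max(float(np.max(np.abs(y))), 1e-12)
    coeffs = _fit_quadratic(u, y)
    diagnostics = {"coefficients": coeffs, "residuals": y - np.polyval(coeffs, u)}

    if np.all(np.abs(y) < 1e-9):
        warnings.warn(
            "recovery profile is identically at baseline; reporting the "
            "day-1 boundary",
            stacklevel=2,
        )
        return lo, False, diagnostics

    a, b, c = (float(v) for v in coeffs)
    roots: list[float] = []
    if abs(a) < 1e-12 * scale:
        if abs(b) > 1e-12 * scale:
            roots = [-c / b] if b > 0 else []
    else:
        disc = b * b - 4 * a * c
        if disc >= 0:
            sq = math.sqrt(disc)
            for r in ((-b - sq) / (2 * a), (-b + sq) / (2 * a)):
                if 2 * a * r + b > 0:  # upward crossing
                    roots.append(r)
    days = sorted(10.0**r for r in roots)
    for d in days:
        if lo < d <= hi:
            return float(d), False, diagnostics
    return np.nan, True, diagnostics


def estimate_pmin(profile: PerfusionProfile) -> float:
    """Minimum measured dB value among post-ligation points (not a fit)."""
    post = [lab for lab in profile.labels if lab != "pre"]
    if not post:
        raise ValueError("profile has no post-ligation points")
    return float(min(profile.value(lab) for lab in post))


def estimate_params(profile: PerfusionProfile) -> IschemicParams:
    """Estimate the full (P_max, P_min, T) triplet for one profile."""
    p_max, p_max_sd, diag_max = estimate_pmax(profile)
    t_days, censored, diag_t = estimate_recovery_time(profile)
    return IschemicParams(
        p_max_db=p_max,
        p_min_db=estimate_pmin(profile),
        t_recovery_days=t_days,
        censored=censored,
        p_max_sd_db=p_max_sd,
        diagnostics={"pmax_fit": diag_max, "recovery_fit": diag_t},
    )


def params_table(profiles) -> pd.DataFrame:
    """Per-mouse parameter table (mouse_id, group, sex, P_max, P_min, T)."""
    rows = []
    for p in profiles:
        est = estimate_params(p)
        rows.append(
            {"mouse_id": p.mouse_id, "group": p.group, "sex": p.sex,
             **est.to_row()}
        )
    return pd.DataFrame(rows)
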