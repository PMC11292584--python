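"""Measurement schedule for the hindlimb-ischemia study.

Perfusion is measured at a fixed set of time points: a pre-ligation
baseline, four acute points in the first hour, daily points through day 3,
and weekly points through four weeks.  Times are stored in minutes
post-ligation; "pre" is the baseline and has no post-ligation time.
"""

from __future__ import annotations

# label -> minutes post-ligation (None for the pre-ligation baseline)
SCHEDULE_MINUTES: dict[str, float | None] = {
    "pre": None,
    "10 m": 10.0,
    "20 m": 20.0,
    "30 m": 30.0,
    "60 m": 60.0,
    "1 d": 1440.0,
    "2 d": 2 * 1440.0,
    "3 d": 3 * 1440.0,
    "1 w": 7 * 1440.0,
    "2 w": 14 * 1440.0,
    "3 w": 21 * 1440.0,
    "4 w": 28 * 1440.0,
}

SCHEDULE_LABELS: tuple[str, ...] = tuple(SCHEDULE_MINUTES)

#: labels used for the acute (P_max) polynomial trend fit — all first-hour
#: points except the 20-min spike itself
PMAX_TREND_LABELS: tuple[str, ...] = ("pre", "10 m", "30 m", "60 m")
PMAX_SPIKE_LABEL: str = "20 m"

#: labels used for the recovery-time (T) polynomial fit: days 1, 2, 3, 7, 14
RECOVERY_FIT_LABELS: tuple[str, ...] = ("1 d", "2 d", "3 d", "1 w", "2 w")


def schedule_minutes(label: str) -> float | None:
    """Minutes post-ligation for a schedule label (None for ``pre``)."""
    try:
        return SCHEDULE_MINUTES[label]
    except KeyError:
        raise ValueError(
            f"unknown schedule label {label!r}; expected one of {SCHEDULE_LABELS}"
        ) from None


def schedule_days(label: str) -> float | None:
    """Days post-ligation for a schedule label (None for ``pre``)."""
    m = schedule_minutes(label)
    return None if m is None else m / 1440.0


def schedule_index(label: str) -> int:
    """Ordinal position of a label in the schedule (used for seeding)."""
    if label not in SCHEDULE_MINUTES:
        raise ValueError(f"unknown schedule label {label!r}")
    return SCHEDULE_LABELS.index(label)
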