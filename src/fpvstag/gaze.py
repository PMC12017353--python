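"""Probability-weighted assignment of fixations to areas of interest.

Eye-tracker calibration error blurs the reported fixation position, so a
fixation near an AOI border cannot be attributed with certainty.  Instead of
hard point-in-rectangle assignment, each fixation spreads its duration over
the AOIs according to the mass of an isotropic bivariate Gaussian centred at
the reported position with SD equal to the subject's calibration validation
error.  Proportional looking time to an AOI is then the weighted duration
attributed to it divided by total fixation duration.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AOIRect:
    """Rectangular area of interest in screen pixels."""

    label: str
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate AOI rectangle {self.label!r}")

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x <= self.x_max and self.y_min <= y <= self.y_max

    def overlaps(self, other: "AOIRect") -> bool:
        return not (
            self.x_max <= other.x_min
            or other.x_max <= self.x_min
            or self.y_max <= other.y_min
            or other.y_max <= self.y_min
        )


@dataclass(frozen=True)
class FixationRecord:
    """One fixation event with subject-level calibration accuracy."""

    x_px: float
    y_px: float
    onset_s: float
    duration_s: float
    subject_id: str = ""
    condition: str = ""
    calibration_error_px: float = 0.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("fixation duration must be positive")
        if self.calibration_error_px < 0:
            raise ValueError("calibration error cannot be negative")


@dataclass
class GazeResult:
    """Proportional looking times per AOI for one subject x condition."""

    subject: str
    condition: str
    proportions: dict[str, float]
    total_duration_s: float
    n_fixations: int

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"proportions sum to {total}, not 1")


def _interval_mass(lo: float, hi: float, mu: float, sd: float) -> float:
    if sd == 0.0:  # degenerate kernel: hard assignment
        return 1.0 if lo <= mu <= hi else 0.0
    return float(norm.cdf((hi - mu) / sd) - norm.cdf((lo - mu) / sd))


def fixation_weights(
    fix: FixationRecord,
    aois: tuple[AOIRect, ...],
    sd_px: float | None = None,
) -> dict[str, float]:
    """Gaussian-mass weight of one fixation on each AOI plus ``outside``.

    The weight on a rectangle is the product of the two 1-D Gaussian
    interval masses; the remainder goes to ``outside``.  ``sd_px`` defaults
    to the fixation's calibration error; 0 gives hard assignment.
    """
    if not (math.isfinite(fix.x_px) and math.isfinite(fix.y_px)):
        raise ValueError("non-finite fixation coordinates")
    for i, a in enumerate(aois):
        for b in aois[i + 1 :]:
            if a.overlaps(b):
                raise ValueError(f"AOIs {a.label!r} and {b.label!r} overlap")
    sd = fix.calibration_error_px if sd_px is None else sd_px
    weights = {
        a.label: _interval_mass(a.x_min, a.x_max, fix.x_px, sd)
        * _interval_mass(a.y_min, a.y_max, fix.y_px, sd)
        for a in aois
    }
    weights["outside"] = max(0.0, 1.0 - sum(weights.values()))
    return weights


def proportional_looking(
    fixations: list[FixationRecord],
    aois: tuple[AOIRect, ...],
    sd_px: float | None = None,
) -> GazeResult:
    """Duration-weighted AOI proportions over a fixation stream.

    proportion(A) = sum_i duration_i * weight_i(A) / sum_i duration_i.
    Fixations with non-finite coordinates are dropped with a logged count.
    """
    valid = [
        f for f in fixations if math.isfinite(f.x_px) and math.isfinite(f.y_px)
    ]
    dropped = len(fixations) - len(valid)
    if dropped:
        logger.warning("dropped %d fixations with non-finite coordinates", dropped)
    if not valid:
        raise ValueError("no valid fixations")
    total = sum(f.duration_s for f in valid)
    if total <= 0:
        raise ValueError("zero total fixation duration")
    labels = [a.label for a in aois] + ["outside"]
    acc = dict.fromkeys(labels, 0.0)
    for f in valid:
        w = fixation_weights(f, aois, sd_px)
        for lab in labels:
            acc[lab] += f.duration_s * w[lab]
    props = {lab: acc[lab] / total for lab in labels}
    # guard against accumulated rounding
    s = sum(props.values())
    props = {lab: p / s for lab, p in props.items()}
    first = valid[0]
    return GazeResult(
        subject=first.subject_id,
        condition=first.condition,
        proportions=props,
        total_duration_s=total,
        n_fixations=len(valid),
    )


def gaze_table(results: list[GazeResult]) -> pd.DataFrame:
    """Tidy export: one row per subject x condition x AOI."""
    rows = []
    for r in results:
        for label, p in r.proportions.items():
            rows.append(
                {
                    "subject": r.subject,
                    "condition": r.condition,
                    "aoi": label,
                    "proportion": p,
                    "total_duration_s": r.total_duration_s,
                    "n_fixations": r.n_fixations,
                }
            )
    return pd.DataFrame(rows)


def read_fixations_csv(path) -> list[FixationRecord]:
    """Read the fixation CSV schema written by the simulator."""
    df = pd.read_csv(path)
    required = {"subject", "condition", "x_px", "y_px", "onset_s", "duration_s",
                "calibration_error_px"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fixation CSV missing columns: {sorted(missing)}")
    return [
        FixationRecord(
            x_px=row.x_px,
            y_px=row.y_px,
            onset_s=row.onset_s,
            duration_s=row.duration_s,
            subject_id=str(row.subject),
            condition=str(row.condition),
            calibration_error_px=row.calibration_error_px,
        )
        for row in df.itertuples()
    ]
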