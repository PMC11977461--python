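"""Experimental layout: cultivation stages, sampling days and bioreactors.

The default layout mirrors a three-stage continuous-cultivation experiment:
a stabilization window (days 4-6) that serves as the pre-perturbation
reference, a press-exposure window (days 7-13) and a recovery window
(days 14-17), sampled daily from four parallel bioreactors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

STAGES: tuple[str, ...] = ("stabilization", "exposure", "recovery")


@dataclass(frozen=True)
class StageWindows:
    """Inclusive day windows for the three cultivation stages.

    Windows must be disjoint, ordered, and contiguous enough to cover every
    sampled day; overlapping windows are a design error.
    """

    stabilization: tuple[int, int] = (4, 6)
    exposure: tuple[int, int] = (7, 13)
    recovery: tuple[int, int] = (14, 17)

    def __post_init__(self) -> None:
        prev_end = None
        for stage in STAGES:
            lo, hi = getattr(self, stage)
            if lo > hi:
                raise ValueError(f"{stage} window {lo}..{hi} has start after end")
            if prev_end is not None and lo <= prev_end:
                raise ValueError(f"stage windows overlap or are out of order at {stage}")
            prev_end = hi

    def stage_of(self, day: int) -> str:
        for stage in STAGES:
            lo, hi = getattr(self, stage)
            if lo <= day <= hi:
                return stage
        raise ValueError(f"day {day} falls outside all stage windows")

    def days(self, stage: str) -> range:
        if stage not in STAGES:
            raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}")
        lo, hi = getattr(self, stage)
        return range(lo, hi + 1)

    @property
    def all_days(self) -> list[int]:
        return [d for stage in STAGES for d in self.days(stage)]


def make_design(windows: StageWindows | None = None, n_bioreactors: int = 4) -> pd.DataFrame:
    """Build the sample metadata table: one row per bioreactor-day.

    Returns a DataFrame with columns sample, bioreactor, day, stage.  Each
    bioreactor-day is treated as one observation downstream.
    """
    windows = windows or StageWindows()
    if n_bioreactors < 1:
        raise ValueError("n_bioreactors must be >= 1")
    rows = [
        {
            "sample": f"B{b}_D{d:02d}",
            "bioreactor": f"B{b}",
            "day": d,
            "stage": windows.stage_of(d),
        }
        for b in range(1, n_bioreactors + 1)
        for d in windows.all_days
    ]
    return pd.DataFrame(rows)


def check_design(design: pd.DataFrame, windows: StageWindows | None = None) -> None:
    """Validate a metadata table: unique samples, known stages, days in window."""
    required = {"sample", "bioreactor", "day", "stage"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"metadata table missing columns: {sorted(missing)}")
    if design["sample"].duplicated().any():
        dupes = design.loc[design["sample"].duplicated(), "sample"].tolist()
        raise ValueError(f"duplicate sample ids: {dupes}")
    unknown = set(design["stage"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels: {sorted(unknown)}")
    if windows is not None:
        for _, row in design.iterrows():
            expected = windows.stage_of(int(row["day"]))
            if row["stage"] != expected:
                raise ValueError(
                    f"sample {row['sample']}: day {row['day']} labelled "
                    f"{row['stage']!r} but the window says {expected!r}"
                )


def stage_samples(design: pd.DataFrame, stage: str) -> list[str]:
    return design.loc[design["stage"] == stage, "sample"].tolist()
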