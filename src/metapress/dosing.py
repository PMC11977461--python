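"""Dose scaling and washout kinetics for continuous bioreactor exposure.

Two pieces of arithmetic frame a press-perturbation experiment in a
continuously stirred tank reactor (CSTR):

* scaling a regulatory Acceptable Daily Intake (ADI, mg per kg body weight
  per day) down to an in-vitro working concentration, assuming the reactor
  holds a stated fraction of the daily faecal microbial load of a reference
  adult; and
* the first-order washout of the compound once dosing stops.  With a media
  exchange period of 24 h the dilution rate is one reactor volume per day,
  and an ideal CSTR mass balance gives exponential decay
  ``c(t) = c0 * exp(-D * t)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .design import StageWindows


def _require_positive(**fields: float) -> None:
    for name, value in fields.items():
        if not value > 0:
            raise ValueError(f"{name} must be > 0, got {value!r}")


def scale_adi_dose(
    adi: float,
    body_mass: float,
    reactor_cell_fraction: float,
    reactor_volume: float,
) -> float:
    """Scale an ADI (mg/kg bw/day) to a reactor concentration in mg/ml.

    The daily dose for a ``body_mass``-kg adult is ``adi * body_mass`` mg;
    the reactor receives the fraction of that dose matching its share of the
    adult's daily faecal cell output, dissolved in ``reactor_volume`` ml.

    >>> scale_adi_dose(6, 70, 0.10, 250)
    0.168
    """
    _require_positive(
        adi=adi,
        body_mass=body_mass,
        reactor_cell_fraction=reactor_cell_fraction,
        reactor_volume=reactor_volume,
    )
    if reactor_cell_fraction > 1:
        raise ValueError(
            f"reactor_cell_fraction must be in (0, 1], got {reactor_cell_fraction!r}"
        )
    return adi * body_mass * reactor_cell_fraction / reactor_volume


def washout_concentration(c0: float, dilution_rate: float, t: float) -> float:
    """Concentration after ``t`` days of washout in an ideal CSTR.

    ``c0`` is the concentration when the feed switches to compound-free
    medium (mg/ml) and ``dilution_rate`` is in reactor volumes per day.
    """
    if c0 < 0:
        raise ValueError(f"c0 must be >= 0, got {c0!r}")
    _require_positive(dilution_rate=dilution_rate)
    if t < 0:
        raise ValueError(f"t must be >= 0, got {t!r}")
    return c0 * math.exp(-dilution_rate * t)


def inoculum_cells(n_strains: int = 8, cells_per_strain: float = 1e9) -> float:
    """Total inoculum per bioreactor: equal cell counts from every strain."""
    if n_strains < 1:
        raise ValueError(f"n_strains must be >= 1, got {n_strains!r}")
    _require_positive(cells_per_strain=cells_per_strain)
    return n_strains * cells_per_strain


@dataclass(frozen=True)
class DosingScenario:
    """ADI-based dosing assumptions; target concentration is derived."""

    adi: float = 6.0  # mg / kg bw / day
    body_mass: float = 70.0  # kg
    reactor_cell_fraction: float = 0.10  # reactor cells / daily faecal CFU output
    reactor_volume: float = 250.0  # ml

    @property
    def target_concentration(self) -> float:
        return scale_adi_dose(
            self.adi, self.body_mass, self.reactor_cell_fraction, self.reactor_volume
        )

    def __post_init__(self) -> None:
        self.target_concentration  # validates all fields


@dataclass(frozen=True)
class WashoutModel:
    """First-order washout from an initial concentration c0 (mg/ml)."""

    c0: float
    dilution_rate: float = 1.0  # reactor volumes / day (24-h media exchange)
    duration: float = 4.0  # days

    def __post_init__(self) -> None:
        if self.c0 < 0:
            raise ValueError(f"c0 must be >= 0, got {self.c0!r}")
        _require_positive(dilution_rate=self.dilution_rate)
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration!r}")

    def concentration(self, t: float) -> float:
        return washout_concentration(self.c0, self.dilution_rate, t)

    @property
    def endpoint(self) -> float:
        return self.concentration(self.duration)


def concentration_timecourse(
    scenario: DosingScenario,
    washout: WashoutModel,
    windows: StageWindows | None = None,
    exposure_concentration: float | None = None,
) -> pd.DataFrame:
    """Expected compound concentration per sampled day across the stages.

    Stabilization days carry 0 (no compound yet); exposure days carry the
    dosing target, or a supplied measured mean concentration; recovery day
    ``d`` decays exponentially from the recovery start.

    Returns a DataFrame with columns day, stage, concentration (mg/ml,
    reported at full precision; round to 3 decimals for display).
    """
    windows = windows or StageWindows()
    if exposure_concentration is None:
        exposure_concentration = scenario.target_concentration
    recovery_start = windows.recovery[0]
    rows = []
    for day in windows.all_days:
        stage = windows.stage_of(day)
        if stage == "stabilization":
            conc = 0.0
        elif stage == "exposure":
            conc = exposure_concentration
        else:
            conc = washout.concentration(day - recovery_start)
        rows.append({"day": day, "stage": stage, "concentration": conc})
    return pd.DataFrame(rows)
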