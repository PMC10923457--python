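"""Empirical source-term models for electro-surgical smoke generation.

An electro-surgical knife cutting tissue releases waste gas (CO, CO2, CH4,
NH3), condensed tar droplets and non-viable particles at rates that depend
on the unit's power setting.  In vitro power-sweep measurements are well
described by low-order polynomials in power P (W):

    T_tip(P)      = 270 - 4.59 P + 0.095 P^2          [degC]
    G_wastegas(P) = 9.30e-6 - 4.49e-8 P + 7.16e-9 P^2 [m^3/s, net at STP]
    F_particle(P) = -4.14e-3 + 6.33e-4 P - 2.06e-6 P^2 + 2.80e-7 P^3 [g/s]
    F_tar(P)      =  2.82e-3 + 4.69e-4 P - 9.69e-6 P^2 + 1.98e-7 P^3 [g/s]

This module evaluates, inverts and refits these calibrations and assembles
a :class:`SourceSpec` — the boundary-condition description of the smoke
source at the incision — from a knife operating point.

The published power <-> tip-temperature correspondence rounds the quadratic
to the nearest 100 degC: 20/60/70/80 W map to 200/300/400/500 degC.  Note
the quadratic has a minimum of ~214.6 degC at ~24.2 W, so 200 degC is not
exactly attainable; ``power_for_temperature`` offers a ``lookup`` mode that
honours the published table for those four canonical temperatures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.polynomial import polynomial as npoly

__all__ = [
    "CalibrationSet",
    "PowerSweepRecord",
    "SourceSpec",
    "CANONICAL_CASES",
    "DEFAULT_COMPOSITION",
    "eval_tip_temperature",
    "eval_waste_gas_flow",
    "eval_particle_rate",
    "eval_tar_rate",
    "power_for_temperature",
    "fit_calibration",
    "make_source_spec",
    "records_to_frame",
    "frame_to_records",
]

#: Published correspondence between canonical tip temperatures (degC) and
#: knife powers (W).
CANONICAL_CASES: dict[float, float] = {200.0: 20.0, 300.0: 60.0, 400.0: 70.0, 500.0: 80.0}

#: Placeholder waste-gas mole fractions at the incision.  The measured
#: composition is available only graphically; these defaults respect the
#: qualitative constraint that CO + CO2 dominate CH4 + NH3.  Any absolute
#: CO concentration downstream is composition-dependent.
DEFAULT_COMPOSITION: dict[str, float] = {"CO": 0.25, "CO2": 0.45, "CH4": 0.06, "NH3": 0.04}

#: Molar masses, g/mol.
MOLAR_MASS: dict[str, float] = {"CO": 28.01, "CO2": 44.01, "CH4": 16.04, "NH3": 17.03, "air": 28.96}

AMBIENT_TEMP_C = 27.0


@dataclass(frozen=True)
class CalibrationSet:
    """Polynomial coefficients (ascending order) of the four calibrations."""

    temp_coeffs: tuple[float, ...] = (270.0, -4.59, 0.095)
    flow_coeffs: tuple[float, ...] = (9.30e-6, -4.49e-8, 7.16e-9)
    particle_coeffs: tuple[float, ...] = (-4.14e-3, 6.33e-4, -2.06e-6, 2.80e-7)
    tar_coeffs: tuple[float, ...] = (2.82e-3, 4.69e-4, -9.69e-6, 1.98e-7)

    def __post_init__(self) -> None:
        for name, n in (("temp_coeffs", 3), ("flow_coeffs", 3),
                        ("particle_coeffs", 4), ("tar_coeffs", 4)):
            c = getattr(self, name)
            if len(c) != n:
                raise ValueError(f"{name} must have {n} coefficients, got {len(c)}")
            object.__setattr__(self, name, tuple(float(v) for v in c))

    def to_dict(self) -> dict[str, list[float]]:
        return {
            "temp_coeffs": list(self.temp_coeffs),
            "flow_coeffs": list(self.flow_coeffs),
            "particle_coeffs": list(self.particle_coeffs),
            "tar_coeffs": list(self.tar_coeffs),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CalibrationSet":
        return cls(**{k: tuple(v) for k, v in d.items() if k.endswith("_coeffs")})


@dataclass
class PowerSweepRecord:
    """One row of an in vitro power-sweep measurement."""

    power: float                       # W
    tip_temp: float                    # degC
    waste_gas_flow: float              # m^3/s net, STP-corrected
    tar_rate: float                    # g/s
    particle_rate: float               # g/s
    composition: dict[str, float] | None = None   # mole fractions

    def __post_init__(self) -> None:
        if self.power <= 0:
            raise ValueError("power must be positive")
        for name in ("waste_gas_flow", "tar_rate", "particle_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.composition is not None:
            vals = list(self.composition.values())
            if any(v < 0 or v > 1 for v in vals) or sum(vals) > 1 + 1e-12:
                raise ValueError("composition fractions must lie in [0,1] and sum to <= 1")


@dataclass
class SourceSpec:
    """Smoke source at the incision, ready to become CFD source terms."""

    volume_flow: float                       # m^3/s at STP
    temperature: float                       # degC
    species_mass_fractions: dict[str, float]
    tar_rate: float                          # g/s
    particle_rate: float                     # g/s
    position: tuple[float, float, float] = (4.0, 3.0, 0.9)   # m, incision point
    power: float | None = None               # W, resolved operating point

    def __post_init__(self) -> None:
        if self.volume_flow <= 0:
            raise ValueError("volume_flow must be positive")
        if self.temperature <= AMBIENT_TEMP_C:
            raise ValueError(
                f"source temperature {self.temperature} degC must exceed "
                f"ambient ({AMBIENT_TEMP_C} degC)")
        s = sum(self.species_mass_fractions.values())
        if any(v < 0 or v > 1 for v in self.species_mass_fractions.values()) or s > 1 + 1e-12:
            raise ValueError("species mass fractions must lie in [0,1] and sum to <= 1")


def _check_power(power: float) -> float:
    p = float(power)
    if p < 0:
        raise ValueError(f"power must be non-negative, got {p}")
    return p


def eval_tip_temperature(power: float, calib: CalibrationSet | None = None) -> float:
    """Knife tip temperature (degC) at a given power (W)."""
    calib = calib or CalibrationSet()
    return float(npoly.polyval(_check_power(power), calib.temp_coeffs))


def eval_waste_gas_flow(power: float, calib: CalibrationSet | None = None) -> float:
    """Net waste-gas volume flow (m^3/s, STP) at a given power (W)."""
    calib = calib or CalibrationSet()
    return float(npoly.polyval(_check_power(power), calib.flow_coeffs))


def eval_particle_rate(power: float, calib: CalibrationSet | None = None,
                       clamp: bool = True) -> float:
    """Non-viable particle formation rate (g/s).

    The fitted cubic is slightly negative at very low power; by default the
    physically meaningless negative branch is clamped to zero.  Pass
    ``clamp=False`` to see the raw polynomial (needed when refitting).
    """
    calib = calib or CalibrationSet()
    v = float(npoly.polyval(_check_power(power), calib.particle_coeffs))
    return max(v, 0.0) if clamp else v


def eval_tar_rate(power: float, calib: CalibrationSet | None = None) -> float:
    """Condensed-tar formation rate (g/s) at a given power (W)."""
    calib = calib or CalibrationSet()
    return float(npoly.polyval(_check_power(power), calib.tar_coeffs))


def power_for_temperature(tip_temp: float, calib: CalibrationSet | None = None,
                          lookup: bool = False) -> tuple[float, bool]:
    """Invert the tip-temperature quadratic.

    Returns ``(power_W, unreachable)``.  ``unreachable`` is True when
    ``tip_temp`` lies below the parabola minimum, in which case the vertex
    power is returned as the closest attainable operating point.

    With ``lookup=True`` the four canonical temperatures {200, 300, 400,
    500} degC resolve to the published powers {20, 60, 70, 80} W instead of
    the exact inverse (which gives ~216/337/414/511 degC at those powers).
    """
    calib = calib or CalibrationSet()
    t = float(tip_temp)
    if lookup and t in CANONICAL_CASES:
        return CANONICAL_CASES[t], False
    c0, c1, c2 = calib.temp_coeffs
    vertex_p = -c1 / (2.0 * c2)
    t_min = float(npoly.polyval(vertex_p, calib.temp_coeffs))
    if t < t_min:
        return vertex_p, True
    disc = c1 * c1 - 4.0 * c2 * (c0 - t)
    return (-c1 + np.sqrt(disc)) / (2.0 * c2), False


def fit_calibration(records: list[PowerSweepRecord]) -> tuple[CalibrationSet, dict[str, float]]:
    """Ordinary least-squares polynomial refit of all four calibrations.

    Degree 2 for tip temperature and waste-gas flow, degree 3 for particle
    and tar formation.  Returns the fitted :class:`CalibrationSet` and the
    residual sum of squares per response.

    Raises ``ValueError`` when the design is rank deficient (fewer distinct
    powers than coefficients).
    """
    p = np.array([r.power for r in records], dtype=float)
    n_distinct = np.unique(p).size
    responses = {
        "temp_coeffs": (np.array([r.tip_temp for r in records]), 2),
        "flow_coeffs": (np.array([r.waste_gas_flow for r in records]), 2),
        "particle_coeffs": (np.array([r.particle_rate for r in records]), 3),
        "tar_coeffs": (np.array([r.tar_rate for r in records]), 3),
    }
    coeffs: dict[str, tuple[float, ...]] = {}
    rss: dict[str, float] = {}
    for name, (y, deg) in responses.items():
        if n_distinct < deg + 1:
            raise ValueError(
                f"need >= {deg + 1} distinct powers to fit {name} "
                f"(degree {deg}), got {n_distinct}")
        c = npoly.polyfit(p, y, deg)
        coeffs[name] = tuple(float(v) for v in c)
        rss[name] = float(np.sum((y - npoly.polyval(p, c)) ** 2))
    return CalibrationSet(**coeffs), rss


def mole_to_mass_fractions(mole_fractions: dict[str, float]) -> dict[str, float]:
    """Convert waste-gas mole fractions to mass fractions; the remainder of
    the mixture is entrained air."""
    bad = [k for k in mole_fractions if k not in MOLAR_MASS]
    if bad:
        raise ValueError(f"unknown species {bad}; known: {sorted(MOLAR_MASS)}")
    x_air = 1.0 - sum(mole_fractions.values())
    if x_air < -1e-12 or any(v < 0 or v > 1 for v in mole_fractions.values()):
        raise ValueError("mole fractions must lie in [0,1] and sum to <= 1")
    m_mix = x_air * MOLAR_MASS["air"] + sum(
        x * MOLAR_MASS[s] for s, x in mole_fractions.items())
    return {s: x * MOLAR_MASS[s] / m_mix for s, x in mole_fractions.items()}


def make_source_spec(tip_temp: float, calib: CalibrationSet | None = None,
                     composition: dict[str, float] | None = None,
                     position: tuple[float, float, float] = (4.0, 3.0, 0.9),
                     lookup: bool = True) -> SourceSpec:
    """Assemble the incision smoke source for a requested tip temperature.

    Power is resolved via :func:`power_for_temperature` (published lookup
    for the four canonical temperatures by default); flow and formation
    rates follow from the calibration polynomials at that power.
    ``composition`` is in mole fractions; the stored spec carries mass
    fractions.
    """
    calib = calib or CalibrationSet()
    comp = DEFAULT_COMPOSITION if composition is None else composition
    mass_frac = mole_to_mass_fractions(comp)
    power, _ = power_for_temperature(tip_temp, calib, lookup=lookup)
    return SourceSpec(
        volume_flow=eval_waste_gas_flow(power, calib),
        temperature=float(tip_temp),
        species_mass_fractions=mass_frac,
        tar_rate=eval_tar_rate(power, calib),
        particle_rate=eval_particle_rate(power, calib),
        position=tuple(position),
        power=power,
    )


# ---------------------------------------------------------------------------
# CSV power-sweep table I/O (header: power_W, tip_temp_C, waste_gas_m3s,
# tar_gs, particle_gs)

SWEEP_COLUMNS = ["power_W", "tip_temp_C", "waste_gas_m3s", "tar_gs", "particle_gs"]


def records_to_frame(records: list[PowerSweepRecord]):
    import pandas as pd

    return pd.DataFrame({
        "power_W": [r.power for r in records],
        "tip_temp_C": [r.tip_temp for r in records],
        "waste_gas_m3s": [r.waste_gas_flow for r in records],
        "tar_gs": [r.tar_rate for r in records],
        "particle_gs": [r.particle_rate for r in records],
    })


def frame_to_records(df) -> list[PowerSweepRecord]:
    missing = [c for c in SWEEP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"power-sweep table missing columns {missing}")
    return [
        PowerSweepRecord(
            power=row.power_W, tip_temp=row.tip_temp_C,
            waste_gas_flow=row.waste_gas_m3s, tar_rate=row.tar_gs,
            particle_rate=row.particle_gs)
        for row in df.itertuples()
    ]
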