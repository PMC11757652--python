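"""Deterministic physics of flow-through Rn-219 breath measurements.

Exhaled air is pumped from a reservoir through a connecting tube into the
measurement chamber of a flow-through radon monitor (an ionization-chamber
instrument such as the Alphaguard PQ2000).  Two deterministic steps relate
the instrument reading ``R`` (kBq/m^3) to the Rn-219 activity concentration
in the exhaled air (kBq/l):

1. a calibration factor converts the reading to the activity concentration
   in the measurement chamber, ``a = f_cal * R`` (with kBq/m^3 -> kBq/l);
2. an in-tube decay correction ``exp(lambda * t)`` recovers the
   concentration at the tube entrance, where ``t`` is the transit time of
   the gas through the tube and ``lambda = ln2 / T_half`` the Rn-219 decay
   constant.  With a half-life of only ~4 s, even sub-second transit times
   lose a few percent of the activity.

Readings are censored on both sides: above the instrument's range limit the
display shows only ">limit" (a greater-than value), and below the
evaluability limit the signal processing changes regime and no calibrated
conversion exists (a less-than value).  :func:`evaluate_recording` applies
the full chain and returns a :class:`CensoredValue` carrying the censor
status explicitly.

All concentrations in this package are kBq/l; instrument readings are
kBq/m^3; the 1000x conversion happens exactly once, inside
:func:`reading_to_chamber`.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

__all__ = [
    "CensorStatus",
    "CensoredValue",
    "NuclideSpec",
    "InstrumentSpec",
    "SamplingConfig",
    "RN219",
    "PQ2000",
    "P30F",
    "DEFAULT_TUBE_VOLUME_ML",
    "travel_time",
    "decay_correction_factor",
    "reading_to_chamber",
    "chamber_to_exhaled",
    "evaluate_recording",
    "parse_reading",
    "display_round",
]


class CensorStatus(enum.Enum):
    """Interpretation of a measured or derived value."""

    POINT = "point"  # value measured directly
    GREATER_THAN = "greater_than"  # true value exceeds the stated bound
    LESS_THAN = "less_than"  # true value lies below the stated bound

    @classmethod
    def from_token(cls, token: str) -> "CensoredValue":
        return _STATUS_TOKENS[token]


_STATUS_TOKENS = {
    "point": CensorStatus.POINT,
    "": CensorStatus.POINT,
    ">": CensorStatus.GREATER_THAN,
    "greater_than": CensorStatus.GREATER_THAN,
    "<": CensorStatus.LESS_THAN,
    "less_than": CensorStatus.LESS_THAN,
}


@dataclass(frozen=True)
class CensoredValue:
    """A concentration (kBq/l or kBq/(l MBq)) with explicit censor status.

    ``value`` is the measured value for a point datum, or the censoring
    bound for a greater-than / less-than datum.  The status is never encoded
    in the number itself.
    """

    value: float
    status: CensorStatus = CensorStatus.POINT

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"censored value must be positive, got {self.value}")

    @property
    def is_point(self) -> bool:
        return self.status is CensorStatus.POINT

    @classmethod
    def parse(cls, text: str) -> "CensoredValue":
        """Parse a printed value such as ``4.53``, ``> 4.85`` or ``<1.70``."""
        s = text.strip()
        if s.startswith(">"):
            return cls(float(s[1:]), CensorStatus.GREATER_THAN)
        if s.startswith("<"):
            return cls(float(s[1:]), CensorStatus.LESS_THAN)
        return cls(float(s), CensorStatus.POINT)

    def __str__(self) -> str:
        prefix = {
            CensorStatus.POINT: "",
            CensorStatus.GREATER_THAN: "> ",
            CensorStatus.LESS_THAN: "< ",
        }[self.status]
        return f"{prefix}{display_round(self.value, 2)}"

    def scaled(self, factor: float) -> "CensoredValue":
        """Multiply the value by a positive factor, preserving the status."""
        if not factor > 0:
            raise ValueError("scale factor must be positive")
        return CensoredValue(self.value * factor, self.status)


@dataclass(frozen=True)
class NuclideSpec:
    """A radionuclide identified by name and half-life in seconds."""

    name: str
    half_life: float  # seconds

    def __post_init__(self) -> None:
        if not self.half_life > 0:
            raise ValueError("half_life must be positive")

    @property
    def decay_constant(self) -> float:
        """lambda = ln2 / T_half, in 1/s."""
        return math.log(2.0) / self.half_life


#: Rn-219 (actinon), direct progeny of Ra-223.
RN219 = NuclideSpec("Rn-219", half_life=3.98)


@dataclass(frozen=True)
class InstrumentSpec:
    """Calibration and range limits of a flow-through radon monitor.

    Parameters
    ----------
    model:
        Instrument model designation, e.g. ``"PQ2000"``.
    calibration_factor:
        Dimensionless factor converting the instrument reading to the
        Rn-219 activity concentration in the measurement chamber.
    evaluability_limit_reading:
        Reading (kBq/m^3) below which the instrument's signal processing
        leaves the calibrated regime; smaller readings are evaluated only
        as less-than values.
    range_limit_reading:
        Upper limit of the measurement range (kBq/m^3); the instrument
        displays larger concentrations only as ``> limit``.
    evaluable:
        Whether datasets recorded with this model enter the analysis at
        all (the P30F's range was two orders of magnitude too small).
    """

    model: str
    calibration_factor: float = 2.3
    evaluability_limit_reading: float = 600.0  # kBq/m^3
    range_limit_reading: float = 2000.0  # kBq/m^3
    evaluable: bool = True

    def __post_init__(self) -> None:
        if not self.calibration_factor > 0:
            raise ValueError("calibration_factor must be positive")
        if not 0 < self.evaluability_limit_reading < self.range_limit_reading:
            raise ValueError(
                "require 0 < evaluability_limit_reading < range_limit_reading"
            )


#: Alphaguard PQ2000F / PQ2000pro as used for the patient measurements.
PQ2000 = InstrumentSpec("PQ2000")

#: Alphaguard P30F: range limit 30 kBq/m^3, far below exhaled Rn-219 levels;
#: its datasets are excluded from analysis.
P30F = InstrumentSpec(
    "P30F", evaluability_limit_reading=2.0e-3, range_limit_reading=30.0,
    evaluable=False,
)

#: Volume of the tube connecting reservoir and pump, millilitres.
DEFAULT_TUBE_VOLUME_ML = 20.0


@dataclass(frozen=True)
class SamplingConfig:
    """Tube volume (ml) and pump flow rate (l/min) of the sampling line."""

    flow_rate: float  # litres per minute
    tube_volume: float = DEFAULT_TUBE_VOLUME_ML  # millilitres

    def __post_init__(self) -> None:
        if not self.flow_rate > 0:
            raise ValueError("flow_rate must be positive")
        if self.tube_volume < 0:
            raise ValueError("tube_volume must be non-negative")


def travel_time(cfg: SamplingConfig) -> float:
    """Transit time of the gas through the sampling tube, in seconds.

    t = V_tube / Q with V_tube in litres and Q in litres per second.
    A 20 ml tube gives 1.2 s at 1 l/min and 0.3 s at 4 l/min.
    """
    volume_l = cfg.tube_volume / 1000.0
    flow_l_per_s = cfg.flow_rate / 60.0
    return volume_l / flow_l_per_s


def decay_correction_factor(t: float, nuclide: NuclideSpec = RN219) -> float:
    """Multiplicative correction exp(lambda t) for decay during transit.

    Recovers the concentration at the tube entrance from the concentration
    surviving a transit of ``t`` seconds.  Always >= 1 for t >= 0.
    """
    if t < 0:
        raise ValueError(f"transit time must be non-negative, got {t}")
    return math.exp(nuclide.decay_constant * t)


def reading_to_chamber(reading: float, instrument: InstrumentSpec = PQ2000) -> float:
    """Convert an instrument reading (kBq/m^3) to the Rn-219 activity
    concentration in the measurement chamber (kBq/l).

    a = f_cal * R / 1000; e.g. 2000 kBq/m^3 -> 4.6 kBq/l with f_cal = 2.3.
    """
    if reading < 0:
        raise ValueError(f"reading must be non-negative, got {reading}")
    return instrument.calibration_factor * reading / 1000.0


def chamber_to_exhaled(chamber_conc: float, decay_factor: float) -> float:
    """Apply the in-tube decay correction to a chamber concentration."""
    if decay_factor < 1.0:
        raise ValueError(
            f"decay correction factor must be >= 1, got {decay_factor}"
        )
    return chamber_conc * decay_factor


#: Tokens accepted as an explicit above-range flag in raw reading tables.
_ABOVE_RANGE_TOKENS = {">", "above", "above_range", "over", "overrange"}


def parse_reading(text: str) -> tuple[float | None, bool]:
    """Parse a raw reading cell into ``(reading, above_range)``.

    Accepts a plain number, an above-range token (``>``, ``above``) or a
    ``>2000``-style display string.  Raises ``ValueError`` on anything else.
    """
    s = text.strip()
    if s.lower() in _ABOVE_RANGE_TOKENS:
        return None, True
    if s.startswith(">"):
        return float(s[1:]), True
    try:
        return float(s), False
    except ValueError:
        raise ValueError(f"unrecognised reading token: {text!r}") from None


def evaluate_recording(
    reading: float | str | None,
    instrument: InstrumentSpec = PQ2000,
    cfg: SamplingConfig = SamplingConfig(flow_rate=4.0),
    nuclide: NuclideSpec = RN219,
    *,
    above_range: bool = False,
    decay_factor: float | None = None,
) -> CensoredValue:
    """Evaluate a single instrument recording as an exhaled concentration.

    Above-range recordings become greater-than values at the exhaled
    equivalent of the range limit; recordings below the evaluability limit
    become less-than values at the exhaled equivalent of that limit; all
    other readings convert to point values through the calibration factor
    and the in-tube decay correction.

    ``reading`` may be a number (kBq/m^3), a string token such as ``">2000"``
    or ``"above"``, or ``None`` together with ``above_range=True``.
    ``decay_factor`` overrides the factor computed from ``cfg`` and
    ``nuclide`` (used when reproducing tabulated results that carry their
    own printed factor).
    """
    if isinstance(reading, str):
        reading, flag = parse_reading(reading)
        above_range = above_range or flag
    if reading is None and not above_range:
        raise ValueError("no reading and no above-range flag supplied")

    if decay_factor is None:
        decay_factor = decay_correction_factor(travel_time(cfg), nuclide)

    def exhaled(r: float) -> float:
        return chamber_to_exhaled(reading_to_chamber(r, instrument), decay_factor)

    if above_range:
        return CensoredValue(
            exhaled(instrument.range_limit_reading), CensorStatus.GREATER_THAN
        )
    assert reading is not None
    if reading >= instrument.range_limit_reading:
        return CensoredValue(
            exhaled(instrument.range_limit_reading), CensorStatus.GREATER_THAN
        )
    if reading < instrument.evaluability_limit_reading:
        return CensoredValue(
            exhaled(instrument.evaluability_limit_reading), CensorStatus.LESS_THAN
        )
    return CensoredValue(exhaled(reading), CensorStatus.POINT)


def display_round(x: float, ndigits: int) -> float:
    """Round half away from zero, as the tabulated results are printed.

    Python's built-in round() rounds half to even; printed concentrations
    (2 d.p.) and decay factors (3 d.p.) use commercial half-up rounding.
    """
    scaled = x * 10**ndigits
    rounded = math.floor(scaled + 0.5) if x >= 0 else math.ceil(scaled - 0.5)
    return rounded / 10**ndigits
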