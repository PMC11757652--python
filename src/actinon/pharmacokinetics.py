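"""Cross-checks against published Ra-223 blood-clearance kinetics.

Because Rn-219 decays within seconds, its concentration in exhaled breath
tracks the Ra-223 concentration in blood; published blood-clearance curves
therefore let exhaled concentrations measured at one time point be scaled
to another.  The factors themselves are read off published diagrams and are
treated as configuration data with citations, never as constants baked into
the analysis.

Shipped defaults:

* factor ~3 between 20-30 min p.i. and 3-4 h p.i. (Nilsson et al.; Yoshida
  et al.; blood-clearance data);
* factor ~22.5 between 1 min p.i. and 4 h p.i.;
* an alternative band 4.1-5.5 between the two measurement time points
  (Carrasquillo et al.), reported as a discussion point.

The consistency verdict between the measured time-point ratio and these
bands is reported, never enforced.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "ClearanceFactor",
    "ConsistencyBand",
    "BandVerdict",
    "DEFAULT_CLEARANCE_FACTORS",
    "DEFAULT_BANDS",
    "extrapolate",
    "timepoint_ratio",
]


@dataclass(frozen=True)
class ClearanceFactor:
    """Blood-concentration ratio between two times after administration.

    ``factor`` is the concentration at ``to_time`` divided by the
    concentration at ``from_time``; :func:`extrapolate` multiplies by it.
    """

    from_time: str
    to_time: str
    factor: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("clearance factor must be positive")

    def inverse(self) -> "ClearanceFactor":
        return ClearanceFactor(
            self.to_time, self.from_time, 1.0 / self.factor, self.source
        )


@dataclass(frozen=True)
class ConsistencyBand:
    """A literature band for the early/late concentration ratio.

    ``margin`` widens the band by a relative fraction on both sides before
    the inside/outside verdict, acknowledging that the factors are read off
    published diagrams.
    """

    name: str
    low: float
    high: float
    margin: float = 0.0
    source: str = ""

    def contains(self, ratio: float) -> bool:
        return self.low * (1.0 - self.margin) <= ratio <= self.high * (
            1.0 + self.margin
        )


DEFAULT_CLEARANCE_FACTORS = {
    "early_to_late": ClearanceFactor(
        "20-30 min p.i.", "3-4 h p.i.", 1.0 / 3.0,
        source="blood-clearance diagrams (Nilsson; Yoshida)",
    ),
    "late_to_1min": ClearanceFactor(
        "3-4 h p.i.", "1 min p.i.", 22.5,
        source="blood-clearance data, 1 min vs 4 h",
    ),
}

DEFAULT_BANDS = (
    ConsistencyBand(
        "blood_clearance_approx_3", 3.0, 3.0, margin=0.5,
        source="blood-clearance diagrams (Nilsson; Yoshida; clearance data)",
    ),
    ConsistencyBand(
        "carrasquillo_4.1_5.5", 4.1, 5.5, margin=0.0,
        source="pharmacokinetic parameters (Carrasquillo)",
    ),
)


def extrapolate(conc: float, cf: ClearanceFactor) -> float:
    """Scale a concentration from ``cf.from_time`` to ``cf.to_time``.

    Exactly multiplicative and invertible:
    ``extrapolate(extrapolate(c, f), f.inverse()) == c``.
    E.g. 4.4 kBq/l at 3-4 h with factor 22.5 to 1 min gives 99 kBq/l.
    """
    if not conc > 0:
        raise ValueError(f"concentration must be positive, got {conc}")
    return conc * cf.factor


@dataclass(frozen=True)
class BandVerdict:
    band: ConsistencyBand
    ratio: float
    inside: bool

    def __str__(self) -> str:
        rel = "inside" if self.inside else "outside"
        band = (
            f"{self.band.low:g}"
            if self.band.low == self.band.high
            else f"{self.band.low:g}-{self.band.high:g}"
        )
        margin = f" (margin {self.band.margin:.0%})" if self.band.margin else ""
        return f"ratio {self.ratio:.2f} {rel} band {band}{margin} [{self.band.name}]"


def timepoint_ratio(
    gm_early: float,
    gm_late: float,
    bands: tuple[ConsistencyBand, ...] = DEFAULT_BANDS,
) -> tuple[float, list[BandVerdict]]:
    """Early/late ratio of the geometric means, checked against literature.

    Returns the ratio and one verdict per configured band.  The check is
    informative only — disagreement with a band is itself a finding (it may
    indicate that heavy censoring biased the early estimate low).
    """
    if not (gm_early > 0 and gm_late > 0):
        raise ValueError("geometric means must be positive")
    ratio = gm_early / gm_late
    return ratio, [BandVerdict(b, ratio, b.contains(ratio)) for b in bands]
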