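"""Measurement sessions: data model, pairing rules, campaign filtering.

A *session* is one administration of Ra-223 measured at one time point
(20-30 min p.i. or 3-4 h p.i.).  Each session carries up to two instrument
recordings taken 3-5 min apart; :func:`combine_recordings` merges them into
a single final censored result following the rules used for the study data:

* two point values -> point at their arithmetic mean;
* two identical greater-than values -> greater-than at that bound;
* one point + one greater-than -> "greater than the lower value";
* two less-than values -> less-than at the bound;
* a below-evaluability recording paired with a point value is only
  discarded when explicitly flagged as an outlier (a judgement call, never
  an automatic rule by default).

:func:`filter_campaign` removes sessions recorded with a non-evaluable
instrument model (the Alphaguard P30F, whose range limit of 30 kBq/m^3 is
far below exhaled Rn-219 levels) and sessions without recordings, keeping a
structured exclusion log.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .physics import CensoredValue, CensorStatus

__all__ = [
    "Timepoint",
    "Session",
    "FinalResult",
    "ExclusionRecord",
    "UnresolvedCombinationError",
    "combine_recordings",
    "per_unit_activity",
    "filter_campaign",
    "finalize",
    "load_campaign",
    "write_campaign",
    "packaged_campaign_path",
    "load_packaged_campaign",
]


class Timepoint(str, Enum):
    """Measurement time point relative to administration."""

    EARLY = "early"  # 20-30 min p.i.
    LATE = "late"  # 3-4 h p.i.

    @property
    def label(self) -> str:
        return {"early": "20-30 min p.i.", "late": "3-4 h p.i."}[self.value]


class UnresolvedCombinationError(ValueError):
    """A recording pair whose combination needs an explicit judgement.

    A point value paired with a below-evaluability (less-than) recording is
    ambiguous: the less-than recording may be a genuine low value or a
    sampling failure.  The study resolved the one occurrence by judgement
    (outlier flag); without that flag the combination is refused unless the
    ``auto_outlier`` heuristic is enabled.
    """


@dataclass(frozen=True)
class Session:
    """One administration x time point with its recordings."""

    admin_id: str
    patient_id: str
    timepoint: Timepoint
    applied_activity: float | None  # MBq
    flow_rate: float | None  # l/min
    instrument_model: str
    recording_1: CensoredValue | None = None
    recording_2: CensoredValue | None = None
    outlier_flag_2: bool = False
    decay_factor: float | None = None  # printed factor, if tabulated
    printed_final: CensoredValue | None = None  # as printed, for cross-checks

    def __post_init__(self) -> None:
        if self.applied_activity is not None and not self.applied_activity > 0:
            raise ValueError("applied_activity must be positive when present")

    @property
    def has_recordings(self) -> bool:
        return self.recording_1 is not None or self.recording_2 is not None


@dataclass(frozen=True)
class FinalResult:
    """Combined result of a session, absolute and per unit applied activity."""

    session_ref: str
    timepoint: Timepoint
    concentration: CensoredValue  # kBq/l
    per_unit_activity: CensoredValue | None  # kBq/(l MBq)


@dataclass(frozen=True)
class ExclusionRecord:
    admin_id: str
    timepoint: Timepoint | None
    reason: str


def combine_recordings(
    r1: CensoredValue | None,
    r2: CensoredValue | None,
    outlier_flag_2: bool = False,
    *,
    auto_outlier: bool = False,
) -> CensoredValue:
    """Combine the two recordings of a session into one final result.

    ``outlier_flag_2`` marks the second recording as a known sampling
    failure (it is discarded, only meaningful for a less-than recording
    paired with a point value).  With ``auto_outlier`` the same discard is
    applied heuristically, with a warning, whenever a point value is paired
    with a less-than recording.
    """
    if r1 is None and r2 is None:
        raise ValueError("at least one recording must be present")
    if r1 is None:
        return r2  # type: ignore[return-value]
    if r2 is None:
        return r1

    if outlier_flag_2 and r2.status is CensorStatus.LESS_THAN:
        # known sampling failure: discard regardless of the partner's status
        return r1

    s1, s2 = r1.status, r2.status
    if s1 is CensorStatus.POINT and s2 is CensorStatus.POINT:
        return CensoredValue((r1.value + r2.value) / 2.0, CensorStatus.POINT)
    if s1 is CensorStatus.GREATER_THAN and s2 is CensorStatus.GREATER_THAN:
        if r1.value != r2.value:
            warnings.warn(
                "combining greater-than recordings with unequal bounds "
                f"({r1.value} vs {r2.value}); using the smaller (weaker) bound",
                stacklevel=2,
            )
        return CensoredValue(min(r1.value, r2.value), CensorStatus.GREATER_THAN)
    if {s1, s2} == {CensorStatus.POINT, CensorStatus.GREATER_THAN}:
        # "greater than the lower value"
        return CensoredValue(min(r1.value, r2.value), CensorStatus.GREATER_THAN)
    if s1 is CensorStatus.LESS_THAN and s2 is CensorStatus.LESS_THAN:
        if r1.value != r2.value:
            warnings.warn(
                "combining less-than recordings with unequal bounds "
                f"({r1.value} vs {r2.value}); using the larger (weaker) bound",
                stacklevel=2,
            )
        return CensoredValue(max(r1.value, r2.value), CensorStatus.LESS_THAN)
    if {s1, s2} == {CensorStatus.POINT, CensorStatus.LESS_THAN}:
        if auto_outlier:
            point = r1 if r1.is_point else r2
            warnings.warn(
                "discarding below-evaluability recording paired with point "
                f"value {point.value} (auto_outlier heuristic)",
                stacklevel=2,
            )
            return point
        raise UnresolvedCombinationError(
            "point value paired with a less-than recording requires an "
            "explicit outlier flag (or the auto_outlier heuristic)"
        )
    raise UnresolvedCombinationError(
        f"no combination rule for statuses {s1.value} + {s2.value}"
    )


def per_unit_activity(final: CensoredValue, applied_activity: float) -> CensoredValue:
    """Normalize a final result by the applied activity (MBq).

    Censor status is preserved: a bound divided by the activity is a bound
    on the normalized quantity.
    """
    if not applied_activity > 0:
        raise ValueError(
            f"applied activity must be positive, got {applied_activity}"
        )
    return final.scaled(1.0 / applied_activity)


def filter_campaign(
    sessions: Sequence[Session],
    non_evaluable_models: Iterable[str] = ("P30F",),
) -> tuple[list[Session], list[ExclusionRecord]]:
    """Drop sessions from non-evaluable instruments or without recordings.

    Returns the retained sessions and a log of exclusions.  An
    administration recorded with a non-evaluable model is logged once even
    if it appears at both time points.
    """
    bad_models = {m.upper() for m in non_evaluable_models}
    retained: list[Session] = []
    log: list[ExclusionRecord] = []
    logged_admins: set[str] = set()
    for s in sessions:
        if s.instrument_model.upper() in bad_models:
            if s.admin_id not in logged_admins:
                log.append(
                    ExclusionRecord(
                        s.admin_id,
                        None,
                        f"instrument model {s.instrument_model} not evaluable",
                    )
                )
                logged_admins.add(s.admin_id)
            continue
        if not s.has_recordings:
            log.append(ExclusionRecord(s.admin_id, s.timepoint, "no recordings"))
            continue
        retained.append(s)
    return retained, log


def finalize(
    session: Session, *, auto_outlier: bool = False
) -> FinalResult:
    """Combine a session's recordings and normalize by applied activity."""
    conc = combine_recordings(
        session.recording_1,
        session.recording_2,
        session.outlier_flag_2,
        auto_outlier=auto_outlier,
    )
    per_unit = (
        per_unit_activity(conc, session.applied_activity)
        if session.applied_activity is not None
        else None
    )
    return FinalResult(session.admin_id, session.timepoint, conc, per_unit)


# ---------------------------------------------------------------------------
# campaign-table I/O

_COLUMNS = [
    "admin_id",
    "patient_id",
    "activity_MBq",
    "flow_l_min",
    "instrument",
    "decay_factor",
    "timepoint",
    "value_1",
    "status_1",
    "value_2",
    "status_2",
    "outlier_2",
    "final_value",
    "final_status",
]


def _cell_to_value(value, status) -> CensoredValue | None:
    if pd.isna(value):
        return None
    status_token = "" if pd.isna(status) else str(status).strip()
    return CensoredValue(float(value), CensorStatus.from_token(status_token))


def load_campaign(path: str | Path) -> list[Session]:
    """Read a concentration-level campaign table (CSV, ``#`` comments).

    One row per administration x time point; recording values are exhaled
    concentrations in kBq/l with separate censor-status columns.
    """
    df = pd.read_csv(path, comment="#", dtype={"admin_id": str, "patient_id": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"campaign table {path} lacks columns: {missing}")
    sessions: list[Session] = []
    for i, row in df.iterrows():
        try:
            sessions.append(
                Session(
                    admin_id=row["admin_id"],
                    patient_id=row["patient_id"],
                    timepoint=Timepoint(row["timepoint"]),
                    applied_activity=None
                    if pd.isna(row["activity_MBq"])
                    else float(row["activity_MBq"]),
                    flow_rate=None
                    if pd.isna(row["flow_l_min"])
                    else float(row["flow_l_min"]),
                    instrument_model=str(row["instrument"]),
                    recording_1=_cell_to_value(row["value_1"], row["status_1"]),
                    recording_2=_cell_to_value(row["value_2"], row["status_2"]),
                    outlier_flag_2=bool(row["outlier_2"])
                    and not pd.isna(row["outlier_2"]),
                    decay_factor=None
                    if pd.isna(row["decay_factor"])
                    else float(row["decay_factor"]),
                    printed_final=_cell_to_value(
                        row["final_value"], row["final_status"]
                    ),
                )
            )
        except (ValueError, KeyError) as exc:
            raise ValueError(
                f"campaign table {path}, row {i + 1} "
                f"(admin {row.get('admin_id', '?')}): {exc}"
            ) from exc
    return sessions


def write_campaign(sessions: Sequence[Session], path: str | Path) -> None:
    """Write sessions as a concentration-level campaign table (CSV)."""
    rows = []
    for s in sessions:
        rows.append(
            {
                "admin_id": s.admin_id,
                "patient_id": s.patient_id,
                "activity_MBq": s.applied_activity,
                "flow_l_min": s.flow_rate,
                "instrument": s.instrument_model,
                "decay_factor": s.decay_factor,
                "timepoint": s.timepoint.value,
                "value_1": None if s.recording_1 is None else s.recording_1.value,
                "status_1": None
                if s.recording_1 is None
                else s.recording_1.status.value,
                "value_2": None if s.recording_2 is None else s.recording_2.value,
                "status_2": None
                if s.recording_2 is None
                else s.recording_2.status.value,
                "outlier_2": s.outlier_flag_2,
                "final_value": None
                if s.printed_final is None
                else s.printed_final.value,
                "final_status": None
                if s.printed_final is None
                else s.printed_final.status.value,
            }
        )
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def packaged_campaign_path() -> Path:
    """Path to the packaged measurement-campaign fixture."""
    return Path(resources.files("actinon") / "data" / "table1_campaign.csv")


def load_packaged_campaign() -> list[Session]:
    """Load the packaged study campaign (21 administrations, 14 patients)."""
    return load_campaign(packaged_campaign_path())
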