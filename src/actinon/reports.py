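"""End-to-end analysis reports for a measurement campaign.

:func:`run_analysis` executes the full pipeline — filter -> combine ->
per-unit normalization -> rank -> q-q fit -> imputation -> summary
statistics -> pharmacokinetic consistency checks — per time point, and
returns an :class:`AnalysisReport` whose every number is traceable to a
pipeline operation.  :func:`reproduce_study` runs the packaged campaign
and lays the results next to the published reference values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import censored_lognormal as cln
from . import pharmacokinetics as pk
from .config import AnalysisConfig
from .sessions import (
    ExclusionRecord,
    FinalResult,
    Session,
    Timepoint,
    filter_campaign,
    finalize,
    load_campaign,
    load_packaged_campaign,
)

__all__ = [
    "TimepointReport",
    "AnalysisReport",
    "run_analysis",
    "report_key_values",
    "render_text",
    "reproduce_study",
]


@dataclass(frozen=True)
class TimepointReport:
    """All statistics derived for one measurement time point."""

    timepoint: Timepoint
    finals: tuple[FinalResult, ...]
    naive_median: float
    naive_min: float
    naive_max: float
    n_points: int
    ranked_concentration: cln.RankedDataset
    fit_concentration: cln.QQFit
    stats_concentration: cln.SummaryStats
    ranked_per_unit: cln.RankedDataset | None
    fit_per_unit: cln.QQFit | None
    stats_per_unit: cln.SummaryStats | None


@dataclass(frozen=True)
class AnalysisReport:
    timepoints: dict[Timepoint, TimepointReport]
    exclusions: tuple[ExclusionRecord, ...]
    ratio_early_late: float | None
    band_verdicts: tuple[pk.BandVerdict, ...]
    extrapolations: dict[str, float]  # clearance-factor name -> kBq/l
    config_echo: dict
    errors: tuple[str, ...] = ()
    warnings_log: tuple[str, ...] = ()


def _analyze_timepoint(
    tp: Timepoint, finals: list[FinalResult], config: AnalysisConfig
) -> TimepointReport:
    conc = [f.concentration for f in finals]
    median, vmin, vmax, n_points = cln.naive_stats(conc)
    ranked = cln.rank_dataset(
        conc, config.convention, strict_less_than=config.strict_less_than
    )
    fit = cln.qq_fit(ranked)
    stats = cln.summarize(ranked, fit, method=config.percentile_method)

    per_unit = [f.per_unit_activity for f in finals if f.per_unit_activity]
    ranked_pu = fit_pu = stats_pu = None
    if len(per_unit) >= 3:
        ranked_pu = cln.rank_dataset(
            per_unit, config.convention, strict_less_than=config.strict_less_than
        )
        fit_pu = cln.qq_fit(ranked_pu)
        stats_pu = cln.summarize(ranked_pu, fit_pu, method=config.percentile_method)
    return TimepointReport(
        timepoint=tp,
        finals=tuple(finals),
        naive_median=median,
        naive_min=vmin,
        naive_max=vmax,
        n_points=n_points,
        ranked_concentration=ranked,
        fit_concentration=fit,
        stats_concentration=stats,
        ranked_per_unit=ranked_pu,
        fit_per_unit=fit_pu,
        stats_per_unit=stats_pu,
    )


def run_analysis(
    campaign: str | Path | list[Session],
    config: AnalysisConfig | None = None,
) -> AnalysisReport:
    """Run the full pipeline on a campaign table or list of sessions."""
    config = config or AnalysisConfig()
    sessions = (
        campaign
        if isinstance(campaign, list)
        else load_campaign(campaign)
    )
    retained, exclusions = filter_campaign(sessions, config.non_evaluable_models)

    captured: list[str] = []
    errors: list[str] = []
    timepoints: dict[Timepoint, TimepointReport] = {}
    with warnings.catch_warnings(record=True) as wlog:
        warnings.simplefilter("always")
        by_tp: dict[Timepoint, list[FinalResult]] = {}
        for s in retained:
            by_tp.setdefault(s.timepoint, []).append(
                finalize(s, auto_outlier=config.auto_outlier)
            )
        for tp in (Timepoint.EARLY, Timepoint.LATE):
            finals = by_tp.get(tp, [])
            if not finals:
                errors.append(f"{tp.value}: no analyzable sessions")
                continue
            try:
                timepoints[tp] = _analyze_timepoint(tp, finals, config)
            except cln.InsufficientDataError as exc:
                errors.append(f"{tp.value}: {exc}")
        captured = [str(w.message) for w in wlog]

    ratio = None
    verdicts: tuple[pk.BandVerdict, ...] = ()
    early, late = timepoints.get(Timepoint.EARLY), timepoints.get(Timepoint.LATE)
    if early and late and early.stats_per_unit and late.stats_per_unit:
        ratio, verdict_list = pk.timepoint_ratio(
            early.stats_per_unit.geometric_mean,
            late.stats_per_unit.geometric_mean,
            config.consistency_bands,
        )
        verdicts = tuple(verdict_list)

    extrapolations: dict[str, float] = {}
    if late is not None:
        for name, cf in config.clearance_factors.items():
            if cf.from_time.startswith("3-4 h"):
                extrapolations[name] = pk.extrapolate(
                    late.stats_concentration.geometric_mean, cf
                )

    return AnalysisReport(
        timepoints=timepoints,
        exclusions=tuple(exclusions),
        ratio_early_late=ratio,
        band_verdicts=verdicts,
        extrapolations=extrapolations,
        config_echo=config.echo(),
        errors=tuple(errors),
        warnings_log=tuple(captured),
    )


def _fmt(x) -> str:
    if isinstance(x, float):
        return f"{x:.10g}"
    return str(x)


def report_key_values(report: AnalysisReport) -> dict[str, str]:
    """Flatten a report into ordered, machine-readable key-value pairs.

    Purely a function of the report: identical inputs and configuration
    yield byte-identical output.
    """
    kv: dict[str, str] = {}
    for key, val in sorted(report.config_echo.items()):
        kv[f"config.{key}"] = _fmt(val)
    kv["n_excluded"] = str(len(report.exclusions))
    for i, ex in enumerate(report.exclusions, 1):
        tp = ex.timepoint.value if ex.timepoint else "all"
        kv[f"exclusion.{i}"] = f"{ex.admin_id}/{tp}: {ex.reason}"
    for tp, rep in sorted(report.timepoints.items(), key=lambda kv_: kv_[0].value):
        p = tp.value
        s = rep.stats_concentration
        kv[f"{p}.n_total"] = str(s.n_total)
        kv[f"{p}.n_real"] = str(s.n_real)
        kv[f"{p}.n_censored"] = str(s.n_censored)
        kv[f"{p}.naive.median_kBq_l"] = _fmt(rep.naive_median)
        kv[f"{p}.naive.min_kBq_l"] = _fmt(rep.naive_min)
        kv[f"{p}.naive.max_kBq_l"] = _fmt(rep.naive_max)
        kv[f"{p}.naive.n_points"] = str(rep.n_points)
        kv[f"{p}.concentration.geometric_mean_kBq_l"] = _fmt(s.geometric_mean)
        kv[f"{p}.concentration.geometric_sd"] = _fmt(s.geometric_sd)
        kv[f"{p}.concentration.percentile_95_kBq_l"] = _fmt(s.percentile_95)
        kv[f"{p}.concentration.r_squared"] = _fmt(rep.fit_concentration.r_squared)
        if rep.stats_per_unit:
            su = rep.stats_per_unit
            kv[f"{p}.per_unit.geometric_mean_kBq_l_MBq"] = _fmt(su.geometric_mean)
            kv[f"{p}.per_unit.geometric_sd"] = _fmt(su.geometric_sd)
            kv[f"{p}.per_unit.percentile_95_kBq_l_MBq"] = _fmt(su.percentile_95)
            kv[f"{p}.per_unit.r_squared"] = _fmt(rep.fit_per_unit.r_squared)
    if report.ratio_early_late is not None:
        kv["pk.ratio_early_late"] = _fmt(report.ratio_early_late)
        for v in report.band_verdicts:
            kv[f"pk.band.{v.band.name}"] = "inside" if v.inside else "outside"
    for name, value in sorted(report.extrapolations.items()):
        kv[f"pk.extrapolated.{name}_kBq_l"] = _fmt(value)
    for i, err in enumerate(report.errors, 1):
        kv[f"error.{i}"] = err
    return kv


def render_text(report: AnalysisReport) -> str:
    """Human-readable plain-text report."""
    lines: list[str] = ["Rn-219 exhalation analysis", "=" * 26, ""]
    if report.errors:
        lines += [f"ERROR: {e}" for e in report.errors] + [""]
    if report.exclusions:
        lines.append(f"Excluded ({len(report.exclusions)}):")
        for ex in report.exclusions:
            lines.append(f"  - administration {ex.admin_id}: {ex.reason}")
        lines.append("")
    for tp, rep in sorted(report.timepoints.items(), key=lambda kv_: kv_[0].value):
        s = rep.stats_concentration
        lines.append(f"Time point {tp.label}")
        lines.append(
            f"  datasets: {s.n_total} (measured {s.n_real}, "
            f"right-censored {s.n_censored})"
        )
        lines.append(
            f"  uncensored points: median {rep.naive_median:.2f} kBq/l, "
            f"range {rep.naive_min:.2f}-{rep.naive_max:.2f} kBq/l "
            f"(n={rep.n_points})"
        )
        lines.append(
            f"  lognormal fit: GM {s.geometric_mean:.2f} kBq/l, "
            f"GSD {s.geometric_sd:.2f}, P95 {s.percentile_95:.2f} kBq/l, "
            f"R^2 {rep.fit_concentration.r_squared:.2f}"
        )
        if rep.stats_per_unit:
            su = rep.stats_per_unit
            lines.append(
                f"  per unit activity: GM {su.geometric_mean:.2f} kBq/(l MBq), "
                f"GSD {su.geometric_sd:.2f}, "
                f"R^2 {rep.fit_per_unit.r_squared:.2f}"
            )
        lines.append("")
    if report.ratio_early_late is not None:
        lines.append(
            f"Early/late per-unit GM ratio: {report.ratio_early_late:.2f}"
        )
        for v in report.band_verdicts:
            lines.append(f"  {v}")
        lines.append("")
    for name, value in sorted(report.extrapolations.items()):
        lines.append(f"Extrapolated concentration ({name}): {value:.0f} kBq/l")
    if report.warnings_log:
        lines.append("")
        lines.append("Warnings:")
        lines += [f"  - {w}" for w in report.warnings_log]
    return "\n".join(lines) + "\n"


#: Published reference values for the packaged campaign (the comparison
#: baseline of :func:`reproduce_study`; never fed into any computation).
STUDY_REFERENCE = {
    "early.n_total": 16,
    "early.n_censored": 12,
    "late.n_total": 17,
    "late.n_censored": 6,
    "late.n_real": 11,
    "early.naive.median_kBq_l": 4.71,
    "early.naive.min_kBq_l": 4.51,
    "early.naive.max_kBq_l": 5.37,
    "late.naive.median_kBq_l": 3.58,
    "late.naive.min_kBq_l": 2.04,
    "late.naive.max_kBq_l": 4.82,
    "early.concentration.geometric_mean_kBq_l": 5.94,
    "early.concentration.geometric_sd": 1.18,
    "early.concentration.r_squared": 0.80,
    "early.per_unit.geometric_mean_kBq_l_MBq": 2.14,
    "early.per_unit.geometric_sd": 1.60,
    "early.per_unit.r_squared": 0.81,
    "late.concentration.geometric_mean_kBq_l": 4.40,
    "late.concentration.geometric_sd": 1.67,
    "late.concentration.r_squared": 0.98,
    "late.per_unit.geometric_mean_kBq_l_MBq": 1.05,
    "late.per_unit.geometric_sd": 1.78,
    "late.per_unit.r_squared": 0.95,
    "pk.ratio_early_late": 2.04,
    "pk.extrapolated.late_to_1min_kBq_l": 99.0,
}


def reproduce_study(config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Run the packaged campaign and compare with the published values.

    Returns a table with the implementation's value, the published value
    and the relative deviation for every quantity in
    :data:`STUDY_REFERENCE`.
    """
    report = run_analysis(load_packaged_campaign(), config)
    kv = report_key_values(report)
    rows = []
    for key, published in STUDY_REFERENCE.items():
        computed = float(kv[key]) if key in kv else float("nan")
        rows.append(
            {
                "quantity": key,
                "computed": computed,
                "published": float(published),
                "relative_deviation": (computed - published) / published,
            }
        )
    return pd.DataFrame(rows)
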