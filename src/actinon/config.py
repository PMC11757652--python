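"""Analysis configuration: instrument constants, conventions, PK factors.

All constants that the analysis depends on — calibration factor, range
limits, tube volume, Rn-219 half-life, plotting-position convention,
percentile method, blood-clearance factors — live here and can be
overridden from a YAML file.  The defaults reproduce the study setup.

YAML schema (all keys optional)::

    convention: hazen | weibull | blom
    percentile_method: distributional | empirical
    strict_less_than: false        # drop less-than entries from the fit
    auto_outlier: false            # heuristic discard of failure readings
    half_life_s: 3.98              # Rn-219 half-life
    tube_volume_ml: 20.0
    calibration_factor: 2.3
    evaluability_limit_kBq_m3: 600.0
    range_limit_kBq_m3: 2000.0
    non_evaluable_models: [P30F]
    clearance_factors:
      late_to_1min: {from: "3-4 h p.i.", to: "1 min p.i.", factor: 22.5,
                     source: "..."}
    consistency_bands:
      - {name: approx_3, low: 3.0, high: 3.0, margin: 0.5, source: "..."}
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from . import pharmacokinetics as pk
from .physics import DEFAULT_TUBE_VOLUME_ML, InstrumentSpec, NuclideSpec

__all__ = ["AnalysisConfig", "load_config"]


@dataclass(frozen=True)
class AnalysisConfig:
    convention: str = "hazen"
    percentile_method: str = "distributional"
    strict_less_than: bool = False
    auto_outlier: bool = False
    half_life_s: float = 3.98
    tube_volume_ml: float = DEFAULT_TUBE_VOLUME_ML
    calibration_factor: float = 2.3
    evaluability_limit_kBq_m3: float = 600.0
    range_limit_kBq_m3: float = 2000.0
    non_evaluable_models: tuple[str, ...] = ("P30F",)
    clearance_factors: dict = field(
        default_factory=lambda: dict(pk.DEFAULT_CLEARANCE_FACTORS)
    )
    consistency_bands: tuple = pk.DEFAULT_BANDS

    @property
    def nuclide(self) -> NuclideSpec:
        return NuclideSpec("Rn-219", self.half_life_s)

    @property
    def instrument(self) -> InstrumentSpec:
        return InstrumentSpec(
            "PQ2000",
            calibration_factor=self.calibration_factor,
            evaluability_limit_reading=self.evaluability_limit_kBq_m3,
            range_limit_reading=self.range_limit_kBq_m3,
        )

    def echo(self) -> dict:
        """Flat key-value echo of every choice that affects results."""
        return {
            "convention": self.convention,
            "percentile_method": self.percentile_method,
            "strict_less_than": self.strict_less_than,
            "auto_outlier": self.auto_outlier,
            "half_life_s": self.half_life_s,
            "tube_volume_ml": self.tube_volume_ml,
            "calibration_factor": self.calibration_factor,
            "evaluability_limit_kBq_m3": self.evaluability_limit_kBq_m3,
            "range_limit_kBq_m3": self.range_limit_kBq_m3,
            "non_evaluable_models": ",".join(self.non_evaluable_models),
        }


def load_config(path: str | Path | None = None, **overrides) -> AnalysisConfig:
    """Build a configuration from defaults, a YAML file, then overrides."""
    cfg = AnalysisConfig()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        cfg = replace(cfg, **_parse_yaml(raw))
    if overrides:
        cfg = replace(cfg, **overrides)
    return cfg


def _parse_yaml(raw: dict) -> dict:
    simple = {
        "convention",
        "percentile_method",
        "strict_less_than",
        "auto_outlier",
        "half_life_s",
        "tube_volume_ml",
        "calibration_factor",
        "evaluability_limit_kBq_m3",
        "range_limit_kBq_m3",
    }
    out: dict = {}
    unknown = set(raw) - simple - {
        "non_evaluable_models", "clearance_factors", "consistency_bands",
    }
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    for key in simple & set(raw):
        out[key] = raw[key]
    if "non_evaluable_models" in raw:
        out["non_evaluable_models"] = tuple(raw["non_evaluable_models"])
    if "clearance_factors" in raw:
        out["clearance_factors"] = {
            name: pk.ClearanceFactor(
                d.get("from", ""), d.get("to", ""), d["factor"],
                d.get("source", ""),
            )
            for name, d in raw["clearance_factors"].items()
        }
    if "consistency_bands" in raw:
        out["consistency_bands"] = tuple(
            pk.ConsistencyBand(
                d["name"], d["low"], d["high"], d.get("margin", 0.0),
                d.get("source", ""),
            )
            for d in raw["consistency_bands"]
        )
    return out
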