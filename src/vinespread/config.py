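"""Pipeline configuration: defaults, YAML loading, strict key validation."""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import yaml

from .economics import EconomicBase, default_economic_base
from .kernel import CalibrationConstraint, DispersalKernel, calibrate_kernel
from .scenarios import ScenarioBand, default_bands
from .sensitivity import SensitivityCase
from .synthetic import SyntheticConfig

__all__ = ["PipelineConfig", "load_config"]

_KNOWN = {
    "seed": None,
    "kernel": {"constraints"},
    "grid": {"n_rows", "n_cols", "cell_size_m", "origin_x", "origin_y"},
    "simulation": {"years", "iterations", "p_floor"},
    "scenarios": {
        "band_a",
        "band_b",
        "scenario_a_includes_b",
        "scenario_c_fraction",
        "report_years",
    },
    "economics": {
        "use_default_base",
        "base_area_acres",
        "direct",
        "multipliers",
        "dollar_year",
    },
    "sensitivity": {"fractions", "report_years"},
    "synthetic": {"mask_fraction", "n_points", "n_clusters", "cluster_sd_m"},
}


@dataclass
class PipelineConfig:
    """Effective settings for a full pipeline run.

    Every default is overridable from a YAML config with sections
    kernel / grid / simulation / scenarios / economics / sensitivity /
    synthetic plus a top-level master ``seed``.  Unknown keys are
    rejected so typos cannot silently fall back to defaults.
    """

    seed: int = 0
    kernel_constraints: tuple[CalibrationConstraint, CalibrationConstraint] = (
        CalibrationConstraint(30.0, 0.90),
        CalibrationConstraint(1610.0, 0.0005),
    )
    n_rows: int = 120
    n_cols: int = 120
    cell_size_m: float = 500.0
    origin_x: float = 0.0
    origin_y: float = 0.0
    years: int = 5
    iterations: int = 6000
    p_floor: float = 1e-6
    band_a: tuple[float, float] = (0.01, 0.25)
    band_b: tuple[float, float] = (0.25, 1.0)
    scenario_a_includes_b: bool = False
    scenario_c_fraction: float = 0.1
    report_years: tuple[int, ...] = (1, 3, 5)
    economic_base: EconomicBase = field(default_factory=default_economic_base)
    sensitivity_fractions: tuple[Fraction, ...] = (
        Fraction(1, 2),
        Fraction(2, 3),
        Fraction(3, 4),
    )
    sensitivity_report_years: tuple[int, ...] = (1, 5)
    mask_fraction: float = 0.4
    n_points: int = 76
    n_clusters: int = 8
    cluster_sd_m: float = 1000.0

    def calibrated_kernel(self) -> DispersalKernel:
        return calibrate_kernel(*self.kernel_constraints)

    def bands(self) -> tuple[ScenarioBand, ScenarioBand, ScenarioBand]:
        a_lo, a_hi = self.band_a
        b_lo, b_hi = self.band_b
        if self.scenario_a_includes_b:
            a_hi = b_hi
        return (
            ScenarioBand("A", a_lo, a_hi, include_max=self.scenario_a_includes_b),
            ScenarioBand("B", b_lo, b_hi, include_max=True),
            ScenarioBand(
                "C", b_lo, b_hi, include_max=True,
                area_multiplier=self.scenario_c_fraction,
            ),
        )

    def sensitivity_cases(self) -> tuple[SensitivityCase, ...]:
        return tuple(
            SensitivityCase(f"{_pct(f)} area of scenario A", f)
            for f in self.sensitivity_fractions
        )

    def synthetic_config(self) -> SyntheticConfig:
        return SyntheticConfig(
            seed=self.seed,
            n_rows=self.n_rows,
            n_cols=self.n_cols,
            cell_size_m=self.cell_size_m,
            mask_fraction=self.mask_fraction,
            n_points=self.n_points,
            n_clusters=self.n_clusters,
            cluster_sd_m=self.cluster_sd_m,
        )

    def to_dict(self) -> dict:
        """Effective configuration as a plain dict (for the run log)."""
        return {
            "seed": self.seed,
            "kernel": {
                "constraints": [
                    [c.distance_m, c.probability] for c in self.kernel_constraints
                ]
            },
            "grid": {
                "n_rows": self.n_rows,
                "n_cols": self.n_cols,
                "cell_size_m": self.cell_size_m,
                "origin_x": self.origin_x,
                "origin_y": self.origin_y,
            },
            "simulation": {
                "years": self.years,
                "iterations": self.iterations,
                "p_floor": self.p_floor,
            },
            "scenarios": {
                "band_a": list(self.band_a),
                "band_b": list(self.band_b),
                "scenario_a_includes_b": self.scenario_a_includes_b,
                "scenario_c_fraction": self.scenario_c_fraction,
                "report_years": list(self.report_years),
            },
            "economics": {
                "base_area_acres": self.economic_base.base_area_acres,
                "direct": dict(self.economic_base.direct_rates),
                "multipliers": dict(self.economic_base.multipliers),
                "dollar_year": self.economic_base.dollar_year,
            },
            "sensitivity": {
                "fractions": [str(f) for f in self.sensitivity_fractions],
                "report_years": list(self.sensitivity_report_years),
            },
            "synthetic": {
                "mask_fraction": self.mask_fraction,
                "n_points": self.n_points,
                "n_clusters": self.n_clusters,
                "cluster_sd_m": self.cluster_sd_m,
            },
        }


def _pct(f: Fraction) -> str:
    # floor, so 2/3 renders as the conventional "66%"
    return f"{int(f * 100)}%"


def _check_keys(section: str, given: dict, allowed: set[str]) -> None:
    unknown = set(given) - allowed
    if unknown:
        raise ValueError(
            f"unknown key(s) in config section {section!r}: {sorted(unknown)}"
        )


def _parse_fraction(v) -> Fraction:
    return Fraction(v) if isinstance(v, str) else Fraction(v).limit_denominator(1000)


def config_from_dict(raw: dict) -> PipelineConfig:
    """Build a PipelineConfig from a nested dict, rejecting unknown keys."""
    _check_keys("<top level>", raw, set(_KNOWN))
    cfg = PipelineConfig()
    if "seed" in raw:
        cfg.seed = int(raw["seed"])
    if "kernel" in raw:
        sec = raw["kernel"]
        _check_keys("kernel", sec, _KNOWN["kernel"])
        if "constraints" in sec:
            pairs = sec["constraints"]
            if len(pairs) != 2:
                raise ValueError("kernel.constraints must hold exactly two pairs")
            cfg.kernel_constraints = tuple(
                CalibrationConstraint(float(d), float(p)) for d, p in pairs
            )
    if "grid" in raw:
        sec = raw["grid"]
        _check_keys("grid", sec, _KNOWN["grid"])
        for k in sec:
            setattr(cfg, k, type(getattr(cfg, k))(sec[k]))
    if "simulation" in raw:
        sec = raw["simulation"]
        _check_keys("simulation", sec, _KNOWN["simulation"])
        for k in sec:
            setattr(cfg, k, type(getattr(cfg, k))(sec[k]))
    if "scenarios" in raw:
        sec = raw["scenarios"]
        _check_keys("scenarios", sec, _KNOWN["scenarios"])
        if "band_a" in sec:
            cfg.band_a = tuple(float(v) for v in sec["band_a"])
        if "band_b" in sec:
            cfg.band_b = tuple(float(v) for v in sec["band_b"])
        if "scenario_a_includes_b" in sec:
            cfg.scenario_a_includes_b = bool(sec["scenario_a_includes_b"])
        if "scenario_c_fraction" in sec:
            cfg.scenario_c_fraction = float(sec["scenario_c_fraction"])
        if "report_years" in sec:
            cfg.report_years = tuple(int(y) for y in sec["report_years"])
    if "economics" in raw:
        sec = raw["economics"]
        _check_keys("economics", sec, _KNOWN["economics"])
        if not sec.get("use_default_base", False) and (
            {"base_area_acres", "direct", "multipliers"} <= sec.keys()
        ):
            cfg.economic_base = EconomicBase(
                base_area_acres=float(sec["base_area_acres"]),
                direct_rates={k: float(v) for k, v in sec["direct"].items()},
                multipliers={k: float(v) for k, v in sec["multipliers"].items()},
                dollar_year=str(sec.get("dollar_year", "2019 USD")),
            )
    if "sensitivity" in raw:
        sec = raw["sensitivity"]
        _check_keys("sensitivity", sec, _KNOWN["sensitivity"])
        if "fractions" in sec:
            cfg.sensitivity_fractions = tuple(
                _parse_fraction(v) for v in sec["fractions"]
            )
        if "report_years" in sec:
            cfg.sensitivity_report_years = tuple(int(y) for y in sec["report_years"])
    if "synthetic" in raw:
        sec = raw["synthetic"]
        _check_keys("synthetic", sec, _KNOWN["synthetic"])
        for k in sec:
            setattr(cfg, k, type(getattr(cfg, k))(sec[k]))
    return cfg


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a YAML config file; ``None`` gives all defaults."""
    if path is None:
        return PipelineConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return config_from_dict(raw)
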