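"""Run configuration, metric scans and result serialization.

A run is described by a flat TOML file with ``[geometry]``, ``[sample]``,
``[material]``, ``[beam]`` and ``[scan]`` tables plus a few top-level
keys.  Missing keys fall back to the packaged beamline defaults (the
IMBL breast-imaging configuration) and are logged.  Scan output is
deterministic: CSV with fixed ``%.10g`` formatting plus a JSON report of
the closed-form and numeric optima.
"""

from __future__ import annotations

import copy
import json
import logging
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np

from . import fixtures, metrics, optimize
from .forward_model import Sample, tie_hom_profile
from .geometry import Geometry, m_res, sigma_sys
from .materials import Material, MaterialModel, MaterialTable

__all__ = ["ConfigError", "RunConfig", "run_scan", "report_summary", "SummaryRow"]

log = logging.getLogger("pbiopt")

CRITERIA = ("resolution", "contrast", "cnr", "q2d", "q3d")

_DEFAULTS: dict[str, Any] = {
    "seed": 0,
    "criteria": list(CRITERIA),
    "geometry": {"R": 140.0, "M": 1.094, "sigma_src": 400.0, "sigma_det": 37.5,
                 "sigma_obj": 0.0},
    "sample": {"T0": 8.60, "T": 0.50, "R_CT": 4.30},
    "material": {"fixture": "imbl_table"},
    "beam": {"I_in": 1.0, "eta": 1.0, "energy_keV": 32.0},
    "scan": {"axis": "M", "start": 1.001, "stop": 1.3, "num": 512},
}


class ConfigError(ValueError):
    """Raised when a run configuration is invalid; names the bad key."""


def _merge_defaults(raw: dict, defaults: dict, prefix: str = "") -> dict:
    merged = {}
    for key, default in defaults.items():
        if key not in raw:
            log.info("config: %s%s missing, using default %r", prefix, key, default)
            merged[key] = copy.deepcopy(default)
        elif isinstance(default, dict):
            if not isinstance(raw[key], dict):
                raise ConfigError(f"config key {prefix}{key} must be a table")
            merged[key] = _merge_defaults(raw[key], default, prefix=f"{prefix}{key}.")
        else:
            merged[key] = raw[key]
    for key in raw:
        if key not in defaults:
            raise ConfigError(f"unknown config key {prefix}{key}")
    return merged


def _build_material(block: dict) -> Material:
    if "fixture" in block:
        name = block["fixture"]
        if name == "imbl_table":
            return fixtures.imbl_material_table()
        if name == "imbl_model":
            return fixtures.imbl_material_model()
        raise ConfigError(f"unknown material.fixture {name!r}")
    if "csv" in block:
        kwargs = {k: block[k] for k in ("k_ref", "k_ref_energy", "p_k") if k in block}
        return MaterialTable.from_csv(block["csv"], **kwargs)
    try:
        return MaterialModel(**block)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid material block: {exc}") from exc


@dataclass
class RunConfig:
    """Validated run configuration with object views of each block."""

    data: dict[str, Any]

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        merged = _merge_defaults(raw, _DEFAULTS)
        cfg = cls(merged)
        cfg.validate()
        return cfg

    @classmethod
    def from_toml(cls, path: str | Path) -> "RunConfig":
        with open(path, "rb") as fh:
            try:
                raw = tomllib.load(fh)
            except tomllib.TOMLDecodeError as exc:
                raise ConfigError(f"cannot parse {path}: {exc}") from exc
        return cls.from_dict(raw)

    def validate(self) -> None:
        try:
            self.geometry
            self.sample
            self.material
        except (ValueError, TypeError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(str(exc)) from exc
        for crit in self.data["criteria"]:
            if crit not in CRITERIA:
                raise ConfigError(f"unknown criterion {crit!r} in criteria")
        scan = self.data["scan"]
        if scan["axis"] not in ("M", "E"):
            raise ConfigError("scan.axis must be 'M' or 'E'")
        if not (scan["stop"] > scan["start"]):
            raise ConfigError("scan range is empty (need scan.stop > scan.start)")
        if int(scan["num"]) < 2:
            raise ConfigError("scan.num must be >= 2")

    @property
    def geometry(self) -> Geometry:
        return Geometry(**self.data["geometry"])

    @property
    def sample(self) -> Sample:
        g = self.data["sample"]
        return Sample(T0=g["T0"], T=g["T"])

    @property
    def r_ct(self) -> float:
        return float(self.data["sample"]["R_CT"])

    @property
    def material(self) -> Material:
        return _build_material(self.data["material"])

    @property
    def beam(self) -> dict[str, float]:
        return self.data["beam"]

    @property
    def seed(self) -> int:
        return int(self.data["seed"])

    def to_toml(self) -> str:
        """Serialize back to TOML (flat tables of scalars/lists only)."""
        return _emit_toml(self.data)


def _toml_scalar(value: Any) -> str:
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (int, float)):
        return repr(value)
    if isinstance(value, str):
        return json.dumps(value)
    if isinstance(value, list):
        return "[" + ", ".join(_toml_scalar(v) for v in value) + "]"
    raise ConfigError(f"cannot serialize config value {value!r}")


def _emit_toml(data: dict[str, Any]) -> str:
    lines = []
    tables = []
    for key, value in data.items():
        if isinstance(value, dict):
            tables.append((key, value))
        else:
            lines.append(f"{key} = {_toml_scalar(value)}")
    for name, table in tables:
        lines.append("")
        lines.append(f"[{name}]")
        for key, value in table.items():
            lines.append(f"{key} = {_toml_scalar(value)}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# scans and summaries

def _metric_fn(cfg: RunConfig, criterion: str, axis: str) -> Callable[[float], metrics.MetricResult]:
    g0, mat, sample = cfg.geometry, cfg.material, cfg.sample
    beam = cfg.beam
    E0 = float(beam["energy_keV"])

    def evaluate(g: Geometry, E: float) -> metrics.MetricResult:
        if criterion == "resolution":
            s = sigma_sys(g)
            return metrics.MetricResult(value=-s, components={"sigma_sys_um": s})
        if criterion == "contrast":
            return metrics.contrast(g, mat, E, sample)
        if criterion == "cnr":
            return metrics.cnr(g, mat, E, sample, beam["I_in"], beam["eta"])
        if criterion == "q2d":
            return metrics.q2d(g, mat, E, sample, beam["eta"])
        if criterion == "q3d":
            return metrics.q3d(g, mat, E, sample, cfg.r_ct, beam["eta"])
        raise ConfigError(f"unknown criterion {criterion!r}")

    if axis == "M":
        return lambda v: evaluate(g0.with_magnification(v), E0)
    return lambda v: evaluate(g0, v)


def _closed_form_m(cfg: RunConfig, criterion: str) -> optimize.Optimum:
    g = cfg.geometry
    fn = {
        "resolution": optimize.opt_m_resolution,
        "contrast": optimize.opt_m_contrast,
        "cnr": optimize.opt_m_cnr,
        "q2d": optimize.opt_m_q2d,
        "q3d": optimize.opt_m_q3d,
    }[criterion]
    return fn(g.sigma_src, g.sigma_det)


def _numeric_objective(cfg: RunConfig, criterion: str, axis: str) -> Callable[[float], float]:
    fn = _metric_fn(cfg, criterion, axis)
    if criterion == "cnr":
        # the analytic M_CNR maximizes the phase-contrast part of the CNR
        return lambda v: fn(v).components["phase"]
    return lambda v: fn(v).value


def run_scan(cfg: RunConfig, out_dir: str | Path) -> dict[str, Any]:
    """Scan each configured criterion over the configured axis.

    Writes one CSV per criterion with columns (axis_value, metric,
    absorption_part, phase_part, validity_ratio) and a companion
    ``report.json`` with closed-form and numeric optima.  Returns the
    report dict.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scan = cfg.data["scan"]
    axis = scan["axis"]
    values = np.linspace(float(scan["start"]), float(scan["stop"]), int(scan["num"]))
    report: dict[str, Any] = {"axis": axis, "criteria": {}}

    for criterion in cfg.data["criteria"]:
        fn = _metric_fn(cfg, criterion, axis)
        rows = []
        for v in values:
            res = fn(v)
            comp = res.components
            rows.append((
                v,
                # resolution scans report sigma_sys itself (the optimizer
                # minimizes it; other metrics are maximized directly)
                comp.get("sigma_sys_um", res.value),
                comp.get("absorption", 0.0),
                comp.get("phase", res.value if criterion in ("q2d", "q3d") else 0.0),
                res.inputs_echo.get("validity_ratio", math.inf),
            ))
        csv_path = out_dir / f"scan_{criterion}_{axis}.csv"
        header = "axis_value,metric,absorption_part,phase_part,validity_ratio"
        body = "\n".join(
            ",".join(f"{x:.10g}" for x in row) for row in rows
        )
        csv_path.write_text(header + "\n" + body + "\n")

        entry: dict[str, Any] = {"csv": csv_path.name}
        numeric = optimize.opt_numeric(
            _numeric_objective(cfg, criterion, axis),
            "magnification" if axis == "M" else "energy",
            (float(scan["start"]), float(scan["stop"])),
            criterion=criterion,
        )
        entry["numeric"] = {"value": numeric.value, "method": numeric.method}
        if axis == "M":
            closed = _closed_form_m(cfg, criterion)
            entry["closed_form"] = {"value": closed.value, "method": closed.method}
            entry["R2_m"] = optimize.r2_at(closed.value, cfg.geometry.R)
        elif criterion in ("contrast", "cnr", "q2d", "q3d"):
            opt_e = optimize.opt_e_transmission(cfg.material, cfg.sample, criterion)
            entry["transmission_condition"] = {
                "value": opt_e.value, "method": opt_e.method,
            }
        report["criteria"][criterion] = entry

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    return report


@dataclass(frozen=True)
class SummaryRow:
    criterion: str
    M_opt: float
    R2_opt_m: float
    E_opt_keV: float | None
    note: str = ""


def report_summary(cfg: RunConfig) -> list[SummaryRow]:
    """Five-row summary of the optimal magnification (and energy where a
    transmission condition applies) for each criterion."""
    g = cfg.geometry
    rows = []
    for criterion in CRITERIA:
        opt = _closed_form_m(cfg, criterion)
        if criterion == "resolution":
            e_opt, note = None, "minimizes system blur"
        else:
            try:
                e_opt = optimize.opt_e_transmission(cfg.material, cfg.sample, criterion).value
            except ValueError:
                e_opt = None
            note = "analytic (slowly varying correction neglected)" if criterion == "q3d" else ""
        rows.append(SummaryRow(
            criterion=criterion,
            M_opt=opt.value,
            R2_opt_m=optimize.r2_at(opt.value, g.R),
            E_opt_keV=e_opt,
            note=note,
        ))
    return rows
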