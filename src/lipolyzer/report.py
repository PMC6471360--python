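"""Pipeline orchestration: run configured stages and collect a RunReport.

The config is a mapping with one optional section per stage::

    simulate:  {oil: PGO, seed: 1, mode: species, out: sim/}
    phstat:    {log: titration.csv, molarity: 0.05, oil_mass_g: 0.3,
                oil_molar_mass: 879.4, volume_ml: 36}
    quantify:  {t0: peaks_0min.csv, tt: peaks_30min.csv,
                calibration: calibration.json, per_species: true,
                total_curve: PGO}
    emulsion:  {psd: psd.csv, scan: scan.csv}

Stages run in that order; each stage's numbers land in the report under its
own key, and every input file is hashed into the provenance block so any
reported number is traceable to its inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np

from . import elsd, emulsion, io, phstat, synthetic
from .errors import CalibrationError, LipolyzerError, ValidationError

__all__ = ["RunReport", "run_pipeline", "REPORT_SCHEMA_VERSION"]

REPORT_SCHEMA_VERSION = 1


def _pkg_version() -> str:
    try:
        return version("lipolyzer")
    except PackageNotFoundError:  # pragma: no cover - editable corner case
        return "unknown"


def _sha256(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


@dataclass
class RunReport:
    """Structured results of one pipeline run."""

    stages: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)
    schema_version: int = REPORT_SCHEMA_VERSION

    def to_dict(self) -> dict:
        return {
            "schema_version": self.schema_version,
            "stages": self.stages,
            "provenance": self.provenance,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(text, encoding="utf-8")
        return text

    def summary(self) -> str:
        """Human-readable digest of every stage's headline numbers."""
        lines = [f"lipolyzer run report (schema v{self.schema_version})"]
        for stage, res in self.stages.items():
            lines.append(f"[{stage}]")
            for key, value in res.items():
                if isinstance(value, float):
                    lines.append(f"  {key}: {value:.4g}")
                elif isinstance(value, dict):
                    inner = ", ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                                      for k, v in value.items())
                    lines.append(f"  {key}: {inner}")
                elif isinstance(value, list):
                    lines.append(f"  {key}: {len(value)} values")
                else:
                    lines.append(f"  {key}: {value}")
        return "\n".join(lines)


def _track(report: RunReport, role: str, path) -> None:
    report.provenance.setdefault("inputs", {})[role] = {
        "path": str(path), "sha256": _sha256(path),
    }


def _stage_simulate(section: dict, report: RunReport) -> None:
    oil = section.get("oil", "PGO")
    seed = int(section.get("seed", 0))
    mode = section.get("mode", "species")
    if mode == "species":
        cfg = synthetic.default_config(oil, seed)
    elif mode == "total":
        cfg = synthetic.total_rate_config(oil, seed)
    else:
        raise ValidationError(f"simulate.mode must be 'species' or 'total', got {mode!r}")
    if "noise_cv" in section:
        from dataclasses import replace
        cfg = replace(cfg, noise_cv=float(section["noise_cv"]))
    out = Path(section["out"])
    out.mkdir(parents=True, exist_ok=True)
    io.write_titration(synthetic.simulate_titration(cfg), out / "titration.csv")
    obs0, obst = synthetic.simulate_peak_tables(cfg)
    io.write_peak_table(obs0, out / "peaks_0min.csv")
    io.write_peak_table(obst, out / f"peaks_{cfg.time_point_min:g}min.csv")
    io.write_psd(synthetic.simulate_psd(cfg), out / "psd.csv")
    io.write_scan(synthetic.simulate_scan(cfg), out / "scan.csv")
    from .calibration import CalibrationCurve
    io.write_calibrations(
        {t: CalibrationCurve(a=a, b=b) for t, (a, b) in cfg.calibration.items()},
        out / "calibration.json",
    )
    report.stages["simulate"] = {
        "oil": oil, "seed": seed, "mode": mode, "out": str(out),
        "true_rates_percent": dict(cfg.true_rates),
        "oil_molar_mass_g_per_mol": cfg.digestion_spec.oil_molar_mass,
    }


def _stage_phstat(section: dict, report: RunReport) -> None:
    log = section["log"]
    series = io.read_titration(log, molarity=float(section["molarity"]))
    _track(report, "phstat.log", log)
    spec = phstat.DigestionSpec(
        oil_mass=float(section["oil_mass_g"]),
        oil_molar_mass=float(section["oil_molar_mass"]),
        total_volume_ml=float(section.get("volume_ml", 36.0)),
    )
    ffa = phstat.ffa_release_percent(series, spec)
    report.stages["phstat"] = {
        "oil_concentration_mg_per_ml": spec.oil_concentration_mg_per_ml,
        "ffa_final_percent": float(ffa[-1]),
        "initial_rate_mM_per_s": phstat.initial_rate(series, spec),
        "ffa_percent": [float(x) for x in ffa],
        "time_s": [float(x) for x in series.times],
    }


def _stage_quantify(section: dict, report: RunReport) -> None:
    obs0 = io.read_peak_table(section["t0"])
    obst = io.read_peak_table(section["tt"])
    curves = io.read_calibrations(section["calibration"])
    for role, key in (("quantify.t0", "t0"), ("quantify.tt", "tt"),
                      ("quantify.calibration", "calibration")):
        _track(report, role, section[key])
    result: dict = {"time_point_min": obst.time_point_min}
    total_curve = section.get("total_curve")
    if total_curve is not None:
        if total_curve not in curves:
            raise CalibrationError(
                f"total_curve {total_curve!r} not in calibration file "
                f"(targets: {sorted(curves)})"
            )
        result["total_rate_percent"] = elsd.lipolysis_rate(
            obs0, obst, curves[total_curve], selector="total"
        )
    if section.get("per_species", False):
        result["species_rates_percent"] = elsd.species_lipolysis_rates(
            obs0, obst, curves
        )
    report.stages["quantify"] = result


def _stage_emulsion(section: dict, report: RunReport) -> None:
    result: dict = {}
    if "psd" in section:
        psd = io.read_psd(section["psd"])
        _track(report, "emulsion.psd", section["psd"])
        result["d32_um"] = emulsion.sauter_mean_diameter(psd)
    if "scan" in section:
        scan = io.read_scan(section["scan"])
        _track(report, "emulsion.scan", section["scan"])
        result["creaming_rate_percent_per_h"] = emulsion.backscatter_rate(
            scan, "creaming")
        result["clarification_rate_percent_per_h"] = emulsion.backscatter_rate(
            scan, "clarification")
    report.stages["emulsion"] = result


_STAGES = (
    ("simulate", _stage_simulate),
    ("phstat", _stage_phstat),
    ("quantify", _stage_quantify),
    ("emulsion", _stage_emulsion),
)


def run_pipeline(config: dict) -> RunReport:
    """Execute the configured stages in order and return a :class:`RunReport`.

    An empty config yields a report with provenance only.  Stage errors
    propagate as :class:`~lipolyzer.errors.LipolyzerError` subclasses so the
    CLI can map them to distinct exit codes.
    """
    report = RunReport()
    report.provenance["version"] = _pkg_version()
    report.provenance["config"] = config
    for name, runner in _STAGES:
        section = config.get(name)
        if section is None:
            continue
        if not isinstance(section, dict):
            raise ValidationError(f"config section {name!r} must be a mapping")
        runner(section, report)
    return report
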