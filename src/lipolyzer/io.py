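"""Delimited-text readers and writers for every pipeline input and output.

All tabular files are comma-delimited UTF-8 with a header row.  The peak
table carries its per-observation scalars (IS area, masses, concentrations)
as ``# key: value`` comment lines before the column header.  Calibration
curves round-trip through a small JSON document keyed by target.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .calibration import CalibrationCurve
from .elsd import Peak, PeakTable
from .emulsion import BackscatterScan, ParticleSizeDistribution
from .errors import ParseError
from .phstat import TitrationSeries
from .species import FattyAcid, OilComposition

__all__ = [
    "read_composition", "write_composition",
    "read_titration", "write_titration",
    "read_peak_table", "write_peak_table",
    "read_psd", "write_psd",
    "read_scan", "write_scan",
    "read_calibrations", "write_calibrations",
    "read_config",
]


def _read_csv(path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed delimited text
        raise ParseError(f"{path}: {exc}") from exc


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}; found {list(df.columns)}")


# -- fatty-acid composition -------------------------------------------------

def read_composition(path, name: str | None = None) -> OilComposition:
    df = _read_csv(path)
    _require(df, ["code", "label", "carbons", "double_bonds", "conjugated",
                  "area_percent"], path)
    entries = []
    unknown = 0.0
    for i, row in df.iterrows():
        try:
            if str(row["code"]).strip().lower() == "unknown":
                unknown += float(row["area_percent"])
                continue
            fa = FattyAcid(
                code=str(row["code"]), label=str(row["label"]),
                carbons=int(row["carbons"]), double_bonds=int(row["double_bonds"]),
                conjugated=bool(row["conjugated"]),
            )
            entries.append((fa, float(row["area_percent"])))
        except (ValueError, TypeError) as exc:
            raise ParseError(f"{path}: row {i}: {exc}") from exc
    return OilComposition(name=name or Path(path).stem, entries=tuple(entries),
                          unknown_percent=unknown)


def write_composition(comp: OilComposition, path) -> None:
    rows = [
        {"code": fa.code, "label": fa.label, "carbons": fa.carbons,
         "double_bonds": fa.double_bonds, "conjugated": fa.conjugated,
         "area_percent": pct}
        for fa, pct in comp.entries
    ]
    if comp.unknown_percent:
        rows.append({"code": "Unknown", "label": "", "carbons": 0,
                     "double_bonds": 0, "conjugated": False,
                     "area_percent": comp.unknown_percent})
    pd.DataFrame(rows).to_csv(path, index=False)


# -- titration log ----------------------------------------------------------

def read_titration(path, molarity: float, target_ph: float = 8.1) -> TitrationSeries:
    df = _read_csv(path)
    _require(df, ["time_s", "cumulative_volume_L"], path)
    return TitrationSeries(
        times=df["time_s"].to_numpy(float),
        volumes=df["cumulative_volume_L"].to_numpy(float),
        molarity=molarity, target_ph=target_ph,
    )


def write_titration(series: TitrationSeries, path) -> None:
    pd.DataFrame({"time_s": series.times,
                  "cumulative_volume_L": series.volumes}).to_csv(path, index=False)


# -- peak tables ------------------------------------------------------------

_PEAK_HEADER_KEYS = {
    "sample_id": str, "time_point_min": float, "is_area": float,
    "m_lp_mg": float, "m_a_mg": float,
    "c_s_mg_per_ml": float, "c_is_mg_per_ml": float,
}


def read_peak_table(path) -> PeakTable:
    header: dict[str, object] = {}
    body_lines = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#"):
                try:
                    key, value = line[1:].split(":", 1)
                except ValueError:
                    raise ParseError(f"{path}: line {lineno}: malformed header line")
                key = key.strip()
                if key not in _PEAK_HEADER_KEYS:
                    raise ParseError(f"{path}: line {lineno}: unknown header key {key!r}")
                try:
                    header[key] = _PEAK_HEADER_KEYS[key](value.strip())
                except ValueError as exc:
                    raise ParseError(f"{path}: line {lineno}: {exc}") from exc
            else:
                body_lines.append(line)
    missing = sorted(set(_PEAK_HEADER_KEYS) - set(header))
    if missing:
        raise ParseError(f"{path}: missing header line(s) for {missing}")
    df = _read_csv(_io.StringIO("".join(body_lines)))
    _require(df, ["retention_min", "area"], path)
    peaks = []
    for i, row in df.iterrows():
        try:
            ann = row.get("annotation")
            ann = None if (ann is None or (isinstance(ann, float) and np.isnan(ann))) \
                else str(ann)
            peaks.append(Peak(retention_min=float(row["retention_min"]),
                              area=float(row["area"]), annotation=ann))
        except (ValueError, TypeError) as exc:
            raise ParseError(
                f"{path}: row {i} (columns retention_min/area): {exc}"
            ) from exc
    return PeakTable(peaks=tuple(peaks), **header)  # type: ignore[arg-type]


def write_peak_table(table: PeakTable, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for key in _PEAK_HEADER_KEYS:
            fh.write(f"# {key}: {getattr(table, key)}\n")
        fh.write("retention_min,area,annotation\n")
        for p in table.peaks:
            fh.write(f"{p.retention_min},{p.area},{p.annotation or ''}\n")


# -- particle sizes and backscatter -----------------------------------------

def read_psd(path) -> ParticleSizeDistribution:
    df = _read_csv(path)
    _require(df, ["diameter_um", "count"], path)
    return ParticleSizeDistribution(
        diameters_um=df["diameter_um"].to_numpy(float),
        counts=df["count"].to_numpy(float),
    )


def write_psd(psd: ParticleSizeDistribution, path) -> None:
    pd.DataFrame({"diameter_um": psd.diameters_um,
                  "count": psd.counts}).to_csv(path, index=False)


def read_scan(path) -> BackscatterScan:
    df = _read_csv(path)
    _require(df, ["time_min", "height_mm", "dbs_percent"], path)
    times = np.unique(df["time_min"].to_numpy(float))
    heights = np.unique(df["height_mm"].to_numpy(float))
    wide = df.pivot_table(index="time_min", columns="height_mm",
                          values="dbs_percent")
    if wide.isna().any().any():
        raise ParseError(f"{path}: incomplete time x height grid")
    return BackscatterScan(times_min=times, heights_mm=heights,
                           dbs_percent=wide.to_numpy(float))


def write_scan(scan: BackscatterScan, path) -> None:
    t, h = np.meshgrid(scan.times_min, scan.heights_mm, indexing="ij")
    pd.DataFrame({"time_min": t.ravel(), "height_mm": h.ravel(),
                  "dbs_percent": scan.dbs_percent.ravel()}).to_csv(path, index=False)


# -- calibration JSON and YAML config ---------------------------------------

def read_calibrations(path) -> dict[str, CalibrationCurve]:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    out = {}
    for target, rec in doc.items():
        try:
            out[target] = CalibrationCurve(
                a=float(rec["a"]), b=float(rec["b"]),
                r_squared=float(rec.get("r_squared", float("nan"))),
            )
        except (KeyError, TypeError, ValueError) as exc:
            raise ParseError(f"{path}: target {target!r}: {exc}") from exc
    return out


def write_calibrations(curves: dict[str, CalibrationCurve], path) -> None:
    doc = {
        target: {"a": c.a, "b": c.b, "r_squared": c.r_squared,
                 "fit_scale": c.fit_scale}
        for target, c in curves.items()
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, indent=2)
        fh.write("\n")


def read_config(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not isinstance(doc, dict):
        raise ParseError(f"{path}: config must be a mapping of stage sections")
    return doc
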