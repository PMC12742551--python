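"""Readers and writers for the plan, layout, measurement and record schemas.

All formats are plain text (JSON, JSONL, CSV, YAML) with a versioned schema
header; write-then-read is the identity on every field.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .chambers import ICStackLayout, MeasuredSet, MeasurementSession, ErrorModel
from .cohort import FieldRecord, records_to_frame
from .dose import DoseGrid, PencilBeamSpot, TreatmentField
from .verify import ToleranceConfig

SCHEMA_VERSION = "1"

__all__ = [
    "write_plan", "read_plan",
    "write_layout", "read_layout",
    "write_measured_set", "read_measured_set",
    "write_session", "read_session",
    "write_records", "read_records",
    "write_dose_grid_meta", "export_grid_slice",
    "read_tolerances", "write_tolerances",
    "report",
]


def _check_version(obj: dict, path) -> None:
    v = obj.get("schema_version")
    if v != SCHEMA_VERSION:
        raise ValueError(f"{path}: unsupported schema_version {v!r} "
                         f"(expected {SCHEMA_VERSION!r})")


def write_plan(fld: TreatmentField, path) -> None:
    doc = {
        "schema_version": SCHEMA_VERSION,
        "ion": fld.ion_species,
        "layers": [{"range_mm": r} for r in fld.energy_layers],
        "spots": [
            {"layer": s.energy_index, "b_mm": s.lateral_position[0],
             "c_mm": s.lateral_position[1], "n_particles": s.particle_number,
             "fwhm_mm": s.fwhm}
            for s in fld.spots
        ],
        "range_shifter": {"present": fld.range_shifter,
                          "wet_mm": fld.range_shifter_wet_mm},
        "room": fld.room,
        "fraction_dose_Gy": fld.fraction_dose,
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_plan(path) -> TreatmentField:
    doc = json.loads(Path(path).read_text())
    _check_version(doc, path)
    spots = tuple(
        PencilBeamSpot(energy_index=int(s["layer"]),
                       lateral_position=(float(s["b_mm"]), float(s["c_mm"])),
                       particle_number=float(s["n_particles"]),
                       fwhm=float(s["fwhm_mm"]))
        for s in doc["spots"])
    return TreatmentField(
        ion_species=doc["ion"],
        energy_layers=tuple(float(l["range_mm"]) for l in doc["layers"]),
        spots=spots,
        range_shifter=bool(doc["range_shifter"]["present"]),
        range_shifter_wet_mm=float(doc["range_shifter"]["wet_mm"]),
        room=doc["room"], fraction_dose=float(doc["fraction_dose_Gy"]))


def write_layout(layout: ICStackLayout, path) -> None:
    df = pd.DataFrame(layout.offsets, columns=["da_mm", "db_mm", "dc_mm"])
    df.insert(0, "chamber_id", np.arange(len(df)))
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION}\n")
        df.to_csv(fh, index=False)


def read_layout(path) -> ICStackLayout:
    with open(path) as fh:
        header = fh.readline()
        if f"schema_version={SCHEMA_VERSION}" not in header:
            raise ValueError(f"{path}: missing or wrong schema header")
        df = pd.read_csv(fh)
    df = df.sort_values("chamber_id")
    return ICStackLayout(offsets=df[["da_mm", "db_mm", "dc_mm"]].to_numpy())


def write_measured_set(ms: MeasuredSet, path) -> None:
    df = pd.DataFrame({"chamber_id": np.arange(len(ms.doses)),
                       "dose_Gy": ms.doses})
    with open(path, "w") as fh:
        fh.write(f"# schema_version={SCHEMA_VERSION} "
                 f"human_error_suspected={ms.human_error_suspected}\n")
        df.to_csv(fh, index=False)


def read_measured_set(path) -> MeasuredSet:
    with open(path) as fh:
        header = fh.readline()
        if f"schema_version={SCHEMA_VERSION}" not in header:
            raise ValueError(f"{path}: missing or wrong schema header")
        flagged = "human_error_suspected=True" in header
        df = pd.read_csv(fh)
    if df.isna().any().any():
        bad = int(df[df.isna().any(axis=1)].index[0])
        raise ValueError(f"{path}: incomplete row {bad}")
    df = df.sort_values("chamber_id")
    return MeasuredSet(doses=df["dose_Gy"].to_numpy(),
                       human_error_suspected=flagged)


def write_session(session: MeasurementSession, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION,
           "placement_mm": list(session.placement),
           "seed": session.seed,
           "error_model": asdict(session.error_model)}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_session(path) -> MeasurementSession:
    doc = json.loads(Path(path).read_text())
    _check_version(doc, path)
    em = doc["error_model"]
    em["wrong_position_shift_mm"] = tuple(em["wrong_position_shift_mm"])
    return MeasurementSession(placement=tuple(doc["placement_mm"]),
                              seed=int(doc["seed"]),
                              error_model=ErrorModel(**em))


def write_records(records, path) -> None:
    """FieldRecords -> JSONL, one record per line, schema header first."""
    df = records_to_frame(records)
    with open(path, "w") as fh:
        fh.write(json.dumps({"schema_version": SCHEMA_VERSION}) + "\n")
        for row in df.to_dict(orient="records"):
            fh.write(json.dumps(row) + "\n")


def read_records(path) -> list[FieldRecord]:
    with open(path) as fh:
        header = json.loads(fh.readline())
        _check_version(header, path)
        rows = [json.loads(line) for line in fh if line.strip()]
    return [FieldRecord(**row) for row in rows]


def write_dose_grid_meta(grid: DoseGrid, path) -> None:
    doc = {"schema_version": SCHEMA_VERSION,
           "origin_mm": list(grid.origin), "spacing_mm": grid.spacing,
           "shape": list(grid.shape), "d_max_Gy": grid.d_max}
    Path(path).write_text(json.dumps(doc, indent=1))


def export_grid_slice(grid: DoseGrid, path, axis: int = 1,
                      index: int | None = None) -> None:
    """CSV slice through the grid, for inspection."""
    if index is None:
        index = grid.shape[axis] // 2
    sl = np.take(grid.values, index, axis=axis)
    pd.DataFrame(sl).to_csv(path, index=False)


def write_tolerances(tol: ToleranceConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(
        {"schema_version": SCHEMA_VERSION, **asdict(tol)}))


def read_tolerances(path) -> ToleranceConfig:
    doc = yaml.safe_load(Path(path).read_text())
    _check_version(doc, path)
    doc.pop("schema_version")
    return ToleranceConfig(**doc)


def _fmt_mmss(seconds: float) -> str:
    m, s = divmod(int(round(seconds)), 60)
    return f"{m:02d}:{s:02d}"


def report(summary: pd.DataFrame, out_csv=None, out_md=None) -> str:
    """Render a cohort summary in the standard report layout.

    Columns: group, fields, mean +/- SD [%], range [min-max] [%],
    mean +/- SD time [mm:ss], passed, failed, activated ICs.  Deviations are
    printed to 0.1%, pass rates to the integer.
    """
    rows = []
    for group, row in summary.iterrows():
        rows.append({
            "group": group,
            "fields": int(row["n"]),
            "mean_sd_pct": f"{row['mean']:.1f} ± {row['sd']:.1f}",
            "range_pct": f"{row['min']:.1f} – {row['max']:.1f}",
            "time_mmss": f"{_fmt_mmss(row['time_mean_s'])} ± "
                         f"{_fmt_mmss(row['time_sd_s'])}",
            "passed": f"{int(row['passed'])} "
                      f"({round(row['pass_rate_pct'])}%)",
            "failed": f"{int(row['failed'])} "
                      f"({round(100 - row['pass_rate_pct'])}%)",
            "activated_ics": f"{row['n_active_mean']:.0f} ± "
                             f"{row['n_active_sd']:.0f}",
        })
    out = pd.DataFrame(rows)
    if out_csv is not None:
        out.to_csv(out_csv, index=False)
    try:
        md = out.to_markdown(index=False)
    except ImportError:   # tabulate not installed
        md = out.to_string(index=False)
    if out_md is not None:
        Path(out_md).write_text(md + "\n")
    return md
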