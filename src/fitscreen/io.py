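"""Readers and writers for the tab-delimited plate/array file formats.

All tables are UTF-8 TSV with header rows.  Readers validate and reject
malformed input (duplicate time rows, non-numeric cells, wells missing
from the map) with errors naming the offending line; writers are plain
``DataFrame.to_csv`` wrappers plus a machine-readable run manifest.
"""

from __future__ import annotations

import hashlib
import json
import platform
from pathlib import Path

import numpy as np
import pandas as pd

from .dssa import ArrayExperiment
from .growth import GrowthCurveSet
from .reporter import ReporterPlate

__all__ = [
    "read_growth_plate",
    "write_growth_plate",
    "read_reporter_plate",
    "write_reporter_plate",
    "read_array_table",
    "write_array_table",
    "write_tsv",
    "write_manifest",
]


def _read_tsv(path) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: cannot parse TSV: {exc}") from exc


def _numeric(df: pd.DataFrame, cols, path) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        vals = pd.to_numeric(out[c], errors="coerce")
        bad = vals.isna() & (out[c].astype(str).str.len() > 0)
        if bad.any():
            line = int(bad.idxmax()) + 2  # +1 header, +1 zero-based
            raise ValueError(f"{path}: non-numeric value in column {c!r} at line {line}")
        out[c] = vals
    return out


def read_growth_plate(table_path, map_path) -> GrowthCurveSet:
    """Read a wide growth plate (``time_min`` + one column per well)."""
    tbl = _read_tsv(table_path)
    if tbl.columns[0] != "time_min":
        raise ValueError(f"{table_path}: first column must be 'time_min'")
    tbl = _numeric(tbl, tbl.columns, table_path)
    dup = tbl["time_min"].duplicated()
    if dup.any():
        raise ValueError(
            f"{table_path}: duplicated time row at line {int(dup.idxmax()) + 2}"
        )
    wm = _read_tsv(map_path)
    need = {"well", "strain", "dose_uM", "replicate", "role"}
    if not need <= set(wm.columns):
        raise ValueError(f"{map_path}: well map needs columns {sorted(need)}")
    wm = _numeric(wm, ["dose_uM"], map_path)
    well_cols = [c for c in tbl.columns if c != "time_min"]
    missing = set(well_cols) - set(wm["well"])
    if missing:
        raise ValueError(f"{map_path}: wells missing from map: {sorted(missing)}")
    wm = wm.set_index("well").loc[well_cols].reset_index()
    return GrowthCurveSet(
        times=tbl["time_min"].to_numpy() / 60.0,          # minutes -> hours
        od=tbl[well_cols].to_numpy().T,
        wells=wm,
    )


def write_growth_plate(curves: GrowthCurveSet, table_path, map_path) -> None:
    tbl = pd.DataFrame({"time_min": curves.times * 60.0})
    for i, well in enumerate(curves.wells["well"]):
        tbl[str(well)] = curves.od[i]
    tbl.to_csv(table_path, sep="\t", index=False)
    curves.wells.to_csv(map_path, sep="\t", index=False)


def read_reporter_plate(table_path, map_path) -> ReporterPlate:
    """Read a long reporter table (``well, time_min, od, gfp``)."""
    tbl = _read_tsv(table_path)
    need = {"well", "time_min", "od", "gfp"}
    if not need <= set(tbl.columns):
        raise ValueError(f"{table_path}: reporter table needs columns {sorted(need)}")
    tbl = _numeric(tbl, ["time_min", "od", "gfp"], table_path)
    dup = tbl.duplicated(subset=["well", "time_min"])
    if dup.any():
        raise ValueError(
            f"{table_path}: duplicate (well, time) row at line {int(dup.idxmax()) + 2}"
        )
    wm = _read_tsv(map_path)
    need_m = {"well", "orf", "stress_category", "dose_mgL", "role", "replicate"}
    if not need_m <= set(wm.columns):
        raise ValueError(f"{map_path}: well map needs columns {sorted(need_m)}")
    wm = _numeric(wm, ["dose_mgL"], map_path)

    od_w = tbl.pivot(index="well", columns="time_min", values="od").sort_index(axis=1)
    gfp_w = tbl.pivot(index="well", columns="time_min", values="gfp").sort_index(axis=1)
    if od_w.isna().any().any() or gfp_w.isna().any().any():
        raise ValueError(f"{table_path}: ragged time grid across wells")
    missing = set(od_w.index) - set(wm["well"])
    if missing:
        raise ValueError(f"{map_path}: wells missing from map: {sorted(missing)}")
    wm = wm.set_index("well").loc[od_w.index].reset_index()
    return ReporterPlate(
        times=od_w.columns.to_numpy(dtype=float),
        od=od_w.to_numpy(),
        gfp=gfp_w.to_numpy(),
        wells=wm,
    )


def write_reporter_plate(plate: ReporterPlate, table_path, map_path) -> None:
    rows = []
    for i, well in enumerate(plate.wells["well"]):
        for j, t in enumerate(plate.times):
            rows.append({"well": well, "time_min": t,
                         "od": plate.od[i, j], "gfp": plate.gfp[i, j]})
    pd.DataFrame(rows).to_csv(table_path, sep="\t", index=False)
    plate.wells.to_csv(map_path, sep="\t", index=False)


def read_array_table(table_path, metadata_path,
                     saturation_ceiling: float = 60000.0) -> ArrayExperiment:
    """Read a probe x array intensity table plus array metadata.

    The table carries ``probe_id, gene_id, is_null_feature`` columns
    followed by one column per array; metadata has ``array_id, dose_uM,
    generations, arm, replicate``.
    """
    tbl = _read_tsv(table_path)
    need = {"probe_id", "gene_id", "is_null_feature"}
    if not need <= set(tbl.columns):
        raise ValueError(f"{table_path}: array table needs columns {sorted(need)}")
    array_cols = [c for c in tbl.columns if c not in need]
    tbl = _numeric(tbl, array_cols, table_path)
    neg = (tbl[array_cols] < 0).any(axis=1)
    if neg.any():
        raise ValueError(
            f"{table_path}: negative intensity at line {int(neg.idxmax()) + 2}"
        )
    meta = _read_tsv(metadata_path)
    need_m = {"array_id", "dose_uM", "generations", "arm", "replicate"}
    if not need_m <= set(meta.columns):
        raise ValueError(f"{metadata_path}: metadata needs columns {sorted(need_m)}")
    meta = _numeric(meta, ["dose_uM", "generations"], metadata_path)
    missing = set(array_cols) - set(meta["array_id"])
    if missing:
        raise ValueError(f"{metadata_path}: arrays missing: {sorted(missing)}")
    probes = pd.DataFrame(
        {
            "gene_id": tbl["gene_id"],
            "is_null_feature": tbl["is_null_feature"]
            .astype(str).str.lower().isin(("1", "true", "yes")),
        }
    )
    probes.index = tbl["probe_id"]
    intensities = tbl[array_cols].copy()
    intensities.index = tbl["probe_id"]
    return ArrayExperiment(
        intensities=intensities,
        probes=probes,
        arrays=meta.set_index("array_id"),
        saturation_ceiling=saturation_ceiling,
    )


def write_array_table(exp: ArrayExperiment, table_path, metadata_path) -> None:
    tbl = pd.DataFrame(
        {
            "probe_id": exp.probes.index,
            "gene_id": exp.probes["gene_id"].to_numpy(),
            "is_null_feature": exp.probes["is_null_feature"].astype(int).to_numpy(),
        }
    )
    for c in exp.intensities.columns:
        tbl[c] = exp.intensities[c].to_numpy()
    tbl.to_csv(table_path, sep="\t", index=False)
    exp.arrays.reset_index().to_csv(metadata_path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    """Atomic-ish TSV write (temp file + rename)."""
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    df.to_csv(tmp, sep="\t", index=index)
    tmp.replace(path)


def display_p(p: float) -> str:
    """Report formatting: one significant figure below 0.01."""
    if p < 0.01:
        return f"{p:.1g}"
    return f"{p:.4g}"


def write_manifest(path, config: dict, seed=None) -> None:
    """Write a run manifest (version, config hash, seed) next to outputs."""
    from . import __version__

    payload = json.dumps(config, sort_keys=True, default=str).encode()
    manifest = {
        "fitscreen_version": __version__,
        "python": platform.python_version(),
        "config_sha256": hashlib.sha256(payload).hexdigest(),
        "config": config,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
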