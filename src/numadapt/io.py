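"""Readers and writers for the pipeline's tabular and imaging artifacts.

All tables are plain delimited text with a ``#``-prefixed provenance header
(package version, config hash, seed) so every artifact records how it was
made.  Voxel time series round-trip either through a pair of delimited
tables (metadata + wide time-series rows; the default, dependency-light
path) or through one NIfTI 4D file per condition with a JSON sidecar.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .models import MAP_LABELS, VoxelRecord

__all__ = [
    "write_table",
    "read_table",
    "voxels_to_tables",
    "tables_to_voxels",
    "write_voxels",
    "read_voxels",
    "write_voxels_nifti",
    "read_voxels_nifti",
]

META_COLUMNS = ["voxel_id", "participant", "hemisphere", "map_label",
                "ecc_deg", "polar_deg"]


def _provenance_lines(provenance: Mapping[str, object] | None) -> list[str]:
    if not provenance:
        return []
    return [f"# {k} = {v}" for k, v in provenance.items()]


def write_table(df: pd.DataFrame, path, provenance: Mapping | None = None) -> Path:
    """Write a DataFrame as CSV with '#' provenance header lines."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(provenance):
            fh.write(line + "\n")
        df.to_csv(fh, index=False)
    return path


def read_table(path) -> pd.DataFrame:
    """Read a CSV written by :func:`write_table`, skipping the header."""
    return pd.read_csv(path, comment="#")


def voxels_to_tables(voxels: Sequence[VoxelRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split voxel records into a metadata table and a wide time-series table.

    The time-series table has one row per voxel x condition x run, with
    sample columns ``s0000..``; lengths may differ between datasets but
    must be constant within one.
    """
    meta = pd.DataFrame(
        [
            {
                "voxel_id": v.voxel_id, "participant": v.participant,
                "hemisphere": v.hemisphere, "map_label": v.map_label,
                "ecc_deg": v.ecc_deg, "polar_deg": v.polar_deg,
            }
            for v in voxels
        ]
    )
    rows = []
    for v in voxels:
        for cond, runs in v.timeseries.items():
            for i, run in enumerate(runs):
                rows.append(
                    {"voxel_id": v.voxel_id, "condition": cond, "run": i,
                     **{f"s{j:04d}": x for j, x in enumerate(run)}}
                )
    return meta, pd.DataFrame(rows)


def tables_to_voxels(meta: pd.DataFrame, ts: pd.DataFrame,
                     expected_length: int | None = None) -> list[VoxelRecord]:
    """Rebuild voxel records from the two tables, validating as it goes."""
    sample_cols = [c for c in ts.columns if c.startswith("s") and c[1:].isdigit()]
    sample_cols.sort()
    voxels = []
    for row_i, m in meta.iterrows():
        if m["map_label"] not in MAP_LABELS:
            raise ValueError(
                f"row {row_i}: unknown map label {m['map_label']!r}; "
                f"allowed labels: {list(MAP_LABELS)}"
            )
        sub = ts.loc[ts["voxel_id"] == m["voxel_id"]]
        series: dict[str, list[np.ndarray]] = {}
        for (cond,), grp in sub.groupby(["condition"], sort=True):
            runs = []
            for _, r in grp.sort_values("run").iterrows():
                vals = r[sample_cols].to_numpy(dtype=float)
                vals = vals[np.isfinite(vals)]
                if expected_length is not None and len(vals) != expected_length:
                    raise ValueError(
                        f"voxel {m['voxel_id']} condition {cond} run "
                        f"{int(r['run'])}: {len(vals)} samples, expected "
                        f"{expected_length}"
                    )
                runs.append(vals)
            lengths = {len(r) for r in runs}
            if len(lengths) > 1:
                raise ValueError(
                    f"voxel {m['voxel_id']} condition {cond}: runs of "
                    f"unequal length {sorted(lengths)}"
                )
            series[cond] = runs
        voxels.append(VoxelRecord(
            voxel_id=m["voxel_id"], participant=m["participant"],
            hemisphere=m["hemisphere"], map_label=m["map_label"],
            ecc_deg=float(m["ecc_deg"]), polar_deg=float(m["polar_deg"]),
            timeseries=series,
        ))
    return voxels


def write_voxels(voxels: Sequence[VoxelRecord], out_dir,
                 provenance: Mapping | None = None) -> dict[str, Path]:
    """Write voxel records as the delimited metadata + time-series pair."""
    out_dir = Path(out_dir)
    meta, ts = voxels_to_tables(voxels)
    return {
        "metadata": write_table(meta, out_dir / "voxel_metadata.csv", provenance),
        "timeseries": write_table(ts, out_dir / "voxel_timeseries.csv", provenance),
    }


def read_voxels(in_dir, expected_length: int | None = None) -> list[VoxelRecord]:
    in_dir = Path(in_dir)
    meta = read_table(in_dir / "voxel_metadata.csv")
    ts = read_table(in_dir / "voxel_timeseries.csv")
    return tables_to_voxels(meta, ts, expected_length)


def write_voxels_nifti(voxels: Sequence[VoxelRecord], out_dir,
                       provenance: Mapping | None = None) -> dict[str, Path]:
    """Write one 4D NIfTI per condition plus JSON sidecar and metadata CSV.

    Voxels are laid out along the first axis in metadata order; runs are
    concatenated along time, with boundaries recorded in the sidecar.
    """
    import nibabel as nib

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    meta, _ = voxels_to_tables(voxels)
    paths = {"metadata": write_table(meta, out_dir / "voxel_metadata.csv",
                                     provenance)}
    conditions = sorted({c for v in voxels for c in v.timeseries})
    for cond in conditions:
        n_runs = len(voxels[0].timeseries[cond])
        n_t = len(voxels[0].timeseries[cond][0])
        data = np.stack(
            [np.concatenate(v.timeseries[cond]) for v in voxels]
        ).astype(np.float32)
        img = nib.Nifti1Image(data[:, None, None, :], affine=np.eye(4))
        nii = out_dir / f"bold_{cond}.nii"
        nib.save(img, nii)
        sidecar = {
            "condition": cond, "n_runs": n_runs, "n_trs_per_run": n_t,
            "voxel_order": [v.voxel_id for v in voxels],
            "provenance": dict(provenance or {}),
        }
        with open(out_dir / f"bold_{cond}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)
        paths[cond] = nii
    return paths


def read_voxels_nifti(in_dir) -> list[VoxelRecord]:
    import nibabel as nib

    in_dir = Path(in_dir)
    meta = read_table(in_dir / "voxel_metadata.csv")
    series: dict[str, dict[str, list[np.ndarray]]] = {
        vid: {} for vid in meta["voxel_id"]
    }
    for sidecar_path in sorted(in_dir.glob("bold_*.json")):
        with open(sidecar_path) as fh:
            sc = json.load(fh)
        cond, n_runs, n_t = sc["condition"], sc["n_runs"], sc["n_trs_per_run"]
        data = np.asarray(
            nib.load(in_dir / f"bold_{cond}.nii").get_fdata(dtype=np.float32),
            dtype=float,
        )[:, 0, 0, :]
        if data.shape[1] != n_runs * n_t:
            raise ValueError(
                f"{cond}: {data.shape[1]} timepoints, sidecar says "
                f"{n_runs} x {n_t}"
            )
        for i, vid in enumerate(sc["voxel_order"]):
            series[vid][cond] = [
                data[i, r * n_t:(r + 1) * n_t] for r in range(n_runs)
            ]
    voxels = []
    for _, m in meta.iterrows():
        voxels.append(VoxelRecord(
            voxel_id=m["voxel_id"], participant=m["participant"],
            hemisphere=m["hemisphere"], map_label=m["map_label"],
            ecc_deg=float(m["ecc_deg"]), polar_deg=float(m["polar_deg"]),
            timeseries=series[m["voxel_id"]],
        ))
    return voxels
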