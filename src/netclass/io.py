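"""File I/O: NIfTI voxel maps, delimited connectivity matrices, CSV tables,
JSON reports, and whole-cohort round trips.

All formats are plain text except NIfTI-1 (the standard neuroimaging
container, written via nibabel with a diagonal affine carrying the voxel
size).  Matrices are whitespace-delimited with a ``#``-prefixed label
header row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .cohort import Cohort, CohortSpec, CovariatePlan, GroundTruth, PlantedEffect

__all__ = [
    "save_voxelmap",
    "load_voxelmap",
    "save_matrix",
    "load_matrix",
    "write_json",
    "read_json",
    "write_object",
    "read_object",
    "write_cohort",
    "read_cohort",
]


def save_voxelmap(path, values: np.ndarray, voxel_size_mm=(1.0, 1.0, 1.0)) -> None:
    affine = np.diag([*voxel_size_mm, 1.0])
    img = nib.Nifti1Image(np.asarray(values, dtype=np.float64), affine)
    img.to_filename(str(path))


def load_voxelmap(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    values = np.asarray(img.dataobj, dtype=np.float64)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return values, voxel_size


def save_matrix(path, matrix: np.ndarray, labels=None) -> None:
    matrix = np.asarray(matrix, dtype=float)
    header = " ".join(labels) if labels is not None else ""
    np.savetxt(str(path), matrix, header=header)


def load_matrix(path) -> tuple[np.ndarray, list[str] | None]:
    path = Path(path)
    labels: list[str] | None = None
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("#"):
        stripped = first[1:].strip()
        labels = stripped.split() if stripped else None
    try:
        matrix = np.loadtxt(str(path))
    except ValueError as exc:
        raise ValueError(f"malformed matrix file {path}: {exc}") from exc
    matrix = np.atleast_2d(matrix)
    if labels is not None and len(labels) != matrix.shape[1]:
        raise ValueError(
            f"{path}: header has {len(labels)} labels for {matrix.shape[1]} columns"
        )
    return matrix, labels


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_jsonable)


def read_json(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_object(path, obj) -> None:
    """Format-dispatching writer (by extension): .nii/.nii.gz voxel maps,
    .csv tables, .json mappings, .txt matrices."""
    path = Path(path)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix in (".nii", ".nii.gz"):
        save_voxelmap(path, obj)
    elif suffix == ".csv":
        pd.DataFrame(obj).to_csv(path, index=False)
    elif suffix == ".json":
        write_json(path, obj)
    elif suffix == ".txt":
        save_matrix(path, obj)
    else:
        raise ValueError(f"unrecognized output format: {path.name}")


def read_object(path):
    path = Path(path)
    suffix = "".join(path.suffixes[-2:]) if path.name.endswith(".nii.gz") else path.suffix
    if suffix in (".nii", ".nii.gz"):
        return load_voxelmap(path)[0]
    if suffix == ".csv":
        try:
            return pd.read_csv(path)
        except pd.errors.ParserError as exc:
            raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if suffix == ".json":
        return read_json(path)
    if suffix == ".txt":
        return load_matrix(path)[0]
    raise ValueError(f"unrecognized input format: {path.name}")


# ---------------------------------------------------------------------------
# cohort round trip
# ---------------------------------------------------------------------------


def _spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["covariate_plan"] = {
        g: dataclasses.asdict(p) if dataclasses.is_dataclass(p) else p
        for g, p in spec.covariate_plan.items()
    }
    d["effect_plan"] = [dataclasses.asdict(e) for e in spec.effect_plan]
    return d


def _spec_from_dict(d: dict) -> CohortSpec:
    d = dict(d)
    d["covariate_plan"] = {
        g: CovariatePlan(
            age=tuple(p["age"]),
            education=tuple(p["education"]),
            cdr=tuple(p["cdr"]),
            mmse=tuple(p["mmse"]),
            female_fraction=p["female_fraction"],
        )
        for g, p in d["covariate_plan"].items()
    }
    d["effect_plan"] = tuple(
        PlantedEffect(
            modality=e["modality"],
            target=_tuplify(e["target"]),
            affected_groups=tuple(e["affected_groups"]),
            effect_size_d=e["effect_size_d"],
            metric=e.get("metric"),
        )
        for e in d["effect_plan"]
    )
    for key in ("group_names", "group_sizes", "grid_dims", "voxel_size_mm"):
        d[key] = tuple(d[key])
    return CohortSpec(**d)


def _tuplify(x):
    if isinstance(x, list):
        return tuple(_tuplify(v) for v in x)
    return x


def write_cohort(cohort: Cohort, truth: GroundTruth | None, out_dir) -> Path:
    """Persist a cohort: subjects.csv, per-subject NIfTI maps and matrix
    files, tracts.csv, the cohort spec and the ground truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.subjects.to_csv(out / "subjects.csv", index=False)
    write_json(out / "cohort_spec.json", _spec_to_dict(cohort.spec))
    if truth is not None:
        (out / "ground_truth.json").write_text(truth.to_json())
    vs = cohort.spec.voxel_size_mm
    maps_dir = out / "maps"
    mats_dir = out / "matrices"
    maps_dir.mkdir(exist_ok=True)
    mats_dir.mkdir(exist_ok=True)
    tract_rows = []
    for sid in cohort.subject_ids:
        for metric, vol in cohort.voxel_maps[sid].items():
            save_voxelmap(maps_dir / f"{sid}_{metric}.nii.gz", vol, vs)
        np.savetxt(mats_dir / f"{sid}_roi_ts.txt", cohort.roi_timeseries[sid])
        save_matrix(mats_dir / f"{sid}_fa.txt", cohort.fa_matrices[sid])
        tab = cohort.tract_metrics[sid].copy()
        tab.insert(0, "tract", tab.index)
        tab.insert(0, "subject_id", sid)
        tract_rows.append(tab)
    pd.concat(tract_rows, ignore_index=True).to_csv(out / "tracts.csv", index=False)
    return out


def read_cohort(in_dir) -> Cohort:
    src = Path(in_dir)
    spec = _spec_from_dict(read_json(src / "cohort_spec.json"))
    subjects = pd.read_csv(src / "subjects.csv")
    tracts = pd.read_csv(src / "tracts.csv")
    roi_ts, voxel_maps, fa, tract_tabs = {}, {}, {}, {}
    from .cohort import VOXELMAP_METRICS

    for sid in subjects["subject_id"]:
        roi_ts[sid] = np.atleast_2d(np.loadtxt(src / "matrices" / f"{sid}_roi_ts.txt"))
        if roi_ts[sid].shape[1] != spec.n_roi and roi_ts[sid].shape[0] == spec.n_roi:
            roi_ts[sid] = roi_ts[sid].T
        fa[sid], _ = load_matrix(src / "matrices" / f"{sid}_fa.txt")
        voxel_maps[sid] = {
            m: load_voxelmap(src / "maps" / f"{sid}_{m}.nii.gz")[0]
            for m in VOXELMAP_METRICS
        }
        tab = tracts[tracts["subject_id"] == sid].set_index("tract")
        tract_tabs[sid] = tab.drop(columns=["subject_id"])
    return Cohort(
        spec=spec,
        subjects=subjects,
        roi_timeseries=roi_ts,
        voxel_maps=voxel_maps,
        fa_matrices=fa,
        tract_metrics=tract_tabs,
    )
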