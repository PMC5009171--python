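"""File I/O: NIfTI volumes, slice stacks, phantoms, overlap reports.

All persisted volumes carry their voxel size in the NIfTI header and
readers consume it (never assume it).  Slice images are stored as
float TIFF, landmarks as CSV, displacement fields in an NPZ container,
reports as tidy CSV plus a JSON summary.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import FormatError
from .fields import DisplacementField2D
from .overlap import OverlapReport
from .phantom import FiberField, Phantom, PhantomConfig, SliceStack
from .tractography import ConnectivityMap

LANDMARK_COLUMNS = ["slice_index", "x_src", "y_src", "x_dst", "y_dst"]


# ----------------------------------------------------------------------
# volumes
# ----------------------------------------------------------------------
def write_volume(path, data: np.ndarray, voxel_size_mm) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    affine = np.diag([vs[0], vs[1], vs[2], 1.0])
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    img.header.set_zooms(tuple(vs))
    nib.save(img, str(path))
    return path


def read_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    try:
        img = nib.load(str(path))
    except Exception as exc:  # malformed header
        raise FormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    if any(z <= 0 for z in zooms):
        raise FormatError(f"{path}: non-positive voxel size in header ({zooms})")
    return np.asarray(img.get_fdata(), dtype=np.float64), zooms


def require_isotropic(zooms, context: str = "") -> float:
    zooms = np.asarray(zooms, dtype=float)
    if not np.allclose(zooms, zooms[0], rtol=1e-6):
        raise FormatError(
            f"unsupported geometry{': ' + context if context else ''}: "
            f"anisotropic voxel size {tuple(zooms)}; field 'pixdim' must be isotropic"
        )
    return float(zooms[0])


def write_connectivity_map(path, cmap: ConnectivityMap) -> Path:
    path = write_volume(path, cmap.counts.astype(np.float64), cmap.voxel_size_mm)
    meta = {
        "n_accepted": int(cmap.n_accepted),
        "n_attempted": int(cmap.n_attempted),
        "normalize_by": cmap.normalize_by,
    }
    Path(str(path) + ".json").write_text(json.dumps(meta, sort_keys=True))
    return path


def read_connectivity_map(path) -> ConnectivityMap:
    data, zooms = read_volume(path)
    vs = require_isotropic(zooms, "connectivity map")
    meta_path = Path(str(path) + ".json")
    if not meta_path.exists():
        raise FormatError(f"missing sidecar {meta_path} (field 'n_accepted' unknown)")
    meta = json.loads(meta_path.read_text())
    counts = np.rint(data).astype(np.int64)
    return ConnectivityMap(
        counts=counts,
        n_accepted=int(meta["n_accepted"]),
        n_attempted=int(meta["n_attempted"]),
        voxel_size_mm=vs,
        normalize_by=meta.get("normalize_by", "accepted"),
    )


# ----------------------------------------------------------------------
# slice stacks
# ----------------------------------------------------------------------
def write_stack(directory, stack: SliceStack) -> Path:
    directory = Path(directory)
    (directory / "slices").mkdir(parents=True, exist_ok=True)
    (directory / "block_faces").mkdir(parents=True, exist_ok=True)
    for i, (sl, bf) in enumerate(zip(stack.slices, stack.block_faces)):
        tifffile.imwrite(directory / "slices" / f"slice_{i:04d}.tif",
                         np.asarray(sl, dtype=np.float64))
        tifffile.imwrite(directory / "block_faces" / f"block_{i:04d}.tif",
                         np.asarray(bf, dtype=np.float64))
    rows = []
    for i, lm in enumerate(stack.landmarks):
        for x_src, y_src, x_dst, y_dst in lm:
            rows.append((i, x_src, y_src, x_dst, y_dst))
    pd.DataFrame(rows, columns=LANDMARK_COLUMNS).to_csv(
        directory / "landmarks.csv", index=False)
    np.savez(directory / "true_fields.npz",
             **{f"u_{i:04d}": f.u for i, f in enumerate(stack.true_fields)})
    meta = {
        "n_slices": stack.n_slices,
        "in_plane_spacing_mm": float(stack.in_plane_spacing_mm),
        "slice_spacing_mm": float(stack.slice_spacing_mm),
        "slice_positions_mm": [float(z) for z in stack.slice_positions_mm],
    }
    (directory / "stack.yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return directory


def read_stack(directory) -> SliceStack:
    directory = Path(directory)
    meta_path = directory / "stack.yaml"
    if not meta_path.exists():
        raise FormatError(f"missing stack metadata {meta_path}")
    meta = yaml.safe_load(meta_path.read_text())
    for key in ("n_slices", "in_plane_spacing_mm", "slice_spacing_mm"):
        if key not in meta:
            raise FormatError(f"{meta_path}: missing field '{key}'")
    n = int(meta["n_slices"])
    slices = [np.asarray(tifffile.imread(directory / "slices" / f"slice_{i:04d}.tif"))
              for i in range(n)]
    blocks = [np.asarray(tifffile.imread(directory / "block_faces" / f"block_{i:04d}.tif"))
              for i in range(n)]
    lm_df = pd.read_csv(directory / "landmarks.csv")
    if list(lm_df.columns) != LANDMARK_COLUMNS:
        raise FormatError(f"landmarks.csv: expected columns {LANDMARK_COLUMNS}")
    landmarks = [
        lm_df[lm_df["slice_index"] == i][LANDMARK_COLUMNS[1:]].to_numpy(dtype=float)
        for i in range(n)
    ]
    sp = float(meta["in_plane_spacing_mm"])
    with np.load(directory / "true_fields.npz") as npz:
        fields = [DisplacementField2D(npz[f"u_{i:04d}"], sp) for i in range(n)]
    return SliceStack(
        slices=slices,
        block_faces=blocks,
        landmarks=landmarks,
        in_plane_spacing_mm=sp,
        slice_spacing_mm=float(meta["slice_spacing_mm"]),
        true_fields=fields,
        slice_positions_mm=np.asarray(meta["slice_positions_mm"], dtype=float),
    )


# ----------------------------------------------------------------------
# phantoms
# ----------------------------------------------------------------------
def write_phantom(directory, phantom: Phantom) -> Path:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cfg = asdict(phantom.config)
    cfg["grid_shape"] = list(cfg["grid_shape"])
    (directory / "config.yaml").write_text(yaml.safe_dump(cfg, sort_keys=True))
    vs = phantom.voxel_size_mm
    write_volume(directory / "intensity.nii", phantom.intensity_volume, vs)
    write_volume(directory / "roi_labels.nii", phantom.roi_labels.astype(float), vs)
    for name in ("tract_mask_left", "tract_mask_right", "seed_mask_left",
                 "seed_mask_right", "target_mask_left", "target_mask_right",
                 "exclusion_mask"):
        write_volume(directory / f"{name}.nii", getattr(phantom, name).astype(float), vs)
    ff = phantom.fiber_field
    lines = {}
    for side, d in phantom.centerlines.items():
        lines[f"{side}_points"] = d["points"]
        lines[f"{side}_tangents"] = d["tangents"]
        lines[f"{side}_arclen"] = d["arclen"]
        lines[f"{side}_s_cross"] = np.asarray(d["s_cross"])
    np.savez(directory / "fiber_field.npz",
             orientations=ff.orientations, fractions=ff.fractions,
             kappa=np.asarray(ff.kappa), **lines)
    return directory


def read_phantom(directory) -> Phantom:
    directory = Path(directory)
    cfg = yaml.safe_load((directory / "config.yaml").read_text())
    cfg["grid_shape"] = tuple(cfg["grid_shape"])
    config = PhantomConfig(**cfg)
    intensity, zooms = read_volume(directory / "intensity.nii")
    vs = require_isotropic(zooms, "phantom intensity volume")
    labels, _ = read_volume(directory / "roi_labels.nii")
    masks = {}
    for name in ("tract_mask_left", "tract_mask_right", "seed_mask_left",
                 "seed_mask_right", "target_mask_left", "target_mask_right",
                 "exclusion_mask"):
        data, _ = read_volume(directory / f"{name}.nii")
        masks[name] = data > 0.5
    with np.load(directory / "fiber_field.npz") as npz:
        ff = FiberField(
            orientations=npz["orientations"],
            fractions=npz["fractions"],
            kappa=float(npz["kappa"]),
            voxel_size_mm=vs,
        )
        centerlines = {}
        for side in ("left", "right"):
            if f"{side}_points" in npz:
                centerlines[side] = {
                    "points": npz[f"{side}_points"],
                    "tangents": npz[f"{side}_tangents"],
                    "arclen": npz[f"{side}_arclen"],
                    "s_cross": float(npz[f"{side}_s_cross"]),
                }
    return Phantom(
        config=config,
        roi_labels=np.rint(labels).astype(np.int8),
        fiber_field=ff,
        intensity_volume=intensity,
        centerlines=centerlines,
        **masks,
    )


# ----------------------------------------------------------------------
# reports
# ----------------------------------------------------------------------
def write_report(basepath, report: OverlapReport) -> tuple[Path, Path]:
    basepath = Path(basepath)
    basepath.parent.mkdir(parents=True, exist_ok=True)
    csv_path = basepath.with_suffix(".csv")
    report.rows.to_csv(csv_path, index=False)
    payload = {
        "summary": report.summary,
        "dilation": {
            roi: {
                "margin_mm": [float(v) for v in df["margin_mm"]],
                "covered_fraction": [float(v) for v in df["covered_fraction"]],
            }
            for roi, df in report.dilation.items()
        },
    }
    json_path = basepath.with_suffix(".json")
    json_path.write_text(json.dumps(payload, sort_keys=True, indent=1))
    return csv_path, json_path


def read_report(basepath) -> OverlapReport:
    basepath = Path(basepath)
    rows = pd.read_csv(basepath.with_suffix(".csv"))
    expected = ["roi", "threshold", "TP", "FP", "TN", "FN", "TPR", "FPR", "SI"]
    if list(rows.columns) != expected:
        raise FormatError(f"report CSV: expected columns {expected}")
    payload = json.loads(basepath.with_suffix(".json").read_text())
    dilation = {
        roi: pd.DataFrame({"margin_mm": d["margin_mm"],
                           "covered_fraction": d["covered_fraction"]})
        for roi, d in payload.get("dilation", {}).items()
    }
    return OverlapReport(rows=rows, summary=payload.get("summary", {}),
                         dilation=dilation)
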