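"""Readers and writers for the interchange formats.

Stacks are NIfTI, one 3-D volume per cardiac phase, with mm voxel
spacing in the header and a JSON sidecar naming the phases and the
slice geometry. Contours are JSON polygons per slice (closed, planar
mm coordinates, origin at the grid corner, y increasing row-wise).
Subject tables and index tables are plain CSV.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import ContourSet, FormatError, ShortAxisStack, SliceContours
from .indices import CutoffRule, SubjectRecord
from .quantify import VolumetricResult
from .stats import ROCReport
from .wall import WallThicknessResult

STACK_SIDECAR = "stack.json"


def write_stack(stack: ShortAxisStack, out_dir: str | Path) -> Path:
    """Write one NIfTI file per phase plus the geometry sidecar."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    slab = stack.slab_thickness
    affine = np.diag([stack.in_plane_spacing, stack.in_plane_spacing, slab, 1.0])
    sidecar = {
        "phases": {},
        "in_plane_spacing": stack.in_plane_spacing,
        "slice_thickness": stack.slice_thickness,
        "slice_gap": stack.slice_gap,
    }
    for phase, data in stack.phases.items():
        fname = f"{phase}.nii"
        img = nib.Nifti1Image(np.asarray(data).transpose(2, 1, 0).astype(np.float64), affine)
        img.header.set_zooms((stack.in_plane_spacing, stack.in_plane_spacing, slab))
        nib.save(img, out_dir / fname)
        sidecar["phases"][phase] = fname
    (out_dir / STACK_SIDECAR).write_text(json.dumps(sidecar, indent=1))
    return out_dir


def read_stack(stack_dir: str | Path) -> ShortAxisStack:
    """Read a phase-labelled NIfTI stack written by :func:`write_stack`."""
    stack_dir = Path(stack_dir)
    sidecar_path = stack_dir / STACK_SIDECAR
    if not sidecar_path.exists():
        raise FormatError(f"missing stack sidecar {sidecar_path}")
    sidecar = json.loads(sidecar_path.read_text())
    for key in ("phases", "in_plane_spacing", "slice_thickness"):
        if key not in sidecar:
            raise FormatError(f"stack sidecar lacks required key {key!r}")
    spacing = float(sidecar["in_plane_spacing"])
    if spacing <= 0:
        raise FormatError("non-positive in-plane spacing in sidecar")
    phases = {}
    for phase, fname in sidecar["phases"].items():
        try:
            img = nib.load(stack_dir / fname)
            data = np.asanyarray(img.dataobj)
        except Exception as exc:  # corrupt/truncated file
            raise FormatError(f"cannot read NIfTI volume {fname}: {exc}") from exc
        zooms = img.header.get_zooms()[:2]
        if not np.allclose(zooms, spacing, rtol=1e-4):
            raise FormatError(
                f"{fname}: header spacing {zooms} disagrees with sidecar {spacing}"
            )
        phases[phase] = np.asarray(data, dtype=float).transpose(2, 1, 0)
    return ShortAxisStack(
        phases=phases,
        in_plane_spacing=spacing,
        slice_thickness=float(sidecar["slice_thickness"]),
        slice_gap=float(sidecar.get("slice_gap", 0.0)),
    )


def write_contours(contours: ContourSet, path: str | Path) -> Path:
    """Write contour polygons as JSON (closed polygons, mm)."""
    payload = {"phases": {}}
    for phase, per_slice in contours.phases.items():
        records = []
        for idx in sorted(per_slice):
            sc = per_slice[idx]
            for role, poly in (("endo", sc.endo), ("epi", sc.epi)):
                if poly is None:
                    continue
                closed = np.vstack([poly, poly[:1]])
                records.append(
                    {"slice_index": idx, "role": role, "polygon": closed.tolist()}
                )
        payload["phases"][phase] = records
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload))
    return path


def read_contours(path: str | Path) -> ContourSet:
    try:
        payload = json.loads(Path(path).read_text())
        phase_records = payload["phases"]
    except (json.JSONDecodeError, KeyError, OSError) as exc:
        raise FormatError(f"cannot read contour JSON {path}: {exc}") from exc
    phases: dict[str, dict[int, SliceContours]] = {}
    for phase, records in phase_records.items():
        per_slice: dict[int, dict[str, np.ndarray]] = {}
        for rec in records:
            poly = np.asarray(rec["polygon"], dtype=float)
            if poly.shape[0] > 1 and np.allclose(poly[0], poly[-1]):
                poly = poly[:-1]  # drop explicit closing vertex
            per_slice.setdefault(int(rec["slice_index"]), {})[rec["role"]] = poly
        phases[phase] = {}
        for idx, roles in per_slice.items():
            if "epi" not in roles:
                raise FormatError(f"phase {phase}, slice {idx}: epicardial contour missing")
            phases[phase][idx] = SliceContours(epi=roles["epi"], endo=roles.get("endo"))
    return ContourSet(phases=phases)


def write_volumetric_result(result: VolumetricResult, path: str | Path) -> Path:
    payload = {
        "method": result.method,
        "lvedv_ml": result.lvedv,
        "lvesv_ml": result.lvesv,
        "lvsv_ml": result.lvsv,
        "lvef_percent": result.lvef,
        "lvm_g": result.lvm,
        "tpm_g": result.tpm_mass,
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=1))
    return path


def read_volumetric_result(path: str | Path) -> VolumetricResult:
    payload = json.loads(Path(path).read_text())
    return VolumetricResult(
        method=payload["method"],
        lvedv=payload["lvedv_ml"],
        lvesv=payload["lvesv_ml"],
        lvm=payload["lvm_g"],
        tpm_mass=payload.get("tpm_g"),
    )


def write_wall_result(result: WallThicknessResult, path: str | Path) -> Path:
    payload = {
        "max_edwt_mm": result.max_edwt,
        "min_edwt_mm": result.min_edwt,
        "max_min_ratio": result.max_min_ratio,
        "slice_of_max": result.slice_of_max,
        "n_skipped": result.n_skipped,
        "warning": result.warning,
        "slice_indices": result.slice_indices,
        "thickness_profile_mm": [
            [None if np.isnan(v) else round(float(v), 4) for v in row]
            for row in result.thickness_profile
        ],
    }
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path


def read_wall_result(path: str | Path) -> WallThicknessResult:
    payload = json.loads(Path(path).read_text())
    profile = np.array(
        [[np.nan if v is None else v for v in row] for row in payload["thickness_profile_mm"]],
        dtype=float,
    )
    return WallThicknessResult(
        max_edwt=payload["max_edwt_mm"],
        min_edwt=payload["min_edwt_mm"],
        slice_of_max=payload["slice_of_max"],
        thickness_profile=profile,
        slice_indices=payload["slice_indices"],
        n_skipped=payload["n_skipped"],
        warning=payload["warning"],
    )


def read_cutoff_rules(path: str | Path) -> tuple[CutoffRule, ...]:
    """Cut-off rules as JSON: a list of {"index": ..., "threshold": ...}."""
    try:
        records = json.loads(Path(path).read_text())
        return tuple(CutoffRule(index=r["index"], threshold=float(r["threshold"])) for r in records)
    except (json.JSONDecodeError, KeyError, TypeError, OSError) as exc:
        raise FormatError(f"cannot read cut-off rules {path}: {exc}") from exc


def read_subjects(path: str | Path) -> list[SubjectRecord]:
    """Subject table CSV: id, sex, group, age, height, weight, heart_rate."""
    df = pd.read_csv(path, comment="#")
    required = {"id", "sex", "group", "age", "height", "weight", "heart_rate"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"subject table lacks columns: {sorted(missing)}")
    return [
        SubjectRecord(
            id=str(row.id),
            sex=str(row.sex),
            group=str(row.group),
            age=float(row.age),
            height=float(row.height),
            weight=float(row.weight),
            heart_rate=float(row.heart_rate),
        )
        for row in df.itertuples(index=False)
    ]


def write_roc_report(report: ROCReport, path: str | Path) -> Path:
    payload = {
        "index": report.index_name,
        "auc": report.auc,
        "optimal_threshold": report.optimal_threshold,
        "thresholds": [None if not np.isfinite(t) else float(t) for t in report.thresholds],
        "sensitivity_percent": report.sensitivity.tolist(),
        "specificity_percent": report.specificity.tolist(),
    }
    if report.optimum is not None:
        payload["at_optimum"] = asdict(report.optimum)
    path = Path(path)
    path.write_text(json.dumps(payload))
    return path
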