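"""File formats: NIfTI label volumes, curve/marker CSVs, JSON sidecars.

All tabular outputs are plain CSV so runs are diffable; label masks are
written as single-slice NIfTI volumes with a 1-mm isotropic header (axis 0
is the sagittal axis, so the mid-sagittal extractor round-trips them).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import REGION_CODES, REGION_NAMES, BoundaryCurve, LabelSlice


def save_slice_nifti(slc: LabelSlice, path) -> Path:
    """Write a label slice as a (1, ny, nx) NIfTI volume, 1-mm isotropic."""
    path = Path(path)
    vol = slc.grid.astype(np.int16)[None, :, :]
    affine = np.diag([slc.pixel_size_mm] * 3 + [1.0])
    img = nib.Nifti1Image(vol, affine)
    img.header.set_zooms((slc.pixel_size_mm,) * 3)
    nib.save(img, str(path))
    return path


def load_slice_nifti(path, subject_id: str = "") -> LabelSlice:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(np.int16)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3D volume")
    idx = int(np.ceil(data.shape[0] / 2)) - 1
    return LabelSlice(grid=data[idx], pixel_size_mm=float(img.header.get_zooms()[1]),
                      subject_id=subject_id)


def curves_to_frame(curves) -> pd.DataFrame:
    rows = []
    for c in curves:
        for i, ((x, y), lab) in enumerate(zip(c.points, c.labels)):
            rows.append((c.subject_id, i, x, y, REGION_NAMES.get(int(lab), "bg")))
    return pd.DataFrame(rows, columns=["subject_id", "point_index", "x_mm", "y_mm", "region"])


def save_curves(curves, path, meta: dict | None = None) -> Path:
    path = Path(path)
    curves = list(curves)
    curves_to_frame(curves).to_csv(path, index=False)
    sidecar = {
        "n_curves": len(curves),
        "pixel_areas_mm2": {c.subject_id: c.pixel_area_mm2 for c in curves},
    }
    if meta:
        sidecar.update(meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_curves(path) -> list:
    df = pd.read_csv(path)
    sidecar = {}
    sc = Path(path).with_suffix(".json")
    if sc.exists():
        sidecar = json.loads(sc.read_text())
    areas = sidecar.get("pixel_areas_mm2", {})
    curves = []
    for sid, grp in df.groupby("subject_id", sort=True):
        grp = grp.sort_values("point_index")
        pts = grp[["x_mm", "y_mm"]].to_numpy(float)
        labels = np.array([REGION_CODES.get(r, 0) for r in grp.region])
        curves.append(BoundaryCurve(points=pts, labels=labels, subject_id=str(sid),
                                    pixel_area_mm2=areas.get(str(sid))))
    return curves


def save_marker_table(table, path) -> Path:
    path = Path(path)
    table.to_long_frame().to_csv(path, index=False)
    sidecar = {
        "template_area_mm2": table.template_area_mm2,
        "areas_mm2": {sid: float(a) for sid, a in zip(table.subject_ids, table.areas_mm2)},
        "regions": [int(r) for r in table.regions],
    }
    sidecar.update(table.meta)
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path


def load_marker_table(path):
    from .lddmm import MarkerTable

    df = pd.read_csv(path)
    sidecar = json.loads(Path(path).with_suffix(".json").read_text())
    wide = df.pivot(index="subject_id", columns="point_index", values="marker").sort_index()
    sids = [str(s) for s in wide.index]
    areas = np.array([sidecar["areas_mm2"][s] for s in sids])
    return MarkerTable(
        subject_ids=sids,
        markers=wide.to_numpy(float),
        regions=np.asarray(sidecar["regions"], dtype=int),
        areas_mm2=areas,
        template_area_mm2=float(sidecar["template_area_mm2"]),
    )


def file_hash(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def json_hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()
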