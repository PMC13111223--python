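"""Standard-format readers and writers.

Volumes round-trip as NIfTI-1 (labels as integers, tensors as 6-component
volumes in lower-triangular order xx, xy, yy, xz, yz, zz — recorded in the
header description), tractograms as TCK, atlases as integer NIfTI plus a
JSON lookup, tables as CSV. Paired inputs must share one affine; grids are
never silently resampled.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .connectome import ParcelAtlas, SCMatrix, Tractogram
from .grids import FieldVolume, LabeledVolume
from .tensors import COMPONENT_ORDER, TensorField

TENSOR_DESCRIP = "symmetric tensor components " + ",".join(COMPONENT_ORDER)


def _spacing_from_affine(affine: np.ndarray) -> np.ndarray:
    return np.linalg.norm(affine[:3, :3], axis=0)


def write_labeled_volume(volume: LabeledVolume, path) -> None:
    img = nib.Nifti1Image(volume.labels.astype(np.int16), volume.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_labeled_volume(path) -> LabeledVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{path}: label volume contains non-integer values")
    affine = img.affine
    return LabeledVolume(np.round(data).astype(np.int16),
                         _spacing_from_affine(affine), affine)


def write_tensor_field(t: TensorField, path) -> None:
    img = nib.Nifti1Image(t.components.astype(np.float64), t.affine)
    img.header["descrip"] = TENSOR_DESCRIP.encode()[:79]
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_tensor_field(path, units: str = "") -> TensorField:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if data.ndim != 4 or data.shape[-1] != 6:
        raise ValueError(
            f"{path}: tensor NIfTI must be 4-D with 6 components, "
            f"got shape {data.shape}"
        )
    mask = np.any(data != 0, axis=-1)
    return TensorField(data, mask, _spacing_from_affine(img.affine),
                       img.affine, units=units)


def write_field_volume(f: FieldVolume, path) -> None:
    vals = f.values.copy()
    vals[~f.mask] = np.nan
    img = nib.Nifti1Image(vals, f.affine)
    img.header["descrip"] = f.kind.encode()[:79]
    img.header.set_xyzt_units("mm")
    nib.save(img, str(path))


def read_field_volume(path, kind: str | None = None) -> FieldVolume:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    if kind is None:
        kind = "efield" if data.ndim == 4 else "potential"
    mask = np.all(np.isfinite(data), axis=-1) if data.ndim == 4 \
        else np.isfinite(data)
    data = np.nan_to_num(data, nan=0.0)
    return FieldVolume(kind, data, mask, _spacing_from_affine(img.affine),
                       img.affine)


def write_tractogram(t: Tractogram, path) -> None:
    tg = nib.streamlines.Tractogram(t.streamlines,
                                    affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tg, str(path))


def read_tractogram(path) -> Tractogram:
    tf = nib.streamlines.load(str(path))
    return Tractogram(list(tf.streamlines))


def write_atlas(atlas: ParcelAtlas, nifti_path, json_path) -> None:
    img = nib.Nifti1Image(atlas.label_volume.astype(np.int16), atlas.affine)
    nib.save(img, str(nifti_path))
    lut = [{"id": pid, "name": atlas.names[pid],
            "hemisphere": atlas.hemisphere[pid]}
           for pid in atlas.parcel_ids]
    Path(json_path).write_text(json.dumps(lut, indent=1))


def read_atlas(nifti_path, json_path=None) -> ParcelAtlas:
    img = nib.load(str(nifti_path))
    data = np.asarray(img.dataobj)
    if not np.allclose(data, np.round(data)):
        raise ValueError(f"{nifti_path}: atlas contains non-integer labels")
    names, hemi = {}, {}
    if json_path is not None:
        for rec in json.loads(Path(json_path).read_text()):
            names[int(rec["id"])] = rec.get("name", str(rec["id"]))
            hemi[int(rec["id"])] = rec.get("hemisphere", "none")
    return ParcelAtlas(np.round(data).astype(np.int32), img.affine,
                       names=names, hemisphere=hemi)


def write_sc_matrix(sc: SCMatrix, path) -> None:
    sc.to_frame().to_csv(path, index_label="parcel")


def read_sc_matrix(path, weighting: str = "raw_count",
                   normalized: bool = False) -> SCMatrix:
    import pandas as pd
    df = pd.read_csv(path, index_col=0)
    ids = []
    for c in df.columns:
        try:
            ids.append(int(c))
        except ValueError:
            ids.append(c)
    return SCMatrix(df.to_numpy(), ids, weighting=weighting,
                    normalized=normalized)


def check_same_grid(*objs) -> None:
    """Reject any pair of volumes that do not share shape and affine."""
    ref = objs[0]
    for o in objs[1:]:
        if o.shape[:3] != ref.shape[:3] or not np.allclose(o.affine,
                                                           ref.affine):
            raise ValueError(
                "grid mismatch between paired inputs: "
                f"{ref.shape} vs {o.shape}; volumes are never resampled"
            )
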