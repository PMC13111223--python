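"""Tissue conductivities and diffusion-to-conductivity tensor mapping.

Isotropic conductivities follow the IT'IS low-frequency tissue database
values used throughout this package; white-matter anisotropy enters by
converting the diffusion tensor to a conductivity tensor that shares its
eigenvectors (the standard effective-medium assumption: the major
eigenvector is parallel to the local fiber bundle).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import TISSUE_CODES, WHITE_MATTER, LabeledVolume
from .tensors import TensorField, mat_to_six, six_to_mat

#: Isotropic tissue conductivities, S/m.
ISOTROPIC_SIGMA_S_PER_M = {
    "skin": 0.148,
    "fat": 0.078,
    "csf": 1.879,
    "grey_matter": 0.419,
    "white_matter": 0.348,
    "bone_cancellous": 0.08,
    "bone_cortical": 0.0063,
    "electrode_sponge": 1.4,
    "electrode_copper": 5.9e7,
}


@dataclass
class ConductivityModel:
    """Per-voxel conductivity: an isotropic table plus optional WM tensors.

    ``mode`` is 'isotropic' (every tissue gets sigma * I) or 'anisotropic_wm'
    (white-matter voxels take their tensor from ``wm_tensors``; everything
    else stays isotropic).
    """

    iso_table: dict  # tissue name -> S/m
    mode: str = "isotropic"
    wm_tensors: TensorField | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.mode not in ("isotropic", "anisotropic_wm"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for t, s in self.iso_table.items():
            if t not in TISSUE_CODES:
                raise ValueError(f"unknown tissue {t!r} in conductivity table")
            if s <= 0:
                raise ValueError(f"sigma for {t!r} must be positive, got {s}")
        if self.mode == "anisotropic_wm" and self.wm_tensors is None:
            raise ValueError("anisotropic_wm mode requires wm_tensors")

    def sigma_of(self, tissue: str) -> float:
        return float(self.iso_table[tissue])

    def voxel_tensors(self, volume: LabeledVolume) -> np.ndarray:
        """Full (nx, ny, nz, 3, 3) conductivity tensors; zero on air."""
        code_to_sigma = np.zeros(max(TISSUE_CODES.values()) + 1)
        for t, s in self.iso_table.items():
            code_to_sigma[TISSUE_CODES[t]] = s
        iso = code_to_sigma[volume.labels]
        out = iso[..., None, None] * np.eye(3)
        if self.mode == "anisotropic_wm":
            tf = self.wm_tensors
            if tf.shape != volume.shape:
                raise ValueError("wm tensor grid does not match the volume")
            wm = volume.labels == WHITE_MATTER
            use = wm & tf.mask
            if not np.array_equal(use, tf.mask):
                raise ValueError("wm_tensors mask extends beyond white matter")
            out[use] = six_to_mat(tf.components[use])
        return out


def assign_isotropic(volume: LabeledVolume, overrides: dict | None = None
                     ) -> ConductivityModel:
    """Isotropic conductivity model for every label present in the volume."""
    table = dict(ISOTROPIC_SIGMA_S_PER_M)
    if overrides:
        table.update(overrides)
    present = {int(c) for c in np.unique(volume.labels)} - {0}
    names = {v: k for k, v in TISSUE_CODES.items()}
    missing = [names[c] for c in sorted(present) if names[c] not in table]
    if missing:
        raise ValueError(f"no conductivity for tissue label(s): {missing}")
    table = {t: s for t, s in table.items()
             if TISSUE_CODES[t] in present or t in (overrides or {})}
    return ConductivityModel(iso_table=table, mode="isotropic")


def diffusion_to_conductivity(d: TensorField, reference_sigma_wm: float = 0.348,
                              mapping: str = "volume_normalized",
                              iso_tol: float = 1e-12) -> TensorField:
    """Map a diffusion tensor field to a conductivity tensor field.

    Eigenvectors are preserved voxel-wise; eigenvalues are scaled:

    - ``scaled_linear``: sigma_v = k * d_v with one global k chosen so the
      field-mean diffusivity maps to ``reference_sigma_wm`` (conductivity FA
      equals diffusion FA everywhere; bulk matches the isotropic value on
      average).
    - ``volume_normalized``: per-voxel k such that the geometric mean of
      the three conductivity eigenvalues equals ``reference_sigma_wm`` at
      every voxel (local anisotropy preserved, local bulk pinned).

    Tensors whose eigenvalue spread is below ``iso_tol`` (relative) are
    mapped to exact isotropy.
    """
    if reference_sigma_wm <= 0:
        raise ValueError("reference conductivity must be positive")
    if mapping not in ("scaled_linear", "volume_normalized"):
        raise ValueError(f"unknown mapping {mapping!r}")
    if not d.mask.any():
        raise ValueError("diffusion tensor field has an empty mask")
    mats = six_to_mat(d.components[d.mask])
    ev, evec = np.linalg.eigh(mats)
    if np.any(ev[:, 0] <= 0):
        bad = np.argwhere(d.mask)[ev[:, 0] <= 0][0]
        raise ValueError(
            f"diffusion tensor at voxel {tuple(bad)} is not SPD "
            f"(min eigenvalue {ev[:, 0].min():.3e})"
        )
    if mapping == "scaled_linear":
        k = reference_sigma_wm / ev.mean()
        sev = k * ev
    else:
        gm = np.exp(np.log(ev).mean(axis=1, keepdims=True))
        sev = reference_sigma_wm * ev / gm
    spread = (ev[:, 2] - ev[:, 0]) / ev[:, 2]
    iso = spread < iso_tol
    if iso.any():
        sev[iso] = sev[iso].mean(axis=1, keepdims=True)
    out_mats = np.einsum("nij,nj,nkj->nik", evec, sev, evec)
    comps = np.zeros(d.shape + (6,))
    comps[d.mask] = mat_to_six(out_mats)
    return TensorField(comps, d.mask.copy(), d.spacing_mm, d.affine,
                       units="S/m")


def anisotropic_model(volume: LabeledVolume, wm_conductivity: TensorField,
                      overrides: dict | None = None) -> ConductivityModel:
    """Isotropic table plus white-matter conductivity tensors (DTI mode)."""
    iso = assign_isotropic(volume, overrides)
    wm = volume.labels == WHITE_MATTER
    if not np.array_equal(wm_conductivity.mask, wm):
        raise ValueError(
            "conductivity tensors must be masked exactly on white matter"
        )
    return ConductivityModel(iso_table=iso.iso_table, mode="anisotropic_wm",
                             wm_tensors=wm_conductivity)
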