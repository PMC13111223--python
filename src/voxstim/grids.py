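"""Voxel grids: tissue-label volumes and scalar/vector field volumes.

All volumes live on a regular rectilinear grid in RAS world coordinates
(mm). Voxel indices are 0-based; a voxel's world position is the position
of its *center*, ``affine @ (i, j, k, 1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

# Registered tissue table. Code 0 is background air; electrodes carry their
# own codes so the solver can locate Dirichlet nodes.
TISSUE_CODES: Mapping[str, int] = {
    "air": 0,
    "skin": 1,
    "bone_cortical": 2,
    "bone_cancellous": 3,
    "csf": 4,
    "grey_matter": 5,
    "white_matter": 6,
    "fat": 7,
    "electrode_sponge": 8,
    "electrode_copper": 9,
}

TISSUE_NAMES: Mapping[int, str] = {v: k for k, v in TISSUE_CODES.items()}

AIR = TISSUE_CODES["air"]
SPONGE = TISSUE_CODES["electrode_sponge"]
COPPER = TISSUE_CODES["electrode_copper"]
WHITE_MATTER = TISSUE_CODES["white_matter"]
GREY_MATTER = TISSUE_CODES["grey_matter"]


def make_affine(spacing_mm, origin_mm=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Diagonal RAS affine mapping voxel index -> world mm (voxel centers)."""
    spacing_mm = np.broadcast_to(np.asarray(spacing_mm, dtype=float), (3,))
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing_mm)
    aff[:3, 3] = np.asarray(origin_mm, dtype=float)
    return aff


def _check_affine(affine: np.ndarray, spacing: np.ndarray) -> None:
    affine = np.asarray(affine, dtype=float)
    if affine.shape != (4, 4):
        raise ValueError(f"affine must be 4x4, got {affine.shape}")
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    col_norms = np.linalg.norm(affine[:3, :3], axis=0)
    if not np.allclose(col_norms, spacing, rtol=1e-6):
        raise ValueError(
            f"spacing {spacing} does not match affine column norms {col_norms}"
        )


@dataclass
class LabeledVolume:
    """3-D integer tissue-label grid with voxel spacing and world affine."""

    labels: np.ndarray  # (nx, ny, nz) integer codes
    spacing_mm: np.ndarray  # (3,)
    affine: np.ndarray  # 4x4 voxel-index -> world-mm
    # voxel indices of each attached electrode, filled by attach_electrodes
    electrode_voxels: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.ascontiguousarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("labels must be a 3-D array")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        self.spacing_mm = np.broadcast_to(
            np.asarray(self.spacing_mm, dtype=float), (3,)
        ).copy()
        if np.any(self.spacing_mm <= 0):
            raise ValueError("spacing must be positive")
        self.affine = np.asarray(self.affine, dtype=float)
        _check_affine(self.affine, self.spacing_mm)
        unknown = set(np.unique(self.labels)) - set(TISSUE_NAMES)
        if unknown:
            raise ValueError(f"unregistered tissue codes: {sorted(unknown)}")

    @property
    def shape(self) -> tuple:
        return self.labels.shape

    def voxel_centers_world(self, idx: np.ndarray) -> np.ndarray:
        """World-mm centers of the voxels at integer index rows ``idx``."""
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return idx @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        """Continuous voxel coordinates of world-mm points."""
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]

    def mask(self, *tissues: str) -> np.ndarray:
        codes = [TISSUE_CODES[t] for t in tissues]
        return np.isin(self.labels, codes)

    def copy(self) -> "LabeledVolume":
        return LabeledVolume(
            self.labels.copy(),
            self.spacing_mm.copy(),
            self.affine.copy(),
            {k: (a.copy(), b.copy()) for k, (a, b) in self.electrode_voxels.items()},
        )


@dataclass
class FieldVolume:
    """Scalar potential (V) or 3-vector electric field (V/m) on a voxel grid.

    ``values`` has shape (nx, ny, nz) for kind='potential' or (nx, ny, nz, 3)
    for kind='efield'. ``mask`` flags the voxels where the field is defined
    (the conductive voxels). Potentials solved by the FEM additionally carry
    the node-grid solution in ``node_values`` (shape (nx+1, ny+1, nz+1)).
    """

    kind: str
    values: np.ndarray
    mask: np.ndarray
    spacing_mm: np.ndarray
    affine: np.ndarray
    node_values: np.ndarray | None = None

    def __post_init__(self):
        if self.kind not in ("potential", "efield"):
            raise ValueError(f"unknown field kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        expected = self.mask.shape + ((3,) if self.kind == "efield" else ())
        if self.values.shape != expected:
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with mask "
                f"{self.mask.shape} for kind={self.kind}"
            )
        self.spacing_mm = np.broadcast_to(
            np.asarray(self.spacing_mm, dtype=float), (3,)
        ).copy()
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def magnitude(self) -> np.ndarray:
        if self.kind != "efield":
            raise ValueError("magnitude is defined for efield volumes")
        return np.linalg.norm(self.values, axis=-1)

    def copy(self) -> "FieldVolume":
        return FieldVolume(
            self.kind,
            self.values.copy(),
            self.mask.copy(),
            self.spacing_mm.copy(),
            self.affine.copy(),
            None if self.node_values is None else self.node_values.copy(),
        )
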