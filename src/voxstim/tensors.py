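"""Per-voxel symmetric 3x3 tensor fields (diffusion or conductivity).

Six unique components are stored per voxel in the order
(xx, xy, yy, xz, yz, zz) — NIfTI lower-triangular convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: component order of the stored 6-vector
COMPONENT_ORDER = ("xx", "xy", "yy", "xz", "yz", "zz")

# index pairs of each stored component in the full 3x3 matrix
_IJ = [(0, 0), (0, 1), (1, 1), (0, 2), (1, 2), (2, 2)]


def six_to_mat(six: np.ndarray) -> np.ndarray:
    """(..., 6) lower-triangular components -> (..., 3, 3) symmetric matrices."""
    six = np.asarray(six, dtype=float)
    mat = np.empty(six.shape[:-1] + (3, 3))
    for c, (i, j) in enumerate(_IJ):
        mat[..., i, j] = six[..., c]
        mat[..., j, i] = six[..., c]
    return mat


def mat_to_six(mat: np.ndarray) -> np.ndarray:
    """(..., 3, 3) symmetric matrices -> (..., 6) stored components."""
    mat = np.asarray(mat, dtype=float)
    return np.stack([mat[..., i, j] for (i, j) in _IJ], axis=-1)


@dataclass
class TensorField:
    """Symmetric 3x3 tensors on a voxel grid, defined where ``mask`` is set.

    Units are mm^2/s for diffusion tensors and S/m for conductivity tensors.
    Masked-out voxels carry zeros and must never be interpreted.
    """

    components: np.ndarray  # (nx, ny, nz, 6)
    mask: np.ndarray  # (nx, ny, nz) bool
    spacing_mm: np.ndarray
    affine: np.ndarray
    units: str = ""

    def __post_init__(self):
        self.components = np.asarray(self.components, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.components.shape != self.mask.shape + (6,):
            raise ValueError(
                f"components shape {self.components.shape} inconsistent with "
                f"mask shape {self.mask.shape}"
            )
        self.spacing_mm = np.broadcast_to(
            np.asarray(self.spacing_mm, dtype=float), (3,)
        ).copy()
        self.affine = np.asarray(self.affine, dtype=float)
        self.components[~self.mask] = 0.0

    @property
    def shape(self) -> tuple:
        return self.mask.shape

    def matrices(self, where: np.ndarray | None = None) -> np.ndarray:
        """Full 3x3 matrices at masked-in voxels (or at ``where``)."""
        sel = self.mask if where is None else where
        return six_to_mat(self.components[sel])

    def eigenvalues(self) -> np.ndarray:
        """Ascending eigenvalues at each masked-in voxel, shape (n, 3)."""
        return np.linalg.eigvalsh(self.matrices())


def check_spd(t: TensorField, tol: float = 0.0) -> dict:
    """Exhaustive SPD diagnostic over the masked-in voxels.

    Returns ``{"n_checked", "n_failures", "min_eigenvalue", "failures"}``
    where ``failures`` lists the voxel indices whose smallest eigenvalue is
    <= ``tol``.
    """
    idx = np.argwhere(t.mask)
    if len(idx) == 0:
        return {"n_checked": 0, "n_failures": 0, "min_eigenvalue": None,
                "failures": []}
    ev = np.linalg.eigvalsh(six_to_mat(t.components[t.mask]))
    lo = ev[:, 0]
    bad = lo <= tol
    return {
        "n_checked": int(len(idx)),
        "n_failures": int(bad.sum()),
        "min_eigenvalue": float(lo.min()),
        "failures": [tuple(v) for v in idx[bad]],
    }


def fractional_anisotropy(eigenvalues: np.ndarray) -> np.ndarray:
    """FA of tensors given their (..., 3) eigenvalues."""
    ev = np.asarray(eigenvalues, dtype=float)
    md = ev.mean(axis=-1, keepdims=True)
    num = np.sqrt(1.5 * ((ev - md) ** 2).sum(axis=-1))
    den = np.sqrt((ev**2).sum(axis=-1))
    return np.divide(num, den, out=np.zeros_like(num), where=den > 0)
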