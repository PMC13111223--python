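"""Structural connectomes: streamline endpoint assignment, weighted
inter-parcel count matrices, inter-subject variability, parcel ranking
and matrix reduction to named regions of interest.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class Tractogram:
    """Streamline polylines in world coordinates (mm).

    Each streamline is an (n_points, 3) float array with n_points >= 2.
    ``weights`` holds one positive multiplier per streamline (default 1;
    the slot accepts SIFT2-style density weights).
    """

    streamlines: list
    weights: np.ndarray | None = None

    def __post_init__(self):
        self.streamlines = [np.asarray(s, dtype=np.float32) for s in self.streamlines]
        for k, s in enumerate(self.streamlines):
            if s.ndim != 2 or s.shape[1] != 3 or s.shape[0] < 2:
                raise ValueError(f"streamline {k} is not an (n>=2, 3) polyline")
        if self.weights is None:
            self.weights = np.ones(len(self.streamlines))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (len(self.streamlines),):
            raise ValueError("one weight per streamline required")
        if np.any(self.weights <= 0):
            raise ValueError("streamline weights must be positive")

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class ParcelAtlas:
    """Integer parcel labels on a voxel grid; 0 = unlabelled."""

    label_volume: np.ndarray
    affine: np.ndarray
    names: dict = field(default_factory=dict)  # id -> str
    hemisphere: dict = field(default_factory=dict)  # id -> left|right|none

    def __post_init__(self):
        self.label_volume = np.asarray(self.label_volume)
        if not np.issubdtype(self.label_volume.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        self.affine = np.asarray(self.affine, dtype=float)
        for pid in self.parcel_ids:
            self.names.setdefault(pid, str(pid))
            self.hemisphere.setdefault(pid, "none")

    @property
    def parcel_ids(self) -> list:
        ids = np.unique(self.label_volume)
        return [int(i) for i in ids if i != 0]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    @property
    def parcel_volumes(self) -> dict:
        """Parcel volumes in mm^3 (voxel count x voxel volume)."""
        ids, counts = np.unique(self.label_volume, return_counts=True)
        vv = self.voxel_volume_mm3
        return {int(i): float(c) * vv for i, c in zip(ids, counts) if i != 0}

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(pts, dtype=float))
        inv = np.linalg.inv(self.affine)
        return pts @ inv[:3, :3].T + inv[:3, 3]


@dataclass
class SCMatrix:
    """Symmetric inter-parcel connectivity matrix with zero diagonal."""

    values: np.ndarray
    parcel_ids: list
    weighting: str = "raw_count"
    normalized: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.parcel_ids)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape must match parcel_ids")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("SC matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("SC matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("SC matrix entries must be nonnegative")

    def edge(self, a, b) -> float:
        ia = self.parcel_ids.index(a)
        ib = self.parcel_ids.index(b)
        return float(self.values[ia, ib])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.parcel_ids,
                            columns=self.parcel_ids)


def _parcel_at(atlas: ParcelAtlas, vox: np.ndarray) -> np.ndarray:
    """Parcel id at each continuous voxel coordinate (0 outside grid)."""
    idx = np.round(vox).astype(int)
    shape = atlas.label_volume.shape
    inside = np.all((idx >= 0) & (idx < shape), axis=1)
    out = np.zeros(len(vox), dtype=int)
    if inside.any():
        ii = idx[inside]
        out[inside] = atlas.label_volume[ii[:, 0], ii[:, 1], ii[:, 2]]
    return out


def assign_endpoints(t: Tractogram, atlas: ParcelAtlas,
                     search_radius_mm: float = 2.0) -> list:
    """Map each streamline's two endpoints to parcels.

    An endpoint inside a parcel takes that parcel; otherwise the nearest
    parcel whose boundary voxel center lies within ``search_radius_mm``;
    otherwise it stays unassigned (None). Returns a list of
    (parcel_a, parcel_b) pairs where either element may be None.
    """
    if search_radius_mm < 0:
        raise ValueError("search radius must be >= 0")
    if len(t) == 0:
        return []
    ends = np.array([[s[0], s[-1]] for s in t.streamlines], dtype=float)
    flat = ends.reshape(-1, 3)
    vox = atlas.world_to_voxel(flat)
    pid = _parcel_at(atlas, vox)

    missing = pid == 0
    if missing.any() and search_radius_mm > 0:
        lab_idx = np.argwhere(atlas.label_volume != 0)
        if len(lab_idx):
            centers = lab_idx @ atlas.affine[:3, :3].T + atlas.affine[:3, 3]
            tree = cKDTree(centers)
            d, j = tree.query(flat[missing], distance_upper_bound=search_radius_mm)
            hit = np.isfinite(d)
            near = np.zeros(missing.sum(), dtype=int)
            if hit.any():
                ii = lab_idx[j[hit]]
                near[hit] = atlas.label_volume[ii[:, 0], ii[:, 1], ii[:, 2]]
            pid[missing] = near
    pairs = pid.reshape(-1, 2)
    return [(int(a) if a else None, int(b) if b else None) for a, b in pairs]


def sc_matrix(t: Tractogram, atlas: ParcelAtlas, weighting: str = "raw_count",
              normalize: bool = False, search_radius_mm: float = 2.0,
              volume_combination: str = "mean") -> SCMatrix:
    """Build the inter-parcel connectivity matrix from a tractogram.

    A streamline contributes its weight to entry (a, b) when both endpoints
    are assigned; with ``weighting='inv_volume'`` the contribution is divided
    by the arithmetic mean (or, with ``volume_combination='sum'``, the sum)
    of the two parcel volumes in mm^3. Self-connections are excluded
    (zero diagonal). With ``normalize`` the matrix is divided by its maximum
    entry.
    """
    if weighting not in ("raw_count", "inv_volume"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if volume_combination not in ("mean", "sum"):
        raise ValueError(f"unknown volume combination {volume_combination!r}")
    ids = atlas.parcel_ids
    pos = {p: i for i, p in enumerate(ids)}
    vols = atlas.parcel_volumes
    n = len(ids)
    m = np.zeros((n, n))
    pairs = assign_endpoints(t, atlas, search_radius_mm)
    n_assigned = 0
    for (a, b), w in zip(pairs, t.weights):
        if a is None or b is None or a == b:
            continue
        n_assigned += 1
        contrib = w
        if weighting == "inv_volume":
            va, vb = vols[a], vols[b]
            den = 0.5 * (va + vb) if volume_combination == "mean" else va + vb
            contrib = w / den
        m[pos[a], pos[b]] += contrib
        m[pos[b], pos[a]] += contrib
    if len(t) and n_assigned == 0:
        import warnings
        warnings.warn("no streamline had both endpoints assigned; zero matrix")
    if normalize:
        peak = m.max()
        if peak > 0:
            m = m / peak
    return SCMatrix(m, ids, weighting=weighting, normalized=normalize)


def adjusted_variability(cohort_matrices: list, region: int) -> float:
    """Adjusted inter-subject variability of one parcel's connectivity profile.

    Var(i) = 1 - E[corr(SC_i(s_p), SC_i(s_q))] over all unordered subject
    pairs p != q, where SC_i is subject s's connectivity row for parcel i
    with the self-entry removed. Returned as a percentage (x100).
    """
    if len(cohort_matrices) < 2:
        raise ValueError("need at least 2 subjects")
    ids0 = cohort_matrices[0].parcel_ids
    for m in cohort_matrices:
        if m.parcel_ids != ids0:
            raise ValueError("subjects must share one parcel set")
    i = ids0.index(region)
    rows = []
    for s, m in enumerate(cohort_matrices):
        row = np.delete(m.values[i], i)
        if np.std(row) == 0:
            raise ValueError(
                f"zero-variance connectivity row for region {region} in "
                f"subject {s}; pairwise correlation undefined"
            )
        rows.append(row)
    cors = [np.corrcoef(rows[p], rows[q])[0, 1]
            for p, q in combinations(range(len(rows)), 2)]
    return 100.0 * (1.0 - float(np.mean(cors)))


def rank_parcels(sc: SCMatrix, seed_parcels: list, scope: str = "all",
                 hemisphere: dict | None = None) -> list:
    """Rank non-seed parcels by total connection weight to the seed set.

    ``scope`` restricts candidates to one hemisphere (requires the
    ``hemisphere`` map for scopes other than 'all'). Descending by weight;
    ties broken by ascending parcel id. Returns (parcel_id, weight) pairs.
    """
    for p in seed_parcels:
        if p not in sc.parcel_ids:
            raise ValueError(f"seed parcel {p} not in matrix")
    if scope not in ("all", "left_hemisphere", "right_hemisphere"):
        raise ValueError(f"unknown scope {scope!r}")
    candidates = [p for p in sc.parcel_ids if p not in seed_parcels]
    if scope != "all":
        side = scope.split("_")[0]
        hemisphere = hemisphere or {}
        candidates = [p for p in candidates if hemisphere.get(p) == side]
    if not candidates:
        raise ValueError(f"no candidate parcels in scope {scope!r}")
    seed_idx = [sc.parcel_ids.index(p) for p in seed_parcels]
    totals = [(p, float(sc.values[sc.parcel_ids.index(p), seed_idx].sum()))
              for p in candidates]
    return sorted(totals, key=lambda t: (-t[1], t[0]))


def reduce_matrix(sc: SCMatrix, roi_groups: dict) -> SCMatrix:
    """Sum parcel-level entries into a small matrix of named ROI groups.

    ``roi_groups`` maps ROI name -> list of parcel ids; groups must be
    disjoint. Entry (R, S) is the sum of sc[a, b] over a in R, b in S;
    the diagonal is set to zero.
    """
    seen = set()
    for name, parcels in roi_groups.items():
        ov = seen & set(parcels)
        if ov:
            raise ValueError(f"ROI group {name!r} overlaps parcels {sorted(ov)}")
        seen |= set(parcels)
        for p in parcels:
            if p not in sc.parcel_ids:
                raise ValueError(f"parcel {p} of group {name!r} not in matrix")
    names = list(roi_groups)
    n = len(names)
    out = np.zeros((n, n))
    idx = {p: sc.parcel_ids.index(p) for p in seen}
    for i, r in enumerate(names):
        for j, s in enumerate(names):
            if i == j:
                continue
            rows = [idx[p] for p in roi_groups[r]]
            cols = [idx[p] for p in roi_groups[s]]
            out[i, j] = sc.values[np.ix_(rows, cols)].sum()
    return SCMatrix(out, names, weighting=sc.weighting, normalized=False)
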