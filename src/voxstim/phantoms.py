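"""Synthetic phantom generation.

Everything the real study obtained from MRI and tractography is emulated
here at desk scale: layered slab and sphere head phantoms, rectangular
sponge/copper electrode pads, white-matter fiber tensor fields and toy
tractograms with exactly known inter-parcel streamline counts. All
generators are pure functions of their arguments plus a seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .connectome import ParcelAtlas, Tractogram
from .grids import (AIR, COPPER, SPONGE, TISSUE_CODES, WHITE_MATTER,
                    LabeledVolume, make_affine)
from .tensors import TensorField, mat_to_six


@dataclass
class ElectrodeSpec:
    """Rectangular sponge/copper pad electrode held at a fixed potential.

    Defaults mirror a standard parietal-supraorbital tDCS montage: anode
    pad 30 x 30 mm, cathode 50 x 50 mm, 1 mm copper over 5 mm of
    conductive sponge, potentials +1 / -1 V. ``normal`` points away from the head.
    A ``sponge_thickness_mm`` of 0 puts the copper plate directly on the
    tissue (used by the analytic slab oracles).
    """

    name: str
    center_world: tuple
    normal: tuple
    pad_size_mm: tuple = (30.0, 30.0)
    copper_thickness_mm: float = 1.0
    sponge_thickness_mm: float = 5.0
    potential_V: float = 1.0

    def __post_init__(self):
        self.center_world = np.asarray(self.center_world, dtype=float)
        n = np.asarray(self.normal, dtype=float)
        nn = np.linalg.norm(n)
        if not np.isclose(nn, 1.0, atol=1e-6):
            raise ValueError(f"electrode normal must be unit length, |n|={nn}")
        self.normal = n / nn
        self.pad_size_mm = tuple(float(x) for x in self.pad_size_mm)
        if min(self.pad_size_mm) <= 0:
            raise ValueError("pad dimensions must be positive")
        if self.copper_thickness_mm <= 0:
            raise ValueError("copper thickness must be positive")
        if self.sponge_thickness_mm < 0:
            raise ValueError("sponge thickness must be nonnegative")


def anode_spec(center_world, normal, potential_V=1.0, name="anode") -> ElectrodeSpec:
    """30 x 30 mm anode pad with the default sponge/copper construction."""
    return ElectrodeSpec(name, center_world, normal, (30.0, 30.0), 1.0, 5.0,
                         potential_V)


def cathode_spec(center_world, normal, potential_V=-1.0, name="cathode") -> ElectrodeSpec:
    """50 x 50 mm cathode pad with the default sponge/copper construction."""
    return ElectrodeSpec(name, center_world, normal, (50.0, 50.0), 1.0, 5.0,
                         potential_V)


def _n_vox(extent_mm: float, spacing: float, what: str) -> int:
    n = extent_mm / spacing
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"spacing {spacing} mm is not commensurate with {what} "
            f"({extent_mm} mm)"
        )
    return int(round(n))


def make_slab_phantom(n_layers: int, layer_labels: list,
                      layer_thicknesses_mm: list, cross_section_mm,
                      spacing_mm: float) -> LabeledVolume:
    """Rectangular box of tissue layers stacked along z.

    Layer 0 occupies the lowest z range. The opposite z faces are the
    intended plate-electrode attachment sites. The grid covers exactly the
    box (no air margin); ``attach_electrodes`` pads with air as needed.
    """
    if len(layer_labels) != n_layers or len(layer_thicknesses_mm) != n_layers:
        raise ValueError("need one label and one thickness per layer")
    th = [float(t) for t in layer_thicknesses_mm]
    if min(th) <= 0:
        raise ValueError("layer thicknesses must be positive")
    wx, wy = (float(c) for c in np.broadcast_to(cross_section_mm, (2,)))
    nx = _n_vox(wx, spacing_mm, "cross-section x")
    ny = _n_vox(wy, spacing_mm, "cross-section y")
    nz_layers = [_n_vox(t, spacing_mm, f"layer {i} thickness")
                 for i, t in enumerate(th)]
    nz = sum(nz_layers)
    labels = np.zeros((nx, ny, nz), dtype=np.int16)
    z0 = 0
    for lab, n in zip(layer_labels, nz_layers):
        labels[:, :, z0:z0 + n] = TISSUE_CODES[lab]
        z0 += n
    # voxel-center affine with the box corner at the world origin
    aff = make_affine(spacing_mm, origin_mm=np.full(3, spacing_mm / 2.0))
    return LabeledVolume(labels, spacing_mm, aff)


def make_layered_sphere_phantom(radii_mm: list, labels: list,
                                spacing_mm: float,
                                air_margin_mm: float | None = None) -> LabeledVolume:
    """Concentric spherical shells labelled outside-in by voxel-center test."""
    radii = [float(r) for r in radii_mm]
    if any(b >= a for a, b in zip(radii, radii[1:])):
        raise ValueError("radii must be strictly decreasing")
    if len(radii) != len(labels):
        raise ValueError("need one label per radius")
    if air_margin_mm is None:
        air_margin_mm = 2.0 * spacing_mm
    if air_margin_mm < 2.0 * spacing_mm:
        raise ValueError("air margin must be at least two voxels")
    half = radii[0] + air_margin_mm
    n = 2 * int(np.ceil(half / spacing_mm))
    aff = make_affine(spacing_mm,
                      origin_mm=np.full(3, -(n / 2.0 - 0.5) * spacing_mm))
    i = np.arange(n)
    c = (i - (n - 1) / 2.0) * spacing_mm
    d = np.sqrt(c[:, None, None] ** 2 + c[None, :, None] ** 2
                + c[None, None, :] ** 2)
    out = np.zeros((n, n, n), dtype=np.int16)
    for r, lab in zip(radii, labels):  # outside-in; inner shells overwrite
        out[d <= r] = TISSUE_CODES[lab]
    # degenerate case: sphere smaller than a voxel still owns its center voxel
    if radii[-1] < spacing_mm and not np.any(d <= radii[-1]):
        ci = np.unravel_index(np.argmin(d), d.shape)
        out[ci] = TISSUE_CODES[labels[-1]]
    return LabeledVolume(out, spacing_mm, aff)


def _tangent_frame(n: np.ndarray):
    ref = np.array([1.0, 0.0, 0.0])
    if abs(n @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(n, ref)
    u /= np.linalg.norm(u)
    v = np.cross(n, u)
    return u, v


def _electrode_voxels(volume: LabeledVolume, e: ElectrodeSpec):
    """Sponge and copper voxel indices for one electrode on ``volume``.

    Air voxels whose center falls inside the pad footprint are classified by
    the distance, along the electrode normal, from their center down to the
    local tissue surface: (0, sponge] -> sponge, (sponge, sponge+copper]
    -> copper. This conforms the pad to the surface column-by-column.
    """
    sp = float(volume.spacing_mm[0])
    n, (u, v) = e.normal, _tangent_frame(e.normal)
    depth = e.sponge_thickness_mm + max(e.copper_thickness_mm, sp)
    air_idx = np.argwhere(volume.labels == AIR)
    if len(air_idx) == 0:
        raise ValueError("phantom has no air voxels to host the electrode")
    p = volume.voxel_centers_world(air_idx) - e.center_world
    a, b, d = p @ u, p @ v, p @ n
    half_w, half_h = e.pad_size_mm[0] / 2.0, e.pad_size_mm[1] / 2.0
    cand = ((np.abs(a) <= half_w + 1e-9) & (np.abs(b) <= half_h + 1e-9)
            & (d > -2.0 * sp) & (d <= depth + 2.0 * sp))
    cand_idx = air_idx[cand]
    if len(cand_idx) == 0:
        raise ValueError(f"electrode {e.name!r} footprint misses the phantom")
    centers = volume.voxel_centers_world(cand_idx)

    # march from each candidate center toward the tissue along -normal;
    # the 0.37 phase keeps samples off exact voxel boundaries
    dt = sp / 8.0
    n_steps = int(np.ceil((depth + 3.0 * sp) / dt))
    t = (np.arange(1, n_steps + 1) + 0.37) * dt
    pts = centers[None, :, :] - t[:, None, None] * n  # (steps, cand, 3)
    vox = np.round(
        volume.world_to_voxel(pts.reshape(-1, 3))).astype(int)
    shape = np.array(volume.shape)
    inside = np.all((vox >= 0) & (vox < shape), axis=1)
    hit = np.zeros(len(vox), dtype=bool)
    vi = vox[inside]
    hit[inside] = volume.labels[vi[:, 0], vi[:, 1], vi[:, 2]] != AIR
    hit = hit.reshape(n_steps, len(cand_idx))
    any_hit = hit.any(axis=0)
    first = np.argmax(hit, axis=0)  # index of first non-air sample
    t_contact = t[first] - dt / 2.0  # distance from center to the surface
    # the copper sheet is voxelized at least one layer thick even when it
    # is thinner than the grid spacing (the Dirichlet plate must exist)
    copper_extent = max(e.copper_thickness_mm, sp)
    sponge_sel = any_hit & (t_contact > 0) & (t_contact <= e.sponge_thickness_mm)
    copper_sel = any_hit & (t_contact > e.sponge_thickness_mm) & \
        (t_contact <= e.sponge_thickness_mm + copper_extent)
    if not copper_sel.any():
        raise ValueError(
            f"electrode {e.name!r} has no copper voxels; footprint does not "
            "project onto the phantom surface"
        )
    if e.sponge_thickness_mm > 0 and not sponge_sel.any():
        raise ValueError(f"electrode {e.name!r} sponge makes no tissue contact")
    return cand_idx[sponge_sel], cand_idx[copper_sel]


def attach_electrodes(volume: LabeledVolume, electrodes: list) -> LabeledVolume:
    """Insert sponge+copper pads flush on the phantom surface.

    The grid is padded with air on all faces (enough to host the thickest
    pad) before marking; only air voxels are overwritten. Electrodes whose
    footprints overlap, or that do not project onto the surface, are
    rejected. The returned volume records each electrode's voxel indices in
    ``electrode_voxels[name] = (sponge_idx, copper_idx)``.
    """
    if not electrodes:
        raise ValueError("no electrodes given")
    names = [e.name for e in electrodes]
    if len(set(names)) != len(names):
        raise ValueError("electrode names must be unique")
    sp = float(volume.spacing_mm[0])
    pad_n = int(np.ceil(max(e.sponge_thickness_mm + e.copper_thickness_mm
                            for e in electrodes) / sp)) + 2
    labels = np.pad(volume.labels, pad_n, constant_values=AIR)
    aff = volume.affine.copy()
    aff[:3, 3] -= aff[:3, :3] @ np.full(3, pad_n)
    padded = LabeledVolume(labels, volume.spacing_mm, aff)

    marked: dict = {}
    claimed = set()
    for e in electrodes:
        sponge_idx, copper_idx = _electrode_voxels(padded, e)
        vox = {tuple(v) for v in np.vstack([sponge_idx, copper_idx])}
        if vox & claimed:
            raise ValueError(f"electrode {e.name!r} overlaps another electrode")
        claimed |= vox
        marked[e.name] = (sponge_idx, copper_idx)
    for name, (sponge_idx, copper_idx) in marked.items():
        if len(sponge_idx):
            padded.labels[tuple(sponge_idx.T)] = SPONGE
        padded.labels[tuple(copper_idx.T)] = COPPER
    padded.electrode_voxels = marked
    return padded


def rotation_to(direction: np.ndarray) -> np.ndarray:
    """Orthonormal basis whose first column is ``direction``."""
    e1 = np.asarray(direction, dtype=float)
    e1 = e1 / np.linalg.norm(e1)
    u, v = _tangent_frame(e1)
    return np.column_stack([e1, u, v])


def make_fiber_tensor_field(volume: LabeledVolume, bundles: list,
                            units: str = "mm^2/s") -> TensorField:
    """Piecewise-constant anisotropic tensor field on the white matter.

    Each bundle is a dict with keys ``principal_direction`` (unit 3-vector),
    ``eigenvalues`` (3 positive reals, descending: the first belongs to the
    fiber direction) and optionally ``predicate`` — a callable mapping world
    points (N, 3) to a boolean selection. A bundle without a predicate claims
    every white-matter voxel not claimed by an earlier bundle. Bundles must
    not overlap and must only select white-matter voxels.
    """
    wm = volume.labels == WHITE_MATTER
    comps = np.zeros(volume.shape + (6,))
    mask = np.zeros(volume.shape, dtype=bool)
    wm_idx = np.argwhere(wm)
    centers = volume.voxel_centers_world(wm_idx) if len(wm_idx) else None
    all_idx = np.argwhere(np.ones(volume.shape, dtype=bool))

    for k, b in enumerate(bundles):
        lam = np.asarray(b["eigenvalues"], dtype=float)
        if np.any(lam <= 0):
            raise ValueError(f"bundle {k}: eigenvalues must be positive (SPD)")
        if np.any(np.diff(lam) > 0):
            raise ValueError(f"bundle {k}: eigenvalues must be sorted descending")
        R = rotation_to(np.asarray(b["principal_direction"], dtype=float))
        tensor = R @ np.diag(lam) @ R.T
        pred = b.get("predicate")
        if pred is None:
            sel_idx = wm_idx[~mask[tuple(wm_idx.T)]]
        else:
            chosen = pred(volume.voxel_centers_world(all_idx))
            sel_idx = all_idx[np.asarray(chosen, dtype=bool)]
            bad = ~wm[tuple(sel_idx.T)]
            if bad.any():
                raise ValueError(
                    f"bundle {k} predicate selects {int(bad.sum())} "
                    "non-white-matter voxels"
                )
            if mask[tuple(sel_idx.T)].any():
                raise ValueError(f"bundle {k} overlaps an earlier bundle")
        if len(sel_idx):
            comps[tuple(sel_idx.T)] = mat_to_six(tensor)
            mask[tuple(sel_idx.T)] = True
    return TensorField(comps, mask, volume.spacing_mm, volume.affine,
                       units=units)


def _as_count_dict(edge_counts, parcel_ids):
    if isinstance(edge_counts, dict):
        out = {}
        for (a, b), c in edge_counts.items():
            if a == b and c:
                raise ValueError("self-connections not allowed")
            key = (min(a, b), max(a, b))
            out[key] = out.get(key, 0) + int(c)
        return out
    m = np.asarray(edge_counts)
    if m.shape != (len(parcel_ids), len(parcel_ids)):
        raise ValueError("edge_counts matrix must match the atlas parcels")
    if not np.array_equal(m, m.T):
        raise ValueError("edge_counts must be symmetric")
    if np.any(np.diag(m) != 0):
        raise ValueError("edge_counts diagonal must be zero")
    out = {}
    for i in range(len(parcel_ids)):
        for j in range(i + 1, len(parcel_ids)):
            if m[i, j]:
                out[(parcel_ids[i], parcel_ids[j])] = int(m[i, j])
    return out


def make_toy_tractogram(atlas: ParcelAtlas, edge_counts, seed: int,
                        n_points: int = 5) -> Tractogram:
    """Streamlines whose endpoint parcels realize ``edge_counts`` exactly.

    ``edge_counts`` is a symmetric nonnegative integer matrix aligned to
    ``atlas.parcel_ids`` (or a {(a, b): count} dict). Endpoints are placed
    strictly inside the named parcels; interior points follow a smooth
    arched curve. Identical seeds give bit-identical geometry.
    """
    rng = np.random.default_rng(seed)
    ids = atlas.parcel_ids
    counts = _as_count_dict(edge_counts, ids)
    vox_by_parcel = {}
    for (a, b), c in sorted(counts.items()):
        for p in (a, b):
            if p not in vox_by_parcel:
                vv = np.argwhere(atlas.label_volume == p)
                if len(vv) == 0:
                    raise ValueError(f"parcel {p} is empty or absent")
                vox_by_parcel[p] = vv
    streamlines = []
    sp = np.abs(np.diag(atlas.affine[:3, :3]))
    for (a, b), c in sorted(counts.items()):
        va, vb = vox_by_parcel[a], vox_by_parcel[b]
        ia = va[rng.integers(0, len(va), size=c)]
        ib = vb[rng.integers(0, len(vb), size=c)]
        # jitter keeps the endpoint strictly inside its voxel, hence parcel
        pa = (ia + rng.uniform(-0.3, 0.3, size=ia.shape)) @ \
            atlas.affine[:3, :3].T + atlas.affine[:3, 3]
        pb = (ib + rng.uniform(-0.3, 0.3, size=ib.shape)) @ \
            atlas.affine[:3, :3].T + atlas.affine[:3, 3]
        arch = rng.normal(0.0, 1.0, size=(c, 3))
        arch = arch / np.maximum(np.linalg.norm(arch, axis=1, keepdims=True),
                                 1e-12) * sp.max()
        s = np.linspace(0.0, 1.0, n_points)
        # quadratic arc from pa to pb bulging along a random direction
        pts = (pa[:, None, :] * (1 - s)[None, :, None]
               + pb[:, None, :] * s[None, :, None]
               + arch[:, None, :] * (s * (1 - s))[None, :, None] * 4.0)
        streamlines.extend(pts.astype(np.float32))
    return Tractogram(streamlines)
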