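"""Anisotropic quasi-static field solver on voxel grids.

Solves div(sigma grad phi) = 0 with Dirichlet potentials on electrode
copper voxels and natural (zero normal current) boundaries against air,
using node-based trilinear hexahedral finite elements with one symmetric
conductivity tensor per voxel. Off-diagonal tensor coupling is handled
naturally by the element stiffness; a two-point finite-volume stencil
could not represent it.

The electric field follows as EF = -grad(phi) and is scaled a posteriori
to a target injected current (the fixed-dose convention: solve at +/-1 V,
rescale to e.g. 0.75 mA).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.linalg import LinearOperator, cg

from .conductivity import ConductivityModel
from .grids import AIR, FieldVolume, LabeledVolume
from .grids import COPPER as _COPPER


@dataclass
class SolveReport:
    iterations: int = 0
    relative_residual: float = np.inf
    converged: bool = False
    electrode_currents_A: dict = field(default_factory=dict)
    anode_current_A: float = 0.0
    cathode_current_A: float = 0.0
    scale_factor: float = 1.0
    residual_history: list = field(default_factory=list)


def _reference_gradients(spacing_mm):
    """Physical shape-function gradients (1/mm) at the 8 Gauss points.

    Returns G of shape (8, 3, 8): Gauss point, spatial axis, corner node.
    Corner c has offsets ((c>>2)&1, (c>>1)&1, c&1) on the unit voxel.
    """
    h = np.asarray(spacing_mm, dtype=float)
    corners = np.array([[(c >> 2) & 1, (c >> 1) & 1, c & 1] for c in range(8)])
    xi_c = 2.0 * corners - 1.0  # (8, 3)
    g = 1.0 / np.sqrt(3.0)
    gauss = xi_c * g  # Gauss points share the corner layout
    G = np.empty((8, 3, 8))
    for gp in range(8):
        x = gauss[gp]
        for c in range(8):
            for a in range(3):
                term = xi_c[c, a] / 2.0
                for b in range(3):
                    if b != a:
                        term *= (1.0 + x[b] * xi_c[c, b]) / 2.0
                G[gp, a, c] = term * (2.0 / h[a])
    return G


def _node_ids(shape):
    nx, ny, nz = shape
    return (ny + 1) * (nz + 1), (nz + 1)


def _element_connectivity(elem_idx: np.ndarray, shape) -> np.ndarray:
    """Global node ids of the 8 corners of each element voxel, (ne, 8)."""
    sx, sy = _node_ids(shape)
    base = elem_idx[:, 0] * sx + elem_idx[:, 1] * sy + elem_idx[:, 2]
    offsets = np.array([((c >> 2) & 1) * sx + ((c >> 1) & 1) * sy + (c & 1)
                        for c in range(8)])
    return base[:, None] + offsets[None, :]


def _assemble(model: ConductivityModel, volume: LabeledVolume):
    """Assemble the FEM stiffness on the conductive voxels.

    Returns (K csr on compact node indexing, node_of_compact, compact_of_node
    dict-array, elem_idx).
    """
    conductive = volume.labels != AIR
    if not conductive.any():
        raise ValueError("volume has no conductive voxels")
    elem_idx = np.argwhere(conductive)
    conn = _element_connectivity(elem_idx, volume.shape)
    used_nodes, compact = np.unique(conn, return_inverse=True)
    conn_c = compact.reshape(conn.shape).astype(np.int32)
    n_nodes = len(used_nodes)

    G = _reference_gradients(volume.spacing_mm)
    vol8 = float(np.prod(volume.spacing_mm)) / 8.0
    tensors = model.voxel_tensors(volume)
    sig = tensors[conductive]  # (ne, 3, 3)

    ne = len(elem_idx)
    chunks = []
    rows_all, cols_all, data_all = [], [], []
    step = 200_000
    for s in range(0, ne, step):
        sl = slice(s, min(s + step, ne))
        Ke = np.einsum("gae,nab,gbf->nef", G, sig[sl], G,
                       optimize=True) * vol8
        cc = conn_c[sl]
        rows_all.append(np.repeat(cc, 8, axis=1).ravel())
        cols_all.append(np.tile(cc, (1, 8)).ravel())
        data_all.append(Ke.ravel())
    rows = np.concatenate(rows_all)
    cols = np.concatenate(cols_all)
    data = np.concatenate(data_all)
    K = coo_matrix((data, (rows, cols)), shape=(n_nodes, n_nodes)).tocsr()
    return K, used_nodes, conn_c, elem_idx


def _check_connectivity(volume: LabeledVolume, electrodes):
    conductive = volume.labels != AIR
    lab, n = ndimage.label(conductive)
    if n != 1:
        raise ValueError(
            f"conductive voxels form {n} disconnected components; "
            "the solver requires a single conductor containing the electrodes"
        )
    for e in electrodes:
        if e.name not in volume.electrode_voxels:
            raise ValueError(f"electrode {e.name!r} not attached to the volume")


def solve_potential(model: ConductivityModel, volume: LabeledVolume,
                    electrodes: list, tol: float = 1e-8,
                    max_iter: int = 10_000) -> tuple:
    """Solve the quasi-static potential with fixed electrode potentials.

    Dirichlet values are imposed on every node of each electrode's copper
    voxels; air (absent from the system) acts as a natural zero-flux
    boundary. Returns a voxel-centered potential FieldVolume (node-grid
    solution attached as ``node_values``) and a SolveReport carrying the
    per-electrode injected currents computed from the discrete reaction
    forces (exactly conservative).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if len(electrodes) < 2:
        raise ValueError("need at least two electrodes")
    _check_connectivity(volume, electrodes)

    K, used_nodes, conn_c, elem_idx = _assemble(model, volume)
    n_nodes = K.shape[0]
    pos_of_node = {int(g): i for i, g in enumerate(used_nodes)}

    fixed_val = np.full(n_nodes, np.nan)
    elec_nodes = {}
    for e in electrodes:
        _, copper_idx = volume.electrode_voxels[e.name]
        if len(copper_idx) == 0:
            raise ValueError(f"electrode {e.name!r} has no copper voxels")
        nodes = np.unique(_element_connectivity(copper_idx, volume.shape))
        comp = np.array([pos_of_node[int(g)] for g in nodes
                         if int(g) in pos_of_node], dtype=np.int64)
        already = ~np.isnan(fixed_val[comp])
        if already.any():
            raise ValueError(f"electrode {e.name!r} shares nodes with another")
        fixed_val[comp] = e.potential_V
        elec_nodes[e.name] = comp
    fixed = ~np.isnan(fixed_val)
    free = ~fixed
    if not free.any():
        raise ValueError("no free nodes: electrodes cover the whole conductor")

    u = np.zeros(n_nodes)
    u[fixed] = fixed_val[fixed]
    Kff = K[free][:, free].tocsr()
    b = -(K[free][:, fixed] @ u[fixed])

    diag = Kff.diagonal()
    if np.any(diag <= 0):
        raise ValueError("non-SPD stiffness diagonal; check conductivities")
    M = LinearOperator(Kff.shape, matvec=lambda x: x / diag)

    history = []
    bnorm = np.linalg.norm(b)

    def cb(xk):
        history.append(float(np.linalg.norm(b - Kff @ xk) / max(bnorm, 1e-300)))

    x, info = cg(Kff, b, rtol=tol, atol=0.0, maxiter=max_iter, M=M,
                 callback=cb)
    rel_res = float(np.linalg.norm(b - Kff @ x) / max(bnorm, 1e-300))
    report = SolveReport(iterations=len(history), relative_residual=rel_res,
                         converged=(info == 0 and rel_res <= 10 * tol),
                         residual_history=history)
    if info != 0:
        raise RuntimeError(
            f"CG failed to converge in {max_iter} iterations "
            f"(relative residual {rel_res:.3e}); history attached"
        )
    u[free] = x

    # injected currents: reaction forces summed over each electrode's nodes
    r = K @ u
    pots = {e.name: e.potential_V for e in electrodes}
    for name, comp in elec_nodes.items():
        report.electrode_currents_A[name] = float(r[comp].sum()) / 1000.0
        # /1000: stiffness is in S*mm (sigma S/m x mm^2/mm); volts stay volts
    anode = max(electrodes, key=lambda e: e.potential_V)
    cathode = min(electrodes, key=lambda e: e.potential_V)
    report.anode_current_A = report.electrode_currents_A[anode.name]
    report.cathode_current_A = report.electrode_currents_A[cathode.name]

    # scatter to the full node grid and average corners to voxel centers
    nshape = tuple(s + 1 for s in volume.shape)
    phi_nodes = np.full(nshape, np.nan)
    phi_nodes.ravel()[used_nodes] = u
    mask = volume.labels != AIR
    pn = np.nan_to_num(phi_nodes, nan=0.0)
    have = ~np.isnan(phi_nodes)
    acc = np.zeros(volume.shape)
    cnt = np.zeros(volume.shape)
    for dx in (0, 1):
        for dy in (0, 1):
            for dz in (0, 1):
                sl = (slice(dx, volume.shape[0] + dx),
                      slice(dy, volume.shape[1] + dy),
                      slice(dz, volume.shape[2] + dz))
                acc += pn[sl]
                cnt += have[sl]
    phi_vox = np.zeros(volume.shape)
    np.divide(acc, cnt, out=phi_vox, where=cnt > 0)
    phi_vox[~mask] = 0.0
    phi = FieldVolume("potential", phi_vox, mask, volume.spacing_mm,
                      volume.affine, node_values=phi_nodes)
    return phi, report


def compute_efield(phi: FieldVolume, volume: LabeledVolume) -> FieldVolume:
    """EF = -grad(phi) in V/m on the conductive voxels.

    Central differences where both neighbours along an axis are inside the
    mask, one-sided at mask boundaries (never differencing across the
    conductor/air interface). Copper voxels — the equipotential Dirichlet
    region — are excluded from the mask, so the gradient is one-sided at
    the electrode surface instead of smearing across it.
    """
    if phi.kind != "potential":
        raise ValueError("compute_efield expects a potential FieldVolume")
    mask = phi.mask & (volume.labels != _COPPER)
    if not mask.any():
        raise ValueError("empty potential mask")
    vals = np.where(mask, phi.values, 0.0)
    E = np.zeros(phi.shape + (3,))
    for a in range(3):
        h_m = phi.spacing_mm[a] / 1000.0  # mm -> m
        up = np.roll(vals, -1, axis=a)
        dn = np.roll(vals, 1, axis=a)
        mup = np.roll(mask, -1, axis=a)
        mdn = np.roll(mask, 1, axis=a)
        # roll wrap-around is invalid at the grid edges
        edge_hi = [slice(None)] * 3
        edge_hi[a] = -1
        edge_lo = [slice(None)] * 3
        edge_lo[a] = 0
        mup[tuple(edge_hi)] = False
        mdn[tuple(edge_lo)] = False
        grad = np.zeros(phi.shape)
        both = mask & mup & mdn
        only_up = mask & mup & ~mdn
        only_dn = mask & ~mup & mdn
        grad[both] = (up[both] - dn[both]) / (2.0 * h_m)
        grad[only_up] = (up[only_up] - vals[only_up]) / h_m
        grad[only_dn] = (vals[only_dn] - dn[only_dn]) / h_m
        E[..., a] = -grad
    if not np.all(np.isfinite(E[mask])):
        raise FloatingPointError("non-finite electric field inside the mask")
    return FieldVolume("efield", E, mask.copy(), phi.spacing_mm, phi.affine)


def electrode_current(phi: FieldVolume, model: ConductivityModel,
                      volume: LabeledVolume, electrode) -> float:
    """Total current (A) leaving one electrode into the tissue.

    Computed as the discrete flux through the electrode boundary: the
    stiffness-times-potential reaction summed over the electrode's fixed
    copper nodes, which in the FEM equals the face-integrated normal
    current sigma grad(phi) . n through any surface separating the
    electrode from the conductor. Positive = current flowing into tissue.
    """
    if phi.node_values is None:
        raise ValueError("potential lacks node values; use solve_potential output")
    if electrode.name not in volume.electrode_voxels:
        raise ValueError(f"electrode {electrode.name!r} not attached")
    sponge_idx, copper_idx = volume.electrode_voxels[electrode.name]
    if len(sponge_idx) == 0 and electrode.sponge_thickness_mm > 0:
        raise ValueError(f"electrode {electrode.name!r} has no tissue contact")
    K, used_nodes, _, _ = _assemble(model, volume)
    u = phi.node_values.ravel()[used_nodes]
    if np.any(np.isnan(u)):
        raise ValueError("potential undefined on part of the conductor")
    r = K @ u
    nodes = np.unique(_element_connectivity(copper_idx, volume.shape))
    pos_of_node = {int(g): i for i, g in enumerate(used_nodes)}
    comp = np.array([pos_of_node[int(g)] for g in nodes], dtype=np.int64)
    return float(r[comp].sum()) / 1000.0


def scale_to_current(ef: FieldVolume, report: SolveReport,
                     target_A: float = 7.5e-4) -> tuple:
    """Rescale the field so the anode injects ``target_A`` amperes.

    Valid by linearity of the Laplace problem. Returns the scaled field and
    an updated report with ``scale_factor`` recorded.
    """
    if ef.kind != "efield":
        raise ValueError("scale_to_current expects an efield FieldVolume")
    if report.anode_current_A == 0:
        raise ValueError("solved anode current is zero; cannot scale")
    s = target_A / report.anode_current_A
    out = ef.copy()
    out.values *= s
    from dataclasses import replace
    new_report = replace(report, scale_factor=report.scale_factor * s)
    new_report.electrode_currents_A = {k: v * s for k, v
                                      in report.electrode_currents_A.items()}
    new_report.anode_current_A = report.anode_current_A * s
    new_report.cathode_current_A = report.cathode_current_A * s
    return out, new_report
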