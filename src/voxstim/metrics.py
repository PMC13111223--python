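"""Electric-field comparison and spread metrics.

Quantifies how the anisotropic (DTI) and isotropic (NoDTI) simulations of
one montage differ: peak field (MaxEF), peak difference (MaxDiff),
relative error (RE), peak angular deviation (MaxAlpha) and the V50/V70/V80
focality measures. Peaks use the 99th percentile to filter spurious voxels
at tissue interfaces; a 2 mm vector block average precedes every metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import GREY_MATTER, WHITE_MATTER, FieldVolume, LabeledVolume


@dataclass
class ROIMask:
    """Named boolean voxel selection aligned to the field grids."""

    name: str
    voxels: np.ndarray
    tissue_scope: str = "white_matter"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=bool)
        if not self.voxels.any():
            raise ValueError(f"ROI {self.name!r} is empty")
        if self.tissue_scope not in ("white_matter", "grey_and_white"):
            raise ValueError(f"unknown tissue scope {self.tissue_scope!r}")


def roi_from_labels(name: str, volume: LabeledVolume,
                    scope: str = "white_matter",
                    within: np.ndarray | None = None) -> ROIMask:
    """ROI of all white-matter (or grey+white) voxels, optionally clipped."""
    if scope == "white_matter":
        m = volume.labels == WHITE_MATTER
    else:
        m = (volume.labels == WHITE_MATTER) | (volume.labels == GREY_MATTER)
    if within is not None:
        m = m & np.asarray(within, dtype=bool)
    return ROIMask(name, m, tissue_scope=scope)


def block_average(ef: FieldVolume, block_mm: float = 2.0) -> FieldVolume:
    """Vector average over non-overlapping cubic blocks aligned to the origin.

    Each block's masked-in voxels are replaced by their component-wise mean
    vector; voxels outside the mask stay masked out. Blocks at the high end
    of a non-divisible axis are simply smaller.
    """
    if ef.kind != "efield":
        raise ValueError("block_average expects an efield volume")
    ratios = block_mm / ef.spacing_mm
    b = np.round(ratios).astype(int)
    if np.any(np.abs(ratios - b) > 1e-9) or np.any(b < 1):
        raise ValueError(
            f"block size {block_mm} mm must be a positive integer multiple "
            f"of the voxel spacing {tuple(ef.spacing_mm)}"
        )
    nx, ny, nz = ef.shape
    bi = np.arange(nx) // b[0]
    bj = np.arange(ny) // b[1]
    bk = np.arange(nz) // b[2]
    nb = (bi[-1] + 1, bj[-1] + 1, bk[-1] + 1)
    bid = (bi[:, None, None] * (nb[1] * nb[2])
           + bj[None, :, None] * nb[2] + bk[None, None, :])
    flat_bid = bid[ef.mask]
    nblocks = nb[0] * nb[1] * nb[2]
    sums = np.zeros((nblocks, 3))
    counts = np.bincount(flat_bid, minlength=nblocks).astype(float)
    for c in range(3):
        sums[:, c] = np.bincount(flat_bid, weights=ef.values[ef.mask][:, c],
                                 minlength=nblocks)
    means = np.divide(sums, counts[:, None],
                      out=np.zeros_like(sums), where=counts[:, None] > 0)
    out = ef.copy()
    out.values = np.zeros_like(ef.values)
    out.values[ef.mask] = means[flat_bid]
    return out


def percentile_peak(values, q: float = 99.0) -> float:
    """q-th percentile with linear interpolation between closest ranks.

    The value at fractional rank 1 + (n - 1) q / 100, interpolated between
    the neighbouring order statistics.
    """
    values = np.asarray(values, dtype=float).ravel()
    if values.size == 0:
        raise ValueError("percentile of an empty set is undefined")
    if not 0 < q <= 100:
        raise ValueError("q must lie in (0, 100]")
    return float(np.percentile(values, q, method="linear"))


def _roi_values(ef: FieldVolume, roi: ROIMask):
    if roi.voxels.shape != ef.shape:
        raise ValueError(
            f"ROI {roi.name!r} shape {roi.voxels.shape} does not match the "
            f"field grid {ef.shape}"
        )
    sel = roi.voxels & ef.mask
    if not sel.any():
        raise ValueError(f"ROI {roi.name!r} has no field voxels")
    return sel


def max_ef(ef: FieldVolume, roi: ROIMask, q: float = 99.0) -> float:
    """Peak (q-th percentile) field magnitude over the ROI, V/m."""
    sel = _roi_values(ef, roi)
    return percentile_peak(ef.magnitude()[sel], q)


def _check_aligned(a: FieldVolume, b: FieldVolume):
    if a.shape != b.shape or not np.allclose(a.affine, b.affine):
        raise ValueError("field grids are not aligned")


def max_diff(ef_a: FieldVolume, ef_b: FieldVolume, roi: ROIMask,
             q: float = 99.0) -> float:
    """Peak voxel-wise |magnitude difference| between two fields, V/m."""
    _check_aligned(ef_a, ef_b)
    sel = _roi_values(ef_a, roi) & ef_b.mask
    d = np.abs(ef_a.magnitude()[sel] - ef_b.magnitude()[sel])
    return percentile_peak(d, q)


def relative_error(ef_nodti: FieldVolume, ef_dti: FieldVolume, roi: ROIMask,
                   variant: str = "as_printed") -> float:
    """Relative difference between the two models' field magnitudes.

    sum_i (|EF_noDTI(i)| - |EF_DTI(i)|)^2 / sum_i |EF_DTI(i)|^2 over the
    ROI; ``variant='root'`` returns the square root (the normalized-RMS
    convention common in the literature).
    """
    if variant not in ("as_printed", "root"):
        raise ValueError(f"unknown RE variant {variant!r}")
    _check_aligned(ef_nodti, ef_dti)
    sel = _roi_values(ef_nodti, roi) & ef_dti.mask
    a = ef_nodti.magnitude()[sel]
    b = ef_dti.magnitude()[sel]
    den = float((b**2).sum())
    if den == 0:
        raise ValueError("reference (DTI) field is zero over the ROI")
    val = float(((a - b) ** 2).sum()) / den
    return float(np.sqrt(val)) if variant == "root" else val


def max_alpha(ef_dti: FieldVolume, ef_nodti: FieldVolume, roi: ROIMask,
              magnitude_floor: float = 1e-6, q: float = 99.0) -> float:
    """Peak (q-th percentile) angle in degrees between the two EF vectors.

    Angles are evaluated only where both magnitudes reach
    ``magnitude_floor`` (arccos is ill-conditioned near zero vectors); the
    cosine is clamped to [-1, 1].
    """
    _check_aligned(ef_dti, ef_nodti)
    sel = _roi_values(ef_dti, roi) & ef_nodti.mask
    a = ef_dti.values[sel]
    b = ef_nodti.values[sel]
    na = np.linalg.norm(a, axis=1)
    nb = np.linalg.norm(b, axis=1)
    ok = (na >= magnitude_floor) & (nb >= magnitude_floor)
    if not ok.any():
        raise ValueError("no voxel passes the magnitude floor")
    cosang = np.clip((a[ok] * b[ok]).sum(axis=1) / (na[ok] * nb[ok]),
                     -1.0, 1.0)
    return percentile_peak(np.degrees(np.arccos(cosang)), q)


def v_spread(ef: FieldVolume, brain_mask: ROIMask, max_ef_value: float,
             fraction: float) -> float:
    """Percentage of brain voxels where |EF| strictly exceeds
    fraction * max_ef_value (the V50/V70/V80 focality measure)."""
    if max_ef_value <= 0:
        raise ValueError("max_ef_value must be positive")
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    if brain_mask.voxels.shape != ef.shape:
        raise ValueError("brain mask grid does not match the field")
    sel = brain_mask.voxels
    if not sel.any():
        raise ValueError("empty brain mask")
    mag = ef.magnitude()[sel]
    return 100.0 * float((mag > fraction * max_ef_value).sum()) / mag.size


V_FRACTIONS = {"V50": 0.5, "V70": 0.7, "V80": 0.8}


def metrics_row(subject_id, roi: ROIMask, ef_nodti: FieldVolume,
                ef_dti: FieldVolume, brain_mask: ROIMask,
                block_mm: float = 2.0, re_variant: str = "as_printed",
                magnitude_floor: float = 1e-6, q: float = 99.0) -> dict:
    """All comparison metrics for one subject and one ROI.

    Block averaging is applied to both fields before any metric. The V
    thresholds use this ROI's white-matter peak while counting over the
    whole grey+white brain mask.
    """
    a = block_average(ef_nodti, block_mm)
    b = block_average(ef_dti, block_mm)
    row = {"subject_id": subject_id, "roi": roi.name}
    row["MaxEF_noDTI"] = max_ef(a, roi, q)
    row["MaxEF_DTI"] = max_ef(b, roi, q)
    row["MaxDiff"] = max_diff(a, b, roi, q)
    row["RE"] = relative_error(a, b, roi, re_variant)
    row["MaxAlpha"] = max_alpha(b, a, roi, magnitude_floor, q)
    for name, frac in V_FRACTIONS.items():
        row[f"{name}_noDTI"] = v_spread(a, brain_mask, row["MaxEF_noDTI"], frac)
        row[f"{name}_DTI"] = v_spread(b, brain_mask, row["MaxEF_DTI"], frac)
    return row


def metrics_table(runs: dict, rois: list, brain_mask: ROIMask,
                  block_mm: float = 2.0, re_variant: str = "as_printed",
                  magnitude_floor: float = 1e-6) -> pd.DataFrame:
    """One row per subject x ROI for a cohort of paired runs.

    ``runs`` maps subject_id -> (ef_nodti, ef_dti); both members of a pair
    must share geometry and current scaling.
    """
    rows = []
    for sid, pair in runs.items():
        if len(pair) != 2 or pair[0] is None or pair[1] is None:
            raise ValueError(f"subject {sid}: need both NoDTI and DTI runs")
        ef_nodti, ef_dti = pair
        for roi in rois:
            rows.append(metrics_row(sid, roi, ef_nodti, ef_dti, brain_mask,
                                    block_mm, re_variant, magnitude_floor))
    return pd.DataFrame(rows)
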