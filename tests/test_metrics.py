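"""Field metrics: block averaging, percentile peaks, RE, angles, V-spread.

Every metric is cross-checked against a naive per-voxel loop implementation
on small random instances.
"""

import numpy as np
import pytest

import voxstim as vx
from voxstim.metrics import ROIMask, V_FRACTIONS

from conftest import random_efield


def _roi_all(shape):
    return ROIMask("all", np.ones(shape, bool))


def _const_field(shape, vec, spacing=1.0):
    vals = np.broadcast_to(np.asarray(vec, float), shape + (3,)).copy()
    return vx.FieldVolume("efield", vals, np.ones(shape, bool),
                          np.full(3, spacing), np.eye(4))


# ---------------------------------------------------------------- oracles

def naive_percentile(values, q):
    """Order statistics with linear interpolation at rank 1+(n-1)q/100."""
    v = sorted(values)
    n = len(v)
    rank = (n - 1) * q / 100.0
    lo = int(np.floor(rank))
    hi = min(lo + 1, n - 1)
    frac = rank - lo
    return v[lo] * (1 - frac) + v[hi] * frac


def naive_relative_error(mag_a, mag_b):
    num = den = 0.0
    for a, b in zip(mag_a, mag_b):
        num += (a - b) ** 2
        den += b * b
    return num / den


def naive_alpha_deg(va, vb):
    out = []
    for a, b in zip(va, vb):
        na = np.sqrt(sum(x * x for x in a))
        nb = np.sqrt(sum(x * x for x in b))
        c = max(-1.0, min(1.0, float(np.dot(a, b)) / (na * nb)))
        out.append(np.degrees(np.arccos(c)))
    return out


def naive_block_average(ef, b):
    out = np.zeros_like(ef.values)
    nx, ny, nz = ef.shape
    for i0 in range(0, nx, b):
        for j0 in range(0, ny, b):
            for k0 in range(0, nz, b):
                sl = (slice(i0, min(i0 + b, nx)), slice(j0, min(j0 + b, ny)),
                      slice(k0, min(k0 + b, nz)))
                m = ef.mask[sl]
                if m.any():
                    out[sl][m] = ef.values[sl][m].mean(axis=0)
    return out


# ----------------------------------------------------------------- tests

class TestBlockAverage:
    def test_constant_field_unchanged(self):
        ef = _const_field((8, 8, 8), (3.0, -1.0, 2.0))
        out = vx.block_average(ef, 2.0)
        np.testing.assert_array_equal(out.values, ef.values)

    def test_opposite_vectors_cancel(self):
        ef = _const_field((2, 2, 2), (0.0, 0.0, 0.0))
        ef.values[0, 0, 0] = (1.0, 0.0, 0.0)
        ef.values[1, 0, 0] = (-1.0, 0.0, 0.0)
        out = vx.block_average(ef, 2.0)
        np.testing.assert_allclose(out.values, 0.0, atol=0.0)

    def test_blocks_share_one_vector(self, rng):
        ef = random_efield(rng, (4, 4, 4), mask_p=1.0)
        out = vx.block_average(ef, 2.0)
        blk = out.values[:2, :2, :2].reshape(-1, 3)
        assert np.allclose(blk, blk[0])
        np.testing.assert_allclose(blk[0],
                                   ef.values[:2, :2, :2].mean(axis=(0, 1, 2)))

    def test_matches_naive_loop_with_partial_mask(self, rng):
        ef = random_efield(rng, (6, 5, 7), mask_p=0.7)
        out = vx.block_average(ef, 2.0)
        np.testing.assert_allclose(out.values, naive_block_average(ef, 2),
                                   atol=1e-12)

    def test_non_multiple_block_rejected(self):
        ef = _const_field((4, 4, 4), (1.0, 0, 0))
        with pytest.raises(ValueError, match="multiple"):
            vx.block_average(ef, 1.5)


class TestPercentilePeak:
    def test_integers_1_to_101_at_q99(self):
        assert vx.percentile_peak(np.arange(1, 102), 99) == 100.0

    def test_constant_values(self):
        assert vx.percentile_peak(np.full(37, 4.2), 50) == 4.2

    def test_q100_is_maximum(self, rng):
        v = rng.random(100)
        assert vx.percentile_peak(v, 100) == v.max()

    @pytest.mark.parametrize("q", [1, 25, 50, 75, 99, 100])
    def test_matches_naive_order_statistics(self, rng, q):
        v = rng.normal(size=257)
        np.testing.assert_allclose(vx.percentile_peak(v, q),
                                   naive_percentile(v, q), rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            vx.percentile_peak([])


class TestMaxEF:
    def test_uniform_field(self):
        ef = _const_field((5, 5, 5), (0, 0, 100.0))
        assert vx.max_ef(ef, _roi_all(ef.shape)) == pytest.approx(100.0)

    def test_outlier_filtered_by_99th_percentile(self):
        shape = (22, 22, 22)  # 10648 voxels
        ef = _const_field(shape, (100.0, 0, 0))
        ef.values[0, 0, 0] = (1e6, 0, 0)
        got = vx.max_ef(ef, _roi_all(shape))
        assert abs(got - 100.0) < 1.0

    def test_single_voxel_roi(self):
        ef = _const_field((3, 3, 3), (0, 30.0, 40.0))
        m = np.zeros(ef.shape, bool)
        m[1, 1, 1] = True
        assert vx.max_ef(ef, ROIMask("one", m)) == pytest.approx(50.0)


class TestMaxDiff:
    def test_identical_fields(self, rng):
        ef = random_efield(rng)
        assert vx.max_diff(ef, ef, _roi_all(ef.shape)) == 0.0

    def test_constant_offset(self, rng):
        ef = _const_field((5, 5, 5), (0, 0, 10.0))
        ef2 = _const_field((5, 5, 5), (0, 0, 15.0))
        assert vx.max_diff(ef, ef2, _roi_all(ef.shape)) == pytest.approx(5.0)

    def test_grid_mismatch_rejected(self, rng):
        a = random_efield(rng, (4, 4, 4))
        b = random_efield(rng, (5, 5, 5))
        with pytest.raises(ValueError, match="aligned"):
            vx.max_diff(a, b, _roi_all((4, 4, 4)))


class TestRelativeError:
    def test_identical_fields_zero_both_variants(self, rng):
        ef = random_efield(rng)
        roi = _roi_all(ef.shape)
        assert vx.relative_error(ef, ef, roi) == 0.0
        assert vx.relative_error(ef, ef, roi, variant="root") == 0.0

    def test_ten_percent_magnitude_offset(self):
        ef_dti = _const_field((5, 5, 5), (0, 0, 100.0))
        ef_no = _const_field((5, 5, 5), (0, 0, 110.0))
        roi = _roi_all(ef_dti.shape)
        assert vx.relative_error(ef_no, ef_dti, roi) == pytest.approx(0.01)
        assert vx.relative_error(ef_no, ef_dti, roi, "root") == \
            pytest.approx(0.1)

    def test_matches_naive_accumulation(self, rng):
        a = random_efield(rng, (5, 5, 4), mask_p=1.0)
        b = random_efield(rng, (5, 5, 4), mask_p=1.0)
        roi = _roi_all(a.shape)
        mag_a = a.magnitude().ravel()
        mag_b = b.magnitude().ravel()
        np.testing.assert_allclose(vx.relative_error(a, b, roi),
                                   naive_relative_error(mag_a, mag_b),
                                   rtol=1e-12)

    def test_zero_reference_rejected(self):
        z = _const_field((3, 3, 3), (0.0, 0.0, 0.0))
        nz = _const_field((3, 3, 3), (1.0, 0.0, 0.0))
        with pytest.raises(ValueError, match="zero"):
            vx.relative_error(nz, z, _roi_all((3, 3, 3)))


class TestMaxAlpha:
    @pytest.mark.parametrize("vec_b,expected", [
        ((0, 0, 2.0), 0.0),          # parallel
        ((3.0, 0, 0), 90.0),         # orthogonal
        ((0, 0, -1.0), 180.0),       # antiparallel
    ])
    def test_constructed_angles(self, vec_b, expected):
        a = _const_field((4, 4, 4), (0, 0, 1.0))
        b = _const_field((4, 4, 4), vec_b)
        got = vx.max_alpha(a, b, _roi_all((4, 4, 4)))
        assert got == pytest.approx(expected, abs=1e-9)

    def test_matches_naive_loop(self, rng):
        a = random_efield(rng, (5, 4, 5), mask_p=1.0)
        b = random_efield(rng, (5, 4, 5), mask_p=1.0)
        roi = _roi_all(a.shape)
        naive = naive_alpha_deg(a.values.reshape(-1, 3),
                                b.values.reshape(-1, 3))
        np.testing.assert_allclose(vx.max_alpha(a, b, roi),
                                   naive_percentile(naive, 99), rtol=1e-10)

    def test_floor_excludes_tiny_vectors(self):
        a = _const_field((3, 3, 3), (0, 0, 1.0))
        b = _const_field((3, 3, 3), (1e-9, 0, 0))
        with pytest.raises(ValueError, match="floor"):
            vx.max_alpha(a, b, _roi_all((3, 3, 3)), magnitude_floor=1e-6)


class TestVSpread:
    def test_linear_ramp_gives_half(self):
        """|EF| ramping 0 -> M: V50 is 50% within one voxel layer."""
        n = 40
        ef = _const_field((4, 4, n), (0, 0, 0.0))
        ramp = np.linspace(0.0, 100.0, n)
        ef.values[..., 2] = np.broadcast_to(ramp, (4, 4, n))
        got = vx.v_spread(ef, _roi_all(ef.shape), 100.0, 0.5)
        assert abs(got - 50.0) <= 100.0 / n + 1e-9

    def test_threshold_is_strict_inequality(self):
        ef = _const_field((4, 4, 4), (0, 0, 50.0))
        assert vx.v_spread(ef, _roi_all(ef.shape), 100.0, 0.5) == 0.0

    def test_nested_superlevel_sets(self, rng):
        ef = random_efield(rng, mask_p=1.0)
        roi = _roi_all(ef.shape)
        m = float(ef.magnitude().max())
        v = {f: vx.v_spread(ef, roi, m, f) for f in (0.5, 0.7, 0.8)}
        assert v[0.8] <= v[0.7] <= v[0.5]


class TestInvariances:
    def test_re_and_alpha_invariant_to_common_rescaling(self, rng):
        a = random_efield(rng, mask_p=1.0)
        b = random_efield(rng, mask_p=1.0)
        roi = _roi_all(a.shape)
        s = 3.7
        a2, b2 = a.copy(), b.copy()
        a2.values *= s
        b2.values *= s
        np.testing.assert_allclose(vx.relative_error(a2, b2, roi),
                                   vx.relative_error(a, b, roi), rtol=1e-12)
        np.testing.assert_allclose(vx.max_alpha(a2, b2, roi),
                                   vx.max_alpha(a, b, roi), rtol=1e-12)

    def test_v_spread_invariant_when_threshold_rescaled(self, rng):
        ef = random_efield(rng, mask_p=1.0)
        roi = _roi_all(ef.shape)
        m = float(ef.magnitude().max())
        v1 = vx.v_spread(ef, roi, m, 0.5)
        ef2 = ef.copy()
        ef2.values *= 2.5
        v2 = vx.v_spread(ef2, roi, 2.5 * m, 0.5)
        assert v1 == v2

    def test_metrics_are_permutation_invariant(self, rng):
        """Scalar metrics depend only on the (paired) voxel multiset."""
        a = random_efield(rng, (4, 4, 4), mask_p=1.0)
        b = random_efield(rng, (4, 4, 4), mask_p=1.0)
        roi = _roi_all(a.shape)
        perm = rng.permutation(64)
        ap, bp = a.copy(), b.copy()
        ap.values = a.values.reshape(64, 3)[perm].reshape(a.values.shape)
        bp.values = b.values.reshape(64, 3)[perm].reshape(b.values.shape)
        np.testing.assert_allclose(vx.max_ef(ap, roi), vx.max_ef(a, roi))
        np.testing.assert_allclose(vx.max_diff(ap, bp, roi),
                                   vx.max_diff(a, b, roi))
        np.testing.assert_allclose(vx.relative_error(ap, bp, roi),
                                   vx.relative_error(a, b, roi))
        np.testing.assert_allclose(vx.max_alpha(ap, bp, roi),
                                   vx.max_alpha(a, b, roi))


class TestMetricsTable:
    def test_self_comparison_row(self, rng):
        ef = random_efield(rng, (8, 8, 8), mask_p=1.0)
        roi = _roi_all(ef.shape)
        row = vx.metrics_row("s0", roi, ef, ef, roi)
        assert row["MaxDiff"] == 0.0
        assert row["RE"] == 0.0
        assert row["MaxAlpha"] == pytest.approx(0.0, abs=1e-5)
        for name in V_FRACTIONS:
            assert row[f"{name}_noDTI"] == row[f"{name}_DTI"]

    def test_row_count_is_subjects_times_rois(self, rng):
        ef = random_efield(rng, (8, 8, 8), mask_p=1.0)
        roi_a = _roi_all(ef.shape)
        m = np.zeros(ef.shape, bool)
        m[:4] = True
        roi_b = ROIMask("half", m)
        runs = {f"s{i}": (ef, ef) for i in range(3)}
        tab = vx.metrics_table(runs, [roi_a, roi_b], roi_a)
        assert len(tab) == 3 * 2

    def test_missing_run_rejected(self, rng):
        ef = random_efield(rng, (8, 8, 8), mask_p=1.0)
        roi = _roi_all(ef.shape)
        with pytest.raises(ValueError, match="both"):
            vx.metrics_table({"s0": (ef, None)}, [roi], roi)
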