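"""Feature channels: downsampling, polar decomposition, Jacobian, assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dbmorph.core import DeformationField
from dbmorph.features import (
    FeatureMatrix,
    build_feature_matrix,
    downsample_field,
    field_to_polar,
    jacobian_determinant,
)


def const_field(rows, cols, vec, cell=1.0):
    u = np.zeros((rows, cols, 2))
    u[..., 0], u[..., 1] = vec
    return DeformationField(u, cell)


class TestDownsample:
    def test_constant_field_stays_constant(self):
        f = const_field(12, 12, (0.7, -0.3))
        for cell in (2, 3, 3.75, 5):
            c = downsample_field(f, cell)
            assert np.allclose(c.u[..., 0], 0.7)
            assert np.allclose(c.u[..., 1], -0.3)
            assert c.cell_size == cell

    def test_hand_computed_block_means(self):
        u = np.zeros((6, 6, 2))
        u[:, :3] = (1.0, 0.0)
        u[:, 3:] = (0.0, 1.0)
        c = downsample_field(DeformationField(u), 3)
        assert c.grid_shape == (2, 2)
        assert np.allclose(c.u[:, 0], (1.0, 0.0))
        assert np.allclose(c.u[:, 1], (0.0, 1.0))

    def test_cell_one_is_identity(self, smooth_field):
        c = downsample_field(smooth_field, 1)
        assert np.array_equal(c.u, smooth_field.u)

    def test_cell_below_one_rejected(self, smooth_field):
        with pytest.raises(ValueError):
            downsample_field(smooth_field, 0.5)

    def test_mean_conserved_exact_division(self, smooth_field):
        c = downsample_field(smooth_field, 2)  # 40 divisible by 2
        assert np.allclose(c.u.mean(axis=(0, 1)),
                           smooth_field.u.mean(axis=(0, 1)), atol=1e-9)

    @pytest.mark.parametrize("cell", [3, 3.75, 5])
    def test_area_weighted_mean_conserved(self, smooth_field, cell):
        """Area weighting is exact also for ragged/fractional cells."""
        c = downsample_field(smooth_field, cell)
        rows, cols = smooth_field.grid_shape
        # per-axis coverage of each coarse cell, computed independently
        def coverage(n, s):
            edges = np.arange(int(np.ceil(n / s)) + 1) * s
            return np.minimum(edges[1:], n) - edges[:-1]

        w = np.outer(coverage(rows, cell), coverage(cols, cell))
        weighted = (c.u * w[..., None]).sum(axis=(0, 1)) / w.sum()
        assert np.allclose(weighted, smooth_field.u.mean(axis=(0, 1)),
                           atol=1e-9)


class TestPolar:
    def test_pythagorean_vector(self):
        f = const_field(3, 3, (3.0, 4.0))
        p = field_to_polar(f)
        assert np.allclose(p.magnitude, 5.0)
        assert np.allclose(p.direction, np.arctan2(3.0, 4.0))

    def test_zero_vector_convention(self):
        p = field_to_polar(const_field(3, 3, (0.0, 0.0)))
        assert np.all(p.magnitude == 0.0)
        assert np.all(p.direction == 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(-10, 10), st.floats(-10, 10))
    def test_round_trip(self, ur, uc):
        p = field_to_polar(const_field(2, 2, (ur, uc)))
        back_r = p.magnitude * np.sin(p.direction)
        back_c = p.magnitude * np.cos(p.direction)
        assert np.allclose(back_r, ur, atol=1e-12)
        assert np.allclose(back_c, uc, atol=1e-12)


class TestJacobian:
    def test_zero_field_gives_unit_determinant(self):
        j = jacobian_determinant(const_field(5, 5, (0.0, 0.0)))
        assert np.allclose(j.detJ, 1.0)

    def test_uniform_expansion(self):
        rr, cc = np.mgrid[0:10, 0:10].astype(float)
        u = np.stack([0.1 * rr, 0.1 * cc], axis=-1)
        j = jacobian_determinant(DeformationField(u))
        assert np.allclose(j.detJ, 1.21, atol=1e-9)

    def test_uniform_shrinkage(self):
        rr, cc = np.mgrid[0:10, 0:10].astype(float)
        u = np.stack([-0.5 * rr, np.zeros_like(cc)], axis=-1)
        j = jacobian_determinant(DeformationField(u))
        assert np.allclose(j.detJ, 0.5, atol=1e-9)

    def test_affine_fields_match_det(self, rng):
        """For u(x) = (A - I)x the interior detJ equals det(A)."""
        rr, cc = np.mgrid[0:12, 0:12].astype(float)
        for _ in range(20):
            A = np.eye(2) + rng.uniform(-0.3, 0.3, size=(2, 2))
            u = np.stack([(A[0, 0] - 1) * rr + A[0, 1] * cc,
                          A[1, 0] * rr + (A[1, 1] - 1) * cc], axis=-1)
            j = jacobian_determinant(DeformationField(u))
            interior = j.detJ[1:-1, 1:-1]
            assert np.allclose(interior, np.linalg.det(A), atol=1e-6)

    def test_spacing_scales_gradient(self):
        rr, cc = np.mgrid[0:10, 0:10].astype(float)
        u = np.stack([0.3 * rr, np.zeros_like(cc)], axis=-1)
        j3 = jacobian_determinant(DeformationField(3 * u, cell_size=3.0))
        j1 = jacobian_determinant(DeformationField(u, cell_size=1.0))
        assert np.allclose(j3.detJ, j1.detJ)

    def test_small_grid_rejected(self):
        with pytest.raises(ValueError):
            jacobian_determinant(const_field(2, 5, (0.0, 0.0)))


class TestFeatureMatrix:
    def _fields(self, rng, n=10, shape=(12, 12)):
        labels = np.array(["control", "diseased"] * (n // 2))
        return [DeformationField(rng.normal(size=shape + (2,)))
                for _ in range(n)], labels

    def test_column_counts_raw_angle(self, rng):
        fields, labels = self._fields(rng)
        mats = build_feature_matrix(fields, labels, [3],
                                    channels=("magnitude", "direction"),
                                    direction_encoding="angle")
        assert mats[3].values.shape == (10, 32)  # 4x4 cells x 2 channels

    def test_column_counts_with_jacobian(self, rng):
        fields, labels = self._fields(rng)
        base = build_feature_matrix(fields, labels, [3],
                                    channels=("magnitude",),
                                    direction_encoding="angle")[3]
        extra = build_feature_matrix(fields, labels, [3],
                                     channels=("magnitude", "jacobian"),
                                     direction_encoding="angle")[3]
        assert extra.n_features == base.n_features + 16

    def test_descriptor_ordering_contract(self, rng):
        fields, labels = self._fields(rng)
        mat = build_feature_matrix(fields, labels, [3],
                                   channels=("magnitude", "direction"),
                                   direction_encoding="angle")[3]
        d0 = mat.descriptors[0]
        assert (d0.grid_row, d0.grid_col, d0.channel, d0.cell_size) == \
            (0, 0, "magnitude", 3.0)
        d1 = mat.descriptors[1]
        assert d1.channel == "direction" and (d1.grid_row, d1.grid_col) == (0, 0)

    def test_sincos_encoding_doubles_direction(self, rng):
        fields, labels = self._fields(rng)
        mat = build_feature_matrix(fields, labels, [3],
                                   channels=("magnitude", "direction"),
                                   direction_encoding="sincos")[3]
        assert mat.n_features == 48  # 16 cells x (mag, sin, cos)

    def test_inconsistent_grids_rejected(self, rng):
        fields = [DeformationField(rng.normal(size=(12, 12, 2))),
                  DeformationField(rng.normal(size=(10, 12, 2)))]
        with pytest.raises(ValueError):
            build_feature_matrix(fields, ["a", "b"], [3])

    def test_csv_round_trip(self, rng, tmp_path):
        fields, labels = self._fields(rng, n=4)
        mat = build_feature_matrix(fields, labels, [3.75])[3.75]
        mat.to_csv(tmp_path / "m.csv")
        back = FeatureMatrix.from_csv(tmp_path / "m.csv")
        assert np.allclose(back.values, mat.values, rtol=0, atol=0)
        assert back.descriptors == mat.descriptors
        assert list(back.labels) == list(mat.labels)
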