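"""Haar transform and anisotropic-wavelet feature correctness.

Oracles: an explicit orthonormal Haar basis matrix built by Kronecker
products (independent of the transform code path), the literal
triple-sum evaluation of the feature definition, and PyWavelets as an
external cross-check.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import imagechain as ic
from imagechain.errors import ArgumentError
from imagechain.volume import ImageVolume, Coordinate, PatchGeometry
from imagechain.wavelets import (collapse_z, flatten_coefficients,
                                 gaussian_z_weights, haar_decompose,
                                 haar_dwt_2d, padded_area)


def haar_matrix_1d(n):
    """Orthonormal single-level 1D Haar analysis matrix (n even):
    first n/2 rows average pairs, last n/2 rows difference pairs."""
    h = np.zeros((n, n))
    for i in range(n // 2):
        h[i, 2 * i] = h[i, 2 * i + 1] = 1 / np.sqrt(2)
        h[n // 2 + i, 2 * i] = 1 / np.sqrt(2)
        h[n // 2 + i, 2 * i + 1] = -1 / np.sqrt(2)
    return h


def haar_oracle(plane, levels):
    """(LL, details coarsest-first) via explicit matrix multiplication."""
    ll = np.asarray(plane, dtype=float)
    details = []
    for _ in range(levels):
        hy = haar_matrix_1d(ll.shape[0])
        hx = haar_matrix_1d(ll.shape[1])
        t = hy @ ll @ hx.T
        my, mx = ll.shape[0] // 2, ll.shape[1] // 2
        ll = t[:my, :mx]
        details.append((t[my:, :mx], t[:my, mx:], t[my:, mx:]))
    details.reverse()
    return ll, details


class TestHaarDwt2d:
    def test_constant_image_has_zero_detail(self):
        out = haar_dwt_2d(np.ones((2, 2)), levels=1)
        assert out[0, 1] == out[1, 0] == out[1, 1] == 0

    def test_orthonormal_ll_of_constant_2x2_is_2(self):
        # (1+1+1+1)/2 under 1/sqrt(2) filters applied in x then y
        assert haar_dwt_2d(np.ones((2, 2)), levels=1)[0, 0] == \
            pytest.approx(2.0)

    @pytest.mark.parametrize("shape,levels", [((4, 4), 1), ((4, 4), 2),
                                              ((8, 8), 2), ((8, 8), 3),
                                              ((8, 4), 2)])
    def test_matches_explicit_basis_matrix_oracle(self, rng, shape, levels):
        plane = rng.uniform(0, 10, shape)
        ll, details = haar_decompose(plane, levels)
        oll, odetails = haar_oracle(plane, levels)
        np.testing.assert_allclose(ll, oll, atol=1e-9)
        for (a, b, c), (oa, ob, oc) in zip(details, odetails):
            np.testing.assert_allclose(a, oa, atol=1e-9)
            np.testing.assert_allclose(b, ob, atol=1e-9)
            np.testing.assert_allclose(c, oc, atol=1e-9)

    def test_matches_pywavelets_cross_check(self, rng):
        pywt = pytest.importorskip("pywt")
        plane = rng.uniform(0, 5, (8, 8))
        ll, details = haar_decompose(plane, 2)
        coeffs = pywt.wavedec2(plane, "haar", level=2)
        np.testing.assert_allclose(ll, coeffs[0], atol=1e-9)
        # sign conventions differ for the high-pass filter; compare
        # magnitudes per subband
        for (lh, hl, hh), (ch, cv, cd) in zip(details, coeffs[1:]):
            np.testing.assert_allclose(np.abs(lh), np.abs(ch), atol=1e-9)
            np.testing.assert_allclose(np.abs(hl), np.abs(cv), atol=1e-9)
            np.testing.assert_allclose(np.abs(hh), np.abs(cd), atol=1e-9)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.integers(0, 2 ** 31 - 1), st.sampled_from([4, 8, 16]),
           st.integers(1, 2))
    def test_energy_conservation_power_of_two(self, seed, n, levels):
        plane = np.random.default_rng(seed).uniform(-3, 3, (n, n))
        out = haar_dwt_2d(plane, levels)
        assert np.sum(out ** 2) == pytest.approx(np.sum(plane ** 2),
                                                 rel=1e-9)

    def test_linearity_of_raw_coefficients(self, rng):
        x = rng.uniform(0, 1, (8, 8))
        y = rng.uniform(0, 1, (8, 8))
        a, b = 2.5, -1.25
        np.testing.assert_allclose(
            haar_dwt_2d(a * x + b * y, 2),
            a * haar_dwt_2d(x, 2) + b * haar_dwt_2d(y, 2), atol=1e-9)

    def test_excessive_levels_rejected(self):
        with pytest.raises(ArgumentError):
            haar_dwt_2d(np.ones((4, 4)), levels=5)

    def test_odd_sides_edge_padded_to_even(self, rng):
        plane = rng.uniform(0, 1, (7, 7))
        padded = np.pad(plane, ((0, 1), (0, 1)), mode="edge")
        np.testing.assert_allclose(haar_dwt_2d(plane, 2),
                                   haar_dwt_2d(padded, 2), atol=1e-12)


class TestAnisoWavelet3d:
    def geometry(self):
        return PatchGeometry(3, 3, 1)

    def test_rz0_degenerates_to_2d_path(self, rng):
        vol = ImageVolume(rng.uniform(0, 10, (3, 9, 9)))
        center = Coordinate(4, 4, 1)
        geom = PatchGeometry(3, 3, 0)
        values, _ = ic.features_aniso_wavelet_3d(vol, center, geom,
                                                 ic.WaveletSpec(2))
        patch2d = vol.data[1, 1:8, 1:8]
        ll, details = haar_decompose(patch2d, 2)
        expected, _ = flatten_coefficients(ll, details)
        np.testing.assert_allclose(values, expected, atol=1e-12)

    def test_constant_volume_has_zero_details(self):
        vol = ImageVolume(np.full((3, 9, 9), 4.0))
        values, tags = ic.features_aniso_wavelet_3d(
            vol, Coordinate(4, 4, 1), self.geometry())
        detail = [v for v, t in zip(values, tags) if "LL" not in t]
        np.testing.assert_allclose(detail, 0, atol=1e-9)

    def test_matches_literal_triple_sum_oracle(self, rng):
        """Evaluate the defining equation with loops: for each (k, n)
        basis function psi, f = sum_z w(z) sum_y sum_x psi(x, y) I(x,y,z)."""
        vol = ImageVolume(rng.uniform(0, 10, (3, 7, 7)))
        center = Coordinate(3, 3, 1)
        geom = PatchGeometry(3, 3, 1)
        w = gaussian_z_weights(1)
        values, _ = ic.features_aniso_wavelet_3d(vol, center, geom,
                                                 ic.WaveletSpec(2), w)
        # evaluate the weighted z-sum by explicit loops, then apply the
        # basis-matrix oracle on the edge-padded even support
        plane = np.zeros((7, 7))
        for zi in range(3):
            for yi in range(7):
                for xi in range(7):
                    plane[yi, xi] += w.weights[zi] * vol.data[zi, yi, xi]
        padded = np.pad(plane, ((0, 1), (0, 1)), mode="edge")
        oll, odetails = haar_oracle(padded, 2)
        expected, _ = flatten_coefficients(oll, odetails)
        np.testing.assert_allclose(values, expected, atol=1e-9)

    def test_per_slice_transform_then_sum_is_identical(self, rng):
        """The equation admits two readings (collapse-then-transform vs
        transform-per-slice-then-weighted-sum); linearity makes them equal."""
        vol = ImageVolume(rng.uniform(0, 10, (3, 7, 7)))
        geom = PatchGeometry(3, 3, 1)
        w = gaussian_z_weights(1)
        values, _ = ic.features_aniso_wavelet_3d(
            vol, Coordinate(3, 3, 1), geom, ic.WaveletSpec(2), w)
        acc = None
        for zi in range(3):
            ll, details = haar_decompose(vol.data[zi], 2)
            flat, _ = flatten_coefficients(ll, details)
            acc = w.weights[zi] * flat if acc is None \
                else acc + w.weights[zi] * flat
        np.testing.assert_allclose(values, acc, atol=1e-9)

    @pytest.mark.parametrize("rz", [0, 1, 2])
    def test_length_is_padded_patch_area_independent_of_rz(self, rng, rz):
        vol = ImageVolume(rng.uniform(0, 1, (5, 15, 15)))
        geom = PatchGeometry(3, 3, rz)
        values, _ = ic.features_aniso_wavelet_3d(
            vol, Coordinate(7, 7, 2), geom, ic.WaveletSpec(2))
        assert len(values) == 64 == padded_area((7, 7), 2)

    def test_z_constant_volume_invariant_to_rz(self):
        plane = np.random.default_rng(3).uniform(0, 5, (11, 11))
        vol = ImageVolume(np.broadcast_to(plane, (5, 11, 11)).copy())
        res = {}
        for rz in (0, 1, 2):
            res[rz], _ = ic.features_aniso_wavelet_3d(
                vol, Coordinate(5, 5, 2), PatchGeometry(3, 3, rz),
                ic.WaveletSpec(2))
        np.testing.assert_allclose(res[0], res[1], atol=1e-9)
        np.testing.assert_allclose(res[0], res[2], atol=1e-9)

    def test_z_weights_normalised_and_peaked(self):
        w = gaussian_z_weights(2)
        assert np.sum(w.weights) == pytest.approx(1.0)
        assert w.weights[2] == max(w.weights)
        np.testing.assert_allclose(w.weights, w.weights[::-1])


class TestHaar2dFeatures:
    def test_constant_image_subband_stats_details_zero(self):
        vol = ImageVolume(np.full((16, 16), 3.0))
        values, tags = ic.features_haar_2d(vol, ic.WaveletSpec(2),
                                           pooling="subband-stats")
        detail = [v for v, t in zip(values, tags) if "LL" not in t]
        np.testing.assert_allclose(detail, 0, atol=1e-12)

    def test_subband_stats_length_formula(self, rng):
        vol = ImageVolume(rng.uniform(0, 1, (16, 16)))
        values, _ = ic.features_haar_2d(vol, ic.WaveletSpec(2),
                                        pooling="subband-stats")
        assert len(values) == 14  # 2 * (3 * levels + 1)

    def test_raw_roi_matches_flattened_dwt(self, rng):
        patch = rng.uniform(0, 1, (8, 8))
        values, _ = ic.features_haar_2d(ImageVolume(patch),
                                        ic.WaveletSpec(2), pooling="raw-roi")
        assert len(values) == 64
        ll, details = haar_decompose(patch, 2)
        expected, _ = flatten_coefficients(ll, details)
        np.testing.assert_allclose(values, expected)
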