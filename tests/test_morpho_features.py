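"""Feature-extraction contracts, with independent brute-force oracles for the
Zernike and Haralick families."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from morphodyn.morpho_features import (
    GLCM_ANGLES,
    GLCM_DISTANCES,
    HARALICK_STATS,
    ZERNIKE_ORDERS,
    extract_table,
    feature_manifest,
    features_for,
    glcm,
    haralick_features,
    haralick_stats,
    intensity_features,
    quantize,
    shape_features,
    zernike_features,
)

from conftest import disk_mask


# ---------------------------------------------------------------------------
# oracles (independent, naive implementations)


def zernike_oracle(mask):
    """Per-pixel double sum evaluating each Zernike polynomial explicitly."""
    coords = np.argwhere(mask).astype(float)
    cy, cx = coords.mean(axis=0)
    radius = max(math.hypot(y - cy, x - cx) for y, x in coords) or 1.0
    out = []
    for n, m in ZERNIKE_ORDERS:
        z = 0j
        for y, x in coords:
            rho = math.hypot(y - cy, x - cx) / radius
            if rho > 1.0:
                continue
            theta = math.atan2(y - cy, x - cx)
            r_nm = 0.0
            for s in range((n - m) // 2 + 1):
                r_nm += (
                    (-1) ** s
                    * math.factorial(n - s)
                    / (
                        math.factorial(s)
                        * math.factorial((n + m) // 2 - s)
                        * math.factorial((n - m) // 2 - s)
                    )
                    * rho ** (n - 2 * s)
                )
            z += r_nm * complex(math.cos(m * theta), -math.sin(m * theta))
        out.append(abs((n + 1) / math.pi * z / radius**2))
    return np.array(out)


def glcm_oracle(q, mask, distance, angle, levels=8):
    """Pair enumeration by explicit double loop, symmetrized and normalized."""
    offsets = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}
    dr, dc = offsets[angle]
    dr, dc = dr * distance, dc * distance
    H, W = mask.shape
    P = np.zeros((levels, levels))
    for r in range(H):
        for c in range(W):
            r2, c2 = r + dr, c + dc
            if 0 <= r2 < H and 0 <= c2 < W and mask[r, c] and mask[r2, c2]:
                P[q[r, c], q[r2, c2]] += 1
                P[q[r2, c2], q[r, c]] += 1
    if P.sum():
        P /= P.sum()
    return P


def haralick_oracle_stats(P):
    """All 13 statistics via direct naive loops over the matrix."""
    L = P.shape[0]
    px = P.sum(axis=1)
    mu = sum(i * px[i] for i in range(L))
    var = sum((i - mu) ** 2 * px[i] for i in range(L))
    sd = math.sqrt(var)

    asm = sum(P[i, j] ** 2 for i in range(L) for j in range(L))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(L) for j in range(L))
    corr = (
        sum((i - mu) * (j - mu) * P[i, j] for i in range(L) for j in range(L)) / var
        if sd > 0
        else 0.0
    )
    variance = sum((i - mu) ** 2 * P[i, j] for i in range(L) for j in range(L))
    idm = sum(P[i, j] / (1 + (i - j) ** 2) for i in range(L) for j in range(L))
    psum = np.zeros(2 * L - 1)
    pdiff = np.zeros(L)
    for i in range(L):
        for j in range(L):
            psum[i + j] += P[i, j]
            pdiff[abs(i - j)] += P[i, j]
    savg = sum(k * psum[k] for k in range(2 * L - 1))
    sent = -sum(p * math.log(p) for p in psum if p > 0)
    svar = sum((k - savg) ** 2 * psum[k] for k in range(2 * L - 1))
    ent = -sum(p * math.log(p) for p in P.ravel() if p > 0)
    dmean = sum(k * pdiff[k] for k in range(L))
    dvar = sum((k - dmean) ** 2 * pdiff[k] for k in range(L))
    dent = -sum(p * math.log(p) for p in pdiff if p > 0)
    hx = -sum(p * math.log(p) for p in px if p > 0)
    hxy1 = -sum(
        P[i, j] * math.log(px[i] * px[j])
        for i in range(L)
        for j in range(L)
        if P[i, j] > 0 and px[i] * px[j] > 0
    )
    hxy2 = -sum(
        px[i] * px[j] * math.log(px[i] * px[j])
        for i in range(L)
        for j in range(L)
        if px[i] * px[j] > 0
    )
    imc1 = (ent - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - ent))))
    return np.array(
        [asm, contrast, corr, variance, idm, savg, svar, sent, ent, dvar, dent,
         imc1, imc2]
    )


def random_blob(rng, size=21):
    """A random connected-ish blob mask: union of a few disks."""
    mask = np.zeros((size, size), bool)
    yy, xx = np.mgrid[:size, :size]
    for _ in range(rng.integers(1, 4)):
        cy, cx = rng.integers(6, size - 6, 2)
        r = rng.integers(3, 6)
        mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
    return mask


# ---------------------------------------------------------------------------
# manifest


def test_manifest_is_fixed_169_with_group_sizes():
    m = feature_manifest()
    assert len(m) == 169
    assert len(set(m.names)) == 169
    sizes = {g: len(ns) for g, ns in m.groups.items()}
    assert sizes == {"shape": 26, "zernike": 30, "haralick": 104, "intensity": 9}
    assert sum(sizes.values()) == 169


# ---------------------------------------------------------------------------
# shape


class TestShape:
    def test_disk_form_factor_near_one(self):
        vals = dict(zip(feature_manifest().groups["shape"], shape_features(disk_mask(20))))
        assert 0.95 <= vals["form_factor"] <= 1.05
        assert vals["eccentricity"] < 0.2
        assert vals["euler_number"] == 1

    def test_extent_in_unit_interval(self, rng):
        for _ in range(10):
            mask = random_blob(rng)
            if not mask.any():
                continue
            vals = dict(zip(feature_manifest().groups["shape"], shape_features(mask)))
            assert 0.0 < vals["extent"] <= 1.0
            assert 0.0 < vals["solidity"] <= 1.0

    def test_square_is_symmetric(self):
        mask = np.zeros((30, 30), bool)
        mask[5:25, 5:25] = True
        vals = dict(zip(feature_manifest().groups["shape"], shape_features(mask)))
        assert vals["eccentricity"] == pytest.approx(0.0, abs=1e-9)
        assert vals["aspect_ratio"] == pytest.approx(1.0, abs=1e-9)
        assert vals["centroid_displacement"] == pytest.approx(0.0, abs=1e-9)

    def test_pixel_size_scales_lengths_and_areas(self):
        mask = disk_mask(12)
        v1 = shape_features(mask, pixel_size=1.0)
        v2 = shape_features(mask, pixel_size=0.5)
        names = feature_manifest().groups["shape"]
        d1, d2 = dict(zip(names, v1)), dict(zip(names, v2))
        assert d2["area"] == pytest.approx(d1["area"] / 4)
        assert d2["perimeter"] == pytest.approx(d1["perimeter"] / 2)
        assert d2["form_factor"] == pytest.approx(d1["form_factor"])

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            shape_features(np.zeros((5, 5), bool))


# ---------------------------------------------------------------------------
# Zernike


class TestZernike:
    def test_centered_disk_has_zero_nonaxial_moments(self):
        """A rasterized disk has the dihedral symmetry of the pixel lattice:
        every m not divisible by 4 vanishes exactly; m in {4, 8} carry only a
        small lattice-anisotropy residual."""
        vals = dict(zip(feature_manifest().groups["zernike"], zernike_features(disk_mask(15))))
        for (n, m), name in zip(ZERNIKE_ORDERS, feature_manifest().groups["zernike"]):
            if m == 0:
                continue
            if m % 4 == 0:
                assert vals[name] <= 0.15, (n, m)
            else:
                assert vals[name] <= 1e-10, (n, m)

    def test_matches_brute_force_oracle_on_small_mask(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 3:8] = True
        mask[1, 4] = True
        mask[6, 1] = True
        np.testing.assert_allclose(zernike_features(mask), zernike_oracle(mask), atol=1e-10)

    def test_rotation_by_90_degrees_preserves_magnitudes(self, rng):
        for _ in range(5):
            mask = random_blob(rng)
            a = zernike_features(mask)
            b = zernike_features(np.rot90(mask))
            scale = np.maximum(np.abs(a), 1e-3)
            assert np.max(np.abs(a - b) / scale) <= 0.02

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            zernike_features(np.zeros((5, 5), bool))


# ---------------------------------------------------------------------------
# Haralick


class TestHaralick:
    def test_constant_region_is_degenerate_texture(self):
        mask = disk_mask(8)
        crop = np.full(mask.shape, 7.0)
        vals = haralick_features(crop, mask)
        names = feature_manifest().groups["haralick"]
        d = dict(zip(names, vals))
        for dist in GLCM_DISTANCES:
            for ang in GLCM_ANGLES:
                assert d[f"haralick_d{dist}_a{ang}_contrast"] == 0.0
                assert d[f"haralick_d{dist}_a{ang}_asm"] == pytest.approx(1.0)
                assert d[f"haralick_d{dist}_a{ang}_entropy"] == 0.0
                assert d[f"haralick_d{dist}_a{ang}_correlation"] == 0.0

    def test_two_level_pattern_matches_pair_enumeration_oracle(self):
        crop = np.array(
            [[0, 1, 0, 1], [1, 0, 1, 0], [0, 0, 1, 1], [1, 1, 0, 0]], float
        )
        mask = np.ones((4, 4), bool)
        mask[0, 0] = False
        q = quantize(crop, mask)
        for dist in GLCM_DISTANCES:
            for ang in GLCM_ANGLES:
                P, npairs = glcm(q, mask, dist, ang)
                P_oracle = glcm_oracle(q, mask, dist, ang)
                np.testing.assert_allclose(P, P_oracle, atol=1e-12)
                if npairs >= 2:
                    np.testing.assert_allclose(
                        haralick_stats(P), haralick_oracle_stats(P_oracle), atol=1e-10
                    )

    def test_random_blob_matches_oracle(self, rng):
        mask = random_blob(rng, 15)
        crop = rng.integers(0, 255, mask.shape).astype(float)
        q = quantize(crop, mask)
        for dist, ang in [(1, 0), (2, 45), (1, 135), (2, 90)]:
            P, _ = glcm(q, mask, dist, ang)
            np.testing.assert_allclose(P, glcm_oracle(q, mask, dist, ang), atol=1e-12)
            np.testing.assert_allclose(
                haralick_stats(P), haralick_oracle_stats(P), atol=1e-10
            )

    def test_180_degree_rotation_leaves_features_unchanged(self, rng):
        mask = random_blob(rng, 17)
        crop = rng.integers(0, 255, mask.shape).astype(float)
        a = haralick_features(crop, mask)
        b = haralick_features(np.rot90(crop, 2), np.rot90(mask, 2))
        np.testing.assert_allclose(a, b, atol=1e-10)

    def test_tiny_mask_emits_zeros_with_warning(self):
        mask = np.zeros((6, 6), bool)
        mask[2, 2] = True
        crop = np.arange(36, dtype=float).reshape(6, 6)
        with pytest.warns(UserWarning, match="in-mask pairs"):
            vals = haralick_features(crop, mask)
        assert np.all(vals == 0.0)


# ---------------------------------------------------------------------------
# intensity


class TestIntensity:
    def test_constant_image(self):
        mask = disk_mask(6)
        vals = intensity_features(np.full(mask.shape, 42.0), mask)
        names = feature_manifest().groups["intensity"]
        d = dict(zip(names, vals))
        assert d["intensity_mean"] == d["intensity_median"] == 42.0
        assert d["intensity_sd"] == 0.0
        assert d["intensity_mass_displacement"] == 0.0

    def test_integrated_equals_mean_times_area(self, rng):
        mask = random_blob(rng)
        crop = rng.uniform(0, 100, mask.shape)
        names = feature_manifest().groups["intensity"]
        d = dict(zip(names, intensity_features(crop, mask)))
        assert d["intensity_integrated"] == pytest.approx(
            d["intensity_mean"] * mask.sum()
        )

    def test_hand_computed_3x3(self):
        crop = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]])
        mask = np.array([[True, True, False], [True, True, False], [False, False, False]])
        names = feature_manifest().groups["intensity"]
        d = dict(zip(names, intensity_features(crop, mask)))
        vals = [1.0, 2.0, 4.0, 5.0]
        assert d["intensity_mean"] == pytest.approx(np.mean(vals))
        assert d["intensity_median"] == pytest.approx(np.median(vals))
        assert d["intensity_sd"] == pytest.approx(np.std(vals))
        assert d["intensity_mad"] == pytest.approx(
            np.median(np.abs(np.array(vals) - np.median(vals)))
        )
        assert d["intensity_min"] == 1.0 and d["intensity_max"] == 5.0
        assert d["intensity_integrated"] == 12.0


# ---------------------------------------------------------------------------
# whole-vector invariances


class TestVectorInvariances:
    def test_translation_invariance(self, rng):
        mask = random_blob(rng, 19)
        crop = rng.uniform(0, 300, mask.shape)
        big_m = np.zeros((40, 40), bool)
        big_c = np.zeros((40, 40))
        big_m[2:21, 3:22] = mask
        big_c[2:21, 3:22] = crop
        shift_m = np.zeros((40, 40), bool)
        shift_c = np.zeros((40, 40))
        shift_m[10:29, 14:33] = mask
        shift_c[10:29, 14:33] = crop
        np.testing.assert_allclose(
            features_for(big_m, big_c), features_for(shift_m, shift_c), atol=1e-9
        )

    def test_scale_doubling_behaviour(self):
        small, big = disk_mask(16), disk_mask(32)
        names = list(feature_manifest().names)
        a = dict(zip(names, features_for(small)))
        b = dict(zip(names, features_for(big)))
        assert b["area"] == pytest.approx(4 * a["area"], rel=0.03)
        assert b["perimeter"] == pytest.approx(2 * a["perimeter"], rel=0.03)
        for name in ("form_factor", "extent", "solidity", "eccentricity"):
            assert abs(b[name] - a[name]) <= 0.03 * max(abs(a[name]), 1.0)

    @settings(max_examples=10, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_zernike_rotation_invariance_property(self, seed):
        mask = random_blob(np.random.default_rng(seed))
        a = zernike_features(mask)
        b = zernike_features(np.rot90(mask))
        scale = np.maximum(np.abs(a), 1e-3)
        assert np.max(np.abs(a - b) / scale) <= 0.02


# ---------------------------------------------------------------------------
# table assembly


class _FakeCell:
    def __init__(self, cell_id, masks, crops, times):
        self.cell_id = cell_id
        self.masks = masks
        self.crops = crops
        self.times_min = times


def _fake_cells(n_cells, n_frames, rng):
    cells = []
    for i in range(n_cells):
        masks = [disk_mask(int(rng.integers(6, 12))) for _ in range(n_frames)]
        crops = [rng.uniform(100, 400, m.shape) for m in masks]
        cells.append(_FakeCell(i, masks, crops, list(range(n_frames))))
    return cells


class TestExtractTable:
    def test_row_and_column_counts(self, rng):
        table = extract_table(_fake_cells(10, 6, rng))
        assert table.shape == (60, 171)
        assert list(table.columns[2:]) == list(feature_manifest().names)

    def test_failed_frames_dropped_and_logged(self, rng):
        cells = _fake_cells(2, 3, rng)
        cells[0].masks[1] = np.zeros((10, 10), bool)
        with pytest.warns(UserWarning, match="dropped 1 frames"):
            table = extract_table(cells)
        assert len(table) == 5

    def test_reextraction_is_bit_identical(self):
        rng = np.random.default_rng(0)
        cells = _fake_cells(3, 4, rng)
        a = extract_table(cells)
        b = extract_table(cells)
        assert a.equals(b)

    def test_no_cells_raises(self):
        with pytest.raises(ValueError):
            extract_table([])
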