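"""Per-cell, per-timepoint morphology features.

Every (cell, frame) pair is reduced to a fixed 169-column vector organised in
four families:

========  =====  =========================================================
family    count  content
========  =====  =========================================================
shape     26     region geometry: area, perimeter, solidity, radii, Feret
                 diameters, concavity statistics, ...
zernike   30     magnitudes |Z_nm| of complex Zernike moments of the binary
                 silhouette over the unit disk, n = 0..9, m >= 0, n-m even
haralick  104    13 classical co-occurrence (GLCM) texture statistics at
                 distances {1, 2} and angles {0, 45, 90, 135} degrees
intensity 9      first-order intensity statistics inside the mask
========  =====  =========================================================

The manifest (names, order, group tags) is frozen: downstream stages depend on
exactly 169 columns in this order.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import measure, morphology

__all__ = [
    "FeatureManifest",
    "feature_manifest",
    "shape_features",
    "zernike_features",
    "haralick_features",
    "intensity_features",
    "features_for",
    "extract_table",
    "ZERNIKE_ORDERS",
    "HARALICK_STATS",
    "GLCM_DISTANCES",
    "GLCM_ANGLES",
]

# ---------------------------------------------------------------------------
# manifest

SHAPE_NAMES = [
    "area",
    "perimeter",
    "convex_area",
    "solidity",
    "extent",
    "eccentricity",
    "major_axis_length",
    "minor_axis_length",
    "aspect_ratio",
    "orientation",
    "form_factor",
    "compactness",
    "equivalent_diameter",
    "euler_number",
    "radius_max",
    "radius_min",
    "radius_mean",
    "radius_median",
    "feret_diameter_max",
    "feret_diameter_min",
    "boundary_roughness",
    "centroid_displacement",
    "n_concavities",
    "concavity_depth_mean",
    "radial_variance",
    "mass_displacement",
]

# (n, m) with n = 0..9, m >= 0, n - m even -> 30 moments
ZERNIKE_ORDERS: list[tuple[int, int]] = [
    (n, m) for n in range(10) for m in range(n % 2, n + 1, 2)
]
ZERNIKE_NAMES = [f"zernike_n{n}_m{m}" for n, m in ZERNIKE_ORDERS]

HARALICK_STATS = [
    "asm",
    "contrast",
    "correlation",
    "variance",
    "idm",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
]
GLCM_DISTANCES = (1, 2)
GLCM_ANGLES = (0, 45, 90, 135)
HARALICK_NAMES = [
    f"haralick_d{d}_a{a}_{s}"
    for d in GLCM_DISTANCES
    for a in GLCM_ANGLES
    for s in HARALICK_STATS
]

INTENSITY_NAMES = [
    "intensity_mean",
    "intensity_median",
    "intensity_sd",
    "intensity_mad",
    "intensity_min",
    "intensity_max",
    "intensity_integrated",
    "intensity_mass_displacement",
    "intensity_edge_interior_ratio",
]

MANIFEST_VERSION = "1.0"


@dataclass(frozen=True)
class FeatureManifest:
    """Frozen, ordered list of the 169 feature columns with group tags."""

    names: tuple[str, ...]
    groups: dict[str, tuple[str, ...]] = field(repr=False)
    version: str = MANIFEST_VERSION

    def __post_init__(self) -> None:
        if len(self.names) != 169:
            raise ValueError(f"manifest must have 169 names, got {len(self.names)}")
        if len(set(self.names)) != len(self.names):
            raise ValueError("manifest names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "names": list(self.names),
            "groups": {g: list(ns) for g, ns in self.groups.items()},
        }


def feature_manifest() -> FeatureManifest:
    """The fixed 169-column manifest (26 shape + 30 Zernike + 104 Haralick + 9 intensity)."""
    return FeatureManifest(
        names=tuple(SHAPE_NAMES + ZERNIKE_NAMES + HARALICK_NAMES + INTENSITY_NAMES),
        groups={
            "shape": tuple(SHAPE_NAMES),
            "zernike": tuple(ZERNIKE_NAMES),
            "haralick": tuple(HARALICK_NAMES),
            "intensity": tuple(INTENSITY_NAMES),
        },
    )


# ---------------------------------------------------------------------------
# shape


def _boundary_pixels(mask: np.ndarray) -> np.ndarray:
    eroded = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    boundary = mask & ~eroded
    if not boundary.any():  # single-pixel / thin masks erode to nothing
        boundary = mask
    return boundary


def _feret_min(coords: np.ndarray) -> float:
    """Minimum caliper width of the point set (rotating calipers on hull edges).

    Pixel centres are dilated by +/-0.5 in both axes so a 1-pixel-thick object
    has width 1, matching the max-Feret convention of regionprops.
    """
    pts = np.concatenate(
        [coords + off for off in ((0.5, 0.5), (0.5, -0.5), (-0.5, 0.5), (-0.5, -0.5))]
    ).astype(float)
    try:
        from scipy.spatial import ConvexHull

        hull = ConvexHull(pts)
        hp = pts[hull.vertices]
    except Exception:  # degenerate (collinear) sets
        hp = pts
    best = np.inf
    n = len(hp)
    for i in range(n):
        e = hp[(i + 1) % n] - hp[i]
        norm = np.hypot(*e)
        if norm == 0:
            continue
        normal = np.array([-e[1], e[0]]) / norm
        proj = (hp - hp[i]) @ normal
        best = min(best, proj.max() - proj.min())
    return float(best) if np.isfinite(best) else 0.0


def shape_features(mask: np.ndarray, pixel_size: float = 1.0) -> np.ndarray:
    """26 geometric descriptors of a single-component binary mask.

    Lengths are in micrometres (``pixel_size`` um/px), areas in um^2;
    dimensionless descriptors (solidity, extent, form factor, ...) are
    unit-free.  ``mass_displacement`` is a placeholder 0 here (the
    intensity-weighted version lives in the intensity family).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("shape_features: empty mask")
    px = float(pixel_size)

    props = measure.regionprops(mask.astype(np.uint8))[0]
    area = props.area * px**2
    # Crofton estimate: far less biased than the chain-code perimeter on
    # rasterized smooth shapes (a disk's form factor lands near 1, not 0.9)
    perimeter = measure.perimeter_crofton(mask, directions=4) * px
    convex_area = props.area_convex * px**2
    solidity = props.solidity
    extent = props.extent
    ecc = props.eccentricity
    major = props.axis_major_length * px
    minor = props.axis_minor_length * px
    aspect = major / minor if minor > 0 else major / px  # thin object: minor ~ 1 px
    orientation = props.orientation
    form_factor = 4 * math.pi * area / perimeter**2 if perimeter > 0 else 0.0
    compactness = 1.0 / form_factor if form_factor > 0 else 0.0
    eq_diam = props.equivalent_diameter_area * px
    euler = float(props.euler_number)

    centroid = np.array(props.centroid)
    bcoords = np.argwhere(_boundary_pixels(mask))
    radii = np.hypot(*(bcoords - centroid).T) * px
    r_max, r_min = float(radii.max()), float(radii.min())
    r_mean, r_median = float(radii.mean()), float(np.median(radii))
    radial_var = float(radii.var())

    feret_max = props.feret_diameter_max * px
    feret_min = _feret_min(np.argwhere(mask)) * px

    convex_img = props.image_convex
    convex_perimeter = measure.perimeter_crofton(convex_img, directions=4) * px
    roughness = perimeter / convex_perimeter if convex_perimeter > 0 else 1.0

    minr, minc, maxr, maxc = props.bbox
    bbox_center = np.array([(minr + maxr - 1) / 2, (minc + maxc - 1) / 2])
    centroid_disp = float(np.hypot(*(centroid - bbox_center))) * px

    # concavities: connected components of hull \ mask, depth from the
    # Euclidean distance transform of the defect region
    local = mask[minr:maxr, minc:maxc]
    defects = convex_img & ~local
    n_conc, depth_mean = 0, 0.0
    if defects.any():
        lab, nlab = ndi.label(defects, structure=np.ones((3, 3), bool))
        edt = ndi.distance_transform_edt(defects)
        depths = []
        for i in range(1, nlab + 1):
            comp = lab == i
            if comp.sum() >= 2:
                depths.append(edt[comp].max() * px)
        n_conc = len(depths)
        depth_mean = float(np.mean(depths)) if depths else 0.0

    return np.array(
        [
            area, perimeter, convex_area, solidity, extent, ecc, major, minor,
            aspect, orientation, form_factor, compactness, eq_diam, euler,
            r_max, r_min, r_mean, r_median, feret_max, feret_min, roughness,
            centroid_disp, float(n_conc), depth_mean, radial_var, 0.0,
        ],
        dtype=float,
    )


# ---------------------------------------------------------------------------
# Zernike


def zernike_radial(n: int, m: int, rho: np.ndarray) -> np.ndarray:
    """Radial Zernike polynomial R_nm evaluated at rho (m >= 0, n - m even)."""
    out = np.zeros_like(rho, dtype=float)
    for s in range((n - m) // 2 + 1):
        c = (
            (-1) ** s
            * math.factorial(n - s)
            / (
                math.factorial(s)
                * math.factorial((n + m) // 2 - s)
                * math.factorial((n - m) // 2 - s)
            )
        )
        out += c * rho ** (n - 2 * s)
    return out


def zernike_features(mask: np.ndarray) -> np.ndarray:
    """Magnitudes |Z_nm| of the binary silhouette's Zernike moments.

    The mask is mapped to the unit disk centred at its binary centroid with
    radius equal to the maximum centroid-to-pixel distance, so the shape lies
    entirely inside the disk.  Each moment is

        Z_nm = (n + 1) / pi * sum_pixels R_nm(rho) exp(-i m theta) dA,

    with the pixel area element dA = 1 / R^2 so the sum approximates the
    continuous integral over the unit disk.  Magnitudes are invariant to
    rotations of the silhouette.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("zernike_features: empty mask")
    coords = np.argwhere(mask).astype(float)
    centroid = coords.mean(axis=0)
    d = coords - centroid
    dist = np.hypot(d[:, 0], d[:, 1])
    radius = dist.max()
    if radius == 0:  # single pixel
        radius = 1.0
    rho = dist / radius
    inside = rho <= 1.0
    rho = rho[inside]
    theta = np.arctan2(d[inside, 0], d[inside, 1])
    dA = 1.0 / radius**2

    out = np.empty(len(ZERNIKE_ORDERS))
    for i, (n, m) in enumerate(ZERNIKE_ORDERS):
        rad = zernike_radial(n, m, rho)
        z = (n + 1) / math.pi * np.sum(rad * np.exp(-1j * m * theta)) * dA
        out[i] = abs(z)
    return out


# ---------------------------------------------------------------------------
# Haralick / GLCM

_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


def quantize(crop: np.ndarray, mask: np.ndarray, levels: int = 8) -> np.ndarray:
    """Equal-width quantization of in-mask intensities to ``levels`` bins."""
    vals = crop[mask]
    lo, hi = float(vals.min()), float(vals.max())
    q = np.zeros(crop.shape, dtype=np.intp)
    if hi > lo:
        q = np.floor((crop.astype(float) - lo) / (hi - lo) * levels).astype(np.intp)
        np.clip(q, 0, levels - 1, out=q)
    return q


def glcm(
    q: np.ndarray, mask: np.ndarray, distance: int, angle: int, levels: int = 8
) -> tuple[np.ndarray, int]:
    """Symmetric, normalized co-occurrence matrix restricted to in-mask pairs.

    Returns (P, n_pairs) where n_pairs counts ordered pixel pairs before
    symmetrization normalization (each unordered pair contributes twice).
    """
    dr, dc = _ANGLE_OFFSETS[angle]
    dr, dc = dr * distance, dc * distance
    H, W = mask.shape
    r0s, r0e = max(0, -dr), min(H, H - dr)
    c0s, c0e = max(0, -dc), min(W, W - dc)
    a_mask = mask[r0s:r0e, c0s:c0e]
    b_mask = mask[r0s + dr : r0e + dr, c0s + dc : c0e + dc]
    both = a_mask & b_mask
    P = np.zeros((levels, levels), float)
    npairs = int(both.sum())
    if npairs:
        a = q[r0s:r0e, c0s:c0e][both]
        b = q[r0s + dr : r0e + dr, c0s + dc : c0e + dc][both]
        np.add.at(P, (a, b), 1.0)
        P = P + P.T
        P /= P.sum()
    return P, 2 * npairs


def _xlogx(p: np.ndarray) -> np.ndarray:
    out = np.zeros_like(p)
    nz = p > 0
    out[nz] = p[nz] * np.log(p[nz])
    return out


def haralick_stats(P: np.ndarray) -> np.ndarray:
    """The 13 classical texture statistics of a normalized symmetric GLCM.

    Natural logarithms; correlation is defined as 0 for zero marginal
    variance; sum variance is taken about the sum average.
    """
    L = P.shape[0]
    i = np.arange(L)
    I, J = np.meshgrid(i, i, indexing="ij")
    px = P.sum(axis=1)
    mu = float((i * px).sum())
    sigma2 = float(((i - mu) ** 2 * px).sum())
    sigma = math.sqrt(sigma2)

    asm = float((P**2).sum())
    contrast = float(((I - J) ** 2 * P).sum())
    correlation = (
        float((((I - mu) * (J - mu)) * P).sum() / sigma2) if sigma > 0 else 0.0
    )
    variance = float((((I - mu) ** 2) * P).sum())
    idm = float((P / (1.0 + (I - J) ** 2)).sum())

    # marginals of i+j and |i-j|
    psum = np.zeros(2 * L - 1)
    np.add.at(psum, (I + J).ravel(), P.ravel())
    pdiff = np.zeros(L)
    np.add.at(pdiff, np.abs(I - J).ravel(), P.ravel())
    k_sum = np.arange(2 * L - 1)
    k_diff = np.arange(L)

    sum_average = float((k_sum * psum).sum())
    sum_entropy = float(-_xlogx(psum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * psum).sum())
    entropy = float(-_xlogx(P).sum())
    diff_mean = float((k_diff * pdiff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * pdiff).sum())
    difference_entropy = float(-_xlogx(pdiff).sum())

    hx = float(-_xlogx(px).sum())
    pxy = np.outer(px, px)
    with np.errstate(divide="ignore"):
        logpxy = np.where(pxy > 0, np.log(pxy), 0.0)
    hxy1 = float(-(P * logpxy).sum())
    hxy2 = float(-(pxy * logpxy).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = math.sqrt(max(0.0, 1.0 - math.exp(-2.0 * (hxy2 - entropy))))

    return np.array(
        [
            asm, contrast, correlation, variance, idm, sum_average, sum_variance,
            sum_entropy, entropy, difference_variance, difference_entropy, imc1, imc2,
        ]
    )


def haralick_features(
    crop: np.ndarray,
    mask: np.ndarray,
    levels: int = 8,
    distances: Sequence[int] = GLCM_DISTANCES,
    angles: Sequence[int] = GLCM_ANGLES,
) -> np.ndarray:
    """104 GLCM texture values: 13 statistics x len(distances) x len(angles).

    In-mask intensities are quantized to ``levels`` equal-width bins over the
    mask's min-max range; each co-occurrence matrix counts only pixel pairs
    with both ends inside the mask.  Offsets with fewer than 2 in-mask pairs
    yield 13 zeros (logged) so downstream stages never see missing values.
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("haralick_features: empty mask")
    q = quantize(crop, mask, levels)
    out = []
    for d in distances:
        for a in angles:
            P, npairs = glcm(q, mask, d, a, levels)
            if npairs < 2:
                warnings.warn(
                    f"GLCM offset (d={d}, angle={a}) has <2 in-mask pairs; "
                    "emitting zeros",
                    stacklevel=2,
                )
                out.append(np.zeros(13))
            else:
                out.append(haralick_stats(P))
    return np.concatenate(out)


# ---------------------------------------------------------------------------
# intensity


def intensity_features(
    crop: np.ndarray, mask: np.ndarray, pixel_size: float = 1.0
) -> np.ndarray:
    """9 first-order intensity statistics inside the mask.

    Mass displacement is the distance (um) between the intensity-weighted and
    binary centroids.  The edge/interior ratio compares boundary-pixel mean to
    interior mean (1.0 when erosion leaves no interior, 0.0 for a zero-signal
    interior).
    """
    mask = np.asarray(mask, bool)
    if not mask.any():
        raise ValueError("intensity_features: empty mask")
    vals = crop[mask].astype(float)
    mean = float(vals.mean())
    median = float(np.median(vals))
    sd = float(vals.std())
    mad = float(np.median(np.abs(vals - median)))
    vmin, vmax = float(vals.min()), float(vals.max())
    integrated = float(vals.sum())

    coords = np.argwhere(mask).astype(float)
    bcent = coords.mean(axis=0)
    total = vals.sum()
    if total > 0:
        wcent = (coords * vals[:, None]).sum(axis=0) / total
        mass_disp = float(np.hypot(*(wcent - bcent))) * pixel_size
    else:
        mass_disp = 0.0

    interior = ndi.binary_erosion(mask, structure=np.ones((3, 3), bool), border_value=0)
    edge = mask & ~interior
    if not interior.any() or not edge.any():
        ratio = 1.0
    else:
        imean = float(crop[interior].mean())
        ratio = float(crop[edge].mean()) / imean if imean != 0 else 0.0

    return np.array(
        [mean, median, sd, mad, vmin, vmax, integrated, mass_disp, ratio]
    )


# ---------------------------------------------------------------------------
# table assembly


def features_for(
    mask: np.ndarray, crop: np.ndarray | None = None, pixel_size: float = 1.0
) -> np.ndarray:
    """Full 169-entry feature vector for one mask (+ optional intensity crop).

    Without a crop, the mask itself serves as the intensity image (binary
    texture), matching the fluorescent-silhouette character of the data.
    """
    if crop is None:
        crop = mask.astype(float)
    return np.concatenate(
        [
            shape_features(mask, pixel_size),
            zernike_features(mask),
            haralick_features(crop, mask),
            intensity_features(crop, mask, pixel_size),
        ]
    )


def extract_table(cell_series_set: Iterable, pixel_size: float = 1.0) -> pd.DataFrame:
    """One row per (cell, frame) with the 169 manifest columns.

    ``cell_series_set`` is an iterable of objects with ``cell_id``, ``masks``
    (per-frame binary arrays), ``crops`` (per-frame intensity patches) and
    ``times_min``.  Frames whose delineation failed (empty mask) are dropped
    and logged.  Raises if no cells are supplied or no rows survive.
    """
    manifest = feature_manifest()
    rows, index = [], []
    n_cells = 0
    n_dropped = 0
    for cell in cell_series_set:
        n_cells += 1
        times = getattr(cell, "times_min", None)
        if times is None:
            times = list(range(len(cell.masks)))
        for t, mask, crop in zip(times, cell.masks, cell.crops):
            if mask is None or not np.asarray(mask, bool).any():
                n_dropped += 1
                continue
            rows.append(features_for(np.asarray(mask, bool), crop, pixel_size))
            index.append((cell.cell_id, int(t)))
    if n_cells == 0:
        raise ValueError("extract_table: no cells supplied")
    if not rows:
        raise ValueError("extract_table: all frames failed delineation")
    if n_dropped:
        warnings.warn(f"extract_table: dropped {n_dropped} frames with empty masks")
    meta = pd.DataFrame(index, columns=["cell_id", "time_min"])
    feats = pd.DataFrame(np.vstack(rows), columns=list(manifest.names))
    return pd.concat([meta, feats], axis=1)
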