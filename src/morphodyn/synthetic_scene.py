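"""Synthetic microwell time-lapse scenes with known ground truth.

No imaging data ships with the method this package reimplements, so the
benchmark substrate is simulated: a regular grid of triangular microwells
(40 um side), mostly single-occupancy, each live cell rendered as a rotating
(0.1 Hz), slowly deforming star-convex fluorescent silhouette with camera
noise, plus a single end-of-run viability frame in which only dead cells
appear (the propidium-iodide analog).

Two generation paths exist:

* ``simulate_timelapse`` renders actual image stacks for testing the
  segmentation and feature-extraction stages;
* ``simulate_feature_table`` bypasses rendering and draws per-cell
  per-timepoint 169-column feature rows directly from a parametric
  class/sub-phenotype mixture — the fast path for the machine-learning
  stages.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage import draw as skdraw

from ._rng import substream
from .morpho_features import feature_manifest

__all__ = [
    "PhenotypeSpec",
    "ScenePlan",
    "MixtureSpec",
    "Scene",
    "CellInstance",
    "default_phenotypes",
    "sample_shape_params",
    "cell_outline",
    "simulate_cell_outline",
    "make_ground_truth",
    "render_frame",
    "simulate_timelapse",
    "truth_mask",
    "default_mixture",
    "null_mixture",
    "simulate_feature_table",
    "CELL_SD",
    "AR1_RHO",
    "COLUMN_VARIANCE",
    "POOLED_SD",
]

MAX_IMAGE_DIM = 8192

# harmonic orders of the boundary model
_HARMONICS = (2, 3, 4, 5, 6)


@dataclass
class PhenotypeSpec:
    """Shape-dynamics distribution for one phenotype class.

    The boundary is a truncated Fourier star-convex curve

        r(theta, t) = r0 * (1 + sum_k a_k cos(k (theta - omega t) - phi_k(t)))

    with k = 2..6, rigid rotation at ``rotation_freq_hz`` (0.1 Hz by default,
    i.e. 6 turns/min), slow phase drift of the lobes, and transient localized
    protrusion bumps at a Poisson rate.  ``subphenotypes`` lists parameter
    offsets defining within-class modes.
    """

    name: str
    base_radius_um: float = 8.0
    lobe_amplitude_mean: tuple[float, ...] = (0.06, 0.04, 0.03, 0.02, 0.01)
    lobe_amplitude_sd: float = 0.01
    lobe_drift_rate: float = 0.05  # rad/min
    protrusion_rate: float = 0.05  # events/min
    protrusion_amplitude: float = 0.10  # fraction of r0
    intensity_mean: float = 300.0  # photon counts
    rotation_freq_hz: float = 0.1
    subphenotypes: tuple[dict, ...] = ({},)

    def __post_init__(self) -> None:
        if self.base_radius_um <= 0:
            raise ValueError("base_radius_um must be positive")
        if self.rotation_freq_hz < 0:
            raise ValueError("rotation_freq_hz must be >= 0")
        if not self.subphenotypes:
            raise ValueError("subphenotypes must be non-empty")
        if len(self.lobe_amplitude_mean) != len(_HARMONICS):
            raise ValueError(f"need {len(_HARMONICS)} lobe amplitudes (k=2..6)")

    def with_offsets(self, offsets: dict) -> "PhenotypeSpec":
        base = dataclasses.asdict(self)
        base.pop("subphenotypes")
        for key, val in offsets.items():
            if key == "lobe_amplitude_mean":
                base[key] = tuple(np.asarray(base[key]) + np.asarray(val))
            elif key in base:
                base[key] = base[key] + val
            else:
                raise KeyError(f"unknown phenotype parameter {key!r}")
        return PhenotypeSpec(subphenotypes=({},), **base)


def default_phenotypes() -> dict[str, PhenotypeSpec]:
    """Two stock phenotypes: a rounder epithelial-like class and a more
    protrusive, lobed mesenchymal-like class (4 and 3 sub-modes)."""
    epithelial = PhenotypeSpec(
        name="epithelial",
        base_radius_um=9.0,
        lobe_amplitude_mean=(0.05, 0.03, 0.02, 0.01, 0.01),
        lobe_amplitude_sd=0.008,
        lobe_drift_rate=0.03,
        protrusion_rate=0.02,
        protrusion_amplitude=0.06,
        intensity_mean=320.0,
        subphenotypes=(
            {},
            {"base_radius_um": 1.5},
            {"lobe_amplitude_mean": (0.04, 0.02, 0.0, 0.0, 0.0)},
            {"base_radius_um": -1.5, "lobe_drift_rate": 0.05},
        ),
    )
    mesenchymal = PhenotypeSpec(
        name="mesenchymal",
        base_radius_um=8.0,
        lobe_amplitude_mean=(0.16, 0.11, 0.07, 0.04, 0.02),
        lobe_amplitude_sd=0.02,
        lobe_drift_rate=0.15,
        protrusion_rate=0.15,
        protrusion_amplitude=0.18,
        intensity_mean=280.0,
        subphenotypes=(
            {},
            {"protrusion_rate": 0.15, "protrusion_amplitude": 0.08},
            {"lobe_amplitude_mean": (-0.08, -0.06, -0.04, -0.02, -0.01),
             "base_radius_um": 1.0},
        ),
    )
    return {"epithelial": epithelial, "mesenchymal": mesenchymal}


@dataclass
class ScenePlan:
    """Geometry, occupancy and camera model of one simulated run."""

    grid_rows: int = 8
    grid_cols: int = 8
    well_side_um: float = 40.0
    well_pitch_um: float = 80.0
    pixel_size_um: float = 0.5
    p_empty: float = 0.3
    p_single: float = 0.6
    p_multi: float = 0.1
    dead_fraction: float = 0.05
    noise_gaussian_sd: float = 3.0
    background_level: float = 100.0
    well_outline_level: float = 20.0
    poisson_noise: bool = True
    frames: int = 60
    frame_interval_min: float = 1.0
    well_depth_um: float = 35.0  # recorded metadata only; rendering is 2-D
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(self.p_empty + self.p_single + self.p_multi - 1.0) > 1e-9:
            raise ValueError("occupancy probabilities must sum to 1")
        if not 0.0 <= self.dead_fraction <= 1.0:
            raise ValueError("dead_fraction must be in [0, 1]")
        if self.frames < 1:
            raise ValueError("frames must be >= 1")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")

    @property
    def pitch_px(self) -> int:
        return int(round(self.well_pitch_um / self.pixel_size_um))

    @property
    def image_shape(self) -> tuple[int, int]:
        return (self.grid_rows * self.pitch_px, self.grid_cols * self.pitch_px)


# ---------------------------------------------------------------------------
# single-cell shape model


@dataclass
class ShapeParams:
    """One cell's frozen draw from its phenotype's shape distribution."""

    r0: float
    amplitudes: np.ndarray  # a_k, k = 2..6
    phases: np.ndarray  # phi_k at t = 0
    drift_rate: float
    rotation_freq_hz: float
    protrusions: tuple[tuple[float, float, float, float], ...]  # (t0, angle, amp, dur)
    intensity_mean: float


_MAX_TOTAL_AMPLITUDE = 0.5  # keeps r > 0 and the curve star-convex/simple


def sample_shape_params(
    spec: PhenotypeSpec,
    rng: np.random.Generator,
    duration_min: float = 60.0,
    max_retries: int = 20,
) -> ShapeParams:
    """Draw a cell's amplitudes/phases/protrusion schedule from ``spec``.

    Amplitude vectors whose total reaches 0.5 (which could drive r <= 0) are
    rejected and redrawn, with bounded retries.
    """
    for _ in range(max_retries):
        amps = rng.normal(spec.lobe_amplitude_mean, spec.lobe_amplitude_sd)
        amps = np.clip(amps, 0.0, None)
        if amps.sum() < _MAX_TOTAL_AMPLITUDE:
            break
    else:
        raise RuntimeError(
            "could not draw admissible lobe amplitudes "
            f"(sum < {_MAX_TOTAL_AMPLITUDE}) in {max_retries} tries"
        )
    phases = rng.uniform(0, 2 * np.pi, size=len(_HARMONICS))
    n_events = rng.poisson(spec.protrusion_rate * duration_min)
    protrusions = tuple(
        (
            float(rng.uniform(0, duration_min)),
            float(rng.uniform(0, 2 * np.pi)),
            float(spec.protrusion_amplitude * rng.uniform(0.5, 1.5)),
            float(rng.uniform(1.0, 4.0)),  # duration, minutes
        )
        for _ in range(n_events)
    )
    return ShapeParams(
        r0=spec.base_radius_um,
        amplitudes=amps,
        phases=phases,
        drift_rate=spec.lobe_drift_rate,
        rotation_freq_hz=spec.rotation_freq_hz,
        protrusions=protrusions,
        intensity_mean=spec.intensity_mean,
    )


def cell_outline(params: ShapeParams, t: float, n_angles: int = 128) -> np.ndarray:
    """Closed boundary polygon (um, (x, y) rows) of one cell at time t (min).

    Rigid rotation by omega = 2*pi*f*60*t plus lobe-phase drift plus transient
    Gaussian protrusion bumps that co-rotate with the cell.  The curve is
    star-convex about the origin (r > 0 everywhere), hence simple.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    theta = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
    omega_t = 2 * np.pi * params.rotation_freq_hz * 60.0 * t
    r = np.ones_like(theta)
    for k, a_k, phi_k in zip(_HARMONICS, params.amplitudes, params.phases):
        r += a_k * np.cos(k * (theta - omega_t) - (phi_k + params.drift_rate * t))
    for t0, angle, amp, dur in params.protrusions:
        dt = (t - t0) / (dur / 2.0)
        if abs(dt) > 3.0:
            continue
        dth = np.angle(np.exp(1j * (theta - (angle + omega_t))))
        r += amp * np.exp(-0.5 * dt**2) * np.exp(-0.5 * (dth / 0.35) ** 2)
    r = params.r0 * np.maximum(r, 1e-3)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def simulate_cell_outline(
    spec: PhenotypeSpec, t: float, rng: np.random.Generator, n_angles: int = 128
) -> np.ndarray:
    """Sample a cell from ``spec`` and return its outline polygon at time t."""
    return cell_outline(sample_shape_params(spec, rng), t, n_angles)


# ---------------------------------------------------------------------------
# scene assembly


@dataclass
class CellInstance:
    well_id: int
    params: ShapeParams
    class_label: str
    subphenotype_id: int
    alive: bool
    center_um: tuple[float, float]  # offset of cell centre from well centre


@dataclass
class Scene:
    plan: ScenePlan
    truth: pd.DataFrame  # one record per well
    cells: dict[int, list[CellInstance]] = field(repr=False)
    phenotypes: dict[str, PhenotypeSpec] = field(repr=False)


def make_ground_truth(
    plan: ScenePlan,
    phenotype_mix: dict[str, float] | None = None,
    phenotypes: dict[str, PhenotypeSpec] | None = None,
) -> Scene:
    """Assign occupancy, class, sub-phenotype and viability to every well."""
    if phenotypes is None:
        phenotypes = default_phenotypes()
    if phenotype_mix is None:
        phenotype_mix = {name: 1.0 / len(phenotypes) for name in phenotypes}
    names = sorted(phenotype_mix)
    probs = np.array([phenotype_mix[n] for n in names], float)
    probs = probs / probs.sum()

    rng = substream(plan.seed, "ground_truth")
    duration = plan.frames * plan.frame_interval_min
    jitter_max = max(0.0, plan.well_side_um / 2 - 12.0)

    records, cells = [], {}
    well_id = 0
    for row in range(plan.grid_rows):
        for col in range(plan.grid_cols):
            occ = rng.choice(
                ["empty", "single", "multi"], p=[plan.p_empty, plan.p_single, plan.p_multi]
            )
            rec = {
                "well_id": well_id,
                "row": row,
                "col": col,
                "occupancy": occ,
                "class_label": "",
                "subphenotype_id": -1,
                "alive": True,
            }
            if occ != "empty":
                name = names[rng.choice(len(names), p=probs)]
                spec = phenotypes[name]
                sub = int(rng.integers(len(spec.subphenotypes)))
                alive = bool(rng.random() >= plan.dead_fraction)
                rec.update(class_label=name, subphenotype_id=sub, alive=alive)
                n_cells = 1 if occ == "single" else 2
                instances = []
                for ci in range(n_cells):
                    sub_spec = spec.with_offsets(spec.subphenotypes[sub])
                    params = sample_shape_params(sub_spec, rng, duration)
                    if occ == "single":
                        center = tuple(rng.uniform(-jitter_max / 4, jitter_max / 4, 2))
                    else:
                        # two cells pushed toward opposite corners of the well
                        sign = -1.0 if ci == 0 else 1.0
                        center = (sign * 9.0, sign * 9.0)
                    instances.append(
                        CellInstance(well_id, params, name, sub, alive, center)
                    )
                cells[well_id] = instances
            records.append(rec)
            well_id += 1
    truth = pd.DataFrame.from_records(records)
    return Scene(plan=plan, truth=truth, cells=cells, phenotypes=phenotypes)


def _well_center_px(plan: ScenePlan, row: int, col: int) -> tuple[float, float]:
    p = plan.pitch_px
    return ((row + 0.5) * p, (col + 0.5) * p)


def _well_triangle_px(plan: ScenePlan, row: int, col: int) -> tuple[np.ndarray, np.ndarray]:
    """Vertex coordinates (rows, cols) of the equilateral well outline."""
    cy, cx = _well_center_px(plan, row, col)
    s = plan.well_side_um / plan.pixel_size_um
    R = s / np.sqrt(3.0)
    ang = np.array([np.pi / 2, np.pi / 2 + 2 * np.pi / 3, np.pi / 2 + 4 * np.pi / 3])
    return cy - R * np.sin(ang), cx + R * np.cos(ang)


def _cell_polygon_px(
    plan: ScenePlan, row: int, col: int, inst: CellInstance, t: float
) -> tuple[np.ndarray, np.ndarray]:
    poly = cell_outline(inst.params, t)
    cy, cx = _well_center_px(plan, row, col)
    rr = cy + (poly[:, 1] + inst.center_um[1]) / plan.pixel_size_um
    cc = cx + (poly[:, 0] + inst.center_um[0]) / plan.pixel_size_um
    return rr, cc


def render_frame(
    plan: ScenePlan,
    scene: Scene,
    t: float,
    channel: str = "fluorescence",
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Render one 16-bit grayscale frame of the scene at time t (minutes).

    The fluorescence channel shows all cells (dead cells static, frozen at
    their t=0 outline); the viability channel shows only dead cells.  Signal
    is background + well outlines + filled cell silhouettes, with Poisson shot
    noise and Gaussian read noise when enabled.
    """
    H, W = plan.image_shape
    if max(H, W) > MAX_IMAGE_DIM:
        raise ValueError(f"image {H}x{W} exceeds maximum dimension {MAX_IMAGE_DIM}")
    img = np.full((H, W), float(plan.background_level))

    # well outlines
    for rec in scene.truth.itertuples():
        ry, rx = _well_triangle_px(plan, rec.row, rec.col)
        rr, cc = skdraw.polygon_perimeter(ry, rx, shape=img.shape)
        img[rr, cc] += plan.well_outline_level

    # cells
    for rec in scene.truth.itertuples():
        if rec.occupancy == "empty":
            continue
        for inst in scene.cells[rec.well_id]:
            if channel == "viability" and inst.alive:
                continue
            t_render = 0.0 if not inst.alive else t  # dead cells do not rotate
            rr, cc = _cell_polygon_px(plan, rec.row, rec.col, inst, t_render)
            pr, pc = skdraw.polygon(rr, cc, shape=img.shape)
            img[pr, pc] += inst.params.intensity_mean

    if rng is not None:
        if plan.poisson_noise:
            img = rng.poisson(np.maximum(img, 0)).astype(float)
        if plan.noise_gaussian_sd > 0:
            img = img + rng.normal(0, plan.noise_gaussian_sd, img.shape)
    return np.clip(np.round(img), 0, 65535).astype(np.uint16)


@dataclass
class SimulationResult:
    stack: np.ndarray  # (frames, H, W) uint16
    viability: np.ndarray  # (H, W) uint16
    truth: pd.DataFrame
    scene: Scene

    @property
    def times_min(self) -> np.ndarray:
        p = self.scene.plan
        return np.arange(p.frames) * p.frame_interval_min


def simulate_timelapse(
    plan: ScenePlan,
    phenotype_mix: dict[str, float] | None = None,
    phenotypes: dict[str, PhenotypeSpec] | None = None,
) -> SimulationResult:
    """Full reproducible run: `frames` fluorescence pages + one viability page.

    Everything derives from ``plan.seed`` through named substreams, so the
    same plan yields a byte-identical stack.
    """
    scene = make_ground_truth(plan, phenotype_mix, phenotypes)
    frames = []
    for i in range(plan.frames):
        t = i * plan.frame_interval_min
        rng = substream(plan.seed, "render", i)
        frames.append(render_frame(plan, scene, t, "fluorescence", rng))
    via_rng = substream(plan.seed, "render_viability")
    viability = render_frame(
        plan, scene, (plan.frames - 1) * plan.frame_interval_min, "viability", via_rng
    )
    return SimulationResult(
        stack=np.stack(frames), viability=viability, truth=scene.truth, scene=scene
    )


def truth_mask(scene: Scene, well_id: int, t: float) -> np.ndarray:
    """Ground-truth binary raster of the cells in one well's crop at time t."""
    plan = scene.plan
    rec = scene.truth.loc[scene.truth.well_id == well_id].iloc[0]
    p = plan.pitch_px
    mask = np.zeros((p, p), bool)
    for inst in scene.cells.get(int(well_id), []):
        t_render = 0.0 if not inst.alive else t
        rr, cc = _cell_polygon_px(plan, rec.row, rec.col, inst, t_render)
        rr = rr - rec.row * p
        cc = cc - rec.col * p
        pr, pc = skdraw.polygon(rr, cc, shape=mask.shape)
        mask[pr, pc] = True
    return mask


# ---------------------------------------------------------------------------
# fast path: parametric feature tables

#: stationary SD of the per-column AR(1) temporal noise (all columns)
AR1_RHO = 0.6
#: SD of the per-cell random offset added to every column
CELL_SD = 0.5
#: total variance of a feature column about its component centre
COLUMN_VARIANCE = 1.0 + CELL_SD**2
#: pooled within-component SD; effect sizes and component separations are
#: expressed in these units
POOLED_SD = float(np.sqrt(COLUMN_VARIANCE))

#: columns carrying the between-class mean shift (10 of 169)
EFFECT_COLUMNS = tuple(range(0, 10))
#: columns spanning the sub-phenotype chain direction.  The chain is spread
#: over every non-effect column so that no single column's variance is
#: dominated by the component structure: per-column standardization (the
#: analysis space) then leaves the component separation intact instead of
#: normalizing it away.
SUBPHENO_COLUMNS = tuple(range(10, 169))


@dataclass
class MixtureSpec:
    """Per-class sub-phenotype components in feature space.

    ``centers`` maps class label -> (n_components, 169) array of component
    centres in pooled-SD units.  Components within a class are sampled
    uniformly.
    """

    centers: dict[int, np.ndarray]

    def n_components(self, label: int) -> int:
        return self.centers[label].shape[0]

    @property
    def labels(self) -> list[int]:
        return sorted(self.centers)


def _chain_direction(n_features: int = 169) -> np.ndarray:
    v = np.zeros(n_features)
    v[list(SUBPHENO_COLUMNS)] = 1.0 / np.sqrt(len(SUBPHENO_COLUMNS))
    return v


def default_mixture(separation: float = 8.0, n_features: int = 169) -> MixtureSpec:
    """The stock 4 + 3 sub-phenotype mixture.

    Seven component centres sit on a 1-D chain with adjacent spacing
    ``separation`` pooled SD; the two classes interleave along the chain
    (A,B,A,B,A,B,A), so class A owns chain positions 0,2,4,6 and class B owns
    1,3,5.  All pairwise centre distances are >= ``separation``, geometric
    neighbours always belong to opposite classes, and both class means sit at
    the chain midpoint, so the chain direction itself carries no class
    information.
    """
    v = _chain_direction(n_features)
    positions = np.arange(7, dtype=float) * separation
    positions -= positions.mean()  # chain midpoint at the origin
    a_pos = positions[[0, 2, 4, 6]]
    b_pos = positions[[1, 3, 5]]
    return MixtureSpec(
        centers={
            0: a_pos[:, None] * v[None, :],
            1: b_pos[:, None] * v[None, :],
        }
    )


def null_mixture(n_features: int = 169) -> MixtureSpec:
    """Single shared component per class: classes differ only by the applied
    effect size (identical distributions at effect_size = 0)."""
    z = np.zeros((1, n_features))
    return MixtureSpec(centers={0: z.copy(), 1: z.copy()})


def simulate_feature_table(
    n_cells_per_class: int | dict[int, int],
    timepoints: int = 10,
    effect_size: float = 0.0,
    mixture: MixtureSpec | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series, pd.DataFrame]:
    """Draw a labelled 169-column feature table directly from the mixture.

    Each cell is assigned a class and one of its sub-phenotype components;
    its rows are ``component centre + class shift + per-cell offset + AR(1)
    temporal noise``.  The class shift adds ``effect_size`` pooled SD to each
    of the 10 EFFECT_COLUMNS of class 1.  Column names follow the manifest.

    Returns ``(table, labels, cell_truth)`` where ``labels`` maps cell_id to
    class and ``cell_truth`` also records the planted sub-phenotype component.
    """
    if mixture is None:
        mixture = default_mixture()
    if isinstance(n_cells_per_class, int):
        if n_cells_per_class <= 0:
            raise ValueError("n_cells_per_class must be positive")
        n_cells = {lab: n_cells_per_class for lab in mixture.labels}
    else:
        n_cells = dict(n_cells_per_class)
    if timepoints <= 0 or any(n <= 0 for n in n_cells.values()):
        raise ValueError("cell and timepoint counts must be positive")

    manifest = feature_manifest()
    n_features = len(manifest)
    rng = substream(seed, "feature_table")
    innovation_sd = float(np.sqrt(1.0 - AR1_RHO**2))  # stationary variance 1

    class_shift = {lab: np.zeros(n_features) for lab in mixture.labels}
    shift = np.zeros(n_features)
    shift[list(EFFECT_COLUMNS)] = effect_size * POOLED_SD
    class_shift[1] = shift

    blocks, meta = [], []
    cell_id = 0
    for lab in mixture.labels:
        centers = mixture.centers[lab] * POOLED_SD
        n_comp = centers.shape[0]
        for _ in range(n_cells[lab]):
            comp = int(rng.integers(n_comp))
            center = centers[comp] + class_shift[lab]
            cell_offset = rng.normal(0.0, CELL_SD, n_features)
            x = rng.normal(0.0, 1.0, n_features)  # stationary AR(1) start
            rows = np.empty((timepoints, n_features))
            for ti in range(timepoints):
                if ti > 0:
                    x = AR1_RHO * x + rng.normal(0.0, innovation_sd, n_features)
                rows[ti] = center + cell_offset + x
            blocks.append(rows)
            meta.append((cell_id, lab, comp))
            cell_id += 1

    n_rows_per_cell = timepoints
    cell_ids = np.repeat([m[0] for m in meta], n_rows_per_cell)
    times = np.tile(np.arange(timepoints), len(meta))
    table = pd.DataFrame(np.vstack(blocks), columns=list(manifest.names))
    table.insert(0, "time_min", times)
    table.insert(0, "cell_id", cell_ids)

    cell_truth = pd.DataFrame(meta, columns=["cell_id", "label", "subphenotype"])
    labels = cell_truth.set_index("cell_id")["label"]
    return table, labels, cell_truth
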