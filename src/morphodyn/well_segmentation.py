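"""Microwell cropping, cell delineation and single-live-cell filtering.

The stage positions of the instrument are programmed, so wells sit at known
grid coordinates and cropping is pure geometry (no detection).  Within each
crop the cell is delineated by Gaussian smoothing + Otsu thresholding +
morphological cleanup — a fully specified, testable alternative to an
interactive CellProfiler pipeline.  Only wells that hold exactly one live
cell survive to feature extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import filters

__all__ = [
    "GridGeometry",
    "WellBox",
    "CellTimeSeries",
    "locate_wells",
    "delineate_cell",
    "classify_occupancy",
    "filter_viability",
    "segment_stack",
]


@dataclass(frozen=True)
class GridGeometry:
    """Pixel-space layout of the microwell grid (0-based, half-open boxes)."""

    origin_row: int
    origin_col: int
    pitch_px: int
    rows: int
    cols: int

    @classmethod
    def from_plan(cls, plan) -> "GridGeometry":
        return cls(0, 0, plan.pitch_px, plan.grid_rows, plan.grid_cols)


@dataclass(frozen=True)
class WellBox:
    well_id: int
    row: int
    col: int
    r0: int
    c0: int
    r1: int
    c1: int

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.r0 : self.r1, self.c0 : self.c1]


@dataclass
class CellTimeSeries:
    """One retained well's per-frame masks and crops (cell_id = well_id)."""

    cell_id: int
    masks: list = field(repr=False)
    crops: list = field(repr=False)
    times_min: list = field(default_factory=list)
    alive: bool = True
    occupancy: list = field(default_factory=list)


def locate_wells(frame_shape: tuple[int, int], grid: GridGeometry) -> list[WellBox]:
    """rows x cols boxes of side = pitch, row-major well ids.

    Raises if any box exceeds the image, listing the offending wells.
    """
    H, W = frame_shape[:2]
    boxes, offending = [], []
    well_id = 0
    for r in range(grid.rows):
        for c in range(grid.cols):
            r0 = grid.origin_row + r * grid.pitch_px
            c0 = grid.origin_col + c * grid.pitch_px
            box = WellBox(well_id, r, c, r0, c0, r0 + grid.pitch_px, c0 + grid.pitch_px)
            if box.r0 < 0 or box.c0 < 0 or box.r1 > H or box.c1 > W:
                offending.append(well_id)
            boxes.append(box)
            well_id += 1
    if offending:
        raise ValueError(
            f"well boxes exceed the {H}x{W} image for wells {offending}"
        )
    return boxes


#: minimum Otsu foreground/background mean separation (counts) for a crop to
#: count as containing an object at all; rejects faint structure such as the
#: microwell walls, which sit only ~20 counts above background while cells sit
#: hundreds above
DEFAULT_MIN_CONTRAST = 50.0


def _threshold(
    crop: np.ndarray, sigma: float, min_contrast: float = DEFAULT_MIN_CONTRAST
) -> np.ndarray:
    smoothed = filters.gaussian(crop.astype(float), sigma=sigma, preserve_range=True)
    if smoothed.max() == smoothed.min():
        return np.zeros(crop.shape, bool)
    thr = filters.threshold_otsu(smoothed)
    fg = smoothed > thr
    if not fg.any() or fg.all():
        return np.zeros(crop.shape, bool)
    if smoothed[fg].mean() - smoothed[~fg].mean() < min_contrast:
        return np.zeros(crop.shape, bool)
    return fg


_SE = np.ones((3, 3), bool)


def delineate_cell(
    crop: np.ndarray, sigma: float = 1.0, min_contrast: float = DEFAULT_MIN_CONTRAST
) -> np.ndarray:
    """Binary mask of the (single) cell in a well crop.

    Gaussian smoothing (sigma px) -> Otsu threshold -> 3x3 binary opening then
    closing -> hole filling -> largest connected component.  An empty mask is
    a valid result (no object above threshold).  The threshold is relative, so
    adding a constant offset to the image leaves the mask unchanged.
    """
    binary = _threshold(crop, sigma, min_contrast)
    binary = ndi.binary_opening(binary, structure=_SE)
    binary = ndi.binary_closing(binary, structure=_SE)
    binary = ndi.binary_fill_holes(binary)
    labels, n = ndi.label(binary, structure=_SE)
    if n == 0:
        return np.zeros(crop.shape, bool)
    sizes = ndi.sum_labels(binary, labels, index=np.arange(1, n + 1))
    # argmax returns the first maximum -> ties break toward lower scan order
    keep = int(np.argmax(sizes)) + 1
    return labels == keep


def classify_occupancy(
    crop: np.ndarray,
    sigma: float = 1.0,
    min_area: int = 30,
    min_contrast: float = DEFAULT_MIN_CONTRAST,
) -> str:
    """'empty' / 'single' / 'multi' from the component census of one crop.

    Counting happens after thresholding and opening but before the
    keep-largest cleanup, so a second cell is still visible here.
    """
    binary = ndi.binary_opening(_threshold(crop, sigma, min_contrast), structure=_SE)
    labels, n = ndi.label(binary, structure=_SE)
    if n == 0:
        return "empty"
    sizes = ndi.sum_labels(binary, labels, index=np.arange(1, n + 1))
    n_big = int((sizes >= min_area).sum())
    if n_big == 0:
        return "empty"
    return "multi" if n_big >= 2 else "single"


def filter_viability(
    cells: list[CellTimeSeries],
    viability_frame: np.ndarray | None,
    boxes: list[WellBox],
    contrast: float = 100.0,
    min_fraction: float = 0.005,
) -> list[CellTimeSeries]:
    """Drop cells whose well lights up in the end-of-run viability frame.

    A well is called dead when more than ``min_fraction`` of its box exceeds
    the frame median (robust background estimate) by ``contrast`` counts — a
    stained cell occupies a few percent of its box at hundreds of counts,
    whereas well walls and camera noise stay far below both cutoffs.  A
    missing frame passes everything through with a warning.
    """
    if viability_frame is None:
        warnings.warn("no viability frame supplied; keeping all cells")
        return list(cells)
    background = float(np.median(viability_frame))
    box_by_id = {b.well_id: b for b in boxes}
    kept, dropped = [], 0
    for cell in cells:
        box = box_by_id[cell.cell_id]
        crop = box.crop(viability_frame).astype(float)
        score = float((crop > background + contrast).mean())
        if score > min_fraction:
            dropped += 1
            cell.alive = False
        else:
            kept.append(cell)
    if dropped:
        warnings.warn(f"viability filter dropped {dropped} of {len(cells)} cells")
    if not kept:
        warnings.warn("viability filter removed every cell")
    return kept


def segment_stack(
    stack: np.ndarray,
    grid: GridGeometry,
    viability_frame: np.ndarray | None = None,
    times_min: np.ndarray | None = None,
    sigma: float = 1.0,
    min_area: int = 30,
    min_contrast: float = DEFAULT_MIN_CONTRAST,
    max_multi_fraction: float = 0.2,
    min_single_fraction: float = 0.8,
    viability_contrast: float = 100.0,
    viability_min_fraction: float = 0.005,
) -> tuple[list[CellTimeSeries], pd.DataFrame]:
    """End-to-end segmentation of a time-lapse stack.

    A well is retained when it is single-occupancy in at least
    ``min_single_fraction`` of frames and multi-occupancy in fewer than
    ``max_multi_fraction`` (transient contact with a neighbour disqualifies
    the well — "only single cells" taken conservatively), and it passes the
    viability filter.  Returns the retained cells plus a per-well summary
    table (well_id, occupancy_summary, retained, alive).
    """
    n_frames = stack.shape[0]
    if times_min is None:
        times_min = np.arange(n_frames)
    boxes = locate_wells(stack.shape[1:], grid)

    candidates, summary = [], []
    for box in boxes:
        occ = []
        masks, crops = [], []
        for f in range(n_frames):
            crop = box.crop(stack[f])
            occ.append(classify_occupancy(crop, sigma, min_area, min_contrast))
            crops.append(crop)
            masks.append(delineate_cell(crop, sigma, min_contrast))
        occ_arr = np.array(occ)
        single_frac = float((occ_arr == "single").mean())
        multi_frac = float((occ_arr == "multi").mean())
        is_single = single_frac >= min_single_fraction and multi_frac < max_multi_fraction
        if is_single:
            candidates.append(
                CellTimeSeries(
                    cell_id=box.well_id,
                    masks=masks,
                    crops=crops,
                    times_min=[int(t) for t in times_min],
                    occupancy=occ,
                )
            )
        summary.append(
            {
                "well_id": box.well_id,
                "single_fraction": single_frac,
                "multi_fraction": multi_frac,
                "occupancy_summary": "single" if is_single else
                ("multi" if multi_frac >= max_multi_fraction else "empty"),
                "retained": is_single,
            }
        )
    retained = filter_viability(
        candidates, viability_frame, boxes, viability_contrast, viability_min_fraction
    )
    retained_ids = {c.cell_id for c in retained}
    table = pd.DataFrame(summary)
    table["alive"] = [
        not (row.retained and row.well_id not in retained_ids)
        for row in table.itertuples()
    ]
    table["retained"] = table["well_id"].isin(retained_ids)
    return retained, table
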