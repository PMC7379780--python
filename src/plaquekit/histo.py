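"""2D slide quantification: compaction, radial cell counts, marker area, FISH.

Operations mirror the slide-based measurements of the study:

* thresholded stain area inside a region of interest,
* plaque compaction (OC/X34 area ratio) and the percent of OC signal not
  bound to a compact X34 core,
* counts of cell nuclei in concentric bands 10/20/40/60 µm from the
  plaque edge,
* marker (APOE/LAMP1-like) area associated with plaques,
* RNAscope puncta coverage near a plaque (50 µm ROI) versus the mean of
  randomly placed background ROIs, and per-microglia Apoe FISH intensity.

All areas and distances are physical (µm², µm) via the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage.measure import label as sk_label

__all__ = [
    "SlideScene",
    "CompactionMeasure",
    "RadialCountProfile",
    "FishMeasure",
    "threshold_area",
    "compaction_metrics",
    "radial_cell_counts",
    "plaque_associated_area",
    "fish_near_far",
    "apoe_per_microglia",
]

RADIAL_DISTANCES = (10.0, 20.0, 40.0, 60.0)


@dataclass
class SlideScene:
    """Named 2D channels plus nucleus annotations for one slide."""

    channels: dict[str, np.ndarray]
    pixel_size: float  # µm per pixel
    nucleus_labels: np.ndarray | None = None  # int label map, 0 = background
    nuclei: pd.DataFrame | None = None  # nucleus_id, y_um, x_um, cell_class
    rois: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {ch: a.shape for ch, a in self.channels.items()}
        if len(set(shapes.values())) > 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def pixel_area(self) -> float:
        return self.pixel_size**2


@dataclass
class CompactionMeasure:
    x34_area: float  # µm²
    oc_area: float  # µm²
    oc_x34_ratio: float | None  # missing when no X34 core present
    noncore_oc_percent: float


@dataclass
class RadialCountProfile:
    """Cell counts around one plaque; cumulative and per-annulus conventions."""

    distances: tuple[float, ...]
    cumulative: pd.DataFrame  # rows: cell class; columns: distances
    annulus: pd.DataFrame
    cell_distances: pd.DataFrame  # nucleus_id/class/distance_um/inside_plaque


@dataclass
class FishMeasure:
    near_area_percent: float
    far_area_percent: float
    far_percents: tuple[float, ...]
    background_centers_um: tuple[tuple[float, float], ...]


def threshold_area(
    channel: np.ndarray,
    threshold: float,
    roi: np.ndarray | None = None,
    pixel_size: float = 1.0,
) -> dict[str, float]:
    """Stain-positive area and percent coverage inside an ROI.

    ``roi=None`` means the whole image.  Returns ``{"area_um2", "percent"}``
    with area = positive-pixel count × pixel area and percent relative to
    the ROI area.
    """
    if roi is None:
        roi = np.ones(channel.shape, dtype=bool)
    n_roi = int(np.count_nonzero(roi))
    if n_roi == 0:
        raise ValueError("empty ROI")
    positive = (channel >= threshold) & roi
    n_pos = int(np.count_nonzero(positive))
    pa = pixel_size**2
    return {"area_um2": n_pos * pa, "percent": 100.0 * n_pos / n_roi}


def compaction_metrics(
    x34_mask: np.ndarray,
    oc_mask: np.ndarray,
    pixel_size: float = 1.0,
) -> CompactionMeasure:
    """Plaque-compaction measures from the X34 (core) and OC (total) masks.

    The OC/X34 area ratio indexes compaction (larger = less compact).  An OC
    connected component is core-bound iff it overlaps at least one
    X34-positive pixel; ``noncore_oc_percent`` is the OC area in components
    with no core, as a percent of total OC area.  Conventions: no OC signal
    -> ratio 0 and noncore 0; OC present but no X34 -> ratio missing,
    noncore 100.
    """
    if x34_mask.shape != oc_mask.shape:
        raise ValueError("masks must share shape")
    pa = pixel_size**2
    x34_area = float(np.count_nonzero(x34_mask)) * pa
    oc_area = float(np.count_nonzero(oc_mask)) * pa
    if oc_area == 0:
        return CompactionMeasure(x34_area, 0.0, 0.0, 0.0)
    if x34_area == 0:
        return CompactionMeasure(0.0, oc_area, None, 100.0)
    comps = sk_label(oc_mask, connectivity=2)
    core_labels = np.unique(comps[(comps > 0) & x34_mask.astype(bool)])
    noncore_pixels = int(np.count_nonzero((comps > 0) & ~np.isin(comps, core_labels)))
    noncore_percent = 100.0 * noncore_pixels * pa / oc_area
    return CompactionMeasure(x34_area, oc_area, oc_area / x34_area, noncore_percent)


def cell_edge_distances(
    plaque_mask: np.ndarray,
    positions_um: np.ndarray,
    pixel_size: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Distance of each cell centroid to the plaque (nearest positive pixel).

    Returns ``(distances_um, inside)``; cells whose centroid pixel is
    plaque-positive are flagged inside (distance 0).
    """
    if not plaque_mask.any():
        raise ValueError("plaque mask is empty")
    positions_um = np.atleast_2d(np.asarray(positions_um, dtype=float))
    plaque_px = np.argwhere(plaque_mask) * pixel_size
    tree = cKDTree(plaque_px)
    d, _ = tree.query(positions_um, k=1)
    ij = np.round(positions_um / pixel_size).astype(int)
    ij[:, 0] = np.clip(ij[:, 0], 0, plaque_mask.shape[0] - 1)
    ij[:, 1] = np.clip(ij[:, 1], 0, plaque_mask.shape[1] - 1)
    inside = plaque_mask[ij[:, 0], ij[:, 1]]
    return d, inside


def radial_cell_counts(
    plaque_mask: np.ndarray,
    cells: pd.DataFrame,
    pixel_size: float,
    distances: Sequence[float] = RADIAL_DISTANCES,
) -> RadialCountProfile:
    """Count cells per class within 10/20/40/60 µm of the plaque edge.

    ``cells`` needs ``y_um``/``x_um``/``cell_class`` columns (and optionally
    ``nucleus_id``).  Counts are cumulative in distance (a cell 15 µm out is
    counted at 20, 40 and 60 µm); a per-annulus table is also returned.
    Cells whose centroid lies inside the plaque mask are excluded.
    """
    distances = tuple(float(d) for d in distances)
    if list(distances) != sorted(distances):
        raise ValueError("distances must be increasing")
    if len(cells) == 0:
        zeros = pd.DataFrame(columns=list(distances))
        empty = pd.DataFrame(columns=["nucleus_id", "cell_class", "distance_um", "inside_plaque"])
        return RadialCountProfile(distances, zeros, zeros.copy(), empty)
    pos = cells[["y_um", "x_um"]].to_numpy(float)
    d, inside = cell_edge_distances(plaque_mask, pos, pixel_size)
    table = pd.DataFrame(
        {
            "nucleus_id": cells.get("nucleus_id", pd.Series(range(len(cells)))).to_numpy(),
            "cell_class": cells["cell_class"].to_numpy(),
            "distance_um": d,
            "inside_plaque": inside,
        }
    )
    classes = sorted(table["cell_class"].unique())
    cum = pd.DataFrame(0, index=classes, columns=list(distances))
    ann = pd.DataFrame(0, index=classes, columns=list(distances))
    outside = table[~table["inside_plaque"]]
    lower = (0.0,) + distances[:-1]
    for cls in classes:
        dc = outside.loc[outside["cell_class"] == cls, "distance_um"]
        for lo, hi in zip(lower, distances):
            cum.loc[cls, hi] = int((dc <= hi).sum())
            ann.loc[cls, hi] = int(((dc > lo) & (dc <= hi)).sum())
    return RadialCountProfile(distances, cum, ann, table)


def plaque_associated_area(
    marker_mask: np.ndarray,
    plaque_mask: np.ndarray,
    pixel_size: float,
    association_radius: float = 0.0,
) -> float:
    """Marker-positive area (µm²) within the plaque mask dilated by a radius.

    ``association_radius=0`` counts only direct overlap.  The dilation is
    Euclidean (pixels within the radius of a plaque-positive pixel).
    """
    if marker_mask.shape != plaque_mask.shape:
        raise ValueError("masks must share shape")
    if association_radius < 0:
        raise ValueError("association_radius must be >= 0")
    if association_radius > 0 and plaque_mask.any():
        dist = ndimage.distance_transform_edt(
            ~plaque_mask.astype(bool), sampling=(pixel_size, pixel_size)
        )
        region = dist <= association_radius
    else:
        region = plaque_mask.astype(bool)
    return float(np.count_nonzero(marker_mask.astype(bool) & region)) * pixel_size**2


def _disc_fraction(
    mask: np.ndarray, center_um: tuple[float, float], radius_um: float, pixel_size: float
) -> float:
    """Percent of disc pixels that are mask-positive."""
    h, w = mask.shape
    yy = np.arange(h) * pixel_size - center_um[0]
    xx = np.arange(w) * pixel_size - center_um[1]
    disc = yy[:, None] ** 2 + xx[None, :] ** 2 <= radius_um**2
    n = int(disc.sum())
    if n == 0:
        raise ValueError("disc contains no pixels")
    return 100.0 * int(np.count_nonzero(mask & disc)) / n


def fish_near_far(
    puncta_mask: np.ndarray,
    plaque_centers_um: Sequence[tuple[float, float]],
    target_center_um: tuple[float, float],
    pixel_size: float,
    radius: float = 50.0,
    n_background: int = 4,
    seed: int = 0,
    max_tries: int = 10000,
) -> FishMeasure:
    """Puncta coverage in the 50 µm plaque ROI vs random background ROIs.

    ``near`` is the percent of pixels positive for puncta inside the disc of
    ``radius`` µm about the target plaque center.  ``far`` is the mean over
    ``n_background`` seeded random discs of identical area placed entirely
    outside every plaque ROI (center more than 2 × ``radius`` from every
    plaque center, so the measured background area lies wholly beyond
    ``radius`` of any plaque) and entirely in the image.  Raises if the
    background ROIs cannot be placed within ``max_tries`` draws.
    """
    rng = np.random.default_rng(seed)
    h, w = puncta_mask.shape
    extent = ((h - 1) * pixel_size, (w - 1) * pixel_size)
    if extent[0] < 2 * radius or extent[1] < 2 * radius:
        raise ValueError("image too small to host a background ROI of this radius")
    near = _disc_fraction(puncta_mask, target_center_um, radius, pixel_size)
    centers = []
    tries = 0
    plaque_centers = [np.asarray(c, float) for c in plaque_centers_um]
    while len(centers) < n_background:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_background} background ROIs of radius {radius} µm "
                f"after {max_tries} tries"
            )
        tries += 1
        c = rng.uniform([radius, radius], [extent[0] - radius, extent[1] - radius])
        if all(np.linalg.norm(c - p) > 2 * radius for p in plaque_centers):
            centers.append(c)
    far_vals = tuple(
        _disc_fraction(puncta_mask, tuple(c), radius, pixel_size) for c in centers
    )
    return FishMeasure(
        near_area_percent=near,
        far_area_percent=float(np.mean(far_vals)),
        far_percents=far_vals,
        background_centers_um=tuple(tuple(map(float, c)) for c in centers),
    )


def apoe_per_microglia(
    apoe_channel: np.ndarray,
    cell_regions: np.ndarray,
    roi_mask: np.ndarray | None = None,
) -> float | None:
    """Summed Apoe FISH intensity per Tmem119-positive cell within an ROI.

    ``cell_regions`` is an integer label map of Tmem119-positive cell
    outlines (0 = background).  A cell belongs to the ROI if any of its
    pixels intersects it; the Apoe intensity is summed over the cell
    regions restricted to the ROI and divided by the number of such cells.
    Returns ``None`` (missing, not zero) when no cell intersects the ROI.
    """
    if roi_mask is None:
        roi_mask = np.ones(apoe_channel.shape, dtype=bool)
    in_roi = cell_regions[roi_mask & (cell_regions > 0)]
    cells = np.unique(in_roi)
    if cells.size == 0:
        return None
    region = np.isin(cell_regions, cells) & roi_mask
    total = float(apoe_channel[region].sum())
    return total / cells.size
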