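"""Two-timepoint 3D plaque volumetry and microglial-barrier morphometry.

Implements the voxel-based analogue of an Imaris surface workflow for
X04 / Thiazine Red (TR) / IBA1 triple-stained confocal stacks:

* background removal at a fixed intensity floor (default 500),
* connected-component segmentation of the amyloid channels,
* voxel-face surface area in physical units (anisotropic voxels),
* a one-voxel shell around each TR plaque,
* percent microglial surface contact (shell voxels touched by IBA1),
* exposed surface area (surface not covered by microglia),
* X04<->TR plaque matching, growth = TR − X04 volume, fold change TR/X04,
* inclusion filters (>=50 µm from the lateral tissue edge and from other
  plaques) and the zero-growth control calibration (TR-on-X04 regression).

All distances, areas and volumes are in µm-based physical units derived
from the per-axis voxel size (z, y, x).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage, stats
from scipy.spatial import cKDTree

__all__ = [
    "VoxelStack",
    "SegmentationParams",
    "PlaqueObject",
    "PlaqueDynamics",
    "remove_background",
    "segment_plaques",
    "surface_area_from_mask",
    "make_shell",
    "percent_surface_contact",
    "exposed_surface_area",
    "match_plaques",
    "plaque_dynamics",
    "inclusion_filter",
    "control_calibration",
    "analyze_stack",
    "binarize_channel",
]

DEFAULT_BACKGROUND_THRESHOLD = 500

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class VoxelStack:
    """Multi-channel 3D intensity grid with per-axis voxel size in µm.

    ``channels`` maps channel names (e.g. ``"X04"``, ``"TR"``, ``"IBA1"``)
    to non-negative integer arrays of identical ``(z, y, x)`` shape;
    ``voxel_size`` is ``(dz, dy, dx)`` in µm.
    """

    channels: dict[str, np.ndarray]
    voxel_size: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("VoxelStack needs at least one channel")
        shapes = {ch: arr.shape for ch, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channels disagree on shape: {shapes}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise ValueError(f"voxel_size must be 3 positive values, got {self.voxel_size}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def voxel_volume(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def require(self, *names: str) -> None:
        missing = [n for n in names if n not in self.channels]
        if missing:
            raise KeyError(f"stack is missing channel(s): {missing}; has {sorted(self.channels)}")


@dataclass
class SegmentationParams:
    """Segmentation parameters for the amyloid/IBA1 channels.

    ``background_threshold`` is the intensity floor removed from all channels
    (default 500).  ``object_threshold`` binarizes a channel for component
    labeling; ``None`` falls back to the background threshold, the string
    ``"otsu"`` selects an Otsu threshold on the nonzero voxels.
    """

    background_threshold: float = DEFAULT_BACKGROUND_THRESHOLD
    object_threshold: float | str | None = None
    min_object_voxels: int = 10
    connectivity: int = 26
    shell_connectivity: int = 26

    def __post_init__(self) -> None:
        if self.background_threshold < 0:
            raise ValueError("background_threshold must be >= 0")
        if self.connectivity not in _STRUCTS:
            raise ValueError(f"connectivity must be one of {sorted(_STRUCTS)}")
        if self.shell_connectivity not in _STRUCTS:
            raise ValueError(f"shell_connectivity must be one of {sorted(_STRUCTS)}")
        if self.min_object_voxels < 1:
            raise ValueError("min_object_voxels must be >= 1")


@dataclass
class PlaqueObject:
    """A segmented connected component with voxel-derived morphometry."""

    id: int
    channel: str
    coords: np.ndarray  # (n, 3) int voxel indices (z, y, x)
    image_shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    volume: float  # µm³
    surface_area: float  # µm²
    shell_coords: np.ndarray  # (m, 3) int voxel indices
    centroid: tuple[float, float, float]  # µm
    distance_to_stack_edge: float  # µm, lateral (y, x) borders
    distance_to_nearest_plaque: float = math.inf  # µm, boundary-to-boundary

    @property
    def n_voxels(self) -> int:
        return len(self.coords)

    def mask(self) -> np.ndarray:
        out = np.zeros(self.image_shape, dtype=bool)
        out[tuple(self.coords.T)] = True
        return out


@dataclass
class PlaqueDynamics:
    """Matched X04/TR pair with growth and barrier metrics."""

    x04_id: int | None
    tr_id: int
    x04_volume: float
    tr_volume: float
    growth: float
    fold_change: float | None
    percent_surface_contact: float
    exposed_surface_area: float
    tr_surface_area: float


def remove_background(stack: VoxelStack, threshold: float = DEFAULT_BACKGROUND_THRESHOLD) -> VoxelStack:
    """Zero all voxels below ``threshold`` in every channel.

    Voxels with intensity < threshold are set to 0; all others are unchanged.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    cleaned = {ch: np.where(arr < threshold, 0, arr) for ch, arr in stack.channels.items()}
    return VoxelStack(cleaned, stack.voxel_size)


def binarize_channel(stack: VoxelStack, channel: str, params: SegmentationParams) -> np.ndarray:
    """Binarize one channel using the object threshold (or Otsu on nonzeros)."""
    stack.require(channel)
    arr = stack.channels[channel]
    thr = params.object_threshold
    if thr is None:
        thr = params.background_threshold
    if isinstance(thr, str):
        if thr.lower() != "otsu":
            raise ValueError(f"unknown threshold method {thr!r}")
        from skimage.filters import threshold_otsu

        nz = arr[arr > 0]
        if nz.size == 0:
            return np.zeros(arr.shape, dtype=bool)
        thr = float(threshold_otsu(nz))
    return arr >= thr


def surface_area_from_mask(mask: np.ndarray, voxel_size: Sequence[float]) -> float:
    """Voxel-face surface area of a binary mask in µm².

    Each face of a positive voxel not shared with another positive voxel
    contributes its physical face area; faces on the image border count as
    exposed.  For voxel size (dz, dy, dx) a face perpendicular to z has
    area dy*dx, etc.
    """
    if not mask.any():
        raise ValueError("mask is empty")
    dz, dy, dx = (float(v) for v in voxel_size)
    face_areas = (dy * dx, dz * dx, dz * dy)  # perpendicular to z, y, x
    total = 0.0
    m = mask.astype(np.int8)
    for axis, fa in enumerate(face_areas):
        padded = np.pad(m, [(1, 1) if a == axis else (0, 0) for a in range(3)])
        diff = np.abs(np.diff(padded, axis=axis))
        total += fa * int(diff.sum())
    return total


def make_shell(
    mask: np.ndarray,
    connectivity: int = 26,
) -> np.ndarray:
    """One-voxel shell around a binary object, clipped at the image bounds.

    Returns the boolean mask of voxels outside the object but within one
    step (6/18/26-neighborhood) of an object voxel.
    """
    if not mask.any():
        raise ValueError("cannot build a shell around an empty object")
    dilated = ndimage.binary_dilation(mask, structure=_STRUCTS[connectivity])
    return dilated & ~mask


def percent_surface_contact(shell_mask: np.ndarray, iba1_mask: np.ndarray) -> float:
    """Percent of shell voxels colocalized with IBA1 signal, in [0, 100]."""
    n_shell = int(np.count_nonzero(shell_mask))
    if n_shell == 0:
        raise ValueError("empty shell: degenerate object")
    n_contact = int(np.count_nonzero(shell_mask & iba1_mask))
    return 100.0 * n_contact / n_shell


def exposed_surface_area(surface_area: float, contact_percent: float) -> float:
    """Surface area not covered by microglia: total × (1 − contact/100)."""
    if not 0.0 <= contact_percent <= 100.0:
        raise ValueError("contact_percent must lie in [0, 100]")
    return surface_area * (1.0 - contact_percent / 100.0)


def _boundary_coords_fast(mask: np.ndarray) -> np.ndarray:
    eroded = ndimage.binary_erosion(mask, structure=_STRUCTS[6], border_value=0)
    return np.argwhere(mask & ~eroded)


def segment_plaques(
    stack: VoxelStack,
    channel: str,
    params: SegmentationParams | None = None,
) -> list[PlaqueObject]:
    """Segment connected components of a binarized channel into plaque objects.

    Components smaller than ``min_object_voxels`` are discarded.  Each object
    carries volume, face surface area, the one-voxel shell, centroid and
    lateral edge distance in physical µm; pairwise nearest-plaque distances
    (boundary-to-boundary) are filled in when 2+ objects are present.
    An empty segmentation returns an empty list.
    """
    params = params or SegmentationParams()
    mask = binarize_channel(stack, channel, params)
    labels, n = ndimage.label(mask, structure=_STRUCTS[params.connectivity])
    if n == 0:
        return []
    dz, dy, dx = stack.voxel_size
    vox_vol = stack.voxel_volume
    objects: list[PlaqueObject] = []
    slices = ndimage.find_objects(labels)
    shape = stack.shape
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        local = labels[sl] == lab
        n_vox = int(local.sum())
        if n_vox < params.min_object_voxels:
            continue
        offset = np.array([s.start for s in sl], dtype=np.int64)
        # pad by one voxel (clipped to image bounds) so shell/surface see the
        # true neighborhood of the component
        lo = np.maximum(offset - 1, 0)
        hi = np.minimum(np.array([s.stop for s in sl]) + 1, np.array(shape))
        box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
        boxed = labels[box] == lab
        coords = np.argwhere(boxed) + lo
        surface = surface_area_from_mask(boxed, stack.voxel_size)
        shell_local = make_shell(boxed, params.shell_connectivity)
        # shell voxels outside the padded box cannot exist: the box includes a
        # 1-voxel margin except where clipped by the image border, where the
        # shell is clipped too.
        shell_coords = np.argwhere(shell_local) + lo
        phys = coords * np.array([dz, dy, dx])
        centroid = tuple(float(c) for c in phys.mean(axis=0))
        # lateral distance from the object to the (y, x) image borders
        ys, xs = coords[:, 1], coords[:, 2]
        edge_dist = min(
            float(ys.min()) * dy,
            float(shape[1] - 1 - ys.max()) * dy,
            float(xs.min()) * dx,
            float(shape[2] - 1 - xs.max()) * dx,
        )
        objects.append(
            PlaqueObject(
                id=lab,
                channel=channel,
                coords=coords,
                image_shape=shape,
                voxel_size=stack.voxel_size,
                volume=n_vox * vox_vol,
                surface_area=surface,
                shell_coords=shell_coords,
                centroid=centroid,
                distance_to_stack_edge=edge_dist,
            )
        )
    _fill_neighbor_distances(objects)
    return objects


def _fill_neighbor_distances(objects: list[PlaqueObject]) -> None:
    """Boundary-to-boundary nearest-plaque distance for each object (µm)."""
    if len(objects) < 2:
        return
    scale = np.array(objects[0].voxel_size)
    trees = []
    for obj in objects:
        mask = obj.mask()
        bnd = _boundary_coords_fast(mask)
        trees.append(cKDTree(bnd * scale))
    pts = [t.data for t in trees]
    for i, obj in enumerate(objects):
        best = math.inf
        for j, tree in enumerate(trees):
            if j == i:
                continue
            d, _ = tree.query(pts[i], k=1)
            best = min(best, float(np.min(d)))
        obj.distance_to_nearest_plaque = best


def match_plaques(
    x04_objects: Sequence[PlaqueObject],
    tr_objects: Sequence[PlaqueObject],
) -> tuple[list[tuple[int, int, int]], list[int], list[int], list[dict]]:
    """Pair TR objects with X04 objects by maximal voxel overlap.

    Greedy one-to-one assignment in decreasing overlap (ties broken by larger
    overlap fraction of the TR object, then lower ids).  Returns
    ``(pairs, unmatched_tr_ids, unmatched_x04_ids, conflict_log)`` where each
    pair is ``(x04_id, tr_id, overlap_voxels)``.  TR objects with zero X04
    overlap are the "new deposit" candidates.
    """
    if not tr_objects:
        return [], [], [o.id for o in x04_objects], []
    shape = tr_objects[0].image_shape
    x04_label = np.zeros(shape, dtype=np.int32)
    for obj in x04_objects:
        x04_label[tuple(obj.coords.T)] = obj.id
    candidates = []
    for tr in tr_objects:
        labs = x04_label[tuple(tr.coords.T)]
        labs = labs[labs > 0]
        if labs.size == 0:
            continue
        counts = np.bincount(labs)
        for x04_id in np.nonzero(counts)[0]:
            ov = int(counts[x04_id])
            candidates.append((ov, ov / tr.n_voxels, -int(x04_id), -tr.id))
    candidates.sort(reverse=True)
    used_x04: set[int] = set()
    used_tr: set[int] = set()
    pairs: list[tuple[int, int, int]] = []
    conflicts: list[dict] = []
    for ov, frac, neg_x, neg_t in candidates:
        x04_id, tr_id = -neg_x, -neg_t
        if x04_id in used_x04 or tr_id in used_tr:
            conflicts.append(
                {"x04_id": x04_id, "tr_id": tr_id, "overlap": ov, "assigned": False}
            )
            continue
        used_x04.add(x04_id)
        used_tr.add(tr_id)
        pairs.append((x04_id, tr_id, ov))
    unmatched_tr = [o.id for o in tr_objects if o.id not in used_tr]
    unmatched_x04 = [o.id for o in x04_objects if o.id not in used_x04]
    return pairs, unmatched_tr, unmatched_x04, conflicts


def plaque_dynamics(
    tr_object: PlaqueObject,
    x04_object: PlaqueObject | None,
    iba1_mask: np.ndarray,
) -> PlaqueDynamics:
    """Growth, fold change and barrier metrics for one matched pair.

    ``x04_object=None`` denotes a new deposit: growth equals the TR volume and
    the fold change is reported missing.  Contact and exposed area are
    computed on the TR object's shell.
    """
    shell_mask = np.zeros(tr_object.image_shape, dtype=bool)
    shell_mask[tuple(tr_object.shell_coords.T)] = True
    contact = percent_surface_contact(shell_mask, iba1_mask)
    exposed = exposed_surface_area(tr_object.surface_area, contact)
    x04_volume = x04_object.volume if x04_object is not None else 0.0
    growth = tr_object.volume - x04_volume
    fold = tr_object.volume / x04_volume if x04_volume > 0 else None
    return PlaqueDynamics(
        x04_id=x04_object.id if x04_object is not None else None,
        tr_id=tr_object.id,
        x04_volume=x04_volume,
        tr_volume=tr_object.volume,
        growth=growth,
        fold_change=fold,
        percent_surface_contact=contact,
        exposed_surface_area=exposed,
        tr_surface_area=tr_object.surface_area,
    )


def inclusion_filter(
    objects: Sequence[PlaqueObject],
    min_edge_dist: float = 50.0,
    min_neighbor_dist: float = 50.0,
) -> tuple[list[PlaqueObject], list[tuple[PlaqueObject, str]]]:
    """Apply the plaque-selection filters (distances in µm).

    Keeps objects at least ``min_edge_dist`` from the lateral image edge and
    at least ``min_neighbor_dist`` (boundary-to-boundary) from any other
    plaque.  Returns ``(kept, [(rejected, primary_reason), ...])``; the edge
    rule is checked first.
    """
    kept: list[PlaqueObject] = []
    rejected: list[tuple[PlaqueObject, str]] = []
    for obj in objects:
        if obj.distance_to_stack_edge < min_edge_dist:
            rejected.append((obj, "edge"))
        elif obj.distance_to_nearest_plaque < min_neighbor_dist:
            rejected.append((obj, "neighbor"))
        else:
            kept.append(obj)
    return kept, rejected


def control_calibration(dynamics: pd.DataFrame) -> dict:
    """Zero-growth control summary: OLS of TR volume on X04 volume.

    Expects a table with ``x04_volume``, ``tr_volume``, ``growth`` and
    ``fold_change`` columns (new deposits, with missing fold change, are
    excluded from the regression).  Returns mean growth, mean fold change,
    regression slope/intercept and R² (squared Pearson r).
    """
    d = dynamics.dropna(subset=["fold_change"])
    if len(d) < 3:
        raise ValueError("control calibration needs at least 3 matched pairs")
    x = d["x04_volume"].to_numpy(float)
    y = d["tr_volume"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("zero variance in X04 volumes: regression undefined")
    res = stats.linregress(x, y)
    return {
        "n": int(len(d)),
        "mean_growth": float(d["growth"].mean()),
        "mean_fold_change": float(d["fold_change"].mean()),
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue ** 2),
    }


def analyze_stack(
    stack: VoxelStack,
    params: SegmentationParams | None = None,
    apply_inclusion: bool = False,
    min_edge_dist: float = 50.0,
    min_neighbor_dist: float = 50.0,
) -> pd.DataFrame:
    """Full two-timepoint analysis of one stack -> per-plaque dynamics table.

    Removes background, segments X04 and TR, matches plaques, and computes
    growth/contact/exposure per matched TR object.  With
    ``apply_inclusion=True`` TR objects failing the 50 µm edge/neighbor rules
    are dropped (reasons recorded in the ``included``/``reject_reason``
    columns either way).
    """
    params = params or SegmentationParams()
    stack.require("X04", "TR", "IBA1")
    clean = remove_background(stack, params.background_threshold)
    x04_objs = segment_plaques(clean, "X04", params)
    tr_objs = segment_plaques(clean, "TR", params)
    iba1_mask = binarize_channel(clean, "IBA1", params)
    pairs, unmatched_tr, _, _ = match_plaques(x04_objs, tr_objs)
    x04_by_id = {o.id: o for o in x04_objs}
    tr_by_id = {o.id: o for o in tr_objs}
    reject = {}
    if tr_objs:
        _, rejected = inclusion_filter(tr_objs, min_edge_dist, min_neighbor_dist)
        reject = {obj.id: reason for obj, reason in rejected}
    rows = []
    for x04_id, tr_id, _ov in pairs:
        dyn = plaque_dynamics(tr_by_id[tr_id], x04_by_id[x04_id], iba1_mask)
        rows.append(dyn)
    for tr_id in unmatched_tr:
        rows.append(plaque_dynamics(tr_by_id[tr_id], None, iba1_mask))
    records = []
    for dyn in rows:
        tr_obj = tr_by_id[dyn.tr_id]
        records.append(
            {
                "x04_id": dyn.x04_id,
                "tr_id": dyn.tr_id,
                "x04_volume": dyn.x04_volume,
                "tr_volume": dyn.tr_volume,
                "growth": dyn.growth,
                "fold_change": dyn.fold_change,
                "percent_surface_contact": dyn.percent_surface_contact,
                "tr_surface_area": dyn.tr_surface_area,
                "exposed_surface_area": dyn.exposed_surface_area,
                "distance_to_stack_edge": tr_obj.distance_to_stack_edge,
                "distance_to_nearest_plaque": tr_obj.distance_to_nearest_plaque,
                "reject_reason": reject.get(dyn.tr_id),
                "included": dyn.tr_id not in reject,
            }
        )
    df = pd.DataFrame.from_records(
        records,
        columns=[
            "x04_id", "tr_id", "x04_volume", "tr_volume", "growth", "fold_change",
            "percent_surface_contact", "tr_surface_area", "exposed_surface_area",
            "distance_to_stack_edge", "distance_to_nearest_plaque",
            "reject_reason", "included",
        ],
    )
    if apply_inclusion and len(df):
        df = df[df["included"]].reset_index(drop=True)
    return df
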