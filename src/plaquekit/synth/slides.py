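"""Synthetic 2D histology/FISH slides with known ground truth.

Each slide emulates a multi-channel fluorescence image of amyloid
pathology: compact plaque cores (X34), diffuse halos (OC), a plaque-area
marker channel (APOE/LAMP1-like staining over a known fraction of the
halo), nuclei of known cell class at known distances from plaque edges,
RNAscope-style puncta with a planted near-plaque density enrichment, and
Tmem119/Apoe channels for per-microglia FISH intensity.

Geometry is analytic (discs), so every truth quantity — nucleus-to-edge
distances, marker fractions, per-region puncta counts — is known exactly
or by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as draw_disk

from ..histo import SlideScene

__all__ = ["PlaqueSpec2D", "NucleusSpec", "SlideSpec", "generate_slide", "default_slide_spec"]

PLAQUE_INTENSITY = 2000
PUNCTA_INTENSITY = 1500


@dataclass
class PlaqueSpec2D:
    center: tuple[float, float]  # (y, x) µm
    core_radius: float  # µm, X34-positive compact core
    halo_radius: float  # µm, OC-positive outer extent

    def __post_init__(self) -> None:
        if self.halo_radius < self.core_radius:
            raise ValueError("halo_radius must be >= core_radius")


@dataclass
class NucleusSpec:
    position: tuple[float, float]  # (y, x) µm
    cell_class: str = "microglia"  # or "astrocyte"


@dataclass
class SlideSpec:
    """Parameters of one synthetic slide (all lengths in µm)."""

    shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.5
    plaques: list[PlaqueSpec2D] = field(default_factory=list)
    nuclei: list[NucleusSpec] = field(default_factory=list)
    puncta_density_near: float = 0.010  # puncta per µm² within near_radius of a plaque center
    puncta_density_far: float = 0.005
    near_radius: float = 50.0
    punctum_radius_px: int = 1
    marker_halo_fraction: float = 0.4
    nucleus_radius: float = 3.0
    cell_region_radius: float = 5.0  # Tmem119+ cell outline around a microglial nucleus
    apoe_intensity_range: tuple[float, float] = (500.0, 1500.0)  # summed per microglia
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.puncta_density_near < 0 or self.puncta_density_far < 0:
            raise ValueError("puncta densities must be >= 0")
        if not 0 <= self.marker_halo_fraction <= 1:
            raise ValueError("marker_halo_fraction must lie in [0, 1]")
        h, w = self.shape
        for nuc in self.nuclei:
            y, x = nuc.position
            if not (0 <= y <= (h - 1) * self.pixel_size and 0 <= x <= (w - 1) * self.pixel_size):
                raise ValueError(f"nucleus at {nuc.position} µm lies outside the image")


def default_slide_spec(seed: int = 0, n_plaques: int = 3, n_nuclei: int = 24) -> SlideSpec:
    """A representative slide: well-separated plaques, nuclei scattered near them."""
    rng = np.random.default_rng(seed)
    spec = SlideSpec(seed=seed)
    h, w = spec.shape
    extent_y, extent_x = (h - 1) * spec.pixel_size, (w - 1) * spec.pixel_size
    margin = spec.near_radius + 30
    centers: list[np.ndarray] = []
    while len(centers) < n_plaques:
        c = rng.uniform([margin, margin], [extent_y - margin, extent_x - margin])
        if all(np.linalg.norm(c - p) > 2.5 * spec.near_radius for p in centers):
            centers.append(c)
    for c in centers:
        core = rng.uniform(5, 10)
        spec.plaques.append(PlaqueSpec2D(tuple(c), core, core * rng.uniform(1.4, 2.2)))
    for _ in range(n_nuclei):
        plaque = spec.plaques[rng.integers(len(spec.plaques))]
        ang = rng.uniform(0, 2 * np.pi)
        dist = rng.uniform(2, 58)  # from plaque edge
        r = plaque.core_radius + dist
        pos = np.array(plaque.center) + r * np.array([np.sin(ang), np.cos(ang)])
        pos = np.clip(pos, 0, [extent_y, extent_x])
        cls = "microglia" if rng.random() < 0.75 else "astrocyte"
        spec.nuclei.append(NucleusSpec(tuple(pos), cls))
    return spec


def _disc_mask(shape: tuple[int, int], center_um, radius_um: float, pixel_size: float) -> np.ndarray:
    mask = np.zeros(shape, dtype=bool)
    cy, cx = (c / pixel_size for c in center_um)
    rr, cc = draw_disk((cy, cx), radius_um / pixel_size + 1e-9, shape=shape)
    mask[rr, cc] = True
    return mask


def generate_slide(spec: SlideSpec) -> tuple[SlideScene, dict[str, pd.DataFrame]]:
    """Render one slide and its truth tables.

    Returns ``(scene, truth)`` where ``truth`` holds three tables:
    ``nuclei`` (positions, class, exact analytic distance to the nearest
    plaque core edge), ``puncta`` (per-region planted puncta counts and
    region areas) and ``plaques`` (geometry plus the realized marker
    fraction of each halo).
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.shape
    px = spec.pixel_size
    pixel_area = px * px

    x34 = np.zeros(spec.shape, dtype=np.uint16)
    oc = np.zeros(spec.shape, dtype=np.uint16)
    marker = np.zeros(spec.shape, dtype=np.uint16)
    plaque_rows = []
    for i, pl in enumerate(spec.plaques):
        core = _disc_mask(spec.shape, pl.center, pl.core_radius, px)
        halo = _disc_mask(spec.shape, pl.center, pl.halo_radius, px)
        x34[core] = PLAQUE_INTENSITY
        oc[halo] = PLAQUE_INTENSITY
        annulus = halo & ~core
        ann_idx = np.flatnonzero(annulus)
        n_pos = int(np.floor(spec.marker_halo_fraction * ann_idx.size))
        chosen = rng.choice(ann_idx, size=n_pos, replace=False) if n_pos else np.array([], int)
        marker.ravel()[chosen] = PLAQUE_INTENSITY
        plaque_rows.append(
            {
                "plaque_id": i,
                "center_y_um": pl.center[0],
                "center_x_um": pl.center[1],
                "core_radius_um": pl.core_radius,
                "halo_radius_um": pl.halo_radius,
                "marker_fraction": n_pos / ann_idx.size if ann_idx.size else np.nan,
            }
        )

    # nuclei: label map + centroid table; truth distance is analytic
    labels = np.zeros(spec.shape, dtype=np.int32)
    tmem = np.zeros(spec.shape, dtype=np.uint16)
    apoe = np.zeros(spec.shape, dtype=np.float64)
    nucleus_rows = []
    apoe_lo, apoe_hi = spec.apoe_intensity_range
    for nid, nuc in enumerate(spec.nuclei, start=1):
        nmask = _disc_mask(spec.shape, nuc.position, spec.nucleus_radius, px)
        labels[nmask] = nid
        dist_edge = min(
            float(np.hypot(nuc.position[0] - pl.center[0], nuc.position[1] - pl.center[1]))
            - pl.core_radius
            for pl in spec.plaques
        ) if spec.plaques else np.inf
        apoe_total = np.nan
        if nuc.cell_class == "microglia":
            region = _disc_mask(spec.shape, nuc.position, spec.cell_region_radius, px)
            tmem[region] = PLAQUE_INTENSITY
            apoe_total = float(rng.uniform(apoe_lo, apoe_hi))
            npix = int(region.sum())
            apoe[region] += apoe_total / npix
        nucleus_rows.append(
            {
                "nucleus_id": nid,
                "y_um": nuc.position[0],
                "x_um": nuc.position[1],
                "cell_class": nuc.cell_class,
                "dist_to_plaque_edge_um": dist_edge,
                "apoe_total_intensity": apoe_total,
            }
        )

    # puncta: homogeneous Poisson within/outside the near-plaque region
    near = np.zeros(spec.shape, dtype=bool)
    for pl in spec.plaques:
        near |= _disc_mask(spec.shape, pl.center, spec.near_radius, px)
    puncta = np.zeros(spec.shape, dtype=np.uint16)
    puncta_rows = []
    for region_name, region_mask, density in (
        ("near", near, spec.puncta_density_near),
        ("far", ~near, spec.puncta_density_far),
    ):
        idx = np.flatnonzero(region_mask)
        area = idx.size * pixel_area
        n = int(rng.poisson(density * area))
        if n and idx.size:
            hits = rng.choice(idx, size=n, replace=True)
            ys, xs = np.unravel_index(hits, spec.shape)
            for y, x in zip(ys, xs):
                rr, cc = draw_disk((y, x), spec.punctum_radius_px + 0.1, shape=spec.shape)
                puncta[rr, cc] = PUNCTA_INTENSITY
        puncta_rows.append(
            {"region": region_name, "n_puncta": n, "area_um2": area, "density": density}
        )

    scene = SlideScene(
        channels={
            "X34": x34,
            "OC": oc,
            "TR": x34.copy(),
            "marker": marker,
            "puncta": puncta,
            "Tmem119": tmem,
            "Apoe": apoe,
        },
        pixel_size=px,
        nucleus_labels=labels,
        nuclei=pd.DataFrame(nucleus_rows),
    )
    truth = {
        "nuclei": pd.DataFrame(nucleus_rows),
        "puncta": pd.DataFrame(puncta_rows),
        "plaques": pd.DataFrame(plaque_rows),
    }
    return scene, truth
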