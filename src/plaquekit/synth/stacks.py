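"""Synthetic two-timepoint confocal stacks with known plaque ground truth.

Emulates the X04 / Thiazine Red (TR) / IBA1 triple stain of the in-vivo
plaque-labeling experiment: spherical dense cores (X04) whose TR extent is
the same object enlarged by a growth thickness, and an IBA1 "microglial
barrier" painted over a chosen angular fraction of each plaque's shell.

Truth volumes are counted on the discretized noise-free masks, not from
the analytic sphere formula, so a faithful pipeline can recover them
exactly up to blur/noise effects.  Intensities live on a 12-bit (0-4095)
scale so the conventional background floor of 500 is meaningful.  Blur is
applied before additive Gaussian noise (truncated at 0), then values are
quantized to integers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import pandas as pd
from scipy import ndimage

from ..volumetry import VoxelStack, make_shell

__all__ = [
    "StackSpec",
    "PlacementError",
    "generate_stack",
    "generate_cohort",
    "generate_coupled_cohort",
]

INTENSITY_MAX = 4095


class PlacementError(RuntimeError):
    """Raised when plaques cannot be placed under the spacing constraints."""


@dataclass
class StackSpec:
    """Parameters of one synthetic stack.

    Geometry is in µm; ``shape`` and ``voxel_size`` are (z, y, x).  The TR
    radius of each plaque is its X04 radius plus a growth thickness drawn
    from ``growth_thickness_range`` (zero allowed — the 48-h control
    condition).  ``coverage_fraction_range`` is the fraction of the TR shell
    covered by the IBA1 barrier.  ``edge_margin`` keeps plaque surfaces at
    least that far from the lateral image borders (the z margin only needs
    to hold the blurred object, mirroring a thin physical section).
    """

    shape: tuple[int, int, int] = (24, 264, 264)
    voxel_size: tuple[float, float, float] = (1.5, 0.5, 0.5)
    n_plaques: int = 1
    core_radius_range: tuple[float, float] = (3.0, 8.0)
    growth_thickness_range: tuple[float, float] = (0.0, 2.0)
    coverage_fraction_range: tuple[float, float] = (0.2, 0.9)
    plaque_intensity: float = 2000.0
    background_level: float = 100.0
    noise_sd: float = 50.0
    psf_sigma: float = 0.3  # µm
    min_separation: float = 50.0  # µm between plaque centers
    edge_margin: float = 50.0  # µm, lateral borders
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("core_radius_range", "growth_thickness_range", "coverage_fraction_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} has low > high: {(lo, hi)}")
        lo, hi = self.coverage_fraction_range
        if lo < 0 or hi > 1:
            raise ValueError("coverage fractions must lie in [0, 1]")
        if self.n_plaques < 1:
            raise ValueError("n_plaques must be >= 1")
        if min(self.core_radius_range) <= 0:
            raise ValueError("core radii must be positive")
        if self.psf_sigma < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma and noise_sd must be >= 0")
        self._validate_geometry()

    def _validate_geometry(self) -> None:
        dz, dy, dx = self.voxel_size
        r_max = self.core_radius_range[1] + self.growth_thickness_range[1]
        pad = r_max + BARRIER_BAND_OUTER + 3 * self.psf_sigma + max(self.voxel_size)
        z_extent = (self.shape[0] - 1) * dz
        y_extent = (self.shape[1] - 1) * dy
        x_extent = (self.shape[2] - 1) * dx
        lat_need = 2 * (self.edge_margin + r_max)
        if y_extent < lat_need or x_extent < lat_need:
            raise ValueError(
                f"stack lateral extent ({y_extent:.0f}x{x_extent:.0f} µm) too small to keep a "
                f"plaque of radius {r_max:.1f} µm at least {self.edge_margin:.0f} µm from the edge"
            )
        if z_extent < 2 * pad:
            raise ValueError(
                f"stack z extent {z_extent:.0f} µm cannot hold a blurred plaque of radius {r_max:.1f} µm"
            )


def _place_centers(spec: StackSpec, rng: np.random.Generator) -> np.ndarray:
    """Seeded rejection sampling of plaque centers (µm), bounded retries."""
    dz, dy, dx = spec.voxel_size
    r_max = spec.core_radius_range[1] + spec.growth_thickness_range[1]
    pad_z = r_max + BARRIER_BAND_OUTER + 3 * spec.psf_sigma + dz
    z_lo, z_hi = pad_z, (spec.shape[0] - 1) * dz - pad_z
    lat = spec.edge_margin + r_max
    y_lo, y_hi = lat, (spec.shape[1] - 1) * dy - lat
    x_lo, x_hi = lat, (spec.shape[2] - 1) * dx - lat
    centers: list[np.ndarray] = []
    max_tries = 200 * spec.n_plaques
    tries = 0
    while len(centers) < spec.n_plaques:
        if tries >= max_tries:
            raise PlacementError(
                f"could not place {spec.n_plaques} plaques with min_separation="
                f"{spec.min_separation} µm in a {spec.shape} stack after {max_tries} tries"
            )
        tries += 1
        c = np.array(
            [rng.uniform(z_lo, z_hi), rng.uniform(y_lo, y_hi), rng.uniform(x_lo, x_hi)]
        )
        if all(np.linalg.norm(c - p) >= spec.min_separation for p in centers):
            centers.append(c)
    return np.asarray(centers)


def _ball_mask_box(
    center: np.ndarray, radius: float, shape: tuple[int, int, int], voxel_size: tuple[float, float, float]
) -> tuple[tuple[slice, slice, slice], np.ndarray]:
    """Discretized ball: voxels whose center lies within ``radius`` of ``center``.

    Returns the bounding-box slices (with a 2-voxel margin, clipped) and the
    local boolean mask.  Voxel centers sit at index*voxel_size.
    """
    vs = np.asarray(voxel_size)
    lo = np.maximum(np.floor((center - radius) / vs).astype(int) - 2, 0)
    hi = np.minimum(np.ceil((center + radius) / vs).astype(int) + 3, np.asarray(shape))
    box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    zz, yy, xx = np.meshgrid(
        (np.arange(lo[0], hi[0]) * vs[0] - center[0]) ** 2,
        (np.arange(lo[1], hi[1]) * vs[1] - center[1]) ** 2,
        (np.arange(lo[2], hi[2]) * vs[2] - center[2]) ** 2,
        indexing="ij",
    )
    mask = zz + yy + xx <= radius * radius
    return box, mask


BARRIER_BAND_OUTER = 2.5  # µm beyond the TR surface painted as IBA1
BARRIER_BAND_INNER = 0.5  # µm inside the TR surface


def _paint_barrier(
    tr_box: tuple[slice, slice, slice],
    tr_local: np.ndarray,
    center: np.ndarray,
    radius_tr: float,
    fraction: float,
    shape: tuple[int, int, int],
    voxel_size: tuple[float, float, float],
    rng: np.random.Generator,
) -> tuple[tuple[slice, slice, slice], np.ndarray, float, int]:
    """IBA1 barrier over an exact angular cap of the TR shell.

    The one-voxel shell of the TR mask (26-neighborhood, the analysis
    convention) is ranked by polar angle about a random axis; the first
    round(f*N) shell voxels define the covered cap, so the true coverage
    fraction is exact by construction.  The painted IBA1 signal is the full
    angular sector (cos angle >= the cap cutoff) of a radial band around the
    TR surface; the band is thick enough radially that small segmentation
    dilations from blur move the measured shell within it, while the angular
    boundary — which is what the coverage fraction measures — stays put.

    Returns (band box slices, local IBA1 mask, true coverage fraction,
    shell voxel count).
    """
    shell_local = make_shell(tr_local, connectivity=26)
    n_shell = int(shell_local.sum())
    vs = np.asarray(voxel_size)
    lo = np.array([s.start for s in tr_box])
    shell_idx = np.argwhere(shell_local)
    phys = (shell_idx + lo) * vs - center
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    cosang = phys @ axis / np.linalg.norm(phys, axis=1)
    m = int(round(fraction * n_shell))
    true_fraction = m / n_shell
    band_box, outer = _ball_mask_box(
        center, radius_tr + BARRIER_BAND_OUTER, shape, voxel_size
    )
    if m == 0:
        return band_box, np.zeros_like(outer), true_fraction, n_shell
    order = np.argsort(-cosang, kind="stable")  # smallest polar angle first
    cos_cut = float(cosang[order[m - 1]])
    blo = np.array([s.start for s in band_box])
    bhi = np.array([s.stop for s in band_box])
    zz = np.arange(blo[0], bhi[0]) * vs[0] - center[0]
    yy = np.arange(blo[1], bhi[1]) * vs[1] - center[1]
    xx = np.arange(blo[2], bhi[2]) * vs[2] - center[2]
    pz, py, px = np.meshgrid(zz, yy, xx, indexing="ij")
    dist = np.sqrt(pz**2 + py**2 + px**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosg = (pz * axis[0] + py * axis[1] + px * axis[2]) / dist
    band = (dist >= max(radius_tr - BARRIER_BAND_INNER, 0)) & (
        dist <= radius_tr + BARRIER_BAND_OUTER
    )
    if m == n_shell:
        cap = band
    else:
        cap = band & (cosg >= cos_cut)
    return band_box, cap, true_fraction, n_shell


def generate_stack(spec: StackSpec) -> tuple[VoxelStack, pd.DataFrame]:
    """Render one synthetic stack and its per-plaque ground-truth table.

    Returns ``(stack, truth)``; truth columns include the true X04/TR
    volumes (voxel counts on the noise-free masks × voxel volume), the
    growth (their exact difference), the planted coverage fraction and the
    shell voxel count.  Identical specs (including seed) give bit-identical
    output.
    """
    rng = np.random.default_rng(spec.seed)
    centers = _place_centers(spec, rng)
    vox_vol = float(np.prod(spec.voxel_size))
    x04 = np.zeros(spec.shape, dtype=np.float32)
    tr = np.zeros(spec.shape, dtype=np.float32)
    iba1 = np.zeros(spec.shape, dtype=np.float32)
    rows = []
    signal_boxes: list[tuple[slice, slice, slice]] = []
    for pid, center in enumerate(centers):
        r_core = rng.uniform(*spec.core_radius_range)
        growth_t = rng.uniform(*spec.growth_thickness_range)
        r_tr = r_core + growth_t
        cov_f = rng.uniform(*spec.coverage_fraction_range)
        box_x, m_x = _ball_mask_box(center, r_core, spec.shape, spec.voxel_size)
        box_t, m_t = _ball_mask_box(center, r_tr, spec.shape, spec.voxel_size)
        x04[box_x][m_x] = spec.plaque_intensity
        tr[box_t][m_t] = spec.plaque_intensity
        band_box, cap, true_f, n_shell = _paint_barrier(
            box_t, m_t, center, r_tr, cov_f, spec.shape, spec.voxel_size, rng
        )
        iba1[band_box][cap] = spec.plaque_intensity
        signal_boxes.append(band_box)
        n_x, n_t = int(m_x.sum()), int(m_t.sum())
        rows.append(
            {
                "plaque_id": pid,
                "center_z_um": center[0],
                "center_y_um": center[1],
                "center_x_um": center[2],
                "core_radius_um": r_core,
                "tr_radius_um": r_tr,
                "x04_volume_um3": n_x * vox_vol,
                "tr_volume_um3": n_t * vox_vol,
                "growth_um3": (n_t - n_x) * vox_vol,
                "coverage_fraction": true_f,
                "shell_voxels": n_shell,
            }
        )
    sigmas = tuple(spec.psf_sigma / v for v in spec.voxel_size)
    # blur only the union bounding box of the painted signal (plus a 4-sigma
    # margin); the field is zero elsewhere so this equals a full-stack blur
    lo = np.min([[s.start for s in b] for b in signal_boxes], axis=0)
    hi = np.max([[s.stop for s in b] for b in signal_boxes], axis=0)
    margin = np.ceil(4 * spec.psf_sigma / np.asarray(spec.voxel_size)).astype(int) + 1
    lo = np.maximum(lo - margin, 0)
    hi = np.minimum(hi + margin, np.asarray(spec.shape))
    blur_box = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    channels = {}
    for name, signal in (("X04", x04), ("TR", tr), ("IBA1", iba1)):
        img = signal
        if spec.psf_sigma > 0:
            img[blur_box] = ndimage.gaussian_filter(img[blur_box], sigma=sigmas)
        img = img + spec.background_level
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=spec.shape).astype(np.float32)
        np.clip(img, 0, INTENSITY_MAX, out=img)
        channels[name] = np.rint(img).astype(np.uint16)
    truth = pd.DataFrame(rows)
    return VoxelStack(channels, spec.voxel_size), truth


def generate_cohort(
    n_plaques: int,
    base_spec: StackSpec | None = None,
    seed: int = 0,
) -> Iterator[tuple[VoxelStack, pd.DataFrame]]:
    """Lazy cohort of single-plaque stacks with independent per-plaque seeds.

    Seeds are derived from ``seed`` through :class:`numpy.random.SeedSequence`
    spawning, so cohorts are reproducible and plaques independent.
    """
    base = base_spec or StackSpec()
    children = np.random.SeedSequence(seed).spawn(n_plaques)
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = replace(base, n_plaques=1, seed=sub_seed)
        yield generate_stack(spec)


def generate_coupled_cohort(
    n_plaques: int,
    true_r: float = 0.9,
    base_spec: StackSpec | None = None,
    seed: int = 0,
    growth_mean: float = 1.5,
    growth_sd: float = 0.4,
) -> Iterator[tuple[VoxelStack, pd.DataFrame]]:
    """Cohort in which growth is coupled to the uncovered shell fraction.

    The growth thickness of plaque i is ``growth_mean + growth_sd *
    (true_r * u_i + sqrt(1-true_r²) * e_i)`` (clipped at 0) where ``u_i`` is
    the standardized uncovered fraction ``1 - coverage`` and ``e_i`` is
    independent noise, so growth and exposed surface are positively coupled
    with correlation ≈ ``true_r`` at the latent level.
    """
    if not 0 <= true_r <= 1:
        raise ValueError("true_r must lie in [0, 1]")
    base = base_spec or StackSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    cov_lo, cov_hi = base.coverage_fraction_range
    coverages = rng.uniform(cov_lo, cov_hi, size=n_plaques)
    u = 1.0 - coverages
    u_z = (u - u.mean()) / u.std() if u.std() > 0 else np.zeros_like(u)
    e = rng.standard_normal(n_plaques)
    growth = growth_mean + growth_sd * (true_r * u_z + np.sqrt(1 - true_r**2) * e)
    growth = np.clip(growth, 0.0, None)
    children = np.random.SeedSequence(seed + 1).spawn(n_plaques)
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31 - 1))
        spec = replace(
            base,
            n_plaques=1,
            seed=sub_seed,
            growth_thickness_range=(float(growth[i]), float(growth[i])),
            coverage_fraction_range=(float(coverages[i]), float(coverages[i])),
        )
        yield generate_stack(spec)
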