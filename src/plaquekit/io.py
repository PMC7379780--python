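"""Readers and writers for stacks, slides, tables and specs.

Stacks are stored as OME-TIFF with axes CZYX and physical voxel sizes in
the OME metadata; slides as multi-page TIFF (one page per channel) with a
JSON description carrying channel names and the pixel size.  Tables go
through pandas CSV at full double precision, specs through YAML.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .histo import SlideScene
from .volumetry import VoxelStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_slide",
    "read_slide",
    "write_spec",
    "read_yaml",
    "write_table",
]

DEFAULT_CHANNEL_ORDER = ("X04", "TR", "IBA1")


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a stack as OME-TIFF (axes CZYX, channel names, voxel size in µm)."""
    path = Path(path)
    names = list(stack.channels)
    data = np.stack([stack.channels[n] for n in names], axis=0)
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        data,
        ome=True,
        metadata={
            "axes": "CZYX",
            "Channel": {"Name": names},
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
        },
    )
    return path


def _parse_ome(ome_xml: str) -> tuple[list[str], tuple[float, float, float] | None]:
    """Channel names and (z, y, x) physical sizes from OME-XML, if present."""
    root = ET.fromstring(ome_xml)
    ns = {"ome": root.tag.split("}")[0].strip("{")}
    names: list[str] = []
    voxel = None
    pixels = root.find(".//ome:Pixels", ns)
    if pixels is not None:
        for ch in pixels.findall("ome:Channel", ns):
            names.append(ch.get("Name") or f"C{len(names)}")
        sz = pixels.get("PhysicalSizeZ")
        sy = pixels.get("PhysicalSizeY")
        sx = pixels.get("PhysicalSizeX")
        if sy and sx:
            voxel = (float(sz) if sz else 1.0, float(sy), float(sx))
    return names, voxel


def read_stack(
    path: str | Path,
    channel_map: dict[str, int] | list[str] | None = None,
    voxel_size: tuple[float, float, float] | None = None,
) -> VoxelStack:
    """Read an OME-TIFF stack into a :class:`VoxelStack`.

    Channel names come from the OME metadata; ``channel_map`` (a
    name → channel-index mapping or an ordered name list) overrides them.
    ``voxel_size`` overrides the metadata physical sizes (the override
    wins; the caller should log it).  Raises a descriptive error for
    missing channels or unresolvable axes.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        series = tif.series[0]
        axes = series.axes.upper()
        data = series.asarray()
        meta_names: list[str] = []
        meta_voxel = None
        if tif.ome_metadata:
            meta_names, meta_voxel = _parse_ome(tif.ome_metadata)
    if axes == "CZYX":
        pass
    elif axes == "ZYX":
        data = data[np.newaxis]
    else:
        raise ValueError(f"cannot resolve axes {axes!r} (expected CZYX or ZYX)")
    n_channels = data.shape[0]
    if isinstance(channel_map, dict):
        names_idx = sorted(channel_map.items(), key=lambda kv: kv[1])
        names = [n for n, _ in names_idx]
        order = [i for _, i in names_idx]
    elif channel_map is not None:
        names = list(channel_map)
        order = list(range(len(names)))
    elif meta_names:
        names = meta_names
        order = list(range(len(names)))
    else:
        names = [f"C{i}" for i in range(n_channels)]
        order = list(range(n_channels))
    bad = [i for i in order if i >= n_channels]
    if bad or len(names) > n_channels:
        raise ValueError(
            f"channel map requests {len(names)} channels but file has {n_channels}"
        )
    vs = voxel_size or meta_voxel
    if vs is None:
        raise ValueError("voxel size not in metadata; pass voxel_size explicitly")
    channels = {name: data[i] for name, i in zip(names, order)}
    return VoxelStack(channels, tuple(float(v) for v in vs))


def write_slide(scene: SlideScene, path: str | Path) -> Path:
    """Write a slide as multi-page TIFF with channel names and pixel size."""
    path = Path(path)
    names = list(scene.channels)
    data = np.stack(
        [np.asarray(scene.channels[n], dtype=np.float32) for n in names], axis=0
    )
    tifffile.imwrite(
        path,
        data,
        metadata={"axes": "CYX", "channels": names, "pixel_size_um": scene.pixel_size},
    )
    return path


def read_slide(path: str | Path, pixel_size: float | None = None) -> SlideScene:
    """Read a multi-page TIFF slide written by :func:`write_slide`."""
    with tifffile.TiffFile(path) as tif:
        data = tif.series[0].asarray()
        meta = tif.shaped_metadata[0] if tif.shaped_metadata else {}
    names = meta.get("channels") or [f"C{i}" for i in range(data.shape[0])]
    px = pixel_size or meta.get("pixel_size_um")
    if px is None:
        raise ValueError("pixel size not in metadata; pass pixel_size explicitly")
    return SlideScene(
        channels={n: data[i] for i, n in enumerate(names)}, pixel_size=float(px)
    )


def write_spec(spec, path: str | Path) -> Path:
    """Dump a generator spec (dataclass) to YAML or JSON by extension."""
    path = Path(path)
    if not is_dataclass(spec):
        raise TypeError("spec must be a dataclass instance")
    payload = asdict(spec)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(payload, sort_keys=False))
    else:
        path.write_text(json.dumps(payload, indent=2, default=str))
    return path


def read_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> Path:
    """CSV at full double precision (checksum-stable across runs)."""
    path = Path(path)
    df.to_csv(path, index=index, float_format="%.17g")
    return path
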