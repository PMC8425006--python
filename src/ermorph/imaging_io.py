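"""Reading multi-channel fields and projecting z-stacks.

A *field* is one imaged position: up to three fluorescence channels
(nucleus counterstain, plasma-membrane counterstain, ER marker), each
either a single optical plane (y, x) or a z-stack (z, y, x).  Everything
downstream of this module works on 2-D maximum-intensity projections,
which suppress out-of-focus artefacts and recover tubules that wander
slightly in z in adherent cells.

Intensities are carried as-is in arbitrary detector units; all
downstream thresholds are relative (per-cell or per-ROI statistics), so
bit depth cancels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

logger = logging.getLogger("ermorph")

#: channel roles the pipeline understands
CHANNEL_ROLES = ("nucleus", "membrane", "er")

#: fallback xy pixel size in µm when no metadata is available
DEFAULT_PIXEL_SIZE_UM = 0.28


@dataclass
class FieldImage:
    """One imaged field: named channels plus physical-size metadata.

    channels maps a role in {"nucleus", "membrane", "er"} to an array of
    shape (y, x) or (z, y, x).  ``pixel_size_um`` is the isotropic xy
    pixel size; ``z_step_um`` is carried as metadata only.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    z_step_um: float | None = None
    field_id: str = "field"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FieldImage needs at least one channel")
        if self.pixel_size_um <= 0:
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        shapes = set()
        zs = set()
        for role, arr in self.channels.items():
            if role not in CHANNEL_ROLES:
                raise ValueError(f"unknown channel role {role!r}")
            arr = np.asarray(arr)
            if arr.ndim not in (2, 3):
                raise ValueError(f"channel {role!r} must be 2-D or 3-D, got ndim={arr.ndim}")
            self.channels[role] = arr
            shapes.add(arr.shape[-2:])
            zs.add(arr.shape[0] if arr.ndim == 3 else 1)
        if len(shapes) > 1:
            raise ValueError(f"channels disagree in y×x extent: {sorted(shapes)}")
        if len(zs) > 1:
            raise ValueError(f"channels disagree in z-plane count: {sorted(zs)}")

    @property
    def shape_yx(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape[-2:]

    @property
    def n_planes(self) -> int:
        arr = next(iter(self.channels.values()))
        return arr.shape[0] if arr.ndim == 3 else 1


@dataclass
class ProjectedField:
    """A field whose channels are all strictly 2-D (after projection)."""

    channels: dict[str, np.ndarray]
    pixel_size_um: float
    field_id: str = "field"
    provenance: str = "max-projection"

    def __post_init__(self) -> None:
        for role, arr in self.channels.items():
            if np.asarray(arr).ndim != 2:
                raise ValueError(f"projected channel {role!r} is not 2-D")


def _pixel_size_from_tiff(tf: tifffile.TiffFile) -> float | None:
    """Pull the xy pixel size (µm) out of OME metadata or resolution tags."""
    if tf.ome_metadata:
        try:
            import xml.etree.ElementTree as ET

            root = ET.fromstring(tf.ome_metadata)
            for el in root.iter():
                if el.tag.endswith("Pixels") and "PhysicalSizeX" in el.attrib:
                    return float(el.attrib["PhysicalSizeX"])
        except Exception:  # malformed OME block: fall through to tags
            pass
    page = tf.pages[0]
    res = page.tags.get("XResolution")
    unit = page.tags.get("ResolutionUnit")
    if res is not None and unit is not None:
        num, den = res.value
        if num > 0 and den > 0:
            px_per_unit = num / den
            unit_um = {2: 25400.0, 3: 10000.0}.get(int(unit.value))  # inch / cm
            if unit_um is not None and px_per_unit > 0:
                return unit_um / px_per_unit
    return None


def read_field(
    paths: str | Path | Mapping[str, str | Path],
    channel_map: Mapping[str, int] | None = None,
    pixel_size_um: float | None = None,
    z_step_um: float | None = None,
    field_id: str | None = None,
) -> FieldImage:
    """Read one field from TIFF/OME-TIFF file(s).

    Two layouts are supported and the channel-role assignment is always
    explicit, never guessed from file order:

    * one container file -> ``paths`` is a single path and ``channel_map``
      maps roles to channel indices along the leading (non-z) axis;
    * one file per channel -> ``paths`` maps roles directly to paths.

    A plain multi-page TIFF is interpreted as a z-stack.  Pixel size is
    taken from file metadata unless ``pixel_size_um`` overrides it; when
    neither exists the 0.28 µm default is used with a logged warning.
    """
    arrays: dict[str, np.ndarray] = {}
    meta_px: float | None = None

    if isinstance(paths, (str, Path)):
        if not channel_map:
            raise ValueError("channel_map (role -> channel index) required for a container file")
        path = Path(paths)
        if not path.exists():
            raise FileNotFoundError(str(path))
        with tifffile.TiffFile(path) as tf:
            data = tf.asarray()
            meta_px = _pixel_size_from_tiff(tf)
        # Accepted container axes: (c,y,x) or (c,z,y,x); channel axis leads.
        if data.ndim == 2:
            data = data[None]
        if data.ndim not in (3, 4):
            raise ValueError(f"cannot interpret container of shape {data.shape}")
        for role, idx in channel_map.items():
            idx = int(idx)
            if idx < 0 or idx >= data.shape[0]:
                raise ValueError(f"channel index {idx} for role {role!r} out of range")
            arrays[role] = data[idx]
        if field_id is None:
            field_id = path.stem
    else:
        for role, p in paths.items():
            p = Path(p)
            if not p.exists():
                raise FileNotFoundError(str(p))
            with tifffile.TiffFile(p) as tf:
                arr = tf.asarray()
                if meta_px is None:
                    meta_px = _pixel_size_from_tiff(tf)
            if arr.ndim == 3 and arr.shape[0] == 1:
                arr = arr[0]
            arrays[role] = arr
        if field_id is None:
            field_id = Path(next(iter(paths.values()))).stem

    if not {"nucleus", "er"} <= set(arrays):
        raise ValueError("channel mapping must cover at least the 'nucleus' and 'er' roles")

    if pixel_size_um is None:
        pixel_size_um = meta_px
    if pixel_size_um is None:
        warnings.warn(
            f"no pixel-size metadata found; assuming {DEFAULT_PIXEL_SIZE_UM} um/px",
            stacklevel=2,
        )
        pixel_size_um = DEFAULT_PIXEL_SIZE_UM

    return FieldImage(
        channels=arrays,
        pixel_size_um=float(pixel_size_um),
        z_step_um=z_step_um,
        field_id=field_id,
    )


def max_project(field: FieldImage) -> ProjectedField:
    """Maximum-intensity projection of every channel over z.

    Each output pixel is the maximum over the source z planes at that
    position; channels that are already 2-D pass through unchanged.
    """
    projected = {}
    for role, arr in field.channels.items():
        projected[role] = arr.max(axis=0) if arr.ndim == 3 else arr.copy()
    return ProjectedField(
        channels=projected,
        pixel_size_um=field.pixel_size_um,
        field_id=field.field_id,
        provenance=f"max-projection of {field.n_planes} plane(s)",
    )


def area_to_um2(pixel_count: int | float | np.ndarray, pixel_size_um: float) -> float | np.ndarray:
    """Convert a pixel count into an area in µm² (count × pixel_size²)."""
    if pixel_size_um <= 0:
        raise ValueError(f"pixel_size_um must be > 0, got {pixel_size_um}")
    if np.any(np.asarray(pixel_count) < 0):
        raise ValueError("pixel_count must be nonnegative")
    out = np.asarray(pixel_count, dtype=float) * pixel_size_um**2
    return float(out) if np.isscalar(pixel_count) or np.ndim(pixel_count) == 0 else out


def write_field(
    path: str | Path,
    field: FieldImage,
    *,
    roles: tuple[str, ...] = CHANNEL_ROLES,
) -> None:
    """Write a field as a single multi-channel OME-TIFF (axes CYX or CZYX)."""
    path = Path(path)
    present = [r for r in roles if r in field.channels]
    stack = np.stack([field.channels[r] for r in present])
    axes = "CZYX" if stack.ndim == 4 else "CYX"
    meta = {
        "axes": axes,
        "PhysicalSizeX": field.pixel_size_um,
        "PhysicalSizeY": field.pixel_size_um,
        "Channel": {"Name": list(present)},
    }
    if field.z_step_um is not None:
        meta["PhysicalSizeZ"] = field.z_step_um
    tifffile.imwrite(path, stack, ome=True, metadata=meta)
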