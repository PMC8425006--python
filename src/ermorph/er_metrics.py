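"""Per-cell ER morphology metrics: SER polygon areas and dense-RER fraction.

The smooth ER (SER) forms a peripheral tubular network whose "gaps" —
polygonal regions enclosed by interconnected tubules — shrink as the
network densifies (more three-way junctions) and grow as it loosens.
The rough ER (RER) appears at confocal resolution as a perinuclear
region of markedly higher ER-marker intensity ("dense ER").

Two readouts are computed per cell:

* **mean polygon area** — a ring-shaped peripheral ROI is cut from the
  cytoplasm by radially shrinking it away from the nucleus; ER tubules
  are masked by a relative intensity threshold inside the ROI; the mask
  is inverted and its 8-connected components are the candidate
  polygons; components touching the cell perimeter are not closed by
  tubules and are discarded; the mean area (µm²) of the survivors is
  the readout.
* **dense-ER percent** — pixels whose ER intensity exceeds a multiple
  of the cytoplasm median form the dense mask; the readout is its
  areal percentage of the cytoplasm (switchable to whole-cell area).

Both default thresholds are relative to per-cell statistics, so the
metrics are invariant under uniform intensity rescaling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .imaging_io import area_to_um2
from .segmentation import STRUCT_8


@dataclass
class PeripheralROI:
    """Ring-shaped peripheral sub-region of one cell's cytoplasm."""

    cell_label: int
    mask: np.ndarray  # boolean, subset of the cytoplasm
    shrink_fraction: float


@dataclass
class PolygonRegion:
    """One candidate SER polygon: a connected gap in the tubule mask."""

    cell_label: int
    mask: np.ndarray
    area_um2: float
    touches_perimeter: bool


@dataclass
class ERMetrics:
    """Per-cell readouts; ``mean_polygon_area_um2`` is NaN when no
    polygon was retained (a missing mean is not a zero area)."""

    cell_label: int
    n_polygons: int
    mean_polygon_area_um2: float
    dense_er_percent: float


def define_peripheral_roi(
    cell_mask: np.ndarray, nucleus_mask: np.ndarray, shrink_fraction: float = 0.0
) -> PeripheralROI:
    """Radially shrink the cytoplasm away from the nucleus.

    For each cytoplasm pixel let Dn be its distance to the nucleus
    border and Dp its distance to the cell perimeter; the ROI keeps the
    pixels with Dn / (Dn + Dp) >= f, i.e. the inner ROI border sits a
    fraction f of the local nucleus-to-perimeter distance away from the
    nucleus.  f = 0 returns the whole cytoplasm.
    """
    f = float(shrink_fraction)
    if not (0.0 <= f < 1.0):
        raise ValueError(f"shrink_fraction must be in [0, 1), got {f}")
    cell = np.asarray(cell_mask, bool)
    nuc = np.asarray(nucleus_mask, bool)
    if (nuc & ~cell).any():
        raise ValueError("nucleus mask is not contained in the cell mask")
    cyto = cell & ~nuc
    if f == 0.0:
        return PeripheralROI(cell_label=0, mask=cyto, shrink_fraction=f)
    d_nuc = ndi.distance_transform_edt(~nuc) if nuc.any() else np.zeros(cell.shape)
    d_per = ndi.distance_transform_edt(cell)  # distance to outside = to perimeter
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(cyto, d_nuc / np.maximum(d_nuc + d_per, 1e-12), 0.0)
    roi = cyto & (ratio >= f)
    return PeripheralROI(cell_label=0, mask=roi, shrink_fraction=f)


def _relative_threshold(
    values: np.ndarray, method: str, otsu_multiplier: float, value: float | None
) -> float | None:
    """Threshold over a pixel population; None when undefinable."""
    if values.max() == values.min():
        return None
    if method == "otsu":
        # Otsu on log intensities: robust when a bright third mode
        # (residual dense ER) sits above the tubule class, and exactly
        # equivariant under uniform intensity scaling.
        shift = float(values.min())
        delta = 1e-6 * float(values.max() - shift)  # scales with the data
        logv = np.log(values - shift + delta)
        t = threshold_otsu(logv)
        return float(np.exp(t) - delta + shift) * otsu_multiplier
    if method == "percentile":
        if value is None:
            raise ValueError("percentile method requires a value")
        return float(np.percentile(values, value))
    if method == "fixed":
        if value is None:
            raise ValueError("fixed method requires a value")
        return float(value)
    raise ValueError(f"unknown threshold method {method!r}")


def mask_er_tubules(
    er_channel: np.ndarray,
    roi: PeripheralROI,
    method: str = "otsu",
    otsu_multiplier: float = 1.0,
    value: float | None = None,
) -> np.ndarray:
    """Threshold the ER-marker signal inside the peripheral ROI.

    Returns a boolean tubule mask ⊆ ROI.  A constant-intensity ROI has
    no definable threshold: empty mask plus a warning.
    """
    img = np.asarray(er_channel, float)
    if not roi.mask.any():
        raise ValueError("empty ROI")
    vals = img[roi.mask]
    thr = _relative_threshold(vals, method, otsu_multiplier, value)
    if thr is None:
        warnings.warn("constant-intensity ROI: no tubule threshold definable", stacklevel=2)
        return np.zeros_like(roi.mask)
    return roi.mask & (img > thr)


def detect_polygons(
    er_mask: np.ndarray,
    roi: PeripheralROI,
    cell_mask: np.ndarray,
    pixel_size_um: float,
    min_polygon_area_um2: float | None = None,
) -> list[PolygonRegion]:
    """Invert the tubule mask and keep the closed polygonal regions.

    The 8-connected components of (ROI − tubule mask) are the candidate
    regions.  A component adjacent (within a 1-pixel dilation) to the
    cell's 1-pixel inner perimeter band is open to the outside — not a
    polygon — and is marked ``touches_perimeter``.  Retained regions are
    the non-touching components with area ≥ ``min_polygon_area_um2``
    (default: 4 pixels, noise suppression).
    """
    cell = np.asarray(cell_mask, bool)
    er = np.asarray(er_mask, bool)
    if (er & ~roi.mask).any():
        raise ValueError("er_mask must be contained in the ROI")
    if min_polygon_area_um2 is None:
        min_polygon_area_um2 = 4 * pixel_size_um**2

    complement = roi.mask & ~er
    labels, n = ndi.label(complement, structure=STRUCT_8)
    if n == 0:
        return []
    perimeter_band = cell & ~ndi.binary_erosion(cell, structure=STRUCT_8)
    near_perimeter = ndi.binary_dilation(perimeter_band, structure=STRUCT_8)
    touching = set(np.unique(labels[near_perimeter])) - {0}

    regions: list[PolygonRegion] = []
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    for lab, area_px in zip(range(1, n + 1), areas):
        touches = lab in touching
        area = area_to_um2(float(area_px), pixel_size_um)
        if touches or area < min_polygon_area_um2:
            continue
        regions.append(
            PolygonRegion(
                cell_label=roi.cell_label,
                mask=labels == lab,
                area_um2=area,
                touches_perimeter=False,
            )
        )
    return regions


def polygon_stats(regions: list[PolygonRegion]) -> tuple[int, float]:
    """(n_polygons, mean area µm²); the mean is NaN when no region exists."""
    if not regions:
        return 0, float("nan")
    areas = [r.area_um2 for r in regions]
    return len(areas), float(np.mean(areas))


def mask_dense_er(
    er_channel: np.ndarray,
    cytoplasm_mask: np.ndarray,
    method: str = "median_multiplier",
    k: float = 2.0,
    value: float | None = None,
) -> np.ndarray:
    """Mask the high-intensity (dense / RER-like) ER within the cytoplasm.

    Default: pixels above k × median cytoplasmic ER intensity
    (k = 2.0).  Alternatives: ``percentile`` of cytoplasm intensities,
    or a ``fixed`` absolute cut.  Constant cytoplasm → empty mask +
    warning.
    """
    img = np.asarray(er_channel, float)
    cyto = np.asarray(cytoplasm_mask, bool)
    if not cyto.any():
        raise ValueError("empty cytoplasm mask")
    vals = img[cyto]
    if vals.max() == vals.min():
        warnings.warn("constant-intensity cytoplasm: no dense-ER threshold definable", stacklevel=2)
        return np.zeros_like(cyto)
    if method == "median_multiplier":
        # lower median: an exactly bimodal 50/50 cytoplasm must cut
        # between the classes, not at their midpoint
        thr = k * float(np.percentile(vals, 50, method="lower"))
    elif method == "percentile":
        if value is None:
            raise ValueError("percentile method requires a value")
        thr = float(np.percentile(vals, value))
    elif method == "fixed":
        if value is None:
            raise ValueError("fixed method requires a value")
        thr = float(value)
    else:
        raise ValueError(f"unknown dense-ER method {method!r}")
    return cyto & (img > thr)


def dense_er_fraction(dense_mask: np.ndarray, reference_mask: np.ndarray) -> float:
    """Percent of the reference area (cytoplasm, or whole cell) covered
    by the dense-ER mask."""
    dense = np.asarray(dense_mask, bool)
    ref = np.asarray(reference_mask, bool)
    n_ref = int(ref.sum())
    if n_ref == 0:
        raise ValueError("empty reference mask")
    if (dense & ~ref).any():
        raise ValueError("dense mask must be contained in the reference mask")
    return 100.0 * float(dense.sum()) / n_ref


def measure_cell(
    er_channel: np.ndarray,
    cell_mask: np.ndarray,
    nucleus_mask: np.ndarray,
    pixel_size_um: float,
    cell_label: int = 0,
    shrink_fraction: float = 0.25,
    tubule_method: str = "otsu",
    tubule_otsu_multiplier: float = 1.0,
    tubule_value: float | None = None,
    min_polygon_area_um2: float | None = None,
    dense_method: str = "median_multiplier",
    dense_k: float = 2.0,
    dense_value: float | None = None,
    dense_denominator: str = "cytoplasm",
) -> tuple[ERMetrics, list[PolygonRegion]]:
    """Both ER readouts for one segmented cell.

    ``dense_denominator`` selects the reference area for the dense-ER
    percentage: "cytoplasm" (default) or "cell".
    """
    roi = define_peripheral_roi(cell_mask, nucleus_mask, shrink_fraction)
    roi.cell_label = cell_label
    cyto = np.asarray(cell_mask, bool) & ~np.asarray(nucleus_mask, bool)

    if roi.mask.any():
        er_mask = mask_er_tubules(
            er_channel, roi, method=tubule_method,
            otsu_multiplier=tubule_otsu_multiplier, value=tubule_value,
        )
        regions = detect_polygons(er_mask, roi, cell_mask, pixel_size_um, min_polygon_area_um2)
    else:
        regions = []
    n_poly, mean_area = polygon_stats(regions)

    if cyto.any():
        dense = mask_dense_er(er_channel, cyto, method=dense_method, k=dense_k, value=dense_value)
        ref = np.asarray(cell_mask, bool) if dense_denominator == "cell" else cyto
        pct = dense_er_fraction(dense & ref, ref)
    else:
        pct = float("nan")

    return (
        ERMetrics(
            cell_label=cell_label,
            n_polygons=n_poly,
            mean_polygon_area_um2=mean_area,
            dense_er_percent=pct,
        ),
        regions,
    )
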