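"""Nucleus / cell / cytoplasm segmentation from the counterstain channels.

The nucleus is the primary object: nuclei are found by smoothing the
DNA-counterstain channel, automatic global thresholding, and a
distance-transform seeded watershed to split touching nuclei.  Cells are
then grown from the nucleus seeds over the plasma-membrane counterstain
(or, when no membrane channel was acquired, the ER channel), constrained
to a foreground mask.  Cytoplasm is the per-cell set difference
cell − nucleus.

Conventions used throughout the package, stated once here:

* images are row-major (y, x), origin top-left;
* object labelling uses 8-connectivity;
* label maps are 2-D int arrays, 0 = background, masks are half-open
  pixel sets (every pixel belongs to exactly one object).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.filters import gaussian, sobel, threshold_otsu
from skimage.segmentation import find_boundaries, watershed

logger = logging.getLogger("ermorph")

#: structuring element for 8-connectivity in 2-D
STRUCT_8 = np.ones((3, 3), bool)


@dataclass
class LabelMap:
    """Integer-labelled 2-D segmentation; 0 is background.

    Labels need not be consecutive after filtering.  ``pixel_size_um``
    travels with the map so areas can be reported in physical units.
    """

    labels: np.ndarray
    pixel_size_um: float = 1.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise ValueError("LabelMap must be 2-D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("LabelMap must hold integers")
        if self.labels.min() < 0:
            raise ValueError("labels must be nonnegative")

    @property
    def ids(self) -> np.ndarray:
        """Sorted nonzero labels present in the map."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    def mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class SegmentationResult:
    """Nuclei, cells, cytoplasm and the nucleus→cell assignment."""

    nuclei: LabelMap
    cells: LabelMap
    cytoplasm: LabelMap
    nucleus_to_cell: dict[int, int]

    def nuclei_of_cell(self, cell_label: int) -> list[int]:
        return [n for n, c in self.nucleus_to_cell.items() if c == cell_label]


def _auto_threshold(image: np.ndarray, method: str = "otsu", value: float | None = None) -> float:
    """Global foreground threshold: Otsu, fixed value, or percentile."""
    if method == "otsu":
        return float(threshold_otsu(image))
    if method == "fixed":
        if value is None:
            raise ValueError("fixed threshold requires a value")
        return float(value)
    if method == "percentile":
        if value is None:
            raise ValueError("percentile threshold requires a value")
        return float(np.percentile(image, value))
    raise ValueError(f"unknown threshold method {method!r}")


def segment_nuclei(
    nucleus_channel: np.ndarray,
    pixel_size_um: float,
    min_nucleus_area_um2: float = 20.0,
    smoothing_scale_um: float = 1.0,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
) -> LabelMap:
    """Label nucleus-like objects in the DNA-counterstain channel.

    Smooth at ``smoothing_scale_um``, take an automatic global
    threshold, split touching nuclei with a distance-transform seeded
    watershed, and drop objects below ``min_nucleus_area_um2``.

    A constant (zero-variance) image yields an empty label map with a
    warning, never an exception.
    """
    img = np.asarray(nucleus_channel, dtype=float)
    if img.ndim != 2:
        raise ValueError("nucleus channel must be 2-D")
    if min_nucleus_area_um2 <= 0 or smoothing_scale_um <= 0 or pixel_size_um <= 0:
        raise ValueError("parameters must be positive")

    empty = LabelMap(np.zeros(img.shape, dtype=np.int32), pixel_size_um)
    if img.max() == img.min():
        warnings.warn("constant nucleus channel: no nuclei found", stacklevel=2)
        return empty

    sigma_px = smoothing_scale_um / pixel_size_um
    smoothed = gaussian(img, sigma=sigma_px, preserve_range=True)
    if smoothed.max() == smoothed.min():
        warnings.warn("nucleus channel flat after smoothing: no nuclei found", stacklevel=2)
        return empty
    fg = smoothed > _auto_threshold(smoothed, threshold_method, threshold_value)
    fg = ndi.binary_fill_holes(fg)
    if not fg.any():
        return empty

    # Distance-transform maxima seed the split of touching nuclei; the
    # minimum seed separation scales with the smallest admissible nucleus.
    min_area_px = min_nucleus_area_um2 / pixel_size_um**2
    dist = ndi.distance_transform_edt(fg)
    min_sep = max(1, int(round(0.5 * np.sqrt(min_area_px))))
    # smooth the distance map so rasterisation bumps along a nucleus'
    # medial ridge do not seed spurious splits
    dist_s = gaussian(dist, sigma=max(1.0, min_sep / 2), preserve_range=True)
    peaks = peak_local_max(dist_s, min_distance=min_sep, labels=fg, exclude_border=False)
    seeds = np.zeros(img.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        seeds[r, c] = i
    if seeds.max() == 0:
        return empty
    labels = watershed(-dist, markers=seeds, mask=fg, connectivity=2)

    # smoothing dilates the thresholded mask past the true boundary,
    # diluting area and intensity measures; trim against the raw image
    labels[img <= _auto_threshold(img, threshold_method, threshold_value)] = 0

    counts = np.bincount(labels.ravel())
    too_small = np.flatnonzero(counts < min_area_px)
    labels[np.isin(labels, too_small[too_small > 0])] = 0
    return LabelMap(labels.astype(np.int32), pixel_size_um)


def segment_cells(
    boundary_channel: np.ndarray,
    nuclei: LabelMap,
    threshold_method: str = "otsu",
    threshold_value: float | None = None,
    smoothing_scale_um: float = 1.0,
) -> LabelMap:
    """Grow one cell per seed nucleus over the membrane (or ER) channel.

    Region growing is a watershed over the channel's gradient magnitude,
    seeded with the nucleus labels and constrained to an automatic
    foreground mask of the channel, so cell labels coincide with their
    seed nucleus labels and every cell contains its nucleus.  When the
    membrane counterstain is absent, callers pass the ER channel here
    instead (marker-only experiments).
    """
    img = np.asarray(boundary_channel, dtype=float)
    out_dtype = np.int32
    if len(nuclei) == 0:
        return LabelMap(np.zeros(img.shape, dtype=out_dtype), nuclei.pixel_size_um)

    sigma_px = smoothing_scale_um / max(nuclei.pixel_size_um, 1e-9)
    smoothed = gaussian(img, sigma=sigma_px, preserve_range=True)
    if smoothed.max() == smoothed.min():
        warnings.warn("constant boundary channel: cells limited to nuclei", stacklevel=2)
        return LabelMap(nuclei.labels.astype(out_dtype), nuclei.pixel_size_um)

    # Background competes as an extra seed so the nucleus/background
    # watershed line locks onto the strongest intensity edge (the cell
    # boundary) instead of the blurred foreground-threshold contour.
    fg = smoothed > _auto_threshold(smoothed, threshold_method, threshold_value)
    fg |= nuclei.labels > 0
    bg_label = int(nuclei.labels.max()) + 1
    markers = nuclei.labels.astype(np.int64).copy()
    bg_seed = ~ndi.binary_dilation(fg, structure=STRUCT_8, iterations=2)
    markers[bg_seed & (markers == 0)] = bg_label

    landscape = sobel(smoothed)
    lab = watershed(landscape, markers=markers, connectivity=2)
    lab[lab == bg_label] = 0

    # Refine against the unsmoothed channel: smoothing spreads a halo of
    # background pixels past the true edge, and the watershed line can
    # follow it; dropping claimed pixels below the raw-image threshold
    # recovers a pixel-accurate boundary.
    raw_thr = _auto_threshold(img, threshold_method, threshold_value)
    bright = img > raw_thr

    # A cell is the connected piece containing its seed nucleus (holes
    # refilled); distant foreground annexed across flat background
    # (e.g. a footprint whose nucleus was filtered out) is released.
    cells = np.zeros(img.shape, dtype=out_dtype)
    for n in nuclei.ids:
        piece = (lab == n) & (bright | (nuclei.labels == n))
        if not piece.any():
            continue
        comp, _ = ndi.label(piece, structure=STRUCT_8)
        seed_ids = np.unique(comp[(nuclei.labels == n) & piece])
        seed_ids = seed_ids[seed_ids > 0]
        if seed_ids.size:
            mask = ndi.binary_fill_holes(np.isin(comp, seed_ids))
            cells[mask & (lab == n)] = n
    return LabelMap(cells, nuclei.pixel_size_um)


def assign_nuclei_to_cells(nuclei: LabelMap, cells: LabelMap) -> dict[int, int]:
    """Map each nucleus to the cell containing (the majority of) it.

    Nuclei not contained in any cell are dropped with a warning.
    """
    assignment: dict[int, int] = {}
    for n in nuclei.ids:
        mask = nuclei.labels == n
        covering = cells.labels[mask]
        covering = covering[covering > 0]
        if covering.size == 0:
            warnings.warn(f"nucleus {n} lies in no cell; ignored", stacklevel=2)
            continue
        vals, counts = np.unique(covering, return_counts=True)
        assignment[int(n)] = int(vals[np.argmax(counts)])
    return assignment


def merge_multinucleate(
    cells: LabelMap,
    nuclei: LabelMap,
    boundary_channel: np.ndarray,
    ridge_factor: float = 1.2,
) -> tuple[LabelMap, dict[int, int]]:
    """Merge seed-split cells that share a boundary with no membrane ridge.

    Seeded growth yields exactly one cell per nucleus, so a genuinely
    multinucleated cell comes out split into adjacent fragments.  Two
    adjacent cells are merged when the mean boundary intensity of the
    membrane channel along their shared border is below ``ridge_factor``
    times the mean of their interiors — i.e. the border is not supported
    by an actual membrane.  Returns the merged map and the
    nucleus→(merged) cell assignment.
    """
    img = np.asarray(boundary_channel, dtype=float)
    lab = cells.labels.copy()
    ids = list(cells.ids)
    if len(ids) < 2:
        return cells, assign_nuclei_to_cells(nuclei, cells)

    interior_mean = {i: float(img[lab == i].mean()) for i in ids}

    # shared-border pixels between each adjacent label pair
    bounds = find_boundaries(lab, mode="thick", connectivity=2) & (lab > 0)
    parent = {i: i for i in ids}

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    pair_pixels: dict[tuple[int, int], list[float]] = {}
    ys, xs = np.nonzero(bounds)
    h, w = lab.shape
    for y, x in zip(ys, xs):
        a = lab[y, x]
        neigh = lab[max(0, y - 1) : y + 2, max(0, x - 1) : x + 2]
        for b in np.unique(neigh):
            if b > a:
                pair_pixels.setdefault((int(a), int(b)), []).append(img[y, x])
    for (a, b), vals in pair_pixels.items():
        ridge = float(np.mean(vals))
        base = 0.5 * (interior_mean[a] + interior_mean[b])
        if ridge < ridge_factor * base:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    merged = lab.copy()
    for i in ids:
        r = find(i)
        if r != i:
            merged[lab == i] = r
    out = LabelMap(merged, cells.pixel_size_um)
    return out, assign_nuclei_to_cells(nuclei, out)


def derive_cytoplasm(
    cells: LabelMap, nuclei: LabelMap, assignment: dict[int, int]
) -> LabelMap:
    """Cytoplasm per cell: the cell's pixels minus its assigned nuclei."""
    cyto = cells.labels.copy()
    for n, c in assignment.items():
        cyto[(nuclei.labels == n) & (cells.labels == c)] = 0
    # nucleus pixels assigned to no cell stay wherever they are (warned upstream)
    return LabelMap(cyto, cells.pixel_size_um)


def remove_border_cells(cells: LabelMap) -> LabelMap:
    """Delete every cell with at least one pixel on the image border."""
    lab = cells.labels
    border = np.unique(
        np.concatenate([lab[0, :], lab[-1, :], lab[:, 0], lab[:, -1]])
    )
    border = border[border > 0]
    if border.size == 0:
        return cells
    out = lab.copy()
    out[np.isin(out, border)] = 0
    return LabelMap(out, cells.pixel_size_um)


def segment_field(
    nucleus_channel: np.ndarray,
    er_channel: np.ndarray,
    pixel_size_um: float,
    membrane_channel: np.ndarray | None = None,
    min_nucleus_area_um2: float = 20.0,
    smoothing_scale_um: float = 1.0,
    threshold_method: str = "otsu",
    merge_ridge_factor: float = 1.2,
) -> SegmentationResult:
    """Full segmentation of one projected field.

    nuclei → cells (membrane channel, falling back to the ER channel) →
    multinucleate merging → border-cell removal → cytoplasm.
    """
    nuclei = segment_nuclei(
        nucleus_channel,
        pixel_size_um,
        min_nucleus_area_um2=min_nucleus_area_um2,
        smoothing_scale_um=smoothing_scale_um,
        threshold_method=threshold_method,
    )
    if membrane_channel is not None:
        boundary = membrane_channel
    else:
        logger.info("no membrane channel: segmenting cells from the ER channel")
        boundary = er_channel
    cells = segment_cells(
        boundary, nuclei, threshold_method=threshold_method, smoothing_scale_um=smoothing_scale_um
    )
    cells, assignment = merge_multinucleate(cells, nuclei, boundary, merge_ridge_factor)
    cells = remove_border_cells(cells)
    kept = set(int(i) for i in cells.ids)
    assignment = {n: c for n, c in assignment.items() if c in kept}
    # drop nuclei whose cell was removed at the border
    nuc = nuclei.labels.copy()
    lost = [n for n in nuclei.ids if int(n) not in assignment]
    if lost:
        nuc[np.isin(nuc, lost)] = 0
    nuclei = LabelMap(nuc, pixel_size_um)
    cyto = derive_cytoplasm(cells, nuclei, assignment)
    return SegmentationResult(nuclei=nuclei, cells=cells, cytoplasm=cyto, nucleus_to_cell=assignment)
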