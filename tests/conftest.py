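"""Shared fixtures and independent oracles for the test suite.

The brute-force polygon oracle here is deliberately primitive (explicit
BFS flood fill and neighbour loops) and shares no code with the package
implementation it checks.
"""

from __future__ import annotations

from collections import deque

import numpy as np
import pytest

from ermorph import GeneratorParams, generate_field


# --------------------------------------------------------------------------
# independent oracles
# --------------------------------------------------------------------------

NEIGHBOURS_8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def brute_force_polygons(
    er_mask: np.ndarray, roi_mask: np.ndarray, cell_mask: np.ndarray
) -> list[tuple[frozenset, bool]]:
    """Flood-fill reference for polygon detection.

    Returns every 8-connected component of (ROI − ER mask) as a frozen
    pixel set together with whether it lies within one pixel of the
    cell's inner perimeter band (cell pixels with a neighbour outside
    the cell, or on the image edge).
    """
    er = np.asarray(er_mask, bool)
    roi = np.asarray(roi_mask, bool)
    cell = np.asarray(cell_mask, bool)
    h, w = cell.shape

    band = set()
    for y in range(h):
        for x in range(w):
            if not cell[y, x]:
                continue
            if y in (0, h - 1) or x in (0, w - 1):
                band.add((y, x))
                continue
            for dy, dx in NEIGHBOURS_8:
                if not cell[y + dy, x + dx]:
                    band.add((y, x))
                    break
    near_band = set(band)
    for (y, x) in band:
        for dy, dx in NEIGHBOURS_8:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w:
                near_band.add((ny, nx))

    complement = roi & ~er
    seen = np.zeros_like(complement)
    components = []
    for y in range(h):
        for x in range(w):
            if not complement[y, x] or seen[y, x]:
                continue
            queue = deque([(y, x)])
            seen[y, x] = True
            pixels = []
            while queue:
                cy, cx = queue.popleft()
                pixels.append((cy, cx))
                for dy, dx in NEIGHBOURS_8:
                    ny, nx = cy + dy, cx + dx
                    if 0 <= ny < h and 0 <= nx < w and complement[ny, nx] and not seen[ny, nx]:
                        seen[ny, nx] = True
                        queue.append((ny, nx))
            touches = any(p in near_band for p in pixels)
            components.append((frozenset(pixels), touches))
    return components


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    union = (a | b).sum()
    return float((a & b).sum() / union) if union else 1.0


def match_truth_cells(truth, cells_labelmap):
    """Map truth cell label -> best-overlapping segmented label (or None)."""
    mapping = {}
    for c in truth.cells:
        tmask = truth.cell_mask(c.label)
        overlap = cells_labelmap.labels[tmask]
        overlap = overlap[overlap > 0]
        mapping[c.label] = int(np.bincount(overlap).argmax()) if overlap.size else None
    return mapping


# --------------------------------------------------------------------------
# fixtures
# --------------------------------------------------------------------------

NOISELESS = dict(poisson_gain=0.0, read_noise_sd=0.0)


@pytest.fixture(scope="session")
def clean_field():
    """Default-parameter synthetic field with shot + read noise."""
    return generate_field(GeneratorParams(seed=1))


@pytest.fixture(scope="session")
def noiseless_field():
    """Default geometry, noise disabled: for exact-recovery checks."""
    return generate_field(GeneratorParams(seed=1, **NOISELESS))


@pytest.fixture(scope="session")
def defect_field():
    """One dark, one mitotic, one binucleate and two clean cells."""
    params = GeneratorParams(
        seed=3, n_cells=5, defects={0: "dark", 1: "mitotic", 2: "binucleate"}
    )
    return generate_field(params)
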