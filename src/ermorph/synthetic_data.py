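"""Synthetic fluorescence fields with full per-stage ground truth.

The generator emulates the phenotypes of adherent, flat cultured cells
expressing a fluorescent ER marker, as seen in a confocal max
projection: ovoid nuclei, convex-ish elliptical cell footprints, a
brighter perinuclear dense-ER region of tunable areal fraction, and a
peripheral tubular mesh built from a seeded planar (Voronoi-like)
partition of the cytoplasmic ring with tunable pitch.  Defect presets
inject the cell classes the QC stage must remove: non-transfected
("dark"), mitotic, binucleated and image-border cells.

Every geometric primitive is recorded as ground truth (masks, true
polygon areas, true dense fraction, intended QC fate), so each pipeline
stage — and end-to-end phenotype recovery — can be tested without any
real image.  Seeding is two-level: the geometry seed and the noise seed
are split, so noise-robustness tests can redraw noise over fixed
geometry.  Identical parameters and seed give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy.spatial import cKDTree

from .imaging_io import FieldImage, write_field
from .segmentation import STRUCT_8

DEFECT_PRESETS = ("dark", "mitotic", "binucleate", "border")


@dataclass
class GeneratorParams:
    """Knobs of the synthetic field generator (lengths in µm)."""

    image_size_px: int = 512
    pixel_size_um: float = 0.28
    n_cells: int = 5
    cell_radius_um: tuple[float, float] = (13.0, 16.0)
    nucleus_radius_um: tuple[float, float] = (5.0, 7.0)
    mesh_pitch_um: float = 3.0
    tubule_width_um: float = 0.5
    dense_fraction: float = 0.20
    # intensity levels (arbitrary detector units); dense ≈ 3× tubule,
    # mirroring the strong perinuclear/peripheral contrast of real ER markers
    background: float = 50.0
    er_lumen: float = 600.0
    tubule_intensity: float = 1100.0
    dense_intensity: float = 3300.0
    nucleus_intensity: float = 3000.0
    membrane_fill: float = 800.0
    membrane_outline: float = 1600.0
    # noise model: Poisson shot noise (photons per intensity unit) then
    # additive Gaussian read noise; either set to 0 disables it
    poisson_gain: float = 0.5
    read_noise_sd: float = 20.0
    # mesh construction: jittered square lattice of partition seeds;
    # jitter 0 gives the regular-grid mode used by exact-count oracles
    mesh_jitter: float = 0.08
    # smallest truth polygon recorded, in px (matches the analysis default)
    min_polygon_area_px: int = 4
    dark_scale: float = 0.05
    defects: dict[int, str] = dc_field(default_factory=dict)
    n_z: int = 1
    z_step_um: float = 0.5
    seed: int = 0
    noise_seed: int | None = None

    def validate(self) -> None:
        if self.image_size_px < 16 or self.n_cells < 0:
            raise ValueError("bad image size or cell count")
        for name in ("pixel_size_um", "mesh_pitch_um", "tubule_width_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0.0 <= self.dense_fraction < 1.0):
            raise ValueError("dense_fraction must be in [0, 1)")
        for preset in self.defects.values():
            if preset not in DEFECT_PRESETS:
                raise ValueError(f"unknown defect preset {preset!r}")
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")


@dataclass
class CellTruth:
    """Ground truth for one synthetic cell."""

    label: int
    intended_fate: str | None  # defect preset, or None for a clean cell
    center_px: tuple[float, float]
    polygon_areas_um2: list[float]
    dense_fraction: float

    @property
    def mean_polygon_area_um2(self) -> float:
        return float(np.mean(self.polygon_areas_um2)) if self.polygon_areas_um2 else float("nan")


@dataclass
class GroundTruth:
    """Truth label maps and per-cell records for one synthetic field."""

    nuclei_labels: np.ndarray
    cell_labels: np.ndarray
    dense_mask: np.ndarray
    tubule_mask: np.ndarray
    cells: list[CellTruth]
    params: GeneratorParams

    def cell_mask(self, label: int) -> np.ndarray:
        return self.cell_labels == label

    def nucleus_mask(self, label: int) -> np.ndarray:
        return self.nuclei_labels == label


def _ellipse_mask(shape, cy, cx, ry, rx, theta) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def _place_cells(params: GeneratorParams, rng: np.random.Generator):
    """Rejection-sample non-overlapping elliptical footprints.

    Cells with the "border" preset are deliberately placed crossing an
    image edge; all others keep a 2-px clearance from the border and
    from each other.
    """
    n_px = params.image_size_px
    px = params.pixel_size_um
    placements = []  # (cy, cx, ry, rx, theta, preset)
    for i in range(params.n_cells):
        preset = params.defects.get(i)
        r_lo, r_hi = (r / px for r in params.cell_radius_um)
        for _attempt in range(2000):
            rx = rng.uniform(r_lo, r_hi)
            ry = rng.uniform(0.8, 1.0) * rx
            theta = rng.uniform(0, np.pi)
            rmax = max(rx, ry)
            if preset == "border":
                edge = rng.integers(4)
                along = rng.uniform(rmax, n_px - rmax)
                off = 0.5 * rmax  # centre half a radius from the edge: must cross it
                cy, cx = [(off, along), (n_px - off, along), (along, off), (along, n_px - off)][edge]
            else:
                cy = rng.uniform(rmax + 2, n_px - rmax - 2)
                cx = rng.uniform(rmax + 2, n_px - rmax - 2)
            ok = all(
                np.hypot(cy - p[0], cx - p[1]) > rmax + max(p[2], p[3]) + 2
                for p in placements
            )
            if ok:
                placements.append((cy, cx, ry, rx, theta, preset))
                break
        else:
            raise ValueError(
                f"infeasible packing: could not place cell {i + 1}/{params.n_cells} "
                f"of radius ~{rmax * px:.1f} um in a {n_px * px:.0f} um field"
            )
    return placements


def _radial_ratio(cyto: np.ndarray, nuc: np.ndarray, cell: np.ndarray) -> np.ndarray:
    """Dn / (Dn + Dp) over the cytoplasm (same coordinate the ROI uses)."""
    d_nuc = ndi.distance_transform_edt(~nuc)
    d_per = ndi.distance_transform_edt(cell)
    with np.errstate(invalid="ignore"):
        return np.where(cyto, d_nuc / np.maximum(d_nuc + d_per, 1e-12), np.inf)


def _mesh_for_cell(
    mesh_region: np.ndarray, params: GeneratorParams, rng: np.random.Generator
) -> np.ndarray:
    """Tubule raster: bisector bands of a jittered-lattice planar partition.

    Partition seeds sit on a square lattice of pitch ``mesh_pitch_um``
    jittered by ``mesh_jitter`` × pitch; a pixel is tubule when its two
    nearest seeds are nearly equidistant (band of ``tubule_width_um``
    around the Voronoi edge).
    """
    p_px = params.mesh_pitch_um / params.pixel_size_um
    w_px = params.tubule_width_um / params.pixel_size_um
    ys, xs = np.nonzero(mesh_region)
    if ys.size == 0:
        return np.zeros_like(mesh_region)
    y0, y1, x0, x1 = ys.min(), ys.max(), xs.min(), xs.max()
    gy = np.arange(y0 - p_px, y1 + p_px, p_px)
    gx = np.arange(x0 - p_px, x1 + p_px, p_px)
    seeds = np.stack(np.meshgrid(gy, gx, indexing="ij"), axis=-1).reshape(-1, 2)
    seeds = seeds + rng.normal(0, params.mesh_jitter * p_px, seeds.shape)
    inside = (
        (seeds[:, 0] >= 0)
        & (seeds[:, 0] < mesh_region.shape[0])
        & (seeds[:, 1] >= 0)
        & (seeds[:, 1] < mesh_region.shape[1])
    )
    seeds = seeds[inside]
    if len(seeds):
        on_mesh = mesh_region[
            np.clip(seeds[:, 0].round().astype(int), 0, mesh_region.shape[0] - 1),
            np.clip(seeds[:, 1].round().astype(int), 0, mesh_region.shape[1] - 1),
        ]
        seeds = seeds[on_mesh]
    if len(seeds) < 2:
        return np.zeros_like(mesh_region)
    tree = cKDTree(seeds)
    pts = np.stack([ys, xs], axis=1).astype(float)
    dists, _ = tree.query(pts, k=2)
    band = (dists[:, 1] - dists[:, 0]) < w_px
    tubules = np.zeros_like(mesh_region)
    tubules[ys[band], xs[band]] = True
    return tubules


def _true_polygons(
    mesh_region: np.ndarray, tubules: np.ndarray, cell: np.ndarray, params: GeneratorParams
) -> list[float]:
    """Areas (µm²) of the closed mesh gaps, mirroring the analysis rule:
    8-connected components not adjacent to the cell perimeter band."""
    comp = mesh_region & ~tubules
    labels, n = ndi.label(comp, structure=STRUCT_8)
    if n == 0:
        return []
    band = cell & ~ndi.binary_erosion(cell, structure=STRUCT_8)
    near = ndi.binary_dilation(band, structure=STRUCT_8)
    touching = set(np.unique(labels[near])) - {0}
    areas = ndi.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    px2 = params.pixel_size_um**2
    return [
        float(a) * px2
        for lab, a in zip(range(1, n + 1), areas)
        if lab not in touching and a >= params.min_polygon_area_px
    ]


def _emit_z(img: np.ndarray, n_z: int) -> np.ndarray:
    """Spread a 2-D render over z planes so that the per-pixel maximum
    over planes reproduces the 2-D image exactly."""
    if n_z == 1:
        return img
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    owner = (yy + xx) % n_z
    # off-planes carry a reduced copy, never exceeding the render even
    # where read noise made a pixel negative
    off = np.minimum(0.55 * img, img)
    stack = np.empty((n_z, h, w), dtype=img.dtype)
    for j in range(n_z):
        stack[j] = np.where(owner == j, img, off)
    return stack


def generate_field(params: GeneratorParams) -> tuple[FieldImage, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Stages: place cells → nuclei (one per cell; two for "binucleate",
    small/bright for "mitotic") → perinuclear dense region sized to
    ``dense_fraction`` of the cytoplasm → peripheral tubule mesh →
    channel render → noise → optional z-stack emission.
    """
    params.validate()
    ss = np.random.SeedSequence(params.seed)
    geom_ss, noise_ss = ss.spawn(2)
    rng = np.random.default_rng(geom_ss)
    noise_rng = (
        np.random.default_rng(params.noise_seed)
        if params.noise_seed is not None
        else np.random.default_rng(noise_ss)
    )

    n_px = params.image_size_px
    px = params.pixel_size_um
    shape = (n_px, n_px)
    cell_labels = np.zeros(shape, dtype=np.int32)
    nuclei_labels = np.zeros(shape, dtype=np.int32)
    dense_mask = np.zeros(shape, dtype=bool)
    tubule_mask = np.zeros(shape, dtype=bool)

    nucleus_ch = np.full(shape, params.background)
    membrane_ch = np.full(shape, params.background)
    er_ch = np.full(shape, params.background)

    placements = _place_cells(params, rng)
    cells: list[CellTruth] = []
    next_nucleus_label = 1

    for i, (cy, cx, ry, rx, theta, preset) in enumerate(placements):
        label = i + 1
        cell = _ellipse_mask(shape, cy, cx, ry, rx, theta)
        cell_labels[cell] = label

        # --- nuclei -----------------------------------------------------
        nr_lo, nr_hi = (r / px for r in params.nucleus_radius_um)
        nuc_intensity = params.nucleus_intensity
        nuc = np.zeros(shape, dtype=bool)
        if preset == "mitotic":
            # condensed chromatin: ~30 um^2 round nucleus at double intensity
            r_mit = np.sqrt(30.0 / np.pi) / px
            nuc = _ellipse_mask(shape, cy, cx, r_mit, r_mit, 0.0)
            nuc_intensity = 2.0 * params.nucleus_intensity
            nuc &= cell
            nuclei_labels[nuc] = next_nucleus_label
            next_nucleus_label += 1
        elif preset == "binucleate":
            nry = rng.uniform(nr_lo, 0.9 * nr_hi)
            nrx = rng.uniform(0.85, 1.0) * nry
            axis = rng.uniform(0, np.pi)
            off = 1.15 * nry
            for s in (-1, 1):
                m = _ellipse_mask(
                    shape, cy + s * off * np.sin(axis), cx + s * off * np.cos(axis),
                    nry, nrx, axis,
                ) & cell & ~nuc
                nuc |= m
                nuclei_labels[m] = next_nucleus_label
                next_nucleus_label += 1
        else:
            nry = rng.uniform(nr_lo, nr_hi)
            nrx = rng.uniform(0.85, 1.0) * nry
            m = _ellipse_mask(
                shape, cy + rng.uniform(-2, 2), cx + rng.uniform(-2, 2),
                nry, nrx, rng.uniform(0, np.pi),
            ) & cell
            nuc = m
            nuclei_labels[m] = next_nucleus_label
            next_nucleus_label += 1
        nucleus_ch[nuc] = nuc_intensity

        cyto = cell & ~nuc

        # --- perinuclear dense region ------------------------------------
        dense = np.zeros(shape, dtype=bool)
        if params.dense_fraction > 0 and cyto.any() and nuc.any():
            ratio = _radial_ratio(cyto, nuc, cell)
            vals = ratio[cyto]
            cut = np.quantile(vals, params.dense_fraction)
            dense = cyto & (ratio <= cut)
        dense_mask |= dense

        # --- peripheral tubule mesh --------------------------------------
        mesh_region = cyto & ~dense
        tubules = _mesh_for_cell(mesh_region, params, rng)
        tubule_mask |= tubules
        poly_areas = _true_polygons(mesh_region, tubules, cell, params)

        # --- render ------------------------------------------------------
        membrane_ch[cell] = params.membrane_fill
        outline = cell & ~ndi.binary_erosion(cell, structure=STRUCT_8, iterations=2)
        membrane_ch[outline] = params.membrane_outline

        er_cell = np.full(shape, 0.0)
        er_cell[cyto] = params.er_lumen
        er_cell[nuc] = 0.6 * params.er_lumen
        er_cell[tubules] = params.tubule_intensity
        er_cell[dense] = params.dense_intensity
        if preset == "dark":
            er_cell[cell] = params.background + params.dark_scale * (
                er_cell[cell] - params.background
            )
        er_ch[cell] = er_cell[cell]

        true_dense_frac = float(dense.sum()) / float(cyto.sum()) if cyto.any() else 0.0
        cells.append(
            CellTruth(
                label=label,
                intended_fate=preset,
                center_px=(float(cy), float(cx)),
                polygon_areas_um2=poly_areas,
                dense_fraction=true_dense_frac,
            )
        )

    # --- noise, applied to the 2-D render --------------------------------
    channels = {"nucleus": nucleus_ch, "membrane": membrane_ch, "er": er_ch}
    for role, img in channels.items():
        noisy = img
        if params.poisson_gain > 0:
            noisy = noise_rng.poisson(np.maximum(noisy, 0) * params.poisson_gain) / params.poisson_gain
        if params.read_noise_sd > 0:
            noisy = noisy + noise_rng.normal(0.0, params.read_noise_sd, size=img.shape)
        channels[role] = noisy.astype(np.float64)

    channels = {role: _emit_z(img, params.n_z) for role, img in channels.items()}

    field = FieldImage(
        channels=channels,
        pixel_size_um=px,
        z_step_um=params.z_step_um if params.n_z > 1 else None,
        field_id=f"synthetic-{params.seed}",
    )
    truth = GroundTruth(
        nuclei_labels=nuclei_labels,
        cell_labels=cell_labels,
        dense_mask=dense_mask,
        tubule_mask=tubule_mask,
        cells=cells,
        params=params,
    )
    return field, truth


@dataclass
class Condition:
    """One simulated experimental condition (e.g. one drug / one well)."""

    name: str
    pitch_multiplier: float
    dense_multiplier: float
    params: GeneratorParams
    fields: list[tuple[FieldImage, GroundTruth]]


def generate_condition_series(
    base: GeneratorParams,
    pitch_multipliers: list[float] = (1.0,),
    dense_multipliers: list[float] = (1.0,),
    n_fields: int = 1,
    seed: int = 0,
) -> tuple[list[Condition], pd.DataFrame]:
    """Simulate a panel of conditions by scaling mesh pitch and dense size.

    The two multiplier lists are paired elementwise (a length-1 list is
    broadcast), one condition per pair — the synthetic analogue of a
    drug panel that loosens/condenses the tubular network or expands
    the dense RER.  Returns the conditions and a per-condition truth
    summary table.
    """
    pm = list(pitch_multipliers)
    dm = list(dense_multipliers)
    if len(pm) == 1:
        pm = pm * len(dm)
    if len(dm) == 1:
        dm = dm * len(pm)
    if len(pm) != len(dm):
        raise ValueError("multiplier lists must match in length (or be length 1)")
    if any(m <= 0 for m in pm + dm):
        raise ValueError("multipliers must be positive")

    conditions = []
    rows = []
    for ci, (p_mul, d_mul) in enumerate(zip(pm, dm)):
        params = replace(
            base,
            mesh_pitch_um=base.mesh_pitch_um * p_mul,
            dense_fraction=min(base.dense_fraction * d_mul, 0.95),
        )
        fields = []
        for fi in range(n_fields):
            child = np.random.SeedSequence(entropy=seed, spawn_key=(ci, fi))
            fparams = replace(params, seed=int(child.generate_state(1)[0] % 2**31))
            fields.append(generate_field(fparams))
        cond = Condition(
            name=f"cond{ci + 1:02d}_p{p_mul:g}_d{d_mul:g}",
            pitch_multiplier=p_mul,
            dense_multiplier=d_mul,
            params=params,
            fields=fields,
        )
        conditions.append(cond)
        all_polys = [a for _, t in fields for c in t.cells for a in c.polygon_areas_um2
                     if c.intended_fate is None]
        all_dense = [c.dense_fraction for _, t in fields for c in t.cells
                     if c.intended_fate is None]
        rows.append(
            {
                "condition": cond.name,
                "pitch_multiplier": p_mul,
                "dense_multiplier": d_mul,
                "mesh_pitch_um": params.mesh_pitch_um,
                "dense_fraction_target": params.dense_fraction,
                "true_mean_polygon_area_um2": float(np.mean(all_polys)) if all_polys else np.nan,
                "true_n_polygons": len(all_polys),
                "true_mean_dense_percent": 100 * float(np.mean(all_dense)) if all_dense else np.nan,
            }
        )
    return conditions, pd.DataFrame(rows)


def write_dataset(out_dir: str | Path, conditions: list[Condition]) -> pd.DataFrame:
    """Write a condition series as an HCS-style plate of OME-TIFF fields.

    One well per condition (r01c01, r01c02, …), one file per field,
    named ``r<row>c<col>f<field>.ome.tif``; the per-cell truth table is
    written alongside as ``ground_truth.csv`` and returned.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ci, cond in enumerate(conditions):
        well = f"r01c{ci + 1:02d}"
        for fi, (field, truth) in enumerate(cond.fields):
            name = f"{well}f{fi + 1:02d}.ome.tif"
            write_field(out_dir / name, field)
            for c in truth.cells:
                rows.append(
                    {
                        "condition": cond.name,
                        "well": well,
                        "field": fi + 1,
                        "cell": c.label,
                        "intended_fate": c.intended_fate or "clean",
                        "true_mean_polygon_area_um2": c.mean_polygon_area_um2,
                        "true_n_polygons": len(c.polygon_areas_um2),
                        "true_dense_percent": 100 * c.dense_fraction,
                    }
                )
    table = pd.DataFrame(rows)
    table.to_csv(out_dir / "ground_truth.csv", index=False)
    return table


# --------------------------------------------------------------------------
# small deterministic oracle fixtures
# --------------------------------------------------------------------------

def grid_fixture(
    size: int = 64, pitch: int = 12, line_width: int = 2, margin: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """A square cell crossed by a regular grid of tubule lines.

    Returns (cell_mask, roi_mask, er_mask).  The grid partitions the
    ROI into rectangular gaps with exactly known interior/border
    membership, which makes this the reference fixture for
    polygon-detection oracles: interior gaps are true polygons, gaps in
    the outermost ring touch the cell perimeter and must be dropped.
    """
    cell = np.zeros((size, size), bool)
    cell[margin : size - margin, margin : size - margin] = True
    roi = cell.copy()
    er = np.zeros_like(cell)
    for start in range(margin + pitch, size - margin, pitch):
        er[start : start + line_width, :] = True
        er[:, start : start + line_width] = True
    er &= roi
    return cell, roi, er


def oval_nuclei_image(
    size: int = 128,
    centers: tuple[tuple[float, float], ...] = ((32, 32), (32, 96), (96, 64)),
    radii: tuple[float, float] = (14.0, 10.0),
    intensity: float = 3000.0,
    background: float = 50.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Bright ovals on a dark background plus their truth label map."""
    img = np.full((size, size), background)
    labels = np.zeros((size, size), np.int32)
    for i, (cy, cx) in enumerate(centers, start=1):
        m = _ellipse_mask((size, size), cy, cx, radii[0], radii[1], 0.4 * i)
        img[m] = intensity
        labels[m] = i
    return img, labels


def write_fixtures(out_dir: str | Path) -> list[Path]:
    """Write the deterministic oracle images used by the unit tests."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    import tifffile

    written = []
    cell, roi, er = grid_fixture()
    for name, arr in (("grid_cell", cell), ("grid_roi", roi), ("grid_er", er)):
        p = out / f"{name}.tif"
        tifffile.imwrite(p, arr.astype(np.uint8))
        written.append(p)
    img, labels = oval_nuclei_image()
    for name, arr in (("ovals", img.astype(np.float32)), ("ovals_labels", labels)):
        p = out / f"{name}.tif"
        tifffile.imwrite(p, arr)
        written.append(p)
    field, _ = generate_field(GeneratorParams(image_size_px=256, n_cells=2, seed=7))
    p = out / "small_field.ome.tif"
    write_field(p, field)
    written.append(p)
    return written
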