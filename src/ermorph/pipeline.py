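"""End-to-end orchestration: read → project → segment → QC → metrics → aggregate.

A *plate* is a directory of field images whose filenames encode the
well and field (HCS-style ``r01c02f03`` by default).  The pipeline runs
every field independently, measures every passed cell, and emits tidy
tables: one row per polygon region (``per_object.csv``), per cell
(``per_cell.csv``) and per well (``per_well.csv``), plus a QC report.
Well summaries (mean ± SEM of both metrics) are computed over passed
cells only; significance testing is left to downstream stats tools.

Outputs use fixed float formatting so re-running on identical inputs
gives byte-identical files.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import er_metrics, imaging_io, qc_filters, segmentation

logger = logging.getLogger("ermorph")

FLOAT_FORMAT = "%.6g"


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

def _from_dict(cls, data: dict):
    """Build a (possibly nested) config dataclass, rejecting unknown keys."""
    names = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(names)
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for key, val in data.items():
        ftype = names[key].type
        sub = _SECTION_TYPES.get((cls.__name__, key))
        kwargs[key] = _from_dict(sub, val) if sub is not None and isinstance(val, dict) else val
    return cls(**kwargs)


@dataclass
class SegmentationConfig:
    # size floor for debris removal only; the QC stage applies its own,
    # stricter nuclear-area cut so small mitotic nuclei survive to be flagged
    min_nucleus_area_um2: float = 20.0
    smoothing_scale_um: float = 1.0
    threshold_method: str = "otsu"
    merge_ridge_factor: float = 1.2


@dataclass
class QCConfig:
    min_nucleus_area_um2: float = 60.0
    max_nucleus_area_um2: float = 600.0
    min_roundness: float = 0.5
    max_mean_intensity: float | None = None  # None -> 1.5x per-image median
    max_nuclei_per_cell: int = 1
    expression_threshold: float | None = None  # absolute, a.u.
    expression_percentile: float | None = 25.0  # of per-image cell means


@dataclass
class MetricsConfig:
    shrink_fraction: float = 0.25
    tubule_method: str = "otsu"
    tubule_otsu_multiplier: float = 1.0
    tubule_value: float | None = None
    min_polygon_area_um2: float | None = None  # None -> 4 px
    dense_method: str = "median_multiplier"
    dense_k: float = 2.0
    dense_value: float | None = None
    dense_denominator: str = "cytoplasm"  # or "cell"


@dataclass
class PipelineConfig:
    """Everything one analysis run needs, loadable from YAML.

    ``channels`` maps roles to container channel indices (ints) or, for
    one-file-per-channel layouts, to filename suffixes (strings).
    ``overrides`` holds per-marker parameter adjustments as nested
    partial configs, selected with :meth:`for_marker`.
    """

    channels: dict = dc_field(default_factory=lambda: {"nucleus": 0, "membrane": 1, "er": 2})
    pixel_size_um: float | None = None  # None -> from file metadata
    field_pattern: str = r"r(?P<row>\d+)c(?P<col>\d+)f(?P<field>\d+)"
    segmentation: SegmentationConfig = dc_field(default_factory=SegmentationConfig)
    qc: QCConfig = dc_field(default_factory=QCConfig)
    metrics: MetricsConfig = dc_field(default_factory=MetricsConfig)
    min_cells_per_well: int = 50
    overrides: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _from_dict(cls, data)

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def for_marker(self, marker: str) -> "PipelineConfig":
        """Apply a named per-marker override block (e.g. a dimmer ER
        marker needing a different threshold multiplier)."""
        if marker not in self.overrides:
            raise KeyError(f"no overrides for marker {marker!r}")
        merged = self.to_dict()
        block = self.overrides[marker]
        for section, values in block.items():
            if isinstance(values, dict) and isinstance(merged.get(section), dict):
                merged[section].update(values)
            else:
                merged[section] = values
        merged["overrides"] = {}
        return PipelineConfig.from_dict(merged)


_SECTION_TYPES = {
    ("PipelineConfig", "segmentation"): SegmentationConfig,
    ("PipelineConfig", "qc"): QCConfig,
    ("PipelineConfig", "metrics"): MetricsConfig,
}


# --------------------------------------------------------------------------
# field discovery
# --------------------------------------------------------------------------

@dataclass
class FieldEntry:
    well: str
    field: str
    paths: Path | dict[str, Path]


def discover_fields(input_root: str | Path, config: PipelineConfig) -> list[FieldEntry]:
    """Find field images under ``input_root`` and group them by well.

    Container layout (int channel mapping): every file matching the
    field pattern is one field.  Per-channel layout (str mapping):
    files are grouped by the matched field identity, one file per role,
    matched by the configured suffix.
    """
    root = Path(input_root)
    pattern = re.compile(config.field_pattern)
    container = all(isinstance(v, int) for v in config.channels.values())
    entries: dict[tuple[str, str], FieldEntry] = {}
    for path in sorted(root.rglob("*")):
        if not path.is_file() or path.suffix.lower() not in (".tif", ".tiff"):
            continue
        m = pattern.search(path.name)
        if not m:
            continue
        g = m.groupdict()
        well = f"r{g['row']}c{g['col']}" if "row" in g and "col" in g else m.group(0)
        fid = g.get("field", m.group(0))
        key = (well, fid)
        if container:
            entries[key] = FieldEntry(well=well, field=fid, paths=path)
        else:
            entry = entries.setdefault(key, FieldEntry(well=well, field=fid, paths={}))
            for role, suffix in config.channels.items():
                if path.name.endswith(str(suffix)):
                    entry.paths[role] = path
    return [entries[k] for k in sorted(entries)]


# --------------------------------------------------------------------------
# per-field analysis
# --------------------------------------------------------------------------

def analyze_projected_field(
    projected: imaging_io.ProjectedField,
    config: PipelineConfig,
    well: str = "",
    field: str = "",
) -> tuple[list[dict], list[dict], dict]:
    """Segment, QC-filter and measure one projected field.

    Returns (per-cell rows, per-object rows, QC flag counts).  ER
    metrics are computed for passed cells only; failed cells keep their
    provenance row with NaN metrics.
    """
    px = projected.pixel_size_um
    seg = segmentation.segment_field(
        projected.channels["nucleus"],
        projected.channels["er"],
        px,
        membrane_channel=projected.channels.get("membrane"),
        min_nucleus_area_um2=config.segmentation.min_nucleus_area_um2,
        smoothing_scale_um=config.segmentation.smoothing_scale_um,
        threshold_method=config.segmentation.threshold_method,
        merge_ridge_factor=config.segmentation.merge_ridge_factor,
    )
    records = qc_filters.build_cell_records(seg, projected.channels["nucleus"])
    qc_filters.flag_by_nucleus(
        records,
        min_area_um2=config.qc.min_nucleus_area_um2,
        max_area_um2=config.qc.max_nucleus_area_um2,
        min_roundness=config.qc.min_roundness,
        max_mean_intensity=config.qc.max_mean_intensity,
        max_nuclei_per_cell=config.qc.max_nuclei_per_cell,
    )
    qc_filters.flag_by_er_expression(
        records,
        seg.cytoplasm,
        projected.channels["er"],
        min_mean_er_intensity=config.qc.expression_threshold,
        percentile=config.qc.expression_percentile,
    )
    passed, report = qc_filters.apply_filters(records)
    passed_labels = {r.cell_label for r in passed}

    mc = config.metrics
    cell_rows, object_rows = [], []
    for rec in records:
        row = {
            "well": well,
            "field": field,
            "cell": rec.cell_label,
            "n_nuclei": len(rec.nucleus_labels),
            "nucleus_area_um2": rec.nuclear_features[0].area_um2 if rec.nuclear_features else np.nan,
            "nucleus_roundness": rec.nuclear_features[0].roundness if rec.nuclear_features else np.nan,
            "cytoplasm_mean_er": rec.cytoplasm_mean_er,
            "qc_flags": ";".join(sorted(rec.qc_flags)),
            "passed": rec.passed,
            "n_polygons": np.nan,
            "mean_polygon_area_um2": np.nan,
            "dense_er_percent": np.nan,
        }
        if rec.cell_label in passed_labels:
            nucleus_mask = np.isin(seg.nuclei.labels, rec.nucleus_labels)
            metrics, regions = er_metrics.measure_cell(
                projected.channels["er"],
                seg.cells.labels == rec.cell_label,
                nucleus_mask,
                px,
                cell_label=rec.cell_label,
                shrink_fraction=mc.shrink_fraction,
                tubule_method=mc.tubule_method,
                tubule_otsu_multiplier=mc.tubule_otsu_multiplier,
                tubule_value=mc.tubule_value,
                min_polygon_area_um2=mc.min_polygon_area_um2,
                dense_method=mc.dense_method,
                dense_k=mc.dense_k,
                dense_value=mc.dense_value,
                dense_denominator=mc.dense_denominator,
            )
            row["n_polygons"] = metrics.n_polygons
            row["mean_polygon_area_um2"] = metrics.mean_polygon_area_um2
            row["dense_er_percent"] = metrics.dense_er_percent
            for pi, region in enumerate(regions, start=1):
                object_rows.append(
                    {
                        "well": well,
                        "field": field,
                        "cell": rec.cell_label,
                        "polygon": pi,
                        "area_um2": region.area_um2,
                    }
                )
        cell_rows.append(row)
    return cell_rows, object_rows, report


# --------------------------------------------------------------------------
# aggregation
# --------------------------------------------------------------------------

def _sem(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    return float(np.std(x, ddof=1) / np.sqrt(len(x))) if len(x) >= 2 else float("nan")


def summarize_wells(per_cell: pd.DataFrame) -> pd.DataFrame:
    """Per-well mean ± SEM of both metrics over passed cells.

    Cells with no retained polygon (NaN mean area) are excluded from
    the polygon-area mean — a missing mean is not a zero area.
    """
    rows = []
    for well, grp in per_cell.groupby("well", sort=True):
        ok = grp[grp["passed"]]
        poly = ok["mean_polygon_area_um2"].to_numpy(float)
        dense = ok["dense_er_percent"].to_numpy(float)
        row = {
            "well": well,
            "n_cells_analysed": int(len(ok)),
            "mean_polygon_area_um2": float(np.nanmean(poly)) if np.isfinite(poly).any() else np.nan,
            "sem_polygon_area_um2": _sem(poly),
            "mean_dense_er_percent": float(np.nanmean(dense)) if np.isfinite(dense).any() else np.nan,
            "sem_dense_er_percent": _sem(dense),
        }
        for flag in qc_filters.QC_FLAGS:
            row[f"n_{flag}"] = int(
                grp["qc_flags"].str.contains(flag, regex=False).fillna(False).sum()
            )
        rows.append(row)
    return pd.DataFrame(rows)


def warn_low_cell_count(per_well: pd.DataFrame, min_cells: int = 50) -> pd.DataFrame:
    """Flag wells analysing fewer than ``min_cells`` cells; population
    variability is only averaged out above that size."""
    out = per_well.copy()
    out["low_cell_count"] = out["n_cells_analysed"] < min_cells
    return out


# --------------------------------------------------------------------------
# the full run
# --------------------------------------------------------------------------

@dataclass
class PipelineResult:
    per_object: pd.DataFrame
    per_cell: pd.DataFrame
    per_well: pd.DataFrame
    qc_report: dict


def run_pipeline(
    config: PipelineConfig,
    input_root: str | Path,
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole analysis over a plate directory.

    Unreadable fields are skipped with a logged error and recorded in
    the QC report; the run fails only when no field is found at all.
    """
    entries = discover_fields(input_root, config)
    if not entries:
        raise FileNotFoundError(f"no fields matching {config.field_pattern!r} under {input_root}")

    container = all(isinstance(v, int) for v in config.channels.values())
    all_cells, all_objects = [], []
    qc_report: dict = {"fields": {}, "skipped": [], "totals": {}}
    for entry in entries:
        t0 = time.perf_counter()
        try:
            if container:
                fimg = imaging_io.read_field(
                    entry.paths, channel_map=config.channels, pixel_size_um=config.pixel_size_um
                )
            else:
                fimg = imaging_io.read_field(entry.paths, pixel_size_um=config.pixel_size_um)
            projected = imaging_io.max_project(fimg)
            cell_rows, object_rows, report = analyze_projected_field(
                projected, config, well=entry.well, field=entry.field
            )
        except (OSError, ValueError) as exc:
            logger.error("skipping field %s/%s: %s", entry.well, entry.field, exc)
            qc_report["skipped"].append({"well": entry.well, "field": entry.field, "error": str(exc)})
            continue
        all_cells.extend(cell_rows)
        all_objects.extend(object_rows)
        qc_report["fields"][f"{entry.well}/{entry.field}"] = report
        logger.info(
            "field %s/%s: %d cells, %d passed (%.2fs)",
            entry.well, entry.field, report.get("n_total", 0), report.get("n_passed", 0),
            time.perf_counter() - t0,
        )

    per_cell = pd.DataFrame(
        all_cells,
        columns=[
            "well", "field", "cell", "n_nuclei", "nucleus_area_um2", "nucleus_roundness",
            "cytoplasm_mean_er", "qc_flags", "passed", "n_polygons",
            "mean_polygon_area_um2", "dense_er_percent",
        ],
    )
    per_object = pd.DataFrame(
        all_objects, columns=["well", "field", "cell", "polygon", "area_um2"]
    )
    per_well = warn_low_cell_count(
        summarize_wells(per_cell) if len(per_cell) else pd.DataFrame(
            columns=["well", "n_cells_analysed"]
        ),
        config.min_cells_per_well,
    )
    totals: dict[str, int] = {}
    for rep in qc_report["fields"].values():
        for k, v in rep.items():
            totals[k] = totals.get(k, 0) + v
    qc_report["totals"] = totals

    result = PipelineResult(
        per_object=per_object, per_cell=per_cell, per_well=per_well, qc_report=qc_report
    )
    if out_dir is not None:
        write_outputs(result, config, out_dir)
    return result


def write_outputs(result: PipelineResult, config: PipelineConfig, out_dir: str | Path) -> None:
    """Write the three tables, the QC report, and an echo of every
    threshold used (provenance)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, df in (
        ("per_object", result.per_object),
        ("per_cell", result.per_cell),
        ("per_well", result.per_well),
    ):
        df.to_csv(out / f"{name}.csv", index=False, float_format=FLOAT_FORMAT)
    with open(out / "qc_report.json", "w") as fh:
        json.dump(result.qc_report, fh, indent=2, sort_keys=True)
    config.save(out / "config_used.yaml")


# --------------------------------------------------------------------------
# inspection exports
# --------------------------------------------------------------------------

def export_label_map(path: str | Path, labels: np.ndarray) -> None:
    """Save a label map as 16-bit TIFF for inspection."""
    import tifffile

    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))


def export_overlay(
    path: str | Path,
    image: np.ndarray,
    nuclei_labels: np.ndarray,
    cell_labels: np.ndarray,
) -> None:
    """Save a QC overlay PNG: grayscale channel with nucleus (cyan) and
    cell (yellow) outlines."""
    import imageio.v3 as iio
    from skimage.segmentation import find_boundaries

    img = np.asarray(image, float)
    lo, hi = np.percentile(img, (1, 99.5))
    norm = np.clip((img - lo) / max(hi - lo, 1e-12), 0, 1)
    rgb = np.stack([norm] * 3, axis=-1)
    rgb[find_boundaries(cell_labels, mode="outer")] = (1.0, 1.0, 0.0)
    rgb[find_boundaries(nuclei_labels, mode="outer")] = (0.0, 1.0, 1.0)
    iio.imwrite(path, (rgb * 255).astype(np.uint8))
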