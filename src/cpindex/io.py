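"""Reading and writing annotations, cell tables and metric results.

Annotations travel as GeoJSON FeatureCollections in the dialect QuPath
exports: each feature carries its class label under
``properties.classification.name`` (older exports use a plain string or
``properties.name``; all are accepted). Cell tables are delimited text
with a header row, in the style of QuPath detection-measurement exports
("Centroid X µm", "Centroid Y µm", "Classification").

All coordinates are converted to microns on load via a
:class:`Calibration`, so downstream modules never see pixel units.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely.affinity
from shapely.geometry import mapping as geom_mapping
from shapely.geometry import shape as geom_shape
from shapely.validation import make_valid

from .geometry import Region, to_polygonal

__all__ = [
    "Annotation",
    "AnnotationError",
    "Calibration",
    "CellRecord",
    "CellTable",
    "CellTableError",
    "read_annotations",
    "read_cells",
    "results_frame",
    "write_annotations",
    "write_cells",
    "write_results",
]


class AnnotationError(ValueError):
    """Malformed or rejected annotation input."""


class CellTableError(ValueError):
    """Malformed cell-table input (e.g. a required column is absent)."""


@dataclass(frozen=True)
class Calibration:
    """Pixel-size calibration applied on load.

    ``microns_per_pixel`` is ignored (scale factor exactly 1) when the
    input coordinates are already in microns.
    """

    microns_per_pixel: float = 1.0
    unit_of_input: str = "micron"  # "pixel" or "micron"

    def __post_init__(self) -> None:
        if self.microns_per_pixel <= 0:
            raise ValueError(f"microns_per_pixel must be > 0, got {self.microns_per_pixel}")
        if self.unit_of_input not in ("pixel", "micron"):
            raise ValueError(f"unit_of_input must be 'pixel' or 'micron', got {self.unit_of_input!r}")

    @property
    def factor(self) -> float:
        """Multiplicative factor taking input coordinates to µm."""
        return self.microns_per_pixel if self.unit_of_input == "pixel" else 1.0


#: Identity calibration: input already in microns.
MICRONS = Calibration()


@dataclass(frozen=True)
class Annotation:
    """A classified polygonal annotation (e.g. class "Lesion" or "Tissue")."""

    class_label: str
    geometry: Region
    name: str | None = None


@dataclass(frozen=True)
class CellRecord:
    """A single cell centroid with its (possibly composite) classification."""

    x: float
    y: float
    classification: str = ""
    id: str | None = None


@dataclass
class CellTable:
    """Column-oriented table of cell centroids in micron coordinates."""

    x: np.ndarray
    y: np.ndarray
    classification: np.ndarray
    id: np.ndarray | None = None
    source: str = ""
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.classification = np.asarray(self.classification, dtype=object)
        if not (len(self.x) == len(self.y) == len(self.classification)):
            raise CellTableError("x, y and classification must have equal length")
        if self.id is not None:
            self.id = np.asarray(self.id, dtype=object)
            if len(self.id) != len(self.x):
                raise CellTableError("id must match the number of cells")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) coordinate array."""
        return np.column_stack([self.x, self.y])

    @property
    def records(self) -> Iterator[CellRecord]:
        ids = self.id if self.id is not None else [None] * len(self)
        for x, y, c, i in zip(self.x, self.y, self.classification, ids):
            yield CellRecord(float(x), float(y), str(c), i)

    def subset(self, mask) -> "CellTable":
        mask = np.asarray(mask)
        return CellTable(
            x=self.x[mask],
            y=self.y[mask],
            classification=self.classification[mask],
            id=None if self.id is None else self.id[mask],
            source=self.source,
        )

    def to_frame(self) -> pd.DataFrame:
        data = {
            "Centroid X µm": self.x,
            "Centroid Y µm": self.y,
            "Classification": [str(c) for c in self.classification],
        }
        if self.id is not None:
            data["Object ID"] = [str(i) for i in self.id]
        return pd.DataFrame(data)


# --------------------------------------------------------------------------
# annotations

def _classification_label(props: Mapping) -> str:
    cls = props.get("classification")
    if isinstance(cls, Mapping) and cls.get("name"):
        return str(cls["name"])
    if isinstance(cls, str) and cls:
        return cls
    if props.get("name"):
        return str(props["name"])
    return "unclassified"


def _repair(geom: Region, index: int) -> Region:
    """Repair slightly-invalid polygons; reject if repair moves area > 1%."""
    if geom.is_valid:
        return geom
    fixed = to_polygonal(make_valid(geom))
    if fixed.is_empty or fixed.area <= 0:
        raise AnnotationError(f"feature {index}: geometry is invalid and unrepairable")
    if abs(fixed.area - geom.area) > 0.01 * fixed.area:
        raise AnnotationError(
            f"feature {index}: invalid geometry; repair changes area by "
            f"{abs(fixed.area - geom.area) / fixed.area:.1%} (> 1%), rejected"
        )
    return fixed


def read_annotations(
    path,
    calibration: Calibration = MICRONS,
    *,
    strict_classes: Sequence[str] = ("Lesion", "Tissue"),
) -> list[Annotation]:
    """Read a GeoJSON FeatureCollection of polygonal annotations.

    Class labels are taken from ``properties.classification.name`` (QuPath
    object form), falling back to a plain ``properties.classification``
    string, then ``properties.name``, then ``"unclassified"``. Coordinates
    are scaled to µm via ``calibration``.

    Features of a class in ``strict_classes`` must be polygonal with
    positive area; offending features raise :class:`AnnotationError`
    naming the feature index. Non-polygonal features of other classes are
    skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"annotation file not found: {path}")
    with open(path, encoding="utf-8") as fh:
        data = json.load(fh)
    if data.get("type") == "FeatureCollection":
        features = data.get("features", [])
    elif data.get("type") == "Feature":
        features = [data]
    else:
        raise AnnotationError(f"{path}: expected a GeoJSON FeatureCollection")

    out: list[Annotation] = []
    f = calibration.factor
    for i, feat in enumerate(features):
        props = feat.get("properties") or {}
        label = _classification_label(props)
        gdict = feat.get("geometry") or {}
        gtype = gdict.get("type")
        if gtype not in ("Polygon", "MultiPolygon"):
            if label in strict_classes:
                raise AnnotationError(
                    f"feature {i}: class {label!r} requires polygonal geometry, got {gtype!r}"
                )
            warnings.warn(f"feature {i}: skipping non-polygonal geometry ({gtype!r})")
            continue
        geom = geom_shape(gdict)
        geom = _repair(geom, i)
        if geom.area <= 0:
            raise AnnotationError(f"feature {i}: zero-area polygon rejected")
        if f != 1.0:
            geom = shapely.affinity.scale(geom, xfact=f, yfact=f, origin=(0, 0))
        name = props.get("name")
        out.append(Annotation(class_label=label, geometry=geom, name=name))
    return out


def write_annotations(annotations: Iterable[Annotation], path) -> None:
    """Write annotations as a QuPath-dialect GeoJSON FeatureCollection (µm)."""
    features = []
    for ann in annotations:
        props = {
            "objectType": "annotation",
            "classification": {"name": ann.class_label},
        }
        if ann.name:
            props["name"] = ann.name
        features.append(
            {
                "type": "Feature",
                "geometry": geom_mapping(ann.geometry),
                "properties": props,
            }
        )
    payload = {"type": "FeatureCollection", "features": features}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


# --------------------------------------------------------------------------
# cell tables

_X_CANDIDATES = ("Centroid X µm", "Centroid X px", "Centroid X", "x", "X")
_Y_CANDIDATES = ("Centroid Y µm", "Centroid Y px", "Centroid Y", "y", "Y")
_CLASS_CANDIDATES = ("Classification", "Class", "classification", "class")
_ID_CANDIDATES = ("Object ID", "id", "ID")


def _resolve_column(columns, explicit, candidates, role, required=True):
    if explicit is not None:
        if explicit not in columns:
            raise CellTableError(f"column {explicit!r} (mapped to {role}) not found in header")
        return explicit
    for cand in candidates:
        if cand in columns:
            return cand
    if required:
        raise CellTableError(
            f"no column found for {role}; tried {list(candidates)}; "
            "pass column_map to name it explicitly"
        )
    return None


def _delimiter_for(path, delimiter):
    if delimiter is not None:
        return delimiter
    return "\t" if Path(path).suffix.lower() in (".tsv", ".txt") else ","


def read_cells(
    path,
    calibration: Calibration = MICRONS,
    column_map: Mapping[str, str] | None = None,
    *,
    delimiter: str | None = None,
) -> CellTable:
    """Read a delimited cell-centroid table into a :class:`CellTable`.

    Columns are auto-detected from common QuPath headers unless
    ``column_map`` (keys ``x``, ``y``, ``classification``, optionally
    ``id``) names them explicitly. Rows with non-numeric coordinates are
    dropped and counted in ``n_dropped``; coordinates are scaled to µm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cell table not found: {path}")
    column_map = dict(column_map or {})
    df = pd.read_csv(path, sep=_delimiter_for(path, delimiter), dtype=str, skipinitialspace=True)
    cols = list(df.columns)
    xcol = _resolve_column(cols, column_map.get("x"), _X_CANDIDATES, "x")
    ycol = _resolve_column(cols, column_map.get("y"), _Y_CANDIDATES, "y")
    ccol = _resolve_column(
        cols, column_map.get("classification"), _CLASS_CANDIDATES, "classification", required=False
    )
    icol = _resolve_column(cols, column_map.get("id"), _ID_CANDIDATES, "id", required=False)

    x = pd.to_numeric(df[xcol], errors="coerce")
    y = pd.to_numeric(df[ycol], errors="coerce")
    ok = x.notna() & y.notna()
    n_dropped = int((~ok).sum())
    f = calibration.factor
    cls = (
        df.loc[ok, ccol].fillna("").astype(str).to_numpy(dtype=object)
        if ccol is not None
        else np.full(int(ok.sum()), "", dtype=object)
    )
    return CellTable(
        x=x[ok].to_numpy(dtype=float) * f,
        y=y[ok].to_numpy(dtype=float) * f,
        classification=cls,
        id=df.loc[ok, icol].astype(str).to_numpy(dtype=object) if icol is not None else None,
        source=str(path),
        n_dropped=n_dropped,
    )


def write_cells(table: CellTable, path, *, delimiter: str | None = None) -> None:
    """Write a cell table with QuPath-style headers (µm coordinates)."""
    table.to_frame().to_csv(path, sep=_delimiter_for(path, delimiter), index=False)


# --------------------------------------------------------------------------
# results

_TCPI_FIELDS = (
    "n_cells",
    "median_border_depth",
    "central_area",
    "peripheral_area",
    "total_area",
)


def _is_tcpi(r) -> bool:
    return hasattr(r, "tcpi")


def _is_immcpi(r) -> bool:
    return hasattr(r, "immcpi")


def _is_band(r) -> bool:
    return hasattr(r, "band_edges")


def results_frame(results: Sequence) -> pd.DataFrame:
    """Tabulate metric results.

    tCPI / immCPI results pivot to one wide row per lesion with columns
    ``tCPI`` and ``ImmCPI(<marker>)`` (mirroring the measurement keys a
    QuPath analysis would attach to the annotation). Band profiles
    tabulate to a long per-band format and cannot be mixed with index
    results in one call.
    """
    results = list(results)
    if not results:
        raise ValueError("no results to write")
    bands = [r for r in results if _is_band(r)]
    if bands and len(bands) != len(results):
        raise ValueError("cannot mix band profiles with index results in one table")
    if bands:
        rows = []
        for b in bands:
            edges = np.asarray(b.band_edges, dtype=float)
            for k in range(len(b.counts)):
                rows.append(
                    {
                        "lesion": b.lesion_name,
                        "band": k,
                        "edge_start_um": edges[k],
                        "edge_end_um": edges[k + 1],
                        "count": int(b.counts[k]),
                        "area_um2": float(b.band_areas[k]),
                        "density_per_um2": float(b.densities[k]),
                        "remainder_count": int(b.remainder_count),
                    }
                )
        return pd.DataFrame(rows)

    by_lesion: dict[str, dict] = {}
    for r in results:
        row = by_lesion.setdefault(r.lesion_name, {"lesion": r.lesion_name})
        if _is_tcpi(r):
            for f in _TCPI_FIELDS:
                row[f] = getattr(r, f)
            row["tCPI"] = r.tcpi
        elif _is_immcpi(r):
            row[f"ImmCPI({r.marker})"] = r.immcpi
            row[f"N({r.marker})"] = r.n_marker_cells
        else:
            raise TypeError(f"unsupported result type: {type(r).__name__}")
    return pd.DataFrame(list(by_lesion.values()))


def _result_dict(r) -> dict:
    if _is_tcpi(r):
        return {
            "type": "tCPI",
            "lesion": r.lesion_name,
            "n_cells": int(r.n_cells),
            "median_border_depth": float(r.median_border_depth),
            "central_area": float(r.central_area),
            "peripheral_area": float(r.peripheral_area),
            "total_area": float(r.total_area),
            "tCPI": float(r.tcpi),
        }
    if _is_immcpi(r):
        val = r.immcpi
        return {
            "type": "ImmCPI",
            "lesion": r.lesion_name,
            "marker": r.marker,
            "n_marker_cells": int(r.n_marker_cells),
            "mean_depth_marker": None if r.mean_depth_marker is None else float(r.mean_depth_marker),
            "mean_depth_all": float(r.mean_depth_all),
            f"ImmCPI({r.marker})": None if val is None or np.isnan(val) else float(val),
        }
    if _is_band(r):
        return {
            "type": "BandProfile",
            "lesion": r.lesion_name,
            "band_edges": [float(e) for e in r.band_edges],
            "counts": [int(c) for c in r.counts],
            "band_areas": [float(a) for a in r.band_areas],
            "densities": [float(d) for d in r.densities],
            "remainder_count": int(r.remainder_count),
        }
    raise TypeError(f"unsupported result type: {type(r).__name__}")


def write_results(results: Sequence, path, format: str = "csv") -> None:
    """Serialize metric results to CSV (wide/long table) or JSON.

    Numeric fields keep full precision (shortest round-trip rendering),
    so a JSON write parses back to identical values.
    """
    results = list(results)
    if not results:
        raise ValueError("refusing to write an empty results file")
    if format == "csv":
        results_frame(results).to_csv(path, index=False)
    elif format == "json":
        with open(path, "w", encoding="utf-8") as fh:
            json.dump([_result_dict(r) for r in results], fh, indent=1)
            fh.write("\n")
    else:
        raise ValueError(f"unknown format {format!r}; use 'csv' or 'json'")
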