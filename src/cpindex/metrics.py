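"""Whole-lesion cell-localization metrics: tCPI, immCPI and band profiles.

The Total Cell Preference Index (tCPI) asks whether a lesion's cells
crowd toward its border or its core, independent of lesion size and
shape. It is computed from the distance of every in-lesion cell to the
lesion border: take the median of those border depths, erode the lesion
inward by that median to obtain the *central* region (where the deeper
50% of cells live), and report

    tCPI = peripheral area / total lesion area,

where peripheral = lesion minus central. A spatially uniform lesion
gives 0.5 (the outer half of cells occupy half the area); values below
0.5 indicate central rarefaction (below ~0.4, frank necrosis); values
toward 1 indicate a center-packed lesion.

The Immune Cell Preference Index (immCPI) localizes one phenotype
relative to all cells:

    immCPI = mean border depth of marker cells / mean border depth of all cells.

1 means the phenotype is distributed like the bulk; > 1 central
preference; < 1 peripheral preference. Because it is normalized to all
cells, it is comparable across lesions with and without necrotic cores.

``infiltration_bands`` implements the classical fixed-width concentric
band analysis (density per band from the lesion border) that the single
number indexes improve upon; it is retained as a baseline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import shapely

from .geometry import (
    LesionGeometry,
    Region,
    area,
    clip,
    inward_offset,
    signed_border_distance,
)
from .io import CellTable

__all__ = [
    "BandProfile",
    "BorderDepths",
    "ImmcpiResult",
    "MetricError",
    "NoCellsError",
    "TcpiResult",
    "border_depths",
    "compute_immcpi",
    "compute_tcpi",
    "infiltration_bands",
    "median_depth",
]


class MetricError(ValueError):
    """A metric is undefined for the given inputs."""


class NoCellsError(MetricError):
    """No cells fall inside the (clipped) lesion, so depth statistics are undefined."""


@dataclass(frozen=True)
class BorderDepths:
    """Border depths of the in-lesion cells of one lesion.

    ``depths[i]`` is the distance (µm, >= 0) from the i-th *in-lesion*
    cell to the lesion border; ``inside`` is the boolean mask over the
    original cell table selecting those cells (boundary cells included);
    ``n_excluded`` counts cells outside the clipped lesion.
    """

    depths: np.ndarray
    inside: np.ndarray
    n_excluded: int


@dataclass(frozen=True)
class TcpiResult:
    """tCPI of one lesion, with the intermediate quantities that define it."""

    lesion_name: str
    n_cells: int
    median_border_depth: float  # µm
    central_area: float  # µm²
    peripheral_area: float  # µm²
    total_area: float  # µm²
    tcpi: float
    n_excluded: int = 0
    central_region: Region | None = field(default=None, repr=False, compare=False)
    peripheral_region: Region | None = field(default=None, repr=False, compare=False)


@dataclass(frozen=True)
class ImmcpiResult:
    """immCPI of one marker in one lesion.

    ``immcpi`` is NaN when the lesion contains no marker cells: the ratio
    is then undefined, and reporting 0 would falsely signal extreme
    peripheral localization.
    """

    lesion_name: str
    marker: str
    n_marker_cells: int
    mean_depth_marker: float | None  # µm, None when no marker cells
    mean_depth_all: float  # µm
    immcpi: float  # NaN when undefined


@dataclass(frozen=True)
class BandProfile:
    """Cell density in fixed-width bands from the lesion border.

    ``band_edges`` are signed offsets from the border (negative inward),
    length ``len(counts) + 1``, ascending. ``remainder_count`` is the
    number of cells beyond the last band (deeper inward, or farther
    outward, than the banded range covers).
    """

    lesion_name: str
    direction: str
    band_edges: np.ndarray
    counts: np.ndarray
    band_areas: np.ndarray
    densities: np.ndarray
    remainder_count: int
    n_cells: int


def border_depths(cells: CellTable, lesion: LesionGeometry) -> BorderDepths:
    """Distance of every in-lesion cell to the lesion border.

    Cells strictly inside or exactly on the boundary of the clipped
    lesion are kept; the rest are excluded and counted. Raises
    :class:`NoCellsError` when no cell lies in the lesion.
    """
    if lesion.clipped_lesion.is_empty:
        raise MetricError("clipped lesion is empty")
    if len(cells) == 0:
        raise NoCellsError(f"lesion {lesion.name!r}: cell table is empty")
    signed = signed_border_distance(cells.xy, lesion.clipped_lesion)
    inside = signed <= 0  # boundary cells (signed == 0) are in-lesion
    depths = np.abs(signed[inside])
    if depths.size == 0:
        raise NoCellsError(f"lesion {lesion.name!r}: no cells inside the lesion")
    return BorderDepths(depths=depths, inside=inside, n_excluded=int((~inside).sum()))


def median_depth(depths) -> float:
    """Median of a non-empty collection of border depths (µm).

    Odd n: the middle sorted value; even n: the mean of the two middle
    values.
    """
    depths = np.asarray(depths, dtype=float)
    if depths.size == 0:
        raise MetricError("median of an empty depth collection is undefined")
    return float(np.median(depths))


def compute_tcpi(cells: CellTable, lesion: LesionGeometry) -> TcpiResult:
    """Total Cell Preference Index of one lesion.

    Erodes the clipped lesion inward by the median cell border depth;
    the eroded part (re-clipped to tissue) is the central region, its
    complement within the lesion the peripheral region, and
    tcpi = peripheral area / total area. A fully eroded (empty) central
    region yields tcpi = 1, flagging an extreme center-packed or
    degenerate lesion.
    """
    bd = border_depths(cells, lesion)
    if bd.depths.size < 2:
        raise MetricError(
            f"lesion {lesion.name!r}: tCPI needs >= 2 in-lesion cells, got {bd.depths.size}"
        )
    med = median_depth(bd.depths)
    central = clip(inward_offset(lesion.clipped_lesion, med), lesion.tissue)
    peripheral = clip(lesion.clipped_lesion.difference(central), lesion.tissue)
    total_area = area(lesion.clipped_lesion)
    if total_area <= 0:
        raise MetricError(f"lesion {lesion.name!r}: zero clipped lesion area")
    central_area = area(central)
    peripheral_area = area(peripheral)
    tcpi = peripheral_area / total_area
    if central.is_empty:
        warnings.warn(
            f"lesion {lesion.name!r}: median depth {med:.1f} µm fully erodes the "
            "lesion (tCPI = 1); extreme center-packed or degenerate geometry"
        )
    return TcpiResult(
        lesion_name=lesion.name,
        n_cells=int(bd.depths.size),
        median_border_depth=med,
        central_area=central_area,
        peripheral_area=peripheral_area,
        total_area=total_area,
        tcpi=tcpi,
        n_excluded=bd.n_excluded,
        central_region=central,
        peripheral_region=peripheral,
    )


def _marker_mask(classifications: np.ndarray, marker: str, match_mode: str) -> np.ndarray:
    if match_mode == "substring":
        return np.fromiter((marker in str(c) for c in classifications), dtype=bool, count=len(classifications))
    if match_mode == "exact":
        def tokens(c):
            return {t.strip() for t in str(c).split(":")}
        return np.fromiter((marker in tokens(c) for c in classifications), dtype=bool, count=len(classifications))
    raise ValueError(f"match_mode must be 'substring' or 'exact', got {match_mode!r}")


def compute_immcpi(
    cells: CellTable,
    lesion: LesionGeometry,
    marker: str,
    match_mode: str = "substring",
) -> ImmcpiResult:
    """Immune Cell Preference Index of one marker in one lesion.

    Marker cells are the in-lesion cells whose classification string
    matches ``marker`` — by substring containment by default, which
    handles composite classes like ``"Opal 690: Opal 570"``; ``exact``
    matches whole ':'-separated tokens instead.
    """
    bd = border_depths(cells, lesion)
    mean_all = float(np.mean(bd.depths))
    if mean_all == 0:
        raise MetricError(
            f"lesion {lesion.name!r}: all cells lie exactly on the border; immCPI undefined"
        )
    inside_cls = cells.classification[bd.inside]
    mmask = _marker_mask(inside_cls, marker, match_mode)
    n_marker = int(mmask.sum())
    if n_marker == 0:
        warnings.warn(f"lesion {lesion.name!r}: no cells match marker {marker!r}; immCPI undefined")
        return ImmcpiResult(
            lesion_name=lesion.name,
            marker=marker,
            n_marker_cells=0,
            mean_depth_marker=None,
            mean_depth_all=mean_all,
            immcpi=float("nan"),
        )
    mean_marker = float(np.mean(bd.depths[mmask]))
    return ImmcpiResult(
        lesion_name=lesion.name,
        marker=marker,
        n_marker_cells=n_marker,
        mean_depth_marker=mean_marker,
        mean_depth_all=mean_all,
        immcpi=mean_marker / mean_all,
    )


def _inward_band_areas(lesion: LesionGeometry, width: float, n_bands: int) -> np.ndarray:
    areas = np.empty(n_bands)
    prev = area(lesion.clipped_lesion)
    for k in range(n_bands):
        inner = area(clip(inward_offset(lesion.clipped_lesion, (k + 1) * width), lesion.tissue))
        areas[k] = prev - inner
        prev = inner
    return areas


def _outward_band_areas(lesion: LesionGeometry, width: float, n_bands: int) -> np.ndarray:
    areas = np.empty(n_bands)
    prev = area(lesion.clipped_lesion)
    for k in range(n_bands):
        outer = area(clip(lesion.clipped_lesion.buffer((k + 1) * width), lesion.tissue))
        areas[k] = outer - prev
        prev = outer
    return areas


def infiltration_bands(
    cells: CellTable,
    lesion: LesionGeometry,
    band_width: float,
    n_bands: int,
    direction: str = "inward",
) -> BandProfile:
    """Classical band-based infiltration analysis.

    Splits the neighbourhood of the lesion border into ``n_bands``
    concentric bands of ``band_width`` µm (inward into the lesion,
    outward into the surrounding tissue, or both) and reports per-band
    cell counts, areas and densities. Bands are half-open on the signed
    border distance, so a cell exactly on the border falls in the first
    inward band. Cells beyond the banded range are returned as
    ``remainder_count``, never silently absorbed.
    """
    if band_width <= 0:
        raise ValueError(f"band_width must be > 0, got {band_width}")
    if n_bands < 1:
        raise ValueError(f"n_bands must be >= 1, got {n_bands}")
    if direction not in ("inward", "outward", "both"):
        raise ValueError(f"direction must be 'inward', 'outward' or 'both', got {direction!r}")

    signed = signed_border_distance(cells.xy, lesion.clipped_lesion)
    in_tissue = shapely.contains_xy(lesion.tissue, cells.x, cells.y) | (signed <= 0)
    w = float(band_width)

    counts_in = counts_out = None
    rem = 0
    n_considered = 0
    if direction in ("inward", "both"):
        depths = np.abs(signed[signed <= 0])
        idx = np.floor(depths / w).astype(int)
        counts_in = np.bincount(idx[idx < n_bands], minlength=n_bands)[:n_bands]
        rem += int((idx >= n_bands).sum())
        n_considered += depths.size
    if direction in ("outward", "both"):
        s_out = signed[(signed > 0) & in_tissue]
        idx = np.floor(s_out / w).astype(int)
        counts_out = np.bincount(idx[idx < n_bands], minlength=n_bands)[:n_bands]
        rem += int((idx >= n_bands).sum())
        n_considered += s_out.size

    if direction == "inward":
        # ascending signed edges: deepest first
        edges = -w * np.arange(n_bands, -1, -1.0)
        counts = counts_in[::-1]
        areas = _inward_band_areas(lesion, w, n_bands)[::-1]
    elif direction == "outward":
        edges = w * np.arange(n_bands + 1.0)
        counts = counts_out
        areas = _outward_band_areas(lesion, w, n_bands)
    else:
        edges = w * np.arange(-n_bands, n_bands + 1.0)
        counts = np.concatenate([counts_in[::-1], counts_out])
        areas = np.concatenate(
            [_inward_band_areas(lesion, w, n_bands)[::-1], _outward_band_areas(lesion, w, n_bands)]
        )

    if np.any((areas <= 0) & (counts > 0)):
        raise MetricError("internal inconsistency: cells counted in a zero-area band")
    with np.errstate(divide="ignore", invalid="ignore"):
        densities = np.where(areas > 0, counts / areas, np.nan)
    return BandProfile(
        lesion_name=lesion.name,
        direction=direction,
        band_edges=edges,
        counts=counts.astype(int),
        band_areas=areas,
        densities=densities,
        remainder_count=rem,
        n_cells=int(n_considered),
    )
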