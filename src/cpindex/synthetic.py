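"""Synthetic lesions and cell point patterns with known radial structure.

Every metric in this package has a closed-form expectation on a disk (or
star-convex) lesion whose cells follow a simple radial law, so the
generator here is the test bed for the whole pipeline:

* ``uniform`` — cells uniform by area over the lesion; tCPI -> 0.5 and
  every marker assigned independently of position has immCPI -> 1.
* ``necrotic_core`` — no cells at normalized radius u < q, uniform
  beyond; emulates a necrotizing lesion; tCPI -> (1 - q²)/2.
* ``center_enriched`` — cells confined to u < q; emulates a
  center-packed aggregate; tCPI -> 1 - q²/2.

Radial position is parameterized on the *normalized radius*
u = ρ / r(θ), where r(θ) is the lesion's boundary radius in the
direction of the point; on a disk u is simply ρ/R, and the closed forms
above stay exact for irregular star-convex shapes.

Shapes are harmonic perturbations of a circle,
r(θ) = R (1 + Σ a_k cos(kθ + φ_k)), sampled as an ``n_vertices``-gon.
Sampling is batched rejection over the bounding box — exact, simple and
fast at the 10⁴–10⁵ cells-per-lesion scale this package targets.

All randomness flows from one integer seed, fanned out to fixed
sub-streams (shape phases, cell positions, marker assignment) so that
regenerating one component never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import shapely
import shapely.affinity
from shapely.geometry import Polygon, box
from shapely.ops import unary_union

from .io import Annotation, CellTable, write_annotations, write_cells

__all__ = [
    "LesionShapeSpec",
    "MarkerSpec",
    "RadialProfile",
    "SCENARIOS",
    "assign_markers",
    "make_fixture",
    "make_lesion",
    "polygon_radial_function",
    "sample_cells",
]

# sub-stream ids for seed fan-out
_STREAM_SHAPE = 0
_STREAM_CELLS = 1
_STREAM_MARKERS = 2


def _substream(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(stream), int(seed)]))


@dataclass(frozen=True)
class LesionShapeSpec:
    """Parametric star-convex lesion outline.

    ``kind`` selects the base curve: a circle of ``radius`` µm, an
    ellipse with semi-axes (radius, radius·axis_ratio), or a ``star`` —
    a circle modulated by harmonics ``amplitudes[i]·cos(harmonics[i]·θ +
    phases[i])``. Phases left unset are drawn once from the shape
    sub-stream of ``seed``. Σ|amplitudes| must stay below 1 so the
    radius is positive everywhere (star-convexity).
    """

    kind: str = "disk"  # disk | ellipse | star
    radius: float = 500.0
    axis_ratio: float = 1.0
    amplitudes: tuple = ()
    harmonics: tuple = ()
    phases: tuple | None = None
    n_vertices: int = 64
    center: tuple = (0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "ellipse", "star"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.radius <= 0:
            raise ValueError("radius must be > 0")
        if self.n_vertices < 16:
            raise ValueError(f"n_vertices must be >= 16, got {self.n_vertices}")
        if self.kind == "star":
            if sum(abs(a) for a in self.amplitudes) >= 1:
                raise ValueError("sum of |amplitudes| must be < 1 (radius must stay positive)")

    def _resolved(self):
        amps = np.asarray(self.amplitudes, dtype=float)
        ks = (
            np.asarray(self.harmonics, dtype=float)
            if self.harmonics
            else np.arange(2.0, 2.0 + len(amps))
        )
        if len(ks) != len(amps):
            raise ValueError("harmonics and amplitudes must have equal length")
        if self.phases is not None:
            phis = np.asarray(self.phases, dtype=float)
            if len(phis) != len(amps):
                raise ValueError("phases and amplitudes must have equal length")
        else:
            phis = _substream(self.seed, _STREAM_SHAPE).uniform(0, 2 * np.pi, len(amps))
        return amps, ks, phis

    def radial_function(self):
        """Vectorized boundary radius r(θ) in µm."""
        R = self.radius
        if self.kind == "disk":
            return lambda theta: np.full_like(np.asarray(theta, dtype=float), R)
        if self.kind == "ellipse":
            a, b = R, R * self.axis_ratio
            return lambda theta: a * b / np.sqrt(
                (b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2
            )
        amps, ks, phis = self._resolved()

        def r(theta):
            theta = np.asarray(theta, dtype=float)
            mod = np.ones_like(theta)
            for a_k, k, phi in zip(amps, ks, phis):
                mod = mod + a_k * np.cos(k * theta + phi)
            return R * mod

        return r


@dataclass(frozen=True)
class RadialProfile:
    """Radial cell-density law on the normalized radius u = ρ/r(θ).

    ``uniform``: constant density over the lesion. ``necrotic_core``:
    density 0 for u < core_fraction, constant beyond (acellular core).
    ``center_enriched``: constant for u < core_fraction, 0 beyond.
    """

    kind: str = "uniform"  # uniform | necrotic_core | center_enriched
    core_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "necrotic_core", "center_enriched"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if not (0 <= self.core_fraction < 1) and self.kind == "necrotic_core":
            raise ValueError("necrotic_core requires 0 <= core_fraction < 1")
        if self.kind == "center_enriched" and self.core_fraction <= 0:
            raise ValueError("center_enriched requires core_fraction > 0 (admissible region empty)")


@dataclass(frozen=True)
class MarkerSpec:
    """Rule assigning one marker label to cells.

    ``uniform_p``: each cell independently with probability ``p``
    (position-independent, so immCPI -> 1). ``central_disk``: cells with
    normalized radius u <= fraction. ``peripheral_band``: cells with
    u >= 1 - fraction.
    """

    name: str
    assignment: str = "uniform_p"  # uniform_p | central_disk | peripheral_band
    p: float = 0.5
    fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.assignment not in ("uniform_p", "central_disk", "peripheral_band"):
            raise ValueError(f"unknown assignment {self.assignment!r}")
        if not 0 <= self.p <= 1:
            raise ValueError("p must be in [0, 1]")
        if not 0 <= self.fraction <= 1:
            raise ValueError("fraction must be in [0, 1]")


def make_lesion(spec: LesionShapeSpec) -> tuple[Annotation, Annotation]:
    """Realize a shape spec as a "Lesion" annotation plus an enclosing "Tissue".

    The lesion polygon samples r(θ) at ``n_vertices`` equally spaced
    angles; the tissue is the lesion's bounding box expanded by 20%.
    Deterministic for a fixed spec (including its seed).
    """
    theta = 2 * np.pi * np.arange(spec.n_vertices) / spec.n_vertices
    r = spec.radial_function()(theta)
    cx, cy = spec.center
    poly = Polygon(np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)]))
    if not poly.is_valid or poly.area <= 0:
        raise ValueError("shape spec produced an invalid polygon")
    tissue = shapely.affinity.scale(box(*poly.bounds), 1.2, 1.2)
    return (
        Annotation(class_label="Lesion", geometry=poly, name=f"synthetic-{spec.kind}"),
        Annotation(class_label="Tissue", geometry=tissue, name="synthetic-tissue"),
    )


def polygon_radial_function(poly: Polygon, center: tuple | None = None):
    """Boundary radius r(θ) of a star-convex polygon, by angular interpolation.

    Fallback for polygons that did not come from a
    :class:`LesionShapeSpec`; only meaningful when the polygon is
    star-convex about ``center`` (default: its centroid).
    """
    if center is None:
        c = poly.centroid
        center = (c.x, c.y)
    coords = np.asarray(poly.exterior.coords)[:-1]
    dx, dy = coords[:, 0] - center[0], coords[:, 1] - center[1]
    ang = np.arctan2(dy, dx)
    rad = np.hypot(dx, dy)
    order = np.argsort(ang)
    ang, rad = ang[order], rad[order]

    def r(theta):
        return np.interp(np.asarray(theta, dtype=float), ang, rad, period=2 * np.pi)

    return r


def _normalized_radius(x, y, center, radial_fn):
    dx, dy = x - center[0], y - center[1]
    theta = np.arctan2(dy, dx)
    return np.hypot(dx, dy) / radial_fn(theta)


def _resolve_radial(lesion: Annotation, shape: LesionShapeSpec | None):
    if shape is not None:
        return shape.center, shape.radial_function()
    c = lesion.geometry.centroid
    return (c.x, c.y), polygon_radial_function(lesion.geometry)


def sample_cells(
    lesion: Annotation,
    n: int,
    profile: RadialProfile = RadialProfile(),
    seed: int = 0,
    shape: LesionShapeSpec | None = None,
) -> CellTable:
    """Sample ``n`` cell centroids inside a lesion under a radial profile.

    Batched rejection sampling over the lesion's bounding box: a
    candidate is accepted when it falls inside the lesion polygon and
    its normalized radius satisfies the profile. With ``shape`` given,
    u uses the analytic r(θ) (exact closed forms); otherwise the
    polygon's interpolated radius is used (star-convex shapes only —
    not needed for the ``uniform`` profile, which works on any polygon).
    Deterministic for a fixed seed.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    poly = lesion.geometry
    rng = _substream(seed, _STREAM_CELLS)
    needs_u = profile.kind != "uniform"
    if needs_u:
        center, radial = _resolve_radial(lesion, shape)
    shapely.prepare(poly)
    minx, miny, maxx, maxy = poly.bounds
    xs, ys = [], []
    got = 0
    while got < n:
        m = max(4096, 2 * (n - got))
        cx = rng.uniform(minx, maxx, m)
        cy = rng.uniform(miny, maxy, m)
        ok = shapely.contains_xy(poly, cx, cy)
        if needs_u:
            u = _normalized_radius(cx, cy, center, radial)
            if profile.kind == "necrotic_core":
                ok &= u >= profile.core_fraction
            else:  # center_enriched
                ok &= u <= profile.core_fraction
        cx, cy = cx[ok], cy[ok]
        take = min(n - got, len(cx))
        xs.append(cx[:take])
        ys.append(cy[:take])
        got += take
    x = np.concatenate(xs)
    y = np.concatenate(ys)
    return CellTable(
        x=x,
        y=y,
        classification=np.full(n, "", dtype=object),
        id=np.array([f"cell_{i}" for i in range(n)], dtype=object),
        source=f"synthetic:{profile.kind}",
    )


def assign_markers(
    cells: CellTable,
    lesion: Annotation,
    specs,
    seed: int = 0,
    shape: LesionShapeSpec | None = None,
) -> CellTable:
    """Attach marker labels to cells according to a list of MarkerSpecs.

    A cell matched by several specs gets a composite classification with
    the names joined by ": " (QuPath composite-class style). Unmatched
    cells keep an empty classification.
    """
    specs = list(specs)
    rng = _substream(seed, _STREAM_MARKERS)
    n = len(cells)
    u = None
    labels: list[list[str]] = [[] for _ in range(n)]
    for spec in specs:
        if spec.assignment == "uniform_p":
            mask = rng.random(n) < spec.p
        else:
            if u is None:
                center, radial = _resolve_radial(lesion, shape)
                u = _normalized_radius(cells.x, cells.y, center, radial)
            if spec.assignment == "central_disk":
                mask = u <= spec.fraction
            else:  # peripheral_band
                mask = u >= 1 - spec.fraction
        for i in np.nonzero(mask)[0]:
            labels[i].append(spec.name)
    classification = np.array([": ".join(lab) for lab in labels], dtype=object)
    return CellTable(
        x=cells.x.copy(),
        y=cells.y.copy(),
        classification=classification,
        id=None if cells.id is None else cells.id.copy(),
        source=cells.source,
    )


# --------------------------------------------------------------------------
# closed-form expectations (disk / star-convex lesion, radius R)

def expected_tcpi_uniform() -> float:
    return 0.5


def expected_tcpi_necrotic(q: float) -> float:
    """Acellular core at u < q, uniform annulus beyond: tCPI = (1 - q²)/2."""
    return (1 - q * q) / 2


def expected_tcpi_center_packed(q: float) -> float:
    """All cells confined to u < q: tCPI = 1 - q²/2."""
    return 1 - q * q / 2


def expected_immcpi_central(c_frac: float, marker_frac: float) -> float:
    """Marker uniform in the central disk u < c_frac against a uniform background.

    Mean marker depth is R(1 - 2c/3R); the all-cell mean mixes background
    (R/3) and marker cells by the marker fraction f, so
    immCPI = m / ((1 - f)/3 + f·m) with m = 1 - 2·c_frac/3 (units of R).
    As f -> 0 this tends to the thin-marker limit 3 - 2·c_frac.
    """
    m = 1 - 2 * c_frac / 3
    return m / ((1 - marker_frac) / 3 + marker_frac * m)


def expected_immcpi_peripheral(q: float, marker_frac: float) -> float:
    """Marker uniform by area in the band u in [q, 1] against a uniform background."""
    m = 1 - (2 / 3) * (1 - q**3) / (1 - q * q)
    return m / ((1 - marker_frac) / 3 + marker_frac * m)


# --------------------------------------------------------------------------
# named fixture scenarios

_R = 500.0
_MARKER_FRAC = 0.1
_SEED_OFFSET_MARKER_POP = 1_000_003  # fixed offset for the second cell population


def _disk_spec(seed: int) -> LesionShapeSpec:
    return LesionShapeSpec(kind="disk", radius=_R, n_vertices=64, seed=seed)


def _dumbbell_lesion() -> tuple[Annotation, Annotation]:
    lobes = unary_union(
        [
            shapely.Point(0, 0).buffer(200, quad_segs=16),
            shapely.Point(600, 0).buffer(200, quad_segs=16),
            box(0, -40, 600, 40),
        ]
    )
    tissue = shapely.affinity.scale(box(*lobes.bounds), 1.2, 1.2)
    return (
        Annotation(class_label="Lesion", geometry=lobes, name="synthetic-dumbbell"),
        Annotation(class_label="Tissue", geometry=tissue, name="synthetic-tissue"),
    )


def _two_population_cells(seed, n, lesion, shape, marker, marker_profile):
    """Uniform background plus a positionally confined marker population."""
    n_marker = int(round(_MARKER_FRAC * n))
    bg = sample_cells(lesion, n - n_marker, RadialProfile("uniform"), seed=seed, shape=shape)
    mk = sample_cells(
        lesion, n_marker, marker_profile, seed=seed + _SEED_OFFSET_MARKER_POP, shape=shape
    )
    x = np.concatenate([bg.x, mk.x])
    y = np.concatenate([bg.y, mk.y])
    cls = np.concatenate(
        [np.full(len(bg), "", dtype=object), np.full(len(mk), marker, dtype=object)]
    )
    ids = np.array([f"cell_{i}" for i in range(n)], dtype=object)
    return CellTable(x=x, y=y, classification=cls, id=ids, source=f"synthetic:{marker_profile.kind}")


def _scenario_uniform(seed, n):
    shape = _disk_spec(seed)
    lesion, tissue = make_lesion(shape)
    cells = sample_cells(lesion, n, RadialProfile("uniform"), seed=seed, shape=shape)
    expected = {"tcpi": expected_tcpi_uniform()}
    params = {"radius_um": _R, "profile": "uniform"}
    return lesion, tissue, cells, expected, params


def _scenario_necrotic(seed, n, q=0.6):
    shape = _disk_spec(seed)
    lesion, tissue = make_lesion(shape)
    cells = sample_cells(lesion, n, RadialProfile("necrotic_core", q), seed=seed, shape=shape)
    expected = {"tcpi": expected_tcpi_necrotic(q)}
    params = {"radius_um": _R, "profile": "necrotic_core", "core_fraction": q}
    return lesion, tissue, cells, expected, params


def _scenario_center_packed(seed, n, q=0.5):
    shape = _disk_spec(seed)
    lesion, tissue = make_lesion(shape)
    cells = sample_cells(lesion, n, RadialProfile("center_enriched", q), seed=seed, shape=shape)
    expected = {"tcpi": expected_tcpi_center_packed(q)}
    params = {"radius_um": _R, "profile": "center_enriched", "core_fraction": q}
    return lesion, tissue, cells, expected, params


def _scenario_marker_central(seed, n, c_frac=0.5):
    shape = _disk_spec(seed)
    lesion, tissue = make_lesion(shape)
    cells = _two_population_cells(
        seed, n, lesion, shape, "CD3", RadialProfile("center_enriched", c_frac)
    )
    expected = {"immcpi": {"CD3": expected_immcpi_central(c_frac, _MARKER_FRAC)}}
    params = {
        "radius_um": _R,
        "marker": "CD3",
        "marker_core_fraction": c_frac,
        "marker_fraction": _MARKER_FRAC,
    }
    return lesion, tissue, cells, expected, params


def _scenario_marker_peripheral(seed, n, q=0.8):
    shape = _disk_spec(seed)
    lesion, tissue = make_lesion(shape)
    cells = _two_population_cells(
        seed, n, lesion, shape, "CD20", RadialProfile("necrotic_core", q)
    )
    expected = {"immcpi": {"CD20": expected_immcpi_peripheral(q, _MARKER_FRAC)}}
    params = {
        "radius_um": _R,
        "marker": "CD20",
        "marker_band_start": q,
        "marker_fraction": _MARKER_FRAC,
    }
    return lesion, tissue, cells, expected, params


def _scenario_dumbbell(seed, n):
    lesion, tissue = _dumbbell_lesion()
    cells = sample_cells(lesion, n, RadialProfile("uniform"), seed=seed)
    expected = {}  # no closed form for this shape; pipeline smoke-test only
    params = {"shape": "dumbbell", "lobe_radius_um": 200, "profile": "uniform"}
    return lesion, tissue, cells, expected, params


SCENARIOS = {
    "uniform": _scenario_uniform,
    "necrotic_q06": _scenario_necrotic,
    "center_packed": _scenario_center_packed,
    "marker_central": _scenario_marker_central,
    "marker_peripheral": _scenario_marker_peripheral,
    "dumbbell": _scenario_dumbbell,
}


def make_fixture(scenario: str, out_dir, seed: int = 0, n: int = 20_000) -> dict:
    """Write a named scenario to disk in the formats the readers accept.

    Produces ``<scenario>_annotations.geojson`` (Lesion + Tissue
    features), ``<scenario>_cells.csv`` and a ``<scenario>_expected.json``
    sidecar recording the ground-truth parameters and the analytic
    expected metrics (where a closed form exists). Byte-identical for a
    fixed seed. Returns the three paths.
    """
    if scenario not in SCENARIOS:
        raise ValueError(
            f"unknown scenario {scenario!r}; valid: {', '.join(sorted(SCENARIOS))}"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lesion, tissue, cells, expected, params = SCENARIOS[scenario](seed, n)
    ann_path = out_dir / f"{scenario}_annotations.geojson"
    cells_path = out_dir / f"{scenario}_cells.csv"
    sidecar_path = out_dir / f"{scenario}_expected.json"
    write_annotations([lesion, tissue], ann_path)
    write_cells(cells, cells_path)
    sidecar = {
        "scenario": scenario,
        "seed": int(seed),
        "n_cells": int(n),
        "parameters": params,
        "expected": expected,
    }
    with open(sidecar_path, "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)
        fh.write("\n")
    return {"annotations": ann_path, "cells": cells_path, "sidecar": sidecar_path}
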