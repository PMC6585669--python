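"""Axon cross-section geometries as polygons and label maps.

An axon is a pair of closed boundaries (inner = axonal membrane, outer =
myelin surface).  A collection of axons on a grid rasterizes to a 3-valued
label map (0 = extra-axonal, 1 = intra-axonal, 2 = myelin), the geometric
substrate of every field and signal simulation.

The generators emulate the statistics of an electron-micrograph template of
mouse white matter: gamma-distributed fiber radii (shape 5.7 about a mean of
0.46 um), g-ratio 0.7, and a fiber density of ~64% (36% extra-axonal space).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from scipy.spatial import cKDTree
from shapely.geometry import Polygon
from shapely.strtree import STRtree

from .grids import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "EXTRA",
    "INTRA",
    "MYELIN",
    "LabelMap",
    "AxonRecord",
    "AxonSet",
    "EllipseSpec",
    "PackingConfig",
    "OrientationMap",
    "PackingError",
    "make_single_ellipse_axon",
    "pack_circles",
    "rasterize",
    "warp_geometry",
    "synthesize_irregular_axons",
    "erode_myelin",
    "measure",
    "orientation_map",
]

EXTRA, INTRA, MYELIN = 0, 1, 2


class PackingError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# data types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LabelMap:
    """3-valued compartment raster (0 extra / 1 intra / 2 myelin)."""

    grid: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        lab = np.asarray(self.labels)
        if lab.shape != self.grid.shape:
            raise ValueError("label raster shape does not match grid")
        if not np.isin(lab, (EXTRA, INTRA, MYELIN)).all():
            raise ValueError("label map may only contain values {0, 1, 2}")
        object.__setattr__(self, "labels", lab.astype(np.uint8))

    def compartment_mask(self, label: int) -> np.ndarray:
        return self.labels == label


def _polygon_area(vertices: np.ndarray) -> float:
    x, y = vertices[:, 0], vertices[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


@dataclass
class AxonRecord:
    """One myelinated fiber: nested closed boundaries plus derived areas.

    ``circle_radii`` caches ``(r_inner, r_outer)`` for analytically circular
    axons so that rasterization and orientation can use exact radial tests.
    """

    center: tuple[float, float]
    inner_boundary: np.ndarray  # (N, 2) um, closed implicitly
    outer_boundary: np.ndarray  # (M, 2) um
    A_i: float = 0.0
    A_t: float = 0.0
    circle_radii: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.inner_boundary = np.asarray(self.inner_boundary, dtype=float)
        self.outer_boundary = np.asarray(self.outer_boundary, dtype=float)
        if not self.A_i:
            self.A_i = _polygon_area(self.inner_boundary)
        if not self.A_t:
            self.A_t = _polygon_area(self.outer_boundary)
        if not 0 < self.A_i < self.A_t:
            raise ValueError("require 0 < A_i < A_t")

    @property
    def g(self) -> float:
        """Generalized g-ratio sqrt(A_i / A_t)."""
        return math.sqrt(self.A_i / self.A_t)

    @property
    def r_effective(self) -> float:
        """Effective axon (inner) radius sqrt(A_i / pi), um."""
        return math.sqrt(self.A_i / math.pi)

    def outer_polygon(self) -> Polygon:
        return Polygon(self.outer_boundary)

    def circularity(self) -> float:
        """Isoperimetric ratio 4*pi*A/P^2 of the outer boundary (1 = circle)."""
        poly = self.outer_polygon()
        return 4.0 * math.pi * poly.area / poly.length**2


@dataclass
class AxonSet:
    """A collection of non-overlapping axons attached to a grid."""

    axons: list[AxonRecord]
    grid: GridSpec
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.axons)

    @property
    def g_ratios(self) -> np.ndarray:
        return np.array([a.g for a in self.axons])

    @property
    def total_fiber_area(self) -> float:
        return float(sum(a.A_t for a in self.axons))

    @property
    def fiber_density(self) -> float:
        return self.total_fiber_area / (self.grid.extent * self.grid.extent_y)

    def to_jsonl(self, path) -> None:
        """Serialize as newline-delimited JSON records (documented text format)."""
        with open(path, "w") as fh:
            fh.write(json.dumps({"grid": {"n": self.grid.n, "extent": self.grid.extent,
                                          "ny": self.grid.ny}, "meta": self.meta}) + "\n")
            for i, a in enumerate(self.axons):
                rec = {
                    "id": i,
                    "center": list(a.center),
                    "inner": np.round(a.inner_boundary, 6).tolist(),
                    "outer": np.round(a.outer_boundary, 6).tolist(),
                    "A_i": a.A_i,
                    "A_t": a.A_t,
                    "g": a.g,
                }
                if a.circle_radii is not None:
                    rec["circle_radii"] = list(a.circle_radii)
                fh.write(json.dumps(rec) + "\n")

    @classmethod
    def from_jsonl(cls, path) -> "AxonSet":
        with open(path) as fh:
            header = json.loads(fh.readline())
            grid = GridSpec(header["grid"]["n"], header["grid"]["extent"],
                            header["grid"].get("ny"))
            axons = []
            for line in fh:
                rec = json.loads(line)
                axons.append(
                    AxonRecord(
                        center=tuple(rec["center"]),
                        inner_boundary=np.array(rec["inner"]),
                        outer_boundary=np.array(rec["outer"]),
                        A_i=rec["A_i"],
                        A_t=rec["A_t"],
                        circle_radii=tuple(rec["circle_radii"]) if "circle_radii" in rec else None,
                    )
                )
        return cls(axons, grid, meta=header.get("meta", {}))


@dataclass(frozen=True)
class EllipseSpec:
    """Elliptical cross-section: eccentricity and in-plane rotation.

    ``axis_ratio`` is major/minor; ``eccentricity = sqrt(1 - (b/a)^2)``.
    ``rotation`` is the angle (rad) of the major axis to the transverse
    projection of the main field (the +x axis of the raster).
    """

    eccentricity: float = 0.0
    rotation: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.eccentricity < 1:
            raise ValueError("eccentricity must lie in [0, 1)")

    @property
    def axis_ratio(self) -> float:
        return 1.0 / math.sqrt(1.0 - self.eccentricity**2)

    @classmethod
    def from_axis_ratio(cls, axis_ratio: float, rotation: float = 0.0) -> "EllipseSpec":
        if axis_ratio < 1:
            raise ValueError("axis_ratio must be >= 1")
        return cls(math.sqrt(1.0 - 1.0 / axis_ratio**2), rotation)


@dataclass(frozen=True)
class PackingConfig:
    """Parameters of the random close packing of polydisperse fibers.

    The gamma distribution applies to the fiber *outer* radius; the inner
    radius is ``g_ratio`` times the outer one.
    """

    n_axons: int = 1434
    gamma_shape: float = 5.7
    mean_radius: float = 0.46  # um
    g_ratio: float = 0.7
    min_gap: float = 0.02  # um
    seed: int = 0
    max_iterations: int = 20000

    def __post_init__(self) -> None:
        if self.gamma_shape <= 0 or self.mean_radius <= 0:
            raise ValueError("gamma_shape and mean_radius must be positive")
        if not 0 < self.g_ratio < 1:
            raise ValueError("g_ratio must lie in (0, 1)")


@dataclass(frozen=True)
class OrientationMap:
    """Per-pixel azimuth (rad, in [0, 2pi)) of the myelin bilayer long axis.

    Defined exactly on myelin pixels; NaN elsewhere.  ``wedge_id`` optionally
    records the azimuthal quadrilateral index used in wedge mode.
    """

    grid: GridSpec
    phi: np.ndarray
    wedge_id: np.ndarray | None = None


# ---------------------------------------------------------------------------
# polygon helpers
# ---------------------------------------------------------------------------


def _circle_vertices(center, radius, n_vertices=None) -> np.ndarray:
    if n_vertices is None:
        n_vertices = 96
    theta = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    # inflate so the inscribed polygon matches the circle area exactly
    r_adj = radius * math.sqrt(2.0 * np.pi / n_vertices / math.sin(2.0 * np.pi / n_vertices))
    return np.column_stack(
        [center[0] + r_adj * np.cos(theta), center[1] + r_adj * np.sin(theta)]
    )


def _circle_record(center, r_inner, r_outer, n_vertices=None) -> AxonRecord:
    return AxonRecord(
        center=tuple(center),
        inner_boundary=_circle_vertices(center, r_inner, n_vertices),
        outer_boundary=_circle_vertices(center, r_outer, n_vertices),
        A_i=math.pi * r_inner**2,
        A_t=math.pi * r_outer**2,
        circle_radii=(r_inner, r_outer),
    )


def _vertex_count(radius_um: float, pixel_size: float) -> int:
    return int(np.clip(math.ceil(2 * math.pi * radius_um / pixel_size), 48, 512))


# ---------------------------------------------------------------------------
# single-axon generator
# ---------------------------------------------------------------------------


def make_single_ellipse_axon(
    spec: EllipseSpec,
    g: float,
    grid: GridSpec,
    r_outer: float | None = None,
) -> LabelMap:
    """Rasterize one nested-ellipse axon centred on the grid.

    The inner boundary is the outer one scaled by ``g``, so the intra and
    total areas (hence the g-ratio) are conserved across eccentricities and
    rotations.  ``r_outer`` is the effective outer radius sqrt(A_t/pi), um;
    it defaults to 28% of the grid extent.
    """
    if not 0 < g < 1:
        raise ValueError("g must lie in (0, 1)")
    if r_outer is None:
        r_outer = 0.28 * grid.extent
    ratio = spec.axis_ratio
    a = r_outer * math.sqrt(ratio)  # semi-major
    b = r_outer / math.sqrt(ratio)  # semi-minor
    margin = grid.extent / 2.0 - a
    if margin < 0.1 * grid.extent:
        raise ValueError(
            f"ellipse semi-major axis {a:.3g} um leaves margin {margin:.3g} um; "
            f"requires extent >= {a / 0.4:.3g} um"
        )
    X, Y = grid.meshgrid()
    cx, cy = grid.center
    c, s = math.cos(spec.rotation), math.sin(spec.rotation)
    u = (X - cx) * c + (Y - cy) * s
    v = -(X - cx) * s + (Y - cy) * c
    q = (u / a) ** 2 + (v / b) ** 2
    labels = np.full(grid.shape, EXTRA, dtype=np.uint8)
    labels[q <= 1.0] = MYELIN
    labels[q <= g**2] = INTRA
    return LabelMap(grid, labels)


# ---------------------------------------------------------------------------
# random close packing
# ---------------------------------------------------------------------------


def _sample_radii(config: PackingConfig, rng: np.random.Generator) -> np.ndarray:
    return rng.gamma(config.gamma_shape,
                     config.mean_radius / config.gamma_shape,
                     size=config.n_axons)


def grid_for_density(
    radii: np.ndarray, fiber_density: float, n_pixels: int
) -> GridSpec:
    """Square grid whose extent realizes ``fiber_density`` for the given radii."""
    extent = math.sqrt(float(np.sum(np.pi * radii**2)) / fiber_density)
    return GridSpec(n_pixels, extent)


def pack_circles(
    config: PackingConfig,
    grid: GridSpec | None = None,
    fiber_density: float = 0.64,
    n_pixels: int = 2227,
) -> AxonSet:
    """Random close packing of gamma-distributed circular fibers.

    Radii are drawn from Gamma(shape, mean/shape); centres start at uniform
    random positions and overlapping pairs are pushed apart iteratively
    (collision-resolving relaxation) until the packing is overlap-free.

    If ``grid`` is omitted, the domain is sized so the realized fiber density
    equals ``fiber_density`` (default 64%, i.e. 36% extra-axonal space, the
    value the electron-microscopy template realizes).
    """
    rng = np.random.default_rng(config.seed)
    radii = _sample_radii(config, rng)
    if grid is None:
        grid = grid_for_density(radii, fiber_density, n_pixels)
    L = grid.extent
    Ly = grid.extent_y
    area = float(np.sum(np.pi * radii**2))
    if area >= 0.9 * L * Ly:
        raise PackingError(
            f"requested fiber area {area:.1f} um^2 exceeds 90% of the "
            f"{L * Ly:.1f} um^2 domain"
        )
    gap = config.min_gap
    # large circles placed first relax faster
    order = np.argsort(radii)[::-1]
    radii = radii[order]
    centers = np.column_stack(
        [
            rng.uniform(radii + gap, L - radii - gap),
            rng.uniform(radii + gap, Ly - radii - gap),
        ]
    )
    reach = 2.0 * radii.max() + gap
    converged = False
    # inflate radii gradually while relaxing: overlaps stay small and the
    # pairwise push-apart sweep cannot deadlock the way a full-size random
    # start does at ~64% density
    growth_steps = max(1, min(400, config.max_iterations // 10))
    for iteration in range(config.max_iterations):
        scale = min(1.0, 0.5 + 0.5 * iteration / growth_steps)
        r_now = radii * scale
        tree = cKDTree(centers)
        pairs = tree.query_pairs(reach, output_type="ndarray")
        if len(pairs):
            i, j = pairs[:, 0], pairs[:, 1]
            delta = centers[j] - centers[i]
            dist = np.hypot(delta[:, 0], delta[:, 1])
            need = r_now[i] + r_now[j] + gap
            bad = dist < need - 1e-9  # femtometre slack kills contact jitter
        else:
            bad = np.zeros(0, dtype=bool)
        if not bad.any():
            if scale >= 1.0:
                converged = True
                break
            continue
        i, j, delta, dist, need = i[bad], j[bad], delta[bad], dist[bad], need[bad]
        zero = dist < 1e-12
        if zero.any():
            ang = rng.uniform(0, 2 * np.pi, zero.sum())
            delta[zero] = np.column_stack([np.cos(ang), np.sin(ang)])
            dist[zero] = 1.0
        push = 0.55 * (need - dist) / dist
        disp = delta * push[:, None]
        np.add.at(centers, j, disp)
        np.add.at(centers, i, -disp)
        centers[:, 0] = np.clip(centers[:, 0], r_now + gap, L - r_now - gap)
        centers[:, 1] = np.clip(centers[:, 1], r_now + gap, Ly - r_now - gap)
    if not converged:
        density = area / (L * Ly)
        raise PackingError(
            f"packing failed to resolve overlaps after {config.max_iterations} "
            f"iterations (n={config.n_axons}, fiber density {density:.2f})"
        )
    px = grid.pixel_size
    axons = [
        _circle_record(centers[k], config.g_ratio * radii[k], radii[k],
                       _vertex_count(radii[k], px))
        for k in range(len(radii))
    ]
    return AxonSet(axons, grid, meta={"seed": config.seed,
                                      "iterations": iteration + 1,
                                      "kind": "circle_packing"})


# ---------------------------------------------------------------------------
# rasterization
# ---------------------------------------------------------------------------


def rasterize(axons: AxonSet, grid: GridSpec | None = None) -> LabelMap:
    """Hard-label raster by pixel-centre inclusion; first axon claims ties.

    Conflicting claims (e.g. tangent circles sharing a pixel) are resolved in
    favour of the lower axon index and counted in the log.
    """
    if grid is None:
        grid = axons.grid
    px = grid.pixel_size
    labels = np.full(grid.shape, EXTRA, dtype=np.uint8)
    claimed = np.zeros(grid.shape, dtype=bool)
    conflicts = 0
    xs, ys = grid.pixel_centers()
    for rec in axons.axons:
        outer = rec.outer_boundary
        if len(outer) < 3:
            raise ValueError("open or degenerate polygon boundary")
        x0, y0 = outer.min(axis=0)
        x1, y1 = outer.max(axis=0)
        ix0 = max(int((x0 - px) / px), 0)
        ix1 = min(int((x1 + px) / px) + 1, grid.n)
        iy0 = max(int((y0 - px) / px), 0)
        iy1 = min(int((y1 + px) / px) + 1, grid.ny)
        if ix0 >= ix1 or iy0 >= iy1:
            continue
        if rec.circle_radii is not None:
            cx, cy = rec.center
            r_i, r_o = rec.circle_radii
            XX, YY = np.meshgrid(xs[ix0:ix1], ys[iy0:iy1])
            rr = (XX - cx) ** 2 + (YY - cy) ** 2
            inside_outer = rr <= r_o**2
            inside_inner = rr <= r_i**2
        else:
            XX, YY = np.meshgrid(xs[ix0:ix1], ys[iy0:iy1])
            pts = np.column_stack([XX.ravel(), YY.ravel()])
            inside_outer = MplPath(outer).contains_points(pts).reshape(XX.shape)
            inside_inner = MplPath(rec.inner_boundary).contains_points(pts).reshape(XX.shape)
        sub_claimed = claimed[iy0:iy1, ix0:ix1]
        conflicts += int((inside_outer & sub_claimed).sum())
        new = inside_outer & ~sub_claimed
        sub = labels[iy0:iy1, ix0:ix1]
        sub[new & inside_inner] = INTRA
        sub[new & ~inside_inner] = MYELIN
        sub_claimed |= inside_outer
    if conflicts:
        logger.info("rasterize: %d pixel claims resolved to lower axon index", conflicts)
    return LabelMap(grid, labels)


# ---------------------------------------------------------------------------
# warping
# ---------------------------------------------------------------------------

DEFAULT_WARP = {"amplitude": 0.7, "frequency": 0.15, "phase": 0.0,
                "decay": 0.02, "r0": 0.5}


def _swirl_points(points: np.ndarray, center, params: dict) -> np.ndarray:
    """Area-preserving azimuthal swirl (r, theta) -> (r, theta + alpha(r))."""
    p = {**DEFAULT_WARP, **params}
    rel = points - np.asarray(center)
    r = np.hypot(rel[:, 0], rel[:, 1])
    alpha = p["amplitude"] * (
        np.log1p(r / p["r0"])
        + 0.25 * np.sin(2 * np.pi * p["frequency"] * r + p["phase"]) * np.exp(-p["decay"] * r)
    )
    c, s = np.cos(alpha), np.sin(alpha)
    out = np.empty_like(rel)
    out[:, 0] = c * rel[:, 0] - s * rel[:, 1]
    out[:, 1] = s * rel[:, 0] + c * rel[:, 1]
    return out + np.asarray(center)


def warp_geometry(
    axons: AxonSet,
    warp_params: dict | None = None,
    check_overlap: bool = True,
) -> AxonSet:
    """Warp every boundary vertex with a smooth area-preserving swirl.

    The map is a bijection of the plane that preserves distance to the domain
    centre, so disjoint axons remain disjoint and areas (hence g-ratio and
    fiber density) are conserved up to polygon discretization.
    """
    params = dict(warp_params or {})
    if params.get("amplitude", DEFAULT_WARP["amplitude"]) == 0.0:
        return axons
    center = axons.grid.center
    warped = []
    for rec in axons.axons:
        inner = _swirl_points(rec.inner_boundary, center, params)
        outer = _swirl_points(rec.outer_boundary, center, params)
        c = outer.mean(axis=0)
        warped.append(AxonRecord(center=(float(c[0]), float(c[1])),
                                 inner_boundary=inner, outer_boundary=outer))
    if check_overlap:
        bad = _overlapping_pairs(warped)
        if bad:
            raise ValueError(f"warped boundaries intersect for axon pairs {bad[:10]}")
    return AxonSet(warped, axons.grid,
                   meta={**axons.meta, "kind": "warped", "warp": {**DEFAULT_WARP, **params}})


def _overlapping_pairs(records: list[AxonRecord]) -> list[tuple[int, int]]:
    polys = [r.outer_polygon() for r in records]
    tree = STRtree(polys)
    bad = []
    for i, poly in enumerate(polys):
        for j in tree.query(poly, predicate="intersects"):
            j = int(j)
            if j > i and polys[j].intersection(poly).area > 1e-12:
                bad.append((i, j))
    return bad


# ---------------------------------------------------------------------------
# irregular synthetic axons
# ---------------------------------------------------------------------------


def synthesize_irregular_axons(
    config: PackingConfig,
    roughness: dict | None = None,
    seed: int | None = None,
    grid: GridSpec | None = None,
    fiber_density: float = 0.64,
    n_pixels: int = 2227,
) -> AxonSet:
    """Packed axons with random low-order radial-harmonic boundary roughness.

    This is a synthetic stand-in for a hand-segmented electron-micrograph
    template: population statistics (radius distribution, density, g-ratio)
    follow :func:`pack_circles`, while each outline is perturbed by a random
    radial-harmonic series ``r(theta) = r * (1 + sum_k a_k cos(k theta) +
    b_k sin(k theta))`` with a red (1/k) spectrum.  The inner boundary gets a
    partially independent perturbation (``thickness_mix`` sets the
    independent share), so the sheath thickness varies azimuthally as it
    does in micrographs; the inner curve is rescaled so each axon's g-ratio
    is preserved exactly.  Inner perturbations that would cross the outer
    boundary are resampled.
    """
    rough = {"n_harmonics": 8, "amplitude_sd": 0.15, "thickness_mix": 0.7,
             "g_sd": 0.05, **(roughness or {})}
    if rough["amplitude_sd"] >= 0.3:
        raise ValueError("roughness amplitude_sd must be < 0.3")
    packed = pack_circles(config, grid=grid, fiber_density=fiber_density,
                          n_pixels=n_pixels)
    if rough["amplitude_sd"] == 0.0:
        return packed
    rng = np.random.default_rng(config.seed if seed is None else seed)
    K = int(rough["n_harmonics"])
    # red spectrum (sigma_k ~ 1/k): smooth, elongated outlines like real
    # sheaths rather than high-frequency ripple
    orders = np.arange(2, K + 2)
    weights = 1.0 / orders
    sigma = rough["amplitude_sd"] * weights / np.sqrt(np.sum(weights**2))
    px = packed.grid.pixel_size
    mix = float(rough["thickness_mix"])
    # micrograph-like per-axon g-ratio scatter about the population target;
    # the population mean stays at the packed value
    g_targets = np.clip(
        rng.normal(config.g_ratio, rough["g_sd"], len(packed.axons)), 0.55, 0.85
    )
    shapes = []
    for rec, g_k in zip(packed.axons, g_targets):
        _, r_o = rec.circle_radii
        r_i = g_k * r_o
        nv = _vertex_count(r_o, px)
        theta = np.linspace(0, 2 * np.pi, nv, endpoint=False)
        cosm = np.cos(np.outer(orders, theta))
        sinm = np.sin(np.outer(orders, theta))
        eps = rng.normal(0.0, sigma) @ cosm + rng.normal(0.0, sigma) @ sinm
        eps = np.clip(eps, -0.6, 0.6)
        g = r_i / r_o
        # inner boundary: correlated share of eps plus an independent
        # component, resampled until it stays strictly inside the outer one
        for _ in range(12):
            eta = rng.normal(0.0, sigma) @ cosm + rng.normal(0.0, sigma) @ sinm
            delta = (1.0 - mix) * eps + mix * eta
            delta = np.clip(delta, -0.6, 0.6)
            # rescale so the inner area is exactly g^2 times the outer area
            s = math.sqrt(np.mean((1.0 + eps) ** 2) / np.mean((1.0 + delta) ** 2))
            if np.all(g * s * (1.0 + delta) < (1.0 + eps) - 1e-6):
                break
            mix *= 0.8
        else:
            delta, s = eps, 1.0  # fall back to the parallel-contour sheath
        shapes.append((rec, theta, eps, delta * s + (s - 1.0), r_i, r_o))

    def build(rec, theta, eps, delta, r_i, r_o, scale, offset):
        cx, cy = np.asarray(rec.center) + offset
        outer_shape = 1.0 + scale * eps
        inner_shape = 1.0 + scale * delta
        outer = np.column_stack([cx + r_o * outer_shape * np.cos(theta),
                                 cy + r_o * outer_shape * np.sin(theta)])
        inner = np.column_stack([cx + r_i * inner_shape * np.cos(theta),
                                 cy + r_i * inner_shape * np.sin(theta)])
        return AxonRecord(center=(float(cx), float(cy)),
                          inner_boundary=inner, outer_boundary=outer)

    offsets = np.zeros((len(shapes), 2))
    scales = np.ones(len(shapes))
    L, Ly = packed.grid.extent, packed.grid.extent_y

    def rebuild(k):
        records[k] = build(*shapes[k], scales[k], offsets[k])

    records = [build(*sh, 1.0, np.zeros(2)) for sh in shapes]
    # collisions are resolved by nudging whole axons apart (there is room at
    # 64% fiber density); roughness is damped only as a last resort
    for rnd in range(120):
        bad = _overlapping_pairs(records)
        if not bad:
            break
        for i, j in bad:
            ci = np.asarray(shapes[i][0].center) + offsets[i]
            cj = np.asarray(shapes[j][0].center) + offsets[j]
            d = cj - ci
            dist = float(np.hypot(*d)) or 1.0
            u = d / dist
            ri = float(np.max((records[i].outer_boundary - ci) @ u))
            rj = float(np.max((records[j].outer_boundary - cj) @ -u))
            pen = ri + rj - dist
            if pen <= 0:
                pen = 0.05 * min(ri, rj)
            shift = 0.55 * pen * u
            offsets[j] += shift
            offsets[i] -= shift
            if rnd >= 60:
                for k in (i, j):
                    scales[k] *= 0.8
                    if scales[k] < 0.05:
                        scales[k] = 0.0
            rebuild(i)
            rebuild(j)
        # keep outlines inside the domain
        for k in range(len(records)):
            ob = records[k].outer_boundary
            dx = min(0.0, ob[:, 0].min()) or max(0.0, ob[:, 0].max() - L)
            dy = min(0.0, ob[:, 1].min()) or max(0.0, ob[:, 1].max() - Ly)
            if dx or dy:
                offsets[k] -= (dx, dy)
                rebuild(k)
    if _overlapping_pairs(records):
        raise PackingError("could not resolve boundary collisions while roughening")
    return AxonSet(records, packed.grid,
                   meta={**packed.meta, "kind": "irregular", "roughness": rough})


# ---------------------------------------------------------------------------
# demyelination
# ---------------------------------------------------------------------------


def erode_myelin(obj, target_g: float):
    """Thin the myelin sheath from the inside out to reach ``target_g``.

    Removed myelin is reassigned to the intra-axonal compartment; the outer
    boundary (hence fiber density) is untouched.  Works on an :class:`AxonSet`
    (exact, by scaling the inner boundary about the centroid) or on a raster
    :class:`LabelMap` (layer-by-layer reassignment ordered by distance to the
    intra-axonal space).
    """
    if not 0 < target_g < 1:
        raise ValueError("target_g must lie in (0, 1)")
    if isinstance(obj, AxonSet):
        return _erode_axon_set(obj, target_g)
    if isinstance(obj, LabelMap):
        return _erode_label_map(obj, target_g)
    raise TypeError("erode_myelin expects an AxonSet or LabelMap")


def _erode_axon_set(axons: AxonSet, target_g: float) -> AxonSet:
    out = []
    for idx, rec in enumerate(axons.axons):
        if target_g < rec.g - 1e-9:
            raise ValueError(
                f"axon {idx}: target g {target_g:.3f} < current {rec.g:.3f} "
                "(remyelination is not modeled)"
            )
        scale = math.sqrt(target_g**2 * rec.A_t / rec.A_i)
        c = np.asarray(rec.center)
        inner = c + (rec.inner_boundary - c) * scale
        circle = None
        if rec.circle_radii is not None:
            circle = (rec.circle_radii[0] * scale, rec.circle_radii[1])
        out.append(
            AxonRecord(center=rec.center, inner_boundary=inner,
                       outer_boundary=rec.outer_boundary.copy(),
                       A_i=target_g**2 * rec.A_t, A_t=rec.A_t,
                       circle_radii=circle)
        )
    return AxonSet(out, axons.grid, meta={**axons.meta, "target_g": target_g})


def _erode_label_map(lmap: LabelMap, target_g: float) -> LabelMap:
    labels = lmap.labels.copy()
    fiber_lab, n_fib = ndimage.label(labels != EXTRA)
    intra = labels == INTRA
    # distance of each pixel to the intra-axonal space: innermost myelin first
    dist = ndimage.distance_transform_edt(~intra)
    slices = ndimage.find_objects(fiber_lab)
    for fid in range(1, n_fib + 1):
        sl = slices[fid - 1]
        comp = fiber_lab[sl] == fid
        sub = labels[sl]
        a_t = int(comp.sum())
        a_i = int((comp & (sub == INTRA)).sum())
        if a_i == 0 or a_t == 0:
            continue
        current_g = math.sqrt(a_i / a_t)
        if target_g < current_g - 1e-9:
            raise ValueError(
                f"fiber {fid}: target g {target_g:.3f} < current {current_g:.3f}"
            )
        need = int(round(target_g**2 * a_t)) - a_i
        if need <= 0:
            continue
        my = comp & (sub == MYELIN)
        my_iy, my_ix = np.nonzero(my)
        order = np.argsort(dist[sl][my_iy, my_ix], kind="stable")
        sel = order[:need]
        sub[my_iy[sel], my_ix[sel]] = INTRA  # sub is a view into labels
    return LabelMap(lmap.grid, labels)


# ---------------------------------------------------------------------------
# measurement
# ---------------------------------------------------------------------------


def measure(lmap: LabelMap, axons: AxonSet | None = None) -> dict:
    """Compartment volume fractions, fiber density and per-axon g-ratios.

    Per-axon statistics come from the axon polygons when provided, otherwise
    from 4-connected fiber components of the raster.  Effective radii are
    ``sqrt(area / pi)``.
    """
    labels = lmap.labels
    total = labels.size
    counts = np.bincount(labels.ravel(), minlength=3)
    fractions = {
        "extra": counts[EXTRA] / total,
        "intra": counts[INTRA] / total,
        "myelin": counts[MYELIN] / total,
    }
    result = {
        "volume_fractions": fractions,
        "fiber_density": (counts[INTRA] + counts[MYELIN]) / total,
    }
    px_area = lmap.grid.pixel_size**2
    if axons is not None:
        result["axon_g"] = axons.g_ratios
        result["axon_r_effective"] = np.array([a.r_effective for a in axons.axons])
    else:
        fiber_lab, n_fib = ndimage.label(labels != EXTRA)
        if n_fib:
            a_t = ndimage.sum_labels(np.ones_like(labels), fiber_lab,
                                     index=np.arange(1, n_fib + 1))
            a_i = ndimage.sum_labels((labels == INTRA).astype(float), fiber_lab,
                                     index=np.arange(1, n_fib + 1))
            with np.errstate(invalid="ignore"):
                result["axon_g"] = np.sqrt(a_i / a_t)
            result["axon_r_effective"] = np.sqrt(a_i * px_area / math.pi)
        else:
            result["axon_g"] = np.array([])
            result["axon_r_effective"] = np.array([])
    return result


# ---------------------------------------------------------------------------
# bilayer orientation
# ---------------------------------------------------------------------------


def orientation_map(
    lmap: LabelMap,
    axons: AxonSet | None = None,
    mode: str = "wedge",
    n_wedges: int | None = None,
) -> OrientationMap:
    """Azimuth of the radially oriented myelin bilayer, per myelin pixel.

    Myelin pixels are attributed to axons through connected fiber components;
    if several axon centres share a component (tangent fibers) the nearest
    centre wins, ties to the lower index.  In ``wedge`` mode the azimuth is
    quantized into per-axon azimuthal quadrilaterals whose arc length is at
    most ~2 pixels (at least 16 wedges); ``continuous`` mode keeps the exact
    per-pixel azimuth about the axon centroid.
    """
    if mode not in ("wedge", "continuous"):
        raise ValueError("mode must be 'wedge' or 'continuous'")
    labels = lmap.labels
    grid = lmap.grid
    px = grid.pixel_size
    fiber_lab, n_fib = ndimage.label(labels != EXTRA)
    my = labels == MYELIN
    phi = np.full(grid.shape, np.nan, dtype=np.float64)
    if not my.any():
        return OrientationMap(grid, phi)
    # per-component centroid (of the intra space when present) and outer radius
    comp_center = np.zeros((n_fib + 1, 2))
    comp_rout = np.zeros(n_fib + 1)
    multi: set[int] = set()
    if axons is not None:
        centers = np.array([a.center for a in axons.axons])
        ix = np.clip((centers[:, 0] / px).astype(int), 0, grid.n - 1)
        iy = np.clip((centers[:, 1] / px).astype(int), 0, grid.ny - 1)
        comp_of_axon = fiber_lab[iy, ix]
        shared = np.bincount(comp_of_axon, minlength=n_fib + 1)
        shared[0] = 0
        multi = {int(c) for c in np.flatnonzero(shared > 1)}
        if multi:
            logger.info("orientation_map: %d fiber components contain several "
                        "axon centres; nearest centre wins", len(multi))
        for k, rec in enumerate(axons.axons):
            cid = comp_of_axon[k]
            if cid and shared[cid] == 1:
                comp_center[cid] = rec.center
                comp_rout[cid] = math.sqrt(rec.A_t / math.pi)
    idx = np.arange(1, n_fib + 1)
    need = comp_rout[1:] == 0
    if need.any():
        src = labels == INTRA
        if not src.any():
            src = labels != EXTRA
        com = ndimage.center_of_mass(src, fiber_lab, index=idx[need])
        com = np.atleast_2d(np.asarray(com, dtype=float))
        # center_of_mass returns (row, col); convert to (x, y) um
        comp_center[idx[need], 0] = (com[:, 1] + 0.5) * px
        comp_center[idx[need], 1] = (com[:, 0] + 0.5) * px
        a_t = ndimage.sum_labels(np.ones_like(labels), fiber_lab, index=idx[need])
        comp_rout[idx[need]] = np.sqrt(a_t * px**2 / math.pi)
    iy, ix = np.nonzero(my)
    cid = fiber_lab[iy, ix]
    x = (ix + 0.5) * px
    y = (iy + 0.5) * px
    pix_center = comp_center[cid]
    if axons is not None and multi:
        # resolve pixels of merged components by distance to the outer
        # boundary (approximated as distance-to-centre minus outer radius);
        # ties fall to the lower axon index via argmin's first-match rule
        centers_arr = np.array([a.center for a in axons.axons])
        r_out = np.array([math.sqrt(a.A_t / math.pi) for a in axons.axons])
        in_multi = np.isin(cid, list(multi))
        if in_multi.any():
            pts = np.column_stack([x[in_multi], y[in_multi]])
            tree = cKDTree(centers_arr)
            k = min(8, len(centers_arr))
            d, cand = tree.query(pts, k=k)
            d = np.atleast_2d(d)
            cand = np.atleast_2d(cand)
            signed = d - r_out[cand]
            best = cand[np.arange(len(pts)), np.argmin(signed, axis=1)]
            pix_center[in_multi] = centers_arr[best]
    ang = np.mod(np.arctan2(y - pix_center[:, 1], x - pix_center[:, 0]),
                 2 * np.pi)
    wid = None
    if mode == "wedge":
        if n_wedges is not None:
            nw = np.full(n_fib + 1, int(n_wedges))
        else:
            nw = np.maximum(16, np.ceil(2 * np.pi * comp_rout / (2 * px))).astype(int)
            nw[0] = 16
        width = 2 * np.pi / nw[cid]
        widx = np.floor(ang / width).astype(int)
        ang = (widx + 0.5) * width
        wid = np.full(grid.shape, -1, dtype=np.int32)
        wid[iy, ix] = widx
    phi[iy, ix] = np.mod(ang, 2 * np.pi)
    return OrientationMap(grid, phi, wid)
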