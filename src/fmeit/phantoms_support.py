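"""Synthetic conductivity phantoms and inner/outer support masks.

Phantoms are ordered lists of shapes (disk, ellipse, annulus, polygon)
with additive contrasts relative to a constant background; later shapes
override earlier ones on overlap.  Ground truth for reconstruction
tests comes as pixel masks:

* support          pixels where σ differs from the background,
* inner support    pixels where |σ−σ₀| ≥ δ, eroded by one pixel
                   (a grid surrogate of the essential-infimum condition),
* outer support    the support plus every hole that is not connected to
                   the measurement arc Σ through the background, computed
                   by 4-connected flood fill seeded at boundary pixels
                   whose angle lies in Σ.

The outer support is what a boundary-data shape-reconstruction method
can at best recover: anomaly holes invisible from Σ get filled.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage

from .boundary_forward import BoundaryArc, ConductivityField
from .virtual_measurements import RegionMask

__all__ = [
    "ShapeSpec",
    "Phantom",
    "PixelGrid",
    "SupportMasks",
    "Scenario",
    "ScenarioOptions",
    "make_phantom",
    "inner_support_mask",
    "support_masks",
    "scenario_generator",
    "jaccard",
]

logger = logging.getLogger("fmeit.phantoms_support")

_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class ShapeSpec:
    """One phantom shape with an additive conductivity contrast.

    kinds and parameters:
      disk     center (2,), radius
      ellipse  center (2,), semi_axes (a, b), angle (radians)
      annulus  center (2,), r_inner, r_outer
      polygon  vertices (n, 2)
    """

    kind: str
    contrast: float
    center: tuple = (0.0, 0.0)
    radius: float = 0.0
    semi_axes: tuple = (0.0, 0.0)
    angle: float = 0.0
    r_inner: float = 0.0
    r_outer: float = 0.0
    vertices: tuple = ()

    def __post_init__(self) -> None:
        if self.kind not in ("disk", "ellipse", "annulus", "polygon"):
            raise ValueError(f"unknown shape kind {self.kind!r}")
        if self.outer_radius() >= 1.0:
            raise ValueError("shape must lie strictly inside the unit disk")

    def outer_radius(self) -> float:
        c = np.hypot(*self.center)
        if self.kind == "disk":
            return c + self.radius
        if self.kind == "ellipse":
            return c + max(self.semi_axes)
        if self.kind == "annulus":
            return c + self.r_outer
        v = np.asarray(self.vertices, dtype=float)
        return float(np.max(np.hypot(v[:, 0], v[:, 1]))) if len(v) else 0.0

    def contains(self, points: np.ndarray) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        rel = pts - np.asarray(self.center, dtype=float)[None, :]
        if self.kind == "disk":
            return np.hypot(rel[:, 0], rel[:, 1]) <= self.radius
        if self.kind == "ellipse":
            ca, sa = np.cos(self.angle), np.sin(self.angle)
            xr = ca * rel[:, 0] + sa * rel[:, 1]
            yr = -sa * rel[:, 0] + ca * rel[:, 1]
            a, b = self.semi_axes
            return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0
        if self.kind == "annulus":
            r = np.hypot(rel[:, 0], rel[:, 1])
            return (r >= self.r_inner) & (r <= self.r_outer)
        return MplPath(np.asarray(self.vertices, dtype=float)).contains_points(pts)


@dataclass
class Phantom:
    """Background conductivity plus an ordered shape list (last wins)."""

    background: float
    shapes: tuple
    field: ConductivityField = None

    def __post_init__(self) -> None:
        if self.background <= 0:
            raise ValueError("background conductivity must be positive")
        self.shapes = tuple(self.shapes)
        for s in self.shapes:
            if self.background + s.contrast <= 0:
                raise ValueError(
                    f"contrast {s.contrast:g} on background {self.background:g} "
                    "violates positivity")
        if self.field is None:
            self.field = self._build_field()
        # positivity on a dense sample grid
        g = PixelGrid(128)
        vals = self.field(g.centers[g.inside])
        if np.any(vals <= 0):
            raise ValueError("phantom conductivity non-positive on sample grid")

    def _build_field(self) -> ConductivityField:
        bg = self.background
        shapes = self.shapes
        values = [bg + s.contrast for s in shapes]

        def evaluator(pts: np.ndarray) -> np.ndarray:
            out = np.full(len(pts), bg)
            for s, val in zip(shapes, values):
                out[np.asarray(s.contains(pts), dtype=bool)] = val
            return out

        lo = min([bg] + values)
        hi = max([bg] + values)
        desc = f"background {bg:g} + {len(shapes)} shapes" if shapes else f"constant {bg:g}"
        return ConductivityField(evaluator, sigma_min=lo, sigma_max=hi,
                                 description=desc)

    def deviation(self, pts: np.ndarray) -> np.ndarray:
        """σ(x) − σ₀ with σ₀ the constant background."""
        return self.field(pts) - self.background

    def region(self, positive: bool | None = None) -> RegionMask:
        """RegionMask of the shapes (optionally only one contrast sign)."""
        if positive is None:
            sel = self.shapes
        elif positive:
            sel = tuple(s for s in self.shapes if s.contrast > 0)
        else:
            sel = tuple(s for s in self.shapes if s.contrast < 0)
        return RegionMask.from_shapes(sel)


def make_phantom(background: float, shapes: Sequence[ShapeSpec]) -> Phantom:
    """Build a phantom; raises if positivity fails anywhere sampled."""
    return Phantom(background=background, shapes=tuple(shapes))


# --------------------------------------------------------------------------
# pixel grids and masks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelGrid:
    """n×n pixel grid of cell centers covering [−1, 1]²."""

    n: int

    def __post_init__(self) -> None:
        if self.n < 8:
            raise ValueError("grid resolution too small")

    @property
    def step(self) -> float:
        return 2.0 / self.n

    @property
    def centers(self) -> np.ndarray:
        c = -1.0 + self.step * (np.arange(self.n) + 0.5)
        X, Y = np.meshgrid(c, c, indexing="ij")
        return np.stack([X, Y], axis=-1)       # (n, n, 2)

    @property
    def inside(self) -> np.ndarray:
        c = self.centers
        return np.hypot(c[..., 0], c[..., 1]) < 1.0

    def boundary_pixels(self) -> np.ndarray:
        """Inside pixels with at least one 4-neighbor outside the disk."""
        inside = self.inside
        eroded = ndimage.binary_erosion(inside, structure=_FOUR_CONN,
                                        border_value=0)
        return inside & ~eroded

    def angles(self) -> np.ndarray:
        c = self.centers
        return np.mod(np.arctan2(c[..., 1], c[..., 0]), 2.0 * np.pi)


@dataclass
class SupportMasks:
    """Ground-truth pixel masks: inner ⊆ support ⊆ outer (w.r.t. Σ)."""

    grid: PixelGrid
    support: np.ndarray
    inner: np.ndarray
    outer: np.ndarray
    arc: BoundaryArc

    def __post_init__(self) -> None:
        if not (np.all(self.support[self.inner]) and np.all(self.outer[self.support])):
            raise ValueError("mask nesting inner ⊆ support ⊆ outer violated")


def inner_support_mask(phantom: Phantom, grid: PixelGrid, delta: float) -> np.ndarray:
    """Pixels with |σ−σ₀| ≥ δ, eroded to interior pixels."""
    if delta <= 0:
        raise ValueError("delta must be positive")
    dev = np.abs(phantom.deviation(grid.centers.reshape(-1, 2))).reshape(grid.n, grid.n)
    level = (dev >= delta) & grid.inside
    return ndimage.binary_erosion(level, structure=_FOUR_CONN, border_value=0)


def support_masks(phantom: Phantom, grid: PixelGrid, arc: BoundaryArc,
                  delta: float = 1e-9) -> SupportMasks:
    """Support, inner support (at level δ), and outer support w.r.t. Σ."""
    inside = grid.inside
    dev = np.abs(phantom.deviation(grid.centers.reshape(-1, 2))).reshape(grid.n, grid.n)
    support = (dev > 1e-14) & inside
    inner = inner_support_mask(phantom, grid, delta)

    # flood fill of the background from boundary pixels whose angle lies in Σ
    complement = inside & ~support
    labels, n_lab = ndimage.label(complement, structure=_FOUR_CONN)
    seeds = grid.boundary_pixels() & complement
    seeds &= np.asarray(arc.contains(grid.angles()), dtype=bool)
    reachable = np.unique(labels[seeds])
    reachable = reachable[reachable > 0]
    visible_background = np.isin(labels, reachable)
    outer = inside & ~visible_background
    return SupportMasks(grid=grid, support=support, inner=inner, outer=outer,
                        arc=arc)


def jaccard(a: np.ndarray, b: np.ndarray) -> float:
    """Jaccard overlap |a∩b| / |a∪b| of two boolean masks (1.0 if both empty)."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    union = np.count_nonzero(a | b)
    if union == 0:
        return 1.0
    return np.count_nonzero(a & b) / union


# --------------------------------------------------------------------------
# seeded scenario generation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioOptions:
    """Bounds for the random scenario generator."""

    max_shapes: int = 3
    radius_range: tuple = (0.10, 0.25)
    contrast_range: tuple = (0.5, 1.5)          # magnitude of positive contrasts
    negative_contrast_range: tuple = (0.25, 0.75)  # magnitude of negative ones
    indefinite: bool = False
    grid_n: int = 96
    arc: BoundaryArc = BoundaryArc.full_circle()
    max_retries: int = 200
    margin: float = 0.2                         # clearance from ∂Ω


@dataclass
class Scenario:
    """One reproducible test case: phantom, excluded region, masks, tag."""

    phantom: Phantom
    excluded: RegionMask
    masks: SupportMasks
    tag: str                                    # 'definite' | 'indefinite'
    seed: int


def scenario_generator(seed: int, options: ScenarioOptions = ScenarioOptions()) -> Scenario:
    """Seeded random phantom scenario.

    Definite scenarios carry uniformly signed contrasts and an empty
    excluded region; indefinite scenarios have mixed signs and an E that
    covers the minority-sign shapes (slightly inflated disks) without
    touching the majority-sign shapes.
    """
    rng = np.random.default_rng(seed)
    n_shapes = int(rng.integers(1, options.max_shapes + 1))
    if options.indefinite and n_shapes < 2:
        n_shapes = 2
    placed: list[ShapeSpec] = []
    signs: list[int] = []
    for i in range(n_shapes):
        if options.indefinite:
            sign = 1 if i < (n_shapes + 1) // 2 else -1
        else:
            sign = 1 if (seed % 2 == 0) else -1
        for _ in range(options.max_retries):
            r = rng.uniform(*options.radius_range)
            rc = rng.uniform(0.0, 1.0 - options.margin - r)
            ang = rng.uniform(0.0, 2.0 * np.pi)
            c = (rc * np.cos(ang), rc * np.sin(ang))
            # keep disks separated (room for inflated exclusion regions)
            if all(np.hypot(c[0] - s.center[0], c[1] - s.center[1])
                   > r + s.radius + 0.1 for s in placed):
                break
        else:
            raise RuntimeError("could not place shapes within retry budget")
        mag = rng.uniform(*(options.negative_contrast_range if sign < 0
                            else options.contrast_range))
        placed.append(ShapeSpec(kind="disk", contrast=sign * mag,
                                center=c, radius=r))
        signs.append(sign)
    phantom = make_phantom(1.0, placed)
    if options.indefinite:
        minority = -1 if signs.count(1) >= signs.count(-1) else 1
        excl = tuple(
            ShapeSpec(kind="disk", contrast=0.0, center=s.center,
                      radius=min(s.radius + 0.05, 0.999 - np.hypot(*s.center)))
            for s, sg in zip(placed, signs) if sg == minority)
        excluded = RegionMask.from_shapes(excl, description="minority-sign cover")
        tag = "indefinite"
    else:
        excluded = RegionMask.empty()
        tag = "definite"
    masks = support_masks(phantom, PixelGrid(options.grid_n), options.arc)
    return Scenario(phantom=phantom, excluded=excluded, masks=masks,
                    tag=tag, seed=seed)
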