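"""Synthetic micrograph generator with exact ground truth.

Renders fields of kidney-shaped fiber cross-sections — bright wall
material with a dark lumen on a dark background — together with the
exact polygons used to draw them and the true metrics computed from
those polygons. Segmentation, quality filtering and the statistics can
therefore be validated end to end without any real micrograph.

Shape model
-----------
A dried mature cotton fiber collapses into a ribbon-like bean. The
outer boundary here is an ellipse of radius ``outer_radius_um`` and
axis ratio ``aspect``, with a single cosine-squared radial dent of
relative depth ``dent_depth`` on one flat side:

    r(φ) = r_ellipse(φ) · (1 − dent_depth·sin²φ)   for sin φ > 0

The lumen is the same shape scaled inward by
``1 − wall_thickness_fraction``, which keeps it strictly inside the
wall everywhere. An oblique cut (fiber axis off the section normal by
``tilt_angle``) is an anisotropic stretch of the whole cross-section by
1/cos(tilt) along a random in-plane direction, so the apparent area is
inflated by exactly that factor.

Quality defects are sampled by kind: ``folded`` fibers are extreme
ribbons whose outer circularity falls below any plausible range, and
``oblique`` fibers are tilted far enough that their apparent area is
implausibly large. Both should be rejected by the default quality
rules; their truth records carry ``good=False`` and the defect kind.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
from skimage import draw as _draw

from .io_formats import table_from_metrics
from .morphometry import (
    CalibrationScale,
    Contour,
    FiberMetrics,
    derive_fiber_metrics,
    measure_shape,
)
from .segmentation import BoundingBox, candidate_letter_sequence, reading_order

__all__ = [
    "SimulationError",
    "FiberShapeParams",
    "PopulationParams",
    "TrueFiber",
    "SyntheticScene",
    "sample_fiber_shape",
    "kidney_contours",
    "tilt_transform",
    "render_scene",
    "simulate_scene",
    "simulate_experiment",
    "ground_truth_table",
]

#: Default calibration: 0.1 μm per pixel puts typical fibers at
#: ~150–250 px across — large enough for sub-percent contour accuracy,
#: small enough to keep scenes fast to render.
DEFAULT_UM_PER_PX = 0.1

_N_VERTICES = 256


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class FiberShapeParams:
    """Geometry of one synthetic cross-section (physical units, μm)."""

    outer_radius_um: float
    aspect: float
    dent_depth: float
    wall_thickness_fraction: float
    rotation: float
    tilt_angle: float = 0.0
    tilt_direction: float = 0.0
    center: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        if self.outer_radius_um <= 0:
            raise SimulationError("outer_radius_um must be positive")
        if not 0 < self.aspect <= 1:
            raise SimulationError("aspect must be in (0, 1]")
        if not 0 <= self.dent_depth < 1:
            raise SimulationError("dent_depth must be in [0, 1)")
        if not 0 < self.wall_thickness_fraction < 1:
            raise SimulationError("wall_thickness_fraction must be in (0, 1)")
        if not 0 <= self.tilt_angle < math.pi / 2:
            raise SimulationError("tilt_angle must be in [0, π/2)")


@dataclass(frozen=True)
class PopulationParams:
    """Distribution a line's fibers are drawn from.

    Wall (true) areas are log-normal with the given mean and coefficient
    of variation; aspect, dent depth and wall-thickness fraction are
    uniform on their ranges; rotation is uniform on [0, 2π); tilt is
    uniform on [0, tilt_max_deg]. The defaults target the ranges healthy
    mature fibers occupy: mean wall area 130 μm², lumen/outer area
    fraction ≈ 0.1, and mean outer circularity ≈ 0.55.
    """

    mean_true_area_um2: float = 130.0
    true_area_cv: float = 0.2
    aspect_range: tuple[float, float] = (0.25, 0.35)
    dent_range: tuple[float, float] = (0.2, 0.6)
    wall_thickness_range: tuple[float, float] = (0.62, 0.72)
    tilt_max_deg: float = 6.0

    def __post_init__(self) -> None:
        if self.mean_true_area_um2 <= 0 or self.true_area_cv < 0:
            raise SimulationError("mean_true_area_um2 > 0 and true_area_cv ≥ 0 required")
        for name in ("aspect_range", "dent_range", "wall_thickness_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise SimulationError(f"{name} must be (low, high) with low ≤ high")
        if not 0 < self.aspect_range[0] and self.aspect_range[1] <= 1:
            raise SimulationError("aspect_range must lie in (0, 1]")
        if not (0 <= self.dent_range[0] and self.dent_range[1] < 1):
            raise SimulationError("dent_range must lie in [0, 1)")
        if not (0 < self.wall_thickness_range[0] and self.wall_thickness_range[1] < 1):
            raise SimulationError("wall_thickness_range must lie in (0, 1)")
        if not 0 <= self.tilt_max_deg < 90:
            raise SimulationError("tilt_max_deg must be in [0, 90)")


@dataclass(frozen=True)
class TrueFiber:
    """Ground truth for one rendered fiber."""

    params: FiberShapeParams
    outer: Contour
    lumen: Contour
    metrics: FiberMetrics
    letter: str
    good: bool = True
    defect: Optional[str] = None


@dataclass(frozen=True)
class SyntheticScene:
    """Rendered image plus exact per-fiber ground truth."""

    image_id: str
    image: np.ndarray
    truth: tuple[TrueFiber, ...]
    scale: CalibrationScale
    seed: int


def _unit_kidney(aspect: float, dent: float, n: int = _N_VERTICES) -> np.ndarray:
    """Unit-radius kidney polygon, long axis along x, dent on +y side."""
    phi = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    r_e = aspect / np.sqrt((aspect * np.cos(phi)) ** 2 + np.sin(phi) ** 2)
    f = np.where(np.sin(phi) > 0, 1.0 - dent * np.sin(phi) ** 2, 1.0)
    r = r_e * f
    return np.c_[r * np.cos(phi), r * np.sin(phi)]


def _poly_area(pts: np.ndarray) -> float:
    x, y = pts[:, 0], pts[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def unit_area_factor(aspect: float, dent: float) -> float:
    """Area of the unit-radius kidney; outer area = factor · r²."""
    return _poly_area(_unit_kidney(aspect, dent))


def sample_fiber_shape(rng: np.random.Generator, population: PopulationParams) -> FiberShapeParams:
    """Draw one fiber's geometry from a line's population.

    The outer radius is solved from the drawn wall area so that the
    polygon's exact wall area equals the draw: with lumen scale
    s = 1 − wall_thickness_fraction, A_true = A_outer·(1 − s²).
    """
    cv = population.true_area_cv
    if cv > 0:
        sigma2 = math.log1p(cv * cv)
        mu = math.log(population.mean_true_area_um2) - sigma2 / 2.0
        a_true = float(rng.lognormal(mu, math.sqrt(sigma2)))
    else:
        a_true = population.mean_true_area_um2
    aspect = float(rng.uniform(*population.aspect_range))
    dent = float(rng.uniform(*population.dent_range))
    wtf = float(rng.uniform(*population.wall_thickness_range))
    rotation = float(rng.uniform(0.0, 2.0 * math.pi))
    tilt = float(rng.uniform(0.0, math.radians(population.tilt_max_deg)))
    tilt_dir = float(rng.uniform(0.0, math.pi))
    lumen_scale = 1.0 - wtf
    a_outer = a_true / (1.0 - lumen_scale**2)
    radius = math.sqrt(a_outer / unit_area_factor(aspect, dent))
    return FiberShapeParams(
        outer_radius_um=radius,
        aspect=aspect,
        dent_depth=dent,
        wall_thickness_fraction=wtf,
        rotation=rotation,
        tilt_angle=tilt,
        tilt_direction=tilt_dir,
    )


def tilt_transform(contour: Contour, tilt_angle: float, direction: float = 0.0) -> Contour:
    """Apparent shape of a cross-section cut at ``tilt_angle`` off-axis.

    Anisotropic stretch by 1/cos(tilt) along ``direction`` (radians,
    in-plane), about the centroid; multiplies the polygon area by
    exactly 1/cos(tilt). tilt = 0 is the identity.
    """
    if not 0 <= tilt_angle < math.pi / 2:
        raise SimulationError("tilt_angle must be in [0, π/2)")
    if tilt_angle == 0:
        return contour
    stretch = 1.0 / math.cos(tilt_angle)
    u = np.array([math.cos(direction), math.sin(direction)])
    pts = contour.points
    c = pts.mean(axis=0)

    def fn(p: np.ndarray) -> np.ndarray:
        rel = p - c
        along = rel @ u
        return p + np.outer((stretch - 1.0) * along, u)

    return contour.transformed(fn)


def kidney_contours(
    params: FiberShapeParams, scale: CalibrationScale
) -> tuple[Contour, Contour]:
    """(outer, lumen) polygon contours in pixel coordinates.

    Applies, in order: unit shape → radial scale → rotation → oblique
    stretch → translation to ``center`` (μm → px via ``scale``).
    """
    base = _unit_kidney(params.aspect, params.dent_depth)
    lumen_scale = 1.0 - params.wall_thickness_fraction
    rot = params.rotation
    R = np.array([[math.cos(rot), math.sin(rot)], [-math.sin(rot), math.cos(rot)]])
    s = scale.um_per_px
    center_px = np.asarray(params.center) / s
    out: list[Contour] = []
    for shape_scale in (1.0, lumen_scale):
        pts = base * params.outer_radius_um * shape_scale / s
        pts = pts @ R
        c = Contour(pts, check_simple=False)
        if params.tilt_angle > 0:
            # stretch both boundaries about the *fiber* centroid so the
            # lumen stays concentric with the wall
            stretch = 1.0 / math.cos(params.tilt_angle)
            u = np.array([math.cos(params.tilt_direction), math.sin(params.tilt_direction)])

            def fn(p: np.ndarray, u=u, stretch=stretch) -> np.ndarray:
                along = p @ u
                return p + np.outer((stretch - 1.0) * along, u)

            c = c.transformed(fn)
        c = c.transformed(lambda p: p + center_px)
        out.append(c)
    return out[0], out[1]


def _bounding_radius_px(params: FiberShapeParams, scale: CalibrationScale) -> float:
    outer, _ = kidney_contours(
        FiberShapeParams(
            outer_radius_um=params.outer_radius_um,
            aspect=params.aspect,
            dent_depth=params.dent_depth,
            wall_thickness_fraction=params.wall_thickness_fraction,
            rotation=params.rotation,
            tilt_angle=params.tilt_angle,
            tilt_direction=params.tilt_direction,
            center=(0.0, 0.0),
        ),
        scale,
    )
    return float(np.hypot(outer.points[:, 0], outer.points[:, 1]).max())


def _place_fibers(
    rng: np.random.Generator,
    radii: Sequence[float],
    image_shape: tuple[int, int],
    margin_px: float,
    max_attempts: int,
) -> list[tuple[float, float]]:
    H, W = image_shape
    centers: list[tuple[float, float]] = []
    placed_r: list[float] = []
    for r in radii:
        lo_x, hi_x = r + margin_px, W - r - margin_px
        lo_y, hi_y = r + margin_px, H - r - margin_px
        if lo_x >= hi_x or lo_y >= hi_y:
            raise SimulationError(
                f"fiber of radius {r:.0f} px does not fit a {W}×{H} image; "
                "use a larger image or smaller fibers"
            )
        for _ in range(max_attempts):
            x = float(rng.uniform(lo_x, hi_x))
            y = float(rng.uniform(lo_y, hi_y))
            if all(
                (x - cx) ** 2 + (y - cy) ** 2 > (r + rr + margin_px) ** 2
                for (cx, cy), rr in zip(centers, placed_r)
            ):
                centers.append((x, y))
                placed_r.append(r)
                break
        else:
            raise SimulationError(
                f"could not place {len(radii)} fibers in a {W}×{H} image after "
                f"{max_attempts} attempts each; use fewer or smaller fibers"
            )
    return centers


def render_scene(
    params_list: Sequence[FiberShapeParams],
    image_shape: tuple[int, int],
    scale: CalibrationScale,
    noise_sigma: float = 6.0,
    seed: int = 0,
    background: float = 30.0,
    wall_intensity: float = 200.0,
    lumen_intensity: float = 30.0,
    n_streaks: int = 0,
    image_id: str = "sim_1_1_1",
    line: str = "",
    labels: Optional[Sequence[tuple[bool, Optional[str]]]] = None,
) -> SyntheticScene:
    """Rasterize placed fibers into an 8-bit image with exact truth.

    ``params_list`` must already carry non-overlapping centers (see
    :func:`simulate_scene` for sampling + placement). ``labels`` gives a
    (good, defect) tag per fiber, defaulting to all-good. Rendering is
    a pure function of its arguments: the same seed reproduces the
    scene bit-exactly.
    """
    H, W = image_shape
    rng = np.random.default_rng(seed)
    img = np.full((H, W), float(background))
    geoms: list[tuple[Contour, Contour]] = []
    for p in params_list:
        outer, lumen = kidney_contours(p, scale)
        rr, cc = _draw.polygon(outer.points[:, 1], outer.points[:, 0], (H, W))
        img[rr, cc] = wall_intensity
        rr, cc = _draw.polygon(lumen.points[:, 1], lumen.points[:, 0], (H, W))
        img[rr, cc] = lumen_intensity
        geoms.append((outer, lumen))
    for _ in range(n_streaks):
        # faint section-crease line: a 2–3 px bright streak across the frame
        theta = rng.uniform(0, math.pi)
        offset = rng.uniform(-0.4, 0.4) * math.hypot(H, W) / 2.0
        width = rng.uniform(2.0, 3.0)
        yy, xx = np.mgrid[0:H, 0:W]
        n_vec = (math.cos(theta), math.sin(theta))
        dist = (xx - W / 2.0) * n_vec[0] + (yy - H / 2.0) * n_vec[1] - offset
        img[np.abs(dist) < width / 2.0] += 25.0
    if noise_sigma > 0:
        img += rng.normal(0.0, noise_sigma, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    if labels is None:
        labels = [(True, None)] * len(params_list)
    boxes = []
    areas = []
    for outer, _ in geoms:
        lo = outer.points.min(axis=0)
        hi = outer.points.max(axis=0)
        boxes.append(
            BoundingBox(
                x=int(math.floor(lo[0])),
                y=int(math.floor(lo[1])),
                w=max(1, int(math.ceil(hi[0] - lo[0]))),
                h=max(1, int(math.ceil(hi[1] - lo[1]))),
            )
        )
        areas.append(outer.area_px())
    order = reading_order(boxes, areas)
    letters = candidate_letter_sequence(len(order))
    truth: list[TrueFiber] = []
    for letter, i in zip(letters, order):
        outer, lumen = geoms[i]
        metrics = derive_fiber_metrics(
            measure_shape(lumen, scale),
            measure_shape(outer, scale),
            name=f"{image_id}_{letter}",
            line=line,
        )
        good, defect = labels[i]
        truth.append(
            TrueFiber(
                params=params_list[i],
                outer=outer,
                lumen=lumen,
                metrics=metrics,
                letter=letter,
                good=good,
                defect=defect,
            )
        )
    return SyntheticScene(
        image_id=image_id, image=img, truth=tuple(truth), scale=scale, seed=seed
    )


#: Defect severity: folded fibers are extreme thin ribbons (outer
#: circularity below the plausible floor); oblique fibers are tilted so
#: their apparent outer area lands in [450, 600] μm², above any
#: plausible single-fiber area.
_FOLDED_ASPECT = (0.06, 0.10)
_FOLDED_DENT = (0.6, 0.85)
_OBLIQUE_APPARENT_AREA = (450.0, 600.0)


def _make_defective(
    rng: np.random.Generator, pop: PopulationParams, kind: str
) -> FiberShapeParams:
    base = sample_fiber_shape(rng, pop)
    if kind == "folded":
        aspect = float(rng.uniform(*_FOLDED_ASPECT))
        dent = float(rng.uniform(*_FOLDED_DENT))
        lumen_scale = 1.0 - base.wall_thickness_fraction
        a_outer = base.outer_radius_um**2 * unit_area_factor(base.aspect, base.dent_depth)
        radius = math.sqrt(a_outer / unit_area_factor(aspect, dent))
        return FiberShapeParams(
            outer_radius_um=radius,
            aspect=aspect,
            dent_depth=dent,
            wall_thickness_fraction=base.wall_thickness_fraction,
            rotation=base.rotation,
            tilt_angle=base.tilt_angle,
            tilt_direction=base.tilt_direction,
        )
    if kind == "oblique":
        a_outer = base.outer_radius_um**2 * unit_area_factor(base.aspect, base.dent_depth)
        target = float(rng.uniform(*_OBLIQUE_APPARENT_AREA))
        # apparent area = A_outer / cos(tilt); solve for the tilt that
        # lands on the target, capped at 80° for numerical sanity
        ratio = a_outer / target if a_outer < target else 1.0
        tilt = math.acos(max(ratio, math.cos(math.radians(80.0))))
        return FiberShapeParams(
            outer_radius_um=base.outer_radius_um,
            aspect=base.aspect,
            dent_depth=base.dent_depth,
            wall_thickness_fraction=base.wall_thickness_fraction,
            rotation=base.rotation,
            tilt_angle=tilt,
            tilt_direction=base.tilt_direction,
        )
    raise SimulationError(f"unknown defect kind {kind!r}")


def simulate_scene(
    n_fibers: int = 50,
    population: PopulationParams = PopulationParams(),
    bad_fraction: float = 0.1,
    seed: int = 0,
    scale: Optional[CalibrationScale] = None,
    image_shape: Optional[tuple[int, int]] = None,
    noise_sigma: float = 6.0,
    n_streaks: int = 1,
    margin_px: float = 8.0,
    max_attempts: int = 1500,
    image_id: str = "sim_1_1_1",
    line: str = "",
) -> SyntheticScene:
    """Sample, place and render one full scene.

    A fraction ``bad_fraction`` of fibers receive a quality defect,
    alternating between folded and oblique kinds. When ``image_shape``
    is omitted the canvas is sized so the fibers occupy roughly a third
    of it, which random sequential placement handles comfortably.
    """
    if n_fibers < 1:
        raise SimulationError("n_fibers must be ≥ 1")
    if not 0 <= bad_fraction < 1:
        raise SimulationError("bad_fraction must be in [0, 1)")
    if scale is None:
        scale = CalibrationScale.from_um_per_px(DEFAULT_UM_PER_PX)
    rng = np.random.default_rng(seed)
    n_bad = int(round(bad_fraction * n_fibers))
    kinds = ["folded" if i % 2 == 0 else "oblique" for i in range(n_bad)]
    shapes: list[FiberShapeParams] = []
    labels: list[tuple[bool, Optional[str]]] = []
    for i in range(n_fibers):
        if i < n_bad:
            shapes.append(_make_defective(rng, population, kinds[i]))
            labels.append((False, kinds[i]))
        else:
            shapes.append(sample_fiber_shape(rng, population))
            labels.append((True, None))
    radii = [_bounding_radius_px(p, scale) for p in shapes]
    if image_shape is None:
        # bounding circles at ~20% coverage: sparse enough for random
        # sequential placement to succeed essentially always
        blocked = sum(math.pi * (r + margin_px) ** 2 for r in radii)
        side = int(math.ceil(math.sqrt(blocked / 0.2)))
        side = max(side, int(2 * (max(radii) + margin_px) + 4))
        image_shape = (side, side)
    centers = _place_fibers(rng, radii, image_shape, margin_px, max_attempts)
    placed = [
        FiberShapeParams(
            outer_radius_um=p.outer_radius_um,
            aspect=p.aspect,
            dent_depth=p.dent_depth,
            wall_thickness_fraction=p.wall_thickness_fraction,
            rotation=p.rotation,
            tilt_angle=p.tilt_angle,
            tilt_direction=p.tilt_direction,
            center=(c[0] * scale.um_per_px, c[1] * scale.um_per_px),
        )
        for p, c in zip(shapes, centers)
    ]
    render_seed = int(rng.integers(2**31))
    return render_scene(
        placed,
        image_shape,
        scale,
        noise_sigma=noise_sigma,
        seed=render_seed,
        n_streaks=n_streaks,
        image_id=image_id,
        line=line,
        labels=labels,
    )


def simulate_experiment(
    lines: Mapping[str, PopulationParams],
    fibers_per_line: int = 100,
    fibers_per_scene: int = 25,
    seed: int = 0,
    bad_fraction: float = 0.0,
    **scene_kwargs,
) -> list[SyntheticScene]:
    """One multi-line study: several scenes per line, deterministic seeds."""
    master = np.random.default_rng(seed)
    scenes: list[SyntheticScene] = []
    for line, pop in lines.items():
        remaining = fibers_per_line
        k = 1
        while remaining > 0:
            n = min(fibers_per_scene, remaining)
            scene_seed = int(master.integers(2**31))
            scenes.append(
                simulate_scene(
                    n_fibers=n,
                    population=pop,
                    bad_fraction=bad_fraction,
                    seed=scene_seed,
                    image_id=f"{line}_1_1_{k}",
                    line=line,
                    **scene_kwargs,
                )
            )
            remaining -= n
            k += 1
    return scenes


def ground_truth_table(scene: SyntheticScene):
    """Exact canonical table plus a labels table for one scene.

    The canonical table is schema-identical to the pipeline's output so
    the two can be diffed row for row; labels carry the good/bad tag
    and defect kind per fiber.
    """
    import pandas as pd

    table = table_from_metrics([t.metrics for t in scene.truth])
    labels = pd.DataFrame(
        [
            {
                "Name": t.metrics.name,
                "letter": t.letter,
                "good": t.good,
                "defect": t.defect or "",
            }
            for t in scene.truth
        ],
        columns=["Name", "letter", "good", "defect"],
    )
    return table, labels
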