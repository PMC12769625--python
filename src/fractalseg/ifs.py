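"""Iterated function systems: category sampling, the chaos game, and rasterization.

An IFS is a finite family of planar affine maps ``w_i(x) = M_i x + t_i`` with
selection probabilities ``p_i``.  Repeatedly applying a randomly chosen map to a
point traces the attractor of the system; rendering the visited points produces a
fractal image.  A *category* is one sampled parameter set ``{(theta_i, p_i)}``;
*instances* of a category are obtained by scaling its parameters with a small
scalar weight and re-rendering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from numba import njit

__all__ = [
    "AffineParams",
    "IFSCategory",
    "PointSet",
    "RenderConfig",
    "FractalImage",
    "DegenerateCategoryError",
    "WEIGHT_GRID",
    "sample_category",
    "apply_affine",
    "chaos_game",
    "rasterize",
    "perturb_category",
    "is_degenerate",
    "render_category",
]

#: Instance weights: each affine parameter is multiplied by one of these scalars.
WEIGHT_GRID = (0.8, 0.9, 1.0, 1.1, 1.2)

#: Coordinates beyond this magnitude abort the chaos game (expansive system).
OVERFLOW_GUARD = 1.0e6


class DegenerateCategoryError(RuntimeError):
    """Raised when an IFS diverges or renders an unusable (empty/saturated) image."""


@dataclass(frozen=True)
class AffineParams:
    """One affine map ``[[a, b], [c, d]] x + [e, f]``.

    Sampled categories keep all six entries in [-1, 1]; instance weighting may
    push entries slightly outside that interval (up to the 1.2 weight).
    """

    a: float
    b: float
    c: float
    d: float
    e: float
    f: float

    def as_tuple(self) -> tuple[float, float, float, float, float, float]:
        return (self.a, self.b, self.c, self.d, self.e, self.f)

    def determinant(self) -> float:
        return self.a * self.d - self.b * self.c


@dataclass(frozen=True)
class IFSCategory:
    """A sampled IFS parameter set; its index doubles as the pretext pseudo-label."""

    transforms: tuple[AffineParams, ...]
    probabilities: tuple[float, ...]
    category_id: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.transforms) < 2:
            raise ValueError("an IFS category needs at least 2 transforms")
        if len(self.probabilities) != len(self.transforms):
            raise ValueError("probabilities and transforms length mismatch")
        p = np.asarray(self.probabilities, dtype=float)
        if np.any(p < 0):
            raise ValueError("selection probabilities must be nonnegative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("selection probabilities must sum to 1 (within 1e-12)")
        if self.category_id < 0:
            raise ValueError("category_id must be >= 0")

    @property
    def n_transforms(self) -> int:
        return len(self.transforms)

    def coefficient_matrix(self) -> np.ndarray:
        """(N, 6) array of the a..f entries, one row per transform."""
        return np.array([t.as_tuple() for t in self.transforms], dtype=float)


@dataclass(frozen=True)
class PointSet:
    """Chaos-game trajectory in abstract IFS coordinates (burn-in already removed)."""

    points: np.ndarray  # (n, 2) float64
    burn_in: int

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.points)):
            raise ValueError("retained chaos-game points must be finite")


@dataclass(frozen=True)
class RenderConfig:
    """Rendering knobs.

    ``n_points`` counts *applied transformations*; the full-scale profile uses
    200,000 per image, the desk-scale default 20,000.  The first ``burn_in``
    points are transient and discarded before rasterization.
    """

    n_points: int = 20_000
    image_side: int = 64
    point_radius: int = 1
    burn_in: int = 100
    normalize_bbox: bool = True

    def __post_init__(self) -> None:
        if not (self.n_points > self.burn_in >= 0):
            raise ValueError("need n_points > burn_in >= 0")
        if self.image_side < 8:
            raise ValueError("image_side must be >= 8")
        if self.point_radius < 0:
            raise ValueError("point_radius must be >= 0")


@dataclass(frozen=True)
class FractalImage:
    """Rendered 8-bit grayscale raster plus its dataset bookkeeping."""

    pixels: np.ndarray  # (side, side) uint8
    category_id: int
    instance_weight: float = 1.0
    seed: int = 0


def apply_affine(point: tuple[float, float], params: AffineParams) -> tuple[float, float]:
    """Apply ``[[a, b], [c, d]] x + [e, f]`` to a single point."""
    x, y = point
    if not (math.isfinite(x) and math.isfinite(y)):
        raise ValueError("apply_affine requires finite input coordinates")
    return (
        params.a * x + params.b * y + params.e,
        params.c * x + params.d * y + params.f,
    )


@njit(cache=False)
def _chaos_loop(coeffs, indices, guard):  # pragma: no cover - compiled
    n = indices.shape[0]
    pts = np.empty((n, 2), dtype=np.float64)
    x = 0.0
    y = 0.0
    for t in range(n):
        i = indices[t]
        xn = coeffs[i, 0] * x + coeffs[i, 1] * y + coeffs[i, 4]
        yn = coeffs[i, 2] * x + coeffs[i, 3] * y + coeffs[i, 5]
        if abs(xn) > guard or abs(yn) > guard:
            return pts, t
        pts[t, 0] = xn
        pts[t, 1] = yn
        x = xn
        y = yn
    return pts, -1


def chaos_game(category: IFSCategory, config: RenderConfig, seed: int) -> PointSet:
    """Run the chaos game: start at (0, 0), repeatedly apply a randomly selected map.

    Transform indices are drawn from ``numpy.random.default_rng(seed)`` with the
    category's selection probabilities, so the trajectory is a pure function of
    (category, config, seed).  Raises :class:`DegenerateCategoryError` if a
    coordinate exceeds the overflow guard (expansive parameter draw).
    """
    rng = np.random.default_rng(seed)
    indices = rng.choice(
        category.n_transforms, size=config.n_points, p=np.asarray(category.probabilities)
    ).astype(np.int64)
    coeffs = category.coefficient_matrix()
    pts, failed_at = _chaos_loop(coeffs, indices, OVERFLOW_GUARD)
    if failed_at >= 0:
        raise DegenerateCategoryError(
            f"chaos game diverged at step {failed_at} (category {category.category_id})"
        )
    return PointSet(points=pts[config.burn_in :], burn_in=config.burn_in)


_DISC_CACHE: dict[int, np.ndarray] = {}


def _disc_offsets(radius: int) -> np.ndarray:
    if radius not in _DISC_CACHE:
        r = np.arange(-radius, radius + 1)
        dy, dx = np.meshgrid(r, r, indexing="ij")
        keep = dy**2 + dx**2 <= radius**2
        _DISC_CACHE[radius] = np.stack([dy[keep], dx[keep]], axis=1)
    return _DISC_CACHE[radius]


def rasterize(points: PointSet, config: RenderConfig) -> FractalImage:
    """Stamp the trajectory onto a square raster.

    With ``normalize_bbox`` the point cloud's bounding box is mapped affinely onto
    the full image extent (aspect preserved per-axis, as is conventional for
    fractal-database rendering); each point lights a disc of ``point_radius``
    pixels with value 255 on a zero background.
    """
    pts = points.points
    if pts.shape[0] == 0:
        raise DegenerateCategoryError("empty point set after burn-in")
    side = config.image_side
    if config.normalize_bbox:
        lo = pts.min(axis=0)
        hi = pts.max(axis=0)
        span = np.where(hi - lo < 1e-12, 1.0, hi - lo)
        unit = (pts - lo) / span
    else:
        unit = np.clip((pts + 1.0) / 2.0, 0.0, 1.0)
    cols = np.minimum((unit[:, 0] * side).astype(np.int64), side - 1)
    rows = np.minimum(((1.0 - unit[:, 1]) * side).astype(np.int64), side - 1)
    img = np.zeros((side, side), dtype=bool)
    img[rows, cols] = True
    if config.point_radius > 0:
        off = _disc_offsets(config.point_radius)
        rr, cc = np.nonzero(img)
        r2 = np.clip(rr[:, None] + off[None, :, 0], 0, side - 1).ravel()
        c2 = np.clip(cc[:, None] + off[None, :, 1], 0, side - 1).ravel()
        img[r2, c2] = True
    return FractalImage(
        pixels=img.astype(np.uint8) * np.uint8(255),
        category_id=-1,
        instance_weight=1.0,
        seed=-1,
    )


def perturb_category(category: IFSCategory, weight: float) -> IFSCategory:
    """Scale all six affine parameters of every transform by one instance weight.

    Only the grid 0.8, 0.9, 1.0, 1.1, 1.2 is accepted; probabilities and the
    pseudo-label are preserved.
    """
    if not any(abs(weight - w) < 1e-9 for w in WEIGHT_GRID):
        raise ValueError(f"instance weight {weight} not in grid {WEIGHT_GRID}")
    scaled = tuple(
        AffineParams(*(weight * v for v in t.as_tuple())) for t in category.transforms
    )
    return replace(category, transforms=scaled)


def is_degenerate(image: FractalImage, min_fill: float = 0.002, max_fill: float = 0.95) -> bool:
    """True when the lit-pixel fraction falls outside [min_fill, max_fill]."""
    if not (0 <= min_fill < max_fill <= 1):
        raise ValueError("need 0 <= min_fill < max_fill <= 1")
    fill = np.count_nonzero(image.pixels) / image.pixels.size
    return fill < min_fill or fill > max_fill


#: Probe render used when screening candidate categories: cheap but dense enough
#: for the fill-fraction filter to be meaningful.
PROBE_CONFIG = RenderConfig(n_points=3_000, image_side=64, point_radius=1, burn_in=100)


def _draw_category(rng: np.random.Generator, n_range: tuple[int, int], category_id: int,
                   seed: int) -> IFSCategory:
    n = int(rng.integers(n_range[0], n_range[1] + 1))
    coeffs = rng.uniform(-1.0, 1.0, size=(n, 6))
    dets = np.abs(coeffs[:, 0] * coeffs[:, 3] - coeffs[:, 1] * coeffs[:, 2])
    if dets.sum() < 1e-12:
        p = np.full(n, 1.0 / n)
    else:
        p = dets / dets.sum()
    # exact renormalization so the sum is 1 to the last ulp
    p = p / p.sum()
    transforms = tuple(AffineParams(*(float(v) for v in row)) for row in coeffs)
    return IFSCategory(transforms=transforms, probabilities=tuple(float(x) for x in p),
                       category_id=category_id, seed=seed)


def sample_category(
    seed: int,
    n_range: tuple[int, int] = (2, 8),
    max_rejects: int = 200,
    category_id: int = 0,
    probe: RenderConfig = PROBE_CONFIG,
    min_fill: float = 0.002,
    max_fill: float = 0.95,
) -> IFSCategory:
    """Sample one fractal category.

    The number of maps N is uniform on ``n_range`` (a sub-interval of [2, 8]);
    all six affine entries are uniform on [-1, 1]; selection probabilities are
    proportional to |det| of each map's linear part (uniform fallback when all
    determinants vanish) and sum to 1.  A candidate is probe-rendered and
    rejected if it diverges or its image is degenerate; sampling then continues
    on the same seeded stream, so the result is deterministic in ``seed``.
    """
    if seed < 0:
        raise ValueError("seed must be >= 0")
    if not (2 <= n_range[0] <= n_range[1] <= 8):
        raise ValueError("n_range must be within [2, 8]")
    rng = np.random.default_rng(seed)
    for attempt in range(max_rejects + 1):
        cand = _draw_category(rng, n_range, category_id, seed)
        try:
            pts = chaos_game(cand, probe, seed=int(rng.integers(0, 2**31 - 1)))
            img = rasterize(pts, probe)
        except DegenerateCategoryError:
            continue
        if not is_degenerate(img, min_fill, max_fill):
            return cand
    raise DegenerateCategoryError(
        f"exhausted {max_rejects} rejects sampling category (seed={seed})"
    )


def render_category(
    category: IFSCategory,
    config: RenderConfig,
    seed: int,
    weight: float = 1.0,
) -> FractalImage:
    """Perturb a category by an instance weight, run the chaos game, rasterize."""
    inst = perturb_category(category, weight) if weight != 1.0 else category
    pts = chaos_game(inst, config, seed)
    img = rasterize(pts, config)
    return FractalImage(
        pixels=img.pixels,
        category_id=category.category_id,
        instance_weight=weight,
        seed=seed,
    )
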