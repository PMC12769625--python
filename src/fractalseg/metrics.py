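"""Contour agreement metrics and the paired statistical comparison.

Implements the volumetric Dice coefficient (vDSC), the surface Dice coefficient
(sDSC) at a tolerance tau in mm, the 95th-percentile Hausdorff distance (HD95),
and the surface-to-volume ratio (SVR) used as a shape-complexity index, plus the
Friedman / Wilcoxon-Holm comparison used to rank training strategies.

Surfaces are represented as the centers of exposed voxel faces (a face between a
foreground voxel and a background or out-of-bounds voxel), expressed in mm via
the voxel spacing.  This representation is integer-exact and deterministic; no
mesher is involved.  The same face enumeration yields the surface area for SVR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree
from statsmodels.stats.multitest import multipletests

__all__ = [
    "BinaryVolume", "SurfaceCloud", "CaseMetrics",
    "vdsc", "extract_surface", "sdsc", "hd95", "svr",
    "median_split_by_svr", "friedman_across_strategies", "pairwise_wilcoxon_holm",
    "evaluate_case",
]


@dataclass(frozen=True)
class BinaryVolume:
    """A binary voxel volume with physical spacing in mm (row, col, slice)."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels)
        if not np.isin(v, (0, 1)).all():
            raise ValueError("voxels must be binary")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be strictly positive")

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def count(self) -> int:
        return int(np.asarray(self.voxels).sum())


@dataclass(frozen=True)
class SurfaceCloud:
    """Exposed-face centers in mm plus the total exposed face area in mm^2."""

    points: np.ndarray  # (M, 3)
    total_area: float


@dataclass(frozen=True)
class CaseMetrics:
    case_id: str
    strategy: str
    vdsc: float
    sdsc: float
    hd95: float
    svr: float


def _check_pair(A: BinaryVolume, B: BinaryVolume) -> None:
    if np.asarray(A.voxels).shape != np.asarray(B.voxels).shape:
        raise ValueError("volume shapes differ")
    if not np.allclose(A.spacing, B.spacing):
        raise ValueError("volume spacings differ")


def vdsc(A: BinaryVolume, B: BinaryVolume) -> float:
    """Volumetric Dice: 2|A∩B| / (|A|+|B|).  Both empty -> 1.0 by convention."""
    _check_pair(A, B)
    a = np.asarray(A.voxels, dtype=bool)
    b = np.asarray(B.voxels, dtype=bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(a, b).sum() / denom)


def extract_surface(V: BinaryVolume) -> SurfaceCloud:
    """Enumerate exposed voxel faces.

    For each axis and direction, a foreground voxel whose 6-neighbour is
    background (or out of bounds) exposes one face; the face center sits half a
    voxel off the voxel center along that axis, and its area is the product of
    the other two spacings.
    """
    vox = np.asarray(V.voxels, dtype=bool)
    if not vox.any():
        raise ValueError("cannot extract a surface from an empty volume")
    sp = np.asarray(V.spacing, dtype=float)
    pts = []
    area = 0.0
    padded = np.pad(vox, 1, constant_values=False)
    for axis in range(3):
        face_area = float(np.prod(np.delete(sp, axis)))
        for sign in (-1, +1):
            neigh = np.roll(padded, -sign, axis=axis)[1:-1, 1:-1, 1:-1]
            exposed = vox & ~neigh
            idx = np.argwhere(exposed).astype(float)
            if idx.size:
                centers = idx * sp
                centers[:, axis] += sign * sp[axis] / 2.0
                pts.append(centers)
                area += face_area * idx.shape[0]
    return SurfaceCloud(points=np.concatenate(pts, axis=0), total_area=area)


def _directed_nn(src: np.ndarray, dst: np.ndarray) -> np.ndarray:
    return cKDTree(dst).query(src, k=1)[0]


def sdsc(A: BinaryVolume, B: BinaryVolume, tau: float = 1.0) -> float:
    """Surface Dice at tolerance tau mm: (|S_A^tau| + |S_B^tau|) / (|S_A| + |S_B|).

    A surface point "matches" when its nearest-neighbour distance to the other
    surface is <= tau.
    """
    if tau <= 0:
        raise ValueError("tau must be > 0")
    _check_pair(A, B)
    sa = extract_surface(A).points
    sb = extract_surface(B).points
    matched = (_directed_nn(sa, sb) <= tau).sum() + (_directed_nn(sb, sa) <= tau).sum()
    return float(matched / (len(sa) + len(sb)))


def hd95(A: BinaryVolume, B: BinaryVolume) -> float:
    """95th percentile (nearest-rank) of pooled bidirectional surface distances."""
    _check_pair(A, B)
    sa = extract_surface(A).points
    sb = extract_surface(B).points
    pooled = np.concatenate([_directed_nn(sa, sb), _directed_nn(sb, sa)])
    return nearest_rank_percentile(pooled, 95.0)


def nearest_rank_percentile(values: np.ndarray, q: float) -> float:
    """Nearest-rank percentile: the ceil(q/100 * n)-th smallest value."""
    v = np.sort(np.asarray(values, dtype=float))
    if v.size == 0:
        raise ValueError("empty distance multiset")
    rank = int(np.ceil(q / 100.0 * v.size))
    return float(v[max(rank, 1) - 1])


def svr(V: BinaryVolume) -> float:
    """Surface-to-volume ratio in 1/mm: exposed face area / voxelized volume."""
    cloud = extract_surface(V)
    return float(cloud.total_area / (V.count() * V.voxel_volume))


def median_split_by_svr(cases: list[CaseMetrics]) -> tuple[list[CaseMetrics], list[CaseMetrics]]:
    """Split cases into (simple, complex) halves by ascending SVR.

    Ties break by case_id; for odd n the median case goes to the simple group.
    """
    if len(cases) < 2:
        raise ValueError("need at least 2 cases to split")
    ordered = sorted(cases, key=lambda c: (c.svr, c.case_id))
    half = (len(ordered) + 1) // 2
    return ordered[:half], ordered[half:]


def friedman_across_strategies(matrix: np.ndarray) -> tuple[float, float]:
    """Friedman chi-square over within-case ranks of a (cases x strategies) matrix.

    Average ranks with the standard tie correction (matching scipy's convention
    for k >= 3; implemented directly so paired two-strategy designs are also
    accepted).  Returns (statistic, p) with p from chi-square with k-1 df.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need a (cases >= 2) x (strategies >= 2) matrix")
    if not np.isfinite(X).all():
        raise ValueError("metric matrix must be finite (paired, no missing cases)")
    n, k = X.shape
    ranks = np.apply_along_axis(stats.rankdata, 1, X)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction (Conover): divide by 1 - sum(t^3 - t) / (n k (k^2 - 1))
    ties = 0.0
    for row in X:
        _, counts = np.unique(row, return_counts=True)
        ties += float(np.sum(counts**3 - counts))
    denom = 1.0 - ties / (n * k * (k**2 - 1.0))
    if denom <= 0:
        return 0.0, 1.0  # every row fully tied
    stat /= denom
    p = float(stats.chi2.sf(stat, df=k - 1))
    return float(stat), p


def _safe_wilcoxon(x: np.ndarray, y: np.ndarray) -> float:
    diff = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(diff == 0):
        return 1.0
    return float(stats.wilcoxon(x, y, alternative="two-sided").pvalue)


def pairwise_wilcoxon_holm(
    matrix: np.ndarray,
    strategy_names: list[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-sided Wilcoxon signed-rank on every strategy pair with Holm correction.

    Callers are expected to gate on a significant Friedman test first (the
    pipeline enforces that ordering).  Returns a table of pair, raw p, Holm-
    adjusted p, and a significance flag at ``alpha``.
    """
    X = np.asarray(matrix, dtype=float)
    n, k = X.shape
    names = strategy_names or [f"s{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError("strategy_names length mismatch")
    pairs = [(i, j) for i in range(k) for j in range(i + 1, k)]
    raw = [_safe_wilcoxon(X[:, i], X[:, j]) for i, j in pairs]
    reject, adjusted, _, _ = multipletests(raw, alpha=alpha, method="holm")
    return pd.DataFrame({
        "pair": [f"{names[i]} vs {names[j]}" for i, j in pairs],
        "p_raw": raw,
        "p_holm": adjusted,
        "significant": reject,
    })


def evaluate_case(
    case_id: str,
    strategy: str,
    pred: BinaryVolume,
    truth: BinaryVolume,
    tau: float = 1.0,
    hd95_empty: float = np.inf,
) -> CaseMetrics:
    """All four per-case numbers for one (case, strategy).

    An empty prediction gets vDSC 0, sDSC 0 and ``hd95_empty`` (default inf) for
    HD95, since surface distances are undefined against an empty surface.
    """
    if pred.count() == 0:
        return CaseMetrics(case_id, strategy, 0.0, 0.0, float(hd95_empty),
                           svr(truth))
    return CaseMetrics(
        case_id=case_id,
        strategy=strategy,
        vdsc=vdsc(pred, truth),
        sdsc=sdsc(pred, truth, tau),
        hd95=hd95(pred, truth),
        svr=svr(truth),
    )
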