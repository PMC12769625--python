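"""ROI preprocessing: slice selection, centroid-centered cropping, resizing,
and intensity normalization.

The tumor occupies a tiny fraction of a planning CT, so training operates on a
64 x 64 pixel window (68.736 x 68.736 mm at 1.074 mm pitch) centered on the 3D
GTV centroid.  One window is shared by all slices of a case — a per-slice
centroid would jitter the crop from slice to slice.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantom import PhantomCase

__all__ = ["ROIPair", "select_slices", "gtv_centroid", "crop_roi",
           "resize_nearest", "normalize_intensity", "prepare_case", "CaseROIs"]

ROI_SIDE = 64
DEFAULT_HU_WINDOW = (-1000.0, 200.0)


@dataclass(frozen=True)
class ROIPair:
    """One 64x64 image/mask pair cut from a single axial slice."""

    image: np.ndarray
    mask: np.ndarray
    case_id: str
    slice_idx: int
    pixel_spacing: tuple[float, float]

    def __post_init__(self) -> None:
        if self.image.shape != self.mask.shape:
            raise ValueError("image and mask shapes differ")
        if not np.isin(self.mask, (0, 1)).all():
            raise ValueError("mask must be binary")


def select_slices(case: PhantomCase) -> list[int]:
    """Indices of axial slices with nonempty GTV, ascending."""
    per_slice = case.gtv.sum(axis=(0, 1))
    if per_slice.sum() == 0:
        raise ValueError(f"case {case.case_id} has an empty GTV")
    return [int(i) for i in np.nonzero(per_slice)[0]]


def gtv_centroid(mask_3d: np.ndarray) -> tuple[float, float]:
    """In-plane (row, col) of the 3D voxel-count centroid of the GTV."""
    rows, cols, _ = np.nonzero(mask_3d)
    if rows.size == 0:
        raise ValueError("empty GTV")
    return float(rows.mean()), float(cols.mean())


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def crop_roi(
    image_2d: np.ndarray,
    mask_2d: np.ndarray,
    centroid: tuple[float, float],
    case_id: str = "",
    slice_idx: int = 0,
    pixel_spacing: tuple[float, float] = (1.074, 1.074),
    side: int = ROI_SIDE,
    pad_value: float = -1000.0,
) -> ROIPair:
    """Cut a ``side x side`` window centered on the (rounded) centroid.

    The window is half-open, [r-side/2, r+side/2) x [c-side/2, c+side/2), so the
    centroid lands on pixel (side/2, side/2).  Out-of-bounds image regions are
    padded with background HU, the mask with 0.
    """
    half = side // 2
    r0 = _round_half_up(centroid[0]) - half
    c0 = _round_half_up(centroid[1]) - half
    img_out = np.full((side, side), pad_value, dtype=np.float64)
    msk_out = np.zeros((side, side), dtype=np.uint8)
    H, W = image_2d.shape
    rs, re = max(r0, 0), min(r0 + side, H)
    cs, ce = max(c0, 0), min(c0 + side, W)
    if rs < re and cs < ce:
        img_out[rs - r0 : re - r0, cs - c0 : ce - c0] = image_2d[rs:re, cs:ce]
        msk_out[rs - r0 : re - r0, cs - c0 : ce - c0] = mask_2d[rs:re, cs:ce]
    return ROIPair(image=img_out, mask=msk_out, case_id=case_id,
                   slice_idx=slice_idx, pixel_spacing=pixel_spacing)


def resize_nearest(patch: np.ndarray, target_side: int) -> np.ndarray:
    """Nearest-neighbour resampling to ``target_side`` square.

    Introduces no new intensity values, so binary masks stay binary, and
    up-then-down by an integer factor is an exact round trip.
    """
    if target_side < 2:
        raise ValueError("target_side must be >= 2")
    src = patch.shape[0]
    idx = np.floor((np.arange(target_side) + 0.5) * src / target_side).astype(int)
    idx = np.clip(idx, 0, src - 1)
    return patch[np.ix_(idx, idx)]


def normalize_intensity(patch: np.ndarray, window: tuple[float, float] = DEFAULT_HU_WINDOW) -> np.ndarray:
    """Clamp to the HU window then min-max scale to [0, 1]."""
    lo, hi = window
    if not lo < hi:
        raise ValueError("window must satisfy lo < hi")
    return (np.clip(patch, lo, hi) - lo) / (hi - lo)


@dataclass(frozen=True)
class CaseROIs:
    """All ROI pairs of one case plus the geometry needed to stack them back
    into a 3D volume for per-case metric computation."""

    case_id: str
    pairs: tuple[ROIPair, ...]
    slice_spacing: float

    @property
    def images(self) -> np.ndarray:
        return np.stack([p.image for p in self.pairs])

    @property
    def masks(self) -> np.ndarray:
        return np.stack([p.mask for p in self.pairs])

    @property
    def spacing3d(self) -> tuple[float, float, float]:
        ps = self.pairs[0].pixel_spacing
        return (ps[0], ps[1], self.slice_spacing)


def prepare_case(
    case: PhantomCase,
    window: tuple[float, float] = DEFAULT_HU_WINDOW,
    side: int = ROI_SIDE,
) -> CaseROIs:
    """Full preprocessing for one case: select slices, crop at the shared 3D
    centroid, window/normalize intensities."""
    centroid = gtv_centroid(case.gtv)
    pairs = []
    for z in select_slices(case):
        pair = crop_roi(case.ct[:, :, z], case.gtv[:, :, z], centroid,
                        case_id=case.case_id, slice_idx=z,
                        pixel_spacing=(case.spacing[0], case.spacing[1]),
                        side=side, pad_value=window[0])
        pairs.append(ROIPair(image=normalize_intensity(pair.image, window),
                             mask=pair.mask, case_id=pair.case_id,
                             slice_idx=pair.slice_idx,
                             pixel_spacing=pair.pixel_spacing))
    return CaseROIs(case_id=case.case_id, pairs=tuple(pairs),
                    slice_spacing=case.spacing[2])


def save_rois(rois: list[CaseROIs], out_dir: str | Path) -> None:
    """Cache prepared ROIs as NPZ arrays with a JSON index."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index = []
    for cr in rois:
        np.savez(out / f"{cr.case_id}.npz", images=cr.images, masks=cr.masks,
                 slices=np.array([p.slice_idx for p in cr.pairs]))
        index.append({"case_id": cr.case_id,
                      "n_slices": len(cr.pairs),
                      "pixel_spacing": list(cr.pairs[0].pixel_spacing),
                      "slice_spacing": cr.slice_spacing})
    (out / "index.json").write_text(json.dumps(index, indent=1))
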