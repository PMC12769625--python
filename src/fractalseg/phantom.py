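"""Synthetic CT phantom cohort: 3D HU volumes with binary tumor masks.

Clinical gross-tumor-volume (GTV) datasets are private, so experiments here run
on a generated cohort: each case is a star-convex blob whose radius field is a
base radius modulated by band-limited angular noise.  The modulation amplitude
(``complexity_amp``) controls boundary intricacy and therefore the
surface-to-volume ratio (SVR), which is the shape-complexity index used for
subgroup splitting.  Voxel spacing defaults to the planning-CT geometry the
pipeline assumes downstream: 1.074 x 1.074 mm in-plane, 2.0 mm slices.

The generator makes no claim of anatomical realism (no vessels, no chest wall);
it exists so that every stage of the pipeline — cropping, training, contour
metrics, statistics — can be exercised end to end with controllable shape
complexity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.special import sph_harm_y

__all__ = ["PhantomConfig", "PhantomCase", "make_tumor_mask", "render_ct",
           "generate_cohort", "load_cohort"]


@dataclass(frozen=True)
class PhantomConfig:
    n_cases: int = 104
    spacing: tuple[float, float, float] = (1.074, 1.074, 2.0)  # (row, col, slice) mm
    volume_shape: tuple[int, int, int] = (96, 96, 40)  # (rows, cols, slices)
    radius_range: tuple[float, float] = (7.0, 20.0)  # mm
    complexity_range: tuple[float, float] = (0.0, 0.6)
    hu_lung: float = -800.0
    hu_tumor: float = 20.0
    noise_sd: float = 40.0
    seed: int = 0

    def __post_init__(self) -> None:
        r_max = self.radius_range[1] * (1.0 + self.complexity_range[1])
        crop_half = 32 * min(self.spacing[0], self.spacing[1])
        if r_max > crop_half:
            raise ValueError(
                f"max tumor radius {r_max:.1f} mm exceeds the 64-pixel crop "
                f"half-extent {crop_half:.1f} mm"
            )


@dataclass(frozen=True)
class PhantomCase:
    case_id: str
    ct: np.ndarray  # (rows, cols, slices) float32 HU
    gtv: np.ndarray  # same shape, uint8 in {0, 1}
    spacing: tuple[float, float, float]
    true_complexity: float

    def __post_init__(self) -> None:
        if self.ct.shape != self.gtv.shape:
            raise ValueError("ct and gtv shapes differ")
        if self.gtv.sum() == 0:
            raise ValueError("gtv mask is empty")


def _angular_field(seed: int, orders: tuple[int, int] = (2, 8)):
    """Band-limited real angular noise field on the sphere, max |F| = 1, zero mean.

    One spherical harmonic per order l in [orders], random m and coefficient; all
    l >= 1 harmonics integrate to zero over the sphere, so the field is zero-mean
    by construction.  Returns a callable F(theta, phi).
    """
    rng = np.random.default_rng(seed)
    terms = []
    for ell in range(orders[0], orders[1] + 1):
        m = int(rng.integers(0, ell + 1))
        coef = rng.normal()
        phase = rng.uniform(0, 2 * np.pi)
        terms.append((ell, m, coef, phase))

    def raw(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        out = np.zeros(np.broadcast(theta, phi).shape)
        for ell, m, coef, phase in terms:
            y = sph_harm_y(ell, m, theta, phi + phase)
            out = out + coef * np.real(y)
        return out

    # normalize to unit max amplitude on a dense direction grid
    tg, pg = np.meshgrid(np.linspace(0, np.pi, 91), np.linspace(0, 2 * np.pi, 181),
                         indexing="ij")
    scale = np.abs(raw(tg, pg)).max()
    if scale < 1e-12:
        scale = 1.0

    def F(theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
        return raw(theta, phi) / scale

    return F


def make_tumor_mask(
    seed: int,
    base_radius_mm: float,
    complexity_amp: float,
    spacing: tuple[float, float, float],
    shape: tuple[int, int, int],
) -> np.ndarray:
    """Voxelize a star-convex blob: inside iff r <= R0 * (1 + amp * F(direction)).

    F is a seeded band-limited angular noise field with zero mean and unit max
    amplitude, so ``amp = 0`` gives a sphere and larger amplitudes give more
    intricate (higher-SVR) boundaries.  Star-convexity about the center
    guarantees a single connected component.
    """
    if not (0.0 <= complexity_amp <= 1.0):
        raise ValueError("complexity_amp must lie in [0, 1]")
    if base_radius_mm < 3.0 * max(spacing):
        raise ValueError("base radius must be at least 3 voxels in every direction")
    sp = np.asarray(spacing, dtype=float)
    center = (np.asarray(shape) - 1) / 2.0 * sp
    axes = [np.arange(n) * s - c for n, s, c in zip(shape, sp, center)]
    X, Y, Z = np.meshgrid(*axes, indexing="ij")
    r = np.sqrt(X**2 + Y**2 + Z**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.arccos(np.clip(np.where(r > 0, Z / np.where(r > 0, r, 1.0), 0.0),
                                  -1.0, 1.0))
    phi = np.mod(np.arctan2(Y, X), 2 * np.pi)
    radius_field = base_radius_mm * (
        1.0 + complexity_amp * _angular_field(seed)(theta, phi)
    )
    mask = (r <= radius_field).astype(np.uint8)
    if mask.sum() == 0:
        raise ValueError("parameters produced an empty mask")
    if (mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any()
            or mask[:, :, 0].any() or mask[:, :, -1].any()):
        raise ValueError("mask touches the volume boundary (clipped tumor)")
    n_comp = ndimage.label(mask)[1]
    if n_comp != 1:  # unreachable for star-convex fields; kept as a hard guarantee
        raise ValueError(f"mask has {n_comp} connected components")
    return mask


def render_ct(mask: np.ndarray, config: PhantomConfig, seed: int) -> np.ndarray:
    """CT-like rendering: two HU plateaus, 1-voxel Gaussian boundary blur, noise."""
    alpha = ndimage.gaussian_filter(mask.astype(np.float32), sigma=1.0)
    ct = config.hu_lung + (config.hu_tumor - config.hu_lung) * alpha
    if config.noise_sd > 0:
        rng = np.random.default_rng(seed)
        ct = ct + rng.normal(0.0, config.noise_sd, size=ct.shape)
    return ct.astype(np.float32)


def _case_seed(base: int, idx: int) -> int:
    return int(np.random.SeedSequence([base, idx]).generate_state(1)[0] % (2**31 - 1))


def generate_cohort(
    config: PhantomConfig, out_dir: str | Path | None = None
) -> list[PhantomCase]:
    """Generate ``n_cases`` phantom cases spanning the radius and complexity ranges.

    Radii and complexities are stratified across the configured ranges so every
    cohort spans the full complexity spectrum (needed for a meaningful
    simple/complex SVR split).  With ``out_dir`` set, writes
    ``<case_id>_ct.nii.gz`` / ``<case_id>_gtv.nii.gz`` pairs plus ``cohort.csv``.
    """
    from .metrics import BinaryVolume, svr  # local import; metrics also imports nothing from here

    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    # stratified draws: shuffle a low-discrepancy grid over each range
    radii = np.linspace(*config.radius_range, n)[rng.permutation(n)]
    amps = np.linspace(*config.complexity_range, n)[rng.permutation(n)]
    cases: list[PhantomCase] = []
    rows = []
    voxel_cc = float(np.prod(config.spacing)) / 1000.0
    for i in range(n):
        case_id = f"case{i:03d}"
        seed = _case_seed(config.seed, i)
        try:
            gtv = make_tumor_mask(seed, float(radii[i]), float(amps[i]),
                                  config.spacing, config.volume_shape)
            ct = render_ct(gtv, config, seed=_case_seed(seed, 1))
        except ValueError as err:
            raise RuntimeError(f"phantom generation failed for {case_id}: {err}") from err
        case = PhantomCase(case_id=case_id, ct=ct, gtv=gtv, spacing=config.spacing,
                           true_complexity=float(amps[i]))
        cases.append(case)
        rows.append({
            "case_id": case_id,
            "radius_mm": float(radii[i]),
            "complexity_amp": float(amps[i]),
            "gtv_volume_cc": float(gtv.sum()) * voxel_cc,
            "svr": svr(BinaryVolume(gtv, config.spacing)),
        })
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        affine = np.diag([*config.spacing, 1.0])
        for case in cases:
            nib.save(nib.Nifti1Image(case.ct, affine), out / f"{case.case_id}_ct.nii.gz")
            nib.save(nib.Nifti1Image(case.gtv.astype(np.uint8), affine),
                     out / f"{case.case_id}_gtv.nii.gz")
        pd.DataFrame(rows).to_csv(out / "cohort.csv", index=False)
    return cases


def load_cohort(cohort_dir: str | Path) -> list[PhantomCase]:
    """Read a cohort written by :func:`generate_cohort` back from NIfTI."""
    out = Path(cohort_dir)
    index = pd.read_csv(out / "cohort.csv")
    cases = []
    for _, row in index.iterrows():
        cid = row["case_id"]
        ct_img = nib.load(out / f"{cid}_ct.nii.gz")
        gtv_img = nib.load(out / f"{cid}_gtv.nii.gz")
        spacing = tuple(float(z) for z in ct_img.header.get_zooms()[:3])
        cases.append(PhantomCase(
            case_id=cid,
            ct=np.asarray(ct_img.dataobj, dtype=np.float32),
            gtv=np.asarray(gtv_img.dataobj, dtype=np.uint8),
            spacing=spacing,
            true_complexity=float(row["complexity_amp"]),
        ))
    return cases
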