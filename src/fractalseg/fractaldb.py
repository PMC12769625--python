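"""FractalDB-style dataset assembly: C categories x I instances with pseudo-labels.

The category index is the label; no human annotation exists anywhere in the
dataset, which is the point of formula-driven pretraining.  Images land on disk
as 8-bit grayscale PNGs under ``<out>/<category_id>/<instance_idx>.png`` next to
a ``manifest.csv`` and a ``db_config.yaml`` echo of the build configuration.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .ifs import (
    WEIGHT_GRID,
    DegenerateCategoryError,
    IFSCategory,
    RenderConfig,
    is_degenerate,
    render_category,
    sample_category,
)

__all__ = ["DBConfig", "build_db", "verify_db", "load_batches", "read_manifest",
           "FRACTALDB_1K"]

MANIFEST_COLUMNS = ["path", "category_id", "instance_idx", "weight", "render_seed"]


@dataclass(frozen=True)
class DBConfig:
    """Build configuration for one fractal database."""

    n_categories: int = 20
    n_instances: int = 50
    render: RenderConfig = field(default_factory=RenderConfig)
    seed: int = 0
    weights: tuple[float, ...] = WEIGHT_GRID
    n_range: tuple[int, int] = (2, 8)

    def __post_init__(self) -> None:
        if self.n_categories < 1 or self.n_instances < 1:
            raise ValueError("need n_categories >= 1 and n_instances >= 1")


#: Full-scale profile matching the public fractal database: 1,000 categories x
#: 1,000 instances rendered with 200,000 transform applications per image.
#: Building it is a cluster-scale job; it is provided as a named config only.
FRACTALDB_1K = DBConfig(
    n_categories=1000,
    n_instances=1000,
    render=RenderConfig(n_points=200_000, image_side=224, point_radius=1),
    seed=0,
)


def _derived_seed(*parts: int) -> int:
    """Stable per-(category, instance) seed so categories rebuild independently."""
    return int(np.random.SeedSequence(list(parts)).generate_state(1)[0] % (2**31 - 1))


def _build_instance(category: IFSCategory, cfg: DBConfig, cat_idx: int,
                    inst_idx: int) -> tuple[np.ndarray, float, int]:
    """Render one instance, backing off toward weight 1.0 if the weighted system
    diverges or renders degenerate (weights > 1 can make a map expansive)."""
    base_weight = cfg.weights[inst_idx % len(cfg.weights)]
    render_seed = _derived_seed(cfg.seed, cat_idx, inst_idx)
    ladder = [base_weight]
    ladder += [w for w in (1.0 + 0.5 * (base_weight - 1.0), 1.0) if w in WEIGHT_GRID
               and w not in ladder]
    if 1.0 not in ladder:
        ladder.append(1.0)
    last_err: Exception | None = None
    for weight in ladder:
        for bump in range(3):
            seed = render_seed if bump == 0 else _derived_seed(render_seed, bump)
            try:
                img = render_category(category, cfg.render, seed, weight)
            except DegenerateCategoryError as err:
                last_err = err
                continue
            if not is_degenerate(img):
                return img.pixels, weight, seed
    raise DegenerateCategoryError(
        f"category {cat_idx} instance {inst_idx} unreusable: {last_err}"
    )


def build_db(config: DBConfig, out_dir: str | Path) -> pd.DataFrame:
    """Build the dataset on disk and return its manifest.

    Exactly ``n_categories * n_instances`` PNGs are written; each category_id
    appears exactly ``n_instances`` times.  Category parameter sets are stored
    as JSON sidecars.  The build is deterministic under ``config.seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows: list[dict] = []
    for c in range(config.n_categories):
        cat_seed = _derived_seed(config.seed, c)
        category = sample_category(cat_seed, n_range=config.n_range, category_id=c)
        cat_dir = out / str(c)
        cat_dir.mkdir(exist_ok=True)
        sidecar = {
            "category_id": c,
            "seed": cat_seed,
            "N": category.n_transforms,
            "transforms": [t.as_tuple() for t in category.transforms],
            "probabilities": list(category.probabilities),
        }
        (cat_dir / "category.json").write_text(json.dumps(sidecar, indent=1))
        for i in range(config.n_instances):
            pixels, weight, seed = _build_instance(category, config, c, i)
            rel = f"{c}/{i}.png"
            Image.fromarray(pixels, mode="L").save(out / rel)
            rows.append({"path": rel, "category_id": c, "instance_idx": i,
                         "weight": weight, "render_seed": seed})
    manifest = pd.DataFrame(rows, columns=MANIFEST_COLUMNS)
    manifest.to_csv(out / "manifest.csv", index=False)
    cfg_echo = asdict(config)
    cfg_echo["render"] = asdict(config.render)
    with open(out / "db_config.yaml", "w") as fh:
        yaml.safe_dump(cfg_echo, fh, sort_keys=False)
    return manifest


def read_manifest(db_dir: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(db_dir) / "manifest.csv")


def verify_db(manifest: pd.DataFrame, db_dir: str | Path,
              expected_side: int | None = None,
              n_categories: int | None = None) -> dict:
    """Audit a built database; returns a pass/fail report, never raises on misses.

    ``n_categories`` defaults to the value recorded in the build directory's
    ``db_config.yaml`` (falling back to inference from the manifest), so a
    manifest label equal to or above the configured category count is flagged.
    """
    db = Path(db_dir)
    if n_categories is None:
        cfg_file = db / "db_config.yaml"
        if cfg_file.exists():
            n_categories = int(yaml.safe_load(cfg_file.read_text())["n_categories"])
    missing = [p for p in manifest["path"] if not (db / p).exists()]
    labels = manifest["category_id"].to_numpy()
    inferred = int(labels.max()) + 1 if len(labels) else 0
    n_cat = n_categories if n_categories is not None else inferred
    counts = manifest.groupby("category_id").size()
    balanced = counts.nunique() <= 1
    label_range_ok = bool((labels >= 0).all() and (labels < n_cat).all()
                          and set(np.unique(labels)) == set(range(n_cat)))
    side_ok, nondegenerate_ok = True, True
    for p in manifest["path"]:
        f = db / p
        if not f.exists():
            continue
        arr = np.asarray(Image.open(f))
        if expected_side is not None and arr.shape != (expected_side, expected_side):
            side_ok = False
        if arr.max() == 0:
            nondegenerate_ok = False
    report = {
        "missing_files": missing,
        "files_ok": not missing,
        "labels_balanced": bool(balanced),
        "label_range_ok": label_range_ok,
        "image_side_ok": side_ok,
        "nondegenerate_ok": nondegenerate_ok,
    }
    report["all_ok"] = all(
        v for k, v in report.items() if k not in ("missing_files", "all_ok")
    )
    return report


def load_batches(
    manifest: pd.DataFrame,
    db_dir: str | Path,
    batch_size: int,
    shuffle_seed: int | None = None,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield (images, labels) batches covering every manifest row exactly once.

    Images come back as float32 in [0, 1] with shape (B, 1, H, W); labels are the
    category pseudo-labels.  Order is deterministic under ``shuffle_seed``.
    """
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    db = Path(db_dir)
    order = np.arange(len(manifest))
    if shuffle_seed is not None:
        order = np.random.default_rng(shuffle_seed).permutation(order)
    for start in range(0, len(order), batch_size):
        idx = order[start : start + batch_size]
        imgs, labels = [], []
        for _, row in manifest.iloc[idx].iterrows():
            f = db / row["path"]
            try:
                arr = np.asarray(Image.open(f), dtype=np.float32) / 255.0
            except OSError as err:
                raise OSError(f"unreadable image {f}: {err}") from err
            imgs.append(arr[None])
            labels.append(int(row["category_id"]))
        yield np.stack(imgs), np.asarray(labels, dtype=np.int64)
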