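"""End-to-end experiment orchestration.

Stages: build the fractal database -> pretext-pretrain the encoder -> generate
the phantom cohort -> fine-tune every strategy on identical folds -> evaluate
per-case contour metrics -> Friedman gate + pairwise Wilcoxon-Holm -> subgroup
analysis by surface-to-volume ratio.  Every strategy sees exactly the same
(case, fold) assignments and test slices, which is what licenses the paired
statistics.

Stage outputs are cached content-addressed: each stage directory is keyed by a
hash of its own config subtree plus its upstream artifacts' keys, so editing,
say, the significance level reruns only the statistics.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import nn
from .fractaldb import DBConfig, build_db, read_manifest
from .metrics import (BinaryVolume, CaseMetrics, evaluate_case,
                      friedman_across_strategies, median_split_by_svr,
                      pairwise_wilcoxon_holm, _safe_wilcoxon)
from .phantom import PhantomConfig, generate_cohort
from .roi import CaseROIs, prepare_case
from .training import (ModelSpec, ScheduleConfig, finetune, make_folds,
                       predict_mask, pretext_train)

log = logging.getLogger("fractalseg")

__all__ = ["StrategySpec", "ExperimentConfig", "run_experiment",
           "subgroup_report", "evaluate_model_on_cases", "miniature_config",
           "miniature_transfer", "load_experiment_config"]


@dataclass(frozen=True)
class StrategySpec:
    """One pretraining strategy to compare: 'scratch', 'pretext' (train the
    fractal pretext here), or 'external:<weights.npz>'."""

    name: str
    init: str = "scratch"


@dataclass(frozen=True)
class ExperimentConfig:
    db: DBConfig = field(default_factory=DBConfig)
    cohort: PhantomConfig = field(default_factory=lambda: PhantomConfig(n_cases=40))
    strategies: tuple[StrategySpec, ...] = (
        StrategySpec("scratch", "scratch"),
        StrategySpec("fractal", "pretext"),
    )
    schedule: ScheduleConfig = field(default_factory=lambda: ScheduleConfig(max_epochs=25))
    model: ModelSpec = field(default_factory=ModelSpec)
    pretext_epochs: int = 15
    k_folds: int = 4
    fold_sizes: tuple[int, int, int] = (25, 5, 10)
    folds_to_run: tuple[int, ...] | None = None  # None = all k folds
    tau: float = 1.0
    alpha: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.strategies) < 2:
            raise ValueError("comparison mode needs >= 2 strategies")


def load_experiment_config(path, seed: int | None = None) -> ExperimentConfig:
    """Build an ExperimentConfig from a YAML master config.

    Top-level keys mirror the dataclass fields; `db`, `cohort`, `schedule` and
    `model` accept nested mappings, `strategies` a list of {name, init}.
    Omitted fields keep their defaults; a `seed` argument overrides the file.
    """
    import yaml

    from .ifs import RenderConfig

    raw = yaml.safe_load(Path(path).read_text()) or {}
    kwargs: dict = {}
    if "db" in raw:
        db = dict(raw["db"])
        if "render" in db:
            db["render"] = RenderConfig(**db["render"])
        kwargs["db"] = DBConfig(**db)
    if "cohort" in raw:
        kwargs["cohort"] = PhantomConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in raw["cohort"].items()})
    if "schedule" in raw:
        kwargs["schedule"] = ScheduleConfig(**raw["schedule"])
    if "model" in raw:
        model = dict(raw["model"])
        if "widths" in model:
            model["widths"] = tuple(model["widths"])
        kwargs["model"] = ModelSpec(**model)
    if "strategies" in raw:
        kwargs["strategies"] = tuple(StrategySpec(**s) for s in raw["strategies"])
    for k in ("pretext_epochs", "k_folds", "tau", "alpha", "seed"):
        if k in raw:
            kwargs[k] = raw[k]
    for k in ("fold_sizes", "folds_to_run"):
        if k in raw:
            kwargs[k] = tuple(raw[k])
    if seed is not None:
        kwargs["seed"] = seed
    return ExperimentConfig(**kwargs)


def _key(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _stage_dir(out: Path, stage: str, key: str) -> tuple[Path, bool]:
    d = out / "cache" / f"{stage}-{key}"
    return d, (d / ".done").exists()


def _mark(d: Path) -> None:
    (d / ".done").write_text("ok")


def evaluate_model_on_cases(
    model: nn.SegNet,
    roi_data: dict[str, CaseROIs],
    case_ids,
    strategy: str,
    input_side: int = 64,
    tau: float = 1.0,
) -> list[CaseMetrics]:
    """Per-case 3D evaluation: predicted 2D slices are stacked into a volume at
    the cohort spacing before computing vDSC/sDSC/HD95 (tolerances are in mm,
    which only makes sense volumetrically)."""
    out = []
    for cid in case_ids:
        cr = roi_data[cid]
        preds = np.stack(
            [predict_mask(model, p.image, input_side=input_side) for p in cr.pairs],
            axis=-1,
        )
        truth = np.stack([p.mask for p in cr.pairs], axis=-1)
        sp = cr.spacing3d
        out.append(evaluate_case(cid, strategy,
                                 BinaryVolume(preds, sp), BinaryVolume(truth, sp),
                                 tau=tau))
    return out


def subgroup_report(
    metrics: pd.DataFrame,
    strategy_a: str,
    strategy_b: str,
    metric: str = "vdsc",
) -> dict:
    """Simple/complex subgroup comparison of two strategies.

    Groups come from the SVR median split of the ground-truth shapes; the
    comparison reuses the main cross-validation inference results (models are
    not retrained per group).  Returns per-group mean +/- SD for both
    strategies and the Wilcoxon signed-rank p-value between them.
    """
    ref = metrics[metrics["strategy"] == strategy_a]
    cms = [CaseMetrics(r.case_id, strategy_a, r.vdsc, r.sdsc, r.hd95, r.svr)
           for r in ref.itertuples()]
    simple, complex_ = median_split_by_svr(cms)
    report = {}
    for label, group in (("simple", simple), ("complex", complex_)):
        ids = [c.case_id for c in group]
        sub = metrics[metrics["case_id"].isin(ids)]
        pivot = sub.pivot(index="case_id", columns="strategy", values=metric)
        if strategy_a not in pivot or strategy_b not in pivot:
            raise ValueError("group/metric mismatch: strategy column missing")
        a = pivot[strategy_a].to_numpy()
        b = pivot[strategy_b].to_numpy()
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("unpaired subgroup data")
        report[label] = {
            "n": len(ids),
            f"{strategy_a}_mean": float(a.mean()), f"{strategy_a}_sd": float(a.std(ddof=1)),
            f"{strategy_b}_mean": float(b.mean()), f"{strategy_b}_sd": float(b.std(ddof=1)),
            "wilcoxon_p": _safe_wilcoxon(a, b),
        }
    return report


def _statistics_block(metrics: pd.DataFrame, strategies, alpha: float) -> dict:
    """Friedman gate per metric, then pairwise Wilcoxon-Holm when significant."""
    names = [s.name for s in strategies]
    stats_block = {}
    for metric in ("vdsc", "sdsc", "hd95"):
        pivot = metrics.pivot(index="case_id", columns="strategy", values=metric)[names]
        mat = pivot.to_numpy()
        finite = np.isfinite(mat).all(axis=1)
        mat = mat[finite]
        stat, p = friedman_across_strategies(mat)
        entry = {"friedman_statistic": stat, "friedman_p": p,
                 "n_cases": int(mat.shape[0]), "pairwise": None}
        if p < alpha:
            table = pairwise_wilcoxon_holm(mat, strategy_names=names, alpha=alpha)
            entry["pairwise"] = table.to_dict(orient="records")
        stats_block[metric] = entry
    return stats_block


def run_experiment(config: ExperimentConfig, out_dir: str | Path) -> dict:
    """Run the full comparison experiment; returns the report bundle dict.

    Writes ``metrics.csv`` (one row per case x strategy x fold), ``report.json``
    (summary stats, Friedman/Wilcoxon-Holm, subgroup analysis) and a small
    ``report.html`` rendering, all reproducible from (config, seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage: fractal database ---------------------------------------
    db_key = _key(asdict(config.db))
    db_dir, done = _stage_dir(out, "db", db_key)
    stage = "build_db"
    try:
        if not done:
            t0 = time.time()
            build_db(config.db, db_dir)
            _mark(db_dir)
            log.info("stage %s (seed %d) done in %.1fs -> %s", stage,
                     config.seed, time.time() - t0, db_dir)
        manifest = read_manifest(db_dir)

        # --- stage: pretext pretraining ---------------------------------
        needs_pretext = any(s.init == "pretext" for s in config.strategies)
        ckpt_path = None
        if needs_pretext:
            stage = "pretext"
            px_key = _key([db_key, config.pretext_epochs, config.seed,
                           asdict(config.model)])
            px_dir, done = _stage_dir(out, "pretext", px_key)
            ckpt_path = px_dir / "encoder.npz"
            if not done:
                t0 = time.time()
                px_dir.mkdir(parents=True, exist_ok=True)
                state, plog = pretext_train(manifest, db_dir, config.model,
                                            epochs=config.pretext_epochs,
                                            seed=config.seed)
                nn.save_checkpoint(ckpt_path, state,
                                   {"strategy": "fractal-pretext",
                                    "seed": config.seed,
                                    "epochs": config.pretext_epochs})
                plog.to_csv(px_dir / "pretext_log.csv", index=False)
                _mark(px_dir)
                log.info("stage pretext (seed %d) done in %.1fs", config.seed,
                         time.time() - t0)

        # --- stage: phantom cohort + ROI prep ----------------------------
        stage = "cohort"
        co_key = _key(asdict(config.cohort))
        co_dir, done = _stage_dir(out, "cohort", co_key)
        if not done:
            t0 = time.time()
            generate_cohort(config.cohort, co_dir)
            _mark(co_dir)
            log.info("stage %s (seed %d) done in %.1fs", stage,
                     config.cohort.seed, time.time() - t0)
        cases = generate_cohort(config.cohort)  # in-memory, deterministic
        roi_data = {c.case_id: prepare_case(c) for c in cases}
        case_ids = [c.case_id for c in cases]

        # --- stage: folds -------------------------------------------------
        stage = "folds"
        folds = make_folds(case_ids, k=config.k_folds, sizes=config.fold_sizes,
                           seed=config.seed)
        which = config.folds_to_run or tuple(range(config.k_folds))

        # --- stage: fine-tune + evaluate ---------------------------------
        stage = "finetune"
        rows = []
        for s in config.strategies:
            init = s.init if s.init != "pretext" else str(ckpt_path)
            spec = ModelSpec(input_side=config.model.input_side,
                             widths=config.model.widths,
                             in_channels=config.model.in_channels,
                             init_source=init)
            for f in which:
                ft_key = _key([db_key, co_key, s.name, f, config.seed,
                               asdict(config.schedule), asdict(config.model),
                               config.pretext_epochs, config.fold_sizes])
                ft_dir, done = _stage_dir(out, f"ft-{s.name}-fold{f}", ft_key)
                mfile = ft_dir / "case_metrics.csv"
                if not done:
                    t0 = time.time()
                    ft_dir.mkdir(parents=True, exist_ok=True)
                    result = finetune(spec, folds[f], roi_data,
                                      sched=config.schedule, seed=config.seed)
                    nn.save_checkpoint(ft_dir / "model.npz", result.model.state(),
                                       {"strategy": s.name, "fold": f,
                                        "seed": config.seed,
                                        "epoch": result.best_epoch})
                    cms = evaluate_model_on_cases(
                        result.model, roi_data, folds[f].test_ids, s.name,
                        input_side=config.model.input_side, tau=config.tau)
                    fold_rows = [dict(case_id=m.case_id, strategy=m.strategy,
                                      fold=f, vdsc=m.vdsc, sdsc=m.sdsc,
                                      hd95=m.hd95, svr=m.svr) for m in cms]
                    pd.DataFrame(fold_rows).to_csv(mfile, index=False)
                    pd.DataFrame({"epoch": np.arange(1, len(result.val_losses) + 1),
                                  "val_loss": result.val_losses,
                                  "lr": result.lr_trace}).to_csv(
                        ft_dir / "val_losses.csv", index=False)
                    _mark(ft_dir)
                    log.info("stage finetune %s fold %d (seed %d) done in %.1fs",
                             s.name, f, config.seed, time.time() - t0)
                # read back from the cache file in both paths so cached and
                # fresh runs share byte-exact provenance
                rows.extend(pd.read_csv(mfile).to_dict(orient="records"))
        metrics = pd.DataFrame(rows)
        metrics.to_csv(out / "metrics.csv", index=False)

        # --- stage: statistics -------------------------------------------
        stage = "statistics"
        summary = {
            s.name: {
                m: {"mean": float(metrics.loc[metrics.strategy == s.name, m]
                                  .replace(np.inf, np.nan).mean()),
                    "sd": float(metrics.loc[metrics.strategy == s.name, m]
                                .replace(np.inf, np.nan).std(ddof=1))}
                for m in ("vdsc", "sdsc", "hd95")
            }
            for s in config.strategies
        }
        stats_block = _statistics_block(metrics, config.strategies, config.alpha)
        sub = subgroup_report(metrics, config.strategies[0].name,
                              config.strategies[1].name)
        report = {"summary": summary, "statistics": stats_block,
                  "subgroups": sub, "seed": config.seed,
                  "n_cases": config.cohort.n_cases,
                  "strategies": [s.name for s in config.strategies]}
        (out / "report.json").write_text(json.dumps(report, indent=1))
        _write_html(out / "report.html", report, metrics)
        return report
    except Exception as err:
        raise RuntimeError(f"experiment failed at stage '{stage}': {err}") from err


def _write_html(path: Path, report: dict, metrics: pd.DataFrame) -> None:
    rows = "".join(
        f"<tr><td>{s}</td>" + "".join(
            f"<td>{report['summary'][s][m]['mean']:.3f} &plusmn; "
            f"{report['summary'][s][m]['sd']:.3f}</td>"
            for m in ("vdsc", "sdsc", "hd95")) + "</tr>"
        for s in report["strategies"])
    path.write_text(
        "<html><body><h1>Strategy comparison</h1>"
        "<table border=1><tr><th>strategy</th><th>vDSC</th><th>sDSC</th>"
        f"<th>HD95 (mm)</th></tr>{rows}</table>"
        f"<p>{len(metrics)} case-strategy rows; statistics in report.json.</p>"
        "</body></html>")


# ---------------------------------------------------------------------------
# desk-scale presets


def miniature_config(seed: int, finetune_epochs: int = 25,
                     pretext_epochs: int = 15) -> ExperimentConfig:
    """The desk-scale study conditions: 20-category x 50-instance fractal DB at
    64 px / 20k points, a 40-case phantom cohort, the small encoder, 15 pretext
    epochs and 25 fine-tuning epochs.  The fractal DB is seed-fixed (it plays
    the role of a fixed public pretraining set); cohort and training vary with
    ``seed``."""
    return ExperimentConfig(
        db=DBConfig(n_categories=20, n_instances=50, seed=7),
        cohort=PhantomConfig(n_cases=40, seed=seed),
        schedule=ScheduleConfig(max_epochs=finetune_epochs, seed=seed),
        pretext_epochs=pretext_epochs,
        k_folds=4,
        fold_sizes=(25, 5, 10),
        folds_to_run=(0,),
        seed=seed,
    )


def miniature_transfer(seeds, out_dir, finetune_epochs: int = 25,
                       pretext_epochs: int = 15) -> pd.DataFrame:
    """Run the scratch-vs-fractal comparison once per seed on one fold each.

    Returns a table of per-seed mean test vDSC for both strategies; the
    directional claim under study is that fractal pretraining matches or beats
    scratch in most seeds.
    """
    rows = []
    for seed in seeds:
        # one shared out_dir: the seed-fixed fractal DB stage is cached across
        # seeds while cohort/pretext/finetune stages key on the seed
        cfg = miniature_config(seed, finetune_epochs, pretext_epochs)
        report = run_experiment(cfg, Path(out_dir))
        rows.append({
            "seed": seed,
            "vdsc_scratch": report["summary"]["scratch"]["vdsc"]["mean"],
            "vdsc_fractal": report["summary"]["fractal"]["vdsc"]["mean"],
        })
    df = pd.DataFrame(rows)
    df["fractal_ge_scratch"] = df["vdsc_fractal"] >= df["vdsc_scratch"]
    return df
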