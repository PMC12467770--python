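"""End-to-end orchestration: simulate -> balance -> train -> extract ->
expressivity -> evaluate -> report.

A single :class:`RunConfig` (YAML-serializable) drives every stage; each
stage's randomness is seeded by a hash of the global seed and the stage
name, so the whole run is reproducible bit-for-bit. Stage outputs are
files under the run directory; a manifest records the config hash, each
output's content hash and per-stage wall time, and lets ``run_stage``
skip stages whose outputs are already up to date.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from PIL import Image

from .evaluation import (ExpressivityProfile, derive_seed, expressivity_profile,
                         metric_report, ordering_check)
from .mine import MineTrainConfig, StatisticsNetConfig
from .representation import (BackboneConfig, TrainRunConfig, build_backbone,
                             load_weights, predict_proba, save_weights,
                             train_classifier)
from .synthetic_data import (CohortConfig, RenderConfig, SyntheticCohort,
                             assign_splits, make_balanced_subset, render_images,
                             sample_cohort)

__all__ = ["RunConfig", "RunManifest", "run_stage", "run_all", "report",
           "STAGES", "default_config"]

STAGES = ("simulate", "balance", "train", "extract", "expressivity",
          "evaluate", "report")


@dataclass
class EvalConfig:
    n_boot: int = 500
    stages: tuple[str, ...] = ("early", "mid", "final")
    attributes: tuple[str, ...] = ("age", "sex", "IVSDd", "LVPWDd", "LVIDd")
    expected_ranking: tuple[str, ...] = ()
    profile_split: str = "test"


@dataclass
class RunConfig:
    """Nested configuration for a full pipeline run."""

    seed: int = 0
    out_dir: str = "runs/default"
    split_proportions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    cohort: CohortConfig = field(default_factory=CohortConfig)
    render: RenderConfig = field(default_factory=RenderConfig)
    backbone: BackboneConfig = field(default_factory=BackboneConfig)
    train: TrainRunConfig = field(default_factory=TrainRunConfig)
    mine_net: StatisticsNetConfig = field(default_factory=StatisticsNetConfig)
    mine_train: MineTrainConfig = field(default_factory=MineTrainConfig)
    eval: EvalConfig = field(default_factory=EvalConfig)

    _SECTIONS = {"cohort": CohortConfig, "render": RenderConfig,
                 "backbone": BackboneConfig, "train": TrainRunConfig,
                 "mine_net": StatisticsNetConfig, "mine_train": MineTrainConfig,
                 "eval": EvalConfig}

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        for k, v in d.items():
            if k in cls._SECTIONS and isinstance(v, dict):
                sec = cls._SECTIONS[k]
                v = {kk: tuple(vv) if isinstance(vv, list) else vv
                     for kk, vv in v.items()}
                kwargs[k] = sec(**v)
            elif isinstance(v, list):
                kwargs[k] = tuple(v)
            else:
                kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(json.loads(json.dumps(self.to_dict())), fh,
                           sort_keys=True)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.seed, "stage", stage)


def default_config() -> RunConfig:
    """The packaged desk-scale default configuration."""
    path = Path(__file__).parent / "configs" / "default.yaml"
    return RunConfig.from_yaml(path)


# ---------------------------------------------------------------------------
# Manifest
# ---------------------------------------------------------------------------

def _file_hash(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class RunManifest:
    """Per-run ledger of stage outputs, hashes, timings and warnings."""

    def __init__(self, run_dir: Path, config_hash: str):
        self.path = Path(run_dir) / "manifest.json"
        if self.path.exists():
            self.data = json.loads(self.path.read_text())
            if self.data.get("config_hash") != config_hash:
                self.data = {"config_hash": config_hash, "stages": {}}
        else:
            self.data = {"config_hash": config_hash, "stages": {}}

    def record(self, stage: str, outputs: list[Path], wall_time: float,
               warnings_: list[str] | None = None, cache_hit: bool = False):
        self.data["stages"][stage] = {
            "outputs": {str(p): _file_hash(p) for p in outputs},
            "wall_time_s": round(wall_time, 3),
            "warnings": warnings_ or [],
            "cache_hit": cache_hit,
        }
        self.save()

    def up_to_date(self, stage: str) -> bool:
        rec = self.data["stages"].get(stage)
        if not rec:
            return False
        for p, h in rec["outputs"].items():
            path = Path(p)
            if not path.exists() or _file_hash(path) != h:
                return False
        return True

    def save(self):
        self.path.parent.mkdir(parents=True, exist_ok=True)
        self.path.write_text(json.dumps(self.data, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------------

def _paths(cfg: RunConfig) -> dict[str, Path]:
    root = Path(cfg.out_dir)
    return {
        "root": root,
        "cohort": root / "cohort.csv",
        "provenance": root / "provenance.json",
        "images": root / "images",
        "splits": root / "splits.json",
        "weights": root / "model_weights.npz",
        "history": root / "train_history.json",
        "features": root / "features",
        "profile": root / "expressivity_profile.json",
        "metrics": root / "metrics.json",
        "roc_csv": root / "roc_curve.csv",
        "pr_csv": root / "pr_curve.csv",
        "report_json": root / "report.json",
        "report_txt": root / "report.txt",
    }


def _load_cohort(cfg: RunConfig) -> SyntheticCohort:
    table = pd.read_csv(_paths(cfg)["cohort"])
    return SyntheticCohort(table=table, config=cfg.cohort)


def _load_images(cfg: RunConfig, sample_ids) -> np.ndarray:
    img_dir = _paths(cfg)["images"]
    out = []
    for sid in sample_ids:
        with Image.open(img_dir / f"{sid}.png") as im:
            out.append(np.asarray(im, dtype=np.float64) / 255.0)
    return np.stack(out)


def _load_splits(cfg: RunConfig) -> dict[str, np.ndarray]:
    data = json.loads(_paths(cfg)["splits"].read_text())
    return {k: np.asarray(v, dtype=int) for k, v in data["balanced"].items()}


def _stage_simulate(cfg: RunConfig, paths) -> list[Path]:
    cohort_cfg = dataclasses.replace(cfg.cohort, seed=cfg.stage_seed("simulate"))
    cohort = sample_cohort(cohort_cfg)
    paths["root"].mkdir(parents=True, exist_ok=True)
    cohort.table.to_csv(paths["cohort"], index=False)
    prov = cohort.provenance()
    prov["run_config_hash"] = cfg.config_hash()
    paths["provenance"].write_text(json.dumps(prov, indent=2, sort_keys=True))
    imgs = render_images(cohort, cfg.render, seed=cfg.stage_seed("render"))
    paths["images"].mkdir(exist_ok=True)
    files = [paths["cohort"], paths["provenance"]]
    for sid, img in zip(cohort.table["sample_id"], imgs):
        p = paths["images"] / f"{sid}.png"
        Image.fromarray(np.round(img * 255.0).astype(np.uint8)).save(p)
        files.append(p)
    return files


def _stage_balance(cfg: RunConfig, paths) -> list[Path]:
    cohort = _load_cohort(cfg)
    split = assign_splits(cohort.n, cfg.split_proportions,
                          seed=cfg.stage_seed("split"))
    balanced = make_balanced_subset(cohort.table["slvh"].to_numpy(), split,
                                    seed=cfg.stage_seed("balance"))
    payload = {"split": split.tolist(),
               "balanced": {k: v.tolist() for k, v in balanced.items()}}
    paths["splits"].write_text(json.dumps(payload, indent=2, sort_keys=True))
    return [paths["splits"]]


def _stage_train(cfg: RunConfig, paths) -> list[Path]:
    cohort = _load_cohort(cfg)
    splits = _load_splits(cfg)
    ids = cohort.table["sample_id"].to_numpy()
    y = cohort.table["slvh"].to_numpy()
    imgs_tr = _load_images(cfg, ids[splits["train"]])
    imgs_va = _load_images(cfg, ids[splits["val"]])
    model = build_backbone(cfg.backbone, seed=cfg.stage_seed("init"))
    run_cfg = dataclasses.replace(cfg.train, seed=cfg.stage_seed("train"))
    model, history = train_classifier(model, (imgs_tr, y[splits["train"]]),
                                      (imgs_va, y[splits["val"]]), run_cfg)
    save_weights(model, paths["weights"])
    paths["history"].write_text(json.dumps(history, indent=2, sort_keys=True))
    return [paths["weights"], paths["history"]]


def _trained_model(cfg: RunConfig, paths):
    model = build_backbone(cfg.backbone, seed=cfg.stage_seed("init"))
    load_weights(model, paths["weights"])
    return model


def _profile_subset(cfg: RunConfig):
    cohort = _load_cohort(cfg)
    splits = _load_splits(cfg)
    idx = splits[cfg.eval.profile_split]
    sub = cohort.table.iloc[idx].reset_index(drop=True)
    imgs = _load_images(cfg, sub["sample_id"])
    return sub, imgs


def _stage_extract(cfg: RunConfig, paths) -> list[Path]:
    from .io import write_feature_csv
    from .representation import extract_features
    model = _trained_model(cfg, paths)
    sub, imgs = _profile_subset(cfg)
    paths["features"].mkdir(exist_ok=True)
    files = []
    for stage in cfg.eval.stages:
        fm = extract_features(model, imgs, stage)
        fm.sample_ids = sub["sample_id"].tolist()
        p = paths["features"] / f"{stage}.csv"
        write_feature_csv(fm, p)
        files.append(p)
    return files


def _stage_expressivity(cfg: RunConfig, paths) -> list[Path]:
    model = _trained_model(cfg, paths)
    sub, imgs = _profile_subset(cfg)
    profile = expressivity_profile(
        model, imgs, sub, stages=cfg.eval.stages,
        attributes=cfg.eval.attributes, net_cfg=cfg.mine_net,
        train_cfg=cfg.mine_train, base_seed=cfg.stage_seed("expressivity"))
    paths["profile"].write_text(json.dumps(profile.to_dict(), indent=2,
                                           sort_keys=True))
    return [paths["profile"]]


def _stage_evaluate(cfg: RunConfig, paths) -> list[Path]:
    cohort = _load_cohort(cfg)
    splits = _load_splits(cfg)
    idx = splits["test"]
    sub = cohort.table.iloc[idx].reset_index(drop=True)
    imgs = _load_images(cfg, sub["sample_id"])
    model = _trained_model(cfg, paths)
    scores = predict_proba(model, imgs)
    rep = metric_report(scores, sub["slvh"].to_numpy(), n_boot=cfg.eval.n_boot,
                        seed=cfg.stage_seed("bootstrap"))
    paths["metrics"].write_text(json.dumps(rep.to_dict(), indent=2,
                                           sort_keys=True))
    roc_df, pr_df = rep.curves_frames()
    roc_df.to_csv(paths["roc_csv"], index=False)
    pr_df.to_csv(paths["pr_csv"], index=False)
    return [paths["metrics"], paths["roc_csv"], paths["pr_csv"]]


def _stage_report(cfg: RunConfig, paths) -> list[Path]:
    rep = json.loads(paths["metrics"].read_text())
    lines = ["== classification metrics (test split) ==",
             f"AUROC {rep['auroc']:.3f} "
             f"[95% CI: {rep['auroc_ci'][0]:.3f}-{rep['auroc_ci'][1]:.3f}]",
             f"AUPRC {rep['auprc']:.3f} "
             f"[95% CI: {rep['auprc_ci'][0]:.3f}-{rep['auprc_ci'][1]:.3f}]"]
    out = {"config_hash": cfg.config_hash(), "metrics": {
        "auroc": rep["auroc"], "auroc_ci": rep["auroc_ci"],
        "auprc": rep["auprc"], "auprc_ci": rep["auprc_ci"]}}
    if paths["profile"].exists():
        profile = ExpressivityProfile.from_dict(
            json.loads(paths["profile"].read_text()))
        lines.append("")
        lines.append("== expressivity (nats), mean +/- sd over seeds ==")
        header = "stage      " + "  ".join(f"{a:>8s}" for a in profile.attributes)
        lines.append(header)
        flags = []
        for s in profile.stages:
            cells = []
            for a in profile.attributes:
                r = profile.cells[(s, a)]
                cells.append(f"{r.mean_estimate:8.3f}")
                if r.mean_estimate < 0:
                    flags.append(f"negative estimate at ({s}, {a}): "
                                 f"{r.mean_estimate:.4f} nats (reported raw)")
            lines.append(f"{s:10s} " + "  ".join(cells))
        lines.extend(flags)
        out["expressivity"] = profile.to_dict()
        out["negative_flags"] = flags
        if cfg.eval.expected_ranking:
            chk = ordering_check(profile, "final",
                                 list(cfg.eval.expected_ranking))
            verdict = "MATCH" if chk["match"] else "MISMATCH"
            lines.append(f"ordering: {verdict} (tau={chk['kendall_tau']:.2f})")
            out["ordering_check"] = chk
    else:
        lines.append("")
        lines.append("expressivity grid not computed; metrics only")
        out["expressivity"] = None
    paths["report_json"].write_text(json.dumps(out, indent=2, sort_keys=True))
    paths["report_txt"].write_text("\n".join(lines) + "\n")
    return [paths["report_json"], paths["report_txt"]]


_STAGE_FNS = {
    "simulate": (_stage_simulate, []),
    "balance": (_stage_balance, ["simulate"]),
    "train": (_stage_train, ["balance"]),
    "extract": (_stage_extract, ["train"]),
    "expressivity": (_stage_expressivity, ["train"]),
    "evaluate": (_stage_evaluate, ["train"]),
    "report": (_stage_report, ["evaluate"]),
}


def run_stage(stage: str, cfg: RunConfig, force: bool = False) -> RunManifest:
    """Run one stage (reusing up-to-date outputs unless ``force``)."""
    if stage not in _STAGE_FNS:
        raise ValueError(f"unknown stage {stage!r}; stages are {STAGES}")
    fn, deps = _STAGE_FNS[stage]
    paths = _paths(cfg)
    manifest = RunManifest(paths["root"], cfg.config_hash())
    for dep in deps:
        if not manifest.up_to_date(dep):
            raise RuntimeError(
                f"stage {stage!r} needs outputs of {dep!r}; run that stage first")
    if not force and manifest.up_to_date(stage):
        rec = manifest.data["stages"][stage]
        manifest.record(stage, [Path(p) for p in rec["outputs"]],
                        wall_time=0.0, cache_hit=True)
        return manifest
    t0 = time.perf_counter()
    outputs = fn(cfg, paths)
    manifest.record(stage, outputs, wall_time=time.perf_counter() - t0)
    return manifest


def run_all(cfg: RunConfig, force: bool = False,
            skip: tuple[str, ...] = ()) -> RunManifest:
    """Run every stage in order; returns the final manifest."""
    manifest = None
    for stage in STAGES:
        if stage in skip:
            continue
        manifest = run_stage(stage, cfg, force=force)
    return manifest


def report(cfg: RunConfig) -> str:
    """The human-readable run summary (report stage must have run)."""
    path = _paths(cfg)["report_txt"]
    if not path.exists():
        raise RuntimeError("no report found; run the 'report' stage first")
    return path.read_text()
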