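"""End-to-end pipeline orchestration with resumable, file-backed stages.

Stages run in a fixed order —
``simulate -> preprocess -> train -> evaluate -> encode -> finetune ->
reconstruct -> report`` — each reading the previous stage's artifacts from
the output directory and writing its own, so any stage can be re-run after
its predecessors have completed.  Every artifact directory carries the
effective configuration and the seeds that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import diffusion as dif
from .io_edf import read_edf, write_edf
from .models import (EEGNetConfig, build_eegnet, build_eegnet_plus,
                     extract_embedding, load_checkpoint, save_checkpoint)
from .preprocessing import (BadTrialCriteria, FilterSpec, PreprocessConfig,
                            drop_report_csv, load_epochs, preprocess_session,
                            save_epochs)
from .sim import (SessionSpec, VEPModel, inject_artifacts, make_session_events,
                  synthesize_recording)
from .stimuli import generate_stimulus_images
from .training import (TrainConfig, evaluate, make_split, merge_epochs,
                       train_classifier)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "preprocess", "train", "evaluate", "encode",
          "finetune", "reconstruct", "report")


class ConfigError(ValueError):
    """Invalid or unknown configuration keys (CLI exit code 2)."""


class MissingArtifactError(FileNotFoundError):
    """An upstream stage's outputs are absent (CLI exit code 3)."""

    def __init__(self, stage: str, what: str):
        super().__init__(f"missing artifact from stage '{stage}': {what}")
        self.stage = stage


def _from_dict(cls, data: dict, context: str):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class PipelineConfig:
    out_dir: str = "pipeline-out"
    seed: int = 0
    n_sessions: int = 4
    snr: float = 2.0
    side_px: int = 32
    model_kind: str = "eegnet"
    session: SessionSpec = field(default_factory=SessionSpec)
    model: EEGNetConfig = field(default_factory=EEGNetConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    filter: FilterSpec = field(default_factory=FilterSpec)
    criteria: BadTrialCriteria = field(default_factory=BadTrialCriteria)
    artifacts: list = field(default_factory=list)   # [[session, trial, kind]]
    # reconstruction stage
    reconstruct_enabled: bool = True
    plms_steps: int = 25
    n_samples: int = 5
    n_way: int = 10
    metric_trials: int = 1000
    max_test_images: int = 100
    max_null_windows: int = 100
    ae_epochs: int = 30
    ae_holdout_mse: float = 0.02
    pretrain_epochs: int = 70
    finetune_epochs: int = 8
    max_finetune_pairs: int = 1024
    schedule_T: int = 300

    def __post_init__(self):
        if self.model_kind not in ("eegnet", "eegnet_plus"):
            raise ConfigError("model_kind must be 'eegnet' or 'eegnet_plus'")
        if self.n_sessions < 3:
            raise ConfigError("need at least 3 sessions (train/val/test split)")
        if self.model.n_classes != self.session.n_classes:
            raise ConfigError("model.n_classes must match session.n_classes")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        try:
            raw = yaml.safe_load(Path(path).read_text()) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse YAML config: {exc}") from exc
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        sub = {}
        try:
            if "session" in raw:
                sub["session"] = _from_dict(SessionSpec, raw.pop("session"),
                                            "session")
            if "model" in raw:
                m = raw.pop("model")
                if "pool_sizes" in m:
                    m["pool_sizes"] = tuple(m["pool_sizes"])
                sub["model"] = _from_dict(EEGNetConfig, m, "model").validate()
            if "train" in raw:
                sub["train"] = _from_dict(TrainConfig, raw.pop("train"), "train")
            if "filter" in raw:
                sub["filter"] = _from_dict(FilterSpec, raw.pop("filter"), "filter")
            if "criteria" in raw:
                sub["criteria"] = _from_dict(BadTrialCriteria,
                                             raw.pop("criteria"), "criteria")
            names = {f.name for f in dataclasses.fields(cls)}
            unknown = set(raw) - names
            if unknown:
                raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
            return cls(**raw, **sub)
        except (TypeError, ValueError) as exc:
            if isinstance(exc, ConfigError):
                raise
            raise ConfigError(str(exc)) from exc

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stamp(cfg: PipelineConfig, stage_dir: Path, extra: dict | None = None):
    meta = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    meta.update(extra or {})
    (stage_dir / "provenance.json").write_text(json.dumps(meta, indent=2))


def _out(cfg: PipelineConfig) -> Path:
    p = Path(cfg.out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# -- stages -------------------------------------------------------------------

def stage_simulate(cfg: PipelineConfig) -> Path:
    out = _out(cfg) / "simulate"
    out.mkdir(exist_ok=True)
    model = VEPModel.default(cfg.session.n_classes, snr=cfg.snr,
                             seed=cfg.seed + 7)
    by_session: dict[int, list] = {}
    for sess, trial, kind in cfg.artifacts:
        by_session.setdefault(int(sess), []).append((int(trial), kind))
    for s in range(cfg.n_sessions):
        ev = make_session_events(cfg.session, cfg.seed * 1009 + s)
        rec = synthesize_recording(ev, model, cfg.seed * 2003 + 7 * s + 1,
                                   session_id=f"session-{s:03d}")
        if s in by_session:
            rec = inject_artifacts(rec, by_session[s], seed=cfg.seed + s)
        write_edf(rec, out / f"session-{s:03d}.edf",
                  out / f"session-{s:03d}_events.tsv")
        logger.info("[simulate] wrote session-%03d (%d trials)", s, len(ev))
    stim = generate_stimulus_images(cfg.session, side_px=cfg.side_px,
                                    seed=cfg.seed + 11)
    stim.save_pngs(out / "stimuli")
    _stamp(cfg, out, {"n_sessions": cfg.n_sessions})
    return out


def _load_sessions(cfg: PipelineConfig):
    sim = _out(cfg) / "simulate"
    recs = []
    for s in range(cfg.n_sessions):
        edf = sim / f"session-{s:03d}.edf"
        tsv = sim / f"session-{s:03d}_events.tsv"
        if not edf.exists() or not tsv.exists():
            raise MissingArtifactError("simulate", str(edf))
        recs.append(read_edf(edf, tsv, cfg.session, session_id=edf.stem))
    return recs


def stage_preprocess(cfg: PipelineConfig) -> Path:
    recs = _load_sessions(cfg)
    out = _out(cfg) / "preprocess"
    out.mkdir(exist_ok=True)
    pconf = PreprocessConfig(filter_spec=cfg.filter, criteria=cfg.criteria)
    reports = []
    for rec in recs:
        epochs, rep = preprocess_session(rec, config=pconf)
        epochs.data = epochs.data.astype(np.float32)
        save_epochs(epochs, out / rec.session_id,
                    channel_names=rec.layout.names)
        reports.append(rep)
        logger.info("[preprocess] %s: dropped %d/%d", rec.session_id,
                    rep.n_dropped, rep.n_total)
    drop_report_csv(reports, out / "drop_report.csv")
    _stamp(cfg, out)
    return out


def _load_epoch_sets(cfg: PipelineConfig):
    pre = _out(cfg) / "preprocess"
    sets = []
    for s in range(cfg.n_sessions):
        d = pre / f"session-{s:03d}"
        if not (d / "header.json").exists():
            raise MissingArtifactError("preprocess", str(d))
        sets.append(load_epochs(d))
    return sets


def stage_train(cfg: PipelineConfig) -> Path:
    epoch_sets = _load_epoch_sets(cfg)
    out = _out(cfg) / "train"
    out.mkdir(exist_ok=True)
    split = make_split(epoch_sets)
    builder = build_eegnet if cfg.model_kind == "eegnet" else build_eegnet_plus
    handle = builder(cfg.model, seed=cfg.seed)
    train = merge_epochs([epoch_sets[i] for i in split.train_idx])
    tcfg = dataclasses.replace(cfg.train, seed=cfg.seed)
    handle, history = train_classifier(handle, train,
                                       epoch_sets[split.val_idx], tcfg)
    save_checkpoint(handle, out / "checkpoint")
    history.to_csv(out / "history.csv")
    (out / "split.json").write_text(json.dumps(dataclasses.asdict(split)))
    _stamp(cfg, out, {"best_epoch": history.best_epoch})
    return out


def _load_model(cfg: PipelineConfig):
    ckpt = _out(cfg) / "train" / "checkpoint"
    if not (ckpt / "config.json").exists():
        raise MissingArtifactError("train", str(ckpt))
    split_file = _out(cfg) / "train" / "split.json"
    if not split_file.exists():
        raise MissingArtifactError("train", str(split_file))
    split_d = json.loads(split_file.read_text())
    from .training import SplitPlan
    return load_checkpoint(ckpt), SplitPlan(**split_d)


def stage_evaluate(cfg: PipelineConfig) -> Path:
    handle, split = _load_model(cfg)
    epoch_sets = _load_epoch_sets(cfg)
    out = _out(cfg) / "evaluate"
    out.mkdir(exist_ok=True)
    report = evaluate(handle, epoch_sets[split.test_idx])
    report.to_json(out / "eval_report.json")
    report.confusion_csv(out / "confusion.csv")
    _stamp(cfg, out, {"test_accuracy_pct": report.accuracy_pct})
    logger.info("[evaluate] test accuracy %.1f%%", report.accuracy_pct)
    return out


def stage_encode(cfg: PipelineConfig) -> Path:
    handle, split = _load_model(cfg)
    if not handle.is_encoder:
        # the encode stage requires the embedding variant; build + retrain it
        raise MissingArtifactError(
            "train", "an 'eegnet_plus' checkpoint (set model_kind: eegnet_plus)")
    epoch_sets = _load_epoch_sets(cfg)
    out = _out(cfg) / "encode"
    out.mkdir(exist_ok=True)
    emb = extract_embedding(handle, epoch_sets[split.test_idx])
    np.save(out / "test_embeddings.npy", emb)
    _stamp(cfg, out, {"n_embeddings": len(emb), "dim": int(emb.shape[1])})
    return out


def stage_finetune(cfg: PipelineConfig) -> Path:
    handle, split = _load_model(cfg)
    if not handle.is_encoder:
        raise MissingArtifactError(
            "train", "an 'eegnet_plus' checkpoint (set model_kind: eegnet_plus)")
    epoch_sets = _load_epoch_sets(cfg)
    sim_dir = _out(cfg) / "simulate" / "stimuli"
    if not (sim_dir / "manifest.csv").exists():
        raise MissingArtifactError("simulate", str(sim_dir / "manifest.csv"))
    out = _out(cfg) / "finetune"
    out.mkdir(exist_ok=True)

    stim = generate_stimulus_images(cfg.session, side_px=cfg.side_px,
                                    seed=cfg.seed + 11)
    images, image_labels = stim.flat()
    ae = dif.train_latent_autoencoder(images, dif.AutoencoderConfig(
        epochs=cfg.ae_epochs, max_holdout_mse=cfg.ae_holdout_mse,
        seed=cfg.seed + 21))
    latents = ae.encode(images)
    schedule = dif.DiffusionSchedule.linear(T=cfg.schedule_T)
    unet = dif.ConditionedUNet(dif.UNetConfig(),
                               np.random.default_rng(cfg.seed + 41))
    # conditional pretraining in a separate context: random class prompts
    prompts = np.random.default_rng(cfg.seed + 43).standard_normal(
        (cfg.session.n_classes, 512)).astype(np.float32)
    dif.train_denoiser(unet, latents, schedule, dif.DiffusionTrainConfig(
        epochs=cfg.pretrain_epochs, seed=cfg.seed + 41),
        embeddings=prompts[image_labels])

    lookup = latents.reshape(cfg.session.n_classes,
                             cfg.session.images_per_class, *latents.shape[1:])
    pairs = merge_epochs([epoch_sets[i]
                          for i in split.train_idx + [split.val_idx]])
    pairs.image_ids = np.concatenate(
        [epoch_sets[i].image_ids for i in split.train_idx + [split.val_idx]])
    pair_latents = lookup[pairs.retained_labels().astype(int),
                          pairs.image_ids[pairs.retained].astype(int)]
    result = dif.finetune(handle, unet, schedule, pairs, pair_latents,
                          dif.FinetuneConfig(epochs=cfg.finetune_epochs,
                                             max_pairs=cfg.max_finetune_pairs,
                                             seed=cfg.seed + 61))
    np.savez(out / "embed_standardizer.npz", mu=result.embed_mu,
             sd=result.embed_sd)
    np.savez(out / "unet.npz", **unet.state_dict())
    np.savez(out / "autoencoder.npz", **ae.net.state_dict(),
             __latent_scale__=ae.latent_scale)
    save_checkpoint(handle, out / "encoder")
    (out / "finetune_history.json").write_text(json.dumps(result.history))
    (out / "trainable.json").write_text(json.dumps(result.trainable_names))
    _stamp(cfg, out)
    return out


def stage_reconstruct(cfg: PipelineConfig) -> Path:
    ft = _out(cfg) / "finetune"
    if not (ft / "unet.npz").exists():
        raise MissingArtifactError("finetune", str(ft / "unet.npz"))
    epoch_sets = _load_epoch_sets(cfg)
    _, split = _load_model(cfg)
    handle = load_checkpoint(ft / "encoder")
    out = _out(cfg) / "reconstruct"
    out.mkdir(exist_ok=True)

    stim = generate_stimulus_images(cfg.session, side_px=cfg.side_px,
                                    seed=cfg.seed + 11)
    images, image_labels = stim.flat()
    ae_net = dif.AutoencoderNet(dif.AutoencoderConfig(),
                                np.random.default_rng(0))
    with np.load(ft / "autoencoder.npz") as z:
        state = {k: z[k] for k in z.files if k != "__latent_scale__"}
        scale = float(z["__latent_scale__"])
    ae_net.load_state_dict(state)
    ae = dif.LatentAutoencoder(net=ae_net, latent_scale=scale)
    unet = dif.ConditionedUNet(dif.UNetConfig(),
                               np.random.default_rng(0))
    with np.load(ft / "unet.npz") as z:
        unet.load_state_dict({k: z[k] for k in z.files})
    schedule = dif.DiffusionSchedule.linear(T=cfg.schedule_T)
    clf = dif.train_surrogate(images, image_labels, cfg.session.n_classes,
                              seed=cfg.seed + 31)

    with np.load(ft / "embed_standardizer.npz") as z:
        emb_mu, emb_sd = z["mu"], z["sd"]

    def transform(e):
        return ((e - emb_mu) / emb_sd).astype(np.float32)

    test = epoch_sets[split.test_idx]
    keep = np.flatnonzero(test.retained)[:cfg.max_test_images]
    sub = test.subset(keep)
    emb = transform(extract_embedding(handle, sub))
    latent_shape = ae.encode(images[:1]).shape[1:]
    stacks, seeds = [], []
    for s in range(cfg.n_samples):
        stacks.append(dif.sample_plms(unet, schedule, emb, latent_shape,
                                      cfg.plms_steps, seed=cfg.seed + 100 + s,
                                      decoder=ae))
        seeds.append(cfg.seed + 100 + s)
    samples = np.stack(stacks, axis=1)
    labels = sub.retained_labels().astype(int)
    report = dif.evaluate_reconstructions(samples, labels, clf, cfg.n_way,
                                          trials=cfg.metric_trials,
                                          seed=cfg.seed, sample_seeds=seeds)
    report.to_json(out / "reconstruction_report.json")

    recs = _load_sessions(cfg)
    null_rep = dif.null_control(recs[split.test_idx], handle, unet, schedule,
                                ae, clf, n_way=cfg.n_way, steps=cfg.plms_steps,
                                n_samples=cfg.n_samples,
                                trials=cfg.metric_trials, seed=cfg.seed + 500,
                                max_windows=cfg.max_null_windows,
                                latent_hw=latent_shape[-1],
                                embed_transform=transform)
    null_rep.to_json(out / "null_report.json")
    _save_sample_grid(samples, out)
    _stamp(cfg, out)
    return out


def _save_sample_grid(samples: np.ndarray, out: Path, max_images: int = 8):
    from PIL import Image
    import pandas as pd
    rows = []
    for i in range(min(max_images, len(samples))):
        for j in range(samples.shape[1]):
            name = f"img{i:03d}_sample{j}.png"
            arr = (np.clip(samples[i, j], 0, 1) * 255).astype(np.uint8)
            Image.fromarray(arr).save(out / name)
            rows.append({"image_id": i, "sample_index": j, "path": name})
    pd.DataFrame(rows).to_csv(out / "samples_manifest.csv", index=False)


def stage_report(cfg: PipelineConfig) -> Path:
    out_root = _out(cfg)
    out = out_root / "report"
    out.mkdir(exist_ok=True)
    summary: dict = {"seed": cfg.seed, "config_hash": cfg.config_hash()}
    eval_file = out_root / "evaluate" / "eval_report.json"
    if not eval_file.exists():
        raise MissingArtifactError("evaluate", str(eval_file))
    summary["classification"] = json.loads(eval_file.read_text())
    drop_file = out_root / "preprocess" / "drop_report.csv"
    if drop_file.exists():
        summary["drop_report"] = drop_file.read_text()
    for name in ("reconstruction_report", "null_report"):
        f = out_root / "reconstruct" / f"{name}.json"
        if f.exists():
            summary[name] = json.loads(f.read_text())
    (out / "summary.json").write_text(json.dumps(summary, indent=2))
    return out


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "preprocess": stage_preprocess,
    "train": stage_train,
    "evaluate": stage_evaluate,
    "encode": stage_encode,
    "finetune": stage_finetune,
    "reconstruct": stage_reconstruct,
    "report": stage_report,
}


def run_stage(cfg: PipelineConfig, stage: str) -> Path:
    if stage not in _STAGE_FUNCS:
        raise ConfigError(f"unknown stage {stage!r}; choose from {STAGES}")
    return _STAGE_FUNCS[stage](cfg)


def run_pipeline(cfg: PipelineConfig, from_stage: str = "simulate") -> Path:
    """Run all stages from ``from_stage`` on; reconstruction stages are
    skipped when disabled or when the classifier has no embedding head."""
    out = _out(cfg)
    (out / "config_used.yaml").write_text(yaml.safe_dump(cfg.to_dict()))
    start = STAGES.index(from_stage)
    for stage in STAGES[start:]:
        if stage in ("encode", "finetune", "reconstruct") and (
                not cfg.reconstruct_enabled or cfg.model_kind != "eegnet_plus"):
            logger.info("[%s] skipped (reconstruction disabled)", stage)
            continue
        logger.info("=== stage %s ===", stage)
        run_stage(cfg, stage)
    return out
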