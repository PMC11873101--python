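"""End-to-end experiment orchestration: simulate -> pretrain -> probe ->
predict -> evaluate -> attribute.

One :class:`ExperimentConfig` drives the whole run. Every stochastic stage
draws its seed from the single master seed, train/test splits are grouped
by participant and held fixed across stages within a trial, and metrics
are averaged over trials. The results bundle written to ``out_dir``
contains per-trial metrics JSON, a mean ± sd summary, predictions TSV,
SSL loss traces, a stage-level data-access audit, and an artifact manifest
with checksums.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .attribution import class_mean_attribution, mean_control_baseline, smooth_threshold
from .augment import AugmentConfig
from .backbone import TEST_TINY, TINY, BackboneConfig, ConvNeXtBackbone
from .metrics import (ConfusionMatrix, balanced_accuracy, mcc, micro_recall,
                      sensitivity_specificity, summarize_trials)
from .nnclr import SSLConfig, train_ssl
from .phantom import LabeledCohort, PhantomSpec, generate_cohort
from .probe import (ProbeConfig, extract_features, participant_split,
                    predict_scan, train_probe, train_probe_finetune)
from .volume import Volume, prepare_slices

__all__ = ["PhantomBlock", "ExperimentConfig", "run_experiment"]

_BACKBONES = {"tiny": TINY, "test_tiny": TEST_TINY}


@dataclass
class PhantomBlock:
    """Synthetic-cohort settings for a run (ignored when data is external)."""

    n_per_class: int = 12
    effect_size: float = 0.3
    noise_sd: float = 0.05
    scans_per_participant: int = 1
    shape: tuple[int, int, int] = (64, 80, 64)


@dataclass
class ExperimentConfig:
    """Configuration of a full experiment; YAML round-trippable."""

    seed: int = 0
    out_dir: str = "results"
    backbone: str = "test_tiny"
    n_keep: int = 20                       # coronal slices per scan
    n_trials: int = 3
    # full-scale protocol uses 0.1; a desk-scale cohort needs a larger
    # fraction to keep the per-trial test set meaningful
    test_fraction: float = 0.2
    freeze_backbone: bool = True
    phantom: PhantomBlock = field(default_factory=PhantomBlock)
    ssl_epochs: int = 60
    ssl_batch_size: int = 64
    queue_size: int = 8192
    temperature: float = 0.1
    ssl_lr: float = 1e-4
    probe_epochs: int = 60
    probe_batch_size: int = 64
    probe_lr: float = 1e-2
    restart_period: int = 20
    attribution_steps: int = 0             # 0 disables the attribution stage
    attribution_sigma: float = 1.0
    attribution_keep_quantile: float = 0.9

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["phantom"]["shape"] = list(d["phantom"]["shape"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ExperimentConfig":
        d = yaml.safe_load(Path(path).read_text())
        pb = d.pop("phantom", {})
        if "shape" in pb:
            pb["shape"] = tuple(pb["shape"])
        return cls(phantom=PhantomBlock(**pb), **d)

    def backbone_config(self) -> BackboneConfig:
        try:
            return _BACKBONES[self.backbone]
        except KeyError:
            raise ValueError(f"unknown backbone {self.backbone!r}; "
                             f"choose from {sorted(_BACKBONES)}") from None


def _slices_for(volumes: list[Volume], n_keep: int):
    out = []
    for v in volumes:
        out.extend(prepare_slices(v, n_keep))
    return out


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_experiment(cfg: ExperimentConfig,
                   cohort: LabeledCohort | None = None) -> dict:
    """Run all stages for every trial and write the results bundle.

    When ``cohort`` is None a phantom cohort is generated from the config.
    Returns a dict with per-trial metrics, the summary table and the
    confusion matrices; everything is also written under ``cfg.out_dir``.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")

    if cohort is None:
        spec = PhantomSpec(shape=cfg.phantom.shape,
                           effect_size=cfg.phantom.effect_size,
                           noise_sd=cfg.phantom.noise_sd,
                           scans_per_participant=cfg.phantom.scans_per_participant,
                           seed=cfg.seed)
        cohort = generate_cohort(spec, cfg.phantom.n_per_class)
    class_names = tuple(sorted(cohort.manifest["diagnosis"].unique()))
    vol_by_id = {v.volume_id: v for v in cohort.volumes}
    manifest = cohort.manifest.assign(
        volume_id=[v.volume_id for v in cohort.volumes])

    splits = participant_split(manifest, cfg.test_fraction, cfg.n_trials,
                               seed=cfg.seed)
    bb_cfg = cfg.backbone_config()
    per_trial: list[dict] = []
    access_log: dict = {}
    all_predictions: list[dict] = []
    confusions: list[ConfusionMatrix] = []

    for trial, (train_m, test_m) in enumerate(splits):
        train_vols = [vol_by_id[i] for i in train_m["volume_id"]]
        test_vols = [vol_by_id[i] for i in test_m["volume_id"]]
        access_log[f"trial{trial}"] = {
            "ssl_and_probe_volumes": sorted(train_m["volume_id"]),
            "evaluation_volumes": sorted(test_m["volume_id"]),
        }
        train_slices = _slices_for(train_vols, cfg.n_keep)

        extractor = ConvNeXtBackbone(bb_cfg, seed=cfg.seed * 101 + trial)
        ssl_cfg = SSLConfig(epochs=cfg.ssl_epochs, batch_size=cfg.ssl_batch_size,
                            queue_size=cfg.queue_size,
                            temperature=cfg.temperature, lr=cfg.ssl_lr,
                            seed=cfg.seed * 101 + trial)
        extractor, _, trace = train_ssl(extractor, train_slices, ssl_cfg)
        trace.to_csv(out / f"ssl_loss_trial{trial}.csv", index=False)

        probe_cfg = ProbeConfig(n_classes=len(class_names),
                                class_names=class_names,
                                freeze_backbone=cfg.freeze_backbone,
                                epochs=cfg.probe_epochs,
                                batch_size=cfg.probe_batch_size,
                                lr=cfg.probe_lr,
                                restart_period=cfg.restart_period,
                                seed=cfg.seed * 101 + trial)
        if cfg.freeze_backbone:
            feats = extract_features(extractor, train_slices)
            fcols = [c for c in feats.columns if c.startswith("f")]
            head = train_probe(feats[fcols].to_numpy(),
                               feats["label"].tolist(), probe_cfg)
        else:
            head = train_probe_finetune(extractor, train_slices, probe_cfg)

        y_true, y_pred = [], []
        for v in test_vols:
            pred = predict_scan(extractor, head, v, cfg.n_keep, class_names)
            y_true.append(v.label)
            y_pred.append(pred.final_label)
            all_predictions.append({
                "trial": trial, "volume_id": v.volume_id,
                "true_label": v.label, "final_label": pred.final_label,
                "vote_margin": pred.vote_margin,
                **{f"mean_score_{c}": float(s)
                   for c, s in zip(class_names, pred.mean_scores)},
            })
        cm = ConfusionMatrix.from_labels(y_true, y_pred, class_names)
        confusions.append(cm)
        row = {"balanced_accuracy": balanced_accuracy(cm),
               "mcc": mcc(cm, positive_class=class_names[-1]),
               "micro_recall": micro_recall(cm)}
        if len(class_names) == 2:
            sens, spec_ = sensitivity_specificity(cm, class_names[-1])
            row.update(sensitivity=sens, specificity=spec_)
        per_trial.append(row)

        if cfg.attribution_steps > 0:
            _run_attribution(cfg, extractor, head, train_vols, test_vols,
                             class_names, out, trial)

    summary = summarize_trials(per_trial)
    summary.to_csv(out / "summary.csv")
    pd.DataFrame(all_predictions).to_csv(out / "predictions.tsv",
                                         sep="\t", index=False)
    (out / "metrics.json").write_text(json.dumps({
        "class_names": list(class_names),
        "per_trial": per_trial,
        "summary": {m: {"mean": float(summary.loc[m, "mean"]),
                        "sd": float(summary.loc[m, "sd"])}
                    for m in summary.index},
        "confusion_matrices": [c.counts.tolist() for c in confusions],
    }, indent=2))
    (out / "data_access_audit.json").write_text(json.dumps(access_log, indent=2))
    artifact_manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                         if p.is_file() and p.name != "artifacts.json"}
    (out / "artifacts.json").write_text(json.dumps(artifact_manifest, indent=2))
    return {"per_trial": per_trial, "summary": summary,
            "confusion_matrices": confusions, "class_names": class_names,
            "predictions": pd.DataFrame(all_predictions)}


def _run_attribution(cfg: ExperimentConfig, extractor, head,
                     train_vols, test_vols, class_names, out: Path,
                     trial: int) -> None:
    """Mean IG maps per class for one trial, saved as .npy stacks."""
    for target, cname in enumerate(class_names):
        controls = [v for v in train_vols if v.label != cname]
        per_index: dict[int, list[np.ndarray]] = {}
        for v in controls:
            for rec in prepare_slices(v, cfg.n_keep):
                per_index.setdefault(rec.slice_index, []).append(rec.pixels)
        baselines = [mean_control_baseline(per_index[i])
                     for i in sorted(per_index)]
        try:
            amap = class_mean_attribution(
                extractor, head, test_vols, target, class_names,
                cfg.n_keep, baselines, n_steps=cfg.attribution_steps)
        except ValueError:
            continue  # no correctly classified scan of this class this trial
        amap = smooth_threshold(amap, cfg.attribution_sigma,
                                cfg.attribution_keep_quantile)
        np.save(out / f"attribution_trial{trial}_{cname}.npy", amap.scores)
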