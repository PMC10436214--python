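"""Experiment orchestration: one reproducible run description binding
data, model family, losses, training and evaluation.

``run_experiment`` executes the full pipeline on a phantom cohort or a
manifest of real volumes: generate/load -> tissue-filter + normalize ->
patient-disjoint split (+ unpaired domains, + FID holdout) -> train ->
lowest-FID epoch selection -> test-set metrics -> regional GM/WM
analysis.  A single global seed fans out to fixed named sub-seeds (data,
split, fid, training) so each randomness source is isolated.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .embedders import RandomConvEmbedder
from .estimators import AutoencoderTranslator, CycleGANTranslator, Pix2PixTranslator
from .exceptions import ConfigurationError
from .metrics import MetricConfig, metric_report
from .networks import MODEL_FAMILIES
from .phantoms import PhantomParams, generate_cohort, load_manifest, load_subject, write_cohort
from .preprocessing import (
    holdout_fid_subset,
    normalize_intensity,
    save_split,
    select_slices,
    split_paired,
    split_unpaired,
)
from .regional import median_correlation, regional_medians
from .training import select_best_epoch

__all__ = ["RunConfig", "run_experiment", "derive_seeds"]


def derive_seeds(global_seed: int) -> dict[str, int]:
    """Fan one global seed out to fixed named sub-seeds (all < 2^31)."""
    state = np.random.SeedSequence(int(global_seed) % 2**31).generate_state(4)
    names = ("data", "split", "fid", "train")
    return {name: int(s % 2**31) for name, s in zip(names, state)}


@dataclass
class RunConfig:
    """One reproducible experiment description."""

    family: str = "pix2pix"
    target: str = "fa"  # "fa" | "md"
    out_dir: str = "runs/experiment"
    seed: int = 0
    phantom: dict | None = None  # PhantomParams fields
    manifest: str | None = None  # alternative: pre-existing data manifest
    model: dict = field(default_factory=dict)  # base_filters, depth, n_resnet_blocks
    loss: dict = field(default_factory=dict)  # lambda_l1, lambda_cycle, label_smoothing
    train: dict = field(default_factory=dict)  # epochs, batch_size, lrs, fid_every_epoch
    metric: dict = field(default_factory=dict)  # MetricConfig fields
    train_fraction: float = 0.8
    slice_threshold: float = 0.15
    fid_images: int = 256
    fid_subjects: int = 9

    def validate(self) -> None:
        if self.family not in MODEL_FAMILIES:
            raise ConfigurationError(f"unknown family {self.family!r}")
        if self.target not in ("fa", "md"):
            raise ConfigurationError("target must be 'fa' or 'md'")
        if (self.phantom is None) == (self.manifest is None):
            raise ConfigurationError("exactly one data source (phantom or manifest) required")
        if not 0 < self.train_fraction < 1:
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.phantom is not None:
            PhantomParams(**{**self.phantom, "seed": 0})  # field validation
        MetricConfig(**self.metric)

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        return cls(**data)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


def _make_estimator(config: RunConfig, seeds: dict[str, int], embedder):
    common = dict(
        random_state=seeds["train"],
        fid_every_epoch=bool(config.train.get("fid_every_epoch", False)),
        embedder=embedder,
        **{k: v for k, v in config.train.items() if k != "fid_every_epoch"},
    )
    model = config.model
    loss = config.loss
    if config.family == "pix2pix":
        return Pix2PixTranslator(
            base_filters=model.get("base_filters", 64),
            depth=model.get("depth"),
            lambda_l1=loss.get("lambda_l1", 100.0),
            label_smoothing=loss.get("label_smoothing", 0.0),
            **common,
        )
    if config.family == "autoencoder":
        common.pop("lr_discriminator", None)
        return AutoencoderTranslator(
            base_filters=model.get("base_filters", 64),
            depth=model.get("depth"),
            **common,
        )
    return CycleGANTranslator(
        paired=(config.family == "cyclegan_paired"),
        base_filters=model.get("base_filters", 64),
        n_resnet_blocks=model.get("n_resnet_blocks"),
        lambda_cycle=loss.get("lambda_cycle", 10.0),
        label_smoothing=loss.get("label_smoothing", 0.1),
        **common,
    )


def _prepare_subject(subject, target: str, threshold: float):
    """Tissue-filter on the source volume, then normalize both modalities."""
    eligible = select_slices(subject.source_volume, threshold)
    target_vol = subject.target_fa if target == "fa" else subject.target_md
    if not eligible:
        return eligible, None, None
    x = normalize_intensity(subject.source_volume)
    y = normalize_intensity(target_vol)
    return eligible, x, y


def run_experiment(config: RunConfig) -> dict:
    """Execute one experiment end to end; returns the run summary dict."""
    config.validate()
    seeds = derive_seeds(config.seed)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config.save(out_dir / "config.yaml")

    # -- data ---------------------------------------------------------------
    if config.phantom is not None:
        params = PhantomParams(**{**config.phantom, "seed": seeds["data"]})
        subjects = generate_cohort(params)
        manifest_path = write_cohort(subjects, out_dir / "data")
        base_dir = out_dir / "data"
    else:
        manifest_path = Path(config.manifest)
        base_dir = manifest_path.parent
        subjects = [load_subject(e, base_dir) for e in load_manifest(manifest_path)]
    by_id = {s.subject_id: s for s in subjects}

    prepared = {}
    for sid, subj in by_id.items():
        eligible, x, y = _prepare_subject(subj, config.target, config.slice_threshold)
        if eligible:
            prepared[sid] = (eligible, x, y)

    # -- splits -------------------------------------------------------------
    split = split_paired(sorted(prepared), config.train_fraction, seed=seeds["split"])
    if config.family == "cyclegan_unpaired":
        split = split_unpaired(split, seed=seeds["split"])
    fid_on = bool(config.train.get("fid_every_epoch", False))
    if fid_on:
        eligible_map = {sid: prepared[sid][0] for sid in split.train_ids}
        split = holdout_fid_subset(
            split, eligible_map, n_images=config.fid_images,
            n_subjects=config.fid_subjects, seed=seeds["fid"],
        )
    save_split(split, out_dir / "split.json")
    held = set(split.fid_holdout)

    def slices_of(sid, which):
        eligible, x, y = prepared[sid]
        vol = x if which == "x" else y
        keep = [z for z in eligible if (sid, z) not in held]
        return [vol[:, :, z] for z in keep]

    if config.family == "cyclegan_unpaired":
        src_dom, tgt_dom = split.unpaired_domains
        x_train = [s for sid in sorted(src_dom) for s in slices_of(sid, "x")]
        y_train = [s for sid in sorted(tgt_dom) for s in slices_of(sid, "y")]
    else:
        x_train = [s for sid in sorted(split.train_ids) for s in slices_of(sid, "x")]
        y_train = [s for sid in sorted(split.train_ids) for s in slices_of(sid, "y")]
    fid_sources = [
        prepared[sid][1][:, :, z] for sid, z in split.fid_holdout
    ] if fid_on else None

    # -- train --------------------------------------------------------------
    embedder = RandomConvEmbedder(seed=seeds["fid"]) if fid_on else None
    est = _make_estimator(config, seeds, embedder)
    est.fit(
        np.asarray(x_train), np.asarray(y_train),
        fid_sources=np.asarray(fid_sources) if fid_sources else None,
    )
    state = est.training_state_
    log = pd.DataFrame(
        {
            "epoch": np.arange(len(state.gen_losses)),
            "gen_loss": state.gen_losses,
            "disc_loss": state.disc_losses,
            "fid": state.fid_history if state.fid_history else np.nan,
        }
    )
    log.to_csv(out_dir / "training_log.csv", index=False)

    # -- test-set evaluation ------------------------------------------------
    metric_config = MetricConfig(**config.metric)
    rows = []
    regional_rows = {"GM": [], "WM": []}
    for sid in sorted(split.test_ids):
        eligible, x, y = prepared[sid]
        real = np.stack([y[:, :, z] for z in eligible], axis=2)
        synth = np.stack(
            list(est.predict(np.asarray([x[:, :, z] for z in eligible]))), axis=2
        )
        for k, z in enumerate(eligible):
            rep = metric_report(real[:, :, k], synth[:, :, k], metric_config, slice_index=z)
            rows.append(
                dict(subject=sid, slice=z, psnr=rep.psnr_db, ssim=rep.ssim,
                     mse=rep.mse, hist_kl=rep.hist_kl)
            )
        subj = by_id[sid]
        for label, mask_vol in (("GM", subj.gm_mask), ("WM", subj.wm_mask)):
            mask = np.stack([mask_vol[:, :, z] for z in eligible], axis=2).astype(bool)
            if mask.sum() == 0:
                continue
            stats = regional_medians(real, synth, mask, label, metric_config)
            regional_rows[label].append(
                dict(subject=sid, median_real=stats.median_real,
                     median_synthetic=stats.median_synthetic,
                     psnr=stats.report.psnr_db, ssim=stats.report.ssim,
                     mse=stats.report.mse, hist_kl=stats.report.hist_kl)
            )
    metrics_df = pd.DataFrame(rows)
    metrics_df.to_csv(out_dir / "metrics.csv", index=False)

    correlations = {}
    for label, entries in regional_rows.items():
        if len(entries) >= 3:
            res = median_correlation(
                [e["median_real"] for e in entries],
                [e["median_synthetic"] for e in entries],
            )
            correlations[label] = {"r": res.r, "p_value": res.p_value, "n": res.n}
    regional_payload = {"per_subject": regional_rows, "correlations": correlations}
    (out_dir / "regional.json").write_text(json.dumps(regional_payload, indent=2))

    summary = {
        "family": config.family,
        "target": config.target,
        "manifest": str(manifest_path),
        "n_train_slices": len(x_train),
        "n_test_subjects": len(split.test_ids),
        "best_epoch": (
            select_best_epoch(state.fid_history) if state.fid_history else None
        ),
        "mean_metrics": {
            k: float(metrics_df[k].replace(np.inf, np.nan).mean())
            for k in ("psnr", "ssim", "mse", "hist_kl")
        } if len(metrics_df) else {},
        "correlations": correlations,
        "paths": {
            "config": str(out_dir / "config.yaml"),
            "split": str(out_dir / "split.json"),
            "training_log": str(out_dir / "training_log.csv"),
            "metrics": str(out_dir / "metrics.csv"),
            "regional": str(out_dir / "regional.json"),
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
    return summary
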