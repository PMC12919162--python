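"""End-to-end orchestration: simulate/ingest -> preprocess -> extract ->
split -> train -> evaluate -> explain, with one root seed fanned out to
named per-stage streams and a JSON manifest recording configuration,
seeds and artifact paths.

The evaluation protocol mirrors the study design: one outer 80/20
subject split; five repeated inner group splits of the training
subjects; per inner fold the feature normalization is fitted on the
fold's training epochs only, both models are trained with early
stopping, the outer test set is scored with the fold's checkpoint, and
attributions are computed for the Transformer.  Reported metrics are
mean +/- SD across the inner folds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .attribution import AttributionConfig, additivity_gap, aggregate, explain
from .connectivity import NullModelConfig
from .evaluation import (
    aggregate_fold_metrics,
    confusion_from_predictions,
    make_split,
    metrics,

)
from .features import (
    FeatureTensor,
    extract_feature_tensor,
    normalize_features,
    save_feature_tensor,
)
from .models import (
    CLASS_ORDER,
    EEGNetConfig,
    TransformerConfig,
    build_eegnet_features,
    build_transformer,
    predict_proba,
    train,
)
from .nonlinear import ChaosParams, EntropyParams
from .preprocess import preprocess_recordings
from .simulate import CohortSpec, generate_cohort

__all__ = ["RunConfig", "stage_seed", "permute_labels_by_subject", "run_all"]

log = logging.getLogger("mcieeg")


@dataclass
class RunConfig:
    """One document holding every stage's configuration."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    data_dir: str | None = None  # ingest CSV cohort instead of simulating
    low_hz: float = 0.5
    high_hz: float = 40.0
    fs_out: float = 100.0
    epoch_duration: float = 3.0
    drop_channels: tuple[str, ...] = ("POz",)
    augment: bool = True
    entropy: EntropyParams = field(default_factory=EntropyParams)
    chaos: ChaosParams = field(default_factory=ChaosParams)
    coherence_threshold: float = 0.5
    null_model: NullModelConfig = field(default_factory=NullModelConfig)
    transformer: TransformerConfig = field(default_factory=TransformerConfig)
    eegnet: EEGNetConfig = field(default_factory=EEGNetConfig)
    n_inner_folds: int = 5
    attribution: AttributionConfig = field(default_factory=AttributionConfig)
    seed: int = 0
    train_eegnet: bool = True
    version: str = __version__

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        nested = {
            "cohort": CohortSpec,
            "entropy": EntropyParams,
            "chaos": ChaosParams,
            "null_model": NullModelConfig,
            "transformer": TransformerConfig,
            "eegnet": EEGNetConfig,
            "attribution": AttributionConfig,
        }
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        for key, typ in nested.items():
            if key in d and isinstance(d[key], dict):
                sub_known = set(typ.__dataclass_fields__)
                sub_unknown = set(d[key]) - sub_known
                if sub_unknown:
                    raise ValueError(
                        f"unknown config field(s) in {key}: {sorted(sub_unknown)}"
                    )
                fixed = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in d[key].items()
                }
                d[key] = typ(**fixed)
        for key in ("drop_channels",):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def stage_seed(root: int, stage: str) -> int:
    """Deterministic per-stage substream of the root seed (< 2**31)."""
    import zlib

    ss = np.random.SeedSequence([root, zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def permute_labels_by_subject(ft: FeatureTensor, seed: int) -> FeatureTensor:
    """Shuffle class labels at the subject level (permutation null).

    Every epoch of a subject receives the subject's permuted label, so
    the within-subject epoch structure is preserved while any true
    label-signal association is destroyed.
    """
    rng = np.random.default_rng(seed)
    subjects, first = np.unique(ft.subject_ids, return_index=True)
    subj_labels = ft.labels[first]
    permuted = subj_labels[rng.permutation(len(subjects))]
    mapping = dict(zip(subjects.tolist(), permuted.tolist()))
    out = ft.subset(np.arange(len(ft)))
    out.labels = np.array([mapping[s] for s in ft.subject_ids])
    return out


def _evaluate(state, ft_eval: FeatureTensor) -> dict[str, float]:
    probs = predict_proba(state, ft_eval)
    pred = np.array([CLASS_ORDER[i] for i in probs.argmax(axis=1)])
    cm = confusion_from_predictions(ft_eval.labels, pred)
    return metrics(cm, scores=probs[:, 1], y_true=ft_eval.labels)


def run_all(config: RunConfig, outdir: str | Path) -> Path:
    """Execute the full pipeline into a run directory; returns its path."""
    import hashlib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config_json = json.dumps(config.to_dict(), sort_keys=True, default=str)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(config_json.encode()).hexdigest(),
        "version": __version__,
        "stage_seeds": {
            name: stage_seed(config.seed, name)
            for name in ["augment", "split"]
            + [f"train{k}" for k in range(config.n_inner_folds)]
            + [f"shap{k}" for k in range(config.n_inner_folds)]
        },
        "stages": {},
    }
    t_all = time.time()

    def stage(name):
        log.info("stage %s started", name)
        return time.time()

    def done(name, t0, **info):
        manifest["stages"][name] = {"seconds": round(time.time() - t0, 2), **info}
        log.info("stage %s finished in %.1fs", name, time.time() - t0)

    try:
        t0 = stage("ingest")
        if config.data_dir is not None:
            from .io import read_csv_cohort

            recordings = read_csv_cohort(config.data_dir)
        else:
            recordings = generate_cohort(config.cohort)
        done("ingest", t0, n_recordings=len(recordings))

        t0 = stage("preprocess")
        eps = preprocess_recordings(
            recordings,
            low=config.low_hz,
            high=config.high_hz,
            fs_out=config.fs_out,
            epoch_duration=config.epoch_duration,
            drop=config.drop_channels,
            augment=config.augment,
            seed=stage_seed(config.seed, "augment"),
        )
        done("preprocess", t0, n_epochs=len(eps), shape=list(eps.epochs.shape))

        t0 = stage("extract")
        ft_raw = extract_feature_tensor(
            eps,
            ep=config.entropy,
            cp=config.chaos,
            null_cfg=config.null_model,
            threshold=config.coherence_threshold,
        )
        done("extract", t0, shape=list(ft_raw.values.shape))

        t0 = stage("split")
        plan = make_split(
            ft_raw.subject_ids,
            ft_raw.labels,
            seed=stage_seed(config.seed, "split"),
            n_inner=config.n_inner_folds,
        )
        test_idx = plan.epoch_indices(ft_raw.subject_ids, plan.outer_test_subjects)
        with open(outdir / "split.json", "w") as fh:
            json.dump(
                {
                    "outer_test_subjects": sorted(plan.outer_test_subjects),
                    "inner_folds": [
                        {"train": sorted(tr), "val": sorted(va)}
                        for tr, va in plan.inner_folds
                    ],
                    "seed": plan.seed,
                },
                fh,
                indent=1,
            )
        done("split", t0, n_test_subjects=len(plan.outer_test_subjects))

        fold_metrics_tf, fold_metrics_en = [], []
        fold_attr = []
        additivity = []
        for k, (tr_subj, va_subj) in enumerate(plan.inner_folds):
            t0 = stage(f"fold{k}")
            tr_idx = plan.epoch_indices(ft_raw.subject_ids, tr_subj)
            va_idx = plan.epoch_indices(ft_raw.subject_ids, va_subj)
            ft_norm = normalize_features(ft_raw, tr_idx)
            ft_tr, ft_va = ft_norm.subset(tr_idx), ft_norm.subset(va_idx)
            ft_te = ft_norm.subset(test_idx)

            seed_k = stage_seed(config.seed, f"train{k}")
            model = build_transformer(config.transformer, seed=seed_k)
            st_tf = train(model, ft_tr, ft_va, config.transformer, seed=seed_k)
            fold_metrics_tf.append(_evaluate(st_tf, ft_te))

            if config.train_eegnet:
                model_e = build_eegnet_features(config.eegnet, seed=seed_k)
                st_en = train(model_e, ft_tr, ft_va, config.eegnet, seed=seed_k)
                fold_metrics_en.append(_evaluate(st_en, ft_te))

            acfg = AttributionConfig(
                background_size=config.attribution.background_size,
                n_explained=config.attribution.n_explained,
                mc_paths=config.attribution.mc_paths,
                mc_steps=config.attribution.mc_steps,
                seed=stage_seed(config.seed, f"shap{k}"),
            )
            fa = explain(st_tf, ft_te, ft_tr, acfg)
            fold_attr.append(fa)
            additivity.append(float(additivity_gap(fa).mean()))
            done(f"fold{k}", t0,
                 best_val_accuracy=st_tf.best_val_accuracy,
                 test_accuracy=fold_metrics_tf[-1]["accuracy"])

        t0 = stage("aggregate")
        report = aggregate(fold_attr)
        results = {
            "transformer": aggregate_fold_metrics(fold_metrics_tf),
            "eegnet": aggregate_fold_metrics(fold_metrics_en)
            if fold_metrics_en
            else None,
            "attribution_additivity_gap_mean": float(np.mean(additivity)),
            "channel_importance": report.channel_importance,
            "channel_importance_sd": report.channel_sd,
            "feature_importance": report.feature_importance,
            "feature_importance_sd": report.feature_sd,
            "band_importance": report.band_importance,
            "band_importance_sd": report.band_sd,
        }
        with open(outdir / "metrics.json", "w") as fh:
            json.dump(results, fh, indent=1, sort_keys=True)
        save_feature_tensor(ft_raw, str(outdir / "features_raw"))
        done("aggregate", t0)
    except Exception as exc:  # persist partial state with the failing stage
        manifest["failed_stage"] = list(manifest["stages"])[-1] if manifest["stages"] else "ingest"
        manifest["error"] = repr(exc)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1, default=str)
        raise

    manifest["total_seconds"] = round(time.time() - t_all, 2)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return outdir
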