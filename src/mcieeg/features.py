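"""Assembly of the (epochs x channels x features) tensor.

Per channel: 12 nonlinear dynamical measures followed, band by band, by
6 node-level graph metrics and 7 graph-level metrics broadcast to every
channel — 12 + 5 x (6 + 7) = 77 features at the default five bands.
Feature-wise z-scoring is fitted on training epochs only and reapplied
verbatim to held-out epochs; undefined feature values are imputed with
the training-set feature mean (never with label information).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import (
    DEFAULT_BANDS,
    GLOBAL_METRIC_NAMES,
    LOCAL_METRIC_NAMES,
    BandDefinition,
    GraphMetrics,
    NullModelConfig,
    connectivity_features,
)
from .nonlinear import FEATURE_NAMES, ChaosParams, EntropyParams, compute_nonlinear_vector
from .preprocess import EpochSet

__all__ = [
    "FeatureTensor",
    "feature_registry",
    "compute_nonlinear_features",
    "compute_connectivity_metrics",
    "assemble",
    "normalize_features",
    "apply_normalization",
    "extract_feature_tensor",
    "save_feature_tensor",
    "load_feature_tensor",
    "to_tidy_frame",
]


def feature_registry(
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    include_permutation: bool = False,
) -> tuple[list[str], list[str | None]]:
    """Ordered feature names and the band tag of each (None = nonlinear)."""
    names = list(FEATURE_NAMES)
    if include_permutation:
        names.append("PermEn")
    tags: list[str | None] = [None] * len(names)
    for band in bands:
        for m in LOCAL_METRIC_NAMES + GLOBAL_METRIC_NAMES:
            names.append(f"{band.name}_{m}")
            tags.append(band.name)
    return names, tags


@dataclass
class FeatureTensor:
    """epochs x channels x features plus registry and provenance."""

    values: np.ndarray
    feature_names: list[str]
    feature_bands: list[str | None]
    channel_names: list[str]
    subject_ids: np.ndarray
    labels: np.ndarray
    is_augmented: np.ndarray
    norm_stats: dict | None = None
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be epochs x channels x features")
        if self.values.shape[1] != len(self.channel_names):
            raise ValueError("channel axis mismatch")
        if self.values.shape[2] != len(self.feature_names):
            raise ValueError("feature axis mismatch")

    def __len__(self) -> int:
        return len(self.values)

    def subset(self, idx) -> "FeatureTensor":
        idx = np.asarray(idx)
        return FeatureTensor(
            values=self.values[idx],
            feature_names=list(self.feature_names),
            feature_bands=list(self.feature_bands),
            channel_names=list(self.channel_names),
            subject_ids=self.subject_ids[idx],
            labels=self.labels[idx],
            is_augmented=self.is_augmented[idx],
            norm_stats=self.norm_stats,
            flags=set(self.flags),
        )


def compute_nonlinear_features(
    eps: EpochSet,
    ep: EntropyParams = EntropyParams(),
    cp: ChaosParams = ChaosParams(),
    include_permutation: bool = False,
) -> np.ndarray:
    """Nonlinear vectors for every (epoch, channel); undefined values NaN."""
    names = list(FEATURE_NAMES) + (["PermEn"] if include_permutation else [])
    n_ep, n_ch, _ = eps.epochs.shape
    out = np.empty((n_ep, n_ch, len(names)))
    for i in range(n_ep):
        for c in range(n_ch):
            v = compute_nonlinear_vector(
                eps.epochs[i, c], ep, cp, include_permutation=include_permutation
            )
            out[i, c] = [v.values[n] for n in names]
    return out


def compute_connectivity_metrics(
    eps: EpochSet,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    null_cfg: NullModelConfig = NullModelConfig(),
    threshold: float = 0.5,
) -> list[dict[str, GraphMetrics]]:
    """Per-epoch, per-band graph metrics of the coherence graphs."""
    return [
        connectivity_features(
            eps.epochs[i], eps.fs, bands, null_cfg,
            channel_names=eps.channel_names, threshold=threshold,
        )
        for i in range(len(eps))
    ]


def assemble(
    eps: EpochSet,
    nonlinear_values: np.ndarray,
    conn_metrics: list[dict[str, GraphMetrics]],
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    include_permutation: bool = False,
) -> FeatureTensor:
    """Stack nonlinear and connectivity outputs in fixed registry order.

    Graph-level scalars are replicated to every channel slot of their
    epoch so each channel carries the full per-channel feature count.
    """
    n_ep, n_ch, _ = eps.epochs.shape
    if len(nonlinear_values) != n_ep or len(conn_metrics) != n_ep:
        raise ValueError(
            f"index mismatch: {n_ep} epochs vs {len(nonlinear_values)} nonlinear "
            f"rows and {len(conn_metrics)} connectivity rows"
        )
    names, tags = feature_registry(bands, include_permutation)
    vals = np.empty((n_ep, n_ch, len(names)))
    n_nl = nonlinear_values.shape[2]
    vals[:, :, :n_nl] = nonlinear_values
    for i, per_band in enumerate(conn_metrics):
        col = n_nl
        for band in bands:
            gm = per_band[band.name]
            for m in LOCAL_METRIC_NAMES:
                vals[i, :, col] = gm.local[m]
                col += 1
            for m in GLOBAL_METRIC_NAMES:
                vals[i, :, col] = gm.global_[m]  # broadcast to all channels
                col += 1
    return FeatureTensor(
        values=vals,
        feature_names=names,
        feature_bands=tags,
        channel_names=list(eps.channel_names),
        subject_ids=eps.subject_ids.copy(),
        labels=eps.labels.copy(),
        is_augmented=eps.is_augmented.copy(),
    )


def normalize_features(ft: FeatureTensor, fit_on: np.ndarray) -> FeatureTensor:
    """Feature-wise z-scoring fitted on ``fit_on`` epochs only.

    Per feature, the mean/SD are pooled over the fit epochs and all
    channels; the same statistics are applied to every epoch.  NaN
    entries are imputed with the fit-set feature mean before scaling;
    zero-variance features are centered and flagged with SD forced to 1.
    """
    fit_on = np.asarray(fit_on)
    if fit_on.dtype == bool:
        fit_on = np.flatnonzero(fit_on)
    if len(fit_on) == 0:
        raise ValueError("fit_on must be nonempty")
    fit_vals = ft.values[fit_on]  # (n_fit, ch, feat)
    import warnings as _warnings

    with np.errstate(invalid="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN features
        mean = np.nanmean(fit_vals, axis=(0, 1))
        sd = np.nanstd(fit_vals, axis=(0, 1))
    mean = np.nan_to_num(mean, nan=0.0)
    flags = set(ft.flags)
    zero = (sd == 0) | ~np.isfinite(sd)
    for f in np.flatnonzero(zero):
        flags.add(f"zero_variance_feature:{ft.feature_names[f]}")
    sd = np.where(zero, 1.0, sd)
    vals = ft.values.copy()
    nan_mask = ~np.isfinite(vals)
    if nan_mask.any():
        vals[nan_mask] = np.broadcast_to(mean, vals.shape)[nan_mask]
    vals = (vals - mean) / sd
    return FeatureTensor(
        values=vals,
        feature_names=list(ft.feature_names),
        feature_bands=list(ft.feature_bands),
        channel_names=list(ft.channel_names),
        subject_ids=ft.subject_ids.copy(),
        labels=ft.labels.copy(),
        is_augmented=ft.is_augmented.copy(),
        norm_stats={"mean": mean, "sd": sd, "fit_on": fit_on.copy()},
        flags=flags,
    )


def apply_normalization(ft: FeatureTensor, mean: np.ndarray,
                        sd: np.ndarray) -> FeatureTensor:
    """Reapply previously fitted per-feature statistics to a raw tensor
    (imputing undefined entries with the stored means)."""
    mean = np.asarray(mean, dtype=float)
    sd = np.asarray(sd, dtype=float)
    vals = ft.values.copy()
    nan_mask = ~np.isfinite(vals)
    if nan_mask.any():
        vals[nan_mask] = np.broadcast_to(mean, vals.shape)[nan_mask]
    vals = (vals - mean) / sd
    out = ft.subset(np.arange(len(ft)))
    out.values = vals
    out.norm_stats = {"mean": mean, "sd": sd, "fit_on": np.array([], dtype=int)}
    return out


def extract_feature_tensor(
    eps: EpochSet,
    ep: EntropyParams = EntropyParams(),
    cp: ChaosParams = ChaosParams(),
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    null_cfg: NullModelConfig = NullModelConfig(),
    threshold: float = 0.5,
    include_permutation: bool = False,
) -> FeatureTensor:
    """End-to-end extraction: nonlinear + connectivity -> raw tensor."""
    nl_vals = compute_nonlinear_features(eps, ep, cp, include_permutation)
    conn = compute_connectivity_metrics(eps, bands, null_cfg, threshold)
    return assemble(eps, nl_vals, conn, bands, include_permutation)


# ---------------------------------------------------------------------------
# persistence


def save_feature_tensor(ft: FeatureTensor, prefix: str) -> None:
    """Write ``<prefix>.npy`` (values) + ``<prefix>.json`` (registry)."""
    np.save(f"{prefix}.npy", ft.values)
    meta = {
        "feature_names": ft.feature_names,
        "feature_bands": ft.feature_bands,
        "channel_names": ft.channel_names,
        "subject_ids": ft.subject_ids.tolist(),
        "labels": ft.labels.tolist(),
        "is_augmented": ft.is_augmented.tolist(),
        "flags": sorted(ft.flags),
        "norm_stats": None
        if ft.norm_stats is None
        else {
            "mean": ft.norm_stats["mean"].tolist(),
            "sd": ft.norm_stats["sd"].tolist(),
            "fit_on": ft.norm_stats["fit_on"].tolist(),
        },
    }
    with open(f"{prefix}.json", "w") as fh:
        json.dump(meta, fh)


def load_feature_tensor(prefix: str) -> FeatureTensor:
    values = np.load(f"{prefix}.npy")
    with open(f"{prefix}.json") as fh:
        meta = json.load(fh)
    ns = meta["norm_stats"]
    return FeatureTensor(
        values=values,
        feature_names=meta["feature_names"],
        feature_bands=meta["feature_bands"],
        channel_names=meta["channel_names"],
        subject_ids=np.array(meta["subject_ids"]),
        labels=np.array(meta["labels"]),
        is_augmented=np.array(meta["is_augmented"], dtype=bool),
        norm_stats=None
        if ns is None
        else {
            "mean": np.array(ns["mean"]),
            "sd": np.array(ns["sd"]),
            "fit_on": np.array(ns["fit_on"]),
        },
        flags=set(meta["flags"]),
    )


def to_tidy_frame(ft: FeatureTensor) -> pd.DataFrame:
    """Long-format view: one row per (epoch, channel, feature)."""
    n_ep, n_ch, n_f = ft.values.shape
    ei, ci, fi = np.meshgrid(
        np.arange(n_ep), np.arange(n_ch), np.arange(n_f), indexing="ij"
    )
    return pd.DataFrame(
        {
            "epoch": ei.ravel(),
            "subject_id": ft.subject_ids[ei.ravel()],
            "label": ft.labels[ei.ravel()],
            "channel": np.asarray(ft.channel_names)[ci.ravel()],
            "feature": np.asarray(ft.feature_names)[fi.ravel()],
            "value": ft.values.ravel(),
        }
    )
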