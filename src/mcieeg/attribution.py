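"""Shapley-value attributions of the trained classifier, aggregated
over channels, features and frequency bands.

Per-sample signed attributions for the MCI output probability are
estimated with expected gradients — the gradient-based approximation of
Shapley values for differentiable models: for an input x and a
background reference set B,

    phi(x) = E_{b ~ B, a ~ U(0,1)} [ grad f(b + a (x - b)) * (x - b) ],

estimated by Monte Carlo with stratified interpolation coefficients.
The estimator satisfies the additivity (completeness) property
approximately: the attributions of one sample sum to about
f(x) - E_b[f(b)].

Global importances follow the standard aggregation protocol: absolute
values averaged over evaluated test samples and cross-validation folds,
per channel (averaging over features) and per feature (averaging over
channels); band-level importance is the *sum* of the band's
connectivity-feature importances, averaged across folds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .features import FeatureTensor
from .models import TrainState

__all__ = [
    "AttributionConfig",
    "FoldAttribution",
    "AttributionReport",
    "explain",
    "additivity_gap",
    "aggregate",
    "report_to_frames",
]


@dataclass(frozen=True)
class AttributionConfig:
    """Monte-Carlo budget: per explained sample, ``mc_paths`` background
    draws, each integrated along ``mc_steps`` stratified interpolation
    points (midpoint quadrature of the integrated-gradients path)."""

    background_size: int = 300
    n_explained: int = 200
    mc_paths: int = 12
    mc_steps: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_size, self.n_explained,
               self.mc_paths, self.mc_steps) < 1:
            raise ValueError("all counts must be >= 1")


@dataclass
class FoldAttribution:
    """Signed per-sample attributions of one fold + bookkeeping."""

    attributions: np.ndarray  # samples x channels x features
    explained_idx: np.ndarray
    predictions: np.ndarray  # f(x), MCI probability of each explained sample
    baselines: np.ndarray  # per-sample mean f(b) over that sample's paths
    background_mean: float  # mean MCI probability over the full background set
    feature_names: list[str]
    feature_bands: list[str | None]
    channel_names: list[str]


@dataclass
class AttributionReport:
    channel_importance: dict[str, float]
    channel_sd: dict[str, float]
    feature_importance: dict[str, float]
    feature_sd: dict[str, float]
    band_importance: dict[str, float]
    band_sd: dict[str, float]
    n_folds: int = 0
    flags: set[str] = field(default_factory=set)


def _mci_probability_grad(model, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """MCI-class probability and its gradient w.r.t. the input batch."""
    model.set_training(False)
    x = nn.Tensor(z, requires_grad=True)
    probs = nn.softmax(model(x), axis=-1)
    pick = probs * np.array([0.0, 1.0])  # mask to the positive-class column
    total = nn.sum_all(pick)
    total.backward()
    return probs.data[:, 1], x.grad


def explain(
    state: TrainState,
    ft_test: FeatureTensor,
    ft_train: FeatureTensor,
    cfg: AttributionConfig = AttributionConfig(),
) -> FoldAttribution:
    """Expected-gradients attributions for one fold.

    Background samples are drawn (seeded) from the training fold, capped
    at the fold size; attributions are computed for up to
    ``n_explained`` seeded test samples.  Train and test must be
    subject-disjoint.
    """
    overlap = set(ft_train.subject_ids) & set(ft_test.subject_ids)
    if overlap:
        raise ValueError(f"subject leakage into the explained set: {sorted(overlap)[:5]}")
    rng = np.random.default_rng(cfg.seed)
    n_bg = cfg.background_size
    if n_bg > len(ft_train):
        warnings.warn(
            f"background_size {n_bg} exceeds the training fold "
            f"({len(ft_train)} epochs); capping", stacklevel=2
        )
        n_bg = len(ft_train)
    bg_idx = rng.choice(len(ft_train), size=n_bg, replace=False)
    background = ft_train.values[bg_idx]

    n_ex = min(cfg.n_explained, len(ft_test))
    ex_idx = rng.choice(len(ft_test), size=n_ex, replace=False)

    from .models import _forward_batches

    model = state.model
    # reference output level over the full background (no gradients needed)
    background_mean = float(_forward_batches(model, background, 64)[:, 1].mean())

    p, q = cfg.mc_paths, cfg.mc_steps
    attrs = np.empty((n_ex,) + ft_test.values.shape[1:])
    preds = np.empty(n_ex)
    baselines = np.empty(n_ex)
    for s, ti in enumerate(ex_idx):
        x = ft_test.values[ti]
        b = background[rng.integers(0, n_bg, size=p)]  # one path per draw
        # stratified midpoint quadrature along each path
        alpha = (np.arange(q)[None, :] + rng.random((p, q))) / q
        z = (
            b[:, None] + alpha[:, :, None, None] * (x[None, None] - b[:, None])
        ).reshape(p * q, *x.shape)
        _, grads = _mci_probability_grad(model, z)
        grads = grads.reshape(p, q, *x.shape)
        attrs[s] = np.mean(grads.mean(axis=1) * (x[None] - b), axis=0)
        baselines[s] = _forward_batches(model, b, max(p, 16))[:, 1].mean()
        preds[s] = _forward_batches(model, x[None], 1)[0, 1]
    return FoldAttribution(
        attributions=attrs,
        explained_idx=ex_idx,
        predictions=preds,
        baselines=baselines,
        background_mean=background_mean,
        feature_names=list(ft_test.feature_names),
        feature_bands=list(ft_test.feature_bands),
        channel_names=list(ft_test.channel_names),
    )


def additivity_gap(fold: FoldAttribution) -> np.ndarray:
    """Per-sample |sum(attributions) - (f(x) - baseline)| — the residual of
    the completeness property, small for a converged estimator.  The
    baseline is each sample's own expected background output, matching
    the reference distribution the attributions were integrated from."""
    sums = fold.attributions.sum(axis=(1, 2))
    return np.abs(sums - (fold.predictions - fold.baselines))


def report_to_frames(report: AttributionReport):
    """The three importance tables (channels, bands, features) as
    DataFrames sorted by mean |attribution|, CSV-ready."""
    import pandas as pd

    def tab(mean, sd, label):
        df = pd.DataFrame(
            {label: list(mean), "mean_abs_shap": list(mean.values()),
             "sd": [sd[k] for k in mean]}
        )
        return df.sort_values("mean_abs_shap", ascending=False,
                              ignore_index=True)

    return {
        "channels": tab(report.channel_importance, report.channel_sd, "channel"),
        "bands": tab(report.band_importance, report.band_sd, "band"),
        "features": tab(report.feature_importance, report.feature_sd, "feature"),
    }


def aggregate(folds: list[FoldAttribution]) -> AttributionReport:
    """Mean-|value| importance tables across samples and folds.

    Channel importance averages |attributions| over samples and features;
    feature importance averages over samples and channels; band
    importance sums the per-feature importances of each band's
    connectivity features.  SDs are across folds.
    """
    if not folds:
        raise ValueError("need at least one fold")
    ref = folds[0]
    for f in folds[1:]:
        if f.feature_names != ref.feature_names or f.channel_names != ref.channel_names:
            raise ValueError("inconsistent feature registries across folds")

    ch_per_fold = np.stack(
        [np.abs(f.attributions).mean(axis=(0, 2)) for f in folds]
    )  # folds x channels
    feat_per_fold = np.stack(
        [np.abs(f.attributions).mean(axis=(0, 1)) for f in folds]
    )  # folds x features

    bands = sorted({b for b in ref.feature_bands if b is not None})
    band_per_fold = np.zeros((len(folds), len(bands)))
    for j, band in enumerate(bands):
        cols = [i for i, b in enumerate(ref.feature_bands) if b == band]
        band_per_fold[:, j] = feat_per_fold[:, cols].sum(axis=1)

    def tab(names, arr):
        return (
            dict(zip(names, arr.mean(axis=0).tolist())),
            dict(zip(names, arr.std(axis=0).tolist())),
        )

    ch_mean, ch_sd = tab(ref.channel_names, ch_per_fold)
    ft_mean, ft_sd = tab(ref.feature_names, feat_per_fold)
    bd_mean, bd_sd = tab(bands, band_per_fold)
    return AttributionReport(
        channel_importance=ch_mean,
        channel_sd=ch_sd,
        feature_importance=ft_mean,
        feature_sd=ft_sd,
        band_importance=bd_mean,
        band_sd=bd_sd,
        n_folds=len(folds),
    )
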