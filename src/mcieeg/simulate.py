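"""Subject-structured two-class synthetic EEG cohorts.

The generator emulates resting-state, eyes-closed scalp EEG in the
standard 10-20 montage (20 channels including POz, 256 Hz): a 1/f pink
background per channel plus stochastic narrowband oscillations centered
at the canonical rhythm frequencies, partially driven by per-band
sources common to all channels (signed per-channel couplings, as dipole
topographies would give) so that inter-channel coherence is graded,
band specific, and survives common-average referencing.  Two
controllable class contrasts mimic the regularity and
connectivity alterations reported in cognitive decline:

``complexity_effect``
    class-B (MCI-like) signals on the affected channels are AR(1)
    low-pass smoothed, lowering entropy, Lempel-Ziv complexity and
    fractal dimension monotonically with the effect size;

``coherence_effect``
    class-B coupling to the common band sources is raised in delta and
    lowered in alpha on the affected channels, shifting band-specific
    coherence monotonically.

Each subject owns an independent RNG stream derived from (seed, class,
subject index), so cohorts are bit-reproducible and stable under
subject-count changes.  Class effects are modulated per subject by a
log-normal factor so that group-wise cross-validation faces genuine
between-subject variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .preprocess import Recording

__all__ = ["MONTAGE_20", "CohortSpec", "generate_cohort"]

#: 10-20 scalp montage of the 20-channel recording setup (19 analysis
#: channels + POz, which preprocessing excludes).
MONTAGE_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2", "POz",
)

#: Rhythm center frequencies (Hz) and baseline amplitudes of the
#: oscillatory components, alpha-dominant as in eyes-closed rest.
_BAND_CENTERS = {"delta": 2.0, "theta": 6.0, "alpha": 10.0, "beta": 20.0, "gamma": 35.0}
_BAND_AMPS = {"delta": 0.7, "theta": 0.5, "alpha": 1.2, "beta": 0.45, "gamma": 0.3}
#: Fraction of each band's oscillation driven by the common source.
_COMMON_FRAC = 0.6


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition description of one synthetic cohort."""

    n_subjects_per_class: int = 20
    epochs_per_subject: int = 20
    n_channels: int = 20
    fs: float = 256.0
    epoch_duration: float = 3.0
    complexity_effect: float = 0.0
    coherence_effect: float = 0.0
    affected_channels: tuple[str, ...] | None = None  # None = all channels
    subject_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_subjects_per_class, self.epochs_per_subject, self.n_channels) < 1:
            raise ValueError("counts must be >= 1")
        if self.fs <= 2 * max(_BAND_CENTERS.values()):
            raise ValueError("fs must exceed twice the highest synthesized frequency")
        for name in ("complexity_effect", "coherence_effect"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.n_channels > len(MONTAGE_20):
            raise ValueError(f"montage provides at most {len(MONTAGE_20)} channels")
        if self.affected_channels is not None:
            unknown = set(self.affected_channels) - set(self.channel_names)
            if unknown:
                raise ValueError(f"affected_channels not in montage: {sorted(unknown)}")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return MONTAGE_20[: self.n_channels]

    @property
    def n_samples(self) -> int:
        return int(round(self.epochs_per_subject * self.epoch_duration * self.fs))


def _narrowband(
    rng: np.random.Generator, shape: tuple[int, ...], fs: float, f0: float,
    bw: float = 2.0,
) -> np.ndarray:
    """Stochastic narrowband oscillation: band-pass filtered white noise."""
    lo = max(0.3, f0 - bw / 2)
    sos = signal.butter(4, [lo, f0 + bw / 2], btype="bandpass", fs=fs,
                        output="sos")
    y = signal.sosfilt(sos, rng.standard_normal(shape), axis=-1)
    return y / np.maximum(y.std(axis=-1, keepdims=True), 1e-12)


def _pink_noise(rng: np.random.Generator, n_ch: int, n_s: int) -> np.ndarray:
    """Spectrally shaped white noise with a 1/f amplitude profile."""
    white = rng.standard_normal((n_ch, n_s))
    spec = np.fft.rfft(white, axis=1)
    f = np.fft.rfftfreq(n_s)
    scale = np.ones_like(f)
    scale[1:] = 1.0 / np.sqrt(f[1:])
    scale[0] = 0.0
    pink = np.fft.irfft(spec * scale, n=n_s, axis=1)
    pink /= pink.std(axis=1, keepdims=True)
    return pink


def _subject_recording(
    spec: CohortSpec, label: str, subject_index: int, class_index: int
) -> Recording:
    ss = np.random.SeedSequence((spec.seed, class_index, subject_index))
    rng = np.random.default_rng(ss)
    n_ch, n_s = spec.n_channels, spec.n_samples
    names = list(spec.channel_names)
    affected = (
        np.ones(n_ch, dtype=bool)
        if spec.affected_channels is None
        else np.isin(names, list(spec.affected_channels))
    )

    # per-subject modulation of the class effects (log-normal, clipped)
    mod = float(np.exp(spec.subject_sd * rng.standard_normal()))
    comp = min(1.0, spec.complexity_effect * mod) if label == "MCI" else 0.0
    cohr = min(1.0, spec.coherence_effect * mod) if label == "MCI" else 0.0

    x = _pink_noise(rng, n_ch, n_s)
    for band, f0 in _BAND_CENTERS.items():
        amp = _BAND_AMPS[band]
        common = _narrowband(rng, (n_s,), spec.fs, f0)
        # signed per-channel coupling to the common source; the signs keep
        # the source from cancelling under common-average referencing
        c = rng.uniform(0.7, 1.0, n_ch) * rng.choice([-1.0, 1.0], n_ch)
        if band == "delta":
            c[affected] *= 1.0 + cohr
        elif band == "alpha":
            c[affected] *= 1.0 - 0.9 * cohr
        private = _narrowband(rng, (n_ch, n_s), spec.fs, f0)
        x += amp * (
            _COMMON_FRAC * c[:, None] * common[None, :]
            + (1 - _COMMON_FRAC) * private
        )

    if comp > 0:
        # AR(1) smoothing on affected channels: y[t] = a y[t-1] + (1-a) x[t]
        a = 0.6 * comp
        sm = signal.lfilter([1 - a], [1, -a], x[affected], axis=1)
        # restore per-channel scale so the contrast is in shape, not gain
        sm *= x[affected].std(axis=1, keepdims=True) / np.maximum(
            sm.std(axis=1, keepdims=True), 1e-12
        )
        x[affected] = sm

    gain = 10.0 * np.exp(spec.subject_sd * rng.standard_normal())
    x *= gain  # microvolt-ish scale with between-subject amplitude variance
    sid = f"sub-{label}-{subject_index:03d}"
    return Recording(
        data=x, fs=spec.fs, channel_names=names, subject_id=sid, label=label
    )


def generate_cohort(spec: CohortSpec) -> list[Recording]:
    """All recordings of the cohort: n_subjects_per_class of each class.

    Class A ("HC") draws from the baseline signal model; class B ("MCI")
    applies the configured complexity and coherence contrasts.  Subject
    IDs are unique; identical spec + seed reproduces identical arrays.
    """
    recs = []
    for ci, label in enumerate(("HC", "MCI")):
        for si in range(spec.n_subjects_per_class):
            recs.append(_subject_recording(spec, label, si, ci))
    return recs
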