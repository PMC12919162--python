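# mcieeg

Feature-driven classification of mild cognitive impairment (MCI) from
resting-state EEG, with interpretable attributions.

Instead of feeding raw waveforms to a network, `mcieeg` represents each
3-second EEG epoch as a structured **19 channels × 77 features** matrix
— 12 nonlinear dynamical descriptors per channel (approximate, sample,
multiscale and fuzzy entropy, Kolmogorov–Sinai entropy, correlation
dimension, DFA and Hurst exponents, Katz and Higuchi fractal
dimensions, largest Lyapunov exponent, Lempel–Ziv complexity) plus,
for each of the five canonical frequency bands (δ, θ, α, β, γ), six
node-level and seven graph-level metrics of the inter-channel
coherence graph (degree, strength, weighted clustering, betweenness,
eigenvector centrality, local efficiency; global efficiency,
characteristic path length L, mean clustering C̄, small-worldness
σ = (C/C_rand)/(L/L_rand), assortativity, density, transitivity).

A Transformer encoder whose attention tokens are the 19 channels is
the primary classifier, with a feature-adapted EEGNet as the compact
convolutional baseline. Evaluation is strictly subject-wise
(GroupShuffleSplit on subject identifiers, one outer 80/20 test split,
five repeated inner train/validation splits), so reported numbers
reflect generalization to unseen individuals. Shapley-value
attributions (expected gradients) are aggregated into per-channel,
per-feature and per-band importance tables.

The package is aimed at EEG-biomarker researchers who want a
reproducible, fully testable reference pipeline: every stage — a
synthetic cohort generator with controllable class contrasts,
preprocessing, both feature families, the models (implemented on a
small in-package numpy autodiff engine), the split protocol and the
attribution aggregation — is importable, seeded and covered by
brute-force oracle tests.

## Worked example

```python
from mcieeg.simulate import CohortSpec, generate_cohort
from mcieeg.preprocess import preprocess_recordings
from mcieeg.features import extract_feature_tensor

spec = CohortSpec(
    n_subjects_per_class=6, epochs_per_subject=6,
    complexity_effect=0.8,          # MCI-like class is more regular
    coherence_effect=0.8,           # delta coupling up, alpha down
    affected_channels=("T5", "O2"),
    seed=42,
)
eps = preprocess_recordings(generate_cohort(spec))
print(eps.epochs.shape)

ft = extract_feature_tensor(eps)
print(ft.values.shape)
print(ft.feature_names[:3], "...", ft.feature_names[-1])
```

prints

```
(72, 19, 300)
(72, 19, 77)
['ApEn', 'SampEn', 'MSE'] ... gamma_transitivity
```

i.e. 12 subjects × 6 epochs survive preprocessing as 19-channel,
300-sample segments (POz dropped, 100 Hz), and extraction yields the
77-feature representation. The planted contrast is visible directly in
the features — on this cohort the class-mean sample entropy on T5 is
1.70 (HC) vs 1.50 (MCI).

The full pipeline (simulate → preprocess → extract → split → train
both models → evaluate → explain) runs from one configuration object:

```python
from mcieeg.pipeline import RunConfig, run_all
run_all(RunConfig(cohort=spec, seed=42), "runs/demo")
```

which writes `metrics.json` (fold-aggregated accuracy/AUC/F1 for both
models, channel/feature/band importance tables) and a manifest with
every stage seed. The same surface is scriptable:

```bash
mcieeg simulate --spec spec.json --out cohort/
mcieeg preprocess --in cohort/ --out epochs
mcieeg run-all --seed 42 --out runs/demo
```

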