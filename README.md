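# repgeom

Representational geometry of neural encoding models: how the latent
dimensionality of a feature representation shapes its ability to predict
brain activity, generalize to novel categories, and concentrate readout
projections.

Deep-network models of visual cortex are routinely scored by how well a
cross-validated linear regression maps their activations onto recorded
neural responses.  A geometric view asks what property of a representation
makes that mapping succeed.  `repgeom` implements the machinery of that
analysis as a reusable library plus a set of narrative analysis scripts:

* **Effective dimensionality (ED)** — the participation ratio of a
  covariance eigenspectrum, ED = (Σᵢλᵢ)²/Σᵢλᵢ², a continuous count of the
  principal components carrying the variance, with PCA-based estimation,
  global average pooling for convolutional feature maps, and log-log
  power-law fits against the 1/i reference decay.
* **Subspace-alignment simulation** — model and brain subspaces sampled
  from a common natural source, with ED controlled by power-law gain
  spectra and an alignment-pressure (AP) knob in [0, 1]; cross-validated
  regression between the projections reproduces the Alignment, Joint, and
  Dimensionality regimes of encoding performance.
* **Encoding pipeline** — 10-fold cross-validated partial-least-squares
  regression (25 latent components) from features to trial-averaged unit
  responses, median per-unit Pearson r, split-half noise ceiling, and the
  ceiling-normalized score (r/r_ceil)²; a 9-fold OLS variant and a
  representational-similarity (RSA) score are included.
* **Prototype transfer** — nearest-centroid classification of novel
  categories under Monte-Carlo cross-validation, reporting accuracy and
  mean reciprocal rank (MRR).
* **Projection concentration** — mean normalized projection distances
  p̂ᵢⱼ = mean|(xₖ−μᵢ)·wᵢⱼ|/Rᵢ between all category pairs, and the
  uniform-ball demonstration of concentration of measure.

Seeded synthetic generators produce every input class (power-law feature
clouds, noisy linear-readout neural responses with trial repeats, labeled
category clouds with controlled latent dimensionality), so the entire
analysis chain runs without downloads.  Any external program that writes
the same CSV/HDF5 feature format can feed the pipeline with real
activations.

## Worked example

```python
import numpy as np
from repgeom import (
    compute_eigenspectrum, effective_dimensionality,
    gen_power_law_features, gen_neural_responses,
    fit_cv_encoder, split_half_reliability, normalized_encoding_score,
)

# ED of an isotropic 3-unit population: eigenspectrum (1, 1, 1)
print(effective_dimensionality(np.array([1.0, 1.0, 1.0])))   # 3.0

# a feature cloud whose eigenvalues decay as 1/i
features = gen_power_law_features(n_stimuli=5000, n_channels=100, alpha=1.0, seed=0)
spectrum = compute_eigenspectrum(features)
print(round(effective_dimensionality(spectrum), 2))          # 16.34

# a synthetic neural population read out from those features, snr = 1
rec = gen_neural_responses(features, n_units=30, n_signal_dims=25,
                           snr=1.0, n_repeats=2, seed=1)
result = fit_cv_encoder(features, rec, variant="pls_monkey", seed=2)
ceiling = split_half_reliability(rec, corrected=False, seed=3)
print(round(ceiling.median, 3))                              # 0.499
print(round(normalized_encoding_score(result, ceiling), 3))  # 2.664
```

The ED of the 1/i cloud (≈16.3) matches the analytic participation ratio of
the truncated spectrum (16.46) to about 1 %.  The uncorrected split-half
ceiling sits at snr/(snr+1) = 0.5, and the encoder recovers essentially all
of the explainable signal: its median per-unit r ≈ 0.82 is the correlation
of a perfect predictor with the two-repeat mean (√(2/3)), so the
ceiling-normalized score exceeds 1 — a known property of the
squared-quotient convention against an uncorrected ceiling (see
`docs/methods.md`).

## Analysis scripts

Numbered drivers under `analysis/` run each study end to end on synthetic
data, print what they find, and write tables under `results/`:

```bash
python analysis/01_dimensionality_of_features.py   # ED vs analytic participation ratio
python analysis/02_simulate_regimes.py             # Alignment / Joint / Dimensionality regimes
python analysis/03_encoding_vs_dimensionality.py   # ED -> normalized encoding score
python analysis/04_transfer_vs_dimensionality.py   # ED -> prototype transfer accuracy & MRR
python analysis/05_projection_concentration.py     # uniform-ball + category-cloud concentration
```

Representative output (seed 0): the dimensionality-regime sweep yields
Spearman ρ(ED, score) = 0.994; transfer accuracy rises from 0.06 to 0.90 as
latent dimensionality goes 2 → 128 at fixed radius and separation; and mean
normalized projection distances fall 9.48 → 1.12 over the same grid.

There is also a CLI mirroring the library surface:

```bash
repgeom synth powerlaw features.h5 --n-stimuli 5000 --n-channels 100 --alpha 1 --seed 0
repgeom ed features.h5 --fit-power-law 1 50
repgeom run-all --seed 0 --out-dir repgeom_report
```

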