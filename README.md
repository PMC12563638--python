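# fuzzent

Fuzzy-entropy feature extraction and evaluation for EEG-based lie
detection, built around the LieWaves recording protocol (27 subjects,
lie/truth conditions, 5 channels AF3/T7/PZ/T8/AF4, 25 trials of 3 s per
condition at 128 Hz).

The package implements three complexity estimators and everything
needed to turn raw multi-channel recordings into per-subject
classification accuracies and representative-channel selections:

- **FE** — fuzzy entropy of a single series: the log-ratio of average
  fuzzy memberships between embedding dimensions `m` and `m + 1`, with
  an exponential membership `exp(-d**n / r)` on Chebyshev distances and
  tolerance `r = 0.15 * sd`.
- **TSMFE** — time-shifted multi-scale fuzzy entropy: for each scale
  `k = 1..10` the series is split into `k` interleaved subsequences
  (`x[j::k]`), FE is computed per subsequence and averaged.
- **HMFE** — hierarchical multi-band fuzzy entropy: a level-4 `db4`
  wavelet decomposition, each band reconstructed in isolation and scored
  with a band-adaptive tolerance `r * sd_band / sd_signal`. At 128 Hz
  the bands approximate the classic delta/theta/alpha/beta split.

Per trial and channel this yields a 16-value feature vector
(`FE`, `TSMFE.1..10`, `HMFE.A4/D4/D3/D2/D1`). Six classifiers
(linear SVM, RBF SVM, 3-NN, 5-NN, Gaussian naive Bayes, LDA) are
evaluated under leave-one-out, stratified 10-fold and
leave-one-subject-out cross-validation with fold-wise standardization,
and the per-subject best channel is tallied across the montage.

A seeded synthetic generator emulates the LieWaves layout with a
planted complexity contrast (extra broadband noise on informative
channels during lie trials), so the full pipeline can be exercised
end-to-end without the original recordings. The published per-subject
accuracy tables are bundled as CSV reference data for aggregate checks.

## Quick start (API)

```python
import numpy as np
from fuzzent.fuzzy import fuzzy_entropy
from fuzzent.tsmfe import tsmfe
from fuzzent.hmfe import hmfe

t = np.arange(384) / 128.0
sine = np.sin(2 * np.pi * 10 * t)
noise = np.random.default_rng(0).standard_normal(384)

fuzzy_entropy(sine).fe      # 0.2488  -- regular signal, low complexity
fuzzy_entropy(noise).fe     # 1.3312  -- white noise, high complexity
tsmfe(noise).values[:3]     # [1.3312, 1.3046, 1.3297]
hmfe(noise).values          # [0.1022, 0.2278, 0.3705, 0.5390, 0.7715]
                            # bands A4, D4, D3, D2, D1
```

End-to-end on synthetic data:

```python
from fuzzent.simulate import SimConfig, generate_dataset
from fuzzent.features import build_feature_matrix
from fuzzent.evaluate import run_loocv

dataset = generate_dataset(SimConfig(n_subjects=4, seed=7))
fm = build_feature_matrix(dataset["S01"], ("PZ",))
run_loocv(fm.X, fm.y, "C6")["accuracy"]   # LDA leave-one-out accuracy (%)
```

## Quick start (CLI)

```sh
fuzzent simulate --subjects 4 --trials 10 --seed 7 --out data/
fuzzent extract  --manifest data/manifest.json --channels "PZ,T7,PZ-T7" --out feats/
fuzzent evaluate --features feats/ --classifiers C2,C6 --schemes loocv,losocv \
                 --seed 7 --out results/
fuzzent report   --results results/
```

`evaluate` writes per-cell accuracies, per-scheme tables with Mean/SD
rows, best-channel selections and channel occurrence counts; every
command records its configuration in a provenance file.

## Tests

```sh
python -m pytest -q tests/
```

The suite checks the estimators against brute-force reference
implementations, the partition/reconstruction structure of TSMFE and
HMFE, cross-validation fold audits, reproduction of the bundled
published aggregates, and recovery of the planted contrast by the full
pipeline. One check in `tests/test_acceptance.py`
(`test_amplitude_scale_invariance_of_entropy_stack`) fails by design:
strict amplitude-scale invariance does not hold for the exponential
membership at the default `n = 2` (see `docs/methods.md`,
Limitations).

## Reproduction

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the headline quantities offline (roughly 4 minutes):
published-table aggregates (LOOCV LDA mean 82.74, SD 10.87; 10-fold
LDA mean 82.00; LOSOCV RBF-SVM mean 64.07, SD 10.49), best-channel
tallies, brute-force agreement of the optimized entropy path, CV fold
structure, and synthetic-pipeline recovery metrics. Reruns with the
same seed are bitwise reproducible.

## Documentation

`docs/methods.md` describes the estimators, parameter choices,
numerical decisions and the scope of the synthetic generator.
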