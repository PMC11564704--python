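# lattice123

Dynamic lattice graph-pattern feature engineering for two-class EEG
classification.

`lattice123` turns one-dimensional signals into local graph-pattern
histogram features and runs a fully self-organized classification pipeline
on multichannel epoch collections. The core is a fixed 19-vertex, 28-edge,
9-tier lattice: every overlapping 19-sample block of a signal is placed on
the lattice, two greedy probability-driven *walking paths* are traced
through it, and three comparison kernels (signum, upper ternary, lower
ternary) along each path produce 8-bit codes that are histogrammed into six
256-bin feature vectors. Combined with a 4-level db4 wavelet decomposition,
each epoch yields six 1280-dimensional vectors per channel, which then pass
through NCA-based iterative feature selection, 1-nearest-neighbor
cross-validated classification, iterative hard majority voting, and greedy
winner selection — first per channel, then across channels.

See [docs/methods.md](docs/methods.md) for the full scientific account,
including the selection-optimism caveat that applies to all self-organized
pipelines of this kind.

## Worked example

```python
from lattice123 import (
    Lattice123Model, PipelineConfig, SynthConfig, generate_synthetic,
)

collection = generate_synthetic(
    SynthConfig(n_channels=4, n_epochs_healthy=30, n_epochs_ad=10, seed=42)
)
model = Lattice123Model(collection, config=PipelineConfig(seed=42))
results = model.fit()
print(results.summary())
```

Output:

```text
Lattice123 self-organized classification results
================================================
epochs: 40   channels: 4   samples/epoch: 3750
overall accuracy: 100.00%   geometric mean: 100.00%
winning candidate: channel-1 of 6
contributing channels: [1]
best single channel: 100.00%

        Metric   Class  Result (%)
   Sensitivity      AD       100.0
   Sensitivity healthy       100.0
   Sensitivity Overall       100.0
   Specificity      AD       100.0
   Specificity healthy       100.0
   Specificity Overall       100.0
     Precision      AD       100.0
     Precision healthy       100.0
     Precision Overall       100.0
      F1-score      AD       100.0
      F1-score healthy       100.0
      F1-score Overall       100.0
      Accuracy Overall       100.0
Geometric mean Overall       100.0
```

The synthetic classes are strongly separated spectrally (elevated theta,
suppressed alpha in the impaired class), so perfect desk-scale accuracy is
expected — and, as docs/methods.md explains, the self-organized pipeline's
accuracy is a selection score, not an unbiased generalization estimate.

Lower-level pieces are importable directly:

```python
import numpy as np
from lattice123 import lattice123_transform, mdwt_decompose, inca_select

hists = lattice123_transform(np.random.default_rng(0).normal(size=3750))
[h.counts.sum() for h in hists]   # each == 3750 - 18 blocks
bands = mdwt_decompose(np.random.default_rng(0).normal(size=3750))
[b.size for b in bands]           # [1878, 942, 474, 240]
```

## Command line

```bash
lattice123 synth --seed 1 --channels 4 --healthy 30 --ad 10 --out data.npz
lattice123 extract --input data.npz --channel 1 --out features
lattice123 run --input data.npz --out results/ --seed 1
lattice123 report --results results/overall.json
```

`run` also accepts an EDF or CSV recording (one row per channel) plus a
labels CSV; it writes `overall.json`, `channels.csv`, `confusion.csv` and a
reproducibility `manifest.json` (config hash, seeds, library versions,
timings).

## Reproduction

```bash
python -m pytest            # full suite (long end-to-end tests included)
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

The acceptance script reruns the pipeline on seeded synthetic studies and
reports structural constants, metric worked examples, end-to-end accuracies
(separated and null spectral profiles) and the planted-feature recovery
rate of the selection stage. All randomness derives from `--seed`.

One suite test — the null-profile calibration check — is expected to fail:
it asserts the idealized property that accuracy on signal-free data stays
near the class prior, which the faithfully implemented self-organized
architecture does not satisfy at desk scale (docs/methods.md, section 7).
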