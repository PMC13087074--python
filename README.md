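# fcdlif

Fully convolutional prediction of the arterial input function (AIF) from
dynamic small-animal PET, with downstream kinetic quantification.

Kinetic modeling of dynamic PET needs the arterial tracer concentration
over time.  In mice the gold standard — arterial cannulation — is
terminal, which rules out longitudinal designs.  `fcdlif` predicts the
input function directly from the reconstructed 4-D image with a compact
convolutional model, then carries it into physiology via Patlak graphical
analysis and irreversible two-tissue compartment fits.  The package is
aimed at preclinical imaging groups who want a non-invasive input
function and a testbed for it: it ships a synthetic phantom generator
with known ground-truth input functions, so the whole pipeline is
trainable and verifiable without animal data.

## Model

A spatial feature extractor (SFE) — a small 3D residual network applied
to every time frame with shared weights — reduces each frame to a
32-dimensional feature vector.  A temporal feature extractor (TFE) — 1-D
convolutions with "same" padding, 32 → 17 → 6 → 1 — maps the stacked
(T, 32) sequence to a curve of length T.  Because both parts are purely
convolutional, the model accepts any number of frames and its output
shifts with the input in time.  The shipped configuration has exactly
90 124 trainable parameters (~352 KB in FP32, over 100× smaller than a
single ~37 MB dynamic scan).

Training minimizes a weighted MSE (peak/intermediate/tail frames weighted
0.4/0.7/1.0 to offset the uneven temporal sampling) with ADAM and
Poisson-noise augmentation Λ = I·p, I + Pois(Λ) − Λ, p ~ Unif(0, 1).

Downstream, the Patlak net influx rate is the slope of
C_T(T)/C_p(T) against ∫₀ᵀC_p dt / C_p(T) over late frames,
K_i = K₁k₃/(k₂+k₃) for an irreversible tracer.

The network engine (convolutions, backprop, ADAM) is implemented on
numpy with numba-JIT-compiled patch gathers — no deep-learning framework
is required.

## Worked example

Train on synthetic phantoms and predict a held-out input function:

```python
import numpy as np
from scipy.stats import pearsonr
from fcdlif import (build_network, reduced_config, sample_dataset,
                    predict_aif, patlak_fit, blood_to_plasma)
from fcdlif.training import desk_scale_config, train

dataset = sample_dataset(25, seed=7)          # 42x32x16x16 phantoms + true AIFs
net = build_network(reduced_config(), seed=7)
net, history = train(net, dataset[:20], desk_scale_config(seed=7))

image, truth = dataset[20]                    # held-out phantom
dlif = predict_aif(net, image)
r = pearsonr(dlif.values, truth.values).statistic
print(f"final wMSE {history[-1]:.4f}, held-out Pearson r {r:.4f}")
```

```
final wMSE 0.0144, held-out Pearson r 0.9994
```

The predicted curve tracks the ground-truth input function almost
perfectly on noiseless phantoms (r ≥ 0.95 is the package's acceptance
bar; the run above reaches 0.999).  Feeding the prediction into Patlak
analysis of a simulated myocardium-like tissue curve recovers the net
influx rate K_i = 0.125/min of the generating model to within ~0.5 %.

Command-line equivalents:

```bash
fcdlif simulate --seed 1 --out phantom/        # phantom + ground-truth AIF
fcdlif describe                                # per-layer table, 90124 params
fcdlif train --data data/ --seed 1 --out run/  # checkpoint + training log
fcdlif patlak --image img.nii.gz --timing t.csv --plasma plasma.csv \
              --tstar 600 --out maps/          # voxelwise Ki maps
```

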