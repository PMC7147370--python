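# stochact

Stochastic selection of activation layers for convolutional networks, and
sum-rule ensembles of the resulting models.

## What problem this addresses

Replacing the activation functions of a trained CNN is a cheap way to
create model diversity: a catalogue of rectifier variants — several of
them with learnable shape parameters that initialize to an exact copy of
ReLU — can be swapped into each activation layer without changing what
the network computes at replacement time. Drawing the function for each
layer *at random* from the catalogue, fine-tuning, and repeating N times
yields N diverse networks whose fused predictions beat any single member.
This package implements that whole pipeline for people studying
activation functions and ensemble design in image classification and
segmentation (e.g. medical imaging and skin detection), at a scale that
runs on one CPU with synthetic data.

## The core machinery

**Activation catalogue** (`stochact.activations`): ReLU, Leaky ReLU, ELU,
PReLU, SReLU, APLU, and the Mexican-hat families MeLU/wMeLU and
GaLU/sGaLU, each with exact forward maps and analytic gradients for the
input and every learnable parameter. The basis families are built from
compactly supported triangular bumps

    φ_{a,λ}(x) = max(λ·M − |x − a·M|, 0),        M = maxInput ∈ {1, 255}

and MeLU is `PReLU_{c₀}(x) + Σ_j c_j φ_{α_j,λ_j}(x)`, which reduces
exactly to ReLU when all `c_j = 0`.

**Surgery** (`stochact.surgery`): enumerate a network's activation slots,
replace them all with one function (`replace_all`) or with independent
uniform draws from a pool (`stochastic_replacement`), preserving every
other weight bit-identically and reproducibly under a seed.

**Ensembles** (`stochact.ensembling`): sum post-softmax scores, argmax
the sum; per-pixel for segmentation (= majority vote on hard masks).
Recipe constructors for FusAct / FusRan / FusAR compositions.

**Training & evaluation** (`stochact.train_eval`): SGD-with-momentum
fine-tuning contract (batch 32, lr 1e-4/1e-3, 30/50 epochs,
reflection + rescale augmentation), accuracy, pixel-level F1
`2tp/(2tp+fn+fp)`, and an exact-enumeration Wilcoxon signed-rank test.

**Synthetic data** (`stochact.synthetic`): frequency-coded texture
classes, ellipse/color-cluster segmentation sets, tiny CNNs with named
activation slots, and a desk benchmark comparing a single all-ReLU model
with a 5-member stochastic ensemble.

## Worked example

Evaluate MeLU at its standard initialization (it is exactly ReLU — note
`f(2) = 2`, `f(−1) = 0` — and the printed `d/dc[j]` rows are the basis
functions themselves, the gradients training would follow):

```
$ stochact act eval --name MeLU --x -2,-1,0,1,2,3
x       y       dy_dx
-2      0       0
-1      0       0
0       0       1
1       1       1
2       2       1
3       3       1
d/dc[0] -2      -1      0       0       0       0
d/dc[1] 0       1       2       1       0       ...
```

Run the desk benchmark (single all-ReLU tiny CNN vs a 5-member
stochastic-replacement ensemble on the 3-class texture task, one row per
repetition seed):

```
$ stochact bench --seed 0 --seeds 3
seed    relu_accuracy   ensemble_accuracy
0       0.7143  1.0000
1       1.0000  0.8095
2       0.5238  0.7619
mean    0.7460  0.8571
```

Individual repetitions are noisy in both directions — these are 21-image
test sets — but the ensemble mean sits above the single-model mean, the
qualitative ordering the method is designed to produce.

The same pipeline is scriptable:

```python
import numpy as np
from stochact import (SynthClassSpec, gen_classification, tiny_cnn,
                      default_pool, create_ensemble, TrainConfig, train)

images, labels = gen_classification(SynthClassSpec(seed=0))
base = tiny_cnn(n_classes=3, n_act_layers=3, seed=0)
cfg = TrainConfig(batch_size=8, learning_rate=0.05, max_epochs=8,
                  augmentation=False)
trainer = lambda m, s: train(m, images, labels, cfg, seed=s)
ens = create_ensemble(base, default_pool(), n=5, seed=0, trainer=trainer)
scores = ens.predict_proba(np.transpose(images, (0, 3, 1, 2)))
```

## Layout

```
src/stochact/
  activations.py   # the ten functions, gradients, finite-difference checker
  model.py         # numpy layer stack with explicit backprop
  surgery.py       # slot enumeration, uniform & stochastic replacement
  ensembling.py    # sum-rule fusion, recipes
  train_eval.py    # trainer, augmentation, metrics, Wilcoxon, reports
  synthetic.py     # fixtures, tiny CNNs, desk benchmark
  datasets.py      # PNG dataset layouts
  config.py, cli.py
```
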