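# layerprobe

How much representational abstraction does a visual behavior need?

`layerprobe` quantifies the level of hierarchical-model representation
required to account for visual-recognition behavior and for neural
population data. Given a layered feature extractor (a convolutional network,
pretrained or randomly initialized, or the built-in test network), it builds
one linear model per layer and asks, layer by layer:

* **Decoding** — can a linear readout of this layer's features solve the
  animal's task and generalize across stimulus transformations? Tasks are
  scored as *yes-no* (one stimulus per trial: correct iff the stimulus falls
  on its true side of the decision boundary of a linear SVM) or *2AFC*
  (target and distractor per trial: correct iff
  f(x<sub>target</sub>) > f(x<sub>distractor</sub>)).
* **Behavioral performance signatures** — does a linear (PLS) mapping from
  the layer's features predict the *pattern* of per-condition percent
  correct? Performance p is logit-transformed, ln(p′/(1−p′)) with the
  half-a-count clip p′ = clip(p, 0.5/n, 1−0.5/n), and prediction quality is
  the explained variance 100·corr(y<sup>pred</sup>, y<sup>obs</sup>)²,
  evaluated on an independent generalization phase or by leave-one-out
  cross-validation.
* **Separability** — the sign-reversed generalized discrimination value
  (GDV): after per-dimension z-scoring and scaling by 0.5,
  −(1/√D)·[mean intra-class distance − mean inter-class distance], which is
  0 for non-separable classes and 1 for perfectly separable point classes.
* **Representational similarity** — 1 − Pearson RDMs over stimulus bins,
  compared across neural areas and model layers by Spearman correlation of
  the upper triangles, normalized by a split-half Spearman-Brown noise
  ceiling 2r/(1+r), embedded with non-metric MDS, and summarized by the
  neural-vs-model RDM distance ratio.

Everything upstream of the statistics follows one discipline: per-feature
standardization, full-rank PCA, decoders, and signature maps are fit on the
training stimuli only and applied unchanged to held-out stimuli.

A first-class synthetic-data module generates all inputs with the structure
the analyses assume — transformation-grid silhouettes with a 14-cell
training cross, reference-vs-distractor silhouette sets, 150-frame category
videos (cut into nine 16-frame bins) with phase-scrambled distractors,
binomially sampled behavioral signatures with a known logit-linear ground
truth, and neural populations that are noisy readouts of a known layer — so
every analysis is testable end-to-end without downloads, and recovery of the
known ground truth (generating layer, signature weights) is itself a test.

## Worked example

```python
from layerprobe import ExperimentConfig, run_experiment

tables = run_experiment(ExperimentConfig(template="transformation_grid", seed=1))
print(tables["accuracy"].pivot(index="layer", columns="partition", values="accuracy").round(1))
```

```
partition  test  train
layer
conv1      53.8  100.0
conv2      63.8  100.0
conv3      76.2  100.0
conv4      73.8  100.0
fc5        62.5  100.0
fc6        62.5   96.4
pixels     61.2  100.0
pool1      66.2  100.0
pool2      66.2  100.0
pool3      70.0  100.0
pool4      75.0  100.0
```

Two synthetic objects are rendered over 6 sizes x 9 rotations; each layer's
decoder is trained on the 14-cell training cross (hence ~100% train
accuracy) and evaluated on the 40 held-out transformation combinations per
object. Test accuracy is the percentage of held-out stimuli classified on
the correct side of the boundary: the pixel baseline generalizes poorly
while mid-level layers of the (randomly initialized) built-in network
transfer best. The `signature` and `gdv` tables from the same run hold the
per-layer explained variance and separability values.

The `examples/` directory walks through each capability (decoding sweep,
signature mapping, video 2AFC, RSA with noise ceilings); each script prints
the numbers it computes and a line on what they mean. A thin CLI covers
batch runs:

```bash
layerprobe decode --config cfg.yaml --out results/
layerprobe rsa    --config cfg.yaml --out results/
```

## Layout

* `src/layerprobe/stimuli.py` — manifests, loading, 16-frame binning, RF-matched rescaling, position jitter
* `src/layerprobe/features.py` — layer registries, the built-in extractor, pre-ReLU extraction, train-only standardize+PCA
* `src/layerprobe/decoding.py` — linear SVM decoders, yes-no/2AFC scoring, layer sweeps, jackknife CIs
* `src/layerprobe/signatures.py` — logit transform, PLS signature maps, explained variance, LOOCV
* `src/layerprobe/separability.py` — sign-reversed GDV
* `src/layerprobe/rsa.py` — response matrices, RDMs, noise ceilings, MDS, distance ratio
* `src/layerprobe/synthetic.py` — all synthetic generators
* `src/layerprobe/pipeline.py` — experiment templates and orchestration
* `docs/methods.md` — the model, its assumptions, parameter choices, and known limitations
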