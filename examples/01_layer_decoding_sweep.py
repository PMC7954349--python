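"""Per-layer decoding of object identity across a transformation grid.

Two synthetic silhouette objects are rendered over a 6 x 9 grid of sizes and
in-plane rotations.  A linear SVM decoder is trained per layer on the 14-cell
training "cross" (28 stimuli) and asked to generalize to the 40 held-out
transformation combinations per object.
"""

from layerprobe import ExperimentConfig, run_experiment

tables = run_experiment(ExperimentConfig(template="transformation_grid", seed=1))
acc = tables["accuracy"].pivot(index="layer", columns="partition", values="accuracy")

print(acc.round(1))
print()
print(
    "Train accuracy is (near-)perfect at every layer because each decoder is\n"
    "fit on the training cross itself; the test column shows generalization\n"
    "to unseen size x rotation combinations.  The pixel baseline generalizes\n"
    "worst; mid-level layers of the built-in network transfer best."
)
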