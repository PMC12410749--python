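"""Train the adapter backbone end to end and print the metric suite.

A reduced run (12 images, 25 epochs, about a minute) - the acceptance script
runs the full study conditions.
"""

from allinsam.backbone import AdapterModel, TrainConfig, train
from allinsam.config import RunConfig, SynthConfig
from allinsam.pipeline import evaluate_model, make_training_annotations, simulate_dataset

cfg = RunConfig(seed=1, synth=SynthConfig(n_train=12, n_val=4, n_test=4))
tr = simulate_dataset(cfg, "train", cfg.synth.n_train)
va = simulate_dataset(cfg, "val", cfg.synth.n_val)
te = simulate_dataset(cfg, "test", cfg.synth.n_test)
anns = make_training_annotations(cfg, tr)  # lay-noise annotations by default

model = AdapterModel(n_classes=2, base_width=8, seed=0)
model, history = train(
    model,
    [(img, ann) for (img, _, _), ann in zip(tr, anns)],
    TrainConfig(epochs=25, batch_size=4, learning_rate=5e-3, seed=0, loss="mocl",
                mocl_warmup=0.8),
    val_dataset=[(img, truth) for img, _, truth in va],
)
print("epoch  loss    val_dice")
for h in history[::3] + [history[-1]]:
    print(f"{h['epoch']:>5}  {h['loss']:.4f}  {h['val_dice']:.4f}")

report = evaluate_model(model, te)
print("\nheld-out test metrics:")
print(report.csv_header())
print(report.to_csv_row())
# Dice/IoU measure pixel accuracy, ADJ (aggregated Jaccard) and instance F1
# measure instance-level quality; AUC/bestF1 are threshold-free.
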