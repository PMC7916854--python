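"""Train a small FCN end-to-end on simulated data and evaluate it.

A reduced run (150 images, 6 epochs) so it finishes in about a minute on
a laptop CPU; the package's standard benchmark (600 images, 15 epochs,
both variants) is what `scripts/acceptance.py` executes.
"""

import numpy as np

from protloc.pipeline import benchmark_net_spec, benchmark_sim_config, run_experiment
from protloc.trainer import TrainConfig

res = run_experiment(
    variant="FCN",
    sim_config=benchmark_sim_config(),
    n_samples=150,
    train_count=120,
    net_spec=benchmark_net_spec(seed=0),
    train_config=TrainConfig(batch_size=8, max_epochs=6, seed=0),
    seed=0,
)

print("epoch  train_loss  val_loss")
for h in res.state.history:
    print(f"{h['epoch']:>5}  {h['train_loss']:.4f}      {h['val_loss']:.4f}")

report = res.report
print(f"\ntest split (n={len(res.test_truths)}):")
print(f"  class-average accuracy (confusion diagonal mean): {report.mean_diag_accuracy:.3f}")
print(f"  unweighted mean dice: {report.mean_dice:.3f}")
print("  dice by cell line:", {k: round(v, 3) for k, v in report.by_group_dice.items()})
# Loss should fall over the 6 epochs; accuracy improves further with the
# full 600-image / 15-epoch benchmark configuration.
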