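"""Train the compact CNN on a small phantom cohort, pick an epoch with the
overfitting-gap criterion, and score the held-out institution.

Training follows the tuned recipe (SGD lr 0.05, momentum 0.9, L2 1e-4,
batch 64, class weights 3.7/0.7, flips/rotations/shifts on training images
only). Model selection takes the epoch with the best validation AUC among
epochs whose train-validation AUC gap is below an escalating threshold
starting at 0.05.
"""

import json
from pathlib import Path

from hncnet.phantom import SyntheticCohortConfig
from hncnet.pipeline import ExperimentConfig, run_experiment
from hncnet.training import TrainConfig

cfg = ExperimentConfig(
    cohort=SyntheticCohortConfig(n_patients=80, prevalence=0.3, effect_size=2.0,
                                 censoring_fraction=0.1, seed=0),
    train=TrainConfig(max_epochs=25, seed=0),
    seed=5,
)
out = run_experiment(cfg, Path("experiment_demo"))
report = json.loads((out / "eval_report.json").read_text())

sel = report["selection"]
print(f"epochs trained: {sel['epochs_trained']}, "
      f"selected epoch {sel['epoch']} at gap threshold {sel['threshold']:.2f}")
for role in ("train", "validation", "test"):
    lo, hi = report["ci"][role]
    print(f"{role:>10s} AUC {report['auc'][role]:.3f}  (95% bootstrap CI {lo:.3f}-{hi:.3f})")
print("-> test = the held-out institution; with a strong phantom effect the")
print("   AUC should sit well above 0.5, with a CI reflecting the small n.")
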