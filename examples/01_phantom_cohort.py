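"""Generate a phantom cohort and inspect its outcome structure.

Each phantom is a CT-like volume with an ellipsoidal tumor whose texture
heterogeneity (the HU standard deviation inside the GTV) drives the event
probability through a logistic model. The script prints the realized event
rate (calibrated to the requested prevalence), the censoring structure,
and how strongly the latent texture statistic separates cases.
"""

import numpy as np
from scipy import stats

from hncnet.phantom import SyntheticCohortConfig, generate_synthetic_cohort

cfg = SyntheticCohortConfig(
    n_patients=200, prevalence=0.135, effect_size=2.0,
    censoring_fraction=0.15, time_frame_days=730, seed=7,
)
_, records = generate_synthetic_cohort(cfg, with_volumes=False)

events = np.array([r.event_dm for r in records])
het = np.array([r.texture_heterogeneity for r in records])
event_free = [r for r in records if not r.event_dm]
short = sum(r.followup_days < cfg.time_frame_days for r in event_free)

ranks = stats.rankdata(het)
npos = events.sum()
auc = (ranks[events == 1].sum() - npos * (npos + 1) / 2) / (npos * (len(events) - npos))

print(f"patients: {len(records)}")
print(f"2-year event rate: {events.mean():.3f} (target prevalence {cfg.prevalence})")
print(f"event-free patients censored before the frame: {short}/{len(event_free)}")
print(f"AUC of raw texture heterogeneity vs outcome: {auc:.3f}")
print("-> the texture statistic alone separates cases from controls, so the")
print("   imaging pipeline has a recoverable signal to learn.")
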