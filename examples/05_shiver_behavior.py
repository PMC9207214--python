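"""Score cold-induced shiver behavior and summarize by group.

Simulates three groups of eight larvae (intact, ablation control,
sensory-OLC ablated) with group-specific true shiver fractions, scores
each 20 s recording with the high-pass + sliding-RMS detector and
reports per-group percent time shivering.
"""

from olcquant import BehaviorSimConfig, detect_shiver, generate_behavior, normalize_window
from olcquant.behavior import group_behavior_summary

group_fracs = {"intact": 0.575, "ablation_control": 0.5375,
               "sensory_olc_ablated": 0.025}

scores, groups = [], []
seed = 0
for group, frac in group_fracs.items():
    for ai in range(8):
        cfg = BehaviorSimConfig(
            shiver_intervals=[(1.0, 1.0 + 20.0 * frac)] if frac else [],
            seed=seed,
        )
        trace, _ = generate_behavior(cfg, animal_id=f"{group}_{ai}", group=group)
        scores.append(detect_shiver(normalize_window(trace)))
        groups.append(group)
        seed += 1

means, pairwise = group_behavior_summary(scores, groups)
print("mean percent time shivering per group:")
print(means.to_string())
print("\npairwise Welch tests:")
print(pairwise.to_string(index=False))
print("\nAblating sensory-associated oligodendrocyte-lineage cells "
      "collapses the shiver response while both control groups shiver "
      "for over half the window.")
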