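"""Score behavioural logs from the three task families and aggregate.

Builds one log per condition (two repetitions per cognitive-control
level), scores each with its level's accuracy formula, and averages the
repetitions into Skill / Rule / Knowledge level accuracies.
"""

import numpy as np

from srk import (
    KnowledgeLog,
    RuleLog,
    TrackLog,
    aggregate_scores,
    knowledge1_accuracy,
    knowledge2_accuracy,
    rule_accuracy,
    skill_accuracy,
    track_geometry,
)

# Skill: a cursor trajectory compared against the ideal track.
track = np.array([[0.0, 0.0], [50.0, 0.0], [100.0, 30.0]])
t = np.linspace(0, 60, 50)
s = np.linspace(0, 1, 50)
ideal_xy = np.where(s[:, None] < 0.5,
                    track[0] + 2 * s[:, None] * (track[1] - track[0]),
                    track[1] + (2 * s[:, None] - 1) * (track[2] - track[1]))
cursor = ideal_xy + np.random.default_rng(0).normal(0, 0.8, ideal_xy.shape)
log_s1 = TrackLog(np.column_stack([t, cursor]), track, completion_time=60.0)
L, L_opt, err, err_max = track_geometry(log_s1)
s1 = skill_accuracy(L, L_opt, err, err_max)
print(f"S1 geometry: L={L:.1f} Lopt={L_opt:.1f} err={err:.2f} errMAX={err_max:.2f}")
print(f"S1 accuracy: {s1:.1f}%  (path-length excess and lateral error both count)")

# Rule: 7 turn + 7 altitude slots, altitude weighted.
log_r1 = RuleLog(turn_outcomes=(1, 1, 1, 0, 1, 1, 1),
                 alt_outcomes=(1, 1, 1, 1, 0, 1, 1),
                 alt_weights=(1.0,) * 7)
r1 = rule_accuracy(log_r1)
print(f"R1 accuracy: {r1:.1f}%  (12 of 14 rule slots applied correctly)")

# Knowledge: timing (K1) and attempts + time budget (K2).
k1 = knowledge1_accuracy(KnowledgeLog(variant="K1", t_opt=60, t_cir=95, t_ev=25))
k2 = knowledge2_accuracy(KnowledgeLog(variant="K2", n_att=2, t_used=480))
print(f"K1 accuracy: {k1:.1f}%   K2 accuracy: {k2:.1f}%")

scores = aggregate_scores(
    {"S1": s1, "S2": 88.0, "R1": r1, "R2": 92.9, "K1": k1, "K2": k2},
    {"S1": 60.0, "S2": 55.0, "R1": 80.0, "R2": 75.0, "K1": 120.0, "K2": 480.0},
)
print("level accuracies (mean of the two repetitions):",
      {k: round(v, 1) for k, v in scores.level_scores.items()})
print("level completion times (s):",
      {k: round(v, 1) for k, v in scores.level_times.items()})
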