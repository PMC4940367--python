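"""A complete simulated neurofeedback study with block statistics.

Simulates a small cohort (responders with a left-lateralized NF gain and
one non-respondent whose NF response is right-lateralized), runs each
subject through the full closed loop, and reports per-block success at
the one-tailed alpha = 0.0125 criterion plus the effect sizes.
"""

import numpy as np

from nfloop import (
    VirtualSubjectProfile,
    closed_loop_run,
    minimal_detectable_effect,
    overlap_coefficient,
    probability_of_superiority,
)

profiles = [
    VirtualSubjectProfile(subject_id="resp01"),                  # responder
    VirtualSubjectProfile(subject_id="resp02"),                  # responder
    VirtualSubjectProfile(subject_id="nonresp",                  # no left gain
                          responder_gain=0.0, right_gain=0.4),
]

all_ds = []
for i, profile in enumerate(profiles):
    res = closed_loop_run(profile, seed=100 + i, n_boot=0,
                          render_timelines=False)
    s = res.summary
    succ_d = [r.d for r in res.block_results if r.success]
    all_ds += succ_d
    print(f"{s.subject_id}: {s.n_success}/{s.n_blocks} blocks successful, "
          f"respondent={s.respondent}, received_feedback={s.received_feedback}")

mean_d = float(np.mean(all_ds))
print(f"\nmean d in successful blocks: {mean_d:.2f}")
print(f"  -> overlap between View and NF distributions: "
      f"{100 * overlap_coefficient(mean_d):.0f}%")
print(f"  -> probability of superiority: "
      f"{100 * probability_of_superiority(mean_d):.0f}%")

d_min, r_min = minimal_detectable_effect(80, alpha=0.0125)
print(f"detection limit at 80 samples/epoch: d_min={d_min:.2f}, "
      f"r_min={r_min:.2f}")
# Responders succeed on most blocks with large standardized shifts; the
# non-respondent never crosses the feedback threshold, exactly the
# behavioral signature the respondent classification keys on.
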