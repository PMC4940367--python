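"""Driving the virtual agent's facial expressions from a feedback stream.

A 2 Hz feedback score is quantized into four engagement levels
(disengaged idle / neutral / mild positive / high positive), each level
offering one or more FACS action-unit behaviors; dwell-based variation
switches behavior every ~2 s and transitions are smoothly cross-faded
into 25 fps AU/BAP frames.
"""

import numpy as np

from nfloop import generate_timeline, quantize_engagement

# a subject who warms up: no feedback, then mild, then sustained high
scores = np.concatenate([np.zeros(6), np.full(6, 0.5), np.full(12, 0.95)])
print("engagement per 2 Hz tick:",
      [quantize_engagement(s).name[:4] for s in scores[::3]])

timeline = generate_timeline(scores, score_fs=2.0, render_fps=25.0,
                             transition_s=1.0, dwell_s=2.0)
print(f"{len(timeline)} frames over {scores.size / 2.0:.0f} s")

for t_probe in (0.5, 4.0, 8.0, 11.0):
    row = timeline.iloc[int(t_probe * 25)]
    smile = row.get("AU12", 0.0)
    print(f"  t={t_probe:4.1f} s  behavior={row['behavior_id']:9s} "
          f"AU12(smile)={smile:.2f}")
# The smile (AU12) is absent in the idle phase, partial for the mild level
# and full once the score sits in the top engagement bin; behavior ids
# alternate within a level at 2-s dwell boundaries.
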