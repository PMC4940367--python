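"""Fitting the per-block feedback map from a View epoch.

The View epoch serves as the within-block reference: its asymmetry values
define the threshold (Min = mean + 1.28 SD, leaving ~90% of View values
unrewarded) and the range (Max = Min + View range). NF asymmetry is then
mapped linearly onto [0, 1].
"""

import numpy as np

from nfloop import fit_feedback_map, normalize_feedback, remove_outliers

rng = np.random.default_rng(42)

# View-epoch asymmetry: 80 samples around 0.05 uMol/L, plus one motion glitch
view = rng.normal(0.05, 0.12, 80)
view[17] = 1.4

trimmed = remove_outliers(view, k=3.0)
print(f"outlier trimming: {view.size} -> {trimmed.size} samples "
      f"(dropped {view[17]:+.2f} uMol/L glitch)")

fmap = fit_feedback_map(trimmed)
print(f"feedback map: Min = {fmap.min_point:.3f}, "
      f"Max = {fmap.max_point:.3f} uMol/L")
print(f"fraction of View below threshold: "
      f"{np.mean(view < fmap.min_point):.2f}  (by design ~0.90)")

# what the agent would receive for a few NF asymmetry values
for a in (0.0, fmap.min_point, (fmap.min_point + fmap.max_point) / 2,
          fmap.max_point, fmap.max_point + 1):
    print(f"  asymmetry {a:+.3f} uMol/L -> feedback "
          f"{normalize_feedback(a, fmap):.2f}")
# Scores are 0 at/below Min, 0.5 halfway, and clamp at 1 above Max.
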