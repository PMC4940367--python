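# nfloop

A tested offline/streaming implementation of a closed-loop fNIRS
neurofeedback system in which prefrontal asymmetry drives a virtual
agent's facial expressions.

## The problem

Functional near-infrared spectroscopy (fNIRS) measures cortical
hemodynamics through intensity changes at two wavelengths (730/850 nm).
Left-minus-right activity in the dorsolateral prefrontal cortex (DL-PFC)
indexes the approach/withdrawal affective dimension, and is amenable to
neurofeedback (NF): a subject watching a virtual agent can learn to
up-regulate left asymmetry, and the agent responds with increasingly
positive expressions. `nfloop` implements every computational stage of
such a system so that protocol design, feedback mapping and statistics
can be developed and validated against a virtual-subject simulator with
known ground truth — no acquisition hardware required.

The pipeline:

1. **signal_core** — modified Beer-Lambert law (MBLL): ΔOD(λ) =
   −log₁₀(I/I_ref), then the exact 2×2 solve of
   ΔOD(λ) = (ε_HbO(λ)·ΔHbO + ε_HbR(λ)·ΔHbR)·L·DPF(λ) for ΔHbO, ΔHbR
   (μMol/L); order-20 FIR low-pass at 0.1 Hz with group-delay
   compensation; sliding-window motion-artifact rejection; per-block
   baseline re-referencing.
2. **session_model** — the 8-block Rest/Prompt/View/Rest/Prompt/NF/Rest
   protocol at 2 Hz, with analysis windows shifted by the ~7 s
   hemodynamic delay (40-s epochs → exactly 80 samples) and the baseline
   taken from the last 10 s of each block's first Rest.
3. **asymmetry_mapping** — asymmetry = mean(HbO, left 4 channels) −
   mean(HbO, right 4 channels); per-block adaptive map fit on the
   outlier-trimmed View window: `Min = mean + 1.28·SD` (no feedback for
   ~90% of View-like values), `Max = Min + range`; NF asymmetry maps
   linearly onto [0, 1].
4. **agent_control** — four engagement levels, eight FACS/BAP behaviors,
   dwell-based (~2 s) behavior variation and smooth cross-faded
   transitions rendered into a 25 fps AU/BAP timeline.
5. **block_stats** — block success = one-tailed pooled t-test (NF > View)
   at α = 0.0125 with a seeded 1000-resample bootstrap CI; Cohen's *d*,
   effect-size *r* = |t|/√(t²+df), overlap OVL = 2·Φ(−|d|/2), probability
   of superiority Φ(d/√2), detection limits d_min = z·√(2/n); respondent
   classification and the Epoch×Side laterality contrast.
6. **synthetic_data** — seeded virtual subjects: double-gamma HRF,
   lateralized NF gain, bilateral View activation, drift, Mayer/respiratory
   oscillations, noise and motion artifacts, with per-block ground truth.

## Worked example

```bash
python examples/04_closed_loop_study.py
```

```
resp01: 8/8 blocks successful, respondent=True, received_feedback=True
resp02: 8/8 blocks successful, respondent=True, received_feedback=True
nonresp: 0/8 blocks successful, respondent=False, received_feedback=False

mean d in successful blocks: 6.61
  -> overlap between View and NF distributions: 0%
  -> probability of superiority: 100%
detection limit at 80 samples/epoch: d_min=0.35, r_min=0.18
```

The two responders (left-lateralized NF gain of 0.47 μMol/L over the
right's 0.13) pass the within-block significance criterion on every
block; the non-respondent, whose NF response is right-lateralized, never
crosses the View-fitted feedback threshold — the exact behavioral
signature distinguishing respondents. The detection limit line says the
protocol (80 samples per epoch, one-tailed α = 0.0125) cannot resolve
standardized shifts below d ≈ 0.35 (r ≈ 0.18). The other examples walk
the signal chain, the feedback map and the agent timeline individually.

A thin CLI wraps the same library:

```bash
nfloop simulate --subjects 17 --seed 1 --out data/
nfloop process  --data data/ --out proc/
nfloop stats    --data data/ --seed 1 --out stats/
nfloop report   --stats-dir stats/ --out report/
```

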