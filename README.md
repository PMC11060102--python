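# cpbci — continuous-pursuit motor-imagery BCI, simulated end to end

`cpbci` is a self-contained framework for **continuous pursuit (CP)**
brain–computer interfacing: a BCI task in which the user steers a cursor in
2D to track a target that drifts under random accelerations for a whole
60 s trial, using motor imagery (MI) — imagine the left hand to go left,
the right hand to go right, both hands to go up, rest to go down. Imagined
movement suppresses the 8–13 Hz alpha rhythm over the contralateral
sensorimotor cortex (event-related desynchronization, ERD), and decoders
turn that suppression into a 2D velocity command every 40 ms.

The package is aimed at BCI methods researchers who want to develop and
stress-test CP decoding pipelines **without human data**: every component is
exercised against a generative model of an MI user (lateralized alpha-band
ERD over C3/C4, reaction lag, 1/f background noise), so claims about the
pipeline are testable in silico.

What it implements:

- **Task core** — CP task dynamics (random-accelerated target, boundary
  repulsion, no wrap-around, 40 ms control tick) and the study schedule
  presets (sessions of 12 decoder runs + 1 chance run; fast/slow speed
  presets related by a 25% cursor-speed and 33% acceleration-variance
  reduction).
- **Synthetic subject** — maps intended direction to left/right-hand MI
  intensities through the additive control model `h = a_R − a_L`,
  `v = a_R + a_L − 1`, applies a reaction delay and first-order smoothing,
  and synthesizes multichannel EEG with multiplicative ERD on the alpha
  envelope plus pink noise.
- **Labeling** — the CP supervised-learning device: each EEG window ending
  at a control tick is labeled with the unit **cursor→target vector** at
  that tick; near-contact windows are excluded.
- **Decoders** — a traditional autoregressive (Burg) alpha-band-power
  decoder with adaptive normalization (no training data needed); an
  EEGNet-style compact CNN on raw windows; and a PointNet-style network
  that treats the electrode array as a 3D point cloud carrying per-channel
  log spectra (three set-abstraction stages, then a fully connected head
  with 40% dropout).
- **Training** — cosine-loss regression of the direction label with
  ADA-based epoch selection, session accumulation, transfer learning
  (pretrain on pooled subjects, fine-tune), and midsession recalibration
  (exactly 5 epochs on the session's first 4 runs, no selection).
- **Evaluation** — NMSE (squared cursor-target distance normalized by the
  squared arena diagonal: 0 = coincident, 1 = opposite corners), per-axis
  Pearson correlation, **ADA** (average difference angle between predicted
  directions and labels; 90° = chance), lag-scan (shift the cursor forward
  in time and find the NMSE-minimizing lag), chance-level runs, and the
  trial-level ADA↔NMSE relationship.

## Worked example

Closed-loop comparison of an oracle decoder (reads the subject's lagged
intent) against chance on a 16-channel smoke-scale configuration:

```python
import numpy as np
from cpbci import (SubjectModel, ARDecoder, OracleDecoder, reduced_montage,
                   run_trial, nmse)
from cpbci.task import get_preset

montage = reduced_montage(16)
subject = SubjectModel(erd_depth=0.6, seed=1)
cfg = get_preset("substudy1_fast").replace(trial_s=20.0)

oracle = OracleDecoder()
rec = run_trial(subject, oracle, cfg, montage, seed=50, fs=250.0, record_eeg=False)
print("oracle NMSE:", round(nmse(rec.cursor_xy, rec.target_xy), 3))

ar = ARDecoder(list(montage.names), 250.0)
rec = run_trial(subject, ar, cfg, montage, seed=50, fs=250.0, chance=True,
                record_eeg=False)
print("chance NMSE:", round(nmse(rec.cursor_xy, rec.target_xy), 3))
```

This prints

```
oracle NMSE: 0.041
chance NMSE: 0.291
```

— the oracle hugs the target (NMSE close to the 0 bound; the residual is
the subject's reaction lag), while the no-intent chance run drifts far from
it. A trained decoder should land between the two.

The same protocol is scriptable from the shell:

```bash
cpbci presets
cpbci simulate -c config.yaml -o out/        # multi-session protocol
cpbci train -c config.yaml --store out/ -o model.npz --arch eegnet
cpbci evaluate out/ --csv metrics.csv --lag
```

with a config such as

```yaml
preset: smoke          # task preset (see `cpbci presets`)
smoke: true            # reduced network specs
n_channels: 16         # 16-channel sensorimotor subset or full 64
fs: 250.0              # synthesis rate (1000 for full scale)
substudy: 1
sessions: [T, "1", "2", "3"]
subject: {erd_depth: 0.6, seed: 1}
training: {epochs: 10}
```

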