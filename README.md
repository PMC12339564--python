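# motionsentry

Biomechanics-aware detection of sports-injury events from multi-sensor
skeletal motion data.

Musculoskeletal overuse injuries often announce themselves in *movement*
before they are visible in imaging: a transient burst of mechanical energy
at one joint, an asymmetric loading pattern, a gait cycle that stops being
periodic. `motionsentry` is a library and CLI for practitioners in sports
medicine and human-movement research who have time series of joint
trajectories (pose estimation, motion capture) plus wearable streams (IMU,
plantar pressure) and want calibrated, interpretable anomaly signals and a
trainable sequence classifier on top of them.

## The method

A motion record is `X ∈ R^{T×J×D}` — T frames, J joints, D coordinates.
From backward differences the package derives velocity, acceleration, and
jerk, and per joint the mechanical energy

```
E_t^j = ½ m_j ‖v_t^j‖² + m_j g h_t^j .
```

Deviations from a reference window of normal motion give an anomaly score
`S_t^j = |E_t^j − E[E^j]|`, and calibration against population statistics a
z-score `z = (E − μ_E)/σ_E`; cells with |z| ≥ 2.5 are flagged (98.8% of a
Gaussian lies inside). A sigmoid confidence `β = σ(z)` down-weights
anomalous joints during feature fusion.

The learned pipeline encodes each frame with graph convolutions over the
anatomical skeleton (`Â = D^{−1/2}AD^{−1/2}`) plus joint-level attention,
mixes frames with scaled dot-product temporal attention
`softmax(QKᵀ/√d′)V` under sinusoidal positional encodings, fuses the three
sensor modalities with adaptive softmax attention weights, and classifies
per frame with a small perceptron fed the encoded features concatenated
with the anomaly scores. Training minimizes cross-entropy plus a
temporal-consistency family — `λ₁Σ(P_t−P_{t+1})² + λ₂Σ|P_t−P_{t−1}| +
λ₃Σ(P_t−P_{t+k})²` — that suppresses spurious single-frame detections.
A seeded synthetic gait simulator (periodic walking, injected single-joint
energy excursions, degraded vision/IMU/pressure channels) provides the
test substrate. See `docs/methods.md` for assumptions and defaults.

## Worked example

```python
import numpy as np
from motionsentry import (
    SyntheticSpec, make_corpus, fit_baseline_stats, zscore, flag_anomalies,
)
from motionsentry import detector as det
from motionsentry.motion import compute_kinematics, total_energy

corpus = make_corpus(SyntheticSpec(n_sequences=200, seed=42))

profiles = [total_energy(compute_kinematics(s), s, corpus.skeleton)
            for s in corpus.sequences]
stats = fit_baseline_stats([p for p, y in zip(profiles, corpus.labels) if y == 0])

i = int(np.nonzero(corpus.labels)[0][0])          # first injured sequence
z = zscore(profiles[i], stats)
t, j = np.unravel_index(np.argmax(np.abs(z)), z.shape)
print(f"peak |z| = {np.abs(z).max():.1f} at frame {t}, "
      f"joint {corpus.skeleton.joint_names[j]}")

fitted = det.train(corpus, det.DetectorConfig(), seed=0)
val = fitted.log["val_indices"]
preds = det.predict(fitted, [corpus.sequences[k] for k in val],
                    [corpus.bundles[k] for k in val])
print(det.evaluate([p.sequence_prob for p in preds], corpus.labels[val]))
```

Output:

```
peak |z| = 16.2 at frame 26, joint l_ankle
{'accuracy': 0.82, 'recall': 0.64, 'f1': 0.78, 'auc': 0.984}
```

The injected injury in that sequence was at the left ankle with onset at
frame 24 — the z-score map localizes it to frame 26 at the same joint, 16
standard deviations above the normal-motion baseline (7 cells cross the
2.5 threshold, all in the injury window). After ~30 epochs of training the
classifier separates injured from normal held-out sequences with AUC 0.98;
accuracy at the default 0.5 threshold is 0.82.

The same pipeline is available from a shell:

```bash
motionsentry --seed 7 simulate --out data/ -n 64
motionsentry --seed 7 train --data data/ --out model/
motionsentry --seed 7 detect --data data/ --model model/ --out preds.csv
motionsentry eval --predictions preds.csv --labels data/labels.csv
```

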