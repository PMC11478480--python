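# gaitphase

Continuous gait-phase estimation from insole plantar-pressure data, for
researchers in wearable gait analysis and assistive-device control.

Walking-aid controllers, gait-disturbance diagnostics and rehabilitation
metrics all need to know *where in the gait cycle* the wearer is — not
just which event happened last, but a continuous phase value at every
sample, robust to terrain. This package implements a two-stage approach
working purely from ten force-sensing-resistor (FSR) channels (toe, first
metatarsal, fifth metatarsal, cuboid and heel sites on each foot, sampled
at 100 Hz):

1. a bidirectional-LSTM **walking-condition classifier** — level walk
   (LW), stair ascent/descent (SA/SD), ramp ascent/descent (RA/RD) — over
   100-sample causal windows of the normalized channels, and
2. a bidirectional-LSTM **phase estimator** fed, over 25-sample windows,
   with the FSR channels, per-foot forefoot/backfoot sums
   (FSR_Fore = toe + 1st + 5th metatarsal, FSR_Back = cuboid + heel) and
   the classifier's condition code.

The gait phase φ ∈ [0, 100) — 0 at each right heel strike — is regressed
through its continuous sinusoidal encoding

    θ = φ · 2π/100,   y = (cos θ, sin θ),

which removes the 0/100 wrap; the estimate is decoded with the
four-quadrant arctangent, φ̂ = atan2(ŷ₂, ŷ₁)·100/2π (mod 100). Errors are
scored circularly, e = ((φ̂ − φ + 50) mod 100) − 50, with RMSE, R² on the
encoded pair, and rRMSE/APEE/NRMSE percentage variants.

Because datasets of this kind are rarely public, the package includes a
first-class **synthetic gait simulator**: per-condition stride templates
(heel-to-toe loading progressions that differ by terrain), subjects with
individual amplitudes, cadences, stance fractions and timing shifts,
stride jitter and sensor noise — with exact ground-truth phase and
condition labels. The recurrent networks themselves are implemented in
NumPy with explicit backpropagation through time (no deep-learning
framework required); gradients are verified against finite differences in
the test suite.

## Worked example

```python
import numpy as np
from gaitphase import (
    make_cohort, default_scripts, simulate_protocol, make_split,
    WcClassifierConfig, PhaseEstimatorConfig,
    train_wc_classifier, train_phase_estimator, run_pipeline,
    phase_error_metrics,
)
from gaitphase.models import fit_norm_stats_per_subject

cohort = make_cohort(2, base_seed=42)          # two synthetic subjects
data = simulate_protocol(cohort, default_scripts(12, 5), trials_per_script=3)
split = make_split(data, test_trial_index=3)   # 3rd trials held out
stats = fit_norm_stats_per_subject(split.train_recordings)

wc = train_wc_classifier(
    split, WcClassifierConfig(max_epochs=6, hop=60, folds=1, seed=1), stats)
ph = train_phase_estimator(
    split, PhaseEstimatorConfig(variant=1, max_epochs=8, hop=10, seed=1),
    norm_stats=stats["S01"])

rec = [r for r in split.test_recordings if r.subject_id == "S01"][0]
res = run_pipeline(rec, ph, wc, hop=10)
idx = res.eval_indices
m = phase_error_metrics(np.asarray(rec.phase)[idx], res.phase_pred[idx],
                        est_csf=res.csf_pred)
print(f"RMSE {m.overall['rmse']:.2f}  R2 {m.overall['r2']:.3f}  "
      f"APEE {m.overall['apee']:.2f}%")
```

Typical output:

```
RMSE 2.24  R2 0.943  APEE 1.83%
```

i.e. on this subject's held-out trials the decoded phase is on average
about 2 % of a gait cycle away from ground truth (RMSE ≈ 2 phase units),
and the estimated sine–cosine pair explains ≈ 94 % of target variance.
Numbers vary with the seed and the (deliberately small) training budget in
this snippet.

There is also a CLI covering the same workflow
(`gaitphase simulate | train | evaluate | predict | ablate`, driven by a
YAML config), and `gaitphase.experiments.run_study` bundles the whole
protocol — shared classifier, per-subject estimators, own- versus
cross-subject grid — into one call.

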