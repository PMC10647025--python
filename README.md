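# ribecho

Rib detection from single-channel pitch-catch ultrasound.

Wearable therapeutic-ultrasound devices aimed at abdominal organs (spleen,
liver, kidney) must transmit through the intercostal space: a rib in the
beam path absorbs and reflects the energy. `ribecho` implements an
imaging-free alternative — classify the device's own received echo signal
(rUS) to decide whether it sits over a rib, partially over one, or over
the gap between ribs — together with a calibrated signal simulator, so the
whole pipeline is testable without clinical recordings. It is aimed at
researchers prototyping onboard rib-detection logic and at anyone who
needs a reproducible test bed for A-mode echo classification.

## The methods

The device emits a 3-cycle tone burst at `f_c = 715 kHz` (4.2 µs) and
records the return at 25 MHz. A rib at depth `d` produces an echo at the
round-trip time of flight `t_e = 2d/c` (`c = 1480 m/s`), so depth can be
read back as `d = c·t_e/2`. Four classifiers are fitted per task and per
BMI cohort (the obesity threshold BMI = 30 splits the cohorts):

* **time-domain thresholding** — the maximum of the rectified signal in a
  fitted time window is compared against one threshold (binary tasks) or
  two (`θ₂ > θ₁`, ternary task); window and thresholds minimize balanced
  error exactly over all achievable cut points;
* **frequency-domain thresholding** — the same rule on the peak magnitude
  of the zero-padded FFT restricted to 493.8–931.3 kHz around `f_c`;
* **logistic regression** and a **linear SVM** on a 70-entry feature
  vector (34 time-bin means, 25 spectral features, 11 demographics),
  trained on class-balanced data with deterministic convex solvers.

Tasks: (1) NoRib vs WholeRib, (2) NoRib vs Rib (partial pooled), (3)
ternary NoRib / PartialRib / WholeRib. Metrics are balanced accuracy
(mean per-class recall), F1 / macro-F1, and stratified k-fold loss.
`docs/methods.md` covers the signal model, cohort calibration and design
choices in detail.

## Worked example

```python
import ribecho as re_
from ribecho.sim import CohortConfig, with_seed
from ribecho.benchmark import run_benchmark

ds = re_.synth_dataset(with_seed(CohortConfig(), 42))   # 1000 traces
model = re_.fit_time_model(ds, task=1, cohort="low_bmi")
print("window: [%.2f, %.2f] us  threshold: %.2f V"
      % (model.window_start_s * 1e6, model.window_end_s * 1e6, model.theta1))

table = run_benchmark(ds, seed=42, methods=("time_threshold", "svm"),
                      tasks=(1,))
print(table[["method", "cohort", "balanced_accuracy", "f1"]]
      .to_string(index=False))
```

prints

```
window: [15.00, 35.00] us  threshold: 0.20 V
        method   cohort  balanced_accuracy       f1
time_threshold      all           0.931250 0.926174
           svm      all           0.931250 0.926174
time_threshold  low_bmi           0.822917 0.784810
           svm  low_bmi           0.822917 0.784810
time_threshold high_bmi           1.000000 1.000000
           svm high_bmi           1.000000 1.000000
```

The fitted low-BMI window ([15, 35] µs) brackets the round-trip delays of
shallow ribs; the threshold sits just above the noise floor. Held-out
balanced accuracy is perfect for the deep-rib high-BMI cohort, while the
low-BMI cohort is capped by ribs so shallow that their echoes arrive
inside the excitation artifact (see `docs/methods.md`).

The same workflow is available from a shell:

```sh
ribecho simulate --out ds/ --seed 42
ribecho train --manifest ds/manifest.json --method time_threshold \
        --task 1 --cohort low_bmi --out model.json
ribecho evaluate --model model.json --manifest ds/manifest.json \
        --report report.json
ribecho benchmark --manifest ds/manifest.json --seed 42 --out metrics.csv
ribecho depth --manifest ds/manifest.json --out depth.csv
```

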