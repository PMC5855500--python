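# fsrcop

Foot plantar **center-of-pressure (COP)** trajectory estimation for low-cost
**force-sensitive-resistor (FSR) instrumented insoles**.

The COP — the point of application of the resultant ground-reaction force
under the foot — is a standard quantity in postural-control and fall-risk
assessment. Laboratory systems (force plates, commercial pressure-mapping
insoles) measure it directly but are expensive and tethered; a cheap insole
with a dozen FSRs can only sample the pressure field sparsely. This package
implements, evaluates and simulates the two estimators used with such
insoles:

- **Weighted-mean baseline.** With sensor coordinates $(x_i, y_i)$ and
  per-sensor forces $F_i$,

  $$X_\mathrm{COP} = \frac{\sum_{i=1}^{12} x_i F_i}{\sum_i F_i},\qquad
    Y_\mathrm{COP} = \frac{\sum_{i=1}^{12} y_i F_i}{\sum_i F_i}.$$

  Its accuracy is limited by the fixed coordinates: sensor gain spread,
  placement error and unregistered load bias it systematically.

- **Individual-specific least-squares model.** The fixed coordinates are
  replaced by coefficients fitted per subject, per foot and per axis from
  that subject's own paired FSR/reference recordings. Two functional forms
  are provided. The *linear* form stacks the 12 forces plus the total force
  $F_\mathrm{tot}=\sum_i F_i$ into an $m\times 13$ design matrix $F$ and
  solves the normal equations $F^\top(F\hat c - X_\mathrm{COP}) = 0$ per
  axis. Because the 13th column is the exact sum of the first twelve, the
  system is rank-deficient; the minimum-norm SVD solution is used, and all
  predictions are invariant to the resulting gauge freedom. The
  *normalized* form (the default for evaluation) regresses on the force
  fractions $F_i/F_\mathrm{tot}$, which makes the estimate scale-invariant
  — the same invariance the true COP has.

Evaluation follows a three-fold cross-validation over a six-task postural
battery (quiet standing eyes open/closed; sit-to-stand and stand-to-sit
with and without armrests), three trials per task, with task-complete
folds, reporting RMSE, Pearson correlation (with p-value), and the
maximum/minimum absolute error per fold and axis.

Because paired insole/reference recordings require hardware, the package
ships a first-class **synthetic-data module**: plantar pressure is modelled
as a mixture of nine anatomical pressure blobs whose amplitudes are solved
to realise a prescribed ground-truth COP path and load profile, then
measured through an imperfect 12-sensor array (per-sensor gains, placement
offsets, noise, 10-bit quantisation). See `docs/methods.md` for the model
and its limitations.

## Worked example

```bash
fsrcop simulate --subjects 1 --seed 42 --out cohort/
fsrcop evaluate --recordings cohort/ --out report.json
```

which prints (numbers from this exact invocation):

```
S00/left (normalized):
  model         AP: RMSE 0.4679 +/- 0.09 mm, CC 0.9997
  model         ML: RMSE 0.1822 +/- 0.018 mm, CC 0.9993
  weighted-mean AP: RMSE 11.89 +/- 0.36 mm, CC 0.9973
  weighted-mean ML: RMSE 8.763 +/- 0.76 mm, CC 0.9587
```

Reading: on this simulated subject the individually fitted model tracks the
ground-truth COP to a fraction of a millimetre, while the weighted mean
carries a systematic error of several millimetres caused by the subject's
sensor-gain spread and placement offsets; errors are larger along the
anterior-posterior (AP) axis than medial-lateral (ML) because AP
excursions are several times larger. The same comparison can be run
library-side:

```python
from fsrcop import default_layout, make_cohort, evaluate_cohort

cohort = make_cohort(20, master_seed=1)
df = evaluate_cohort(cohort, default_layout())
print(df.groupby("axis")[["model_rmse", "baseline_rmse"]].mean())
```

Other subcommands: `fsrcop fit` (write a model JSON), `fsrcop compare`
(paired fold-by-fold comparison of two reports), `fsrcop calibrate`
(fourth-order voltage-to-force polynomial from bench pairs), `fsrcop plot`
(estimate-vs-reference figure).

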