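# opsweep

Quantifying how occlusal-plane rotation changes facial aesthetics across
skeletal types, with a neural surrogate interrogated counterfactually.

## The problem

In orthodontics, rotating the occlusal plane (OP) — measured as the SN-OP
angle between the sella–nasion line and the bisected occlusal plane — drives
mandibular rotation and therefore the patient's profile. Two cephalometric
indices summarize the aesthetic consequences:

* **FHR** (P-A face height ratio, S-Go/N-Me, in percent): vertical balance;
  higher values mean a shorter, hypodivergent face.
* **FA** (facial angle, NPo-FH, in degrees): mandibular protrusion; higher
  values mean a more prognathic (concave) profile.

Clinicians want to know the *sensitivity* of each index to OP rotation —
`dFHR/dSN-OP` and `dFA/dSN-OP` — and whether it differs among the nine
skeletal types formed by crossing the sagittal classes (I/II/III, by ANB)
with the vertical growth patterns (hypo-/normo-/hyperdivergent, by a 2-of-3
rule over SN-MP, FH-MP and FHR).

Because craniofacial geometry is interdependent and nonlinear, the analysis
trains a feedforward network (10 skeletal inputs → 10 tanh hidden units →
linear output) to emulate each index, then asks it a counterfactual
question per patient: *holding the other nine skeletal measurements fixed,
sweep SN-OP over 9–25° and regress the predicted index on the swept angle.*
The per-patient ordinary-least-squares line gives a slope `k` (sensitivity)
and intercept `b` (the patient's inherent level); cell-wise summaries with
ANOVA/Bonferroni or Kruskal–Wallis/Dunn comparisons give the group
conclusions. Since patient radiographs are private, a calibrated synthetic
cohort generator (903 records, the published cell allocation, per-cell
feature moments and per-cell `k`/`b` coefficients) stands in for the
measurement data, making every stage testable end to end.

## Worked example

```python
from opsweep import GeneratorConfig, SurrogateRegression, generate_cohort, run_sweep
from opsweep.pipeline import stage_seeds

seeds = stage_seeds(1)                               # one global seed -> per-stage seeds
cohort, truth = generate_cohort(GeneratorConfig(seed=seeds["generate"]))
res = SurrogateRegression.from_dataframe(cohort.to_frame(), "FA").fit(seed=seeds["fit_FA"])
print(res.summary())
sw = run_sweep(res, cohort)                          # 9-25 degree sweep, 17 points
print(sw.summarize(cohort.labels).round(3))
```

prints (exactly this, for this seed):

```
Surrogate regression results: FA
==========================================================
inputs: 10  hidden units: 10  seed: 1320224556
epochs run: 37  best epoch: 17  converged: True
split sizes: 632/135/136
MSE (normalized) at best epoch: train 0.01058  val 0.01332  test 0.02295
train: r = 0.9581  paired t = +0.515 (p = 0.607)  LoA [-1.428, +1.458]  within = 94.3%
  val: r = 0.9528  paired t = -0.056 (p = 0.955)  LoA [-1.629, +1.621]  within = 94.8%
 test: r = 0.9039  paired t = -0.403 (p = 0.688)  LoA [-2.168, +2.093]  within = 94.1%

sagittal vertical   n  k_mean  k_sd  b_mean  b_sd
       I     hypo 102  -0.378 0.108  94.937 2.862
       I      nor 109  -0.299 0.102  93.350 2.729
       I    hyper 106  -0.264 0.092  92.210 2.370
      II     hypo  85  -0.360 0.073  93.872 1.635
      II      nor 107  -0.307 0.077  93.222 1.813
      II    hyper 101  -0.254 0.076  91.400 2.057
     III     hypo 103  -0.473 0.121  97.521 2.819
     III      nor 103  -0.404 0.146  95.915 3.521
     III    hyper  87  -0.357 0.088  94.717 2.223
```

Reading the output: the surrogate tracks FA with held-out correlation 0.90
and Bland–Altman limits of ±~2°, with ~95% of pairs inside the limits (no
systematic bias: paired t p ≈ 0.69). The sweep slopes reproduce the two
qualitative findings: within every sagittal class the hypodivergent cell is
the most sensitive (`|k|` hypo > nor > hyper, e.g. Class I: 0.378 > 0.299 >
0.264 °/°), and Class III is more sensitive than Classes I and II in every
vertical pattern (hypo column: 0.473 vs 0.378/0.360). FHR slopes, by
contrast, are nearly constant near −0.28 %/° everywhere — a 10° OP rotation
moves the face-height ratio by about 2.8 percentage points regardless of
skeletal type.

The same analysis is scriptable end to end:

```bash
opsweep run-all --seed 1 --outdir out/     # cohort, 2 models, slopes, annotated tables, manifest
```

## Package layout

| module | contents |
| --- | --- |
| `opsweep.data` | `CephRecord`, `Cohort`, validation, CSV/JSON I/O |
| `opsweep.tables` | reference-cohort calibration constants |
| `opsweep.classify` | ANB bands + 2-of-3 vertical quorum rule |
| `opsweep.synthetic` | calibrated cohort generator, outcome surfaces, rater-reliability emulation |
| `opsweep.surrogate` | `SurrogateRegression` / `SurrogateResults` (Levenberg–Marquardt trainer, early stopping, Bland–Altman agreement) |
| `opsweep.sweep` | `SweepGrid`, per-patient counterfactual sweep and OLS slopes |
| `opsweep.stats` | normality screen, ANOVA/Bonferroni vs Kruskal–Wallis/Dunn routing, annotated tables, ICC |
| `opsweep.pipeline`, `opsweep.cli` | orchestration, seeds, manifests, `opsweep` command |

See `docs/methods.md` for the model, its assumptions and the design
decisions behind the generator.
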