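# ibsim

Simulation and analysis of **sustained inattentional blindness** in
multiple-object-tracking displays.

In this paradigm, observers count how often one colour of object bounces
off the edges of a display while an unexpected object (UO) — a cross —
drifts across the screen once, on the critical trial only. Roughly half of
observers never notice it. The scientific question is *when* noticing
happens: is detection a stochastic process whose probability accumulates
with exposure time, P(notice) = 1 − e^(−λT), or is it triggered by a
discrete event (the object's onset, its offset, or its crossing behind
fixation), predicting exposure-invariant rates but distinct clusters of
"where did you first see it?" reports?

`ibsim` is a tested, fully seeded implementation of that inferential loop
for researchers in visual attention and for methodologists studying
one-shot designs:

* **`ibsim.display`** — the 700×600 px display: eight objects moving at
  {66, 132, 198} px/s along 45° diagonals with reflecting speed walks and
  edge bounces; the UO's occluded trajectory and frame-by-frame visible
  fraction for every condition of three experiments; ground-truth bounce
  counts.
* **`ibsim.observers`** — generative observers for four noticing accounts
  (onset window, offset window, fixation crossing, constant hazard) with a
  shared report-noise model: noisy location placements on the two-thirds
  scale response panel, von Mises hue reports, 9-option menu reports,
  bounce-count errors and screening covariates. Emits complete synthetic
  cohorts as tidy DataFrames.
* **`ibsim.screening`** — the paradigm's exclusion rules, including
  Farnsworth D-15 confusion-index scoring (moment-of-inertia method, cap
  chromaticities packaged), with per-rule accounting tables.
* **`ibsim.analysis`** — percentile-bootstrap proportion and difference
  estimates, localisation distance tables and onset-side fractions,
  circular error summaries (angular deviation √(2(1−R))), and the Monte
  Carlo chance null for hue responding.
* **`ibsim.evaluation`** — cohort signatures, a rule-based classifier that
  recovers the generating account, maximum-likelihood hazard recovery with
  a lack-of-fit check, and the end-to-end pipeline with a seed manifest.

## Worked example

Generate a colour-report cohort under a constant-hazard observer
(λ = 0.3/s), screen it, estimate noticing rates, and recover the
generating model and its hazard:

```python
from ibsim import analysis, evaluation, observers, screening

model = observers.NoticingModel("constant_hazard", hazard_per_s=0.3)
cohort = observers.generate_cohort("E3", model, n_per_condition=500, seed=7)
retained, report = screening.apply_exclusions(cohort, "E3")
retained = analysis.add_noticer_column(retained)
print(f"recruited {report.total_recruited}, retained {report.total_retained}")
for label, sub in retained[retained.onset_type != "none"].groupby("exposure_label_s"):
    est = analysis.rate_with_ci(sub["noticer"].to_numpy(), seed=1)
    print(f"{label} s exposure: {est.point:.1f}% noticed "
          f"(95% CI {est.ci_low:.1f}-{est.ci_high:.1f}, n={est.n})")
sig = evaluation.compute_signature(retained, seed=2)
print("classified model:", evaluation.classify_model(sig))
fit = evaluation.recover_hazard(retained)
print(f"recovered hazard {fit.hazard_per_s:.3f}/s (se {fit.se:.3f})")
```

Output:

```
recruited 1000, retained 774
1.5 s exposure: 32.4% noticed (95% CI 27.5-37.2, n=374)
5.0 s exposure: 72.5% noticed (95% CI 68.0-76.8, n=400)
classified model: constant_hazard
recovered hazard 0.285/s (se 0.015)
```

A quarter of the synthetic cohort fails the screening rules (miscounts,
uncorrected vision, technical problems, colour deficiency, ...). The
noticing rate more than doubles from the 1.5 s to the 5 s exposure —
the stochastic-accumulation signature — so the classifier returns
`constant_hazard`, and the refitted hazard (0.285/s ± 0.015) recovers the
generating value of 0.3/s. An onset-triggered cohort would instead show
flat rates with location reports piled near the onset point.

The same stages are scriptable from the shell:

```bash
ib synth --experiment E3 --model constant_hazard --hazard 0.3 --n 250 \
         --seed 11 --out cohort.csv
ib screen --experiment E3 --in cohort.csv --out retained.csv --report excl.csv
ib analyze --in retained.csv --out results/
ib simulate --experiment E1 --condition E1-5s --direction LtoR --seed 7 \
            --out trace.jsonl
ib null-colour --batches 1000 --size 100 --seed 3
ib score-d15 1-2-3-4-5-6-7-8-9-10-11-12-13-14-15
```

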