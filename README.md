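# ccshape — deformation-based shape analysis of the mid-sagittal corpus callosum

`ccshape` is an analysis pipeline for localized shape morphometry of the 2D
mid-sagittal corpus callosum (CC) in case–control neuroimaging studies —
the setting where global area or volume comparisons of the CC and its
sub-regions (genu, body, splenium) miss focal effects, and where
deformation-based markers can localize *where* on the boundary a patient
group differs from controls.  It is aimed at researchers who have labeled
CC segmentations (e.g. from a multi-atlas whole-brain pipeline) plus a
covariate table, and at methodologists who want a fully testable
implementation with a synthetic cohort generator standing in for clinical
data.

## The method

1. **Curves.** The mid-sagittal slice (slice ⌈n/2⌉ of the sagittal axis;
   91 of 181 in MNI space) is reduced to an ordered, closed, clockwise
   boundary curve by Moore-neighbour tracing, each point labeled
   genu/body/splenium (gCC/bCC/sCC).
2. **Template.** The cohort template is the subject whose CC area is
   closest to the cohort mean, resampled to K equally spaced points.
3. **Registration.** Each target curve is rigidly aligned (rotation +
   translation only) and then matched by LDDMM curve registration: the
   template flows along a time-varying Gaussian-kernel velocity field
   v_t(x) = Σᵢ K_V(x, xᵢ(t)) αᵢ(t), minimizing kinetic energy plus a
   currents mismatch ‖[φ₁(template)] − [target]‖², which compares curves
   without point correspondence.  The flow is a diffeomorphism; at each
   template point k the ambient Jacobian D is integrated along the flow and
   the **deformation marker** J_k = det D_k records local area change:
   J > 1 expansion, J < 1 inward deformation of the target relative to the
   template.
4. **Statistics.** Pointwise linear models
   J_k(s) = β_k0 + β_k1 γ(s) + Σ α_cov X_cov(s) + ε_k(s) (γ = 1 for
   patients; covariates age, gender, TIV) are tested by Freedman–Lane
   permutation (10,000 permutations by default), with single-step max-|t|
   control of the family-wise error rate across points, an omnibus shape
   p-value, a gender × group interaction test gating per-gender post-hoc
   comparisons, and pooled-SD Cohen's d effect sizes.  The same machinery
   compares CC/gCC/bCC/sCC areas.

A synthetic cohort generator produces labeled CC-like mask slices with
per-subject diffeomorphic shape variation, TIV-coupled size, and a
controlled inward "disease" effect on the superior genu (female-specific by
default), so every stage is testable without access to clinical data.  See
`docs/methods.md` for the full model description and numerical choices.

## Worked example

The numbered scripts under `analysis/` drive the default synthetic study
(100 subjects, 25 per group × gender cell, 0.8-mm female-only genu effect)
through the cached pipeline; run them in order, or jump ahead — completed
stages are skipped:

```bash
python analysis/01_simulate_cohort.py --seed 1
python analysis/04_register_cohort.py --seed 1
python analysis/05_shape_statistics.py --seed 1
```

Output of `04_register_cohort.py` (seed 1):

```
registered 100 subjects (1 met the strict energy tolerance within the iteration cap; markers are cap-stable, see docs/methods.md)
mean marker: 0.995 +/- 0.039
area consistency: corr(template area x mean marker, CC area) = 0.9923
predicted areas 792.1 +/- 31.2 mm^2 vs actual 795.9 +/- 34.0 mm^2
marker-thickness correlation: 0.7560
```

The mean marker sits near 1 (the template is a cohort member); multiplying
the template area by each subject's mean marker reproduces that subject's
actual CC area almost exactly (r = 0.992) — the internal consistency check
that the Jacobian marker really measures local area change.  And from
`05_shape_statistics.py`:

```
gender x group interaction (shape): p = 0.0485 -> post-hoc gate passed

scope all: omnibus shape p = 0.0065, 9 FWER-significant points
  by region: {'gCC': 9, 'bCC': 0, 'sCC': 0}
  Cohen's d over significant points: 0.647 +/- 0.038
  effect (-beta1) at significant points: 0.055 .. 0.073

scope female: omnibus shape p = 0.0030, 8 FWER-significant points
  by region: {'gCC': 8, 'bCC': 0, 'sCC': 0}
  Cohen's d over significant points: 1.090 +/- 0.059
  effect (-beta1) at significant points: 0.092 .. 0.121

scope male: omnibus shape p = 0.3743, 0 FWER-significant points
```

The pipeline flags inward deformation confined to the genu in the female
scope only — exactly the effect the generator injected — with large effect
sizes (d ≈ 1.1) at the flagged points, while the male scope (no injected
effect) stays clean.  `ccshape report` renders the template colored by the
inward-deformation effect with significant points highlighted.

The same pipeline runs from a shell for external data
(`ccshape run-all --config my_study.yaml`), consuming NIfTI label maps and
a `subject_id,group,gender,age,tiv` CSV.

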