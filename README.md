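# pmbrainvol

Brain volumetry for **post-mortem fetal and newborn MRI**.

Estimating brain weight is an integral part of perinatal autopsy, but
manual segmentation of post-mortem MR images is too labor-intensive for
routine practice — and after death the tissue relaxation times converge
toward free-water values, collapsing the gray/white/CSF contrast that
in-vivo segmentation tools rely on.  `pmbrainvol` implements a
semi-automatic pipeline for this setting, aimed at researchers in
perinatal imaging and minimally invasive autopsy:

1. **Preprocessing** — multiplicative bias-field estimation (log-domain
   polynomial fit with tissue demeaning) and atlas-based intracranial
   mask propagation.
2. **Segmentation** — expectation-maximization with atlas priors, a
   mean-field Potts MRF and prior relaxation, classifying cerebrum,
   cerebellum, brainstem and CSF; a second stage merges cerebrum with
   CSF, which cannot be separated by intensity post mortem.
3. **Groupwise atlas** — an average template and average segmentation
   built by registering a cohort to an evolving mean (rigid → affine →
   non-rigid rounds), so a post-mortem-specific atlas can replace an
   in-vivo one for the next cohort.
4. **Volumetry** — per-subject CSF intensity thresholds exclude free
   fluid from the merged region; volume is `voxels × voxel volume`, and
   weight is `volume × ρ` with brain density ρ = 1.08 g/mL.
5. **Validation** — Dice overlap, `2|A∩B|/(|A|+|B|)`, and Bland–Altman
   agreement (differences autopsy − MRI, limits of agreement
   `mean ± 1.96·SD`).

Everything is exercised end-to-end on synthetic 3-D brain phantoms
(nested ellipsoids with analytic volumes, bias, noise, and cohort warps),
and the statistics layer reproduces the per-subject weight tables of two
17-subject post-mortem cohorts that ship with the package.

## Worked example

Reproduce the cohort agreement statistics from the packaged tables:

```bash
$ pmbrainvol reproduce-tables
newborn: n=15 MRI mean 418 g, autopsy mean 434 g, mean |diff| 20 g, LoA [-32, 65] g
fetal: n=13 MRI mean 310 g, autopsy mean 312 g, mean |diff| 5 g, LoA [-7, 12] g
all aggregate checks passed
```

Read: across the 15 newborns with autopsy weights, the MRI-derived
cerebrum weight averages 418 g against 434 g on the scale; the mean
absolute disagreement is 20 g and 95 % of differences are expected within
[−32, 65] g.  The fetal cohort agrees even more closely (5 g mean
absolute difference) — fetal subjects vary less in age, size and shape.

The same pipeline in Python, on synthetic phantoms:

```python
from pmbrainvol import (PhantomSpec, generate_cohort, atlas_from_truth,
                        PipelineConfig, run_newborn_pipeline)

atlas = atlas_from_truth(
    [t for _, t in generate_cohort(PhantomSpec(seed=900, deform_sd=1.5), 3)])
cohort = generate_cohort(PhantomSpec(seed=17, deform_sd=1.5), 5)
cfg = PipelineConfig(csf_thresholds={f"s{i}": 750.0 for i in range(5)})
out = run_newborn_pipeline(cfg, [(f"s{i}", im) for i, (im, _) in enumerate(cohort)], atlas)
for s in out.subjects:
    print(s.subject_id, round(s.record.mri_volume_mL, 2), "mL",
          round(s.record.mri_weight_g, 2), "g")
```

Each subject gets a merged-label map, a retained cerebrum volume and a
weight; `out.atlas` is the groupwise average atlas built from the cohort.
On the default phantoms the merged cerebrum+CSF Dice against ground truth
is ≈ 0.99 and the thresholded cerebrum volume is within a fraction of a
percent of the analytic truth.

A command-line interface mirrors every stage:
`pmbrainvol {simulate, preprocess, register, segment, atlas, volumetry,
validate, run-newborn, run-fetal, reproduce-tables}`.

## Layout

```
src/pmbrainvol/
  core.py           grid containers (VolumeImage, LabelMap, ProbabilisticAtlas)
  phantom.py        synthetic phantoms, cohorts, truth-derived atlases
  preprocess.py     bias field, mask propagation/refinement/edits
  registration.py   rigid/affine/B-spline/Demons registration + resampling
  em.py             EM-MRF segmentation and class merging
  atlas_builder.py  groupwise template construction
  volumetry.py      CSF threshold, volumes, weights, cohort tables
  validation.py     Dice, Bland–Altman, prior-source comparison
  pipeline.py       cohort pipelines and table reproduction
  cli.py            command-line interface
  data/             packaged cohort tables (CSV)
```

`docs/methods.md` documents the model, parameter defaults, phantom
assumptions and design decisions.
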