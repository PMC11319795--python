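# echosway

Links **ultrasound-derived muscle composition** to **posturographic
stability** in young and older adults, as a tested, reusable Python
pipeline. It is aimed at researchers in muscle physiology, ageing and
balance who want to quantify B-mode muscle images, summarize quiet-stance
force-plate recordings, and relate the two — without writing the plumbing
themselves.

The chain covers:

- **Ultrasound image quantification** (`echosway.us_image`): echo-intensity
  (EI, the mean gray level 0–255 inside a muscle cross-section polygon),
  muscle and subcutaneous-fat thickness (MT, SAT) from interface landmarks,
  and gray-level co-occurrence matrix (GLCM) texture at a one-pixel offset
  in four directions (0°, 90°, 180°, 270°, averaged), summarized by five
  Haralick features:
  ASM = Σᵢⱼ p(i,j)², Contrast = Σᵢⱼ (i−j)² p(i,j),
  Correlation = Σᵢⱼ (i−μᵢ)(j−μⱼ) p(i,j)/(σᵢσⱼ),
  IDM = Σᵢⱼ p(i,j)/(1+(i−j)²), Entropy = −Σᵢⱼ p(i,j) log p(i,j).
- **Posturography** (`echosway.posturography`): center of pressure from
  force-plate channels (COP_ML = −My/Fz, COP_AP = Mx/Fz), zero-phase
  4th-order Butterworth band-pass 0.1–10 Hz, and stability as the standard
  deviation of the filtered COP (sdCOP) per axis, normalized by body height.
- **Group statistics** (`echosway.group_stats`): pooled-variance Student
  t-tests (from raw samples or printed mean ± SD summaries), Fisher's exact
  test, ICC(2,1) test–retest reliability with 95% CI, and a two-way
  condition × age-group ANOVA with classical η² and Bonferroni post-hocs.
- **ROC classification** (`echosway.roc`): empirical ROC/AUC per ultrasound
  parameter for young-vs-old classification (fixed a-priori score
  orientation), with DeLong z-tests for paired AUC comparisons.
- **Regularized CCA** (`echosway.cca`): the association analysis — z-score,
  winsorize at ±2.5 SD, residualize on age, then the first canonical pair of
  (Sxx+λxI)⁻¹Sxy(Syy+λyI)⁻¹Syx with λ chosen by leave-one-out
  cross-validation, permutation inference (shuffling the ultrasound block
  only), and a pooled Pearson follow-up using the canonical weight signs.
- **Synthetic data** (`echosway.synthetic`): generators for cohorts (with a
  controllable latent muscle-quality ↔ sway coupling), layered
  speckle images with ground-truth ROIs, and force-plate recordings with
  exactly planted sway SDs — so every stage runs and is testable with no
  external data.

## Worked example

Run the full pipeline on a synthetic cohort (32 young, 34 old; default
coupling 0.53 in the young group, 0 in the old group):

```bash
echosway run-all --output-dir demo --master-seed 1
```

or in Python:

```python
from echosway.pipeline import RunConfig, run_pipeline
results = run_pipeline(RunConfig(output_dir="demo", master_seed=1))
```

With master seed 1 this prints (excerpt):

```
AUCs:  EI 0.990  MT 0.950  SAT 0.453  ASM 0.720  IDM 0.947  Entropy 0.856
ANOVA: condition F=61.5 (eta2 0.259), group F=233.8 (eta2 0.328),
       interaction F=12.8 (eta2 0.054)
young: canonical r=0.605, perm_p=0.055, pooled r=0.563 (moderate)
old:   canonical r=0.450, perm_p=0.844, pooled r=0.120 (very weak)
```

Reading: echo-intensity and muscle thickness separate young from old almost
perfectly (AUC ≈ 0.95–0.99) while subcutaneous fat is near chance; sway
depends strongly on condition and age; and the muscle-quality ↔ sway
association planted in the young group is recovered (moderate pooled
correlation) while the old group is correctly flagged as null. Individual
runs vary with the seed — at n = 32 the permutation test has roughly 60%
power against a planted coupling of 0.5.

The output directory contains the cohort (wide and long CSV), per-variable
group comparisons, ANOVA tables, ROC points and pairwise AUC comparisons,
pooled CCA scores, and a `results.json` embedding the package version and a
hash of the configuration.

## Layout

```
src/echosway/
  synthetic.py       cohort / image / force-plate generators
  us_image.py        EI, thicknesses, GLCM + Haralick features
  posturography.py   COP, band-pass, sway summaries
  group_stats.py     t-tests, Fisher, ICC, two-way ANOVA, labels
  roc.py             empirical ROC/AUC, DeLong comparisons
  cca.py             preprocessing, ridge CCA, LOO selection, permutations
  pipeline.py        end-to-end orchestration (RunConfig, run_pipeline)
  __main__.py        CLI: simulate | texture | posture | classify | associate | run-all
docs/methods.md      models, assumptions, parameter choices, limitations
```
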