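# dbmtk — deformation-based morphometry of brain aging and disease

`dbmtk` separates the morphological changes visible in a brain MRI scan
into two interpretable components: the part explained by **normal
aging** and the **disease-specific residual** that normal aging cannot
account for. It is aimed at neuroimaging researchers studying
neurodegeneration (e.g. Alzheimer's disease cohorts staged by clinical
dementia rating, CDR), who want per-scan, per-region biomarkers rather
than raw deformation fields.

## The model

All deformations are parameterized by stationary velocity fields
(SVFs). An SVF $v$ defines a diffeomorphism $\phi = \exp(v)$ through
the flow ODE $\dot\phi^{(t)} = v(\phi^{(t)})$, $\phi^{(0)} = \mathrm{id}$,
integrated over unit time by scaling and squaring. Given

- $v_0$ — the **one-year normal-aging field**: the SVF aligning a
  young (60 y) healthy template to an old (90 y) one, divided by the
  30-year age gap, and
- $v_{\mathrm{subject}}$ — the SVF aligning the reference template with
  a subject's scan,

each voxel's deformation vector is split by orthogonal projection:

$$AS = \frac{\langle v_{\mathrm{subject}},\, v_0\rangle}{\lVert v_0\rVert^2},
\qquad
ADS = \lVert v_{\mathrm{subject}} - AS \cdot v_0 \rVert .$$

The **aging score** $AS$ (years) says how many years of normal aging
the local deformation is worth — negative values mean younger-looking
than the reference; the **disease-specific score** $ADS$ (voxels) is
the magnitude of the residual deformation orthogonal to normal aging.
Scores are computed voxel-wise, cleaned by quantile thresholding on
$\lVert v_0\rVert$ (voxels with near-zero normal-aging signal produce
unstable quotients), and averaged over anatomical regions: whole brain,
ventricles (labels 4/14/15/43), hippocampi & amygdala (17/53/18/54),
and the ventricle *edge map* (the difference between the old- and
young-template ventricle segmentations). The rejection quantile is
chosen per region by maximizing the $R^2$ of the AS-versus-age fit in
cognitively normal (CN) scans over the grid $0, 0.1, \dots, 0.9$.

The cohort layer provides ordinary-least-squares AS/ADS-versus-age
fits, ANCOVA age adjustment with CN-mean centering, Welch t-tests with
Bonferroni correction, and Cohen's $d$ with banded effect sizes
(medium $[0.35, 0.65)$, large $[0.65, 0.9)$, very large $\ge 0.9$).

Also included: an entropy-focus criterion (EFC) for template sharpness,
a deterministic multiresolution SVF registration (classical demons-style
optimizer), and a synthetic phantom/cohort generator so the entire
pipeline runs with zero downloads.

## Worked example

```python
import numpy as np
from dbmtk import AgingDecomposition, build_aging_field
from dbmtk.synthetic import CohortSpec, make_aging_field, make_cohort, make_phantom

template, seg = make_phantom()
v_age = make_aging_field(template, seg)           # ground-truth 1-year field
cohort = make_cohort(CohortSpec(seed=42), template, seg, v_age)

v0 = build_aging_field(pair_svf=30.0 * v_age, age_young=60, age_old=90)
model = AgingDecomposition.from_cohort(cohort, v0, seg_ref=seg)
results = model.fit(quantile="auto")

fit = results.fit_vs_age("ventricles", "AS")
print(f"CN aging-score slope: {fit.slope:.3f} /yr (R^2 = {fit.r_squared:.3f})")
for ps in results.pairwise_tests("hippocampi-amygdala", "ADS")[:3]:
    print(f"{ps.group_a} vs {ps.group_b}: d = {ps.cohens_d:+.2f} "
          f"({ps.effect_band}), p_corr = {ps.p_corrected:.2e} {ps.significance}")
```

prints

```
CN aging-score slope: 0.994 /yr (R^2 = 0.999)
CDR0 vs CDR0.5: d = -4.38 (very large), p_corr = 1.65e-15 ****
CDR0 vs CDR1: d = -9.93 (very large), p_corr = 3.69e-21 ****
CDR0 vs CN: d = +2.68 (very large), p_corr = 3.04e-10 ****
```

The simulated cohort plants an aging-score slope of 1 year per year of
chronological age, recovered here as 0.994, and increasing
disease-specific offsets across CDR stages, which surface as large
positive effect sizes of later stages over earlier ones (the effect
sizes on noiseless-by-construction synthetic data are far larger than
anything seen on real scans).

The same pipeline is available from the shell:

```bash
dbm simulate --preset cohort-small --out cohort/ --seed 7
dbm run --cohort-dir cohort/ --out results/ --seed 7
dbm efc cohort/template_60.nii.gz --mask cohort/seg_60.nii.gz
```

`dbm run` writes `scores.csv` (one row per scan and region),
`stats.csv` (pairwise group tests), plots, and a `run_config.json`
recording the chosen quantiles, seed and input checksums. Real data
can be plugged in at any stage: externally computed SVFs are ingested
as 4-D NIfTI (`dbm score --cohort-dir ...`), templates and
segmentations as 3-D NIfTI.

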