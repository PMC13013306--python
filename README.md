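# stasfd

**3D box-counting fractal dimension and a logistic nomogram pipeline for
predicting spread through air spaces (STAS) in stage IA lung
adenocarcinoma.**

STAS — detached clusters of tumor cells in alveolar spaces beyond the main
tumor edge — is a WHO-recognized invasion pattern that argues for lobectomy
over sublobar resection, yet it can only be confirmed on the resected
specimen. A preoperative, imaging-based risk estimate is therefore
clinically valuable. This package implements the quantitative core of such
an estimate:

1. **3D fractal dimension (FD 3D)** of a binary tumor mask by classical
   box counting: cover the voxel lattice with cubic boxes of edge `s`,
   count the boxes `N(s)` containing tumor, and take

   `FD = slope of log N(s) vs log(1/s)` (ordinary least squares).

   A spatially continuous tumor fills space and scores near 3; the
   fragmented, "skip"-pattern growth of STAS-positive tumors lowers the
   slope.
2. **Cohort statistics** — χ²/Fisher group comparisons, Woolf-interval odds
   ratios, pooled t and Mann–Whitney tests, logistic regression with Wald
   intervals, VIF, and ICC for rater agreement.
3. **A nomogram** over the four independent predictors (CTR, morphological
   irregularity, lobulation, FD 3D), evaluated by ROC/Youden analysis with
   a bootstrap AUC interval, Hosmer–Lemeshow + bootstrap calibration, and
   decision-curve analysis.
4. **Risk stratification** at a probability cutoff with PPV/NPV and a
   continuity-corrected χ² group comparison.
5. **Synthetic data** — fractal phantoms of known dimension (cube, plane,
   line, Menger sponge), tumor-like phantoms with a controllable fraction
   of detached satellite clusters, and simulated cohorts with the
   group-conditional feature structure of the reference 110-patient
   population — so the entire pipeline is testable without patient data.

## Worked example

```python
import numpy as np
import stasfd as sf

# FD of an exactly self-similar phantom: level-2 Menger sponge
menger = sf.make_fractal_phantom(sf.PhantomSpec("menger", 2))
est = sf.fit_fractal_dimension(sf.box_count(menger, [1, 3, 9]))
print(f"Menger level-2: FD = {est.fd:.4f} (analytic {np.log(20)/np.log(3):.4f})")

# fragmentation lowers FD 3D at identical tumor volume
solid = sf.make_tumor_phantom(48, fragmentation=0.0, seed=1)
frag  = sf.make_tumor_phantom(48, fragmentation=0.5, seed=1)
print(sf.fd_pipeline(solid).fd, sf.fd_pipeline(frag).fd)

# full pipeline on a simulated 110-patient cohort
from stasfd.cli import run_pipeline
from stasfd.io import RunConfig
res = run_pipeline(RunConfig(cohort_n=110, seed=1, output_dir="demo_out"))
print(res["summary"])
```

prints (abridged):

```
Menger level-2: FD = 2.7268 (analytic 2.7268), r^2 = 1.000000
continuous tumor phantom: 3669 voxels, FD 3D = 2.353
fragmented tumor phantom: 3669 voxels, FD 3D = 1.936
simulated cohort n=110: AUC 0.923 (95% CI 0.872-0.964)
Youden cutoff 0.490, sens 86.96%, spec 84.38%
Hosmer-Lemeshow p = 0.808
high-risk 50 (PPV 80.00%), low-risk 60 (NPV 90.00%)
```

The Menger sponge hits its analytic dimension `log 20 / log 3 ≈ 2.7268`
exactly because its box-count points are collinear on the natural `1-3-9`
size ladder. The two tumor phantoms contain the same 3 669 voxels; moving
half of the volume into detached satellite clusters drops FD 3D from 2.35
to 1.94 — the geometric signature the model exploits. The pipeline output
is the discrimination/calibration/stratification summary of the nomogram
refit on the simulated cohort.

## Command line

```bash
stasfd simulate --kind menger --size 2 --out menger.nii.gz
stasfd fd3d --in menger.nii.gz --out fd.csv --qc-dir qc/
stasfd simulate --kind cohort --size 110 --seed 1 --out cohort.csv
stasfd stats --cohort cohort.csv --out-dir stats/
stasfd fit --cohort cohort.csv --out nomogram.json
stasfd evaluate --cohort cohort.csv --model nomogram.json --out-dir eval/
stasfd stratify --cohort cohort.csv --model nomogram.json --cutoff 0.56 --out-dir strata/
stasfd pipeline --config cfg.json      # end-to-end
```

## Layout

```
src/stasfd/
  fractal.py       box counting, log-log fitting, QC
  synthetic.py     phantoms and cohort simulation
  cohort_stats.py  contingency/continuous tests, logistic, VIF, ICC
  model.py         nomogram, ROC, calibration, decision curves
  stratify.py      cutoff-based risk groups
  io.py, cli.py    NIfTI/CSV I/O, run config, command line
docs/methods.md    model assumptions, defaults, limitations
```
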