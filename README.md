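# kneessm

Statistical shape modelling of the tibio-femoral joint, and the question it
serves: **can knee malalignment be read off bone shape alone, without
landmarks?**  Clinically, knee instability is graded by five angles measured
from manually placed landmarks — hip–knee–ankle (HKA), femoral and tibial
varus–valgus (FVV, TVV), internal–external femoral rotation (IER) and tibial
slope (TS).  `kneessm` builds a joint statistical shape model (SSM) of the
distal femur + proximal tibia complex and tests whether its modes of
variation predict, per angle, whether a knee lies inside or outside the
physiological range.

The package is aimed at biomechanics and orthopedic-imaging researchers who
want a fully testable, end-to-end reference implementation: every stage runs
on synthetic cohorts with known ground truth, so no patient data are needed
to validate any claim.

## The model

A cohort of M knees, each reduced to the same P reference-indexed surface
points, is stacked as 3P-vectors.  PCA of the sample covariance gives the
mean shape m̄, orthonormal modes v_i and mode SDs σ_i (at most M−1 modes):

* explained variance  EV_j = σ_j² / Σ_i σ_i²
* morphing            Š = m̄ + Σ_i λ_i σ_i v_i
* projection          λ_i = v_i · (s − m̄) / σ_i

Weights λ are unitless SD multiples; λ = 0 is the mean shape.  Dense
correspondences come from a single rigid alignment of each femur+tibia pair
(preserving the joint space) followed by per-bone coherent point drift and
closest-point projection onto the sample surface.  Stability labels per
angle (normal ranges HKA 0°±3, FVV −6°±2, IER ±5°, TVV ±5°, TS 7°±4) are
then classified from the retained mode weights with shrinkage-regularized
LDA/QDA and logistic regression under leave-one-out cross-validation, and
each mode is screened with rank-sum tests and Spearman correlations against
the corrected variables X̂ = |X − X̄|.

See `docs/methods.md` for conventions, parameters and design choices.

## Worked example

Generate a 12-knee synthetic cohort driven by five latent parameters, build
the shape space, and ask which mode carries the frontal (HKA) rotation:

```python
import numpy as np
from kneessm import (synthetic, select_reference, build_correspondences,
                     fit_ssm, project, reconstruction_errors, spearman)

cohort = synthetic.latent_study_cohort(seed=42, n=12, resolution=0.4)
ref = select_reference(cohort)
corr = build_correspondences(cohort, ref)
model = fit_ssm(corr)

k = model.n_modes_for(0.95)
print("modes for 95% EV:", k)
print("EV:", np.round(model.explained_variance[:k], 3))
rec = reconstruction_errors(model, corr, k)["summary"]
print("reconstruction rms %.2f mm" % rec["rms_mean"])

W = np.array([project(model, s, n_modes=k) for s in corr.as_matrix()])
hka = np.array([s.angles.hka for s in cohort])
c, p = max((spearman(W[:, j], hka) for j in range(k)), key=lambda t: abs(t[0]))
print("dominant HKA mode: c=%.2f, p=%.1e" % (c, p))
```

Output:

```
modes for 95% EV: 4
EV: [0.612 0.238 0.094 0.035]
reconstruction rms 0.27 mm
dominant HKA mode: c=-0.73, p=7.4e-03
```

Four modes explain 97.8% of the cohort's shape variance (five latent
parameters drive it; scale dominates), reconstructions sit within a fraction
of a millimetre of the correspondences, and one mode correlates strongly with
the ground-truth HKA rotation — the shape space has recovered the alignment
signal without ever seeing a landmark.

## Command line

The same pipeline runs from a config file:

```bash
kneessm generate -c config.yaml          # synthetic cohort -> PLYs + CSVs
kneessm run -c config.yaml               # preprocess, register, model, classify
kneessm report -c config.yaml            # print AC/SE/SP per angle & classifier
```

with a YAML config such as

```yaml
outdir: out/demo
seed: 1
synthetic: {n: 20}
preprocess: {smooth_iterations: 5}
ev_threshold: 0.95
```

Real cohorts are read from a directory of `<id>_femur.ply` / `<id>_tibia.ply`
meshes plus `cohort.csv` (id, side, angles) and `landmarks.csv` — set
`cohort_dir` instead of `synthetic`.  Outputs: `angles.csv`, `weights.csv`,
`model.npz`, `report.json`, flat `classification.csv` / `correlations.csv`
tables, and a `manifest.json` with stage timings and the config hash; reruns
with an unchanged config are cached and byte-identical.

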