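# hippomorph

Surface-based morphometry of tube-like subcortical structures, built around
the hippocampus. Given per-subject binary masks (e.g. from a model-based
subcortical segmentation tool), the pipeline reconstructs and QC's triangle
meshes, maps each genus-0 surface conformally onto a rectangle with a
holomorphic 1-form basis, registers every subject's "feature image"
(conformal factor + mean curvature) to a template with an inverse-consistent
viscous-fluid model, and tests group differences vertex by vertex with a
multivariate statistic combining tensor-based morphometry and radial
distance. It is aimed at researchers studying localized shape effects —
for example dose-graded atrophy in carriers of a risk allele — who need
corrected, map-level inference rather than a single volume number.

## The statistic and the test

At each template vertex a subject contributes a 4-vector

```
(L11, sqrt(2) L12, L22, r),    L = log (J^T J)^(1/2)
```

where `J` is the 2x2 tangent-plane derivative of the template-to-subject
correspondence (mTBM: the log-Euclidean deformation tensor, invariant to
rigid motion) and `r` is the radial distance from the vertex to the medial
core, the iso-parameter center line of the tube. Two groups
`S_1..S_p, T_1..T_q` of such vectors are compared with the Mahalanobis
distance

```
M = (N_S N_T / (N_S + N_T)) (S̄ − T̄)^T Σ⁻¹ (S̄ − T̄)
```

with Σ the pooled covariance — Hotelling's two-sample T². Vertex p-values
come from a label-permutation test (one shared shuffle schedule across
vertices); map-level correction is the permutation probability of an
equal-or-larger total surface area of vertices passing p ≤ 0.05. CDFs of
the vertex p-values against the uniform null line summarize effect sizes
across contrasts.

Because real cohort MRIs are access-restricted, the package ships a
first-class synthetic cohort generator: banana-shaped genus-0 masks with
smooth per-subject shape noise and a localized radial atrophy window whose
depth scales with a 0/1/2 allele-dose covariate, so every claim the package
makes is testable against known ground truth.

## Worked example

```python
from hippomorph import load_config, run_pipeline

result = run_pipeline(load_config({
    "output_dir": "demo_run",
    "seed": 11,
    "n_perm": 200,
    "cohort": {"n_per_dose": {0: 6, 2: 6}, "max_radial_shrink": 0.15},
    "contrasts": [{"name": "hom_vs_non", "doses_s": [2], "doses_t": [0]}],
}))
pm, cdf, report = result.contrast_results["hom_vs_non"]
print(report["n_s"], report["n_t"], pm.suprathreshold_area, pm.overall_p)
```

prints

```
6 6 504.896920163971 0.009950248756218905
```

meaning: 6 homozygote vs 6 non-carrier subjects, 505 mm² of template
surface passed the pointwise p ≤ 0.05 threshold, and a map that large arose
in 1 of the 201 permutation-equivalent datasets — corrected p ≈ 0.01, so
the implanted 15% shrink is detected. The same run from a shell:

```bash
hippomorph all --config demo.yaml
hippomorph validate --seed 0     # property suites, JSON report
```

The numbered scripts under `analysis/` run the full study narrative
(simulate a three-dose cohort, run the pipeline, plot dose-graded p-value
CDFs, check calibration and power) and write their tables under `results/`.

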