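# somatoseg

Segregation of motor somatotopy maps across fMRI acquisition protocols.

Functional MRI of body-part ("somatotopy") maps faces a trade-off: finer
voxels resolve smaller structures but lose BOLD sensitivity, and the loss is
worst in deep-brain nuclei (putamen, pallidum, motor thalamus). `somatoseg`
is a tested pipeline for quantifying that trade-off. It simulates a visually
cued motor block experiment (foot / hand / face x left / right) under three
acquisition presets — 1.5 mm 3D, 2 mm 3D and 3 mm 2D EPI, all covering the
same 90 mm head-foot slab — fits subject-level GLMs, and measures how well
the resulting activity patterns are segregated, per region of interest.

The core quantity comes from **pattern component modeling (PCM)**. Per ROI,
condition x voxel coefficients `Y` follow the random-effects model

    Y = Z U + E,   U[:, j] ~ N(0, G),   E iid N(0, sigma2),

over the 9 cells of the MOVEMENT x RESOLUTION factorial (`Z = I9`, no
constraints on `G`). `G` and `sigma2` are estimated by (parameter-expanded)
EM on the marginal likelihood `y_j ~ N(0, Z G Z' + sigma2 I)`, validated
against an independent numerical maximizer. The pattern covariance is
normalized to correlations `r_ij = G_ij / sqrt(G_ii G_jj)` and each
condition pair gets an **Index of Similarity**

    IoS = |atanh(r)|,

low IoS meaning well-segregated representations. IoS differences are tested
with Fisher Z statistics and Benjamini-Hochberg FDR per family. Around this
sit BOLD-sensitivity metrics (residual tSNR and acquisition-weighted
variants, top-5% t-scores, head-motion and scaled-variance summaries),
somatotopy geometry (centers of mass, activation maxima, ROI-adjusted
volumes, betweenness/gradient checks, SVD projection onto ROI-specific
axes) and group statistics (IoS-tSNR correlations, ANCOVA with interaction
and model comparison, MANOVA with Pillai's trace, ANOVAs with
Bonferroni-Holm post hocs).

## Worked example

```python
import numpy as np
import somatoseg as ss
from somatoseg.similarity import similarity_report

truth = ss.scenario_preset("subcortical_protocol_dependent")
Y = ss.simulate_patterns(truth.G_true, np.eye(9), v=2000, sigma2=0.5, seed=0)
fit = ss.fit_pcm_em(Y, np.eye(9), roi_name="putamen_left")
rep = similarity_report(fit, ss.factorial_cells(), n_eff=2000)
wr = rep.pairs[rep.pairs.family == "within_resolution"]
for res in (1.5, 2.0, 3.0):
    print(res, wr[wr.pair.str.contains(f"@{res:g}\\|")]["ios"].mean())
```

prints

```
1.5 0.074
2.0 0.339
3.0 0.053
```

— the mean within-resolution IoS per protocol for one simulated deep-brain
ROI. The programmed ground truth makes between-movement patterns most
similar at 2 mm, and the fitted IoS reproduces that: segregation is good at
1.5 mm and 3 mm (IoS ~ 0.05-0.07) and poor at 2 mm (IoS ~ 0.34). The full
study is one call:

```python
result = ss.run_pipeline(ss.RunConfig(seed=0), out_dir="study_output")
print(result.summary["flag_subcortical_2mm_least_segregated"])  # True
print(result.summary["flag_cortical_resolution_invariant"])     # True
```

which simulates every subject x protocol run, writes tidy TSV tables
(similarity pairs and tests, sensitivity, geometry, motion, group inputs)
plus `summary.json`, and flags the study's qualitative outcome: deep-brain
somatotopy least segregated at the intermediate resolution, cortical
segregation flat across resolutions. The `examples/` scripts walk through
each capability (paradigm/protocols, GLM fitting, PCM + IoS, sensitivity
metrics, full study).

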