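# cada — computer-aided DaT-SPECT analysis

`cada` quantifies dopamine-transporter SPECT (DaTSCAN) brain volumes fully
automatically. It is aimed at researchers in nuclear-medicine image
analysis who want reproducible striatal uptake *and shape* measurements for
distinguishing parkinsonian patients from controls — without the manual ROI
placement that makes semi-quantitative reads slow and operator-dependent.

The pipeline: rigid spatial normalization to a symmetric control template;
linear intensity normalization via α-stable histogram fits
(`Y = aᵢX − bᵢ`, with `aᵢ = γ*/γᵢ`, `bᵢ = aᵢμᵢ − μ*` sending every image's
fitted dispersion/location to the pooled values); unsupervised per-hemisphere
striatal segmentation with a two-component Gaussian mixture over
(intensity, x, y, z) voxel vectors fitted by EM and maximum-likelihood
labeling; least-squares ellipsoid fitting to each striatal mask
(`(X−U)ᵀRᵀDR(X−U) = 1`, minimizing Σ Lᵢ² over centre, orientation and
semi-axes); and per-side features

* **MEU** — mean ellipsoid uptake, the mean normalized intensity inside the
  fitted ellipsoid;
* **DI** — dysmorphic index, `1 − Π |Eᵢ^S · Eᵢ^T|` over rank-paired unit
  eigenvectors of the subject and template ellipsoids (0 = normal
  orientation, 1 = maximal dysmorphism);
* **SMU** — shape-modulated uptake, `MEU·(1 − DI)`;
* **SBR** — the classical specific binding ratio
  `(C_str − C_occ)/C_occ` against an occipital reference ROI.

An SVM (linear kernel, leave-one-out cross-validation) classifies subjects
from these features, and SMU is correlated with motor severity (Spearman
rank correlation, linear and exponential regression with adjusted R²).
A digital-phantom module generates cohorts with ground-truth striatal
geometry, uptake and linked clinical scores, so the whole chain is testable
without patient data.

## Worked example

Generate a cohort of phantoms, run the pipeline, classify and correlate:

```python
from cada.phantom import generate_cohort
from cada.pipeline import process_cohort
from cada.classify import ExperimentConfig, build_design, evaluate
from cada.stats import correlate_severity

cohort = generate_cohort(n_pd=31, n_hc=12, seed=7)
volumes = [v for v, _, _ in cohort]
groups = {v.id: c.group for v, _, c in cohort}

result = process_cohort(volumes, groups)          # ~4 min on one CPU

config = ExperimentConfig(name="exp4_smu")        # [SMU_left, SMU_right]
X, y, ids, _ = build_design(result.records, config, groups)
print(evaluate(X, y, config, ids=ids).summary())

fits = correlate_severity(result.records, [c for _, _, c in cohort])
lin = fits["linear"]
print(f"Spearman rho = {lin.spearman_rho:.2f} (p = {lin.spearman_p:.4f})")
```

Output:

```
SVM report (loo, 31 PD / 12 HC)
  correct rate : 100.00 %
  AUC          : 1.0000
  sensitivity  : 100.00 %
  specificity  : 100.00 %
Spearman rho = -0.43 (p = 0.0164)
```

Every control keeps SMU ≈ 1.6–1.7 on both sides, while every patient has at
least one side collapsed toward 0–1.3 by the programmed uptake loss and
shape rotation — which is why the two-feature SVM separates the groups
perfectly, and why lower SMU tracks higher motor scores.

The same run from the shell:

```bash
cada phantom cohort --n-pd 31 --n-hc 12 --seed 7 --out cohort/
cada run --config pipeline.yaml          # manifest + stage parameters
cada classify --features out/features.csv --experiment exp4_smu --out report.json
cada correlate --features out/features.csv --clinical cohort/clinical.csv --out corr.json
```

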