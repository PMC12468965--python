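# pleuradx

A hybrid image-analysis pipeline for binary classification of chest-CT
slices as malignant pleural mesothelioma (MPM) versus benign pleural
disease. MPM is an aggressive asbestos-associated pleural cancer whose
CT correlate — unilateral pleural thickening, often nodular — is subtle
and easily confused with benign disease; cohorts are small,
single-center, and patient-grouped (several slices per patient). The
package is aimed at researchers studying hybrid
deep-feature/kernel-classifier designs under exactly those constraints.

## The method

The pipeline composes five stages:

1. **Segmentation overlay.** Region masks from a pluggable provider
   (`MaskProvider`; the testable default is an Otsu +
   connected-components segmenter, a promptable foundation segmenter can
   be adapted behind the same contract) are composited over the source
   slice with opacity α ≤ 0.5, keeping the segmented region and the
   underlying tissue simultaneously visible.
2. **Class-based features.** An image classifier with a K-way logits
   head is trained on the patient-grouped training split; the softmax
   probabilities of that head, F₁…F_K with Σₖ Fₖ = 1, are carried
   forward as each slice's feature vector z (K = 2 here).
3. **Generative rendering.** Each z is rendered into three small
   candidate images by a Decoder-MLP, a conditional GAN generator, and a
   NeRV-style index-conditioned network, all trained to reconstruct a
   shared deterministic target encoding T(z) (a Gaussian
   probability-bump field, one anchor per class).
4. **Discriminative selection.** With class centroids C_pos, C_neg
   fitted on training-split candidates, each candidate m receives the
   score DS(m) = d(m, C_neg) / d(m, C_pos) (Euclidean d); the
   highest-scoring candidate represents the sample. A label-blind
   variance-threshold selector is the ablation alternative.
5. **Residual SVM.** Penultimate features of a small residual CNN feed
   a cubic-kernel SVM (C = 1, kernel scale 1/(d·Var[x]), one-vs-one,
   Platt-calibrated probabilities). Ablations: logistic regression on
   the same features, and a "direct logits" SVM that bypasses rendering.

Evaluation is patient-grouped throughout (70/30 holdout and k = 5
cross-validation, stratified by patient label) and reports macro
sensitivity/specificity/precision/F-score/accuracy, ROC and
precision-recall curves, calibration bins, decision-curve net benefit,
and seeded bootstrap confidence intervals.

Because real MPM CT cohorts are not public, the package ships a seeded
synthetic phantom cohort (`pleuradx.cohort`): elliptical thorax slices
whose pleural rim is thickened and nodular in the diseased class, with
patient-level grouping, ~5.8 slices per patient, and demographics drawn
from fixed 172-patient reference marginals.

## Worked example

```python
from pleuradx import PipelineConfig, run_pipeline
from pleuradx.cohort import CohortConfig
from pleuradx.backbone import BackboneSpec
from pleuradx.pipeline import SplitSettings

config = PipelineConfig(
    cohort=CohortConfig(n_patients_per_class=10, slices_mean=2,
                        image_size=64, class_effect=6),
    backbone=BackboneSpec(learning_rate=1e-3, epochs=3, input_size=48),
    split=SplitSettings(schemes=("holdout",)),
    seed=5,
)
result = run_pipeline(config)
rep = result.reports["holdout"]
print(f"acc={rep.macro['acc']:.3f} se={rep.macro['se']:.3f} "
      f"sp={rep.macro['sp']:.3f} auc={rep.auc:.3f}")
print(result.manifest["accuracy"])
```

prints

```
acc=1.000 se=1.000 sp=1.000 auc=1.000
{'holdout': 1.0}
```

i.e. on a 20-patient phantom cohort with a strong pleural effect
(6-pixel rim thickening), the full pipeline separates the held-out
patients perfectly: every test slice is assigned the correct class and
the ROC of the positive-class probability is saturated. Weaker
`class_effect` or higher `noise_sd` values degrade these numbers
smoothly.

The same run from a shell:

```
pleuradx pipeline run --config pipeline.yaml    # full pipeline
pleuradx pipeline ablate --config pipeline.yaml # 4-scenario ablation grid
pleuradx cohort generate --config cohort.yaml --out cohort/
pleuradx report render reports/report_holdout.json --out plots/
```

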