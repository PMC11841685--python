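# icusurv

Multimodal survival analysis for ICU mortality prediction.

Intensive-care scoring systems such as SAPS-II summarise a patient's first
24 hours into a single severity score and predict mortality from structured
data alone, ignoring what radiologists write and see. `icusurv` implements
a survival-analysis pipeline that fuses three sources — SAPS-II severity
factors, radiology-report representations (finding labels, pooled
transformer token embeddings, or a graph-convolutional encoding over a
finding concept graph) and chest X-ray image embeddings — in a Cox
proportional-hazards framework, and quantifies what each modality adds.

It is aimed at methods researchers in clinical survival modelling: every
stage is importable, seeded and testable without access to any restricted
clinical database, because the package ships a synthetic cohort generator
that reproduces the statistical structure such studies assume.

## The model

The survival function is the Cox model

    S(t | x) = S0(t) ^ exp(psi(x))

with shared baseline `S0` (Breslow estimator) and per-subject
log-relative-hazard `psi(x)`:

* **Linear Cox** — `psi(x) = x beta`, Newton–Raphson maximum partial
  likelihood (Breslow ties; Efron optional) with hazard ratios `exp(beta)`,
  Wald 95% CIs and p-values.
* **DeepSurv-style network** — per-modality MLP heads (15→15 severity,
  14→14 labels, 768→32 text, 1024→32 image), elementwise **average fusion**
  of the text/image hidden vectors concatenated with the severity block,
  and a nonlinear risk head; trained by minimising the batchwise negative
  Cox partial likelihood with Adam (lr 0.001, batch 72, dropout 0.5, early
  stopping on validation loss).

Models are compared by the concordance index (C-index: probability that of
two comparable patients, the one who dies earlier carries the higher
predicted risk; 0.5 = random, 1 = perfect) under a bootstrap protocol:
resample the cohort with replacement, split 70/10/20, train, score the test
C-index; 200 replicates give the mean and percentile 95% CI, and shared
replicate seeds give paired Wilcoxon model comparisons.

See `docs/methods.md` for the full model description, numerical choices and
the generator's design.

## Worked example

```bash
python examples/04_bootstrap_comparison.py
```

runs the paired bootstrap protocol (10 replicates here) for three models on
a synthetic cohort with a planted multimodal hazard signal (n=1000):

```
     model  mean_c_index  ci_lower  ci_upper  n_replicates
 saps_only      0.638557  0.590568  0.701036            10
 saps_text      0.796794  0.765993  0.826140            10
multimodal      0.800936  0.773518  0.833314            10

multimodal - saps_only: mean C-index difference +0.1624, paired wilcoxon p = 1.95e-03 (b>a)
```

The severity-only model ranks survival at C ≈ 0.64; adding the report
embedding lifts the bootstrap mean to ≈ 0.80, and fusing the image
embedding on top adds a little more — the ordering the pipeline is designed
to detect, with a paired signed-rank p-value ≈ 0.002 across shared
replicates. The other examples show cohort generation (`01`), the finding
hazard-ratio table with severity adjustment (`02`), single-model training
(`03`) and the GCN text encoder plus per-patient survival curves (`05`).

A thin CLI wraps the same library calls:

```bash
icusurv simulate --n 1000 --seed 0 --out scratch/cohort
icusurv train --cohort scratch/cohort --modalities saps,transformer_text,image \
              --epochs 40 --out scratch/model.npz
icusurv hr-table --cohort scratch/cohort --out scratch/hr.csv
icusurv report --config experiment.yaml
```

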