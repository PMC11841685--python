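# Methods

## The model

`icusurv` is built around the Cox proportional-hazards survival model

    S(t | x) = S0(t) ^ exp(psi(x))

where `S0` is a baseline survival function shared by all subjects and
`psi(x)` is the per-subject log-relative-hazard (the *risk score*). Two
families of `psi` are implemented:

* **linear** — `psi(x) = x @ beta`, fitted by Newton–Raphson maximisation of
  the Breslow partial likelihood (`cox.fit_linear_cox`), with Wald standard
  errors from the inverse observed information, hazard ratios `exp(beta)`,
  95% CIs `exp(beta ± 1.96·se)` and two-sided Wald p-values;
* **neural** — a DeepSurv-style multilayer perceptron over fused multimodal
  features (`fusion`), trained by minimising the negative Cox partial
  likelihood computed within each mini-batch.

Right censoring is handled throughout via the observed pair
`(y, delta) = (min(T, C), 1[T <= C])`; death and censoring are mutually
exclusive.

### Ties and numerics

Tied event times use the Breslow approximation by default (it is also what
batchwise neural training implicitly assumes); Efron is available through
`ties="efron"` and is cross-checked against an external reference
implementation in the test-suite. All log-sum-exp terms subtract the maximum
score first — exact under the partial likelihood's shift invariance. Newton
iterations use step-halving whenever a step would decrease the likelihood,
and converge when the score norm drops below `tol * sqrt(#events)` (the
score scales with the event count, so a fixed absolute tolerance is
unattainable for large cohorts in double precision). Monotone likelihoods
(separation) are flagged in two ways: diverging coefficients (`|beta| > 30`)
and essentially infinite Wald SEs (`se * covariate span > 50`); both raise a
`ConvergenceError` carrying the last iterate.

The Breslow baseline estimator is
`H0(t) = sum_{t_k <= t} d_k / sum_{j at risk} exp(psi_j)`, `S0 = exp(-H0)`,
a right-continuous step function equal to 1 before the first event.

## Feature encoders

* **Severity factors** — the 15 SAPS-II inputs are z-scored against fixed
  reference constants (documented in `encoders.SAPS_FACTOR_SCALING`) with
  the two categoricals as small integer codes; fixed constants keep
  encodings portable across cohorts.
* **SAPS-II score** — the scorer implements the published point table,
  shipped as a versioned JSON data file (`data/saps2_points.json`). The
  PaO2/FiO2 component only applies to ventilated/CPAP patients in the
  original score; since the factor vector carries no ventilation flag, a
  `None` ratio encodes "not ventilated" and scores 0 points. The attainable
  range is exactly [0, 163].
* **Text, labels mode** — the 14 finding indicators pass through unchanged.
* **Text, transformer mode** — average pooling of the m×768 token-embedding
  matrix.
* **Text, GCN mode** — node features are initialised by a 1-D convolution
  along the token axis (one length-k kernel per node, shared across
  embedding dimensions, valid padding, mean over positions, default k=3), so
  every token contributes to every node and the node width stays 768. Two
  propagation layers follow: `H1 = ReLU(A_hat H0 W0 + b0)`,
  `Z = softmax(A_hat H1 W1 + b1)` with softmax per node row and
  `A_hat = D^{-1/2}(A + I)D^{-1/2}` precomputed once. Defaults:
  hidden width 64, **2 outputs per node** (a per-node softmax over a single
  output would be constantly 1 and carry no information, so one output per
  node is not a usable default), flattened to a 28-vector. GCN parameters
  are frozen at seeded Glorot initialisation: the encoder plays the role of
  a fixed pretrained feature extractor; only the downstream fusion heads
  are trained.
* **Concept graph** — the default 14-node graph (editable JSON) encodes the
  standard radiographic hierarchy: lung opacity connected to its parenchymal
  children (atelectasis, consolidation, edema, lung lesion, pneumonia),
  consolidation–pneumonia, enlarged cardiomediastinum–cardiomegaly, and the
  pleural findings grouped.
* **Image** — a precomputed 1024-vector from an `EmbeddingProvider`;
  bundled providers are the seeded synthetic one and a file-backed archive
  reader. Real report/image backbones plug in behind the same interface.

## The fused risk network

Each enabled modality passes through its own fully-connected head (defaults:
saps 15→15, labels 14→14, text 768→32, image 1024→32, gcn 28→32). The
non-saps hidden vectors — which must share a width — are fused by
**elementwise averaging**; the averaged block is concatenated with the saps
head output (averaged block first, saps second, fixed so checkpoints are
portable). A risk head (by default one ReLU hidden layer of the fused width
with dropout) maps the fused vector to the scalar `psi`.

Training: Adam (lr 0.001), batch size 72, dropout 0.5, up to 250 epochs with
early stopping on the validation partial likelihood (patience 10, best
weights restored). Batches are built by dealing event subjects round-robin
so every batch's partial likelihood is defined. An L2 penalty on weight
matrices (`weight_decay`) defaults to 1e-3; experiment grids with
high-dimensional heads share a stronger value (0.1) across **all** models in
the grid, mirroring the study design of one hyperparameter set for every
configuration. The implementation is plain numpy with hand-written
backpropagation (verified against finite differences to ~1e-7); all default
sizes train in seconds per model on one CPU.

Two deliberate design choices where the architecture was open:

* the saps head is **linear** by default (`saps_activation=False`): with
  only 15 structured inputs a ReLU after the first layer discards
  information at initialisation and measurably hurts the linear-risk regime,
  while the risk head already supplies the nonlinearity; a flag restores the
  activation;
* the risk head defaults to a single hidden layer — the smallest
  architecture that is genuinely nonlinear.

## Evaluation protocol

The **C-index** counts ordered pairs in which the subject with the strictly
shorter observed time had an observed event; the pair is concordant when
that subject also has the strictly higher risk (0.5 credit on risk ties).
Pairs with tied observed times, or whose shorter time is censored, are not
comparable. This is the standard convention in which a random score gives
0.5 and a perfect anti-ordering gives 1; a literal reading of the usual
summation formula without the event indicator in the numerator could exceed
1, so the convention above is used. Orientation is fixed: higher risk must
mean shorter survival.

The **bootstrap experiment** resamples n subjects with replacement, splits
70/10/20 into train/validation/test, trains (validation drives early
stopping) and scores the test C-index; 200 replicates by default, 95% CI by
the 2.5/97.5 percentiles (normal approximation behind a flag). Replicate
seeds are shared across models, so model comparisons use a paired Wilcoxon
signed-rank test on per-replicate differences (paired t-test behind a
flag). Replicates with a degenerate test split or a degenerate training fit
(e.g. separation on a rare finding) are redrawn with a perturbed seed and
logged; more than 10 consecutive failures abort. Note that resampling with
replacement before splitting lets duplicated subjects appear on both sides
of a split; this is inherent to the protocol, inflates absolute C-indexes
for flexible models, and is why conclusions are drawn from *comparisons*
under shared replicates rather than absolute values.

Subgroup evaluation restricts the test-set C-index to normal/abnormal chest
X-ray subgroups and to each finding; degenerate subgroups are reported as
not evaluable rather than raising.

## The synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any real patient data:

1. latent severity `z ~ N(0,1)`;
2. the 15 SAPS-II factors drawn from physiologic distributions shifted by
   `z` (the induced SAPS-II score has mean ≈ 29.8, SD ≈ 12.0 — these are
   the frozen standardisation constants — and correlation ≈ 0.6 with `z`);
3. 13 finding labels, Bernoulli with logit `logit(p_j) + 0.8 z` at realistic
   ICU prevalences (abnormal ≈ 90%); `no_finding` derived, never sampled;
4. `psi` linear in *observed* covariates: standardized SAPS score, an
   any-abnormality indicator, and optional per-finding log hazard ratios.
   The default per-finding coefficients plant moderate mixed-sign effects
   (log HRs between −0.45 and +0.32) of the magnitude reported in ICU chest
   X-ray survival analyses, so hazard-ratio machinery is exercised on
   realistic effect sizes. A quadratic risk form
   (`quadratic_gain * ((age_z² − 1) + (hr_z² − 1))`) supports
   linear-vs-nonlinear model experiments;
5. event times inverted from the Weibull-baseline Cox model
   `S(t|psi) = exp(−scale · t^shape · e^psi)` (shape 1.2, scale 0.0022;
   median event time ≈ 120 h at `psi = 0`), in hours since ICU admission;
6. log-normal administrative censoring (sigma 0.8) whose median is
   calibrated by bisection against the realized event times so the observed
   event fraction hits the 0.22 target exactly up to discreteness;
7. surrogate embeddings: a fixed seeded projection of the label vector,
   `P @ labels * signal_strength`, plus Gaussian noise — per token for text
   (token count uniform in [20, 200]) and once for the 1024-dim image
   vector. `noise_sd` and `image_noise_sd` are separate because average
   pooling over m tokens shrinks text noise by sqrt(m); making the pooled
   text noise comparable to the image noise is what gives the elementwise
   average of the two hidden vectors its denoising value.

Because psi depends only on observed covariates, parameter-recovery
experiments are unconfounded by construction when the fitted model includes
the planted covariates. Planted-effect experiments use the most balanced
indicator (support devices, ≈55% prevalence); the any-abnormality indicator
is too rare (≈90%) to give sharp single-cohort estimates.

What the generator does **not** emulate: longitudinal trajectories,
informative censoring, label noise in the findings, real report text, and
real embedding geometry (the surrogates are linear in the labels). Passing
tests therefore demonstrate the correctness and statistical behaviour of
the machinery under the declared generative model, not clinical performance
on real ICU data.

## Experiment profiles and problem sizes

* **Planted-multimodal-signal ordering** (`pipeline.multimodal_signal_config`
  / `ordering_trial`): n = 1500, finding coefficients scaled ×2.5, token
  noise 3.0, image noise 0.3; three models (saps-only, saps+text,
  multimodal) with shared hyperparameters (40 epochs max, patience 6,
  weight decay 0.1), 20 bootstrap replicates per master seed. These sizes
  keep a 10-master-seed run in a few CPU-minutes while leaving the planted
  signal comfortably recoverable.
* **Quadratic-risk comparison** (`pipeline.quadratic_gap`): n = 2000 per
  seed, single 70/10/20 split, neural saps model vs linear Cox on the same
  15 inputs.
* **Recovery experiments**: n = 2000 (CI coverage over 100 seeds) and
  n = 5000 (point estimates, averaged over 3 seeds).

## Known limitations

* The C-index is evaluated by dense pair comparison, O(n²) memory — fine up
  to a few thousand test subjects, not for very large cohorts.
* The neural implementation is CPU-oriented numpy; it is not meant for
  large embedding corpora or joint fine-tuning of upstream extractors (the
  encoders are frozen by design).
* Linear Cox fitting recomputes risk-set statistics per unique event time;
  adequate to tens of thousands of subjects, but not optimised beyond that.
* Bootstrap C-index levels are optimistic in absolute terms (see above);
  only paired comparisons are interpreted.
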