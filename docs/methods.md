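# Methods

## The generating model

A cohort is a table of mixed-type covariates plus a right-censored
time-to-event outcome. Covariates are drawn marginal-by-marginal through a
Gaussian copula: each linked continuous variable (age, BMI, age started
smoking, the smoking-duration fraction, cigarettes/day) gets a latent
standard-normal score; the latent correlation matrix (defaults in
`simulate.DEFAULT_COPULA`) is a configuration parameter, and marginals are
exact by probability-integral transform regardless of it.

Marginal families and the published descriptives they were solved against:

| Variable | Family | Target mean (SD) |
|---|---|---|
| age | truncated normal on [40, 73] (underlying μ 57.95, σ 10.14) | 57.39 (7.93) |
| BMI | lognormal, clipped to [15, 48] | 27.76 (4.78) |
| age started smoking | truncated normal on [10, 40] | 17.42 (4.33) |
| years smoked | Beta(1.46, 0.78) fraction × (age − age started), floor 0.5 y | 26.32 (12.91) |
| cigarettes/day | lognormal base, then with probability 0.6 rounded to the nearest 5 (min 5) | 18.20 (10.20) after heaping |

Categorical and binary prevalences (sex, ethnicity, five qualification
levels, smoking status, five comorbidity flags) use the same published
column. Pack-years ≡ cigarettes/day ÷ 20 × years smoked holds exactly;
quit-years is max(0, age − age started − years smoked) for former smokers
and 0 for current smokers. Five truncated-standard-normal and two Bernoulli
pure-noise columns give feature selection true negatives.

Underlying distribution parameters were solved numerically (large-sample
root finding) so the *realised* moments match the targets to ≲0.02; the
frozen values live in `default_schema()`.

### Outcome

Event times follow a proportional-hazards model with Weibull baseline,
S(t|x) = exp(−(t/λ)^k · e^{xᵀβ}), sampled by inverse transform. β lives on
the encoded scale (min-max by the schema's fixed bounds; `var=Category`
indicators) and is nonzero exactly for: age (+1.5), BMI (−0.95), years
smoked (+1.5), pack-years (+2.0), quit-years (−1.45), current smoking
(+0.45), family history of lung cancer (+0.45), degree-level qualification
(−0.42). Censoring is min(13 years administrative, Exp(0.015/y) dropout).
The baseline scale (λ = 380.69 y, k = 1.3) was calibrated by
`calibrate_baseline_scale` so the observed 5-year event prevalence is ~1.9%
— the rare-event regime of lung-cancer risk modelling. Effect sizes were
fixed by pre-simulation: at n = 2×10⁴ (≈1160 events) every informative
feature is selected (Wald p < 0.05) with ≥96% per-replicate power while the
mean coefficient bias stays ≤0.08 despite the strong structural collinearity
of the smoking variables. The encoding bounds of pack-years (0–130),
quit-years (0–50) and BMI (15–48) truncate <0.4% tails; without that the
encoded variances of those features are so small that absolute-scale
recovery tolerances become statistically meaningless.

## Encoding and splitting

Continuous variables are min-max scaled to [0, 1]; categoricals are one-hot
blocks; the outcome can be folded in (time min-max scaled, event as a
two-column block) so generators model the full table. Encoders fitted on
data take bounds from the training portion only, mirroring deployment;
`Encoder.from_schema` uses the fixed ground-truth bounds (used wherever
estimates are compared to β). The 80:20 split takes round(0.8 n) training
rows, ties toward train.

## Generators

All three mechanisms share one adversarial core, written in numpy: MLP
generator and discriminator (two hidden layers of 64, ReLU), non-saturating
GAN loss, Adam (lr 2·10⁻⁴, β₁ 0.5). The output head applies sigmoid to
continuous columns and Gumbel-softmax (temperature 0.6) within each one-hot
block, with block logits squashed through 2.5·tanh(·/2.5); the discriminator
sees PacGAN-style packs of 4 samples. The last two choices are mode-collapse
guards: with a plain softmax head the category frequencies saturate
irreversibly (the softmax Jacobian vanishes at the corner), and a per-sample
discriminator cannot express frequency mismatch at all — packing makes it a
property of a single input.

* **DPGAN** — the discriminator's real-data gradients are computed
  per example, clipped at C = 1 and noised with N(0, (σC)²); σ is calibrated
  by binary search so the full training run meets the ε budget at
  δ = 1/n_train. Generator updates are post-processing of the private
  discriminator. An infinite budget disables the mechanism (used by the
  adversarial-core sanity test).
* **PATE-GAN** — rows are partitioned across 5 teacher discriminators;
  each round the teachers take an adversarial step, then a batch of
  generated samples is labelled by teacher majority vote with Laplace(1/λ)
  noise on the vote counts (λ = 10⁻⁴ default); the student learns the noisy
  labels and the generator trains against the student. Teachers are never
  released; only vote queries spend budget.
* **ADSGAN** — a conditional generator G(z, x_source) with two extra
  per-sample gradient terms: a reconstruction anchor pulling the output
  toward its source record (weight 2.0), and the identifiability penalty
  λ·mean(max(0, d_within − d(x_syn, x_source))), where d_within is the
  source's nearest-neighbour distance inside the training data. The anchor
  is what makes the conditioning effective at this scale: without it the
  generator ignores the source, nothing ever memorizes, and λ has nothing
  to trade off. With it, λ = 0 measurably memorizes and raising λ pushes
  samples back out past the nearest-neighbour shell — the privacy lever the
  λ sweep tests. ADSGAN carries no differential-privacy guarantee and its
  ledger says so.

The deep generative ensemble trains members on consecutive seeds and pools
⌈total/m⌉ samples from each. Its ledger reports the **maximum member ε**;
strict sequential composition across members would sum the budgets, and the
provenance record carries both numbers rather than absorbing the choice
silently.

### Accounting

DP-SGD accounting uses the data-independent Rényi-DP upper bound of the
subsampled Gaussian at integer orders 2–64 (binomial expansion; exact at
q = 1, where it reduces to α/(2σ²)), composed linearly over steps and
converted by ε = min_α [T·RDP(α) + log(1/δ)/(α−1)]. The PATE bound is basic
composition of pure-DP vote queries, ε = 2λ·n_queries — deliberately
conservative; the data-dependent moments accountant is out of scope. Both
feed a per-run ledger whose spent ε is monotone and never exceeds the
budget (training halts first).

## Evaluation batteries

* **Fidelity** — per-feature 1-D Wasserstein distances and Jensen-Shannon
  divergences (base 2; continuous features in 20 equal-width bins on the
  encoded scale), plus α-precision / β-recall (medoid-ball coverage curves,
  ΔP = 1 − 2∫|P(α) − α|dα) and authenticity (fraction of synthetic points
  strictly farther from their nearest real neighbour than that neighbour is
  from its own nearest other real point). These are computed with Euclidean
  distance in the normalized encoded space — an embedding-free rendering of
  the metrics' definitions, not the original authors' learned-embedding
  estimator.
* **Privacy audit** — k-anonymity (minimum equivalence class over binned
  quasi-identifiers; default age in 5-year bins, sex, ethnicity) and a
  density-ratio membership-inference score p̂_synth/p̂_ref computed with
  Gaussian KDEs in the space of the reference data's first five principal
  components. The KDE bandwidth is 0.05× Scott's rule: memorization shows
  up as near-point-mass density elevations at member records, which the
  plain Scott bandwidth smooths away entirely; the sharpened bandwidth
  detects exact copies (AUC ≈ 0.75 at n = 2000) while independent synthetic
  data stays at chance. Calibrated on those two limit cases only.
* **EDA transfer** — scree profiles; probabilistic-PCA test log-likelihood
  (4 components; maximum-likelihood residual variance = mean of discarded
  eigenvalues; reported per sample); K-means BIC curves for k = 2..28 under
  a spherical-mixture reading (shared variance SSE/(nd), k·d + k + 1
  parameters); and ARI/AMI between test-set labelings from real-trained vs
  synthetic-trained K-means at K = 15 (AMI max-normalized, 10 restarts).
  K-means inputs are canonicalized to lexicographic row order before
  fitting so results are invariant to row permutation; the K = 15 landscape
  on one-hot-heavy data is genuinely multimodal, and without
  canonicalization even a reshuffled copy of the same data lands in a
  different local optimum (ARI ≈ 0.85).
* **Feature selection** — one multivariable Cox fit per dataset (Efron
  ties, Wald tests, reference level dropped per categorical; ridge 10⁻⁶ and
  Newton step 0.5 for the near-collinear smoking block), α = 0.05 selection,
  and precision/recall/AUROC of the synthetic selection against the real
  one (AUROC ranks by −log p).
* **Hyperparameter transfer** — a 20-configuration random grid for the
  discrete-time survival network (α ∈ [0.1, 1], σ ∈ {0.1, 0.25, 0.5, 1},
  dropout ∈ [0, 0.5], hidden ∈ {16, 32, 64}, lr log-uniform [10⁻⁴, 10⁻²],
  batch ∈ {64, 128, 256}, patience ∈ {5, 10}); selection on a synthetic
  80:20 split, every config also retrained on real data, baseline = mean
  real-test C-index of the grid, uplift = selected − baseline.
* **TSTR / TRTR** — full-feature Cox fit on the training table (ridge
  escalation 10⁻⁴ → 1 if degenerate synthetic data breaks convergence);
  Harrell's C-index on the real test set (risk ties half credit) and the
  IPCW Brier score at τ = 5 years with the censoring Kaplan–Meier estimated
  on the test data. Absolute risks come from the fitting set's Breslow
  baseline — all a synthetic-data user has.

### The survival network

A dropout MLP over softmaxed discrete time bins (20 equal-quantile bins of
observed times). Loss: α·NLL + (1−α)·ranking, the NLL giving events the
probability mass at their bin and censored subjects the survivor mass past
theirs (censored in the last bin are treated as surviving into it), and the
ranking term averaging exp((F(tᵢ|xⱼ) − F(tᵢ|xᵢ))/σ) over comparable
within-batch pairs. Early stopping on validation loss.

## What the simulator does and does not show

Passing tests demonstrate that the pipeline's machinery is correct and that
its qualitative conclusions (identity generators score at the ceiling;
ε = 1 DP generators lose utility; the oracle dominates TSTR) reproduce
under a known generative law with realistic marginals, rare events and the
real data's derived-feature structure. The simulator does **not** model
missingness, measurement error beyond heaping, competing risks,
time-varying covariates, or the unknown higher-order dependence of the real
cohort; synthetic-data utility measured here should not be read as a
quantitative forecast for any particular real dataset.

## Problem sizes and defaults

Desk-scale defaults keep every experiment single-CPU: cohorts of 2×10³–2×10⁴
(the full study default 5×10³), generator training 30–200 epochs at batch
128, ensembles of 2 members (10 at full scale, configurable), 50 replicates
for the calibration studies. Degenerate inputs are handled explicitly:
constant columns are dropped with a warning before Cox fits, empty K-means
clusters trigger one re-seeded retry, budget-infeasible DP configurations
raise before training starts, and all stochastic components are pure
functions of their seeds.

## Known limitations

* The PATE bound's conservatism means ε = 1 permits only ~50 vote rounds at
  the default λ; the resulting generator is weak — faithful to the bound,
  not to what a moments accountant would allow.
* The numpy GAN core is a minimal architecture; its fidelity ceiling is
  well below modern tabular synthesizers, which is acceptable here because
  every claim tested is an ordering or a calibration, not a state-of-the-art
  fidelity number.
* α-precision/β-recall use the raw encoded space; values are not comparable
  to published numbers computed in learned embeddings.
* k-anonymity depends entirely on the binning of its quasi-identifiers;
  the default is a convention, not a recommendation.
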