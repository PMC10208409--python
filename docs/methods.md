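# Methods

## Model

Patients are instances, prognosis subgroups are bags. Each patient i of
subgroup m carries a d-dimensional mutation-burden vector x_mi (default
d = 3: SNV, INS, DEL counts). A fully connected network with tanh hidden
layers (default one layer of 16 units) and componentwise logistic outputs
maps standardized burdens to (0,1)^k; k = 1 for category labels, k = 2 for
[pR, pT] labels. Instance outputs are pooled into the bag prediction ô_m by
one of four aggregation metrics — median, maximum, minimum, mean — mirroring
the clinical conventions by which a subgroup's efficacy may be summarized
(e.g. a trial powered on median survival). The empty hidden-layer
configuration degenerates exactly to logistic regression, which is used
where a smooth, low-capacity instance model is required (see the learner
comparison below).

Features are standardized per dimension with a scaler fitted on training
data only and reapplied to validation/test folds; zero-variance dimensions
are centered but not scaled.

## Labels

**Category labels** (expert style): a bag is favorable (1) iff its response
proportion reaches a threshold (default 0.5) and its median PFS exceeds a
horizon (default 183 days ≈ 6 months, the conventional favorable-prognosis
cut). A three-class variant adds an intermediate band. All rule parameters
are explicit configuration, because this style of labeling is inherently
subjective; nothing is hard-coded.

**Probabilistic labels**: y_m = [pR, pT]. pR aggregates the members'
response values (with the mean metric it is exactly the subgroup ORR). pT
aggregates per-patient probabilities of surviving beyond t0, obtained from
a Cox proportional-hazards fit of time ~ burdens (lifelines, partial
likelihood). Both components live on the probability scale, which puts the
two endpoints — a proportion and a time — on commensurate units.

The per-patient survival probability uses a product-limit form of the
Breslow baseline: with hazard increment h_s = d_s / Σ_{j∈R(s)} exp(η_j) at
each distinct event time s, S_i(t0) = Π_{s≤t0} (1 − h_s)^{exp(η_i)} with η
centered at the cohort mean. Unlike the exponentiated cumulative hazard,
this estimate reaches 0 when the risk set is exhausted and coincides with
Kaplan–Meier under a null covariate effect. Degenerate designs are handled
explicitly: zero-variance covariates are dropped; a collinear or separable
fit is retried with ridge penalties (0.1, then 10); a design with no
varying covariates falls back to the pooled Kaplan–Meier curve; an
all-censored cohort is an error.

## Losses

For binary bag labels, the calibration loss
E = Σ_m (y_m−ô_m)²/ô_m + (y_m−ô_m)²/(1−ô_m), with ô clipped to
[ε, 1−ε], ε = 1e-7. Its gradient in ô is
((ô²−1)/ô²) · sign-adjusted terms, implemented analytically and verified
against central finite differences. The un-weighted sum is the default
(literal) form; with per-term bag-size weights n_m, mean aggregation and
labels taken as group event proportions the loss is *identically* the
Hosmer–Lemeshow statistic — the equivalence is asserted to 1e-9 relative in
the test suite, with an independent HL implementation on the other side.

For vector labels, E = Σ_m dist(ô_m, y_m) with dist one of:

* squared Euclidean (y₁−y₂)(y₁−y₂)ᵀ — the default training form; a `sqrt`
  flag yields the metric form;
* Mahalanobis (y₁−y₂)V⁻¹(y₁−y₂)ᵀ — V must be symmetric positive definite
  (checked by eigendecomposition, the failing eigenvalue is reported;
  near-singular V is ridge-regularized with a warning). V defaults to the
  pooled sample covariance of the per-patient (response, pT) pairs;
* Minkowski (Σ|Δ_i|^p)^{1/p}, p > 0 (p = 2 recovers metric Euclidean; large
  p approaches the max component).

Baselines: summed squared error (MSE) and cross-entropy (CEL) with the same
ε-clipping. Every loss exposes an analytic gradient in ô; all are
gradient-checked.

## Training

Full-batch gradient descent on the global bag-level loss: one forward pass
over the cohort per epoch, aggregation per bag, analytic loss gradient,
distribution back to instances through the aggregation subgradient
(selected instance for max/min with ties averaged; 0.5/0.5 over the central
pair for an even-count median, spread over value ties; uniform 1/n for the
mean), then backpropagation. Training stops at E ≤ δ (default 1e-3) or
max_epochs (default 5000). The default learning rate is 0.2 — the loss is a
*sum* over a handful of bags, so its gradients are small and a rate sized
for averaged losses underestimates the usable step. Optional classical
momentum (default off) roughly triples convergence speed on the default
cohort; the faster setting (lr 0.2, momentum 0.9, ≤3000 epochs) is used in
the test suite and acceptance script where many fits are run. Determinism:
identical seed, architecture and data order give identical parameters.

## Evaluation

**Cross-validation** splits patients *within* bags (every fold retains all
bags with ~1/k of their members), because the bags carry the supervision
and only five exist — holding out whole bags would leave folds without
labels. The scaler is refit on each fold's training split.

**Learning curve**: a fixed bag-stratified train/validation split; training
subsets of increasing size (bag proportions preserved) are drawn, fitted
and scored, averaged over repeats.

**Hosmer–Lemeshow test**: subjects sorted by predicted probability, g
near-equal-count groups (tied predictions are never split across groups),
statistic Σ_g (O_g − n_g p̄_g)² [1/(n_g p̄_g) + 1/(n_g(1−p̄_g))], referred to
χ²(g−2): df 8 at g = 10, df 18 at g = 20. Degenerate groups (p̄ ∈ {0,1})
are ε-guarded with a warning.

**Learner comparison**: calibration-loss, MSE and CEL multiple-instance
learners trained on identical bag-stratified splits toward the subgroup
responder fractions, plus an instance-level RBF-SVM with Platt probability
outputs fit on the binary responses; each learner's per-patient predicted
probability is scored against the binary response by the HL test on the
train, test and full slices at g = 10 and 20. The comparison uses the
hidden-free (logistic-regression) instance model: bag-mean supervision
leaves within-bag outputs unconstrained, so a higher-capacity network can
saturate instance outputs to 0/1 while matching every bag mean — patient-
level calibration then degenerates for *every* loss and the comparison
stops being about the losses. With the linear instance model the HL
statistics fall in the single-to-low-double-digit range at df 8, and the
relative ordering of the losses is meaningful.

## Synthetic cohort generator

The generator emulates an immunotherapy cohort at the burden-vector level;
the sequencing, alignment and somatic-calling stages of real pipelines are
deliberately out of scope, with their measurement-error role played by a
configurable multiplicative log-normal count noise (σ = 0.1).

Default study design: 660 patients in five subgroups of sizes
90/212/64/202/92 with target labels (0.223, 0.246), (0.326, 0.397),
(0.461, 0.558), (0.654, 0.733), (0.908, 0.922); t0 = 183 days; seed 0.

* **Burdens**: negative-binomial counts (dispersion r = 8) with
  subgroup-specific mean vectors rising from (8, 2, 1.5) to (36, 9.5, 7.5)
  across subgroups — better-prognosis groups carry more mutations, the
  monotone burden-benefit association the model is meant to learn; slopes
  differ per class so the surface is monotone but not uniform.
* **Response**: per-patient probability expit(b0_m + z·β) on cohort-
  standardized burdens z, slopes β = (0.9, 0.5, 0.4); the subgroup
  intercept b0_m is calibrated by monotone root-finding (Brent) so the
  subgroup-mean latent probability equals the target pR exactly. The binary
  response is a Bernoulli draw; the latent probability is retained in the
  ground-truth table and is what subgroup labels are defined on.
* **Survival**: exponential-baseline proportional hazards,
  λ_i = λ0·exp(c0_m + z·γ) with λ0 = 0.00385 /day (median ≈ 6 months) and
  γ = (−0.8, −0.45, −0.35) (higher burden → lower hazard); c0_m calibrated
  the same way so the subgroup-mean S(t0) hits the target pT.
* **Censoring**: independent exponential, rate solved so the expected
  censored fraction is 20%.

What the generator does *not* emulate: caller-specific error profiles,
inter-assay batch effects, non-proportional hazards, informative censoring,
and correlation between response and survival beyond their shared burden
dependence. Tests passing on this cohort therefore demonstrate the
machinery (calibration, recovery, ordering) under a clean generative
model, not clinical performance.

Unreachable calibration targets raise an error naming the subgroup. All
draws flow from one `numpy` Generator seeded from the config.

## Numerical choices

* ε = 1e-7 clipping before divisions/logs; gradients are zeroed at the
  clipping boundary.
* Glorot-uniform initialization under the configured seed; biases zero.
* Mahalanobis V is Cholesky-factorized; SPD is pre-checked by eigenvalues.
* Even-count medians are midpoints of the central pair everywhere
  (aggregation, label rules, HL grouping keeps ties together instead).
* Checkpoints are self-describing JSON (architecture, seed, weights,
  scaler); loading refuses a mismatched input dimension.

## Problem sizes

The test suite and acceptance script run the full 660-patient design for
generation, training, cross-validation and the learner comparison; the
learning curve uses training subsets of 60–495 patients with 2 repeats, and
multi-seed qualitative checks use five seeds. These sizes keep a full run
in the low minutes on a single CPU while leaving the study design itself
untouched.

## Known limitations

* Bag-level supervision identifies instance-level behavior only weakly;
  with a flexible network the per-patient outputs should not be read as
  calibrated individual risks (this is intrinsic to the MIL setting, and
  the reason the learner comparison pins the instance model to logistic
  regression).
* The Cox step assumes proportional hazards and right-censoring
  non-informativeness; no competing risks or time-varying covariates.
* Subgroup membership is an input everywhere; discovering subgroups is out
  of scope.
* The aggregation subgradients (median/max/min) make the loss piecewise
  smooth; convergence to the global optimum is not guaranteed, and the
  median/extremum metrics train more slowly than the mean.
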