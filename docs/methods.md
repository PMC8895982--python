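# Methods

`magicgp` implements Bayesian kernel regression (the GBLUP family) for the
kinds of traits measured on cereal seedlings in a multiparent (MAGIC)
panel: ordinal root counts, continuous root angles known only up to a
confidence interval, and transpiration-rate (TR) responses to vapour
pressure deficit (VPD). This note records the models, the numerical
choices, and what the synthetic data generator does and does not emulate.

## Models

All response families share one linear predictor over lines *i* and
(optionally) replicates *k*:

    eta_ik = beta_k + L_i + g_i + gA_i

* `beta_k` — fixed replicate effects (a full dummy set with no separate
  intercept; per-line traits without replication get a lone intercept
  instead, matching model statements that carry no replicate term).
* `L ~ N(0, I sigma_L^2)` — iid line effects.
* `g ~ N(0, G sigma_g^2)` — additive genomic effects; **G** is VanRaden's
  method-1 relationship matrix, `W W' / (2 sum p(1-p))` with `W` the
  dosage matrix centred at twice the *sample* allele frequencies.
* `gA ~ N(0, (G∘G) sigma_gA^2)` — first-order additive×additive epistatic
  effects with the Hadamard square of G as covariance (PSD by the Schur
  product theorem). The element-wise square is an explicit modelling
  assumption: "first-order multiplicative epistasis" is conventionally
  realized this way, and no other construction is available from dosages
  alone.

The five standard predictor sets are numbered 1–5: R+L, R+G, R+G+G×G,
R+L+G, R+L+G+G×G (`PredictorSpec.from_model_number`).

Response families:

* **Gaussian** — `y_i = eta_i + e_i`, `e ~ N(0, sigma_e^2)`.
* **Interval-censored Gaussian** — each record is either exact
  (`a = y = b`) or an interval `a_i < y_i < b_i`; latent values of
  interval records are re-imputed each sweep from the truncated normal
  `N(eta_i, sigma_e^2)` on `(a_i, b_i)`. Intended for BLUE adjusted means
  reported with a standard error (interval = BLUE ± 2 SE). Whether that
  "SE" is the BLUE's standard error or a replicate-level SD is not
  determined by the data layout; the package takes the BLUE standard
  error, and the interval construction is explicit at the call site.
* **Ordinal probit (threshold)** — category `c` observed iff the latent
  liability falls in `(gamma_{c-1}, gamma_c)`; residual liability variance
  is fixed at 1 for identification. Liabilities are imputed from
  truncated normals; each cut-point is drawn from its uniform full
  conditional between the largest liability of its lower category and the
  smallest of its upper one (the Albert–Chib scheme). Because a constant
  can trade between `beta` and `gamma`, recovery comparisons use anchored
  quantities (`gamma - mean(beta)`, `beta - mean(beta)`), exposed as
  `GPFit.anchored` alongside the raw draws.
* **Log-normal counts** — counts are analysed as `log(y+1)` through the
  Gaussian engine; fitted counts are reported back-transformed as
  `exp(fitted) - 1`. Poisson / negative-binomial likelihoods are out of
  scope.

## Sampler

One Gibbs engine serves all families. Each kernel effect is sampled in
its eigenbasis: with `K = V diag(lambda) V'` and `u = V delta`, the prior
is `delta_j ~ N(0, sigma^2 lambda_j)`. For balanced designs (equal
records per line — including all per-line traits) the full conditional of
`delta` is diagonal, giving O(n) updates per term; unbalanced designs
fall back to an exact joint draw through a Cholesky factor of the m×m
conditional precision. Eigenvalues ≤ 1e-10 are clipped to zero and their
directions dropped, which also confines `g` to the row space of G (G has
null vector **1** by centring, so genomic effects carry no intercept).

Variance components have scaled-inverse-chi-square full conditionals with
a weak proper prior: df = 5, and scales set so the prior mode splits
`prior_r2 = 0.5` of the (latent) response variance equally among the
included random terms, the remainder going to the residual — the
documented default behaviour of the reference Bayesian GP software, made
explicit and configurable. Chain defaults are 30 000 iterations, 5 000
burn-in, thinning 5 (cross-validation folds default to 6 000 / 1 000 / 5);
the effective sample size of every variance component is computed by
Geyer's initial-positive-sequence rule and a warning is logged below 100.
All randomness flows from one `numpy` Generator seeded by the settings.

Truncated-normal draws use the inverse-CDF method on `ndtr`/`ndtri` with
tail clipping to the interval; degenerate windows (numerically empty
threshold windows, e.g. unobserved intermediate categories) leave the
current value unchanged, and unobserved categories between the extreme
labels are kept — with a warning — rather than merged, so labels such as
2–8 survive.

Prediction for lines outside the training set is the kernel-regression
conditional mean per term, `K_new,train K_train^+ u_hat` (pseudo-inverse
through the training spectrum); iid line effects of unseen lines are 0 and
the fixed-effect level is the mean of the fitted fixed effects.

## Cross-validation and scores

Leave-one-out CV supports two units. *Observation* mode removes a single
replicate record; the line's remaining records stay, so predictions use
the fitted line-level effects. *Line* mode removes all of a line's
records and predicts it through its kernel rows — the honest protocol for
per-line traits. For censored traits, `retain_bounds=True` keeps the
held-out record in the fold as a bounds-only observation (value hidden,
interval kept). This leaks the value to within ±2 SE and inflates
predictive ability dramatically (measured here: ~0.999 vs ~0.14 honest on
the synthetic angle trait); it exists because published per-line
predictive abilities of intercept-plus-line models are only reproducible
under such a convention, and every result records which mode was used.

Scores: halved Brier score `BS = (1/n) sum_i sum_c (pi_ic - d_ic)^2 / 2`
(0 best, 1 worst); PCCC, the modal-category accuracy with ties broken
toward the lower label; and Pearson predictive ability between predicted
and observed values. Honest line-level LOO of a model with no genomic
term degrades to the classic fold-mean artifact (each fold's mean moves
away from the held-out value, so r is strongly negative); the package
reports it as computed and the acceptance script simply omits that
uninformative combination.

## Trait pre-processing

* **BLUEs** — two-way fixed-effects model (line + replicate) solved by
  least squares with sum-to-zero replicate coding, so each line's BLUE is
  its estimate at the mean replicate level; SEs from the pooled residual
  variance. A line confined to replicates containing no other line is
  adjusted only through the constraint, so it is flagged `estimable=False`
  rather than silently dropped. The original experiment's full design
  model (trays, positions) is not recoverable from the data layout; the
  two-way model is the minimal stand-in and is swappable behind
  `compute_blues`.
* **TR response** — per line, an OLS line and a continuous two-segment
  model `b0 + b1 min(v, bp) + b2 max(0, v - bp)` with the breakpoint found
  by SSE grid search (default step 0.01 kPa) over the grid interior.
  R² is the selection criterion with a minimum gain of 0.01 (R² of nested
  models never decreases, so a gain threshold is required); R² is defined
  as 0 for a constant response. The per-line TR value used downstream is
  the model-selected fit evaluated at 2.7 kPa (a flag switches to the
  nearest raw measurement).

## Correlations

Pearson correlation (two-sided t test) for continuous pairs;
polyserial correlation for continuous × ordinal pairs by the two-step
estimator — thresholds from inverse-normal cumulative category
proportions, then the latent correlation by one-dimensional likelihood
maximisation on (−1, 1), with a likelihood-ratio p-value against rho = 0.
Full joint ML is a possible extension; the two-step estimator is the
conventional default of the standard polyserial implementations.
Sample SD (n−1) throughout; pairwise-complete case handling with dropped
pairs logged. GGE biplot scores come from the SVD of the
environment-centred line × environment matrix with symmetric
singular-value scaling.

## Synthetic data

The generator emulates the target study: 89 fully inbred lines from an
8-founder MAGIC funnel, ~20 400 biallelic SNPs, ordinal root counts in 7
categories (2–8) over 12 replicates with a bell-shaped distribution
(modal category probability ≈ 0.5), a root-angle-like trait centred at
86.6° with SD ≈ 9–12°, and TR curves on a 0.4–5.4 kPa grid with
breakpoints drawn from 2.3–2.5 kPa and 28/90 of lines linear.

Genotypes are founder mosaics: per marker, k of 8 founders carry the
minor allele (k set so the panel frequency lands in `maf_range`), and
each line tiles the marker axis with geometric founder blocks. The
study-condition factories use ~35 founder segments per line
(`segment_length_mean = n_markers/35`), the order expected after an 8-way
funnel with a handful of meioses across seven chromosomes; the generic
default is 250 markers per block. There is no genetic map, no pedigree,
no mutation or selection — block-level LD and founder-derived relatedness
are the only structures, which is what kernel construction and the
samplers need. Real-data features deliberately not emulated include
genotyping error, map-dependent recombination hot/cold spots, population
substructure beyond the single funnel, and trait measurement artefacts;
passing tests therefore demonstrate statistical correctness of the
machinery under the stated generative model, not robustness to every
field phenomenon.

Default ground-truth variance components mirror the analysis results the
package targets (liability-scale 0.02 per genetic term for the ordinal
trait against a unit residual; angle-scale 15/15/15 against 40). The
count generator inverts the analysis link exactly:
`y = max(0, round(exp(eta) - 1))`.

## Problem sizes in tests and the acceptance script

Oracle agreement uses n = 30 with variance components fixed (tolerance
0.02 against the closed-form joint-Gaussian conditional mean). Recovery
experiments use 300–500 lines and 20 000 iterations; the acceptance
script runs the full 89-line × 20 426-marker study emulation with
12 000-iteration fits and 3 000-iteration CV folds — sizes chosen so the
whole analysis reruns in minutes on one core while keeping Monte-Carlo
error well inside the stated tolerances.

## Known limitations

* Honest genomic prediction in an 89-line panel with ~35 founder
  segments per line is intrinsically weak (measured r ≈ 0.1–0.3); large
  published per-line predictive abilities are reproduced only under the
  bounds-retaining CV convention, which the package treats as a
  deliberately available leak, never a default.
* Thresholds of sparsely populated ordinal categories mix slowly under
  the uniform conditional scheme (a Metropolis cut-point sampler is out
  of scope).
* The BLUE model ignores any incomplete-block or spatial structure of the
  original experiment.
* Breakpoint localisation to ±0.05 kPa requires dense VPD logging; on a
  0.5-kPa grid with realistic noise only the linear/segmented
  classification (not the breakpoint) is reliable.
* Multi-trait models, Bayes A/B/Cπ marker priors, REML, and k-fold CV are
  out of scope.
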