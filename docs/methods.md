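# Methods

## The model

`caselatent` treats a work-injury case as a path through a latent space.
The representation is learned by a mixed-type variational autoencoder
(VAE); prediction and recommendation are layered on top of the frozen
encoder/decoder pair.

**Inputs and outputs.** The encoder consumes the case covariates that are
known while a case is open: age (years), monthly salary, the case
manager's alertness score (0–10, a flag that the case needs extra
attention), seven categorical fields (injured body parts, nature of loss,
cause, industry, position, physical demand level, handling frequency),
and two dynamic components — days passed since the accident *t* and the
HLM day (the day high-level management was applied, when known).  The
decoder reconstructs all encoder inputs and additionally emits the
outcome fields: total sick-leave days, the Form-7 permanent-disability
percentage, and the benign/serious (BLM/HLM) flag.  Outcome fields are
deliberately excluded from the encoder: feeding the sick-leave total into
the input side would make open-case prediction circular, since the
quantity being predicted would be part of the query.  Calendar dates are
never fed raw; they enter only as derived day offsets.

**Architecture.** Each continuous input is projected to an 8-dimensional
embedding by a one-layer fully connected (FC) map with LeakyReLU
(negative slope 0.01); the concatenated one-hot block goes through one FC
layer to 64 dimensions with LeakyReLU.  The concatenated embeddings pass
through three processing layers of 100 neurons each; linear heads emit
the posterior mean and log-variance of a 100-dimensional
diagonal-Gaussian latent.  Two two-layer FC decoders (100-unit LeakyReLU
hidden layer, linear output) produce the continuous block and the
categorical logits, the latter soft-maxed per field group.  The latent
dimension and processing width are both 100 by design: the
nearest-neighbour layer operates on "points with 100-dimension
coordinates".

**Loss and training.** The loss is the batch mean of

    sum-of-squares error on standardized continuous outputs
  + per-group categorical cross-entropy
  + kl_weight · KL(q(z|x) ‖ N(0, I)).

Training uses the reparameterization trick, Adam (learning rate 1e-3),
minibatches of 64, and a default of 100 epochs; at inference the
posterior mean is returned, so encoding is a pure function of (weights,
input) — the nearest-neighbour index implicitly requires deterministic
coordinates.  The network and its analytic gradients are implemented
directly in NumPy; the gradients are verified against central finite
differences in the test suite, and the diagonal-Gaussian KL closed form
is verified against numerical quadrature.

`kl_weight` defaults to 0.05 rather than the textbook 1.0.  With a
100-dimensional latent and a ~45-dimensional reconstruction target, a
unit-weight summed KL dominates the objective and collapses most latent
coordinates toward the prior before they can carry case information; the
downstream regressions then have nothing to work with.  A small β keeps
the sampling machinery (and the regularizing pull toward a smooth,
centred latent) while preserving reconstruction fidelity; β = 0 recovers
a plain autoencoder for ablation.  The weight is configurable in
`VaeConfig`.

**Training rows.** The VAE is fitted on closed cases, each contributing
`vae_t_samples` (default 4) rows: the path start *t* = 0, the endpoint
*t* = RTW_Days, and uniform draws in between.  The HLM-day input is
populated only on rows whose *t* has reached it, mirroring what would be
known at that point of the timeline; before that (and for all benign
cases) it is encoded as the sentinel — zero in standardized day units —
plus a binary "HLM applied" indicator.  Day-valued inputs (*t*, HLM day)
are standardized with the sick-leave scaler so a given number of days
means the same thing wherever it enters the network.

## Latent-path predictors

Four maps operate on latent points (default: scikit-learn MLPs with two
64-unit hidden layers; a linear family is available for diagnostics):

* `p_blm`: Z_0 → Z_End, fitted on benign cases only.  Benign predictions
  use exclusively the information available at the start of the case, so
  they are invariant to the query day by construction.
* `p_hlm_endpoint`: Z_t → Z_End with *t* the case's HLM day, fitted on
  serious cases.
* `p_pd`: Z_End → PD percent, fitted on true endpoints and applied to
  predicted endpoints at inference (predicted-endpoint training is the
  tested alternative; true endpoints keep the estimator's target clean).
* `p_hlm_classifier`: Z_t → P(HLM), fitted on latent snapshots sampled
  uniformly along each training case's timeline (default 4 per case),
  with the case's class as label and the HLM day withheld — exactly the
  information state of an open case being triaged.  Because benign cases
  close early, large *t* is increasingly dominated by serious cases and
  the predicted probability grows with days passed; sweeping it over a
  day grid yields the HLM cliff, with a default decision threshold of
  0.5 (the threshold is a free parameter; no canonical value exists).

A regime with fewer than 10 training cases is refused rather than fitted.
Predicted RTW days are decoded from the sick-leave field of D(Z_p),
de-standardized, rounded half-up to whole days and clipped at zero; PD is
clipped at zero.  When a new case is escalated at day *t* without a known
HLM day, *t* itself stands in for the HLM day — the classifier has just
fired, so today is the escalation day as far as the model knows.

## Strategy recommendation

Closed cases are indexed by their endpoint coordinates Z_End.  Retrieval
is an exact exhaustive scan (no approximate index): K = 50 by default,
Euclidean metric (cosine available), ties at equal distance broken by
case id so results are reproducible.  Weights are normalized inverse
distances; exact matches (distance 0) take all the mass, shared equally.
A strategy's probability is the summed weight of neighbours whose logs
contain it — probabilities are not normalized across strategies, since a
case can receive several — and its expected day is the weight-averaged
first-occurrence day among those neighbours (median available by flag).
Strategies with probability **strictly greater than 0.40** are
recommended.

## The synthetic cohort

The generator emulates the structure the predictors assume, not any real
provider's distributions (which are unavailable):

* **Severity classes.** Each case is serious (HLM) with probability 0.2.
  Sick leave is log-normal per class — benign location log 14 days,
  serious location log 150 days, spread 0.5 — plus additive log-scale
  effects of industry and injured body part (the recoverable signal),
  floored at 1 day.  Serious recovery times are therefore long-tailed.
* **PD** = slope · SL / 100 + Gaussian noise, floored at 0; slope 0.5
  (benign) / 1.0 (serious) percent per 100 days.
* **HLM day** drawn uniformly over [0.1, 0.6] of the case duration.
* **Strategies.** Benign cases draw 1–2, serious cases 3–8 distinct
  strategies, sampled without replacement in proportion to class-
  conditional profile weights under which "RTW—Full Duties" is by far the
  most frequent action overall; occurrence days are uniform over the
  case duration.
* **Case-manager estimates.** Each case carries time-stamped estimated-SL
  and estimated-PD log entries: truth plus zero-centred Gaussian noise
  truncated at zero.  The noise scale is per class — SL sd 20.5 / 194
  days, PD sd 0.34 / 2.64 percent — chosen so the simulated manager's
  mean absolute error sits on the scale reported for practising case
  managers (≈16 days benign, ≈155 days serious; the half-normal mean is
  sd·√(2/π)).  Benign cases are estimated once or twice early; serious
  cases several times, always including an estimate near the HLM day,
  because the comparison protocol selects the first estimate for benign
  cases and the nearest-to-HLM-day estimate for serious ones.
* **Alertness** is class-dependent (mean 3 benign / 7 serious, sd 1.5,
  clipped to [0, 10]), making it a usable escalation signal and the
  natural target of the ablation experiment.

What the generator does **not** emulate: free-text fields, the full
124-column administrative export, within-class correlation structure
beyond the planted industry/body-part effects, non-stationarity over
accident years, censoring (all synthetic cases are closed), and
company-policy effects on strategy choice.  Passing tests therefore
demonstrate that the pipeline recovers planted structure of realistic
shape and scale — not that it would achieve any particular error on a
real caseload.

## Evaluation design

Held-out cases are predicted under the protocol used for human
comparison: benign cases from the path start, serious cases from their
HLM day.  Errors are mean absolute errors (the unit-preserving reading of
"average error"), reported separately per class.  Strategy accuracy
applies the >40% rule; per-case accuracy is |predicted ∩ truth| / |truth|
— false positives are not penalized by that metric, so per-strategy
precision is reported alongside recall (recall over cases whose ground
truth contains the strategy is the documented interpretation of
per-strategy accuracy).  The alertness ablation runs two complete
train-and-evaluate passes with identical seeds, differing only in the
inclusion of the alertness feature.

## Numerical choices and problem sizes

* Standard scores use the sample standard deviation (n−1); scaler and
  vocabulary are fitted on the training split only; zero-variance fields
  are an error.  The split ratio default is 0.05; test size is
  round(ratio·n), seeded.
* Missing data are dropped whole-record, never imputed — mean replacement
  distorts exactly the duration signal being modelled.  The HLM day is
  exempt for benign cases, where its absence is structural.
* Unknown categorical levels at inference map to an explicit catch-all
  level appended to every vocabulary; a strict mode raises instead.
* Posterior log-variance is clipped to ±10 for numerical stability;
  gradients through clipped entries are zeroed.  Non-finite loss aborts
  training.
* Inverse-distance weights are computed as (d_min/d) / Σ(d_min/d), which
  is scale-invariant and cannot overflow for denormal distances.
* Default experiment sizes in the test suite and acceptance script:
  2,000-case cohorts, 40 training epochs, 4 timeline samples per case.
  These sizes are where the recovery experiments stabilize while keeping
  a full pipeline fit under half a minute on one CPU; the architecture
  itself is unchanged at larger scales.

## Known limitations

* **Out-of-sample evaluation is essential.**  With near-unique continuous
  covariates (age, salary), the VAE plus classifiers can memorize
  training cases — on training data the HLM classifier appears to know
  the class at *t* = 0.  All recovery experiments in this package
  therefore measure held-out cases only.
* **The HLM cliff is a classifier sweep, not a geometric boundary.**  The
  per-case crossing day is noisy: its systematic variation across
  covariate profiles (tens of days) is comparable to classifier smoothing
  noise, so crossing days track the true escalation timing reliably at
  the level of covariate-profile means, which is how the package's tests
  assess it.
* Only start, HLM and end points of a path are modelled; intermediate
  events in the change logs are used for evaluation, not prediction.
* The human baseline is simulated; with real case-manager logs supplied
  in the same CSV schema, the identical comparison code applies, but the
  calibration of the simulated noise is an assumption, not a measurement.
* Exact KNN is O(index size) per query by design; approximate indexing is
  out of scope at the intended case volumes.
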