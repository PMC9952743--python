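# caselatent

Latent-space modelling of occupational work-injury cases: prediction of
sick-leave duration (SL), permanent disability percentage (PD) and the
need for high-level management (HLM), plus distance-weighted
nearest-neighbour recommendation of case-management strategies.

The package is written for occupational-rehabilitation analytics: given a
table of closed work-injury case records (worker demographics, injury
characteristics, industry and job demands) and the case managers' change
logs, it trains a decision-support model that answers, for a new case at
day *t*, three questions — *when will the worker return to work, how much
permanent disability should be expected, and does this case need
escalated management?* — and retrieves what was done for the most similar
historical cases.  Because real case files of this kind are proprietary,
the package ships a first-class synthetic cohort generator that emulates
their structure (a benign majority with short sick leave, a serious
minority with long recovery, PD correlated with duration, strategy sets
that grow with severity, and time-stamped noisy case-manager estimates),
so the whole system is trainable, testable and benchmarkable end to end.

## Model

A case is modelled as a **path through a latent space**.  A mixed-type
variational autoencoder maps case features *f* (standardized continuous
fields, one-hot categorical fields, and two dynamic components: the days
passed *t* and, once known, the HLM day) into a 100-dimensional latent
space *L* via the encoder, z = E(f), and back via the decoder, f = D(z).
The network uses per-field continuous embeddings and a categorical
embedding (one FC layer + LeakyReLU each), three 100-neuron processing
layers, diagonal-Gaussian posterior heads, and two-layer FC decoders; the
loss is MSE + categorical cross-entropy + β·KL(q‖N(0,I)).

A case that has passed *t* days sits at Z_t = E({C_s, t}); it starts at
Z_0 = E({C_s, 0}) and, once closed, ends at Z_End = E({C_s, RTW_Days}).
Four maps operate on these points:

* **Benign endpoint** Z_p = P_BLM(Z_0) — benign cases follow a common
  pattern derivable from information available at the start;
* **Serious endpoint** Z_p = P_HLM(Z_t) with *t* the HLM day;
* **PD estimator** PD = P_PD(Z_p);
* **HLM classifier** L_HLM = P_HLM(Z_t) ∈ [0, 1] — sweeping it over a day
  grid traces the *HLM cliff*, the day a case's predicted probability of
  needing escalation crosses the decision threshold.

The predicted return-to-work day is read off the decoded sick-leave field
of D(Z_p).  For strategy recommendation, all closed cases are indexed by
Z_End; the K = 50 nearest neighbours of a predicted endpoint are
retrieved by exact search, inverse-distance weights are computed, each
strategy's probability is the total weight of the neighbours whose
history contains it, and strategies with probability strictly above 40%
are recommended together with their expected occurrence day.

## Worked example

```python
import caselatent as cl

cohort = cl.generate_cohort(cl.CohortConfig(n_cases=2000, seed=11))
model = cl.WorkInjuryModel.from_cohort(cohort, vae_config=cl.VaeConfig(epochs=40))
results = model.fit(seed=0)
print(results.summary())

case = results.test.iloc[0]
outcome = results.predict_outcome(case, t=0)
print(f"case {case.case_id}: predicted RTW day {outcome.rtw_days:.0f}, "
      f"PD {outcome.pd_percent:.2f}%, P(HLM) = {outcome.hlm_probability:.2f}")
for s in results.recommend(case)["recommended"]:
    print(f"  {s.strategy}: p={s.probability:.2f}, expected day {s.expected_day:.0f}")
print(results.evaluate().error_table.round(3))
```

prints

```
Work-injury latent-path model
================================================================
cases: 1900 train / 100 test (dropped incomplete: 0)
latent dim: 100; processing: 3 x 100
encoder widths: 6 continuous, 41 one-hot
decoder widths: 8 continuous, groups [7, 6, 6, 6, 6, 5, 5, 2]
parameters: 79,835
kl_weight: 0.05; epochs run: 40
final loss: total 2.3510 (cont 0.3280, cat 0.2897, kl 34.6659)
endpoint index: 1900 cases, metric euclidean, k=50, strategy threshold 0.4

case C000007: predicted RTW day 64, PD 0.47%, P(HLM) = 1.00
  RTW—Full Duties: p=0.72, expected day 53
  Physiotherapy: p=0.58, expected day 53
  RTW—Modified Duties: p=0.55, expected day 38

                   sl_mae_blm  sl_mae_hlm  pd_mae_blm  pd_mae_hlm  n_blm  n_hlm
model                   9.855      63.083       0.083       0.619     76     24
human                  12.432     117.483       0.205       2.074     76     24
model/human ratio       0.793       0.537       0.402       0.299     76     24
```

The table is the standard results layout: mean absolute error of
sick-leave days and PD percent, split into benign (BLM) and serious (HLM)
cases, for the model and for the simulated case manager whose estimate
noise is calibrated to the scale reported for real case managers.  Ratios
below 1 mean the model beats the human baseline in that cell.

The same pipeline is available from the shell:

```sh
caselatent run --workdir myrun --seed 0     # simulate -> train -> evaluate
caselatent recommend --workdir myrun --case-id C000007
```

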