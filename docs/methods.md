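# Methods

## The decision problem and the normative observer

Each scenario puts a focal actor at the end of a short sequence of binary
decisions.  Two states (coded A/B internally; urn A / urn B or
appendicitis / sigmoid diverticulitis at the interface) are a priori
equally likely.  Every actor privately observes one signal that matches
the true state with reliability *p* (2/3 in all packaged designs;
arbitrary values in (0, 1) \ {0.5} are supported) and sees all previous
public decisions.

The normative posterior uses the log-odds form: each signal contributes
*f(x) = ln p(x|A)/p(x|B)*, and the posterior of A is the logistic of the
summed contributions (plus the prior log odds).  Under symmetric
reliabilities only the difference between a- and b-signal counts matters.
An independent brute-force route (likelihood products into Bayes's
theorem) is kept in the package purely as a cross-check; tests verify the
two routes agree to 1e−12 on every ledger with up to five signals at
three reliability settings.

**Signal inference.**  The one place behavioural content enters the
normative engine is reading signals off decisions.  We maintain the
running count `net` of inferred a- minus b-signals over already-processed
predecessors and infer the decision-matching signal while |net| ≤ 1:

* net = 0 — ties are broken by the actor's own draw, so the decision
  reveals the signal exactly;
* |net| = 1 — an opposing signal would bring that actor to indifference
  and hence (tie-break) to their own signal, so again decision = signal;
* |net| ≥ 2 — the actor follows the majority under either signal
  (cascade); nothing is inferred, and `net` is left unchanged.

This rule is not free to vary: it is forced by the worked cascade example
(two same-direction decisions reveal two signals) together with the fact
that three same-direction decisions must yield the same posterior as two.
A decision *opposing* a |net| ≥ 2 state cannot be rationalised under
either signal; scenario validation rejects such sequences, naming the
offending position.

## The social influence model

Subjective log odds re-weight the f(x) sums while conserving total
weight: the two-source form weights public evidence by β_soc ∈ (0, 2) and
private evidence by 2 − β_soc; the three-source form splits public
evidence by source rank into β_HR (authority) and β_ER (peer), with
private weight 3 − β_HR − β_ER.  β_bias is an additive log-odds bias.
Choices follow `1/(1 + exp(θ(p_B − p_A)))` with sensitivity θ.  Weighting
applies only to *inferred* signals: an uninformative cascade decision by
an authority contributes nothing, by construction of the ledger.

**Predicted probability judgments.**  A respondent who chose X reports
the subjective posterior of X.  Because the model is probabilistic about
the choice, the scenario-level prediction is by default the expectation
over the model's own choice distribution,
`p_c·p_subj(A) + (1 − p_c)·p_subj(B)`, which matches how observed
per-scenario means average over participants who chose either side; the
alternative convention (subjective posterior of the modal choice) is
available via `judgment_rule="argmax"`.  Both are clamped to the [0.5, 1]
response scale and both are ≥ 0.5 for θ ≥ 0.  On the three indifference
urn scenarios under the canonical group parameters the two conventions
evaluate to 0.543 and 0.585 respectively — the choice of convention
matters at the second decimal, which is why both are exposed.

## Synthetic cohorts

The generator emulates the questionnaire studies: a fixed scenario list
per participant (the 12 urn tasks, optionally mirrored and repeated, or
the 40 clinical scenarios), Bernoulli choices from the model's choice
rule, and judgments equal to the subjective posterior of the drawn choice
plus Gaussian noise (sd 0.05 by default — roughly the granularity of a
50–100% slider), clamped to [0.5, 1].  Default population means are the
group medians estimated in the urn study (β_bias = −0.12, β_soc = 0.78,
θ = 6.08) and its clinical extension (0.06, β_HR = 1.12, β_ER = 0.85,
θ = 7.37); between-participant heterogeneity uses independent truncated
Gaussians (sd 0.15 for weights, 0.1 for the bias, 1.0 for θ — modest
values chosen so the population stays well inside the legal ranges).
Fixed-parameter cohorts are used for recovery studies.  One master seed
spawns per-participant substreams, so enlarging a cohort never changes
existing participants.

What the generator does **not** emulate: live sequential play (every
synthetic participant answers fixed scenarios, as in the studies),
learning across trials, response omissions, and any normative-influence
mechanism beyond the β weights.  A green recovery test therefore
establishes that the estimation machinery works on data generated by the
model itself — not that the model is true of people.

## Estimation

Per participant, the likelihood is the Bernoulli probability of the
observed choices (judgments are never part of the likelihood; predicting
them afterwards is the generalisation test).  Priors: β_bias ~
normal(0, sd 10) truncated at ±1 — effectively uniform on the interval —
and uniform(0, 2) / uniform(0, 10) for the weights and θ.

The sampler is component-wise random-walk Metropolis with per-component
Gaussian proposals.  Proposal scales adapt every 50 iterations during
burn-in toward a 40% acceptance rate and are frozen afterwards, so the
recorded chain has a fixed kernel.  All participants and chain replicates
advance in lock-step through one vectorised likelihood evaluation; this
makes a 40-participant cohort fit take a few seconds at the desk profile.
The full protocol (burn-in 10 000, thinning 100, ≈50 000 post-burn-in
iterations over 4 chains) is the default `ChainConfig`; the desk profile
(`ChainConfig.desk()`: 4 chains, burn-in 500, thinning 4, 5 000 kept
samples) is used throughout the tests.  Convergence is monitored with
split-R̂ (< 1.01 required, otherwise the summary is flagged, not
discarded); the sampler was verified against brute-force grid integration
of the exact posterior (posterior means agree to MC error, ≤ 0.02 on the
weights) for both model forms.

Group estimates follow the chain-averaging convention: sample *i* of the
group chain is the mean over participants of their sample *i*; medians,
95% HDIs (narrowest sorted window) and sample-wise contrasts — e.g.
(2 − β_soc) − β_soc, β_HR − β_ER — are computed on the averaged chain.
Chains of unequal length are strided down to the shortest
deterministically.  Index-averaging is the default; note that
concatenation would instead produce a mixture distribution with much
wider intervals.

## Numerical choices

* Log odds are clipped at ±50 before exponentiation; with θ < 10 choice
  probabilities then stay within (4e−5, 1 − 4e−5), so the Bernoulli
  log-likelihood is always finite.
* HDI requires ≥ 100 samples; point masses give zero-width intervals.
* Truncated-Gaussian draws use rejection sampling (acceptance is high for
  all defaults).
* The authority contrasts use per-participant condition means first, then
  paired tests across participants.  Because those means average only
  3–7 binary trials, the classic zero-dropped normal-approximation
  signed-rank p-value over-rejects (≈ 0.085 at nominal 0.05 in a
  600-replicate null simulation); p-values therefore come from a
  sign-flip permutation of the signed-rank statistic (zeros ranked but
  contributing nothing), which is exact-level under the symmetric null
  (0.053 in the same simulation).  The z statistic of the normal
  approximation is still reported for comparability with published
  analyses.  The permutation seed derives from the data, keeping results
  deterministic.
* Type-I calibration of that test is checked under the exact null
  (β_HR = β_ER, zero bias) at the 0.50-posterior level only: at other
  levels the baseline and MD-opposes groups mix Bayes-favoured and
  cascade scenarios in different proportions, so their expected
  private-consistency differs even without any authority effect and the
  null is false by design.

## Known limitations

* **Group-HDI coverage for weakly identified weights.**  The
  chain-averaged group HDI narrows as 1/√n_participants, but the
  per-participant posterior-mean shrinkage toward the uniform-prior mean
  does not.  For the authority weight at its canonical value 1.12 on the
  40-scenario design with 40 participants, the pooled median is biased by
  about −0.06 while the group HDI half-width is ≈ 0.07, so replicate
  coverage of the truth is ≈ 70%, well below nominal.  The peer weight
  (0.85, better identified) and all Study-1-style parameters are
  unaffected.  This is a property of the pooling convention, not of the
  sampler; a hierarchical model with hyperpriors would address it but is
  out of scope.
* Predecessors are modelled as error-free Bayesians; "probably would
  have decided" softening is not modelled, so informative decisions
  reveal signals with certainty.
* Only two options and exchangeable signal reliabilities are supported.
* The [0.5, 1] clamp makes simulated judgments slightly exceed the
  expectation-convention prediction when the model is near-indifferent;
  self-consistency between generator and predictor is exact only in the
  high-θ limit.
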