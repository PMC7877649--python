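# Methods

## The problem

Psycholinguistic predictability effects (faster reading, reduction,
omission of predictable material) are usually manipulated through
*linguistic* context, quantified with n-gram language models over words.
This package implements the complementary corpus-based route for
*extralinguistic* context: script knowledge — stereotyped knowledge of
how everyday activities such as cooking pasta unfold — is represented as
a probabilistic event network estimated from crowd-sourced
event-sequence descriptions (ESDs), and the predictability of an
utterance is proxied by the surprisal of the event it refers to.

The pipeline has five stages, each a module:

1. **esd_corpus** — read/validate/write ESD corpora (XML and a tabular
   dialect).
2. **event_labeling** — reduce each description to a canonical
   verb–noun event label via parsing, lexicon-driven normalization
   (synonym pooling, pronoun and ellipsis resolution), and a uniqueness
   screen.
3. **event_lm** — fit event-level bigram models; surprisal in bits.
4. **chain_extraction** — greedy maximum-likelihood event chains and
   predictable/unpredictable stimulus specifications.
5. **rating_analysis** — exclusion filter, sum coding, cumulative link
   mixed models (CLMMs) with likelihood-ratio backward selection, for
   the Likert ratings such stimuli elicit.

**synthetic_data** generates inputs with known ground truth for all of
the above.

## Event labels

An event label is the main verb plus its post-verbal object noun
("pour pasta").  Labels need only *distinguish* events within one
scenario; they are not meant to be accurate paraphrases.  Parsing is a
provider contract (tokens, POS tags, head-verb index, object index).
The bundled `fallback_parse` is a deterministic rule-based parser tuned
to the genre: ESDs are dominated by verb-first imperatives with frequent
subject omission and object ellipsis, which trip general-purpose
statistical parsers.  Its rules: the head verb is the first token on a
verb list, or any sentence-initial open-class token; the direct object
is the first noun or pronoun after the verb, skipping determiners,
adjectives and adverbs, with a preposition or conjunction closing the
object position (so "pour in pan" is objectless).  Lemmatization is a
small exception dictionary plus deterministic suffix rules — chosen over
a statistical lemmatizer so that tests are locale-independent and
byte-reproducible.

Normalization is lexicon lookup, applied in a fixed order: pronoun map →
default-object map (for elided objects) → synonym map → whole-label
event map.  Canonical values are required to be fixed points, making
normalization idempotent.  What the original workflow did by manual
review is here versioned data (four TSV tables per scenario) plus a
screening report listing unresolved placeholders and merge candidates
(same verb with nouns within Levenshtein distance 2, or same noun with
near-identical verbs — a deliberately high-recall screen).

## Event language models

Sequences are wrapped in begin/end markers so first events have defined
conditional probabilities.  The default is a bigram model with raw
maximum-likelihood estimation.  MLE (no smoothing) is a modeling
decision, not an omission: stimulus construction relies on events having
probability *exactly* 0 in a context, a notion additive smoothing
destroys.  Add-k smoothing is available for robustness checks.  Roughly
100 sequences per scenario cannot support orders above 2.  Zero
probabilities surface as an infinite-surprisal sentinel rather than an
exception so that chains and reports can carry them.  Vocabulary size
excludes the boundary markers; the distinct-bigram count excludes
boundary pairs by default (a documented switch includes them).
Surprisal is −log2 p in bits; `bits_to_percent` converts back to a
likelihood percentage (100 · 2^−bits), rounded to one decimal by
default.

## Chain extraction

A chain is a greedy walk: from a start event, repeatedly move to the
eligible, not-yet-visited successor with maximal conditional
probability.  Eligibility requires a unigram count of at least 8
(configurable), so that an event mentioned by one contributor in a
hundred never represents population script knowledge.  Three choices
the source procedure leaves open are fixed here for determinism:

* ties broken lexicographically on the label string;
* no event revisited within a chain (scripts are linear in intent;
  revisiting would loop on symmetric data) — the walk stops early,
  flagged, when no eligible unvisited successor has positive
  probability;
* the default start is the eligible event most likely to open a
  sequence (highest p(e | begin marker)).

A stimulus takes the first three chain events as context, the fourth as
the predictable target (contiguous-prefix mode; a per-position re-seeded
mode is not provided because the contiguous reading is the conservative
one), and fills the unpredictable slot from human-proposed candidates
filtered to probability 0 given the last context event.  Candidate
plausibility is a human judgment and out of scope.

## Synthetic data: what it emulates and what it does not

`ScriptGraph` is a first-order Markov chain over "verb noun" states with
an explicit terminal, so sequence lengths vary realistically.  Rendering
uses one deterministic template ("verb the noun") with noise operating
on slots: synonym selection with per-set probabilities, pronominalization
(each distinct noun gets one pronoun from a fixed inventory, so lexicon
lookup can invert it), object ellipsis (only for verbs whose object is
unique in the graph, so a default-object entry can restore it), and
whole-event skipping.  `make_lexicon` returns the lexicon that exactly
inverts this noise.

This emulates the *structure* of the real preprocessing problem, not its
hardness: real pronouns are ambiguous and context-resolved, real
synonymy is open-class, real ESDs vary in granularity and syntax.
Passing round-trip tests therefore validates the bookkeeping (order
preservation, idempotence, lexicon application, count arithmetic) and
the estimation statistics, not parser accuracy on natural text.  States
must be lemma fixed points; the generator rejects graphs where rendering
would not be invertible.

Rating tables are drawn from a cumulative-logit model: latent response =
fixed effects (±1 sum-coded factors, pooled z-scored familiarity, raw
presentation position) + independent normal random effects + standard
logistic noise, thresholded into 7 categories.  Logistic noise matches
the analysis model exactly, making recovery tests well-specified.
Generator defaults are the reference study's conditions: 48 subjects,
24 items, 2 × 2 Latin square (condition of item *i* in list *l* is
(*i* + *l*) mod 4), fixed effects at the published final-model
estimates (Sententiality −0.958, Predictability −0.554,
ScriptFamiliarity −0.012, Position −0.021, Sententiality:Predictability
−0.22, Predictability:ScriptFamiliarity −0.206), and five ungrammatical
control trials per subject with a latent shift of −4.  Random-effect
SDs are not published; the defaults (subject intercept 1.0, item
intercept 0.5, subject slopes 0.3, item slopes 0.2 for the two
manipulated factors) are in the range ordinal acceptability studies
typically report, with subjects more variable than items.  Thresholds
default to ±0.5, ±1.5, ±2.5 (symmetric, one logistic unit apart).
Familiarity is simulated as a discretized 1–5 score with item, subject
and residual components; coefficients for familiarity apply to its
pooled z-score, matching the analysis transform.

Factor coding: sentence = −1 / fragment = +1 and predictable = −1 /
unpredictable = +1.  With the published negative coefficients this
yields the reported directions: sentences preferred overall, predictable
utterances preferred, the sentence preference weaker in predictable
contexts, and the predictability contrast growing with familiarity.

## The CLMM estimator

The model is proportional odds on a latent logistic scale,
P(Y ≤ k | u) = logistic(θ_k − x′β − z′u), with crossed by-subject and
by-item random effects, independent (diagonal covariance) with one
variance per term.  No installed package fits this class, so the
estimator is implemented here:

* **Laplace approximation.**  The marginal likelihood integrates the
  random effects around their joint mode.  The ordinal-logistic
  log-likelihood is concave in (θ, β, u) jointly, so the mode is found
  by damped Newton with an analytic gradient and Hessian; steps that
  would break the threshold ordering are rejected in the line search.
* **Profiled outer problem.**  Thresholds and coefficients are profiled
  at the joint penalized mode; the outer L-BFGS-B optimization runs
  over the random-effect log-SDs only, minimizing the penalized
  deviance at the mode plus half the log-determinant of the
  random-effects information block.  This is the scheme generalized
  mixed-model packages use at one quadrature point, and is roughly 15×
  faster than optimizing all parameters against the Laplace objective
  directly (verified to give the same estimates well within a tenth of
  a standard error).
* **Starting values and determinism.**  Thresholds start at the
  marginal cumulative-frequency logits, coefficients at 0, SDs at 0.5;
  log-SDs are bounded in [−4, 3].  All settings are fixed, so a fit is
  a pure function of the data.
* **Standard errors** come from the inverse Schur complement of the
  joint Hessian over the threshold/coefficient block (random effects
  integrated out at their mode), conditioning on the estimated
  variances — the convention mixed-model software reports.
* **Degenerate inputs.**  With no random terms the estimator reduces
  exactly to a plain cumulative-logit fit; the test suite checks this
  reduction against `statsmodels` `OrderedModel` (coefficients, SEs and
  log-likelihood agree to ~1e-5).  Per-category probabilities are
  floored at 1e-12 in logs; non-convergence is reported via a flag,
  never silently.

Likelihood-ratio tests use 2·Δ(Laplace log-likelihood) with df = the
fixed-parameter difference.  Backward selection drops the least
significant droppable term (marginality respected: a term is droppable
only if no retained higher-order interaction contains it) while its LR
p ≥ α (default 0.05), holding the random structure fixed, and returns
the full decision trail.

Missing familiarity (the reference instance lacks scores for 2 of 24
scenarios) is handled by setting the z-scored value to 0 (the z-scale
mean) and carrying an explicit missingness indicator column, keeping
the choice auditable; the z-transform pools all available
subject × scenario observations.

## Problem sizes used in tests and the acceptance script

Property suites use 100 random toy corpora (≤ 8 labels, ≤ 30
sequences) for the language-model oracle and 100 random transition
matrices (≤ 10 states) for the chain argmax check; transition recovery
uses the 3-state graph at n = 2000 ESDs over 10 seeds; CLMM recovery
runs 20 replicates at the full study size (48 × 24) and the null
simulation 40 replicates at 12 × 8 with intercept-only random effects.
These sizes keep each statistical check's expected error an order of
magnitude inside its asserted bound.

## Known limitations

* The rule-based parser is a genre-specific stand-in; accuracy on
  arbitrary natural text is untested and out of scope.  A statistical
  parser can be plugged in through the provider contract.
* Pronoun resolution is lookup, not coreference: one pronoun maps to
  one noun per scenario.
* Random-effect covariances are diagonal; correlated intercept/slope
  structures are not estimable.
* The Laplace approximation is one-point; no adaptive quadrature.
* Corpus-level statistics of the original study (vocabulary sizes
  121/192, bigram inventories 351/672, mean stimulus surprisals
  2.13/2.18 bits) depend on the DeScript corpus and the authors'
  curation lexicons, which are separate artifacts; the package verifies
  its machinery on synthetic ground truth instead and reproduces only
  the closed-form bit↔percent correspondences of those published
  surprisals.
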