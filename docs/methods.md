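# Methods

This note defines the model implemented in `refbias`, the input generator,
the learning rule and its calibration, and the package's known limitations.

## 1. Architecture

The engine is a minimal production-system: four buffers with ordered,
unlabeled slots —

- `V1..V3` — input (the words of the current sentence, or the continuation),
- `WM1..WM5` — working memory (`WM1`=subject, `WM2`=verb, `WM3`=object,
  `WM4`=predicted form token, `WM5`=predicted referent),
- `RT1..RT4` — declarative retrieval (chunk type, form, part of speech,
  meaning),
- `AC1` — external action.

Declarative memory is a lexicon of chunks, one per word, with meaning
`"c-" + form`; the single pronoun chunk is *she* (all referents are female).
Retrieval is exact-match and deterministic (base-level activation is
disabled); an empty or ambiguous match is an error.

Operators are named bundles of **condition prims** (slot comparisons:
equal, unequal, empty, non-empty) and **action prims** (copy slot→slot,
write constant, emit external action). Two semantics matter:

- **Comparisons require filled slots.** `WM1 = WM5` does not hold when both
  are empty. Without this, the subject-name form operator would be eligible
  at the start of every trial.
- **Writes into `RT` form a retrieval request**, resolved immediately against
  the lexicon. The trial loop clears `RT` after a `store-Vk` operator
  consumes a retrieved chunk, which lets the next retrieval be requested.

### Operator selection

Every candidate operator is scored

```
score = Σ_{v ∈ context} strength(v, operator) + ε,   ε ~ Logistic(0, noise_sd)
```

where the context is the multiset of non-empty values of `WM1..WM3` (the
current sentence), keyed by *value*, not slot. Candidates are visited in
descending score; the first whose conditions all hold fires (condition
gating). Exact ties break uniformly at random. If no candidate is eligible,
nothing fires.

### The fixed operator set (14 operators)

| stage | operators |
| --- | --- |
| comprehension | `retrieve-V1..V3`, `store-V1..V3` (the k>1 pairs also require `WM(k−1)` filled, enforcing word order) |
| referent prediction | `predict-subj` (`WM1→WM5`), `predict-obj` (`WM3→WM5`), both gated on `WM3` filled, `WM4`/`WM5` empty |
| form prediction | `predict-subj-name` (gated on `WM1=WM5`), `predict-obj-name` (gated on `WM3=WM5`), `predict-pro` + `retrieve-pro` (retrieve the pronoun chunk, `RT2→WM4`); each form operator ends the prediction with a `read-next` action |
| revision | `correct-re` (`WM4≠V1 → V1→WM4`), `correct-ref` (`WM5≠V2 → V2→WM5`), eligible only while `V3` is empty (i.e. when the continuation pair is in `V`) |

The gating asymmetry is the model's central mechanism: once the subject is
predicted (`WM5=WM1`), `predict-obj-name` can never fire, so the only form
competition on predicted-subject trials is name-of-subject vs pronoun —
while on predicted-object trials the name and pronoun operators compete
freely. This produces a verb-type × form interaction on predicted-object
trials without any verb-form contingency in the input.

### Trial loop

1. **Comprehend** — present `V = (subject, verb, object)`; operators fire
   until `WM1..WM3` hold the sentence.
2. **Predict** — a referent operator sets `WM5`, then a form operator sets
   `WM4` and emits `read-next`.
3. **Observe** — present the continuation as `V1 = surface token` ("she" or
   a name), `V2 = referent name`. The trial is **rewarded** iff
   `WM4 = V1` and `WM5 = V2` (both the referent and its form were right).
   Afterwards the applicable revision operators fire, leaving working memory
   aligned with the actual continuation whether or not reward was issued.

## 2. Learning rule

All learned state is the association store `strength(symbol, operator) ∈
[0, R]`, initially all-zero. After the outcome of a trial, for every context
symbol `v` (non-empty `WM1..WM3` values) and every operator `o` that fired
during comprehension or prediction:

- rewarded: `s(v,o) ← s(v,o) + α (R − s(v,o))`
- unrewarded: `s(v,o) ← s(v,o) + α (failure_target − s(v,o))`, with
  `failure_target = 0`.

Operators that did not fire are never touched; revision operators fire after
the outcome and are never updated. There is no negative reward, no partial
reward, and no temporal discounting. With `failure_target = 0`, each strength
is an exponentially-weighted estimate of `P(reward | o fired)` in contexts
containing `v` — this is what lets asymmetric input settle into stable,
*graded* biases rather than saturating.

A success-only variant (`failure_target=None`: no update at all on
unrewarded trials) is available for comparison. It is not the default
because it provably destroys the target phenomenon: any operator that keeps
being fired-and-rewarded, however rarely, has `R` as its only fixed point, so
all recurrently used (context, operator) pairs saturate and every measured
rate drifts to the majority response (in simulation: object-biased verbs end
at 0.82 *subject* predictions and pronoun rates exceed 0.94 everywhere).

## 3. Input generator

Each of the 10,000 training items is sampled independently:

1. verb uniform from the 10-verb table — 5 subject-biased (*repulsed* .76,
   *angered* .80, *fascinated* .75, *disappointed* .78, *apologized* .70),
   3 object-biased (*comforted* .25, *feared* .30, *congratulated* .20),
   2 neutral (*interrupted* .50, *filmed* .52); the numbers are
   `P(continuation rementions the subject)`. Only *repulsed*'s value is a
   published norm; the others are category-consistent placeholders and fully
   configurable.
2. two distinct names uniform without replacement from 40 synthetic
   CV-syllable female names (e.g. *melira*);
3. continuation role ~ Bernoulli(verb's p_subject); form: pronoun with
   probability 0.75 for subject continuations, name with probability 0.75
   for object continuations. Pronoun continuations present the token *she*
   with the referent's name as meaning; name continuations repeat the name.

The 25 novel evaluation sentences (no continuations): 5 fully novel
(novel verb + novel names), 5 novel verb + familiar names, 15 familiar verb
(5 per category) + novel names. Novel tokens are generated with the same
scheme and checked disjoint from the trained inventories.

## 4. Experiment and aggregation

A cohort is `n_runs` independent learners (default 100), each a fresh
all-zero model with its own derived seed, trained on the *same* corpus in a
run-specific random order (a per-run resampled corpus is available via
`fresh_corpus_per_run`). Curves bin presentations into blocks of 100 and
report, per verb category: `p_subject_prediction`,
`p_pronoun_given_predicted_subject`, `p_pronoun_given_predicted_object` —
always pooled within run first and then averaged across runs (each run is one
simulated participant). The asymptotic form quantities are the same grand
averages over each run's final 2,000 presentations. Novel-item evaluation
freezes learning (the store is checked bit-identical afterwards), extends the
lexicon with the unseen tokens (which carry zero associations), and presents
each sentence `n_reps` times per run.

## 5. Parameters and calibration

| parameter | default | role |
| --- | --- | --- |
| `alpha` | 0.25 | learning rate of the delta rule |
| `reward` | 1.0 | reward magnitude, upper bound of strengths |
| `noise_sd` | 0.1 | scale of the logistic selection noise |
| `failure_target` | 0.0 | outcome value propagated on unrewarded trials |

`alpha` and `noise_sd` are free parameters with no published values; the
asymptotic form rates depend on them, so they were calibrated once against
the target quantities (≈40% / ≈10% pronoun predictions on predicted-object
trials for subject-/object-biased verbs) on development seeds, then frozen.
The calibrated regime is a genuine trade-off:

- **Fast learning, low noise (the defaults).** Verb-specific strengths
  differentiate before the corpus-wide subject/pronoun majority can dominate;
  asymptotes, ordering, ceilings, and the novel-item pattern all match. The
  cost: learning is measurable within the first 100 presentations, so the
  first curve bin is *not* at chance (subject-biased ≈ 0.65) even though the
  naive model is exactly at chance by construction.
- **Slow learning (e.g. alpha = 0.02).** The first bin stays at chance, but
  the early-established general pronoun preference then poisons the measured
  success rate of object predictions (a pronoun predicted for an expected
  object is usually wrong) before verb-specific evidence accumulates, and all
  verb types drift to a global subject+pronoun attractor.

Two further quantitative notes at the defaults (25-run smoke cohort):
the object-biased final subject-prediction rate levels off near 0.45 rather
than below 0.25 — the general subject bias carried by the names (the very
mechanism that produces novel-verb generalization) adds a subject-ward term
to every selection — and the fully-novel subject rate is within sampling
error of chance (0.41–0.50 across cohorts). The corresponding tests assert
the stricter values and fail honestly where these apply.

## 6. Numerical and reproducibility choices

- Pure-Python `random.Random` streams everywhere; a model owns one stream
  (selection noise + tie-breaks), a run derives its model seed and its
  frozen-evaluation seed from the run seed, a cohort derives pairwise
  distinct run seeds (< 2³¹) from the master seed. Identical seeds give
  bit-identical trial logs and stores.
- Logistic noise via inverse-CDF with a guard against `u ∈ {0, 1}`.
- Strengths live in plain dict-of-dicts; the delta rule keeps them in
  `[0, R]` by construction (property-tested).
- Aggregation uses pandas; figures use the Agg backend.

## 7. Limitations and non-goals

- No bottom-up operator learning, base-level activation/decay, latency or
  reaction-time modeling — the operator set is fixed and hand-specified.
- Single pronoun, female referents only; no gender/number competition, no
  connectives, no multi-sentence discourse.
- The generator's non-published verb probabilities are placeholders; results
  by individual verb (as opposed to category) should not be over-read.
- `alpha`/`noise_sd` are calibrated, not fitted to human data; conclusions
  should rest on the qualitative pattern (ordering, ceilings, one-sided
  interaction, novel-item gradient), which is robust across the calibrated
  neighborhood, not on exact percentages.
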