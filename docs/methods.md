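# Methods

This note documents the models and procedures implemented in
`ftrclassify`, the defaults that matter, and what the synthetic-data
tests do and do not establish.

## Corpus handling and segmentation

Posts carry an id, author, text, posting timestamp and a condition
label (`mental_health` / `control` / `unlabeled`). Timestamps parse as
ISO-8601 or epoch seconds; timezone-naive values are treated as UTC.
Because the horizon statistic works at day resolution, the timezone
convention only needs to be consistent — any error is bounded by one
day. Text is NFC-normalized before segmentation.

Segmentation is rule-based: split at runs of terminal punctuation
(`.?!`) unless the preceding token is a known abbreviation or a single
initial. This is deterministic, requires no model download, and the
backend used is logged per corpus. It does not handle unpunctuated
run-on text or sentence boundaries inside quotations; for corpora
where that matters, segment externally and feed sentences directly.
Posts that yield no sentences (whitespace/emoji-only) are dropped with
a logged count.

## Time-reference stage

A single multinomial model over {FTR, PTR, OTHER}. OTHER is a
residual, not "present tense": statements of fact, ability, or present
reference all land there, so the contrast FTR-vs-rest must not be read
as future-vs-present.

The architecture is a bag-of-n-grams (1–2) count vectorizer feeding an
L2-regularized multinomial logistic regression (`C = 1`, lbfgs,
tolerance 1e-8). The choice is deliberate: scalar class probabilities
(the downstream contract), convex training to tolerance, bit-level
reproducibility under a fixed split seed, and no GPU or pretrained
weights. `p_ftr` and `p_ptr` are the softmax masses of the two
classes; binary flags split at `p ≥ 0.5` (the boundary itself counts
as positive). No class reweighting is applied by default;
`class_weight="balanced"` is available. Training uses a seeded 80/20
split and reports held-out confusion metrics per label, with
zero-denominator ratios reported as absent rather than zero. Models
persist as a single JSON file (vocabulary + weights), so artifacts are
inspectable and diffable.

## FTR-type stage

A deterministic closed-vocabulary classifier over future-referring
sentences. Categories: two tense (future, present-residual) and the
modal set — verbal low certainty (*could, may, might, should*), other
low certainty (*possibly, probably, potentially, possible,
possibility, perhaps, maybe, likely, I think/guess/suppose/reckon*),
other high certainty (*definitely, certainly, absolutely, certain,
surely, for sure, undoubtedly, ...*), deontic (*must, have to, need to*
and inflections), bouletic (*hope, want, wish* and inflections,
*would like to*), irrealis (*if, would*). The `verbal_high_certainty`
slot exists (it appears in downstream analyses as a variable) but
ships with an **empty** keyword list: no defensible trigger set exists
for it, so it never fires unless configured. The full lexicon is
versioned and overridable from a YAML/JSON config.

Rules, in order:

1. **Negation exclusion.** Any negator token (*not, never, n't, ...*)
   excludes the sentence: negation flips modal polarity (*"Rain
   tomorrow is not possible"* expresses high certainty through a
   low-certainty keyword), so keyword matching cannot classify it.
   Scope is not analysed — presence anywhere in the sentence excludes,
   which is deliberately conservative.
2. **Mixed-modal exclusion.** Both a high- and a low-certainty keyword
   present (*"There is definitely a possibility of rain"*): no
   principled class criterion exists.
3. **Dominance.** Any modal keyword sets its flag(s) and zeroes both
   tense flags: *"It will possibly rain"* and *"It will rain"* express
   different semantics and must not share a label.
4. **Tense.** Otherwise a future-tense keyword (*will, shall,
   be going to*) sets `future_tense`; failing everything, the sentence
   is residual `present_tense`.

Flags are dichotomous and may co-occur across modal categories;
low-certainty concord (*"It could probably rain"*) is the documented
two-flag case. Tokenization lowercases, strips punctuation and expands
contractions (*won't* → *will not*, *I'll* → *I will*, *'d* →
*would*) so the underlying modal or negator is visible; *'d* is read
as *would* because the conditional reading dominates in
future-referring text. Multi-word keys match as contiguous token
sequences on token boundaries (*mayo* never matches *may*).

Group proportions per type are the per-flag means renormalised to sum
to one.

## Temporal horizons

A from-scratch rule inventory (deterministic regular expressions):
deictic words (*today, tomorrow, yesterday, tonight*), *next/last* +
unit or weekday, *this* + weekday (nearest forward occurrence, 0–6
days; *next* is strictly forward 1–7; *last* strictly backward), *in N
units* / *N units ago* with digit or number-word N, month-name dates
with optional year, numeric dates, and ISO dates. Overlaps resolve
leftmost-longest; unparseable candidates (impossible calendar dates)
are skipped with a log entry. Numeric dates such as `10-06-2020` parse
**day-first** by default, with a `dayfirst=False` switch; month/year
offsets use calendar arithmetic (`relativedelta`), so *next year*
means same month/day, year + 1.

Deltas are computed on calendar dates (posting time truncated), so
*tomorrow* is exactly +1 day regardless of posting hour. `H(s)` is the
arithmetic mean of a sentence's deltas; `t_ref` is 0 for future
(H > 0) and 1 for past. Records with no expressions are dropped.
Sub-day expressions resolve to the posting date itself, anchored at
midnight for the raw-clock check: a record whose references all land
on the posting day with a negative raw clock delta (e.g. *tonight*
posted at 16:00 → −16 h) is a midnight-anchoring artifact and is
dropped as `same_day_past`. Surviving H = 0 records (sub-day future
reference) are excluded only from the log-scale transform `ln|H|`,
with a logged count; applying the single-record log transform to an
H = 0 record is an error by contract.

Durations, recurrences (*every Monday*) and season/decade granularity
are out of scope.

## Discounting

Subjective value is hyperbolic, `V = A/(1 + kD)`, with `k` per day.
The battery fully crosses 10 smaller-sooner amounts (GBP 50–95, step
5) with 11 delays of the fixed GBP 100 larger-later reward. The delay
labels map to days as: later today = 0, tomorrow = 1, one week = 7,
one month = 30, two months = 61, three months = 91, six months = 182,
one year = 365, two years = 730, five years = 1825, ten years = 3650 —
the standard convention for these labels, configurable.

The candidate grid contains every indifference rate
`k_i = (LLR/SSR − 1)/D` over nonzero-delay items (100 candidates
before collisions). Zero-delay items have no finite indifference rate
and are excluded from the grid, but they stay in match counting, where
every candidate predicts the delayed (strictly larger) reward. The
decision rule is strict: `LLR/(1 + kD) > SSR` predicts the delayed
choice; exact equality predicts the immediate one — a deterministic
tie rule on a measure-zero boundary. The participant's `k` is the
candidate maximising matches with their empirical choices; when
several candidates tie, the estimate is the geometric mean of the
**full** tied set (a singleton is returned exactly — a log/exp
round-trip would perturb boundary predictions). `match_prop` and its
complement `stochasticity` are recorded alongside `ln k`. The
attention check fails a participant who ever chooses the smaller of
two same-day rewards; absent check items pass with a warning.

## DASS-21, sliders and mediation

Subscale scores are twice the sum of the dimension's seven 0–3 items,
hence 0–42; missing or out-of-range items raise with the offending
item numbers. The mediator M is the participant's mean 0–100 slider
rating over the 11 delays.

The mediation system is two least-squares equations (predictors
entered raw; a `standardize` flag z-scores everything). Uncertainty is
nonparametric case-resampling bootstrap, default 4000 draws — chosen
to mirror a 4-chain × 1000-kept-iteration sampler run; with flat
priors the posterior is likelihood-dominated at these sample sizes and
the two approaches agree closely, which is why no sampler dependency
is shipped. Per draw, both equations are refit and indirect (`αβ`),
direct (`τ′`) and total effects computed within the draw, so
`total = indirect + direct` holds exactly draw-wise and the summary of
the total is the summary of sums. Summaries are draw means with
central 90% and 95% quantile intervals (90% alongside 95% because
one-tailed directional decisions conventionally use the narrower
band); the one-tailed `pp` is the fraction of draws with the
hypothesised sign, a per-effect configuration input. R² per equation
is draw-wise explained variance over explained-plus-empirical-residual
variance (the residual term is empirical rather than model-based; at
these n the difference is negligible).

Degenerate inputs error out: fewer than 10 complete cases, constant
columns, or a rank-deficient design (checked by SVD of the full
design matrix). Note one analytic subtlety: a simulated dataset with
*zero mediator noise* makes M an exact linear combination of the
predictors and the outcome equation unidentified — such input raises
the collinearity error rather than returning arbitrary coefficients.

## Synthetic generators

All generators are pure functions of their arguments and a seed.

- **Template sentences** cover every default-firable FTR-type flag
  (future/present tense, both low-certainty flags, high certainty,
  deontic, bouletic, irrealis), modal concord, both exclusion cases,
  PTR and OTHER. Templates are rendered from the shipped lexicon, so
  FTR-type classification of the corpus is a closure test: any
  disagreement is a classifier bug. `verbal_high_certainty` cannot be
  templated under the default (empty) lexicon. Distractor tokens
  absent from the lexicon are mixed in so the trainable stage cannot
  succeed by memorising type keywords. The generated text is
  deliberately schematic — short single-clause sentences with overt
  temporal adverbials. Real social-media text has typos, slang,
  sarcasm, multi-clause structure and covert time reference; passing
  on templates shows the machinery is correct, not that real-corpus
  accuracy will match.
- **Timed posts** embed expressions at requested integer day offsets
  (*tomorrow*, *in N days*, *N days ago*), so horizon recovery is
  exact by date arithmetic.
- **Simulated choosers** answer the battery deterministically from a
  planted `k`, then flip each response independently with probability
  ε. At ε = 0.1 the measured stochasticity sits just at 0.10 — the
  argmax over ~100 candidates can re-absorb only the rare flip that
  lands next to the participant's own boundary.
- **Simulated participants** draw anxiety/depression from a bivariate
  normal (defaults: means 4.4 and 6.9, SDs 7.1 and 9.7, ρ = 0.5)
  discretized and clipped to the 0–42 scale range — discretization
  attenuates the requested ρ by a percent or two — then generate M and
  Y from the planted equations applied to the *observed* scores plus
  Gaussian noise (defaults σ₁ = 14, σ₂ = 2, giving R² near 0.2 and
  0.1). Default planted paths (α₁ = 1.0, β = 0.04, τ′₁ = 0.04, zero
  depression paths; intercepts 28.25 and −4.41) put the anxiety
  indirect effect at 0.04 and the total at 0.08 on the ln(k) scale —
  survey-realistic magnitudes for this design.

## Problem sizes

The shipped tests and the acceptance script use: 30 sentences per
template category (390 total) for classifier training; 200 simulated
choosers per noise condition; mediation recovery at n = 5000 and
interval calibration with 100–200 replicates of n = 202 participants
at 400 bootstrap draws. These sizes give stable statistics while
keeping the whole suite fast on a single CPU.

## Known limitations

- English only; the lexicon is a documented, versioned superset of the
  canonical category exemplars, not a recovered original list.
- Negation handling is presence-based exclusion, not scope analysis.
- The temporal tagger is a compact rule set, not a full TIMEX-style
  system; coverage beyond the documented inventory is absent rather
  than approximate.
- The time-reference model is only as good as its annotations; the
  synthetic corpus demonstrates the training/evaluation machinery, not
  real-world accuracy.
- The mediation bootstrap assumes independent participants; clustered
  or longitudinal designs need a different resampling scheme.
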