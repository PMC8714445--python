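# Methods

## Problem and model

`comd` recognizes symptom phrases in free-text medical consultation
sentences using only a dictionary of standard symptom phrases as training
signal. The premise is compositionality: a symptom phrase is an arrangement
of *components* (tokenizer words, or single characters in character mode),
and both the arrangement and the mutual compatibility of components can be
learned from the dictionary alone.

Two models are estimated from the dictionary.

**Position model.** Every dictionary phrase is annotated automatically:
one-component phrases are Single (S), otherwise the first component is
Begin (B), the last is End (E), and interiors are Intermediate (I). For
each component the counts over positions are modelled as a multinomial
(n, π_B, π_I, π_E, π_S) with maximum-likelihood estimates counts/n. No
smoothing is applied: a component never observed at a position has
probability exactly 0 there and may not take that label during
recognition. This is deliberate — the zero pattern is what restricts the
candidate label sets and makes inference tractable; with per-type counting
over a deduplicated dictionary the estimates are exact rationals.

**Interaction model.** Components are embedded with a skip-gram model
(stochastic gradient descent with negative sampling) trained on the
dictionary's component sequences, optionally augmented with unlabeled
corpus sentences. Rather than using raw vector distance — which in high
dimension conflates unrelated regions of the semantic space — interaction
is measured through *neighbourhood distributions*: the embedding is
partitioned into C clusters by k-means, each component is mapped to the
distribution of its k nearest neighbours' (cosine distance, query
excluded) cluster memberships, and two components interact with score

    I(w_a, w_b) = exp(−ν · JSD(P_a ‖ P_b) + γ),

where JSD is the Jensen–Shannon divergence with natural logarithm (bounded
by ln 2). With γ = 0 the score lies in (exp(−ν ln 2), 1].

**Recognition.** A sentence is split on a configurable terminator set,
tokenized, and filtered (very common words, words with corpus count below
a floor, and words unknown to both models are masked out). Each kept token
receives the label set {X ∈ {B,I,E,S} : π_X > 0} ∪ {O}; any token with
nonzero π_I *or* an embedding may additionally take I, which is how
colloquial fillers can sit inside a span and be judged rather than
silently break it. A candidate segmentation assigns non-O labels forming
non-overlapping subsequences — S singletons or B…E spans — and is scored by

    score = Σ_i  π_S(w)           for singletons
          | Σ_i  π_B(first)·π_E(last)  for spans.

Consecutive B labels collapse to the leftmost start and consecutive E
labels to the rightmost end. The best segmentation is selected, then each
span's interior I components are kept only if their *utility* — the mean
interaction with the two boundary components — reaches the threshold δ.
Kept components are concatenated into the extracted phrase, which is how
disjoint colloquial mentions reassemble into standard-form phrases.

## Selection as an exact dynamic program

Because the boundary score is additive over segments, and every raw
labeling normalizes to a set of non-overlapping segments (s, e) whose
start can be B and whose end can be E, the argmax is a weighted
interval-scheduling problem. `extract()` solves it exactly by memoized
recursion over token positions at any sentence length, with a total
tie-break order: higher score, then larger token coverage, then leftmost
span starts, then leftmost ends. Raw labelings differing only in interior
I-versus-O (or in collapsed B/E runs) normalize to the same segments; the
coverage tie-break always favours the maximal-interior variant, so the
implementation assigns I to every I-eligible interior and lets the utility
filter decide. An exhaustive enumerator over segment sets (plus an
optional left-to-right beam) is kept for inspection; a beam at least as
wide as the number of valid segmentations reproduces the exhaustive list.
The test suite additionally checks the dynamic program against a fully
independent brute-force enumeration over the raw label product space.

Degenerate cases: an empty sentence yields no extractions; a sentence
whose tokens only admit O yields the empty segmentation (q = 0). Because
permissible boundary labels require strictly positive probabilities, every
candidate segment has positive weight and the optimum is the maximum-weight
compatible segment set. An optional per-segment score floor
(`min_segment_score`, default 0) can prune weak segments; the default
preserves the plain scoring formula.

## Modes

* `full` — position model + utility filtering (the method proper).
* `no-interaction` — every interior I component inside the chosen
  boundaries is kept (equivalently δ = 0 when all interiors are in the
  embedding vocabulary).
* `no-position` — no boundary model: kept in-vocabulary tokens are grouped
  by pairwise interaction ≥ δ (connected components); groups of two or
  more are emitted in sentence order. The grouping rule is our
  interpretation of "components that interact with each other"; singletons
  are not emitted because a single component carries no interaction
  evidence.

Interior tokens labeled I but absent from the interaction vocabulary have
undefined utility and are discarded in `full` mode (matching the treatment
of out-of-vocabulary words generally: ignored, never guessed).

## Parameters

| parameter | default | meaning / rationale |
|---|---|---|
| d | 500 | embedding dimension; sized for a dictionary of ~10⁵–10⁶ phrases, desk-scale runs use 32 |
| window | 5 | skip-gram context half-width (dynamic shrink per token) |
| ν | 7.5 | decay of interaction with JSD; at ν=7.5 a maximally divergent pair scores ≈ 0.0055 |
| γ | 0 | offset; positive values are capped so scores stay ≤ 1 |
| C | 500 | k-means clusters; `InteractionParams.scaled` shrinks to ⌈V/4⌉ for small vocabularies |
| k | 2000 | neighbourhood size; scaled to V−1 for small vocabularies, but see below |
| δ | 0.2 | utility threshold for interior components |
| ε | 0.6–1.0 | IoU threshold at evaluation time |
| common ceiling | top 0.1% document frequency | common-word filter |
| rare floor | count < 2 | rare-word filter |

The scale-down rule k = min(2000, V−1) is a safe upper bound but becomes
uninformative at very small vocabularies (k ≈ V makes every neighbourhood
the whole vocabulary and all scores ≈ 1), so the synthetic benchmarks pass
an explicit k ≈ community size (k = 10 at V ≈ 54) and C = 6.

## Numerical choices

* Natural logarithm throughout KL/JSD; the base is absorbable into ν but
  must be fixed for reproducibility.
* KL returns `inf` on unsupported mass; inside JSD the mixture dominates
  both arguments, so JSD is always finite (clamped to [0, ln 2] against
  float noise).
* Skip-gram training is single-threaded numpy with one seeded generator:
  identical seeds give bit-identical vectors. Sigmoid inputs are clipped
  at ±30.
* k-means uses 10 restarts with a fixed seed; nearest neighbours exclude
  the query by index (not by distance), so duplicate vectors cannot vote
  for themselves.
* Greedy evaluation matching sorts pairs by (−IoU, extraction index, gold
  index): order-invariant with deterministic ties. Thresholds compare with
  ≥ so that ε = 1.0 accepts exact matches. Zero-denominator rates are
  reported as 0 with a logged warning.
* Token spans are 0-based and half-open everywhere.

## The synthetic study

The generator (`comd.simulate`) emulates the statistical structure the
method assumes, with opaque ASCII tokens so no Chinese segmentation is
needed. Components are partitioned into topical groups, each with
begin/interior/end/single role vocabularies; phrases are drawn as S or
B–I\*–E compositions, sampling each slot from the matching role
distribution within one group. Corpus sentences embed 1–2 phrases — by
default *recombined* fresh compositions that are position-legal but
typically absent from the dictionary, exercising generalization beyond
lookup — with filler tokens (a disjoint vocabulary with its own
co-occurrence context from pure-filler sentences) inserted inside and
around the spans.

Because slots are sampled by role, a component's empirical BIES
frequencies converge to the induced conditional P(position | component),
which the generator returns in closed form as the recoverable ground
truth. Default study conditions: 3 groups × (4 begin + 4 interior + 4 end
+ 2 single) components, 12 fillers, role purity 1.0, phrase-length
distribution (0.25, 0.30, 0.25, 0.15, 0.05) over lengths 1–5, 300 phrases,
100 sentences, filler rate 0.3, 20% pure-filler sentences. Desk-scale
models: d = 32, window 3, 12 epochs, C = 6, k = 10, ν = 7.5, γ = 0,
δ = 0.2. Parameter-recovery runs use 10,000 phrases and role purity 0.8
(so boundary components genuinely mix roles); paired ablations use 20
seeds.

What passing these benchmarks does *not* show: the generator's groups are
cleanly separable and its fillers are lexically disjoint from symptom
components, whereas real colloquial Chinese mixes function words into
symptom vocabulary, has tokenizer errors, idioms that refuse segmentation,
and out-of-vocabulary mentions — the known failure modes of the method.
Absolute synthetic scores (micro-F1 near 100 in full mode) therefore say
nothing about absolute performance on real consultation data; only the
relative structure (full ≥ no-interaction ≫ no-position, degradation with
rising ε) is meaningful at desk scale.

The embedding-interaction sanity check samples only components that occur
in multi-component phrases: single-role components never share a skip-gram
window with anything, so their vectors are uninformative and they are not
"co-trained" in any sense.

## Known limitations

* Phrases that the tokenizer cannot split (idioms) are invisible to
  word-granularity composition; character mode is the fallback.
* Utility compares interiors against the two boundary components only, per
  the definition — not against adjacent kept components.
* The exhaustive enumerator is exponential in the worst case and intended
  for short sentences and testing; `extract()` itself is polynomial.
* Whether several disjoint symptom spans in one sentence compete or
  coexist is resolved in favour of coexistence (q > 1), which evaluation
  against multi-phrase gold records implies.
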