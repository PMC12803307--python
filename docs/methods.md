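# Methods

## Problem and scope

ICD-based phenotype definitions — curated lists of diagnosis codes that
stand in for a clinical phenotype in EHR research — are labour-intensive
to build and easy to leave incomplete, which under-ascertains cohorts.
`icdsem` implements the retrieval-side alternative: embed the free-text
phenotype description and every ICD code description into a shared vector
space, rank the whole catalogue by cosine similarity, fuse rankings from
several encoders, and hand a short, blinded, PPV-truncated list to an
expert for review.  Reviewer-confirmed codes beyond the original
reference set then feed a cohort-size accounting step.

## Retrieval model

Each encoder backend maps a batch of texts to vectors; rows are
L2-normalised, so the score of a code for a query is the cosine of their
embeddings.  The *full* catalogue ordering is materialised (scores kept)
because score-level fusion needs all models' scores over one universe.
Ties are broken lexicographically by (vocabulary, code); together with a
stable sort this makes every ranking a deterministic function of
(scores, keys), invariant to catalogue row order.

Vocabulary is part of the code key: `("ICD9CM", "250.0")` never collides
with an ICD-10-CM code, and code strings are kept verbatim (dots
included) because silent normalisation creates cross-vocabulary
collisions.

## Rank fusion

Eight unsupervised methods over rankings that share one universe:

| method | fused statistic | notes |
|---|---|---|
| zsum | Σ z-scores | population SD; constant vectors give zeros |
| combsum | Σ min–max-normalised scores | constant vectors map to 0.5 |
| combmnz | combsum × #members ranking item ≤ `hit_depth` | depth defaults to 100 (the evaluation depth); full-universe rankings make the classical "retrieved" notion vacuous without one |
| fisher | −2 Σ ln(rank/N) | top item gets p = 1/N, never 0 |
| mean_rank / median_rank | −mean / −median of ranks | ascending in aggregate rank |
| rrf | Σ 1/(60 + rank) | reciprocal rank fusion |
| borda | Σ (N − rank) | |

All methods are member-order invariant and reduce to the identity for a
single member; zsum/combsum are invariant to positive affine rescaling of
any member's scores, the rank-based methods to any strictly monotone
transform.  These invariants, plus equivalence to straight-line oracle
recomputation on small universes, are the correctness argument — there is
no ground-truth fusion output to compare against.

## Evaluation

R@k = |relevant ∩ top-k| / |relevant| is the primary measure (a missed
code is a missed patient); AP@k = Σ P@i·rel(i) / min(|relevant|, k)
rewards early placement.  The AP denominator convention makes AP@k able
to reach 1.0 exactly when R@k can; it is recorded in benchmark metadata
since other conventions (|relevant|, hits-only) exist.  Benchmarks use
k = 100, exclude *trivial* definitions (≤ 10 codes after restriction to
the catalogue — their retrieval is dominated by lexical overlap) and
definitions whose restricted set is empty, and summarise with the median
across phenotypes because reference-set sizes are strongly right-skewed.
Model agreement uses Jaccard overlap of top-k sets, restricted to the
reference (ground-truth mode) or excluding it (candidate mode); an empty
union is reported as undefined and excluded from medians rather than
coerced to 0 or 1, either of which would bias the summary.  The model
distance matrix is 1 − mean(J_ground, J_candidate).

## Expert review and hierarchy

Each producer's ranking is truncated at its own PPV cutoff — the largest
rank ≤ k with running precision ≥ the threshold (default 0.5); the
"largest qualifying rank" convention is monotone in the threshold and
keeps the whole list when PPV never dips below it.  Truncations are
pooled, the reference set is added back, and the deduplicated list is
shuffled with a recorded seed; the exported sheet carries no scores or
provenance (blinding), which live in a separate keyed file.  Labels:
2 → strict set, {1,2} → extended set; strict ⊆ extended by construction.
A confirmed code is *out-of-hierarchy* when absent from the union of the
phenotype's reference set and all transitive parents' sets — i.e. not
findable by walking parent mappings.  Truncate → union → dedupe ordering
is this package's documented choice; the truncation-before-pooling order
is implied by the workflow, the dedupe position is not.

## Cohort accounting

Per person and ICD set, the count is the number of distinct calendar
days with any code from the set (same-day codes collapse to one event;
dates are taken from the stored timestamp with no time-zone arithmetic —
inputs are assumed pre-localised).  Cohort size at threshold t counts
persons with ≥ t distinct days, overall and within sex/ancestry strata;
stratum levels are taken from the strata table so tables from different
ICD sets stay cell-for-cell comparable, persons missing from the strata
table fall into an "unknown" stratum (totals must equal the sum over
strata), and a zero reference cell yields an undefined fold, never
infinity.  If the expanded set contains the reference set, every defined
fold is ≥ 1 and cohort size is non-increasing in t — both are asserted
property-style in the tests.

## Synthetic world

The generator emulates every input: catalogue, definitions (two-level
hierarchy, 18 category labels), diagnosis records with deliberate
same-day multi-code events, and strata.  Semantic signal is constructed,
not learned: each phenotype owns three disjoint "concept" tokens forming
its query; member descriptions carry them with probability
`signal_rate` (default 0.9), non-members pick up a random phenotype's
token with probability `noise_rate` (default 0.05).  Tokens are random
8-letter strings — a structured scheme (cpt001a, cpt002a, …) would leak
shared character 3-grams across concept groups and break the intended
disjointness under the hashing encoder.

Reference-set sizes are log-normal, calibrated analytically (not fitted
to test outcomes): the trivial-inclusive preset (median 7, σ = 1.0)
gives P(size ≤ 10) = Φ(ln(10/7)) ≈ 0.64, matching the real-world regime
where roughly two-thirds of phenotypes are trivial; the non-trivial
preset (median 28, σ = 0.75, truncated to > 10) has a truncated median
≈ 30, inside the published IQR band 18–59.  Strata default to
sex {F: 0.5, M: 0.5} and ancestry {EUR: 0.6, AFR: 0.25, HIS: 0.15}.

The toy encoder hashes tokens and their character 3-grams into
`dimension` buckets (default 256 — large enough that accidental bucket
collisions stay well below concept-token overlap), accumulates term
frequencies and L2-normalises.  Its optional noise term adds a
pseudo-random unit vector scaled by `noise_sigma`, seeded from the
encoder seed *and the text*, so it is deterministic yet independent
across differently-seeded encoders: three such encoders emulate an
ensemble with partially independent errors.  `noise_sigma = 1.0` (unit
signal-to-noise) is the ensemble fixture's setting; at that level single
encoders reach median R@100 ≈ 0.86 on the default world and Z-sum
fusion recovers ≈ 0.90, reproducing the qualitative ensemble benefit.

What a green synthetic test does *not* establish: real encoder quality
on clinical text, realistic ICD code grammar, correlated reviewer
behaviour, or the headline metric values of any real catalogue — those
require the real 67k-code universe and pretrained models, which are out
of scope here by design.

## Numerical and degenerate-input choices

- Unit-norm tolerance 1e-6 (float32 backends round-trip within it).
- Constant score vectors: z-scores → 0, min–max → 0.5 (both keep
  degenerate members neutral instead of producing NaNs).
- Median: standard interpolated median for even counts.
- Empty restricted reference sets mark a definition unevaluable rather
  than raising; empty relevant sets at metric time are an error (they
  should have been filtered upstream).
- Duplicate catalogue rows collapse to the first occurrence with a
  warning; blank descriptions are dropped and logged.

## Known limitations

- The bundled encoder is a lexical stand-in; semantic (synonym-level)
  retrieval quality claims require a real embedding backend plugged into
  the same contract.
- Single-reviewer audit only; no inter-rater machinery.
- No ICD-9 ↔ ICD-10 crosswalk construction.
- Cohort numbers describe potential ascertainment, not validated case
  counts.
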