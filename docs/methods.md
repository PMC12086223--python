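# Methods

`lexdrift` measures whether two families of clinical vocabulary — a grouped
"base" family (e.g. metastatic-cancer synonyms) and individual "target"
terms (e.g. palliative-care words) — drift together or apart across calendar
years of a note corpus. This note records the model, the synthetic study
design, the numerical choices, and what the tests do and do not establish.

## The statistic

One CBOW word2vec model is trained per year, on that year's documents only.
For year *t* and target term *w*, with base-family vectors
*b₁ … b_k* from that year's model, the package reports three estimators of
the base-target association:

- **centroid** (the headline statistic): cos( (1/k) Σᵢ bᵢ , w )
- **mean**: (1/k) Σᵢ cos(bᵢ, w)
- **precision-weighted**: Σᵢ wᵢ cos(bᵢ, w) / Σᵢ wᵢ with wᵢ = 1/Var̂ᵢ, where
  Var̂ᵢ is the bootstrap variance of cos(bᵢ, w) across replicates. The
  weighting is across base terms (an interpretation choice; weighting across
  replicates would be the alternative reading). Without a bootstrap context
  the estimator degrades to the plain mean and warns.

All three coincide exactly for a singleton base family. Because every
reported quantity is a within-year cosine, and cosines are invariant under a
common orthogonal rotation of a model's vectors, no cross-year alignment
(Procrustes or otherwise) is needed — yearly models live in arbitrary,
mutually rotated spaces without affecting any statistic.

The temporal question is answered by unweighted OLS of the yearly point
estimates on calendar year: slope (cosine units/year), r², and a two-sided
t-test on the slope with n−2 degrees of freedom. Years are centred before
fitting for conditioning; the intercept is reported back on the raw scale.
Conventions: a constant series has slope 0, r² = 0, p = 1 (nothing to
explain); with exactly two years the slope is reported and the p-value is an
explicit gap. Significance labels use p < 0.05, two-sided, with no
multiplicity correction across targets — a reporting convention, not a
recommendation; raw p-values are always emitted. An inverse-CI-width
weighted fit exists but is off by default, since the default procedure fits
point estimates only.

## Uncertainty

Document-level bootstrap with model retraining, percentile-style
(2.5/97.5). Three design points matter, all driven by measured calibration
at desk-scale corpora (2000 notes/year), where the cosine statistic has not
converged in corpus size:

- **Conditional on the training seed.** Replicate *r* resamples with RNG
  seed `boot_seed + r` but trains with the same seed as the full-data
  model. Giving each replicate its own training seed smears the replicate
  distribution with optimiser noise that the (single-seed) point estimate
  does not share, mis-centring the interval.
- **Bayesian reweighting by default** (`mode="bayesian"`). Classical
  with-replacement resampling (`mode="documents"`, also available) leaves
  ~37% of distinct documents out of every replicate; an embedding statistic
  trained on less distinct evidence is biased — measurably downward here,
  by about the CI half-width. Rubin's Bayesian bootstrap keeps every
  document and draws Exp(1) weights (normalised to mean 1) that scale each
  document's learning-rate contribution, preserving the evidence base. It
  also cannot drop a term out of vocabulary, so no replicates are discarded.
- **Recentred percentile intervals** for the document-level modes. Even
  reweighting reduces the effective sample (any weight dispersion does), so
  replicates remain slightly biased low. The interval is the 2.5/97.5
  percentiles of θ*ᵣ − mean(θ*) + θ̂: replicate *deviations* estimate the
  sampling variability; the full-data point estimate anchors the location.
  At large corpus scale the bias vanishes and this coincides with the plain
  percentile interval.

Remaining knobs: `replicate_epochs` can shorten replicate training but
changes the statistic being replicated (visibly mis-centred CIs) — a
documented footgun, not a default. `mode="terms"` resamples the base-term
set over the fixed model, a cheap screen capturing only across-term
dispersion; it keeps raw percentiles (a single replicate collapses the
interval to that replicate's value). In the classical documents mode,
replicates in which a target or the whole base family drops below the
vocabulary floor are discarded with a warning; more than 20% discards is an
error. The point estimate is always the full-data statistic.

## CBOW trainer

No suitable embedding library is part of the runtime environment, so the
package carries a compact CBOW trainer (`_cbow.py`): negative sampling
(unigram^0.75 table), word2vec-style reduced windows (effective window
uniform on 1..window), context averaging, linear learning-rate decay
0.025 → 1e-4, and frequent-word subsampling at threshold 1e-3. Subsampling
is not optional decoration here: the most frequent background token is ~15%
of all tokens, and without subsampling its presence in every context window
collapses all vectors onto a single shared direction (all cosines ≈ 1).
Training is strictly sequential with an internal xorshift64* generator, so
(corpus, hyperparameters, seed) determines the vectors bit-for-bit;
`workers` is accepted for interface compatibility but training always runs
single-threaded. Defaults — dim 100, window 5, min_count 5, epochs 5,
5 negatives — are conventional word2vec settings, chosen as sensible
defaults rather than tuned values. min_count = 5 deliberately equals the
lexicon presence floor so the embedding vocabulary and the lexicon filter
agree about which terms exist.

## Lexicon refinement

Seeds → union of top-50 contextual neighbours of every seed in every yearly
model (union, not intersection, across years — the more inclusive reading),
with (year, rank) provenance → presence filter (term must occur ≥ 5 times in
*every* analysed year, applied to phrase-merged tokens) → finalization.
The human-judgment step of a real analysis is represented declaratively:
an exclusion list (term → mandatory reason string) and, optionally, a
reviewed family-assignment map (term → base/target); survivors outside the
assignment are excluded with a recorded reason. A re-expansion report
(neighbours of each survivor) is generated for audit rather than filtered
automatically. In the synthetic studies the reviewed assignment is exactly
the planted family map, playing the role of the authors' review.

## Preprocessing

Lowercase, punctuation stripped except intra-token hyphens, whitespace
split; no stemming or lemmatization, because the analysis distinguishes
morphological variants of one stem ("palliate" / "palliation" /
"palliative") and stemming would erase the question. Phrases are learned on
the pooled all-years corpus (so a phrase maps to the same token in every
year) by scoring adjacent bigrams with
(count(ab) − min_count) · N / (count(a) · count(b)), N the **total token
count** (the original word2phrase convention; with the distinct-vocabulary
variant of N, genuinely planted phrases score ~2 against the default
threshold of 10 and never merge). Defaults min_count 5, threshold 10, two
passes so three-word units are reachable. Merging is a greedy
left-to-right single pass per table; merged tokens are not re-merged within
a pass.

Cohort subsetting by diagnosis-code list is patient-level: a patient with
any code on the list contributes all of their notes.

## The synthetic corpus

The generator emulates the statistical structure the analysis assumes, not
clinical language:

- **Background**: `vocab_size` = 500 synthetic word types with Zipf(1.1)
  marginal frequencies. The background has topical structure: 20 topics,
  words assigned round-robin across the frequency ranks; each note draws one
  topic and takes each background token from the topic's own renormalized
  Zipf subset with probability 0.5, else from the global distribution. This
  is load-bearing: on an i.i.d. background the shifted-PMI structure CBOW
  factorizes is flat, the learned space is effectively rank-1, and every
  cosine saturates near 1 regardless of planted signal. Differential
  co-occurrence structure is a precondition of the method.
- **Planted families**: 5 base terms (one of them the two-word phrase
  "widely metastatic", inserted as separate words so the phrase learner must
  discover it) and 2 targets. Families are anchored to disjoint topic
  subsets (base-mentioning notes draw from topics 0–2, background-target
  notes from topics 3–5): at rho = 0 the families live in separated contexts
  and their cosine is low; raising rho moves target terms into base-context
  notes and the measured association rises monotonically.
- **Association knob**: a note mentions a base term with probability 0.3;
  a base-mentioning note also gets a target with the year's scheduled rho; a
  non-base note gets a target with probability 0.15. The background rate is
  deliberately not small: it keeps the target family's own-context
  occurrence mass comparable to its base-context mass over rho ∈ [0, 0.6],
  so the cosine responds through the whole range instead of saturating by
  rho ≈ 0.4.
- **Notes**: length ~ Poisson(40), truncated at ≥ 5 background tokens;
  planted terms are spliced in at uniform positions (an optional
  `pair_max_distance` knob can force co-occurring pairs close together for
  window-sensitivity experiments; default is anywhere in the note).
- **Patients and codes**: 500 patients, 30% carrying a flagged diagnosis
  code; base-term notes are assigned to flagged patients at 5:1 enrichment
  odds, so code-based cohort subsetting selects a base-enriched subcorpus.
- Determinism: a single NumPy generator seeded from the config; identical
  configs produce byte-identical JSONL.

What the generator does **not** model: real clinical language, note
templates and copy-paste, negation, section structure, de-identification
artifacts, secular vocabulary growth. Passing recovery tests therefore
demonstrates that the pipeline detects planted co-occurrence trends of
realistic magnitude under Zipfian, topically structured text — not that any
particular real-world corpus has such trends.

## Standing study designs and problem sizes

The reference designs (`lexdrift.study`) use 8 years × 2000 notes/year:
the declining design interpolates rho linearly 0.6 → 0.2 (endpoints exact),
the null design holds rho at 0.4. At these sizes one yearly model trains in
a fraction of a second and a full pipeline run (with a 10-replicate
document bootstrap per year) completes in under a minute on one CPU, which
is what makes multi-seed recovery and null-calibration checks practical as
ordinary tests. The type-I bound used for the null design is deliberately
loose (≤ 15% at nominal 5%): yearly estimates share training noise
structure, so mild miscalibration of the unweighted OLS test is expected
and documented rather than corrected.

## Known limitations

- The bootstrap treats documents as exchangeable within a year; patient-level
  clustering (many notes per patient) is not resampled jointly.
- Precision weights use per-term bootstrap variances with a 1e-12 floor;
  terms observed in fewer than 2 replicates fall back to the floor (i.e.
  near-maximal weight) and a degenerate, effectively zero-variance term can
  dominate the weighted estimate.
- OLS on 8 yearly points has little power against non-monotone change, and
  the t-test ignores estimation error in the yearly points (matching the
  default procedure's convention of fitting point estimates).
- Tie-breaking in neighbour ranking is lexicographic and documented, but
  exact cosine ties are measure-zero in practice.
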