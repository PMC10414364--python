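# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic generator does and does not
emulate, and the numerical/design choices made where the method description
left the design open.

## Problem setting

Adverse events (AEs) — patient harm associated with medical care — are
under-reported through spontaneous reporting systems, and clinical notes
often describe the *components* of an event (hypotension after a procedure,
new hypoxia after a transfusion) without attributing them to a cause. The
pipeline is therefore unsupervised: it never starts from a list of event
terms. It contrasts groups of admissions, keeps the terms that statistically
separate them, and lets a topic model organize the target group's filtered
text into reviewable themes.

Two contrast designs are supported:

* **group contrast** — exposed vs unexposed admissions (e.g. transfused vs
  not), using the classifier-ensemble term selection;
* **temporal contrast** — a recent 12-month period vs the prior 12 months,
  using the classification ∩ frequency-analysis selection, for near-real-time
  surveillance of new or increasing events.

## Preprocessing

* Admissions with patient age < 16, and admissions without notes, are
  excluded (`min_age`, default 16).
* One document per admission: member notes sorted by charttime (stable on
  ties, i.e. input order — the source description is silent on ties) and
  joined with a newline (join string also unstated; newline preserves the
  line-oriented structure the segmenter relies on).
* **Duplicate removal** operates within one admission document only. Units
  are sentences, newline-delimited fragments, and numbered/bulleted list
  items; a period inside a decimal or a known abbreviation ("dr.", "1.23")
  does not end a unit. The duplicate key is the unit text lowercased with
  whitespace runs collapsed; matching is exact (fuzzy matching is out of
  scope). Only the first occurrence is kept (`mode="remove"`); `mode="mark"`
  wraps later occurrences in visible markers for audit. When a removed unit
  ended a line, its line break is retained so that the output re-segments to
  exactly the surviving units (this makes dedup idempotent in the presence of
  list items).
* Normalization removes the PII mask string exactly and lowercases.
  Punctuation, numerals and stop words are retained, so "s/p", "120/80" and
  "dr." are tokens.

## Vectorization

Tokens are whitespace-delimited. Multiword terms (n ≤ `max_n` = 5) are
admitted by an iterative collocation score on adjacent units,

    score(a, b) = (count(ab) − δ) · N / (count(a) · count(b)),

with discount δ = 5, `collocation_min_count` = 5 and
`collocation_threshold` = 10 by default (the upstream description cites a
collocation/skip-gram phrase method without parameters; these are the
conventional phrase-detection defaults and are exposed in config). Counting
is greedy left-to-right longest-match; tokens inside a matched phrase are not
also counted as unigrams unless `count_unigrams_in_phrases=True` (the
alternative reading — both behaviours are flag-gated because the original
counting rule is unstated). Restricting a matrix to a sub-vocabulary
("trimming") preserves the retained columns' counts exactly.

## Term selection

**Ensemble (group contrast).** Logistic regression (L2, C = 1.0, lbfgs) and
multinomial naive Bayes (Laplace α = 1) are fit on raw counts (presence
indicators behind `binary_features`) to label target vs comparison. Selected
terms are the union of: top-`k_lr` terms by positive LR coefficient, top-`k_nb`
terms by the *lowest* NB log-probability ratio
log P(t|comparison) − log P(t|target), and target-exclusive terms with corpus
count ≥ `exclusive_min_count` (default 3). Margins (default 1e-6) require
strictly positive discriminative evidence, so identical corpora select
nothing. Module defaults k = 20 000 reflect surveillance-scale corpora and
cannot be pinned down further without the original restricted data; the
synthetic benchmark uses k = 20 (the number of injected signal terms). Ties
break by (score, then term string) for reproducibility.

**Temporal.** Both models are refit on the full two-period corpus without a
train/test split; the classification set is (top-5000 LR positive
coefficients) ∪ (top-5000 NB lowest log ratios). The frequency set is
(terms in < 10% of period-2 documents, period-2 count ≥ 1, with period-3 raw
corpus count ≥ 1.3 × the period-2 count) ∪ (terms absent from period 2 and
present in period 3, digit-only terms removed — a term is digit-only iff
*every* whitespace token matches `^[0-9]+$`). "Raw frequency" is read
literally as total corpus occurrence count, not normalized for period sizes;
a per-document-normalized variant sits behind `normalize_counts=True`. The
selection is the intersection of the two sets.

`evaluate_classifiers` reports held-out weighted F1 per model from a
stratified split — the diagnostic used to compare LR and NB before refitting.

## Topic model

LDA via batch variational inference (scikit-learn backend), chosen for
seeded determinism; collapsed Gibbs sampling could differ in small numeric
detail. Symmetric priors α = η = 1/K (the source is silent on
hyperparameters; 1/K is the common default that shrinks evenly as K grows),
max 100 passes, E-step mean-change tolerance 1e-4.

* `doc_topic` rows are probabilities summing to 1 (tolerance 1e-6 asserted).
* A document with zero in-vocabulary terms has variational posterior equal to
  the prior: exactly 1/K per topic — 0.022 at K = 45, the floor score.
* `term_topic` is reported in pseudo-count scale (η + expected assignments),
  matching the large integer-like published top-term scores; a normalized
  probability view is provided.
* Because rows are normalized, at most ⌊1/t⌋ topics can score ≥ t in one
  document (33 at the significance threshold t = 0.03).
* K is a human choice; `tune_k` fits a candidate list (default
  25–85 in steps of 10) and reports per-K counts of coherent topics (top
  document score ≥ 0.5), low-score topics (< 0.1) and mean topics per
  document at t = 0.03.

## Review selection and trends

The review set is: top-`top_k` (3) documents per topic (ties by ascending
document id — unstated upstream), the `n_multi` (7) documents with the most
topics ≥ 0.03 in strict count order, and `n_random` (24) documents sampled
uniformly without replacement. The random sample is *not* forced disjoint
from the other routes, and clinical screening of the random sample is out of
scope — an `exclude_ids` list stands in for it. The cross-table counts
documents by (number of topics ≥ 0.03) × (maximum-score band ≥0.5 /
0.2–0.5 / 0.1–0.2); a catch-all <0.1 column is added so the table totals the
corpus size.

Presence criteria are boolean expressions over word atoms (case-insensitive
whole-token match after normalization, `*` = any suffix), code atoms (same
wildcard rule on the admission's code list) and a stay-length predicate.
Quarter = calendar quarter of the admission's first note. The trend model is
unweighted OLS of the quarterly proportion on the quarter index (matching the
"slope, 95% CI, P" reporting style); slopes are per quarter. A binomial GLM
(logit-scale slope) is available via `method="glm"`. A zero-residual perfect
fit has 0/0 t statistics and is mapped to CI width 0 with p = 1 (slope 0) or
p = 0 (otherwise). The Fisher exact test enumerates all tables with the
observed margins in exact rational arithmetic and sums the probabilities not
exceeding the observed table's (two-sided convention, ties included); all
margins must be positive.

## Synthetic generator: what it emulates, and what it does not

The generator emulates the *structural* properties the method is sensitive
to: multiple note types per admission with strictly increasing timestamps;
sentences ending in periods, bare newlines, or numbered-list formats;
within-admission replicated sentences (`duplicate_fraction`, default 0.30);
PII mask tokens in ≥ 10% of notes; abbreviations, misspellings and
punctuation-bearing tokens; a Zipf-weighted background lexicon
(`background_vocab_size`, default 200); group-specific signal terms injected
per document at Bernoulli rates (defaults 0.60 target vs 0.05 comparison, 20
terms — a strong-contrast benchmark); and trend terms whose document
prevalence follows base + slope × quarter over 28 quarters (July 2001–June
2008), with slopes ±0.002–0.005 per quarter, the magnitude of published
surveillance slopes. One under-16 admission and one zero-note admission are
always emitted as cohort-filter fodder. One integer seed drives everything;
output is byte-identical per seed.

It does **not** emulate clinical language (no grammar, no semantics, no
note-type-specific style), fuzzy near-duplicates, cross-admission
boilerplate, code–text correlation beyond a group-defining procedure code, or
realistic vocabulary scale (hundreds of terms, not millions). A green test
therefore establishes algorithmic correctness and statistical calibration on
the stated world — not clinical performance on real notes. Generator quirks
worth knowing: injected tokens are never placed sentence-final (a trailing
period would fuse with the token and split its document frequency between
"term" and "term."), and sentences that would end in an abbreviation-like
token ("no.") are newline-terminated so segmentation is context-free.

## Degenerate inputs and tie-breaking (summary)

* Empty corpus, empty vocabulary, empty term selection, single-group input,
  K < 2, fewer documents than topics, < 3 quarters, empty Fisher margins,
  n_random > corpus size: all raise `ConfigError`/`PipelineError` rather than
  degrade silently.
* All top-k selections and per-topic orderings break ties lexicographically
  (term string or document id), so every selection is reproducible.
* One global seed fans out to per-stage seeds by fixed offsets (synth +0,
  select +101, topics +202, review +303, mod 2^31).

## Known limitations

* Collocation parameters are conventions, not calibrated values; published
  headline counts (41 664 ensemble terms; 9 896 ∪ / 6 122 ∩ temporal terms;
  weighted F1 0.76/0.69) depend on the original restricted clinical corpus
  and are treated as reference points, not reproduction targets.
* The temporal LR/NB were possibly fit on presence indicators rather than
  counts upstream; counts are the default here, with a flag.
* OLS on proportions ignores the binomial variance structure; the GLM flag
  exists precisely because the published fits could have used either.
* Stay-length atoms evaluate against a caller-supplied length of stay; the
  assembled document alone only carries the first note time.
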