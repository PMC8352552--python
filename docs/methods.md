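# Methods

## Corpus model and windowing

A corpus is a list of records (id, title, optional abstract, publication
date). Records with an empty title or unparseable date are dropped and
counted; duplicate ids are fatal. Documents are binned into half-open
calendar intervals [start, end) at yearly, monthly or ISO-8601-week
granularity; ISO numbering is used for weeks because it is the testable
standard and the window label ("2020-W05") is unambiguous. Windows with no
documents are *retained* as empty so that every per-window series stays
calendar-aligned — a changepoint index always names a calendar boundary,
never an index into a compacted list.

Tokens are maximal runs of alphanumeric characters (underscore excluded),
lowercased, with tokens shorter than 2 characters discarded by default.
Stop-word removal uses a frozen copy of the standard NLTK English list
shipped in the package, so tokenization is byte-stable across
environments. Stage defaults differ deliberately: entropy and term-count
statistics keep stop-words (the entropy of the full title vocabulary is
the quantity of interest), while differential weights and embedding
preprocessing remove them (function words would dominate both otherwise).
Every flag is configurable per call.

## Entropy and term series

Within a window, the word distribution is `p(w) = count(w) / Σ count` and
the entropy `S = −Σ p log₂ p` is reported in bits; an empty window has no
distribution and is an error (NaN in series form). A term's time series is
its *frequency per title*: total occurrences in the window divided by the
number of titles, using total counts rather than binary document frequency
because a term recurring within titles should weigh more; binary mode is a
flag. Empty windows contribute 0 and are flagged.

Differential weights contrast a single window B against the *cumulative*
pool of all windows up to and including A: weight(t) = freq-per-title in B
minus freq-per-title in the pool. The cumulative convention treats the
past as one legacy collection, and it is also the comparator convention
used by the novelty strategies. Zero-weight terms and stop-words are
excluded; sign encodes direction (positive = rising, conventionally
rendered black; negative = falling, red).

## Exact Bayesian changepoint posterior

The series x₁..xₙ is segmented by interior boundaries, each a changepoint
independently with prior probability h (constant hazard, default
h = 1/(n+1) so the expected number of changepoints stays below 1 for any
series length). Within a segment, observations are i.i.d. Gaussian with
unknown mean and variance under a normal–inverse-gamma prior
(μ₀ = 0, κ₀ = 1, α₀ = 1, β₀ = 1 by default). The segment marginal
likelihood is the closed-form Student-t evidence

    log m(x_{s:t}) = lnΓ(αₙ) − lnΓ(α₀) + α₀ ln β₀ − αₙ ln βₙ
                     + ½ ln(κ₀/κₙ) − (n_seg/2) ln 2π

with the usual conjugate updates. The posterior probability of each
boundary is computed *exactly* — a sum over all 2^(n−1) segmentations —
via a forward/backward dynamic program over prefix and suffix evidences,
O(n²) segment evaluations, entirely in log space (verified finite and
stable for values up to 10⁶ and series of thousands of points; the suite
exercises n = 2000).

Numerical and interface choices:

- **Standardization** (default on): the series is z-scored before fitting,
  making the default hyperparameters scale-free. A constant series is
  centred only.
- **Calls**: a "changepoint call" is a boundary whose posterior exceeds a
  threshold (default 0.5) *and* is a local maximum; ties in a flat run
  report the earliest boundary. The full probability vector is always
  emitted so calls are reproducible from the report alone.
- **Oracle**: `brute_force_posterior` enumerates all segmentations for
  n ≤ 12 and is the independent ground truth in the tests (agreement to
  1e-9 required; observed ~1e-14). The closed-form segment marginal is
  additionally verified against 2-D numerical quadrature over (μ, σ²) and
  against the sequential product of one-step posterior predictives.
- Batch runs over a vocabulary record per-term failures instead of
  aborting.

The hazard, hyperparameters and standardization flag are configuration,
not constants of the method: published work built on comparable
changepoint packages rarely reports them, so they are surfaced explicitly
with the defaults above.

## Embedding and novelty

Embedding preprocessing lowercases, strips punctuation and removes
stop-words, then space-joins. The built-in reference embedder hashes each
token with a seeded keyed digest into one of `dim` buckets (default 64)
with a pseudo-random sign; it is bit-stable for a fixed (text, dim, seed),
order-insensitive, and gives zero expected inner product for disjoint
vocabularies — enough structure to exercise every downstream path.
External embedders (e.g. 700-d BioSentVec) are supported only through the
vector-TSV adapter: the model is multi-gigabyte and is never bundled, and
every downstream operation consumes only the embedded-corpus container, so
swapping embedders touches no analysis code.

Distances are Euclidean throughout (cosine is available but never the
default). E-min is an exact scan — corpora here are ≤10⁴ documents, so no
approximate index is warranted — with distance ties broken toward the
lexicographically smallest id for determinism.

- **T1** flags documents with E-min strictly above S-rel against the
  comparator (cumulative past by default; previous-window mode
  available). Strictness also governs Y2, for internal consistency.
- **T2** requires the T1 flag plus a denser new neighbourhood:
  distance to the k-th nearest same-window neighbour (self excluded,
  otherwise a zero distance biases the density) below the distance to the
  k-th nearest past document. The k-th-neighbour distance (not an average
  over k) operationalizes "closer to k papers"; the reported ratio is
  old/new so values >1 indicate trends. Per-document ratios plus their
  median are reported; no single aggregation is imposed.
- **Y1** reports per-window centroids and hop lengths *in the full
  embedding space*; the attached 2-D PCA projection is a plotting aid
  only, since projected hop lengths are not faithful. Empty windows are
  skipped with the spanning hop flagged.
- **Y2** reports novel/total counts and the proportion per window against
  the cumulative past.

The shipped thresholds S-rel = 2.3 and S-unrel = 4.0 are the published
calibration for BioSentVec title embeddings (2.3 corresponds to a false
discovery rate for relatedness under 1 %); they are a named preset, not
universal constants, and using them with any other embedder logs a
warning. `calibrate_thresholds` re-derives them from labelled pair
distances (largest distance keeping the empirical FDR below 1 %, placed in
the gap before the next observed distance); with unlabelled distances it
returns quantile candidates flagged as requiring human review and never
auto-applies them.

## Synthetic study conditions

The generators define the controlled conditions under which detection is
demonstrated; their defaults are the study, not tuning knobs.

**Corpus scenario** — 20 yearly windows × 50 titles; titles are
multisets drawn from a 30-word vocabulary with Zipf weights, lengths
Poisson(8) clipped to ≥2 (loosely matching short biomedical titles); the
planted term gains Poisson(2.0) extra occurrences per title from window 10
onward, i.e. a +2.0 step in expected frequency-per-title. Under these
conditions the posterior's maximal boundary sits at the true boundary in
100/100 seeds and a no-step control stays below the 0.5 call threshold in
≥95 % of seeds (sampling noise alone rarely concentrates posterior mass).

**Cloud scenario** — 4 windows × 100 documents in 2 dimensions,
background N(0, I), and from window 2 onward 10 of the 100 documents form
a cluster at offset (10, 0) with unit spread. Dimension 2 is deliberate:
nearest-neighbour distances among a few hundred isotropic background
points then sit well below S-rel = 2.3 (as in a projected embedding
space), so background documents are self-covered while cluster members sit
≈10 away — high-dimensional isotropic noise would put *every* pairwise
distance far above S-rel and make the planted-signal study meaningless.
The background density (100/window) is chosen so background
nearest-neighbour tails stay below S-rel with margin: at 50/window a
background outlier occasionally exceeds 2.3 (≈1 window in 300), at
100/window none does in 300 seeded replicates. Cloud ids encode ground
truth (`w02-nov-003`), so sensitivity/specificity are computed against
labels, not eyeballs.

What the generators do **not** emulate: real title semantics, the
geometry of any trained sentence embedder (anisotropy, hubness, scale),
bursty vocabulary growth, or label noise in relatedness. Passing the
planted-signal studies therefore demonstrates correctness of the
machinery — exact posteriors, exact distances, correct thresholding and
bookkeeping — not end-to-end retrieval quality on real literature, which
depends on the external embedder and corpus.

## CLI and reproducibility

Every subcommand validates its configuration before computing, writes
TSV/JSON reports with any timestamp confined to `manifest.json` (so
reports are byte-identical across reruns), and records the effective
configuration, package version and SHA-256 digests of all inputs in the
manifest. All randomness flows through explicit seeds. Usage errors exit
with code 2, computation errors with code 3.

## Known limitations

- The changepoint model is offline, univariate and Gaussian; abrupt steps
  are its regime, steady drift spreads posterior mass across adjacent
  boundaries. No multivariate or non-Gaussian segment families.
- Frequency-per-title series are heteroscedastic (windows differ in title
  counts); the Gaussian segment model ignores this.
- The O(n²) dynamic program and the exact E-min scan are quadratic;
  fine for the intended scale (decades of yearly windows, ≤10⁴ documents),
  not for streaming use.
- Threshold presets transfer across embedders only after recalibration.
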