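# semshift

Semantic changepoint and novelty detection for time-stamped literature
corpora.

How has the focus of research on a disease shifted over time, and which
papers sit at the cusp of a change? `semshift` answers this for any
collection of document records (id, title, optional abstract, publication
date) with two complementary machines:

1. **Lexical changepoints.** Titles are binned into calendar windows
   (years, ISO weeks, or months) and reduced to a bag of words. For each
   window the package computes word probabilities
   `p(w) = count(w) / Σ count` and the Shannon entropy
   `S = −Σ p(w) log₂ p(w)` of the title vocabulary, and for each term the
   *frequency-per-title* series (occurrences in a window divided by the
   number of titles). An exact offline Bayesian changepoint model is then
   fit to each series: every interior boundary is a changepoint with prior
   probability *h* (constant hazard), segments are i.i.d. Gaussian with a
   normal–inverse-gamma prior, and the posterior probability of a boundary
   is computed by marginalizing over **all** 2^(n−1) segmentations with an
   O(n²) forward–backward dynamic program in log space. A brute-force
   enumerator verifies the DP exactly on small series. Signed differential
   word weights (frequency-per-title in a recent window minus the pooled
   cumulative past) provide the numbers behind "differential word clouds".

2. **Embedding-space novelty.** Documents are mapped to fixed-dimension
   vectors — by an external sentence embedder whose output is loaded from
   a TSV (e.g. 700-d BioSentVec run offline), or by the built-in
   deterministic hashing embedder for self-contained runs — and four
   strategies score novelty by Euclidean distance:
   - **T1**: a document is *potentially novel* when its minimum distance
     E-min to every past document exceeds the relatedness threshold S-rel
     (shipped BioSentVec-calibrated preset: S-rel = 2.3, S-unrel = 4.0);
   - **T2**: a T1-novel document is part of an *emerging trend* when its
     k-th nearest neighbour in its own window is closer than its k-th
     nearest neighbour in the past (default k = 3);
   - **Y1**: the trajectory of per-window mean vectors; long hops between
     consecutive centroids flag directional change;
   - **Y2**: the per-window proportion of T1-novel documents; upward jumps
     flag a growing new area.

Everything is exercisable end-to-end on seeded synthetic corpora with
planted signals, so no external data or model is required.

## Worked example

Generate a synthetic corpus of 8 yearly windows × 30 titles in which the
term *vaccine* gains 2.0 expected occurrences per title from 2004 onward,
then locate the change:

```bash
semshift synth --kind corpus --seed 1 --n-windows 8 --docs-per-window 30 --out-dir demo
```

```python
from semshift import (read_documents, assign_windows, term_counts,
                      term_series, changepoint_posterior, differential_weights)

docs = read_documents("demo/corpus.jsonl").documents
wc = assign_windows(docs, granularity="year")
ts = term_counts(wc)

s = term_series(ts, "vaccine")
print(list(s.values.round(3)))
# [0.1, 0.167, 0.133, 0.067, 1.867, 2.467, 2.0, 1.933]

cp = changepoint_posterior(s.values.to_numpy())
print(cp.boundary_probs.round(4))
# [0.0603 0.0629 0.1154 0.6338 0.1493 0.0637 0.0624]
print(cp.max_boundary(), cp.calls)
# (3, 0.6338016702057638) [3]
```

The frequency series is flat near 0.1 until 2003 and jumps to ≈2 from
2004. The posterior puts probability 0.63 on a boundary between 2003 and
2004 (boundary index 3) — the planted changepoint — and calls exactly that
boundary at the default 0.5 threshold; every other boundary stays near the
hazard-level baseline. The matching differential weights contrast 2006
against the cumulative past up to 2003:

```python
w = differential_weights(wc, "2003", "2006").weights
print(sorted(w.items(), key=lambda kv: -kv[1])[:3])
# [('vaccine', 1.883), ('patients', 0.333), ('children', 0.142)]
```

*vaccine* rises by 1.88 occurrences per title — the planted surge — far
ahead of any background term.

The same pipeline runs from the shell: `semshift ingest | entropy |
termseries | changepoint | diffcloud | embed-ref | novelty-t1 | novelty-t2
| novelty-y1 | novelty-y2 | calibrate | synth`, each writing diff-stable
TSV reports plus a `manifest.json` with the effective configuration and
input digests.

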