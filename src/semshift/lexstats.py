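"""Per-window bag-of-words statistics.

Given a windowed corpus this module builds a window x term count table and
derives from it: per-window word probabilities p(w) = count(w) / total,
Shannon entropy S = -sum p log2 p (the information content of a window's
titles), per-term frequency-per-title time series (the input to changepoint
analysis), and signed differential term weights contrasting a recent window
against the cumulative past (the numbers behind differential word clouds).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .corpus import TokenizerConfig, WindowedCorpus, tokenize
from .stopwords import ENGLISH_STOPWORDS

logger = logging.getLogger(__name__)


@dataclass
class TermStats:
    """Window x term occurrence counts plus the number of titles per window.

    ``counts`` is a windows-by-vocabulary integer DataFrame indexed by
    window label; ``titles_per_window`` counts the documents contributing to
    each window (zero for empty windows).
    """

    counts: pd.DataFrame
    titles_per_window: pd.Series

    def __post_init__(self) -> None:
        if self.counts.columns.duplicated().any():
            raise ValueError("vocabulary contains duplicate terms")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative term count")

    @property
    def vocabulary(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def window_labels(self) -> list[str]:
        return list(self.counts.index)


@dataclass
class TermSeries:
    """Frequency-per-title of one term across windows."""

    term: str
    values: pd.Series
    empty_windows: list[str] = field(default_factory=list)


@dataclass
class DiffWeightTable:
    """Signed frequency-per-title differences, Group B minus Group A.

    Positive weight = term rose (rendered black in the word-cloud
    convention), negative = fell (rendered red).  Zero-weight terms and
    stop-words are excluded.
    """

    weights: dict[str, float]
    year_a: str
    year_b: str

    def to_frame(self) -> pd.DataFrame:
        rows = sorted(self.weights.items(), key=lambda kv: (-abs(kv[1]), kv[0]))
        return pd.DataFrame(
            {
                "term": [t for t, _ in rows],
                "weight": [w for _, w in rows],
                "direction": ["increase" if w > 0 else "decrease" for _, w in rows],
            }
        )


def term_counts(
    wc: WindowedCorpus,
    field_name: str = "title",
    config: TokenizerConfig = TokenizerConfig(),
) -> TermStats:
    """Tokenize the chosen field of every document and tabulate counts per window.

    In abstract mode, documents without an abstract are skipped with a
    warning; if no document has the field at all this is an error.
    """
    if field_name not in ("title", "abstract"):
        raise ValueError(f"field must be 'title' or 'abstract', got {field_name!r}")

    per_window: list[Counter] = [Counter() for _ in wc.windows]
    titles = np.zeros(len(wc.windows), dtype=int)
    n_used = 0
    for doc in wc.documents:
        text = doc.title if field_name == "title" else doc.abstract
        if text is None:
            logger.warning("document %s lacks %s; skipped", doc.doc_id, field_name)
            continue
        w = wc.assignment[doc.doc_id]
        per_window[w].update(tokenize(text, config))
        titles[w] += 1
        n_used += 1
    if n_used == 0:
        raise ValueError(f"no document provides field {field_name!r}")

    vocab = sorted(set().union(*per_window)) if any(per_window) else []
    labels = wc.labels
    table = pd.DataFrame(
        [[c.get(t, 0) for t in vocab] for c in per_window],
        index=pd.Index(labels, name="window"),
        columns=vocab,
        dtype=int,
    )
    return TermStats(counts=table, titles_per_window=pd.Series(titles, index=table.index, name="titles"))


def word_probability(ts: TermStats, window) -> pd.Series:
    """Empirical word distribution of one window: count / total count."""
    row = ts.counts.iloc[window] if isinstance(window, (int, np.integer)) else ts.counts.loc[window]
    total = int(row.sum())
    if total == 0:
        raise ValueError(f"window {window!r} has no tokens; distribution undefined")
    return row / total


def window_entropy(ts: TermStats, window) -> float:
    """Shannon entropy of a window's word distribution, in bits."""
    p = word_probability(ts, window).to_numpy(dtype=float)
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum() + 0.0)  # +0.0 avoids -0.0


def entropy_series(ts: TermStats) -> pd.Series:
    """Entropy per window; NaN for windows with no tokens."""
    out = []
    for label in ts.window_labels:
        try:
            out.append(window_entropy(ts, label))
        except ValueError:
            out.append(np.nan)
    return pd.Series(out, index=ts.counts.index, name="entropy_bits")


def term_series(ts: TermStats, term: str) -> TermSeries:
    """Frequency-per-title series of one term: counts / titles per window.

    Empty windows contribute 0 and are listed in ``empty_windows`` so
    changepoint indices stay calendar-aligned.
    """
    if term not in ts.counts.columns:
        raise KeyError(f"term {term!r} not in vocabulary")
    titles = ts.titles_per_window.to_numpy(dtype=float)
    counts = ts.counts[term].to_numpy(dtype=float)
    values = np.divide(counts, titles, out=np.zeros_like(counts), where=titles > 0)
    empty = [lab for lab, n in ts.titles_per_window.items() if n == 0]
    return TermSeries(term=term, values=pd.Series(values, index=ts.counts.index, name=term), empty_windows=empty)


def top_terms(ts: TermStats, n: int) -> list[str]:
    """The n most frequent terms by total count; ties break lexicographically."""
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = ts.counts.sum(axis=0)
    order = sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))
    return [t for t, _ in order[:n]]


def _group_freq_per_title(titles: list[str], config: TokenizerConfig) -> tuple[Counter, int]:
    c: Counter = Counter()
    for t in titles:
        c.update(tokenize(t, config))
    return c, len(titles)


def differential_weights(
    wc: WindowedCorpus,
    year_a: str,
    year_b: str,
    config: TokenizerConfig | None = None,
) -> DiffWeightTable:
    """Signed term weights contrasting window ``year_b`` with the pooled
    cumulative past up to and including ``year_a``.

    weight(t) = freq_per_title_B(t) - freq_per_title_A(t), with Group A the
    titles of every window at or before ``year_a`` and Group B exactly
    window ``year_b``.  Stop-words are removed before weighting.
    """
    if config is None:
        config = TokenizerConfig(remove_stopwords=True)
    ia = wc.window_by_label(year_a).index
    ib = wc.window_by_label(year_b).index
    if ia >= ib:
        raise ValueError(f"year_a {year_a!r} must strictly precede year_b {year_b!r}")

    titles_a = [d.title for d in wc.documents if wc.assignment[d.doc_id] <= ia]
    titles_b = [d.title for d in wc.documents if wc.assignment[d.doc_id] == ib]
    if not titles_a or not titles_b:
        raise ValueError("both comparison groups must be non-empty")

    ca, na = _group_freq_per_title(titles_a, config)
    cb, nb = _group_freq_per_title(titles_b, config)
    weights: dict[str, float] = {}
    for term in set(ca) | set(cb):
        if term in config.stopword_list:
            continue
        w = cb.get(term, 0) / nb - ca.get(term, 0) / na
        if w != 0.0:
            weights[term] = w
    return DiffWeightTable(weights=weights, year_a=year_a, year_b=year_b)
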