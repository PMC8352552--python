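"""Reading, validation, tokenization and time-windowing of document records.

A corpus here is a set of time-stamped records (id, title, optional
abstract, publication date).  Documents are binned into contiguous calendar
windows (years, ISO weeks, or months); empty windows are retained so that
downstream time series keep calendar-aligned indices.
"""

from __future__ import annotations

import csv
import datetime
import json
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .stopwords import ENGLISH_STOPWORDS

logger = logging.getLogger(__name__)

DEFAULT_FIELD_MAP = {"id": "id", "title": "title", "abstract": "abstract", "date": "date"}

# maximal runs of alphanumeric characters (underscore excluded)
_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


@dataclass(frozen=True)
class Document:
    """One literature record."""

    doc_id: str
    title: str
    abstract: str | None
    date: datetime.date

    def __post_init__(self) -> None:
        if not self.doc_id:
            raise ValueError("doc_id must be non-empty")
        if not self.title.strip():
            raise ValueError(f"document {self.doc_id!r}: title empty after trim")


@dataclass(frozen=True)
class TimeWindow:
    """Half-open calendar interval [start_date, end_date)."""

    label: str
    index: int
    start_date: datetime.date
    end_date: datetime.date

    def contains(self, d: datetime.date) -> bool:
        return self.start_date <= d < self.end_date


@dataclass(frozen=True)
class TokenizerConfig:
    lowercase: bool = True
    strip_punctuation: bool = True
    remove_stopwords: bool = False
    stopword_list: frozenset[str] = ENGLISH_STOPWORDS
    min_token_chars: int = 2

    def __post_init__(self) -> None:
        if self.min_token_chars < 1:
            raise ValueError("min_token_chars must be >= 1")
        if self.remove_stopwords and not self.stopword_list:
            raise ValueError("remove_stopwords set but stopword_list empty")


@dataclass
class WindowedCorpus:
    """Documents partitioned into ordered, disjoint time windows."""

    windows: list[TimeWindow]
    documents: list[Document]
    assignment: dict[str, int]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        ids = [d.doc_id for d in self.documents]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate doc_id in corpus")
        missing = [i for i in ids if i not in self.assignment]
        if missing:
            raise ValueError(f"documents without window assignment: {missing[:5]}")

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    def docs_in_window(self, index: int) -> list[Document]:
        return [d for d in self.documents if self.assignment[d.doc_id] == index]

    def window_sizes(self) -> list[int]:
        sizes = [0] * len(self.windows)
        for d in self.documents:
            sizes[self.assignment[d.doc_id]] += 1
        return sizes

    def window_by_label(self, label: str) -> TimeWindow:
        for w in self.windows:
            if w.label == label:
                return w
        raise KeyError(f"no window labelled {label!r}")


@dataclass
class ReadResult:
    """Documents surviving validation plus the number of records dropped."""

    documents: list[Document]
    n_dropped: int

    def __iter__(self):
        return iter(self.documents)

    def __len__(self) -> int:
        return len(self.documents)


def _parse_date(value) -> datetime.date:
    if isinstance(value, datetime.date):
        return value
    return datetime.date.fromisoformat(str(value).strip())


def _record_to_document(rec: dict, field_map: dict[str, str]) -> Document | None:
    """None means the record fails a non-fatal filter (missing title/date)."""
    doc_id = rec.get(field_map["id"])
    title = rec.get(field_map["title"]) or ""
    if doc_id is None or str(doc_id) == "":
        return None
    if not str(title).strip():
        return None
    raw_date = rec.get(field_map["date"])
    if raw_date is None or str(raw_date).strip() == "":
        return None
    try:
        date = _parse_date(raw_date)
    except ValueError:
        logger.warning("dropping record %r: unparseable date %r", doc_id, raw_date)
        return None
    abstract = rec.get(field_map["abstract"])
    if abstract is not None and not str(abstract).strip():
        abstract = None
    return Document(doc_id=str(doc_id), title=str(title), abstract=abstract, date=date)


def read_documents(path, format: str | None = None, field_map: dict[str, str] | None = None) -> ReadResult:
    """Read JSONL or CSV document records, keeping input order.

    Records with a missing/empty title or an unparseable date are dropped
    with a warning; a duplicate doc_id is a fatal error.
    """
    fmap = dict(DEFAULT_FIELD_MAP)
    if field_map:
        fmap.update(field_map)
    path = str(path)
    if format is None:
        format = "csv" if path.endswith(".csv") else "jsonl"
    if format not in ("jsonl", "csv"):
        raise ValueError(f"unknown format {format!r}")

    records: list[dict] = []
    if format == "jsonl":
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                line = line.strip()
                if line:
                    records.append(json.loads(line))
    else:
        with open(path, encoding="utf-8", newline="") as fh:
            records.extend(csv.DictReader(fh))

    docs: list[Document] = []
    seen: set[str] = set()
    dropped = 0
    for rec in records:
        doc = _record_to_document(rec, fmap)
        if doc is None:
            dropped += 1
            continue
        if doc.doc_id in seen:
            raise ValueError(f"duplicate doc_id {doc.doc_id!r}")
        seen.add(doc.doc_id)
        docs.append(doc)
    if dropped:
        logger.warning("read_documents: dropped %d of %d records", dropped, len(records))
    return ReadResult(documents=docs, n_dropped=dropped)


def _window_of_date(d: datetime.date, granularity: str) -> tuple[str, datetime.date, datetime.date]:
    if granularity == "year":
        start = datetime.date(d.year, 1, 1)
        return str(d.year), start, datetime.date(d.year + 1, 1, 1)
    if granularity == "month":
        start = datetime.date(d.year, d.month, 1)
        end = datetime.date(d.year + (d.month == 12), d.month % 12 + 1, 1)
        return f"{d.year}-{d.month:02d}", start, end
    if granularity == "iso_week":
        year, week, _ = d.isocalendar()
        start = d - datetime.timedelta(days=d.isocalendar()[2] - 1)  # Monday
        return f"{year}-W{week:02d}", start, start + datetime.timedelta(days=7)
    raise ValueError(f"unknown granularity {granularity!r}")


def _next_window_start(start: datetime.date, granularity: str) -> datetime.date:
    return _window_of_date(start, granularity)[2]


def assign_windows(
    docs: Sequence[Document],
    granularity: str = "year",
    date_range: tuple[datetime.date, datetime.date] | None = None,
) -> WindowedCorpus:
    """Bin documents into contiguous calendar windows.

    ``date_range`` is an inclusive (first, last) date filter; documents
    outside it are dropped and counted.  Windows with no documents are kept
    so window indices remain contiguous in calendar time.
    """
    kept = list(docs)
    dropped = 0
    if date_range is not None:
        lo, hi = (_parse_date(date_range[0]), _parse_date(date_range[1]))
        kept = [d for d in kept if lo <= d.date <= hi]
        dropped = len(docs) - len(kept)
    if not kept:
        raise ValueError("no documents remain after date-range filter")

    first = min(d.date for d in kept)
    last = max(d.date for d in kept)
    windows: list[TimeWindow] = []
    label, start, end = _window_of_date(first, granularity)
    idx = 0
    while start <= last:
        windows.append(TimeWindow(label=label, index=idx, start_date=start, end_date=end))
        idx += 1
        label, start, end = _window_of_date(end, granularity)

    by_label = {w.label: w.index for w in windows}
    assignment = {d.doc_id: by_label[_window_of_date(d.date, granularity)[0]] for d in kept}
    return WindowedCorpus(windows=windows, documents=kept, assignment=assignment, n_dropped=dropped)


def tokenize(text: str, config: TokenizerConfig = TokenizerConfig()) -> list[str]:
    """Split text into tokens: maximal alphanumeric runs, optionally
    lowercased, length- and stop-word-filtered.  Deterministic."""
    if config.lowercase:
        text = text.lower()
    if config.strip_punctuation:
        tokens = _TOKEN_RE.findall(text)
    else:
        tokens = text.split()
    tokens = [t for t in tokens if len(t) >= config.min_token_chars]
    if config.remove_stopwords:
        tokens = [t for t in tokens if t not in config.stopword_list]
    return tokens
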