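"""Seeded synthetic corpora and embedding clouds with planted signals.

These generators define the controlled conditions under which every
analysis stage is exercised: (a) windowed title corpora whose planted term
undergoes a step change in frequency-per-title at a known window, for the
changepoint pipeline; and (b) per-window point clouds in which a compact
offset cluster is born at a known window, for the T1/T2/Y1/Y2 novelty
strategies.  Ground truth travels with the generated objects (scenario
dataclasses, and cloud doc-ids encode cluster membership), so detection
tests can score sensitivity and specificity exactly.  Both generators are
pure functions of their scenario, including the seed.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np

from .corpus import Document, WindowedCorpus, assign_windows
from .embedding import EmbeddedCorpus

#: small vocabulary of generic biomedical title words with Zipf-ish weights
DEFAULT_VOCAB: tuple[tuple[str, float], ...] = tuple(
    (w, 1.0 / r)
    for r, w in enumerate(
        [
            "disease", "patients", "treatment", "clinical", "analysis",
            "study", "infection", "cases", "therapy", "diagnosis",
            "response", "model", "gene", "protein", "cell",
            "immune", "risk", "outcome", "population", "drug",
            "trial", "review", "effect", "expression", "virus",
            "vaccine", "screening", "children", "skin", "nerve",
        ],
        start=1,
    )
)


@dataclass(frozen=True)
class CorpusScenario:
    """A windowed title corpus with a planted step in one term's
    frequency-per-title.

    From ``step_window`` onward the planted term receives, per title, an
    extra Poisson(``step_magnitude``) occurrences, raising its expected
    frequency-per-title by exactly ``step_magnitude``.
    """

    n_windows: int = 20
    titles_per_window: int = 50
    base_vocab: tuple[tuple[str, float], ...] = DEFAULT_VOCAB
    planted_term: str = "vaccine"
    step_window: int = 10
    step_magnitude: float = 2.0
    seed: int = 0
    start_year: int = 2000
    title_len_mean: float = 8.0

    def __post_init__(self) -> None:
        if not self.base_vocab:
            raise ValueError("base_vocab must be non-empty")
        if not 0 <= self.step_window < self.n_windows:
            raise ValueError("step_window out of range")
        if self.step_magnitude < 0:
            raise ValueError("step_magnitude must be >= 0")

    @property
    def true_boundary(self) -> int:
        """Index of the boundary between the pre- and post-step windows."""
        return self.step_window - 1


def gen_corpus(scenario: CorpusScenario) -> WindowedCorpus:
    """Sample a yearly windowed corpus from a :class:`CorpusScenario`."""
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    words = [w for w, _ in sc.base_vocab]
    weights = np.array([p for _, p in sc.base_vocab], dtype=float)
    weights /= weights.sum()

    docs: list[Document] = []
    for w in range(sc.n_windows):
        year = sc.start_year + w
        for i in range(sc.titles_per_window):
            length = max(2, int(rng.poisson(sc.title_len_mean)))
            tokens = list(rng.choice(words, size=length, p=weights))
            if w >= sc.step_window and sc.step_magnitude > 0:
                tokens.extend([sc.planted_term] * int(rng.poisson(sc.step_magnitude)))
            day = int(rng.integers(0, 365))
            docs.append(
                Document(
                    doc_id=f"d{w:03d}-{i:04d}",
                    title=" ".join(tokens),
                    abstract=None,
                    date=datetime.date(year, 1, 1) + datetime.timedelta(days=day),
                )
            )
    return assign_windows(
        docs,
        granularity="year",
        date_range=(datetime.date(sc.start_year, 1, 1), datetime.date(sc.start_year + sc.n_windows - 1, 12, 31)),
    )


@dataclass(frozen=True)
class CloudScenario:
    """Per-window point clouds with a cluster of ``cluster_size`` documents
    born at ``birth_window`` at ``cluster_offset`` from the background mean.

    Each window holds ``docs_per_window`` documents in total; from the
    birth window onward, ``cluster_size`` of them are cluster members.
    The default dimension is 2: low-dimensional clouds keep background
    nearest-neighbour distances on the same scale as calibrated
    relatedness thresholds (as in a projected embedding space), which
    high-dimensional isotropic noise would not.
    """

    n_windows: int = 4
    docs_per_window: int = 100
    dim: int = 2
    background_mean: tuple[float, ...] | None = None  # zeros if None
    background_spread: float = 1.0
    cluster_offset: tuple[float, ...] | None = None  # (10, 0, ...) if None
    cluster_size: int = 10
    cluster_spread: float = 1.0
    birth_window: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.background_spread < 0 or self.cluster_spread < 0:
            raise ValueError("spreads must be >= 0")
        if self.cluster_size > self.docs_per_window:
            raise ValueError("cluster_size exceeds docs_per_window")
        if not 0 <= self.birth_window < self.n_windows:
            raise ValueError("birth_window out of range")

    def mean_vector(self) -> np.ndarray:
        if self.background_mean is None:
            return np.zeros(self.dim)
        v = np.asarray(self.background_mean, dtype=float)
        if len(v) != self.dim:
            raise ValueError("background_mean has wrong dimension")
        return v

    def offset_vector(self) -> np.ndarray:
        if self.cluster_offset is None:
            v = np.zeros(self.dim)
            v[0] = 10.0
            return v
        v = np.asarray(self.cluster_offset, dtype=float)
        if len(v) != self.dim:
            raise ValueError("cluster_offset has wrong dimension")
        return v


def is_cluster_member(doc_id: str) -> bool:
    """Ground-truth membership encoded in gen_cloud doc ids."""
    return "-nov-" in doc_id


def gen_cloud(scenario: CloudScenario) -> EmbeddedCorpus:
    """Sample an embedded corpus from a :class:`CloudScenario`.

    Doc ids are ``w{window:02d}-bg-{i:03d}`` for background documents and
    ``w{window:02d}-nov-{i:03d}`` for cluster members.
    """
    sc = scenario
    rng = np.random.default_rng(sc.seed)
    mu = sc.mean_vector()
    off = sc.offset_vector()

    ids: list[str] = []
    rows: list[np.ndarray] = []
    window_of: dict[str, int] = {}
    for w in range(sc.n_windows):
        m = sc.cluster_size if w >= sc.birth_window else 0
        n_bg = sc.docs_per_window - m
        for i in range(n_bg):
            did = f"w{w:02d}-bg-{i:03d}"
            ids.append(did)
            rows.append(mu + sc.background_spread * rng.standard_normal(sc.dim))
            window_of[did] = w
        for i in range(m):
            did = f"w{w:02d}-nov-{i:03d}"
            ids.append(did)
            rows.append(mu + off + sc.cluster_spread * rng.standard_normal(sc.dim))
            window_of[did] = w
    return EmbeddedCorpus(
        doc_ids=ids,
        vectors=np.vstack(rows),
        window_of=window_of,
        embedder_tag=f"synthetic-cloud(dim={sc.dim},seed={sc.seed})",
    )
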