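"""Exact offline Bayesian changepoint posteriors for univariate series.

Model
-----
A series x_1..x_n is partitioned into contiguous segments.  Each interior
boundary (between x_i and x_{i+1}) is a changepoint independently with
prior probability ``hazard``; within a segment, observations are i.i.d.
Gaussian with unknown mean and variance under a normal-inverse-gamma
(NIG) prior, so the segment marginal likelihood is available in closed
form (a multivariate Student-t evidence).

The posterior probability that a boundary is a changepoint is computed
*exactly* — marginalizing over all 2^(n-1) segmentations — by a
forward/backward dynamic program over segment marginals, O(n^2) segment
evaluations, entirely in log space.  A brute-force enumerator over all
segmentations is provided as an independent oracle for small n.

Hyperparameter defaults (mu0=0, kappa0=1, alpha0=1, beta0=1) are meant to
be applied to a z-standardized copy of the series (``standardize=True``),
which makes them scale-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from math import lgamma, log, pi

import numpy as np
from scipy.special import gammaln, logsumexp
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "SegmentModel",
    "ChangepointPosterior",
    "BayesianChangepointDetector",
    "segment_log_marginal",
    "changepoint_posterior",
    "brute_force_posterior",
    "batch_changepoints",
]


@dataclass(frozen=True)
class SegmentModel:
    """Normal-inverse-gamma prior over a segment's (mean, variance)."""

    mu0: float = 0.0
    kappa0: float = 1.0
    alpha0: float = 1.0
    beta0: float = 1.0

    def __post_init__(self) -> None:
        for name in ("kappa0", "alpha0", "beta0"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass
class ChangepointPosterior:
    """Exact boundary-wise changepoint probabilities for one series.

    ``boundary_probs[i]`` is the posterior probability of a segment
    boundary between observations i and i+1 (length n-1).
    """

    boundary_probs: np.ndarray
    log_evidence: float
    hazard: float
    calls: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.boundary_probs) + 1

    def max_boundary(self) -> tuple[int, float]:
        """(index, probability) of the highest-probability boundary;
        earliest wins ties."""
        i = int(np.argmax(self.boundary_probs))
        return i, float(self.boundary_probs[i])


def segment_log_marginal(x: np.ndarray, s: int, t: int, model: SegmentModel = SegmentModel()) -> float:
    """log marginal likelihood of the inclusive segment x[s..t] under the NIG prior.

    Closed form: with n = t-s+1, kap_n = kap0+n, alpha_n = alpha0+n/2 and
    beta_n = beta0 + SS/2 + kap0*n*(xbar-mu0)^2 / (2*kap_n),

        log m = lgamma(alpha_n) - lgamma(alpha0) + alpha0*log(beta0)
                - alpha_n*log(beta_n) + 0.5*log(kap0/kap_n) - (n/2)*log(2*pi)
    """
    x = np.asarray(x, dtype=float)
    if s > t:
        raise IndexError(f"segment start {s} > end {t}")
    if s < 0 or t >= len(x):
        raise IndexError("segment out of bounds")
    seg = x[s : t + 1]
    n = len(seg)
    xbar = seg.mean()
    ss = float(((seg - xbar) ** 2).sum())
    kap_n = model.kappa0 + n
    alpha_n = model.alpha0 + n / 2.0
    beta_n = model.beta0 + 0.5 * ss + model.kappa0 * n * (xbar - model.mu0) ** 2 / (2.0 * kap_n)
    return (
        lgamma(alpha_n)
        - lgamma(model.alpha0)
        + model.alpha0 * log(model.beta0)
        - alpha_n * log(beta_n)
        + 0.5 * log(model.kappa0 / kap_n)
        - (n / 2.0) * log(2.0 * pi)
    )


def _segment_marginal_matrix(x: np.ndarray, model: SegmentModel) -> np.ndarray:
    """M[s, t] = segment_log_marginal(x, s, t) for all s <= t, vectorized per row."""
    n = len(x)
    c1 = np.concatenate([[0.0], np.cumsum(x)])
    c2 = np.concatenate([[0.0], np.cumsum(x * x)])
    M = np.full((n, n), -np.inf)
    ends = np.arange(n)
    for s in range(n):
        t = ends[s:]
        m = t - s + 1.0
        seg_sum = c1[t + 1] - c1[s]
        xbar = seg_sum / m
        ss = np.maximum(c2[t + 1] - c2[s] - seg_sum * xbar, 0.0)  # clip FP negatives
        kap_n = model.kappa0 + m
        alpha_n = model.alpha0 + m / 2.0
        beta_n = model.beta0 + 0.5 * ss + model.kappa0 * m * (xbar - model.mu0) ** 2 / (2.0 * kap_n)
        M[s, s:] = (
            gammaln(alpha_n)
            - gammaln(model.alpha0)
            + model.alpha0 * np.log(model.beta0)
            - alpha_n * np.log(beta_n)
            + 0.5 * np.log(model.kappa0 / kap_n)
            - (m / 2.0) * np.log(2.0 * np.pi)
        )
    return M


def _standardize(x: np.ndarray) -> np.ndarray:
    mu = x.mean()
    sd = x.std()
    if sd < 1e-12:
        return x - mu
    return (x - mu) / sd


class BayesianChangepointDetector(BaseEstimator):
    """Exact Bayesian changepoint posterior for a univariate series.

    Parameters
    ----------
    hazard : float or None
        Prior probability that any interior boundary is a changepoint.
        None (default) uses 1/(n+1), set at fit time.
    mu0, kappa0, alpha0, beta0 : float
        Normal-inverse-gamma segment prior (defaults 0, 1, 1, 1).
    standardize : bool
        z-standardize the series before fitting so the default prior is
        scale-free (default True).
    call_threshold : float
        A "changepoint call" is a boundary whose posterior probability
        exceeds this threshold and is a local maximum (default 0.5).

    Attributes
    ----------
    boundary_probs_ : ndarray of shape (n-1,)
        Exact posterior probability of a boundary between x[i] and x[i+1].
    log_evidence_ : float
        Log marginal likelihood of the series under the segmentation prior.
    hazard_ : float
        Hazard actually used.
    calls_ : list of int
        Boundary indices called as changepoints, ascending.
    """

    def __init__(
        self,
        hazard: float | None = None,
        mu0: float = 0.0,
        kappa0: float = 1.0,
        alpha0: float = 1.0,
        beta0: float = 1.0,
        standardize: bool = True,
        call_threshold: float = 0.5,
    ):
        self.hazard = hazard
        self.mu0 = mu0
        self.kappa0 = kappa0
        self.alpha0 = alpha0
        self.beta0 = beta0
        self.standardize = standardize
        self.call_threshold = call_threshold

    def _model(self) -> SegmentModel:
        return SegmentModel(self.mu0, self.kappa0, self.alpha0, self.beta0)

    def fit(self, X, y=None):
        x = np.asarray(X, dtype=float).ravel()
        n = len(x)
        if n < 2:
            raise ValueError("need at least 2 observations (no interior boundary otherwise)")
        if not np.all(np.isfinite(x)):
            raise ValueError("series contains non-finite values")
        hazard = 1.0 / (n + 1) if self.hazard is None else float(self.hazard)
        if not 0.0 < hazard < 1.0:
            raise ValueError(f"hazard must be in (0, 1), got {hazard}")
        if self.standardize:
            x = _standardize(x)

        M = _segment_marginal_matrix(x, self._model())
        logh, log1mh = log(hazard), log(1.0 - hazard)

        # A[j]: log evidence of x[0:j] with a boundary at position j
        # (boundary factor log h included for interior j < n).
        A = np.full(n + 1, -np.inf)
        A[0] = 0.0
        for j in range(1, n + 1):
            s = np.arange(j)
            terms = A[:j] + M[s, j - 1] + (j - 1 - s) * log1mh
            A[j] = logsumexp(terms) + (logh if j < n else 0.0)

        # B[j]: log evidence of the suffix x[j:] given a boundary at j
        # (the boundary-at-j factor is carried by A, not B).
        B = np.full(n + 1, -np.inf)
        B[n] = 0.0
        for j in range(n - 1, -1, -1):
            t = np.arange(j + 1, n + 1)
            terms = M[j, t - 1] + (t - j - 1) * log1mh + B[t]
            terms[t < n] += logh
            B[j] = logsumexp(terms)

        probs = np.exp(A[1:n] + B[1:n] - A[n])
        self.boundary_probs_ = np.clip(probs, 0.0, 1.0)
        self.log_evidence_ = float(A[n])
        self.hazard_ = hazard
        self.n_ = n
        self.calls_ = self._call_boundaries(self.boundary_probs_)
        return self

    def _call_boundaries(self, p: np.ndarray) -> list[int]:
        calls = []
        for i, v in enumerate(p):
            if v <= self.call_threshold:
                continue
            left = p[i - 1] if i > 0 else -np.inf
            right = p[i + 1] if i + 1 < len(p) else -np.inf
            if v >= left and v >= right:  # local maximum; earliest of a flat run wins
                if calls and calls[-1] == i - 1 and p[i - 1] == v:
                    continue
                calls.append(i)
        return calls

    def posterior_(self) -> ChangepointPosterior:
        check_is_fitted(self, "boundary_probs_")
        return ChangepointPosterior(
            boundary_probs=self.boundary_probs_.copy(),
            log_evidence=self.log_evidence_,
            hazard=self.hazard_,
            calls=list(self.calls_),
        )


def changepoint_posterior(
    x,
    hazard: float | None = None,
    model: SegmentModel = SegmentModel(),
    standardize: bool = True,
    call_threshold: float = 0.5,
) -> ChangepointPosterior:
    """Exact boundary posterior for one series (functional wrapper)."""
    det = BayesianChangepointDetector(
        hazard=hazard,
        mu0=model.mu0,
        kappa0=model.kappa0,
        alpha0=model.alpha0,
        beta0=model.beta0,
        standardize=standardize,
        call_threshold=call_threshold,
    ).fit(x)
    return det.posterior_()


def brute_force_posterior(
    x,
    hazard: float,
    model: SegmentModel = SegmentModel(),
    standardize: bool = False,
) -> ChangepointPosterior:
    """Enumerate all 2^(n-1) segmentations exactly (oracle; n <= 12)."""
    x = np.asarray(x, dtype=float).ravel()
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 observations")
    if n > 12:
        raise ValueError(f"brute force refuses n={n} > 12")
    if not 0.0 < hazard < 1.0:
        raise ValueError("hazard must be in (0, 1)")
    if standardize:
        x = _standardize(x)

    logh, log1mh = log(hazard), log(1.0 - hazard)
    positions = list(range(1, n))
    log_weights = []
    memberships = []
    for r in range(n):
        for bset in combinations(positions, r):
            cuts = [0, *bset, n]
            lw = sum(segment_log_marginal(x, cuts[i], cuts[i + 1] - 1, model) for i in range(len(cuts) - 1))
            lw += len(bset) * logh + (n - 1 - len(bset)) * log1mh
            log_weights.append(lw)
            memberships.append(frozenset(bset))
    log_weights = np.array(log_weights)
    total = logsumexp(log_weights)
    probs = np.empty(n - 1)
    for i, pos in enumerate(positions):
        mask = np.array([pos in m for m in memberships])
        probs[i] = np.exp(logsumexp(log_weights[mask]) - total) if mask.any() else 0.0
    return ChangepointPosterior(boundary_probs=probs, log_evidence=float(total), hazard=hazard)


def batch_changepoints(
    ts,
    terms: list[str],
    hazard: float | None = None,
    model: SegmentModel = SegmentModel(),
    standardize: bool = True,
    call_threshold: float = 0.5,
) -> dict[str, ChangepointPosterior | Exception]:
    """Changepoint posterior for each term's frequency-per-title series.

    Per-term failures are returned as the exception, not raised, so one
    degenerate series cannot abort a vocabulary-wide sweep.
    """
    from .lexstats import term_series

    out: dict[str, ChangepointPosterior | Exception] = {}
    for term in terms:
        try:
            series = term_series(ts, term)
            out[term] = changepoint_posterior(
                series.values.to_numpy(),
                hazard=hazard,
                model=model,
                standardize=standardize,
                call_threshold=call_threshold,
            )
        except Exception as exc:  # noqa: BLE001 - per-term failure record
            out[term] = exc
    return out
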