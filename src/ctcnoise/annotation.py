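"""Interobserver annotation matrices and agreement statistics.

The central object is the :class:`AnnotationMatrix`: ``N`` image cutouts
labelled CTC (1) or no-CTC (0) by each of ``M`` observers.  From it the
module derives pairwise agreement (one minus the normalised Hamming
distance), per-observer agreement summaries, CTC-count statistics, and a
Bernoulli-model estimate of how many unanimous cutouts would be expected
if every cutout were equally hard.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AnnotationMatrix:
    """Binary labels for N cutouts (rows) by M observers (columns)."""

    labels: np.ndarray
    observer_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels)
        if labels.ndim != 2:
            raise ValueError("labels must be a 2-D matrix (cutouts x observers)")
        if labels.shape[0] < 1 or labels.shape[1] < 2:
            raise ValueError("need at least 1 cutout and 2 observers")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("labels must be binary (0/1) with no missing entries")
        ids = tuple(str(o) for o in self.observer_ids)
        if len(ids) != labels.shape[1]:
            raise ValueError("observer_ids must match the number of columns")
        if len(set(ids)) != len(ids):
            raise ValueError("observer_ids must be unique")
        object.__setattr__(self, "labels", labels.astype(np.int8))
        object.__setattr__(self, "observer_ids", ids)

    @property
    def n_points(self) -> int:
        return self.labels.shape[0]

    @property
    def n_observers(self) -> int:
        return self.labels.shape[1]

    def column(self, observer_id: str) -> np.ndarray:
        return self.labels[:, self.observer_ids.index(observer_id)]

    # -- I/O ---------------------------------------------------------------

    @classmethod
    def from_csv(cls, path) -> "AnnotationMatrix":
        """Read a delimited annotation matrix.

        First row holds observer identifiers; an optional ``cutout_id``
        column keys rows to image files and is ignored here.
        """
        df = pd.read_csv(path)
        if "cutout_id" in df.columns:
            df = df.drop(columns=["cutout_id"])
        return cls(df.to_numpy(), tuple(df.columns))

    def to_csv(self, path, cutout_ids: Sequence[str] | None = None) -> None:
        df = pd.DataFrame(self.labels, columns=list(self.observer_ids))
        if cutout_ids is not None:
            df.insert(0, "cutout_id", list(cutout_ids))
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class AgreementMatrix:
    """Symmetric M x M matrix of pairwise observer agreements in [0, 1]."""

    values: np.ndarray
    observer_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("agreement matrix must be square")
        if not np.allclose(v, v.T):
            raise ValueError("agreement matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("agreement matrix must have unit diagonal")
        if (v < 0).any() or (v > 1).any():
            raise ValueError("agreements must lie in [0, 1]")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "observer_ids", tuple(self.observer_ids))

    def off_diagonal(self) -> np.ndarray:
        """The M(M-1)/2 unordered pairwise agreements."""
        iu = np.triu_indices(self.values.shape[0], k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        ids = list(self.observer_ids)
        return pd.DataFrame(self.values, index=ids, columns=ids)


@dataclass(frozen=True)
class ObserverSummary:
    """Per-observer agreement and CTC-count summary (one point of the
    agreement-vs-count scatter)."""

    observer_id: str
    n_ctc: int
    mean_agreement: float
    delta_ctc: float
    se_agreement: float


@dataclass(frozen=True)
class BernoulliEstimate:
    """Equal-difficulty Bernoulli model of observer agreement.

    If every observer independently matches the (latent) label of every
    cutout with the same probability ``p``, two observers agree with
    probability ``p^2 + (1-p)^2 ~ p^2`` for ``p`` near 1, so ``p`` is
    estimated as the square root of the mean pairwise agreement and the
    expected number of unanimous cutouts is ``N * p^M``.
    """

    mean_pairwise_agreement: float
    p: float
    expected_unanimous: float


@dataclass(frozen=True)
class CountStatistics:
    mean: float
    median: float
    #: (gap, lower-count observer id, higher-count observer id), descending gaps
    sorted_gaps: tuple[tuple[int, str, str], ...]


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def _as_binary_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x)
    if v.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional")
    if not np.isin(v, (0, 1)).all():
        raise ValueError(f"{name} must contain only 0/1 entries")
    return v.astype(np.int8)


def pairwise_agreement(a, b) -> float:
    """Agreement between two observers: 1 - (1/N) * sum |a_i - b_i|.

    Equals one minus the normalised Hamming distance between the two
    binary label vectors; 1 means identical annotation, 0 total
    disagreement.
    """
    av = _as_binary_vector(a, "a")
    bv = _as_binary_vector(b, "b")
    if av.shape != bv.shape:
        raise ValueError("label vectors must have equal length")
    return 1.0 - float(np.abs(av - bv).mean())


def agreement_matrix(ann: AnnotationMatrix) -> AgreementMatrix:
    """All pairwise agreements (the heat-map quantity)."""
    m = ann.n_observers
    values = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            values[i, j] = values[j, i] = pairwise_agreement(
                ann.labels[:, i], ann.labels[:, j]
            )
    return AgreementMatrix(values, ann.observer_ids)


def observer_summaries(ann: AnnotationMatrix) -> list[ObserverSummary]:
    """Per-observer mean agreement, signed mean CTC-count difference and
    the standard error of the M-1 pairwise agreements.

    ``delta_ctc`` is signed: conservative observers (few CTC calls) come
    out negative.
    """
    agr = agreement_matrix(ann).values
    counts = ann.labels.sum(axis=0).astype(int)
    m = ann.n_observers
    out = []
    for i, oid in enumerate(ann.observer_ids):
        partners = np.delete(agr[i], i)
        mean_agr = float(partners.mean())
        delta = float(np.mean(counts[i] - np.delete(counts, i)))
        se = float(np.std(partners, ddof=1) / math.sqrt(m - 1)) if m > 2 else 0.0
        out.append(
            ObserverSummary(
                observer_id=oid,
                n_ctc=int(counts[i]),
                mean_agreement=mean_agr,
                delta_ctc=delta,
                se_agreement=se,
            )
        )
    return out


def count_statistics(
    counts: Sequence[int], observer_ids: Sequence[str] | None = None
) -> CountStatistics:
    """Mean, median and ordered-gap structure of per-observer CTC counts.

    ``sorted_gaps`` lists consecutive differences of the ascending-sorted
    counts in descending order, each with the identifiers of the two
    flanking observers, so outlying (conservative) observers show up as
    large leading gaps.
    """
    c = np.asarray(counts)
    if c.size == 0:
        raise ValueError("counts must be nonempty")
    if (c < 0).any():
        raise ValueError("counts must be nonnegative")
    ids = (
        [str(i) for i in observer_ids]
        if observer_ids is not None
        else [str(i) for i in range(c.size)]
    )
    if len(ids) != c.size:
        raise ValueError("observer_ids must match counts length")
    order = np.argsort(c, kind="stable")
    sorted_counts = c[order]
    gaps = [
        (int(sorted_counts[k + 1] - sorted_counts[k]), ids[order[k]], ids[order[k + 1]])
        for k in range(c.size - 1)
    ]
    gaps.sort(key=lambda g: g[0], reverse=True)
    return CountStatistics(
        mean=float(c.mean()), median=float(np.median(c)), sorted_gaps=tuple(gaps)
    )


def bernoulli_estimate(ann: AnnotationMatrix) -> BernoulliEstimate:
    """Fit the equal-difficulty Bernoulli agreement model.

    The mean is taken over the M(M-1)/2 unordered observer pairs.  A
    shortfall of the observed unanimous count against ``N * p^M`` is
    evidence that disagreement probability varies across cutouts.
    """
    mean_agr = float(agreement_matrix(ann).off_diagonal().mean())
    p = math.sqrt(mean_agr)
    return BernoulliEstimate(
        mean_pairwise_agreement=mean_agr,
        p=p,
        expected_unanimous=ann.n_points * p**ann.n_observers,
    )


def expected_unanimous(n_points: int, mean_pairwise_agreement: float, n_observers: int) -> float:
    """``N * sqrt(agreement)^M`` without constructing a matrix."""
    return n_points * math.sqrt(mean_pairwise_agreement) ** n_observers


def agreement_ttest(agreements, hypothesized_mean: float):
    """One-sample two-sided t-test of pairwise agreements against a
    hypothesised mean (e.g. the agreement implied by the observed
    unanimity rate)."""
    a = np.asarray(agreements, dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 agreement values")
    if np.ptp(a) == 0:
        raise ValueError("agreement values have zero variance; t-test undefined")
    res = stats.ttest_1samp(a, popmean=hypothesized_mean)
    return {"t_statistic": float(res.statistic), "p_value": float(res.pvalue)}
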