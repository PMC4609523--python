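"""Consensus annotation: binomial consensus limit, GT/probGT partition
and probabilistic annotations.

A cutout reaches *consensus* when at least ``c`` of the ``M`` observers
give the same label, where ``c`` is the smallest count whose one-sided
fair-coin binomial tail falls below a significance level ``alpha``
(default 0.05) — i.e. such concordance is unlikely to arise from
coin-flipping observers.  Unanimous cutouts form the ground-truth (GT)
stratum; the remainder (probGT) only admits *probabilistic annotations*,
each point labelled by a uniformly drawn observer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationMatrix

#: Returned by :func:`consensus_limit` when no count of agreeing observers
#: is improbable enough under the fair-coin model.
NO_CONSENSUS: int = -1


def consensus_limit(n_observers: int, alpha: float = 0.05) -> int:
    """Smallest c with P(X >= c) < alpha for X ~ Binomial(n_observers, 1/2).

    Computed with exact binomial coefficients (no floating-point tail
    summation).  Returns :data:`NO_CONSENSUS` if even unanimity is not
    improbable enough, which happens for small panels (n <= 4 at
    alpha = 0.05).
    """
    if n_observers < 2:
        raise ValueError("need at least 2 observers")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    denom = Fraction(1, 2**n_observers)
    alpha_frac = Fraction(alpha).limit_denominator(10**12)
    tail = Fraction(0)
    # walk the tail downward from c = n; the first c (from above) whose tail
    # meets alpha, minus the overshoot, is found by scanning upward instead
    best = NO_CONSENSUS
    for c in range(n_observers, n_observers // 2, -1):
        tail += math.comb(n_observers, c) * denom
        if tail < alpha_frac:
            best = c
        else:
            break
    return best


@dataclass(frozen=True)
class ConsensusConfig:
    """Panel size, significance level and the implied consensus limit."""

    n_observers: int
    alpha: float = 0.05

    def __post_init__(self) -> None:
        c = consensus_limit(self.n_observers, self.alpha)
        if c == NO_CONSENSUS:
            raise ValueError(
                f"no consensus limit exists for {self.n_observers} observers "
                f"at alpha={self.alpha}"
            )
        object.__setattr__(self, "_c", c)

    @property
    def c(self) -> int:
        return self._c  # type: ignore[attr-defined]


@dataclass(frozen=True)
class ConsensusPartition:
    """Assignment of every cutout to consensus strata and GT/probGT."""

    consensus_mask: np.ndarray
    total_consensus_mask: np.ndarray
    consensus_labels: np.ndarray  # -1 where no consensus
    gt_indices: np.ndarray
    probgt_indices: np.ndarray
    n_votes_ctc: np.ndarray
    config: ConsensusConfig

    @property
    def n_points(self) -> int:
        return self.consensus_mask.size

    @property
    def consensus_fraction(self) -> float:
        return float(self.consensus_mask.mean())

    @property
    def consensus_indices(self) -> np.ndarray:
        return np.flatnonzero(self.consensus_mask)

    def to_frame(self, cutout_ids: Sequence[str] | None = None) -> pd.DataFrame:
        """Tabular export: one row per cutout with vote count, stratum and
        consensus label ('' where undefined)."""
        n = self.n_points
        ids = list(cutout_ids) if cutout_ids is not None else [str(i) for i in range(n)]
        stratum = np.where(self.total_consensus_mask, "GT", "probGT")
        consensus = np.where(self.consensus_mask, "1", "0")
        labels = [
            str(int(l)) if m else "" for l, m in zip(self.consensus_labels, self.consensus_mask)
        ]
        return pd.DataFrame(
            {
                "cutout_id": ids,
                "n_votes_ctc": self.n_votes_ctc,
                "consensus": consensus,
                "stratum": stratum,
                "consensus_label": labels,
            }
        )


def build_partition(ann: AnnotationMatrix, config: ConsensusConfig) -> ConsensusPartition:
    """Partition cutouts by vote counts under the consensus limit.

    A row is consensus when >= c observers agree in either direction; the
    consensus label is the winning vote.  Unanimous rows form GT, all
    others probGT.  Rows split exactly M/2 vs M/2 (even panels only) have
    no majority and are never consensus.
    """
    if config.n_observers != ann.n_observers:
        raise ValueError("config panel size must match the annotation matrix")
    votes = ann.labels.sum(axis=1)
    m = ann.n_observers
    c = config.c
    pro = votes >= c
    contra = (m - votes) >= c
    consensus = pro | contra
    total = (votes == m) | (votes == 0)
    labels = np.full(ann.n_points, -1, dtype=np.int8)
    labels[pro] = 1
    labels[contra] = 0
    return ConsensusPartition(
        consensus_mask=consensus,
        total_consensus_mask=total,
        consensus_labels=labels,
        gt_indices=np.flatnonzero(total),
        probgt_indices=np.flatnonzero(~total),
        n_votes_ctc=votes.astype(int),
        config=config,
    )


def sample_probabilistic_annotation(
    ann: AnnotationMatrix, indices, rng_seed: int
) -> np.ndarray:
    """One probabilistic annotation over the given rows.

    Each row independently takes the label of a uniformly drawn observer,
    so the marginal P(label=1) at row i equals that row's CTC vote
    fraction.  Deterministic under ``rng_seed``.
    """
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("index set must be nonempty")
    rng = np.random.default_rng(rng_seed)
    chosen = rng.integers(0, ann.n_observers, size=idx.size)
    return ann.labels[idx, chosen].astype(np.int8)


def expected_label_changes(ann: AnnotationMatrix, indices) -> float:
    """Expected Hamming distance between two independent probabilistic
    annotations over the given rows: sum_i 2 q_i (1 - q_i) with q_i the
    CTC vote fraction."""
    idx = np.asarray(indices, dtype=int)
    if idx.size == 0:
        raise ValueError("index set must be nonempty")
    q = ann.labels[idx].mean(axis=1)
    return float(np.sum(2.0 * q * (1.0 - q)))
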