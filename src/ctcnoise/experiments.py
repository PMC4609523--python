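"""Evaluation protocols: cross-observer whole-set evaluation, the
GT/probGT label-noise grid and the consensus-set evaluation.

All three protocols share the same skeleton: split a data set into
randomized folds, train on some folds, test on a fold that was not used
for training, and rotate until every test point has been classified.
They differ in where the *labels* come from — a single observer's raw
annotation, the unanimous ground truth (GT), freshly sampled
probabilistic annotations over the non-unanimous remainder (probGT), or
the consensus labelling — which is exactly the experimental contrast of
interest: how label noise in training and test material moves measured
classifier performance.

Seed schedule: one master seed deterministically expands to fold seeds,
per-repetition annotation seeds and per-fit RF seeds through a counter
scheme (``_derive_seed``), so any single cell of a grid can be re-run
in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationMatrix
from .classify import (
    ClassifierSpec,
    ConfusionCounts,
    PerformanceReport,
    confusion,
    measures,
    predict,
    train,
)
from .consensus import ConsensusPartition, sample_probabilistic_annotation


def _derive_seed(master: int, *path: int) -> int:
    """Stable child seed (< 2^31) for a position in the experiment tree."""
    return int(np.random.SeedSequence((master,) + path).generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldAssignment:
    """Balanced random partition of an index set into folds."""

    indices: np.ndarray
    fold_id: np.ndarray  # aligned with indices
    n_folds: int
    seed: int
    stratum: str = "none"  # GT / probGT / none

    def fold(self, k: int) -> np.ndarray:
        return self.indices[self.fold_id == k]

    def sizes(self) -> list[int]:
        return [int((self.fold_id == k).sum()) for k in range(self.n_folds)]


def make_folds(indices, n_folds: int, seed: int, stratum: str = "none") -> FoldAssignment:
    """Uniformly random partition with fold sizes differing by at most 1."""
    idx = np.asarray(indices, dtype=int)
    if n_folds > idx.size:
        raise ValueError("more folds than data points")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(idx)
    fold_id = np.empty(idx.size, dtype=int)
    pos = 0
    order = np.empty(idx.size, dtype=int)
    for k, chunk in enumerate(np.array_split(perm, n_folds)):
        order[pos : pos + chunk.size] = chunk
        fold_id[pos : pos + chunk.size] = k
        pos += chunk.size
    return FoldAssignment(order, fold_id, n_folds, seed, stratum)


def _audit_disjoint(train_idx: np.ndarray, test_idx: np.ndarray) -> None:
    # invariant: no test point may appear in its own training set
    if np.intersect1d(train_idx, test_idx).size:
        raise AssertionError("train/test overlap detected")


# ---------------------------------------------------------------------------
# Cross-observer whole-set evaluation
# ---------------------------------------------------------------------------

def run_cross_observer(
    features: np.ndarray,
    ann: AnnotationMatrix,
    specs: Sequence[ClassifierSpec],
    n_folds: int = 5,
    seed: int = 0,
) -> dict[str, PerformanceReport]:
    """Train/test against each observer's raw annotation in turn.

    The full set is split into ``n_folds`` random folds; when fold t is
    the test fold, fold (t+1) mod n_folds is excluded and training uses
    the remaining folds, so every point is classified exactly once per
    sweep.  Per observer the confusion counts are pooled over the
    sweep; the report per classifier is the unweighted mean ± SD of
    Acc/Pre/Rec across observers (SD is NaN for a single observer).
    """
    X = np.asarray(features, dtype=float)
    if X.shape[0] != ann.n_points:
        raise ValueError("features must be row-aligned with the annotation matrix")
    folds = make_folds(np.arange(ann.n_points), n_folds, _derive_seed(seed, 0))
    out: dict[str, PerformanceReport] = {}
    for s_i, spec in enumerate(specs):
        per_observer = []
        for o_i, oid in enumerate(ann.observer_ids):
            y = ann.labels[:, o_i]
            pooled = ConfusionCounts(0, 0, 0, 0)
            for t in range(n_folds):
                test_idx = folds.fold(t)
                skip = (t + 1) % n_folds
                train_idx = np.concatenate(
                    [folds.fold(k) for k in range(n_folds) if k not in (t, skip)]
                )
                _audit_disjoint(train_idx, test_idx)
                model = train(
                    spec.with_seed(_derive_seed(seed, 1, s_i, o_i, t)),
                    X[train_idx],
                    y[train_idx],
                )
                pooled = pooled + confusion(predict(model, X[test_idx]), y[test_idx])
            per_observer.append(measures(pooled))
        vals = np.array(per_observer, dtype=float)
        sd = vals.std(axis=0, ddof=1) if vals.shape[0] > 1 else np.full(3, np.nan)
        mean = vals.mean(axis=0)
        out[spec.kind] = PerformanceReport(
            accuracy=float(mean[0]),
            precision=float(mean[1]),
            recall=float(mean[2]),
            accuracy_sd=float(sd[0]),
            precision_sd=float(sd[1]),
            recall_sd=float(sd[2]),
            condition_label="whole_set",
        )
    return out


# ---------------------------------------------------------------------------
# GT / probGT label-noise grid
# ---------------------------------------------------------------------------

NOISE_CONDITIONS = ("train_2GT", "train_1GT_1probGT", "train_2probGT")


@dataclass(frozen=True)
class ExperimentGrid:
    """Which noise-grid conditions to run and how often.

    Pure-GT training has no label randomness, so fewer repetitions
    suffice there (they only probe classifier-internal randomness);
    probGT-containing conditions re-draw the probabilistic annotation
    every repetition.
    """

    conditions: tuple[str, ...] = NOISE_CONDITIONS
    n_repetitions_gt: int = 10
    n_repetitions_noise: int = 50
    seed: int = 0

    def n_reps(self, condition: str) -> int:
        return self.n_repetitions_gt if condition == "train_2GT" else self.n_repetitions_noise


@dataclass(frozen=True)
class NoiseGridResult:
    """Machine-readable analogue of the label-noise performance table."""

    reports: dict  # (condition, classifier kind) -> PerformanceReport
    per_repetition: dict  # (condition, kind) -> (reps, 3) array of Acc/Pre/Rec

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (cond, kind), rep in self.reports.items():
            d = rep.as_dict()
            d["classifier"] = kind
            rows.append(d)
        return pd.DataFrame(rows)


def _consensus_gt_labels(ann: AnnotationMatrix, partition: ConsensusPartition) -> np.ndarray:
    """Labels on GT rows (unanimous, so any column works); -1 elsewhere."""
    labels = np.full(ann.n_points, -1, dtype=np.int8)
    labels[partition.gt_indices] = ann.labels[partition.gt_indices, 0]
    return labels


def run_noise_grid(
    features: np.ndarray,
    partition: ConsensusPartition,
    ann: AnnotationMatrix,
    specs: Sequence[ClassifierSpec],
    grid: ExperimentGrid | None = None,
) -> NoiseGridResult:
    """Controlled label noise in training, clean GT test labels.

    GT is split into three folds and probGT into two, giving five folds
    of comparable size.  Per condition, training uses two folds — both
    GT, one GT + one probGT, or both probGT — and testing uses a GT
    fold not used in training, rotating the test fold over all three GT
    folds.  probGT folds carry a freshly drawn probabilistic annotation
    each repetition; GT folds always carry the unanimous labels.
    Confusion counts are pooled over the three rotations within a
    repetition; reported are mean ± SD over repetitions.
    """
    grid = grid or ExperimentGrid()
    X = np.asarray(features, dtype=float)
    if X.shape[0] != ann.n_points:
        raise ValueError("features must be row-aligned with the annotation matrix")
    if partition.n_points != ann.n_points:
        raise ValueError("partition inconsistent with the annotation matrix")
    if partition.gt_indices.size < 3:
        raise ValueError("GT stratum too small for three folds")
    has_probgt = partition.probgt_indices.size >= 2

    gt_folds = make_folds(partition.gt_indices, 3, _derive_seed(grid.seed, 10), "GT")
    probgt_folds = (
        make_folds(partition.probgt_indices, 2, _derive_seed(grid.seed, 11), "probGT")
        if has_probgt
        else None
    )
    gt_labels = _consensus_gt_labels(ann, partition)
    pos = {int(i): k for k, i in enumerate(partition.probgt_indices)}

    reports: dict = {}
    per_rep: dict = {}
    for cond in grid.conditions:
        if cond not in NOISE_CONDITIONS:
            raise ValueError(f"unknown condition: {cond}")
        if cond != "train_2GT" and not has_probgt:
            # nothing non-unanimous: every condition collapses to pure GT
            cond_effective = "train_2GT"
        else:
            cond_effective = cond
        for s_i, spec in enumerate(specs):
            n_reps = grid.n_reps(cond)
            vals = np.empty((n_reps, 3))
            for r in range(n_reps):
                rng = np.random.default_rng(_derive_seed(grid.seed, 20, s_i, r))
                prob_labels = None
                if cond_effective != "train_2GT":
                    # one probabilistic annotation per repetition (seed = base + r)
                    prob_labels = sample_probabilistic_annotation(
                        ann, partition.probgt_indices, _derive_seed(grid.seed, 30, r)
                    )
                pooled = ConfusionCounts(0, 0, 0, 0)
                for t in range(3):
                    test_idx = gt_folds.fold(t)
                    others = [k for k in range(3) if k != t]
                    if cond_effective == "train_2GT":
                        train_idx = np.concatenate([gt_folds.fold(k) for k in others])
                        train_y = gt_labels[train_idx]
                    elif cond_effective == "train_1GT_1probGT":
                        g = others[int(rng.integers(0, 2))]
                        p = int(rng.integers(0, 2))
                        gt_part = gt_folds.fold(g)
                        pg_part = probgt_folds.fold(p)
                        train_idx = np.concatenate([gt_part, pg_part])
                        train_y = np.concatenate(
                            [
                                gt_labels[gt_part],
                                prob_labels[[pos[int(i)] for i in pg_part]],
                            ]
                        )
                    else:  # train_2probGT
                        train_idx = partition.probgt_indices
                        train_y = prob_labels
                    _audit_disjoint(train_idx, test_idx)
                    model = train(
                        spec.with_seed(_derive_seed(grid.seed, 40, s_i, r, t)),
                        X[train_idx],
                        train_y,
                    )
                    pooled = pooled + confusion(
                        predict(model, X[test_idx]), gt_labels[test_idx]
                    )
                vals[r] = measures(pooled)
            mean = vals.mean(axis=0)
            sd = vals.std(axis=0, ddof=1) if n_reps > 1 else np.zeros(3)
            reports[(cond, spec.kind)] = PerformanceReport(
                accuracy=float(mean[0]),
                precision=float(mean[1]),
                recall=float(mean[2]),
                accuracy_sd=float(sd[0]),
                precision_sd=float(sd[1]),
                recall_sd=float(sd[2]),
                condition_label=cond,
            )
            per_rep[(cond, spec.kind)] = vals
    return NoiseGridResult(reports, per_rep)


# ---------------------------------------------------------------------------
# Consensus-set evaluation
# ---------------------------------------------------------------------------

def run_consensus_eval(
    features: np.ndarray,
    partition: ConsensusPartition,
    ann: AnnotationMatrix,
    specs: Sequence[ClassifierSpec],
    n_folds: int = 4,
    seed: int = 0,
) -> tuple[dict[str, PerformanceReport], dict[str, PerformanceReport]]:
    """Cross-validate classifiers on the consensus set, against
    consensus labels, and score each observer against the same labels.

    Returns ``(classifier_reports, observer_reports)``.  Note the
    documented caveat: each observer voted in the consensus the
    classifiers are measured against, which flatters the observers.
    """
    X = np.asarray(features, dtype=float)
    cons_idx = partition.consensus_indices
    if cons_idx.size == 0:
        raise ValueError("consensus set is empty")
    if cons_idx.size < n_folds:
        raise ValueError("consensus set smaller than the number of folds")
    y = partition.consensus_labels[cons_idx].astype(np.int8)
    folds = make_folds(np.arange(cons_idx.size), n_folds, _derive_seed(seed, 50))

    classifier_reports: dict[str, PerformanceReport] = {}
    for s_i, spec in enumerate(specs):
        pooled = ConfusionCounts(0, 0, 0, 0)
        for t in range(n_folds):
            test_loc = folds.fold(t)
            train_loc = np.concatenate([folds.fold(k) for k in range(n_folds) if k != t])
            _audit_disjoint(train_loc, test_loc)
            model = train(
                spec.with_seed(_derive_seed(seed, 60, s_i, t)),
                X[cons_idx[train_loc]],
                y[train_loc],
            )
            pooled = pooled + confusion(predict(model, X[cons_idx[test_loc]]), y[test_loc])
        acc, pre, rec = measures(pooled)
        classifier_reports[spec.kind] = PerformanceReport(
            accuracy=acc, precision=pre, recall=rec, condition_label="consensus_eval"
        )

    observer_reports: dict[str, PerformanceReport] = {}
    for o_i, oid in enumerate(ann.observer_ids):
        acc, pre, rec = measures(confusion(ann.labels[cons_idx, o_i], y))
        observer_reports[oid] = PerformanceReport(
            accuracy=acc, precision=pre, recall=rec, condition_label=f"observer:{oid}"
        )
    return classifier_reports, observer_reports


# ---------------------------------------------------------------------------
# Consensus vs probabilistic test references
# ---------------------------------------------------------------------------

def compare_test_references(
    features: np.ndarray,
    partition: ConsensusPartition,
    ann: AnnotationMatrix,
    spec: ClassifierSpec,
    n_repetitions: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Paired comparison of test-label choices for one fitted model.

    A classifier is trained once on the unanimous (GT) rows and
    evaluated on the non-unanimous (probGT) rows twice: against the
    majority-vote labels, and against freshly drawn probabilistic
    annotations (mean over repetitions).  Measures how much accuracy is
    lost merely by letting annotation noise into the test reference.
    """
    X = np.asarray(features, dtype=float)
    gt, pg = partition.gt_indices, partition.probgt_indices
    if pg.size == 0:
        raise ValueError("no probGT rows to evaluate on")
    gt_labels = _consensus_gt_labels(ann, partition)
    model = train(spec.with_seed(_derive_seed(seed, 70)), X[gt], gt_labels[gt])
    pred = predict(model, X[pg])
    majority = (ann.labels[pg].mean(axis=1) > 0.5).astype(np.int8)
    acc_consensus = float((pred == majority).mean())
    accs = [
        float(
            (
                pred
                == sample_probabilistic_annotation(ann, pg, _derive_seed(seed, 71, r))
            ).mean()
        )
        for r in range(n_repetitions)
    ]
    return {
        "accuracy_vs_consensus": acc_consensus,
        "accuracy_vs_probabilistic": float(np.mean(accs)),
    }
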