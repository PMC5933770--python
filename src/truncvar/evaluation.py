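"""Classifier evaluation: metrics, homology clustering, clustered CV,
and the feature-reduction procedure.

Cross-validation is homology-aware: proteins sharing >= 35% sequence
identity (single-linkage) are confined to the same fold, so no fold is
evaluated on close homologs of its training proteins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .boosting import Hyperparams, train_pair
from .datatypes import ProteinRecord, TruncatingVariant
from .features import FeatureSchema, featurize_dataset

DEFAULT_IDENTITY_CUTOFF = 0.35
DEFAULT_CUTOFF = 0.5


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion-matrix counts with pathogenic as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")


@dataclass
class EvalReport:
    """Threshold metrics plus (optionally) the full ROC sweep."""

    mcc: float
    sensitivity: float
    specificity: float
    f_score: float
    fpr: float
    fdr: float
    counts: Optional[ConfusionCounts] = None
    roc_points: Optional[list[tuple[float, float]]] = None

    def summary(self) -> str:
        lines = [
            "Evaluation report",
            "-----------------",
            f"MCC                   {self.mcc:8.3f}",
            f"Sensitivity           {self.sensitivity:8.3f}",
            f"Specificity           {self.specificity:8.3f}",
            f"F-score               {self.f_score:8.3f}",
            f"False positive rate   {self.fpr:8.3f}",
            f"False discovery rate  {self.fdr:8.3f}",
        ]
        if self.counts is not None:
            c = self.counts
            lines.append(
                f"Counts                TP={c.tp} FP={c.fp} TN={c.tn} FN={c.fn}"
            )
        if self.roc_points is not None:
            lines.append(f"ROC AUC               {auc(self.roc_points):8.3f}")
        return "\n".join(lines)


@dataclass
class ClusterPartition:
    """Single-linkage sequence-identity clusters of a protein set."""

    clusters: list[set[str]]
    identity_cutoff: float


def confusion(scores, labels, cutoff: float = DEFAULT_CUTOFF) -> ConfusionCounts:
    """Count calls at a score cutoff (positive call iff score >= cutoff)."""
    scores = np.asarray(scores, dtype=float)
    labels = list(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels disagree on length")
    bad = {l for l in labels if l not in ("pathogenic", "neutral")}
    if bad:
        raise ValueError(f"unknown labels {sorted(bad)!r}")
    truth = np.array([l == "pathogenic" for l in labels])
    call = scores >= cutoff
    return ConfusionCounts(
        tp=int((call & truth).sum()),
        fp=int((call & ~truth).sum()),
        tn=int((~call & ~truth).sum()),
        fn=int((~call & truth).sum()),
    )


def metrics(counts: ConfusionCounts) -> EvalReport:
    """Threshold metrics from confusion counts.

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)), defined as
    0 when any factor of the denominator vanishes; the F-score is the
    harmonic mean of precision and recall (0 when TP = 0); FDR is the
    fraction of positive calls that are false.
    """
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom > 0 else 0.0
    sensitivity = tp / (tp + fn) if tp + fn else 0.0
    specificity = tn / (tn + fp) if tn + fp else 0.0
    precision = tp / (tp + fp) if tp + fp else 0.0
    f_score = (
        2 * precision * sensitivity / (precision + sensitivity)
        if precision + sensitivity > 0
        else 0.0
    )
    fpr = fp / (tn + fp) if tn + fp else 0.0
    fdr = fp / (tp + fp) if tp + fp else 0.0
    return EvalReport(
        mcc=mcc,
        sensitivity=sensitivity,
        specificity=specificity,
        f_score=f_score,
        fpr=fpr,
        fdr=fdr,
        counts=counts,
    )


def roc_points(scores, labels) -> list[tuple[float, float]]:
    """ROC sweep over all distinct score thresholds.

    Returns (FPR, TPR) points, monotone non-decreasing in both coordinates,
    anchored at (0, 0) and (1, 1).  Requires both classes to be present.
    """
    scores = np.asarray(scores, dtype=float)
    truth = np.array([l == "pathogenic" for l in labels])
    pos = int(truth.sum())
    neg = len(truth) - pos
    if pos == 0 or neg == 0:
        raise ValueError("ROC requires both classes")
    order = np.argsort(-scores, kind="stable")
    sorted_truth = truth[order]
    tps = np.cumsum(sorted_truth)
    fps = np.cumsum(~sorted_truth)
    # Keep only the last index of each distinct score (threshold = that score).
    distinct = np.r_[np.diff(scores[order]) != 0, True]
    points = [(0.0, 0.0)]
    points += [
        (fps[i] / neg, tps[i] / pos) for i in np.where(distinct)[0]
    ]
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def auc(points: Sequence[tuple[float, float]]) -> float:
    """Trapezoidal area under an ROC point list."""
    pts = np.asarray(points, dtype=float)
    return float(np.trapezoid(pts[:, 1], pts[:, 0]))


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment sequence identity of two protein sequences.

    Needleman-Wunsch with match +1, mismatch 0, gap open/extend -1;
    identity = identical aligned positions / min(length).  Symmetric.
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-1,
        extend_gap_score=-1,
    )
    alignment = aligner.align(seq_a, seq_b)[0]
    matches = 0
    for (s1, e1), (s2, e2) in zip(*alignment.aligned):
        matches += sum(
            seq_a[i] == seq_b[j] for i, j in zip(range(s1, e1), range(s2, e2))
        )
    return matches / min(len(seq_a), len(seq_b))


def cluster_sequences(
    proteins: dict[str, ProteinRecord] | dict[str, str],
    cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    identity_fn=pairwise_identity,
) -> ClusterPartition:
    """Single-linkage clustering at a sequence-identity cutoff.

    Any two proteins with identity >= cutoff are joined; clusters are the
    transitive closure (union-find).  ``identity_fn`` is pluggable so other
    identity definitions (e.g. BLAST-style) can be substituted.
    """
    ids = sorted(proteins)
    seqs = {
        pid: (p.sequence if isinstance(p, ProteinRecord) else p)
        for pid, p in proteins.items()
    }
    parent = {pid: pid for pid in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if find(a) == find(b):
                continue
            if identity_fn(seqs[a], seqs[b]) >= cutoff:
                parent[find(b)] = find(a)

    groups: dict[str, set[str]] = {}
    for pid in ids:
        groups.setdefault(find(pid), set()).add(pid)
    clusters = sorted(groups.values(), key=lambda c: sorted(c)[0])
    return ClusterPartition(clusters=clusters, identity_cutoff=cutoff)


def merge_to_k_clusters(partition: ClusterPartition, k: int) -> ClusterPartition:
    """Merge the smallest clusters pairwise until exactly ``k`` remain."""
    if k < 1 or k > len(partition.clusters):
        raise ValueError(
            f"cannot merge {len(partition.clusters)} clusters down to {k}"
        )
    clusters = [set(c) for c in partition.clusters]
    while len(clusters) > k:
        clusters.sort(key=lambda c: (len(c), sorted(c)[0]))
        a = clusters.pop(0)
        clusters[0] |= a
    return ClusterPartition(clusters=clusters, identity_cutoff=partition.identity_cutoff)


def clustered_kfold(
    partition: ClusterPartition, k: int, seed: int = 0
) -> list[set[str]]:
    """Assign whole clusters to ``k`` folds.

    Clusters are shuffled with ``seed``, then dealt round-robin in order of
    descending size so fold sizes stay balanced.  Every protein lands in
    exactly one fold; no protein's variants straddle folds.
    """
    clusters = partition.clusters
    if k > len(clusters):
        raise ValueError(f"requested {k} folds but only {len(clusters)} clusters")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(clusters))
    by_size = sorted(order, key=lambda i: -len(clusters[i]))
    folds: list[set[str]] = [set() for _ in range(k)]
    for slot, ci in enumerate(by_size):
        folds[slot % k] |= clusters[ci]
    return folds


@dataclass
class CrossValidationResult:
    """Pooled held-out scores and the metrics derived from them."""

    report: EvalReport
    scores: np.ndarray
    labels: list[str]
    variants: list[TruncatingVariant]
    folds: list[set[str]]


def crossvalidate(
    proteins: dict[str, ProteinRecord],
    variants: list[TruncatingVariant],
    schema: FeatureSchema,
    k: int = 10,
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
    eval_subset: str = "both",
    cutoff: float = DEFAULT_CUTOFF,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
    folds: Optional[list[set[str]]] = None,
) -> CrossValidationResult:
    """Homology-clustered k-fold cross-validation.

    For each fold a balanced model pair is trained on the other folds'
    variants and scores the held-out variants; all held-out scores are
    pooled, filtered by ``eval_subset`` (``both``/``frameshift``/
    ``nonsense`` — filtering affects only evaluation, never training), and
    reduced to metrics at ``cutoff``.  With ``k`` equal to the number of
    clusters this is leave-one-cluster-out.
    """
    if eval_subset not in ("both", "frameshift", "nonsense"):
        raise ValueError(f"unknown eval_subset {eval_subset!r}")
    labeled = [v for v in variants if v.label in ("pathogenic", "neutral")]
    if not labeled:
        raise ValueError("no labeled variants to cross-validate")
    frame, failures = featurize_dataset(proteins, labeled, schema)
    if failures:
        raise ValueError(
            f"{len(failures)} variants could not be featurized; first: "
            f"{failures[0][1]}"
        )
    if folds is None:
        used = {v.protein_id for v in labeled}
        partition = cluster_sequences(
            {pid: proteins[pid] for pid in used}, cutoff=identity_cutoff
        )
        folds = clustered_kfold(partition, k, seed=seed)

    X = frame[schema.columns].to_numpy(dtype=float)
    y = np.array([l == "pathogenic" for l in frame["label"]])
    pids = frame["protein_id"].to_numpy()

    pooled_scores = np.full(len(labeled), np.nan)
    for fold_i, held in enumerate(folds):
        test_mask = np.isin(pids, sorted(held))
        train_mask = ~test_mask
        if not test_mask.any():
            continue
        n_pos = int(y[train_mask].sum())
        n_neg = int(train_mask.sum()) - n_pos
        if n_pos == 0 or n_neg == 0:
            raise ValueError(
                f"fold {fold_i}: training data contains a single class "
                f"({n_pos} pathogenic, {n_neg} neutral)"
            )
        pair = train_pair(
            X[train_mask & y],
            X[train_mask & ~y],
            seed=seed + fold_i,
            hyperparams=hyperparams,
        )
        pooled_scores[test_mask] = pair.predict(X[test_mask])

    evaluated = np.isfinite(pooled_scores)
    if eval_subset != "both":
        evaluated &= frame["type"].to_numpy() == eval_subset
    scores = pooled_scores[evaluated]
    labels = [frame["label"].iloc[i] for i in np.where(evaluated)[0]]
    report = metrics(confusion(scores, labels, cutoff=cutoff))
    report.roc_points = roc_points(scores, labels)
    return CrossValidationResult(
        report=report,
        scores=scores,
        labels=labels,
        variants=[labeled[i] for i in np.where(evaluated)[0]],
        folds=folds,
    )


@dataclass
class FeatureReductionResult:
    """Outcome of the leave-one-cluster-out feature elimination."""

    final_schema: FeatureSchema
    baseline_mcc: float
    ledger: list[tuple[str, float]] = field(default_factory=list)
    discarded: list[str] = field(default_factory=list)

    def summary(self) -> str:
        lines = [
            "Feature reduction (leave-one-cluster-out)",
            "-----------------------------------------",
            f"baseline MCC (all groups): {self.baseline_mcc:.3f}",
        ]
        for group, mcc in self.ledger:
            verdict = "discarded" if group in self.discarded else "retained"
            lines.append(f"  without {group:<13} MCC {mcc:8.3f}  -> {verdict}")
        lines.append(f"final schema: {self.final_schema.schema_id} "
                     f"({self.final_schema.n_features} features)")
        return "\n".join(lines)


def reduce_features(
    proteins: dict[str, ProteinRecord],
    variants: list[TruncatingVariant],
    candidate_schema: FeatureSchema | None = None,
    seed: int = 0,
    hyperparams: Hyperparams | None = None,
    n_clusters: int = 10,
    cutoff: float = DEFAULT_CUTOFF,
    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
) -> FeatureReductionResult:
    """One-pass feature-group elimination under leave-one-cluster-out CV.

    Proteins are clustered at the identity cutoff, merged down to
    ``n_clusters`` clusters, and each cluster is held out in turn.  A group
    is discarded iff removing it strictly improves the pooled MCC at the
    default score cutoff over the full-schema baseline.  The elimination is
    a single pass against the fixed baseline, in schema order.
    """
    schema = candidate_schema or FeatureSchema.candidate66()
    if len(schema.groups) < 2:
        raise ValueError("candidate schema needs at least two groups")
    labeled = [v for v in variants if v.label in ("pathogenic", "neutral")]
    used = {v.protein_id for v in labeled}
    partition = cluster_sequences(
        {pid: proteins[pid] for pid in used}, cutoff=identity_cutoff
    )
    partition = merge_to_k_clusters(partition, min(n_clusters, len(partition.clusters)))
    folds = [set(c) for c in partition.clusters]  # leave one cluster out

    def loocv_mcc(s: FeatureSchema) -> float:
        result = crossvalidate(
            proteins,
            labeled,
            s,
            k=len(folds),
            seed=seed,
            hyperparams=hyperparams,
            cutoff=cutoff,
            folds=folds,
        )
        return result.report.mcc

    baseline = loocv_mcc(schema)
    ledger: list[tuple[str, float]] = []
    discarded: list[str] = []
    for group in schema.groups:
        mcc_without = loocv_mcc(schema.without(group))
        ledger.append((group, mcc_without))
        if mcc_without > baseline:
            discarded.append(group)
    final = schema
    for group in discarded:
        final = final.without(group)
    if set(final.groups) == set(FeatureSchema.final46().groups):
        final = FeatureSchema.final46()
    return FeatureReductionResult(
        final_schema=final,
        baseline_mcc=baseline,
        ledger=ledger,
        discarded=discarded,
    )
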