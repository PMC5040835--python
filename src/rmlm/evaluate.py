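"""Fivefold cross-validation, ROC/AUC, and threshold link counting.

Known miRNA-target links are split into five random folds; each fold in
turn is hidden from the network (its entries zeroed in the link relation
and its inverse), the full RM feature stack is recomputed from the masked
network, a model is fitted on the remaining positives plus sampled unknown
pairs, and the hidden links are scored against sampled unknown test pairs.
Recomputing features from the masked network is what makes the protocol
leakage-free: a held-out link never contributes path counts to its own
features, and this is asserted per fold.

Three scoring methods are supported: the fitted logistic model over RM
channels (RMLM), the same with three binary sequence-evidence channels
(RMLMSe), and the unweighted sum of RM channels (RM-sum), a fit-free
baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_auc_score, roc_curve

from .features import (
    PairIndex,
    SequenceEvidence,
    append_sequence_features,
    build_rmlm_features,
)
from .hetnet import HeteroNetwork, enumerate_metapaths
from .model import (
    ScoreTable,
    TrainingSet,
    fit_weights,
    posterior,
    sample_negative_pairs,
)
from .relatedness import RelatednessMatrix, rm_stack

__all__ = [
    "FoldAssignment",
    "EvaluationReport",
    "CVConfig",
    "split_folds",
    "roc_auc",
    "rm_sum_baseline",
    "cross_validate",
    "count_above_thresholds",
]

METHODS = ("RMLM", "RMLMSe", "RM-sum")


@dataclass(frozen=True)
class FoldAssignment:
    """A disjoint k-way split of the known positives."""

    k: int
    fold_of: tuple[int, ...]
    seed: int

    def fold_pairs(self, positives: PairIndex, fold: int) -> PairIndex:
        return PairIndex(tuple(
            p for p, f in zip(positives.pairs, self.fold_of) if f == fold))

    def rest_pairs(self, positives: PairIndex, fold: int) -> PairIndex:
        return PairIndex(tuple(
            p for p, f in zip(positives.pairs, self.fold_of) if f != fold))


@dataclass
class CVConfig:
    """Everything that determines a cross-validation run."""

    k: int = 5
    seed: int = 0
    method: str = "RMLM"
    max_len: int = 3
    ridge: float = 1e-4
    negative_ratio: float = 1.0
    test_negative_ratio: float = 10.0
    mirna_type: str = "mirna"
    gene_type: str = "gene"
    link_relation: str = "regulate"
    sequence_evidence: list[SequenceEvidence] | None = None

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method == "RMLMSe" and not self.sequence_evidence:
            raise ValueError("RMLMSe requires sequence evidence")


@dataclass
class EvaluationReport:
    fold_aucs: list[float]
    mean_auc: float
    pooled_roc: tuple[np.ndarray, np.ndarray]
    pooled_auc: float
    config: dict = field(default_factory=dict)


def split_folds(positives: PairIndex, k: int, seed: int) -> FoldAssignment:
    """Random k-way split with fold sizes differing by at most one."""
    if k < 2:
        raise ValueError("k must be at least 2")
    n = len(positives)
    if n < k:
        raise ValueError(f"need at least {k} positives, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(order, k)):
        fold_of[chunk] = f
    return FoldAssignment(k, tuple(int(f) for f in fold_of), seed)


def roc_auc(scores, labels) -> tuple[tuple[np.ndarray, np.ndarray], float]:
    """ROC points and AUC (the tie-corrected Mann-Whitney probability)."""
    y = np.asarray(labels, dtype=float).ravel()
    s = np.asarray(scores, dtype=float).ravel()
    if y.min() == y.max():
        raise ValueError("both classes must be present to compute a ROC curve")
    fpr, tpr, _ = roc_curve(y, s)
    return (fpr, tpr), float(roc_auc_score(y, s))


def rm_sum_baseline(stack: list[RelatednessMatrix], pairs: PairIndex) -> np.ndarray:
    """Unweighted sum of RM channels at each pair (fit-free comparator)."""
    if not stack:
        raise ValueError("relatedness stack is empty")
    return build_rmlm_features(stack, pairs).values.sum(axis=1)


def _fold_features(stack, pairs, config, net):
    table = build_rmlm_features(stack, pairs)
    if config.method == "RMLMSe":
        table = append_sequence_features(
            table,
            config.sequence_evidence,
            net.catalogs[config.mirna_type],
            net.catalogs[config.gene_type],
        )
    return table


def cross_validate(
    net: HeteroNetwork, positives: PairIndex, config: CVConfig
) -> EvaluationReport:
    """Leakage-free k-fold evaluation of link recovery.

    Per fold: zero the held-out positives in the link relation, recompute
    the RM stack from the masked network, fit on the remaining positives
    plus uniformly sampled unknown pairs, then score the held-out positives
    against unknown test pairs drawn from the same miRNAs.
    """
    folds = split_folds(positives, config.k, config.seed)
    mirna_paths = enumerate_metapaths(net, config.mirna_type, config.max_len)
    gene_paths = enumerate_metapaths(net, config.gene_type, config.max_len)
    inv_name = config.link_relation + "^-1"

    fold_aucs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []

    for fold in range(config.k):
        test_pos = folds.fold_pairs(positives, fold)
        train_pos = folds.rest_pairs(positives, fold)
        rng = np.random.default_rng([config.seed, fold])

        masked = net.copy()
        w = masked.relation(config.link_relation).weights
        w[test_pos.rows(), test_pos.cols()] = 0.0
        masked.relation(inv_name).weights = w.T.copy()
        # leakage guard: a held-out positive must be invisible to features
        if w[test_pos.rows(), test_pos.cols()].any():
            raise AssertionError("leakage: held-out positive still present in W")

        stack = rm_stack(masked, mirna_paths, gene_paths, config.link_relation)

        # test negatives are set aside first so training never sees them;
        # capped at half the unknown pool so training keeps its own share
        w_full = net.relation(config.link_relation).weights
        n_unknown = int(np.sum(w_full == 0))
        n_test_neg = min(
            int(round(config.test_negative_ratio * len(test_pos))),
            n_unknown // 2,
        )
        test_neg = sample_negative_pairs(
            net.relation(config.link_relation).weights, positives,
            n_test_neg, rng, mirna_rows=np.unique(test_pos.rows()))
        n_train_neg = int(round(config.negative_ratio * len(train_pos)))
        exclude = PairIndex(positives.pairs + test_neg.pairs)
        train_neg = sample_negative_pairs(
            net.relation(config.link_relation).weights, exclude,
            n_train_neg, rng)
        if not len(train_neg) or not len(test_neg):
            raise ValueError(
                "not enough unknown pairs to sample negatives; "
                "the network is almost fully linked")

        test_pairs = PairIndex(test_pos.pairs + test_neg.pairs)
        test_labels = np.concatenate(
            [np.ones(len(test_pos)), np.zeros(len(test_neg))])

        if config.method == "RM-sum":
            scores = rm_sum_baseline(stack, test_pairs)
        else:
            train_pairs = PairIndex(train_pos.pairs + train_neg.pairs)
            train_labels = np.concatenate(
                [np.ones(len(train_pos)), np.zeros(len(train_neg))])
            table = _fold_features(stack, train_pairs, config, net)
            weights = fit_weights(
                TrainingSet(table, train_labels), ridge=config.ridge)
            test_table = _fold_features(stack, test_pairs, config, net)
            scores = np.atleast_1d(posterior(test_table.values, weights))

        _, auc = roc_auc(scores, test_labels)
        fold_aucs.append(auc)
        pooled_scores.append(np.asarray(scores, dtype=float))
        pooled_labels.append(test_labels)

    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    (fpr, tpr), pooled = roc_auc(all_scores, all_labels)

    echo = asdict(config)
    echo["sequence_evidence"] = (
        None if config.sequence_evidence is None
        else {ev.source: len(ev.pairs) for ev in config.sequence_evidence})
    return EvaluationReport(
        fold_aucs=fold_aucs,
        mean_auc=float(np.mean(fold_aucs)),
        pooled_roc=(fpr, tpr),
        pooled_auc=pooled,
        config=echo,
    )


def count_above_thresholds(finals: ScoreTable | np.ndarray,
                           thresholds: list[float]) -> list[int]:
    """Number of pairs whose final score reaches each threshold."""
    q = finals.final if isinstance(finals, ScoreTable) else np.asarray(finals)
    for th in thresholds:
        if not (0.0 <= th <= 1.0):
            raise ValueError(f"threshold {th} outside [0, 1]")
    return [int(np.sum(q >= th)) for th in thresholds]
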