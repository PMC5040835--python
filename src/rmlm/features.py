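"""Per-pair feature assembly.

A candidate miRNA-gene pair is described by one RM relatedness value per
meta-path channel (the RMLM feature vector) and, optionally, three binary
indicators of sequence-based support (the RMLMSe extension): conserved
TargetScan predictions with Pct above 0.9, miRanda predictions with mirSVR
score above 0.6, and membership in the PITA top list.  Sequence evidence
enters as hard-filtered indicators, not raw scores, because the three
tools' scores are not commensurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .hetnet import NodeCatalog
from .relatedness import RelatednessMatrix

logger = logging.getLogger(__name__)

SEQUENCE_SOURCES = ("targetscan", "miranda", "pita")

TARGETSCAN_PCT_THRESHOLD = 0.9
MIRANDA_MIRSVR_THRESHOLD = 0.6

__all__ = [
    "PairIndex",
    "FeatureTable",
    "SequenceEvidence",
    "build_rmlm_features",
    "filter_targetscan",
    "filter_miranda",
    "filter_pita",
    "append_sequence_features",
    "SEQUENCE_SOURCES",
]


@dataclass(frozen=True)
class PairIndex:
    """An ordered, duplicate-free list of (miRNA index, gene index) pairs."""

    pairs: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        pairs = tuple((int(i), int(j)) for i, j in self.pairs)
        if len(set(pairs)) != len(pairs):
            raise ValueError("duplicate pairs in pair index")
        object.__setattr__(self, "pairs", pairs)

    def __len__(self) -> int:
        return len(self.pairs)

    def rows(self) -> np.ndarray:
        return np.array([p[0] for p in self.pairs], dtype=int)

    def cols(self) -> np.ndarray:
        return np.array([p[1] for p in self.pairs], dtype=int)

    @staticmethod
    def all_cells(n_mirna: int, n_gene: int) -> "PairIndex":
        return PairIndex(tuple(
            (i, j) for i in range(n_mirna) for j in range(n_gene)
        ))


@dataclass
class FeatureTable:
    """Pairs-by-features matrix with labelled columns."""

    pair_index: PairIndex
    columns: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.pair_index), len(self.columns)):
            raise ValueError("feature matrix shape does not match index/columns")
        if len(set(self.columns)) != len(self.columns):
            raise ValueError("feature column labels must be unique")
        self.values = v


@dataclass(frozen=True)
class SequenceEvidence:
    """Identifier pairs from one sequence predictor that survive its filter."""

    source: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        if self.source not in SEQUENCE_SOURCES:
            raise ValueError(f"unknown sequence source {self.source!r}")
        object.__setattr__(self, "pairs", frozenset(self.pairs))


def build_rmlm_features(
    stack: list[RelatednessMatrix], pairs: PairIndex
) -> FeatureTable:
    """Gather each RM channel's value at each candidate pair."""
    if not stack:
        raise ValueError("relatedness stack is empty")
    rows, cols = pairs.rows(), pairs.cols()
    n_mirna, n_gene = stack[0].values.shape
    if len(pairs) and (rows.max() >= n_mirna or cols.max() >= n_gene
                       or rows.min() < 0 or cols.min() < 0):
        raise IndexError("pair index out of range for the relatedness matrices")
    values = np.column_stack([ch.values[rows, cols] for ch in stack]) \
        if len(pairs) else np.zeros((0, len(stack)))
    return FeatureTable(pairs, tuple(ch.label for ch in stack), values)


def _check_numeric(score, source: str) -> float:
    try:
        return float(score)
    except (TypeError, ValueError):
        raise ValueError(f"non-numeric {source} score: {score!r}") from None


def filter_targetscan(records: list[tuple[str, str, float]]) -> SequenceEvidence:
    """Keep conserved predictions with Pct strictly greater than 0.9."""
    kept = {
        (m, g) for m, g, pct in records
        if _check_numeric(pct, "targetscan") > TARGETSCAN_PCT_THRESHOLD
    }
    return SequenceEvidence("targetscan", frozenset(kept))


def filter_miranda(
    records: list[tuple[str, str, float]], abs_mode: bool = False
) -> SequenceEvidence:
    """Keep predictions with mirSVR score strictly greater than 0.6.

    mirSVR scores are conventionally negative (more negative = stronger
    downregulation); ``abs_mode`` compares the magnitude instead of the
    literal signed value.
    """
    kept = set()
    for m, g, score in records:
        s = _check_numeric(score, "miranda")
        if abs_mode:
            s = abs(s)
        if s > MIRANDA_MIRSVR_THRESHOLD:
            kept.add((m, g))
    return SequenceEvidence("miranda", frozenset(kept))


def filter_pita(records: list[tuple[str, str]]) -> SequenceEvidence:
    """PITA top-list membership, deduplicated; the ranking is external."""
    return SequenceEvidence("pita", frozenset((m, g) for m, g in records))


def append_sequence_features(
    table: FeatureTable,
    evidence: list[SequenceEvidence],
    mirna_catalog: NodeCatalog,
    gene_catalog: NodeCatalog,
) -> FeatureTable:
    """Append the three binary sequence-support columns in fixed order.

    Sources missing from ``evidence`` contribute an all-zero column.
    Evidence pairs whose identifiers do not resolve to catalog entries are
    ignored with a logged count.
    """
    by_source: dict[str, SequenceEvidence] = {}
    for ev in evidence:
        if ev.source in by_source:
            raise ValueError(f"duplicate sequence source {ev.source!r}")
        by_source[ev.source] = ev

    mirna_idx = {m: i for i, m in enumerate(mirna_catalog.ids)}
    gene_idx = {g: j for j, g in enumerate(gene_catalog.ids)}

    extra = np.zeros((len(table.pair_index), len(SEQUENCE_SOURCES)))
    pair_pos = {p: r for r, p in enumerate(table.pair_index.pairs)}
    for c, source in enumerate(SEQUENCE_SOURCES):
        ev = by_source.get(source)
        if ev is None:
            continue
        unresolved = 0
        for m, g in ev.pairs:
            if m not in mirna_idx or g not in gene_idx:
                unresolved += 1
                continue
            r = pair_pos.get((mirna_idx[m], gene_idx[g]))
            if r is not None:
                extra[r, c] = 1.0
        if unresolved:
            logger.info(
                "sequence source %s: %d pairs with unresolvable ids ignored",
                source, unresolved,
            )
    return FeatureTable(
        table.pair_index,
        table.columns + tuple(f"seq:{s}" for s in SEQUENCE_SOURCES),
        np.hstack([table.values, extra]),
    )
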