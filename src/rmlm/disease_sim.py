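"""miRNA functional similarity from disease annotations (MISIM scheme).

miRNAs that act in similar processes tend to be implicated in similar
diseases.  This module turns per-miRNA disease profiles plus a disease
hierarchy (a MeSH-style directed acyclic graph) into a dense miRNA-miRNA
similarity matrix ``SM``:

1. every disease gets a *semantic contribution* score for itself and each
   ancestor, decaying by a factor ``delta`` per hierarchy level;
2. two diseases are compared by the contributions of their shared
   ancestors, normalised by their total semantic values;
3. two miRNAs are compared by best-match averaging of the pairwise disease
   similarities across their two disease sets.

All scores lie in ``[0, 1]``; a miRNA is maximally similar (1) to itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hetnet import RelationMatrix

__all__ = [
    "DiseaseDAG",
    "MiRNADiseaseProfile",
    "DiseaseSimilarityMatrix",
    "semantic_contribution",
    "semantic_value",
    "disease_pair_similarity",
    "mirna_functional_similarity",
    "build_similarity_matrix",
]


@dataclass
class DiseaseDAG:
    """A disease hierarchy as a set of terms with (parent, child) edges.

    A term may occupy several positions in the hierarchy (multiple parents);
    its ancestor closure is the union over all positions.  ``delta`` is the
    per-level decay of semantic contribution, in ``(0, 1)``.
    """

    terms: frozenset[str]
    parent_edges: frozenset[tuple[str, str]]
    delta: float = 0.5
    _parents: dict[str, set[str]] = field(init=False, repr=False)
    _children: dict[str, set[str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not (0.0 < self.delta < 1.0):
            raise ValueError("delta must lie in (0, 1)")
        self.terms = frozenset(self.terms)
        self.parent_edges = frozenset(self.parent_edges)
        self._parents = {t: set() for t in self.terms}
        self._children = {t: set() for t in self.terms}
        for parent, child in self.parent_edges:
            if parent not in self.terms or child not in self.terms:
                raise ValueError(f"edge ({parent!r}, {child!r}) references unknown term")
            self._parents[child].add(parent)
            self._children[parent].add(child)
        self._check_acyclic()

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(t: str) -> None:
            state[t] = 1
            for p in self._parents[t]:
                s = state.get(p, 0)
                if s == 1:
                    raise ValueError("disease hierarchy contains a cycle")
                if s == 0:
                    visit(p)
            state[t] = 2

        for term in self.terms:
            if state.get(term, 0) == 0:
                visit(term)

    def parents(self, term: str) -> set[str]:
        self._require(term)
        return set(self._parents[term])

    def children(self, term: str) -> set[str]:
        self._require(term)
        return set(self._children[term])

    def ancestor_closure(self, term: str) -> set[str]:
        """The term plus all its ancestors, over every hierarchy position."""
        self._require(term)
        closure = {term}
        frontier = [term]
        while frontier:
            t = frontier.pop()
            for p in self._parents[t]:
                if p not in closure:
                    closure.add(p)
                    frontier.append(p)
        return closure

    def _require(self, term: str) -> None:
        if term not in self.terms:
            raise KeyError(f"unknown disease term {term!r}")


@dataclass(frozen=True)
class MiRNADiseaseProfile:
    """The nonempty set of diseases a miRNA is associated with."""

    mirna_id: str
    diseases: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "diseases", frozenset(self.diseases))
        if not self.diseases:
            raise ValueError(f"miRNA {self.mirna_id!r} has an empty disease set")


@dataclass
class DiseaseSimilarityMatrix:
    """Symmetric disease-disease similarity with unit diagonal."""

    disease_ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        n = len(self.disease_ids)
        if v.shape != (n, n):
            raise ValueError("similarity matrix shape does not match disease ids")
        if not np.allclose(v, v.T):
            raise ValueError("similarity matrix must be symmetric")
        if not np.allclose(np.diag(v), 1.0):
            raise ValueError("similarity matrix diagonal must be 1")
        if v.size and (v.min() < -1e-12 or v.max() > 1.0 + 1e-12):
            raise ValueError("similarity values outside [0, 1]")
        self.values = np.clip(v, 0.0, 1.0)
        self._index = {d: i for i, d in enumerate(self.disease_ids)}

    def get(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])


def semantic_contribution(dag: DiseaseDAG, disease: str) -> dict[str, float]:
    """Decayed contribution of ``disease`` to itself and each ancestor.

    The disease contributes 1 to itself; an ancestor ``t`` receives
    ``delta`` times the best contribution among its children inside the
    disease's ancestor closure.
    """
    closure = dag.ancestor_closure(disease)
    scores: dict[str, float] = {disease: 1.0}

    def score(t: str) -> float:
        if t in scores:
            return scores[t]
        inside = [c for c in dag.children(t) if c in closure]
        # t is an ancestor of `disease`, so at least one child is in the closure
        scores[t] = dag.delta * max(score(c) for c in inside)
        return scores[t]

    for t in closure:
        score(t)
    return scores


def semantic_value(dag: DiseaseDAG, disease: str) -> float:
    """Total semantic value: sum of contributions over the ancestor closure."""
    return float(sum(semantic_contribution(dag, disease).values()))


def disease_pair_similarity(dag: DiseaseDAG, a: str, b: str) -> float:
    """Similarity of two diseases through their shared ancestry.

    Sum of both diseases' contributions over the shared part of their
    ancestor closures, normalised by the sum of their semantic values.
    """
    ca = semantic_contribution(dag, a)
    cb = semantic_contribution(dag, b)
    shared = set(ca) & set(cb)
    if not shared:
        return 0.0
    num = sum(ca[t] + cb[t] for t in shared)
    return float(num / (sum(ca.values()) + sum(cb.values())))


def _best_match_sum(from_set: list[str], to_set: list[str],
                    dsim: DiseaseSimilarityMatrix) -> float:
    return sum(max(dsim.get(d, e) for e in to_set) for d in from_set)


def mirna_functional_similarity(
    profile_i: MiRNADiseaseProfile,
    profile_j: MiRNADiseaseProfile,
    dsim: DiseaseSimilarityMatrix,
) -> float:
    """Best-match average of disease similarities across two disease sets."""
    di = sorted(profile_i.diseases)
    dj = sorted(profile_j.diseases)
    total = _best_match_sum(di, dj, dsim) + _best_match_sum(dj, di, dsim)
    return float(total / (len(di) + len(dj)))


def build_disease_similarity(dag: DiseaseDAG, diseases: list[str]) -> DiseaseSimilarityMatrix:
    """Pairwise disease similarity over the given terms."""
    n = len(diseases)
    contrib = {d: semantic_contribution(dag, d) for d in diseases}
    values = np.eye(n)
    for i in range(n):
        ci = contrib[diseases[i]]
        sv_i = sum(ci.values())
        for j in range(i + 1, n):
            cj = contrib[diseases[j]]
            shared = set(ci) & set(cj)
            if shared:
                s = sum(ci[t] + cj[t] for t in shared) / (sv_i + sum(cj.values()))
            else:
                s = 0.0
            values[i, j] = values[j, i] = s
    return DiseaseSimilarityMatrix(tuple(diseases), values)


def build_similarity_matrix(
    profiles: list[MiRNADiseaseProfile],
    dag: DiseaseDAG,
    *,
    relation_name: str = "sim",
    node_type: str = "mirna",
) -> RelationMatrix:
    """The dense miRNA-miRNA functional similarity matrix ``SM``.

    Row/column order follows the profile order; the result is symmetric
    with unit diagonal and is returned as a same-type relation ready for
    registration in a heterogeneous network.
    """
    if not profiles:
        raise ValueError("need at least one miRNA profile")
    diseases = sorted({d for p in profiles for d in p.diseases})
    for d in diseases:
        if d not in dag.terms:
            raise KeyError(f"profile disease {d!r} missing from the hierarchy")
    dsim = build_disease_similarity(dag, diseases)
    n = len(profiles)
    sm = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            sm[i, j] = sm[j, i] = mirna_functional_similarity(
                profiles[i], profiles[j], dsim
            )
    return RelationMatrix(relation_name, node_type, node_type, sm)
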