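"""Typed heterogeneous network model and meta-path machinery.

A heterogeneous information network couples several node types (here
typically ``mirna`` and ``gene``) through named, weighted relations.  Each
relation carries a weight matrix with entries in ``[0, 1]`` interpreted as
link existence probabilities; an unknown link is exactly 0.  Registering a
relation automatically registers its inverse (transposed weights, name
suffixed ``^-1``) so that meta-paths can traverse links in either direction.

A *meta-path* is an ordered, type-consistent sequence of relation names.
The weighted number of path instances between two nodes along a meta-path
is the corresponding entry of the product of the step weight matrices; the
empty meta-path acts as the identity.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

INVERSE_SUFFIX = "^-1"

__all__ = [
    "NodeCatalog",
    "RelationMatrix",
    "HeteroNetwork",
    "MetaPath",
    "register_relation",
    "enumerate_metapaths",
    "compose_metapath",
    "path_count_matrix",
    "INVERSE_SUFFIX",
]


@dataclass(frozen=True)
class NodeCatalog:
    """An ordered catalog of node identifiers of one type.

    The order of ``ids`` is the row/column index authority for every
    relation touching this type and is fixed at construction.
    """

    type_name: str
    ids: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = tuple(str(i) for i in self.ids)
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate node ids in catalog {self.type_name!r}")
        object.__setattr__(self, "ids", ids)

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, node_id: str) -> int:
        return self.ids.index(node_id)


@dataclass
class RelationMatrix:
    """A named weighted relation between two node types.

    ``weights[s, t]`` is the existence probability of a link from the
    ``s``-th source node to the ``t``-th target node; entries lie in
    ``[0, 1]`` and unknown links are exactly 0.
    """

    name: str
    source_type: str
    target_type: str
    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError(f"relation {self.name!r}: weights must be 2-D")
        if w.size and (w.min() < 0.0 or w.max() > 1.0):
            raise ValueError(f"relation {self.name!r}: weights outside [0, 1]")
        self.weights = w

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape

    def inverse(self) -> "RelationMatrix":
        return RelationMatrix(
            name=self.name + INVERSE_SUFFIX,
            source_type=self.target_type,
            target_type=self.source_type,
            weights=self.weights.T.copy(),
        )

    def is_symmetric(self) -> bool:
        return (
            self.source_type == self.target_type
            and self.weights.shape[0] == self.weights.shape[1]
            and np.array_equal(self.weights, self.weights.T)
        )


@dataclass(frozen=True)
class MetaPath:
    """An ordered, type-consistent sequence of relation names.

    The empty sequence is the identity meta-path and is legal only when
    ``source_type == target_type``.
    """

    relation_names: tuple[str, ...]
    source_type: str
    target_type: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "relation_names", tuple(self.relation_names))
        if not self.relation_names and self.source_type != self.target_type:
            raise ValueError("empty meta-path requires matching endpoint types")

    @property
    def length(self) -> int:
        return len(self.relation_names)

    def label(self) -> str:
        return "[" + ",".join(self.relation_names) + "]"


@dataclass
class HeteroNetwork:
    """Catalogs of typed nodes plus named relations (with inverses)."""

    catalogs: dict[str, NodeCatalog] = field(default_factory=dict)
    relations: dict[str, RelationMatrix] = field(default_factory=dict)

    def add_catalog(self, catalog: NodeCatalog) -> None:
        if catalog.type_name in self.catalogs:
            raise ValueError(f"catalog {catalog.type_name!r} already present")
        self.catalogs[catalog.type_name] = catalog

    def relation(self, name: str) -> RelationMatrix:
        try:
            return self.relations[name]
        except KeyError:
            raise KeyError(f"unknown relation {name!r}") from None

    def copy(self) -> "HeteroNetwork":
        net = HeteroNetwork(catalogs=dict(self.catalogs))
        for name, rel in self.relations.items():
            net.relations[name] = RelationMatrix(
                rel.name, rel.source_type, rel.target_type, rel.weights.copy()
            )
        return net

    def validate_metapath(self, mp: MetaPath) -> None:
        """Check that every step exists and the type chain is consistent."""
        current = mp.source_type
        for name in mp.relation_names:
            rel = self.relation(name)
            if rel.source_type != current:
                raise ValueError(
                    f"meta-path step {name!r} expects source type "
                    f"{rel.source_type!r}, got {current!r}"
                )
            current = rel.target_type
        if current != mp.target_type:
            raise ValueError(
                f"meta-path ends at type {current!r}, declared {mp.target_type!r}"
            )


def register_relation(net: HeteroNetwork, rel: RelationMatrix) -> HeteroNetwork:
    """Register ``rel`` and its inverse in ``net`` (mutates and returns it)."""
    for t in (rel.source_type, rel.target_type):
        if t not in net.catalogs:
            raise KeyError(f"relation {rel.name!r} references unknown type {t!r}")
    expected = (len(net.catalogs[rel.source_type]), len(net.catalogs[rel.target_type]))
    if rel.shape != expected:
        raise ValueError(
            f"relation {rel.name!r}: shape {rel.shape} does not match catalogs {expected}"
        )
    inv = rel.inverse()
    for r in (rel, inv):
        if r.name in net.relations:
            raise ValueError(f"relation {r.name!r} already registered")
    net.relations[rel.name] = rel
    net.relations[inv.name] = inv
    return net


def _step_names(net: HeteroNetwork, source_type: str) -> list[str]:
    """Relation names usable as a meta-path step out of ``source_type``.

    Inverse aliases of *symmetric same-type* relations are excluded: the
    alias carries identical weights, so keeping it would enumerate every
    meta-path through that relation twice under two names.
    """
    names = []
    for name, rel in net.relations.items():
        if rel.source_type != source_type:
            continue
        if name.endswith(INVERSE_SUFFIX):
            base = net.relations.get(name[: -len(INVERSE_SUFFIX)])
            if base is not None and base.is_symmetric():
                continue
        names.append(name)
    return names


def enumerate_metapaths(
    net: HeteroNetwork, node_type: str, max_len: int
) -> list[MetaPath]:
    """All type-consistent meta-paths from ``node_type`` back to itself.

    Includes the empty (identity) path; ordered canonically by length and
    then lexicographically on relation names, so feature-channel identity
    is stable across runs.
    """
    if node_type not in net.catalogs:
        raise KeyError(f"unknown node type {node_type!r}")
    if max_len < 0:
        raise ValueError("max_len must be >= 0")

    found: list[MetaPath] = [MetaPath((), node_type, node_type)]

    def extend(prefix: tuple[str, ...], current: str) -> None:
        if len(prefix) == max_len:
            return
        for name in _step_names(net, current):
            target = net.relations[name].target_type
            seq = prefix + (name,)
            if target == node_type:
                found.append(MetaPath(seq, node_type, node_type))
            extend(seq, target)

    extend((), node_type)
    found.sort(key=lambda mp: (mp.length, mp.relation_names))
    return found


def compose_metapath(p_iis: MetaPath, r_ij: str, p_jjt: MetaPath, *,
                     net: HeteroNetwork | None = None) -> MetaPath:
    """Join a source-side loop, a cross-type relation and a target-side loop.

    When ``net`` is given the type chain of the result is validated against
    the registered relations.
    """
    if p_iis.source_type != p_iis.target_type or p_jjt.source_type != p_jjt.target_type:
        raise ValueError("side meta-paths must start and end on their own type")
    composed = MetaPath(
        p_iis.relation_names + (r_ij,) + p_jjt.relation_names,
        p_iis.source_type,
        p_jjt.target_type,
    )
    if net is not None:
        rel = net.relation(r_ij)
        if rel.source_type != p_iis.target_type or rel.target_type != p_jjt.source_type:
            raise ValueError(
                f"relation {r_ij!r} does not link {p_iis.target_type!r} "
                f"to {p_jjt.source_type!r}"
            )
        net.validate_metapath(composed)
    return composed


def path_count_matrix(net: HeteroNetwork, mp: MetaPath) -> np.ndarray:
    """Weighted path-instance counts along ``mp`` as a matrix product.

    The empty meta-path yields the identity.  For binary weights, entry
    ``(p, q)`` is the number of concrete path instances from node ``p`` to
    node ``q`` following the meta-path.
    """
    net.validate_metapath(mp)
    n_source = len(net.catalogs[mp.source_type])
    result = np.eye(n_source)
    for name in mp.relation_names:
        result = result @ net.relations[name].weights
    return result


def reverse_metapath(net: HeteroNetwork, mp: MetaPath) -> MetaPath:
    """The inverse meta-path: reversed steps, each relation inverted."""
    inverted = []
    for name in reversed(mp.relation_names):
        if name.endswith(INVERSE_SUFFIX):
            inverted.append(name[: -len(INVERSE_SUFFIX)])
        else:
            inverted.append(name + INVERSE_SUFFIX)
    return MetaPath(tuple(inverted), mp.target_type, mp.source_type)


def product_metapath_pairs(
    mirna_paths: list[MetaPath], gene_paths: list[MetaPath]
) -> list[tuple[MetaPath, MetaPath]]:
    """Canonical (miRNA-side, gene-side) pair order used for feature channels."""
    return list(itertools.product(mirna_paths, gene_paths))
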