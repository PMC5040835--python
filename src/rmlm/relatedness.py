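"""RM relatedness along composite meta-paths.

The RM measure scores a candidate miRNA-gene link by the Linkage Homophily
Principle: two nodes are likely linked if most of their meta-path
neighbours are linked.  For a miRNA-side loop meta-path with path-count
matrix ``RMP_ii`` and a gene-side loop with ``RMP_jj``, the expected
weighted path count through the central miRNA->gene relation ``W`` is

    RMP_ii @ W @ RMP_jj

and the RM score divides it by the same quantity with ``W`` replaced by the
all-ones matrix, giving a value in ``[0, 1]``.  Each (miRNA-side path,
gene-side path) pair yields one relatedness matrix — one feature channel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hetnet import HeteroNetwork, MetaPath, path_count_matrix, product_metapath_pairs

__all__ = [
    "RelatednessMatrix",
    "expected_path_number",
    "rm_denominator",
    "rm_score",
    "rm_stack",
]


@dataclass
class RelatednessMatrix:
    """RM scores for one composite meta-path (one feature channel)."""

    metapath_pair: tuple[MetaPath, MetaPath]
    values: np.ndarray

    @property
    def label(self) -> str:
        left, right = self.metapath_pair
        return f"{left.label()}|{right.label()}"


def expected_path_number(
    rmp_iis: np.ndarray, w_ij: np.ndarray, rmp_jjt: np.ndarray
) -> np.ndarray:
    """Expected weighted path count: the triple matrix product."""
    rmp_iis = np.asarray(rmp_iis, dtype=float)
    w_ij = np.asarray(w_ij, dtype=float)
    rmp_jjt = np.asarray(rmp_jjt, dtype=float)
    return rmp_iis @ w_ij @ rmp_jjt


def rm_denominator(rmp_iis: np.ndarray, rmp_jjt: np.ndarray) -> np.ndarray:
    """Triple product with the all-ones central matrix.

    Entry (p, q) is rowsum_p(rmp_iis) * colsum_q(rmp_jjt); computed as an
    outer product so the all-ones matrix is never materialised.
    """
    rmp_iis = np.asarray(rmp_iis, dtype=float)
    rmp_jjt = np.asarray(rmp_jjt, dtype=float)
    return np.outer(rmp_iis.sum(axis=1), rmp_jjt.sum(axis=0))


def rm_score(
    rmp_iis: np.ndarray,
    w_ij: np.ndarray,
    rmp_jjt: np.ndarray,
    metapath_pair: tuple[MetaPath, MetaPath] | None = None,
) -> RelatednessMatrix:
    """RM relatedness: expected path count over its all-ones normaliser.

    Entries with a zero denominator (nodes isolated under the meta-path,
    hence no evidence either way) are set to 0.  Because central weights
    lie in [0, 1] the quotient is bounded by 1.
    """
    num = expected_path_number(rmp_iis, w_ij, rmp_jjt)
    den = rm_denominator(rmp_iis, rmp_jjt)
    values = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    # guard against float round-off at entries where num ~= den
    np.clip(values, 0.0, 1.0, out=values)
    if metapath_pair is None:
        metapath_pair = (MetaPath((), "i", "i"), MetaPath((), "j", "j"))
    return RelatednessMatrix(metapath_pair, values)


def rm_stack(
    net: HeteroNetwork,
    mirna_paths: list[MetaPath],
    gene_paths: list[MetaPath],
    link_relation: str,
) -> list[RelatednessMatrix]:
    """One RM channel per (miRNA-side, gene-side) meta-path pair.

    Channels appear in canonical pair order (miRNA paths outer, gene paths
    inner), so the feature-column identity is reproducible.
    """
    w = net.relation(link_relation).weights
    left_counts = {mp: path_count_matrix(net, mp) for mp in mirna_paths}
    right_counts = {mp: path_count_matrix(net, mp) for mp in gene_paths}
    stack = []
    for mp_i, mp_j in product_metapath_pairs(mirna_paths, gene_paths):
        stack.append(rm_score(left_counts[mp_i], w, right_counts[mp_j], (mp_i, mp_j)))
    return stack
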