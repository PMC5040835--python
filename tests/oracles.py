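"""Independent brute-force oracles used by the test suite.

These deliberately avoid matrix algebra: path instances are enumerated by
explicit depth-first walks over adjacency lists, RM scores are rebuilt
from those counts, the logistic MLE is checked against a grid search, and
ranking quantities are recomputed by direct pairwise counting.
"""

from __future__ import annotations

import itertools

import numpy as np


def dfs_path_weight(matrices: list[np.ndarray], source: int, target: int) -> float:
    """Total weight of concrete path instances from source to target.

    Pure recursive walk: at step k the walker moves from its current node
    to every node with a nonzero weight in matrices[k], multiplying the
    weights along the way.  For binary matrices this counts path instances.
    """
    def walk(node: int, step: int) -> float:
        if step == len(matrices):
            return 1.0 if node == target else 0.0
        total = 0.0
        row = matrices[step][node]
        for nxt in np.nonzero(row)[0]:
            total += row[nxt] * walk(int(nxt), step + 1)
        return total

    return walk(source, step=0)


def dfs_path_count_matrix(matrices: list[np.ndarray], n_source: int,
                          n_target: int) -> np.ndarray:
    out = np.zeros((n_source, n_target))
    for p in range(n_source):
        for q in range(n_target):
            out[p, q] = dfs_path_weight(matrices, p, q)
    return out


def brute_rm(rmp_iis: np.ndarray, w_ij: np.ndarray,
             rmp_jjt: np.ndarray) -> np.ndarray:
    """RM scores from explicitly enumerated expected/possible link weights."""
    n_i, n_j = w_ij.shape
    out = np.zeros((rmp_iis.shape[0], rmp_jjt.shape[1]))
    for p in range(out.shape[0]):
        for q in range(out.shape[1]):
            num = 0.0
            den = 0.0
            for s in range(n_i):
                for t in range(n_j):
                    num += rmp_iis[p, s] * w_ij[s, t] * rmp_jjt[t, q]
                    den += rmp_iis[p, s] * 1.0 * rmp_jjt[t, q]
            out[p, q] = num / den if den > 0 else 0.0
    return out


def grid_search_logistic(x: np.ndarray, y: np.ndarray, ridge: float,
                         lo: float = -5.0, hi: float = 5.0) -> np.ndarray:
    """Best 2-parameter weight vector by coarse-to-fine grid search.

    Final resolution 0.001 per coordinate over [lo, hi]^2.
    """
    def obj(w0: np.ndarray, w1: np.ndarray) -> np.ndarray:
        # vectorised penalised log likelihood over a grid of weight pairs
        z = np.tensordot(np.stack([w0, w1], axis=-1), x.T, axes=1)
        ll = np.sum(y * z - np.logaddexp(0.0, z), axis=-1)
        return ll - 0.5 * ridge * (w0 ** 2 + w1 ** 2)

    center = np.zeros(2)
    half = (hi - lo) / 2.0
    for step in (0.1, 0.01, 0.001):
        g0 = np.arange(center[0] - half, center[0] + half + step / 2, step)
        g1 = np.arange(center[1] - half, center[1] + half + step / 2, step)
        w0, w1 = np.meshgrid(g0, g1, indexing="ij")
        vals = obj(w0, w1)
        k = np.unravel_index(np.argmax(vals), vals.shape)
        center = np.array([g0[k[0]], g1[k[1]]])
        half = 2 * step
    return center


def counting_final_scores(posteriors) -> list[float]:
    p = list(posteriors)
    n = len(p)
    return [sum(1 for pj in p if pi >= pj) / n for pi in p]


def pairwise_auc(scores, labels) -> float:
    """Mann-Whitney AUC with ties counted as half wins."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    wins = 0.0
    for sp, sn in itertools.product(pos, neg):
        if sp > sn:
            wins += 1.0
        elif sp == sn:
            wins += 0.5
    return wins / (len(pos) * len(neg))


def random_binary_network(rng: np.random.Generator, n_mirna: int, n_gene: int,
                          density: float = 0.25):
    """Random binary relations (sim symmetric, regulate, ppi symmetric)."""
    sim = np.triu((rng.random((n_mirna, n_mirna)) < density), k=1)
    sim = (sim | sim.T).astype(float)
    ppi = np.triu((rng.random((n_gene, n_gene)) < density), k=1)
    ppi = (ppi | ppi.T).astype(float)
    mg = (rng.random((n_mirna, n_gene)) < density).astype(float)
    return sim, mg, ppi
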