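"""Synthetic heterogeneous networks with planted ground truth.

Real miRNA-target studies hinge on curated resources (miRNA-disease
catalogs, protein-interaction maps, validated target databases) that
cannot ship with a library.  This module generates desk-scale stand-ins
with the same shapes and a *known* generative story, so every stage of the
pipeline — disease-derived similarity, RM relatedness, weight fitting,
cross-validation — can be tested against ground truth:

* a random disease hierarchy and per-miRNA disease profiles, from which
  the miRNA similarity matrix is built exactly as for real data;
* a random symmetric protein-interaction relation;
* miRNA-target links planted in two stages: a seeded fraction of links
  forms an initial adjacency, RM features are computed from it, and the
  remaining cells are drawn from the logistic link model with known
  weights.  The two stages resolve the circularity that RM features are
  themselves functions of the link matrix.

Defaults are desk-scale: 60 miRNAs, 120 genes, 20 diseases.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .disease_sim import DiseaseDAG, MiRNADiseaseProfile, build_similarity_matrix
from .features import (
    FeatureTable,
    PairIndex,
    SequenceEvidence,
    append_sequence_features,
    build_rmlm_features,
)
from .hetnet import (
    HeteroNetwork,
    NodeCatalog,
    RelationMatrix,
    enumerate_metapaths,
    register_relation,
)
from .model import WeightVector, posterior
from .relatedness import rm_stack

__all__ = [
    "SyntheticStudy",
    "generate_network",
    "plant_links",
    "toy_fixture",
    "default_true_weights",
    "set_link_weights",
    "DEFAULT_N_MIRNA",
    "DEFAULT_N_GENE",
    "DEFAULT_N_DISEASE",
]

DEFAULT_N_MIRNA = 60
DEFAULT_N_GENE = 120
DEFAULT_N_DISEASE = 20
DEFAULT_PPI_DENSITY = 0.05
DEFAULT_SEED_FRACTION = 0.05
DEFAULT_MAX_LEN = 3

MIRNA_TYPE = "mirna"
GENE_TYPE = "gene"
SIM_RELATION = "sim"
PPI_RELATION = "ppi"
LINK_RELATION = "regulate"


@dataclass
class SyntheticStudy:
    """A generated network with its ground truth.

    ``planting_features``/``planting_labels`` record the stage-2 draw of
    :func:`plant_links` — the feature table computed from the seeded
    adjacency and the drawn outcome for every non-seed cell — so that
    weight recovery can be checked against the exact regression the links
    were generated from.
    """

    network: HeteroNetwork
    dag: DiseaseDAG
    profiles: list[MiRNADiseaseProfile]
    true_weights: WeightVector
    positives: PairIndex
    seed: int
    sequence_evidence: list[SequenceEvidence] | None = None
    seed_pairs: PairIndex | None = None
    planting_features: "FeatureTable | None" = None
    planting_labels: np.ndarray | None = None


def set_link_weights(
    net: HeteroNetwork, relation: str, pairs: PairIndex, value: float
) -> None:
    """Set entries of a relation (and its inverse) at the given pairs."""
    rel = net.relation(relation)
    inv = net.relation(relation + "^-1")
    rel.weights[pairs.rows(), pairs.cols()] = value
    inv.weights[pairs.cols(), pairs.rows()] = value


def _random_dag(n_disease: int, rng: np.random.Generator,
                delta: float = 0.5) -> DiseaseDAG:
    """Random hierarchy: each non-root term gets 1-2 earlier parents."""
    terms = [f"D{i:03d}" for i in range(n_disease)]
    edges = set()
    for i in range(1, n_disease):
        n_parents = int(rng.integers(1, 3))
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            edges.add((terms[int(p)], terms[i]))
    return DiseaseDAG(frozenset(terms), frozenset(edges), delta=delta)


def generate_network(
    n_mirna: int = DEFAULT_N_MIRNA,
    n_gene: int = DEFAULT_N_GENE,
    n_disease: int = DEFAULT_N_DISEASE,
    ppi_density: float = DEFAULT_PPI_DENSITY,
    seed: int = 0,
) -> tuple[HeteroNetwork, DiseaseDAG, list[MiRNADiseaseProfile]]:
    """Random typed network with disease-derived miRNA similarity.

    The miRNA-gene link relation is registered all-zero; links are planted
    separately by :func:`plant_links`.
    """
    if min(n_mirna, n_gene, n_disease) < 2:
        raise ValueError("all sizes must be at least 2")
    if not (0.0 < ppi_density < 1.0):
        raise ValueError("ppi_density must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    dag = _random_dag(n_disease, rng)
    terms = sorted(dag.terms)
    profiles = []
    for i in range(n_mirna):
        k = int(rng.integers(1, 5))
        picked = rng.choice(len(terms), size=k, replace=False)
        profiles.append(MiRNADiseaseProfile(
            f"mir-{i:03d}", frozenset(terms[int(p)] for p in picked)
        ))

    net = HeteroNetwork()
    net.add_catalog(NodeCatalog(MIRNA_TYPE, tuple(p.mirna_id for p in profiles)))
    net.add_catalog(NodeCatalog(GENE_TYPE, tuple(f"gene-{j:04d}" for j in range(n_gene))))

    register_relation(net, build_similarity_matrix(
        profiles, dag, relation_name=SIM_RELATION, node_type=MIRNA_TYPE))

    upper = rng.random((n_gene, n_gene)) < ppi_density
    ppi = np.triu(upper, k=1)
    ppi = (ppi | ppi.T).astype(float)
    register_relation(net, RelationMatrix(PPI_RELATION, GENE_TYPE, GENE_TYPE, ppi))

    register_relation(net, RelationMatrix(
        LINK_RELATION, MIRNA_TYPE, GENE_TYPE, np.zeros((n_mirna, n_gene))))
    return net, dag, profiles


def default_true_weights(n_channels: int, with_sequence: bool = False,
                         labels: tuple[str, ...] | None = None) -> WeightVector:
    """Planting weights used by the standard synthetic study.

    A handful of channels carry strong signal of mixed sign; under the
    default seed fraction this yields a link rate around one third with a
    clearly recoverable weight direction.  With ``with_sequence`` three
    extra positive weights drive informative binary evidence channels.
    """
    w = np.zeros(n_channels + (3 if with_sequence else 0))
    # indices into the canonical 8 x 8 channel grid (miRNA side x gene side):
    # 1 = ([],[ppi]), 16 = ([regulate,regulate^-1],[]), 3 = ([],[reg^-1,reg]),
    # 6 = ([],[reg^-1,reg,ppi]).  These channels are only weakly mutually
    # correlated, which keeps the planted direction identifiable from a
    # single study; the negative weights hold the overall link rate down.
    signal = {1: 14.0, 16: 12.0, 3: -18.0, 6: -18.0}
    for k, v in signal.items():
        if k < n_channels:
            w[k] = v
    if with_sequence:
        w[n_channels:] = [2.0, 1.5, 1.0]
    return WeightVector(w, feature_labels=labels)


def plant_links(
    net: HeteroNetwork,
    dag: DiseaseDAG,
    profiles: list[MiRNADiseaseProfile],
    true_w: WeightVector | None = None,
    seed_fraction: float = DEFAULT_SEED_FRACTION,
    seed: int = 0,
    max_len: int = DEFAULT_MAX_LEN,
    with_sequence: bool = False,
    sequence_rate: float = 0.15,
) -> SyntheticStudy:
    """Plant miRNA-gene links from the logistic model with known weights.

    Stage 1 seeds ``seed_fraction`` of the cells as initial links.  Stage 2
    computes RM features from that seeded adjacency and draws each
    remaining cell as a link with its model posterior.  With
    ``with_sequence``, three binary evidence matrices are drawn at
    ``sequence_rate`` and enter the planting posterior through the last
    three weights; the surviving pairs are recorded as per-source evidence.
    """
    rng = np.random.default_rng(seed)
    n_mirna = len(net.catalogs[MIRNA_TYPE])
    n_gene = len(net.catalogs[GENE_TYPE])
    n_cells = n_mirna * n_gene

    mirna_paths = enumerate_metapaths(net, MIRNA_TYPE, max_len)
    gene_paths = enumerate_metapaths(net, GENE_TYPE, max_len)
    n_channels = len(mirna_paths) * len(gene_paths)
    if true_w is None:
        true_w = default_true_weights(n_channels, with_sequence)
    expected_len = n_channels + (3 if with_sequence else 0)
    if len(true_w.weights) != expected_len:
        raise ValueError(
            f"true weight length {len(true_w.weights)} does not match "
            f"{n_channels} RM channels"
            + (" plus 3 sequence channels" if with_sequence else "")
        )

    n_seeds = max(1, int(round(seed_fraction * n_cells)))
    seed_cells = rng.choice(n_cells, size=n_seeds, replace=False)
    w0 = np.zeros(n_cells)
    w0[seed_cells] = 1.0
    w0 = w0.reshape(n_mirna, n_gene)

    seeded = net.copy()
    seeded.relation(LINK_RELATION).weights = w0
    seeded.relation(LINK_RELATION + "^-1").weights = w0.T

    stack = rm_stack(seeded, mirna_paths, gene_paths, LINK_RELATION)
    all_pairs = PairIndex.all_cells(n_mirna, n_gene)
    table = build_rmlm_features(stack, all_pairs)

    evidence: list[SequenceEvidence] | None = None
    if with_sequence:
        mirna_ids = net.catalogs[MIRNA_TYPE].ids
        gene_ids = net.catalogs[GENE_TYPE].ids
        evidence = []
        for source in ("targetscan", "miranda", "pita"):
            mask = rng.random((n_mirna, n_gene)) < sequence_rate
            pairs = frozenset(
                (mirna_ids[i], gene_ids[j]) for i, j in zip(*np.nonzero(mask))
            )
            evidence.append(SequenceEvidence(source, pairs))
        table = append_sequence_features(
            table, evidence, net.catalogs[MIRNA_TYPE], net.catalogs[GENE_TYPE])

    probs = np.atleast_1d(posterior(table.values, true_w))
    draws = rng.random(n_cells) < probs
    final = draws.reshape(n_mirna, n_gene) | (w0 > 0)

    if final.all() or not final.any():
        raise RuntimeError("degenerate planting: all cells share one label")

    planted = net.copy()
    planted.relation(LINK_RELATION).weights = final.astype(float)
    planted.relation(LINK_RELATION + "^-1").weights = final.T.astype(float)

    positives = PairIndex(tuple(
        (int(i), int(j)) for i, j in zip(*np.nonzero(final))))
    non_seed = w0.reshape(-1) == 0
    return SyntheticStudy(
        network=planted,
        dag=dag,
        profiles=profiles,
        true_weights=true_w,
        positives=positives,
        seed=seed,
        sequence_evidence=evidence,
        seed_pairs=PairIndex(tuple(
            all_pairs.pairs[k] for k in np.nonzero(~non_seed)[0])),
        planting_features=FeatureTable(
            PairIndex(tuple(all_pairs.pairs[k] for k in np.nonzero(non_seed)[0])),
            table.columns,
            table.values[non_seed],
        ),
        planting_labels=draws[non_seed].astype(float),
    )


@lru_cache(maxsize=1)
def _toy_parts() -> tuple:
    dag = DiseaseDAG(
        frozenset({"R", "A", "B"}),
        frozenset({("R", "A"), ("R", "B")}),
        delta=0.5,
    )
    profiles = (
        MiRNADiseaseProfile("mir-a", frozenset({"A"})),
        MiRNADiseaseProfile("mir-b", frozenset({"B"})),
        MiRNADiseaseProfile("mir-ab", frozenset({"A", "B"})),
    )
    return dag, profiles


def toy_fixture() -> SyntheticStudy:
    """A fixed 3-miRNA x 4-gene x 3-disease network, hand-checkable.

    The disease hierarchy is a root with two sibling leaves; with decay
    0.5 the sibling similarity is 1/3, which propagates to hand-computable
    off-diagonal miRNA similarities (1/3 and 7/9).
    """
    dag, profiles = _toy_parts()
    net = HeteroNetwork()
    net.add_catalog(NodeCatalog(MIRNA_TYPE, tuple(p.mirna_id for p in profiles)))
    net.add_catalog(NodeCatalog(GENE_TYPE, ("g1", "g2", "g3", "g4")))
    register_relation(net, build_similarity_matrix(
        list(profiles), dag, relation_name=SIM_RELATION, node_type=MIRNA_TYPE))
    ppi = np.array([
        [0, 1, 0, 0],
        [1, 0, 0, 0],
        [0, 0, 0, 1],
        [0, 0, 1, 0],
    ], dtype=float)
    register_relation(net, RelationMatrix(PPI_RELATION, GENE_TYPE, GENE_TYPE, ppi))
    mp = np.array([
        [1, 0, 0, 1],
        [0, 1, 0, 0],
        [0, 0, 1, 0],
    ], dtype=float)
    register_relation(net, RelationMatrix(LINK_RELATION, MIRNA_TYPE, GENE_TYPE, mp))

    positives = PairIndex(tuple(
        (int(i), int(j)) for i, j in zip(*np.nonzero(mp))))
    n_channels = (len(enumerate_metapaths(net, MIRNA_TYPE, DEFAULT_MAX_LEN))
                  * len(enumerate_metapaths(net, GENE_TYPE, DEFAULT_MAX_LEN)))
    return SyntheticStudy(
        network=net,
        dag=dag,
        profiles=list(profiles),
        true_weights=WeightVector(np.zeros(n_channels)),
        positives=positives,
        seed=0,
    )
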