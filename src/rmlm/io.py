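"""Tabular readers/writers, the MeSH-style hierarchy parser, and the pipeline.

All tables are plain TSV with ``#`` comment lines.  Identifiers are kept
verbatim; catalog index order is the order of first appearance in the
defining input file (the miRNA-disease table for miRNAs, the
protein-interaction table for genes).  Every output file embeds the
effective configuration as ``#key<TAB>value`` header lines, so a run is
reconstructible from its outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

from .disease_sim import DiseaseDAG, MiRNADiseaseProfile, build_similarity_matrix
from .evaluate import CVConfig, EvaluationReport, cross_validate, count_above_thresholds
from .features import (
    PairIndex,
    SequenceEvidence,
    append_sequence_features,
    build_rmlm_features,
    filter_miranda,
    filter_pita,
    filter_targetscan,
)
from .hetnet import (
    HeteroNetwork,
    NodeCatalog,
    RelationMatrix,
    enumerate_metapaths,
    register_relation,
)
from .model import (
    ScoreTable,
    TrainingSet,
    WeightVector,
    final_scores,
    fit_weights,
    posterior,
    sample_negative_pairs,
    write_model,
)
from .relatedness import rm_stack
from .evaluate import rm_sum_baseline
from .synthetic import (
    GENE_TYPE,
    LINK_RELATION,
    MIRNA_TYPE,
    PPI_RELATION,
    SIM_RELATION,
    SyntheticStudy,
)

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_pair_table",
    "read_mesh_tree",
    "read_profiles",
    "write_scores",
    "write_matrix",
    "build_network_from_tables",
    "load_sequence_evidence",
    "run_pipeline",
    "dump_study",
]


@dataclass
class RunConfig:
    """Structured configuration of a full pipeline run."""

    mirna_disease: str = ""
    mesh_tree: str = ""
    ppi: str = ""
    mirna_target: str = ""
    targetscan: str | None = None
    miranda: str | None = None
    pita: str | None = None
    out_dir: str = "rmlm_out"
    method: str = "RMLM"
    max_len: int = 3
    delta: float = 0.5
    ridge: float = 1e-4
    negative_ratio: float = 1.0
    k_folds: int = 5
    seed: int = 0
    miranda_abs: bool = False
    thresholds: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5)

    @staticmethod
    def from_yaml(path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = RunConfig(**data)
        if cfg.thresholds is not None:
            cfg.thresholds = tuple(float(t) for t in cfg.thresholds)
        return cfg

    def echo(self) -> dict:
        return asdict(self)


def _data_lines(path: str):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            yield lineno, line.split("\t")


def read_pair_table(path: str, kind: str = "pair"):
    """Read a 2-column pair table or a 3-column pair+score table.

    Returns an ordered, deduplicated list of ``(a, b)`` tuples for
    ``kind='pair'`` or ``(a, b, score)`` for ``kind='scored'`` (the first
    score wins on duplicates).  Malformed rows raise with the line number.
    """
    if kind not in ("pair", "scored"):
        raise ValueError("kind must be 'pair' or 'scored'")
    want = 2 if kind == "pair" else 3
    seen: dict[tuple[str, str], float | None] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != want:
            raise ValueError(
                f"{path}:{lineno}: expected {want} tab-separated columns, "
                f"got {len(fields)}"
            )
        a, b = fields[0], fields[1]
        score = None
        if kind == "scored":
            try:
                score = float(fields[2])
            except ValueError:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric score {fields[2]!r}"
                ) from None
        seen.setdefault((a, b), score)
    if kind == "pair":
        return list(seen.keys())
    return [(a, b, s) for (a, b), s in seen.items()]


def read_mesh_tree(path: str, delta: float = 0.5) -> DiseaseDAG:
    """Build a disease hierarchy from (term id, dotted tree number) rows.

    A term's parent at each tree position is the term owning the tree
    number with the last dot-component removed; top-level numbers have no
    parent.  A dangling parent prefix is an error listing the offenders.
    """
    term_of_number: dict[str, str] = {}
    numbers_of_term: dict[str, list[str]] = {}
    for lineno, fields in _data_lines(path):
        if len(fields) != 2:
            raise ValueError(
                f"{path}:{lineno}: expected 2 columns (term, tree number)")
        term, number = fields
        if number in term_of_number and term_of_number[number] != term:
            raise ValueError(
                f"{path}:{lineno}: tree number {number!r} assigned to two terms")
        term_of_number[number] = term
        numbers_of_term.setdefault(term, []).append(number)

    edges: set[tuple[str, str]] = set()
    orphans: list[str] = []
    for term, numbers in numbers_of_term.items():
        for number in numbers:
            if "." not in number:
                continue
            prefix = number.rsplit(".", 1)[0]
            parent = term_of_number.get(prefix)
            if parent is None:
                orphans.append(number)
            elif parent != term:
                edges.add((parent, term))
    if orphans:
        raise ValueError(
            "tree numbers with no term at their parent prefix: "
            + ", ".join(sorted(orphans)))
    return DiseaseDAG(frozenset(numbers_of_term), frozenset(edges), delta=delta)


def read_profiles(path: str, dag: DiseaseDAG) -> list[MiRNADiseaseProfile]:
    """miRNA-disease associations -> per-miRNA profiles, in file order.

    Associations naming a disease absent from the hierarchy are dropped
    with a logged count; a miRNA left with no mapped disease is an error,
    because its functional similarity would be undefined.
    """
    diseases_of: dict[str, set[str]] = {}
    dropped = 0
    for mirna, disease in read_pair_table(path, "pair"):
        if disease not in dag.terms:
            dropped += 1
            diseases_of.setdefault(mirna, set())
            continue
        diseases_of.setdefault(mirna, set()).add(disease)
    if dropped:
        logger.info("dropped %d associations with unmapped diseases", dropped)
    empty = [m for m, ds in diseases_of.items() if not ds]
    if empty:
        raise ValueError(
            "miRNAs with no disease mapped to the hierarchy: " + ", ".join(empty))
    return [MiRNADiseaseProfile(m, frozenset(ds)) for m, ds in diseases_of.items()]


def _header_lines(echo: dict | None) -> str:
    if not echo:
        return ""
    return "".join(f"#{k}\t{v}\n" for k, v in echo.items())


def write_scores(
    table: ScoreTable,
    path: str,
    mirna_ids: tuple[str, ...],
    gene_ids: tuple[str, ...],
    echo: dict | None = None,
) -> None:
    """Score table as TSV, best-scoring pairs first."""
    rows = []
    for (i, j), p, q in zip(table.pair_index.pairs, table.posterior, table.final):
        rows.append((mirna_ids[i], gene_ids[j], p, q))
    rows.sort(key=lambda r: (-r[3], r[0], r[1]))
    with open(path, "w") as fh:
        fh.write(_header_lines(echo))
        fh.write("miRNA\tgene\tposterior\tfinal_score\n")
        for m, g, p, q in rows:
            fh.write(f"{m}\t{g}\t{p:.10g}\t{q:.10g}\n")


def read_scores(path: str) -> list[tuple[str, str, float, float]]:
    rows = []
    for _, fields in _data_lines(path):
        if fields[0] == "miRNA":
            continue
        rows.append((fields[0], fields[1], float(fields[2]), float(fields[3])))
    return rows


def write_matrix(weights: np.ndarray, row_ids, col_ids, path: str,
                 echo: dict | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_lines(echo))
        fh.write("id\t" + "\t".join(col_ids) + "\n")
        for rid, row in zip(row_ids, np.asarray(weights)):
            fh.write(rid + "\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")


def build_network_from_tables(config: RunConfig) -> tuple[
    HeteroNetwork, DiseaseDAG, list[MiRNADiseaseProfile], PairIndex
]:
    """Assemble the heterogeneous network from the configured input tables.

    miRNA catalog order follows the miRNA-disease file, gene catalog order
    the protein-interaction file; target links whose endpoints are missing
    from the catalogs are dropped with a logged count.
    """
    dag = read_mesh_tree(config.mesh_tree, delta=config.delta)
    profiles = read_profiles(config.mirna_disease, dag)

    ppi_pairs = read_pair_table(config.ppi, "pair")
    gene_ids: list[str] = []
    seen_genes = set()
    for a, b in ppi_pairs:
        for g in (a, b):
            if g not in seen_genes:
                seen_genes.add(g)
                gene_ids.append(g)

    net = HeteroNetwork()
    net.add_catalog(NodeCatalog(MIRNA_TYPE, tuple(p.mirna_id for p in profiles)))
    net.add_catalog(NodeCatalog(GENE_TYPE, tuple(gene_ids)))

    register_relation(net, build_similarity_matrix(
        profiles, dag, relation_name=SIM_RELATION, node_type=MIRNA_TYPE))

    gidx = {g: j for j, g in enumerate(gene_ids)}
    ppi = np.zeros((len(gene_ids), len(gene_ids)))
    for a, b in ppi_pairs:
        if a != b:
            ppi[gidx[a], gidx[b]] = ppi[gidx[b], gidx[a]] = 1.0
    register_relation(net, RelationMatrix(PPI_RELATION, GENE_TYPE, GENE_TYPE, ppi))

    midx = {p.mirna_id: i for i, p in enumerate(profiles)}
    mp = np.zeros((len(profiles), len(gene_ids)))
    dropped = 0
    for m, g in read_pair_table(config.mirna_target, "pair"):
        if m in midx and g in gidx:
            mp[midx[m], gidx[g]] = 1.0
        else:
            dropped += 1
    if dropped:
        logger.info("dropped %d target links with endpoints outside catalogs",
                    dropped)
    register_relation(net, RelationMatrix(LINK_RELATION, MIRNA_TYPE, GENE_TYPE, mp))

    positives = PairIndex(tuple(
        (int(i), int(j)) for i, j in zip(*np.nonzero(mp))))
    return net, dag, profiles, positives


def load_sequence_evidence(config: RunConfig) -> list[SequenceEvidence]:
    """Read and hard-filter the configured sequence-predictor tables."""
    evidence = []
    if config.targetscan:
        evidence.append(filter_targetscan(read_pair_table(config.targetscan, "scored")))
    if config.miranda:
        evidence.append(filter_miranda(
            read_pair_table(config.miranda, "scored"), abs_mode=config.miranda_abs))
    if config.pita:
        evidence.append(filter_pita(read_pair_table(config.pita, "pair")))
    return evidence


@dataclass
class PipelineArtifacts:
    scores_path: str
    model_path: str | None
    report_path: str
    net: HeteroNetwork
    scores: ScoreTable
    weights: WeightVector | None


def run_pipeline(config: RunConfig) -> PipelineArtifacts:
    """End-to-end scoring of the unknown miRNA-gene pairs.

    Stages: similarity construction, meta-path enumeration, RM stack,
    feature assembly, weight fitting (skipped for RM-sum), posterior and
    percentile scoring, and output writing.  Any stage error aborts with
    the stage name.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    echo = config.echo()
    stage = "read inputs"
    try:
        net, dag, profiles, positives = build_network_from_tables(config)
        evidence = (load_sequence_evidence(config)
                    if config.method == "RMLMSe" else [])

        stage = "meta-path enumeration"
        mirna_paths = enumerate_metapaths(net, MIRNA_TYPE, config.max_len)
        gene_paths = enumerate_metapaths(net, GENE_TYPE, config.max_len)

        stage = "relatedness stack"
        stack = rm_stack(net, mirna_paths, gene_paths, LINK_RELATION)

        stage = "feature assembly"
        w_mg = net.relation(LINK_RELATION).weights
        unknown = PairIndex(tuple(
            (int(i), int(j)) for i, j in zip(*np.nonzero(w_mg == 0))))

        def features_for(pairs: PairIndex):
            table = build_rmlm_features(stack, pairs)
            if config.method == "RMLMSe":
                table = append_sequence_features(
                    table, evidence,
                    net.catalogs[MIRNA_TYPE], net.catalogs[GENE_TYPE])
            return table

        weights = None
        model_path = None
        if config.method == "RM-sum":
            stage = "baseline scoring"
            raw = rm_sum_baseline(stack, unknown)
            scores = ScoreTable(unknown, raw, final_scores(raw))
        else:
            stage = "weight fitting"
            rng = np.random.default_rng([config.seed, 977])
            n_neg = int(round(config.negative_ratio * len(positives)))
            negatives = sample_negative_pairs(w_mg, positives, n_neg, rng)
            train_pairs = PairIndex(positives.pairs + negatives.pairs)
            labels = np.concatenate(
                [np.ones(len(positives)), np.zeros(len(negatives))])
            weights = fit_weights(
                TrainingSet(features_for(train_pairs), labels), ridge=config.ridge)
            model_path = str(out / "model.txt")
            write_model(weights, model_path)

            stage = "posterior scoring"
            p = np.atleast_1d(posterior(features_for(unknown).values, weights))
            scores = ScoreTable(unknown, p, final_scores(p))

        stage = "write outputs"
        scores_path = str(out / "scores.tsv")
        write_scores(scores, scores_path,
                     net.catalogs[MIRNA_TYPE].ids, net.catalogs[GENE_TYPE].ids,
                     echo=echo)
        report_path = str(out / "report.tsv")
        counts = count_above_thresholds(scores, list(config.thresholds))
        with open(report_path, "w") as fh:
            fh.write(_header_lines(echo))
            fh.write("threshold\tn_pairs\n")
            for th, c in zip(config.thresholds, counts):
                fh.write(f"{th:g}\t{c}\n")
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    return PipelineArtifacts(scores_path, model_path, report_path,
                             net, scores, weights)


def evaluate_tables(config: RunConfig) -> EvaluationReport:
    """Cross-validate the configured method on the input tables."""
    net, _, _, positives = build_network_from_tables(config)
    evidence = load_sequence_evidence(config) if config.method == "RMLMSe" else None
    cv = CVConfig(
        k=config.k_folds, seed=config.seed, method=config.method,
        max_len=config.max_len, ridge=config.ridge,
        negative_ratio=config.negative_ratio,
        sequence_evidence=evidence,
    )
    return cross_validate(net, positives, cv)


def _tree_numbers(dag: DiseaseDAG) -> dict[str, list[str]]:
    """Assign dotted positional numbers to every term (one per parent path)."""
    roots = sorted(t for t in dag.terms if not dag.parents(t))
    numbers: dict[str, list[str]] = {t: [] for t in dag.terms}

    def assign(term: str, number: str) -> None:
        numbers[term].append(number)
        for k, child in enumerate(sorted(dag.children(term)), start=1):
            assign(child, f"{number}.{k:02d}")

    for r, root in enumerate(roots, start=1):
        assign(root, f"C{r:02d}")
    return numbers


def dump_study(study: SyntheticStudy, out_dir: str) -> RunConfig:
    """Write a synthetic study in the pipeline's TSV input formats.

    Returns a :class:`RunConfig` pointing at the written files, so the CLI
    and pipeline can be exercised end to end on generated data.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    net = study.network
    mirna_ids = net.catalogs[MIRNA_TYPE].ids
    gene_ids = net.catalogs[GENE_TYPE].ids

    with open(out / "mirna_disease.tsv", "w") as fh:
        for p in study.profiles:
            for d in sorted(p.diseases):
                fh.write(f"{p.mirna_id}\t{d}\n")

    with open(out / "mesh_tree.tsv", "w") as fh:
        for term, numbers in sorted(_tree_numbers(study.dag).items()):
            for n in numbers:
                fh.write(f"{term}\t{n}\n")

    ppi = net.relation(PPI_RELATION).weights
    with open(out / "ppi.tsv", "w") as fh:
        rows, cols = np.nonzero(np.triu(ppi, k=1))
        for i, j in zip(rows, cols):
            fh.write(f"{gene_ids[i]}\t{gene_ids[j]}\n")
        # keep isolated genes in the catalog via self-free placeholder rows
        isolated = np.nonzero(ppi.sum(axis=0) == 0)[0]
        for j in isolated:
            fh.write(f"{gene_ids[j]}\t{gene_ids[j]}\n")

    with open(out / "mirna_target.tsv", "w") as fh:
        for i, j in study.positives.pairs:
            fh.write(f"{mirna_ids[i]}\t{gene_ids[j]}\n")

    cfg = RunConfig(
        mirna_disease=str(out / "mirna_disease.tsv"),
        mesh_tree=str(out / "mesh_tree.tsv"),
        ppi=str(out / "ppi.tsv"),
        mirna_target=str(out / "mirna_target.tsv"),
        out_dir=str(out / "results"),
        delta=study.dag.delta,
    )
    if study.sequence_evidence:
        passing = {"targetscan": 0.95, "miranda": 0.7}
        for ev in study.sequence_evidence:
            path = out / f"{ev.source}.tsv"
            with open(path, "w") as fh:
                for m, g in sorted(ev.pairs):
                    if ev.source == "pita":
                        fh.write(f"{m}\t{g}\n")
                    else:
                        fh.write(f"{m}\t{g}\t{passing[ev.source]}\n")
            setattr(cfg, ev.source, str(path))
    return cfg
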