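"""End-to-end pipeline: ingest → annotate → predict → build → write.

One config object wires all stages; identical config and inputs produce
byte-identical output tables.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import yaml

from . import corpus
from .annotator import AnnotationParams, annotate_corpus
from .errors import BioTagmeError, ValidationError
from .graph import KnowledgeGraph, build_graph
from .scoring import ScoringConfig, predict
from .wiki import read_wiki

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class PipelineConfig:
    """Paths and parameters of one full pipeline run.

    ``references`` maps an origin label (database name) to the TSV path of
    its edge set; the STRING origin is the one whose edges carry scores.
    """

    docs: str | None = None
    sentences: str | None = None
    wiki: str = "wiki"
    references: dict[str, str] = dataclasses.field(default_factory=dict)
    synonyms: str | None = None
    out: str = "out"
    rho_threshold: float = 0.2
    max_ngram: int = 6
    max_depth: int = 3
    lambda_: float = 0.5
    min_biotg: float = 0.0
    seed: int = 0

    @property
    def annotation_params(self) -> AnnotationParams:
        return AnnotationParams(
            rho_threshold=self.rho_threshold, max_ngram=self.max_ngram, max_depth=self.max_depth
        )

    @property
    def scoring_config(self) -> ScoringConfig:
        return ScoringConfig(lambda_=self.lambda_, min_biotg=self.min_biotg)

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def _stage(name: str):
    logger.info("[%s] starting", name)


def run_pipeline(config: PipelineConfig) -> tuple[KnowledgeGraph, dict]:
    """Execute every stage and write the graph plus a JSON run report.

    Returns the built graph and the report (stage counts + parameters).
    Any stage failure aborts with the stage name attached.
    """
    report: dict = {"parameters": dataclasses.asdict(config), "stages": {}}
    stage = "ingest"
    try:
        docs = []
        if config.sentences:
            docs.extend(corpus.aggregate_sentences(corpus.read_sentence_rows(config.sentences)))
        if config.docs:
            docs.extend(corpus.read_documents(config.docs))
        if not docs:
            raise ValidationError("no documents supplied (set docs and/or sentences)")
        wiki = read_wiki(config.wiki)
        synonyms = corpus.read_synonyms(config.synonyms) if config.synonyms else corpus.SynonymTable()
        report["stages"][stage] = {"documents": len(docs), "wiki_pages": wiki.n_pages}

        stage = "annotate"
        _stage(stage)
        annotations = annotate_corpus(docs, wiki, config.annotation_params)
        report["stages"][stage] = {"annotations": len(annotations)}

        stage = "predict"
        _stage(stage)
        predictions = predict(annotations, wiki, config.scoring_config)
        report["stages"][stage] = {"scored_pairs": len(predictions)}

        stage = "integrate"
        _stage(stage)
        literature: list[corpus.ReferenceEdge] = []
        string_edges: list[corpus.ReferenceEdge] = []
        for origin in sorted(config.references):
            edges = corpus.read_reference_edges(config.references[origin], origin)
            edges = corpus.harmonize_names(edges, synonyms)
            (string_edges if origin == "STRING" else literature).extend(edges)
        report["stages"][stage] = {
            "literature_edges": len(literature),
            "string_edges": len(string_edges),
        }

        stage = "build"
        _stage(stage)
        graph = build_graph(predictions, literature, string_edges, synonyms, annotations, wiki=wiki)
        report["stages"][stage] = {"nodes": graph.n_nodes, "edges": graph.n_edges}

        stage = "write"
        _stage(stage)
        out_dir = Path(config.out)
        corpus.write_graph(graph, out_dir)
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True) + "\n", encoding="utf-8"
        )
    except BioTagmeError as exc:
        raise BioTagmeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return graph, report


def load_reference_sets(
    reference_paths: dict[str, str], synonyms: corpus.SynonymTable
) -> tuple[list[corpus.ReferenceEdge], list[corpus.ReferenceEdge]]:
    """Read and harmonize reference TSVs, split into literature vs STRING."""
    literature: list[corpus.ReferenceEdge] = []
    string_edges: list[corpus.ReferenceEdge] = []
    for origin in sorted(reference_paths):
        edges = corpus.harmonize_names(
            corpus.read_reference_edges(reference_paths[origin], origin), synonyms
        )
        (string_edges if origin == "STRING" else literature).extend(edges)
    return literature, string_edges
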