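"""End-to-end pipeline orchestration and the QC + dominant-clone report.

The pipeline sequence: read inputs -> pair chains -> count full-length
clonotypes -> filter singletons -> attach binding scores -> select the
dominant clonotype -> normalize expression -> assemble features ->
PCA -> UMAP -> HDBSCAN -> phenotype clusters -> dominant-clone cohesion.
Every stage's parameters and the seed are recorded in the report for
provenance.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import clonotyping, embedding
from .binding import PeptideContext, build_predictor_input, stub_predictor, write_predictor_input
from .clonotyping import (
    DominantClonotype,
    FilterReport,
    FullLengthKey,
    Resolution,
    export_dominant,
    percent,
    write_clonotype_table,
)
from .embedding import DEFAULT_MARKERS, CohesionReport, EmbeddingResult
from .io_airr import (
    read_airr_rearrangements,
    read_binding_scores,
    read_expression_matrix,
    read_sample_tags,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "QcSummary", "PipelineResult", "compute_recovery", "run_pipeline"]


def compute_recovery(n_loaded: int, n_called: int) -> float:
    """Cell recovery: 100 * called / loaded, half-up to one decimal."""
    if n_loaded <= 0:
        raise ValueError("n_loaded must be > 0")
    if n_called > n_loaded:
        logger.warning("n_called (%d) exceeds n_loaded (%d)", n_called, n_loaded)
    return percent(n_called, n_loaded)


@dataclass
class PipelineConfig:
    """Input paths and stage parameters for one pipeline run."""

    airr: str | Path
    expression: str | Path
    sample_tags: str | Path | None = None
    scores: str | Path | None = None
    use_stub_scores: bool = False
    peptide: str = "KIFGSLAFL"
    mhc: str = "HLA-A*02:01"
    t_cell_type: str = "CD8"
    n_loaded: int | None = None
    markers: tuple[str, ...] = DEFAULT_MARKERS
    pca_k: int | None = None
    umap_n_neighbors: int = 15
    umap_min_dist: float = 0.1
    hdbscan_min_cluster_size: int = 5
    seed: int = 42
    outdir: str | Path | None = None


@dataclass
class QcSummary:
    """Per-run QC numbers plus the dominant-clonotype call."""

    n_called_cells: int
    n_complete_cells: int
    n_loaded: int | None = None
    recovery_pct: float | None = None
    n_clonotypes_before: int = 0
    n_after_singleton_filter: int = 0
    retained_pct: float | None = None
    n_clusters: int = 0
    dominant_key: dict | None = None
    dominant_cell_count: int | None = None
    dominant_binding_score: float | None = None
    dominant_cohesion_fraction: float | None = None
    seed: int = 42
    parameters: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class PipelineResult:
    summary: QcSummary
    full_table: clonotyping.ClonotypeTable
    pair_table: clonotyping.ClonotypeTable
    dominant: DominantClonotype
    filter_report: FilterReport
    embedding: EmbeddingResult
    phenotypes: embedding.ClusterPhenotype
    cohesion: CohesionReport


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline on the configured inputs."""
    ctx = PeptideContext(config.peptide, config.mhc, config.t_cell_type)

    with _stage("read"):
        contigs = read_airr_rearrangements(config.airr)
        matrix = read_expression_matrix(config.expression)
        tags = read_sample_tags(config.sample_tags) if config.sample_tags else {}

    with _stage("pair_chains"):
        cells = clonotyping.pair_chains(contigs)

    with _stage("count_clonotypes"):
        full = clonotyping.count_clonotypes(cells, Resolution.FULL_LENGTH)
        pairs = clonotyping.count_clonotypes(cells, Resolution.CDR3_PAIR)
        if not full.entries:
            raise ValueError("no complete cells: clonotype table is empty")

    with _stage("filter_singletons"):
        retained, filt = clonotyping.filter_singletons(full)

    with _stage("attach_scores"):
        if config.use_stub_scores:
            scores = stub_predictor(build_predictor_input(full, ctx))
        elif config.scores is not None:
            scores = read_binding_scores(config.scores)
        else:
            raise ValueError("no binding scores: pass scores= or use_stub_scores=True")
        scored = clonotyping.attach_scores(retained, scores)
        scored_full = clonotyping.attach_scores(full, scores)

    with _stage("select_dominant"):
        dominant = clonotyping.select_dominant(scored)

    with _stage("normalize"):
        norm = embedding.normalize_log2_cpm(matrix)

    with _stage("assemble_features"):
        features = embedding.assemble_features(matrix, norm, scored_full, config.markers)

    with _stage("embed"):
        emb = embedding.embed(
            features,
            k=config.pca_k,
            seed=config.seed,
            n_neighbors=config.umap_n_neighbors,
            min_dist=config.umap_min_dist,
            min_cluster_size=config.hdbscan_min_cluster_size,
        )

    with _stage("phenotype"):
        phenotypes = embedding.phenotype_clusters(
            emb.cluster_labels, norm, matrix.gene_ids, config.markers
        )

    with _stage("cohesion"):
        cohesion = embedding.dominant_cohesion(emb.cluster_labels, emb.cell_ids, dominant)

    n_called = matrix.n_cells
    summary = QcSummary(
        n_called_cells=n_called,
        n_complete_cells=full.n_cells,
        n_loaded=config.n_loaded,
        recovery_pct=(
            compute_recovery(config.n_loaded, n_called) if config.n_loaded else None
        ),
        n_clonotypes_before=filt.n_before,
        n_after_singleton_filter=filt.n_after,
        retained_pct=filt.retained_pct,
        n_clusters=emb.n_clusters,
        dominant_key=dict(zip(FullLengthKey._fields, dominant.key)),
        dominant_cell_count=dominant.cell_count,
        dominant_binding_score=dominant.binding_score,
        dominant_cohesion_fraction=cohesion.fraction,
        seed=config.seed,
        parameters={
            "peptide": ctx.peptide,
            "mhc": ctx.mhc,
            "t_cell_type": ctx.t_cell_type,
            "markers": list(config.markers),
            "pca_k": config.pca_k,
            "umap_n_neighbors": config.umap_n_neighbors,
            "umap_min_dist": config.umap_min_dist,
            "hdbscan_min_cluster_size": config.hdbscan_min_cluster_size,
            "n_donors_labelled": len(set(tags.values())) if tags else 0,
        },
    )

    if config.outdir is not None:
        _write_artifacts(Path(config.outdir), summary, retained, pairs, dominant, emb, full, ctx)

    return PipelineResult(
        summary=summary,
        full_table=full,
        pair_table=pairs,
        dominant=dominant,
        filter_report=filt,
        embedding=emb,
        phenotypes=phenotypes,
        cohesion=cohesion,
    )


def _write_artifacts(outdir, summary, retained, pairs, dominant, emb, full, ctx) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "report.json").write_text(summary.to_json() + "\n")
    write_clonotype_table(retained, outdir / "clonotypes_retained.csv")
    write_clonotype_table(pairs, outdir / "clonotypes_cdr3_pairs.csv")
    export_dominant(dominant, outdir / "dominant.json", outdir / "dominant_cdr3.fasta")
    emb.to_frame().to_csv(outdir / "embedding.csv", index=False)
    write_predictor_input(build_predictor_input(full, ctx), outdir / "predictor_input.csv")
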