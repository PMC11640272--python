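"""Expression normalization, feature assembly, co-embedding and clustering.

Cells are described by a small feature vector combining the targeted
panel's phenotype markers (log2 CPM, z-scored) with two clonotype-derived
numeric surrogates — log2 clone size and the predicted binding score — so
that repertoire structure and transcriptome co-embed in one map.  The map
is PCA -> UMAP, clustered with HDBSCAN (density-based, noise = -1), and
clusters are phenotyped by comparing per-marker cluster medians with the
global median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from sklearn.cluster import HDBSCAN
from sklearn.decomposition import PCA

from .clonotyping import ClonotypeTable, DominantClonotype, Resolution
from .io_airr import ExpressionMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_MARKERS",
    "PHENOTYPE_ORDER",
    "CellFeatureMatrix",
    "EmbeddingResult",
    "ClusterPhenotype",
    "CohesionReport",
    "normalize_log2_cpm",
    "assemble_features",
    "run_pca",
    "run_umap",
    "run_hdbscan",
    "embed",
    "phenotype_clusters",
    "dominant_cohesion",
]

#: markers used both as clustering features and for phenotyping
DEFAULT_MARKERS = ("CD4", "CD8", "FOXP3", "NKG7", "GZMB", "GZMA")

#: canonical marker order of the phenotype string
PHENOTYPE_ORDER = ("CD8", "CD4", "FOXP3", "NKG7", "GZMA", "GZMB")


def normalize_log2_cpm(m: ExpressionMatrix) -> np.ndarray:
    """Per-cell counts-per-million, log2(cpm + 1).

    All-zero cells (no library) stay all-zero rows and are counted in
    the log rather than producing NaN.
    """
    if m.n_cells == 0:
        raise ValueError("cannot normalize an empty matrix (0 cells)")
    counts = m.counts.astype(np.float64)
    totals = counts.sum(axis=1, keepdims=True)
    zero = totals[:, 0] == 0
    if zero.any():
        logger.warning("%d all-zero cell(s) left as zero rows", int(zero.sum()))
    safe = np.where(totals == 0, 1.0, totals)
    cpm = counts * 1e6 / safe
    return np.log2(cpm + 1.0)


@dataclass
class CellFeatureMatrix:
    """Per-cell features feeding PCA/UMAP/HDBSCAN (rows align with cells)."""

    cell_ids: list[str]
    feature_names: list[str]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (len(self.cell_ids), len(self.feature_names)):
            raise ValueError("feature matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("feature matrix contains missing values")


def _zscore(col: np.ndarray) -> np.ndarray:
    mu = col.mean()
    sd = col.std()
    if sd == 0:
        # zero-variance feature: centered column is all zero; keep it
        logger.info("zero-variance feature left at 0 after centering")
        return col - mu
    return (col - mu) / sd


def assemble_features(
    matrix: ExpressionMatrix,
    norm: np.ndarray,
    table: ClonotypeTable,
    markers: tuple[str, ...] = DEFAULT_MARKERS,
) -> CellFeatureMatrix:
    """Marker log2-CPM + log2 clone size + binding score, all z-scored.

    ``table`` must be the (scored) full-length clonotype table: each
    cell inherits the cell count and binding score of its clonotype.
    Cells without a complete receptor (or with an unscored clonotype)
    get clone_size 0 and score 0 before scaling, and are counted in the
    log — they stay in the embedding, the repertoire features simply
    carry no signal for them.
    """
    if table.resolution is not Resolution.FULL_LENGTH:
        raise ValueError("feature assembly requires the full_length table")
    missing = [g for g in markers if g not in matrix.gene_ids]
    if missing:
        raise ValueError(
            f"marker gene(s) {missing} absent from panel; panel has "
            f"{matrix.n_genes} genes"
        )
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    cols = [norm[:, gene_index[g]] for g in markers]

    size_of: dict[str, int] = {}
    score_of: dict[str, float] = {}
    for rec in table.entries.values():
        for cid in rec.cell_ids:
            size_of[cid] = rec.cell_count
            if rec.binding_score is not None:
                score_of[cid] = rec.binding_score
    clone_size = np.array(
        [np.log2(size_of.get(cid, 0) + 1) for cid in matrix.cell_ids]
    )
    score = np.array([score_of.get(cid, 0.0) for cid in matrix.cell_ids])
    n_blank = sum(1 for cid in matrix.cell_ids if cid not in size_of)
    if n_blank:
        logger.info("%d cell(s) without a clonotype: clone_size/score set to 0", n_blank)

    values = np.column_stack([_zscore(c) for c in [*cols, clone_size, score]])
    names = [*markers, "clone_size", "binding_score"]
    return CellFeatureMatrix(list(matrix.cell_ids), names, values)


class PcaResult(NamedTuple):
    coords: np.ndarray
    explained_variance_ratio: np.ndarray


def run_pca(features: CellFeatureMatrix, k: int | None = None) -> PcaResult:
    """Deterministic PCA to k components (default min(8, n_features))."""
    n_features = len(features.feature_names)
    if k is None:
        k = min(8, n_features)
    if k > n_features:
        raise ValueError(f"k={k} exceeds {n_features} features")
    pca = PCA(n_components=k, svd_solver="full")
    coords = pca.fit_transform(features.values)
    return PcaResult(coords, pca.explained_variance_ratio_)


def run_umap(
    coords: np.ndarray,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
) -> np.ndarray:
    """2-D UMAP embedding, reproducible at a fixed seed."""
    import umap  # deferred: numba compilation is slow at import

    if coords.shape[0] <= n_neighbors:
        raise ValueError(
            f"{coords.shape[0]} cells <= n_neighbors={n_neighbors}; "
            "reduce n_neighbors"
        )
    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
        n_jobs=1,
    )
    return np.asarray(reducer.fit_transform(coords), dtype=np.float64)


def run_hdbscan(coords: np.ndarray, min_cluster_size: int = 5) -> np.ndarray:
    """Density-based cluster labels; -1 marks noise."""
    if coords.shape[0] < min_cluster_size:
        logger.warning(
            "%d points < min_cluster_size=%d: all points labelled noise",
            coords.shape[0],
            min_cluster_size,
        )
        return np.full(coords.shape[0], -1, dtype=int)
    labels = HDBSCAN(min_cluster_size=min_cluster_size, copy=True).fit_predict(coords)
    return np.asarray(labels, dtype=int)


@dataclass
class EmbeddingResult:
    """PCA + UMAP coordinates and HDBSCAN labels, row-aligned with cells."""

    cell_ids: list[str]
    pca_coords: np.ndarray = field(repr=False)
    pca_explained_variance: np.ndarray = field(repr=False)
    umap_coords: np.ndarray = field(repr=False)
    cluster_labels: np.ndarray = field(repr=False)
    random_seed: int = 42

    @property
    def n_clusters(self) -> int:
        return len(set(self.cluster_labels.tolist()) - {-1})

    def to_frame(self) -> pd.DataFrame:
        k = self.pca_coords.shape[1]
        df = pd.DataFrame({"cell_id": self.cell_ids})
        for i in range(k):
            df[f"PC{i + 1}"] = self.pca_coords[:, i]
        df["UMAP1"] = self.umap_coords[:, 0]
        df["UMAP2"] = self.umap_coords[:, 1]
        df["cluster"] = self.cluster_labels
        return df


def embed(
    features: CellFeatureMatrix,
    k: int | None = None,
    seed: int = 42,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    min_cluster_size: int = 5,
) -> EmbeddingResult:
    """PCA -> UMAP -> HDBSCAN in one deterministic pass."""
    pca = run_pca(features, k)
    umap_coords = run_umap(pca.coords, seed, n_neighbors, min_dist)
    labels = run_hdbscan(umap_coords, min_cluster_size)
    return EmbeddingResult(
        cell_ids=list(features.cell_ids),
        pca_coords=pca.coords,
        pca_explained_variance=pca.explained_variance_ratio,
        umap_coords=umap_coords,
        cluster_labels=labels,
        random_seed=seed,
    )


@dataclass
class ClusterPhenotype:
    """Per-cluster marker signs and the derived phenotype string.

    A marker is ``+`` in a cluster iff the cluster's median normalized
    expression strictly exceeds the global median over all cells —
    scale-free, no magic cutoffs.  Example string:
    ``CD8+ FOXP3- NKG7+ GZMA+ GZMB+``.
    """

    signs: dict[int, dict[str, str]]  # cluster -> marker -> "+"/"-"
    medians: dict[int, dict[str, float]]
    global_medians: dict[str, float]

    def phenotype_string(self, cluster: int, markers: tuple[str, ...] = PHENOTYPE_ORDER) -> str:
        return " ".join(f"{m}{self.signs[cluster][m]}" for m in markers if m in self.signs[cluster])


def phenotype_clusters(
    labels: np.ndarray,
    norm: np.ndarray,
    gene_ids: list[str],
    markers: tuple[str, ...] = DEFAULT_MARKERS,
) -> ClusterPhenotype:
    """Assign +/- marker signs to every non-noise cluster."""
    gene_index = {g: i for i, g in enumerate(gene_ids)}
    missing = [m for m in markers if m not in gene_index]
    if missing:
        raise ValueError(f"marker gene(s) {missing} absent from panel")
    global_med = {m: float(np.median(norm[:, gene_index[m]])) for m in markers}
    signs: dict[int, dict[str, str]] = {}
    medians: dict[int, dict[str, float]] = {}
    for cluster in sorted(set(labels.tolist()) - {-1}):
        mask = labels == cluster
        medians[cluster] = {
            m: float(np.median(norm[mask, gene_index[m]])) for m in markers
        }
        signs[cluster] = {
            m: "+" if medians[cluster][m] > global_med[m] else "-" for m in markers
        }
    return ClusterPhenotype(signs, medians, global_med)


class CohesionReport(NamedTuple):
    n_in_modal_cluster: int
    n_members: int
    fraction: float
    modal_cluster: int
    all_noise: bool


def dominant_cohesion(
    labels: np.ndarray, cell_ids: list[str], dominant: DominantClonotype
) -> CohesionReport:
    """How tightly the dominant clone's cells cluster together.

    Finds the modal non-noise cluster among the member cells and reports
    the member fraction in it.  If every member is noise, the mode is
    taken over the noise label and flagged.
    """
    label_of = dict(zip(cell_ids, labels.tolist()))
    member_labels = [label_of[c] for c in dominant.cell_ids if c in label_of]
    if not member_labels:
        raise ValueError("no dominant-clone member has embedding coordinates")
    non_noise = [l for l in member_labels if l != -1]
    pool = non_noise if non_noise else member_labels
    values, counts = np.unique(pool, return_counts=True)
    modal = int(values[np.argmax(counts)])
    n_in = int(sum(1 for l in member_labels if l == modal))
    return CohesionReport(
        n_in_modal_cluster=n_in,
        n_members=len(member_labels),
        fraction=n_in / len(member_labels),
        modal_cluster=modal,
        all_noise=not non_noise,
    )
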