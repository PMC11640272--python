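"""Synthetic single-cell TCR + targeted-expression data with planted truth.

The generators emulate the statistical structure the pipeline assumes:

* clonal expansion — clone sizes follow a Zipf (power) law, so a few
  clones dominate the repertoire while most are singletons;
* paired alpha/beta chains drawn from small V/J gene pools, with an
  optional chain-dropout rate mimicking capture failure;
* negative-binomial marker expression with a cytotoxic subpopulation
  (CD8/NKG7/GZMA/GZMB high, CD4/FOXP3 low) on a ~397-gene targeted panel;
* Beta-distributed binding scores with a planted expanded high-score
  clone, so dominant-clone recovery can be tested against ground truth;
* multi-donor sample tags.

:func:`build_worked_example` is fully deterministic (no RNG) and encodes
the canonical repertoire structure used as the package's worked example:
a dominant CDR3 pair spanning 21 cells — one 7-cell full-length clonotype
plus seven 2-cell clonotypes differing only in V/J genes — among three
7-cell clonotypes, over a background that brings the table to 1429
clonotypes (110 after singleton filtering).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .binding import BindingQuery, PeptideContext, stub_predictor
from .clonotyping import FullLengthKey, strip_allele
from .io_airr import (
    ExpressionMatrix,
    Locus,
    TcrContig,
    write_airr_rearrangements,
    write_binding_scores,
    write_expression_matrix,
    write_sample_tags,
)

__all__ = [
    "TRAV_POOL",
    "TRAJ_POOL",
    "TRBV_POOL",
    "TRBJ_POOL",
    "RepertoireSpec",
    "ExpressionSpec",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_repertoire",
    "simulate_expression",
    "simulate_binding_scores",
    "simulate_planted_repertoire",
    "simulate_dataset",
    "simulate_four_populations",
    "build_worked_example",
]

# Small pools of real gene-segment names; a few carry allele suffixes so
# that allele stripping is exercised end to end.
TRAV_POOL = (
    "TRAV1-1", "TRAV1-2*01", "TRAV2", "TRAV3", "TRAV8-1", "TRAV9-2",
    "TRAV12-1", "TRAV13-1*02", "TRAV17", "TRAV21", "TRAV26-1", "TRAV38-1",
)
TRAJ_POOL = (
    "TRAJ3", "TRAJ6", "TRAJ9*01", "TRAJ12", "TRAJ23", "TRAJ31",
    "TRAJ37", "TRAJ42", "TRAJ49",
)
TRBV_POOL = (
    "TRBV2", "TRBV4-1", "TRBV5-1*01", "TRBV6-5", "TRBV7-9", "TRBV9",
    "TRBV11-2", "TRBV19", "TRBV20-1", "TRBV27", "TRBV28", "TRBV30",
)
TRBJ_POOL = (
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-5*01", "TRBJ2-1", "TRBJ2-3", "TRBJ2-7",
)

_AA20 = "ACDEFGHIKLMNPQRSTVWY"

#: negative-binomial marker means per population (molecules per cell)
DEFAULT_PROFILES: dict[str, dict[str, float]] = {
    "cytotoxic": {"CD8": 50.0, "NKG7": 40.0, "GZMA": 35.0, "GZMB": 30.0,
                  "CD4": 2.0, "FOXP3": 1.0},
    "helper": {"CD8": 2.0, "NKG7": 3.0, "GZMA": 3.0, "GZMB": 2.0,
               "CD4": 30.0, "FOXP3": 8.0},
}

#: four well-separated T/NK-like marker profiles for clustering tests.
#: "off" markers sit at ~6 molecules, not ~1: zero counts put log2-CPM on a
#: bimodal 0/11 scale whose variance would swamp the between-population signal
FOUR_POPULATION_PROFILES: dict[str, dict[str, float]] = {
    "cytotoxic": {"CD8": 120.0, "NKG7": 80.0, "GZMA": 70.0, "GZMB": 60.0,
                  "CD4": 6.0, "FOXP3": 6.0},
    "helper": {"CD8": 6.0, "NKG7": 8.0, "GZMA": 8.0, "GZMB": 6.0,
               "CD4": 120.0, "FOXP3": 8.0},
    "regulatory": {"CD8": 6.0, "NKG7": 6.0, "GZMA": 6.0, "GZMB": 6.0,
                   "CD4": 90.0, "FOXP3": 100.0},
    "nk_like": {"CD8": 6.0, "NKG7": 150.0, "GZMA": 120.0, "GZMB": 120.0,
                "CD4": 6.0, "FOXP3": 6.0},
}


@dataclass
class RepertoireSpec:
    """Parameters of a simulated repertoire.

    ``zipf_s`` is the exponent of the clone-size power law (clone k gets
    cells with probability proportional to k^-s); ``sizes`` overrides
    the law with an explicit size list; ``dropout`` is the per-cell
    probability of losing one chain.
    """

    n_cells: int = 600
    n_clones: int = 150
    zipf_s: float = 1.5
    sizes: list[int] | None = None
    cdr3_len: tuple[int, int] = (10, 17)
    n_donors: int = 3
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sizes is not None and sum(self.sizes) != self.n_cells:
            raise ValueError("explicit sizes must sum to n_cells")
        if self.zipf_s <= 0:
            raise ValueError("zipf_s must be > 0")
        if not 0 <= self.dropout < 1:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class ExpressionSpec:
    """Negative-binomial expression model for a targeted panel.

    ``dispersion`` is the NB size parameter (variance = m + m^2/size);
    large values approach Poisson.  The panel is the marker genes plus
    background genes up to ``n_genes`` (default 397, a targeted
    immune-response panel size).
    """

    profiles: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PROFILES.items()}
    )
    dispersion: float = 2.0
    background_mean: float = 2.0
    n_genes: int = 397
    seed: int = 0

    def __post_init__(self) -> None:
        for pop, prof in self.profiles.items():
            if any(m <= 0 for m in prof.values()):
                raise ValueError(f"profile {pop!r} has a non-positive marker mean")
        if self.dispersion <= 0 or self.background_mean <= 0:
            raise ValueError("dispersion and background_mean must be > 0")


@dataclass
class GroundTruth:
    """What was planted: the answer key for recovery tests."""

    planted_key: FullLengthKey
    clone_keys: list[FullLengthKey]
    clone_sizes: list[int]
    cell_clone: dict[str, int]  # cell_id -> clone index
    populations: dict[str, str]  # cell_id -> population name

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_key": list(self.planted_key),
                "clone_sizes": self.clone_sizes,
                "n_clones": len(self.clone_keys),
            },
            indent=2,
        )


@dataclass
class SimulatedDataset:
    """All four pipeline inputs plus the planted ground truth."""

    contigs: list[TcrContig]
    expression: ExpressionMatrix
    sample_tags: dict[str, str]
    binding_scores: pd.DataFrame
    ground_truth: GroundTruth

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "airr": outdir / "contigs.airr.tsv",
            "expression": outdir / "expression.csv",
            "tags": outdir / "sample_tags.csv",
            "scores": outdir / "binding_scores.csv",
            "truth": outdir / "ground_truth.json",
        }
        write_airr_rearrangements(self.contigs, paths["airr"])
        write_expression_matrix(self.expression, paths["expression"])
        write_sample_tags(self.sample_tags, paths["tags"])
        write_binding_scores(self.binding_scores, paths["scores"])
        paths["truth"].write_text(self.ground_truth.to_json() + "\n")
        return paths


def _index_cdr3(prefix: str, index: int, width: int = 4) -> str:
    """Deterministic distinct CDR3: C + prefix + base-20 index + F."""
    letters = []
    for _ in range(width):
        index, r = divmod(index, 20)
        letters.append(_AA20[r])
    return "C" + prefix + "".join(letters) + "F"


def _random_cdr3(rng: np.random.Generator, lo: int, hi: int) -> str:
    n = int(rng.integers(lo, hi + 1))
    inner = "".join(_AA20[i] for i in rng.integers(0, 20, size=max(n - 2, 1)))
    return "C" + inner + "F"


def _clone_chains(
    rng: np.random.Generator, n_clones: int, cdr3_len: tuple[int, int]
) -> list[tuple[tuple[str, str, str], tuple[str, str, str]]]:
    """Distinct (V, J, CDR3) per chain for each clone."""
    capacity = 20 ** (cdr3_len[1] - 2)
    if n_clones > capacity:
        raise ValueError(f"n_clones={n_clones} exceeds distinct-key capacity")
    chains = []
    seen: set[tuple[str, str]] = set()
    while len(chains) < n_clones:
        a_cdr3 = _random_cdr3(rng, *cdr3_len)
        b_cdr3 = _random_cdr3(rng, *cdr3_len)
        if (a_cdr3, b_cdr3) in seen:
            continue
        seen.add((a_cdr3, b_cdr3))
        alpha = (
            TRAV_POOL[int(rng.integers(len(TRAV_POOL)))],
            TRAJ_POOL[int(rng.integers(len(TRAJ_POOL)))],
            a_cdr3,
        )
        beta = (
            TRBV_POOL[int(rng.integers(len(TRBV_POOL)))],
            TRBJ_POOL[int(rng.integers(len(TRBJ_POOL)))],
            b_cdr3,
        )
        chains.append((alpha, beta))
    return chains


def _stripped_key(
    alpha: tuple[str, str, str], beta: tuple[str, str, str]
) -> FullLengthKey:
    return FullLengthKey(
        strip_allele(alpha[0]), strip_allele(alpha[1]), alpha[2],
        strip_allele(beta[0]), strip_allele(beta[1]), beta[2],
    )


def simulate_repertoire(spec: RepertoireSpec) -> tuple[list[TcrContig], GroundTruth]:
    """Draw a clonally expanded repertoire of paired-chain cells.

    Clone sizes follow the Zipf law (or the explicit list); every cell
    inherits its clone's chains; at rate ``dropout`` a cell loses one
    chain (alpha or beta with equal probability).  Deterministic per seed.
    """
    rng = np.random.default_rng(spec.seed)
    chains = _clone_chains(rng, spec.n_clones, spec.cdr3_len)
    if spec.sizes is not None:
        sizes = np.asarray(spec.sizes, dtype=int)
    else:
        p = np.arange(1, spec.n_clones + 1, dtype=float) ** -spec.zipf_s
        p /= p.sum()
        assignment = rng.choice(spec.n_clones, size=spec.n_cells, p=p)
        sizes = np.bincount(assignment, minlength=spec.n_clones)

    contigs: list[TcrContig] = []
    cell_clone: dict[str, int] = {}
    width = len(str(int(sizes.sum())))
    cell_no = 0
    for clone_idx, size in enumerate(sizes):
        alpha, beta = chains[clone_idx]
        for _ in range(int(size)):
            cell_no += 1
            cid = f"cell-{cell_no:0{width}d}"
            cell_clone[cid] = clone_idx
            keep_alpha = keep_beta = True
            if spec.dropout and rng.random() < spec.dropout:
                if rng.random() < 0.5:
                    keep_alpha = False
                else:
                    keep_beta = False
            if keep_alpha:
                contigs.append(
                    TcrContig(cid, Locus.TRA, alpha[0], alpha[1], alpha[2],
                              True, int(rng.integers(1, 20)))
                )
            if keep_beta:
                contigs.append(
                    TcrContig(cid, Locus.TRB, beta[0], beta[1], beta[2],
                              True, int(rng.integers(1, 20)))
                )
    keys = [_stripped_key(a, b) for a, b in chains]
    truth = GroundTruth(
        planted_key=keys[0],
        clone_keys=keys,
        clone_sizes=[int(s) for s in sizes],
        cell_clone=cell_clone,
        populations={},
    )
    return contigs, truth


def _nb_draw(
    rng: np.random.Generator, mean: float, dispersion: float, size: tuple[int, ...]
) -> np.ndarray:
    """Gamma-Poisson mixture: NB with var = mean + mean^2/dispersion."""
    lam = rng.gamma(shape=dispersion, scale=mean / dispersion, size=size)
    return rng.poisson(lam)


def simulate_expression(
    cell_ids: list[str],
    populations: dict[str, str],
    spec: ExpressionSpec,
) -> ExpressionMatrix:
    """Negative-binomial counts on a targeted panel, per population profile."""
    rng = np.random.default_rng(spec.seed)
    unknown = {populations[c] for c in cell_ids} - set(spec.profiles)
    if unknown:
        raise ValueError(f"unknown population id(s): {sorted(unknown)}")
    markers = sorted({m for prof in spec.profiles.values() for m in prof})
    n_background = spec.n_genes - len(markers)
    if n_background < 0:
        raise ValueError("n_genes smaller than the marker set")
    gene_ids = markers + [f"PANEL{i:04d}" for i in range(n_background)]
    counts = np.zeros((len(cell_ids), spec.n_genes), dtype=np.int64)
    pop_of = np.array([populations[c] for c in cell_ids])
    for pop, prof in spec.profiles.items():
        mask = pop_of == pop
        n = int(mask.sum())
        if n == 0:
            continue
        for j, m in enumerate(markers):
            counts[mask, j] = _nb_draw(rng, prof[m], spec.dispersion, (n,))
    counts[:, len(markers):] = _nb_draw(
        rng, spec.background_mean, spec.dispersion, (len(cell_ids), n_background)
    )
    return ExpressionMatrix(list(cell_ids), gene_ids, counts)


def simulate_binding_scores(
    clone_keys: list[FullLengthKey],
    planted_key: FullLengthKey,
    ctx: PeptideContext | None = None,
    beta_a: float = 2.0,
    beta_b: float = 5.0,
    margin: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Beta(a, b) scores with the planted clone a strict argmax.

    The planted clone scores max(others) + margin, capped at 1; Beta
    draws are < 1 almost surely, so the argmax stays strict.
    """
    if ctx is None:
        ctx = PeptideContext()
    rng = np.random.default_rng(seed)
    rows = []
    others: list[float] = []
    for key in clone_keys:
        if key == planted_key:
            score = None  # filled after the loop
        else:
            score = float(rng.beta(beta_a, beta_b))
            others.append(score)
        rows.append((key, score))
    planted_score = min(1.0, (max(others) if others else 0.5) + margin)
    df = pd.DataFrame(
        [
            {
                "cdr3_alpha": k.cdr3_alpha,
                "cdr3_beta": k.cdr3_beta,
                "v_alpha": k.v_alpha,
                "j_alpha": k.j_alpha,
                "v_beta": k.v_beta,
                "j_beta": k.j_beta,
                "peptide": ctx.peptide,
                "mhc": ctx.mhc,
                "t_cell_type": ctx.t_cell_type,
                "score": planted_score if s is None else s,
            }
            for k, s in rows
        ]
    )
    return df


def simulate_planted_repertoire(
    n_cells: int = 600,
    n_clones: int = 150,
    zipf_s: float = 1.5,
    dropout: float = 0.0,
    ctx: PeptideContext | None = None,
    seed: int = 0,
) -> tuple[list[TcrContig], GroundTruth, pd.DataFrame]:
    """Repertoire + scores in the unambiguous-expansion regime.

    The largest clone is boosted, if needed, to at least twice the
    runner-up size by minting extra cells with its chains, and is given
    the strictly maximal binding score — the regime in which the
    dominant-clone call has a single right answer.
    """
    rng = np.random.default_rng(seed)
    spec = RepertoireSpec(
        n_cells=n_cells, n_clones=n_clones, zipf_s=zipf_s,
        dropout=dropout, seed=int(rng.integers(2**31)),
    )
    contigs, truth = simulate_repertoire(spec)
    sizes = np.array(truth.clone_sizes)
    order = np.argsort(-sizes, kind="stable")
    top, runner = int(order[0]), int(order[1])
    if sizes[runner] > 0 and sizes[top] < 2 * sizes[runner]:
        # grow the top clone to 2x the runner-up with extra cells
        need = 2 * int(sizes[runner]) - int(sizes[top])
        extra_contigs, extra_ids = _grow_clone(contigs, truth, top, need)
        contigs = contigs + extra_contigs
        sizes[top] += need
        truth.clone_sizes[top] = int(sizes[top])
        for cid in extra_ids:
            truth.cell_clone[cid] = top
    truth.planted_key = truth.clone_keys[top]
    present = [k for k, s in zip(truth.clone_keys, truth.clone_sizes) if s > 0]
    scores = simulate_binding_scores(
        present, truth.planted_key, ctx, seed=int(rng.integers(2**31))
    )
    truth.populations = {
        cid: "cytotoxic" if truth.cell_clone[cid] == top else "helper"
        for cid in truth.cell_clone
    }
    return contigs, truth, scores


def simulate_dataset(
    n_cells: int = 600,
    n_clones: int = 150,
    zipf_s: float = 1.5,
    n_donors: int = 3,
    dropout: float = 0.0,
    expression_spec: ExpressionSpec | None = None,
    ctx: PeptideContext | None = None,
    seed: int = 0,
) -> SimulatedDataset:
    """Full four-file dataset with a planted dominant clone.

    The planted clone is at least twice the runner-up size with the
    strictly maximal binding score (see
    :func:`simulate_planted_repertoire`); its cells carry the cytotoxic
    expression profile, all others the helper profile.
    """
    rng = np.random.default_rng(seed)
    contigs, truth, scores = simulate_planted_repertoire(
        n_cells=n_cells, n_clones=n_clones, zipf_s=zipf_s,
        dropout=dropout, ctx=ctx, seed=int(rng.integers(2**31)),
    )
    cell_ids = sorted(truth.cell_clone)
    if expression_spec is None:
        expression_spec = ExpressionSpec(seed=int(rng.integers(2**31)))
    expression = simulate_expression(cell_ids, truth.populations, expression_spec)
    donors = rng.integers(1, n_donors + 1, size=len(cell_ids))
    tags = {cid: f"donor{d}" for cid, d in zip(cell_ids, donors)}
    return SimulatedDataset(contigs, expression, tags, scores, truth)


def _grow_clone(
    contigs: list[TcrContig], truth: GroundTruth, clone_idx: int, n_new: int
) -> tuple[list[TcrContig], list[str]]:
    """Mint extra cells carrying an existing clone's chains."""
    key = truth.clone_keys[clone_idx]
    extra, ids = [], []
    for i in range(n_new):
        cid = f"cell-extra-{i + 1:04d}"
        ids.append(cid)
        extra.append(TcrContig(cid, Locus.TRA, key.v_alpha, key.j_alpha,
                               key.cdr3_alpha, True, 5))
        extra.append(TcrContig(cid, Locus.TRB, key.v_beta, key.j_beta,
                               key.cdr3_beta, True, 5))
    return extra, ids


def simulate_four_populations(
    n_per_pop: int = 50,
    dispersion: float = 10.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, dict[str, str]]:
    """Expression for four well-separated marker populations.

    Returns the matrix and the cell -> population labels.  The profiles
    (cytotoxic / helper / regulatory / NK-like) differ strongly on the
    six phenotype markers, so a density-based clustering of the
    marker-feature embedding should recover exactly four clusters.
    """
    pops = list(FOUR_POPULATION_PROFILES)
    cell_ids = [
        f"cell-{p}-{i:03d}" for p in pops for i in range(n_per_pop)
    ]
    labels = {cid: cid.split("-")[1] for cid in cell_ids}
    spec = ExpressionSpec(
        profiles={k: dict(v) for k, v in FOUR_POPULATION_PROFILES.items()},
        dispersion=dispersion,
        seed=seed,
    )
    return simulate_expression(cell_ids, labels, spec), labels


# ---------------------------------------------------------------------------
# Deterministic worked example
# ---------------------------------------------------------------------------

def build_worked_example() -> SimulatedDataset:
    """The canonical repertoire structure, fully deterministic (no RNG).

    Composition (1429 full-length clonotypes, 1554 cells):

    * three 7-cell clonotypes (the expanded candidates);
    * one of the three shares its CDR3 pair with seven 2-cell clonotypes
      that differ only in V/J genes, so the pair spans 7 + 7*2 = 21 cells;
    * 100 further 2-cell background clonotypes (110 clonotypes survive
      the singleton filter: 110/1429 = 7.7%);
    * 1319 singleton clonotypes.

    Binding scores make the shared-pair 7-cell clonotype the argmax
    among the three candidates (0.52 vs 0.31/0.47); all 21 shared-pair
    cells carry the cytotoxic expression profile.
    """
    ctx = PeptideContext()
    shared_a, shared_b = "CAVRGDSSYKLIF", "CASSPGTEAYF"

    clones: list[tuple[FullLengthKey, int]] = []
    # the dominant clonotype and the two rival 7-cell clonotypes
    dominant = FullLengthKey("TRAV12-1", "TRAJ12", shared_a,
                             "TRBV9", "TRBJ2-7", shared_b)
    clones.append((dominant, 7))
    clones.append((FullLengthKey("TRAV1-1", "TRAJ3", "CAVNDYKLSF",
                                 "TRBV2", "TRBJ1-1", "CASSLGQAYF"), 7))
    clones.append((FullLengthKey("TRAV2", "TRAJ6", "CAASGGSYIPTF",
                                 "TRBV4-1", "TRBJ1-2", "CASSQDRGYTF"), 7))
    # seven 2-cell clonotypes sharing the dominant CDR3 pair, distinct V/J
    vj_variants = [
        ("TRAV1-1", "TRAJ3", "TRBV2", "TRBJ1-1"),
        ("TRAV2", "TRAJ6", "TRBV4-1", "TRBJ1-2"),
        ("TRAV3", "TRAJ23", "TRBV6-5", "TRBJ2-1"),
        ("TRAV8-1", "TRAJ31", "TRBV7-9", "TRBJ2-3"),
        ("TRAV9-2", "TRAJ37", "TRBV11-2", "TRBJ1-1"),
        ("TRAV17", "TRAJ42", "TRBV19", "TRBJ2-1"),
        ("TRAV21", "TRAJ49", "TRBV20-1", "TRBJ2-3"),
    ]
    for va, ja, vb, jb in vj_variants:
        clones.append((FullLengthKey(va, ja, shared_a, vb, jb, shared_b), 2))
    # background: 100 two-cell + 1319 singleton clonotypes, distinct CDR3s
    for i in range(100):
        clones.append((_background_key(i), 2))
    for i in range(100, 100 + 1319):
        clones.append((_background_key(i), 1))

    contigs: list[TcrContig] = []
    cell_clone: dict[str, int] = {}
    populations: dict[str, str] = {}
    cell_no = 0
    for clone_idx, (key, size) in enumerate(clones):
        cytotoxic = key.cdr3_alpha == shared_a and key.cdr3_beta == shared_b
        for _ in range(size):
            cell_no += 1
            cid = f"WE-{cell_no:04d}"
            cell_clone[cid] = clone_idx
            populations[cid] = "cytotoxic" if cytotoxic else "helper"
            contigs.append(TcrContig(cid, Locus.TRA, key.v_alpha, key.j_alpha,
                                     key.cdr3_alpha, True, 3))
            contigs.append(TcrContig(cid, Locus.TRB, key.v_beta, key.j_beta,
                                     key.cdr3_beta, True, 3))

    cell_ids = sorted(cell_clone)
    expression = _worked_example_expression(cell_ids, populations)
    tags = {cid: f"donor{1 + i % 3}" for i, cid in enumerate(cell_ids)}

    queries = [
        BindingQuery(k.cdr3_alpha, k.cdr3_beta, k.v_alpha, k.j_alpha,
                     k.v_beta, k.j_beta, ctx.peptide, ctx.mhc, ctx.t_cell_type)
        for k, _ in clones
    ]
    scores = stub_predictor(queries)
    # compress stub scores under the candidates, then pin the three
    # 7-cell clonotypes so the shared-pair clone is the strict argmax
    scores["score"] = scores["score"] * 0.30
    scores.loc[0, "score"] = 0.52
    scores.loc[1, "score"] = 0.31
    scores.loc[2, "score"] = 0.47

    truth = GroundTruth(
        planted_key=dominant,
        clone_keys=[k for k, _ in clones],
        clone_sizes=[s for _, s in clones],
        cell_clone=cell_clone,
        populations=populations,
    )
    return SimulatedDataset(contigs, expression, tags, scores, truth)


def _background_key(i: int) -> FullLengthKey:
    return FullLengthKey(
        TRAV_POOL[i % len(TRAV_POOL)].split("*")[0],
        TRAJ_POOL[i % len(TRAJ_POOL)].split("*")[0],
        _index_cdr3("AL", i),
        TRBV_POOL[i % len(TRBV_POOL)].split("*")[0],
        TRBJ_POOL[i % len(TRBJ_POOL)].split("*")[0],
        _index_cdr3("SS", i),
    )


def _worked_example_expression(
    cell_ids: list[str], populations: dict[str, str]
) -> ExpressionMatrix:
    """Deterministic counts: fixed profiles plus small index-based jitter."""
    markers = ["CD4", "CD8", "FOXP3", "GZMA", "GZMB", "NKG7"]
    n_background = 397 - len(markers)
    gene_ids = markers + [f"PANEL{i:04d}" for i in range(n_background)]
    idx = np.arange(len(cell_ids))
    cyto = np.array([populations[c] == "cytotoxic" for c in cell_ids])
    counts = np.zeros((len(cell_ids), 397), dtype=np.int64)
    profile = {
        #        cytotoxic base, helper base
        "CD4": (1, 20), "CD8": (45, 2), "FOXP3": (0, 6),
        "GZMA": (32, 2), "GZMB": (28, 1), "NKG7": (38, 3),
    }
    for j, m in enumerate(markers):
        base_c, base_h = profile[m]
        counts[:, j] = np.where(cyto, base_c, base_h) + idx % 3
    counts[:, len(markers):] = (
        idx[:, None] + 7 * np.arange(n_background)[None, :]
    ) % 5
    return ExpressionMatrix(list(cell_ids), gene_ids, counts)
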