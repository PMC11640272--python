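# Methods

## Model of the data

A sample of antigen-enriched T cells is observed through three channels:

* **Receptor** — per-cell TCR contigs in the AIRR Rearrangement schema
  (`cell_id, locus, v_call, j_call, junction_aa, productive,
  duplicate_count`). The CDR3 is the amino-acid `junction_aa` string with
  its conserved flanking residues, used verbatim (no trimming).
* **Transcriptome** — a cells × genes matrix of post-error-correction
  molecule counts from a targeted panel (~397 genes). The pipeline consumes
  corrected counts; no UMI error correction is re-implemented.
* **Binding** — one predicted TCR–pMHC binding score in [0, 1] per
  full-length clonotype, produced out-of-band by an external neural
  predictor from CDR3α/β, V/J genes, peptide, MHC and T-cell type. The
  pipeline builds the predictor's input CSV and validates its output;
  scores outside [0, 1] are rejected, never clamped.

The analytical premise is clonal expansion: among enriched cells, clones
that recognise the target peptide–MHC have proliferated, so cell count per
clonotype is the primary specificity signal and the predicted binding score
is the discriminator among equally expanded clones.

## Procedure and conventions

**Chain pairing.** Only productive contigs are considered. Per cell and
locus the highest-UMI contig wins; UMI ties break on the lexicographically
smallest CDR3, so pairing is deterministic. Cells lacking either chain are
"incomplete": excluded from clonotype counting but retained in the
expression matrix for embedding (their clone-size and score features are 0).

**Clonotype identity.** Gene calls are stripped of IMGT allele suffixes
(`TRBV9*01` → `TRBV9`) before keying: predictors consume gene-level V/J and
allele calls are unreliable at single-cell depth. CDR3 identity is
amino-acid level; nucleotide clonotyping is not offered. Full-length keys
(six components) refine CDR3-pair keys, which is what
`compare_resolutions` exploits: per pair, the cell count equals the sum of
the full-length clonotype counts sharing it.

**Singleton filter.** Clonotypes with one cell are dropped before
repertoire-level analysis; the filter is idempotent. Percentages print
half-up at one decimal (e.g. 110/1429 → 7.7), matching the reporting
convention used across the QC summary.

**Dominant selection.** Argmax by (cell count, binding score), remaining
ties broken by lexicographically smallest key so that the result is
invariant to table row order. Every max-count candidate must carry a score;
a missing score at the maximum is an error rather than a silent skip,
because the score is the designated tie-breaker. The full candidate set is
reported alongside the winner.

**Embedding.** log2(CPM + 1) with pseudocount 1; all-zero cells stay
all-zero (logged). Features are z-scored per column; zero-variance columns
stay at 0 after centering. Clonotype *identity* is categorical and has no
meaningful metric, so it enters the embedding only through two numeric
surrogates — log2 clone size and binding score — and can be overlaid on the
map for reporting. Defaults: PCA k = min(8, n_features) with the exact
(full SVD) solver; UMAP n_neighbors = 15, min_dist = 0.1, seed 42, single
threaded for reproducibility; HDBSCAN min_cluster_size = 5. None of these
is forced by the method; all are configurable.

**Phenotyping.** Per cluster and marker, the sign is `+` iff the cluster
median of normalized expression strictly exceeds the global median across
all cells. This is scale-free and threshold-free; uniform expression yields
all `-`. The phenotype string lists markers in the canonical order CD8,
CD4, FOXP3, NKG7, GZMA, GZMB.

**Cohesion.** For the dominant clone, the modal non-noise cluster among its
member cells and the member fraction inside it. If every member is noise
the mode is taken over the noise label and flagged.

## Synthetic data

The generator exists to exercise the pipeline against planted ground truth,
emulating the structure the analysis assumes:

* **Repertoire** — clone sizes from a Zipf law with exponent s = 1.5
  (default; the few-dominant/many-singleton shape of an enriched culture —
  the true size law of such cultures is unknown, so this is a testing
  assumption, not an estimate); distinct (V, J, CDR3) per clone drawn from
  small pools of real TRAV/TRAJ/TRBV/TRBJ names (some with allele suffixes
  so stripping is exercised); CDR3 = `C` + random residues + `F`; optional
  chain dropout. The planted-regime generator boosts the largest clone to
  ≥ 2× the runner-up and gives it the strictly maximal binding score — the
  regime where the dominant call has one right answer.
* **Expression** — negative-binomial (Gamma–Poisson) counts, dispersion 2
  by default, on a 397-gene panel (six phenotype markers + background at
  mean 2). The four-population profiles used for clustering tests keep
  "off" markers at ~6–8 molecules rather than ~1: at means near zero the
  log2-CPM of a count is bimodal (0 vs ~11), and after z-scoring that
  technical noise would swamp the between-population signal the test is
  about. For that test HDBSCAN's min_cluster_size is 20, scaled to the
  50-cell planted populations.
* **Scores** — Beta(2, 5) for non-planted clones; planted =
  max(others) + 0.05, capped at 1 (Beta draws are < 1 a.s., so the argmax
  stays strict).
* **Sample tags** — 3 donors by default.

The deterministic worked example (`build_worked_example`, no RNG) encodes
the canonical repertoire shape exactly: three 7-cell clonotypes; seven
2-cell clonotypes sharing the dominant clonotype's CDR3 pair (pair span
7 + 7×2 = 21 cells); 100 further 2-cell clonotypes and 1319 singletons, so
that 110 of 1429 clonotypes (7.7%) survive the singleton filter. Its
expression uses fixed per-population profiles with small index-based
jitter; this keeps it reproducible byte-for-byte but makes the expression
lattice-like, so density clustering on it fragments — the fixture is the
reference for repertoire arithmetic, not for clustering behaviour.

What the generator does **not** emulate: V(D)J recombination statistics,
convergent recombination, UMI/sequencing error, doublets, batch effects,
or any real relationship between receptor sequence and binding score.
Passing tests therefore demonstrate the correctness of the pipeline's
logic under its stated assumptions, not performance on real repertoires.

## Problem sizes and determinism

Simulation-based checks use 200-cell/60-clone repertoires (100 seeds) for
dominant-clone recovery and 4 × 50-cell populations (100 seeds) for cluster
recovery — sizes at which the planted structure is unambiguous while the
whole suite runs in about a minute. Every stochastic component takes an
explicit seed; the pipeline re-run with the same inputs and seed is
byte-identical. The stub predictor hashes each query with CRC-32 and
divides by the digest maximum, giving platform-stable scores in [0, 1]
with no biological content.

## Known limitations

* Chain pairing keeps one α and one β per cell; genuine dual-α cells are
  collapsed to the better-supported chain.
* Whether the external predictor's score is comparable across V/J contexts
  is taken on trust; the pipeline only ranks.
* The median-sign phenotype is relative to the analysed cell population —
  a cluster is `CD8+` with respect to this sample, not an absolute gate.
* "Number of clusters" from density-based clustering depends on
  min_cluster_size and on UMAP's stochastic layout; noise cells (label −1)
  are excluded from the count.
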