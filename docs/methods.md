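# Methods

This note documents the models, conventions and design choices behind
`hippocoupling`, in the order the pipeline runs.

## Preprocessing

Counts are consumed as a sparse genes × cells matrix (Matrix Market
coordinate triplets, 1-based, with `features.tsv` / `barcodes.tsv`
sidecars). Quality control removes cells with fewer than `min_features`
detected genes (default 100) and then genes detected in fewer than
`min_cells` cells (default 1) — the creation-time semantics of the standard
single-cell toolkit. The cells-then-genes order makes the filter idempotent
at the default `min_cells = 1`: genes removed are detected in zero
remaining cells, so no cell's feature count changes on a second pass.

Normalization is LogNormalize:
`value(g, c) = ln(1 + count(g, c) · scale_factor / total(c))` with
`scale_factor = 10000`. The natural log with pseudocount 1 is the default
(log1p); the transform preserves the sparsity pattern (0 ↦ 0), is monotone
in the raw count within a cell, and is invariant to rescaling a cell's
counts — the two properties the property tests assert.

An optional variance-stabilized gene ranking (`rank_variable_genes`) fits a
quadratic mean–variance trend on log10 scale, standardizes counts by the
trend standard deviation with clipping at √n_cells, and ranks genes by the
variance of the standardized counts. It is a pass-through: no downstream
stage depends on it, because profiling and coupling operate on named gene
sets.

## Cell-type profiles

`aggregate` computes `x_it`, the arithmetic mean of log-normalized values of
gene *i* over the cells of group *t*, and the percent-positive
(fraction of the group's cells with nonzero raw count, reported 0–100;
computed from the preserved sparsity pattern). Groups are displayed in the
hippocampal subclass order (Astro, Oligo, Endo, Micro-PVM, Lamp5, Vip,
Pvalb, Sncg, Sst, DG, CA1-ProS, CA2, CA3) when all labels belong to it,
else lexicographically. `zscore` row-standardizes `x` with the sample
standard deviation (ddof = 1); constant rows map to all-zero z rather than
NaN. `split_by` crosses annotation keys (e.g. cell type × sex) into
composite labels so the same aggregation yields per-sex profiles.

## Coupling score

For receptor *j* ∈ {Nr3c1, Nr3c2}, gene *i* in gene set *S* and cell type
*t*:

- raw score `k_ijt = log10(max(x_it, ε) · max(x_jt, ε))` with
  `ε = 1e-6`. Flooring at ε keeps `k` finite when a gene is absent from a
  cell type and parks such pairs at the block minimum, which is the desired
  reading: genes not expressed anywhere (e.g. *Esr1*/*Esr2* in most
  hippocampal cells) produce uniformly very low scores. `k` is symmetric in
  the two gene roles by construction.
- normalized score `∁_ijt^S = (k − min k) / (max k − min k)`, min-max over
  a normalization block. The default scope is the full (i ∈ S) × (t) grid
  per receptor — one shared scale per heatmap, which is how a single-color-
  bar heatmap across cell types is read; a `per_group` scope (each cell
  type rescaled separately) is available by flag since the min/max
  subscripting is a genuinely open choice. A degenerate block (max = min)
  maps to all zeros.
- the shortlist keeps (gene, cell type) combinations with `∁ > 0.6`
  (strict). The receptor rule defaults to `either` (pass for at least one
  receptor, annotated per receptor) with `both` selectable; "either" is the
  inclusive reading when one wants an overview of candidates coupled to
  glucocorticoid signaling through either receptor.

`x_it` fed to the score is the average of log-normalized values (the same
quantity the profiles report); a de-logged average would change `k` by a
monotone per-entry transform but not the qualitative ranking, and can be
obtained by aggregating `expm1` values externally.

## Consensus target-gene filter

Evidence rows are (gene, source_type ∈ {meta_transcriptomic,
inhouse_rnaseq, chipseq}, study_id, direction ∈ {up, down, na}, binding ∈
{GR, MR, both, none}); chipseq rows must carry a binding annotation and
direction `na`, transcriptomic rows a direction; (gene, study, source) must
be unique. A gene is called when it has ≥ 1 meta-analysis row, ≥ 1 in-house
row (configurable off), one common direction across *all* its
transcriptomic rows, a non-none ChIP-seq binding class (union over rows:
GR-only, MR-only, or both), and ≥ `min_reporting_studies` distinct
transcriptomic studies (default 3; ChIP-seq studies never count). The
≥ 3-studies clause is treated as an enabled-by-default criterion rather
than a description of survivors, because that is the conservative reading;
setting it to 1 disables it. Criteria are conjunctive, so evaluation order
does not affect the call set; the per-criterion flags and contributing
study ids are reported per call, and `summarize_counts` reports the
evidence-integration funnel (union size, per-binding-class counts, per-
source gene counts, direction-consistent overlap, final calls by direction
and binding). Gene symbols are matched case-sensitively after whitespace
trimming; no orthology mapping is attempted, on the rationale that
functional glucocorticoid response elements are largely conserved across
rodents.

## Rank tests and markers

Both contrast tests are two-sided Wilcoxon tests: the paired signed-rank
test on per-cell-type averages (pairs (x_a,t, x_b,t) over groups; zero
differences dropped, all-zero → p = 1) and the two-sample rank-sum test on
the cells of one group. The exact null is enumerated when it is cheap and
valid — ≤ 25 tie-free non-zero differences (signed-rank) or ≤ 50 tie-free
pooled observations (rank-sum) — otherwise the normal approximation with
tie correction and 0.5 continuity correction is used (scipy backs the
computation; independent enumeration oracles back the tests). Two-sided
exact p-values follow the standard doubling rule, capped at 1.

Fold changes default to `log2((mean(expm1(a)) + 1) / (mean(expm1(b)) + 1))`
— de-log, average, pseudocount 1, the convention of the toolkit this
pipeline mirrors — with a difference-of-log-means mode as an alternative,
since published fold changes rarely state their formula.

One-vs-rest markers test each gene in each group against all other cells,
with pre-filters requiring detection in ≥ 10 % of cells on at least one
side and |log2FC| ≥ 0.25 (the cited toolkit's documented defaults; both
configurable, and `prefilter=False` exists for oracle testing). Groups
under 3 cells are skipped with a warning. Benjamini–Hochberg adjustment is
applied across all gene × group hypotheses tested in one run; the scope is
a convention and is therefore explicit here.

## Synthetic data

The count simulator draws gene *g*, cell *c* of group *t* as negative
binomial with mean `μ_g · m_gt · f_c` and variance `μ + μ²/r`
(`r = dispersion`):

- `μ_g = base_mean · LogNormal(−0.5, 1)` — a mean-one log-normal spread of
  gene-level means around `base_mean` (default 0.5), giving the skewed
  expression distribution typical of UMI data;
- `m_gt` — per-group multipliers: the receptor emulation (Nr3c2 ×6 in
  neuronal subclasses, Nr3c1 ×4 in non-neuronal ones, mirroring the
  qualitative hippocampal pattern) and planted pairs, which multiply both
  genes' means by `fold` in one designated group;
- `f_c = LogNormal(−σ²/2, σ)` — mean-one library-size factors
  (σ = 0.3 default), so expected counts equal the configured means and the
  moment-convergence test has a closed target.

Defaults are the desk-scale stand-in for a full hippocampal atlas matrix:
13 subclasses × 200 cells × 2000 genes. Dispersion r = 2 is a typical
droplet-data value. The same seed yields byte-identical matrices, files
and annotation. Recovery-rate analyses use 300 (tests) or 150 (acceptance
replicates) background genes: argmax recovery of a planted pair depends on
the pair, not on the number of background genes, and this keeps 100
replicates fast.

The evidence simulator emits `n_true_targets` genes satisfying all four
criteria (2–17 meta studies from a 17-study pool, plus the single in-house
study, consistent direction, binding drawn GR/MR/both with probabilities
0.7/0.1/0.2 — a GR-skewed mix) and, per failure mode, decoys violating
exactly one criterion: no meta row, no in-house row, inconsistent
direction, or no binding. Truth labels refer to the four core criteria; a
`no_meta` decoy necessarily also has fewer than three reporting studies, so
exact truth-recovery checks run the filter with `min_reporting_studies = 1`
(the call set is identical either way on these tables, since true targets
always carry ≥ 3 studies).

What the simulator does **not** emulate: doublets, ambient RNA, batch
effects, cell-type abundance imbalance, gene–gene correlation beyond the
planted pairs, or a taxonomy hierarchy. Passing tests therefore demonstrate
the correctness of the computations and the recoverability of planted
signal under idealized NB sampling — not robustness to those artifacts in
real data.

## Pipeline and determinism

`run_pipeline` executes preprocess → profiles → coupling (per gene set) →
consensus → markers from one config, writing long/wide TSVs, a shortlist,
a manifest and a provenance log (parameters and SHA-256 input digests; no
timestamps, so a rerun of the same config is byte-identical). Stage
failures abort with a stage-tagged error. All tables are UTF-8 TSVs with
explicit headers and locale-independent number formatting.

## Known limitations

- The coupling score has no significance model; it ranks co-expression
  within a gene set and is not comparable across sets (the normalization is
  per set by construction).
- Exact rank tests switch to the normal approximation in the presence of
  ties, which is the dominant regime in sparse single-cell data; p-values
  near the exact/asymptotic boundary can shift slightly with sample size.
- Binding annotations are consumed as per-gene booleans; peak-to-gene
  assignment and the underlying differential-expression analyses are out of
  scope.
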