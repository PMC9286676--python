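# hippocoupling

Cell-type-resolved co-expression analysis of the corticosteroid receptors in
single-cell RNA-seq data.

The hippocampus is a prime target of glucocorticoid stress hormones, which
act through two nuclear receptors: the glucocorticoid receptor (GR, encoded
by *Nr3c1*) and the mineralocorticoid receptor (MR, *Nr3c2*). Whether a
given cell type can mount a receptor-dependent transcriptional response
depends on where each receptor is expressed *together with* its interaction
partners — coregulators, other steroid receptors, neurotransmitter and
neuropeptide receptors, and its target genes. `hippocoupling` implements
that analysis as a reusable, fully tested pipeline for researchers in stress
neurobiology and single-cell transcriptomics:

- **Preprocessing** — Matrix Market + features/barcodes I/O, the standard QC
  filters (`min_cells`, `min_features`) and LogNormalize
  (`scale_factor = 10000`).
- **Profiles** — per-cell-type average expression `x_it`, percent-positive
  cells, and row z-scores.
- **Coupling score** — for receptor *j*, gene *i* and cell type *t*,

  ```
  k_ijt = log10(x_it · x_jt)
  ∁_ijt^S = (k_ijt − min_S k) / (max_S k − min_S k)
  ```

  min-max normalized over a named gene set *S*, with a `> 0.6` shortlist of
  the strongest receptor–gene–cell-type combinations.
- **Consensus target genes** — a gene is called a GR/MR target when it is
  (1) glucocorticoid-regulated in published transcriptomic studies,
  (2) responsive in an in-house RNA-seq experiment, (3) direction-consistent
  across all reporting studies, and (4) bound by GR and/or MR in ChIP-seq,
  with a configurable minimum number of reporting studies.
- **Contrasts and markers** — paired signed-rank tests across cell-type
  averages, rank-sum tests within a cell type, one-vs-rest marker detection
  with Benjamini–Hochberg adjustment. Exact null distributions are used
  wherever enumeration is cheap.
- **Simulator** — a seeded negative-binomial count generator with labeled
  cell types, library-size variation and *planted* receptor–partner
  co-expression, plus an evidence-table generator with known consensus
  truth, so every stage is testable without downloads.

## Worked example

```python
import hippocoupling as hc

# plant a fold-50 co-expression signal between Nr3c1 and a partner gene in CA2
planted = hc.PlantedPair("Nr3c1", "Gene00050", group=11, fold=50.0)
cfg = hc.SimulationConfig(n_genes=300, planted_pairs=[planted], seed=3)
matrix, annotation = hc.simulate_counts(cfg)

filtered, _ = hc.qc_filter(matrix, min_features=0)
annotation = annotation[annotation["cell_id"].isin(set(filtered.cell_ids))]
profile = hc.aggregate(hc.log_normalize(filtered), annotation)

gene_set = hc.GeneSet("demo", ["Gene00050"] + [f"Gene{i:05d}" for i in range(10, 30)])
records = hc.couple(profile, ["Nr3c1", "Nr3c2"], gene_set)
partner = records.query("gene == 'Gene00050' and receptor == 'Nr3c1'")
print(partner.set_index("group")["c_norm"].idxmax())   # -> CA2
```

The normalized coupling of the planted partner peaks exactly in the planted
cell type (`c_norm = 1.000` in CA2, ≤ 0.39 elsewhere in this run): the score
ranks (gene, cell type) combinations by joint receptor–gene expression.
Rank-based contrasts come out as, e.g.

```
Nr3c2 vs Nr3c1 across 13 cell types (paired signed-rank): log2FC=1.15, p=0.01
Nr3c2 vs Nr3c1 within CA2 cells (rank-sum):               log2FC=2.61, p=6.2e-12
```

i.e. under the default receptor emulation the MR transcript is
systematically higher than GR across cell types and strongly so within CA2.
The `examples/` directory has one narrative script per capability
(profiling, coupling, consensus calling, contrasts/markers, full pipeline);
each prints its numbers and a line on what they mean. A thin CLI mirrors
the stages: `hippocoupling simulate | preprocess | profile | couple |
targets | markers | run`.

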