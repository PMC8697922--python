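# cernet

Competing-endogenous-RNA (ceRNA) network inference from multi-layer
RNA expression data.

`cernet` is for analysts studying post-transcriptional regulation —
e.g. ovarian follicle development in livestock — who have
feature-by-sample quantifications of mRNAs, lncRNAs, miRNAs and
circRNAs in two conditions and want the lncRNA/circRNA–miRNA–mRNA
"sponge" network connecting them.  It provides the whole analysis as
tested, reusable library code plus a CLI, together with a seeded
synthetic-data generator with planted ground truth so every stage can
be validated without touching real sequencing data.

## The method

Starting from per-layer count matrices in two conditions (large
follicles `GF_C` versus small follicles `GF_T`):

1. **Normalization** — FPKM for mRNA/lncRNA, TPM for miRNA clean tags,
   RPM (back-spliced reads per million, `10^6·C/N`) for circRNAs, and
   2^−ΔΔCt for qPCR validation data.
2. **Differential expression** — a conditional negative-binomial exact
   test (TMM library factors, method-of-moments dispersion,
   `var = μ + φμ²`), enumerating every split of each feature's total
   count.  Calls: |log₂FC| > 1 with BH FDR < 0.05 (mRNA, lncRNA) or
   p < 0.05 (miRNA, circRNA); all inequalities strict.
3. **circRNA filtering** — seven conjunctive criteria on back-splice
   junction candidates (single breakpoint; anchor overlap ≤ 2 bp;
   edit distance ≤ 2 bp; > 2 unique junction reads; anchor mapping
   margin > 35; unique reads > ⌊samples/2⌋; span < 100 kb).
4. **miRNA–target pairing** — candidates must appear in all three
   sequence-based prediction sources, then pass a negative
   coexpression gate: Spearman SCC < −0.7 with p < 0.05 (exact
   permutation p at n ≤ 8 samples).
5. **Network assembly** — a (ceRNA, miRNA, mRNA) triplet is admitted
   when both miRNA-incident pairs are gated and the ceRNA–mRNA pair is
   positively coexpressed, Pearson PCC > 0.9 with p < 0.05.  The
   network keeps only miRNA-incident edges, with node types,
   regulation directions, degrees and hubs; exports to GraphML and SIF
   for Cytoscape.
6. **Enrichment** — one-sided hypergeometric tests of gene sets
   against GMT annotation, BH-corrected p < 0.05.

See `docs/methods.md` for the statistical details and the design
decisions behind them.

## Worked example

Run the complete pipeline on a synthetic dataset (2,000 mRNAs, 500
lncRNAs, 300 miRNAs, 1,000 circRNAs over 3+3 pooled sample groups,
with 10 planted ceRNA triplets):

```bash
cernet run-all --seed 11 --out demo_run
```

prints

```
DE mRNA: 20 (12 up / 8 down)
DE lncRNA: 9 (8 up / 1 down)
DE miRNA: 23 (9 up / 14 down)
DE circRNA: 26 (11 up / 15 down)
network: 28 nodes, 23 edges, 14 triplets
report: demo_run/report.json
```

The DE lines count features passing each layer's thresholds with
their regulation direction in `GF_T` relative to `GF_C`.  The network
line summarizes triplet admission: 14 triplets collapsed to 28 typed
nodes and 23 deduplicated miRNA-incident edges.  `report.json` breaks
the edges down by type and lists the hub nodes:

```json
"edges_by_type": {"circRNA-miRNA": 8, "lncRNA-miRNA": 6, "mRNA-miRNA": 9},
"hubs": [["miR_00294", 3], ["miR_00295", 3], ["miR_00296", 3]]
```

Per-stage TSVs (counts, normalized matrices, DE tables, filter
verdicts, gated pairs, triplets) and the GraphML/SIF exports are
written under `demo_run/`; every stage can be re-run from those files
alone.  The same stages are available individually (`cernet simulate`,
`cernet de`, `cernet circ-filter`, `cernet pairs`, `cernet enrich`) and
as library functions (`cernet.diffexpr.call_de`,
`cernet.cernanet.build_network`, ...).

To analyse your own data, point a YAML config at your TSV inputs:

```yaml
synthetic: false
inputs:
  conditions: data/conditions.tsv        # sample <TAB> condition
  counts_mRNA: data/mrna_counts.tsv      # feature_id x samples
  counts_lncRNA: data/lnc_counts.tsv
  counts_miRNA: data/mirna_counts.tsv
  counts_circRNA: data/circ_counts.tsv
  lengths_mRNA: data/mrna_lengths.tsv
  circ_candidates: data/candidates.tsv
  predictions: [data/rnahybrid.tsv, data/miranda.tsv, data/targetscan.tsv]
  annotation_gmt: data/terms.gmt
```

```bash
cernet run-all --config config.yaml --seed 0 --out results
```

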