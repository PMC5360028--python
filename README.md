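# panconserv

Cross-species comparison of pancreatic cell-type transcriptomes: which genes
are enriched in which sorted cell population, and which of those enrichments
are evolutionarily conserved between zebrafish, mouse and human?

The package is written for comparative transcriptomics of FACS-sorted bulk
RNA-seq libraries — the setting where zebrafish alpha, beta, delta, acinar
and duct cells can be purified directly, while mammalian endocrine/exocrine
signatures must be proxied by purified islets versus whole pancreas. It
provides, as a tested library with a thin CLI:

- **Negative-binomial Wald enrichment calling.** Counts are modelled as
  `K_gj ~ NB(mean = s_j q_gc, dispersion = alpha_g)` with `Var = mu + alpha
  mu^2`; size factors `s_j` come from the median-of-ratios estimator,
  per-gene dispersions from a Cox–Reid adjusted profile likelihood with
  empirical-Bayes moderation, and each contrast is a two-sided Wald test on
  `log2(q_A/q_B)` with Benjamini–Hochberg adjustment. A gene is *enriched*
  when fold change > 4 at adjusted p < 0.05 (both configurable).
- **In-silico pooling.** Pan-endocrine libraries built by exact summation of
  same-numbered alpha/beta/delta replicates.
- **Mutually exclusive Venn regions.** A gene's region is the tissue set
  that beats every outside tissue at the threshold with no internal
  separation, so region counts add up to the number of enriched genes.
- **Dual orthology tables.** Ortholog groups are connected components of a
  Biomart-style link table; table one keeps strict 1-1-1 triples (used for
  joint PCA), table two every group with all three species represented (used
  for conservation accounting, where zebrafish paralog pairs must count as
  one signal).
- **Conservation partition.** The seven-region Venn (ZHM/ZM/ZH/HM/Z/M/H) of
  per-species enriched sets at the ortholog-group level, with anchor-species
  primary counts and bracketed ortholog counts, plus per-gene labels
  (`N-orth` for enriched genes without a three-species group).
- **Variance-stabilized PCA.** `y = log2(n/s + 1/(4 alpha_bar))` then
  gene-centered SVD, within one species or jointly across species on the
  1-1-1 ortholog space.
- **Hypergeometric term enrichment** as a transparent over-representation
  test for gene-set annotation.
- **A synthetic three-species generator** that emulates the full study
  design — NB counts with library-size variation, an orthology map with
  zebrafish paralog expansions, and planted conserved/species-specific
  markers — so every stage can be tested against ground truth.

## Worked example

```python
import panconserv as pc

dataset = pc.simulate(pc.SyntheticConfig(rng_seed=2))     # 500 ortholog groups
full = pc.analyze_dataset(dataset.counts, dataset.orthology, run_pca=False)
print(full.endocrine_partition.summary_table().to_string(index=False))
```

prints

```
region  n_groups anchor_species  primary_count bracket_counts
     H         8          human              8
    HM         8          human              8            M=8
     M         8          mouse              8
     Z        12      zebrafish             14
    ZH        10      zebrafish             12           H=10
   ZHM        25      zebrafish             29      H=25;M=25
    ZM        10      zebrafish             10           M=10
```

Each row is one conservation region: `ZHM` holds the 25 ortholog groups whose
members are endocrine-enriched in all three species; the primary count (29)
is the number of enriched *zebrafish genes* in those groups — larger than the
group count because zebrafish paralog pairs contribute two genes to one
conserved signal — and the brackets give the corresponding human and mouse
ortholog counts. The planted design behind this run is exactly 25/10/10/8
ZHM/ZM/ZH/HM groups plus 12/8/8 species-specific ones, so the partition
recovered every region. The `examples/` directory walks through tissue
signatures, conservation, joint PCA, subtype conservation and term
enrichment, one script per capability.

The same flows are available from a shell:

```bash
panconserv simulate --seed 1 --out-dir sim/
panconserv de --counts sim/mouse_counts.tsv --meta sim/mouse_metadata.tsv \
    --contrast islet:pancreas --out de.tsv
panconserv run --config pipeline.yaml     # full pipeline with manifest
```

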