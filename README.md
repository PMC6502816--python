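# mtfe

Organelle fold-enrichment scoring and biomarker discovery for paired
total-lysate / organelle-enriched proteomic quantification matrices.

Given two protein × sample log2 abundance matrices from the same samples —
one measured in total cellular lysate, one in an organelle-enriched fraction
(typically a crude mitochondrial pellet) — the package computes a per-protein,
per-sample **fold-enrichment score** (log2 enriched minus log2 lysate) and
runs the full discovery workflow built around it:

* **io_core** — TSV/GMT data model: quantification matrices with explicit
  missing-value masks, sample metadata (genotype, condition, cohort,
  tumor/adjacent pairing), marker panels, fraction alignment and presence
  filtering.
* **enrichment** — enrichment-score computation, organelle marker-panel
  means, replicate CVs (linear-scale), cross-data-type Spearman correlograms.
* **differential** — missing-aware vectorized one-way ANOVA with
  Tukey–Kramer post-hoc contrasts, Benjamini–Hochberg adjustment across
  proteins, paired and pooled-variance t-tests, significant-set unions and
  Venn-region accounting.
* **classify** — single-feature classifier ranking: logistic regression and
  Gaussian naive Bayes per protein under stratified k-fold or leave-one-out
  cross-validation, pooled out-of-fold AUC/accuracy, consensus top-k, and
  direct-value ROC evaluation of markers on validation cohorts.
* **cluster** — agglomerative clustering of samples on Manhattan distances of
  the row-scaled matrix (deterministic tie-breaking, pairwise-complete
  distances), with adjusted-Rand / purity agreement against sample labels.
* **synthetic** — a cohort generator with known ground truth: organelle-class
  fraction offsets, ten condition-effect scenario types (including moderate
  opposite-direction redistribution), a genotype confounder that cancels in
  the enrichment score, shared biological noise, replicate samples, and
  MCAR missingness; plus detection-rate / type-I-error recovery evaluation.
* **cli** — the `mtfe` command with `simulate`, `compute`, `qc`, `diff`,
  `classify`, `cluster`, `validate` and `report` subcommands.

## CLI quick start

```sh
# generate a synthetic discovery cohort with ground truth
mtfe simulate --seed 7 -o cohort/

# enrichment scores
mtfe compute --mito cohort/mito.tsv --lysate cohort/lysate.tsv \
     --meta cohort/meta.tsv -o mtfe.tsv

# QC: panel means, replicate CVs, correlogram
mtfe qc --mito cohort/mito.tsv --lysate cohort/lysate.tsv \
     --meta cohort/meta.tsv --panels cohort/panels.gmt -o qc.tsv

# four-group differential analysis (ANOVA + Tukey + BH)
mtfe diff --input mtfe.tsv --meta cohort/meta.tsv --design fourgroup \
     --alpha 0.05 -o diff.tsv

# single-feature classifier ranking
mtfe classify --input mtfe.tsv --meta cohort/meta.tsv \
     --restrict cohort/panels.gmt:mitochondrion --cv kfold5 --seed 17 -o rank.tsv

# everything at once, with a machine-readable JSON summary
mtfe report --mito cohort/mito.tsv --lysate cohort/lysate.tsv \
     --meta cohort/meta.tsv --panels cohort/panels.gmt -o report/
```

Matrix TSVs have a `protein_id` first column, one column per sample, empty
cells for missing values.  Metadata TSVs carry `sample_id`, `subject_id`,
`genotype`, `condition`, `cohort`, `pair_id`, `replicate`.  Marker panels are
standard GMT lines (`name<TAB>organelle<TAB>member...`).

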