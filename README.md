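# perturbscope

Analysis pipeline for pooled in vivo CRISPR screens read out by
single-nucleus RNA-seq, plus aggregate-deletion cohorts:

* **guide assignment** — per-nucleus gRNA calling from raw guide count
  tables with coverage (reads/UMI ≥ 60), molecule (UMI ≥ 2) and
  within-nucleus fraction (≥ 10%) filters; unique / multiplet /
  unassigned status calls;
* **pseudobulk differential expression** — raw UMI counts summed per
  (cell type × perturbation × lane) or per animal, per-gene
  negative-binomial GLM likelihood-ratio tests with TMM effective
  library sizes and empirical-Bayes dispersion shrinkage, plus a
  single-nucleus logistic-regression comparator;
* **perturbation filtering** — ≥5-DEG relevance calls, an LDA
  resubstitution filter that removes guide-carrying nuclei whose
  transcriptome looks like control (the unedited mosaic fraction), and
  Hotelling's T² on PCA scores;
* **signatures** — up/down gene programs (|log2FC| > 0.5, FDR < 0.01),
  per-nucleus program scores, Pearson/cosine LFC similarity matrices,
  and exact hypergeometric overlap tests;
* **decomposition** — Huber robust regression (IRLS, tuning 1.345)
  expressing a deletion LFC profile as a linear combination of
  single-perturbation profiles, scored by distance correlation;
* **zygosity** — diffusion-map embedding of control + perturbed nuclei
  and k-means (k = 3) on the first diffusion component to separate
  control-like / intermediate / strong expression states;
* **synthetic data** — a seeded generator (negative-binomial counts,
  editing mosaicism, het/hom zygosity, ambient guide contamination,
  deletion cohorts at half dosage) with full ground truth, so the whole
  pipeline is testable without external data.

## CLI

Each stage is a subcommand of `perturbscope`:

```sh
# generate a synthetic screen with ground truth
perturbscope simulate --n-genes 2000 --n-nuclei 5000 --seed 1 --out-dir sim/

# per-nucleus guide calling
perturbscope assign-guides --guide-table sim/guide_table.tsv \
    --library library.tsv --out assignments.tsv

# one pseudobulk NB-GLM contrast
perturbscope pseudobulk-de --counts-dir sim/ --group Tgt00 \
    --control SH-control --replicate-key lane --out de_Tgt00.csv

# programs, similarity, decomposition, zygosity
perturbscope programs --de-table de_Tgt00.csv --out programs.gmt
perturbscope similarity --de-table de_Tgt00.csv --de-table de_Tgt01.csv --out sim.csv
perturbscope decompose --deletion-de del.csv \
    --perturbation-de de_A.csv --perturbation-de de_B.csv --out-prefix dec
perturbscope zygosity --counts-dir sim/ --perturbation Tgt00 --k 3 \
    --seed 7 --out-prefix zyg

# full pipeline from a YAML config
perturbscope run --config pipeline.yaml --seed 1 --out-dir out/
```

Counts travel as Matrix Market (`matrix.mtx`) with `features.tsv` /
`barcodes.tsv` sidecars and a `metadata.tsv` nucleus table (columns:
lane, animal, cell_type, perturbation). Guide tables are TSV with
columns `barcode`, `guide_id`, `umi_count`, `read_count`.

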