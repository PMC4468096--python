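# tagnat

Tag-based digital gene expression (DGE) and natural antisense transcript
(NAT) analysis for NlaIII/MmeI 21-bp tag libraries.

In this assay, cDNA is cut at every NlaIII site (`CATG`) and MmeI releases
a fragment carrying exactly 17 downstream bases, so each transcript is
represented by 21-base tags whose sequencing counts are a digital measure
of expression. Tags are strand-specific: a tag matching the strand
opposite an annotated gene evidences a natural antisense transcript of
that gene. This package implements the complete analysis for a two-group
comparison (e.g. super-fine "S" vs fine "F" wool sheep skin, 3 biological
replicates each):

- **Reference tag DB** — every `CATG`+17 tag on both strands of every
  annotated gene, with ambiguity classification.
- **Cleaning** — adapter trimming, length filter (<21 nt dropped),
  singleton removal.
- **Mapping** — exact-dictionary lookup with a 1-mismatch Hamming
  neighborhood, unique (gene, strand) assignments only; ambiguous and
  unmatched tags are tracked so categories always partition the library.
- **Quantification** — TPM (transcripts per million clean tags,
  `count/total × 10⁶`) in separate sense and antisense layers, plus
  per-sample NAT profiles (fractions, sense:antisense ratios, Spearman
  correlation of sense vs antisense expression).
- **Differential expression** — a nonparametric caller on the two
  statistics `M = log2((μ_S+k)/(μ_F+k))` and `D = |μ_S − μ_F|`: the
  empirical noise distribution of (|M|, D) is pooled from all
  within-condition replicate pairs across transcripts, and a transcript's
  probability of differential expression is the fraction of noise pairs
  its signal strictly dominates. Significance: probability ≥ 0.8 (4:1
  odds), |M| ≥ 1, TPM ≥ 1 in the lower condition. Genes and NATs are
  called identically on their respective layers.
- **Enrichment** — exact hypergeometric upper-tail
  `P(X ≥ m)` on an annotated background with Benjamini–Hochberg
  correction (significant at adjusted P ≤ 0.05).
- **Simulator** — a synthetic genome/expression/read generator that
  emulates the study design (3+3 libraries, ~98% CATG-bearing genes,
  ~33% of genes with antisense transcription at a 10:1 sense:antisense
  tag ratio and rank correlation ~0.55, planted DE), so the whole
  pipeline is testable without any external download.

## Worked example

Run a scaled synthetic study end to end (1,000 genes, 500k tags/sample):

```python
from tagnat.pipeline import RunConfig, run_pipeline

rep = run_pipeline(RunConfig(outdir="demo", seed=1, n_genes=1000,
                             depth=500_000, n_de=30, n_de_nat=5))
print(rep.refdb_stats["pct_genes_with_catg"])   # 97.4
print(rep.significant_counts)
print(rep.nat_profile[["sample_id", "pct_genes_with_nat",
                       "ratio_total_tags", "spearman_r"]].round(3))
```

prints

```
97.4
{'degs_up': 15, 'degs_down': 14, 'nats_up': 4, 'nats_down': 4, 'total': 37}
  sample_id  pct_genes_with_nat  ratio_total_tags  spearman_r
0        S1                28.9            10.950       0.439
1        S2                29.1            10.865       0.435
...
```

Reading this: 97.4% of the synthetic genes carry a usable `CATG` site
(the generator's target is 97.9%); the standard filter calls 29 DEGs and
8 NATs of the 30 + 5 planted; per sample, ~29% of genes show antisense
signal, total sense tags outnumber antisense roughly 10:1, and sense and
antisense expression are rank-correlated at ~0.45 — all close to the
planted truth (33%, 10:1, 0.55; detection loses the weakest NATs at this
depth). Outputs (FASTA/BED/FASTQ inputs, count and TPM matrices per
strand, NAT profile, DE records, enrichment table, manifest with every
parameter and seed) are written under `demo/`.

The same stages are available as a CLI:

```sh
tagnat simulate --n-genes 1000 --depth 500000 --outdir demo --seed 1
tagnat build-refdb --fasta demo/genome.fa --bed demo/genes.bed --out db.tsv.gz
tagnat clean --fastq demo/S1.fastq --out S1.clean.tsv
tagnat map --clean S1.clean.tsv --refdb db.tsv.gz --out S1.map.tsv
tagnat run-all --outdir full --seed 1          # everything in one go
```

The package also bundles the published study's printed summary tables
(`tagnat.datasets`): per-library tag totals, mapping summaries, reference
DB statistics, and the 47 reported DE transcripts, so the study-side
arithmetic (percentages such as 49.05% uniquely mapped or 33.45% of genes
with NATs, and the 9 up / 31 down / 7 NAT split of the significance
filter) can be replayed exactly.

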