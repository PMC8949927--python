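# qtlcascade

Backcross QTL interval mapping and candidate-gene prioritization as a
tested, reusable pipeline. Starting from an (NZOxB6)-style N2 backcross
it runs:

1. **linkage** — single-QTL genome scan by an EM normal-mixture fit at
   pseudomarker positions (Haldane map function, no interference), with
   permutation-based genome-wide significance thresholds and
   peak-marker effect summaries (Welch t / ANOVA + Bonferroni).
2. **haplomap** — strain-vs-strain haplotype map: tiling 250 kb windows
   over the critical interval, counting strain-discordant SNPs per
   window, flagging windows with more than 100 discordant SNPs, and
   keeping genes that overlap at least one flagged window.
3. **exprfilter** — per-contrast log2 fold changes on `log2(x + 1)`
   with Welch tests, the strict `|LFC| > 1` filter, `2^-dCt` qPCR
   quantification, and the intersection of all evidence into a
   per-gene candidate table.
4. **scprofile** — single-cell dot-plot statistics (fraction of cells
   expressing, mean normalized expression per cluster) and marker-based
   labeling of the proliferating `BetaP` cluster via `Mki67`.
5. **synthdata** — generators for every input: cross simulation with a
   planted additive QTL, two-strain SNP catalogs with declared
   haplotype-block layouts, interval gene annotations, expression
   matrices with planted effects, and negative-binomial single-cell
   counts. The packaged `fig3` preset reproduces the full candidate
   cascade 644 genes → 111 (SNP-density filter) → 8 (parental DE) → 5
   (congenic intersection).
6. **pipeline / cli** — configuration, orchestration and TSV reports.

## Command line

```sh
# write a complete synthetic input bundle plus its run.cfg manifest
qtlcascade simulate --out fixture/ --seed 7 --n 600 --perms 200

# full pipeline: scan -> haplotype filter -> DE cascade -> single cell
qtlcascade report --config fixture/run.cfg --out results/

# individual stages
qtlcascade scan --map fixture/map.tsv --genotypes fixture/genotypes.tsv \
    --phenotypes fixture/phenotypes.tsv --trait glucose --step-mb 0.5 \
    --perms 1000 --alpha 0.01 --seed 0 --out lod.tsv
qtlcascade haplomap --vcf fixture/snps.vcf --bed fixture/genes.bed \
    --interval chr13:78000000-120400000 --window-kb 250 --threshold 100 \
    --out-windows windows.tsv --out-genes genes.txt
qtlcascade deg --expr fixture/expr_parental.tsv \
    --groups fixture/groups_parental.tsv --lfc 1 --out de.tsv
qtlcascade sc --dir fixture/sc --genes S100z,Iqgap2,Rnf180,Ankrd55,Acot12 \
    --marker Mki67 --out dotplot.tsv
qtlcascade prioritize --config fixture/run.cfg --out results/
```

`report` writes `lod.tsv`, `windows.tsv`, `blocks.tsv`,
`de_<contrast>.tsv`, `dotplot.tsv`, `evidence.tsv` and `summary.txt`;
outputs are byte-identical for identical config and seeds, and any
stage failure aborts with a stage-tagged message and removes partial
outputs.

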