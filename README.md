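# strainwss

Window-based SNV similarity (WSS) strain tracking for longitudinal
metagenome samples. Given per-species multi-sample variant calls (VCF),
per-base depth tracks (samtools-depth TSV) and a reference catalog
(FASTA + species table), the pipeline:

1. builds per-sample profiles and applies sample-level QC
   (breadth < 30% or genome-wide mean depth < 3.5 excluded);
2. tiles the reference into non-overlapping windows (default 1 kb), drops
   windows where either sample of a pair has more than 50% of bases below
   depth 5, scores each remaining window as the fraction of matching
   genotype states over the union of the pair's variant positions, and
   averages the per-window similarities into the pairwise WSS score;
3. calibrates per-species related/unrelated cutoffs from within- vs
   between-individual score distributions (gap midpoint when disjoint,
   kernel-density crossing otherwise), or loads published cutoffs from the
   species table;
4. classifies each sample pair (related iff score > cutoff) and emits the
   summary tables (counts, relative abundance %, per-dataset unrelated-strain
   matrix, long-format plot table);
5. cross-checks calls with a neighbor-joining tree built from genome-wide
   SNV p-distances, calling a pair related when its leaf-to-leaf branch
   length distance falls below a threshold.

A synthetic-cohort generator (`strainwss.simulate`) produces references,
strain haplotypes, drift-vs-replacement longitudinal dynamics, Poisson
depth with dropout and genotype-call error, written as FASTA + VCF + depth
TSVs with ground-truth labels, so the whole real-data path is testable
offline.

## CLI

All stages are subcommands of `strainwss` (thresholds may also be collected
in one YAML passed as `strainwss --config config.yaml <subcommand> ...`;
explicit options win):

```bash
# generate a synthetic cohort
strainwss simulate --params params.yaml --out-dir data/

# sample-level QC report
strainwss filter --vcf data/variants.vcf --depth-dir data/depth \
    --ref-fasta data/reference.fasta --species-table data/species_table.tsv \
    --sample-map data/sample_map.tsv --out qc.tsv

# pairwise WSS scores (within each individual)
strainwss wss --vcf data/variants.vcf --depth-dir data/depth \
    --ref-fasta data/reference.fasta --species-table data/species_table.tsv \
    --sample-map data/sample_map.tsv --window-size 1000 --out scores.tsv

# per-species cutoff from a calibration cohort
strainwss calibrate --vcf data/variants.vcf --depth-dir data/depth \
    --ref-fasta data/reference.fasta --species-table data/species_table.tsv \
    --sample-map data/sample_map.tsv --out cutoffs.tsv

# related/unrelated calls and summary tables
strainwss classify --scores scores.tsv --cutoffs cutoffs.tsv \
    --dataset-id demo --comparison-label "t0 vs t1" --out calls.tsv
strainwss report --calls calls.tsv --summary-out summary.tsv \
    --matrix-out unrelated_matrix.tsv

# NJ tree cross-check
strainwss concord --vcf data/variants.vcf --depth-dir data/depth \
    --ref-fasta data/reference.fasta --species-table data/species_table.tsv \
    --tree-out tree.nwk --matrix-out dist.tsv --agreement-out agree.tsv \
    --branch-threshold 0.5
```

Sentinels follow the source tables: `CO:NA` = species without a cutoff
(excluded from classification), `NS` = pair without a computable score.

## Notes on conventions

- Coordinates are 1-based inclusive in all file I/O (VCF / depth TSV) and
  0-based half-open internally for window arithmetic.
- QC and window thresholds are strict (`<`), so boundary values pass.
- `score == cutoff` classifies as unrelated (related is strictly above).
- Mean depth averages over all reference positions by default;
  `depth_over_covered=True` averages over covered positions only.
- Genotypes are treated as haploid dominant-strain states (allele index per
  multi-sample VCF record); indel records are skipped with a logged count.
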