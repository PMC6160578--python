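# ggkit

Genotype-matrix toolkit for germplasm collection management. Given a
samples × loci table of diploid SNP calls (or a VCF), ggkit runs the full
identification workflow used to curate clonally propagated crop
collections:

- **marker QC** — contig-level discovery filters (design score, read/EST
  support, minor-allele reads, intra-contig spacing) and panel-level
  filters (GenTrain score, call frequency/rate, MAF, heterozygote excess,
  missing-call count),
- **identity matching** — pairwise multilocus allele-difference distances,
  automatic detection of the intra/inter-cultivar gap in the distance
  histogram, redundancy groups (connected components under the gap
  threshold), and annotation of groups as replicate confirmations,
  synonymy candidates or mutant variants, plus homonymy flags,
- **diversity statistics** — per-locus Na, Ne, MAF, Ho, He, uHe, Shannon
  I, F, PIC, null-allele estimate and an exact Hardy–Weinberg test;
  summaries and SNP-vs-SSR style marker-set comparisons,
- **AMOVA** — one-way analysis of molecular variance over squared pairwise
  distances with a permutation test for φst,
- **NJ trees** — neighbor-joining with locus-resampling bootstrap support
  and newick export,
- **synthetic cohorts** — a generator that plants clonal duplicate groups,
  somatic-mutant variants (1–10 allele flips), unrelated cultivars, a
  Balding–Nichols-differentiated wild pool and Mendelian F1 progeny, with
  truth labels, so the whole pipeline is testable end to end without
  external data.

## CLI

```sh
# simulate a cohort (YAML file with CohortSpec fields)
ggkit simulate --spec cohort.yaml --out-dir sim/

# QC, identity, diversity, AMOVA, tree — each runs on a genotype TSV or VCF
ggkit qc        --genotypes sim/genotypes.tsv --out qc_report.tsv
ggkit identity  --genotypes sim/genotypes.tsv --meta sim/metadata.tsv --out-dir identity/
ggkit diversity --genotypes sim/genotypes.tsv --out stats.tsv
ggkit amova     --genotypes sim/genotypes.tsv --groups sim/metadata.tsv --perm 999 --out amova.tsv
ggkit tree      --genotypes sim/genotypes.tsv --bootstrap 500 --seed 1 --out tree.nwk

# format conversion and the full pipeline
ggkit convert --in genotypes.vcf --out genotypes.tsv
ggkit run --config run.yaml
```

`ggkit run` takes a YAML config with an output directory, either input
paths (`genotypes_path`, `meta_path`, `loci_path`) or a `cohort:` block of
simulation parameters, and the per-stage options (`thresholds:`,
`min_gap_width`, `n_permutations`, `bootstrap_reps`, `seed`). Reruns with
the same config and seed reproduce byte-identical outputs; a
`manifest.json` records the seed, package version and input digests.

### Genotype table format

TSV with a header row of locus ids and the sample id in the first column;
calls are two-character strings (`AA`, `AB`) or slash pairs (`A/B`), with
`--` for missing. Heterozygotes are unordered (`AB` ≡ `BA`). VCF import
takes diploid GT fields from biallelic records; other records are skipped
and counted.

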