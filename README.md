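# adaptmut

Simulation and analysis of mutation repertoires in independently adapting
yeast lineages: ancestor-vs-strain variant calling from nucleotide count
tables, coverage-based whole-chromosome duplication detection,
mutation-incidence and locus-enrichment statistics, mutation-emergence
timing, and three-phase colony growth segmentation — all exercised against
a synthetic-experiment simulator so no sequencing data is required.

## Components

| Module | Purpose |
| --- | --- |
| `adaptmut.experiment` | 96-well lineage-separation simulator: pre-existing (Luria–Delbrück jackpot) vs induced (Poisson-like) mutation-timing models, fluctuation summaries, synthetic three-phase growth curves |
| `adaptmut.genomes` | Toy haploid references with gene models, planted SNPs/indels/duplications, per-position nucleotide count tables and coverage tracks |
| `adaptmut.calling` | Frequency-comparison SNP/indel calling against an ancestor, coverage QC, low-complexity indel filtering, strand-aware functional classification, mixed-colony detection |
| `adaptmut.aneuploidy` | Windowed-coverage chromosome duplication calls (median ratio vs the rest of the genome) |
| `adaptmut.stats` | Per-base incidence tables, per-strain mutation histograms, exact Poisson locus-enrichment test, emergence-generation inference |
| `adaptmut.growth` | Piecewise log-linear three-phase segmentation; binary-mask colony area |
| `adaptmut.io` / `adaptmut.config` / `adaptmut.pipeline` / `adaptmut.cli` | TSV/FASTA/VCF readers and writers, strict config, end-to-end pipeline, CLI |

## CLI

Each stage has a console script and a subcommand of the umbrella `adaptmut`
command:

```bash
simulate-experiment --model induced --lineages 56 --seed 1 --out lineages.tsv
simulate-genomes --strains 4 --seed 1 --out-dir data/
call-variants --ancestor data/counts_ancestor.tsv --strain data/counts_s1.tsv \
    --ref data/reference.fa --genes data/genes.tsv --out s1.vcf --tsv s1.tsv
call-duplications --coverage data/coverage_s1.tsv --seed 7
adaptmut mutation-stats enrichment --observed 8 --colonies 192 \
    --locus-len 1304 --genome-len 12071326 --per-genome-rate 0.82
segment-growth --series colony.tsv
adaptmut run-all --config demo.yaml --out-dir out/
```

All positions are 1-based inclusive; count tables are TSV with columns
`strain chrom pos A C G T ins del`; coverage tracks are run-length-encoded
BEDGRAPH-like TSV; variant calls are exported as VCF 4.2 (haploid
genotypes, allele fraction in INFO) plus a TSV mirror.

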