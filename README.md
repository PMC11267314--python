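# pansv

Analyses for cohorts of haplotype-resolved plant genome assemblies:

* **Pan-gene classification** — presence/absence matrix from an orthogroup
  cluster table; core / softcore (> 80 % of assemblies) / shell / cloud
  categories, per-assembly composition, saturation curves and
  new-cluster increments over random assembly orderings.
* **SV cataloging** — per-haplotype VCF calls (symbolic or explicit alleles,
  INS/DEL ≥ 50 bp, plus INV/TRA) merged into a non-redundant catalog
  (greedy start-to-start clustering, max distance 50 bp, max size
  difference 20 bp) with carrier sets, accession-frequency spectrum and
  per-accession counts.
* **SV context & group analysis** — exonic / intronic / promoter (2 kb
  strand-aware upstream) / downstream / intergenic classification,
  promoter-SV × differential-expression intersection, group-specific SV
  detection, pathway-gene association.
* **Hotspots** — 400 kb / 200 kb sliding-window SV counts; windows with
  more than 80 SVs merged into maximal hotspot spans.
* **Variation graph** — coordinate-preserving graph from the reference plus
  the INS/DEL catalog, GFA 1.0 output with one path per haplotype and per
  reference chromosome.
* **Evolutionary statistics** — counting-method Ka/Ks (equal pathway
  weighting, Jukes–Cantor correction) for pre-aligned CDS pairs, and
  Mann–Whitney contrasts of CDS length / expression / Ka/Ks between
  categories.
* **Synthetic cohort generator** — a fully specified, seeded bundle
  (reference FASTA, per-haplotype GFF3 / CDS / SV VCFs, orthogroups,
  expression, labels and a truth table) with planted category proportions,
  SV hotspots and a group-exclusive 51 bp promoter deletion coupled to an
  expression effect, so every stage is testable end to end offline.

## Command line

One executable with subcommands (`pansv --help`):

```sh
pansv --seed 1 simulate --out cohort/
pansv pangene  --orthogroups cohort/orthogroups.tsv --labels cohort/labels.tsv --out out/pangene
pansv svmerge  --vcf-dir cohort/svs --labels cohort/labels.tsv \
               --chrom-lengths cohort/chrom_lengths.tsv --out out/merged.vcf
pansv annotate --merged-vcf out/merged.vcf --gff3 cohort/genes/RF1.hap1.gff3 --out out/contexts.tsv
pansv hotspots --merged-vcf out/merged.vcf --chrom-lengths cohort/chrom_lengths.tsv --out-prefix out/hotspots
pansv groupsv  --merged-vcf out/merged.vcf --labels cohort/labels.tsv --focal GF --out out/gf.tsv
pansv graph    --fasta cohort/reference.fa --merged-vcf out/merged.vcf \
               --labels cohort/labels.tsv --out out/pan.gfa
pansv kaks     --cds-a cohort/cds/RF1.hap1.fa --cds-b cohort/cds/RF1.hap2.fa \
               --pairs pairs.tsv --out out/kaks.tsv
pansv --seed 1 run-all --out out/   # simulate + every stage
```

Thresholds live in a YAML config passed with the global `--config` option;
defaults: softcore fraction 0.80, merge 50 bp / 20 bp, hotspot window
400 kb / step 200 kb / min count 80, promoter & downstream 2 kb, DE cut
|log2FC| > 1 and p < 0.05, SV minimum length 50 bp.

Conventions worth knowing: internal coordinates are 1-based inclusive
everywhere (BED converted at the boundary); SV merge distance is measured
start-to-start and size difference in absolute bp; hotspot windows count an
SV by its POS only; the naive Welch-t DE surrogate is for synthetic data
only and is not a negative-binomial DE model.

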