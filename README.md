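# chimpop

Analysis toolkit for chimeric genes born of unequal crossing-over between
tandem paralogs. Given two parental gene pools ("B1" and "B2") and chimeric
alleles ("B3") formed by a single 5'-B2 → 3'-B1 crossover, the package can:

- **simulate** every input it consumes: parental allele pools with allelic
  SNP diversity, chimeras at configurable breakpoints, diploid regional
  populations with specified genotype-class frequencies, and a variant
  matrix over a ~150 kb segment with a planted selective-sweep footprint
  (diversity thinning + singleton excess), always recording the planted
  truths for oracle testing (`chimpop.synthetic_data`);
- **detect** chimera carriers by in-silico PCR: primer-site search with a
  3'-anchor rule, amplicon prediction, and diploid genotype classification
  into B3/B3, B3/par, par/par or unknown (`chimpop.chimera_detect`);
- **map crossover breakpoints** as intervals between informative sites of
  the aligned parents, flagging multi-switch (gene-conversion-like) cases,
  and cluster chimeras into named allele variants with intron SNP-difference
  matrices (`chimpop.breakpoint_map`);
- **tabulate** genotype-class and allele frequencies per region and run a
  from-scratch sliding-window π / Tajima's D scan (2500 bp windows, 1250 bp
  steps by default) over a single-contig VCF (`chimpop.popgen`);
- **assess origins**: p-distances, neighbor-joining trees, a monophyly test
  with column bootstrap, and a divergence-rate feasibility calculation
  (fold increase over a 1.5–2.5 %/Myr baseline needed to fit an observed
  divergence into a given time window) (`chimpop.origins`).

I/O is plain text throughout: FASTA (headers may carry `id|gene|region`
labels), minimal GT-only VCF v4.2 (single contig, biallelic SNPs kept,
drop-log returned), tab-separated metadata/result tables, and Newick.

## Command line

One executable with subcommands; global flags `--seed`, `--config`
(flat `key=value` file mirroring the flags), `--out-dir`, `--log-level`.

```sh
chimpop --seed 1 --out-dir run simulate --preset paper-global
chimpop --out-dir run detect --templates run/templates.fasta \
        --primers run/primers.tsv --alleles run/chimeras.fasta
chimpop --out-dir run freqs --genotypes run/genotypes.tsv \
        --metadata run/metadata.tsv --by region
chimpop --out-dir run sweep --vcf run/variants.vcf
chimpop breakpoints --alignment aln.fasta --out-prefix run/bp
chimpop --seed 1 origins --alignment introns.fasta --replicates 1000 \
        --rate-d 0.001 --rate-t 50 --out-prefix run/org
```

`simulate --preset paper-global` emits a 999-individual cohort with an
88/9/3 homozygous-chimeric / heterozygous / parental-only split and an
8-allele chimera pool, plus primers, templates, truth tables and a sweep
VCF.

## Notes

- Coordinates are 0-based half-open internally, 1-based inclusive at file
  and report boundaries (VCF convention).
- The sweep generator is a phenomenological stand-in (site thinning plus a
  singleton-inflated frequency spectrum), not a coalescent model; it exists
  to exercise detection of low-π / rare-variant-excess footprints.
- Tajima's D is undefined (reported as missing, never 0) in windows with no
  segregating sites.
- Breakpoints are reported as intervals, never points: between informative
  sites the crossover position is unidentifiable.
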