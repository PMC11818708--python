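# allelobis

Allele-specific CpG/CCWGG methylation analysis for bisulfite
clone-sequencing experiments, with companion allelic-expression and
2^−ΔΔCt relative-expression calculations.

## The problem

Bisulfite treatment converts unmethylated cytosine to uracil (read as T
after PCR) while 5-methylcytosine stays C, so cloning and Sanger
sequencing individual molecules of a converted promoter amplicon reads
out the methylation pattern of single epialleles at base-pair
resolution. When the amplicon carries a heterozygous SNP, each clone can
additionally be phased to a parental allele, separating *monoallelic*
from *biallelic* promoter methylation — the distinction that decides
whether a gene is silenced on one allele (imprinting-like), both, or
neither. `allelobis` implements this analysis for promoters assayed at
two methylation contexts: canonical **CpG** dinucleotides and Dcm-like
**CCWGG** (W = A/T) pentanucleotides, whose internal C is the assayed
base.

The pipeline is aimed at clone/Sanger-scale data (tens of clones per
sample), not short-read BS-seq.

## What it computes

For each clone aligned globally against the conversion-neutral reference
(every reference C degenerated to Y, which matches both C and T):

* **per-site calls** — C ⇒ methylated, T ⇒ unmethylated, anything else
  ambiguous, at every CpG/CCWGG site in the analysis window;
* **conversion efficiency** — the fraction of cytosines *outside* any
  assayed context that read T,
  `efficiency = n_converted / n_eligible`; clones below **98%** are
  omitted (strict `<`), the standard QC proxy for incomplete bisulfite
  treatment;
* **allele** — the base at the phasing SNP (alleles are required to be
  non-C so conversion cannot scramble them);
* **epiallele class** — unmethylated, CG-only, CG+CCWGG, or partial,
  with a flag for the proximal (CCWGG)₂ pair nearest the TSS.

Per sample it then calls the genotype from phased clone counts and a
**promoter methylation state**: `monoallelic_methylation`,
`biallelic_methylated`, `biallelic_unmethylated`,
`stochastic_biallelic` or `indeterminate`, plus a two-sided Fisher exact
test of the allele × methylation clone table for heterozygous samples.

The expression module counts cDNA clones by the base at a transcribed
SNP with an exact binomial test of allelic balance, and implements Livak
relative quantification `rq = 2^−ΔΔCt` with replicate-SD propagation.

A seeded synthetic-data generator builds promoter-like references with
exact CpG/CCWGG compositions and simulates clone sets under incomplete
conversion and sequencing error, including five bundled benchmark
samples (HPrEpiC, BPH1, LNCaP, PC3, PA1, plus an LNCaP cDNA set) with
known truth tables.

## Worked example

```bash
python examples/03_promoter_state_profiles.py
```

prints, for the five bundled samples:

```
HPrEpiC   genotype=het      state=stochastic_biallelic     [A/partial=8, G/partial=8]
BPH1      genotype=het      state=monoallelic_methylation  [A/cg_only_methylated=3, A/unmethylated=8, G/cg_ccwgg_methylated=5]  Fisher p=0.0256
LNCaP     genotype=hom_alt  state=biallelic_unmethylated   [A/unmethylated=20]
PC3       genotype=hom_alt  state=biallelic_methylated     [A/cg_ccwgg_methylated=1, A/cg_only_methylated=19]
PA1       genotype=hom_alt  state=monoallelic_methylation  [A/cg_ccwgg_methylated=10, A/unmethylated=10]
```

BPH1 is the monoallelic archetype: all 8 unmethylated clones carry the A
allele while all 5 CG+CCWGG-methylated clones carry G (Fisher p ≈ 0.026
for allele–methylation association). PA1 shows the same bimodal
full-vs-none split but is homozygous, so the monoallelic call comes from
the pattern, not the SNP. The script also renders a text "lollipop" map
(● / ○ for CpG, ▲ / △ for CCWGG, one row per clone grouped by allele).

The other examples cover site scanning (`01`), per-clone QC on noisy
simulations (`02`), allelic expression — a 10/10 G/A cDNA clone split,
binomial p = 1.0, verdict *biallelic* (`04`) — and ΔΔCt arithmetic
(`05`).

The same functionality is available as a CLI:

```bash
allelobis run-all --fixtures --seed 0 --outdir out/
allelobis call --ref ref.fa --config region.yaml --clones clones.fa --out report.tsv
allelobis ddct --ct ct.tsv --reference-gene TBP --calibrator BPH1
```

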