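# Methods

## Model and coordinate conventions

The unit of analysis is a promoter **analysis window** anchored on the
transcription start site. Coordinates are 0-based half-open internally;
user-facing labels follow the promoter convention (+1 at the TSS, −1
immediately upstream, no position 0), so the bundled 444-nt window maps
to −393..+51. The window, not any printed amplicon length, defines which
sites are assayed.

Two methylation contexts are modelled:

* **CpG** — the assayed cytosine is the C of the CG dinucleotide.
* **CCWGG** (W = A/T) — the assayed cytosine defaults to the *internal*
  (second) C, mirroring Dcm-type C(m)CWGG methylation. Which of the two
  Cs carries the mark is not settled biology, so `MotifSpec.assayed_offset`
  makes it configurable. The two CCWGG sites nearest the TSS are
  designated the "proximal (CCWGG)₂ pair" unless the region config names
  an explicit pair.

Only the top (amplified) strand is analysed by default: a bisulfite
primer set amplifies one strand, and clone sets report that strand only.
Reverse-strand scanning exists as an option (`scan_motifs(..., strand="-")`);
because CCAGG/CCTGG are mutual reverse complements the CCWGG site count
is strand-symmetric, which the test suite exploits as an invariant.

Phasing requires a biallelic SNP whose alleles are both non-C on the
analysed strand; a C allele would be conflated with methylation state
after conversion, so the constructor rejects it outright.

## Alignment

Each clone is aligned **once**, globally, against the reference with
every C degenerated to Y (pyrimidine). Y scores as a full match to both
C and T, so the alignment is neutral to methylation state and the C/T
readout is taken from the reference-coordinate map afterwards. This
avoids the assignment bias of aligning against either a
converted-methylated or converted-unmethylated template.

Scoring (Biopython `PairwiseAligner`, global): match +2, mismatch −3,
gap open −5, gap extend −2; a gap of length L costs 5 + 2(L−1), end gaps
included. N is scored −1 against everything — present but neither
rewarded nor punished as a mismatch. The test suite checks optimal
scores against an independent textbook Gotoh DP on small instances.
cDNA reads are unconverted, so the expression module reuses the same
aligner against the plain (non-Y) transcript.

## Conversion-efficiency QC

`efficiency = n_converted / n_eligible`, where eligible positions are
reference Cs inside the window **outside every assayed context** — both
CpG and CCWGG Cs are excluded from the denominator, because CCWGG Cs can
be genuinely methylated and would deflate the statistic
(`exclude_assayed_contexts=False` restores a CpG-only exclusion).
Positions reading neither C nor T (gap, N, substitution) are dropped
from both counts. The statistic is the *converted* fraction, so the
omission rule reads naturally: clones **< 98%** are omitted (98.0%
exactly passes — 49/50 eligible Cs converted is retained, 48/50 is not).
Clones covering less than 90% of the window are omitted as `truncated`;
clones with no eligible C at all are omitted with their own reason code.

A caveat inherent to the method: at a single clone, a failed conversion
at an assayed site is indistinguishable from genuine methylation. The
QC statistic bounds the genome-wide failure rate but cannot rescue
individual sites; no disambiguation is attempted.

## Epiallele classes and promoter state

Per clone, with f = methylated fraction of non-ambiguous CpG calls:
`unmethylated` (f = 0, no methylated CCWGG), `cg_only_methylated`
(f ≥ 0.9, no methylated CCWGG), `cg_ccwgg_methylated` (f ≥ 0.9, ≥ 1
methylated CCWGG), else `partial`. The full threshold is 0.9 rather
than 1.0 so a single ambiguous or discordant site does not demote a
fully methylated clone. A separate flag records whether both proximal
(CCWGG)₂ sites are methylated.

Genotype: heterozygous when both alleles have ≥ 2 supporting clones and
the minor allele reaches 10% of determined clones; a thinner minority is
treated as error/contamination and the call is homozygous.

Promoter state (≥ 6 determinate clones, rules in order):

1. **SNP-phased monoallelic** — het; ≥ 2 unmethylated clones all on one
   allele and ≥ 2 signature-methylated clones (CG+CCWGG if any exist,
   else CG-only) all on the other, with ≤ 1 discordant clone. CG-only
   or partial clones on the unmethylated allele are *not* discordant:
   a monoallelically methylated promoter may carry minor CG-only
   epialleles on the silent allele without breaking the phased split.
2. **Biallelic methylated** — ≥ 90% fully methylated clones.
3. **Biallelic unmethylated** — no fully methylated clone, ≤ 25% of
   clones with any methylated call, ≤ 1 clone with ≥ 2 methylated CpGs.
4. **Pattern-based monoallelic** — the bimodal all-or-none split,
   usable without phasing (required for homozygous samples): 30–70%
   fully methylated, ≥ 25% unmethylated, ≤ 20% partial clones.
5. **Stochastic biallelic** — every clone carries ≥ 1 methylated CpG
   but per-clone patterns are heterogeneous.

No published quantitative boundaries exist for "stochastic",
"monoallelic" or "fully methylated" in clone data of this scale; every
threshold above is a design decision of this package. The tolerances in
rules 3 and 4 are sized for the noise the QC filter lets through: at a
1% conversion-failure rate a clone has ≈ 11% probability of carrying a
spurious methylated call at one of the 11 assayed sites *while passing*
the 98% efficiency rule (failures at eligible sites are what QC sees,
failures at assayed sites are not), and a ~20-clone sample needs
headroom of roughly the expectation plus 1.5 binomial SDs. Tighter
bands turn the state call into a coin flip at realistic noise; the
zero-noise behaviour is unchanged. The Fisher exact association p is
reported alongside the rule-based state and never overrides it.

States are pattern labels only — the package makes no claim about
imprinting mechanism, gDMR/sDMR status or RNA decay.

## Expression

Allelic expression: cDNA clones are tallied by the aligned base at a
transcribed SNP; an exact two-sided binomial test against 0.5 yields a
verdict — `biallelic` (p ≥ 0.05 and minor-allele fraction ≥ 0.2),
`monoallelic_skewed` (minor fraction < 0.05), else `indeterminate`;
fewer than 10 determined clones is always indeterminate.

Relative expression uses plain Livak quantification: ΔCt = mean
Ct(target) − mean Ct(reference gene) per sample, ΔΔCt vs a calibrator
sample, rq = 2^−ΔΔCt, with no amplification-efficiency correction.
Replicates aggregate by arithmetic mean; the ΔCt SD is the root sum of
squares of the sample's target and reference replicate SDs, reported as
an rq range. The calibrator is an explicit argument — there is no
sensible default.

## Synthetic data

`make_reference` builds a window from a C-free A/T/G backbone and plants
exactly the requested number of CpG and CCWGG occurrences plus 36
isolated "sentinel" cytosines (the efficiency denominator), with ≥ 2 bp
clearance between planted elements so no accidental motif can arise;
composition is verified by re-scanning before the region is returned.
The SNP sits at promoter position −158 with G/A alleles, clear of all
motifs. Defaults (444-nt window, 6 CpG + 5 CCWGG, ~41 eligible Cs)
mirror a compact mammalian proximal promoter panel.

`simulate_clone` applies the chemistry in order: set the SNP base to the
pattern's allele; retain methylated Cs; convert unmethylated Cs to T
except with probability `conversion_failure_rate`; then apply uniform
substitution errors at `sequencing_error_rate`. Conversion failure never
creates a C from a non-C base. No indels are simulated (Sanger clone
consensus rarely has them), though the aligner supports gaps.

The bundled benchmark samples encode five archetypal clone
compositions (see `allelobis.fixtures`); the stochastic HPrEpiC-style
patterns draw 1–4 methylated CpGs per clone from a seeded generator,
guaranteed heterogeneous. What passing tests on these data shows:
the pipeline recovers planted truth exactly at zero noise and keeps
state calls stable under 1% conversion failure + 0.2% sequencing error.
What it does not show: robustness to cloning bias, PCR chimeras,
chromatogram miscalls, indels, or promoters whose site density differs
greatly from the bundled composition.

## Problem sizes and determinism

Unit and regression tests run on the bundled 16–20-clone samples; the
state-recovery sweep re-simulates 200 samples per state per noise
condition. All randomness flows through explicit integer seeds
(`numpy.random.default_rng`); a fixed seed reproduces every sequence,
clone set and verdict bit-for-bit. `scripts/acceptance.py` derives all
of its randomness from its `--seed` argument.

## Known limitations

* Clone-scale only; no quality scores, no trimming, no short-read mode.
* Alignment tie-breaks among equal-scoring alignments follow Biopython's
  deterministic enumeration order rather than an explicit
  substitution-over-gap preference; at clone-scale noise levels,
  equal-scoring ambiguity does not reach the assayed sites.
* Homozygous samples cannot be SNP-phased; their monoallelic calls rest
  entirely on the bimodal pattern rule and should be treated as weaker
  evidence than a phased split.
* The efficiency statistic assumes unmethylated non-CpG/non-CCWGG
  cytosines; genuine methylation outside the configured contexts would
  read as conversion failure.
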