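"""Allelic expression from cDNA clone sequencing at a transcribed SNP.

20 transcript clones are counted by the base at the exon-3 G/A
polymorphism; an even split is biallelic expression, a strong skew would
indicate monoallelic expression (e.g. imprinting).
"""

from allelobis import fixtures
from allelobis.expression import count_allelic_clones

dataset = fixtures.load_sample("LNCaP_cDNA")
result = count_allelic_clones(dataset.reads, dataset.transcript, dataset.snp)
print(f"SNP {result.snp.name} at transcript index {result.snp.position}")
print(f"clone counts: {result.counts}, undetermined: {result.n_undetermined}")
print(f"two-sided binomial p vs 0.5: {result.binomial_p:.4f}")
print(f"verdict: {result.verdict}")
# p = 1.0 for a 10/10 split: no evidence of allelic imbalance, i.e. both
# parental alleles contribute transcripts equally.
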