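"""Profile all five benchmark samples: genotype, clone classes, promoter state.

The five archetypes span the full state space: stochastic biallelic
methylation (HPrEpiC), SNP-phased monoallelic methylation (BPH1), a fully
unmethylated promoter (LNCaP), complete biallelic methylation (PC3) and a
bimodal monoallelic pattern that cannot be SNP-phased (PA1).
"""

from allelobis import fixtures, io, pipeline
from allelobis.patterns import build_profile

region = fixtures.promoter_region()
for sample in fixtures.GDNA_SAMPLES:
    dataset = fixtures.load_sample(sample, seed=0)
    passed, omitted = pipeline.process_clones(dataset.reads, region)
    profile = build_profile(sample, passed, omitted, region.snp.alleles)
    counts = ", ".join(f"{allele}/{cls}={n}" for (allele, cls), n in
                       sorted(profile.clone_counts.items()))
    p = f"  Fisher p={profile.association_p:.4f}" if profile.association_p else ""
    print(f"{sample:<9} genotype={profile.genotype:<8} "
          f"state={profile.promoter_state:<24} [{counts}]{p}")

print("\nBPH1 lollipop (rows grouped by allele; ●/○ CpG, ▲/△ CCWGG):")
dataset = fixtures.load_sample("BPH1", seed=0)
passed, _ = pipeline.process_clones(dataset.reads, region)
print(io.render_lollipop(passed, region))
# The Fisher p for BPH1 quantifies how unlikely the observed allele/
# methylation split would be if methylation were allele-independent.
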