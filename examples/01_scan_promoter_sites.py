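"""Discover assayable CpG and CCWGG sites in the bundled promoter region.

The region spans promoter coordinates -393..+51 around the TSS (+1) and
carries 6 CpG and 5 CCWGG (W=A/T) motifs plus a phasing SNP at -158.
"""

from allelobis import fixtures
from allelobis.reference import CCWGG, CPG, scan_motifs, tss_label

region = fixtures.promoter_region()
print(f"region {region.name}: {len(region)} nt, window "
      f"{tss_label(region, region.window[0]):+d}..{tss_label(region, region.window[1] - 1):+d}, "
      f"SNP {region.snp.label} at {tss_label(region, region.snp.position):+d}")

for spec in (CPG, CCWGG):
    sites = scan_motifs(region, spec)
    labels = ", ".join(f"{s.tss_label:+d}" for s in sites)
    print(f"{spec.name}: {len(sites)} sites at {labels}")

proximal = [s for s in region.sites() if s.proximal_pair_member]
print("proximal (CCWGG)2 pair (nearest the TSS):",
      ", ".join(f"{s.tss_label:+d}" for s in proximal))
# Each listed position is the assayed cytosine a bisulfite clone reports:
# C after conversion means methylated, T means unmethylated.
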