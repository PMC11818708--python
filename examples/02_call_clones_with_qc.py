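"""Simulate a noisy clone set, then align, QC-filter and phase each clone.

Clones are simulated with 2% incomplete bisulfite conversion, so several
should fall below the 98% conversion-efficiency threshold and be omitted
exactly as a wet-lab analysis would discard them.
"""

import numpy as np

from allelobis import fixtures, pipeline
from allelobis.simulate import SimulationConfig, random_pattern, simulate_clone_set

region = fixtures.promoter_region()
rng = np.random.default_rng(42)
patterns = [random_pattern(region, rng) for _ in range(12)]
reads = simulate_clone_set(region, patterns,
                           SimulationConfig(conversion_failure_rate=0.02, seed=42))

passed, omitted = pipeline.process_clones(reads, region)
print(f"{len(reads)} clones: {len(passed)} passed QC, {len(omitted)} omitted\n")
for report in passed + omitted:
    eff = f"{report.conversion_efficiency:.3f}"
    verdict = "pass" if report.passes_qc else f"OMIT ({report.omit_reason})"
    print(f"{report.clone_id:<28} efficiency={eff} "
          f"({report.n_converted_c}/{report.n_eligible_c})  allele={report.allele}  {verdict}")
# Efficiency counts only cytosines outside CpG/CCWGG contexts, which can
# only read C through failed conversion -- the QC proxy for treatment quality.
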