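"""Relative expression by the Livak 2^-ddCt method.

Constructed Ct values: the sample's DNMT1 runs 1.737 cycles later than the
calibrator's after TBP normalisation, i.e. ddCt = -log2(0.3), so relative
quantity rq = 0.3 (a 0.3-fold, 70% reduced expression).
"""

import math

from allelobis.expression import CtRecord, delta_delta_ct

dd = -math.log2(0.3)  # ~1.737 cycles
result = delta_delta_ct(
    target=CtRecord("LNCaP", "DNMT1", (25.0 + dd, 25.1 + dd, 24.9 + dd)),
    reference=CtRecord("LNCaP", "TBP", (25.0, 25.1, 24.9)),
    calibrator_target=CtRecord("BPH1", "DNMT1", (25.0, 25.0, 25.0)),
    calibrator_reference=CtRecord("BPH1", "TBP", (25.0, 25.0, 25.0)),
)
print(f"dCt(sample)     = {result.delta_ct:.4f}")
print(f"dCt(calibrator) = {result.delta_ct_calibrator:.4f}")
print(f"ddCt            = {result.delta_delta_ct:.4f}")
print(f"rq = 2^-ddCt    = {result.rq:.4f}  (range {result.rq_low:.4f}..{result.rq_high:.4f})")
# rq < 1 means the target gene is expressed below the calibrator sample
# after normalisation to the reference gene; the range propagates the
# replicate SDs of the sample's Ct values.
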