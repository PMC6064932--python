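"""Solve for the minimum CRF percentage that covers the largest requirement.

How many percent of the Consolidated Revenue Fund would the BHCPF need to
be (keeping the 50% NHIS allocation and equal 37-way sharing) to cover the
most expensive state's ALL-MCH requirement?
"""

from uhc_feasim import FundAllocation, minimum_crf_percent
from uhc_feasim.reference import REQUIRED

alloc = FundAllocation()
largest_state = max(REQUIRED, key=lambda s: REQUIRED[s]["all_mch"])
largest = REQUIRED[largest_state]["all_mch"]

x, ceiling = minimum_crf_percent(largest, alloc, "0.50")
print(f"largest ALL-MCH requirement: {largest:,d} Naira ({largest_state})")
print(f"continuous minimum CRF %:    {float(x):.2f}")
print(f"ceiling (whole percent):     {ceiling}")
print()
print("At the current 1% the NHIS share covers well under half of this")
print("requirement; at least ~4.7% of CRF would be needed for full coverage.")
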