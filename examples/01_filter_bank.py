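"""Build the default simple-cell filter bank and measure its size.

The bank holds 18 filters on a 15x15 grid at 1 deg/pixel: one ON and one
OFF Gaussian plus eight ON/OFF pairs per dominant polarity, with the
subfield-separation axis stepping through 45-deg increments.
"""

from collections import Counter

from latnet import build_v1_basis, effective_filter_radius

bank = build_v1_basis()
print(f"filters: {len(bank)}  classes: {dict(Counter(bank.classes))}")
print(f"oriented filters: {int(bank.oriented_mask().sum())} "
      f"(preferred orientations {sorted(set(bank.preferred_orientation[bank.oriented_mask()]))})")

r = effective_filter_radius(bank, threshold_frac=0.05)
print(f"mean effective radius at the 5% intensity threshold: {r:.2f} deg")
print("-> the spatial scale of one classical receptive field; lateral "
      "connections in the full model reach about three times this far.")
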