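"""Sizing degenerate RNAI libraries.

The full ~100-nt RNAI cannot be searched exhaustively; restricting the
degeneracy to the three hairpin loops (N codes) and their immediate
vicinity (K = G/T codes) shrinks the search space by ~50 orders of
magnitude while preserving the stems that hold the structure together.
"""

from oricompat import (
    FULL_RNAI_TEMPLATE,
    LOOP_RESTRICTED_TEMPLATES,
    degenerate_space_size,
)

full = degenerate_space_size(FULL_RNAI_TEMPLATE)
restricted = degenerate_space_size(LOOP_RESTRICTED_TEMPLATES)

print(f"full 100-nt diversification : {float(full):.2g} sequences")
print(f"loop-restricted design      : {float(restricted):.2g} sequences")
print(f"reduction                   : {float(full) / float(restricted):.1g}x")
# The restricted space (~4.3e9) is still far beyond what transformation
# can sample (~1e4-1e5 colonies), but dense enough near the wild type
# that viable, compatible origins are recoverable.
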