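"""When can absolute differences be recovered from relative data?

Ratio-based analysis needs a set of non-differential reference taxa that
is larger than any subcompositionally equivalent set of differential
taxa.  This example walks through two tiny five-taxon populations that
differ only in that property, using the small-p diagnostic.
"""

import numpy as np

from optimem import closure, max_subcompositionally_equivalent_set

# Group 1 has true mean abundances (5, 4, 3, 2, 2).  In group 2 the
# first three taxa double, 1.6x, and double again proportionally:
mu1 = np.array([5.0, 4.0, 3.0, 2.0, 2.0])
mu2 = np.array([10.0, 8.0, 6.0, 2.0, 2.0])

print("closure(mu1) =", np.round(closure(mu1), 4))
print("closure(mu2) =", np.round(closure(mu2), 4))

# Taxa 1-3 all doubled, so *within themselves* their relative profile is
# unchanged: they form a subcompositionally equivalent DA set of size 3,
# while only two taxa (4 and 5) are non-differential.
non_da, s_max, holds = max_subcompositionally_equivalent_set([mu1, mu2])
print("\nCase A: mu2 =", mu2)
print("  non-DA taxa (0-based):", non_da)
print("  largest equivalent DA subset:", s_max)
print("  identifiability assumption holds:", holds)
# With 3 >= 2 the data cannot tell "taxa 1-3 went up" apart from "taxa
# 4-5 went down": the reference is not identifiable.

# Swap two of the fold changes and the equivalence is broken: no DA
# subset larger than a singleton keeps its internal profile.
mu2b = np.array([10.0, 6.0, 8.0, 2.0, 2.0])
non_da, s_max, holds = max_subcompositionally_equivalent_set([mu1, mu2b])
print("\nCase B: mu2 =", mu2b)
print("  non-DA taxa (0-based):", non_da)
print("  largest equivalent DA subset:", s_max)
print("  identifiability assumption holds:", holds)
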