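"""Why proportions mislead and reference ratios do not.

When the differential taxa carry unequal total abundance across groups,
the unit-sum constraint drags every proportion up or down, so testing
proportions flags many non-differential taxa.  Dividing by the summed
abundance of a non-differential reference set removes that artifact.
"""

import numpy as np

from optimem import da_test, design_basic, ratio_transform, score_calls, simulate
from optimem.core import TaxonomicProfile

rng = np.random.default_rng(7)

# 40 taxa, 25 samples/group; the DA taxa gain much more total abundance
# in group 2 than in group 1 ("unbalance" design).
design = design_basic(
    40, 2, 25, n_da_range=(8, 12), balance="unbalance", model="nb", rng=rng
)
ds = simulate(design, rng)
truth = ds.da_flags
print(f"{truth.sum()} of 40 taxa are truly differential")

# --- Naive route: test each taxon's proportion ------------------------
prop = ds.profile.abundance / ds.profile.abundance.sum(axis=1, keepdims=True)
prop_profile = TaxonomicProfile(
    abundance=prop,
    sample_ids=ds.profile.sample_ids,
    taxon_ids=ds.profile.taxon_ids,
)
# Using every taxon as the denominator is exactly "test the proportions".
res_prop = da_test(ratio_transform(prop_profile, prop_profile.taxon_ids), ds.groups)
tpr, fdr, _ = score_calls(res_prop.calls, truth)
print(f"proportions:       {res_prop.n_called:2d} called, TPR={tpr:.2f}, FDR={fdr:.2f}")

# --- Reference route: divide by the true non-DA taxa ------------------
reference = [ds.profile.taxon_ids[j] for j in np.flatnonzero(~truth)]
res_ratio = da_test(ratio_transform(ds.profile, reference), ds.groups)
tpr, fdr, _ = score_calls(res_ratio.calls, truth)
print(f"reference ratios:  {res_ratio.n_called:2d} called, TPR={tpr:.2f}, FDR={fdr:.2f}")

# The proportion route inflates the false discovery rate because the
# denominator itself differs between groups; the reference-sum
# denominator is group-stable by construction.  In practice the
# reference is unknown — see select_reference.py for how it is found.
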