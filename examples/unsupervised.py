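"""Reference selection without group labels.

If sample groupings are unknown (or deliberately withheld), samples can
first be clustered with k-medoids on Bray-Curtis dissimilarities and the
cluster labels used in place of group membership.  On well-separated
data the selected reference closely matches the supervised one.
"""

import numpy as np

from optimem import (
    SearchConfig,
    cluster_samples,
    design_basic,
    run_optimem,
    run_optimem_unsupervised,
    simulate,
)

rng = np.random.default_rng(31)
design = design_basic(
    30, 2, 20, n_da_range=(6, 10), fold_range=(2.5, 5.0), model="nb", rng=rng
)
ds = simulate(design, rng)

# How well does clustering recover the real groups?
labels = cluster_samples(ds.profile, n_clusters=2, seed=31)
agree = float(np.mean(labels.codes == ds.groups.codes))
agree = max(agree, 1 - agree)  # cluster ids are arbitrary
print(f"cluster/group agreement: {agree:.2f}")

cfg = SearchConfig(R=500, seed=31)
sup = run_optimem(ds.profile, ds.groups, cfg)
uns = run_optimem_unsupervised(ds.profile, n_clusters=2, cfg=cfg)

print(f"\nsupervised:   {sup.outcome}, {len(sup.taxa)} reference taxa")
print(f"unsupervised: {uns.outcome}, {len(uns.taxa)} reference taxa")

both = set(sup.taxa) & set(uns.taxa)
either = set(sup.taxa) | set(uns.taxa)
print(f"overlap: {len(both)}/{len(either)} taxa selected by both")
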