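# optimem

Reference-based normalization and differential abundance (DA) analysis
for sparse compositional count data, such as 16S/shotgun microbiome
taxonomic profiles.

Sequencing counts only carry *relative* information: if a few taxa bloom
in one condition, every other taxon's proportion drops even though its
absolute abundance never changed. Testing proportions therefore produces
systematic false discoveries. `optimem` addresses this by

1. **finding a reference set of non-differential taxa** directly from
   the data, by sequentially removing the taxon whose removal makes the
   remaining profile look least differential, as scored by a
   mean-sum-of-squares (MSS) statistic over random amalgamations, and
   stopping when the MSS falls inside a permutation null;
2. **normalizing** each sample by the summed abundance of the reference
   taxa, so every taxon is expressed as a group-stable ratio; and
3. **testing** each ratio with Wilcoxon rank-sum (two groups) or
   Kruskal–Wallis (three or more), with Benjamini–Hochberg correction.

The only assumption is that the non-differential taxa outnumber every
*subcompositionally equivalent* subset of differential taxa — much
weaker than requiring that most taxa are non-differential.

## Quick start (library)

```python
import numpy as np
from optimem import (SearchConfig, da_test, design_basic,
                     ratio_transform, run_optimem, simulate)

rng = np.random.default_rng(0)
design = design_basic(30, 2, 20, n_da_range=(5, 8), model="nb", rng=rng)
ds = simulate(design, rng)                    # or load your own counts

ref = run_optimem(ds.profile, ds.groups, SearchConfig(R=500, seed=0))
print(ref.outcome, ref.taxa)                  # reference taxa

ratios = ratio_transform(ds.profile, ref)     # reference-sum ratios
result = da_test(ratios, ds.groups, fdr_target=0.05)
print(result.table)
```

Real data enter through `optimem.io.read_profile` (TSV counts,
samples-by-taxa or transposed) and `read_metadata` (sample → group).

If group labels are unavailable, `run_optimem_unsupervised` first
clusters samples with k-medoids on Bray–Curtis dissimilarities and uses
the cluster labels instead.

## Quick start (CLI)

```sh
optimem simulate --p 30 --n 20 --seed 1 --out demo
optimem select-ref --counts demo.counts.tsv --metadata demo.metadata.tsv \
    --seed 1 --out demo.reference.tsv
optimem da --counts demo.counts.tsv --metadata demo.metadata.tsv \
    --reference demo.reference.tsv --seed 1 --out demo.da.tsv
```

Every command is deterministic given `--seed` and records a
`<command>.run.json` sidecar with its parameters and input digests.
`optimem benchmark` sweeps the built-in antagonistic simulation
scenarios; `optimem assumption-check` runs the small-p identifiability
diagnostic on user-supplied mean vectors.

## Search outcomes

`run_optimem` classifies its result as one of:

- `ref_found` — removal crossed the null threshold; use `ref.taxa`.
- `no_da_taxa` — the full profile already looks null; all taxa kept.
- `all_da_taxa` — removal hit the taxon floor without ever looking
  null; no usable reference exists (a warning is raised).

## Layout

- `src/optimem/` — the library (`core`, `mss`, `nullref`, `search`,
  `downstream`, `simulate`, `io`, `cli`).
- `examples/` — narrative walkthroughs: the identifiability assumption,
  the compositional artifact, reference selection, end-to-end DA
  analysis, unsupervised selection.
- `scripts/acceptance.py` — regenerates the headline simulation numbers
  as JSON (`--seed`, `--out`; roughly 12 minutes on one CPU).
- `docs/methods.md` — statistical details, design choices, and known
  limitations.

## Testing

```sh
pytest -q
```

The suite includes simulation-based acceptance tests that take several
minutes; everything else finishes in seconds. See `docs/methods.md` for
the performance bands they assert and the known gaps.
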