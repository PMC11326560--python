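"""TSV input/output for profiles, metadata, and result tables.

All tables are tab-separated with a header row and a leading identifier
column.  Output tables written by the command-line interface start with
a ``#`` comment line recording the package version and the seed, which
readers here skip transparently.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GroupLabels, TaxonomicProfile
from .downstream import DAResult, RatioProfile
from .search import ReferenceSet
from .simulate import SimulatedDataset

__all__ = [
    "read_profile",
    "write_profile",
    "read_metadata",
    "write_reference",
    "write_da_table",
    "write_ratio_profile",
    "write_dataset",
]

log = logging.getLogger("optimem")


class ParseError(ValueError):
    """Malformed input table."""


def _read_tsv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


def read_profile(path, orientation: str = "samples_by_taxa") -> TaxonomicProfile:
    """Read a count table; taxa-by-samples input is transposed.

    Non-numeric cells, duplicate identifiers, and negative values raise
    :class:`ParseError` naming the offending coordinates.  All-zero
    taxa are dropped with a logged warning.
    """
    if orientation not in ("samples_by_taxa", "taxa_by_samples"):
        raise ValueError("orientation must be samples_by_taxa or taxa_by_samples")
    df = _read_tsv(path)
    if orientation == "taxa_by_samples":
        df = df.T
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"duplicate sample identifiers: {dup}")
    if df.columns.has_duplicates:
        dup = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"duplicate taxon identifiers: {dup}")
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError):
        for j, col in enumerate(df.columns):
            bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
            if bad.any():
                i = int(np.flatnonzero(bad)[0])
                raise ParseError(
                    f"non-numeric cell at sample {df.index[i]!r}, taxon {col!r}"
                ) from None
        raise
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise ParseError(f"missing cell at sample {df.index[i]!r}, taxon {df.columns[j]!r}")
    neg = np.argwhere(values < 0)
    if neg.size:
        i, j = neg[0]
        raise ParseError(
            f"negative value at sample {df.index[i]!r}, taxon {df.columns[j]!r}"
        )
    empty = values.sum(axis=0) == 0
    if empty.any():
        dropped = [str(c) for c in df.columns[empty]]
        log.warning("dropping %d all-zero taxa: %s", len(dropped), dropped[:10])
        df = df.loc[:, ~empty]
        values = values[:, ~empty]
    return TaxonomicProfile(
        abundance=values,
        sample_ids=[str(s) for s in df.index],
        taxon_ids=[str(t) for t in df.columns],
    )


def _header_comment(seed=None) -> str:
    from . import __version__

    seed_part = "" if seed is None else f" seed={seed}"
    return f"# optimem v{__version__}{seed_part}\n"


def write_profile(profile: TaxonomicProfile, path, seed=None) -> None:
    df = pd.DataFrame(
        profile.abundance, index=profile.sample_ids, columns=profile.taxon_ids
    )
    df.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t")


def read_metadata(path, group_column: str, sample_ids: list[str]) -> GroupLabels:
    """Read a sample metadata table and align labels to ``sample_ids``.

    Samples missing from the metadata are an error; extra metadata rows
    are ignored with a warning.
    """
    df = _read_tsv(path)
    if group_column not in df.columns:
        raise ParseError(
            f"metadata lacks column {group_column!r} (has {list(df.columns)})"
        )
    idx = df.index.astype(str)
    if idx.has_duplicates:
        raise ParseError("duplicate sample identifiers in metadata")
    series = pd.Series(df[group_column].values, index=idx)
    missing = [s for s in sample_ids if s not in series.index]
    if missing:
        raise ParseError(f"samples missing from metadata: {missing}")
    extra = set(series.index) - set(sample_ids)
    if extra:
        warnings.warn(f"ignoring {len(extra)} metadata rows with unknown samples")
    values = [series[s] for s in sample_ids]
    if any(pd.isna(v) for v in values):
        raise ParseError("missing group value for some samples")
    return GroupLabels.from_values(values)


def write_reference(ref: ReferenceSet, path, seed=None) -> None:
    """Write the reference set with its audit fields (MSS, threshold, outcome)."""
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write(f"# outcome={ref.outcome} final_mss={ref.final_q:.6g} ")
        fh.write(f"threshold={ref.threshold:.6g} mode={ref.mode}\n")
        fh.write("taxon_id\n")
        for t in ref.taxa:
            fh.write(f"{t}\n")


def write_da_table(result: DAResult, path, seed=None) -> None:
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        fh.write(f"# test={result.test} fdr_target={result.fdr_target}\n")
        result.table.to_csv(fh, sep="\t", index=False)


def write_ratio_profile(rp: RatioProfile, path, seed=None) -> None:
    df = pd.DataFrame(rp.ratios, index=rp.sample_ids, columns=rp.taxon_ids)
    df.index.name = "sample_id"
    with open(path, "w") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t")


def write_dataset(ds: SimulatedDataset, prefix, seed=None) -> dict:
    """Write counts TSV, metadata TSV, and a JSON truth sidecar.

    Returns the mapping of written paths.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    counts = prefix.with_suffix(".counts.tsv")
    meta = prefix.with_suffix(".metadata.tsv")
    truth = prefix.with_suffix(".truth.json")
    write_profile(ds.profile, counts, seed=seed)
    md = pd.DataFrame(
        {
            "sample_id": ds.profile.sample_ids,
            "group": [ds.groups.group_names[c] for c in ds.groups.codes],
        }
    )
    with open(meta, "w") as fh:
        fh.write(_header_comment(seed))
        md.to_csv(fh, sep="\t", index=False)
    with open(truth, "w") as fh:
        json.dump(
            {
                "seed": ds.seed if seed is None else seed,
                "model": ds.design.model,
                "scenario": ds.design.scenario,
                "da_flags": ds.da_flags.astype(int).tolist(),
                "fold_changes": np.round(ds.fold_changes, 8).tolist(),
                "taxon_ids": ds.profile.taxon_ids,
            },
            fh,
            indent=1,
        )
    return {"counts": counts, "metadata": meta, "truth": truth}
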