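"""Repeat-aware relative 6mA density statistics from modification calls.

The per-segment statistic is the number of m6A calls falling inside the
segment divided by the segment length.  For a TE family the calls over all
copies are pooled and divided by an *effective length* equal to the element
(consensus) length times the family's copy number, so high-copy families are
not over-weighted.  Reported levels are relative: each row is normalized to
the mean density of the gene class, which makes the constant factors
(adenine content, strand doubling) cancel.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import NormalizationError
from .methylome_sim import ModCallSet
from .synthgenome import FamilySpec, Feature

GENE_KINDS = ("gene", "control_gene")


@dataclass(frozen=True)
class SegmentDensity:
    ident: str
    n_calls: int
    effective_length: int
    density: float


def _count_calls(calls: ModCallSet, feature: Feature) -> int:
    df = calls.df
    if df.empty:
        return 0
    mask = ((df["chrom"] == feature.chrom)
            & (df["pos"] >= feature.start)
            & (df["pos"] < feature.end))
    return int(mask.sum())


def segment_density(calls: ModCallSet, feature: Feature) -> SegmentDensity:
    """Calls per bp over one feature interval (both strands pooled)."""
    length = feature.end - feature.start
    if length <= 0:
        raise ValueError(f"{feature.feature_id}: zero-length feature")
    n = _count_calls(calls, feature)
    return SegmentDensity(feature.feature_id, n, length, n / length)


def family_density(calls: ModCallSet, features: list[Feature],
                   family: FamilySpec) -> SegmentDensity:
    """Pooled family statistic: total calls over all copies divided by
    element length x copy count."""
    copies = [f for f in features
              if f.kind == "te_copy" and f.family_id == family.family_id]
    if not copies:
        raise ValueError(f"family {family.family_id!r} absent from annotations")
    n = sum(_count_calls(calls, f) for f in copies)
    eff = family.consensus_length * family.copy_count
    return SegmentDensity(family.family_id, n, eff, n / eff)


def relative_density_table(calls: ModCallSet, features: list[Feature],
                           families: list[FamilySpec],
                           normalize_to: str = "gene") -> pd.DataFrame:
    """Per-gene and per-family densities, normalized to the mean density of
    the reference class (genes by default).  Columns: id, class, n_calls,
    effective_length, density, relative_density."""
    rows = []
    for f in features:
        if f.kind in GENE_KINDS:
            d = segment_density(calls, f)
            rows.append((d.ident, "gene", d.n_calls, d.effective_length, d.density))
    for fam in families:
        d = family_density(calls, features, fam)
        rows.append((d.ident, "te_family", d.n_calls, d.effective_length, d.density))
    table = pd.DataFrame(rows, columns=["id", "class", "n_calls",
                                        "effective_length", "density"])
    ref = table.loc[table["class"] == normalize_to, "density"]
    if ref.empty or ref.mean() == 0:
        raise NormalizationError(
            f"no usable {normalize_to!r} rows to normalize against")
    table["relative_density"] = table["density"] / ref.mean()
    return table


def class_mean_relative(table: pd.DataFrame, cls: str) -> float:
    """Mean relative density of one class (the figure-style bar height)."""
    sub = table.loc[table["class"] == cls, "relative_density"]
    if sub.empty:
        raise ValueError(f"no rows of class {cls!r}")
    return float(sub.mean())


def top_n_ranking(table: pd.DataFrame, n: int, cls: str) -> pd.DataFrame:
    """Rows of a class ranked by density (descending), ties broken by id."""
    if n < 1:
        raise ValueError("n must be >= 1")
    sub = table[table["class"] == cls]
    ranked = sub.sort_values(["density", "id"], ascending=[False, True],
                             kind="mergesort").reset_index(drop=True)
    return ranked.head(n)


def locus_site_map(calls: ModCallSet, feature: Feature) -> pd.DataFrame:
    """Called-site offsets relative to the feature start (genome-forward,
    not orientation-corrected), sorted ascending.  Columns: offset, strand."""
    df = calls.df
    if df.empty:
        return pd.DataFrame({"offset": pd.Series(dtype="int64"),
                             "strand": pd.Series(dtype="object")})
    mask = ((df["chrom"] == feature.chrom)
            & (df["pos"] >= feature.start)
            & (df["pos"] < feature.end))
    out = df.loc[mask, ["pos", "strand"]].copy()
    out["offset"] = out["pos"] - feature.start
    return (out[["offset", "strand"]]
            .sort_values(["offset", "strand"]).reset_index(drop=True))
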