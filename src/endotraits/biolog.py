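"""Biolog phenotype-microarray scoring.

A Biolog SF-P2 plate exposes one isolate to 95 carbon substrates plus a
water control well; growth after 3 days is read as optical density at
590 nm (OD590). The derived quantities are:

standardized growth
    well OD590 minus the same isolate's water-control OD590 (negative
    values are retained);
resource use
    a binary flag: standardized growth below 0.005 (the photometric
    accuracy of the plate reader) counts as no growth, >= 0.005 as growth;
niche width
    the number of resources an isolate uses;
mean standardized growth
    the per-isolate mean of standardized growth, computed over (a) the
    "common" resources used by at least half of all isolates, (b) all
    resources, and (c) only the resources the isolate itself uses
    ("growth efficiency", undefined at niche width 0).

Variant (a) is the input to the slow/fast assemblage classification; (b)
and (c) exist to check that the bimodal structure is not an artifact of
the resource subset.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "BiologPlate",
    "TraitTable",
    "USE_THRESHOLD",
    "standardize",
    "binarize",
    "common_resources",
    "mean_growth",
    "growth_efficiency",
    "niche_width",
    "use_frequency",
    "build_trait_table",
    "read_plate",
]

#: Default detection threshold for resource use, in OD590 units.
USE_THRESHOLD = 0.005

#: Default prevalence cutoff defining the "common" resource set.
COMMON_FRACTION = 0.5


@dataclass
class BiologPlate:
    """Raw day-3 OD590 readings: isolates x resources, plus water controls.

    ``od`` is indexed by isolate id with one column per resource; ``water``
    holds the per-isolate water-control reading. The water control is not a
    member of the resource columns.
    """

    od: pd.DataFrame
    water: pd.Series

    def __post_init__(self) -> None:
        if self.od.columns.duplicated().any():
            dups = self.od.columns[self.od.columns.duplicated()].tolist()
            raise ValueError(f"duplicate resource names: {dups}")
        if self.od.index.duplicated().any():
            raise ValueError("duplicate isolate ids in plate")
        if self.od.isna().any().any():
            bad = self.od.isna().any(axis=1)
            raise ValueError(
                f"missing OD readings for isolates: {list(self.od.index[bad])}"
            )
        missing = self.od.index.difference(self.water.index)
        if len(missing) or self.water.reindex(self.od.index).isna().any():
            nul = self.water.reindex(self.od.index)
            names = sorted(set(missing) | set(nul.index[nul.isna()]))
            raise ValueError(f"missing water control for isolates: {names}")
        self.water = self.water.reindex(self.od.index).astype(float)
        self.od = self.od.astype(float)

    @property
    def isolates(self) -> list[str]:
        return list(self.od.index)

    @property
    def resources(self) -> list[str]:
        return list(self.od.columns)

    def to_csv(self, path: str) -> None:
        wide = self.od.copy()
        wide.insert(0, "water", self.water)
        wide.to_csv(path, index_label="isolate_id")


def read_plate(path: str, water_name: str = "water") -> BiologPlate:
    """Read a plate CSV, auto-detecting the dialect from the header.

    Wide format: one row per isolate, a ``water`` column, and one column
    per resource. Long format: columns ``isolate_id, resource, od590``
    with one row per well and the water control as resource "water".
    """
    head = pd.read_csv(path, nrows=0)
    cols = set(head.columns)
    if {"isolate_id", "resource", "od590"} <= cols:
        long = pd.read_csv(path)
        wide = long.pivot(index="isolate_id", columns="resource", values="od590")
        if water_name not in wide.columns:
            raise ValueError(f"long-format plate lacks a {water_name!r} resource")
        water = wide[water_name]
        od = wide.drop(columns=[water_name])
        return BiologPlate(od=od, water=water)
    if water_name in cols:
        idcol = "isolate_id" if "isolate_id" in cols else head.columns[0]
        wide = pd.read_csv(path, index_col=idcol)
        return BiologPlate(od=wide.drop(columns=[water_name]), water=wide[water_name])
    raise ValueError(
        "unrecognized plate CSV: need either long columns "
        "(isolate_id, resource, od590) or a wide table with a 'water' column"
    )


def standardize(plate: BiologPlate) -> pd.DataFrame:
    """Standardized growth: well OD590 minus the isolate's water control.

    Negative values are retained; they simply count as no growth when
    binarized.
    """
    return plate.od.sub(plate.water, axis=0)


def binarize(sg: pd.DataFrame, threshold: float = USE_THRESHOLD) -> pd.DataFrame:
    """Binary resource use: 1 where standardized growth >= threshold.

    Values below the threshold (the reader's photometric accuracy) are
    scored as no growth; the boundary value itself counts as growth.
    """
    return (sg >= threshold).astype(int)


def common_resources(
    use: pd.DataFrame, min_frac: float = COMMON_FRACTION
) -> list[str]:
    """Resources used by at least ``min_frac`` of all isolates, in plate order."""
    if use.shape[0] == 0:
        raise ValueError("empty plate: no isolates")
    frac = use.mean(axis=0)
    return [r for r in use.columns if frac[r] >= min_frac]


def mean_growth(sg: pd.DataFrame, resource_set: list[str]) -> pd.Series:
    """Per-isolate mean standardized growth over a fixed resource set."""
    if len(resource_set) == 0:
        raise ValueError("resource_set is empty")
    missing = set(resource_set) - set(sg.columns)
    if missing:
        raise ValueError(f"resources not on plate: {sorted(missing)}")
    return sg[list(resource_set)].mean(axis=1)


def growth_efficiency(sg: pd.DataFrame, use: pd.DataFrame) -> pd.Series:
    """Per-isolate mean standardized growth over the resources it uses.

    NaN (undefined) for isolates with niche width 0.
    """
    masked = sg.where(use.astype(bool))
    return masked.mean(axis=1)


def niche_width(use: pd.DataFrame) -> pd.Series:
    """Number of resources used per isolate (row sums of the use matrix)."""
    return use.sum(axis=1).astype(int)


def use_frequency(use: pd.DataFrame, groups: pd.Series | None = None) -> pd.DataFrame:
    """Percent of isolates using each resource, overall and optionally by group.

    ``groups`` maps isolate id to a grouping label (e.g. isolation method).
    """
    out = pd.DataFrame({"percent_all": 100.0 * use.mean(axis=0)})
    if groups is not None:
        for name, idx in use.groupby(groups.reindex(use.index)).groups.items():
            out[f"percent_{name}"] = 100.0 * use.loc[idx].mean(axis=0)
    out.index.name = "resource"
    return out


@dataclass
class TraitTable:
    """Derived per-isolate traits plus the matrices they came from."""

    sg: pd.DataFrame
    use: pd.DataFrame
    common: list[str]
    summary: pd.DataFrame  # niche_width, mean_sg_common, mean_sg_all, growth_efficiency

    def write(self, traits_csv: str, sg_csv: str | None = None,
              use_csv: str | None = None) -> None:
        self.summary.to_csv(traits_csv, index_label="isolate_id")
        if sg_csv:
            self.sg.to_csv(sg_csv, index_label="isolate_id")
        if use_csv:
            self.use.to_csv(use_csv, index_label="isolate_id")


def build_trait_table(
    plate: BiologPlate,
    threshold: float = USE_THRESHOLD,
    min_frac: float = COMMON_FRACTION,
) -> TraitTable:
    """Full scoring pass: standardize, binarize, and summarize one plate."""
    sg = standardize(plate)
    use = binarize(sg, threshold=threshold)
    common = common_resources(use, min_frac=min_frac)
    width = niche_width(use)
    summary = pd.DataFrame(
        {
            "niche_width": width,
            "mean_sg_common": mean_growth(sg, common) if common else np.nan,
            "mean_sg_all": mean_growth(sg, list(sg.columns)),
            "growth_efficiency": growth_efficiency(sg, use),
        }
    )
    return TraitTable(sg=sg, use=use, common=common, summary=summary)
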