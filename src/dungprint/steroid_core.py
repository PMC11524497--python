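"""Sample tables, compositional transformation and species profile summaries.

Concentration data (mass of compound per dry mass of dung or sediment) are
converted to *relative abundances within a compound family* before any
multivariate comparison, because absolute steroid yields vary strongly with
preservation and organic content while the within-family proportions carry the
source signature.  Profiles are closed compositions: the retained compounds of
one family sum to 1 for every sample.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .registry import DEFAULT_REGISTRY, ZOOSTANOLS, CompoundRegistry

__all__ = [
    "SteroidTable",
    "relative_abundance",
    "zoostanol_profiles",
    "species_summary",
    "read_steroid_csv",
    "write_steroid_csv",
    "MissingCompoundError",
]

logger = logging.getLogger(__name__)

#: Bile acids dropped from ordination by default: rarely detected in dung.
DEFAULT_BILE_ACID_EXCLUSIONS = ("chenodeoxycholic acid", "ursodeoxycholic acid")

META_COLUMNS = ("source", "species", "depth_cm")


class MissingCompoundError(KeyError):
    """A required compound column is absent from a table."""


@dataclass
class SteroidTable:
    """Concentrations per sample x compound plus sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by sample_id with canonical compound columns.
        Concentrations are non-negative; below-detection cells are zero.
    meta
        DataFrame indexed by sample_id with columns ``source`` (``dung`` |
        ``sediment``), ``species`` (dung only) and ``depth_cm`` (sediment only).
    units
        ``ug_per_g`` (dung convention) or ``ng_per_g`` (sediment convention);
        never mixed within one table.
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    units: str = "ug_per_g"
    registry: CompoundRegistry = field(default_factory=lambda: DEFAULT_REGISTRY)

    def __post_init__(self) -> None:
        if self.units not in ("ug_per_g", "ng_per_g"):
            raise ValueError(f"units must be ug_per_g or ng_per_g, got {self.units!r}")
        self.values = self.values.rename(columns=self.registry.canonical)
        self.values = self.values.astype(float)
        if (self.values.to_numpy() < 0).any():
            bad = self.values[(self.values < 0).any(axis=1)].index.tolist()
            raise ValueError(f"negative concentrations in samples {bad}")
        if not self.values.index.equals(self.meta.index):
            raise ValueError("values and meta must share the same sample index")
        sources = set(self.meta["source"].unique())
        if not sources <= {"dung", "sediment"}:
            raise ValueError(f"invalid sources {sources - {'dung', 'sediment'}}")
        sed = self.meta["source"] == "sediment"
        if sed.any() and self.meta.loc[sed, "depth_cm"].isna().any():
            raise ValueError("sediment samples must carry depth_cm")
        dung = self.meta["source"] == "dung"
        if dung.any() and self.meta.loc[dung, "species"].isna().any():
            raise ValueError("dung samples must carry species")

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def compounds(self) -> list[str]:
        return list(self.values.columns)

    def subset(self, sample_ids: Sequence[str]) -> "SteroidTable":
        return SteroidTable(
            self.values.loc[sample_ids].copy(),
            self.meta.loc[sample_ids].copy(),
            self.units,
            self.registry,
        )

    def species_labels(self) -> pd.Series:
        return self.meta["species"]


def relative_abundance(
    table: SteroidTable,
    compound_class: str,
    exclude: Iterable[str] = (),
) -> pd.DataFrame:
    """Close each sample's concentrations over one compound family.

    ``compound_class`` may be any registry class (``sterol``, ``stanol``,
    ``stanone``, ``bile_acid``) or the combined families ``neutral`` (sterols +
    stanols + stanones, the usual ordination input) and ``zoostanol``.

    Returns a DataFrame of fractions (rows sum to 1).  Samples whose class sum
    is zero after exclusions are omitted with a logged warning — they carry no
    signal in this family, and silently keeping NaNs would poison downstream
    ordination.
    """
    reg = table.registry
    if compound_class == "neutral":
        members = reg.neutral_members()
    elif compound_class == "zoostanol":
        members = list(ZOOSTANOLS)
    else:
        members = reg.members(compound_class)
    excluded = {reg.canonical(name) for name in exclude}
    for name in excluded:
        if name not in members:
            raise ValueError(
                f"excluded compound {name!r} is not a member of class "
                f"{compound_class!r}"
            )
    retained = [m for m in members if m not in excluded]
    missing = [m for m in retained if m not in table.values.columns]
    if compound_class == "zoostanol" and missing:
        # Attribution needs the full four-component composition.
        raise MissingCompoundError(f"table lacks zoostanol columns: {missing}")
    retained = [m for m in retained if m in table.values.columns]
    if not retained:
        raise MissingCompoundError(
            f"table has no {compound_class} columns (class members: {members})"
        )
    sub = table.values[retained]
    totals = sub.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        for sid in sub.index[zero]:
            logger.warning(
                "sample %s has zero total %s concentration; omitted from profiles",
                sid,
                compound_class,
            )
    frac = sub.loc[~zero].div(totals[~zero], axis=0)
    return frac


def zoostanol_profiles(table: SteroidTable) -> pd.DataFrame:
    """Four-component 5β-stanol composition per sample (rows sum to 1)."""
    missing = [z for z in ZOOSTANOLS if z not in table.values.columns]
    if missing:
        raise MissingCompoundError(
            f"table lacks zoostanol columns: {missing}; all four of "
            f"{list(ZOOSTANOLS)} are required"
        )
    return relative_abundance(table, "zoostanol")


def species_summary(
    profiles: pd.DataFrame, labels: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-species mean and standard error of profile fractions.

    ``labels`` maps sample_id -> species for at least the profiled samples.
    Returns ``(mean, se)`` DataFrames indexed by species.  SE = sample SD
    (ddof=1) / sqrt(n); for singleton species the SE is NaN (undefined).
    """
    valid = sorted(pd.Series(labels).dropna().unique())
    labels = labels.reindex(profiles.index)
    unknown = labels.isna()
    if unknown.any():
        raise ValueError(
            f"no species label for samples {list(profiles.index[unknown])}; "
            f"valid labels: {valid}"
        )
    grouped = profiles.groupby(labels)
    mean = grouped.mean()
    n = grouped.size()
    sd = grouped.std(ddof=1)
    se = sd.div(np.sqrt(n), axis=0)
    se[n == 1] = np.nan
    return mean, se


# ---------------------------------------------------------------------------
# CSV interchange (wide layout: sample_id, meta_* columns, compound columns)
# ---------------------------------------------------------------------------

def read_steroid_csv(
    path: str | Path,
    units: str = "ug_per_g",
    registry: CompoundRegistry = DEFAULT_REGISTRY,
) -> SteroidTable:
    """Read a wide-layout steroid table.

    First column is ``sample_id``; columns prefixed ``meta_`` carry sample
    metadata (``meta_source``, ``meta_species``, ``meta_depth_cm``); all other
    columns are compound common names (any accepted synonym).  Empty cells are
    below-detection and read as zero.
    """
    df = pd.read_csv(path)
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be sample_id, got {df.columns[0]!r}")
    df = df.set_index("sample_id")
    meta_cols = [c for c in df.columns if c.startswith("meta_")]
    meta = df[meta_cols].rename(columns=lambda c: c[len("meta_"):])
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = np.nan
    if meta["source"].isna().all():
        # Infer: depth present -> sediment, else dung.
        meta["source"] = np.where(meta["depth_cm"].notna(), "sediment", "dung")
    values = df.drop(columns=meta_cols).fillna(0.0)
    return SteroidTable(values, meta[list(META_COLUMNS)], units, registry)


def write_steroid_csv(table: SteroidTable, path: str | Path) -> None:
    out = table.meta.rename(columns=lambda c: f"meta_{c}").join(table.values)
    out.index.name = "sample_id"
    out.to_csv(path)
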