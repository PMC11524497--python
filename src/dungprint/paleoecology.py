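"""Pollen summaries, herbivore biomass and record-to-record comparison.

This module holds the non-steroid proxies that contextualise the biomarker
record: pollen percentages and accumulation rates (with an exotic-marker
spike), the steppe/forest openness ratio, herbivore census-to-biomass
conversion, windowed Pearson correlation between sediment biomarker levels
and regional herbivore biomass, and presence/absence from fossil minimum
numbers of individuals (MNI).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "pollen_percentages",
    "openness_ratio",
    "biomass_series",
    "windowed_correlation",
    "mni_presence",
    "DEFAULT_BODY_MASS_KG",
]

logger = logging.getLogger(__name__)

#: Average adult body masses used to convert census counts to biomass.
DEFAULT_BODY_MASS_KG = {"bison": 665.0, "elk": 235.0}

#: Openness-ratio taxa: steppe shrubs and grasses over dominant conifers.
OPENNESS_NUMERATOR = ("Artemisia", "Poaceae")
OPENNESS_DENOMINATOR = ("Pinus", "Pseudotsuga")


def pollen_percentages(
    counts: pd.DataFrame,
    taxon_groups: dict[str, str],
    spike_counted: pd.Series | None = None,
    spike_added: float | pd.Series | None = None,
    volume_cm3: float | pd.Series = 1.0,
    age_model=None,
    depths: pd.Series | None = None,
) -> dict[str, pd.DataFrame]:
    """Pollen percentages, concentrations and accumulation rates.

    ``counts`` is samples x taxa (non-negative integers); ``taxon_groups``
    maps each taxon to ``terrestrial`` or ``aquatic``.  Terrestrial taxa are
    converted to percentages on the terrestrial sum; aquatic taxa on the total
    (terrestrial + aquatic) sum.  When an exotic-marker spike is supplied,
    concentration = (taxon count / spike counted) x spike added / volume
    (grains cm^-3), and with an age model the accumulation rate
    (grains cm^-2 yr^-1) = concentration x SAR.

    Returns ``{"percent": ..., "concentration": ..., "accumulation": ...}``
    (the latter two only when computable).
    """
    unknown = [t for t in counts.columns if t not in taxon_groups]
    if unknown:
        raise ValueError(f"taxa without terrestrial/aquatic group: {unknown}")
    bad = {t: g for t, g in taxon_groups.items() if g not in ("terrestrial", "aquatic")}
    if bad:
        raise ValueError(f"taxon groups must be terrestrial|aquatic, got {bad}")
    arr = counts.to_numpy(dtype=float)
    if (arr < 0).any() or np.any(arr != np.round(arr)):
        raise ValueError("pollen counts must be non-negative integers")
    terr = [t for t in counts.columns if taxon_groups[t] == "terrestrial"]
    terr_sum = counts[terr].sum(axis=1)
    if (terr_sum <= 0).any():
        raise ValueError(
            f"zero terrestrial pollen sum in samples "
            f"{list(counts.index[terr_sum <= 0])}"
        )
    total_sum = counts.sum(axis=1)
    percent = pd.DataFrame(index=counts.index, columns=counts.columns, dtype=float)
    for taxon in counts.columns:
        base = terr_sum if taxon_groups[taxon] == "terrestrial" else total_sum
        percent[taxon] = 100.0 * counts[taxon] / base
    out: dict[str, pd.DataFrame] = {"percent": percent}
    if spike_counted is not None and spike_added is not None:
        spike_counted = spike_counted.reindex(counts.index)
        zero_spike = spike_counted <= 0
        if zero_spike.any():
            for sid in counts.index[zero_spike]:
                logger.warning(
                    "sample %s has zero marker-spike count; concentration undefined",
                    sid,
                )
        conc = counts.div(spike_counted.where(~zero_spike), axis=0)
        conc = conc.mul(spike_added, axis=0) if isinstance(spike_added, pd.Series) else conc * spike_added
        conc = conc.div(volume_cm3, axis=0) if isinstance(volume_cm3, pd.Series) else conc / volume_cm3
        out["concentration"] = conc
        if age_model is not None and depths is not None:
            from .chronology import sar

            rates = sar(age_model, depths.reindex(counts.index).to_numpy())
            out["accumulation"] = conc.mul(rates["SAR_cm_per_yr"].to_numpy(), axis=0)
    return out


def openness_ratio(percent: pd.DataFrame) -> pd.Series:
    """(Artemisia% + Poaceae%) / (Pinus% + Pseudotsuga%) per sample.

    High values indicate open steppe-shrub vegetation, low values closed
    conifer forest.  Samples with a zero denominator yield NaN (undefined).
    """
    missing = [t for t in OPENNESS_NUMERATOR + OPENNESS_DENOMINATOR if t not in percent.columns]
    if missing:
        raise ValueError(f"openness ratio requires percentage columns {missing}")
    num = percent[list(OPENNESS_NUMERATOR)].sum(axis=1)
    den = percent[list(OPENNESS_DENOMINATOR)].sum(axis=1)
    zero = den <= 0
    if zero.any():
        for sid in percent.index[zero]:
            logger.warning("sample %s has zero Pinus+Pseudotsuga; openness undefined", sid)
    return (num / den.where(~zero)).rename("openness_ratio")


def biomass_series(
    populations: pd.DataFrame,
    body_mass_kg: dict[str, float] | None = None,
    interpolate: bool = True,
) -> pd.DataFrame:
    """Convert census counts to biomass and combine species by year.

    ``populations`` needs columns ``year``, ``species``, ``count``.  Each
    species' biomass (kg) = count x its average body mass.  Gaps within a
    species' observed span are linearly interpolated (never extrapolated
    beyond it).  Returns a frame indexed by year CE with one biomass column
    per species and ``total_biomass_kg``.
    """
    masses = dict(DEFAULT_BODY_MASS_KG if body_mass_kg is None else body_mass_kg)
    unknown = set(populations["species"]) - set(masses)
    if unknown:
        raise ValueError(f"no body mass for species {sorted(unknown)}; known: {sorted(masses)}")
    if (populations["count"] < 0).any():
        raise ValueError("population counts must be non-negative")
    years = np.arange(populations["year"].min(), populations["year"].max() + 1)
    out = pd.DataFrame(index=pd.Index(years, name="year"))
    for species, grp in populations.groupby("species"):
        grp = grp.sort_values("year")
        biomass = grp["count"].to_numpy(dtype=float) * masses[species]
        col = pd.Series(np.nan, index=out.index)
        col.loc[grp["year"].to_numpy()] = biomass
        if interpolate:
            span = (out.index >= grp["year"].min()) & (out.index <= grp["year"].max())
            col[span] = (
                col[span].interpolate(method="index", limit_area="inside")
            )
        out[f"biomass_{species}_kg"] = col
    out["total_biomass_kg"] = out.filter(like="biomass_").sum(axis=1, min_count=1)
    return out


def windowed_correlation(
    biomarker: pd.DataFrame,
    biomass: pd.DataFrame,
    window_ce: tuple[float, float],
    value_column: str,
    biomass_column: str = "total_biomass_kg",
    pairing: str = "interpolate",
) -> tuple[float, float, int]:
    """Pearson correlation of a sediment biomarker series with biomass.

    ``biomarker`` needs an ``age_cal_BP`` column plus ``value_column``; sample
    ages are converted to calendar years CE (1950 - age BP) and matched with
    the annual ``biomass`` frame, either by linear interpolation of biomass at
    each sample's (median-age) year (``pairing="interpolate"``) or by nearest
    observed year (``pairing="nearest"``).  Biomass is never extrapolated
    beyond its observed span.  Returns (r, two-sided p, n pairs); fewer than
    three pairs in the window is an error.
    """
    lo, hi = sorted(window_ce)
    year = 1950.0 - biomarker["age_cal_BP"].to_numpy(dtype=float)
    in_window = (year >= lo) & (year <= hi)
    y_years = year[in_window]
    y_values = biomarker.loc[in_window, value_column].to_numpy(dtype=float)
    bm = biomass[biomass_column].dropna()
    if pairing == "interpolate":
        matched = np.interp(
            y_years, bm.index.to_numpy(dtype=float), bm.to_numpy(), left=np.nan, right=np.nan
        )
    elif pairing == "nearest":
        idx = bm.index.to_numpy(dtype=float)
        pos = np.abs(idx[None, :] - y_years[:, None]).argmin(axis=1)
        matched = bm.to_numpy()[pos]
        matched[(y_years < idx.min()) | (y_years > idx.max())] = np.nan
    else:
        raise ValueError(f"pairing must be 'interpolate' or 'nearest', got {pairing!r}")
    ok = ~np.isnan(matched) & ~np.isnan(y_values)
    n = int(ok.sum())
    if n < 3:
        raise ValueError(
            f"need >=3 paired observations in window {window_ce}, got {n}"
        )
    r, p = stats.pearsonr(y_values[ok], matched[ok])
    return float(r), float(p), n


def mni_presence(levels: pd.DataFrame) -> pd.DataFrame:
    """Presence/absence matrix (stratum x species) from fossil MNI counts.

    ``levels`` needs columns ``stratum``, ``species``, ``mni`` and optionally
    ``age_cal_BP``.  Presence is MNI >= 1; absence is MNI = 0.
    """
    mni = levels["mni"].to_numpy()
    if (mni < 0).any() or np.any(mni != np.round(mni)):
        raise ValueError("MNI must be non-negative integers")
    present = levels.assign(present=levels["mni"] >= 1)
    matrix = present.pivot_table(
        index="stratum", columns="species", values="present", aggfunc="any", fill_value=False
    ).astype(bool)
    if "age_cal_BP" in levels.columns:
        ages = levels.groupby("stratum")["age_cal_BP"].first()
        matrix.insert(0, "age_cal_BP", ages)
    return matrix
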