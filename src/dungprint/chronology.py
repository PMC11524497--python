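"""Deterministic age-depth modelling, radiocarbon calibration and influx.

The age model is a piecewise-linear interpolant through the median ages of
dated control points (calendar markers, 210Pb ages, calibrated 14C dates,
event layers), with linear extrapolation beyond the terminal segments.  If the
median ages are not monotone in depth, they are first replaced by their
pool-adjacent-violators (isotonic) fit, which is logged.  This is a
transparent, reproducible stand-in for Bayesian accumulation modelling: it
reproduces every control age exactly and yields well-defined per-segment
sediment accumulation rates.

Conventions
-----------
* Ages are calendar years BP (before 1950 CE); negative ages denote post-1950
  deposition (year CE = 1950 - age BP).
* Deposition time (yr cm^-1) = dAge/dDepth on a segment; the sediment
  accumulation rate SAR (cm yr^-1) is its reciprocal.  Both are exposed to
  keep the two reciprocal conventions from being confused.
* Influx (= accumulation rate of a proxy) is
  concentration x dry bulk density x SAR; density defaults to 1 g cm^-3 with a
  logged unit caveat when not supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "AgeControlPoint",
    "AgeModel",
    "build_age_model",
    "calibrate_radiocarbon",
    "sar",
    "influx",
    "read_chronology_csv",
    "read_calibration_curve",
]

logger = logging.getLogger(__name__)

VALID_SOURCES = ("calendar", "pb210", "c14", "event")


@dataclass(frozen=True)
class AgeControlPoint:
    depth_cm: float
    age_cal_BP: float
    age_lo_2sigma: float | None = None
    age_hi_2sigma: float | None = None
    source: str = "calendar"

    def __post_init__(self) -> None:
        if self.source not in VALID_SOURCES:
            raise ValueError(f"source must be one of {VALID_SOURCES}, got {self.source!r}")
        if self.age_lo_2sigma is not None and self.age_hi_2sigma is not None:
            if not self.age_lo_2sigma <= self.age_cal_BP <= self.age_hi_2sigma:
                raise ValueError(
                    f"control point at {self.depth_cm} cm: need "
                    f"age_lo <= age <= age_hi, got "
                    f"({self.age_lo_2sigma}, {self.age_cal_BP}, {self.age_hi_2sigma})"
                )


@dataclass
class AgeModel:
    """Piecewise-linear depth -> age mapping through control points."""

    depths: np.ndarray
    ages: np.ndarray  # monotone non-decreasing, reproduces control ages
    points: list[AgeControlPoint] = field(default_factory=list)

    def age_at(self, depth) -> np.ndarray:
        """Interpolated (and linearly extrapolated) age at arbitrary depths."""
        d = np.atleast_1d(np.asarray(depth, dtype=float))
        age = np.interp(d, self.depths, self.ages)
        # np.interp clamps; replace the clamped ends with linear extrapolation.
        lo, hi = self.depths[0], self.depths[-1]
        below, above = d < lo, d > hi
        if below.any():
            slope = (self.ages[1] - self.ages[0]) / (self.depths[1] - self.depths[0])
            age[below] = self.ages[0] + slope * (d[below] - lo)
        if above.any():
            slope = (self.ages[-1] - self.ages[-2]) / (self.depths[-1] - self.depths[-2])
            age[above] = self.ages[-1] + slope * (d[above] - hi)
        return age if np.ndim(depth) else float(age[0])

    def segment_index(self, depth) -> np.ndarray:
        """Index i of the segment [depths[i], depths[i+1]] containing depth.

        Depths outside the model map to the terminal segments.
        """
        d = np.atleast_1d(np.asarray(depth, dtype=float))
        idx = np.searchsorted(self.depths, d, side="right") - 1
        return np.clip(idx, 0, len(self.depths) - 2)


def build_age_model(points: list[AgeControlPoint]) -> AgeModel:
    """Fit the deterministic age model through control-point median ages."""
    if len(points) < 2:
        raise ValueError(f"need >=2 control points, got {len(points)}")
    pts = sorted(points, key=lambda p: p.depth_cm)
    depths = np.array([p.depth_cm for p in pts], dtype=float)
    ages = np.array([p.age_cal_BP for p in pts], dtype=float)
    if np.any(np.diff(depths) == 0):
        raise ValueError("control point depths must be distinct")
    if np.any(np.diff(ages) < 0):
        from sklearn.isotonic import IsotonicRegression

        logger.warning(
            "control ages are not monotone in depth; replacing with the "
            "pool-adjacent-violators monotone fit"
        )
        ages = IsotonicRegression(increasing=True).fit_transform(depths, ages)
    return AgeModel(depths=depths, ages=ages, points=pts)


def calibrate_radiocarbon(
    c14_age: float,
    c14_error: float,
    curve_table: pd.DataFrame,
) -> tuple[float, tuple[float, float]]:
    """Calibrate a radiocarbon date against a user-supplied curve.

    ``curve_table`` must have columns ``cal_BP``, ``c14_BP``, ``sigma``
    (the standard calibration-curve distribution layout).  The posterior over
    calendar age on the curve's grid is proportional to the normal density of
    the measured 14C age at the curve's 14C age, with variance
    ``c14_error^2 + sigma^2``.  Returns the posterior median and the highest
    posterior density 95.4% interval.
    """
    curve = curve_table.sort_values("cal_BP").reset_index(drop=True)
    mu = curve["c14_BP"].to_numpy(dtype=float)
    sig = curve["sigma"].to_numpy(dtype=float)
    cal = curve["cal_BP"].to_numpy(dtype=float)
    tol = 5.0 * np.sqrt(c14_error**2 + sig.max() ** 2)
    if c14_age < mu.min() - tol or c14_age > mu.max() + tol:
        raise ValueError(
            f"date {c14_age} +/- {c14_error} outside calibration-curve coverage "
            f"[{mu.min()}, {mu.max()}] (+/- 5 sigma)"
        )
    var = c14_error**2 + sig**2
    logdens = -0.5 * (c14_age - mu) ** 2 / var - 0.5 * np.log(var)
    dens = np.exp(logdens - logdens.max())
    # Integrate on the (possibly non-uniform) calendar grid.
    w = np.gradient(cal)
    mass = dens * np.abs(w)
    total = mass.sum()
    if total <= 0:
        raise ValueError("date outside calibration-curve coverage")
    prob = mass / total
    cdf = np.cumsum(prob)
    median = float(np.interp(0.5, cdf, cal))
    # Highest-density 95.4% region: include grid points by descending density.
    order = np.argsort(dens)[::-1]
    included = order[: int(np.searchsorted(np.cumsum(prob[order]), 0.954)) + 1]
    lo, hi = float(cal[included].min()), float(cal[included].max())
    return median, (lo, hi)


def sar(age_model: AgeModel, depths) -> pd.DataFrame:
    """Per-depth sediment accumulation rate and deposition time.

    Each sample takes the rate of the age-model segment containing it.
    A segment with zero age change is rejected (instantaneous deposition has
    no defined rate).
    """
    d = np.atleast_1d(np.asarray(depths, dtype=float))
    if len(np.unique(age_model.depths)) < 2:
        raise ValueError("age model needs >=2 distinct depths")
    seg = age_model.segment_index(d)
    d_age = np.diff(age_model.ages)
    d_depth = np.diff(age_model.depths)
    if np.any(d_age[np.unique(seg)] == 0):
        bad = [int(i) for i in np.unique(seg) if d_age[i] == 0]
        raise ValueError(
            f"zero age change on segment(s) {bad}: deposition time undefined "
            "(non-physical instantaneous deposition)"
        )
    dep_time = d_age[seg] / d_depth[seg]  # yr per cm
    return pd.DataFrame(
        {
            "depth_cm": d,
            "age_cal_BP": age_model.age_at(d),
            "deposition_time_yr_per_cm": dep_time,
            "SAR_cm_per_yr": 1.0 / dep_time,
        }
    )


def influx(
    concentrations: pd.DataFrame,
    depths: pd.Series,
    age_model: AgeModel,
    dry_bulk_density: float | pd.Series | None = None,
) -> pd.DataFrame:
    """Convert concentrations to influxes over the age model.

    ``concentrations`` is samples x compounds (any concentration unit C);
    influx is C x cm^-2 x yr^-1 when a density (g cm^-3) is given.  Without a
    density, influx = concentration x SAR with a logged unit caveat (density
    treated as 1 g cm^-3).

    Returns a frame with depth, age, SAR, per-compound influx columns
    (``influx_<compound>``) and — when all four zoostanols are present —
    ``influx_total_zoostanols`` (their sum).
    """
    if (concentrations.to_numpy(dtype=float) < 0).any():
        raise ValueError("negative concentrations")
    depths = depths.reindex(concentrations.index)
    rates = sar(age_model, depths.to_numpy())
    rates.index = concentrations.index
    if dry_bulk_density is None:
        logger.warning(
            "no dry bulk density supplied; influx computed as concentration x SAR "
            "(density 1 g cm^-3 assumed, units are per-gram not per-cm^2)"
        )
        density = 1.0
    elif isinstance(dry_bulk_density, pd.Series):
        density = dry_bulk_density.reindex(concentrations.index).to_numpy()
    else:
        density = float(dry_bulk_density)
    out = rates.copy()
    sar_col = rates["SAR_cm_per_yr"].to_numpy()
    for comp in concentrations.columns:
        out[f"influx_{comp}"] = concentrations[comp].to_numpy() * density * sar_col
    from .registry import ZOOSTANOLS

    if all(z in concentrations.columns for z in ZOOSTANOLS):
        out["influx_total_zoostanols"] = sum(
            out[f"influx_{z}"] for z in ZOOSTANOLS
        )
    return out


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def read_chronology_csv(path: str | Path) -> list[AgeControlPoint]:
    """Read control points: columns depth_cm, age_calBP, age_lo, age_hi, source."""
    df = pd.read_csv(path)
    required = {"depth_cm", "age_calBP"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: chronology CSV needs columns {sorted(required)}")
    points = []
    for _, row in df.iterrows():
        points.append(
            AgeControlPoint(
                depth_cm=float(row["depth_cm"]),
                age_cal_BP=float(row["age_calBP"]),
                age_lo_2sigma=float(row["age_lo"]) if "age_lo" in df and pd.notna(row.get("age_lo")) else None,
                age_hi_2sigma=float(row["age_hi"]) if "age_hi" in df and pd.notna(row.get("age_hi")) else None,
                source=str(row["source"]) if "source" in df and pd.notna(row.get("source")) else "calendar",
            )
        )
    return points


def read_calibration_curve(path: str | Path) -> pd.DataFrame:
    """Read a 3-column calibration curve (cal BP, 14C BP, sigma).

    Accepts comma or whitespace separation, with or without a header, matching
    the standard curve distribution layout.
    """
    df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    if isinstance(df.iloc[0, 0], str):  # header row present
        df = df.iloc[1:].reset_index(drop=True)
    df = df.iloc[:, :3].astype(float)
    df.columns = ["cal_BP", "c14_BP", "sigma"]
    return df
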