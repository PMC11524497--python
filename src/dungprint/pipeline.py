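"""Run configuration, input validation and the end-to-end pipeline.

A run is described by a plain-text YAML config naming the input CSVs and the
analysis options; :func:`run_pipeline` executes whichever stages the inputs
support (attribution, influx, charcoal, pollen, correlation) and writes each
result as CSV plus a JSON manifest recording the config hash, seeds and
package version, so that reruns with identical config reproduce identical
numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .charcoal_fire import char_from_counts, background, detect_peaks, fire_return_interval
from .chronology import build_age_model, influx, read_chronology_csv
from .paleoecology import biomass_series, openness_ratio, pollen_percentages, windowed_correlation
from .registry import ZOOSTANOLS
from .source_attribution import attribute_sediments, fit_pca, hcpc_cluster
from .steroid_core import read_steroid_csv, zoostanol_profiles

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "validate_inputs"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage}: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and options for one reproducible pipeline run."""

    output_dir: str = "dungprint_out"
    dung_csv: str | None = None
    sediment_csv: str | None = None
    chronology_csv: str | None = None
    charcoal_csv: str | None = None
    pollen_csv: str | None = None
    taxon_groups: dict[str, str] = field(default_factory=dict)
    population_csv: str | None = None
    # ordination / clustering
    standardize: bool = True
    n_components: int = 4
    k: int | None = 3
    consolidate: bool = False
    # charcoal
    charcoal_window_yr: float = 500.0
    charcoal_percentile: float = 0.99
    # correlation windows (year CE) and biomarker column
    correlation_windows: list[tuple[float, float]] = field(
        default_factory=lambda: [(1920, 1970), (1971, 2020)]
    )
    correlation_compound: str = "lithocholic acid"
    dry_bulk_density: float | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "correlation_windows" in raw:
            raw["correlation_windows"] = [tuple(w) for w in raw["correlation_windows"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["correlation_windows"] = [list(w) for w in self.correlation_windows]
        return d

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()


def _require(config: RunConfig, stage: str, *names: str) -> None:
    for name in names:
        if getattr(config, name) is None:
            raise PipelineError(stage, f"config lacks required input {name!r}")


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages the config supports; return the result bundle.

    Outputs written under ``config.output_dir``: ``attribution.csv``,
    ``influx.csv``, ``charcoal.csv`` + ``episodes.csv``, ``pollen_percent.csv``
    + ``openness.csv``, ``correlations.csv`` and ``manifest.json``.  Any stage
    error aborts with the stage name.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    outputs: dict[str, str] = {}

    age_model = None
    if config.chronology_csv:
        try:
            age_model = build_age_model(read_chronology_csv(config.chronology_csv))
        except Exception as exc:  # noqa: BLE001 - stage context re-raise
            raise PipelineError("chronology", str(exc)) from exc

    sediment = None
    if config.sediment_csv:
        sediment = read_steroid_csv(config.sediment_csv, units="ng_per_g")

    if config.dung_csv and sediment is not None:
        try:
            dung = read_steroid_csv(config.dung_csv, units="ug_per_g")
            profiles = zoostanol_profiles(dung)
            model = fit_pca(profiles, config.n_components, config.standardize)
            clusters = hcpc_cluster(model.training_scores, config.k, config.consolidate)
            attribution = attribute_sediments(
                model,
                clusters,
                zoostanol_profiles(sediment),
                age_model=age_model,
                depths=sediment.meta["depth_cm"],
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("steroid_core/source_attribution", str(exc)) from exc
        attribution.index.name = "sample_id"
        path = out_dir / "attribution.csv"
        attribution.to_csv(path)
        outputs["attribution"] = str(path)
        results["attribution"] = attribution
        results["cluster_assignments"] = clusters.assignments

    if sediment is not None and age_model is not None:
        try:
            zoo_cols = [z for z in ZOOSTANOLS if z in sediment.values.columns]
            flux = influx(
                sediment.values[zoo_cols],
                sediment.meta["depth_cm"],
                age_model,
                config.dry_bulk_density,
            )
        except Exception as exc:
            raise PipelineError("chronology/influx", str(exc)) from exc
        flux.index.name = "sample_id"
        path = out_dir / "influx.csv"
        flux.to_csv(path)
        outputs["influx"] = str(path)
        results["influx"] = flux

    if config.charcoal_csv and age_model is not None:
        try:
            counts = pd.read_csv(config.charcoal_csv)
            series = char_from_counts(counts, age_model)
            background(series, config.charcoal_window_yr)
            episodes = detect_peaks(
                series,
                percentile=config.charcoal_percentile,
                window_yr=config.charcoal_window_yr,
                seed=config.seed,
            )
        except Exception as exc:
            raise PipelineError("charcoal_fire", str(exc)) from exc
        path = out_dir / "charcoal.csv"
        series.resampled.to_csv(path, index=False)
        outputs["charcoal"] = str(path)
        ep_path = out_dir / "episodes.csv"
        episodes.to_csv(ep_path, index=False)
        outputs["episodes"] = str(ep_path)
        results["charcoal"] = series
        results["episodes"] = episodes
        results["mean_fri_yr"] = fire_return_interval(episodes)

    if config.pollen_csv:
        try:
            pollen = pd.read_csv(config.pollen_csv, index_col=0)
            pct = pollen_percentages(pollen, config.taxon_groups)["percent"]
            ratio = openness_ratio(pct)
        except Exception as exc:
            raise PipelineError("paleoecology/pollen", str(exc)) from exc
        path = out_dir / "pollen_percent.csv"
        pct.to_csv(path)
        outputs["pollen_percent"] = str(path)
        ratio_path = out_dir / "openness.csv"
        ratio.to_csv(ratio_path)
        outputs["openness"] = str(ratio_path)
        results["pollen_percent"] = pct
        results["openness"] = ratio

    if config.population_csv and "influx" in results:
        try:
            populations = pd.read_csv(config.population_csv)
            biomass = biomass_series(populations)
            conc_col = config.correlation_compound
            if sediment is not None and conc_col in sediment.values.columns:
                marker = pd.DataFrame(
                    {
                        "age_cal_BP": results["influx"]["age_cal_BP"],
                        "value": sediment.values[conc_col],
                    }
                )
            else:
                marker = pd.DataFrame(
                    {
                        "age_cal_BP": results["influx"]["age_cal_BP"],
                        "value": results["influx"]["influx_total_zoostanols"],
                    }
                )
            rows = []
            for window in config.correlation_windows:
                try:
                    r, p, n = windowed_correlation(marker, biomass, window, "value")
                    rows.append(
                        {"window_start_CE": window[0], "window_end_CE": window[1], "r": r, "p": p, "n": n}
                    )
                except ValueError as exc:
                    logger.warning("correlation window %s skipped: %s", window, exc)
            correlations = pd.DataFrame(rows)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("paleoecology/correlation", str(exc)) from exc
        path = out_dir / "correlations.csv"
        correlations.to_csv(path, index=False)
        outputs["correlations"] = str(path)
        results["correlations"] = correlations

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "config_sha256": config.content_hash(),
        "seed": config.seed,
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    return results


def validate_inputs(paths: dict[str, str]) -> pd.DataFrame:
    """Schema-check input files; returns a machine-readable pass/fail report.

    ``paths`` maps kind -> file path for kinds ``dung``, ``sediment``,
    ``chronology``, ``charcoal``, ``pollen``, ``population``.  Each check row
    has columns file, check, status (pass|fail|warn) and detail.
    """
    rows: list[dict] = []

    def add(file: str, check: str, status: str, detail: str = "") -> None:
        rows.append({"file": file, "check": check, "status": status, "detail": detail})

    for kind, path in paths.items():
        if not Path(path).exists():
            add(path, "exists", "fail", "file not found")
            continue
        add(path, "exists", "pass")
        try:
            if kind in ("dung", "sediment"):
                table = read_steroid_csv(path)
                add(path, "steroid_schema", "pass")
                neg = (table.values < 0).any()
                if neg.any():
                    col = neg[neg].index[0]
                    row_id = table.values.index[(table.values[col] < 0)][0]
                    add(path, "non_negative", "fail", f"row {row_id}, column {col}")
                else:
                    add(path, "non_negative", "pass")
            elif kind == "chronology":
                points = read_chronology_csv(path)
                add(path, "chronology_schema", "pass")
                ages = [p.age_cal_BP for p in sorted(points, key=lambda p: p.depth_cm)]
                if any(b < a for a, b in zip(ages, ages[1:])):
                    add(
                        path,
                        "monotone_medians",
                        "warn",
                        "median ages not monotone in depth; monotone fit will apply",
                    )
                else:
                    add(path, "monotone_medians", "pass")
            elif kind == "charcoal":
                df = pd.read_csv(path)
                need = {"depth_top", "depth_bot", "volume_cm3", "count"}
                if need <= set(df.columns):
                    add(path, "charcoal_schema", "pass")
                    if (df["volume_cm3"] <= 0).any():
                        add(path, "positive_volume", "fail", "non-positive sample volume")
                    else:
                        add(path, "positive_volume", "pass")
                else:
                    add(path, "charcoal_schema", "fail", f"missing columns {sorted(need - set(df.columns))}")
            elif kind == "pollen":
                df = pd.read_csv(path, index_col=0)
                arr = df.to_numpy(dtype=float)
                if (arr < 0).any():
                    i, j = np.argwhere(arr < 0)[0]
                    add(path, "non_negative_counts", "fail", f"row {df.index[i]}, column {df.columns[j]}")
                else:
                    add(path, "non_negative_counts", "pass")
            elif kind == "population":
                df = pd.read_csv(path)
                need = {"year", "species", "count"}
                if need <= set(df.columns):
                    add(path, "population_schema", "pass")
                else:
                    add(path, "population_schema", "fail", f"missing columns {sorted(need - set(df.columns))}")
            else:
                add(path, "known_kind", "fail", f"unknown input kind {kind!r}")
        except Exception as exc:  # noqa: BLE001 - report, don't crash validation
            add(path, f"{kind}_schema", "fail", str(exc))
    return pd.DataFrame(rows, columns=["file", "check", "status", "detail"])
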