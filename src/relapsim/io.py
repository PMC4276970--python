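"""CSV / config I/O, run manifests, and the end-to-end pipeline driver.

All tabular interchange is plain CSV.  Survival tables use the schema
``patient_id, time_months, event[, group]`` with times as float months
(6 decimal places on write) and events as 0/1.  Configuration files are
YAML mirroring :class:`~relapsim.cohort.SimConfig`.  Every pipeline run
writes a JSON manifest recording the command, config hash, master seed
and outputs, so deterministic stages are byte-reproducible.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibrate import TargetCurves, fit_mixture
from .cohort import (
    GroupConfig,
    GroupLabel,
    SimConfig,
    simulate_cohort,
)
from .growth import GrowthRateDistribution
from .hazard import (
    BinnedHazard,
    SmoothedHazard,
    SurvivalDataset,
    discrete_hazard,
    kernel_smooth,
)
from .peaks import RobustnessReport, robustness_scan
from .synthetic import SyntheticSpec

__all__ = [
    "SchemaError",
    "read_survival_csv",
    "write_survival_csv",
    "write_hazard_csv",
    "write_peaks_csv",
    "read_target_csv",
    "load_sim_config",
    "save_sim_config",
    "load_synthetic_spec",
    "RunManifest",
    "run_pipeline",
]

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """Input file does not match the documented schema."""


def read_survival_csv(path) -> SurvivalDataset:
    """Read a survival table, validating schema and row contents.

    Rows with non-positive or unparsable times are reported with their
    (0-based, data-row) indices.
    """
    df = pd.read_csv(path)
    required = {"patient_id", "time_months", "event"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing required columns {sorted(missing)}")
    times = pd.to_numeric(df["time_months"], errors="coerce")
    events = pd.to_numeric(df["event"], errors="coerce")
    bad = df.index[times.isna() | events.isna() | (times <= 0)].tolist()
    if bad:
        raise SchemaError(
            f"{path}: invalid time/event values in rows {bad} "
            "(times must be positive numbers, events 0/1)"
        )
    if not events.isin([0, 1]).all():
        bad = df.index[~events.isin([0, 1])].tolist()
        raise SchemaError(f"{path}: event must be 0/1, offending rows {bad}")
    labels = df["group"].to_numpy() if "group" in df.columns else None
    return SurvivalDataset(
        times=times.to_numpy(float), events=events.to_numpy(bool), labels=labels
    )


def write_survival_csv(data: SurvivalDataset, path) -> None:
    df = data.to_dataframe()
    df["time_months"] = df["time_months"].map(lambda t: f"{t:.6f}")
    df.to_csv(path, index=False)


def write_hazard_csv(
    binned: BinnedHazard, path, smoothed: Optional[SmoothedHazard] = None
) -> None:
    df = binned.to_dataframe()
    if smoothed is not None:
        df["smoothed"] = smoothed.values
    df.to_csv(path, index=False)


def write_peaks_csv(report: RobustnessReport, path) -> None:
    """One row per setting per peak, plus stable-peak summary rows."""
    df = report.to_dataframe()
    stable = pd.DataFrame(
        {
            "method": "stable",
            "peak_time": report.stable_peaks,
            "prominence": np.nan,
            "peak_height": np.nan,
            "bin_width": np.nan,
            "bandwidth": np.nan,
            "stable_fraction": report.stable_fractions,
        }
    )
    pd.concat([df, stable], ignore_index=True).to_csv(path, index=False)


def read_target_csv(path) -> TargetCurves:
    """Read a calibration target.

    Accepts either a hazard table with columns ``bin_start, bin_end,
    hazard`` (optional ``n_at_risk``) or a DFS table with columns
    ``time_months, dfs``.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    if {"bin_start", "bin_end", "hazard"} <= cols:
        edges = np.concatenate(
            [df["bin_start"].to_numpy(float), [float(df["bin_end"].iloc[-1])]]
        )
        widths = np.diff(edges)
        n_at_risk = (
            df["n_at_risk"].to_numpy(float) if "n_at_risk" in cols else None
        )
        binned = BinnedHazard(
            bin_width=float(widths[0]),
            edges=edges,
            n_at_risk=n_at_risk,
            n_events=None,
            hazard=df["hazard"].to_numpy(float),
        )
        return TargetCurves(hazard=binned)
    if {"time_months", "dfs"} <= cols:
        return TargetCurves(
            dfs_times=df["time_months"].to_numpy(float),
            dfs_values=df["dfs"].to_numpy(float),
        )
    raise SchemaError(
        f"{path}: expected columns (bin_start, bin_end, hazard) or "
        "(time_months, dfs)"
    )


# --- configuration ---------------------------------------------------------

def _config_to_mapping(config: SimConfig) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "n_patients": config.n_patients,
        "horizon": config.horizon,
        "seed": config.seed,
        "censor_rate": config.censor_rate,
        "growth": {
            "median_a": config.growth.median_a,
            "sigma_log": config.growth.sigma_log,
        },
        "thresholds": {
            "avascular_limit": config.avascular_limit,
            "detection_size": config.detection_size,
            "n_inf": config.n_inf,
        },
        "groups": {
            g.label.value: {
                "weight": g.weight,
                "rate_switch": g.rate_switch,
                "switch_shape": g.switch_shape,
                "rate_exit_dormancy": g.rate_exit_dormancy,
                "exit_shape": g.exit_shape,
            }
            for g in config.groups
        },
    }


def save_sim_config(config: SimConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(_config_to_mapping(config), sort_keys=False)
    )


def load_sim_config(path) -> SimConfig:
    raw = yaml.safe_load(Path(path).read_text())
    major = int(raw.get("schema_version", SCHEMA_VERSION))
    if major > SCHEMA_VERSION:
        raise SchemaError(
            f"{path}: config schema version {major} is newer than supported "
            f"({SCHEMA_VERSION})"
        )
    thresholds = raw.get("thresholds", {})
    groups = []
    for label, spec in raw["groups"].items():
        groups.append(
            GroupConfig(
                label=GroupLabel(label),
                weight=float(spec["weight"]),
                rate_switch=float(spec.get("rate_switch", 0.0)),
                switch_shape=int(spec.get("switch_shape", 1)),
                rate_exit_dormancy=float(spec.get("rate_exit_dormancy", 0.0)),
                exit_shape=int(spec.get("exit_shape", 1)),
            )
        )
    return SimConfig(
        n_patients=int(raw["n_patients"]),
        groups=tuple(groups),
        growth=GrowthRateDistribution(
            median_a=float(raw["growth"]["median_a"]),
            sigma_log=float(raw["growth"].get("sigma_log", 0.0)),
        ),
        horizon=float(raw.get("horizon", 120.0)),
        avascular_limit=float(thresholds.get("avascular_limit", 1e5)),
        detection_size=float(thresholds.get("detection_size", 1e9)),
        n_inf=float(thresholds.get("n_inf", 1e12)),
        censor_rate=float(raw.get("censor_rate", 0.0)),
        seed=int(raw.get("seed", 0)),
    )


def load_synthetic_spec(path) -> SyntheticSpec:
    raw = yaml.safe_load(Path(path).read_text())
    comps = tuple(
        (float(c["weight"]), float(c["location"]), float(c["log_spread"]))
        for c in raw["components"]
    )
    return SyntheticSpec(
        n=int(raw["n"]),
        cure_fraction=float(raw["cure_fraction"]),
        components=comps,
        censor_rate=float(raw.get("censor_rate", 0.0)),
        horizon=float(raw.get("horizon", 120.0)),
        seed=int(raw.get("seed", 0)),
    )


# --- manifest and pipeline -------------------------------------------------

@dataclass
class RunManifest:
    command: str
    config_hash: str
    master_seed: int
    inputs: Dict[str, str]
    outputs: Dict[str, str]
    package_version: str = __version__
    timestamp: str = ""
    status: str = "ok"

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _hash_config(config: SimConfig) -> str:
    text = yaml.safe_dump(_config_to_mapping(config), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def run_pipeline(
    config: SimConfig,
    outdir,
    bin_width: float = 3.0,
    bandwidths=(4.5, 6.0, 9.0),
    target: Optional[TargetCurves] = None,
    target_path: Optional[str] = None,
) -> Dict[str, str]:
    """Simulate -> hazard -> smooth -> peaks (-> calibrate), with manifest.

    Returns a mapping of artifact names to file paths.  Any stage failure
    is recorded in the manifest with ``status`` set before the exception
    propagates.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    outputs: Dict[str, str] = {}
    manifest = RunManifest(
        command="run",
        config_hash=_hash_config(config),
        master_seed=config.seed,
        inputs={"target": target_path} if target_path else {},
        outputs=outputs,
        timestamp=datetime.datetime.now(datetime.timezone.utc).isoformat(),
    )
    try:
        records = simulate_cohort(config)
        data = SurvivalDataset.from_records(records)
        cohort_path = outdir / "cohort.csv"
        write_survival_csv(data, cohort_path)
        outputs["cohort"] = str(cohort_path)

        binned = discrete_hazard(data, bin_width)
        smoothed = kernel_smooth(binned, 2.0 * bin_width)
        hazard_path = outdir / "hazard.csv"
        write_hazard_csv(binned, hazard_path, smoothed)
        outputs["hazard"] = str(hazard_path)

        report = robustness_scan(
            data, bin_widths=(bin_width,), bandwidths=tuple(bandwidths)
        )
        peaks_path = outdir / "peaks.csv"
        write_peaks_csv(report, peaks_path)
        outputs["peaks"] = str(peaks_path)

        if target is not None:
            result = fit_mixture(target, config)
            calib_path = outdir / "calibration.csv"
            result.to_dataframe().to_csv(calib_path, index=False)
            fitted = config.with_weights(
                [result.weights[g.label.value] for g in config.groups]
            )
            fitted_path = outdir / "fitted_config.yaml"
            save_sim_config(fitted, fitted_path)
            outputs["calibration"] = str(calib_path)
            outputs["fitted_config"] = str(fitted_path)
    except Exception:
        manifest.status = "failed"
        manifest.write(outdir / "manifest.json")
        raise
    manifest.write(outdir / "manifest.json")
    outputs["manifest"] = str(outdir / "manifest.json")
    return outputs
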