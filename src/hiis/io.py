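"""CSV/YAML interchange and run configuration.

Formats (UTF-8, LF, '.' decimal separator, times in hours from surgery
onset):

* clinical series CSV: columns ``branch, observable, time_h, median, mae``
* trajectory CSV: long format ``time_h, variable, value_internal,
  value_clinical`` (clinical value only where a clinical unit exists:
  AP species in IU/L, cytokines in pg/mL)
* parameters: the YAML written by :meth:`hiis.model.ModelParameters.to_yaml`
* run config: flat YAML validated against a known key set
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import dosing
from .calibrate import OBSERVABLES, ClinicalSeries
from .model import STATE_NAMES, ModelError
from .simulate import Trajectory

__all__ = [
    "read_clinical_series",
    "write_clinical_series",
    "write_trajectory",
    "read_trajectory",
    "Config",
    "load_config",
]

log = logging.getLogger(__name__)

SERIES_COLUMNS = ["branch", "observable", "time_h", "median", "mae"]
TRAJECTORY_COLUMNS = ["time_h", "variable", "value_internal", "value_clinical"]

#: clinical conversion per state variable (divide internal by this factor)
_CLINICAL_FACTOR = {
    "ap_endo_blood": dosing.AP_IU_PER_L_TO_MOLEC_MM3,
    "ap_endo_tissue": dosing.AP_IU_PER_L_TO_MOLEC_MM3,
    "ap_supp_blood": dosing.AP_IU_PER_L_TO_MOLEC_MM3,
    "ap_supp_tissue": dosing.AP_IU_PER_L_TO_MOLEC_MM3,
    "ch": dosing.CYTOKINE_PG_ML_TO_MOLEC_MM3,
    "ach": dosing.CYTOKINE_PG_ML_TO_MOLEC_MM3,
}


def read_clinical_series(path: str | Path) -> list[ClinicalSeries]:
    """Load and validate a clinical-series CSV.

    Rejects schema mismatches, unknown observables, non-positive MAEs,
    negative values and unsorted times with line-numbered messages (line 1
    is the header).
    """
    path = Path(path)
    if not path.exists():
        raise ModelError(f"no such file: {path}")
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ModelError(f"{path}: file is empty (no header)") from None
    if list(df.columns) != SERIES_COLUMNS:
        raise ModelError(
            f"{path}: header mismatch; expected {SERIES_COLUMNS}, got {list(df.columns)}"
        )
    if df.empty:
        raise ModelError(f"{path}: no data rows")
    problems = []
    for i, row in df.iterrows():
        line = i + 2
        if row["observable"] not in OBSERVABLES:
            problems.append(f"line {line}: unknown observable {row['observable']!r}")
        if not np.isfinite(row["time_h"]) or row["time_h"] < 0:
            problems.append(f"line {line}: invalid time {row['time_h']!r}")
        if not np.isfinite(row["median"]) or row["median"] < 0:
            problems.append(f"line {line}: negative or non-finite median {row['median']!r}")
        if not np.isfinite(row["mae"]) or row["mae"] <= 0:
            problems.append(f"line {line}: mae must be > 0, got {row['mae']!r}")
    if problems:
        raise ModelError(f"{path}: " + "; ".join(problems))
    out = []
    for (branch, obs), grp in df.groupby(["branch", "observable"], sort=True):
        times = grp["time_h"].to_numpy()
        if np.any(np.diff(times) <= 0):
            first_bad = int(grp.index[np.argmax(np.diff(times) <= 0) + 1]) + 2
            raise ModelError(
                f"{path}: line {first_bad}: times not strictly increasing "
                f"within series {branch}/{obs}"
            )
        out.append(
            ClinicalSeries(
                branch=branch,
                observable=obs,
                points=tuple(zip(times, grp["median"].to_numpy(), grp["mae"].to_numpy())),
            )
        )
    return out


def write_clinical_series(series_list: list[ClinicalSeries], path: str | Path) -> None:
    rows = [
        {"branch": s.branch, "observable": s.observable, "time_h": t, "median": m, "mae": e}
        for s in series_list
        for (t, m, e) in s.points
    ]
    pd.DataFrame(rows, columns=SERIES_COLUMNS).to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n"
    )


def write_trajectory(trajectory: Trajectory, path: str | Path) -> None:
    """Long-format trajectory CSV, 10 significant digits, variables in
    canonical state order."""
    frames = []
    for name in STATE_NAMES:
        values = trajectory.get(name)
        factor = _CLINICAL_FACTOR.get(name)
        frames.append(
            pd.DataFrame(
                {
                    "time_h": trajectory.times,
                    "variable": name,
                    "value_internal": values,
                    "value_clinical": values / factor if factor else np.nan,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format="%.10g", lineterminator="\n"
    )


def read_trajectory(path: str | Path) -> pd.DataFrame:
    """Read a trajectory CSV back as a tidy DataFrame (schema-checked)."""
    df = pd.read_csv(path)
    if list(df.columns) != TRAJECTORY_COLUMNS:
        raise ModelError(
            f"{path}: header mismatch; expected {TRAJECTORY_COLUMNS}, got {list(df.columns)}"
        )
    return df


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

_CONFIG_DEFAULTS: dict = {
    "parameters_file": None,      # YAML from ModelParameters.to_yaml; None = nominal
    "protocol": {
        "bolus_iu": 1000.0,
        "infusion_total_iu": 8000.0,
        "infusion_duration_h": 8.0,
        "scale": 1.0,
    },
    "horizon_h": 36.0,
    "seed": 42,
    "noise_frac": 0.25,
    "sample_times": [0.0, 0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 12.0, 24.0, 36.0],
    "insult_multiple": 1.0,
    "insult_center_h": 6.0,
    "insult_width_h": 1.0,
    "dose_scales": [1.0, 2.0, 3.0],
}

_PROTOCOL_KEYS = set(_CONFIG_DEFAULTS["protocol"])


@dataclass
class Config:
    """Validated run configuration with defaults applied."""

    parameters_file: str | None
    protocol: dict
    horizon_h: float
    seed: int
    noise_frac: float
    sample_times: list[float]
    insult_multiple: float
    insult_center_h: float
    insult_width_h: float
    dose_scales: list[float]

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in _CONFIG_DEFAULTS}


def load_config(path: str | Path | None) -> Config:
    """Load a YAML run config, apply defaults, reject unknown keys.

    ``None`` yields the pure-default configuration.  Every effective value
    is echoed to the log so the run is auditable.
    """
    raw = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ModelError(f"{path}: config must be a mapping")
        raw = loaded
    unknown = sorted(set(raw) - set(_CONFIG_DEFAULTS))
    bad_proto = sorted(set(raw.get("protocol", {}) or {}) - _PROTOCOL_KEYS)
    errors = []
    if unknown:
        errors.append(f"unknown key(s): {unknown}")
    if bad_proto:
        errors.append(f"unknown protocol key(s): {bad_proto}")
    if errors:
        raise ModelError("invalid config: " + "; ".join(errors))
    merged = {**_CONFIG_DEFAULTS, **raw}
    merged["protocol"] = {**_CONFIG_DEFAULTS["protocol"], **(raw.get("protocol") or {})}
    cfg = Config(**merged)
    for key, value in cfg.as_dict().items():
        log.info("config: %s = %r", key, value)
    return cfg
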