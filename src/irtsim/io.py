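"""Delimited-text readers and writers with provenance headers.

Every output file starts with ``#``-prefixed header lines recording the
package version, the master seed and a hash of the configuration, so any
table can be traced back to the run that produced it.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import Measurement
from .outcomes import DoseVolumeHistogram

__all__ = [
    "write_table",
    "read_table",
    "read_measurements",
    "read_dvh",
    "header_meta",
]


def header_meta(seed: int, config_hash: str) -> dict[str, str]:
    return {
        "irtsim_version": __version__,
        "seed": str(seed),
        "config_hash": config_hash,
    }


def write_table(df: pd.DataFrame, path: str | Path, meta: dict[str, str]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for key, value in meta.items():
            fh.write(f"# {key}={value}\n")
        df.to_csv(fh, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_measurements(path: str | Path) -> dict[str, list[Measurement]]:
    """Measurement file with columns patient_id, day, volume_cm3."""
    df = read_table(path)
    required = {"patient_id", "day", "volume_cm3"}
    if not required.issubset(df.columns):
        raise ValueError(f"measurement file must have columns {sorted(required)}")
    if df.empty:
        raise ValueError("measurement file contains no rows")
    out: dict[str, list[Measurement]] = {}
    for i, row in df.iterrows():
        try:
            m = Measurement(day=float(row["day"]), volume=float(row["volume_cm3"]))
        except (TypeError, ValueError) as exc:
            raise ValueError(f"unparseable measurement at row {i}: {exc}") from exc
        out.setdefault(str(row["patient_id"]), []).append(m)
    for pid, ms in out.items():
        ms.sort(key=lambda m: m.day)
    return out


def read_dvh(path: str | Path) -> DoseVolumeHistogram:
    """DVH file with columns dose_gy, fractional_volume."""
    df = read_table(path)
    if not {"dose_gy", "fractional_volume"}.issubset(df.columns):
        raise ValueError("DVH file must have columns dose_gy, fractional_volume")
    return DoseVolumeHistogram(
        doses=tuple(df["dose_gy"].astype(float)),
        fractional_volumes=tuple(df["fractional_volume"].astype(float)),
    )
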