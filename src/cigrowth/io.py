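"""File formats: confluency CSV, trajectory CSV, plain-text lattice grids,
YAML/JSON configs, and JSON fit results.

CSV dialect is fixed: comma separator, '.' decimal point, UTF-8, header row
mandatory, numbers written with 12 significant digits so a write/read/write
round trip is byte-identical.
"""

from __future__ import annotations

import json
import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abm import Trajectory
from .fitting import ExperimentSet, FitResult

logger = logging.getLogger("cigrowth")

__all__ = [
    "read_timeseries_csv",
    "write_timeseries_csv",
    "write_trajectory_csv",
    "read_trajectory_csv",
    "save_grid_txt",
    "load_grid_txt",
    "load_config",
    "write_fit_results_json",
]

_MAX_CONFLUENCY = 1.05


def read_timeseries_csv(path: str | Path) -> ExperimentSet:
    """Read a confluency experiment CSV with required columns
    (cell_line, u0, time, confluency, replicate).

    Times are sorted within each series; confluency must lie in (0, 1.05],
    values in (1, 1.05] are clipped to 1 with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in ExperimentSet.REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    for col in ("u0", "time", "confluency"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    df["replicate"] = df["replicate"].astype(int)
    if df.empty:
        raise ValueError(f"{path}: no data rows")
    if (df["confluency"] <= 0).any() or (df["confluency"] > _MAX_CONFLUENCY).any():
        bad = df.loc[
            (df["confluency"] <= 0) | (df["confluency"] > _MAX_CONFLUENCY), "confluency"
        ]
        raise ValueError(
            f"{path}: confluency values outside (0, {_MAX_CONFLUENCY}]: "
            f"{bad.head().tolist()}"
        )
    over = df["confluency"] > 1.0
    if over.any():
        msg = f"{path}: clipped {int(over.sum())} confluency value(s) > 1 to 1.0"
        warnings.warn(msg)
        logger.warning(msg)
        df.loc[over, "confluency"] = 1.0
    df = df.sort_values(["cell_line", "u0", "replicate", "time"], kind="mergesort")
    return ExperimentSet(df.reset_index(drop=True))


def _fmt(x) -> str:
    return format(float(x), ".12g")


def write_timeseries_csv(exp: ExperimentSet, path: str | Path) -> None:
    """Write an ExperimentSet in the canonical column order with 12
    significant digits."""
    path = Path(path)
    df = exp.data[list(ExperimentSet.REQUIRED)]
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(ExperimentSet.REQUIRED) + "\n")
        for row in df.itertuples(index=False):
            fh.write(
                f"{row.cell_line},{_fmt(row.u0)},{int(row.replicate)},"
                f"{_fmt(row.time)},{_fmt(row.confluency)}\n"
            )


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="\n") as fh:
        fh.write("step,time,n,blocked,surface\n")
        for i in range(traj.times.size):
            fh.write(
                f"{i},{_fmt(traj.times[i])},{int(traj.n[i])},"
                f"{int(traj.blocked[i])},{int(traj.surface[i])}\n"
            )


def read_trajectory_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = ["step", "time", "n", "blocked", "surface"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing trajectory column(s) {missing}")
    return df


def save_grid_txt(grid: np.ndarray, path: str | Path) -> None:
    """Occupancy snapshot as plain text, one lattice row per line of 0/1."""
    np.savetxt(path, np.asarray(grid, dtype=np.uint8), fmt="%d", delimiter="")


def load_grid_txt(path: str | Path) -> np.ndarray:
    lines = Path(path).read_text().split()
    return np.array([[int(ch) for ch in row] for row in lines], dtype=np.uint8)


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON configuration file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def write_fit_results_json(
    fits: list[tuple[tuple, FitResult]] | list[FitResult],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    records = []
    for item in fits:
        if isinstance(item, FitResult):
            records.append(item.to_dict())
        else:
            key, fit = item
            rec = fit.to_dict()
            rec["cell_line"], rec["u0"], rec["replicate"] = (
                str(key[0]),
                float(key[1]),
                int(key[2]),
            )
            records.append(rec)
    payload = {"fits": records}
    if metadata:
        payload["metadata"] = metadata
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
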