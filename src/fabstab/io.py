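"""CSV/JSON interchange for umbrella windows, traces and cohort tables.

Window sets are stored as one CSV per window (columns step, time_ps, cv_nm)
plus a JSON manifest carrying the bias parameters, so externally produced
umbrella data in the same schema can enter the pipeline unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .descriptors import validate_trace
from .reweighting import UmbrellaWindow


def write_windows(windows: list[UmbrellaWindow], directory: str | Path,
                  dt_ps: float = 1.0, meta: dict | None = None) -> None:
    """One CSV per window plus a ``manifest.json``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"dt_ps": dt_ps, "windows": [], **(meta or {})}
    for w in windows:
        name = f"window_{w.index:03d}.csv"
        steps = np.arange(w.n_samples)
        pd.DataFrame({"step": steps, "time_ps": steps * dt_ps,
                      "cv_nm": w.samples}).to_csv(directory / name, index=False)
        manifest["windows"].append({
            "index": w.index, "file": name, "center_nm": w.center,
            "spring_kJmol_nm2": w.spring, "temperature_K": w.temperature,
            "n_discarded": w.n_discarded,
        })
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_windows(directory: str | Path) -> list[UmbrellaWindow]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    windows = []
    for rec in manifest["windows"]:
        df = pd.read_csv(directory / rec["file"])
        windows.append(UmbrellaWindow(
            index=rec["index"], center=rec["center_nm"],
            spring=rec["spring_kJmol_nm2"], temperature=rec["temperature_K"],
            samples=df["cv_nm"].to_numpy(), n_discarded=rec["n_discarded"]))
    return sorted(windows, key=lambda w: w.index)


def write_trace(trace: pd.DataFrame, path: str | Path) -> None:
    validate_trace(trace).to_csv(path, index=False)


def read_trace(path: str | Path) -> pd.DataFrame:
    return validate_trace(pd.read_csv(path))


def write_cohort(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_cohort(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = {"system_id", "true_depth", "tm"} - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns {sorted(missing)}")
    return df
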