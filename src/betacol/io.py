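"""Delimited-text input/output for simulation results.

Spike events are one line per action potential (time_ms, cell, population,
column); LFP-source currents and voltage traces are columnar time-series
files with a ``time_ms`` column; the run manifest (seed, config hash,
package version) is JSON.  The analysis layer accepts these files, so its
statistics can be applied to externally produced spike/LFP data with the
same layout.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .analysis import LFPTrace

__all__ = [
    "save_spikes",
    "load_spikes",
    "save_lfp",
    "load_lfp",
    "save_manifest",
    "save_result",
]


def save_spikes(spikes: pd.DataFrame, path) -> None:
    spikes.rename(columns={"time": "time_ms"}).to_csv(path, sep="\t", index=False)


def load_spikes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "time_ms" not in df.columns:
        raise ValueError(f"{path}: expected a 'time_ms' column")
    return df.rename(columns={"time_ms": "time"})


def save_lfp(sim, path) -> None:
    """Per-cell synaptic-current traces (LFP sources) as columns."""
    if sim.lfp is None:
        raise ValueError("no LFP sources recorded")
    t = np.arange(sim.lfp.shape[1]) * sim.lfp_dt
    cols = {"time_ms": t}
    for i, (cell, col) in enumerate(zip(sim.lfp_cells, sim.lfp_columns)):
        cols[f"cell{cell}_col{col}"] = sim.lfp[i]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_lfp(path, column: int | None = None) -> LFPTrace:
    """Summed LFP trace from a per-cell source file (optionally one column
    of the network only)."""
    df = pd.read_csv(path, sep="\t")
    t = df.pop("time_ms").to_numpy()
    if len(t) < 2:
        raise ValueError(f"{path}: trace too short")
    keep = [c for c in df.columns if column is None or c.endswith(f"_col{column}")]
    if not keep:
        raise ValueError(f"{path}: no trace columns for column {column}")
    return LFPTrace(values=df[keep].to_numpy().sum(axis=1), dt=float(t[1] - t[0]))


def save_manifest(sim, path, extra: dict | None = None) -> None:
    manifest = {
        "seed": sim.seed,
        "config_hash": sim.config_hash,
        "duration_ms": sim.duration,
        "dt_ms": sim.dt,
        "lfp_dt_ms": sim.lfp_dt,
        "n_spikes": int(len(sim.spikes)),
        "stimuli": sim.stimulus_log,
        "betacol_version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=2, default=str))


def save_result(sim, outdir, save_voltages: bool = False) -> Path:
    """Write spikes, LFP sources, optional voltages and the manifest."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    save_spikes(sim.spikes, out / "spikes.tsv")
    if sim.lfp is not None:
        save_lfp(sim, out / "lfp_sources.tsv")
    if save_voltages and sim.v is not None:
        t = np.arange(sim.v.shape[0]) * sim.v_dt
        df = pd.DataFrame(sim.v, columns=[
            f"{r.population}{r.cell}_{r.compartment}" for r in sim.comp_meta.itertuples()
        ])
        df.insert(0, "time_ms", t)
        df.to_csv(out / "voltages.tsv", sep="\t", index=False, float_format="%.5g")
    save_manifest(sim, out / "manifest.json")
    return out
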