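"""Plain-text trajectory/series files, window manifests, and ion tables.

Series files are whitespace-delimited with '#'-prefixed header lines of
``key = value`` metadata (column names, units, the step↔ns factor and the
seed), one row per frame.  A compact binary variant with the same schema is
available via ``.npz`` paths.  Window manifests (center, force constant,
series path) and GHK ion-condition tables are CSV, read with pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .ghk import GhkSetup, IonSpecies
from .wham import UmbrellaWindow

__all__ = [
    "write_series",
    "read_series",
    "write_window_manifest",
    "read_window_manifest",
    "read_ion_table",
    "write_pmf_csv",
]


def write_series(path, data: np.ndarray, meta: Optional[Dict] = None,
                 columns: Sequence[str] = ("xi",)) -> None:
    """Write a frame series; '.npz' suffix selects the binary variant."""
    path = Path(path)
    data = np.asarray(data, dtype=float)
    if data.ndim == 1:
        data = data[:, None]
    if data.shape[1] != len(columns):
        raise ValueError("column names do not match data width")
    meta = dict(meta or {})
    meta.setdefault("columns", " ".join(columns))
    if path.suffix == ".npz":
        np.savez_compressed(path, data=data,
                            meta=np.array([json.dumps(meta)]))
        return
    header = "\n".join(f"{k} = {v}" for k, v in meta.items())
    np.savetxt(path, data, header=header, fmt="%.8g")


def read_series(path) -> Tuple[np.ndarray, Dict[str, str]]:
    """Read a series file back as (data, metadata)."""
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as f:
            data = f["data"]
            meta = json.loads(str(f["meta"][0]))
        return data, meta
    meta: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            stripped = line.lstrip("#").strip()
            if "=" in stripped:
                k, v = stripped.split("=", 1)
                meta[k.strip()] = v.strip()
    data = np.loadtxt(path)
    if data.ndim == 1:
        data = data[:, None]
    return data, meta


def write_window_manifest(path, windows: Sequence[Tuple[float, float, str]]) -> None:
    """CSV manifest: one row (center, force_constant, series_path) per window."""
    pd.DataFrame(windows, columns=["center", "force_constant", "path"]).to_csv(
        path, index=False)


def read_window_manifest(
    path,
    n_equilibration_discard: int = 0,
    block_length: Optional[int] = None,
) -> List[UmbrellaWindow]:
    """Load umbrella windows listed in a CSV manifest; series paths are
    resolved relative to the manifest location."""
    path = Path(path)
    table = pd.read_csv(path)
    required = {"center", "force_constant", "path"}
    if not required.issubset(table.columns):
        raise ValueError(f"manifest must have columns {sorted(required)}")
    windows = []
    for row in table.itertuples(index=False):
        series_path = Path(row.path)
        if not series_path.is_absolute():
            series_path = path.parent / series_path
        data, _ = read_series(series_path)
        windows.append(UmbrellaWindow(
            center=float(row.center),
            force_constant=float(row.force_constant),
            samples=data[:, 0],
            n_equilibration_discard=n_equilibration_discard,
            block_length=block_length,
        ))
    return windows


def read_ion_table(path, temperature_k: float = 298.15) -> GhkSetup:
    """CSV with columns name, valence, conc_cytosolic, conc_luminal,
    permeability → GhkSetup."""
    table = pd.read_csv(path)
    species = tuple(
        IonSpecies(
            name=str(r["name"]),
            valence=int(r["valence"]),
            conc_cytosolic=float(r["conc_cytosolic"]),
            conc_luminal=float(r["conc_luminal"]),
            permeability=float(r.get("permeability", 1.0)),
        )
        for r in table.to_dict("records")
    )
    return GhkSetup(species=species, temperature_k=temperature_k)


def write_pmf_csv(path, profile, convergence_path=None) -> None:
    """PMF as CSV (xi, free_energy, sem, n_samples) plus an optional JSON
    convergence record."""
    table = pd.DataFrame({
        "xi": profile.xi,
        "free_energy": profile.free_energy,
        "sem": profile.error if profile.error is not None
               else np.full_like(profile.xi, np.nan),
        "n_samples": profile.n_samples if profile.n_samples is not None
                     else np.full_like(profile.xi, np.nan),
    })
    table.to_csv(path, index=False)
    if convergence_path and profile.convergence:
        rec = {
            "iterations": profile.convergence.iterations,
            "final_residual": profile.convergence.final_residual,
            "n_empty_bins": profile.convergence.n_empty_bins,
            "shift": profile.shift,
        }
        Path(convergence_path).write_text(json.dumps(rec, indent=2))
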