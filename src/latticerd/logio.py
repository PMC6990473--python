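"""Gather utilities for per-rank logger CSV files.

Each worker writes its own numbers/coordinates file during a run; these
helpers merge them into a single conventional CSV — summing counts per time
row for numbers, and converting integer voxel coordinates to real 3D
coordinates for the trajectory log.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import GatherError
from .lattice import LatticeConfig, to_real_array

__all__ = ["gather_numbers", "gather_coordinates"]


def _rank_files(out_dir, stem: str, n_workers: int) -> list[Path]:
    out_dir = Path(out_dir)
    files = [out_dir / f"{stem}_rank{r}.csv" for r in range(n_workers)]
    missing = [f.name for f in files if not f.exists()]
    if missing:
        raise GatherError(f"missing rank files: {missing}")
    return files


def gather_numbers(out_dir, n_workers: int, write_to=None) -> pd.DataFrame:
    """Sum per-rank species counts row-by-row into one CSV/DataFrame."""
    files = _rank_files(out_dir, "numbers", n_workers)
    dfs = [pd.read_csv(f) for f in files]
    t0 = dfs[0]["time"].to_numpy()
    for f, d in zip(files, dfs):
        if len(d) != len(dfs[0]) or not np.allclose(d["time"].to_numpy(), t0):
            raise GatherError(f"log times inconsistent in {f.name}")
    out = dfs[0].copy()
    for d in dfs[1:]:
        out.iloc[:, 1:] += d.iloc[:, 1:]
    if write_to is not None:
        out.to_csv(write_to, index=False)
    return out


def gather_coordinates(
    out_dir, n_workers: int, lattice: LatticeConfig, real: bool = True, write_to=None
) -> pd.DataFrame:
    """Concatenate per-rank trajectories; ids persist across subdomains."""
    files = _rank_files(out_dir, "coordinates", n_workers)
    df = pd.concat([pd.read_csv(f) for f in files], ignore_index=True)
    df = df.sort_values(["time", "id"], kind="stable").reset_index(drop=True)
    if real:
        xyz = to_real_array(df["i"], df["j"], df["k"], lattice.voxel_radius)
        df[["x", "y", "z"]] = xyz
    if write_to is not None:
        df.to_csv(write_to, index=False)
    return df
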