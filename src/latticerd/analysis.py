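"""Analysis references: mass-action ODE baseline, MSD / effective-D fitting.

The ODE integrator uses *effective* rates and serves as the well-mixed
comparison baseline for the stochastic lattice runs; the MSD routine fits an
effective diffusion coefficient through the 3D law MSD(t) = 6 D t.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import AnalysisError
from .model import CompiledModel, ModelConfig, compile_model

__all__ = ["ode_reference", "msd_analysis", "fit_effective_D"]


def ode_reference(cfg_or_compiled, y0: dict, t_grid, rtol=1e-8, atol=1e-10) -> pd.DataFrame:
    """Deterministic mass-action trajectories using effective rates.

    ``y0`` maps species names to concentrations in molecules/μm³; bimolecular
    rates are in μm³/s so propensities are k·c_a·c_b.  Returns one column per
    species over ``t_grid``.
    """
    compiled = (
        cfg_or_compiled
        if isinstance(cfg_or_compiled, CompiledModel)
        else compile_model(cfg_or_compiled)
    )
    names = compiled.species_names()
    n = len(names)
    y_init = np.zeros(n)
    for nm, v in y0.items():
        y_init[compiled.sid[nm]] = v
    channels = [
        (
            [compiled.sid[nm] for nm in ch.reactants],
            [compiled.sid[nm] for nm in ch.products],
            ch.k_eff,
        )
        for ch in compiled.channels
    ]

    def rhs(t, y):
        dy = np.zeros_like(y)
        for reac, prod, k in channels:
            rate = k
            for s in reac:
                rate *= y[s]
            for s in reac:
                dy[s] -= rate
            for s in prod:
                dy[s] += rate
        return dy

    t_grid = np.asarray(t_grid, dtype=float)
    sol = solve_ivp(
        rhs,
        (t_grid[0], t_grid[-1]),
        y_init,
        t_eval=t_grid,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise AnalysisError(f"ODE integration failed (rtol={rtol}, atol={atol}): {sol.message}")
    df = pd.DataFrame(sol.y.T, columns=names)
    df.insert(0, "time", sol.t)
    return df


def msd_analysis(coords: pd.DataFrame) -> pd.DataFrame:
    """Ensemble mean-squared displacement from a (real-coordinate) trajectory log.

    Expects columns time, id, x, y, z; displacement is measured from each
    molecule's position at the earliest log time.
    """
    required = {"time", "id", "x", "y", "z"}
    if not required.issubset(coords.columns):
        raise AnalysisError(f"coordinate log must have columns {sorted(required)}")
    times = np.sort(coords["time"].unique())
    if len(times) < 2:
        raise AnalysisError("MSD needs at least two log times")
    ref = coords[coords["time"] == times[0]].set_index("id")[["x", "y", "z"]]
    rows = []
    for t in times:
        cur = coords[coords["time"] == t].set_index("id")[["x", "y", "z"]]
        common = cur.index.intersection(ref.index)
        d = cur.loc[common].to_numpy() - ref.loc[common].to_numpy()
        rows.append((t - times[0], float(np.mean(np.sum(d * d, axis=1))), len(common)))
    return pd.DataFrame(rows, columns=["t", "msd", "n"])


def fit_effective_D(msd: pd.DataFrame) -> float:
    """Least-squares slope through the origin of MSD(t) = 6 D t."""
    t = msd["t"].to_numpy()
    y = msd["msd"].to_numpy()
    mask = t > 0
    if mask.sum() < 1:
        raise AnalysisError("MSD fit needs at least one positive-lag point")
    t, y = t[mask], y[mask]
    slope = float(np.sum(t * y) / np.sum(t * t))
    return slope / 6.0
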