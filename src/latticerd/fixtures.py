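"""Validation model generators.

Every model used for validation is generated here: free and crowded
diffusion, the irreversible dissociation A → B + C (dilute and crowded), the
reversible association B + C ⇌ A with effective-to-intrinsic rate
conversion, the Michaelis-Menten benchmark, and the MAPK dual
phosphorylation-dephosphorylation cycle.

Full-scale defaults reproduce the published study conditions (lattices up to
960³, tens of thousands of molecules — cluster-scale); every fixture accepts
``scale`` to shrink the linear lattice dimensions while preserving
concentrations, occupancy fractions and all rate constants, so the same
physics is exercised at desk scale.  Molecule counts scale with the actual
(even-rounded) volume ratio.

MAPK rate constants are not part of this codebase's own parameterization:
they are the literature values of the Takahashi-Tanase-Nicola-ten Wolde
distributive MAPK model (PNAS 2005), converted from nM⁻¹s⁻¹ to μm³/s.
"""

from __future__ import annotations

import math

from .errors import ConfigurationError
from .kinetics import SpeciesSpec
from .lattice import VOXEL_RADIUS_FACTOR
from .model import InitialPlacement, LatticeConfig, LoggerSpec, ModelConfig, ReactionSpec

__all__ = ["make_fixture", "FIXTURES", "NM_INV_S_TO_UM3_S"]

#: 1 nM⁻¹ s⁻¹ in μm³ s⁻¹ (1 nM = 0.6022 molecules/μm³).
NM_INV_S_TO_UM3_S = 1.0 / 0.60221408


def _even(x: float, minimum: int = 4) -> int:
    return max(minimum, int(round(x / 2.0)) * 2)


def _scaled(full_dims, scale: float):
    dims = tuple(_even(d * scale) for d in full_dims)
    ratio = (dims[0] * dims[1] * dims[2]) / (full_dims[0] * full_dims[1] * full_dims[2])
    return dims, ratio


def _count(n_full: int, ratio: float) -> int:
    return max(1, int(round(n_full * ratio)))


def _rv_from_volume(volume_um3: float, dims) -> float:
    """Voxel radius giving the requested physical volume for these dims."""
    n = dims[0] * dims[1] * dims[2]
    return (volume_um3 / (n * 4.0 * math.sqrt(2.0))) ** (1.0 / 3.0)


def diffusion(
    scale: float = 1.0,
    D: float = 1.0,
    count: int = 1,
    voxel_radius: float = 2.5e-3,
    t_end: float = 0.04,
    log_interval: float | None = None,
    seed: int = 0,
    n_workers: int = 1,
) -> ModelConfig:
    """Dilute single-species random walk (trajectory / MSD validation).

    Full scale: one molecule on a 960³ lattice of 2.5 nm voxels, walked
    repeatedly for 40 ms; ``count`` may be raised to average an ensemble in
    a single run instead of over repeats.  Walkers start in the central
    half-box (the published runs start at the lattice center) so the MSD
    window stays clear of the reflective walls.
    """
    dims, _ = _scaled((960, 960, 960), scale)
    region = tuple((d // 4, d - d // 4) for d in dims)
    return ModelConfig(
        name="diffusion",
        lattice=LatticeConfig(dims=dims, voxel_radius=voxel_radius),
        species=[SpeciesSpec(name="A", D=D)],
        initial=[InitialPlacement(species="A", count=count, region=region)],
        loggers=[LoggerSpec(kind="coordinates", interval=log_interval or t_end / 10.0)],
        t_end=t_end,
        seed=seed,
        n_workers=n_workers,
    )


def crowded_diffusion(
    scale: float = 1.0,
    phi: float = 0.3,
    D: float = 1.0,
    count: int = 100,
    voxel_radius: float = 2.5e-3,
    t_end: float = 0.04,
    log_interval: float | None = None,
    seed: int = 0,
    n_workers: int = 1,
) -> ModelConfig:
    """Tracer diffusion among immobile crowders at voxel occupancy ``phi``.

    A fresh random crowder arrangement is drawn per seed; tracers start in
    the central half-box, away from the reflective walls.
    """
    dims, _ = _scaled((476, 476, 476), scale)
    region = tuple((d // 4, d - d // 4) for d in dims)
    return ModelConfig(
        name="crowded_diffusion",
        lattice=LatticeConfig(dims=dims, voxel_radius=voxel_radius),
        species=[
            SpeciesSpec(name="tracer", D=D),
            SpeciesSpec(name="crowder", D=0.0, mobile=False),
        ],
        initial=[
            InitialPlacement(species="tracer", count=count, region=region),
            *([InitialPlacement(species="crowder", phi=phi)] if phi > 0 else []),
        ],
        loggers=[
            LoggerSpec(kind="coordinates", interval=log_interval or t_end / 10.0, species=("tracer",))
        ],
        t_end=t_end,
        seed=seed,
        n_workers=n_workers,
    )


def irreversible(
    scale: float = 1.0,
    k: float = 1.0,
    D: float = 10.0,
    voxel_radius: float = 5.0e-3,
    count: int | None = None,
    t_end: float | None = None,
    log_interval: float | None = None,
    seed: int = 0,
    n_workers: int = 1,
) -> ModelConfig:
    """Dilute irreversible dissociation A → B + C against the exponential law.

    Full scale: 64,000 A molecules on a 960³ lattice of 5 nm voxels, all
    species diffusing at 10 μm²/s.  The published runs used three (unprinted)
    rates; ``k`` defaults to 1 s⁻¹ and the run covers three decay times.
    """
    dims, ratio = _scaled((960, 960, 960), scale)
    t_end = t_end if t_end is not None else 3.0 / k
    return ModelConfig(
        name="irreversible",
        lattice=LatticeConfig(dims=dims, voxel_radius=voxel_radius),
        species=[
            SpeciesSpec(name="A", D=D),
            SpeciesSpec(name="B", D=D),
            SpeciesSpec(name="C", D=D),
        ],
        reactions=[ReactionSpec(reactants=("A",), products=("B", "C"), k=k)],
        initial=[InitialPlacement(species="A", count=count if count is not None else _count(64000, ratio))],
        loggers=[LoggerSpec(kind="numbers", interval=log_interval or t_end / 60.0)],
        t_end=t_end,
        seed=seed,
        n_workers=n_workers,
    )


def crowded_irreversible(
    scale: float = 1.0,
    phi: float = 0.7,
    k: float = 10.0,
    D: float = 10.0,
    placement_mode: str = "fail_if_full",
    reactant_fraction: float = 0.06,
    t_end: float | None = None,
    log_interval: float | None = None,
    seed: int = 0,
    n_workers: int = 1,
) -> ModelConfig:
    """Dissociation under crowding: total initial voxel occupancy ``phi``.

    Full scale mirrors the published setup: a 64³ lattice spanning 90 μm³
    (voxel radius ≈ 39 nm), mobile crowders, everything diffusing at
    10 μm²/s.  ``phi`` counts *all* initially occupied voxels (φ = 1 fills
    the lattice completely, ≈ 74% true volume occupancy).  The reactant pool
    is kept at ~6% of the voxels so the +1-voxel growth per dissociation
    never exhausts the lattice at φ = 0.9, which would otherwise mask the
    placement-mode comparison.
    """
    full_dims = (64, 64, 64)
    dims, ratio = _scaled(full_dims, scale)
    r_v = _rv_from_volume(90.0, full_dims)  # voxel size is physics: keep it under scaling
    n_vox = dims[0] * dims[1] * dims[2]
    n_a = max(1, int(round(reactant_fraction * n_vox)))
    t_end = t_end if t_end is not None else 2.0 / k
    return ModelConfig(
        name="crowded_irreversible",
        lattice=LatticeConfig(dims=dims, voxel_radius=r_v),
        species=[
            SpeciesSpec(name="A", D=D),
            SpeciesSpec(name="B", D=D),
            SpeciesSpec(name="C", D=D),
            SpeciesSpec(name="crowder", D=D),
        ],
        reactions=[ReactionSpec(reactants=("A",), products=("B", "C"), k=k)],
        initial=[
            InitialPlacement(species="A", count=n_a),
            InitialPlacement(species="crowder", phi=phi),
        ],
        loggers=[LoggerSpec(kind="numbers", interval=log_interval or t_end / 40.0)],
        t_end=t_end,
        seed=seed,
        n_workers=n_workers,
        placement_mode=placement_mode,
    )


def reversible(
    scale: float = 1.0,
    k_f: float = 2.0,
    k_r: float = 1.35,
    D: float = 10.0,
    voxel_radius: float = 5.0e-3,
    t_end: float = 0.3,
    log_interval: float | None = None,
    seed: int = 0,
    n_workers: int = 1,
) -> ModelConfig:
    """Reversible association B + C ⇌ A with effective rates converted to
    intrinsic ones (k_f' = k_f k_D/(k_D − k_f), k_r' = k_f' k_r/k_f).

    Full scale: 64,000 B and 64,000 C on a 960³ lattice of 5 nm voxels.
    """
    dims, ratio = _scaled((960, 960, 960), scale)
    n0 = _count(64000, ratio)
    return ModelConfig(
        name="reversible",
        lattice=LatticeConfig(dims=dims, voxel_radius=voxel_radius),
        species=[
            SpeciesSpec(name="A", D=D),
            SpeciesSpec(name="B", D=D),
            SpeciesSpec(name="C", D=D),
        ],
        reactions=[
            ReactionSpec(reactants=("B", "C"), products=("A",), k=k_f, rate_type="effective"),
            ReactionSpec(reactants=("A",), products=("B", "C"), k=k_r, rate_type="effective"),
        ],
        initial=[
            InitialPlacement(species="B", count=n0),
            InitialPlacement(species="C", count=n0),
        ],
        loggers=[LoggerSpec(kind="numbers", interval=log_interval or t_end / 60.0)],
        t_end=t_end,
        seed=seed,
        n_workers=n_workers,
    )


def mm_benchmark(
    scale: float = 1.0,
    D: float = 10.0,
    k1: float = 0.01,
    k2: float = 1.0,
    k3: float = 1.0,
    t_end: float = 10.0,
    log_interval: float = 0.1,
    seed: int = 0,
    n_workers: int = 1,
) -> ModelConfig:
    """Michaelis-Menten benchmark: E + S ⇌ ES → E + P.

    Full scale: 909 μm³ with 9090 E and 90910 S, everything at 10 μm²/s.
    The 64³ lattice spanning that volume gives a ≈0.5 ms walk interval.
    """
    full_dims = (64, 64, 64)
    dims, ratio = _scaled(full_dims, scale)
    r_v = _rv_from_volume(909.0, full_dims)
    return ModelConfig(
        name="mm_benchmark",
        lattice=LatticeConfig(dims=dims, voxel_radius=r_v),
        species=[
            SpeciesSpec(name="E", D=D),
            SpeciesSpec(name="S", D=D),
            SpeciesSpec(name="ES", D=D),
            SpeciesSpec(name="Prod", D=D),
        ],
        reactions=[
            ReactionSpec(reactants=("E", "S"), products=("ES",), k=k1, rate_type="effective"),
            ReactionSpec(reactants=("ES",), products=("E", "S"), k=k2, rate_type="effective"),
            ReactionSpec(reactants=("ES",), products=("E", "Prod"), k=k3),
        ],
        initial=[
            InitialPlacement(species="E", count=_count(9090, ratio)),
            InitialPlacement(species="S", count=_count(90910, ratio)),
        ],
        loggers=[LoggerSpec(kind="numbers", interval=log_interval)],
        t_end=t_end,
        seed=seed,
        n_workers=n_workers,
    )


#: Takahashi et al. (PNAS 2005) distributive MAPK constants, nM⁻¹s⁻¹ and s⁻¹.
MAPK_RATES = {
    "k1": 0.027 * NM_INV_S_TO_UM3_S,  # μm³/s  K+KK / Kpp+P association
    "k2": 1.35,  # s⁻¹  complex dissociation
    "k3": 1.5,  # s⁻¹  catalysis, first modification
    "k4": 0.056 * NM_INV_S_TO_UM3_S,  # μm³/s  Kp+KK / Kp+P association
    "k5": 1.73,  # s⁻¹
    "k6": 15.0,  # s⁻¹  catalysis, second modification
}


def mapk(
    scale: float = 1.0,
    D: float = 4.0,
    kk_ratio: float = 1.0,
    tau_rel: float = 1.0e-6,
    molecule_radius: float = 2.5e-3,
    t_end: float = 300.0,
    log_interval: float = 0.5,
    seed: int = 0,
    n_workers: int = 1,
) -> ModelConfig:
    """Dual phosphorylation-dephosphorylation cycle of the MAPK cascade.

    MAPK kinase KK phosphorylates K twice (via Kp) to Kpp; phosphatase P
    reverses both steps.  After releasing a product, each enzyme passes
    through an inactive state (KK_x, P_x) that recovers at rate
    k_a = 1/tau_rel.  All bimolecular rates are intrinsic (the source model
    is a microscopic one); every species diffuses at ``D``.

    Full scale: 1200 K, 300 KK and 300 P in 10 μm³ (476³ lattice, 2.5 nm
    molecule radius so r_v = 1.0209 × 2.5 nm), simulated for 300 s.
    ``kk_ratio`` = KK₀/P₀ with P₀ held at its full-scale-equivalent value.
    """
    dims, ratio = _scaled((476, 476, 476), scale)
    r = MAPK_RATES
    ka = 1.0 / tau_rel
    p0 = _count(300, ratio)
    kk0 = max(1, int(round(p0 * kk_ratio)))
    k0 = _count(1200, ratio)
    sp = [
        SpeciesSpec(name=nm, D=D)
        for nm in ("K", "Kp", "Kpp", "KK", "KK_x", "P", "P_x", "K_KK", "Kp_KK", "Kpp_P", "Kp_P")
    ]
    rx = [
        ReactionSpec(("K", "KK"), ("K_KK",), r["k1"], "intrinsic"),
        ReactionSpec(("K_KK",), ("K", "KK"), r["k2"], "intrinsic"),
        ReactionSpec(("K_KK",), ("Kp", "KK_x"), r["k3"], "intrinsic"),
        ReactionSpec(("Kp", "KK"), ("Kp_KK",), r["k4"], "intrinsic"),
        ReactionSpec(("Kp_KK",), ("Kp", "KK"), r["k5"], "intrinsic"),
        ReactionSpec(("Kp_KK",), ("Kpp", "KK_x"), r["k6"], "intrinsic"),
        ReactionSpec(("KK_x",), ("KK",), ka, "intrinsic"),
        ReactionSpec(("Kpp", "P"), ("Kpp_P",), r["k1"], "intrinsic"),
        ReactionSpec(("Kpp_P",), ("Kpp", "P"), r["k2"], "intrinsic"),
        ReactionSpec(("Kpp_P",), ("Kp", "P_x"), r["k3"], "intrinsic"),
        ReactionSpec(("Kp", "P"), ("Kp_P",), r["k4"], "intrinsic"),
        ReactionSpec(("Kp_P",), ("Kp", "P"), r["k5"], "intrinsic"),
        ReactionSpec(("Kp_P",), ("K", "P_x"), r["k6"], "intrinsic"),
        ReactionSpec(("P_x",), ("P",), ka, "intrinsic"),
    ]
    return ModelConfig(
        name="mapk",
        lattice=LatticeConfig(dims=dims, voxel_radius=VOXEL_RADIUS_FACTOR * molecule_radius),
        species=sp,
        reactions=rx,
        initial=[
            InitialPlacement(species="K", count=k0),
            InitialPlacement(species="KK", count=kk0),
            InitialPlacement(species="P", count=p0),
        ],
        loggers=[LoggerSpec(kind="numbers", interval=log_interval)],
        t_end=t_end,
        seed=seed,
        n_workers=n_workers,
        radius_convention="molecule",
    )


FIXTURES = {
    "diffusion": diffusion,
    "crowded_diffusion": crowded_diffusion,
    "irreversible": irreversible,
    "crowded_irreversible": crowded_irreversible,
    "reversible": reversible,
    "mm_benchmark": mm_benchmark,
    "mapk": mapk,
}


def make_fixture(name: str, **overrides) -> ModelConfig:
    """Build a named validation model; see FIXTURES for the catalogue."""
    try:
        builder = FIXTURES[name]
    except KeyError:
        raise ConfigurationError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return builder(**overrides)
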