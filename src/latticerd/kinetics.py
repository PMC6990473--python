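"""Rate and probability mathematics for lattice reaction-diffusion.

Units: lengths in μm, times in s, diffusion coefficients in μm²/s,
unimolecular rates in s⁻¹, bimolecular rates in μm³/s.

A molecule hops to a neighbor voxel every ``tau_d = 2 r_v² / (3 D)`` seconds,
which reproduces a 3D mean-squared displacement of 6 D t.  When reactants
collide, the reaction fires with the Smoluchowski-Collins-Kimball acceptance
probability ``W = k / (6 √2 (D_i + D_j) r_v)`` built from the *intrinsic*
rate ``k``.  Strongly diffusion-limited channels can push W above 1; the walk
probability ``alpha`` rescales both W and the walk interval so that every
acceptance probability stays below the user cap P while preserving the
effective kinetics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ConfigurationError, ImmobileSpeciesError, InfeasibleRateError

__all__ = [
    "SpeciesSpec",
    "WalkSchedule",
    "ReactionChannel",
    "diffusion_interval",
    "acceptance_probability_raw",
    "walk_probability",
    "k_diffusion_limited",
    "intrinsic_forward",
    "intrinsic_reverse",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """One molecular species: diffusion coefficient, radius, mobility, W cap."""

    name: str
    D: float = 0.0
    radius: float | None = None
    mobile: bool | None = None
    P: float = 1.0

    def __post_init__(self):
        if self.D < 0:
            raise ConfigurationError(f"species {self.name}: D must be >= 0, got {self.D}")
        if not (0.0 < self.P <= 1.0):
            raise ConfigurationError(f"species {self.name}: P must be in (0, 1], got {self.P}")
        mobile = self.mobile if self.mobile is not None else self.D > 0
        if mobile and self.D == 0:
            raise ConfigurationError(f"species {self.name}: mobile species needs D > 0")
        object.__setattr__(self, "mobile", mobile)


@dataclass(frozen=True)
class WalkSchedule:
    """Derived walk timing for one mobile species."""

    tau_d: float
    rho: float
    alpha: float
    tau_e: float

    def __post_init__(self):
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(f"walk probability alpha must be in (0, 1], got {self.alpha}")
        if self.tau_e > self.tau_d * (1 + 1e-12):
            raise ConfigurationError("tau_e cannot exceed tau_d")


@dataclass
class ReactionChannel:
    """A unimolecular or bimolecular mass-action channel.

    ``k_eff`` is the macroscopic rate; ``k_intrinsic`` the contact reactivity
    used on lattice.  For activation-limited channels the two coincide.
    ``W`` is the rescaled acceptance probability of a bimolecular channel for
    each possible moving reactant (filled in at model build time).
    """

    kind: str  # "unimolecular" | "bimolecular"
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k_eff: float
    k_intrinsic: float
    W: dict = field(default_factory=dict)
    placement_mode: str = "fail_if_full"

    def __post_init__(self):
        if self.kind not in ("unimolecular", "bimolecular"):
            raise ConfigurationError(f"unknown channel kind {self.kind!r}")
        n = len(self.reactants)
        if (self.kind == "unimolecular") != (n == 1) or (self.kind == "bimolecular") != (n == 2):
            raise ConfigurationError(f"{self.kind} channel must have {'1' if self.kind == 'unimolecular' else '2'} reactants, got {n}")
        if not 0 <= len(self.products) <= 2:
            raise ConfigurationError("channels support 0-2 products")
        if self.placement_mode not in ("fail_if_full", "vacate_neighbor"):
            raise ConfigurationError(f"unknown placement mode {self.placement_mode!r}")


def diffusion_interval(D: float, r_v: float) -> float:
    """Base diffusion (hop) interval tau_d = 2 r_v² / (3 D), in seconds."""
    if D <= 0:
        raise ImmobileSpeciesError("diffusion interval undefined for D <= 0 (immobile species walk no event)")
    if r_v <= 0:
        raise ConfigurationError(f"voxel radius must be positive, got {r_v}")
    return 2.0 * r_v * r_v / (3.0 * D)


def acceptance_probability_raw(k_intrinsic: float, D_i: float, D_j: float, r_v: float) -> float:
    """Unrescaled SCK acceptance probability W = k / (6 √2 (D_i + D_j) r_v).

    May exceed 1 for highly diffusion-limited channels; rescaling by the walk
    probability restores a valid probability.
    """
    if D_i + D_j <= 0:
        raise ConfigurationError("bimolecular channel requires at least one mobile reactant")
    return k_intrinsic / (6.0 * math.sqrt(2.0) * (D_i + D_j) * r_v)


def walk_probability(rho: float, P: float = 1.0) -> float:
    """Walk probability alpha: P/rho when the max acceptance rho exceeds the cap P, else 1."""
    if rho < 0:
        raise ConfigurationError(f"rho must be >= 0, got {rho}")
    if not (0.0 < P <= 1.0):
        raise ConfigurationError(f"P must be in (0, 1], got {P}")
    return P / rho if rho > P else 1.0


def k_diffusion_limited(r_v: float, D_B: float, D_C: float) -> float:
    """Diffusion-limited encounter rate k_D = 8 π r_v (D_B + D_C), in μm³/s."""
    if r_v <= 0:
        raise ConfigurationError(f"voxel radius must be positive, got {r_v}")
    return 8.0 * math.pi * r_v * (D_B + D_C)


def intrinsic_forward(k_f: float, k_D: float) -> float:
    """Intrinsic forward rate k_f' = k_f k_D / (k_D - k_f) from the effective rate.

    The effective rate must lie strictly below the diffusion limit k_D.
    """
    if k_f < 0:
        raise ConfigurationError(f"k_f must be >= 0, got {k_f}")
    if k_f >= k_D:
        raise InfeasibleRateError(
            f"effective rate k_f={k_f} must be below the diffusion-limited rate k_D={k_D}"
        )
    return k_f * k_D / (k_D - k_f)


def intrinsic_reverse(k_f_prime: float, k_r: float, k_f: float) -> float:
    """Intrinsic reverse rate k_r' = k_f' k_r / k_f; preserves K_eq = k_f/k_r."""
    if k_f <= 0:
        raise ConfigurationError(f"k_f must be > 0, got {k_f}")
    return k_f_prime * k_r / k_f


def walk_schedule(D: float, r_v: float, rho: float, P: float = 1.0) -> WalkSchedule:
    """Assemble the full walk schedule for a mobile species."""
    tau_d = diffusion_interval(D, r_v)
    alpha = walk_probability(rho, P)
    return WalkSchedule(tau_d=tau_d, rho=rho, alpha=alpha, tau_e=tau_d * alpha)
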