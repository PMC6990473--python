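"""Model configuration: schema, validation, and compilation to runtime tables.

A model is a JSON document (or the equivalent :class:`ModelConfig`) naming the
lattice, the species, the reaction channels, the initial placements, the
loggers and the run controls.  ``compile_model`` resolves every derived
quantity — hop intervals, walk probabilities, intrinsic rates, rescaled
acceptance probabilities — once, up front, and validates the whole document
with itemized errors.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import kinetics as kin
from .errors import ConfigurationError, ValidationError
from .kinetics import ReactionChannel, SpeciesSpec
from .lattice import VOXEL_RADIUS_FACTOR, LatticeConfig, lattice_volume

__all__ = [
    "LoggerSpec",
    "InitialPlacement",
    "ReactionSpec",
    "ModelConfig",
    "CompiledModel",
    "compile_model",
    "load_model",
    "write_model",
]


@dataclass(frozen=True)
class LoggerSpec:
    kind: str  # "numbers" | "coordinates"
    interval: float
    species: tuple[str, ...] | None = None  # None = all species

    def __post_init__(self):
        if self.kind not in ("numbers", "coordinates"):
            raise ConfigurationError(f"unknown logger kind {self.kind!r}")
        if not self.interval > 0:
            raise ConfigurationError("logger interval must be positive")


@dataclass(frozen=True)
class InitialPlacement:
    """Initial molecules: an explicit coordinate list, a random count, or a
    lattice occupancy fraction ``phi`` (total occupied voxels = round(phi * n),
    counting molecules from the other placements).

    ``region`` restricts a random count to an axis-aligned sub-box given as
    ((i0, i1), (j0, j1), (k0, k1)) with half-open ranges — used e.g. to start
    tracers away from the reflective walls in diffusion validation."""

    species: str
    count: int | None = None
    phi: float | None = None
    coords: tuple | None = None
    region: tuple | None = None


@dataclass(frozen=True)
class ReactionSpec:
    """A reaction as written in the model file; rates may be effective or intrinsic."""

    reactants: tuple[str, ...]
    products: tuple[str, ...]
    k: float
    rate_type: str = "effective"
    placement_mode: str | None = None


@dataclass
class ModelConfig:
    lattice: LatticeConfig
    species: list[SpeciesSpec]
    reactions: list[ReactionSpec] = field(default_factory=list)
    initial: list[InitialPlacement] = field(default_factory=list)
    loggers: list[LoggerSpec] = field(default_factory=list)
    t_end: float = 1.0
    seed: int = 0
    n_workers: int = 1
    placement_mode: str = "fail_if_full"
    radius_convention: str = "voxel"  # how r_v was specified, echoed to the manifest
    name: str = "model"

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "lattice": {
                "dims": list(self.lattice.dims),
                "voxel_radius": self.lattice.voxel_radius,
                "boundary": self.lattice.boundary,
            },
            "species": [
                {"name": s.name, "D": s.D, "radius": s.radius, "mobile": s.mobile, "P": s.P}
                for s in self.species
            ],
            "reactions": [
                {
                    "reactants": list(r.reactants),
                    "products": list(r.products),
                    "k": r.k,
                    "rate_type": r.rate_type,
                    **({"placement_mode": r.placement_mode} if r.placement_mode else {}),
                }
                for r in self.reactions
            ],
            "initial": [
                {
                    "species": p.species,
                    **({"count": p.count} if p.count is not None else {}),
                    **({"phi": p.phi} if p.phi is not None else {}),
                    **({"coords": [list(c) for c in p.coords]} if p.coords is not None else {}),
                    **({"region": [list(r) for r in p.region]} if p.region is not None else {}),
                }
                for p in self.initial
            ],
            "loggers": [
                {
                    "kind": lg.kind,
                    "interval": lg.interval,
                    **({"species": list(lg.species)} if lg.species is not None else {}),
                }
                for lg in self.loggers
            ],
            "t_end": self.t_end,
            "seed": self.seed,
            "n_workers": self.n_workers,
            "placement_mode": self.placement_mode,
            "radius_convention": self.radius_convention,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        lat = d["lattice"]
        if "voxel_radius" in lat:
            r_v = float(lat["voxel_radius"])
            convention = "voxel"
        elif "molecule_radius" in lat:
            r_v = VOXEL_RADIUS_FACTOR * float(lat["molecule_radius"])
            convention = "molecule"
        else:
            raise ValidationError(["lattice needs voxel_radius or molecule_radius"])
        lattice = LatticeConfig(
            dims=tuple(lat["dims"]), voxel_radius=r_v, boundary=lat.get("boundary", "reflective")
        )
        species = [
            SpeciesSpec(
                name=s["name"],
                D=float(s.get("D", 0.0)),
                radius=s.get("radius"),
                mobile=s.get("mobile"),
                P=float(s.get("P", 1.0)),
            )
            for s in d.get("species", [])
        ]
        reactions = [
            ReactionSpec(
                reactants=tuple(r["reactants"]),
                products=tuple(r.get("products", [])),
                k=float(r["k"]),
                rate_type=r.get("rate_type", "effective"),
                placement_mode=r.get("placement_mode"),
            )
            for r in d.get("reactions", [])
        ]
        initial = [
            InitialPlacement(
                species=p["species"],
                count=p.get("count"),
                phi=p.get("phi"),
                coords=tuple(tuple(c) for c in p["coords"]) if "coords" in p else None,
                region=tuple(tuple(r) for r in p["region"]) if "region" in p else None,
            )
            for p in d.get("initial", [])
        ]
        loggers = [
            LoggerSpec(
                kind=lg["kind"],
                interval=float(lg["interval"]),
                species=tuple(lg["species"]) if "species" in lg else None,
            )
            for lg in d.get("loggers", [])
        ]
        return cls(
            lattice=lattice,
            species=species,
            reactions=reactions,
            initial=initial,
            loggers=loggers,
            t_end=float(d.get("t_end", 1.0)),
            seed=int(d.get("seed", 0)),
            n_workers=int(d.get("n_workers", 1)),
            placement_mode=d.get("placement_mode", "fail_if_full"),
            radius_convention=d.get("radius_convention", convention),
            name=d.get("name", "model"),
        )


def load_model(path) -> ModelConfig:
    """Read and validate a JSON model file; raises ValidationError with all problems."""
    with open(path) as fh:
        d = json.load(fh)
    cfg = ModelConfig.from_dict(d)
    compile_model(cfg)  # full validation with derived quantities
    return cfg


def write_model(cfg: ModelConfig, path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Compilation


class CompiledModel:
    """Runtime tables derived from a validated ModelConfig.

    Attributes
    ----------
    sid : dict name -> integer species id
    D, P, mobile, tau_d, alpha, tau_e, rho : per-species arrays
    channels : list[ReactionChannel] with effective and intrinsic rates
    bi_pair_channel, bi_pair_W : (n_sp, n_sp) collision tables; ``bi_pair_W[i, j]``
        is the acceptance probability applied when a molecule of species i
        walks into a reactant partner of species j (raw W rescaled by alpha_i)
    uni_channels : list of (channel_index, reactant_sid, k, product_sids)
    walk_groups : list of tuples of species ids sharing one walk interval
    """

    def __init__(self, cfg: ModelConfig):
        problems: list[str] = []
        self.cfg = cfg
        self.n_species = len(cfg.species)
        self.sid = {s.name: i for i, s in enumerate(cfg.species)}
        if len(self.sid) != self.n_species:
            problems.append("duplicate species names")
        r_v = cfg.lattice.voxel_radius

        self.D = np.array([s.D for s in cfg.species], dtype=np.float64)
        self.P = np.array([s.P for s in cfg.species], dtype=np.float64)
        self.mobile = np.array([s.mobile for s in cfg.species], dtype=bool)

        # --- channels: resolve intrinsic/effective rates -------------------
        self.channels: list[ReactionChannel] = []
        seen_pairs: dict[frozenset, int] = {}
        for idx, r in enumerate(cfg.reactions):
            for nm in (*r.reactants, *r.products):
                if nm not in self.sid:
                    problems.append(f"reaction {idx}: unknown species {nm!r}")
            if any(nm not in self.sid for nm in (*r.reactants, *r.products)):
                continue
            mode = r.placement_mode or cfg.placement_mode
            if len(r.reactants) == 2:
                a, b = (self.sid[n] for n in r.reactants)
                key = frozenset((a, b))
                if key in seen_pairs:
                    problems.append(
                        f"reaction {idx}: second bimolecular channel for pair {r.reactants}; "
                        "one channel per unordered species pair is supported"
                    )
                    continue
                seen_pairs[key] = idx
                Dsum = self.D[a] + self.D[b]
                if Dsum <= 0:
                    problems.append(f"reaction {idx}: both reactants immobile")
                    continue
                k_D = kin.k_diffusion_limited(r_v, self.D[a], self.D[b])
                if r.rate_type == "effective":
                    if r.k >= k_D:
                        problems.append(
                            f"reaction {idx}: effective rate k={r.k} μm³/s reaches the "
                            f"diffusion-limited rate k_D={k_D:.6g} μm³/s and cannot be converted"
                        )
                        continue
                    k_int = kin.intrinsic_forward(r.k, k_D)
                    k_eff = r.k
                else:
                    k_int = r.k
                    k_eff = r.k * k_D / (r.k + k_D)
                self.channels.append(
                    ReactionChannel(
                        kind="bimolecular",
                        reactants=r.reactants,
                        products=r.products,
                        k_eff=k_eff,
                        k_intrinsic=k_int,
                        placement_mode=mode,
                    )
                )
            elif len(r.reactants) == 1:
                self.channels.append(
                    ReactionChannel(
                        kind="unimolecular",
                        reactants=r.reactants,
                        products=r.products,
                        k_eff=r.k,
                        k_intrinsic=r.k,  # possibly overwritten below for reverse channels
                        placement_mode=mode,
                    )
                )
            else:
                problems.append(f"reaction {idx}: needs 1 or 2 reactants")

        # Reverse unimolecular channels paired with an effective-rate forward
        # bimolecular channel get the intrinsic reverse rate k_r' = k_f' k_r / k_f
        # so that the simulated equilibrium matches the effective-rate one.
        raw_by_channel = [r for r in cfg.reactions if all(n in self.sid for n in (*r.reactants, *r.products))]
        for ch, raw in zip(self.channels, raw_by_channel):
            if ch.kind != "unimolecular" or raw.rate_type != "effective":
                continue
            rev = next(
                (
                    c
                    for c in self.channels
                    if c.kind == "bimolecular"
                    and frozenset(c.reactants) == frozenset(ch.products)
                    and c.products == ch.reactants
                ),
                None,
            )
            if rev is not None and rev.k_eff != rev.k_intrinsic:
                ch.k_intrinsic = kin.intrinsic_reverse(rev.k_intrinsic, ch.k_eff, rev.k_eff)

        # --- collision tables and walk schedules ---------------------------
        n = self.n_species
        self.bi_pair_channel = np.full((n, n), -1, dtype=np.int32)
        W_raw = np.zeros((n, n), dtype=np.float64)
        for ci, ch in enumerate(self.channels):
            if ch.kind != "bimolecular":
                continue
            a, b = (self.sid[nm] for nm in ch.reactants)
            w = kin.acceptance_probability_raw(ch.k_intrinsic, self.D[a], self.D[b], r_v)
            W_raw[a, b] = W_raw[b, a] = w
            self.bi_pair_channel[a, b] = self.bi_pair_channel[b, a] = ci

        # rho_i: max raw W over channels involving species i
        self.rho = W_raw.max(axis=1)
        self.alpha = np.ones(n, dtype=np.float64)
        self.tau_d = np.full(n, np.inf, dtype=np.float64)
        self.tau_e = np.full(n, np.inf, dtype=np.float64)
        for i in range(n):
            if not self.mobile[i]:
                if self.rho[i] > 0 and self.D[i] == 0 and W_raw[i].max() > 0:
                    pass  # immobile reactant of a bimolecular pair: partner must move
                continue
            self.alpha[i] = kin.walk_probability(self.rho[i], self.P[i])
            self.tau_d[i] = kin.diffusion_interval(self.D[i], r_v)
            self.tau_e[i] = self.tau_d[i] * self.alpha[i]
        # acceptance probability applied when species i is the mover
        self.bi_pair_W = W_raw * self.alpha[:, None]
        for i in range(n):
            if self.mobile[i] and self.bi_pair_W[i].max() > self.P[i] * (1 + 1e-12):
                problems.append(
                    f"species {cfg.species[i].name}: rescaled W exceeds cap P "
                    f"({self.bi_pair_W[i].max():.4g} > {self.P[i]})"
                )
        self.W_raw = W_raw

        # channel product tables for the walk kernel
        nch = len(self.channels)
        self.ch_n_products = np.zeros(nch, dtype=np.int32)
        self.ch_p1 = np.full(nch, -1, dtype=np.int32)
        self.ch_p2 = np.full(nch, -1, dtype=np.int32)
        for ci, ch in enumerate(self.channels):
            ps = [self.sid[nm] for nm in ch.products]
            self.ch_n_products[ci] = len(ps)
            if len(ps) >= 1:
                self.ch_p1[ci] = ps[0]
            if len(ps) == 2:
                self.ch_p2[ci] = ps[1]

        self.uni_channels = [
            (ci, self.sid[ch.reactants[0]], ch.k_intrinsic, tuple(self.sid[nm] for nm in ch.products), ch.placement_mode)
            for ci, ch in enumerate(self.channels)
            if ch.kind == "unimolecular"
        ]

        # walk groups: mobile species sharing a bitwise-identical walk interval
        groups: dict[float, list[int]] = {}
        for i in range(n):
            if self.mobile[i]:
                groups.setdefault(float(self.tau_e[i]), []).append(i)
        self.walk_groups = [tuple(groups[t]) for t in sorted(groups)]

        # --- initial placements -------------------------------------------
        n_vox = cfg.lattice.n_voxels
        total = 0
        phi_entries = 0
        for idx, p in enumerate(cfg.initial):
            if p.species not in self.sid:
                problems.append(f"initial {idx}: unknown species {p.species!r}")
                continue
            modes = sum(x is not None for x in (p.count, p.phi, p.coords))
            if modes != 1:
                problems.append(f"initial {idx}: give exactly one of count, phi, coords")
                continue
            if p.count is not None:
                if p.count < 0:
                    problems.append(f"initial {idx}: negative count")
                total += p.count or 0
            elif p.coords is not None:
                total += len(p.coords)
            else:
                phi_entries += 1
                if not 0.0 <= p.phi <= 1.0:
                    problems.append(f"initial {idx}: phi must be in [0, 1], got {p.phi}")
        if phi_entries > 1:
            problems.append("at most one phi-based placement is supported")
        elif phi_entries == 1:
            phi = next(p.phi for p in cfg.initial if p.phi is not None)
            if 0.0 <= phi <= 1.0:
                phi_count = int(round(phi * n_vox)) - total
                if phi_count < 0:
                    problems.append(
                        f"phi={phi} implies {int(round(phi * n_vox))} occupied voxels, fewer than "
                        f"the {total} placed explicitly"
                    )
                total += max(phi_count, 0)
        if total > n_vox:
            problems.append(f"initial molecules ({total}) exceed voxel count ({n_vox})")
        self.n_initial = total

        if cfg.t_end <= 0:
            problems.append("t_end must be positive")
        if not self.walk_groups and not self.uni_channels and not cfg.loggers:
            problems.append("model defines no events (no mobile species, reactions or loggers)")

        if problems:
            raise ValidationError(problems)

    # -- convenience -------------------------------------------------------
    @property
    def volume(self) -> float:
        return lattice_volume(self.cfg.lattice)

    def species_names(self) -> list[str]:
        return [s.name for s in self.cfg.species]

    def initial_counts(self) -> dict[str, int]:
        """Molecule counts per species implied by the initial placements."""
        n_vox = self.cfg.lattice.n_voxels
        counts = {s.name: 0 for s in self.cfg.species}
        explicit = 0
        for p in self.cfg.initial:
            if p.count is not None:
                counts[p.species] += p.count
                explicit += p.count
            elif p.coords is not None:
                counts[p.species] += len(p.coords)
                explicit += len(p.coords)
        for p in self.cfg.initial:
            if p.phi is not None:
                counts[p.species] += max(int(round(p.phi * n_vox)) - explicit, 0)
        return counts

    def summary(self) -> dict:
        """Derived-quantity echo for run manifests and the CLI."""
        return {
            "volume_um3": self.volume,
            "species": [
                {
                    "name": s.name,
                    "D": s.D,
                    "mobile": bool(self.mobile[i]),
                    "tau_d": None if not self.mobile[i] else self.tau_d[i],
                    "rho": self.rho[i],
                    "alpha": self.alpha[i] if self.mobile[i] else None,
                    "tau_e": None if not self.mobile[i] else self.tau_e[i],
                }
                for i, s in enumerate(self.cfg.species)
            ],
            "channels": [
                {
                    "kind": ch.kind,
                    "reactants": list(ch.reactants),
                    "products": list(ch.products),
                    "k_eff": ch.k_eff,
                    "k_intrinsic": ch.k_intrinsic,
                    "W": (
                        {
                            nm: self.bi_pair_W[self.sid[nm], self.sid[other]]
                            for nm, other in (
                                (ch.reactants[0], ch.reactants[1]),
                                (ch.reactants[1], ch.reactants[0]),
                            )
                            if self.mobile[self.sid[nm]]
                        }
                        if ch.kind == "bimolecular"
                        else None
                    ),
                    "placement_mode": ch.placement_mode,
                }
                for ch in self.channels
            ],
        }


def compile_model(cfg: ModelConfig) -> CompiledModel:
    return CompiledModel(cfg)
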