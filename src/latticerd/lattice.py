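"""Hexagonal close-packed lattice geometry in twisted Cartesian coordinates.

Voxels are spheres of radius ``r_v`` arranged in an HCP packing and addressed
by integer coordinates ``(i, j, k)``.  The mapping to real space is

    x = 2 r (i + ((j + k) mod 2) / 2)
    y = sqrt(3) r (j + (k mod 2) / 3)
    z = (2 sqrt(6) / 3) r k

so each interior voxel has twelve nearest neighbors, all at center distance
``2 r_v``.  Which integer offsets reach those neighbors depends on the
parities of ``j`` and ``k``; the four offset tables below are frozen from
that parameterization and are validated against a brute-force real-coordinate
search in the test suite.

Lengths are in micrometres throughout.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError, CoordinateError

__all__ = [
    "LatticeConfig",
    "DomainLayout",
    "NEIGHBOR_OFFSETS",
    "neighbor_coords",
    "to_real",
    "to_real_array",
    "packing_density",
    "packing_density_monte_carlo",
    "volume_occupancy",
    "lattice_volume",
    "decompose",
]

#: Sphere-center distance between neighbors, in units of r_v.
NEIGHBOR_DISTANCE = 2.0

# Parity-dependent neighbor offsets, indexed [j % 2][k % 2][neighbor 0-11][axis].
# Order within a parity class: the six in-plane neighbors (dk = 0) first, then
# the three in the upper plane (dk = +1), then the three in the lower plane
# (dk = -1); within each plane sorted by (dj, di).  This order is part of the
# public contract: uniform random target selection draws an index 0-11.
NEIGHBOR_OFFSETS = np.array(
    [
        [  # j even
            [  # k even
                (-1, -1, 0), (0, -1, 0), (-1, 0, 0), (1, 0, 0), (-1, 1, 0), (0, 1, 0),
                (0, -1, 1), (-1, 0, 1), (0, 0, 1),
                (0, -1, -1), (-1, 0, -1), (0, 0, -1),
            ],
            [  # k odd
                (0, -1, 0), (1, -1, 0), (-1, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                (0, 0, 1), (1, 0, 1), (0, 1, 1),
                (0, 0, -1), (1, 0, -1), (0, 1, -1),
            ],
        ],
        [  # j odd
            [  # k even
                (0, -1, 0), (1, -1, 0), (-1, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
                (0, -1, 1), (0, 0, 1), (1, 0, 1),
                (0, -1, -1), (0, 0, -1), (1, 0, -1),
            ],
            [  # k odd
                (-1, -1, 0), (0, -1, 0), (-1, 0, 0), (1, 0, 0), (-1, 1, 0), (0, 1, 0),
                (-1, 0, 1), (0, 0, 1), (0, 1, 1),
                (-1, 0, -1), (0, 0, -1), (0, 1, -1),
            ],
        ],
    ],
    dtype=np.int8,
)

#: Factor relating voxel radius to molecule radius for SCK-consistent kinetics.
VOXEL_RADIUS_FACTOR = 1.0209


@dataclass(frozen=True)
class LatticeConfig:
    """HCP lattice geometry: integer dimensions, voxel radius, boundary."""

    dims: tuple[int, int, int]
    voxel_radius: float
    boundary: str = "reflective"

    def __post_init__(self):
        dims = tuple(int(d) for d in self.dims)
        object.__setattr__(self, "dims", dims)
        if len(dims) != 3 or any(d < 4 for d in dims):
            raise ConfigurationError(f"lattice dims must be three integers >= 4, got {dims}")
        if not (self.voxel_radius > 0):
            raise ConfigurationError(f"voxel radius must be positive, got {self.voxel_radius}")
        if self.boundary != "reflective":
            raise ConfigurationError(f"unsupported boundary {self.boundary!r}")

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.dims
        return nx * ny * nz

    def contains(self, c) -> bool:
        i, j, k = c
        nx, ny, nz = self.dims
        return 0 <= i < nx and 0 <= j < ny and 0 <= k < nz


def _check_coord(c, cfg: LatticeConfig):
    if not cfg.contains(c):
        raise CoordinateError(f"voxel {tuple(c)} outside lattice dims {cfg.dims}")


def neighbor_coords(c, cfg: LatticeConfig):
    """In-bounds nearest neighbors of voxel ``c``, in the documented 0-11 order.

    Interior voxels have exactly twelve; boundary voxels lose the offsets that
    leave the lattice (reflective truncation).
    """
    _check_coord(c, cfg)
    i, j, k = (int(v) for v in c)
    out = []
    for di, dj, dk in NEIGHBOR_OFFSETS[j % 2][k % 2]:
        t = (i + int(di), j + int(dj), k + int(dk))
        if cfg.contains(t):
            out.append(t)
    return out


def to_real(c, cfg: LatticeConfig):
    """Real-space center (x, y, z) in μm of voxel ``c``."""
    _check_coord(c, cfg)
    i, j, k = (int(v) for v in c)
    r = cfg.voxel_radius
    x = 2.0 * r * (i + ((j + k) % 2) / 2.0)
    y = math.sqrt(3.0) * r * (j + (k % 2) / 3.0)
    z = (2.0 * math.sqrt(6.0) / 3.0) * r * k
    return (x, y, z)


def to_real_array(ii, jj, kk, voxel_radius: float):
    """Vectorized integer-to-real coordinate conversion (no bounds check)."""
    ii = np.asarray(ii, dtype=np.float64)
    jj = np.asarray(jj, dtype=np.float64)
    kk = np.asarray(kk, dtype=np.float64)
    r = voxel_radius
    x = 2.0 * r * (ii + np.mod(jj + kk, 2) / 2.0)
    y = math.sqrt(3.0) * r * (jj + np.mod(kk, 2) / 3.0)
    z = (2.0 * math.sqrt(6.0) / 3.0) * r * kk
    return np.stack([x, y, z], axis=-1)


def packing_density(kind: str) -> float:
    """Sphere packing fraction of the lattice: hcp = π/(3√2), cubic = π/6."""
    if kind == "hcp":
        return math.pi / (3.0 * math.sqrt(2.0))
    if kind == "cubic":
        return math.pi / 6.0
    raise ValueError(f"unknown lattice kind {kind!r}; expected 'hcp' or 'cubic'")


def packing_density_monte_carlo(kind: str, n_points: int = 1_000_000, seed: int = 0) -> float:
    """Monte-Carlo packing fraction: uniform points tested against lattice spheres.

    Points are drawn in a box deep inside a 30³ block of sites: the box must
    span many unit cells, otherwise its incommensurability with the lattice
    cell biases the estimate.
    """
    rng = np.random.default_rng(seed)
    r = 1.0
    n = 30
    if kind == "hcp":
        ii, jj, kk = np.meshgrid(np.arange(n), np.arange(n), np.arange(n), indexing="ij")
        centers = to_real_array(ii.ravel(), jj.ravel(), kk.ravel(), r)
    elif kind == "cubic":
        g = 2.0 * r * np.arange(n, dtype=np.float64)
        xx, yy, zz = np.meshgrid(g, g, g, indexing="ij")
        centers = np.stack([xx.ravel(), yy.ravel(), zz.ravel()], axis=-1)
    else:
        raise ValueError(f"unknown lattice kind {kind!r}; expected 'hcp' or 'cubic'")
    lo = centers.min(axis=0) + 6.0 * r
    hi = centers.max(axis=0) - 6.0 * r
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    from scipy.spatial import cKDTree

    tree = cKDTree(centers)
    d, _ = tree.query(pts, k=1)
    return float(np.mean(d <= r))


def volume_occupancy(phi: float) -> float:
    """True volume fraction occupied when a fraction ``phi`` of voxels is filled.

    phi = 1 corresponds to the full HCP packing fraction (≈ 74%)."""
    if not 0.0 <= phi <= 1.0:
        raise ValueError(f"phi must be in [0, 1], got {phi}")
    return phi * packing_density("hcp")


def lattice_volume(cfg: LatticeConfig) -> float:
    """Physical volume in μm³: n_voxels × per-site HCP cell volume 4√2 r_v³."""
    return cfg.n_voxels * 4.0 * math.sqrt(2.0) * cfg.voxel_radius**3


# ---------------------------------------------------------------------------
# Domain decomposition


@dataclass(frozen=True)
class DomainLayout:
    """Equal block decomposition of the lattice into worker subdomains.

    Each subdomain carries a one-voxel ghost shell and is split into 2×2×2
    subvolumes during walk events, so each subdomain dimension must be even.
    """

    n_workers: int
    worker_grid: tuple[int, int, int]
    subdomain_dims: tuple[int, int, int]
    dims: tuple[int, int, int]
    subvolume_count: int = field(default=8)
    ghost_thickness: int = field(default=1)

    def rank_to_coords(self, rank: int) -> tuple[int, int, int]:
        gx, gy, gz = self.worker_grid
        cz = rank % gz
        cy = (rank // gz) % gy
        cx = rank // (gz * gy)
        return (cx, cy, cz)

    def coords_to_rank(self, coords) -> int:
        gx, gy, gz = self.worker_grid
        cx, cy, cz = coords
        return (cx * gy + cy) * gz + cz

    def origin(self, rank: int) -> tuple[int, int, int]:
        c = self.rank_to_coords(rank)
        return tuple(ci * si for ci, si in zip(c, self.subdomain_dims))

    def neighbor_rank(self, rank: int, axis: int, side: int):
        """Rank of the face neighbor along ``axis`` (side 0 = low, 1 = high), or None."""
        c = list(self.rank_to_coords(rank))
        c[axis] += 1 if side else -1
        if not 0 <= c[axis] < self.worker_grid[axis]:
            return None
        return self.coords_to_rank(c)

    def owner_of(self, coord) -> int:
        c = tuple(g // s for g, s in zip(coord, self.subdomain_dims))
        return self.coords_to_rank(c)

    def is_out_voxel(self, rank: int, local) -> bool:
        """Whether a local (1-based, ghost-shell indexed) voxel adjoins another subdomain."""
        for axis in range(3):
            n = self.subdomain_dims[axis]
            if local[axis] == 1 and self.neighbor_rank(rank, axis, 0) is not None:
                return True
            if local[axis] == n and self.neighbor_rank(rank, axis, 1) is not None:
                return True
        return False


def _factor_triples(n: int):
    for gx in range(1, n + 1):
        if n % gx:
            continue
        rest = n // gx
        for gy in range(1, rest + 1):
            if rest % gy:
                continue
            yield (gx, gy, rest // gy)


def decompose(cfg: LatticeConfig, n_workers: int) -> DomainLayout:
    """Split the lattice into ``n_workers`` equal subdomains with even dims.

    Among all factorizations of ``n_workers`` that divide the lattice evenly
    into even-sized blocks, the most surface-minimizing (most cubic) grid is
    chosen; ties break lexicographically for determinism.
    """
    if n_workers < 1:
        raise ConfigurationError("n_workers must be >= 1")
    dims = cfg.dims
    candidates = []
    for grid in _factor_triples(n_workers):
        sub = []
        ok = True
        for d, g in zip(dims, grid):
            if d % g:
                ok = False
                break
            s = d // g
            if s % 2 or s < 2:
                ok = False
                break
            sub.append(s)
        if ok:
            sx, sy, sz = sub
            surface = sx * sy + sy * sz + sx * sz
            candidates.append((surface, grid, tuple(sub)))
    if not candidates:
        valid = sorted(
            {
                w
                for w in range(1, 65)
                if any(
                    all(d % g == 0 and (d // g) % 2 == 0 for d, g in zip(dims, grid))
                    for grid in _factor_triples(w)
                )
            }
        )
        raise ConfigurationError(
            f"{n_workers} workers cannot evenly divide dims {dims} into even subdomains; "
            f"valid worker counts up to 64: {valid}"
        )
    candidates.sort(key=lambda t: (t[0], t[1]))
    _, grid, sub = candidates[0]
    return DomainLayout(n_workers=n_workers, worker_grid=grid, subdomain_dims=sub, dims=dims)
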