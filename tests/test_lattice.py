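"""HCP geometry: neighbor stencils, real coordinates, packing, decomposition."""

import itertools

import numpy as np
import pytest

from latticerd import (
    ConfigurationError,
    CoordinateError,
    LatticeConfig,
    decompose,
    lattice_volume,
    neighbor_coords,
    packing_density,
    packing_density_monte_carlo,
    to_real,
    volume_occupancy,
)
from latticerd.lattice import to_real_array


def brute_force_neighbors(c, cfg):
    """Oracle: the 12 sites whose centers lie at distance 2 r_v, by exhaustive search."""
    p0 = np.array(to_real(c, cfg))
    out = []
    nx, ny, nz = cfg.dims
    for t in itertools.product(range(nx), range(ny), range(nz)):
        if t == tuple(c):
            continue
        d = np.linalg.norm(np.array(to_real(t, cfg)) - p0)
        if abs(d - 2 * cfg.voxel_radius) < 1e-9 * 2 * cfg.voxel_radius:
            out.append(t)
    return set(out)


class TestNeighbors:
    def test_interior_voxel_has_twelve_neighbors(self, small_lattice):
        assert len(neighbor_coords((4, 4, 4), small_lattice)) == 12

    def test_corner_voxel_truncated(self, small_lattice):
        nbs = neighbor_coords((0, 0, 0), small_lattice)
        assert 0 < len(nbs) < 12
        assert all(small_lattice.contains(c) for c in nbs)

    def test_out_of_range_raises(self, small_lattice):
        with pytest.raises(CoordinateError):
            neighbor_coords((8, 0, 0), small_lattice)

    def test_stencil_matches_brute_force_all_parities(self):
        # all four (j, k) parity classes on an interior voxel of a 16^3 lattice
        cfg = LatticeConfig(dims=(16, 16, 16), voxel_radius=1.0)
        for pj, pk in itertools.product((0, 1), repeat=2):
            c = (4, 4 + pj, 4 + pk)
            assert set(neighbor_coords(c, cfg)) == brute_force_neighbors(c, cfg)

    def test_stencil_oracle_equivalence_10cubed(self):
        """Every interior voxel of a 10³ lattice: stencil == nearest-site search."""
        cfg = LatticeConfig(dims=(10, 10, 10), voxel_radius=1.0)
        ii, jj, kk = np.meshgrid(*[np.arange(10)] * 3, indexing="ij")
        pts = to_real_array(ii.ravel(), jj.ravel(), kk.ravel(), 1.0)
        from scipy.spatial import cKDTree

        tree = cKDTree(pts)
        coords = list(itertools.product(range(1, 9), repeat=3))
        for c in coords:
            flat = np.ravel_multi_index(c, (10, 10, 10))
            d, idx = tree.query(pts[flat], k=13)
            assert abs(d[1:].max() - 2.0) < 1e-9  # 12 equidistant nearest sites
            oracle = {tuple(np.unravel_index(i, (10, 10, 10))) for i in idx[1:]}
            assert set(neighbor_coords(c, cfg)) == oracle

    def test_neighbor_symmetry_exhaustive(self, small_lattice):
        for c in itertools.product(range(8), repeat=3):
            for nb in neighbor_coords(c, small_lattice):
                assert tuple(c) in neighbor_coords(nb, small_lattice)

    def test_equal_distance_property(self, small_lattice):
        r = small_lattice.voxel_radius
        for c in itertools.product(range(8), repeat=3):
            p0 = np.array(to_real(c, small_lattice))
            for nb in neighbor_coords(c, small_lattice):
                d = np.linalg.norm(np.array(to_real(nb, small_lattice)) - p0)
                assert d == pytest.approx(2 * r, rel=1e-9)


class TestRealCoordinates:
    def test_origin(self, small_lattice):
        assert to_real((0, 0, 0), small_lattice) == (0.0, 0.0, 0.0)

    def test_reference_point(self):
        cfg = LatticeConfig(dims=(4, 4, 4), voxel_radius=1.0)
        x, y, z = to_real((0, 0, 1), cfg)
        assert x == pytest.approx(1.0)
        assert y == pytest.approx(np.sqrt(3) / 3)
        assert z == pytest.approx(2 * np.sqrt(6) / 3)


class TestPacking:
    def test_closed_forms(self):
        assert packing_density("hcp") == pytest.approx(0.74048, abs=1e-5)
        assert packing_density("cubic") == pytest.approx(0.52359, abs=1e-5)

    def test_unknown_kind(self):
        with pytest.raises(ValueError):
            packing_density("fcc")

    @pytest.mark.parametrize("kind", ["hcp", "cubic"])
    def test_monte_carlo_agrees(self, kind):
        est = packing_density_monte_carlo(kind, n_points=1_000_000, seed=42)
        assert est == pytest.approx(packing_density(kind), abs=1e-3)

    def test_volume_occupancy(self):
        assert volume_occupancy(1.0) == pytest.approx(0.74048, abs=1e-5)
        assert volume_occupancy(0.0) == 0.0

    def test_lattice_volume_consistent_with_packing(self):
        # total sphere volume / lattice volume = HCP packing fraction
        cfg = LatticeConfig(dims=(16, 16, 16), voxel_radius=0.01)
        spheres = cfg.n_voxels * 4 / 3 * np.pi * cfg.voxel_radius**3
        assert spheres / lattice_volume(cfg) == pytest.approx(packing_density("hcp"), rel=1e-12)


class TestDecompose:
    def test_eight_workers(self):
        cfg = LatticeConfig(dims=(12, 12, 12), voxel_radius=1.0)
        lay = decompose(cfg, 8)
        assert lay.worker_grid == (2, 2, 2)
        assert lay.subdomain_dims == (6, 6, 6)
        assert lay.subvolume_count == 8 and lay.ghost_thickness == 1

    def test_single_worker_whole_lattice(self):
        cfg = LatticeConfig(dims=(12, 12, 12), voxel_radius=1.0)
        lay = decompose(cfg, 1)
        assert lay.subdomain_dims == (12, 12, 12)
        assert all(
            not lay.is_out_voxel(0, (i, j, k))
            for i, j, k in [(1, 1, 1), (12, 12, 12), (6, 6, 6)]
        )

    def test_indivisible_raises_with_valid_counts(self):
        cfg = LatticeConfig(dims=(12, 12, 12), voxel_radius=1.0)
        with pytest.raises(ConfigurationError, match="valid worker counts"):
            decompose(cfg, 5)

    def test_partition_property(self):
        cfg = LatticeConfig(dims=(8, 12, 16), voxel_radius=1.0)
        lay = decompose(cfg, 4)
        owners = np.zeros(cfg.dims, dtype=int) - 1
        for g in itertools.product(range(8), range(12), range(16)):
            r = lay.owner_of(g)
            assert 0 <= r < 4
            owners[g] = r
        # every voxel assigned exactly once, all workers non-empty and equal
        counts = np.bincount(owners.ravel(), minlength=4)
        assert (counts == cfg.n_voxels // 4).all()
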