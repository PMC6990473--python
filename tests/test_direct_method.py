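"""Gillespie direct method: propensities, draws, rescheduling, product placement."""

import math

import numpy as np
import pytest
from scipy import stats

from latticerd import (
    InitialPlacement,
    SpeciesSpec,
    ReactionSpec,
    compile_model,
    neighbor_coords,
)
from latticerd import direct_method as dm
from latticerd.lattice import LatticeConfig, decompose
from latticerd.runtime import NullTransport, Worker

from conftest import build_model


class _FixedRng:
    def __init__(self, value):
        self.value = value

    def random(self):
        return self.value


class TestAggregate:
    def test_sum_over_workers(self):
        # 3 A on one worker, 5 A on another, k = 2/s -> a_g = 16/s
        a = dm.aggregate_propensities([2.0], [3 + 5])
        assert a.sum() == 16.0

    def test_empty_lattice_never_fires(self):
        a = dm.aggregate_propensities([2.0], [0])
        assert dm.new_interval(float(a.sum()), np.random.default_rng(0)) == math.inf

    def test_partition_invariance(self, rng):
        counts = rng.multinomial(1000, np.ones(8) / 8)
        assert dm.aggregate_propensities([0.7], [counts.sum()]) == pytest.approx(700.0)
        assert counts.sum() == 1000


class TestInterval:
    def test_closed_form(self):
        assert dm.new_interval(1.0, _FixedRng(1 / math.e)) == pytest.approx(1.0, rel=1e-12)

    def test_scaling(self):
        r = _FixedRng(0.3)
        assert dm.new_interval(2.0, r) == pytest.approx(dm.new_interval(1.0, r) / 2, rel=1e-12)

    def test_sample_mean(self):
        rng = np.random.default_rng(7)
        n = 100_000
        xs = np.array([dm.new_interval(2.0, rng) for _ in range(n)])
        assert abs(xs.mean() - 0.5) < 3 * 0.5 / math.sqrt(n)


class TestSelectChannel:
    def test_direct_evaluation(self):
        # a = [1,2,3], r2 = 0.5: target 3 lies in (1, 3] -> channel 2 (index 1)
        assert dm.select_channel([1.0, 2.0, 3.0], _FixedRng(0.5)) == 1

    def test_single_channel(self):
        rng = np.random.default_rng(1)
        assert all(dm.select_channel([4.2], rng) == 0 for _ in range(10))

    def test_frequencies_multinomial(self):
        rng = np.random.default_rng(11)
        a = np.array([1.0, 2.0, 3.0])
        n = 100_000
        picks = np.bincount([dm.select_channel(a, rng) for _ in range(n)], minlength=3)
        p = a / a.sum()
        for i in range(3):
            sigma = math.sqrt(n * p[i] * (1 - p[i]))
            assert abs(picks[i] - n * p[i]) < 3 * sigma


class TestReschedule:
    def test_identity_when_unchanged(self):
        assert dm.reschedule_after_walk(2.0, 2.0, 5.0, 1.0) == 5.0

    def test_halving(self):
        # a doubles: remaining 1 s shrinks to 0.5 s
        assert dm.reschedule_after_walk(2.0, 4.0, 2.0, 1.0) == pytest.approx(1.5)

    def test_edges(self):
        assert dm.reschedule_after_walk(2.0, 0.0, 5.0, 1.0) == math.inf
        assert dm.reschedule_after_walk(0.0, 3.0, math.inf, 1.0) is None

    def test_rescaling_preserves_exponential_law(self):
        """Piecewise-constant propensity via rescaling vs the analytic survival law."""
        rng = np.random.default_rng(5)
        a0, a1, s = 2.0, 1.0, 0.3
        times = np.empty(10_000)
        for i in range(len(times)):
            t_e = dm.new_interval(a0, rng)
            if t_e > s:  # propensity halves at time s: rescale the remainder
                t_e = dm.reschedule_after_walk(a0, a1, t_e, s)
            times[i] = t_e

        def cdf(t):
            t = np.asarray(t, dtype=float)
            cum = np.where(t < s, a0 * t, a0 * s + a1 * (t - s))
            return 1 - np.exp(-cum)

        ks = stats.kstest(times, cdf).statistic
        assert ks < 0.02


CENTER = (5, 5, 5)


def _worker(cfg):
    compiled = compile_model(cfg)
    return Worker(compiled, decompose(cfg.lattice, 1), 0, NullTransport(), cfg.seed)


class TestExecuteUnimolecular:
    def test_single_product_replaces_in_place(self):
        sp = [SpeciesSpec(name="A", D=0.0, mobile=False), SpeciesSpec(name="B", D=0.0, mobile=False)]
        cfg = build_model(
            species=sp,
            reactions=[ReactionSpec(("A",), ("B",), k=1.0)],
            initial=[InitialPlacement(species="A", coords=(CENTER,))],
        )
        w = _worker(cfg)
        assert w._execute_unimolecular_local(0, 0)
        assert dict(zip(w.c.species_names(), w.st.counts)) == {"A": 0, "B": 1}
        b = int(np.flatnonzero(w.st.mol_alive == 1)[0])
        assert w.st.to_global((w.st.mol_x[b], w.st.mol_y[b], w.st.mol_z[b])) == CENTER

    def _crowded_cfg(self, crowder_mobile, placement_mode):
        lat = LatticeConfig(dims=(12, 12, 12), voxel_radius=5e-3)
        nbs = neighbor_coords(CENTER, lat)
        sp = [
            SpeciesSpec(name="A", D=0.0, mobile=False),
            SpeciesSpec(name="B", D=0.0, mobile=False),
            SpeciesSpec(name="C", D=0.0, mobile=False),
            SpeciesSpec(name="W", D=1.0 if crowder_mobile else 0.0, mobile=crowder_mobile),
        ]
        return build_model(
            species=sp,
            reactions=[ReactionSpec(("A",), ("B", "C"), k=1.0)],
            initial=[
                InitialPlacement(species="A", coords=(CENTER,)),
                InitialPlacement(species="W", coords=tuple(nbs)),
            ],
            placement_mode=placement_mode,
        )

    def test_fully_crowded_neighborhood_fails_reaction(self):
        w = _worker(self._crowded_cfg(False, "fail_if_full"))
        before = w.st.counts.copy()
        assert not w._execute_unimolecular_local(0, 0)
        assert (w.st.counts == before).all()
        w.st.audit()

    def test_vacate_neighbor_rescues_reaction(self):
        # mobile crowders with a vacant second shell can be pushed aside
        w = _worker(self._crowded_cfg(True, "vacate_neighbor"))
        total_before = int(w.st.counts.sum())
        assert w._execute_unimolecular_local(0, 0)
        c = dict(zip(w.c.species_names(), w.st.counts))
        assert c["A"] == 0 and c["B"] == 1 and c["C"] == 1 and c["W"] == 12
        assert int(w.st.counts.sum()) == total_before + 1
        w.st.audit()

    def test_immobile_crowders_cannot_be_vacated(self):
        w = _worker(self._crowded_cfg(False, "vacate_neighbor"))
        assert not w._execute_unimolecular_local(0, 0)
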