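"""Walk event semantics: moves, collisions, volume exclusion, bimolecular firing."""

import math

import numpy as np
import pytest

from latticerd import (
    InitialPlacement,
    LatticeConfig,
    SpeciesSpec,
    ReactionSpec,
    compile_model,
    neighbor_coords,
)
from latticerd.lattice import decompose
from latticerd.runtime import NullTransport, Worker
from latticerd.walk import walk_species_phase1

from conftest import build_model


def make_worker(cfg):
    compiled = compile_model(cfg)
    return Worker(compiled, decompose(cfg.lattice, 1), 0, NullTransport(), cfg.seed)


CENTER = (5, 5, 5)


class TestMoves:
    def test_single_molecule_moves_to_a_neighbor(self):
        cfg = build_model(initial=[InitialPlacement(species="A", coords=(CENTER,))], t_end=1e-5)
        w = make_worker(cfg)
        tau = float(w.c.tau_e[0])
        w.run(t_end=tau)  # exactly one firing, alpha = 1
        pos = w.st.to_global((w.st.mol_x[0], w.st.mol_y[0], w.st.mol_z[0]))
        assert tuple(pos) in neighbor_coords(CENTER, cfg.lattice)

    def test_vanishing_walk_probability_freezes_molecule(self):
        # cap P -> 0 with a diffusion-limited channel makes alpha ~ 0: no hops
        sp = [
            SpeciesSpec(name="A", D=1.0, P=1e-12),
            SpeciesSpec(name="B", D=1.0),
            SpeciesSpec(name="C", D=1.0),
        ]
        k = 10.0 * 6 * math.sqrt(2) * 2.0 * 5e-3  # raw W = 10
        cfg = build_model(
            species=sp,
            reactions=[ReactionSpec(("A", "B"), ("C",), k=k, rate_type="intrinsic")],
            initial=[InitialPlacement(species="A", coords=(CENTER,))],
            t_end=1e-5,
        )
        w = make_worker(cfg)
        assert w.c.alpha[0] == pytest.approx(1e-13, rel=1e-6)
        w.run(t_end=200 * float(w.c.tau_e[0]))
        assert w.st.to_global((w.st.mol_x[0], w.st.mol_y[0], w.st.mol_z[0])) == CENTER

    def test_collision_with_unreactive_occupants_blocks_all_moves(self):
        # a fully packed lattice of mutually unreactive molecules cannot move
        sp = [SpeciesSpec(name="A", D=1.0), SpeciesSpec(name="U", D=0.0, mobile=False)]
        cfg = build_model(
            dims=(8, 8, 8),
            species=sp,
            initial=[
                InitialPlacement(species="A", coords=(CENTER,)),
                InitialPlacement(species="U", phi=1.0),
            ],
            t_end=1e-5,
        )
        w = make_worker(cfg)
        w.run(t_end=50 * float(w.c.tau_e[0]))
        assert w.st.to_global((w.st.mol_x[0], w.st.mol_y[0], w.st.mol_z[0])) == CENTER
        w.st.audit()

    def test_single_occupancy_after_many_events(self):
        cfg = build_model(dims=(10, 10, 10), t_end=1e-5,
                          initial=[InitialPlacement(species="A", count=400)])
        w = make_worker(cfg)
        w.run()
        w.st.audit()  # includes the at-most-one-molecule-per-voxel audit


class TestBimolecular:
    def _surrounded(self, W_raw, products):
        sp = [SpeciesSpec(name="E", D=1.0), SpeciesSpec(name="S", D=0.0, mobile=False),
              SpeciesSpec(name="ES", D=1.0), SpeciesSpec(name="X", D=1.0)]
        cfg = LatticeConfig(dims=(12, 12, 12), voxel_radius=5e-3)
        k = W_raw * 6 * math.sqrt(2) * 1.0 * 5e-3
        nbs = neighbor_coords(CENTER, cfg)
        return build_model(
            species=sp,
            reactions=[ReactionSpec(("E", "S"), products, k=k, rate_type="intrinsic")],
            initial=[
                InitialPlacement(species="E", coords=(CENTER,)),
                InitialPlacement(species="S", coords=tuple(nbs)),
            ],
            t_end=1e-5,
        )

    def test_certain_reaction_on_collision(self):
        # W = 1 and every neighbor is a partner: the first firing must react
        cfg = self._surrounded(1.0, ("ES",))
        w = make_worker(cfg)
        w.run(t_end=float(w.c.tau_e[0]))
        c = dict(zip(w.c.species_names(), w.st.counts))
        assert c == {"E": 0, "S": 11, "ES": 1, "X": 0}
        # product sits in the partner's (target) voxel
        es = int(np.flatnonzero((w.st.mol_alive == 1) & (w.st.mol_species == w.c.sid["ES"]))[0])
        pos = w.st.to_global((w.st.mol_x[es], w.st.mol_y[es], w.st.mol_z[es]))
        assert tuple(pos) in neighbor_coords(CENTER, cfg.lattice)
        w.st.audit()

    def test_two_products_conserve_occupied_voxels(self):
        cfg = self._surrounded(1.0, ("ES", "X"))
        w = make_worker(cfg)
        occupied_before = int((w.st.mol_alive == 1).sum())
        w.run(t_end=float(w.c.tau_e[0]))
        assert int((w.st.mol_alive == 1).sum()) == occupied_before
        c = dict(zip(w.c.species_names(), w.st.counts))
        assert c["ES"] == 1 and c["X"] == 1 and c["E"] == 0
        w.st.audit()

    def test_acceptance_frequency_matches_W(self):
        """Bernoulli oracle: at fixed adjacency the reaction fires with rate W."""
        W = 0.3
        cfg = self._surrounded(W, ("ES",))
        w = make_worker(cfg)
        st = w.st
        snap = {
            name: getattr(st, name).copy()
            for name in (
                "occ_species", "occ_gid", "occ_slot", "mol_species", "mol_gid",
                "mol_x", "mol_y", "mol_z", "mol_alive", "free_stack", "free_top", "counts",
            )
        }
        rng = np.random.default_rng(123)
        slots = st.species_slots(w.c.sid["E"]).copy()
        n_trials, hits = 10_000, 0
        for _ in range(n_trials):
            out = walk_species_phase1(st, slots, rng.random(2), w.next_gid, 1, False)
            hits += out.n_reactions
            for name, arr in snap.items():
                getattr(st, name)[...] = arr
            st.invalidate_slots()
        p = hits / n_trials
        sigma = math.sqrt(W * (1 - W) / n_trials)
        assert abs(p - W) < 3 * sigma
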