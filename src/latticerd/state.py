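"""Per-worker voxel and molecule state.

Each worker owns one subdomain block of the lattice, stored with a one-voxel
shell.  Shell positions are either *ghost voxels* (mirrors of a neighboring
subdomain's out voxels) or, at the global boundary, marked OUTSIDE and never
written.  Three parallel 3D arrays describe occupancy:

``occ_species``  species id of the occupant, VACANT, or OUTSIDE
``occ_gid``      persistent global molecule id of the occupant
``occ_slot``     local molecule-table slot (only for owned molecules)

Molecule attributes live in flat capacity-managed arrays so the walk kernel
can run compiled.  At most one molecule occupies a voxel at all times.
"""

from __future__ import annotations

import numpy as np

from .lattice import DomainLayout
from .model import CompiledModel

VACANT = -1
OUTSIDE = -2

__all__ = ["VACANT", "OUTSIDE", "WorkerState"]


class WorkerState:
    def __init__(self, compiled: CompiledModel, layout: DomainLayout, rank: int, capacity: int = 64):
        self.compiled = compiled
        self.layout = layout
        self.rank = rank
        self.origin = layout.origin(rank)
        self.sub = layout.subdomain_dims
        nx, ny, nz = self.sub
        shape = (nx + 2, ny + 2, nz + 2)
        self.occ_species = np.full(shape, VACANT, dtype=np.int32)
        self.occ_gid = np.full(shape, -1, dtype=np.int64)
        self.occ_slot = np.full(shape, -1, dtype=np.int32)
        # mark shell positions beyond the global lattice as OUTSIDE
        dims = compiled.cfg.lattice.dims
        for axis in range(3):
            if self.origin[axis] == 0:
                self._shell_slice(axis, 0)[...] = OUTSIDE
            if self.origin[axis] + self.sub[axis] == dims[axis]:
                self._shell_slice(axis, 1)[...] = OUTSIDE

        cap = max(capacity, 64)
        self.mol_species = np.full(cap, -1, dtype=np.int32)
        self.mol_gid = np.full(cap, -1, dtype=np.int64)
        self.mol_x = np.zeros(cap, dtype=np.int32)
        self.mol_y = np.zeros(cap, dtype=np.int32)
        self.mol_z = np.zeros(cap, dtype=np.int32)
        self.mol_alive = np.zeros(cap, dtype=np.uint8)
        self.free_stack = np.arange(cap - 1, -1, -1, dtype=np.int32)
        self.free_top = np.array([cap], dtype=np.int64)
        self.counts = np.zeros(compiled.n_species, dtype=np.int64)
        self._slot_cache: dict[int, np.ndarray] = {}
        #: bumped on every membership change; lets callers cache derived slot lists
        self.mutation_counter = 0
        # reusable kernel scratch (grown on demand)
        self._dead_stack = np.empty(256, dtype=np.int32)
        self._dead_top = np.zeros(1, dtype=np.int64)

    def scratch_dead(self, n: int):
        if len(self._dead_stack) < n:
            self._dead_stack = np.empty(max(n, 2 * len(self._dead_stack)), dtype=np.int32)
        self._dead_top[0] = 0
        return self._dead_stack, self._dead_top

    # -- geometry helpers --------------------------------------------------
    def _shell_slice(self, axis: int, side: int):
        idx = [slice(None)] * 3
        idx[axis] = 0 if side == 0 else self.sub[axis] + 1
        return self.occ_species[tuple(idx)]

    def to_local(self, g) -> tuple[int, int, int]:
        return tuple(int(gi - oi + 1) for gi, oi in zip(g, self.origin))

    def to_global(self, l) -> tuple[int, int, int]:
        return tuple(int(li + oi - 1) for li, oi in zip(l, self.origin))

    def owns_global(self, g) -> bool:
        return all(0 <= gi - oi < si for gi, oi, si in zip(g, self.origin, self.sub))

    # -- molecule table ----------------------------------------------------
    @property
    def capacity(self) -> int:
        return len(self.mol_species)

    @property
    def n_free(self) -> int:
        return int(self.free_top[0])

    def ensure_free(self, n: int) -> None:
        """Grow the molecule tables until at least ``n`` free slots exist."""
        while self.n_free < n:
            old = self.capacity
            new = max(old * 2, old + n)
            for name in ("mol_species", "mol_gid", "mol_x", "mol_y", "mol_z", "mol_alive"):
                arr = getattr(self, name)
                grown = np.zeros(new, dtype=arr.dtype)
                grown[:old] = arr
                if name in ("mol_species", "mol_gid"):
                    grown[old:] = -1
                setattr(self, name, grown)
            stack = np.zeros(new, dtype=np.int32)
            top = int(self.free_top[0])
            stack[:top] = self.free_stack[:top]
            stack[top : top + (new - old)] = np.arange(new - 1, old - 1, -1, dtype=np.int32)
            self.free_stack = stack
            self.free_top[0] = top + (new - old)

    def add_molecule(self, sp: int, lx: int, ly: int, lz: int, gid: int) -> int:
        self.ensure_free(1)
        self.free_top[0] -= 1
        slot = int(self.free_stack[self.free_top[0]])
        self.mol_species[slot] = sp
        self.mol_gid[slot] = gid
        self.mol_x[slot] = lx
        self.mol_y[slot] = ly
        self.mol_z[slot] = lz
        self.mol_alive[slot] = 1
        assert self.occ_species[lx, ly, lz] == VACANT, "single-occupancy violation"
        self.occ_species[lx, ly, lz] = sp
        self.occ_gid[lx, ly, lz] = gid
        self.occ_slot[lx, ly, lz] = slot
        self.counts[sp] += 1
        self.mutation_counter += 1
        cached = self._slot_cache.get(sp)
        if cached is not None:  # keep the id-sorted cache incremental
            pos = int(np.searchsorted(self.mol_gid[cached], gid))
            self._slot_cache[sp] = np.insert(cached, pos, slot)
        return slot

    def remove_slot(self, slot: int, clear_voxel: bool = True) -> None:
        sp = int(self.mol_species[slot])
        if clear_voxel:
            lx, ly, lz = int(self.mol_x[slot]), int(self.mol_y[slot]), int(self.mol_z[slot])
            self.occ_species[lx, ly, lz] = VACANT
            self.occ_gid[lx, ly, lz] = -1
            self.occ_slot[lx, ly, lz] = -1
        self.mol_alive[slot] = 0
        self.free_stack[self.free_top[0]] = slot
        self.free_top[0] += 1
        self.counts[sp] -= 1
        self.mutation_counter += 1
        cached = self._slot_cache.get(sp)
        if cached is not None:
            pos = int(np.searchsorted(self.mol_gid[cached], self.mol_gid[slot]))
            self._slot_cache[sp] = np.delete(cached, pos)

    def species_slots(self, sp: int) -> np.ndarray:
        """Slots of the living molecules of a species, ascending by molecule id."""
        cached = self._slot_cache.get(sp)
        if cached is not None:
            return cached
        slots = np.flatnonzero((self.mol_alive == 1) & (self.mol_species == sp))
        order = np.argsort(self.mol_gid[slots], kind="stable")
        slots = slots[order].astype(np.int64)
        self._slot_cache[sp] = slots
        return slots

    def invalidate_slots(self, sp: int | None = None) -> None:
        self.mutation_counter += 1
        if sp is None:
            self._slot_cache.clear()
        else:
            self._slot_cache.pop(sp, None)

    # -- audits (test support) ----------------------------------------------
    def audit(self) -> None:
        """Full consistency check between occupancy arrays and molecule tables."""
        nx, ny, nz = self.sub
        owned_slots = self.occ_slot[1 : nx + 1, 1 : ny + 1, 1 : nz + 1]
        live = np.flatnonzero(self.mol_alive == 1)
        assert len(live) == np.count_nonzero(owned_slots >= 0), "slot/table count mismatch"
        for slot in live:
            lx, ly, lz = self.mol_x[slot], self.mol_y[slot], self.mol_z[slot]
            assert self.occ_slot[lx, ly, lz] == slot, "occ_slot mismatch"
            assert self.occ_species[lx, ly, lz] == self.mol_species[slot], "occ_species mismatch"
            assert self.occ_gid[lx, ly, lz] == self.mol_gid[slot], "occ_gid mismatch"
        counts = np.bincount(
            self.mol_species[live], minlength=self.compiled.n_species
        ).astype(np.int64)
        assert np.array_equal(counts, self.counts), "species counters drifted"
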