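"""The walk event: species-wide random walk with volume exclusion and
bimolecular reactions.

Phase 1 (compiled kernel) processes every molecule of the walking species in
ascending molecule-id order against voxels owned by the worker.  A uniformly
random neighbor index 0-11 picks the target through the parity-dependent HCP
stencil; the move is accepted with the walk probability alpha, a collision
with a reactant partner fires the channel with the rescaled acceptance
probability W, any other occupant blocks the move, and a target beyond the
global lattice is a failed (reflected) attempt.  Targets in the ghost shell
are deferred to phase 2, which the parallel runtime executes subvolume by
subvolume with fresh ghost state.

Random numbers come from the worker's locally seeded Mersenne Twister: two
uniforms per molecule (target choice and acceptance), pre-drawn as one block
and consumed unconditionally so the stream advances identically whatever the
occupancy.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .lattice import NEIGHBOR_OFFSETS
from .state import WorkerState

__all__ = ["walk_species_phase1", "walk_phase1_fast", "WalkOutcome"]


@njit(cache=True)
def _phase1_kernel(
    slots,
    rand,  # 2 uniforms per molecule: target index, acceptance
    mol_species,
    mol_gid,
    mol_x,
    mol_y,
    mol_z,
    mol_alive,
    occ_sp,
    occ_gid,
    occ_slot,
    params,  # ox, oy, oz, dimx, dimy, dimz, gid_stride
    offsets,
    alpha,
    pair_W,
    pair_ch,
    ch_np,
    ch_p1,
    ch_p2,
    counts,
    free_stack,
    free_top,
    dead_stack,
    dead_top,
    next_gid,
    def_buf,  # (n, 4): slot, tx, ty, tz
    def_n,
):
    ox = params[0]
    oy = params[1]
    oz = params[2]
    dimx = params[3]
    dimy = params[4]
    dimz = params[5]
    gid_stride = params[6]
    nx = occ_sp.shape[0] - 2
    ny = occ_sp.shape[1] - 2
    nz = occ_sp.shape[2] - 2
    n_react = 0
    for t in range(slots.shape[0]):
        m = slots[t]
        if mol_alive[m] == 0:
            continue
        sp = mol_species[m]
        lx = mol_x[m]
        ly = mol_y[m]
        lz = mol_z[m]
        gj = oy + ly - 1
        gk = oz + lz - 1
        nbr = int(rand[2 * t] * 12.0)
        if nbr > 11:
            nbr = 11
        o = offsets[gj & 1, gk & 1, nbr]
        tx = lx + o[0]
        ty = ly + o[1]
        tz = lz + o[2]
        gx1 = ox + tx - 1
        gy1 = oy + ty - 1
        gz1 = oz + tz - 1
        if gx1 < 0 or gx1 >= dimx or gy1 < 0 or gy1 >= dimy or gz1 < 0 or gz1 >= dimz:
            continue  # reflective boundary: the attempt fails, molecule stays
        if tx == 0 or tx == nx + 1 or ty == 0 or ty == ny + 1 or tz == 0 or tz == nz + 1:
            d = def_n[0]
            def_buf[d, 0] = m
            def_buf[d, 1] = tx
            def_buf[d, 2] = ty
            def_buf[d, 3] = tz
            def_n[0] = d + 1
            continue
        tsp = occ_sp[tx, ty, tz]
        r = rand[2 * t + 1]
        if tsp == -1:
            if r <= alpha[sp]:
                occ_sp[lx, ly, lz] = -1
                occ_gid[lx, ly, lz] = -1
                occ_slot[lx, ly, lz] = -1
                occ_sp[tx, ty, tz] = sp
                occ_gid[tx, ty, tz] = mol_gid[m]
                occ_slot[tx, ty, tz] = m
                mol_x[m] = tx
                mol_y[m] = ty
                mol_z[m] = tz
        else:
            w = pair_W[sp, tsp]
            if w > 0.0 and r <= w:
                ci = pair_ch[sp, tsp]
                pslot = occ_slot[tx, ty, tz]
                mol_alive[pslot] = 0
                counts[tsp] -= 1
                dead_stack[dead_top[0]] = pslot
                dead_top[0] += 1
                mol_alive[m] = 0
                counts[sp] -= 1
                dead_stack[dead_top[0]] = m
                dead_top[0] += 1
                occ_sp[lx, ly, lz] = -1
                occ_gid[lx, ly, lz] = -1
                occ_slot[lx, ly, lz] = -1
                occ_sp[tx, ty, tz] = -1
                occ_gid[tx, ty, tz] = -1
                occ_slot[tx, ty, tz] = -1
                npd = ch_np[ci]
                if npd >= 1:
                    free_top[0] -= 1
                    s1 = free_stack[free_top[0]]
                    g1 = next_gid[0]
                    next_gid[0] += gid_stride
                    p1 = ch_p1[ci]
                    mol_species[s1] = p1
                    mol_gid[s1] = g1
                    mol_alive[s1] = 1
                    mol_x[s1] = tx
                    mol_y[s1] = ty
                    mol_z[s1] = tz
                    occ_sp[tx, ty, tz] = p1
                    occ_gid[tx, ty, tz] = g1
                    occ_slot[tx, ty, tz] = s1
                    counts[p1] += 1
                if npd == 2:
                    free_top[0] -= 1
                    s2 = free_stack[free_top[0]]
                    g2 = next_gid[0]
                    next_gid[0] += gid_stride
                    p2 = ch_p2[ci]
                    mol_species[s2] = p2
                    mol_gid[s2] = g2
                    mol_alive[s2] = 1
                    mol_x[s2] = lx
                    mol_y[s2] = ly
                    mol_z[s2] = lz
                    occ_sp[lx, ly, lz] = p2
                    occ_gid[lx, ly, lz] = g2
                    occ_slot[lx, ly, lz] = s2
                    counts[p2] += 1
                n_react += 1
            # else: collision (or failed reaction draw) — molecule stays
    return n_react


class WalkOutcome:
    """Deferred (ghost-target) molecules recorded by phase 1.

    ``gids`` snapshots each deferred molecule's id at defer time: a deferred
    molecule can be consumed as a reaction partner later in the same phase, so
    phase 2 must skip slots whose occupant changed.
    """

    __slots__ = ("slots", "targets", "gids", "n_reactions")

    def __init__(self, slots, targets, gids, n_reactions):
        self.slots = slots
        self.targets = targets
        self.gids = gids
        self.n_reactions = n_reactions


_DUMMY_DEF = np.zeros((1, 4), dtype=np.int32)
_DUMMY_I64 = np.zeros(1, dtype=np.int64)


def _params(st: WorkerState) -> np.ndarray:
    p = st.__dict__.get("_kernel_params")
    if p is None:
        dims = st.compiled.cfg.lattice.dims
        p = np.array(
            [*st.origin, dims[0], dims[1], dims[2], 0], dtype=np.int64
        )
        st.__dict__["_kernel_params"] = p
    return p


def walk_phase1_fast(st: WorkerState, slots, rand, next_gid, gid_stride) -> int:
    """Lean single-worker phase 1: no deferral, reusable scratch, returns n_reactions."""
    c = st.compiled
    n = len(slots)
    st.ensure_free(2 * n)
    dead_stack, dead_top = st.scratch_dead(2 * n)
    params = _params(st)
    params[6] = gid_stride
    _DUMMY_I64[0] = 0
    n_react = _phase1_kernel(
        slots,
        rand,
        st.mol_species,
        st.mol_gid,
        st.mol_x,
        st.mol_y,
        st.mol_z,
        st.mol_alive,
        st.occ_species,
        st.occ_gid,
        st.occ_slot,
        params,
        NEIGHBOR_OFFSETS,
        c.alpha,
        c.bi_pair_W,
        c.bi_pair_channel,
        c.ch_n_products,
        c.ch_p1,
        c.ch_p2,
        st.counts,
        st.free_stack,
        st.free_top,
        dead_stack,
        dead_top,
        next_gid,
        _DUMMY_DEF,
        _DUMMY_I64,
    )
    ndead = int(dead_top[0])
    if ndead:
        st.free_stack[st.free_top[0] : st.free_top[0] + ndead] = dead_stack[:ndead]
        st.free_top[0] += ndead
        st.invalidate_slots()
    return n_react


def walk_species_phase1(
    st: WorkerState, slots: np.ndarray, rand: np.ndarray,
    next_gid: np.ndarray, gid_stride: int, allow_defer: bool
) -> WalkOutcome:
    """Run phase 1 for the given (id-ordered) molecule slots on one worker."""
    n = len(slots)
    st.ensure_free(2 * n)
    c = st.compiled
    dead_stack = np.empty(max(2 * n, 1), dtype=np.int32)
    dead_top = np.zeros(1, dtype=np.int64)
    def_buf = np.empty((max(n, 1), 4), dtype=np.int32) if allow_defer else _DUMMY_DEF
    def_n = np.zeros(1, dtype=np.int64)
    params = _params(st)
    params[6] = gid_stride
    n_react = _phase1_kernel(
        slots,
        rand,
        st.mol_species,
        st.mol_gid,
        st.mol_x,
        st.mol_y,
        st.mol_z,
        st.mol_alive,
        st.occ_species,
        st.occ_gid,
        st.occ_slot,
        params,
        NEIGHBOR_OFFSETS,
        c.alpha,
        c.bi_pair_W,
        c.bi_pair_channel,
        c.ch_n_products,
        c.ch_p1,
        c.ch_p2,
        st.counts,
        st.free_stack,
        st.free_top,
        dead_stack,
        dead_top,
        next_gid,
        def_buf,
        def_n,
    )
    # return consumed slots to the free list only after the kernel, so a slot
    # freed by a reaction can never be reused (and walked) within the same event
    ndead = int(dead_top[0])
    if ndead:
        st.free_stack[st.free_top[0] : st.free_top[0] + ndead] = dead_stack[:ndead]
        st.free_top[0] += ndead
    if n_react:
        st.invalidate_slots()
    nd = int(def_n[0])
    dslots = def_buf[:nd, 0].astype(np.int64)
    targets = def_buf[:nd, 1:4].copy()
    return WalkOutcome(dslots, targets, st.mol_gid[dslots].copy(), int(n_react))
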