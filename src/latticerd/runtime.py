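"""Worker lifecycle, RNG streams, ghost exchange, and the run driver.

Every worker executes the same scheduler loop (SPMD): the event queue, the
globally seeded Mersenne Twister and all event times are identical across
workers, so the only communication is the staged ghost/out voxel exchange
inside walk events and the propensity all-gathers of the direct method.

Ghost exchange uses the three-stage directional scheme: a pull before a
subvolume is processed updates ghost voxels consecutively in the x, y and z
directions (later stages forward the just-received shell columns, which is
how edge and corner values travel without diagonal messages), and a push
after processing returns ghost *mutations* in reverse (z, y, x) order.
Pushes carry explicit mutation records rather than whole slabs so that a
molecule that left its out voxel during the same subvolume step cannot be
resurrected by a stale mirror.

Transports: ``null`` (single worker), ``thread`` (all ranks in one process —
the deterministic reference transport used by the test suite, which can also
run white-box coherence and isolation checks), and ``process`` (one OS
process per rank over pipes).
"""

from __future__ import annotations

import json
import math
import queue
import threading
from pathlib import Path

import numpy as np

from . import direct_method as dm
from .errors import CommunicationError, ConfigurationError
from .lattice import NEIGHBOR_OFFSETS, decompose
from .model import CompiledModel, ModelConfig, compile_model
from .scheduler import EventRecord, Scheduler
from .state import OUTSIDE, VACANT, WorkerState
from .walk import walk_phase1_fast, walk_species_phase1

__all__ = ["Worker", "RunResult", "spawn_and_run", "initial_placement"]

_RECV_TIMEOUT = 120.0


# ---------------------------------------------------------------------------
# Transports


class NullTransport:
    """Single-worker transport: no neighbors, trivial allgather."""

    rank = 0

    def sendrecv(self, dst, payload, src):
        if dst is not None or src is not None:
            raise CommunicationError("single-worker run has no neighbors")
        return None

    def allgather(self, obj):
        return [obj]


class ThreadHub:
    """Shared state for the in-process reference transport."""

    def __init__(self, n: int):
        self.n = n
        self.queues = {
            (s, d): queue.Queue() for s in range(n) for d in range(n) if s != d
        }
        self.barrier = threading.Barrier(n)
        self.gather_buf: list = [None] * n

    def endpoint(self, rank: int) -> "ThreadTransport":
        return ThreadTransport(self, rank)


class ThreadTransport:
    def __init__(self, hub: ThreadHub, rank: int):
        self.hub = hub
        self.rank = rank

    def sendrecv(self, dst, payload, src):
        if dst is not None:
            self.hub.queues[(self.rank, dst)].put(payload)
        if src is not None:
            try:
                return self.hub.queues[(src, self.rank)].get(timeout=_RECV_TIMEOUT)
            except queue.Empty:
                raise CommunicationError(
                    f"rank {self.rank}: timeout receiving from rank {src}"
                ) from None
        return None

    def allgather(self, obj):
        self.hub.gather_buf[self.rank] = obj
        self.hub.barrier.wait(timeout=_RECV_TIMEOUT)
        snapshot = list(self.hub.gather_buf)
        self.hub.barrier.wait(timeout=_RECV_TIMEOUT)
        return snapshot


class PipeTransport:
    """One OS process per rank, full mesh of multiprocessing pipes."""

    def __init__(self, rank: int, conns: dict):
        self.rank = rank
        self.conns = conns  # other rank -> Connection

    def sendrecv(self, dst, payload, src):
        if dst is not None:
            self.conns[dst].send(payload)
        if src is not None:
            if not self.conns[src].poll(_RECV_TIMEOUT):
                raise CommunicationError(f"rank {self.rank}: timeout receiving from rank {src}")
            return self.conns[src].recv()
        return None

    def allgather(self, obj):
        for r, c in self.conns.items():
            c.send(obj)
        out = [None] * (len(self.conns) + 1)
        out[self.rank] = obj
        for r, c in self.conns.items():
            if not c.poll(_RECV_TIMEOUT):
                raise CommunicationError(f"rank {self.rank}: allgather timeout from rank {r}")
            out[r] = c.recv()
        return out


# ---------------------------------------------------------------------------
# Initial placement (identical on every worker)


def initial_placement(compiled: CompiledModel, seed: int):
    """Global molecule placement: (species_ids, flat_voxel_indices).

    Uniform-random placements draw distinct voxels from a seeded permutation
    of the lattice, so the arrangement depends only on the seed — not on the
    worker count.  Molecule ids are assigned in placement order.
    """
    cfg = compiled.cfg
    dims = cfg.lattice.dims
    n_vox = cfg.lattice.n_voxels
    rng = np.random.Generator(np.random.MT19937(np.random.SeedSequence((seed, 555))))

    species_out: list[np.ndarray] = []
    voxels_out: list[np.ndarray] = []
    used = set()
    explicit_total = 0
    for p in cfg.initial:
        if p.coords is not None:
            flat = np.array(
                [np.ravel_multi_index(c, dims) for c in p.coords], dtype=np.int64
            )
            for f in flat:
                if int(f) in used:
                    raise ConfigurationError(f"duplicate initial coordinate {f}")
                used.add(int(f))
            species_out.append(np.full(len(flat), compiled.sid[p.species], dtype=np.int32))
            voxels_out.append(flat)
            explicit_total += len(flat)
        elif p.count is not None:
            explicit_total += p.count

    random_counts = []
    for p in cfg.initial:
        if p.count is not None:
            random_counts.append((p.species, p.count, p.region))
        elif p.phi is not None:
            want = int(round(p.phi * n_vox)) - explicit_total
            random_counts.append((p.species, max(want, 0), p.region))
    global_it = None
    for name, count, region in random_counts:
        if count == 0:
            continue
        sid = compiled.sid[name]
        if region is not None:
            ranges = [np.arange(lo, hi, dtype=np.int64) for lo, hi in region]
            ii, jj, kk = np.meshgrid(*ranges, indexing="ij")
            flats = np.ravel_multi_index((ii.ravel(), jj.ravel(), kk.ravel()), dims)
            it = iter(rng.permutation(flats))
        else:
            if global_it is None:
                global_it = iter(rng.permutation(n_vox))
            it = global_it
        chosen = np.empty(count, dtype=np.int64)
        got = 0
        for f in it:
            if int(f) in used:
                continue
            used.add(int(f))
            chosen[got] = f
            got += 1
            if got == count:
                break
        if got < count:
            raise ConfigurationError("not enough vacant voxels for initial placement")
        species_out.append(np.full(count, sid, dtype=np.int32))
        voxels_out.append(chosen)
    if not species_out:
        return np.empty(0, dtype=np.int32), np.empty(0, dtype=np.int64)
    return np.concatenate(species_out), np.concatenate(voxels_out)


# ---------------------------------------------------------------------------
# Worker


class Worker:
    """One subdomain's simulation loop; identical scheduler on every rank."""

    def __init__(
        self,
        compiled: CompiledModel,
        layout,
        rank: int,
        transport,
        seed: int,
        out_dir=None,
        record_trace: bool = False,
        debug_checks: bool = False,
    ):
        self.c = compiled
        self.layout = layout
        self.rank = rank
        self.n_workers = layout.n_workers
        self.transport = transport
        self.seed = seed
        self.out_dir = Path(out_dir) if out_dir is not None else None
        self.record_trace = record_trace
        self.debug_checks = debug_checks
        self.trace: list = []

        self.local_rng = np.random.Generator(
            np.random.MT19937(np.random.SeedSequence((seed, rank + 1)))
        )
        self.global_rng = np.random.Generator(
            np.random.MT19937(np.random.SeedSequence((seed, 0)))
        )

        self.st = WorkerState(compiled, layout, rank)
        sp_ids, flats = initial_placement(compiled, seed)
        dims = compiled.cfg.lattice.dims
        coords = np.stack(np.unravel_index(flats, dims), axis=1) if len(flats) else np.empty((0, 3), dtype=np.int64)
        for gid, (sp, g) in enumerate(zip(sp_ids, coords)):
            if self.st.owns_global(g):
                lx, ly, lz = self.st.to_local(g)
                self.st.add_molecule(int(sp), lx, ly, lz, gid)
        self.next_gid = np.array([len(sp_ids) + rank], dtype=np.int64)
        self.gid_stride = self.n_workers

        # --- events --------------------------------------------------------
        self.events: dict[int, EventRecord] = {}
        self.sched = Scheduler()
        eid = 0
        for group in compiled.walk_groups:
            tau = float(compiled.tau_e[group[0]])
            rec = EventRecord(event_id=eid, kind="walk", interval=tau, payload=tuple(group))
            self.events[eid] = rec
            self.sched.schedule(eid, tau)
            eid += 1
        self.rxn_eid = None
        self.rxn_rates = np.array([k for _, _, k, _, _ in compiled.uni_channels])
        self.rxn_rsids = np.array([r for _, r, _, _, _ in compiled.uni_channels], dtype=np.int64)
        if compiled.uni_channels:
            self.rxn_eid = eid
            rec = EventRecord(event_id=eid, kind="unimolecular_reaction", interval=None)
            self.events[eid] = rec
            eid += 1
        self._logs: dict[int, list] = {}
        for lg in compiled.cfg.loggers:
            kind = "numbers_logger" if lg.kind == "numbers" else "coordinates_logger"
            rec = EventRecord(event_id=eid, kind=kind, interval=lg.interval, payload=lg)
            self.events[eid] = rec
            self._logs[eid] = []
            self.sched.schedule(eid, 0.0)
            eid += 1
        if not self.events:
            raise ConfigurationError("model defines no events")

        self._pending_mut: list = []
        self._counts_dirty = False
        self._group_slots: dict = {}
        self._rxn_initialized = False
        self.rxn_a0 = 0.0
        self.rxn_te = math.inf

    # -- helpers -----------------------------------------------------------
    def _global_counts(self) -> np.ndarray:
        per_rank = self.transport.allgather(self.st.counts.copy())
        return np.sum(per_rank, axis=0)

    def _neighbor_rank(self, axis, side):
        return self.layout.neighbor_rank(self.rank, axis, side)

    # -- main loop -----------------------------------------------------------
    def run(self, t_end: float | None = None):
        t_end = self.c.cfg.t_end if t_end is None else t_end
        if self.rxn_eid is not None and not self._rxn_initialized:
            # first reaction time needs a collective count; must run inside
            # the worker's own thread/process, not at construction
            counts = self._global_counts()
            a = dm.aggregate_propensities(self.rxn_rates, counts[self.rxn_rsids])
            self.rxn_a0 = float(a.sum())
            self.rxn_te = dm.new_interval(self.rxn_a0, self.global_rng)
            if not math.isinf(self.rxn_te):
                self.sched.schedule(self.rxn_eid, self.rxn_te)
            self._rxn_initialized = True
        sched = self.sched
        events = self.events
        while True:
            nxt = sched.pop_due(t_end)
            if nxt is None:
                break
            t, eid = nxt
            rec = events[eid]
            if self.record_trace:
                self.trace.append((rec.kind, t, eid))
            if rec.kind == "walk":
                self._exec_walk(rec)
                rec.n_fired += 1
                self.sched.schedule(eid, rec.interval * (rec.n_fired + 1))
                if self.rxn_eid is not None and (self.n_workers > 1 or self._counts_dirty):
                    # counts (hence propensities) only change when a reaction fired;
                    # with several workers the check itself must stay collective
                    self._update_reaction_after_walk(t)
            elif rec.kind == "unimolecular_reaction":
                self._exec_reaction(t)
            else:
                self._exec_logger(rec, t)
                rec.n_fired += 1
                self.sched.schedule(eid, rec.interval * rec.n_fired)
        self.flush_logs()
        return self

    # -- walk event ----------------------------------------------------------
    def _exec_walk(self, rec: EventRecord):
        sids = rec.payload
        if self.n_workers == 1:
            cached = self._group_slots.get(sids)
            if cached is not None and cached[0] == self.st.mutation_counter:
                slots = cached[1]
            else:
                slot_lists = [self.st.species_slots(s) for s in sids]
                slots = np.concatenate(slot_lists) if len(slot_lists) > 1 else slot_lists[0]
                self._group_slots[sids] = (self.st.mutation_counter, slots)
            n = len(slots)
            if n == 0:
                return
            rand = self.local_rng.random(2 * n)
            if walk_phase1_fast(self.st, slots, rand, self.next_gid, self.gid_stride):
                self._counts_dirty = True
            return
        for sid in sids:
            slots = self.st.species_slots(sid)
            n = len(slots)
            if n:
                rand = self.local_rng.random(2 * n)
                outcome = walk_species_phase1(
                    self.st, slots, rand, self.next_gid, self.gid_stride, True
                )
            else:
                outcome = None
            self._phase2(sid, outcome)

    def _phase2(self, sid: int, outcome):
        """Subvolume-synchronized processing of deferred (ghost-target) walks."""
        st = self.st
        nx, ny, nz = st.sub
        order = self.global_rng.permutation(8)
        if outcome is not None and len(outcome.slots):
            ox_half = (st.mol_x[outcome.slots] > nx // 2).astype(np.int64)
            oy_half = (st.mol_y[outcome.slots] > ny // 2).astype(np.int64)
            oz_half = (st.mol_z[outcome.slots] > nz // 2).astype(np.int64)
            octant = ox_half | (oy_half << 1) | (oz_half << 2)
        else:
            octant = np.empty(0, dtype=np.int64)
        for h in order:
            hvec = (int(h) & 1, (int(h) >> 1) & 1, (int(h) >> 2) & 1)
            self._pull(hvec)
            if outcome is not None:
                for i in np.flatnonzero(octant == h):
                    m = int(outcome.slots[i])
                    if st.mol_alive[m] == 0 or st.mol_gid[m] != outcome.gids[i]:
                        continue  # consumed as a partner during phase 1
                    tx, ty, tz = (int(v) for v in outcome.targets[i])
                    tsp = int(st.occ_species[tx, ty, tz])
                    if tsp == OUTSIDE:
                        raise CommunicationError("deferred target marked outside lattice")
                    gid = int(st.mol_gid[m])
                    if tsp == VACANT:
                        r = self.local_rng.random()
                        if r <= self.c.alpha[sid]:
                            st.remove_slot(m)  # leaves this subdomain
                            st.occ_species[tx, ty, tz] = sid
                            st.occ_gid[tx, ty, tz] = gid
                            self._pending_mut.append([tx, ty, tz, sid, gid, -1])
                    elif self.c.bi_pair_W[sid, tsp] > 0.0:
                        r = self.local_rng.random()
                        if r <= self.c.bi_pair_W[sid, tsp]:
                            ci = int(self.c.bi_pair_channel[sid, tsp])
                            lx, ly, lz = int(st.mol_x[m]), int(st.mol_y[m]), int(st.mol_z[m])
                            partner_gid = int(st.occ_gid[tx, ty, tz])
                            st.remove_slot(m)
                            npd = int(self.c.ch_n_products[ci])
                            if npd >= 1:
                                g1 = int(self.next_gid[0])
                                self.next_gid[0] += self.gid_stride
                                p1 = int(self.c.ch_p1[ci])
                                st.occ_species[tx, ty, tz] = p1
                                st.occ_gid[tx, ty, tz] = g1
                                self._pending_mut.append([tx, ty, tz, p1, g1, partner_gid])
                            else:
                                st.occ_species[tx, ty, tz] = VACANT
                                st.occ_gid[tx, ty, tz] = -1
                                self._pending_mut.append([tx, ty, tz, VACANT, -1, partner_gid])
                            if npd == 2:
                                g2 = int(self.next_gid[0])
                                self.next_gid[0] += self.gid_stride
                                st.add_molecule(int(self.c.ch_p2[ci]), lx, ly, lz, g2)
                    # else: collision with a non-reactive occupant — stay
            self._push(hvec)

    def _slab_indices(self, hvec, d, stage_order):
        """Index arrays over the two non-exchange axes of a stage-``d`` slab.

        Each slab covers the active subvolume's half of the axis *plus one
        voxel* into the neighboring half: an HCP hop from a subvolume-edge
        voxel can target a ghost voxel one row beyond the half boundary.
        Axes exchanged in an *earlier* stage additionally include the shell
        index (that is how edge/corner data crosses without diagonal
        messages), and axes exchanged in a *later* stage include the out
        layer that the later stage will itself send — otherwise the
        forwarded corner columns would carry stale values.  Access to the
        overlap rows stays mutually exclusive because a deferred molecule's
        subvolume is fixed by its *origin*, and origins adjacent to any
        given boundary voxel select pairwise-distinct octants across the
        workers that mirror it.
        """
        out = []
        seen_d = False
        for a in stage_order:
            if a == d:
                seen_d = True
                continue
            n = self.st.sub[a]
            half = n // 2
            if not seen_d:  # exchanged before stage d: include the shell index
                rows = np.arange(0, half + 2) if hvec[a] == 0 else np.arange(half, n + 2)
            else:  # exchanged after stage d: include that stage's send layer
                if hvec[a] == 0:
                    rows = np.unique(np.r_[np.arange(1, half + 2), n])
                else:
                    rows = np.unique(np.r_[1, np.arange(half, n + 1)])
            out.append((a, rows))
        return dict(out)

    def _pull(self, hvec):
        st = self.st
        for d in (0, 1, 2):
            side = hvec[d]
            src = self._neighbor_rank(d, 0 if side == 0 else 1)
            dst = self._neighbor_rank(d, 1 if side == 0 else 0)
            if src is None and dst is None:
                continue
            n_d = st.sub[d]
            send_layer = n_d if side == 0 else 1
            recv_layer = 0 if side == 0 else n_d + 1
            other = self._slab_indices(hvec, d, (0, 1, 2))
            idx_send = [None, None, None]
            idx_recv = [None, None, None]
            idx_send[d] = np.array([send_layer])
            idx_recv[d] = np.array([recv_layer])
            for a, rows in other.items():
                idx_send[a] = rows
                idx_recv[a] = rows
            idx_send = np.ix_(*idx_send)
            idx_recv = np.ix_(*idx_recv)
            payload = None
            if dst is not None:
                payload = (st.occ_species[idx_send].copy(), st.occ_gid[idx_send].copy())
            recv = self.transport.sendrecv(dst, payload, src)
            if recv is not None:
                st.occ_species[idx_recv] = recv[0]
                st.occ_gid[idx_recv] = recv[1]
            if self.debug_checks:
                payload2 = None
                if dst is not None:
                    payload2 = (st.occ_species[idx_send].copy(), st.occ_gid[idx_send].copy())
                recv2 = self.transport.sendrecv(dst, payload2, src)
                if recv2 is not None:
                    if not (
                        np.array_equal(st.occ_species[idx_recv], recv2[0])
                        and np.array_equal(st.occ_gid[idx_recv], recv2[1])
                    ):
                        raise CommunicationError(
                            f"rank {self.rank}: ghost voxels incoherent with owner "
                            f"after pull (axis {d}, side {side})"
                        )

    def _push(self, hvec):
        st = self.st
        nx, ny, nz = st.sub
        pending = self._pending_mut
        self._pending_mut = []
        for d in (2, 1, 0):
            side = hvec[d]
            shell_idx = 0 if side == 0 else st.sub[d] + 1
            outgoing = [m for m in pending if m[d] == shell_idx]
            pending = [m for m in pending if m[d] != shell_idx]
            dst = self._neighbor_rank(d, side)
            src = self._neighbor_rank(d, 1 - side)
            if dst is None and src is None:
                if outgoing:
                    raise CommunicationError(
                        f"rank {self.rank}: ghost mutation at a global boundary (axis {d})"
                    )
                continue
            if dst is None and outgoing:
                raise CommunicationError(
                    f"rank {self.rank}: ghost mutation with no owner (axis {d}, side {side})"
                )
            translated = []
            owner_idx = st.sub[d] if side == 0 else 1
            for m in outgoing:
                mm = list(m)
                mm[d] = owner_idx
                translated.append(mm)
            recv = self.transport.sendrecv(
                dst if dst is not None else None,
                translated if dst is not None else None,
                src,
            )
            for m in recv or []:
                x, y, z, sp, gid, expect_prev = m
                if 1 <= x <= nx and 1 <= y <= ny and 1 <= z <= nz:
                    if self.debug_checks:
                        halves = (
                            (x > nx // 2) == (hvec[0] == 1),
                            (y > ny // 2) == (hvec[1] == 1),
                            (z > nz // 2) == (hvec[2] == 1),
                        )
                        if all(halves):
                            raise CommunicationError(
                                f"rank {self.rank}: pushed mutation targets the active "
                                f"subvolume at {(x, y, z)} — isolation violated"
                            )
                    slot = int(st.occ_slot[x, y, z])
                    prev_gid = int(st.occ_gid[x, y, z])
                    if prev_gid != expect_prev:
                        raise CommunicationError(
                            f"rank {self.rank}: ghost mutation conflict at {(x, y, z)}: "
                            f"expected occupant {expect_prev}, found {prev_gid}"
                        )
                    if slot >= 0:
                        st.remove_slot(slot)
                    if sp >= 0:
                        st.add_molecule(int(sp), int(x), int(y), int(z), int(gid))
                else:
                    # still in our shell: mirror it and forward in a later stage
                    st.occ_species[x, y, z] = sp
                    st.occ_gid[x, y, z] = gid if sp >= 0 else -1
                    pending.append(list(m))
        if pending:
            raise CommunicationError(f"rank {self.rank}: unroutable ghost mutations {pending}")

    # -- unimolecular reaction event ------------------------------------------
    def _update_reaction_after_walk(self, t_s: float):
        counts = self._global_counts()
        self._counts_dirty = False
        a = dm.aggregate_propensities(self.rxn_rates, counts[self.rxn_rsids])
        a_g = float(a.sum())
        if a_g == self.rxn_a0:
            return
        new_t = dm.reschedule_after_walk(self.rxn_a0, a_g, self.rxn_te, t_s)
        if new_t is None:
            new_t = t_s + dm.new_interval(a_g, self.global_rng)
        self.rxn_a0 = a_g
        self.rxn_te = new_t
        self.sched.schedule(self.rxn_eid, new_t)
        self._counts_dirty = False

    def _exec_reaction(self, t: float):
        per_rank = self.transport.allgather(self.st.counts.copy())
        counts = np.sum(per_rank, axis=0)
        a = dm.aggregate_propensities(self.rxn_rates, counts[self.rxn_rsids])
        a_g = float(a.sum())
        if a_g > 0.0:
            u = dm.select_channel(a, self.global_rng)
            ci, rsid, k, products, mode = self.c.uni_channels[u]
            n_total = int(counts[rsid])
            gidx = int(self.global_rng.integers(n_total))
            # owner via prefix sums of per-rank reactant counts
            offset = gidx
            owner = 0
            for r in range(self.n_workers):
                c_r = int(per_rank[r][rsid])
                if offset < c_r:
                    owner = r
                    break
                offset -= c_r
            if self.rank == owner:
                self._execute_unimolecular_local(u, offset)
        per_rank = self.transport.allgather(self.st.counts.copy())
        counts = np.sum(per_rank, axis=0)
        a = dm.aggregate_propensities(self.rxn_rates, counts[self.rxn_rsids])
        a_g = float(a.sum())
        tau = dm.new_interval(a_g, self.global_rng)
        self.rxn_a0 = a_g
        self.rxn_te = t + tau
        self._counts_dirty = False
        if not math.isinf(tau):
            self.sched.schedule(self.rxn_eid, self.rxn_te)

    def _owned_neighbors(self, lx, ly, lz):
        """The ≤12 neighbors of an owned voxel that are themselves owned and in-lattice."""
        st = self.st
        gj = st.origin[1] + ly - 1
        gk = st.origin[2] + lz - 1
        offs = NEIGHBOR_OFFSETS[gj & 1, gk & 1]
        out = []
        nx, ny, nz = st.sub
        for o in offs:
            tx, ty, tz = lx + int(o[0]), ly + int(o[1]), lz + int(o[2])
            if 1 <= tx <= nx and 1 <= ty <= ny and 1 <= tz <= nz:
                out.append((tx, ty, tz))
            else:
                out.append(None)  # shell or outside: not a placement candidate
        return out

    def _execute_unimolecular_local(self, u: int, offset: int) -> bool:
        """Fire unimolecular channel ``u`` on this worker's ``offset``-th reactant."""
        ci, rsid, k, products, mode = self.c.uni_channels[u]
        st = self.st
        slots = st.species_slots(rsid)
        m = int(slots[offset])
        lx, ly, lz = int(st.mol_x[m]), int(st.mol_y[m]), int(st.mol_z[m])
        if len(products) == 0:
            st.remove_slot(m)
            return True
        if len(products) == 1:
            st.remove_slot(m)
            g = int(self.next_gid[0])
            self.next_gid[0] += self.gid_stride
            st.add_molecule(products[0], lx, ly, lz, g)
            return True
        # two products: first replaces the reactant, second needs a vacant neighbor
        neighbors = self._owned_neighbors(lx, ly, lz)
        vacant = [
            nb for nb in neighbors if nb is not None and st.occ_species[nb] == VACANT
        ]
        target = None
        if vacant:
            target = vacant[int(self.local_rng.integers(len(vacant)))]
        elif mode == "vacate_neighbor":
            for j in self.local_rng.permutation(12):
                nb = neighbors[int(j)]
                if nb is None:
                    continue
                osp = int(st.occ_species[nb])
                if osp < 0 or not self.c.mobile[osp]:
                    continue
                nb2s = [
                    q
                    for q in self._owned_neighbors(*nb)
                    if q is not None and st.occ_species[q] == VACANT and q != (lx, ly, lz)
                ]
                if not nb2s:
                    continue
                dest = nb2s[int(self.local_rng.integers(len(nb2s)))]
                oslot = int(st.occ_slot[nb])
                ogid = int(st.mol_gid[oslot])
                st.remove_slot(oslot)
                st.add_molecule(osp, *dest, ogid)
                target = nb
                break
        if target is None:
            return False  # failed unimolecular reaction: state unchanged
        st.remove_slot(m)
        g1 = int(self.next_gid[0])
        self.next_gid[0] += self.gid_stride
        st.add_molecule(products[0], lx, ly, lz, g1)
        g2 = int(self.next_gid[0])
        self.next_gid[0] += self.gid_stride
        st.add_molecule(products[1], *target, g2)
        return True

    # -- loggers --------------------------------------------------------------
    def _exec_logger(self, rec: EventRecord, t: float):
        lg = rec.payload
        if rec.kind == "numbers_logger":
            self._logs[rec.event_id].append((t, self.st.counts.copy()))
        else:
            names = lg.species or tuple(self.c.species_names())
            sids = [self.c.sid[nm] for nm in names]
            rows = []
            for sid in sids:
                for m in self.st.species_slots(sid):
                    g = self.st.to_global(
                        (self.st.mol_x[m], self.st.mol_y[m], self.st.mol_z[m])
                    )
                    rows.append((int(self.st.mol_gid[m]), sid, *g))
            self._logs[rec.event_id].append((t, rows))

    def flush_logs(self):
        if self.out_dir is None:
            return
        self.out_dir.mkdir(parents=True, exist_ok=True)
        names = self.c.species_names()
        for eid, rec in self.events.items():
            if rec.kind == "numbers_logger":
                path = self.out_dir / f"numbers_rank{self.rank}.csv"
                with open(path, "w") as fh:
                    fh.write("time," + ",".join(names) + "\n")
                    for t, counts in self._logs[eid]:
                        fh.write(f"{t:.9g}," + ",".join(str(int(c)) for c in counts) + "\n")
            elif rec.kind == "coordinates_logger":
                path = self.out_dir / f"coordinates_rank{self.rank}.csv"
                with open(path, "w") as fh:
                    fh.write("time,id,species,i,j,k\n")
                    for t, rows in self._logs[eid]:
                        for gid, sid, i, j, kk in rows:
                            fh.write(f"{t:.9g},{gid},{names[sid]},{i},{j},{kk}\n")

    # -- in-memory log access (tests / analysis without file IO) --------------
    def numbers_log(self):
        import pandas as pd

        for eid, rec in self.events.items():
            if rec.kind == "numbers_logger":
                ts = [t for t, _ in self._logs[eid]]
                arr = np.array([c for _, c in self._logs[eid]])
                df = pd.DataFrame(arr, columns=self.c.species_names())
                df.insert(0, "time", ts)
                return df
        return None

    def coordinates_log(self):
        import pandas as pd

        names = self.c.species_names()
        for eid, rec in self.events.items():
            if rec.kind == "coordinates_logger":
                recs = [
                    (t, gid, names[sid], i, j, kk)
                    for t, rows in self._logs[eid]
                    for gid, sid, i, j, kk in rows
                ]
                return pd.DataFrame(
                    recs, columns=["time", "id", "species", "i", "j", "k"]
                )
        return None


# ---------------------------------------------------------------------------
# Run driver


class RunResult:
    """Handle to a finished run: output paths and (in-process) worker states."""

    def __init__(self, cfg, compiled, layout, out_dir, workers=None):
        self.cfg = cfg
        self.compiled = compiled
        self.layout = layout
        self.out_dir = Path(out_dir) if out_dir is not None else None
        self.workers = workers

    def numbers(self):
        """Species counts summed over ranks, as a DataFrame."""
        if self.workers is not None:
            dfs = [w.numbers_log() for w in self.workers]
            dfs = [d for d in dfs if d is not None]
            if not dfs:
                return None
            out = dfs[0].copy()
            for d in dfs[1:]:
                out.iloc[:, 1:] += d.iloc[:, 1:]
            return out
        from .logio import gather_numbers

        return gather_numbers(self.out_dir, self.layout.n_workers)

    def coordinates(self, real: bool = True):
        """All molecule coordinates, ids persistent across subdomains."""
        import pandas as pd

        if self.workers is not None:
            dfs = [w.coordinates_log() for w in self.workers]
            dfs = [d for d in dfs if d is not None]
            if not dfs:
                return None
            df = pd.concat(dfs, ignore_index=True).sort_values(["time", "id"], kind="stable")
            df = df.reset_index(drop=True)
        else:
            from .logio import gather_coordinates

            return gather_coordinates(
                self.out_dir, self.layout.n_workers, self.cfg.lattice, real=real
            )
        if real:
            from .lattice import to_real_array

            xyz = to_real_array(df["i"], df["j"], df["k"], self.cfg.lattice.voxel_radius)
            df[["x", "y", "z"]] = xyz
        return df


def _write_manifest(cfg, compiled, layout, out_dir, transport_name, seed):
    manifest = {
        "model": cfg.to_dict(),
        "derived": _jsonable(compiled.summary()),
        "n_workers": layout.n_workers,
        "worker_grid": list(layout.worker_grid),
        "subdomain_dims": list(layout.subdomain_dims),
        "transport": transport_name,
        "base_seed": seed,
        "rng": "MT19937; global stream SeedSequence((seed, 0)), "
        "local stream SeedSequence((seed, rank+1)); one local stream per worker "
        "serves both walk phases",
        "radius_convention": cfg.radius_convention,
        "events": [
            {"event_id": 0, "note": "event table duplicated on every worker"},
        ],
    }
    Path(out_dir).mkdir(parents=True, exist_ok=True)
    (Path(out_dir) / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def _process_worker_main(cfg_dict, rank, conns, out_dir, seed, t_end):
    cfg = ModelConfig.from_dict(cfg_dict)
    compiled = compile_model(cfg)
    layout = decompose(cfg.lattice, cfg.n_workers)
    transport = PipeTransport(rank, conns)
    w = Worker(compiled, layout, rank, transport, seed, out_dir=out_dir)
    w.run(t_end)


def spawn_and_run(
    cfg: ModelConfig,
    n_workers: int | None = None,
    transport: str = "thread",
    out_dir=None,
    seed: int | None = None,
    t_end: float | None = None,
    record_trace: bool = False,
    debug_checks: bool = False,
) -> RunResult:
    """Run a model to ``t_end`` with N lockstep workers; returns a RunResult.

    ``transport='thread'`` runs all ranks inside this process (deterministic
    reference transport); ``'process'`` forks one OS process per rank and
    requires ``out_dir`` for the per-rank logger files.
    """
    compiled = compile_model(cfg)
    n = n_workers if n_workers is not None else cfg.n_workers
    seed = cfg.seed if seed is None else seed
    t_end = cfg.t_end if t_end is None else t_end
    layout = decompose(cfg.lattice, n)

    if transport == "process":
        if out_dir is None:
            raise ConfigurationError("process transport requires out_dir for logger files")
        import multiprocessing as mp

        cfg2 = ModelConfig.from_dict(cfg.to_dict())
        cfg2.n_workers = n
        cfg2.seed = seed
        ctx = mp.get_context("fork")
        pair_conns = {}
        for a in range(n):
            for b in range(a + 1, n):
                ca, cb = ctx.Pipe(duplex=True)
                pair_conns[(a, b)] = (ca, cb)
        procs = []
        for r in range(n):
            conns = {}
            for (a, b), (ca, cb) in pair_conns.items():
                if a == r:
                    conns[b] = ca
                elif b == r:
                    conns[a] = cb
            p = ctx.Process(
                target=_process_worker_main,
                args=(cfg2.to_dict(), r, conns, out_dir, seed, t_end),
            )
            procs.append(p)
        for p in procs:
            p.start()
        for p in procs:
            p.join(timeout=600)
        bad = [i for i, p in enumerate(procs) if p.exitcode != 0]
        if bad:
            for p in procs:
                if p.is_alive():
                    p.terminate()
            raise CommunicationError(f"worker process(es) {bad} failed; see stderr")
        _write_manifest(cfg2, compiled, layout, out_dir, "process", seed)
        return RunResult(cfg, compiled, layout, out_dir, workers=None)

    if n == 1:
        w = Worker(
            compiled,
            layout,
            0,
            NullTransport(),
            seed,
            out_dir=out_dir,
            record_trace=record_trace,
            debug_checks=debug_checks,
        )
        w.run(t_end)
        if out_dir is not None:
            _write_manifest(cfg, compiled, layout, out_dir, "null", seed)
        return RunResult(cfg, compiled, layout, out_dir, workers=[w])

    if transport != "thread":
        raise ConfigurationError(f"unknown transport {transport!r}")
    hub = ThreadHub(n)
    workers = [
        Worker(
            compiled,
            layout,
            r,
            hub.endpoint(r),
            seed,
            out_dir=out_dir,
            record_trace=record_trace,
            debug_checks=debug_checks,
        )
        for r in range(n)
    ]
    errors: list = [None] * n

    def _target(r):
        try:
            workers[r].run(t_end)
        except BaseException as exc:  # propagate with rank context
            errors[r] = exc

    threads = [threading.Thread(target=_target, args=(r,), daemon=True) for r in range(n)]
    for th in threads:
        th.start()
    for th in threads:
        th.join(timeout=600)
    for r, exc in enumerate(errors):
        if exc is not None:
            raise CommunicationError(f"rank {r} failed: {exc!r}") from exc
    if out_dir is not None:
        _write_manifest(cfg, compiled, layout, out_dir, "thread", seed)
    return RunResult(cfg, compiled, layout, out_dir, workers=workers)
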