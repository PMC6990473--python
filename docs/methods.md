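# Methods

## Lattice geometry

Voxels are spheres of radius `r_v` on a hexagonal close-packed lattice,
addressed by integer coordinates `(i, j, k)` in a "twisted Cartesian" scheme:
the real-space center of a voxel is

    x = 2 r_v (i + ((j + k) mod 2)/2)
    y = √3 r_v (j + (k mod 2)/3)
    z = (2√6/3) r_v k

so neighbor access needs no pointers, only parity conditionals.  The twelve
nearest-neighbor integer offsets depend on the parities of `j` and `k`; the
four offset tables are frozen in `lattice.NEIGHBOR_OFFSETS` (derived from the
parameterization above, ordered in-plane first, then the upper plane, then
the lower plane, each sorted by `(dj, di)`).  Their validity is enforced by a
test that compares them against a brute-force nearest-site search in real
coordinates for every interior voxel of a 10³ lattice; neighbor symmetry and
the equal-distance property (all neighbors at `2 r_v`, relative tolerance
1e-9) are tested exhaustively on an 8³ lattice.

Units are μm and seconds throughout; modulo operations use non-negative
residues; coordinates are 0-based.  Boundaries are reflective only: a hop
whose target lies outside the lattice fails and consumes the molecule's
attempt for that event.  A model file may give `voxel_radius` directly or a
`molecule_radius` R, in which case `r_v = 1.0209 R` (the voxel size at which
lattice kinetics match the Smoluchowski–Collins–Kimball continuum framework);
the convention used is echoed in the run manifest.

## Events and scheduling

A priority queue ordered by (time, event id) drives four event kinds: walk,
unimolecular reaction, species-numbers logger and coordinates logger.  Ties
break on event id (creation order), so the pop sequence is deterministic.
Fixed-interval events compute their n-th firing time as `n × interval` by
multiplication, keeping times bit-identical across workers and free of
accumulated rounding; the run ends when the next event time exceeds `t_end`
(inclusive at equality).

Mobile species whose derived walk intervals `τ_e` are bitwise identical are
scheduled as one *walk group* that executes its species consecutively in
species-id order.  This is exactly the order separate per-species events
with equal times would execute under the tie-break rule; grouping only
removes per-event overhead.  In single-worker runs the group is processed as
one concatenated sweep whose membership is snapshotted at the start of the
firing, so molecules created during the firing first walk at the next one;
in multi-worker runs each species completes its full two-phase walk before
the next species starts.

## Walk event

For each molecule, in ascending molecule-id order: draw a uniform neighbor
index (0–11); if the target is outside the lattice, stay (reflection); if it
is a ghost voxel, defer to phase 2; if vacant, move with probability α_i; if
occupied by a reactant partner, react with the rescaled probability W_ij;
otherwise collide and stay.  Two uniforms per molecule are pre-drawn from
the worker's local Mersenne Twister and consumed unconditionally, so the
stream advances identically whatever the occupancy pattern.  Bimolecular
products are placed with the first product in the partner's (target) voxel
and the second, if any, in the mover's vacated voxel — a convention that is
symmetric in distribution for equal-diffusivity reactants.  ρ_i is computed
at model build time as the maximum raw W over all channels involving the
species; on a collision the raw W is rescaled by the α of the *moving*
molecule's species, compensating for that species' increased event
frequency.  One bimolecular channel per unordered species pair is allowed;
multi-channel collision arbitration is deliberately unsupported.

## Unimolecular reactions (parallel direct method)

Per-channel propensities use global reactant counts (`a_j = k_j N_j`)
assembled by an all-gather; waiting times and channel selections are drawn
from the globally seeded stream, so every worker computes the same firing
without synchronization.  The reacting molecule is chosen by drawing a
global index and mapping it through per-worker prefix sums; the owning
worker resolves it by offset into its id-sorted molecule list.  After a walk
event changes counts, the scheduled time is rescaled by `a_0(t_e − t_s)/a_g`
(a fresh interval is drawn when the propensity rises from zero; the event is
postponed indefinitely when it vanishes).  In single-worker runs the
propensity update is skipped when no reaction fired during the walk event —
the counts, hence the update, would be a no-op.

With two products, the first replaces the reactant in place and the second
goes to a uniformly chosen vacant neighbor.  If no neighbor is vacant, the
`fail_if_full` rule fails the reaction outright; the `vacate_neighbor` rule
tries the twelve neighbors in a random order, moving a *mobile* occupant to
one of its own vacant neighbors to make room, and fails only if no neighbor
can be vacated.  Placement candidates are restricted to voxels owned by the
executing worker: ghost mirrors are stale between walk events, and the
slight boundary bias this introduces affects only multi-worker runs, which
are validated statistically rather than molecule-by-molecule.  Product
molecules receive fresh ids (rank-strided counters keep them globally
unique); id persistence across subdomains applies to diffusing molecules.

## Domain decomposition and communication

The lattice splits into equal blocks (even dimensions, so each subdomain
divides into 2×2×2 subvolumes) with a one-voxel ghost shell.  Within a walk
event, the eight subvolumes are processed in an order shuffled by the global
stream, identical on every worker.  Before a subvolume is processed, its
ghost voxels are *pulled* with a three-stage directional exchange (x, then
y, then z; later stages forward the shell columns received earlier, which is
how edge and corner values cross without diagonal messages).  After
processing, ghost *mutations* — molecule arrivals and reaction products —
are *pushed* back in reverse stage order as explicit records rather than
slab copies, so a molecule that left its out voxel during the same step can
never be resurrected by a stale mirror.

Each exchanged slab covers the subvolume's half of each transverse axis
*plus one voxel* (an HCP hop from a subvolume-edge voxel can target a ghost
voxel one row past the half boundary), plus — for axes exchanged in a later
stage — the out-voxel layer that the later stage itself sends, so the
forwarded edge/corner columns are fresh rather than stale.  Mutual
exclusion survives this overlap because a deferred molecule's subvolume is
fixed by its origin, and the origins adjacent to any boundary voxel select
pairwise-distinct octants across the workers that mirror it.  Every pushed
mutation carries the molecule id the sender observed at the target, and the
owner refuses to apply a mutation whose prior occupant does not match — a
permanent runtime invariant that turns any exclusion violation into an
immediate error instead of a silently lost molecule.  A debug mode (used by
the tests) additionally re-fetches every pulled slab to assert ghost–owner
coherence and verifies that no pushed mutation ever targets the receiver's
active subvolume.

Transports: `thread` (all ranks in one process, deterministic reference
implementation), `process` (one OS process per rank over pipes, fork start
method), and a trivial null transport for single-worker runs.  Per-worker
RNG streams are MT19937: the global stream is seeded from
`SeedSequence((seed, 0))` and the local streams from
`SeedSequence((seed, rank+1))` — a seed-derivation choice that keeps the
rank-0 local stream distinct from the global one (a plain XOR of seed and
rank would make them identical).  One local stream serves both walk phases.
Initial placement is computed identically on every worker from
`SeedSequence((seed, 555))`, so molecule arrangements and ids do not depend
on the worker count.

## Validation fixtures and what they do (and do not) show

All validation inputs are generated, not loaded.  The fixtures reproduce the
published study conditions at full scale and accept a `scale` factor that
shrinks linear lattice dimensions while preserving concentrations, occupancy
fractions and rate constants.  Desk-scale conditions used by the test suite
(chosen once for statistical adequacy within a workstation-size run, and
fixed):

- **Free diffusion** — an ensemble of 20 dilute runs × 50 walkers (1000
  trajectories) on 64³ lattices, walkers starting in the central half-box
  (the published runs start a single tracer at the lattice center), log
  interval aligned to 4 hops, 40 hops total.  Acceptance: fitted D within 5%
  of the model D.  Uniform whole-lattice placement would mix in reflective-
  wall suppression; dense single-run ensembles add ~2–3% self-crowding bias.
- **Crowded diffusion** — 32-scale lattice, immobile crowders at φ ∈
  {0, 0.3, 0.5}, fresh arrangement per seed; checks strict monotonicity of
  the fitted effective D.
- **Irreversible dissociation** — 10⁴ molecules, k = 10 s⁻¹ (the published
  rates are not printed; the value is immaterial to the scaled law), 96³
  lattice with 80 nm voxels (dilute decay statistics are independent of the
  voxel size; the coarser lattice just reduces hop events), 30 replicate
  seeds, compared at t = 3/k against N₀e^{−kt} within 2%.
- **Crowded dissociation** — the published 64³/90 μm³ geometry (at scale 0.5
  for the routine suite), total initial occupancy φ counting the reactants,
  mobile crowders, reactant pool ≈ 6% of voxels so product growth cannot
  exhaust the lattice at φ = 0.9, compared at t = 2/k.  Operationalization,
  fixed up front: "matches the ODE" = |deviation| < 15%, "visibly slows" =
  deviation > 50%.  Observed: ≈ +7% (φ=0.7, fail-if-full), ≈ +130% (φ=0.9,
  fail-if-full), ≈ +9% (φ=0.9, vacate-neighbor).
- **Reversible association** — published rates (k_f = 2 μm³/s,
  k_r = 1.35 s⁻¹, D = 10 μm²/s, 5 nm voxels) on a 192³ lattice (scale 0.2,
  512 B + 512 C), run to 0.25 s with the final 0.1 s time-averaged;
  acceptance: equilibrium A within 3% of the effective-rate ODE.
- **Michaelis–Menten benchmark** — fixture ships the published 909 μm³ /
  9090 E / 90910 S model; its 64³ lattice yields the published ≈0.5 ms walk
  interval.  It is exercised through the ODE conservation tests and the CLI.
- **MAPK cycle** — rate constants from the distributive MAPK literature
  model (association 0.027 and 0.056 nM⁻¹s⁻¹, dissociations 1.35 and
  1.73 s⁻¹, catalysis 1.5 and 15 s⁻¹, enzyme reactivation τ_rel = 1 μs),
  which reproduce this simulator's published walk schedule at D = 0.06
  μm²/s (τ_d = 72 μs, α = 0.028, τ_e = 2 μs) exactly.  Desk scale: 176³
  lattice (≈ 0.5 μm³, 61 K + 15 KK + 15 P, concentrations preserved), 8 s
  per run with the final 2 s averaged, response measured at KK₀/P₀ ∈
  {0.5, 2}.  Acceptance is qualitative, as scaled: the response spread is
  larger at D = 4 μm²/s (switch-like, observed ≈ 0.67) than at
  D = 0.06 μm²/s (graded, observed ≈ 0.39).  Eight seconds does not reach
  the fully developed steady state of the published 300 s runs; the
  steepness ordering is already stable and is the claim under test.

What passing these tests shows: the lattice geometry, walk statistics,
SCK acceptance machinery, direct-method timing and parallel exchange are
mutually consistent and reproduce well-mixed kinetics in their validity
regimes.  What they do not show: agreement with off-lattice continuum
dynamics for strongly crowded diffusion (effective-D values on a lattice
differ from continuum hard-sphere suspensions), behavior of multi-voxel or
differently sized molecules (unsupported), surface (2D) diffusion, or
periodic boundaries.

## Numerical choices

- Event-time ties: ascending event id; event times from multiplication, not
  accumulation; no floating-point tolerances in the scheduler.
- Neighbor index from `⌊12u⌋` of a uniform `u ∈ [0,1)` (clamped at 11).
- Kernel state lives in flat capacity-doubled arrays; slots freed by a
  reaction within a walk sweep are quarantined until the sweep ends so a
  product can never be iterated in the event that created it; a deferred
  molecule consumed as a partner during phase 1 is recognized in phase 2 by
  an id snapshot and skipped.
- Degenerate inputs: `a_g = 0` schedules the reaction event at infinity;
  propensity rising from zero draws a fresh interval (the rescaling formula
  would divide by zero); `log(0)` guards in the exponential sampler.
- The ODE baseline integrates mass-action kinetics with *effective* rates
  (LSODA, rtol 1e-8), which is the correct comparison target for converted
  intrinsic-rate simulations.

## Known limitations

Only elementary (uni/bimolecular) channels; no compartment-scale well-mixed
species; one bimolecular channel per species pair; product placement for
multi-worker unimolecular reactions is restricted to owner-held voxels; the
process transport targets correctness, not speed (Python pipes, no
overlapping communication); wall-clock scaling of the original
supercomputer implementation is out of scope.
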