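# Methods

## Scope and data model

The package analyzes equilibrium trajectories of membrane water channels.
Everything operates on a single in-memory `Trajectory` (atom table +
timestamped coordinate frames); coordinates are in Å and times in ps
throughout, and permeabilities are converted to cm³ s⁻¹ only when reported.
PDB (multi-MODEL), multi-frame XYZ and optionally DCD are read through
MDAnalysis. Periodic boundary conditions are *not* unwrapped: the analysis
assumes the channel-forming molecule and its waters are whole and contiguous
in the input, as is the case for typical post-processed channel trajectories
and for the synthetic data.

A channel is described per monomer by a `ChannelDefinition`: two boundary
atoms whose axial positions delimit the constriction region (CR), a unit
axis vector (the membrane normal, global +z by default; configurable per
monomer), and a lateral cutoff (default 8 Å — generous against typical
~2 Å pore radii yet far below the ~25 Å spacing of neighbouring monomers,
so waters cannot be captured by the wrong channel; ties go to the nearest
axis, making per-monomer water sets a partition). Axial coordinates are
measured from the midpoint of the two boundary atoms, which makes them
exactly invariant under rigid translations of the frame. The CR interval is
taken from the *instantaneous* boundary-atom positions by default; a fixed
z-window mode exists for reproducing published profile axes whose interval
conventions differ (published CR bounds are quoted variously as −9…12 Å and
−9…11 Å; with instantaneous bounds the package does not need to pick one).

## Diffusive permeability p_d

Event detection is a per-water, per-monomer state machine over the frame
sequence with five states: axially below, inside, axially above, and
"beside the channel" in the lower or upper half (within the axial interval
but past the lateral cutoff). A complete permeation event requires entry
through one axial boundary and exit through the opposite one; backing out
through the entry boundary or drifting out sideways resets the state
without an event, and waters already inside at the first analyzed frame
have an unknown entry side and can never complete an event — only full
lumen traversals count. The axial interval is half-open
(z_bottom ≤ z < z_top) so a water exactly on a boundary belongs to exactly
one side. Detection is exact as long as no water crosses the full
boundary-to-boundary span within one frame stride.

From the bidirectional count N±, k₀ = N±/(2 n_m t_sim) and p_d = v_w k₀
with v_w = V_w/N_A (18.0 cm³ mol⁻¹ / 6.022×10²³ ≈ 2.99×10⁻²³ cm³). The
analyzed span t_sim excludes a configurable burn-in (default 0). Reports
carry both the pooled (all-monomer) value and per-monomer values whose
mean ± sample SD forms the aggregate column.

## Osmotic permeability p_f

The collective coordinate accumulates, per frame pair, the axial
displacements of CR waters in units of the average CR length L̄ (the
time-averaged Euclidean distance between the two boundary atoms, frozen per
analysis run). Which waters contribute is a genuine convention choice:

- **either_clipped (default):** waters inside at either endpoint contribute
  the part of their displacement lying inside the CR (z clipped to the
  interval at both endpoints). A concerted advance of a file of N waters
  then contributes exactly dn = 1.
- **both_inside:** only waters inside at both endpoints contribute. This
  drops the entering/leaving half-steps, and for single-file hopping biases
  D_n low by ≈((N−1)/N)² — about 27 % at N = 7, measured directly on the
  simulator — so it is not the default.

⟨n²(τ)⟩ is averaged over multiple time origins (default: 100 ps windows,
non-overlapping — a 20 ns series yields exactly 200 origins; overlapping
strides are available). D_n is the least-squares slope/2 of ⟨n²⟩ versus lag
over τ ∈ [10, 100] ps with a free intercept: the lower bound skips the
correlated onset, and the fitted intercept absorbs any residual offset.
Fitting slope rather than forcing the origin makes the estimate robust to
short-lag anticorrelation. A negative fitted slope (possible in very short
noisy runs) clamps to D_n = 0 with a warning. p_f = v_w D_n, and
p_f/p_d is reported per monomer and as mean ± SD; it is undefined (NaN)
when p_d = 0.

Membrane-level osmotic permeabilities P_f (μm s⁻¹) are converted to
single-channel values by dividing by the channel areal density (channels
per cm²).

## Occupancy and water orientation

Occupancy is the per-frame CR water count; its histogram, mean and
sample SD are reported per monomer, with the cross-monomer mean ± SD as the
aggregate. Dipole order parameters use the geometric (HOH-bisector) dipole
direction — identical in direction to the point-charge dipole for
symmetric-charge three-point waters; a charge-weighted mode is available.
Each CR water contributes cos θ = d̂·n̂_z to the 1 Å bin (default) of its
oxygen's axial coordinate; P₁ and P₂ pool all frames and waters per bin,
and the error bars are the SD across per-frame bin means. Bins never
visited are NaN (missing), not zero. Bounds −1 ≤ P₁ ≤ 1 and
−0.5 ≤ P₂ ≤ 1 hold by construction.

## Pore radius

At each axial station the pore radius is max over in-plane centers c of
min_i(|c − xᵢ| − Rᵢ). The maximization is a deterministic multi-start
pattern search (starts: the previous station's optimum plus a ring of eight
0.8 Å offsets around the axis point; 8-direction moves, step 0.5 Å halved
to 10⁻³ Å, confined to a 5 Å in-plane search radius). On random atom clouds
it agrees with a dense 0.05 Å grid search to within 0.05 Å, and it is
reproducible without the tuning that stochastic annealing needs. Stations
march along the axis at 0.5 Å (default), each seeded with the previous
center; negative clearance (an occluded plane) is recorded as radius 0 with
an occluded flag. Waters, lipid-like residues and the synthetic boundary
markers are excluded from the atom set by default. Radii come from the atom
table (Bondi by default); a HOLE-compatible table is provided — the two
differ by up to ~0.2 Å for some elements, shifting absolute profiles
accordingly, which is why absolute comparisons between radius sets are
qualitative.

## Structural metrics

RMSD uses closed-form Kabsch superposition (SVD with a determinant
correction so the rotation is always proper; collinear point sets are
rejected). Superposition defaults to on — without it, per-monomer RMSD is
confounded by drift of the whole assembly. RMSF superposes each frame onto
the mean structure and recomputes the mean once, per monomer by default.
Average structures are plain per-atom coordinate means over a frame window,
optionally after superposition.

## Synthetic single-file channels

The generator provides trajectories whose transport statistics are known
exactly, in the same formats and geometry the analysis consumes: lattice
sites spanning the CR at the water–water hydrogen-bond spacing (2.8 Å),
reservoir waters stacked beyond each mouth, three-point waters with a
bipolar dipole field (pointing toward the channel midplane from both
sides), small transverse jitter, and static boundary-marker atoms defining
the CR.

Transport follows the continuous-time random-walk picture of single-file
channels, with two elementary mechanisms mixed by the interchange
probability q:

- **concerted column shifts** at rate (1−q)k per direction — the whole file
  advances one site; the leading water exits into one reservoir and a new
  water enters from the other. This is single-file exclusion in its exact
  form: no water advances unless the column does.
- **bypass (interchange) hops** at rate qk per water per direction (with
  matching entry propensities at the mouths) — a water slips past its
  neighbours independently, the microscopic event behind water–water
  interchange.

Both limits are closed-form. A new entrant must win an (N+1)-step
gambler's ruin before exiting the far side, so k₀ = k/(N+1) for every q,
while the collective coordinate steps ±1 per shift and ±1/N per bypass hop,
giving D_n = (1−q)k + qk/N and hence p_f/p_d = (N+1)(1−q+q/N): the
single-file relation N+1 at q = 0, and (N+1)/N ≈ 1 at q = 1, where tagged
waters are independent walkers. A long-dynamics check (10 μs of hopping)
reproduces the k₀ closed form to within sampling error. Dynamics are
generated by an exact Gillespie algorithm and only *sampled* onto the fixed
frame grid, so frame aliasing is a test dimension rather than a model
property; reservoir queues are FIFO and are equalized between frames by
recirculating their longest-rested members (bulk mixing), which keeps the
finite pools from ever reflecting the collective walk while staying
consistent with frame-level event detection.

Default parameters emulate an aquaporin-scale channel: n_sites = 8
(occupancy exactly 8 at q = 0), spacing 2.8 Å, frame interval 2 ps, and
hop rate 2.5 ns⁻¹, which yields k₀ ≈ 0.28 ns⁻¹ and p_f ≈ 7.5×10⁻¹⁴
cm³ s⁻¹ — the magnitudes reported for real aquaporin tetramer simulations.
What the generator does **not** emulate: continuous sub-site water motion,
protein flexibility and water–protein energetics, correlated occupancy
fluctuations, and membrane/solvent structure. Passing the validation suite
therefore demonstrates that the estimators are correct for the transport
statistics they assume, not that those assumptions hold for any particular
force field or channel.

Geometric fixtures complete the validation: stacked-ring cylinder and
tapered pores with analytic radius profiles, and water sets with prescribed
dipole fields (aligned, perpendicular, isotropic, bipolar with a smooth
inversion of width 3 Å at a configurable midplane).

## Validation problem sizes

The end-to-end single-file check runs a 7-site tetramer for 200 ns of
simulated hopping at 2 ps sampling (≈500 traversals) and requires the
pipeline-recovered p_f/p_d within 25 % of N+1 = 8; the full-interchange arm
uses 50 ns (interchange multiplies the event statistics). Estimator
recovery uses a 20 ns synthetic random walk (exactly 200 non-overlapping
100 ps origins, 20 % tolerance) and exact event-log agreement on a 50 ns
two-monomer run. Geometry oracles use the cylinder fixture (0.05 Å) and
10⁵ isotropic dipoles (|P₁|, |P₂| ≤ 0.01).

## Conventions and known limitations

- Aggregates are arithmetic mean ± *sample* (n−1) SD of per-monomer values;
  presentation tables round to one decimal in 10⁻¹⁴ cm³ s⁻¹, and rounding
  never feeds back into computation (the JSON report is full precision).
- Worked-example arithmetic for the published tetramer uses t_sim = 19 ns
  (20 ns production minus 1 ns burn-in), matching the printed calculation;
  burn-in is configurable for other data.
- Chain-to-monomer mapping is user configuration; nothing is inferred from
  chain order.
- The default axis is the global membrane normal; strongly tilted channels
  need a per-monomer axis in the channel definition.
- Event detection and the collective coordinate assume the sampling theorem
  of their state machines: no full CR traversal (events) within one frame
  stride.
- The pattern-search pore radius assumes convex-ish cross-sections; deeply
  lobed cross-sections could in principle trap it, which the multi-start
  ring mitigates but does not exclude.
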