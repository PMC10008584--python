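# Methods

## Protomer-state bookkeeping

A dodecameric gap-junction channel contributes 12 symmetry-expanded records
to a subunit-focused classification table (6 under C6). `expand_symmetry`
replicates each particle over the 60°-grid of in-plane rotations, crossed
with the two hemichannel views for D6; the expansion rotation is stored in
`rot_deg` and fixes the ring position as `position_index =
round(rot_deg/60) mod 6`, with `hemichannel_index = 1` for the flipped view
(tilt > 90°). The sign convention for the rotation is not dictated by the
data model; we fix the one above and keep it consistent between the
generator, the expander and the reader, which is all the downstream
statistics require.

Particle identity is the verbatim `rlnImageName` string — never parsed —
and class numbers map to states through an explicit `ClassStateMap`. The
default eight-class map (classes 5, 6, 8 flexible; 1–4, 7 pore-lining)
reflects a typical protomer-focused classification outcome, and any map can
be supplied. Third states (e.g. a gate-covering conformation) are carried as
`OTHER` and excluded from the binary FN:PLN statistics rather than folded
into either group.

`group_by_particle` deduplicates on `(particle_id, hemichannel_index,
position_index)` before counting — the natural key for "the same protomer
view appearing twice" — and excludes (never imputes) particles whose record
multiplicity differs from the group order after deduplication; both
removals are reported. Hetero-junctional selection labels a hemichannel ring
PLN-group or FN-group when at least `threshold` of its six protomers share
that state (default: all six). This is a protomer-count approximation of
selection by hemichannel-level 3D classes; the threshold is exposed because
the appropriate stringency depends on per-protomer classification accuracy.
Thresholds ≤ 3 are rejected as ambiguous.

State fractions are computed per protomer record (each of the 12 subunits
counts once); weighting per particle instead would only differ if
incomplete particles were retained, which they are not.

## Ring-arrangement statistics

Length-6 state strings are reduced to necklace classes under cyclic rotation
only — the two faces of a docked hemichannel are distinguishable, so
reflections are not identified. Enumerating the 64 strings gives 14 classes
with multiplicities {1,1,3,4,3,1,1} for k = 0…6 (Burnside:
(64+8+8+4)/6). Under independence a class with orbit size m has expected
count `N·m·pᵏ(1−p)⁶⁻ᵏ`, which sums to N for any p.

The goodness-of-fit test is Pearson's χ² with classes of expected count < 5
pooled into one bin and `df = bins − 1 − 1` when p is the plug-in estimate
from the same rings (the default; a fixed-p mode keeps the full df). An
exact multinomial Monte-Carlo variant (default 10,000 replicates,
seed mandatory, add-one-corrected p-value) is available for very sparse
tables. The adjacency statistic — mean cyclically-adjacent same-state pairs
per ring — is calibrated by permuting states across positions within each
ring, which conditions on the observed ring compositions and therefore
isolates positional clustering from composition effects. Wilson 95%
intervals are used for state fractions because they behave correctly at the
p → 0/1 boundaries that uniform-state datasets produce.

## Synthetic metadata generator

Protomer states are drawn per hemichannel ring from a 6-cycle Ising model
with spin +1 for pore-lining: `P(σ) ∝ exp(J Σσᵢσᵢ₊₁ + h Σσᵢ)`. J = 0 gives
exact independent Bernoulli(p) states — the condition the composition
analysis assumes — and J ≠ 0 produces controlled neighbour coupling for
power studies. The field h is solved from the exact single-site marginal
(direct enumeration of the 64 ring states, equivalent to the transfer-matrix
trace at this size) by Brent root-finding to 10⁻¹² so that the marginal
equals p for any J. Sampling uses a position-sequential Gibbs sweep
vectorised across rings with 500 burn-in sweeps from a Bernoulli(p) start;
its total-variation distance to the exact distribution is tested at 10⁶
samples (< 0.01) for representative (p, J) settings. Class ids are drawn
uniformly within each state's class list, and records are emitted exactly
as `expand_symmetry` would lay them out, so generated tables exercise the
same code paths as real metadata. Defaults (p = 0.57, eight classes split
5/3) mirror the protomer-state equilibrium the package is designed to
analyse.

The two rings of a particle are sampled independently: the generator
encodes no trans-junctional coupling, matching the observation that the
two docked hemichannels change conformation independently. What the
generator does **not** emulate: per-protomer misclassification noise,
particle-quality covariates, or preferred-orientation effects — so passing
tests demonstrate correctness of the bookkeeping and statistics, not
robustness to classification error in real data.

## Ion permeation

The channel axis is z with the junction midplane at z = 0. Crossing events
use two-plane hysteresis with a default gate of ±5 Å: an ion last below the
lower plane that first rises above the upper plane scores one up-crossing.
This suppresses the diffusive recrossing noise a single plane would count.
Periodic wrap jumps (|Δz| > box/2) re-arm the detector without counting, as
they move the ion between reservoir ends rather than through the gate. The
current is `I = q·e·(n_up − n_down)/T`; its uncertainty is the standard
error over 20 contiguous time blocks. Conductance follows the exact unit
chain `g[pS] = 10⁶·I[nA]/V[mV]`, and the viscosity-corrected value divides
by 3.0 (overridable): the rigid three-site water models used in typical
simulations are roughly three-fold less viscous than real water, inflating
diffusion coefficients and thus currents by about that factor.

Concentration profiles convert mean cylinder-bin occupancy to molarity via
`π r² Δz × 10⁻²⁷ L`. The density–flux map accumulates time-averaged number
density per voxel and the occupancy-weighted mean step velocity (periodic-
unwrapped displacement / dt, assigned to the step midpoint's voxel); density
times flux is the local current density. An axial displacement-based current
profile (`axial_current_profile`, Σδz per slab scaled by q·e/(T·L_slab)) is
provided as a lower-variance cross-check of the crossing-count current; the
two agree within 5% on long drift-dominated synthetic runs and the profile's
flatness is a stationarity diagnostic. Where along the axis flux peaks is
left to the user to read from the profile; the estimators make no claim
about its argmax.

## Drift–diffusion generator and its oracle

Ions follow overdamped Langevin dynamics in a cylinder: `Δz = (D q E(z)/kT +
D F_well/kT)Δt + √(2DΔt)·ξ`, isotropic diffusion in x,y with reflection at
the wall, z-periodic. The field `E = V/L_pore` acts only inside the pore
segment, a deliberate simplification of a double-bilayer simulation box in
which the applied potential drops across the junction. Optional Gaussian
axial wells (depth in kT, centre, width) mimic acidic binding bands; a
2 kT well raises local occupancy by ≈ e² as a Boltzmann check. Construction
rejects timesteps whose maximum drift per step exceeds 0.5 Å. With
`pore_length == box_length` the system is homogeneous and the crossing
current must equal the constant-field Nernst–Planck value `I = q·e·c·A·v`
with `v = D q E/kT` — the closed-form oracle, which refuses configurations
(wells, partial field) where it is not exact. Test problem sizes (tens of
ions, 30–60 ns at 1 ps steps) are chosen so that 3 block-SE bands give the
oracle comparisons real power while the whole suite stays interactive.

## Pore profiling

At each z the profiler maximises the clearance `min_i(|c − xᵢ| − r_vdw,i)`
over in-plane centres c using multi-start Nelder–Mead (5 starts: the nominal
axis, the previous plane's optimum, and the best coarse-grid points), with
atoms culled beyond a 15 Å slab cutoff and the radius clamped to
[0, r_max = 20 Å]. The centre is confined to a disk of 5 Å around the
nominal axis: without this the "largest sphere" escapes sideways out of any
finite structure, where clearance grows without bound. A profile therefore
assumes the supplied axis runs within 5 Å of the true lumen — adequate for
symmetric channels profiled along their symmetry axis; the optimizer is
validated against an exhaustive 0.01 Å grid search on toy fixtures
(agreement < 0.05 Å). Radii are a single Bondi-style table (C 1.70, N 1.55,
O 1.52, S 1.80 …), configurable because published "solvent-accessible
diameter" values depend on the radius convention of the software that
produced them; unknown elements fall back to 1.70 Å with a warning. Waters
and hetero compounds are excluded by default. The profiler follows a
straight axis only — no Monte-Carlo path wandering.

## Known limitations

- The metadata statistics treat class→state assignments as error-free.
- The hetero-junctional selector approximates hemichannel-level class
  membership by protomer-count thresholds.
- The drift–diffusion generator has no explicit solvent, ion–ion
  interactions, or channel flexibility; it validates estimators, not
  channel physics.
- The pore profiler requires a user-supplied axis and does not compute
  pore volumes or surface areas.
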