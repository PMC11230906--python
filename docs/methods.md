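# Methods

`kemix` implements a computational pipeline for studying the miscibility of
biomolecular condensates formed by charge-patterned intrinsically disordered
regions (IDRs), using model "KE" polyampholytes — chains of lysine (K, +1)
and glutamate (E, −1) beads — together with the image-analysis readout used
for condensates in cells.

## Sequence patterning metrics

The sequence charge decoration metric,

    SCD = (1/N) Σ_{i<j} q_i q_j (j − i)^{1/2},

scores charge blockiness: it is negative for attractive polyampholyte
patterns and grows in magnitude from strictly alternating (KE)ₙ to the
diblock KⁿEⁿ.  We use the prefactor 1/N (not 1/(N−1)); both appear in the
literature.

The normalized score is Ω = SCD(s) / SCD(diblock with the same length and
composition), so Ω ∈ (0, 1] for neutral sequences with Ω = 1 for the
diblock itself.  The normalization by the maximally blocky arrangement is a
package choice (the normalized-SCD literature contains several variants);
it is dimensionless, length-comparable, and the stand-in sequence series
built with it reproduces the one quantitative anchor available for the
KE4/KE6 pair (ΔΩ = 0.09, see below).  ΔΩ(p, q) = Ω(p) − Ω(q).

NCPR tracks are sliding-window means of the signed charges with windows
truncated at the termini (no padding invents charge outside the chain).

### Stand-in KE series

The KE1–KE7 polyampholyte series is loadable from a registry file when
available.  When it is not, `synth.ke_standins()`
generates a deterministic, length-50, charge-neutral stand-in series by
Monte-Carlo pair-swap annealing toward target Ω values
(0.05, 0.10, 0.17, 0.26, 0.31, 0.35, 0.60).  The targets ascend (the series
is defined by increasing blockiness) and place Ω(KE6) − Ω(KE4) = 0.09, the
printed patterning difference for that pair.  The anneal minimizes
|Ω − target| under a geometric temperature schedule and typically lands
within 10⁻⁴ of each target, far inside the 0.02 guarantee.

## Coarse-grained model

Beads interact through the hydrophobicity-scale (HPS) implicit-solvent
model: an Ashbaugh–Hatch–scaled Lennard-Jones potential

    U(r) = U_LJ(r) + (1 − λ_ij) ε     r ≤ 2^{1/6} σ_ij
    U(r) = λ_ij U_LJ(r)               r > 2^{1/6} σ_ij

with arithmetic mixing of σ and λ, plus Debye–Hückel screened
electrostatics U = q_i q_j k_e/(ε_r r) · exp(−r/λ_D).  Parameters (from the
published HPS set): K σ = 6.36 Å, λ = 0.514, m = 128.17 Da; E σ = 5.92 Å,
λ = 0.459, m = 129.12 Da; ε = 0.2 kcal/mol; harmonic bonds
U = k/2 (r − r₀)² with k = 10 kcal mol⁻¹ Å⁻², r₀ = 3.8 Å; λ_D = 10 Å
(≈100 mM salt), ε_r = 80.  Potentials are shifted to zero at their cutoffs
(20 Å short-range, 35 Å electrostatic by default); whether to shift or
switch is a package choice, as is the whole electrostatic companion — the
model is otherwise specified only through the HPS reference.  Bonded pairs
are excluded from the non-bonded sums.

Oligomerization is modelled as a star polymer: f copies of the arm sequence
bonded to a central CORE bead.  The core is purely repulsive (λ = 0),
charge-free, with σ = 12.72 Å — twice the lysine diameter.  (The source
text prints "1.2 Å" alongside "roughly double the diameter of a lysine or
glutamate bead", which is internally inconsistent; we follow the
parenthetical intent and expose the value as a parameter.)  The mass
balance of a binary mixture counts polyampholyte beads only: the
"components" whose mass fractions are equalized are the IDR material, not
the scaffold.

Internal units are Å / Da / kcal·mol⁻¹, giving a derived time unit of
48.89 fs; the 10 fs step is converted internally.

## Dynamics

The integrator is BAOAB Langevin splitting: half-kick, half-drift, exact
Ornstein–Uhlenbeck velocity refresh, half-drift, half-kick.  At zero
friction it reduces to velocity Verlet, which the tests use as an NVE
energy-conservation oracle.  Runs are exactly reproducible from a master
seed.  Non-bonded sums use a Verlet pair list (3 Å skin, rebuilt when any
bead has moved more than half the skin); an independent cell-list /
brute-force reference kernel is kept and cross-checked in the tests.

The pressure tensor diagonal is P_aa = (Σ m v_a² + Σ_pairs F_a d_a)/V,
including bond terms.  Production runs are fixed-box NVT on slab
geometries; a constant-pressure (NPAT) production ensemble is out of scope — with a large vacuum fraction along z, a
fixed-Lz NVT slab yields the same coexistence observables at the scales
simulated here.

## Direct-coexistence protocol and desk scaling

The protocol keeps the standard shape: random placement of both species
at equal polyampholyte mass fraction in a cubic box, a compression run
(box rescaled geometrically each step with dynamics on), z-extension into
a slab (molecules unwrapped along their bond trees so no bond spans the
new vacuum), NVT equilibration and production at 250 K with a 10 fs step.

Full-scale direct-coexistence runs (50 nm boxes, microseconds, tens of
thousands of beads) are far beyond one CPU, so the desk preset scales
everything down and is the problem size at which all trend results here
are computed:

- chains/arms of length 20; ~700 beads total;
- 15 nm assembly cube → 5.5 × 5.5 × 14 nm dense column → 32 nm slab;
- 3 000 compression, 10 000 equilibration, 40 000–80 000 production steps;
- Langevin friction 0.01 ps⁻¹ during production (the reference value of
  1 ps⁻¹ remains the engine default).  At 1 ps⁻¹ a 20-mer's rms
  displacement over a desk-length run is a few Å — no compositional
  rearrangement could be observed at any desk-reachable length.  The weaker
  coupling accelerates configurational sampling without changing the
  sampled (NVT) distribution; equilibration stages use 0.5 ps⁻¹ to
  dissipate assembly and condensation heat quickly.
- electrostatic cutoff 20 Å in the desk force field (tail < 0.06 kT per
  unit-charge pair), roughly halving the pair count per step relative to
  the 35 Å default;
- pressure-tensor statistics recorded every 50 steps (the virial comes
  free with each force evaluation) while positions are stored every 500.

The narrow x/y cross-section is deliberate: it is smaller than the typical
demixed-domain size, so when two condensed phases segregate they stack as
lamellae along z — the geometry that the z density profile, the tanh fits
and the partition coefficient read directly.  Desk runs expose *orderings*
(K_p with valence, γ and φ_B between oligomerization configurations), not
converged absolute values; absolute plateau densities, tensions and
partition coefficients at these sizes carry large finite-size and
finite-time effects.

## Coexistence observables

**Density profiles.**  Per-frame bead-number concentrations along z,
recentred per frame on the circular (periodic) centre of mass of all
polyampholyte beads, then averaged.  CORE beads are excluded from species
concentrations throughout.

**tanh fits.**  ρ(z) = (ρ_den+ρ_dil)/2 − (ρ_den−ρ_dil)/2 ·
tanh((|z−z_c| − z₀)/w), with the dense excess constrained non-negative and
the slab centre z_c a free parameter under the periodic z metric: in a
demixed binary slab each species occupies a one-sided sub-slab away from
the box middle.  Non-convergent or contrast-free profiles return flagged
results carrying 10th/90th-percentile plateau estimates, never silent
failures.

**Partition coefficient.**  K_p = C_p(q-lean phase)/C_p(q-rich phase);
K_p ≈ 1 means p is indifferent (miscible) and K_p ≫ 1 means p is excluded
from q's phase.  The q-rich region is where q's fitted profile exceeds its
midpoint; the q-lean condensed region is p's fitted dense extent outside
q-rich; bins within 2w of a fitted interface are excluded.  When the two
dense regions coincide (mixed single slab), bins of the condensed region
are ranked by the q fraction x_q = ρ_q/(ρ_p+ρ_q) — the shared slab shape
cancels in x_q — and the lean/rich halves are compared, so an
identical-species system reads K_p = 1 (the miscible baseline).  Within
each block, region classification uses the even frames and the ρ_p
measurement the odd frames: selecting "q-lean" bins on the same noisy data
that supplies ρ_p would bias K_p away from 1.  Errors are SEMs over 5 equal
contiguous blocks after a 20% burn-in.

**Interfacial tension.**  The mechanical route,
γ = (Lz/2)[⟨P_zz⟩ − (⟨P_xx⟩+⟨P_yy⟩)/2], the 1/2 for the two interfaces of
a periodic slab, block-averaged; reported in kcal mol⁻¹ Å⁻² and in reduced
ε/σ̄² units with σ̄ the composition-weighted mean bead σ.  In a
vacuum-flanked slab this measures the total interfacial cost, and at desk
scale the condensate–vapour interface fluctuations dominate the anisotropy
noise; the condensate–condensate comparison therefore runs in the fully
dense column (``desk_coexistence(..., vacuum=False)``), where the only
interfaces are between the two condensed phases.

**Bond ratio.**  A non-covalent "bond" is an inter-molecular K/E bead pair
within 1.5 σ_ij (first coordination shell; the 1.2–2.0 range gives the same
orderings).  φ_B counts heterotypic versus homotypic bonds of the
oligomerized species per contact-end: φ_B = het/(2·hom), so a randomly
relabelled single-species system reads φ_B = 1.  Because intra-molecular
pairs are excluded, φ_B is comparable between configurations at equal
valence (the asymmetry comparison), but not across different
valences.

## Imaging readout

Condensates are segmented per channel by iterative intermeans
(Ridler–Calvard) thresholding floored at 20% of the condition-average
per-image maximum, 26-connected components, minimum size 50 voxels.
Radii are equivalent-sphere radii from voxel counts (area-equivalent
circles in 2D).  Overlapping objects across channels (intersecting voxel
sets; one record per overlapping pair) yield centre-to-centre distances
normalized by the summed radii: ≈0 for miscible (concentric) condensates,
≈1 for associated-but-demixed (tangent) ones.  Frequency distributions use
right-open bins of width 0.1 (the measurement-noise scale) and medians are
taken on unbinned values.  Centroids are geometric (intensity weighting is
available but off by default).

## Synthetic data

Every generator embeds its ground truth: annealed sequence series (targets
above), tanh profiles with known plateaus (noise is additive Gaussian and
deliberately *unclipped*: clipping at zero would skew the dilute plateau
statistics that the fit-recovery tests measure), pressure-tensor series
with known anisotropy, and two-channel volumes of rasterized spheres at
programmed normalized offsets with optional Gaussian blur, shot noise and
additive noise.  What the image generator does not emulate: realistic
point-spread functions, anisotropic voxels, cellular background structure,
or autofluorescence — recovery results bound algorithmic error, not
microscope error.

### What desk-scale trend runs can and cannot show

Composition transport in the dense phase is the slowest process in these
systems: over a desk-length run a chain moves only a few nanometres inside
the condensate, so the molecular composition field is largely *quenched* at
the value set by random assembly.  Three consequences, measured by the
acceptance-style tests themselves:

- An identical-species system read by the partition estimator does not
  return exactly 1: the estimator honestly reports the amplitude of the
  frozen random-labelling fluctuations, a noise floor well above 1 at
  ~15–20 molecules per species.  Only runs long enough to mix composition
  (orders of magnitude beyond desk scale, and beyond microsecond
  full-scale runs as well at these transport rates) would push the
  floor to 1.
- The K_p valence ordering rides on that same floor, so its resolvability
  depends on seed pooling; the ordering of the means is reproducible, the
  separation of error bars at desk scale is marginal.
- The pressure-anisotropy γ in the dense column measures (k/2)·γ_pq with k
  the seed-dependent number of lamellar interfaces;
  ``count_lamellar_interfaces`` estimates k, but at these sizes the
  interface count itself is noisy, and the γ ordering between
  oligomerization configurations does not resolve reliably.  The bond
  ratio φ_B, a local observable that needs no z-sorting, resolves the same
  asymmetry cleanly and is the desk-scale readout of choice.

## Numerical notes and limitations

- Assembly places molecules with random rotations/positions, rejecting any
  inter-molecular bead pair closer than 0.9× the smallest σ (5.3 Å); this
  bounds the initial forces without minimization.
- The stoichiometry solver enumerates copy numbers to balance polyampholyte
  bead counts within one molecule's worth.
- Desk trend runs are far from full phase-separation equilibrium; K_p
  values grow over the run as domains coarsen.  Orderings are assessed with
  block SEMs precisely because of this drift.
- The hydrophobicity-scale λ for K and E makes the short-range attraction
  weak; demixing at 250 K is driven mainly by the patterned electrostatics,
  so results are sensitive to the Debye length (10 Å default).
- Single-precision frame storage (float32) in the HDF5 container is
  adequate for all analyses (bin widths ≫ 10⁻³ Å).
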