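# Methods

## Model

`enmdyn` treats a protein as one bead per residue at the Cα position,
carrying the total residue mass (built-in 20-residue table of average
residue masses; 110 amu for unknown types).  Beads closer than a cutoff
r_c in the reference structure are joined by harmonic springs:

    E(r) = Σ_{i<j, Γ_ij=1} (γ_ij / 2) (r_ij − r_ij°)²,
    γ_ij = γ (r_ij°)^(−p)

where Γ is the binary contact map (Γ_ij = 1 iff 0 < r_ij° < r_c), r_ij°
the reference distance, γ a uniform spring constant and p ≥ 0 an optional
distance-weight exponent (p = 0 gives the classic uniform network).  The
sum runs over unordered pairs, so one spring stretched by Δ stores
(γ/2)Δ² — the convention of the elastic-network literature.  Note that
the weight parameter is sometimes quoted with a length unit in
anisotropic-network-model sources; here it is the dimensionless exponent
of the r^(−p) spring weighting.

Two stage parameterizations are used as defaults, matching common
practice for each route:

| stage            | r_c (Å) | γ (kcal mol⁻¹ Å⁻²) | p   |
|------------------|---------|--------------------|-----|
| normal modes     | 10.0    | 1.0                | 2.5 |
| CG dynamics      | 8.0     | 1.0                | 0   |

## Normal modes (ANM)

The 3N×3N Hessian of E at the reference has super-elements
H_ij = −(γ_ij / r_ij°²)(r_ij° ⊗ r_ij°) for contacts, with diagonal blocks
fixed by the translational sum rule.  Dense symmetric eigendecomposition
(`scipy.linalg.eigh`) gives the mode spectrum; eigenvalues below
10⁻⁸·λ_max are flagged as zero modes.  A connected, non-collinear
structure has exactly 6 (a collinear dimer has 5); more than 6 signals a
disconnected network and is propagated as a warning.  "Mode k" always
means the k-th internal (nonzero) mode counted from the softest.

Thermal statistics weight modes by λ⁻¹ (equipartition), giving the
mode-restricted positional covariance C = k_BT Σ_k λ_k⁻¹ v_k v_kᵀ.  From
C follow:

* B-factors: B_i = (8π²/3)·tr(C_ii), default over all internal modes;
* cross-correlation maps (DCCM):
  CC_ij = tr(C_ij)/√(tr(C_ii)·tr(C_jj)), default over modes 1–3.
  This is the standard 3-D vector form of the scalar cross-correlation
  coefficient; it reduces to the per-coordinate definition component-wise.
  CC is invariant to temperature and to uniform rescaling of γ.  Beads
  with zero fluctuation in the selected subspace get zeroed correlations
  (0/0 guard) and a warning.

## Coarse-grained Langevin dynamics

NVT dynamics on the network potential uses the BAOAB splitting of the
Langevin equation, with the exact Ornstein–Uhlenbeck velocity refresh in
the O step.  Units: Å, ps, amu, kcal/mol (1 kcal/mol = 418.4 amu Å² ps⁻²;
k_B = 1.987204259×10⁻³ kcal mol⁻¹ K⁻¹).  Defaults: dt = 0.02 ps, 298 K,
Maxwell–Boltzmann initial velocities, mass-weighted center-of-mass drift
and net momentum removed at every save point.  The run refuses time steps
above the Verlet bound 2/ω_max (ω_max from the stiffest Hessian mode and
lightest bead) and reports the bound.  A trajectory is a pure function of
(network, parameters, seed): identical inputs reproduce it bit-for-bit.

**Friction.**  The default friction is 0.1 ps⁻¹, deliberately weak.  The
thermostat's job here is sampling the configurational ensemble, and for a
harmonic mode of frequency ω the position decorrelation time is ≈ g/ω²
when overdamped but ≈ 2/g when underdamped.  The soft hinge modes of
multi-domain models (λ ~ 10⁻⁴–10⁻³ kcal mol⁻¹ Å⁻²) would relax over
nanoseconds at g = 5 ps⁻¹; at 0.1 ps⁻¹ every mode decorrelates within
tens of ps, so runs of 10⁵ steps (2 ns) average hundreds of independent
configurations per mode.  Friction is configurable per run; checks aimed
specifically at velocity-space quantities (kinetic temperature) use
g = 1 ps⁻¹, where the temperature estimator decorrelates in ~0.5 ps.

**Known discretization effects.**  BAOAB samples configurations with
O(dt²) accuracy; the *kinetic* temperature estimator carries a small
negative O((ω dt)²) bias.  In addition the estimator divides by 3N
degrees of freedom (the conventional definition) while the net-momentum
removal at save points freezes 3 of them, contributing a further −3/3N
(−1% at N = 100).  Together these appear as time-averaged kinetic
temperatures of ~293–296 K at a 298 K setpoint — a known, explained
offset well inside the 3% verification band.

**Closed-form checks.**  A two-bead spring (γ = 1, 298 K) has bond-length
variance k_BT/γ ≈ 0.592 Å² — but only in the harmonic regime.  In 3-D the
radial measure tilts the equilibrium density by r², depressing Var(r) by
≈ 2σ²/r₀²: −7.3% at r₀ = 3.8 Å, −1.2% at r₀ = 10 Å (numerical
integration).  The k_BT/γ check therefore uses a 10 Å dimer, and a
separate test verifies the simulation reproduces the Jacobian-corrected
variance at 3.8 Å.  With friction off and T = 0 the integrator reduces to
velocity Verlet; total energy is conserved to <0.1% over 10⁴ steps at
ω_max dt ≲ 0.05.

## Essential dynamics (EDA/CEDA)

Trajectory analysis follows the standard three steps: (i) remove
translation/rotation by least-squares superposition onto a reference
(Kabsch rotation via `scipy.spatial.transform.Rotation.align_vectors`;
proper rotations only), (ii) form the 3N×3N coordinate covariance about
the mean after discarding a burn-in fraction (default 1/6, the
25-of-30-ns convention expressed as a fraction so it scales to short
runs), (iii) diagonalize.  PCs are ordered by descending variance (Å²);
eigenvalue round-off below 10⁻¹² of the leading variance snaps to zero.
Applied to a coarse-grained trajectory this is "CEDA".

**Cluster selection.**  Frames are binned on a regular grid (default 20
bins/axis) in the space of the first 3 PCs; clusters are face-connected
sets of occupied bins; the selected cluster maximizes conformations per
unit fluctuation, defined as n_frames / RMS fluctuation of the cluster's
projections (projection space, not Cartesian — the natural metric of the
binning space; the Cartesian alternative differs only by the weight of
the discarded PCs).  A cluster with zero projection spread cannot be
localized below the grid resolution and is assigned half a bin diagonal
as its fluctuation, so isolated single-frame bins never win by division
by zero.  Ties break to the lowest cluster id; the selection is invariant
to frame order.

**Trajectory DCCM and B-factors.**  The default DCCM reconstructs the
covariance from PCs 1–3, mirroring the combined-modes-1–3 maps of the
normal-mode route; the raw-frame covariance (equivalently, all PCs) is
available by passing `mode_list=None`.  B-factors are (8π²/3)·MSD about
the mean over the selected frames.

## Cross-method comparison

The overlap of two per-residue displacement fields,

    O = |Σ_i Δr_i^A · Δr_i^B| / √(Σ_i |Δr_i^A|² · Σ_i |Δr_i^B|²) ∈ [0, 1],

is sign- and scale-invariant; it is evaluated mode-k-against-PC-k
(index pairing, as overlap tables in this field imply), full-protein and
restricted to each annotated domain, with a per-scope average row that is
the arithmetic mean of the per-mode overlaps.  An optional best-match
pairing exists for diagnostics and is never substituted silently.  A
domain on which a field vanishes yields an explicit "undefined" row
rather than a number.

B-factor tracks from different sources (crystal column, normal modes,
trajectory) are z-scored (population SD) before overlay or differencing —
chosen because the sources differ by arbitrary scale; min–max is
available.  Two DCCMs are composed into one matrix (first method above
the diagonal, second below) with per-block mean CC and mean |CC|
summaries as the quantitative handle on which method sees stronger
coupling in a region.

## Synthetic structures and ensembles

`make_two_domain_structure` emulates the architecture of multi-domain
enzymes such as aminoacyl-tRNA synthetases: a compact catalytic core
(self-avoiding 3.8 Å walk confined to a sphere of radius
compactness·n^(1/3) Å; compactness 3.0 ≈ 115 Å³/residue, protein-like
packing) with a smaller inserted domain grown in a sphere 1.35× looser,
tethered into the middle of the chain by two kinked linkers.  Perfectly
straight linkers would be mechanisms (zero transverse stiffness) under
central-force springs, so linker beads zigzag ±0.8 Å about the linker
axis while keeping exact 3.8 Å virtual bonds.  Each draw is validated
against the generator's contract — connected network, exactly six zero
modes, a well-conditioned softest mode, lower insert contact degree,
≥1.5× insert/core B-factor contrast, and core×insert mean DCCM ≤ −0.02 at
both stage parameterizations — inside a bounded, seed-deterministic
restart loop; an unsatisfiable spec raises a generation error suggesting
larger compactness.  The generator is a pure function of (spec, seed).

`sample_anm_ensemble` draws exact Gaussian thermal frames
ref + Σ_k √(k_BT/λ_k) z_k v_k, giving trajectories with a known
covariance for testing the EDA route; frames carry no rigid-body motion
and are marked superposed.

**What the generator does not emulate:** secondary-structure statistics,
sequence-specific contacts and masses (beads are 110 amu), crystal-packing
effects on experimental B-factors, solvent and anharmonic effects beyond
the network potential.  Tests passing on these systems validate the
machinery (mechanics, sampling, spectral analysis, statistics), not
biological accuracy on real proteins.

## Verification design and problem sizes

The verification suite runs at desk scale: 10-bead networks for
finite-difference checks, a 20-bead helix cross-checked against an
independently computed ANM reference, 98-bead two-domain and 100-bead
single-domain models, 10⁵-step (2 ns) dynamics runs, 5000-frame
ensembles, and a 10⁶-step dimer.  Two choices deserve explanation:

* **Ensemble consistency** (CG-MD MSF vs all-mode ANM B-factors,
  Pearson r ≥ 0.9) is checked on the compact single-domain globule.  On
  the two-domain hinge systems the softest modes have thermal amplitudes
  √(k_BT/λ) of tens of Å at 298 K; there the network potential is
  strongly anharmonic in Cartesian coordinates and the sampled ensemble
  *genuinely* departs from the harmonic-covariance prediction (r
  saturates near 0.8–0.9 no matter how long the run).  The globule keeps
  amplitudes within a few Å, isolating what the check is about —
  integrator and ensemble correctness (r ≈ 0.98–0.999).
* **Mode recovery** by PCA is checked on ensembles generated from modes
  with prescribed ≥2× eigenvalue gaps (the two-domain model's
  eigenvectors with eigenvalues 0.02/0.05/0.12).  Per-mode, index-paired
  recovery is only well-posed given spectral gaps: for near-degenerate
  pairs the PCA eigenvectors mix within the degenerate subspace with an
  error ~ √(2τ/T)/gap, which no desk-scale trajectory can beat.  This is
  the same reason finite-trajectory overlap tables in the literature
  spread widely for higher modes while subspace-level agreement stays
  high.

## Limitations

* Harmonic-network physics only: no sequence specificity, no side
  chains, no solvent damping model, no anharmonic force field.
* Mass-unweighted modes; no frequencies in cm⁻¹.
* The cluster-density definition ("conformations per unit fluctuation")
  has no unique published formula; ours is deterministic and documented
  above, with the grid resolution as its only tunable.
* PDB support covers the ATOM/MODEL/ENDMDL subset plus plain XYZ;
  binary trajectory dialects are out of scope.
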