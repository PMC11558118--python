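# Methods

`ssbwrap` has two halves that meet in a single physical story: how strongly a
single-stranded-DNA-binding (SSB) protein holds a short ssDNA probe, and how
the distribution of charge on the protein surface decides how far the chain
wraps around the tetramer.  The first half is a magnetic-tweezers analysis
pipeline (trace segmentation, dwell-time kinetics, critical forces, binding
free energies); the second is a coarse-grained Langevin simulator of a
protein–ssDNA complex with a structure-based interface term and screened
electrostatics.  Because the real experimental recordings and the crystal
structure are not shipped, a synthetic-data layer generates statistically
matched stand-ins whose ground truth is known exactly; everything below
states what those stand-ins do and do not establish.

## Tweezers thermodynamics

### Model

A constant-force recording of the probe is a two-state telegraph signal:
long extensions mark the unbound state, short extensions the bound state.
Both rates follow Bell kinetics,

    k_on(F)  = k_on0  exp(-F Δx_on / k_BT)
    k_off(F) = k_off0 exp(+F Δx_off / k_BT),

so ln k is linear in force and the critical force F_c is the crossover of
the two lines.  At F_c the observed association constant satisfies
K_obs/[L] = 1, and the null-force binding free energy is

    ΔG0 = -ΔΔG(F_c),   ΔΔG(F) = F·Δx(F) - ΔG_stretch(F),

where Δx(F) is the equilibrium extension of the released ssDNA segment at
force F and ΔG_stretch its stored elastic energy.  Since the instrument
holds force constant across a jump, the work term is F·Δx(F); equivalently
ΔΔG = ∫₀^F Δx(F′) dF′ by the usual Legendre identity.  ssDNA elasticity is
the Marko–Siggia interpolated worm-like chain.  Sign convention: ΔG0 < 0 is
favorable; summaries may report |ΔG0|.

Parameters and defaults:

| parameter | default | why |
|---|---|---|
| persistence length L_p | 1.0 nm | conventional ssDNA value; configurable |
| contour per nucleotide | 0.56 nm/nt | conventional ssDNA value |
| released nucleotides | 20 | the probe length; the site size (35 nt) exceeds the probe, so the probe length bounds the released contour |
| temperature | 300 K | matches the simulation temperature |

The elastic integral uses adaptive quadrature (`scipy.integrate.quad`) and
is verified in the tests against a dense trapezoid evaluation.

### Segmentation and rates

Levels are estimated by a two-component Gaussian mixture on the
boxcar-filtered extension, followed by dual-threshold hysteresis labelling
at μ_low + 0.3Δ and μ_low + 0.7Δ.  The filter width adapts: starting from
0.1 s, it grows until the filtered noise SD is at most Δ/6, with the raw
noise estimated robustly (median absolute deviation of the first
differences, immune to the level jumps themselves).  Without this guard,
poorly separated traces sprout noise-induced events that bias both rates
upward asymmetrically.  The filter erases dwells shorter than roughly its
width; because the loss applies to both states nearly symmetrically near
the crossover, the crossover force itself is essentially unbiased — this is
verified against generator truth in the acceptance tests.  A trace whose
filtered histogram is effectively unimodal (level separation below twice
the pooled SD) is reported as "no transitions", not an error.

Dwells are run lengths times the sampling interval; the first and last
dwell of each trace are censored.  The exponential MLE with right
censoring is k = (uncensored events)/(total observed time), SE = k/√n.
Unbound dwells end in binding events, so they estimate the binding rate,
and conversely.

The crossover is computed from weighted least-squares lines of ln k versus
F (weights from the delta-method SE of ln k), F_c = (a₁-a₂)/(b₂-b₁), with a
seeded 1000-resample parametric bootstrap for its SE.  Parallel lines raise
a no-crossover error; a crossover outside the sampled force range is
flagged as extrapolated.

### Two interaction modes

At intermediate salt a condition can host two binding modes; each trace
belongs to one of them, so pooling rates per force would mix them.  The
pipeline instead forms one critical-force sample per balanced trace:
s = ln(k_off/k_on) is linear in F with a slope shared by both modes (the
fixtures use equal Bell lengths, and empirically the fitted slopes agree),
so F_c,i = F_i - s_i/β̂.  β̂ is initialised by a grid search minimising the
2-cluster spread of the implied crossovers and refined by EM-style
weighted least squares with per-cluster intercepts.  Traces with
|s| > 2.5 (farther than ~5 pN from their own crossover) are excluded
because the extrapolation noise grows exponentially.  A Gaussian-mixture
test on the F_c samples (k-means initialised, seeded) reports two modes
only when the BIC improves by ≥ 6 *and* the means separate by ≥ 2 pooled
SDs.  Traces are then assigned to modes and per-mode rate-force lines are
refit for the reported mode crossovers.  The "transition midpoint" of a
salt ladder is operationalised as the condition whose mode weights are
closest to 1/2.

### Synthetic trace generator

The generator is the study-conditions oracle: a continuous-time two-state
Markov chain with Bell rates, started from its stationary distribution,
sampled at 100 Hz with 5 nm Gaussian noise.  Extension levels are
force-dependent — the unbound level sits one WLC extension of the released
20-nt segment above the bound level — so segmentation difficulty varies
with force exactly as in practice (≈ 4.9 nm separation at 4 pN versus
≈ 8 nm at 15 pN, against 5 nm noise).  Shipped fixtures encode the
experimental salt ladder at 10 nM ligand: analytic crossovers of 15 pN
(20 mM), an equal-weight pair of 10 and 15 pN (42 mM), and 7 pN (75 mM);
rate scale 1 s⁻¹ at the crossover so a 200 s trace holds ~100 events; Bell
lengths Δx_on = Δx_off = 1 nm.  What the generator does *not* emulate:
drift, bead-tracking noise spectra, force-calibration error, and any
microscopic structure behind the two modes — recovery tests therefore
establish the correctness of the estimators under the stated noise model,
not instrument robustness.

A note on the free-energy gap between the two 42 mM modes: with the WLC
defaults above and 20 released nucleotides, crossovers of 10 and 15 pN
imply |ΔG0| values of 11.8 and 21.1 k_BT, i.e. a gap of ≈ 9.3 k_BT.  The
pipeline reports exactly what this conversion yields from the recovered
crossovers; no parameter choice consistent with those two critical forces
can make the gap substantially smaller, because the gap is the force
integral of the released segment's extension between 10 and 15 pN.

## Coarse-grained wrapping simulator

### Energy function

Protein: one bead per residue at the Cα position.  A plain Gō model is
used: harmonic bonds (100 kcal mol⁻¹ Å⁻²), harmonic angles
(20 kcal mol⁻¹ rad⁻²) and dihedrals (1 kcal mol⁻¹ rad⁻²) about their
native values, and 12-10 native-contact attractions (uniform depth
0.3 kcal/mol) for residue pairs within 6.5 Å (sequence separation ≥ 4
within a chain; any separation across chains, which is what holds the
tetramer together).  Sequence-flavoured local potentials are deliberately
omitted — the physics probed here (interface + electrostatics) does not
depend on them; this is a documented fidelity reduction.

ssDNA: three beads per nucleotide (phosphate, sugar, base; the 5′-terminal
nucleotide lacks its phosphate, 3N-1 beads).  The three-site model is
reduced to bonds, backbone/orientation angles, nearest-neighbour base
stacking (12-10, 0.5 kcal/mol), excluded volume and phosphate charges
(-0.6e): base pairing and cross stacking are irrelevant for poly-dT.  The
backbone bending constant (1.5 kcal mol⁻¹ rad⁻²) is chosen so thermal bond
angle fluctuations correspond to a persistence length of order 1 nm.

Inter-molecular terms:

* **Interface (structure-based 12-10).**  For every residue i with a
  reference distance r_i0 (the distance to its *nearest* base in the
  reference complex, tabulated only for residues within 10 Å of any base)
  and every base j:  ε[5(r_i0/r_ij)¹² - 6(r_i0/r_ij)¹⁰], ε = 0.2325
  kcal/mol.  Each pair's minimum is exactly -ε at r_i0.  Poly-dT makes all
  bases equivalent, so one r_i0 per residue suffices.
* **Electrostatics (Debye–Hückel).**  C q_i q_j/(ε_r r) · exp(-r/λ_D) with
  ε_r = 78, truncated and shifted to zero at 5λ_D.  λ_D comes from the
  ionic strength of a 1:1 salt (0.785 nm at 150 mM, 300 K).  Pairs:
  protein×phosphate plus intra-DNA phosphate–phosphate (nucleotide
  separation ≥ 2) — the chain's self-repulsion is what makes low salt
  resist wrapping.
* **Excluded volume.**  Purely repulsive ε_ev(σ/r)¹², σ = 4 Å,
  ε_ev = 0.2 kcal/mol, truncated and shifted at 2σ, for all non-bonded
  pairs without a specific pair term (1-2/1-3/1-4 excluded).

Restraints: harmonic anchors on the two 3′-terminal base beads
(0.3 kcal mol⁻¹ Å⁻²) at their reference-site positions; one
"equivalent-length" spring (rest length one backbone rise, 10 kcal mol⁻¹
Å⁻²) from a fixed site to the 3′-terminal sugar, standing in for the
twentieth nucleotide so the chain's mechanical length matches the 20-nt
probe; and a half-harmonic spherical wall of radius 85 Å (10 kcal mol⁻¹
Å⁻²) that confines the free end the way a 170 Å periodic box would,
implemented as a soft wall rather than a reflecting one so the force field
stays differentiable.

All terms have analytic gradients, cross-checked against central finite
differences to < 1e-5 relative error on randomly perturbed configurations
of the full complex.

### Dynamics

BAOAB-discretised underdamped Langevin dynamics at 300 K with unit bead
masses; energies in kcal/mol and lengths in Å define the reduced time
unit.  Defaults: dt = 1% of the stiffest bond period (0.0044 reduced
units for k = 100 bonds — the reduced time step of the original protocol
is not portable across codes, so the stability criterion replaces it);
friction γ = 0.5 per reduced time, a low-friction choice that accelerates
configurational sampling without affecting equilibrium averages (all
reported observables are equilibrium means, which are friction- and
mass-independent).  Equal masses slightly redistribute the kinetics among
bead types but, again, leave equilibrium statistics untouched.  The
integrator is bit-reproducible for a fixed seed (a seeded per-run RNG
drives both velocity initialisation and the thermostat), conserves energy
to < 1e-4 relative over 1e5 steps at γ = 0, small dt, and reproduces
⟨x²⟩ = k_BT/k in a harmonic well to within statistical error.  Excluded
volume uses a candidate-pair Verlet list (skin 4 Å) rebuilt every 40
steps; bead displacements per rebuild interval are far below the skin.

### Toy complex

The reference structure is a synthetic stand-in, generated
deterministically from a seed: one 40-residue subunit grown as a
self-avoiding collapsed chain, replicated by 222 (D2) point-group symmetry
into a tetramer with a controlled inter-subunit gap (≈ 4.6 Å, inside the
contact cutoff so native inter-subunit contacts exist); a 19-nt poly-dT
reference path laid on a ring that passes the equatorial surface of all
four subunits (bases inward, ≈ 4 Å clearance); and two per-residue charge
overlays standing in for charge-fitting against the two surface states
seen at low and high salt:

* **unbridged** (paired with 0.01 M): groove residues neutral, +0.2e
  dispersed over eight off-groove residues per subunit, and four weak
  acidic patches (-0.3e) flanking each groove — a weakly, patchily
  positive surface;
* **bridged** (paired with 0.3 M): +0.8e concentrated on the eight groove
  residues per subunit — the same surface with its positive potential
  enhanced and focused on the DNA path.

The toy is explicitly not an OB-fold and reproduces no real structural
topology (S-like/O-like profile shapes are out of scope); it exists so
that topology building, the interface term, electrostatics, the
integrator, and the occupancy/PMF analyses can be exercised and falsified
against brute-force oracles.  The 19-nt ring cannot close on itself
(327° of arc), so one subunit's interface table may be nearly empty —
a real asymmetry of a finite probe, not a bug.

### Wrapping analysis

The protein-local frame has its origin at the centre of geometry and axes
along the principal axes of the native structure, ordered by decreasing
extent, sign-fixed toward the anchored subunit, determinant +1 (the
original local-frame definition is not available, so principal axes are
the package's choice; an explicit rotation can be supplied instead).  DNA
base beads are projected on the frame's X-Y plane; the 2D PMF is
-k_BT ln(count/max count) with unsampled bins reported as missing (NaN),
never as 0.  Subunit occupancy counts a subunit when ≥ 3 nucleotides have
any bead within 10 Å of any of its residues (both thresholds are package
choices, configurable).

The headline qualitative result — the bridged/high-salt state wraps more
subunits than the unbridged/low-salt state — is assessed on paired seeds
(same thermostat stream for both states) with a one-sided sign test.
Runs start from a half-wrapped configuration (the anchored eight
nucleotides on their reference path, the rest extended along the local
tangent), midway between the two expected equilibria, and discard the
first 1/7 of frames as burn-in, mirroring the original protocol's
burn-in fraction at a desk scale of 5×10⁵ steps per run.

## Problem sizes

Test-suite and acceptance problem sizes are the package's own choices:
trace recovery uses 20 traces × 6–7 forces × 200 s at 100 Hz per
condition; the wrapping contrast uses 10 seed pairs × 5×10⁵ steps (the
original protocol's 30 × 3.5×10⁸ steps is scaled down by ~3 orders of
magnitude, which is why only the robust occupancy ordering — not absolute
occupancy values — is asserted).

## Known limitations

* The segmentation's adaptive filter trades short-dwell sensitivity for
  false-event immunity; rate magnitudes at the force extremes are biased
  low by missed sub-filter dwells even though crossovers are not.
* The shared-slope critical-force sampler assumes the modes' Bell slopes
  are similar; strongly unequal slopes would need a full
  mixture-of-regressions treatment.
* The toy complex tests machinery, not structural biology: absolute
  occupancies, PMF topologies and the free-energy gap between charge
  states have no quantitative counterpart in the real system.
* Charge regulation (protonation changes) and sidechain rearrangement on
  binding are outside the model, as is any all-atom treatment.
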