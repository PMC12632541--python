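# Methods

`msxref` computes *multi-state multi-condition* models of a protein crystal:
N complete atomic conformations ("states") plus an N×J matrix W of state
weights, one column per experimental condition (e.g. temperature).  All J
X-ray amplitude datasets inform one set of conformations; only the weights
differ between conditions.  This note records the model, the numerical
choices, and what the synthetic benchmark does and does not demonstrate.

## Posterior and score

The posterior over a model M = ({M_i}, W) given datasets D_1…D_J factorizes
into per-dataset likelihoods and a per-state molecular-mechanics prior.  The
working score is the negative log-posterior

    S = Σ_j (−log L_j) + Σ_i E_prior(M_i),

with additive constants and the prior's partition function dropped (neither
affects rankings).  `ScoreBreakdown` keeps the per-dataset and per-state
terms separate.

### Amplitude likelihood

Each observed amplitude F_O is scored against the model amplitude F_M with
the standard maximum-likelihood targets: the Rice density for acentric
reflections (complex structure factor ~ 2-D Gaussian with per-component
variance εβ/2 and scale α) and the Woolfson folded Gaussian (variance εβ)
for centric ones.  ε is the symmetry enhancement factor *without* the
lattice-centering multiplicity (the centering factor is absorbed by the
overall scale; the test suite pins this convention against gemmi's
`epsilon_factor_without_centering`).  Everything is evaluated in log space;
log I₀ is computed as `log(i0e(x)) + |x|` from the exponentially scaled
Bessel function, which is exact and cannot overflow, so arguments of 10⁶ and
beyond are safe.  Free (withheld) reflections never enter the likelihood or
any nuisance fit — they exist only for Rfree reporting.  Both branches
integrate to 1 over F_O (verified by quadrature at 10⁻⁶).

### Forward model

F_M = k_total (F_C + k_mask F_B), with F_C(h) = Σ_i w_ij F_i(h): the
multi-state amplitude is exactly the weight-weighted complex sum of
single-state structure factors (the partial-occupancy degeneracy; see the
degeneracy experiment below).  Per-state factors use direct summation over
symmetry operators and atoms with embedded 4-Gaussian + constant scattering
coefficients (H, C, N, O, S, P, Zn; other elements loadable from a text
table) and isotropic Debye–Waller smearing exp(−B·stol²), stol = 1/(2d).
Direct summation is O(atoms × reflections) and is the right tool at the
package's toy scale; there is deliberately no FFT structure-factor path.

Bulk solvent is a flat binary mask of the weighted-average structure (probe
1.1 Å, shrink 0.9 Å, grid d_min/4), Fourier-transformed with unit density —
the physical solvent density is absorbed by k_mask.  It is OFF by default
(k_mask = 0): synthetic data are simulated without solvent, and the mask is
held fixed in gradients (standard practice).

Nuisance parameters: k_total (and k_mask when solvent is on) minimize the
work-set residual Σ(F_obs − |F_M|)²; α_s is initialized at 1 and β_s is the
per-shell moment estimate mean((F_obs − |F_M|)²/ε), clamped below at
10⁻³·⟨F_obs²⟩ so noiseless data cannot drive β to zero.  Shells are
equal-count in d; shells with fewer than 20 work reflections merge.  Full
joint ML estimation of (α, β) is not implemented — the moment estimate is
deterministic, testable, and refreshed every macro-cycle, which is enough
for the benchmark's purposes.

### Prior

CHARMM-functional-form energy: k_b(b−b₀)² + k_θ(θ−θ₀)² + k_φ[1+cos(nφ−δ)] +
k_ω(ω−ω₀)² + Lennard-Jones ε[(R_min/r)¹² − 2(R_min/r)⁶], no electrostatics.
LJ pairs combine per-type (ε, R_min/2) geometrically/arithmetically; 1-2 and
1-3 pairs are excluded, 1-4 scaled (default 1.0); a CHARMM switching
function takes LJ to zero between 7.5 and 9 Å.  States are isolated
molecules — no periodic images, since the prior factorizes per state and
crystal-packing contacts are out of scope.  All gradients are analytic and
finite-difference-tested to ~10⁻⁸ relative.  A minimal embedded parameter
subset covers the toy chain; full parameter files load through the same
sectioned text format, completeness being the user's responsibility.

## Sampling

Biased Langevin (BAOAB) dynamics with the force

    F = w_xray · w_auto · (−∇ NLL) + (−∇ E_prior).

w_auto equalizes the mean atomic gradient magnitudes of likelihood and prior
(recomputed every macro-cycle; clamped at 10⁶ if the likelihood gradient
vanishes).  w_xray deliberately under-weights the data term; the protocol
sweeps {1.0, 0.5, 0.25}.  Defaults: temperature 5000 K, timestep 1 fs,
friction 1 ps⁻¹, macro-cycle 100 steps.  The high "temperature" is a search
device, not a physical temperature, and the likelihood force is
non-conservative — hence the thermostat.  Langevin was chosen over a
velocity-rescaling thermostat because it is robust under non-conservative
forces and gives clean per-state noise streams for the relabeling-symmetry
test.  Weight columns are drawn once per trajectory from the flat Dirichlet
(the distribution is this package's documented choice; uniform over the
simplex is the least-informative option) and held fixed; an option resamples
them every K macro-cycles.  Blow-ups (non-finite coordinates) truncate and
flag a trajectory rather than failing the batch.

Between macro-cycle refreshes the per-reflection likelihood gradient uses a
frozen second-order Taylor expansion of −log p around the refresh-point
|F_M| (value, exact first derivative, finite-difference curvature); the
exact derivative path is available via `exact_likelihood_gradient` and both
agree at the refresh point by construction.

Every trajectory's final snapshot is polished by Polak–Ribière conjugate
gradients with Armijo backtracking on S (w_xray = 1, nuisance frozen at
entry, exact likelihood gradients), which guarantees a non-increasing score;
iteration stops at gradient RMS < 10⁻³ kcal/mol/Å or the iteration cap.

Determinism: one `numpy` Generator drives each trajectory; protocol
trajectories get independent children of a `SeedSequence` derived from the
config seed.  Identical seed + config + inputs reproduce trajectories bit
for bit.

## Assessment

- Free sets: within each of 10 equal-count resolution bins, 5% of the hkl
  union is flagged free (both numbers configurable) and the *same* flags
  apply to every condition — the datasets are strongly correlated, so
  distinct free sets would leak work-set information.
- R factors: R = Σ|F_obs − |F_M|| / ΣF_obs after nuisance scaling, reported
  separately over work and free sets.
- RMSD\*: for each condition, the RMSD between the two models' weighted-
  average structures (atom k at Σ_i w_ij x_ik), averaged over conditions —
  computed on raw crystal-frame coordinates with no superposition (an
  optional superposed variant exists but is not the default).  It is
  symmetric, non-negative, zero iff the weighted averages coincide, and
  invariant under state relabeling and equal-weight state mixing, matching
  the forward model's own degeneracies.
- Best-model selection minimizes Rfree per dataset (ties: lower total score,
  then earlier trajectory).  Convergence curves resample trajectory subsets
  and track the best score/accuracy; decoy landscapes tabulate (RMSD* to
  native, joint NLL) and count decoys scoring below the native.

## Synthetic benchmark

The generator builds a 17-residue helical chain with 6 atoms per residue
(N, CA, C, O, CB, CG → 102 atoms per state) from ideal internal coordinates.
State 2 differs from state 1 by a smoothed random backbone displacement
rescaled to exactly 0.3 Å RMS over backbone atoms, plus a rotamer-like
rotation of each CG about its CA–CB axis sized to bring the side-chain-mimic
RMS near 1.5 Å; the rotation sign is chosen per residue for steric
clearance, so state 2 is a plausible alternative conformation rather than a
clash.  B = 15 Å² and occupancy 1 everywhere; default weights make state 1
dominant under condition 1 (0.8/0.2) and state 2 under condition 2
(0.3/0.7).  The cell is P1 with 5 Å padding (other shipped groups: P-1, P2,
P212121, C2).

Datasets: complete asymmetric-unit hkl to d_min (2.0 Å by default; the
refinement benchmark uses 2.5 Å), amplitudes from the forward model with the
native weights, relative Gaussian noise (s.d. = 5% of each amplitude —
"relative" because the noise level is quoted as a percentage; negatives
clamp to 0), the true s.d. recorded in the sigma column, and one shared free
set.

Decoys: short prior-only Langevin bursts from the native over a temperature
ladder (400–3600 K), snapshots binned by RMSD* and sampled to uniform
coverage of the requested accuracy range; a variant randomizes weights at
native conformations.

Degeneracy experiment: five finite-crystal configurations of a two-state
cell (per-cell Bernoulli mixture; two contiguous blocks; partial occupancy;
the Bernoulli mixture relabeled; per-atom independent mixture).  At the
reciprocal lattice points of the single-cell lattice every inter-cell phase
factor is exactly 1, so the supercell DFT restricted to those points equals
the sum of per-cell single-cell DFTs; the implementation uses that exact
reduction (per-state and per-atom gridded-density DFTs plus binomial cell
counts) instead of materializing an n³ supercell, and a test verifies the
identity against a literal tiled-supercell FFT.  Per-point error is
‖F − F_ref‖/‖F_ref‖ against the partial-occupancy weighted sum, averaged
over points with non-negligible reference amplitude and over 16 independent
assignment draws (so the error-versus-size trend is stable for any seed).
Partial occupancy is exact at every size; the stochastic configurations
shrink roughly as n^(−3/2) in cells per axis.  The "two crystals"
configuration is modeled as coherent blocks by default; the incoherent
intensity-sum variant is available but its amplitudes do not converge to the
coherent reference — the option exists for comparison only.

### Benchmark protocol and problem sizes

The shipped recovery benchmark (`msxref.benchmark`, reproduced by
`scripts/acceptance.py`) runs, per model class, 8 trajectories × 3 w_xray
values of 100 steps (macro-cycle 50) from a 0.4 Å-jittered start, each
polished with ≤30 CG iterations — sizes chosen so the whole study runs in
minutes on one core while the orderings of interest (2-state vs 1-state,
2-condition vs 1-condition, weight recovery within 0.15 L1) are already
stable.  Assertions are on orderings, never on absolute R values.

## What passing tests do and do not show

The toy chain has no hydrogens, no solvent, a single molecule per asymmetric
unit, idealized geometry, and noise that is uncorrelated and exactly
relative — so the benchmark demonstrates the *machinery* (likelihood,
forward model, gradients, sampling, cross-validation bookkeeping) and the
information-content argument for multiple conditions, not performance on
real data.  Real crystals add bulk solvent, anisotropic effects, systematic
measurement error, and far larger models; full-protein benchmark numbers are
not reproducible at this scale and are not asserted anywhere — every
assertion is an ordering or property of the toy study.

## Known limitations

- No electrostatics, Urey–Bradley, CMAP, or implicit solvent in the prior.
- No anisotropic scaling or resolution-dependent k_mask; no anomalous
  scattering; no intensity-based or phase-including targets.
- Occupancies and B-factors are fixed during sampling (B = 15, occ = 1).
- Space groups are limited to an explicit-operator table (P1, P-1, P2,
  P212121, C2); no general symbol parser.
- MTZ I/O is best-effort via gemmi; CSV is the canonical reflection format.
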