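# Methods

This note records the models behind `xtalens`, the defaults and why they
were chosen, what the synthetic generator does and does not emulate, and the
numerical decisions a maintainer would otherwise have to reverse-engineer.

## Data model

Coordinates are fractional internally with half-open [0, 1) wrapping; grids
are 0-based and cell-commensurate.  The orthogonalization convention is the
standard crystallographic one (a along x, b in the xy plane), so Cartesian
quantities (U tensors, interatomic vectors, peak displacements) are always
expressed in that frame.

Atomic displacement is stored as a Cartesian U tensor (Å²); the isotropic
B = 8π²·U_iso is derived, never stored independently, so the two can not
drift apart.  On input, ANISOU records (U·10⁴, Cartesian) are converted at
read time; isotropic-only atoms fall back to (B/8π²)·I where a tensor is
required (with a warning).

Grouped-occupancy conformers are first-class: an *alternation unit* is a
named set of conformers (altloc groups) sharing one occupancy each.  Because
coordinate formats cannot express grouping, units are inferred on read from
maximal runs of consecutive residues sharing (altloc label, occupancy), and
partial-occupancy blank-altloc HETATM residues become single-conformer units
whose absent state is allowed.  Conditionality (a covalent adduct that can
exist only on one host conformer) is likewise not expressible in PDB; it is
declared in code or on the command line, never guessed.

## Supercell conformer assignment

A refined structure with a 0.64/0.36 loop describes the average over ~10¹²
unit cells; a 2×2×2 supercell has only 32 protein copies, and i.i.d.
sampling at that size routinely misses the refined populations.  The default
*quota* assignment therefore gives each conformer its largest-remainder
share of the copies — 32 × 0.64 → 20/12, 32 × 0.85 → 27/5 — and randomizes
only the placement.  A multinomial mode exists for studying exactly that
sampling noise.

Within the global quota, each conformer's count is split as evenly as
possible across the symmetry-operator classes (each class holds the
N₁N₂N₃ lattice copies of one operator).  The reason is a lattice-averaging
identity: folding a supercell back into the unit cell cancels lattice
translations but not operator identity, so the ensemble-averaged structure
factors equal those of the occupancy-weighted single model exactly *iff*
per-operator populations are equal.  When the count divides evenly (20/12
over 4 operators → 5/3 each) the identity is exact to machine precision;
when it cannot (27/5), the remainder is spread minimally and the residual is
the genuine, irreducible lattice-averaging error (~10⁻³ relative on the toy).

The adduct is assigned in a second, conditional round restricted to copies
whose host residue realized the reactive conformer, with quota
round(n_reactive·p); it never appears on inert copies.  Copies are indexed
(operator, lattice vector) lexicographically and the RNG consumes draws in
that order, so a seed pins the realization.

Ion bookkeeping uses N = round(C·V·N_A) per species with N_A = 6.022×10²³;
the rounding rule is configurable (nearest/ceiling) because published ion
counts are not always reproducible from published concentrations — the
count is reported, not silently reconciled.  Neutralization counter-ions
are a separate, explicitly labeled budget.

## Structure factors

`sf_direct` is the oracle: exact direct summation over symmetry images with
4-Gaussian form factors f(s) = Σ aᵢ exp(−bᵢs²/4) + c (coefficients from the
standard International Tables set, covering H/C/N/O/S/Mg/Cl/K and a few
spares) and Debye–Waller exp(−2π² hᵀ(A⁻¹ U A⁻ᵀ)h) for anisotropic atoms,
exp(−B s²/4) for isotropic ones.  Reflection sets hold the full sphere to
d_min with F(000) excluded, so Friedel symmetry is a testable property, not
a storage convention.

`sf_fft` is the fast path: each form-factor Gaussian term becomes a
real-space Gaussian of covariance U + (bᵢ + blur)/(8π²)·I, accumulated on
the grid within 4.5σ of the atom and FFT'd; the extra isotropic blur (set
from the grid spacing so the sharpest term stays resolvable) is divided out
in reciprocal space.  Defaults: grid spacing d_min/3, truncation 4.5σ.
Under these defaults the amplitude-weighted disagreement with `sf_direct`
is ~10⁻⁵–10⁻⁴ on the test fixtures, well under the 1% the test suite
enforces.  Doubling the grid density moves amplitudes by <0.2%.

`sf_ensemble` folds every supercell frame into the unit cell
(fraction × dims mod 1), computes per-frame structure factors with per-atom
B = 0 — the disorder is carried by the ensemble itself — and averages
complex F over frames, normalized per unit cell.  Averaging complex F is
equivalent to averaging electron density; it is the reciprocal-space
analogue of the time-and-lattice averaging a diffraction measurement
performs.  Component selections (protein / water / per-ion-species) restrict
the atom set before summation and sum exactly to the full calculation, by
linearity.

No bulk-solvent model is applied and F(000) is always omitted: every
downstream consumer is a difference map, where a flat solvent contribution
cancels.  Hydrogens, when present, scatter with their own form factor
rather than being special-cased.

## Difference maps and real-space analytics

Two amplitude sets are put on a common scale by the least-squares scalar
k minimizing Σ(|F_a| − k|F_b|)², computed over common indices only.  The
difference synthesis anchors the scale on whichever input carries the larger
total intensity, which makes the map exactly antisymmetric under exchange of
the two inputs (per-direction least-squares scales are not mutual inverses,
so a naive convention loses that property).  Coefficients are the unweighted
(|F_on| − k|F_off|)·exp(iφ_calc) with phases from a reference model; a
weighting hook exists but defaults off.  The map σ is the RMS over the whole
unit-cell grid, matching the usual "contoured at 3σ" convention; difference
maps have mean ≈ 0 because F(000) is omitted.

Peaks are 26-neighborhood local extrema of either sign with |ρ| ≥ threshold
× σ, positioned by 3-point quadratic interpolation per axis (ties broken by
grid order, offsets clamped to ±half a voxel), annotated with the nearest
model atom by minimum-image distance, and filtered to a maximum model
distance (default 5 Å).  The census is invariant under global map scaling
because the threshold is σ-relative.

IADDAT is, per residue, the *mean* over voxels within a radius of the
residue's selected atoms of (|ρ| − threshold)₊.  Defaults: threshold 3σ,
radius 2.5 Å.  The mean (not the sum) decouples the score from residue
size; the defaults are declared choices, configurable, since the literature
varies.  Masked map correlation is the Pearson correlation over voxels
within a radius (default 2.0 Å, a tight main-chain mask) of the selected
atoms; a featureless map returns 0.

## ADP analytics

B_diff profiles average (B_on − B_off) over selected atoms per residue,
using the altloc-A conformer where alternates exist; unmatched residues are
skipped with a warning.  Principal axes come from a sorted symmetric
eigen-decomposition with a deterministic sign convention (largest component
positive).  Peak/axis alignment is |cos θ| between the +/− peak displacement
vector and the major axis (the best over all three axes is also reported).
The Rosenfield matrix is Δ_AB = n̂ᵀU_A n̂ − n̂ᵀU_B n̂ — antisymmetric, zero
diagonal, and exactly zero for any common-U (pure-translation rigid-body)
model; the residue-binned reduction averages |Δ| within bin pairs,
excluding the structural zero diagonal.  The rigid-body "pass" criterion is
binned mean |Δ| < 0.001 Å², a declared operationalization of what is
usually a visual judgement.

## Titration and kinetics

The occupancy model is Occ(pH) = base + amp/(1 + 10^(s·(pH − pKa))) with
base, amp ∈ [0, 1] (crystallographic occupancies rarely span the full
range) and the direction s ∈ {±1} *fitted* by trying both orientations and
keeping the lower residual sum — the textbook equation has the ratio
increasing with pH, but shifted-conformer occupancies can fall with pH, and
the fitter must not hard-code either.  Data flatter than a constant model
(by AIC) return a fit flagged `ok=False` rather than raising.  Confidence
intervals are a seeded 1000-resample bootstrap, appropriate for the ~6–8
point series this is meant for.

Rate profiles use v(pH) = vmax/((1+10^(pKa_rise−pH))(1+10^(pH−pKa_fall))).
For this functional form the analytic optimum is the midpoint of the two
pKas, which is what is reported; empirical dose-response fits with other
shape parameters can place their maximum elsewhere.  Absorbance slopes
convert to µM/s via Beer–Lambert, rate = slope/(ε·path)·10⁶, default
ε = 1.33×10⁴ M⁻¹cm⁻¹.

Free energies between conformers use ΔG = −RT ln(n₂/n₁) with
R = 8.314 J mol⁻¹ K⁻¹, reported in kJ/mol; positive when conformer 2 is the
minority.  At (0.64, 0.36, 298 K) this evaluates to 1.43 kJ/mol.  Published
figures computed from unrounded occupancies can differ at the 0.1 kJ/mol
level (e.g. 0.645/0.355 gives 1.48, 0.65/0.35 gives 1.53); the function
evaluates the formula and nothing else.

## The synthetic toy crystal

Residues are 4-atom main-chain + 1 side-chain pseudo-residues (C/N/O with a
C or S side chain): enough scattering contrast for every analysis stage,
none of the force-field machinery.  The default cell is 25×20×18 Å, P1,
10 residues, ~1.5 Å data — FFTs run in fractions of a second; a C2 variant
(and a C2 option on the toy spec) exercises every symmetry path with 4
operators.  The two states differ by exactly the features the analyses
target: inverted loop occupancies (0.64 → 0.39 closed), a 0.53-occupancy
3-atom planar adduct bonded to the 0.85-occupancy reactive nucleophile
conformer only, a 0.64-occupancy water whose site is < 2.2 Å from a
closed-conformer atom (steric gating encoded in geometry) and > 3 Å from
the open conformer, and a +4 Å² ADP elevation on the mobile residues.
Anisotropic tensors on mobile atoms are elongated along their displacement
directions, so the peak/axis-alignment analysis has a planted signal.

Generation is deterministic; requested geometries whose open conformer
would land within 0.9 Å of a fixed atom (minimum image) raise a generation
error rather than producing a silently unphysical crystal.  Ensembles fix
each copy's conformer across frames and add per-frame Gaussian
displacements with each atom's U as covariance (Cholesky sampling); the
sample covariance over 10⁴ frames recovers U within 10%.  Observation noise
is multiplicative Gaussian on amplitudes (σ = noise_frac·|F|, recorded in
the sigma column) — sufficient for testing σ-thresholded difference-map
logic, and the stated σ model keeps scaling exact.

What the toy does *not* emulate: real protein topology and chemistry,
solvent beyond the single gated water, bulk-solvent scattering, radiation
damage, merging statistics, or refinement — so passing tests demonstrate
the correctness of the analysis machinery on data with known ground truth,
not the behavior of any real crystal.  Problem sizes (10-residue cell,
2×2×2 supercells, 1–8 frames, 1.5 Å cutoff) were chosen so the whole suite
and the acceptance script run in about a minute each on one core; all
quantities they compute are stable well below the tolerances asserted.

## Numerical choices and degenerate inputs

* Least-squares scaling requires ≥ 50 common reflections; fewer is an error.
* Difference synthesis requires the phase model to cover ≥ 95% of the
  common set at the requested resolution.
* A σ = 0 (empty) map yields an empty peak list, all-zero IADDAT, and map
  correlation 0 by definition.
* Quota assignment rejects units whose occupancies sum below 0.99 unless an
  absent state is declared; sums in (0.99, 1] are renormalized.
* Eigen-decompositions require symmetry to 10⁻⁸; tensors are checked
  positive-semidefinite to −10⁻⁸.
* Bounded trust-region least squares with tolerances 10⁻¹⁴ makes noiseless
  titration round trips exact to ~10⁻⁸ pH units.
* Seeds: every stochastic stage takes an explicit integer seed; derived
  seeds are drawn from a master generator and kept below 2³¹.
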