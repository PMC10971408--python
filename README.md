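# xtalens

Conformational-ensemble analytics for time-resolved crystallography.

When an enzyme crystal is probed before and after a reaction step, the
changes are rarely whole-scale rearrangements: occupancies of pre-existing
alternate conformers shift, a covalent adduct forms on one conformer of the
nucleophile but not the other, and ordered waters appear or vanish as loops
gate their binding sites.  `xtalens` implements the computational machinery
for analyzing such systems and for checking that analysis end-to-end on
synthetic crystals whose ground truth is known:

* **Supercell conformer sampling** — a refined model with grouped alternate
  conformers describes a lattice *average*; a simulation or ensemble model
  needs each of the N₁×N₂×N₃×n_ops protein copies in exactly one state.
  Copies are assigned by quota (largest remainder, so populations match the
  refined occupancies) or multinomially, with a second conditional round for
  a partially formed covalent adduct that can only ride on the reactive
  conformer.  Buffer-ion bookkeeping (`N = round(C·V·N_A)`) is included.
* **Structure factors** — an exact direct-summation path
  `F(h) = Σ_ops Σ_atoms occ·f(s)·DW(h)·exp(2πi h·(Rx+t))` with anisotropic
  Debye–Waller factors, a fast FFT path (Gaussian atoms on a grid, blur
  divided out in reciprocal space), and ensemble averaging: frames of a
  supercell are folded back into the unit cell and complex F is averaged
  over time and lattice, the reciprocal-space counterpart of what a
  diffraction experiment measures.
* **Isomorphous difference maps** — unweighted F_o−F_o (or F_ens−F_ens)
  syntheses from least-squares-scaled amplitudes with model phases, with
  σ-thresholded peak picking, per-residue integration of absolute
  difference density above a noise threshold (IADDAT), and masked
  real-space map correlations.
* **Anisotropic-ADP analytics** — per-residue B_diff between two states,
  ellipsoid principal axes, alignment of paired ± difference peaks with
  those axes, and Rosenfield rigid-body difference matrices
  (Δ_AB = n̂ᵀU_A n̂ − n̂ᵀU_B n̂ on the interatomic direction n̂).
* **Titration and kinetics fits** — Henderson–Hasselbalch occupancy-vs-pH
  fits `Occ(pH) = base + amp/(1 + 10^(s·(pH−pKa)))` with the direction s
  fitted, two-pKa bell fits for rate-vs-pH profiles, Beer–Lambert
  slope→rate conversion, and conformer free energies ΔG = −RT ln(n₂/n₁).
* **Synthetic data** — a deterministic toy crystal (ten 5-atom
  pseudo-residues, ~25×20×18 Å cell, P1 or C2) with a two-conformer loop
  (occupancies 0.64/0.36 at rest, inverted to 0.39/0.61 after reaction), a
  nucleophile with reactive (0.85) and inert conformers, a 0.53-occupancy
  adduct on the reactive conformer only, and a 0.64-occupancy gated water
  whose site clashes with the closed loop conformer.

## Worked example

```python
from xtalens import (make_toy_pair, make_observations, fo_minus_fo_map,
                     find_peaks, modification_fraction, delta_g)

s0, s30 = make_toy_pair()                      # resting / reacted states
obs0  = make_observations(s0,  dmin=1.5, noise_frac=0.03, seed=1)
obs30 = make_observations(s30, dmin=1.5, noise_frac=0.03, seed=2)
dmap  = fo_minus_fo_map(obs30, obs0, phase_model=s0, dmin=1.5)
peaks = find_peaks(dmap, threshold_sigma=3.2, model=s30, max_dist=5.0)
print(len(peaks), round(peaks[0].height_sigma, 1))

print(round(modification_fraction(0.53, 0.85), 1))  # % of reactive conformer modified
print(round(delta_g(0.64, 0.36, 298.0), 2))         # kJ/mol between loop conformers
```

prints (seeds as shown):

```
61 26.3
62.4
1.43
```

61 difference peaks survive the 3.2σ cut; the strongest (26.3σ, positive)
sits on the gated water site — it vanishes if the toy is generated with
`occ_water=0`.  The reactive nucleophile conformer is 62.4% modified by a
0.53-occupancy adduct, and the 0.64/0.36 loop populations correspond to a
1.43 kJ/mol free-energy gap at 298 K.

The full pipeline (`xtalens pipeline --out report.json`, or
`run_pipeline(PipelineConfig())` in Python) adds the supercell-ensemble
stage: quota-sampled 2×2×2 ensembles are built for both states, their
ensemble-averaged difference map is correlated with the "observed" F_o−F_o
map, and the masked correlation is higher over the mobile-loop main chain
(0.76) than over the whole chain (0.62) — the agreement concentrates
exactly where the two states differ.

## Command line

`xtalens` exposes each stage: `simulate`, `supercell`, `sf`, `sf-ensemble`,
`diffmap`, `peaks`, `iaddat`, `mapcc`, `adp bdiff`, `adp rosenfield`,
`titrate fit-pka|fit-rate|dg`, `ions`, and `pipeline`.  Run any of them
with `--help` for options.

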