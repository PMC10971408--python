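"""Synthetic toy crystals, ensembles, observations, and titration series.

The toy system emulates the statistical structure of a small enzyme crystal
caught before and after partial formation of a covalent intermediate:

* a mobile loop with two grouped conformers (closed/open) whose occupancies
  invert between the resting (0 s) and reacted (30 s) states
  (0.64 closed at rest, 0.39 after reaction);
* a nucleophilic cysteine-like side chain with a reactive conformer
  (occupancy 0.85) and a catalytically inert one;
* a 3-atom planar covalent adduct (occupancy 0.53) bonded to the reactive
  conformer only, so the adduct rides on a second, conditional round of
  conformer sampling;
* a gated water (occupancy 0.64) whose site sterically clashes (< 2.2 A)
  with the closed loop conformer, encoding the correlated-disorder gate;
* pH-dependent occupancies following a single-pKa titration.

Residues are 4-atom main-chain + 1 side-chain pseudo-residues (C/N/O/S);
this captures the scattering contrast the analysis needs without force-field
machinery.  Default cell ~25 x 20 x 18 A in P1 keeps FFTs at seconds scale;
a C2 variant exercises the symmetry paths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .model import (EIGHT_PI_SQ, P1, AltGroup, Atom, SpaceGroup, Structure,
                    UnitCell, write_structure)
from .sf import ReflectionSet, sf_fft
from .supercell import assign_adduct, assign_conformers, realize
from .titration import TitrationSeries, hh_logistic


class GenerationError(RuntimeError):
    """Toy-system geometry cannot be built as requested."""


# --------------------------------------------------------------------------- #
# Specs

@dataclass
class ToyCrystalSpec:
    """Parameters of the two-state toy crystal (defaults are the study-like
    occupancy structure)."""

    cell: UnitCell = field(default_factory=lambda: UnitCell(25.0, 20.0, 18.0))
    spacegroup: SpaceGroup = P1
    n_residues: int = 10
    loop_range: tuple = (5, 7)
    loop_shift: float = 1.6          # A, closed -> open displacement
    occ_closed: float = 0.64         # resting closed-loop occupancy
    occ_closed_bound: float = 0.39   # closed-loop occupancy after reaction
    nucleophile_resid: int = 8
    occ_reactive: float = 0.85
    occ_adduct: float = 0.53
    occ_water: float = 0.64
    adp_scale: float = 10.0          # baseline B, A^2
    bdiff: float = 4.0               # extra B on mobile residues at 30 s
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("occ_closed", "occ_closed_bound", "occ_reactive",
                     "occ_adduct", "occ_water"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.occ_adduct > self.occ_reactive + 1e-9:
            raise ValueError("adduct occupancy cannot exceed the reactive "
                             "conformer occupancy")
        lo, hi = self.loop_range
        if not (1 <= lo <= hi <= self.n_residues):
            raise ValueError("loop_range outside the chain")


@dataclass
class TitrationSpec:
    pka: float = 5.7
    ph_values: tuple = (3.5, 4.2, 5.0, 5.4, 6.0, 6.6, 7.4, 8.3)
    noise_sd: float = 0.0
    direction: str = "protonation-favors-shifted"
    base: float = 0.0
    amp: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        ph = np.asarray(self.ph_values, dtype=float)
        if not (np.diff(ph) > 0).all():
            raise ValueError("ph_values must be strictly increasing")


# --------------------------------------------------------------------------- #
# Toy geometry

_MAIN_CHAIN = (("N", "N", np.array([0.0, 0.0, 0.0])),
               ("CA", "C", np.array([1.0, 0.9, 0.3])),
               ("C", "C", np.array([2.0, 0.2, 0.7])),
               ("O", "O", np.array([2.2, -0.9, 1.1])))
_SIDE_OFFSET = np.array([1.1, 2.2, 1.0])
_LOOP_DIR = np.array([0.0, 0.30, -0.95]) / np.linalg.norm([0.0, 0.30, -0.95])
_NUC_ALT = np.array([-1.1, 1.3, 0.8]) / np.linalg.norm([-1.1, 1.3, 0.8]) * 1.8


def _residue_origin(i: int) -> np.ndarray:
    return np.array([1.5 + 2.2 * (i - 1),
                     8.0 + 1.2 * math.sin(0.9 * i),
                     9.0 + 1.0 * math.cos(0.7 * i)])


def _aniso_u(b_iso: float, elongate: np.ndarray | None = None,
             factor: float = 1.5) -> np.ndarray:
    u0 = b_iso / EIGHT_PI_SQ
    u = u0 * np.eye(3)
    if elongate is not None:
        n = np.asarray(elongate) / np.linalg.norm(elongate)
        u = u + factor * u0 * np.outer(n, n)
    return u


def _add_atom(s: Structure, element, name, resnum, resname, cart, occ, u,
              altloc="", chain="A", hetatm=False) -> int:
    a = Atom(element=element, name=name, chain=chain, resnum=resnum,
             resname=resname, altloc=altloc, frac=s.cell.cart_to_frac(cart),
             occ=occ, biso=float(np.trace(u)) / 3.0 * EIGHT_PI_SQ, uaniso=u,
             hetatm=hetatm)
    s.atoms.append(a)
    return len(s.atoms) - 1


def _build_state(spec: ToyCrystalSpec, bound: bool) -> Structure:
    s = Structure(cell=spec.cell, spacegroup=spec.spacegroup)
    lo, hi = spec.loop_range
    loop_res = set(range(lo, hi + 1))
    occ_closed = spec.occ_closed_bound if bound else spec.occ_closed
    shift = spec.loop_shift * _LOOP_DIR
    mobile = loop_res | {spec.nucleophile_resid}
    loop_a, loop_b, fixed_idx = [], [], []
    nuc_a = nuc_b = None
    for i in range(1, spec.n_residues + 1):
        origin = _residue_origin(i)
        b_res = spec.adp_scale + (spec.bdiff if bound and i in mobile else 0.0)
        in_loop = i in loop_res
        side_el = "S" if i == spec.nucleophile_resid else "C"
        side_name = "SG" if side_el == "S" else "CB"
        atoms = list(_MAIN_CHAIN) + [(side_name, side_el, _SIDE_OFFSET)]
        for name, el, off in atoms:
            cart = origin + off
            if in_loop:
                u = _aniso_u(b_res, elongate=shift)
                ia = _add_atom(s, el, name, i, "GLY", cart, occ_closed, u, "A")
                ib = _add_atom(s, el, name, i, "GLY", cart + shift,
                               1.0 - occ_closed, u, "B")
                loop_a.append(ia)
                loop_b.append(ib)
            elif name == side_name and i == spec.nucleophile_resid:
                u = _aniso_u(b_res, elongate=_NUC_ALT)
                nuc_a = _add_atom(s, el, name, i, "CYS", cart,
                                  spec.occ_reactive, u, "A")
                nuc_b = _add_atom(s, el, name, i, "CYS", cart + _NUC_ALT,
                                  1.0 - spec.occ_reactive, u, "B")
            else:
                resname = "CYS" if i == spec.nucleophile_resid else "ALA"
                u = _aniso_u(b_res)
                fixed_idx.append(_add_atom(s, el, name, i, resname, cart, 1.0, u))
    s.altgroups = [
        AltGroup("loop", "A", occ_closed, loop_a),
        AltGroup("loop", "B", 1.0 - occ_closed, loop_b),
        AltGroup("nuc", "A", spec.occ_reactive, [nuc_a]),
        AltGroup("nuc", "B", 1.0 - spec.occ_reactive, [nuc_b]),
    ]
    if bound:
        sg_cart = s.cell.frac_to_cart(s.atoms[nuc_a].frac)
        b_add = spec.adp_scale + spec.bdiff
        add_idx = []
        c1 = sg_cart + np.array([0.95, 1.25, 0.55])
        for name, el, cart in (("C1", "C", c1),
                               ("N1", "N", c1 + np.array([1.05, 0.85, 0.35])),
                               ("O1", "O", c1 + np.array([-0.35, 1.30, -0.55]))):
            add_idx.append(_add_atom(s, el, name, 100, "ADU", cart,
                                     spec.occ_adduct, _aniso_u(b_add),
                                     hetatm=True))
        if spec.occ_adduct > 0:
            s.altgroups.append(AltGroup("adduct", "A", spec.occ_adduct, add_idx))
            s.absent_ok.add("adduct")
            s.conditional["adduct"] = ("nuc", "A")
        else:
            del s.atoms[add_idx[0]:]
        if spec.occ_water > 0:
            closed_anchor = s.cell.frac_to_cart(s.atoms[loop_a[-1]].frac)
            # offset opposes the loop-shift direction: the site clashes with
            # the closed conformer (< 2.2 A) but is well clear of the open one
            w_cart = closed_anchor + np.array([0.3, 0.6, 1.8])
            wi = _add_atom(s, "O", "O", 200, "HOH", w_cart, spec.occ_water,
                           _aniso_u(spec.adp_scale), hetatm=True)
            s.altgroups.append(AltGroup("wat", "A", spec.occ_water, [wi]))
            s.absent_ok.add("wat")
    _check_clashes(s, spec)
    s.validate()
    return s


def _check_clashes(s: Structure, spec: ToyCrystalSpec,
                   min_dist: float = 0.9) -> None:
    """Open-conformer atoms must not collide with atoms outside their unit."""
    grouped: dict = {}
    for g in s.altgroups:
        for i in g.atom_indices:
            grouped[i] = g.unit
    frac = s.frac_coords()
    open_idx = [i for g in s.altgroups if g.unit == "loop" and g.label == "B"
                for i in g.atom_indices]
    other = [i for i in range(len(s.atoms))
             if grouped.get(i) != "loop" and not s.atoms[i].hetatm]
    for i in open_idx:
        d = frac[other] - frac[i]
        d -= np.round(d)  # periodic minimum image
        dist = np.linalg.norm(s.cell.frac_to_cart(d), axis=1)
        if (dist < min_dist).any():
            raise GenerationError(
                f"loop_shift {spec.loop_shift} places the open conformer "
                f"within {min_dist} A of a fixed atom")


def water_site(spec: ToyCrystalSpec) -> np.ndarray:
    """Fractional coordinates of the gated-water site."""
    s30 = _build_state(spec, bound=True)
    for a in s30.atoms:
        if a.resname == "HOH":
            return a.frac.copy()
    raise GenerationError("spec has occ_water = 0: no water site")


def make_toy_pair(spec: ToyCrystalSpec | None = None):
    """Build the (resting, reacted) toy structure pair.

    The two structures share topology; the reacted (30 s) state differs only
    by the adduct (on the reactive conformer, occupancy ``occ_adduct``),
    inverted loop occupancies, and the gated water.  Deterministic.
    """
    spec = spec or ToyCrystalSpec()
    return _build_state(spec, bound=False), _build_state(spec, bound=True)


def make_c2_toy(adp_scale: float = 8.0) -> Structure:
    """Small monoclinic C2 structure for exercising symmetry paths."""
    cell = UnitCell(28.0, 16.0, 14.0, 90.0, 100.0, 90.0)
    s = Structure(cell=cell, spacegroup=SpaceGroup.from_symbol("C 1 2 1"))
    positions = [("N", "N", (2.0, 1.5, 2.2)), ("C", "CA", (3.0, 2.3, 2.6)),
                 ("C", "C", (4.1, 1.7, 3.3)), ("O", "O", (4.2, 0.5, 3.5)),
                 ("S", "SG", (3.2, 3.6, 4.0))]
    for k, (el, name, cart) in enumerate(positions):
        u = _aniso_u(adp_scale, elongate=(1.0, 0.5, 0.2) if el == "S" else None)
        _add_atom(s, el, name, k + 1, "ALA" if el != "S" else "CYS",
                  np.array(cart), 1.0, u)
    return s


# --------------------------------------------------------------------------- #
# Ensembles

@dataclass
class Ensemble:
    """Multi-frame supercell coordinate set sharing one topology."""

    structure: Structure            # realized P1 supercell (frame template)
    coords: np.ndarray              # (n_frames, n_atoms, 3) fractional
    dims: tuple
    manifest: dict | None = None

    @property
    def n_frames(self) -> int:
        return len(self.coords)

    def frame_structure(self, k: int) -> Structure:
        s = self.structure.copy()
        for a, f in zip(s.atoms, self.coords[k]):
            a.frac = f.copy()
        return s

    def write_pdb(self, path) -> None:
        from .model import write_multimodel
        write_multimodel([self.frame_structure(k)
                          for k in range(self.n_frames)], path)


def make_ensemble(s: Structure, dims=(2, 2, 2), n_frames: int = 1,
                  seed: int = 0, displace: bool = True) -> Ensemble:
    """Occupancy-consistent multi-frame supercell ensemble.

    Conformers are fixed per copy across frames (quota assignment, with a
    conditional round for adduct units); per-frame atomic displacements are
    Gaussian with each atom's U tensor as covariance.  ``displace=False``
    (or zero ADPs) gives static frames equal to the realization.
    """
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    master = np.random.default_rng(seed)
    sub = master.integers(2 ** 31, size=3)
    model = assign_conformers(s, dims, seed=int(sub[0]))
    for unit, (host_unit, host_label) in s.conditional.items():
        occ_unit = next(g.occ for g in s.altgroups if g.unit == unit)
        occ_host = next(g.occ for g in s.altgroups
                        if g.unit == host_unit and g.label == host_label)
        assign_adduct(model, occ_unit / occ_host, seed=int(sub[1]), unit=unit)
    realized = realize(model)
    n_atoms = len(realized.atoms)
    base = realized.frac_coords()
    coords = np.broadcast_to(base, (n_frames, n_atoms, 3)).copy()
    if displace:
        rng = np.random.default_rng(int(sub[2]))
        fracm = realized.cell.frac
        for i, a in enumerate(realized.atoms):
            u = a.uaniso if a.uaniso is not None else \
                (a.biso / EIGHT_PI_SQ) * np.eye(3)
            if np.trace(u) <= 0:
                continue
            chol = np.linalg.cholesky(u + 1e-12 * np.eye(3))
            z = rng.standard_normal((n_frames, 3))
            coords[:, i, :] += (z @ chol.T) @ fracm.T
    return Ensemble(structure=realized, coords=coords, dims=tuple(dims),
                    manifest=model.manifest())


# --------------------------------------------------------------------------- #
# Observations and titrations

def make_observations(s: Structure, dmin: float = 1.5,
                      noise_frac: float = 0.0, seed: int = 0) -> ReflectionSet:
    """Synthetic amplitude observations: |F_calc| with multiplicative
    Gaussian noise of sd = noise_frac * |F|; the sigma column records that
    sd.  F(000) is excluded by construction."""
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    r = sf_fft(s, dmin)
    amp = np.abs(r.f)
    sd = noise_frac * amp
    if noise_frac > 0:
        rng = np.random.default_rng(seed)
        amp = amp + rng.standard_normal(len(amp)) * sd
    return ReflectionSet(r.cell, r.hkl, amp=amp, sig=sd, dmin=dmin)


def make_titration(spec: TitrationSpec | None = None) -> TitrationSeries:
    """Occupancy-vs-pH series following the single-pKa logistic (clipped to
    [0, 1]) plus Gaussian noise."""
    spec = spec or TitrationSpec()
    sign = {"protonation-favors-shifted": +1,
            "deprotonation-favors-shifted": -1}[spec.direction]
    ph = np.asarray(spec.ph_values, dtype=float)
    occ = np.clip(hh_logistic(ph, spec.pka, spec.base, spec.amp, sign),
                  0.0, 1.0)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        occ = occ + rng.standard_normal(len(ph)) * spec.noise_sd
    sd = np.full(len(ph), max(spec.noise_sd, 1e-6))
    return TitrationSeries(ph=ph, y=np.clip(occ, 0.0, 1.0), sd=sd,
                           kind="occupancy")


def write_toy_pair(spec: ToyCrystalSpec, outdir) -> dict:
    """Emit the toy pair as PDB files; returns the path map."""
    from pathlib import Path
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    s0, s30 = make_toy_pair(spec)
    paths = {"state_0s": outdir / "toy_0s.pdb",
             "state_30s": outdir / "toy_30s.pdb"}
    write_structure(s0, paths["state_0s"])
    write_structure(s30, paths["state_30s"])
    return {k: str(v) for k, v in paths.items()}
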