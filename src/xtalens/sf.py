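"""Structure factors and electron density.

Two routes are provided and must agree: :func:`sf_direct` is the exact
direct-summation oracle,

    F(h) = sum_ops sum_atoms occ * f(s) * DW(h) * exp(2 pi i h.(Rx + t)),

with anisotropic Debye-Waller exp(-2 pi^2 h^T (A^-1 U A^-T) h) (A the
orthogonalization matrix, U Cartesian); :func:`sf_fft` samples Gaussian
atoms on a grid and FFTs, the fast path used for maps and ensembles.

Ensemble structure factors fold supercell frames back into the unit cell and
average complex F over frames — time-and-lattice averaging, the reciprocal
counterpart of averaging electron density.  F(000) is always omitted and no
bulk-solvent model is applied: every downstream consumer is a difference map
in which a flat solvent term cancels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import gemmi
import numpy as np
import scipy.fft

from .model import (EIGHT_PI_SQ, P1, Structure, UnitCell, expand_to_unit_cell)

TWO_PI = 2.0 * math.pi


# --------------------------------------------------------------------------- #
# Form factors

@dataclass(frozen=True)
class FormFactorTable:
    """Element -> 4-Gaussian x-ray scattering coefficients (a_i, b_i, c).

    f(s) = sum_i a_i exp(-b_i s^2 / 4) + c with s = 1/d.  f(0) is the
    electron count.
    """

    coeffs: dict

    def __contains__(self, element: str) -> bool:
        return element.upper() in self.coeffs

    def evaluate(self, element: str, s2) -> np.ndarray:
        """f(s) for an array of s^2 = 1/d^2 values."""
        try:
            a, b, c = self.coeffs[element.upper()]
        except KeyError:
            raise KeyError(f"no form-factor coefficients for element "
                           f"{element!r}") from None
        s2 = np.asarray(s2, dtype=float)
        f = np.full_like(s2, c)
        for ai, bi in zip(a, b):
            f = f + ai * np.exp(-bi * s2 / 4.0)
        return f

    def f0(self, element: str) -> float:
        a, _, c = self.coeffs[element.upper()]
        return float(sum(a) + c)


def _default_coeffs() -> dict:
    # International Tables 4-Gaussian coefficients, taken from gemmi's tables
    out = {}
    for el in ("H", "C", "N", "O", "S", "MG", "CL", "K", "P", "NA", "CA", "FE"):
        it = gemmi.Element(el.capitalize()).it92
        a1, a2, a3, a4, b1, b2, b3, b4, c = it.get_coefs()
        out[el] = ((a1, a2, a3, a4), (b1, b2, b3, b4), c)
    return out


DEFAULT_FORM_FACTORS = FormFactorTable(_default_coeffs())


# --------------------------------------------------------------------------- #
# Reflection sets

@dataclass
class ReflectionSet:
    """Miller indices with complex structure factors or amplitudes (+sigma).

    Indices cover the full sphere to d_min with F(000) excluded, so Friedel
    mates are explicit; for real scatterers F(-h) = conj(F(h)).
    """

    cell: UnitCell
    hkl: np.ndarray                    # (n, 3) int
    f: np.ndarray | None = None        # complex
    amp: np.ndarray | None = None
    sig: np.ndarray | None = None
    dmin: float | None = None

    def __post_init__(self) -> None:
        self.hkl = np.asarray(self.hkl, dtype=int)
        uniq = {tuple(h) for h in self.hkl}
        if len(uniq) != len(self.hkl):
            raise ValueError("duplicate Miller indices")
        if (0, 0, 0) in uniq:
            raise ValueError("F(000) must be excluded")

    def __len__(self) -> int:
        return len(self.hkl)

    def amplitudes(self) -> np.ndarray:
        if self.amp is not None:
            return self.amp
        return np.abs(self.f)

    def phases(self) -> np.ndarray:
        if self.f is None:
            raise ValueError("no phases: reflection set holds amplitudes only")
        return np.angle(self.f)

    def index_map(self) -> dict:
        return {tuple(h): i for i, h in enumerate(self.hkl)}

    def d_spacings(self) -> np.ndarray:
        return 1.0 / np.sqrt(self.cell.inv_d2(self.hkl))

    def copy(self) -> "ReflectionSet":
        return ReflectionSet(
            self.cell, self.hkl.copy(),
            None if self.f is None else self.f.copy(),
            None if self.amp is None else self.amp.copy(),
            None if self.sig is None else self.sig.copy(), self.dmin)


def generate_indices(cell: UnitCell, dmin: float) -> np.ndarray:
    """Full-sphere Miller indices with d >= dmin, origin excluded."""
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    hmax = int(math.ceil(cell.a / dmin)) + 1
    kmax = int(math.ceil(cell.b / dmin)) + 1
    lmax = int(math.ceil(cell.c / dmin)) + 1
    h, k, l = np.meshgrid(np.arange(-hmax, hmax + 1),
                          np.arange(-kmax, kmax + 1),
                          np.arange(-lmax, lmax + 1), indexing="ij")
    hkl = np.stack([h.ravel(), k.ravel(), l.ravel()], axis=1)
    inv_d2 = cell.inv_d2(hkl)
    keep = (inv_d2 <= 1.0 / dmin ** 2 + 1e-12) & (inv_d2 > 1e-12)
    return hkl[keep]


# --------------------------------------------------------------------------- #
# Direct summation

def _symmetry_images(s: Structure):
    """Flatten symmetry copies into (frac, occ, element, biso, U) arrays."""
    p1 = expand_to_unit_cell(s)
    frac = p1.frac_coords()
    occ = np.array([a.occ for a in p1.atoms])
    biso = np.array([a.biso for a in p1.atoms])
    elements = [a.element.upper() for a in p1.atoms]
    uanisos = [a.uaniso for a in p1.atoms]
    return frac, occ, elements, biso, uanisos


def sf_direct(s: Structure, hkl=None, dmin: float | None = None,
              table: FormFactorTable = DEFAULT_FORM_FACTORS,
              b_override: float | None = None) -> ReflectionSet:
    """Exact direct-summation structure factors (the oracle path).

    Either an explicit index list or a resolution limit must be given.
    ``b_override`` replaces every atom's displacement model with a single
    isotropic B (0 gives static atoms).
    """
    if hkl is None:
        if dmin is None:
            raise ValueError("provide hkl or dmin")
        hkl = generate_indices(s.cell, dmin)
    hkl = np.asarray(hkl, dtype=int)
    frac, occ, elements, biso, uanisos = _symmetry_images(s)
    for el in set(elements):
        if el not in table:
            raise KeyError(f"no form-factor coefficients for element {el!r}")
    s2 = s.cell.inv_d2(hkl)
    fel = {el: table.evaluate(el, s2) for el in set(elements)}
    finv = s.cell.frac  # A^-1
    hq = hkl @ finv     # rows: h^T A^-1 -> Cartesian reciprocal (x 2pi)
    f_total = np.zeros(len(hkl), dtype=complex)
    for i in range(len(frac)):
        phase = np.exp(TWO_PI * 1j * (hkl @ frac[i]))
        if b_override is not None:
            dw = np.exp(-b_override * s2 / 4.0)
        elif uanisos[i] is not None:
            u = uanisos[i]
            dw = np.exp(-2.0 * math.pi ** 2 *
                        np.einsum("ni,ij,nj->n", hq, u, hq))
        else:
            dw = np.exp(-biso[i] * s2 / 4.0)
        f_total += occ[i] * fel[elements[i]] * dw * phase
    return ReflectionSet(s.cell, hkl, f=f_total,
                         dmin=dmin or float(1.0 / math.sqrt(s2.max())))


# --------------------------------------------------------------------------- #
# FFT path

def good_grid_shape(cell: UnitCell, dmin: float, rate: float = 3.0) -> tuple:
    """FFT-friendly grid with spacing <= dmin/rate along each axis."""
    shape = []
    for length in (cell.a, cell.b, cell.c):
        n = int(math.ceil(length * rate / dmin))
        shape.append(scipy.fft.next_fast_len(max(n, 4), real=False))
    return tuple(shape)


def density_on_grid(s: Structure, shape, table: FormFactorTable = DEFAULT_FORM_FACTORS,
                    blur: float = 0.0, b_override: float | None = None,
                    cutoff_sigmas: float = 4.5) -> np.ndarray:
    """Sample ADP-broadened Gaussian atoms on a cell-commensurate grid.

    Each form-factor Gaussian term (a_i, b_i) plus the constant term c
    becomes a real-space Gaussian of covariance U + (b_i + B_atom_extra +
    blur) / (8 pi^2) I, truncated at ``cutoff_sigmas`` of its widest sigma.
    Returns electron density in e/A^3 (symmetry-expanded, periodic).
    """
    frac, occ, elements, biso, uanisos = _symmetry_images(s)
    orth = s.cell.orth
    shape = tuple(int(n) for n in shape)
    rho = np.zeros(shape)
    nvec = np.array(shape, dtype=float)
    # fractional half-widths per Cartesian A: bound |f_i| <= r * ||A^-1 row i||
    finv_row_norms = np.linalg.norm(s.cell.frac, axis=1)
    for i in range(len(frac)):
        a_coefs, b_coefs, c_coef = table.coeffs[elements[i]]
        terms = list(zip(a_coefs, b_coefs)) + [(c_coef, 0.0)]
        if b_override is not None:
            u_atom = (b_override / EIGHT_PI_SQ) * np.eye(3)
        elif uanisos[i] is not None:
            u_atom = uanisos[i]
        else:
            u_atom = (biso[i] / EIGHT_PI_SQ) * np.eye(3)
        u_blur = (blur / EIGHT_PI_SQ) * np.eye(3)
        covs = [u_atom + u_blur + (b / EIGHT_PI_SQ) * np.eye(3)
                for _, b in terms]
        sigma_max = math.sqrt(max(np.linalg.eigvalsh(c).max() for c in covs))
        r_cut = cutoff_sigmas * sigma_max
        # bounding box of grid points in fractional space
        lo = frac[i] - r_cut * finv_row_norms
        hi = frac[i] + r_cut * finv_row_norms
        idx = []
        for ax in range(3):
            n = shape[ax]
            i0 = int(math.floor(lo[ax] * n))
            i1 = int(math.ceil(hi[ax] * n))
            if i1 - i0 >= n:
                idx.append(np.arange(n))
            else:
                idx.append(np.arange(i0, i1 + 1) % n)
        fa, fb, fc = np.meshgrid(*[idx[ax] / nvec[ax] for ax in range(3)],
                                 indexing="ij")
        pts = np.stack([fa, fb, fc], axis=-1).reshape(-1, 3)
        delta = pts - frac[i]
        delta -= np.round(delta)  # minimum image
        dc = delta @ orth.T
        contrib = np.zeros(len(pts))
        for (amp, _), cov in zip(terms, covs):
            if amp == 0.0:
                continue
            cinv = np.linalg.inv(cov)
            det = np.linalg.det(cov)
            q = np.einsum("ni,ij,nj->n", dc, cinv, dc)
            norm = amp / ((2.0 * math.pi) ** 1.5 * math.sqrt(det))
            contrib += norm * np.exp(-0.5 * q)
        contrib *= occ[i]
        ii, jj, kk = np.meshgrid(idx[0], idx[1], idx[2], indexing="ij")
        np.add.at(rho, (ii.ravel(), jj.ravel(), kk.ravel()), contrib)
    return rho


def _auto_blur(cell: UnitCell, shape) -> float:
    spacing = max(cell.a / shape[0], cell.b / shape[1], cell.c / shape[2])
    return EIGHT_PI_SQ * (0.65 * spacing) ** 2


def sf_fft(s: Structure, dmin: float, rate: float = 3.0,
           table: FormFactorTable = DEFAULT_FORM_FACTORS,
           shape=None, b_override: float | None = None) -> ReflectionSet:
    """FFT structure factors: Gaussian-atom density -> FFT -> truncate to dmin.

    An extra isotropic blur keeps the sharpest Gaussian resolvable on the
    grid and is divided out in reciprocal space, so agreement with
    :func:`sf_direct` is limited only by the 4.5-sigma real-space truncation.
    """
    if dmin <= 0:
        raise ValueError("dmin must be positive")
    if shape is None:
        shape = good_grid_shape(s.cell, dmin, rate)
    spacing = max(s.cell.a / shape[0], s.cell.b / shape[1], s.cell.c / shape[2])
    if spacing > dmin / 2.0:
        raise ValueError(f"grid {shape} too coarse for dmin={dmin}")
    blur = _auto_blur(s.cell, shape)
    rho = density_on_grid(s, shape, table=table, blur=blur,
                          b_override=b_override)
    volume = s.cell.volume
    fgrid = volume * scipy.fft.ifftn(rho)
    hkl = generate_indices(s.cell, dmin)
    s2 = s.cell.inv_d2(hkl)
    idx = tuple((hkl % np.array(shape)).T)
    f = fgrid[idx] * np.exp(blur * s2 / 4.0)
    return ReflectionSet(s.cell, hkl, f=f, dmin=dmin)


def amplitude_weighted_r(a: ReflectionSet, b: ReflectionSet) -> float:
    """R = sum ||Fa| - |Fb|| / sum |Fa| over common indices."""
    amap = a.index_map()
    fa, fb = [], []
    bmap = b.index_map()
    for h, i in amap.items():
        j = bmap.get(h)
        if j is not None:
            fa.append(a.amplitudes()[i])
            fb.append(b.amplitudes()[j])
    fa, fb = np.array(fa), np.array(fb)
    return float(np.sum(np.abs(fa - fb)) / np.sum(fa))


# --------------------------------------------------------------------------- #
# Ensemble structure factors

SELECTIONS = ("all", "protein", "water", "ion")
_WATER_NAMES = {"HOH", "WAT"}
_ION_NAMES = {"MG", "CL", "K", "NA", "CA"}


def atom_category(atom) -> str:
    if atom.resname.upper() in _WATER_NAMES:
        return "water"
    if atom.resname.upper() in _ION_NAMES:
        return "ion"
    return "protein"


def _selection_mask(atoms, selection: str) -> np.ndarray:
    if selection == "all":
        return np.ones(len(atoms), dtype=bool)
    if selection.startswith("ion:"):
        species = selection.split(":", 1)[1].upper()
        return np.array([a.resname.upper() == species for a in atoms])
    if selection not in SELECTIONS:
        raise ValueError(f"unknown selection {selection!r}")
    return np.array([atom_category(a) == selection for a in atoms])


def sf_ensemble(ensemble, dmin: float, selection: str = "all",
                method: str = "fft",
                table: FormFactorTable = DEFAULT_FORM_FACTORS) -> ReflectionSet:
    """Ensemble-averaged structure factors from a multi-frame supercell.

    Every atom is folded to unit-cell fractional coordinates (supercell
    fraction x dims mod 1); per-frame structure factors are computed with
    per-atom B = 0 (disorder is carried by the ensemble itself) and averaged
    as complex numbers over frames, normalized per unit cell.
    """
    base = ensemble.structure
    dims = np.asarray(ensemble.dims, dtype=float)
    n_cells = int(np.prod(ensemble.dims))
    mask = _selection_mask(base.atoms, selection)
    if not mask.any():
        raise ValueError(f"selection {selection!r} matches no atoms")
    cell = UnitCell(base.cell.a / dims[0], base.cell.b / dims[1],
                    base.cell.c / dims[2], base.cell.alpha, base.cell.beta,
                    base.cell.gamma)
    sel_atoms = [a for a, m in zip(base.atoms, mask) if m]
    hkl = generate_indices(cell, dmin)
    acc = np.zeros(len(hkl), dtype=complex)
    for frame in ensemble.coords:
        folded = (frame[mask] * dims) % 1.0
        frame_struct = Structure(cell=cell, spacegroup=P1)
        for a, fr in zip(sel_atoms, folded):
            b = a.copy()
            b.frac = fr
            b.occ = 1.0
            b.biso = 0.0
            b.uaniso = None
            frame_struct.atoms.append(b)
        if method == "fft":
            r = sf_fft(frame_struct, dmin, table=table)
            fmap = r.index_map()
            order = [fmap[tuple(h)] for h in hkl]
            acc += r.f[order]
        else:
            acc += sf_direct(frame_struct, hkl=hkl, table=table).f
    acc /= len(ensemble.coords) * n_cells
    return ReflectionSet(cell, hkl, f=acc, dmin=dmin)


# --------------------------------------------------------------------------- #
# Map synthesis

@dataclass
class DensityGrid:
    """Real-space scalar field on a cell-commensurate grid (e/A^3)."""

    cell: UnitCell
    values: np.ndarray
    sigma: float | None = None

    @property
    def shape(self) -> tuple:
        return self.values.shape

    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.values ** 2)))

    def sigma_normalize(self) -> "DensityGrid":
        """Record the map RMS so thresholds can be given in sigma units."""
        return DensityGrid(self.cell, self.values, sigma=self.rms())

    def grid_frac(self) -> tuple:
        return tuple(np.arange(n) / n for n in self.shape)

    def value_at_frac(self, f) -> float:
        idx = tuple(int(round(fi * n)) % n for fi, n in zip(f, self.shape))
        return float(self.values[idx])


def map_from_sf(r: ReflectionSet, shape=None, rate: float = 3.0) -> DensityGrid:
    """Inverse-FFT synthesis rho(x) = (1/V) sum_h F(h) exp(-2 pi i h.x).

    Friedel mates absent from the set are filled in by conjugation so the
    synthesized map is real.
    """
    if r.f is None:
        raise ValueError("reflection set has no phases; supply complex F "
                         "(e.g. from a phase model via sf_fft/sf_direct)")
    if shape is None:
        shape = good_grid_shape(r.cell, r.dmin or float(r.d_spacings().min()), rate)
    shape = tuple(int(n) for n in shape)
    grid = np.zeros(shape, dtype=complex)
    present = r.index_map()
    narr = np.array(shape)
    for i, h in enumerate(r.hkl):
        grid[tuple(h % narr)] = r.f[i]
        if tuple(-h) not in present:
            grid[tuple((-h) % narr)] = np.conj(r.f[i])
    rho = scipy.fft.fftn(grid) / r.cell.volume
    return DensityGrid(r.cell, rho.real)


# --------------------------------------------------------------------------- #
# Reflection / map I/O

def write_reflections(r: ReflectionSet, path) -> None:
    """Tab-separated h k l F sigF [phase_deg]."""
    with open(path, "w") as fh:
        cols = ["h", "k", "l", "F", "sigF"]
        has_phase = r.f is not None
        if has_phase:
            cols.append("phase_deg")
        fh.write("\t".join(cols) + "\n")
        amp = r.amplitudes()
        sig = r.sig if r.sig is not None else np.zeros(len(r))
        phases = np.degrees(r.phases()) if has_phase else None
        for i, h in enumerate(r.hkl):
            row = [str(h[0]), str(h[1]), str(h[2]),
                   f"{amp[i]:.6f}", f"{sig[i]:.6f}"]
            if has_phase:
                row.append(f"{phases[i]:.4f}")
            fh.write("\t".join(row) + "\n")


def read_reflections(path, cell: UnitCell) -> ReflectionSet:
    import pandas as pd
    df = pd.read_csv(path, sep="\t")
    hkl = df[["h", "k", "l"]].to_numpy(dtype=int)
    amp = df["F"].to_numpy(dtype=float)
    sig = df["sigF"].to_numpy(dtype=float) if "sigF" in df else None
    f = None
    if "phase_deg" in df:
        f = amp * np.exp(1j * np.radians(df["phase_deg"].to_numpy(dtype=float)))
    return ReflectionSet(cell, hkl, f=f, amp=amp, sig=sig)


def read_reflections_mmcif(path) -> ReflectionSet:
    """Read the _refln structure-factor block of an mmCIF file."""
    doc = gemmi.cif.read(str(path))
    block = doc.sole_block()
    cell = UnitCell(*(float(block.find_value(f"_cell.length_{x}"))
                      for x in "abc"),
                    *(float(block.find_value(f"_cell.angle_{x}"))
                      for x in ("alpha", "beta", "gamma")))
    tab = block.find("_refln.", ["index_h", "index_k", "index_l",
                                 "F_meas_au", "F_meas_sigma_au"])
    hkl, amp, sig = [], [], []
    for row in tab:
        hkl.append([int(row[0]), int(row[1]), int(row[2])])
        amp.append(float(row[3]))
        sig.append(float(row[4]))
    return ReflectionSet(cell, np.array(hkl), amp=np.array(amp),
                         sig=np.array(sig))


def write_ccp4_map(grid: DensityGrid, path) -> None:
    m = gemmi.Ccp4Map()
    m.grid = gemmi.FloatGrid(np.ascontiguousarray(grid.values, dtype=np.float32))
    m.grid.unit_cell = gemmi.UnitCell(grid.cell.a, grid.cell.b, grid.cell.c,
                                      grid.cell.alpha, grid.cell.beta,
                                      grid.cell.gamma)
    m.grid.spacegroup = gemmi.SpaceGroup("P 1")
    m.update_ccp4_header(2)
    m.write_ccp4_map(str(path))


def read_ccp4_map(path) -> DensityGrid:
    m = gemmi.read_ccp4_map(str(path))
    c = m.grid.unit_cell
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    return DensityGrid(cell, np.array(m.grid, dtype=float))
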