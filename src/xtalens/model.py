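"""Core crystallographic data model: unit cells, space groups, atoms, structures.

Coordinates are fractional internally (half-open [0, 1) wrapping); grids are
0-based.  Anisotropic displacement is stored as a Cartesian U tensor (A^2),
the single source of truth, with B = 8 pi^2 * U_iso derived from it whenever
a tensor is present.

File I/O (PDB with ATOM/HETATM/ANISOU/CRYST1, an mmCIF subset, multi-model
PDB) is delegated to gemmi behind this module's surface.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import gemmi
import numpy as np

EIGHT_PI_SQ = 8.0 * math.pi ** 2

#: electron counts for the elements the toy chemistry and buffers use
ELECTRONS = {
    "H": 1, "C": 6, "N": 7, "O": 8, "S": 16, "MG": 12, "CL": 17, "K": 19,
}


class ParseError(ValueError):
    """Raised when a coordinate or reflection file cannot be interpreted."""


class ConsistencyError(ValueError):
    """Raised when records in a file contradict each other."""


# --------------------------------------------------------------------------- #
# Unit cell

@dataclass(frozen=True)
class UnitCell:
    """Crystallographic unit cell (lengths in Angstrom, angles in degrees)."""

    a: float
    b: float
    c: float
    alpha: float = 90.0
    beta: float = 90.0
    gamma: float = 90.0

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        for ang in (self.alpha, self.beta, self.gamma):
            if not 0.0 < ang < 180.0:
                raise ValueError("cell angles must lie in (0, 180) degrees")
        if self.volume <= 0:
            raise ValueError("degenerate cell: non-positive volume")

    @property
    def volume(self) -> float:
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        arg = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
        if arg <= 0:
            return 0.0
        return self.a * self.b * self.c * math.sqrt(arg)

    @property
    def orth(self) -> np.ndarray:
        """Orthogonalization matrix A (cart = A @ frac): a along x, b in xy."""
        ca, cb, cg = (math.cos(math.radians(x))
                      for x in (self.alpha, self.beta, self.gamma))
        sg = math.sin(math.radians(self.gamma))
        v = self.volume / (self.a * self.b * self.c)
        return np.array([
            [self.a, self.b * cg, self.c * cb],
            [0.0, self.b * sg, self.c * (ca - cb * cg) / sg],
            [0.0, 0.0, self.c * v / sg],
        ])

    @property
    def frac(self) -> np.ndarray:
        """Fractionalization matrix, inverse of :attr:`orth`."""
        return np.linalg.inv(self.orth)

    def frac_to_cart(self, f) -> np.ndarray:
        return np.asarray(f, dtype=float) @ self.orth.T

    def cart_to_frac(self, x) -> np.ndarray:
        return np.asarray(x, dtype=float) @ self.frac.T

    def recip_metric(self) -> np.ndarray:
        """Reciprocal metric tensor G*; 1/d^2 = h^T G* h."""
        inv = self.frac
        return inv @ inv.T

    def inv_d2(self, hkl) -> np.ndarray:
        """1/d^2 for an (n, 3) array of Miller indices."""
        h = np.atleast_2d(np.asarray(hkl, dtype=float))
        g = self.recip_metric()
        return np.einsum("ni,ij,nj->n", h, g, h)

    def scaled(self, dims) -> "UnitCell":
        n1, n2, n3 = dims
        return UnitCell(self.a * n1, self.b * n2, self.c * n3,
                        self.alpha, self.beta, self.gamma)


def frac_to_cart(cell: UnitCell, frac) -> np.ndarray:
    """Orthogonalize fractional coordinates (a along x, b in the xy plane)."""
    return cell.frac_to_cart(frac)


def cart_to_frac(cell: UnitCell, xyz) -> np.ndarray:
    return cell.cart_to_frac(xyz)


# --------------------------------------------------------------------------- #
# Space group

@dataclass(frozen=True)
class SpaceGroup:
    """Symmetry operators (fractional rotation + translation pairs)."""

    symbol: str
    rotations: tuple  # of 3x3 int tuples
    translations: tuple  # of 3-float tuples

    @classmethod
    def from_symbol(cls, symbol: str) -> "SpaceGroup":
        sg = gemmi.SpaceGroup(symbol)
        rots, trans = [], []
        den = float(gemmi.Op.DEN)
        for op in sg.operations():
            rots.append(tuple(tuple(int(round(v / den)) for v in row)
                              for row in op.rot))
            trans.append(tuple(v / den for v in op.tran))
        return cls(sg.hm, tuple(rots), tuple(trans))

    @property
    def n_ops(self) -> int:
        return len(self.rotations)

    def operators(self):
        """Yield (R, t) pairs as float numpy arrays."""
        for r, t in zip(self.rotations, self.translations):
            yield np.array(r, dtype=float), np.array(t, dtype=float)

    def is_p1(self) -> bool:
        return self.n_ops == 1

    def check_closure(self, tol: float = 1e-9) -> bool:
        """Operators form a group modulo lattice translations."""
        ops = [(np.array(r, float), np.array(t, float))
               for r, t in zip(self.rotations, self.translations)]
        keyed = {self._key(r, t) for r, t in ops}
        if self._key(np.eye(3), np.zeros(3)) not in keyed:
            return False
        for r1, t1 in ops:
            for r2, t2 in ops:
                r = r1 @ r2
                t = (r1 @ t2 + t1) % 1.0
                if self._key(r, t) not in keyed:
                    return False
        return True

    @staticmethod
    def _key(r, t):
        return (tuple(np.round(np.ravel(r)).astype(int)),
                tuple(np.round(np.asarray(t) % 1.0, 6)))


P1 = SpaceGroup.from_symbol("P 1")


# --------------------------------------------------------------------------- #
# Atoms and structures

@dataclass
class Atom:
    element: str
    name: str
    chain: str
    resnum: int
    resname: str
    altloc: str = ""
    frac: np.ndarray = field(default_factory=lambda: np.zeros(3))
    occ: float = 1.0
    biso: float = 0.0
    uaniso: np.ndarray | None = None  # Cartesian U, A^2
    hetatm: bool = False

    def __post_init__(self) -> None:
        self.frac = np.asarray(self.frac, dtype=float)
        if not 0.0 <= self.occ <= 1.0 + 1e-9:
            raise ValueError(f"occupancy {self.occ} outside [0, 1]")
        if self.uaniso is not None:
            self.uaniso = np.asarray(self.uaniso, dtype=float)
            if self.uaniso.shape != (3, 3):
                raise ValueError("uaniso must be 3x3")

    @property
    def resid(self) -> tuple:
        return (self.chain, self.resnum, self.resname)

    @property
    def uiso(self) -> float:
        if self.uaniso is not None:
            return float(np.trace(self.uaniso)) / 3.0
        return self.biso / EIGHT_PI_SQ

    @property
    def n_electrons(self) -> int:
        return ELECTRONS[self.element.upper()]

    def validate(self, tol: float = 1e-3) -> None:
        if self.uaniso is not None:
            if not np.allclose(self.uaniso, self.uaniso.T, atol=1e-8):
                raise ConsistencyError(f"{self.name}: U tensor not symmetric")
            eig = np.linalg.eigvalsh(self.uaniso)
            if eig.min() < -1e-8:
                raise ConsistencyError(f"{self.name}: U not positive semidefinite")
            if abs(self.uiso * EIGHT_PI_SQ - self.biso) > tol:
                raise ConsistencyError(
                    f"{self.name}: B {self.biso} inconsistent with trace(U)")

    def copy(self) -> "Atom":
        return dataclasses.replace(
            self, frac=self.frac.copy(),
            uaniso=None if self.uaniso is None else self.uaniso.copy())


@dataclass
class AltGroup:
    """One conformer of one alternation unit: atoms sharing a single occupancy."""

    unit: str       # name of the alternation unit (e.g. "loop", "nuc")
    label: str      # altloc label of this conformer
    occ: float
    atom_indices: list


@dataclass
class Structure:
    """An atomic model: cell, symmetry, ordered atoms, occupancy groups.

    ``altgroups`` name the grouped-occupancy conformers; groups sharing a
    ``unit`` are alternatives of each other.  Units in ``absent_ok`` may have
    occupancies summing to < 1 (the remainder is the "absent" state: partially
    occupied waters, partially formed adducts).  ``conditional`` maps a unit
    to the (unit, label) of the conformer that must be realized for it to be
    present at all — the covalent-adduct case.
    """

    cell: UnitCell
    spacegroup: SpaceGroup = P1
    atoms: list = field(default_factory=list)
    altgroups: list = field(default_factory=list)
    absent_ok: set = field(default_factory=set)
    conditional: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.atoms)

    def copy(self) -> "Structure":
        return Structure(
            cell=self.cell, spacegroup=self.spacegroup,
            atoms=[a.copy() for a in self.atoms],
            altgroups=[dataclasses.replace(g, atom_indices=list(g.atom_indices))
                       for g in self.altgroups],
            absent_ok=set(self.absent_ok),
            conditional=dict(self.conditional))

    def alt_units(self) -> dict:
        """unit name -> list of AltGroup (its alternative conformers)."""
        units: dict = {}
        for g in self.altgroups:
            units.setdefault(g.unit, []).append(g)
        return units

    def frac_coords(self) -> np.ndarray:
        return np.array([a.frac for a in self.atoms])

    def cart_coords(self) -> np.ndarray:
        return self.cell.frac_to_cart(self.frac_coords())

    def electron_count(self) -> float:
        """Total scattering: sum of occupancy x electron count."""
        return sum(a.occ * a.n_electrons for a in self.atoms)

    def residues(self) -> list:
        seen, out = set(), []
        for a in self.atoms:
            if a.resid not in seen:
                seen.add(a.resid)
                out.append(a.resid)
        return out

    def select(self, predicate) -> list:
        return [i for i, a in enumerate(self.atoms) if predicate(a)]

    def validate(self) -> None:
        for a in self.atoms:
            a.validate()
        # occupancies of distinct altlocs of one atom name sum to <= 1
        sums: dict = {}
        for a in self.atoms:
            if a.altloc:
                sums.setdefault((a.resid, a.name), 0.0)
                sums[(a.resid, a.name)] += a.occ
        for key, s in sums.items():
            if s > 1.0 + 1e-6:
                raise ConsistencyError(f"altloc occupancies of {key} sum to {s}")
        for g in self.altgroups:
            occs = {round(self.atoms[i].occ, 9) for i in g.atom_indices}
            if len(occs) > 1:
                raise ConsistencyError(
                    f"altgroup {g.unit}:{g.label} members do not share occupancy")


# --------------------------------------------------------------------------- #
# Symmetry expansion

def expand_to_unit_cell(s: Structure) -> Structure:
    """Replicate every asymmetric-unit atom under all symmetry operators.

    Output is P1 with coordinates wrapped to [0, 1); atom count is
    n_ops x ASU count.  Cartesian U tensors are rotated with each copy.
    """
    if s.spacegroup.is_p1():
        out = s.copy()
        for a in out.atoms:
            a.frac = a.frac % 1.0
        return out
    orth, fracm = s.cell.orth, s.cell.frac
    atoms = []
    groups = []
    for k, (rot, tran) in enumerate(s.spacegroup.operators()):
        m_cart = orth @ rot @ fracm  # rotation in Cartesian frame
        offset = len(atoms)
        for a in s.atoms:
            b = a.copy()
            b.frac = (rot @ a.frac + tran) % 1.0
            if b.uaniso is not None:
                b.uaniso = m_cart @ b.uaniso @ m_cart.T
            atoms.append(b)
        for g in s.altgroups:
            groups.append(AltGroup(f"{g.unit}#op{k}", g.label, g.occ,
                                   [i + offset for i in g.atom_indices]))
    return Structure(cell=s.cell, spacegroup=P1, atoms=atoms, altgroups=groups,
                     absent_ok={f"{u}#op{k}" for u in s.absent_ok
                                for k in range(s.spacegroup.n_ops)})


# --------------------------------------------------------------------------- #
# Occupancy-group inference

def infer_altgroups(s: Structure) -> None:
    """Infer grouped-occupancy conformers and store them on the structure.

    Atoms with a non-blank altloc are grouped into maximal runs of
    consecutive residues sharing (altloc label, occupancy).  HETATM residues
    with blank altloc and occupancy < 1 (partial waters, adducts) each become
    a single-conformer unit whose absent state is allowed.
    """
    groups: list = []
    absent_ok: set = set()
    # (chain, altloc, occ) runs over residue numbers
    runs: dict = {}
    order: list = []
    for i, a in enumerate(s.atoms):
        if a.altloc:
            key = (a.chain, a.altloc, round(a.occ, 6))
            if key not in runs:
                runs[key] = []
                order.append(key)
            runs[key].append(i)
    for key in order:
        chain, alt, occ = key
        idx = runs[key]
        # split non-consecutive residue numbers into separate units
        by_res: list = []
        for i in idx:
            rn = s.atoms[i].resnum
            if by_res and rn <= by_res[-1][-1][0] + 1:
                by_res[-1].append((rn, i))
            else:
                by_res.append([(rn, i)])
        for block in by_res:
            lo, hi = block[0][0], block[-1][0]
            unit = f"{chain}:{lo}-{hi}"
            groups.append(AltGroup(unit, alt, occ, [i for _, i in block]))
    # partial-occupancy blank-altloc HETATM residues: absent-allowed units
    part: dict = {}
    for i, a in enumerate(s.atoms):
        if not a.altloc and a.hetatm and a.occ < 1.0 - 1e-6:
            part.setdefault((a.resid, round(a.occ, 6)), []).append(i)
    for (resid, occ), idx in part.items():
        unit = f"{resid[0]}:{resid[1]}:{resid[2]}"
        groups.append(AltGroup(unit, "A", occ, idx))
        absent_ok.add(unit)
    s.altgroups = groups
    s.absent_ok = absent_ok


# --------------------------------------------------------------------------- #
# File I/O (gemmi-backed)

def _from_gemmi(st: gemmi.Structure, model_index: int = 0) -> Structure:
    c = st.cell
    if c.a <= 0 or not c.is_crystal():
        raise ParseError("missing or invalid CRYST1/cell record")
    cell = UnitCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
    symbol = st.spacegroup_hm or "P 1"
    sg = SpaceGroup.from_symbol(symbol)
    atoms = []
    fracm = cell.frac
    for chain in st[model_index]:
        for res in chain:
            for at in res:
                u = None
                if at.aniso.nonzero():
                    a_ = at.aniso
                    u = np.array([[a_.u11, a_.u12, a_.u13],
                                  [a_.u12, a_.u22, a_.u23],
                                  [a_.u13, a_.u23, a_.u33]], dtype=float)
                pos = np.array([at.pos.x, at.pos.y, at.pos.z])
                biso = at.b_iso
                if u is not None:
                    biso = float(np.trace(u)) / 3.0 * EIGHT_PI_SQ
                atoms.append(Atom(
                    element=at.element.name, name=at.name, chain=chain.name,
                    resnum=res.seqid.num, resname=res.name,
                    altloc=at.altloc if at.altloc != "\x00" else "",
                    frac=fracm @ pos, occ=at.occ, biso=biso, uaniso=u,
                    hetatm=res.het_flag == "H"))
    s = Structure(cell=cell, spacegroup=sg, atoms=atoms)
    infer_altgroups(s)
    return s


def read_structure(path, dialect: str = "auto") -> Structure:
    """Read a model (PDB or mmCIF) into a :class:`Structure`.

    Altloc groups are inferred from shared labels and occupancies; anisotropic
    records are matched to their atoms and stored as Cartesian U tensors.
    """
    path = str(path)
    try:
        if dialect == "pdb" or (dialect == "auto" and not path.endswith(("cif", "cif.gz"))):
            st = gemmi.read_pdb(path)
        else:
            st = gemmi.read_structure(path)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc
    return _from_gemmi(st)


def _to_gemmi(s: Structure) -> gemmi.Structure:
    st = gemmi.Structure()
    st.cell = gemmi.UnitCell(s.cell.a, s.cell.b, s.cell.c,
                             s.cell.alpha, s.cell.beta, s.cell.gamma)
    st.spacegroup_hm = s.spacegroup.symbol
    model = gemmi.Model("1")
    orth = s.cell.orth
    chains: dict = {}
    for a in s.atoms:
        key = a.chain
        if key not in chains:
            chains[key] = gemmi.Chain(a.chain)
        chain = chains[key]
        res = None
        if len(chain) and chain[-1].seqid.num == a.resnum and chain[-1].name == a.resname:
            res = chain[-1]
        if res is None:
            res = gemmi.Residue()
            res.name = a.resname
            res.seqid = gemmi.SeqId(a.resnum, " ")
            res.het_flag = "H" if a.hetatm else "A"
            chain.add_residue(res)
            res = chain[-1]
        ga = gemmi.Atom()
        ga.name = a.name
        ga.element = gemmi.Element(a.element)
        ga.altloc = a.altloc or "\x00"
        pos = orth @ a.frac
        ga.pos = gemmi.Position(*pos)
        ga.occ = a.occ
        ga.b_iso = a.uiso * EIGHT_PI_SQ
        if a.uaniso is not None:
            u = a.uaniso
            ga.aniso = gemmi.SMat33f(u[0, 0], u[1, 1], u[2, 2],
                                     u[0, 1], u[0, 2], u[1, 2])
        res.add_atom(ga)
    for chain in chains.values():
        model.add_chain(chain)
    st.add_model(model)
    return st


def write_structure(s: Structure, path) -> None:
    """Write a PDB file (CRYST1, ATOM/HETATM, ANISOU for tensor-carrying atoms)."""
    st = _to_gemmi(s)
    st.write_pdb(str(path))


def write_multimodel(structures, path) -> None:
    """Write frames sharing one topology as a multi-model PDB."""
    st = _to_gemmi(structures[0])
    for k, s in enumerate(structures[1:], start=2):
        st2 = _to_gemmi(s)
        m = st2[0]
        m.num = k
        st.add_model(m)
    st.write_pdb(str(path))


def read_multimodel(path) -> list:
    st = gemmi.read_structure(str(path))
    return [_from_gemmi(st, i) for i in range(len(st))]
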