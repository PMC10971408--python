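"""Anisotropic-ADP analytics.

Tensors are handled in Cartesian A^2 (conversion from file conventions
happens at read time), so eigen-analysis is frame-unambiguous.  Provided
here: per-residue B_diff profiles between two states, ellipsoid principal
axes, alignment of paired difference-map peaks with those axes, and the
Rosenfield rigid-body difference matrix (for a rigid body the mean-square
displacements of two atoms projected on their interatomic vector are equal,
so nonzero differences flag internal motion).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import EIGHT_PI_SQ, Atom, Structure
from .diffmap import ResidueProfile


# --------------------------------------------------------------------------- #
# Per-residue B_diff

def residue_bdiff(s_on: Structure, s_off: Structure,
                  selection=None) -> ResidueProfile:
    """Mean over selected atoms of (B_on - B_off) per residue.

    Where alternate conformers exist the altloc-A conformer is used.
    Residues present in only one structure are skipped with a warning.
    """
    sel = selection if selection is not None else (lambda a: True)

    def pick(s):
        out = {}
        for a in s.atoms:
            if not sel(a):
                continue
            if a.altloc not in ("", "A"):
                continue
            out[(a.resid, a.name)] = a.biso
        return out

    on, off = pick(s_on), pick(s_off)
    if not on:
        raise ValueError("selection matches no atoms")
    per_res: dict = {}
    skipped = set()
    for key, b_on in on.items():
        resid, _name = key
        if key not in off:
            skipped.add(resid)
            continue
        per_res.setdefault(resid, []).append(b_on - off[key])
    if skipped:
        warnings.warn(f"unmatched residues skipped: {sorted(skipped)}",
                      stacklevel=2)
    return ResidueProfile({r: float(np.mean(v)) for r, v in per_res.items()})


# --------------------------------------------------------------------------- #
# Principal axes

@dataclass
class AdpEllipsoid:
    """Eigen-decomposition of a U tensor: eigenvalues sorted descending,
    orthonormal axes as columns, deterministic sign convention."""

    U: np.ndarray
    eigenvalues: np.ndarray
    axes: np.ndarray           # axes[:, i] belongs to eigenvalues[i]

    @property
    def major_axis(self) -> np.ndarray:
        return self.axes[:, 0]

    @property
    def anisotropy(self) -> float:
        """Smallest/largest eigenvalue ratio (1 = isotropic)."""
        return float(self.eigenvalues[-1] / self.eigenvalues[0])


def principal_axes(u) -> AdpEllipsoid:
    """Sorted eigen-decomposition with the largest-magnitude component of
    each axis made positive (deterministic signs)."""
    u = np.asarray(u, dtype=float)
    if u.shape != (3, 3) or not np.allclose(u, u.T, atol=1e-8):
        raise ValueError("U must be a symmetric 3x3 tensor")
    w, v = np.linalg.eigh(u)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    for i in range(3):
        j = np.argmax(np.abs(v[:, i]))
        if v[j, i] < 0:
            v[:, i] = -v[:, i]
    return AdpEllipsoid(U=u, eigenvalues=w, axes=v)


def atom_u(atom: Atom) -> np.ndarray:
    if atom.uaniso is not None:
        return atom.uaniso
    return (atom.biso / EIGHT_PI_SQ) * np.eye(3)


# --------------------------------------------------------------------------- #
# Peak / axis alignment

def peak_axis_alignment(peak_plus, peak_minus, atom: Atom, cell=None):
    """|cos theta| between the +/- peak displacement vector and the atom's
    ADP principal axes.

    Positions may be Cartesian, or fractional if ``cell`` is given.  Returns
    ``(cos_major, cos_best)``: alignment with the major axis and the best
    alignment over all three axes.
    """
    if atom.uaniso is None:
        raise ValueError("atom has no anisotropic U tensor")
    p, m = np.asarray(peak_plus, float), np.asarray(peak_minus, float)
    if cell is not None:
        d = p - m
        d -= np.round(d)
        vec = cell.frac_to_cart(d)
    else:
        vec = p - m
    norm = np.linalg.norm(vec)
    if norm < 1e-9:
        raise ValueError("coincident peaks")
    vec = vec / norm
    ell = principal_axes(atom.uaniso)
    cosines = np.abs(ell.axes.T @ vec)
    return float(cosines[0]), float(cosines.max())


# --------------------------------------------------------------------------- #
# Rosenfield rigid-body difference matrix

@dataclass
class RosenfieldMatrix:
    """Pairwise projected mean-square-displacement differences.

    matrix[i, j] = n^T U_i n - n^T U_j n with n the unit vector from atom i
    to atom j; antisymmetric with zero diagonal.  ``binned`` averages |delta|
    within residue-bin pairs (symmetric), the form usually plotted.
    """

    atom_indices: list
    resnums: np.ndarray
    matrix: np.ndarray
    binned: np.ndarray | None = None
    bin_edges: np.ndarray | None = None

    def max_binned(self) -> float:
        return float(np.abs(self.binned).max()) if self.binned is not None \
            else float(np.abs(self.matrix).max())

    def is_rigid(self, tol: float = 1e-3) -> bool:
        """Rigid-body criterion: binned mean |delta| below tol (A^2)."""
        m = self.binned if self.binned is not None else np.abs(self.matrix)
        return float(np.mean(m)) < tol


def rosenfield(s: Structure, selection=None, bins: int = 30,
               cell=None) -> RosenfieldMatrix:
    """Rosenfield difference matrix over the selected atoms.

    Isotropic-only atoms are converted via U = (B / 8 pi^2) I with a warning.
    Interatomic vectors are Cartesian (computed from the structure's cell).
    """
    sel = selection if selection is not None else (lambda a: True)
    idx = [i for i, a in enumerate(s.atoms) if sel(a)
           and a.altloc in ("", "A")]
    if len(idx) < 2:
        raise ValueError("need at least two selected atoms")
    if any(s.atoms[i].uaniso is None for i in idx):
        warnings.warn("isotropic atoms converted to U = (B/8pi^2) I",
                      stacklevel=2)
    us = np.array([atom_u(s.atoms[i]) for i in idx])
    cart = s.cell.frac_to_cart(np.array([s.atoms[i].frac for i in idx]))
    n_at = len(idx)
    d = cart[None, :, :] - cart[:, None, :]
    dist = np.linalg.norm(d, axis=-1)
    np.fill_diagonal(dist, 1.0)
    n = d / dist[:, :, None]
    # proj[i, j] = n_ij^T U_i n_ij ; proj_t[i, j] = n_ij^T U_j n_ij
    proj_i = np.einsum("ijk,ikl,ijl->ij", n, us, n)
    proj_j = np.einsum("ijk,jkl,ijl->ij", n, us, n)
    mat = proj_i - proj_j
    np.fill_diagonal(mat, 0.0)
    resnums = np.array([s.atoms[i].resnum for i in idx])
    binned = edges = None
    if bins and bins > 0:
        edges = np.linspace(resnums.min(), resnums.max() + 1, bins + 1)
        which = np.clip(np.digitize(resnums, edges) - 1, 0, bins - 1)
        binned = np.zeros((bins, bins))
        counts = np.zeros((bins, bins))
        absmat = np.abs(mat)
        for bi in range(bins):
            mi = which == bi
            if not mi.any():
                continue
            for bj in range(bins):
                mj = which == bj
                if not mj.any():
                    continue
                sub = absmat[np.ix_(mi, mj)]
                if bi == bj:
                    # exclude the zero diagonal from the average
                    k = min(mi.sum(), mj.sum())
                    total = sub.sum()
                    cnt = sub.size - k
                    binned[bi, bj] = total / cnt if cnt else 0.0
                else:
                    binned[bi, bj] = sub.mean()
                counts[bi, bj] = sub.size
    return RosenfieldMatrix(atom_indices=idx, resnums=resnums, matrix=mat,
                            binned=binned, bin_edges=edges)
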