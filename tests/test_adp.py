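"""ADP analytics: B_diff, principal axes, peak alignment, Rosenfield."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.transform import Rotation

from xtalens.adp import (peak_axis_alignment, principal_axes, residue_bdiff,
                         rosenfield)
from xtalens.diffmap import mainchain
from xtalens.model import EIGHT_PI_SQ, P1, Atom, Structure, UnitCell


def _chain_structure(n_res=12, u_fn=None):
    """Linear pseudo-chain with per-atom U tensors from u_fn(index, pos)."""
    cell = UnitCell(40, 20, 20)
    s = Structure(cell=cell, spacegroup=P1)
    k = 0
    for i in range(1, n_res + 1):
        for name, off in (("N", (0, 0, 0)), ("CA", (1.0, 0.8, 0.2)),
                          ("C", (2.0, 0.1, 0.5)), ("O", (2.1, -1.0, 0.8))):
            cart = np.array([3.0 * (i - 1) + off[0], 8 + off[1], 8 + off[2]])
            u = u_fn(k, cart) if u_fn else 0.02 * np.eye(3)
            s.atoms.append(Atom("C" if name != "O" else "O", name, "A", i,
                                "ALA", frac=cell.cart_to_frac(cart), occ=1.0,
                                biso=float(np.trace(u)) / 3 * EIGHT_PI_SQ,
                                uaniso=u))
            k += 1
    return s


class TestResidueBdiff:
    def test_identical_structures_zero(self, toy_pair):
        s0, _ = toy_pair
        prof = residue_bdiff(s0, s0, mainchain())
        assert all(v == 0.0 for _, v in prof.items())

    def test_constant_shift(self):
        s_off = _chain_structure()
        s_on = _chain_structure(u_fn=lambda k, c: (0.02 + 5.0 / EIGHT_PI_SQ)
                                * np.eye(3))
        prof = residue_bdiff(s_on, s_off, mainchain())
        assert all(v == pytest.approx(5.0, abs=1e-9) for _, v in prof.items())

    def test_matches_brute_force_average(self):
        rng = np.random.default_rng(17)
        offsets = {}

        def u_on(k, c):
            offsets[k] = rng.uniform(0, 10)
            return (0.02 + offsets[k] / EIGHT_PI_SQ) * np.eye(3)

        s_off = _chain_structure()
        s_on = _chain_structure(u_fn=u_on)
        prof = residue_bdiff(s_on, s_off, mainchain())
        for resid, val in prof.items():
            i = resid[1]
            ks = range((i - 1) * 4, (i - 1) * 4 + 4)
            assert val == pytest.approx(np.mean([offsets[k] for k in ks]),
                                        abs=1e-9)

    def test_uses_altloc_a_for_alternates(self, toy_pair):
        s0, s30 = toy_pair
        prof = residue_bdiff(s30, s0, mainchain())
        # mobile loop residues gain B; remote residues do not
        assert prof[("A", 5, "GLY")] > 0
        assert prof[("A", 1, "ALA")] == pytest.approx(0.0, abs=1e-9)

    def test_unmatched_residue_warns_and_skips(self, toy_pair):
        s0, s30 = toy_pair  # 30 s has the extra water residue
        with pytest.warns(UserWarning, match="unmatched"):
            residue_bdiff(s30, s0, lambda a: True)


class TestPrincipalAxes:
    def test_isotropic_degenerate(self):
        ell = principal_axes(0.03 * np.eye(3))
        assert np.allclose(ell.eigenvalues, 0.03)
        assert np.allclose(ell.axes @ ell.axes.T, np.eye(3), atol=1e-10)

    def test_diagonal_tensor(self):
        ell = principal_axes(np.diag([0.09, 0.04, 0.01]))
        assert np.allclose(ell.eigenvalues, [0.09, 0.04, 0.01])
        assert np.allclose(np.abs(ell.axes), np.eye(3), atol=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_similarity_transform(self, seed):
        rng = np.random.default_rng(seed)
        rot = Rotation.random(random_state=int(seed)).as_matrix()
        diag = np.diag(sorted(rng.uniform(0.005, 0.08, 3), reverse=True))
        u = rot @ diag @ rot.T
        ell = principal_axes(u)
        assert np.allclose(ell.eigenvalues, np.diag(diag), atol=1e-10)
        # axes span the same directions (signs fixed by convention)
        for i in range(3):
            c = abs(np.dot(ell.axes[:, i], rot[:, i]))
            assert c == pytest.approx(1.0, abs=1e-8)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            principal_axes(np.array([[1, 2, 0], [0, 1, 0], [0, 0, 1.0]]))


class TestAlignment:
    def atom_with_u(self, u):
        return Atom("S", "SG", "A", 1, "CYS", frac=np.zeros(3),
                    biso=float(np.trace(u)) / 3 * EIGHT_PI_SQ, uaniso=u)

    def test_parallel_gives_one(self):
        at = self.atom_with_u(np.diag([0.05, 0.01, 0.008]))
        cm, cb = peak_axis_alignment([2.0, 0, 0], [-1.0, 0, 0], at)
        assert cm == pytest.approx(1.0)

    def test_perpendicular_gives_zero(self):
        at = self.atom_with_u(np.diag([0.05, 0.01, 0.008]))
        cm, cb = peak_axis_alignment([0, 1.0, 0], [0, -1.0, 0], at)
        assert cm == pytest.approx(0.0, abs=1e-12)
        assert cb == pytest.approx(1.0)  # second axis matches exactly

    def test_coincident_peaks_rejected(self):
        at = self.atom_with_u(np.diag([0.05, 0.01, 0.008]))
        with pytest.raises(ValueError):
            peak_axis_alignment([1.0, 0, 0], [1.0, 0, 0], at)

    def test_rotation_invariance(self):
        u = np.diag([0.06, 0.02, 0.01])
        at = self.atom_with_u(u)
        cm0, _ = peak_axis_alignment([1.5, 0.4, 0.1], [-1.0, -0.2, 0.0], at)
        rot = Rotation.from_euler("zyx", [31, -12, 57], degrees=True).as_matrix()
        at_r = self.atom_with_u(rot @ u @ rot.T)
        cm1, _ = peak_axis_alignment(rot @ np.array([1.5, 0.4, 0.1]),
                                     rot @ np.array([-1.0, -0.2, 0.0]), at_r)
        assert cm1 == pytest.approx(cm0, abs=1e-9)

    def test_displaced_along_major_axis_fixture(self):
        # atoms displaced along the axis their U is elongated along:
        # the +/- difference peaks bracket the mean position along that axis
        rng = np.random.default_rng(5)
        scores = []
        for _ in range(20):
            axis = rng.standard_normal(3)
            axis /= np.linalg.norm(axis)
            u = 0.01 * np.eye(3) + 0.05 * np.outer(axis, axis)
            at = self.atom_with_u(u)
            delta = 0.4 * axis + 0.02 * rng.standard_normal(3)
            cm, _ = peak_axis_alignment(delta, -delta, at)
            scores.append(cm)
        assert np.mean(scores) > 0.9


class TestRosenfield:
    def test_common_u_is_zero_everywhere(self):
        u = np.array([[0.03, 0.008, 0.0], [0.008, 0.02, 0.004],
                      [0.0, 0.004, 0.025]])
        s = _chain_structure(u_fn=lambda k, c: u.copy())
        mat = rosenfield(s, mainchain(), bins=6)
        assert np.abs(mat.matrix).max() < 1e-12
        assert mat.is_rigid()

    def test_antisymmetry(self, toy_pair):
        s0, _ = toy_pair
        mat = rosenfield(s0, mainchain(), bins=5)
        assert np.abs(mat.matrix + mat.matrix.T).max() < 1e-10
        assert np.abs(np.diag(mat.matrix)).max() == 0.0

    def test_two_body_fixture(self):
        # two halves with independent U: inter-half bins nonzero,
        # intra-half bins zero
        ua = 0.02 * np.eye(3)
        ub = np.diag([0.08, 0.01, 0.01])

        def u_fn(k, cart):
            return (ua if cart[0] < 18 else ub).copy()

        s = _chain_structure(n_res=12, u_fn=u_fn)
        mat = rosenfield(s, mainchain(), bins=2)
        assert mat.binned[0, 0] < 1e-12
        assert mat.binned[1, 1] < 1e-12
        assert mat.binned[0, 1] > 1e-3

    def test_isotropic_conversion_warns(self, tiny_structure):
        with pytest.warns(UserWarning, match="isotropic"):
            mat = rosenfield(tiny_structure, bins=0)
        # isotropic U differences project uniformly
        assert np.abs(mat.matrix + mat.matrix.T).max() < 1e-12
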