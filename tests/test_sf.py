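"""Structure-factor engine: oracle agreement, symmetry, linearity, maps."""

import gemmi
import numpy as np
import pytest

from xtalens.model import (P1, Atom, Structure, UnitCell,
                           expand_to_unit_cell, write_structure)
from xtalens.sf import (DEFAULT_FORM_FACTORS, ReflectionSet,
                        amplitude_weighted_r, generate_indices, map_from_sf,
                        sf_direct, sf_ensemble, sf_fft)
from xtalens.synth import make_c2_toy, make_ensemble, make_toy_pair


def single_atom(element="C", cart=(0.0, 0.0, 0.0), b=0.0, occ=1.0):
    cell = UnitCell(10, 10, 10)
    s = Structure(cell=cell, spacegroup=P1)
    s.atoms.append(Atom(element=element, name="X", chain="A", resnum=1,
                        resname="XXX", frac=cell.cart_to_frac(cart), occ=occ,
                        biso=b))
    return s


class TestFormFactors:
    @pytest.mark.parametrize("el,z", [("H", 1), ("C", 6), ("N", 7), ("O", 8),
                                      ("S", 16), ("MG", 12), ("CL", 17),
                                      ("K", 19)])
    def test_f0_is_electron_count(self, el, z):
        assert DEFAULT_FORM_FACTORS.f0(el) == pytest.approx(z, abs=0.1)

    def test_unknown_element_named_in_error(self):
        s = single_atom()
        s.atoms[0].element = "XE"
        with pytest.raises(KeyError, match="XE"):
            sf_direct(s, dmin=3.0)


class TestDirect:
    def test_atom_at_origin_gives_form_factor(self):
        s = single_atom("C", b=0.0)
        r = sf_direct(s, dmin=2.0)
        s2 = s.cell.inv_d2(r.hkl)
        expected = DEFAULT_FORM_FACTORS.evaluate("C", s2)
        assert np.allclose(r.f.real, expected, rtol=1e-12)
        assert np.allclose(r.f.imag, 0.0, atol=1e-12)

    def test_linearity_in_occupancy(self):
        full = sf_direct(single_atom(occ=1.0), dmin=2.0)
        half = sf_direct(single_atom(occ=0.5), dmin=2.0)
        assert np.allclose(np.abs(half.f), 0.5 * np.abs(full.f))

    def test_centrosymmetric_pair_is_real(self):
        cell = UnitCell(10, 10, 10)
        s = Structure(cell=cell, spacegroup=P1)
        for sign in (+1, -1):
            s.atoms.append(Atom("C", "X", "A", 1, "XXX",
                                frac=np.array([sign * 0.13, 0, 0]) % 1.0,
                                occ=1.0, biso=5.0))
        r = sf_direct(s, dmin=2.0)
        assert np.abs(r.f.imag).max() < 1e-10 * np.abs(r.f).max()

    def test_friedel_symmetry(self, toy_pair):
        s0, _ = toy_pair
        r = sf_direct(s0, dmin=2.5)
        imap = r.index_map()
        for i, h in enumerate(r.hkl[:200]):
            j = imap[tuple(-h)]
            assert abs(r.f[i] - np.conj(r.f[j])) <= 1e-8 * abs(r.f[i]) + 1e-12


class TestFftVsDirect:
    def test_toy_structure_r_below_1pct(self, toy_pair):
        for s in toy_pair:
            rd = sf_direct(s, dmin=1.5)
            rf = sf_fft(s, 1.5)
            assert amplitude_weighted_r(rd, rf) < 0.01

    def test_tiny_structure_r(self, tiny_structure):
        rd = sf_direct(tiny_structure, dmin=1.5)
        rf = sf_fft(tiny_structure, 1.5)
        assert amplitude_weighted_r(rd, rf) < 0.01

    def test_c2_symmetry_path_equivalence(self):
        c2 = make_c2_toy()
        via_ops = sf_direct(c2, dmin=1.8)
        p1 = expand_to_unit_cell(c2)
        via_expand = sf_direct(p1, hkl=via_ops.hkl)
        rel = np.abs(via_ops.f - via_expand.f) / np.abs(via_ops.f).max()
        assert rel.max() < 1e-6
        via_fft = sf_fft(c2, 1.8)
        assert amplitude_weighted_r(via_ops, via_fft) < 0.01

    def test_grid_refinement_convergence(self, tiny_structure):
        coarse = sf_fft(tiny_structure, 1.5, rate=3.0)
        fine = sf_fft(tiny_structure, 1.5, rate=6.0)
        imap = fine.index_map()
        order = [imap[tuple(h)] for h in coarse.hkl]
        a, b = np.abs(coarse.f), np.abs(fine.f[order])
        assert np.sum(np.abs(a - b)) / np.sum(b) < 0.002

    def test_too_coarse_grid_rejected(self, tiny_structure):
        with pytest.raises(ValueError, match="too coarse"):
            sf_fft(tiny_structure, 1.5, shape=(8, 8, 8))


class TestGemmiOracle:
    """Independent cross-check against gemmi's direct SF calculator."""

    def test_toy_structure_matches_gemmi(self, tmp_path, toy_pair):
        s0, _ = toy_pair
        path = tmp_path / "toy.pdb"
        write_structure(s0, path)
        st = gemmi.read_pdb(str(path))
        calc = gemmi.StructureFactorCalculatorX(st.cell)
        hkl = generate_indices(s0.cell, 2.5)[::37]
        mine = sf_direct(s0, hkl=hkl).f
        ref = np.array([calc.calculate_sf_from_model(st[0], tuple(int(x) for x in h))
                        for h in hkl])
        # PDB round-trip quantizes coordinates/U, so ~1% agreement
        assert np.abs(mine - ref).max() / np.abs(ref).max() < 0.01


class TestEnsembleSF:
    def test_single_static_frame_equals_direct(self, toy_pair):
        s0, _ = toy_pair
        ens = make_ensemble(s0, (1, 1, 1), n_frames=1, seed=4, displace=False)
        r_ens = sf_ensemble(ens, 2.0, method="direct")
        frame = ens.frame_structure(0)
        for a in frame.atoms:
            a.occ = 1.0
        r_dir = sf_direct(frame, hkl=r_ens.hkl, b_override=0.0)
        assert np.allclose(r_ens.f, r_dir.f, rtol=1e-10, atol=1e-9)

    def test_lattice_translation_invariance(self, toy_pair):
        s0, _ = toy_pair
        ens = make_ensemble(s0, (2, 2, 2), n_frames=1, seed=4, displace=False)
        r1 = sf_ensemble(ens, 2.0)
        ens.coords = (ens.coords + np.array([0.5, 0.0, 0.0])) % 1.0
        r2 = sf_ensemble(ens, 2.0)
        assert np.allclose(np.abs(r1.f), np.abs(r2.f), rtol=1e-8)

    def test_component_selections_sum_to_all(self, toy_pair):
        _, s30 = toy_pair
        ens = make_ensemble(s30, (1, 1, 1), n_frames=2, seed=4)
        r_all = sf_ensemble(ens, 2.0, selection="all", method="direct")
        parts = [sf_ensemble(ens, 2.0, selection=sel, method="direct").f
                 for sel in ("protein", "water")]
        assert np.allclose(r_all.f, sum(parts), rtol=1e-10, atol=1e-9)

    def test_empty_selection_rejected(self, toy_pair):
        s0, _ = toy_pair  # resting state has no waters
        ens = make_ensemble(s0, (1, 1, 1), n_frames=1, seed=4)
        with pytest.raises(ValueError):
            sf_ensemble(ens, 2.0, selection="water")


class TestMaps:
    def test_zero_sf_gives_zero_map(self, tiny_structure):
        hkl = generate_indices(tiny_structure.cell, 2.0)
        r = ReflectionSet(tiny_structure.cell, hkl,
                          f=np.zeros(len(hkl), dtype=complex), dmin=2.0)
        grid = map_from_sf(r)
        assert np.abs(grid.values).max() == 0.0

    def test_map_peaks_at_atom_positions(self, tiny_structure):
        r = sf_fft(tiny_structure, 1.2)
        grid = map_from_sf(r)
        shape = np.array(grid.shape)
        for a in tiny_structure.atoms:
            idx = tuple((np.round(a.frac * shape).astype(int)) % shape)
            # atom voxel well above map RMS
            assert grid.values[idx] > 5.0 * grid.rms()

    def test_synthesis_analysis_inverse(self, tiny_structure):
        r = sf_fft(tiny_structure, 1.5)
        grid = map_from_sf(r)
        import scipy.fft
        fgrid = grid.cell.volume * scipy.fft.ifftn(grid.values)
        narr = np.array(grid.shape)
        back = np.array([fgrid[tuple(h % narr)] for h in r.hkl])
        assert np.abs(back - r.f).max() < 1e-8 * np.abs(r.f).max()

    def test_parseval(self, tiny_structure):
        r = sf_fft(tiny_structure, 1.5)
        grid = map_from_sf(r)
        n_vox = np.prod(grid.shape)
        lhs = np.sum(grid.values ** 2) * grid.cell.volume / n_vox
        # full-sphere F includes both Friedel mates
        rhs = np.sum(np.abs(r.f) ** 2) / grid.cell.volume
        assert lhs == pytest.approx(rhs, rel=1e-6)

    def test_amplitudes_without_phases_rejected(self, tiny_structure):
        hkl = generate_indices(tiny_structure.cell, 2.5)
        r = ReflectionSet(tiny_structure.cell, hkl, amp=np.ones(len(hkl)))
        with pytest.raises(ValueError, match="phase"):
            map_from_sf(r)


class TestReflectionSet:
    def test_duplicates_rejected(self, tiny_structure):
        with pytest.raises(ValueError):
            ReflectionSet(tiny_structure.cell, [[1, 0, 0], [1, 0, 0]])

    def test_f000_rejected(self, tiny_structure):
        with pytest.raises(ValueError):
            ReflectionSet(tiny_structure.cell, [[0, 0, 0]])

    def test_tsv_roundtrip(self, tmp_path, tiny_structure):
        from xtalens.sf import read_reflections, write_reflections
        r = sf_fft(tiny_structure, 2.0)
        path = tmp_path / "refl.tsv"
        write_reflections(r, path)
        back = read_reflections(path, tiny_structure.cell)
        assert np.array_equal(back.hkl, r.hkl)
        assert np.allclose(back.amplitudes(), np.abs(r.f), rtol=1e-4)
        assert np.allclose(np.angle(back.f), np.angle(r.f), atol=1e-4)

    def test_ccp4_roundtrip(self, tmp_path, tiny_structure):
        from xtalens.sf import read_ccp4_map, write_ccp4_map
        grid = map_from_sf(sf_fft(tiny_structure, 2.0))
        path = tmp_path / "m.ccp4"
        write_ccp4_map(grid, path)
        back = read_ccp4_map(path)
        assert back.shape == grid.shape
        assert np.allclose(back.values, grid.values, rtol=1e-5, atol=1e-6)
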