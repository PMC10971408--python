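"""Difference maps: scaling, peaks, IADDAT, masked correlations."""

import dataclasses

import numpy as np
import pytest

from conftest import DMIN, periodic_dist
from xtalens.diffmap import (ScalingError, find_peaks, fo_minus_fo_map,
                             iaddat, mainchain, map_cc_masked,
                             scale_amplitudes)
from xtalens.model import Atom
from xtalens.sf import DensityGrid, ReflectionSet, generate_indices, map_from_sf
from xtalens.synth import make_observations, make_toy_pair, water_site


class TestScaling:
    def test_exact_scalar_recovered(self, clean_obs):
        obs0, _ = clean_obs
        doubled = ReflectionSet(obs0.cell, obs0.hkl, amp=2.0 * obs0.amp,
                                sig=obs0.sig, dmin=obs0.dmin)
        sub_a, scaled, k = scale_amplitudes(obs0, doubled)
        assert k == pytest.approx(0.5)
        assert np.allclose(scaled.amp, sub_a.amp)

    def test_identity_scale(self, clean_obs):
        obs0, _ = clean_obs
        _, _, k = scale_amplitudes(obs0, obs0)
        assert k == pytest.approx(1.0)

    def test_noisy_scale_recovery(self, clean_obs):
        obs0, _ = clean_obs
        rng_master = np.random.default_rng(123)
        k_true = 1.7
        ks = []
        for _ in range(100):
            rng = np.random.default_rng(rng_master.integers(2 ** 31))
            noisy = ReflectionSet(
                obs0.cell, obs0.hkl,
                amp=(obs0.amp / k_true) * (1 + 0.05 * rng.standard_normal(len(obs0))),
                dmin=obs0.dmin)
            ks.append(scale_amplitudes(obs0, noisy)[2])
        se = np.std(ks) / np.sqrt(len(ks))
        assert abs(np.mean(ks) - k_true) < 3 * se + 0.01

    def test_too_few_common_rejected(self, clean_obs):
        obs0, _ = clean_obs
        small = ReflectionSet(obs0.cell, obs0.hkl[:10], amp=obs0.amp[:10])
        with pytest.raises(ScalingError):
            scale_amplitudes(obs0, small)


class TestDifferenceMap:
    def test_identical_inputs_give_machine_zero_map(self, toy_pair, clean_obs):
        s0, _ = toy_pair
        obs0, _ = clean_obs
        grid = fo_minus_fo_map(obs0, obs0, s0, DMIN)
        assert np.abs(grid.values).max() < 1e-10
        assert len(find_peaks(grid, 3.0, s0, 5.0)) == 0

    def test_map_mean_is_zero(self, diff_map):
        assert abs(diff_map.values.mean()) < 1e-12 * np.abs(diff_map.values).max()

    def test_antisymmetry_under_order_exchange(self, toy_pair, clean_obs):
        s0, _ = toy_pair
        obs0, obs30 = clean_obs
        fwd = fo_minus_fo_map(obs30, obs0, s0, DMIN)
        rev = fo_minus_fo_map(obs0, obs30, s0, DMIN)
        assert np.allclose(fwd.values, -rev.values, atol=1e-12)

    def test_added_half_occupancy_oxygen_is_strongest_peak(self, toy_pair):
        s0, _ = toy_pair
        pert = s0.copy()
        site = np.array([0.62, 0.30, 0.55])
        pert.atoms.append(Atom("O", "O", "W", 300, "HOH", frac=site,
                               occ=0.5, biso=10.0, hetatm=True))
        obs_off = make_observations(s0, DMIN, 0.0, seed=1)
        obs_on = make_observations(pert, DMIN, 0.0, seed=1)
        grid = fo_minus_fo_map(obs_on, obs_off, s0, DMIN)
        peaks = find_peaks(grid, 3.0, pert, 5.0)
        top = peaks[0]
        assert top.sign > 0
        spacing = max(grid.cell.a / grid.shape[0], grid.cell.b / grid.shape[1],
                      grid.cell.c / grid.shape[2])
        assert periodic_dist(grid.cell, top.frac, site) < spacing


class TestWaterGating:
    def test_positive_peak_at_water_site_only_with_water(self, toy_spec):
        ws = water_site(toy_spec)
        for occ_w, expect in ((0.64, True), (0.0, False)):
            spec = dataclasses.replace(toy_spec, occ_water=occ_w)
            s0, s30 = make_toy_pair(spec)
            grid = fo_minus_fo_map(make_observations(s30, DMIN, 0.0, 1),
                                   make_observations(s0, DMIN, 0.0, 2),
                                   s0, DMIN)
            top_pos = find_peaks(grid, 3.0, s30, 5.0).positive()[0]
            near = periodic_dist(grid.cell, top_pos.frac, ws) < 3.0
            assert near == expect


class TestPeaks:
    def test_constructed_pair_found_with_signs(self, tiny_structure):
        shape = (24, 20, 18)
        vals = np.zeros(shape)
        vals[6, 5, 4] = 1.0
        vals[15, 12, 9] = -0.8
        grid = DensityGrid(tiny_structure.cell, vals).sigma_normalize()
        peaks = find_peaks(grid, 3.0)
        assert len(peaks) == 2
        assert peaks[0].sign == 1 and peaks[1].sign == -1
        assert periodic_dist(grid.cell, peaks[0].frac,
                             np.array([6, 5, 4]) / np.array(shape)) < 0.6
        assert periodic_dist(grid.cell, peaks[1].frac,
                             np.array([15, 12, 9]) / np.array(shape)) < 0.6

    def test_threshold_monotonicity(self, diff_map, toy_pair):
        _, s30 = toy_pair
        counts = [len(find_peaks(diff_map, t, s30, 5.0))
                  for t in (2.5, 3.0, 3.5, 4.5, 6.0)]
        assert counts == sorted(counts, reverse=True)

    def test_census_invariant_under_global_scaling(self, diff_map, toy_pair):
        _, s30 = toy_pair
        scaled = DensityGrid(diff_map.cell, 7.3 * diff_map.values).sigma_normalize()
        n1 = len(find_peaks(diff_map, 3.2, s30, 5.0))
        n2 = len(find_peaks(scaled, 3.2, s30, 5.0))
        assert n1 == n2

    def test_sorted_by_height_and_annotated(self, diff_map, toy_pair):
        _, s30 = toy_pair
        peaks = find_peaks(diff_map, 3.2, s30, 5.0)
        heights = [abs(p.height) for p in peaks]
        assert heights == sorted(heights, reverse=True)
        for p in peaks:
            assert abs(p.height_sigma) >= 3.2
            assert p.distance is not None and p.distance <= 5.0


class TestIaddat:
    def test_zero_map_all_zero(self, tiny_structure):
        grid = DensityGrid(tiny_structure.cell,
                           np.zeros((24, 20, 18))).sigma_normalize()
        prof = iaddat(grid, tiny_structure)
        assert all(v == 0.0 for _, v in prof.items())

    def test_subthreshold_map_all_zero(self, toy_pair, diff_map):
        s0, _ = toy_pair
        tame = DensityGrid(diff_map.cell, diff_map.values /
                           np.abs(diff_map.values).max(),
                           sigma=1.0)  # |rho| <= 1 everywhere, threshold 3
        prof = iaddat(tame, s0, threshold_sigma=3.0)
        assert all(v == 0.0 for _, v in prof.items())

    def test_localization_to_adjacent_residue(self):
        # two residues 8 A apart: a peak beside residue 1 registers there only
        from xtalens.model import P1, Structure, UnitCell
        cell = UnitCell(20, 14, 12)
        s = Structure(cell=cell, spacegroup=P1)
        for resnum, x in ((1, 4.0), (2, 12.0)):
            s.atoms.append(Atom("C", "CA", "A", resnum, "ALA",
                                frac=cell.cart_to_frac((x, 7.0, 6.0)),
                                occ=1.0, biso=10.0))
        shape = (40, 28, 24)
        vals = np.zeros(shape)
        peak_frac = cell.cart_to_frac((5.0, 7.0, 6.0))  # 1 A from residue 1
        vals[tuple((np.round(peak_frac * shape)).astype(int) % shape)] = 5.0
        grid = DensityGrid(cell, vals, sigma=1.0)
        prof = iaddat(grid, s, threshold_sigma=3.0, radius=2.5)
        assert prof[("A", 1, "ALA")] > 0.0
        assert prof[("A", 2, "ALA")] == 0.0

    def test_profile_nonnegative_and_covers_residues(self, diff_map, toy_pair):
        s0, _ = toy_pair
        prof = iaddat(diff_map, s0)
        assert len(prof.values) == len(s0.residues())
        assert (prof.as_array() >= 0).all()


class TestMapCC:
    def test_identity_and_negation(self, diff_map, toy_pair):
        s0, _ = toy_pair
        sel = mainchain()
        assert map_cc_masked(diff_map, diff_map, s0, sel) == pytest.approx(1.0)
        neg = DensityGrid(diff_map.cell, -diff_map.values, diff_map.sigma)
        assert map_cc_masked(diff_map, neg, s0, sel) == pytest.approx(-1.0)

    def test_random_phase_maps_uncorrelated(self, toy_pair):
        s0, _ = toy_pair
        hkl = generate_indices(s0.cell, 2.5)
        amp = np.ones(len(hkl))
        rng = np.random.default_rng(99)
        ccs = []
        for _ in range(100):
            maps = []
            for _ in range(2):
                phi = rng.uniform(0, 2 * np.pi, len(hkl))
                r = ReflectionSet(s0.cell, hkl, f=amp * np.exp(1j * phi),
                                  dmin=2.5)
                maps.append(map_from_sf(r, shape=(24, 20, 18)))
            ccs.append(map_cc_masked(maps[0], maps[1], s0, mainchain(), 2.0))
        assert abs(np.mean(ccs)) < 0.1

    def test_tiny_mask_rejected(self, diff_map, toy_pair):
        s0, _ = toy_pair
        with pytest.raises(ValueError):
            map_cc_masked(diff_map, diff_map, s0, mainchain(), radius=0.01)

    def test_grid_mismatch_rejected(self, diff_map, toy_pair):
        s0, _ = toy_pair
        other = DensityGrid(diff_map.cell, diff_map.values[:-1])
        with pytest.raises(ValueError):
            map_cc_masked(diff_map, other, s0, mainchain())
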