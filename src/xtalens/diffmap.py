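"""Isomorphous difference maps and their real-space analytics.

An F_o - F_o (or F_ens - F_ens) difference map is synthesized from unweighted
differences of least-squares-scaled amplitudes with phases from a reference
model; its sigma (RMS over the whole unit-cell grid) sets the contouring
scale.  On top of the map this module provides sigma-thresholded peak
picking, per-residue integration of absolute difference density above a
noise threshold (IADDAT), and masked real-space map correlations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .model import Structure
from .sf import DensityGrid, ReflectionSet, map_from_sf, sf_fft


class ScalingError(ValueError):
    """Too few common reflections to determine a scale."""


# --------------------------------------------------------------------------- #
# Amplitude scaling and difference synthesis

def scale_amplitudes(ref_a: ReflectionSet, ref_b: ReflectionSet,
                     min_common: int = 50):
    """Least-squares scale of ref_b onto ref_a.

    Returns ``(scaled_b, k)`` where k minimizes sum(|F_a| - k |F_b|)^2 over
    the common indices; both outputs keep only the common set.
    """
    amap, bmap = ref_a.index_map(), ref_b.index_map()
    common = [h for h in amap if h in bmap]
    if len(common) < min_common:
        raise ScalingError(f"only {len(common)} common reflections "
                           f"(need >= {min_common})")
    ia = np.array([amap[h] for h in common])
    ib = np.array([bmap[h] for h in common])
    fa = ref_a.amplitudes()[ia]
    fb = ref_b.amplitudes()[ib]
    k = float(np.dot(fa, fb) / np.dot(fb, fb))
    hkl = np.array(common)
    scaled = ReflectionSet(
        ref_b.cell, hkl,
        f=None if ref_b.f is None else k * ref_b.f[ib],
        amp=k * ref_b.amplitudes()[ib],
        sig=None if ref_b.sig is None else k * ref_b.sig[ib],
        dmin=ref_b.dmin)
    subset_a = ReflectionSet(
        ref_a.cell, hkl,
        f=None if ref_a.f is None else ref_a.f[ia],
        amp=ref_a.amplitudes()[ia],
        sig=None if ref_a.sig is None else ref_a.sig[ia],
        dmin=ref_a.dmin)
    return subset_a, scaled, k


def fo_minus_fo_map(ref_on: ReflectionSet, ref_off: ReflectionSet,
                    phase_model: Structure, dmin: float,
                    shape=None, weighting: str = "none") -> DensityGrid:
    """Unweighted isomorphous difference map.

    Coefficients are (|F_on| - k |F_off|) exp(i phi_calc) with phi_calc from
    the phase model; the synthesized map is sigma-normalized and has mean
    ~ 0 (F000 omitted).  A weighting hook exists but defaults off.

    The least-squares scale is anchored on whichever input has the larger
    total intensity (order-independent anchor), so exchanging the two inputs
    negates the map exactly.
    """
    if weighting != "none":
        raise NotImplementedError("only unweighted difference maps are "
                                  "implemented")
    amap, bmap = ref_on.index_map(), ref_off.index_map()
    common = [h for h in amap if h in bmap]
    pow_on = float(np.sum(ref_on.amplitudes()[[amap[h] for h in common]] ** 2))
    pow_off = float(np.sum(ref_off.amplitudes()[[bmap[h] for h in common]] ** 2))
    if pow_on >= pow_off:
        sub_on, sub_off, _k = scale_amplitudes(ref_on, ref_off)
    else:
        sub_off, sub_on, _k = scale_amplitudes(ref_off, ref_on)
    phases = sf_fft(phase_model, dmin)
    pmap = phases.index_map()
    keep, phi_idx = [], []
    for i, h in enumerate(sub_on.hkl):
        j = pmap.get(tuple(h))
        if j is not None:
            keep.append(i)
            phi_idx.append(j)
    if len(keep) < 0.95 * len(sub_on.hkl):
        raise ValueError("phase model does not cover >= 95% of the common "
                         "reflection set at this dmin")
    keep = np.array(keep)
    dphi = np.angle(phases.f[np.array(phi_idx)])
    diff = (sub_on.amplitudes()[keep] - sub_off.amplitudes()[keep]) \
        * np.exp(1j * dphi)
    coeffs = ReflectionSet(sub_on.cell, sub_on.hkl[keep], f=diff, dmin=dmin)
    grid = map_from_sf(coeffs, shape=shape)
    return grid.sigma_normalize()


# --------------------------------------------------------------------------- #
# Peaks

@dataclass
class Peak:
    frac: np.ndarray
    height: float               # e/A^3
    height_sigma: float
    sign: int
    nearest_atom: int | None    # index into the model's atom list
    distance: float | None      # A


@dataclass
class PeakList:
    peaks: list
    threshold_sigma: float
    sigma: float

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def __getitem__(self, i):
        return self.peaks[i]

    def positive(self):
        return [p for p in self.peaks if p.sign > 0]

    def negative(self):
        return [p for p in self.peaks if p.sign < 0]

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([{
            "x": p.frac[0], "y": p.frac[1], "z": p.frac[2],
            "height_e_A3": p.height, "height_sigma": p.height_sigma,
            "sign": p.sign, "nearest_atom": p.nearest_atom,
            "distance_A": p.distance} for p in self.peaks])


def _periodic_deltas(cell, frac_a: np.ndarray, frac_b: np.ndarray) -> np.ndarray:
    """Minimum-image Cartesian distances between two frac coordinate sets."""
    d = frac_a[:, None, :] - frac_b[None, :, :]
    d -= np.round(d)
    dc = d @ cell.orth.T
    return np.linalg.norm(dc, axis=-1)


def find_peaks(grid: DensityGrid, threshold_sigma: float,
               model: Structure | None = None,
               max_dist: float = 5.0) -> PeakList:
    """Local extrema of a sigma-normalized map, both signs.

    Sub-grid positions come from 3-point quadratic interpolation per axis
    (ties broken by grid order); peaks farther than ``max_dist`` from every
    model atom are dropped when a model is given.
    """
    sigma = grid.sigma if grid.sigma is not None else grid.rms()
    if sigma == 0.0:
        return PeakList([], threshold_sigma, 0.0)
    v = grid.values
    above = np.abs(v) >= threshold_sigma * sigma
    pos_max = np.ones_like(v, dtype=bool)
    neg_min = np.ones_like(v, dtype=bool)
    for ax in range(3):
        for shift in (1, -1):
            nb = np.roll(v, shift, axis=ax)
            pos_max &= v >= nb
            neg_min &= v <= nb
    # full 26-neighborhood
    for sx in (-1, 0, 1):
        for sy in (-1, 0, 1):
            for sz in (-1, 0, 1):
                if (sx, sy, sz) == (0, 0, 0):
                    continue
                nb = np.roll(np.roll(np.roll(v, sx, 0), sy, 1), sz, 2)
                pos_max &= v >= nb
                neg_min &= v <= nb
    cand = above & ((pos_max & (v > 0)) | (neg_min & (v < 0)))
    idx = np.argwhere(cand)
    shape = np.array(grid.shape)
    peaks = []
    model_frac = model.frac_coords() if model is not None else None
    for ijk in idx:
        center = v[tuple(ijk)]
        offset = np.zeros(3)
        height = center
        for ax in range(3):
            m = ijk.copy(); m[ax] = (m[ax] - 1) % shape[ax]
            p = ijk.copy(); p[ax] = (p[ax] + 1) % shape[ax]
            vm, vp = v[tuple(m)], v[tuple(p)]
            denom = vm - 2.0 * center + vp
            if abs(denom) > 1e-12:
                d = 0.5 * (vm - vp) / denom
                d = float(np.clip(d, -0.5, 0.5))
                offset[ax] = d
                height += -0.25 * (vm - vp) * d
        frac = ((ijk + offset) / shape) % 1.0
        peaks.append(Peak(frac=frac, height=float(height),
                          height_sigma=float(height / sigma),
                          sign=1 if center > 0 else -1,
                          nearest_atom=None, distance=None))
    if model_frac is not None and peaks:
        pf = np.array([p.frac for p in peaks])
        dist = _periodic_deltas(grid.cell, pf, model_frac)
        nearest = dist.argmin(axis=1)
        kept = []
        for p, ni, dmin_ in zip(peaks, nearest, dist.min(axis=1)):
            if dmin_ <= max_dist:
                p.nearest_atom = int(ni)
                p.distance = float(dmin_)
                kept.append(p)
        peaks = kept
    peaks.sort(key=lambda p: -abs(p.height))
    return PeakList(peaks, threshold_sigma, sigma)


# --------------------------------------------------------------------------- #
# IADDAT

@dataclass
class ResidueProfile:
    """residue id -> scalar (IADDAT, B_diff, ...)."""

    values: dict

    def __getitem__(self, resid):
        return self.values[resid]

    def items(self):
        return self.values.items()

    def as_array(self):
        return np.array(list(self.values.values()))

    def argmax(self):
        return max(self.values, key=self.values.get)

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame(
            [{"chain": r[0], "resnum": r[1], "resname": r[2], "value": v}
             for r, v in self.values.items()])


def _grid_points_near(grid: DensityGrid, frac_centers: np.ndarray,
                      radius: float) -> np.ndarray:
    """Boolean mask over grid voxels within ``radius`` A of any center."""
    shape = grid.shape
    mask = np.zeros(shape, dtype=bool)
    cell = grid.cell
    finv_row_norms = np.linalg.norm(cell.frac, axis=1)
    orth = cell.orth
    n = np.array(shape)
    for c in np.atleast_2d(frac_centers):
        lo = c - radius * finv_row_norms
        hi = c + radius * finv_row_norms
        idx = []
        for ax in range(3):
            i0 = int(math.floor(lo[ax] * shape[ax]))
            i1 = int(math.ceil(hi[ax] * shape[ax]))
            if i1 - i0 >= shape[ax]:
                idx.append(np.arange(shape[ax]))
            else:
                idx.append(np.arange(i0, i1 + 1) % shape[ax])
        ii, jj, kk = np.meshgrid(*idx, indexing="ij")
        pts = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3) / n
        d = pts - c
        d -= np.round(d)
        within = np.linalg.norm(d @ orth.T, axis=1) <= radius
        flat = (ii.ravel()[within], jj.ravel()[within], kk.ravel()[within])
        mask[flat] = True
    return mask


def iaddat(grid: DensityGrid, model: Structure, threshold_sigma: float = 3.0,
           radius: float = 2.5, selection=None) -> ResidueProfile:
    """Per-residue integration of absolute difference density above a noise
    threshold: the mean over voxels within ``radius`` of the residue's
    selected atoms of (|rho| - threshold)+, in e/A^3.

    The mean (not the sum) decouples the score from residue size.
    """
    sigma = grid.sigma if grid.sigma is not None else grid.rms()
    thr = threshold_sigma * sigma
    excess = np.clip(np.abs(grid.values) - thr, 0.0, None)
    sel = selection if selection is not None else (lambda a: True)
    values: dict = {}
    for resid in model.residues():
        atoms = [a for a in model.atoms if a.resid == resid and sel(a)]
        if not atoms:
            continue
        mask = _grid_points_near(grid, np.array([a.frac for a in atoms]),
                                 radius)
        values[resid] = float(excess[mask].mean()) if mask.any() else 0.0
    if not values:
        raise ValueError("selection matches no atoms")
    return ResidueProfile(values)


# --------------------------------------------------------------------------- #
# Masked map correlation

def map_cc_masked(map_a: DensityGrid, map_b: DensityGrid, model: Structure,
                  selection=None, radius: float = 2.0,
                  min_points: int = 10) -> float:
    """Pearson correlation of two maps over voxels within ``radius`` of the
    selected atoms (e.g. a main-chain mask of a mobile loop)."""
    if map_a.shape != map_b.shape:
        raise ValueError("maps must share one grid")
    sel = selection if selection is not None else (lambda a: True)
    frac = np.array([a.frac for a in model.atoms if sel(a)])
    if len(frac) == 0:
        raise ValueError("selection matches no atoms")
    mask = _grid_points_near(map_a, frac, radius)
    npts = int(mask.sum())
    if npts < min_points:
        raise ValueError(f"mask covers only {npts} grid points "
                         f"(need >= {min_points})")
    va, vb = map_a.values[mask], map_b.values[mask]
    if va.std() == 0.0 or vb.std() == 0.0:
        return 0.0  # featureless map: correlation undefined, report none
    return float(np.corrcoef(va, vb)[0, 1])


def mainchain(resnums=None, chain=None):
    """Selection predicate for main-chain atoms, optionally restricted to
    residue numbers / chain."""
    names = {"N", "CA", "C", "O"}
    def pred(a):
        if a.hetatm or a.name not in names:
            return False
        if resnums is not None and a.resnum not in resnums:
            return False
        if chain is not None and a.chain != chain:
            return False
        return True
    return pred
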