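"""Occupancy-consistent supercell realizations and buffer-ion bookkeeping.

A crystal refined with alternate conformers describes a lattice average; a
supercell simulation needs each protein copy in exactly one conformation.
This module assigns conformers to the N1 x N2 x N3 x n_ops copies so that
population fractions match the refined occupancies (quota / largest-remainder
assignment, the default) or are drawn i.i.d. (multinomial), runs a second
conditional round for a covalent adduct that can only sit on one conformer of
its host residue, and materializes the result as an explicit P1 supercell.

Copies are indexed (symmetry operator, lattice vector) in lexicographic order
and the RNG consumes draws in that order, so a seed pins the realization.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import P1, Structure

AVOGADRO = 6.022e23

ABSENT = "-"  # conformer label for the "not present" state of a partial unit


class ConfigurationError(ValueError):
    """Occupancy bookkeeping that cannot be satisfied."""


# --------------------------------------------------------------------------- #
# Copy bookkeeping

@dataclass
class CopyState:
    """One protein copy: symmetry-op index, lattice vector, resolved conformers."""

    op: int
    lattice: tuple
    conformer: dict = field(default_factory=dict)  # unit -> label
    adduct: bool = False


@dataclass
class SupercellModel:
    base: Structure
    dims: tuple
    copies: list

    @property
    def n_copies(self) -> int:
        return len(self.copies)

    def counts(self, unit: str) -> dict:
        out: dict = {}
        for c in self.copies:
            lab = c.conformer.get(unit, ABSENT)
            out[lab] = out.get(lab, 0) + 1
        return out

    def manifest(self) -> dict:
        return {
            "dims": list(self.dims),
            "copies": [
                {"op": c.op, "lattice": list(c.lattice),
                 "conformer": dict(c.conformer), "adduct": c.adduct}
                for c in self.copies
            ],
        }

    def write_manifest(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.manifest(), fh, indent=1, sort_keys=True)


def _copy_index(dims, n_ops) -> list:
    """(op, lattice) lexicographic: op-major, then i, j, k."""
    out = []
    for op in range(n_ops):
        for lat in itertools.product(range(dims[0]), range(dims[1]),
                                     range(dims[2])):
            out.append((op, lat))
    return out


def largest_remainder(fractions, total: int) -> list:
    """Integer quotas summing to ``total`` with counts = round(total * f)
    reconciled by largest remainder."""
    raw = [f * total for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    short = total - sum(counts)
    order = sorted(range(len(raw)), key=lambda i: raw[i] - counts[i],
                   reverse=True)
    for i in order[:short]:
        counts[i] += 1
    return counts


def _stratify_counts(counts, n_classes: int, capacity: int, rng) -> list:
    """Split global conformer counts as evenly as possible over symmetry-op
    classes of ``capacity`` copies each.

    Each label gets floor(c/n_classes) per class; its remainder units go to
    the classes with the most free capacity (ties broken at random).  Even
    splits make lattice averaging reproduce the occupancy-weighted model
    exactly; uneven remainders are spread so the residual is minimal.
    """
    per_class = [[c // n_classes for c in counts] for _ in range(n_classes)]
    free = [capacity - sum(row) for row in per_class]
    for li in range(len(counts)):
        r = counts[li] % n_classes
        if r == 0:
            continue
        order = sorted(range(n_classes),
                       key=lambda k: (-free[k], rng.random()))
        for k in order[:r]:
            per_class[k][li] += 1
            free[k] -= 1
    assert all(f == 0 for f in free)
    return per_class


# --------------------------------------------------------------------------- #
# Conformer assignment

def assign_conformers(base: Structure, dims, seed: int,
                      method: str = "quota") -> SupercellModel:
    """Resolve every alternation unit to one conformer per copy.

    quota: each conformer receives its largest-remainder quota of copies,
    placed uniformly at random.  multinomial: i.i.d. per copy.  Units listed
    in ``base.conditional`` (adducts) are left to :func:`assign_adduct`.
    """
    if method not in ("quota", "multinomial"):
        raise ValueError(f"unknown method {method!r}")
    dims = tuple(int(d) for d in dims)
    if min(dims) < 1:
        raise ValueError("supercell dims must be >= 1")
    index = _copy_index(dims, base.spacegroup.n_ops)
    copies = [CopyState(op=op, lattice=lat) for op, lat in index]
    rng = np.random.default_rng(seed)
    units = base.alt_units()
    for unit in sorted(units):
        if unit in base.conditional:
            continue
        groups = units[unit]
        labels = [g.label for g in groups]
        occs = [g.occ for g in groups]
        total = sum(occs)
        if total < 0.99 and unit not in base.absent_ok:
            raise ConfigurationError(
                f"unit {unit!r}: occupancies sum to {total:.3f} < 0.99 and no "
                f"absent conformer is declared")
        if total < 1.0:
            labels.append(ABSENT)
            occs.append(1.0 - total)
        else:
            occs = [o / total for o in occs]
        n = len(copies)
        if method == "quota":
            counts = largest_remainder(occs, n)
            n_ops = base.spacegroup.n_ops
            n_lat = n // n_ops
            per_class = _stratify_counts(counts, n_ops, n_lat, rng)
            for k in range(n_ops):
                pool = [lab for lab, cnt in zip(labels, per_class[k])
                        for _ in range(cnt)]
                perm = rng.permutation(n_lat)
                for slot, lat_i in enumerate(perm):
                    copies[k * n_lat + lat_i].conformer[unit] = pool[slot]
        else:
            draws = rng.choice(len(labels), size=n, p=occs)
            for copy_i, d in enumerate(draws):
                copies[copy_i].conformer[unit] = labels[d]
    return SupercellModel(base=base, dims=dims, copies=copies)


def assign_adduct(model: SupercellModel, p_adduct_given_reactive: float,
                  seed: int, method: str = "quota",
                  unit: str | None = None,
                  host: tuple | None = None) -> SupercellModel:
    """Second-round conditional sampling: attach the adduct to a fraction of
    the copies whose host residue is in the reactive conformer.

    The adduct never appears on copies in the inert conformation.  The quota
    count is round(n_reactive * p).
    """
    p = p_adduct_given_reactive
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    base = model.base
    if unit is None:
        if len(base.conditional) != 1:
            raise ConfigurationError("adduct unit is ambiguous; pass unit=")
        unit = next(iter(base.conditional))
    if host is not None:
        host_unit, host_label = host
    elif unit in base.conditional:
        host_unit, host_label = base.conditional[unit]
    else:
        raise ConfigurationError(
            f"unit {unit!r} has no declared host conformer; pass host=")
    eligible = [i for i, c in enumerate(model.copies)
                if c.conformer.get(host_unit) == host_label]
    for c in model.copies:
        c.adduct = False
        c.conformer[unit] = ABSENT
    if p > 0 and not eligible:
        warnings.warn("no copies in the reactive conformation; no adducts "
                      "assigned", stacklevel=2)
        return model
    rng = np.random.default_rng(seed)
    if method == "quota":
        n_add = int(round(len(eligible) * p))
        # spread the quota over symmetry-op classes in proportion to each
        # class's eligible count, then pick uniformly within a class
        by_class: dict = {}
        for i in eligible:
            by_class.setdefault(model.copies[i].op, []).append(i)
        classes = sorted(by_class)
        raw = [len(by_class[k]) * p for k in classes]
        counts = [int(math.floor(x)) for x in raw]
        order = sorted(range(len(raw)), key=lambda j: raw[j] - counts[j],
                       reverse=True)
        for j in order[:n_add - sum(counts)]:
            counts[j] += 1
        # cap at class capacity, push overflow to classes with room
        for j, k in enumerate(classes):
            if counts[j] > len(by_class[k]):
                spill = counts[j] - len(by_class[k])
                counts[j] -= spill
                for j2 in range(len(classes)):
                    room = len(by_class[classes[j2]]) - counts[j2]
                    take = min(room, spill)
                    counts[j2] += take
                    spill -= take
                    if spill == 0:
                        break
        picked = []
        for j, k in enumerate(classes):
            sel = rng.permutation(len(by_class[k]))[:counts[j]]
            picked.extend(by_class[k][i] for i in sel)
    else:
        draws = rng.random(len(eligible)) < p
        picked = [i for i, d in zip(eligible, draws) if d]
    label = next(g.label for g in base.altgroups if g.unit == unit)
    for i in picked:
        model.copies[i].adduct = True
        model.copies[i].conformer[unit] = label
    return model


# --------------------------------------------------------------------------- #
# Occupancy arithmetic

def modification_fraction(occ_adduct: float, occ_host: float) -> float:
    """Percent of the host conformer carrying the covalent modification."""
    if not 0.0 < occ_host <= 1.0:
        raise ValueError("host occupancy must be in (0, 1]")
    if not 0.0 <= occ_adduct <= occ_host + 1e-9:
        raise ValueError("adduct occupancy cannot exceed host occupancy")
    return 100.0 * occ_adduct / occ_host


# --------------------------------------------------------------------------- #
# Ion bookkeeping

@dataclass
class IonBudget:
    """Integer ion counts for a solvent volume at given buffer concentrations."""

    species: list
    concentrations: dict        # mol/L
    solvent_volume: float       # liters
    counts: dict
    rounding: str = "nearest"


def ion_counts(concentrations: dict, solvent_volume: float,
               rounding: str = "nearest") -> IonBudget:
    """count(species) = rounding(C * V * N_A).

    ``concentrations`` maps species label to total molarity (summed over all
    buffer components contributing that species).  ``rounding`` is "nearest"
    or "ceil".
    """
    if solvent_volume <= 0:
        raise ValueError("solvent volume must be positive")
    rounders = {"nearest": lambda x: int(round(x)),
                "ceil": lambda x: int(math.ceil(x))}
    if rounding not in rounders:
        raise ValueError(f"unknown rounding rule {rounding!r}")
    counts = {}
    for sp, conc in concentrations.items():
        if conc < 0:
            raise ValueError(f"negative concentration for {sp}")
        counts[sp] = rounders[rounding](conc * solvent_volume * AVOGADRO)
    return IonBudget(species=sorted(concentrations), concentrations=dict(concentrations),
                     solvent_volume=solvent_volume, counts=counts,
                     rounding=rounding)


def neutralization_budget(net_charge: int, counter_species: str = "K") -> IonBudget:
    """Counter-ions required to neutralize the system, kept as a separate,
    explicitly labeled budget added after the buffer ions."""
    n = max(0, -net_charge) if counter_species in ("K", "NA", "MG") else max(0, net_charge)
    return IonBudget(species=[counter_species],
                     concentrations={counter_species: float("nan")},
                     solvent_volume=float("nan"),
                     counts={counter_species: n}, rounding="exact")


# --------------------------------------------------------------------------- #
# Realization

_CHAIN_IDS = ("ABCDEFGHIJKLMNOPQRSTUVWXYZ"
              "abcdefghijklmnopqrstuvwxyz0123456789")


def realize(model: SupercellModel) -> Structure:
    """Materialize the supercell as one explicit P1 atom set.

    Cell lengths are scaled by dims; every copy is placed by its symmetry
    operator plus lattice translation; each copy carries a single conformer
    with occupancy 1 (the disorder is now explicit).  U tensors rotate with
    the symmetry operators.
    """
    base = model.base
    dims = np.asarray(model.dims, dtype=float)
    cell = base.cell.scaled(model.dims)
    orth, fracm = base.cell.orth, base.cell.frac
    ops = list(base.spacegroup.operators())
    # atom index -> owning unit (if any)
    owner: dict = {}
    for g in base.altgroups:
        for i in g.atom_indices:
            owner[i] = (g.unit, g.label)
    atoms = []
    for ci, c in enumerate(model.copies):
        rot, tran = ops[c.op]
        m_cart = orth @ rot @ fracm
        lat = np.asarray(c.lattice, dtype=float)
        chain_id = _CHAIN_IDS[ci % len(_CHAIN_IDS)]
        for i, a in enumerate(base.atoms):
            own = owner.get(i)
            if own is not None:
                unit, label = own
                if c.conformer.get(unit, ABSENT) != label:
                    continue
            b = a.copy()
            b.frac = ((rot @ a.frac + tran) % 1.0 + lat) / dims
            if b.uaniso is not None:
                b.uaniso = m_cart @ b.uaniso @ m_cart.T
            b.occ = 1.0
            b.altloc = ""
            b.chain = chain_id
            atoms.append(b)
    return Structure(cell=cell, spacegroup=P1, atoms=atoms)
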