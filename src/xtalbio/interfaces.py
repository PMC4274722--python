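"""Lattice interface enumeration, buried surface area and residue regions.

The buried surface area (BSA) of a pair of chain copies is
``(ASA_a + ASA_b - ASA_complex) / 2`` where ASA is the solvent-accessible
surface area of each isolated partner and of the two-chain complex.  Each
residue of a detected interface partner is labelled by its burial ratio
``(ASA_unbound - ASA_bound) / ASA_unbound``:

* CORE     — burial ratio at or above the core threshold,
* RIM      — partially buried (ratio in (0, threshold)),
* SURFACE  — untouched by the partner but solvent exposed,
* INTERIOR — buried inside the monomer already.

ASA is computed with the Shrake-Rupley rolling-probe point method on a
deterministic spherical point set (a Fibonacci spiral lattice), so repeated
runs are bit-identical without any random state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import Atom, ChainModel, CrystalStructure
from .symmetry import (
    OperatorClass,
    SymOperator,
    SymmetryError,
    classify_operator,
    interface_fingerprint,
)

__all__ = [
    "Region",
    "AsaResult",
    "Interface",
    "compute_asa",
    "chain_asa",
    "find_interfaces",
    "assign_regions",
    "fibonacci_sphere",
    "DEFAULT_CONTACT_DISTANCE",
    "DEFAULT_MIN_AREA",
    "CORE_THRESHOLD_GEOMETRY",
    "CORE_THRESHOLD_EVOLUTION",
    "DEFAULT_SURFACE_MIN_ASA",
]

DEFAULT_CONTACT_DISTANCE = 5.9   # Å, any heavy-atom pair
DEFAULT_MIN_AREA = 35.0          # Å², cataloguing bound for an interface
CORE_THRESHOLD_GEOMETRY = 0.95   # burial ratio for the geometry core count
CORE_THRESHOLD_EVOLUTION = 0.70  # burial ratio for the evolutionary core set
DEFAULT_SURFACE_MIN_ASA = 5.0    # Å², minimum exposure to count as surface
DEFAULT_PROBE = 1.4              # Å, water probe
DEFAULT_N_POINTS = 960


class Region(str, Enum):
    CORE = "CORE"
    RIM = "RIM"
    SURFACE = "SURFACE"
    INTERIOR = "INTERIOR"


@dataclass
class AsaResult:
    atom_areas: np.ndarray        # Å² per atom, input order
    residue_areas: np.ndarray     # Å² per residue index
    probe_radius: float
    n_sphere_points: int

    @property
    def total(self) -> float:
        return float(self.atom_areas.sum())


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere point set (spiral lattice)."""
    i = np.arange(n, dtype=float) + 0.5
    phi = np.arccos(1.0 - 2.0 * i / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * i
    return np.column_stack([
        np.cos(theta) * np.sin(phi),
        np.sin(theta) * np.sin(phi),
        np.cos(phi),
    ])


def compute_asa(atoms, probe_radius: float = DEFAULT_PROBE,
                n_points: int = DEFAULT_N_POINTS,
                n_residues: Optional[int] = None) -> AsaResult:
    """Shrake-Rupley accessible surface area.

    Each atom's van der Waals sphere is expanded by the probe radius and
    sampled with ``n_points`` quasi-uniform points; a point is accessible iff
    it lies outside every neighbouring expanded sphere.  The per-atom area is
    ``4 pi (r + probe)^2`` times the accessible fraction.
    """
    if not atoms:
        raise ValueError("empty atom list")
    if n_points < 92:
        raise ValueError("n_points must be >= 92")
    if probe_radius <= 0:
        raise ValueError("probe_radius must be positive")

    coords = np.array([a.coords for a in atoms], dtype=float)
    radii = np.array([a.vdw_radius for a in atoms], dtype=float) + probe_radius
    sphere = fibonacci_sphere(n_points)

    tree = cKDTree(coords)
    max_r = radii.max()
    areas = np.empty(len(atoms))
    for i in range(len(atoms)):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r)
                     if j != i]
        if neighbors:
            nb = np.asarray(neighbors)
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            buried = (d2 < (radii[nb] ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac

    n_res = n_residues if n_residues is not None else (
        max(a.residue_index for a in atoms) + 1)
    res_areas = np.zeros(n_res)
    for a, ar in zip(atoms, areas):
        res_areas[a.residue_index] += ar
    return AsaResult(areas, res_areas, probe_radius, n_points)


def chain_asa(chain: ChainModel, probe_radius: float = DEFAULT_PROBE,
              n_points: int = DEFAULT_N_POINTS) -> AsaResult:
    """ASA of an isolated chain, hydrogens excluded."""
    return compute_asa(chain.heavy_atoms(), probe_radius, n_points,
                       n_residues=chain.n_residues)


# ---------------------------------------------------------------------------
# interfaces

@dataclass
class Interface:
    """A unique pairwise contact between chain copies in the lattice."""

    id: int
    chain_a: str
    chain_b: str
    op_b: SymOperator                 # maps chain_b's reference copy onto its image
    operator_class: OperatorClass
    area: float                       # Å², BSA
    contacts: list                    # [(res_index_a, res_index_b), ...]
    asa_a_unbound: AsaResult = None
    asa_b_unbound: AsaResult = None
    asa_a_bound: np.ndarray = None    # per-residue ASA of A within the complex
    asa_b_bound: np.ndarray = None
    fingerprint: str = ""

    def burial_ratios(self, partner: str) -> np.ndarray:
        """Per-residue burial ratio for partner 'A' or 'B' (NaN where the
        residue has zero unbound ASA)."""
        unbound = (self.asa_a_unbound if partner == "A" else self.asa_b_unbound).residue_areas
        bound = self.asa_a_bound if partner == "A" else self.asa_b_bound
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (unbound - bound) / unbound
        return np.where(unbound > 0, ratio, np.nan)

    def regions(self, core_burial_threshold: float,
                surface_min_asa: float = DEFAULT_SURFACE_MIN_ASA) -> dict:
        """Region labels per partner at a given core burial threshold."""
        out = {}
        for partner in ("A", "B"):
            unbound = (self.asa_a_unbound if partner == "A" else self.asa_b_unbound)
            bound = self.asa_a_bound if partner == "A" else self.asa_b_bound
            out[partner] = assign_regions(unbound.residue_areas, bound,
                                          core_burial_threshold, surface_min_asa)
        return out

    def core_count(self, core_burial_threshold: float) -> int:
        regs = self.regions(core_burial_threshold)
        return sum(1 for p in ("A", "B") for r in regs[p] if r == Region.CORE)


def assign_regions(asa_unbound: np.ndarray, asa_bound: np.ndarray,
                   core_burial_threshold: float,
                   surface_min_asa: float = DEFAULT_SURFACE_MIN_ASA) -> list:
    """Label residues CORE / RIM / SURFACE / INTERIOR from per-residue ASA.

    ``asa_unbound`` is the isolated partner, ``asa_bound`` the same residues
    within the complex.
    """
    if not 0 < core_burial_threshold <= 1:
        raise ValueError("core_burial_threshold must lie in (0, 1]")
    asa_unbound = np.asarray(asa_unbound, float)
    asa_bound = np.asarray(asa_bound, float)
    if asa_unbound.shape != asa_bound.shape:
        raise ValueError("residue sets of the two ASA results do not match")
    labels = []
    for u, b in zip(asa_unbound, asa_bound):
        if u <= 0:
            labels.append(Region.INTERIOR)
            continue
        ratio = (u - b) / u
        if ratio >= core_burial_threshold:
            labels.append(Region.CORE)
        elif ratio > 1e-9:
            labels.append(Region.RIM)
        elif u >= surface_min_asa:
            labels.append(Region.SURFACE)
        else:
            labels.append(Region.INTERIOR)
    return labels


def _image_coords(chain: ChainModel, op: SymOperator, cell) -> np.ndarray:
    frac = cell.fractionalize(chain.coords())
    return cell.orthogonalize(op.apply(frac))


def _transformed_atoms(chain: ChainModel, coords: np.ndarray) -> list:
    atoms = chain.heavy_atoms()
    out = []
    for a, xyz in zip(atoms, coords):
        b = Atom.__new__(Atom)
        b.serial = a.serial
        b.element = a.element
        b.name = a.name
        b.residue_index = a.residue_index
        b.coords = xyz
        b.vdw_radius = a.vdw_radius
        out.append(b)
    return out


def _shift_range(cell, chains, contact_distance: float) -> int:
    """Half-width of the cell-shift search box.

    An image at shift magnitude m along the shortest cell axis is at least
    ``m*min_len - diam`` away from the reference chain, so shifts beyond
    ``(diam + cutoff)/min_len`` cannot produce contacts.
    """
    diam = 0.0
    for c in chains:
        xyz = c.coords()
        if len(xyz) > 1:
            diam = max(diam, float(np.ptp(xyz, axis=0).max()))
    min_len = min(cell.a, cell.b, cell.c)
    k = int(np.ceil((diam + contact_distance + 1.0) / min_len))
    return max(1, min(k, 5))


def _contact_pairs(tree_a, atoms_a, coords_b, atoms_b, cutoff) -> list:
    pairs = set()
    hits = tree_a.query_ball_point(coords_b, cutoff)
    for jb, lst in enumerate(hits):
        for ia in lst:
            pairs.add((atoms_a[ia].residue_index, atoms_b[jb].residue_index))
    return sorted(pairs)


def find_interfaces(structure: CrystalStructure,
                    contact_distance: float = DEFAULT_CONTACT_DISTANCE,
                    min_area: float = DEFAULT_MIN_AREA,
                    probe_radius: float = DEFAULT_PROBE,
                    n_points: int = DEFAULT_N_POINTS,
                    min_chain_length: int = 10) -> list:
    """Enumerate unique pairwise interfaces in the crystal.

    Every protein chain's reference copy is tested against every image of
    every protein chain under all space-group operators and cell shifts in a
    box wide enough for the chain diameter.  A pair is an interface iff any
    heavy-atom distance is within ``contact_distance``; duplicates are
    removed both by the unordered operator fingerprint and by congruent
    contact sets (the same physical interface seen from symmetry-equivalent
    viewpoints).  Interfaces with BSA below ``min_area`` are dropped; the
    survivors are sorted by descending area and numbered from 1.
    """
    chains = structure.protein_chains(min_chain_length)
    if not chains:
        return []
    if structure.cell is None:
        if structure.experimental_method.value == "XRAY":
            raise SymmetryError(f"{structure.entry_id}: X-ray entry without cell")
        # no lattice: only asymmetric-unit pairs
        cell = None
    else:
        cell = structure.cell

    asa_cache = {c.chain_id: chain_asa(c, probe_radius, n_points) for c in chains}
    trees = {c.chain_id: cKDTree(c.coords()) for c in chains}
    heavy = {c.chain_id: c.heavy_atoms() for c in chains}

    candidates = []
    seen_fp = set()
    seen_contacts = set()

    if cell is not None:
        k = _shift_range(cell, chains, contact_distance)
        shifts = list(itertools.product(range(-k, k + 1), repeat=3))
        operators = structure.operators
    else:
        shifts = [(0, 0, 0)]
        operators = [SymOperator()]

    order = {c.chain_id: i for i, c in enumerate(chains)}
    for ca in chains:
        for cb in chains:
            for base_op in operators:
                for shift in shifts:
                    op = base_op.with_shift(shift)
                    if op.is_identity():
                        if ca.chain_id == cb.chain_id:
                            continue  # a chain vs itself
                        if order[ca.chain_id] > order[cb.chain_id]:
                            continue  # AU pair counted once
                    fp = interface_fingerprint(ca.chain_id, cb.chain_id, op)
                    if fp in seen_fp:
                        continue
                    seen_fp.add(fp)
                    if cell is not None:
                        coords_b = _image_coords(cb, op, cell)
                    else:
                        coords_b = cb.coords()
                    # cheap bounding check before the KD query
                    pa = trees[ca.chain_id]
                    if len(coords_b) == 0:
                        continue
                    contacts = _contact_pairs(pa, heavy[ca.chain_id], coords_b,
                                              heavy[cb.chain_id], contact_distance)
                    if not contacts:
                        continue
                    pair_key = tuple(sorted((ca.chain_id, cb.chain_id)))
                    if ca.chain_id <= cb.chain_id:
                        sig = (pair_key, tuple(sorted(contacts)))
                    else:
                        sig = (pair_key, tuple(sorted((b, a) for a, b in contacts)))
                    if ca.chain_id == cb.chain_id:
                        sig_rev = (pair_key, tuple(sorted((b, a) for a, b in contacts)))
                        sig = min(sig, sig_rev)
                    if sig in seen_contacts:
                        continue
                    seen_contacts.add(sig)
                    candidates.append((ca, cb, op, contacts, coords_b))

    results = []
    for ca, cb, op, contacts, coords_b in candidates:
        atoms_a = heavy[ca.chain_id]
        atoms_b = _transformed_atoms(cb, coords_b)
        asa_a = asa_cache[ca.chain_id]
        asa_b = asa_cache[cb.chain_id]
        # complex ASA: both partners' atoms together, residue areas split back
        combined = []
        for a in atoms_a:
            combined.append((a, 0, a.residue_index))
        for b in atoms_b:
            combined.append((b, 1, b.residue_index))
        coords = np.array([a.coords for a, _, _ in combined])
        radii = np.array([a.vdw_radius for a, _, _ in combined]) + probe_radius
        sphere = fibonacci_sphere(n_points)
        tree = cKDTree(coords)
        max_r = radii.max()
        bound_a = np.zeros(ca.n_residues)
        bound_b = np.zeros(cb.n_residues)
        total_complex = 0.0
        for i, (a, side, ridx) in enumerate(combined):
            pts = coords[i] + radii[i] * sphere
            nbs = [j for j in tree.query_ball_point(coords[i], radii[i] + max_r) if j != i]
            if nbs:
                nb = np.asarray(nbs)
                d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
                frac = 1.0 - (d2 < (radii[nb] ** 2)[None, :]).any(axis=1).mean()
            else:
                frac = 1.0
            area = 4.0 * np.pi * radii[i] ** 2 * frac
            total_complex += area
            if side == 0:
                bound_a[ridx] += area
            else:
                bound_b[ridx] += area
        # analytically >= 0; clamp away point-sampling noise on grazing contacts
        bsa = max(0.0, (asa_a.total + asa_b.total - total_complex) / 2.0)
        if bsa < min_area:
            continue
        cls = classify_operator(op, cell)
        results.append(Interface(
            id=0, chain_a=ca.chain_id, chain_b=cb.chain_id, op_b=op,
            operator_class=cls, area=bsa, contacts=contacts,
            asa_a_unbound=asa_a, asa_b_unbound=asa_b,
            asa_a_bound=bound_a, asa_b_bound=bound_b,
            fingerprint=interface_fingerprint(ca.chain_id, cb.chain_id, op),
        ))

    results.sort(key=lambda it: -it.area)
    for i, it in enumerate(results, start=1):
        it.id = i
    return results
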