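"""Synthetic crystals and alignments with controlled statistical structure.

Every stage of the pipeline is testable without downloads: this module
builds compact pseudo-protein blobs (collision-free pseudo-atoms with
realistic radii — not stereochemically valid protein, which the contact and
surface machinery does not require), places them in a chosen space group
with the unit cell scaled until lattice neighbours touch at a controlled
depth, and emits matching alignments whose per-column conservation is set
by construction (conserved columns identical across rows; variable columns
drawn uniformly from a small symbol set with a known entropy).

Each generated crystal carries an independent brute-force ground truth
(all-images, all-pairs distance scan plus the operator-iteration
infiniteness oracle) against which the enumeration machinery is checked.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .structure_io import (
    Alignment,
    Atom,
    ChainModel,
    CrystalCell,
    CrystalStructure,
    Residue,
    VDW_RADII,
)
from .symmetry import (
    SymOperator,
    interface_fingerprint,
    is_infinite_by_iteration,
    spacegroup_operators,
)

__all__ = [
    "FixtureSpec",
    "GroundTruthContact",
    "make_crystal_fixture",
    "make_alignment_fixture",
    "make_classification_case",
    "write_fixture",
    "bruteforce_interfaces",
    "SUPPORTED_SPACEGROUPS",
]

#: Space groups the generator knows how to build sensible cells for.
SUPPORTED_SPACEGROUPS = {
    "P 1": dict(kind="triclinic"),
    "P 1 21 1": dict(kind="monoclinic", beta=100.0),
    "P 21 21 21": dict(kind="orthorhombic"),
    "C 1 2 1": dict(kind="monoclinic", beta=105.0),
    "P 43 21 2": dict(kind="tetragonal"),
    "P 61": dict(kind="hexagonal"),
}

_ALIASES = {
    "P1": "P 1", "P21": "P 1 21 1", "P212121": "P 21 21 21",
    "C2": "C 1 2 1", "P43212": "P 43 21 2", "P61": "P 61",
}

_AA20 = "ACDEFGHIKLMNPQRSTVWY"
_ONE2THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


@dataclass
class FixtureSpec:
    spacegroup_symbol: str = "P 1"
    chain_length: int = 24
    interface_target: str = "LARGE"     # NONE | SMALL (<600 Å²) | LARGE (>600 Å²)
    core_positions: tuple = ()
    conservation: Optional[list] = None  # per-position "CONSERVED"/"VARIABLE"
    n_homologs: int = 50
    identity_to_query: Optional[float] = None
    seed: int = 0

    def canonical_spacegroup(self) -> str:
        sym = _ALIASES.get(self.spacegroup_symbol.replace(" ", ""),
                           self.spacegroup_symbol)
        if sym not in SUPPORTED_SPACEGROUPS:
            raise ValueError(
                f"unsupported space group {self.spacegroup_symbol!r}; "
                f"supported: {sorted(SUPPORTED_SPACEGROUPS)}")
        return sym


@dataclass
class GroundTruthContact:
    chain_a: str
    chain_b: str
    operator: SymOperator
    fingerprint: str
    contacts: tuple       # sorted ((res_a, res_b), ...) mapped to reference
    is_infinite: bool


# ---------------------------------------------------------------------------
# blob construction

def _make_blob(n_residues: int, rng: np.random.Generator, sequence: str):
    """Compact self-avoiding chain of residue centres, three pseudo-atoms
    each (C/N/O radii), centred at the origin."""
    centers = [np.zeros(3)]
    while len(centers) < n_residues:
        prev = centers[-1]
        for _ in range(200):
            step = rng.normal(size=3)
            step *= 3.8 / np.linalg.norm(step)
            cand = prev + step
            # compactness bias: pull toward the centroid
            cand -= 0.15 * cand / max(1.0, np.linalg.norm(cand) / 6.0)
            ok = all(np.linalg.norm(cand - c) > 3.4 for c in centers[:-1])
            if ok:
                centers.append(cand)
                break
        else:  # restart the walk from a random neighbour of the centroid
            centers.append(prev + rng.normal(scale=2.0, size=3))
    centers = np.array(centers) - np.mean(centers, axis=0)

    residues = []
    serial = 0
    # six pseudo-atoms per residue in a tight cluster: roughly the heavy-atom
    # density of real protein, so a 1.4 Å probe cannot slip between residues
    atom_spec = (("C", "CA", 0.0), ("N", "N", 1.3), ("C", "C", 1.5),
                 ("O", "O", 1.8), ("C", "CB", 1.6), ("C", "CG", 2.4))
    for i, c in enumerate(centers):
        atoms = []
        dirs = rng.normal(size=(len(atom_spec), 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        for (el, nm, dist), u in zip(atom_spec, dirs):
            serial += 1
            atoms.append(Atom(serial, el, nm, i, c + dist * u, VDW_RADII[el]))
        residues.append(Residue(_ONE2THREE[sequence[i]], i + 1, atoms))
    return residues


def _random_sequence(n: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(_AA20)) for _ in range(n))


def _build_cell(sym: str, base: np.ndarray, scale) -> CrystalCell:
    """Cell for the group with per-axis (or scalar) scale applied to the
    base lengths; lattice-system constraints (a=b) enforced afterwards."""
    info = SUPPORTED_SPACEGROUPS[sym]
    a, b, c = base * np.broadcast_to(np.asarray(scale, float), (3,))
    kind = info["kind"]
    if kind == "tetragonal":
        a = b = min(a, b)
        return CrystalCell(a, b, c, 90, 90, 90)
    if kind == "hexagonal":
        a = b = min(a, b)
        return CrystalCell(a, b, c, 90, 90, 120)
    if kind == "monoclinic":
        return CrystalCell(a, b, c, 90, info["beta"], 90)
    return CrystalCell(a, b, c, 90, 90, 90)


def _structure_at_scale(sym: str, base, scale, residues, sequence,
                        entry_id, frac_center=(0.31, 0.27, 0.23)):
    cell = _build_cell(sym, base, scale)
    center = cell.orthogonalize(np.array(frac_center))
    chain_res = []
    serial = 0
    for r in residues:
        atoms = []
        for a in r.atoms:
            serial += 1
            atoms.append(Atom(serial, a.element, a.name, a.residue_index,
                              a.coords + center, a.vdw_radius))
        chain_res.append(Residue(r.name, r.seq_num, atoms))
    chain = ChainModel("A", sequence, chain_res)
    return CrystalStructure(
        entry_id=entry_id, chains=[chain], cell=cell,
        spacegroup_symbol=sym, operators=spacegroup_operators(sym),
        resolution=1.9, r_free=0.22,
    )


def _pair_ops(sym: str, infinite_only: bool) -> list:
    """Non-identity pair operators (base op x shifts in [-1,1]^3),
    optionally restricted to infinite-assembly ones."""
    ops = []
    for base_op in spacegroup_operators(sym):
        for shift in itertools.product((-1, 0, 1), repeat=3):
            op = base_op.with_shift(shift)
            if op.is_identity():
                continue
            if infinite_only and not is_infinite_by_iteration(op):
                continue
            ops.append(op)
    return ops


def _image_min_distance(structure: CrystalStructure, infinite_only: bool):
    """Minimum heavy-atom distance from the reference chain to any
    non-identity image (optionally infinite-operator images only)."""
    chain = structure.chains[0]
    cell = structure.cell
    ref = chain.coords()
    frac = cell.fractionalize(ref)
    best = np.inf
    for op in _pair_ops(structure.spacegroup_symbol, infinite_only):
        img = cell.orthogonalize(op.apply(frac))
        best = min(best, cdist(ref, img).min())
    return best


def bruteforce_interfaces(structure: CrystalStructure,
                          contact_distance: float = 5.9,
                          shift_range: Optional[int] = None) -> list:
    """Independent all-images all-pairs contact scan.

    Enumerates every chain image under every operator and cell shift in
    ``[-shift_range, shift_range]^3`` (default: one wider than any shift
    that could bring an image within contact range), collects residue-level
    contact sets by direct distance computation, and deduplicates congruent
    contact sets.  Infiniteness comes from the operator-iteration oracle,
    not from the geometric classifier.
    """
    chains = [c for c in structure.chains if c.is_protein]
    cell = structure.cell
    if shift_range is None:
        if cell is None:
            shift_range = 0
        else:
            diam = max((float(np.ptp(c.coords(), axis=0).max())
                        for c in chains if len(c.coords()) > 1), default=0.0)
            min_len = min(cell.a, cell.b, cell.c)
            shift_range = 1 + max(1, min(
                int(np.ceil((diam + contact_distance + 1.0) / min_len)), 5))
    out = {}
    order = {c.chain_id: i for i, c in enumerate(chains)}
    for ca in chains:
        ref = ca.coords()
        atoms_a = ca.heavy_atoms()
        for cb in chains:
            frac_b = cell.fractionalize(cb.coords()) if cell is not None else None
            atoms_b = cb.heavy_atoms()
            ops = structure.operators if cell is not None else [SymOperator()]
            shifts = (itertools.product(range(-shift_range, shift_range + 1), repeat=3)
                      if cell is not None else [(0, 0, 0)])
            for base_op, shift in itertools.product(ops, shifts):
                op = base_op.with_shift(shift)
                if op.is_identity():
                    if ca.chain_id == cb.chain_id:
                        continue
                    if order[ca.chain_id] > order[cb.chain_id]:
                        continue
                if cell is not None:
                    img = cell.orthogonalize(op.apply(frac_b))
                else:
                    img = cb.coords()
                d = cdist(ref, img)
                ia, jb = np.nonzero(d <= contact_distance)
                if len(ia) == 0:
                    continue
                contacts = sorted({(atoms_a[i].residue_index,
                                    atoms_b[j].residue_index)
                                   for i, j in zip(ia, jb)})
                pair = tuple(sorted((ca.chain_id, cb.chain_id)))
                if ca.chain_id <= cb.chain_id:
                    sig = (pair, tuple(contacts))
                else:
                    sig = (pair, tuple(sorted((b, a) for a, b in contacts)))
                if ca.chain_id == cb.chain_id:
                    sig = min(sig, (pair, tuple(sorted((b, a) for a, b in contacts))))
                if sig in out:
                    continue
                out[sig] = GroundTruthContact(
                    chain_a=ca.chain_id, chain_b=cb.chain_id, operator=op,
                    fingerprint=interface_fingerprint(ca.chain_id, cb.chain_id, op),
                    contacts=sig[1],
                    is_infinite=is_infinite_by_iteration(op),
                )
    return list(out.values())


def _choose_press_op(sym: str):
    """The lattice image a contact fixture is pressed against.

    Prefers a screw-axis image (the infinite-assembly workhorse of chiral
    space groups), falling back to a whole-cell or fractional translation
    in groups without one (P1, C2's centring).  Returns the operator and
    the axis mask along which the cell is compressed — the direction of
    the operator's net translational component.
    """
    from .symmetry import classify_operator

    candidates = []
    for op in _pair_ops(sym, infinite_only=True):
        cls = classify_operator(op)
        shift_norm = sum(abs(v) for v in op.cell_shift)
        candidates.append((op, cls, shift_norm))
    if not candidates:
        raise ValueError(f"{sym}: no infinite-assembly operator available")
    # best: a screw with the smallest added cell shift and the tightest
    # pitch (closest consecutive images along the axis)
    def pitch(cls):
        w = cls.screw_component if cls.code.endswith("S") else None
        return float(np.linalg.norm(w)) if w is not None else 10.0
    candidates.sort(key=lambda t: (not t[1].code.endswith("S"), t[2],
                                   pitch(t[1]), t[1].fold))
    op, cls = candidates[0][0], candidates[0][1]
    t = np.abs(np.asarray(cls.screw_component)
               if cls.code.endswith("S") else op.total_translation)
    mask = (t > 1e-6).astype(float)
    if mask.sum() == 0:  # pragma: no cover - defensive
        mask = np.array([1.0, 0.0, 0.0])
    return op, mask, _press_center(op)


def _press_center(op: SymOperator) -> np.ndarray:
    """Fractional position for the blob centroid: on the rotation axis of a
    screw press operator (so consecutive images stack coaxially along the
    axis instead of swinging away laterally), anywhere for a translation."""
    r = op.rot_matrix
    if np.allclose(r, np.eye(3)):
        return np.array([0.31, 0.27, 0.23])
    t = op.total_translation
    n = {-1: 2, 0: 3, 1: 4, 2: 6}[round(np.trace(r))]
    acc = np.zeros(3)
    p = np.eye(3)
    for _ in range(n):
        acc += p @ t
        p = r @ p
    w = acc / n                      # intrinsic (screw) part, along the axis
    t_perp = t - w
    center = np.linalg.lstsq(np.eye(3) - r, t_perp, rcond=None)[0]
    center -= np.floor(center)       # an equivalent axis inside the cell
    axis_idx = int(np.argmax(np.abs(w)))
    center[axis_idx] = 0.27          # generic position along the axis
    return center


def _calibrate_scale(sym, base, residues, depth, press_op, mask,
                     frac_center):
    """Bisect the cell scale along the masked axes so the pressed image
    sits at the requested surface separation ``depth`` (Å; may be negative
    for interpenetration of the pseudo-atom blobs)."""
    blob = np.array([a.coords for r in residues for a in r.atoms
                     if a.element != "H"])
    radii = np.array([a.vdw_radius for r in residues for a in r.atoms
                      if a.element != "H"])
    rsum = radii[:, None] + radii[None, :]

    def f(s):
        # clearance between van der Waals surfaces: negative = interpenetration
        cell = _build_cell(sym, base, 1.0 + (s - 1.0) * mask)
        ref = blob + cell.orthogonalize(frac_center)
        frac = cell.fractionalize(ref)
        img = cell.orthogonalize(press_op.apply(frac))
        return float((cdist(ref, img) - rsum).min())

    lo, hi = 0.15, 4.0
    for _ in range(8):
        if f(hi) > depth:
            break
        hi *= 1.5
    for _ in range(24):
        mid = 0.5 * (lo + hi)
        if f(mid) < depth:
            lo = mid
        else:
            hi = mid
        if hi - lo < 2e-3:
            break
    return 0.5 * (lo + hi)


def make_crystal_fixture(spec: FixtureSpec):
    """Build a toy crystal and its brute-force ground truth.

    Returns ``(structure, ground_truth)`` where ground truth is the list of
    :class:`GroundTruthContact` from :func:`bruteforce_interfaces`.
    Deterministic given ``spec.seed``.
    """
    from .interfaces import find_interfaces

    sym = spec.canonical_spacegroup()
    rng = np.random.default_rng(spec.seed)
    sequence = _random_sequence(spec.chain_length, rng)
    residues = _make_blob(spec.chain_length, rng, sequence)
    entry_id = f"FX{spec.seed:04d}"

    target = spec.interface_target.upper()
    if target == "NONE":
        coords = np.array([a.coords for r in residues for a in r.atoms])
        base = np.ptp(coords, axis=0).max() + 8.0 + np.zeros(3)
        st = _structure_at_scale(sym, base, 3.0, residues, sequence, entry_id)
        if _image_min_distance(st, False) < 12.0:  # pragma: no cover
            st = _structure_at_scale(sym, base, 5.0, residues, sequence, entry_id)
        return st, bruteforce_interfaces(st)

    press_op, mask, frac_center = _choose_press_op(sym)
    # flatten the blob perpendicular to the press axis: a disc pressed
    # face-on buries a wide patch, giving controllable interface sizes
    axis = int(np.argmax(mask))
    # lateral spread plus a smooth clamp along the press axis: the blob
    # becomes a slab with flat faces, so face-on stacking buries a wide,
    # controllable patch
    half_thickness = 3.2
    for r in residues:
        for a in r.atoms:
            c = a.coords * 1.1
            c[axis] = half_thickness * np.tanh(a.coords[axis] / half_thickness)
            a.coords = c
    coords = np.array([a.coords for r in residues for a in r.atoms])
    diam = float(np.ptp(coords, axis=0).max())
    base = np.array([diam, diam, diam]) + 8.0

    if target == "LARGE":
        depth, area_lo, area_hi = -2.2, 600.0, np.inf
    elif target == "SMALL":
        depth, area_lo, area_hi = 1.2, 60.0, 600.0
    else:
        raise ValueError(f"unknown interface_target {spec.interface_target!r}")

    # clearance bisection cannot press past ~ -2 r_vdw (the closest pair
    # bottoms out); once the depth floor is reached, keep shrinking the
    # pressed axis directly until the interface reaches its size class
    st = None
    shrink = 1.0
    for _ in range(14):
        s = _calibrate_scale(sym, base, residues, max(depth, -3.0),
                             press_op, mask, frac_center)
        scale_vec = 1.0 + (s * shrink - 1.0) * mask
        st = _structure_at_scale(sym, base, scale_vec, residues, sequence,
                                 entry_id, frac_center)
        ifaces = find_interfaces(st)
        pool = [i for i in ifaces if i.operator_class.is_infinite]
        top = max((i.area for i in pool), default=0.0)
        if area_lo <= top < area_hi:
            break
        if top >= area_hi:
            if shrink < 1.0:
                shrink = min(1.0, shrink / 0.93)
            else:
                depth = min(depth + 0.5, 2.4)
        else:
            if depth <= -3.0:
                shrink = max(0.55, shrink * 0.93)
            else:
                depth -= 0.8
    return st, bruteforce_interfaces(st)


# ---------------------------------------------------------------------------
# alignments

def make_alignment_fixture(spec: FixtureSpec, sequence: Optional[str] = None,
                           n_variable_symbols: int = 4) -> Alignment:
    """Alignment with controlled per-column conservation.

    CONSERVED columns are identical across all rows; VARIABLE columns are
    drawn from a ``n_variable_symbols``-letter set containing the query
    symbol — uniformly when no identity target is set (entropy
    ``log2(n_variable_symbols)`` in the many-homolog limit), otherwise with
    the query-match probability solved from the requested identity.
    """
    rng = np.random.default_rng(spec.seed + 7919)
    if sequence is None:
        sequence = _random_sequence(spec.chain_length, rng)
    n = len(sequence)
    if spec.conservation is not None:
        conserved = [c.upper() == "CONSERVED" for c in spec.conservation]
        if len(conserved) != n:
            raise ValueError("conservation pattern length != sequence length")
    else:
        conserved = [i in set(spec.core_positions) for i in range(n)]

    frac_conserved = sum(conserved) / n
    if spec.identity_to_query is None:
        p_match = 1.0 / n_variable_symbols
    else:
        t = spec.identity_to_query
        if t < frac_conserved - 1e-9 or t > 1.0 + 1e-9:
            raise ValueError(
                f"identity target {t} infeasible: conserved positions "
                f"force identity in [{frac_conserved:.3f}, 1]")
        if frac_conserved >= 1.0 - 1e-12 or t >= 1.0 - 1e-12:
            p_match = 1.0
        else:
            p_match = (t - frac_conserved) / (1.0 - frac_conserved)

    # per-column symbol pools containing the query symbol
    pools = []
    for i, q in enumerate(sequence):
        others = [a for a in _AA20 if a != q]
        start = (spec.seed + i) % (len(others) - n_variable_symbols + 2)
        pools.append([q] + others[start:start + n_variable_symbols - 1])

    rows = [("query", sequence)]
    for h in range(spec.n_homologs):
        out = []
        for i, q in enumerate(sequence):
            if conserved[i]:
                out.append(q)
            elif spec.identity_to_query is None:
                out.append(pools[i][rng.integers(len(pools[i]))])
            else:
                if rng.random() < p_match:
                    out.append(q)
                else:
                    alt = pools[i][1:]
                    out.append(alt[rng.integers(len(alt))])
        rows.append((f"hom{h + 1}", "".join(out)))

    q_cols = range(n)
    identities = [sum(1 for i in q_cols if seq[i] == sequence[i]) / n
                  for _, seq in rows[1:]]
    return Alignment("query", rows, identities)


# ---------------------------------------------------------------------------
# end-to-end classification cases

def make_classification_case(kind: str, seed: int, chain_length: int = 38,
                             n_homologs: int = 50):
    """A full pipeline smoke case with a known expected consensus.

    ``kind='bio'``: a dimer whose second chain is molded onto a face patch
    of the first — every accessible surface point of the patch residues is
    capped by a partner atom, so the patch is deeply buried (a large,
    tightly packed interface core) and its alignment columns are conserved
    while the rest of the surface stays variable: the statistical signature
    of a biological interface.

    ``kind='xtal'``: a single chain contacting its lattice images through
    an infinite-assembly operator with a small, evolutionarily anonymous
    interface.  Returns ``(structure, alignments dict, expected call)``.
    """
    from .interfaces import (CORE_THRESHOLD_EVOLUTION, Region,
                             fibonacci_sphere, find_interfaces)

    rng = np.random.default_rng(seed)

    if kind == "xtal":
        chain_length = min(chain_length, 28)  # small anonymous contact
        spec = FixtureSpec(spacegroup_symbol="P 1 21 1",
                           chain_length=chain_length,
                           interface_target="SMALL", seed=seed,
                           n_homologs=n_homologs)
        st, _ = make_crystal_fixture(spec)
        # keep geometry on the crystal side of the core-count boundary
        ifaces = find_interfaces(st)
        for _ in range(8):
            if not ifaces or max(i.core_count(0.95) for i in ifaces) < 6:
                break
            spec = FixtureSpec(spacegroup_symbol="P 1 21 1",
                               chain_length=chain_length,
                               interface_target="SMALL", seed=seed + 100_003,
                               n_homologs=n_homologs)
            st, _ = make_crystal_fixture(spec)
            ifaces = find_interfaces(st)
            seed += 100_003
        aln = make_alignment_fixture(
            FixtureSpec(chain_length=chain_length, seed=seed,
                        n_homologs=n_homologs, identity_to_query=0.68),
            sequence=st.chains[0].sequence)
        return st, {"A": aln}, "XTAL"

    if kind != "bio":
        raise ValueError("kind must be 'bio' or 'xtal'")

    sequence = _random_sequence(chain_length, rng)
    residues = _make_blob(chain_length, rng, sequence)
    atoms_a = [a for r in residues for a in r.atoms]
    coords = np.array([a.coords for a in atoms_a])
    radii = np.array([a.vdw_radius for a in atoms_a])
    probe = 1.4

    # interface patch: the 8 surface residues closest to the +x-most one
    centers = np.array([np.mean([a.coords for a in r.atoms], axis=0)
                        for r in residues])
    anchor = int(np.argmax(centers[:, 0]))
    order = np.argsort(np.linalg.norm(centers - centers[anchor], axis=1))
    patch = set(int(i) for i in order[:8])

    # accessible points of the patch atoms (coarse rolling-probe scan)
    sphere = fibonacci_sphere(92)
    shell_pts = []
    for idx, a in enumerate(atoms_a):
        if a.residue_index not in patch:
            continue
        pts = a.coords + (a.vdw_radius + probe) * sphere
        d2 = ((pts[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
        exp2 = (radii + probe) ** 2
        d2[:, idx] = np.inf
        acc = pts[(d2 >= exp2[None, :]).all(axis=1)]
        for p in acc:
            shell_pts.append((p, a.coords, a.vdw_radius))

    # mold the partner: one atom just beyond each accessible probe site,
    # subsampled so neighbouring cap atoms overlap and seal the surface
    cap_positions = []
    for p, ac, rv in shell_pts:
        if any(np.linalg.norm(p - q) < 2.0 for q in cap_positions):
            continue
        u = (p - ac) / np.linalg.norm(p - ac)
        cap_positions.append(ac + (rv + probe + 0.3) * u)
    if len(cap_positions) < 36:  # partner cap must give several residues
        raise ValueError("patch too small to mold a partner chain")

    # graft a body blob onto the outer side of the cap so the partner has
    # genuine surface residues (the core-surface indicator samples them)
    n_cap_res = len(cap_positions) // 6
    cap_used = np.array(cap_positions[:6 * n_cap_res])
    body_len = 20
    seq_body = _random_sequence(body_len, rng)
    body_res = _make_blob(body_len, rng, seq_body)
    body_local = np.array([a.coords for r in body_res for a in r.atoms])
    body_radii = np.array([a.vdw_radius for r in body_res for a in r.atoms])
    existing = np.vstack([coords, cap_used])
    existing_r = np.concatenate([radii, np.full(len(cap_used), VDW_RADII["C"])])
    u = cap_used.mean(axis=0) - coords.mean(axis=0)
    u /= np.linalg.norm(u)
    rsum_body = body_radii[:, None] + existing_r[None, :]
    lo_t, hi_t = 0.0, 80.0
    for _ in range(40):
        mid = 0.5 * (lo_t + hi_t)
        gap = (cdist(body_local + cap_used.mean(axis=0) + mid * u, existing)
               - rsum_body).min()
        if gap < -0.3:
            lo_t = mid
        else:
            hi_t = mid
    body_shift = cap_used.mean(axis=0) + 0.5 * (lo_t + hi_t) * u

    cell_size = float(np.ptp(coords, axis=0).max()) + 90.0
    cell = CrystalCell(cell_size, cell_size, cell_size, 90, 90, 90)
    center = cell.orthogonalize(np.array([0.4, 0.4, 0.4]))

    res_a = [Residue(r.name, r.seq_num,
                     [Atom(a.serial, a.element, a.name, a.residue_index,
                           a.coords + center, a.vdw_radius) for a in r.atoms])
             for r in residues]
    seq_b = _random_sequence(n_cap_res, rng) + seq_body
    res_b = []
    for i in range(n_cap_res):
        chunk = cap_used[6 * i:6 * (i + 1)]
        res_b.append(Residue(_ONE2THREE[seq_b[i]], i + 1,
                             [Atom(2000 + 6 * i + j, "C", "CB", i, c + center,
                                   VDW_RADII["C"]) for j, c in enumerate(chunk)]))
    for k, r in enumerate(body_res):
        idx = n_cap_res + k
        res_b.append(Residue(r.name, idx + 1,
                             [Atom(3000 + 6 * k + j, a.element, a.name, idx,
                                   a.coords + body_shift + center, a.vdw_radius)
                              for j, a in enumerate(r.atoms)]))
    st = CrystalStructure(
        entry_id=f"BI{seed:04d}",
        chains=[ChainModel("A", sequence, res_a),
                ChainModel("B", seq_b, res_b)],
        cell=cell, spacegroup_symbol="P 1",
        operators=spacegroup_operators("P 1"),
        resolution=1.9, r_free=0.22)

    iface = find_interfaces(st)[0]
    regs = iface.regions(CORE_THRESHOLD_EVOLUTION)
    alignments = {}
    for chain, partner_key in ((st.chains[0], "A"), (st.chains[1], "B")):
        core_cols = [i for i, lab in enumerate(regs[partner_key])
                     if lab == Region.CORE]
        conservation = ["CONSERVED" if i in set(core_cols) else "VARIABLE"
                        for i in range(chain.n_residues)]
        alignments[chain.chain_id] = make_alignment_fixture(
            FixtureSpec(chain_length=chain.n_residues, seed=seed,
                        n_homologs=n_homologs, conservation=conservation,
                        identity_to_query=0.68),
            sequence=chain.sequence)
    return st, alignments, "BIO"


# ---------------------------------------------------------------------------
# file output

def write_fixture(structure: CrystalStructure, alignments: dict, outdir) -> dict:
    """Write the fixture as standard files: mmCIF plus one aligned FASTA per
    chain, so the whole pipeline can run from disk exactly as on real data.
    Returns the written paths."""
    import gemmi

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    st = gemmi.Structure()
    st.name = structure.entry_id
    cell = structure.cell
    if cell is not None:
        st.cell = gemmi.UnitCell(cell.a, cell.b, cell.c,
                                 cell.alpha, cell.beta, cell.gamma)
    st.spacegroup_hm = structure.spacegroup_symbol
    if structure.resolution is not None:
        st.resolution = structure.resolution
    model = gemmi.Model("1")
    for ch in structure.chains:
        gch = gemmi.Chain(ch.chain_id)
        for res in ch.residues:
            gr = gemmi.Residue()
            gr.name = res.name
            gr.seqid = gemmi.SeqId(res.seq_num, " ")
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.coords)
                ga.occ = 1.0
                ga.b_iso = 20.0
                gr.add_atom(ga)
            gch.add_residue(gr)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_mmcif_document()
    block = doc.sole_block()
    block.set_pair("_exptl.method", gemmi.cif.quote("X-RAY DIFFRACTION"))
    if structure.r_free is not None:
        block.set_pair("_refine.ls_R_factor_R_free", f"{structure.r_free:.4f}")
    if structure.resolution is not None:
        block.set_pair("_refine.ls_d_res_high", f"{structure.resolution:.2f}")
    cif_path = outdir / f"{structure.entry_id}.cif"
    doc.write_file(str(cif_path))

    paths = {"structure": cif_path}
    for chain_id, aln in (alignments or {}).items():
        fa = outdir / f"{structure.entry_id}_{chain_id}.fasta"
        with open(fa, "w") as fh:
            for rid, seq in aln.rows:
                fh.write(f">{rid}\n{seq}\n")
        paths[f"alignment_{chain_id}"] = fa
    return paths
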