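"""Crystallographic operator algebra and geometric classification.

A pair of chain copies in a crystal lattice is related by an affine operator
in the fractional basis: ``x' = R x + t + s`` with ``R`` the rotation part of
a space-group operator, ``t`` its intrinsic+location translation and ``s`` an
added whole-cell shift.  Classifying that operator geometrically tells us
whether iterating it closes into a finite assembly (point-group symmetry) or
marches off to infinity (translations and screw axes).  Interfaces generated
by the latter kind can only belong to the crystal lattice, never to a finite
biological oligomer — the classical open-symmetry argument.

Operator class codes follow the standard vocabulary:

======  =====================================================
code    meaning
======  =====================================================
AU      non-crystallographic pair (distinct chains in the AU)
XT      whole unit-cell translation
FT      fractional translation (centred lattices)
2,3,4,6 pure n-fold rotation axes
2S..6S  n-fold screw axes
-1      inversion centre
-4      four-fold rotoinversion
GL      glide plane (mirrors reported as zero-glide GL)
======  =====================================================

Whole and fractional translations and screw axes generate non-closed
(infinite) assemblies; everything else is closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import gemmi
import numpy as np

__all__ = [
    "SymOperator",
    "OperatorClass",
    "SymmetryError",
    "OperatorClassificationError",
    "compose",
    "classify_operator",
    "operator_fingerprint",
    "interface_fingerprint",
    "spacegroup_operators",
    "is_infinite_by_iteration",
    "INFINITE_CODES",
]

#: Codes whose generated assembly is non-closed.
INFINITE_CODES = frozenset({"XT", "FT", "2S", "3S", "4S", "6S"})

_TOL = 1e-6


class SymmetryError(ValueError):
    """Unknown space group or missing symmetry information."""


class OperatorClassificationError(ValueError):
    """Matrix is not a crystallographic operator in a supported setting."""


@dataclass(frozen=True)
class SymOperator:
    """Affine operator in the fractional basis.

    ``rot`` is a 3x3 matrix with entries in {-1, 0, 1} for the standard
    crystallographic settings used here, ``trans`` the translation part in
    fractional units and ``cell_shift`` an extra integral lattice translation
    (kept separate for bookkeeping; classification always uses the total
    translation ``trans + cell_shift``).
    """

    rot: tuple = field(default=((1, 0, 0), (0, 1, 0), (0, 0, 1)))
    trans: tuple = field(default=(0.0, 0.0, 0.0))
    cell_shift: tuple = field(default=(0, 0, 0))

    def __post_init__(self):
        rot = tuple(tuple(int(v) for v in row) for row in self.rot)
        object.__setattr__(self, "rot", rot)
        object.__setattr__(self, "trans", tuple(float(v) for v in self.trans))
        object.__setattr__(self, "cell_shift", tuple(int(v) for v in self.cell_shift))
        r = self.rot
        det = (r[0][0] * (r[1][1] * r[2][2] - r[1][2] * r[2][1])
               - r[0][1] * (r[1][0] * r[2][2] - r[1][2] * r[2][0])
               + r[0][2] * (r[1][0] * r[2][1] - r[1][1] * r[2][0]))
        if det not in (1, -1):
            raise OperatorClassificationError(f"det(rot) = {det}, expected +/-1")

    # -- array views ------------------------------------------------------
    @property
    def rot_matrix(self) -> np.ndarray:
        return np.asarray(self.rot, dtype=float)

    @property
    def trans_vector(self) -> np.ndarray:
        return np.asarray(self.trans, dtype=float)

    @property
    def total_translation(self) -> np.ndarray:
        return self.trans_vector + np.asarray(self.cell_shift, dtype=float)

    # -- algebra ----------------------------------------------------------
    def apply(self, frac_coords: np.ndarray) -> np.ndarray:
        """Apply to fractional coordinates (n x 3 or length-3)."""
        x = np.asarray(frac_coords, dtype=float)
        return x @ self.rot_matrix.T + self.total_translation

    def with_shift(self, shift) -> "SymOperator":
        s = np.asarray(self.cell_shift) + np.asarray(shift, dtype=int)
        return SymOperator(self.rot, self.trans, tuple(int(v) for v in s))

    def inverse(self) -> "SymOperator":
        rinv = np.rint(np.linalg.inv(self.rot_matrix)).astype(int)
        total = -(rinv @ self.total_translation)
        return _split(rinv, total)

    def is_identity(self, ignore_cell_shift: bool = False) -> bool:
        if self.rot != ((1, 0, 0), (0, 1, 0), (0, 0, 1)):
            return False
        if not ignore_cell_shift and self.cell_shift != (0, 0, 0):
            return False
        return all(abs(t) < _TOL for t in self.trans)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SymOperator({operator_fingerprint(self)!r})"


def _split(rot: np.ndarray, total: np.ndarray) -> SymOperator:
    """Split a total translation into a canonical [0,1) part plus cell shift."""
    shift = np.floor(total + _TOL).astype(int)
    frac = total - shift
    frac[np.abs(frac) < _TOL] = 0.0
    frac[np.abs(frac - 1.0) < _TOL] = 0.0
    return SymOperator(
        tuple(tuple(int(v) for v in row) for row in np.rint(rot).astype(int)),
        tuple(frac),
        tuple(int(v) for v in shift),
    )


def compose(op1: SymOperator, op2: SymOperator) -> SymOperator:
    """Composition ``op1 after op2``: (op1.op2)(x) = op1(op2(x)).

    The integral part of the combined translation is folded into
    ``cell_shift`` so the fractional part stays canonical in [0, 1).
    """
    rot = op1.rot_matrix @ op2.rot_matrix
    total = op1.rot_matrix @ op2.total_translation + op1.total_translation
    return _split(rot, total)


@dataclass(frozen=True)
class OperatorClass:
    """Geometric classification of a pair-relating operator."""

    code: str
    fold: int
    is_proper: bool
    screw_component: tuple
    is_infinite: bool
    anomalous: bool = False  # improper operators in protein crystals

    def __str__(self) -> str:
        return self.code


# trace -> fold for proper crystallographic rotations
_FOLD_FROM_TRACE = {3: 1, -1: 2, 0: 3, 1: 4, 2: 6}


def classify_operator(op: SymOperator, cell=None) -> OperatorClass:
    """Classify the operator relating two concrete chain copies.

    The decision uses the *total* translation (including the cell shift),
    because the same space-group coset element combined with different
    lattice shifts relates geometrically different pairs.  The intrinsic
    (screw) translation of a proper rotation is its translation averaged
    over the cyclic group, ``w = (1/n) sum_k R^k t``, i.e. the projection of
    ``t`` onto the rotation axis.  An operator is conducive to an infinite
    assembly exactly when its iteration never returns a copy to the start:
    translations, fractional translations, and any rotation with a non-zero
    intrinsic translation.

    ``cell`` is accepted for interface symmetry with callers that carry it;
    the classification is metric-independent in the fractional basis.
    """
    r = op.rot_matrix
    t = op.total_translation
    det = round(np.linalg.det(r))
    trace = round(np.trace(r))

    if det == 1:
        if trace not in _FOLD_FROM_TRACE:
            raise OperatorClassificationError(
                f"proper rotation with trace {trace} is not crystallographic"
            )
        n = _FOLD_FROM_TRACE[trace]
        if n == 1:
            if np.all(np.abs(t) < _TOL):
                return OperatorClass("AU", 1, True, (0.0, 0.0, 0.0), False)
            if np.all(np.abs(t - np.rint(t)) < _TOL):
                return OperatorClass("XT", 1, True, (0.0, 0.0, 0.0), True)
            return OperatorClass("FT", 1, True, (0.0, 0.0, 0.0), True)
        # intrinsic translation: average of R^k t over the cyclic group
        acc = np.zeros(3)
        p = np.eye(3)
        for _ in range(n):
            acc += p @ t
            p = r @ p
        w = acc / n
        if np.all(np.abs(w) < _TOL):
            return OperatorClass(str(n), n, True, (0.0, 0.0, 0.0), False)
        return OperatorClass(f"{n}S", n, True, tuple(w), True)

    # improper operators: only seen in racemic crystals; flagged anomalous
    if np.array_equal(np.rint(r).astype(int), -np.eye(3, dtype=int)):
        return OperatorClass("-1", 2, False, (0.0, 0.0, 0.0), False, anomalous=True)
    if trace == -1 and not np.allclose(r @ r, np.eye(3)):
        # -4 rotoinversion (order 4)
        return OperatorClass("-4", 4, False, (0.0, 0.0, 0.0), False, anomalous=True)
    if np.allclose(r @ r, np.eye(3)):
        # mirror or glide; intrinsic in-plane translation = (t + R t)/2
        w = (t + r @ t) / 2.0
        w[np.abs(w) < _TOL] = 0.0
        return OperatorClass("GL", 2, False, tuple(w), False, anomalous=True)
    raise OperatorClassificationError(
        "improper operator outside the supported code vocabulary "
        "(-3/-6 rotoinversions do not occur in protein crystals)"
    )


import functools


@functools.lru_cache(maxsize=65536)
def is_infinite_by_iteration(op: SymOperator, max_power: int = 12) -> bool:
    """Brute-force infiniteness oracle.

    An operator closes a finite assembly iff some power ``<= max_power``
    returns to the identity with zero net translation (crystallographic
    orders divide 12, so 12 suffices in any space-group setting).
    Independent of :func:`classify_operator`; used as a cross-check.
    """
    acc = op
    for _ in range(max_power):
        if acc.is_identity():
            return False
        acc = compose(op, acc)
    return True


# ---------------------------------------------------------------------------
# canonical text form

def _frac_str(x: float) -> str:
    f = Fraction(x).limit_denominator(24)
    if f == 0:
        return ""
    sign = "+" if f > 0 else "-"
    f = abs(f)
    return f"{sign}{f.numerator}/{f.denominator}" if f.denominator != 1 else f"{sign}{f.numerator}"


def operator_fingerprint(op: SymOperator) -> str:
    """Canonical triplet string, e.g. ``-x,y+1/2,-z|0,1,0``.

    Stable under equivalent numeric representations (translations are
    rendered as exact rationals with denominator <= 24, the finest used in
    standard space-group settings).  Used to match interfaces across tools
    and to deduplicate lattice pairs.
    """
    names = "xyz"
    rows = []
    for i in range(3):
        terms = ""
        for j in range(3):
            c = op.rot[i][j]
            if c == 1:
                terms += ("+" if terms else "") + names[j]
            elif c == -1:
                terms += "-" + names[j]
        terms += _frac_str(op.trans[i])
        rows.append(terms.lstrip("+") or "0")
    shift = ",".join(str(v) for v in op.cell_shift)
    return ",".join(rows) + "|" + shift


def interface_fingerprint(chain_a: str, chain_b: str, op: SymOperator) -> str:
    """Unordered fingerprint of a chain-pair relation.

    The pair (A, B, g) and its reversed view (B, A, g^-1) describe the same
    physical interface and map to the same string.
    """
    fwd = f"{chain_a}~{chain_b}~{operator_fingerprint(op)}"
    rev = f"{chain_b}~{chain_a}~{operator_fingerprint(op.inverse())}"
    return min(fwd, rev)


# ---------------------------------------------------------------------------
# space-group tables (resolved through gemmi's full 230-group table)

def from_gemmi_op(gop: "gemmi.Op") -> SymOperator:
    rot = tuple(tuple(v // gop.DEN for v in row) for row in gop.rot)
    trans = tuple(v / gop.DEN for v in gop.tran)
    return SymOperator(rot, trans)


def spacegroup_operators(symbol: str) -> list[SymOperator]:
    """Operators (including identity) of a space group given by symbol.

    Accepts Hermann-Mauguin names with or without spaces ("P 1 21 1",
    "P21", "P212121", ...).  Raises :class:`SymmetryError` for unknown
    symbols.
    """
    sg = gemmi.find_spacegroup_by_name(symbol)
    if sg is None:
        raise SymmetryError(f"unknown space-group symbol: {symbol!r}")
    ops = [from_gemmi_op(o) for o in sg.operations()]
    if not any(o.is_identity() for o in ops):  # pragma: no cover - gemmi always includes it
        raise SymmetryError(f"operator list for {symbol!r} lacks the identity")
    return ops
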