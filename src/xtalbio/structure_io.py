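"""Structure and alignment I/O: the package's data model.

Crystal structures come in as mmCIF or PDB (read through gemmi), multiple
sequence alignments as aligned FASTA (first record = query), and analyzed
interfaces go out as TSV or JSON reports.  Only protein polymer chains enter
interface analysis; waters and ligands are dropped from the chain model but
the raw gemmi structure is kept for provenance.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import gemmi
import numpy as np

from .symmetry import SymOperator, SymmetryError, from_gemmi_op, spacegroup_operators

__all__ = [
    "Atom",
    "Residue",
    "ChainModel",
    "CrystalCell",
    "CrystalStructure",
    "Alignment",
    "ExperimentalMethod",
    "StructureFormatError",
    "AlignmentError",
    "VDW_RADII",
    "read_structure",
    "read_alignment",
    "write_interface_report",
    "REPORT_COLUMNS",
]

#: Van der Waals radii (Å) per element; standard values, configurable at call
#: sites that take a radius table.
VDW_RADII = {
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "S": 1.80,
    "H": 1.20,
    "P": 1.80,
}
DEFAULT_VDW = 1.70

_AA3TO1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}


class StructureFormatError(ValueError):
    """File failed to parse under the named standard."""


class AlignmentError(ValueError):
    """Malformed alignment input."""


class ExperimentalMethod(str, Enum):
    XRAY = "XRAY"
    NMR = "NMR"
    OTHER = "OTHER"


@dataclass
class Atom:
    serial: int
    element: str
    name: str
    residue_index: int  # 0-based into the parent chain
    coords: np.ndarray  # (3,) Å, orthogonal frame
    vdw_radius: float

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite atom coordinates")
        if self.vdw_radius <= 0:
            raise ValueError("vdw_radius must be positive")


@dataclass
class Residue:
    name: str       # 3-letter code
    seq_num: int    # author sequence number
    atoms: list


@dataclass
class ChainModel:
    chain_id: str
    sequence: str
    residues: list
    is_protein: bool = True

    def __post_init__(self):
        if len(self.sequence) != len(self.residues):
            raise ValueError("sequence length must equal residue count")

    @property
    def n_residues(self) -> int:
        return len(self.residues)

    def heavy_atoms(self) -> list:
        return [a for r in self.residues for a in r.atoms if a.element != "H"]

    def coords(self, heavy_only: bool = True) -> np.ndarray:
        atoms = self.heavy_atoms() if heavy_only else [a for r in self.residues for a in r.atoms]
        return np.array([a.coords for a in atoms]).reshape(-1, 3)


@dataclass
class CrystalCell:
    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self):
        if min(self.a, self.b, self.c) <= 0:
            raise ValueError("cell lengths must be positive")
        if not all(0 < x < 180 for x in (self.alpha, self.beta, self.gamma)):
            raise ValueError("cell angles must lie in (0, 180)")
        cell = gemmi.UnitCell(self.a, self.b, self.c, self.alpha, self.beta, self.gamma)
        self.orth_matrix = np.array(cell.orth.mat.tolist())
        self.frac_matrix = np.array(cell.frac.mat.tolist())

    def orthogonalize(self, frac: np.ndarray) -> np.ndarray:
        return np.asarray(frac, float) @ self.orth_matrix.T

    def fractionalize(self, orth: np.ndarray) -> np.ndarray:
        return np.asarray(orth, float) @ self.frac_matrix.T


@dataclass
class CrystalStructure:
    entry_id: str
    chains: list
    cell: Optional[CrystalCell]
    spacegroup_symbol: str
    operators: list
    resolution: Optional[float] = None
    r_free: Optional[float] = None
    experimental_method: ExperimentalMethod = ExperimentalMethod.XRAY
    author_biounit: Optional[list] = None  # [(chain_id, SymOperator), ...]

    def __post_init__(self):
        if not self.operators:
            raise SymmetryError("operator list must include at least the identity")
        if not any(op.is_identity() for op in self.operators):
            raise SymmetryError("operator list lacks the identity")

    def protein_chains(self, min_length: int = 10) -> list:
        return [c for c in self.chains if c.is_protein and c.n_residues >= min_length]

    def get_chain(self, chain_id: str) -> ChainModel:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(chain_id)


@dataclass
class Alignment:
    """Aligned FASTA content; first row is the query."""

    query_id: str
    rows: list  # [(id, aligned_sequence), ...] query first
    identity_to_query: list  # per non-query row, fraction

    @property
    def query_seq(self) -> str:
        return self.rows[0][1]

    @property
    def n_homologs(self) -> int:
        return len(self.rows) - 1

    def ungapped_query(self) -> str:
        return self.query_seq.replace("-", "").replace(".", "")


# ---------------------------------------------------------------------------
# structure reading

def _one_letter(resname: str) -> str:
    return _AA3TO1.get(resname.upper(), "X")


def _is_amino(resname: str) -> bool:
    return resname.upper() in _AA3TO1


def _chain_from_gemmi(chain: "gemmi.Chain") -> Optional[ChainModel]:
    residues = []
    serial = 0
    n_amino = 0
    for res in chain:
        if res.is_water():
            continue
        atoms = []
        for at in res:
            serial += 1
            el = at.element.name if at.element.name else "C"
            atoms.append(Atom(
                serial=serial,
                element=el,
                name=at.name,
                residue_index=len(residues),
                coords=np.array([at.pos.x, at.pos.y, at.pos.z]),
                vdw_radius=VDW_RADII.get(el, DEFAULT_VDW),
            ))
        if not atoms:
            continue  # zero-atom residues dropped
        residues.append(Residue(res.name, res.seqid.num, atoms))
        if _is_amino(res.name):
            n_amino += 1
    if not residues:
        return None
    seq = "".join(_one_letter(r.name) for r in residues)
    is_protein = n_amino >= max(1, len(residues) // 2)
    if not is_protein:
        seq = "X" * len(residues)
    return ChainModel(chain.name, seq, residues, is_protein=is_protein)


def _cif_scalar(block: "gemmi.cif.Block", tag: str) -> Optional[str]:
    v = block.find_value(tag)
    if v is None or v in ("?", "."):
        return None
    return gemmi.cif.as_string(v)


def _parse_method(text: Optional[str]) -> ExperimentalMethod:
    if not text:
        return ExperimentalMethod.XRAY
    t = text.upper()
    if "NMR" in t:
        return ExperimentalMethod.NMR
    if "X-RAY" in t or "XRAY" in t:
        return ExperimentalMethod.XRAY
    return ExperimentalMethod.OTHER


def _transform_to_fractional(tr: "gemmi.Transform", cell: Optional[CrystalCell]):
    """Best-effort conversion of an orthogonal-frame assembly operator to a
    fractional :class:`SymOperator`; returns None for non-crystallographic
    matrices (kept out of the biounit operator list)."""
    mat = np.array(tr.mat.tolist())
    vec = np.array(tr.vec.tolist())
    if np.allclose(mat, np.eye(3), atol=1e-4) and np.allclose(vec, 0, atol=1e-4):
        return SymOperator()
    if cell is None:
        return None
    rot = cell.frac_matrix @ mat @ cell.orth_matrix
    trans = cell.frac_matrix @ vec
    rot_i = np.rint(rot)
    if not np.allclose(rot, rot_i, atol=1e-4) or np.any(np.abs(rot_i) > 1):
        return None
    try:
        return SymOperator(tuple(tuple(int(v) for v in row) for row in rot_i),
                           tuple(trans))
    except ValueError:
        return None


def read_structure(path, fmt: str = "auto") -> CrystalStructure:
    """Read an mmCIF or PDB file into a :class:`CrystalStructure`.

    Space-group operators are taken from the file's symbol via the standard
    230-group table; an unknown symbol raises :class:`SymmetryError`.
    Resolution, free R-factor and experimental method are read when present
    (``_refine.ls_R_factor_R_free`` etc. in mmCIF, REMARK/EXPDTA in PDB).
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "auto":
        fmt = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if fmt == "mmcif":
            doc = gemmi.cif.read(str(path))
            block = doc.sole_block()
            st = gemmi.make_structure_from_block(block)
        elif fmt == "pdb":
            block = None
            st = gemmi.read_pdb(str(path))
        else:
            raise ValueError(f"unknown format {fmt!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"cannot parse {path}: {exc}") from exc

    st.setup_entities()
    if len(st) == 0:
        raise StructureFormatError(f"{path}: no models")

    chains = []
    for ch in st[0]:
        cm = _chain_from_gemmi(ch)
        if cm is not None:
            chains.append(cm)

    r_free = None
    method_text = None
    resolution_text = None
    if block is not None:
        rf = _cif_scalar(block, "_refine.ls_R_factor_R_free")
        r_free = float(rf) if rf is not None else None
        method_text = _cif_scalar(block, "_exptl.method")
        resolution_text = (_cif_scalar(block, "_refine.ls_d_res_high")
                           or _cif_scalar(block, "_reflns.d_resolution_high"))
    else:
        text = path.read_text(errors="replace")
        for line in text.splitlines():
            if line.startswith("EXPDTA"):
                method_text = line[6:].strip()
            if line.startswith("REMARK   3") and "FREE R VALUE" in line and ":" in line \
                    and "ERROR" not in line and "SET" not in line:
                tail = line.split(":", 1)[1].strip()
                try:
                    r_free = float(tail)
                except ValueError:
                    pass
    method = _parse_method(method_text)

    if resolution_text is not None:
        resolution = float(resolution_text)
    else:
        resolution = (float(st.resolution)
                      if st.resolution and st.resolution > 0 else None)

    if method == ExperimentalMethod.NMR or not st.cell.is_crystal():
        cell = None
        operators = [SymOperator()]
        sg_symbol = st.spacegroup_hm or "P 1"
    else:
        c = st.cell
        cell = CrystalCell(c.a, c.b, c.c, c.alpha, c.beta, c.gamma)
        sg_symbol = st.spacegroup_hm or "P 1"
        operators = spacegroup_operators(sg_symbol)

    author_biounit = None
    if len(st.assemblies) > 0:
        asm = st.assemblies[0]
        pairs = []
        for gen in asm.generators:
            names = list(gen.chains) or [c.chain_id for c in chains]
            for opx in gen.operators:
                sym = _transform_to_fractional(opx.transform, cell)
                if sym is None:
                    continue
                for nm in names:
                    pairs.append((nm, sym))
        author_biounit = pairs or None

    return CrystalStructure(
        entry_id=st.name or path.stem,
        chains=chains,
        cell=cell,
        spacegroup_symbol=sg_symbol,
        operators=operators,
        resolution=resolution,
        r_free=r_free,
        experimental_method=method,
        author_biounit=author_biounit,
    )


# ---------------------------------------------------------------------------
# alignment reading

def read_alignment(path) -> Alignment:
    """Read an aligned FASTA; the first record is the query.

    Per-row identity to the query is computed over columns where the query
    has a residue (gap columns in the query are ignored; a homolog gap at a
    query residue counts as a mismatch).
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise AlignmentError(f"{path}: empty alignment")
    rows = [(r.id, str(r.seq).upper()) for r in records]
    length = len(rows[0][1])
    for rid, seq in rows:
        if len(seq) != length:
            raise AlignmentError(f"{path}: row {rid} has length {len(seq)} != {length}")
    query = rows[0][1]
    q_cols = [i for i, ch in enumerate(query) if ch not in "-."]
    if not q_cols:
        raise AlignmentError(f"{path}: query row is all gaps")
    identities = []
    for _, seq in rows[1:]:
        matches = sum(1 for i in q_cols if seq[i] == query[i])
        identities.append(matches / len(q_cols))
    return Alignment(query_id=rows[0][0], rows=rows, identity_to_query=identities)


# ---------------------------------------------------------------------------
# report writing

REPORT_COLUMNS = [
    "interface_id", "chain_a", "chain_b", "operator", "operator_class",
    "area", "n_core_geom", "core_rim_ratio", "core_surface_score",
    "call_geometry", "call_corerim", "call_coresurface", "consensus", "robust",
]


def _call_record(call) -> dict:
    def fmt(x):
        if x is None:
            return ""
        if isinstance(x, float):
            return round(x, 4) if math.isfinite(x) else ""
        return x
    return {k: fmt(getattr(call, k)) for k in REPORT_COLUMNS}


def write_interface_report(calls: list, path, fmt: str = "tsv") -> None:
    """Write one row per analyzed interface as TSV or JSON."""
    import pandas as pd

    records = [_call_record(c) for c in calls]
    path = Path(path)
    if fmt.lower() == "tsv":
        df = pd.DataFrame(records, columns=REPORT_COLUMNS)
        df.to_csv(path, sep="\t", index=False)
    elif fmt.lower() == "json":
        path.write_text(json.dumps(records, indent=1))
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_interface_report(path, fmt: str = "auto") -> list:
    """Read a report back as a list of dicts (round-trip of the writer)."""
    import pandas as pd

    path = Path(path)
    if fmt == "auto":
        fmt = "json" if path.suffix.lower() == ".json" else "tsv"
    if fmt == "json":
        return json.loads(path.read_text())
    df = pd.read_csv(path, sep="\t")
    return df.to_dict(orient="records")
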