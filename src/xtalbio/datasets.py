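"""Automatic benchmark-set construction for interface classification.

Two complementary label sources give large benchmark sets without manual
curation:

* **BioMany** (biological interfaces): interfaces preserved across many
  crystal forms (appearing in >= 10 forms and in >= 80% of the known forms
  of a cluster), plus dimer interfaces validated by solution NMR and mapped
  onto X-ray entries (resolution < 2.5 Å, area >= 500 Å²).  Interfaces
  larger than 2,000 Å² are dropped to keep the difficult-to-classify range.
* **XtalMany** (crystal contacts): homomeric interfaces generated by screw
  axes or translations, which can only propagate infinite, non-closed
  assemblies; filtered to resolution < 2.5 Å and area >= 600 Å², excluding
  entries whose author biological unit declares helical symmetry.

Both sets are made non-redundant by greedy single-linkage sequence
clustering at 80% identity, one representative per cluster.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .symmetry import INFINITE_CODES

__all__ = [
    "InterfaceRecord",
    "DatasetLabel",
    "Provenance",
    "cluster_sequences",
    "build_biomany",
    "build_xtalmany",
    "area_probability_curve",
    "read_records_tsv",
    "write_records_tsv",
    "write_labels_tsv",
    "BIOMANY_MIN_FORMS",
    "BIOMANY_MIN_FRACTION",
    "BIOMANY_NMR_MIN_AREA",
    "BIOMANY_MAX_AREA",
    "XTALMANY_MIN_AREA",
    "MAX_RESOLUTION",
    "CLUSTER_IDENTITY",
]

BIOMANY_MIN_FORMS = 10       # crystal forms an interface must appear in
BIOMANY_MIN_FRACTION = 0.80  # fraction of known forms it must be present in
BIOMANY_NMR_MIN_AREA = 500.0  # Å², NMR-branch lower area bound
BIOMANY_MAX_AREA = 2000.0    # Å², upper bound keeping the hard range
XTALMANY_MIN_AREA = 600.0    # Å², trivially small contacts excluded
MAX_RESOLUTION = 2.5         # Å, strictly better required (both sets)
CLUSTER_IDENTITY = 0.80      # sequence-identity cutoff for redundancy removal


class Provenance(str, Enum):
    PROTCID = "PROTCID"   # preserved across crystal forms
    NMR = "NMR"           # NMR dimer mapped to X-ray
    INFINITE = "INFINITE"  # screw/translation operator


@dataclass
class InterfaceRecord:
    """One interface's tabular metadata used by the dataset filters."""

    entry_id: str
    interface_id: int
    sequence_a: str
    sequence_b: str
    area: float
    operator_code: str          # operator-class code (AU, XT, 2S, ...)
    resolution: Optional[float]
    method: str = "XRAY"
    crystal_form_id: str = ""
    protcid_cluster_id: Optional[str] = None
    n_crystal_forms_in_cluster: int = 0
    fraction_forms_present: float = 0.0
    biounit_symmetry: str = ""
    nmr_matched: bool = False

    def __post_init__(self):
        if not 0.0 <= self.fraction_forms_present <= 1.0:
            raise ValueError("fraction_forms_present must lie in [0, 1]")
        if self.area < 0:
            raise ValueError("area must be non-negative")

    @property
    def is_infinite(self) -> bool:
        return self.operator_code in INFINITE_CODES

    @property
    def key(self):
        return (self.entry_id, self.interface_id)


@dataclass
class DatasetLabel:
    record: InterfaceRecord
    label: str                 # "BIO" or "XTAL"
    provenance: Provenance
    cluster_representative: bool = True


# ---------------------------------------------------------------------------
# sequence clustering (stand-in for BLASTClust with the same cutoff semantics)

def _pair_identity(s1: str, s2: str, aligner=None) -> float:
    """Global-alignment identity: matches / min(len1, len2)."""
    if not s1 or not s2:
        return 0.0
    if s1 == s2:
        return 1.0
    if aligner is None:
        aligner = _make_aligner()
    aln = aligner.align(s1, s2)[0]
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        matches += sum(1 for x, y in zip(s1[a0:a1], s2[b0:b1]) if x == y)
    return matches / min(len(s1), len(s2))


def _make_aligner():
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = 0
    aligner.open_gap_score = -1
    aligner.extend_gap_score = -0.5
    return aligner


def _record_identity(r1: InterfaceRecord, r2: InterfaceRecord, aligner) -> float:
    """Interface-level similarity: best pairing of the two partner chains,
    taking the weaker of the matched partners."""
    straight = min(_pair_identity(r1.sequence_a, r2.sequence_a, aligner),
                   _pair_identity(r1.sequence_b, r2.sequence_b, aligner))
    crossed = min(_pair_identity(r1.sequence_a, r2.sequence_b, aligner),
                  _pair_identity(r1.sequence_b, r2.sequence_a, aligner))
    return max(straight, crossed)


def cluster_sequences(records: list, identity_cutoff: float = CLUSTER_IDENTITY):
    """Greedy single-linkage clustering of interface records by sequence.

    Records whose pairwise identity reaches the cutoff share a cluster
    (transitively).  Returns (cluster_index per record, representative flag
    per record); the representative is the record with the longest combined
    sequence, ties broken by lexicographic entry id.
    """
    n = len(records)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    aligner = _make_aligner()
    for i in range(n):
        for j in range(i + 1, n):
            if find(i) == find(j):
                continue
            if _record_identity(records[i], records[j], aligner) >= identity_cutoff:
                parent[find(j)] = find(i)

    roots = {}
    assignment = []
    for i in range(n):
        r = find(i)
        roots.setdefault(r, len(roots))
        assignment.append(roots[r])

    representative = [False] * n
    for cl in set(assignment):
        members = [i for i in range(n) if assignment[i] == cl]
        best = min(members, key=lambda i: (
            -(len(records[i].sequence_a) + len(records[i].sequence_b)),
            records[i].entry_id, records[i].interface_id))
        representative[best] = True
    return assignment, representative


# ---------------------------------------------------------------------------
# dataset builders

def build_biomany(records: list,
                  min_forms: int = BIOMANY_MIN_FORMS,
                  min_fraction: float = BIOMANY_MIN_FRACTION,
                  nmr_min_resolution: float = MAX_RESOLUTION,
                  nmr_min_area: float = BIOMANY_NMR_MIN_AREA,
                  max_area: float = BIOMANY_MAX_AREA,
                  identity_cutoff: float = CLUSTER_IDENTITY) -> list:
    """Biological-interface benchmark labels.

    Crystal-form branch: interfaces present in >= ``min_forms`` crystal
    forms and in >= ``min_fraction`` of the forms known for their cluster.
    NMR branch: NMR-dimer-matched X-ray interfaces with resolution <
    ``nmr_min_resolution`` and area >= ``nmr_min_area``.  The union is
    capped at ``max_area``, clustered, and labelled BIO.
    """
    selected = {}
    for r in records:
        if (r.protcid_cluster_id is not None
                and r.n_crystal_forms_in_cluster >= min_forms
                and r.fraction_forms_present >= min_fraction):
            selected.setdefault(r.key, (r, Provenance.PROTCID))
    for r in records:
        if (r.nmr_matched and r.resolution is not None
                and r.resolution < nmr_min_resolution
                and r.area >= nmr_min_area):
            selected.setdefault(r.key, (r, Provenance.NMR))

    survivors = [(r, prov) for r, prov in selected.values() if r.area <= max_area]
    if not survivors:
        return []
    recs = [r for r, _ in survivors]
    _, reps = cluster_sequences(recs, identity_cutoff)
    return [DatasetLabel(r, "BIO", prov, rep)
            for (r, prov), rep in zip(survivors, reps)]


def build_xtalmany(records: list,
                   min_area: float = XTALMANY_MIN_AREA,
                   max_resolution: float = MAX_RESOLUTION,
                   identity_cutoff: float = CLUSTER_IDENTITY) -> list:
    """Crystal-contact benchmark labels from infinite-assembly operators.

    Homomeric interfaces (the two partner sequences cluster together at the
    identity cutoff) produced by screw axes or translations, at resolution
    < ``max_resolution`` and area >= ``min_area``; entries whose biological
    unit declares helical symmetry are excluded (genuine fibres).
    """
    aligner = _make_aligner()
    survivors = []
    for r in records:
        if not r.is_infinite:
            continue
        if r.area < min_area:
            continue
        if r.resolution is None or r.resolution >= max_resolution:
            continue
        if r.biounit_symmetry.strip().lower() == "helical":
            continue
        if _pair_identity(r.sequence_a, r.sequence_b, aligner) < identity_cutoff:
            continue  # not homomeric
        survivors.append(r)
    if not survivors:
        return []
    _, reps = cluster_sequences(survivors, identity_cutoff)
    return [DatasetLabel(r, "XTAL", Provenance.INFINITE, rep)
            for r, rep in zip(survivors, reps)]


# ---------------------------------------------------------------------------
# statistics

def area_probability_curve(areas, bin_width: float = 100.0,
                           min_area: float = 0.0):
    """Normalized area-probability histogram of a set of interfaces.

    Returns (bin_edges, probabilities); bins are half-open [lo, hi) and the
    probabilities sum to one.  Used e.g. for the area distribution of
    infinite-assembly contacts, the lattice-contact reference curve.
    """
    areas = np.asarray([a for a in areas if a >= min_area], dtype=float)
    if areas.size == 0:
        raise ValueError("empty selection: no areas at or above min_area")
    hi = float(areas.max())
    n_bins = int(np.floor((hi - min_area) / bin_width)) + 1
    edges = min_area + bin_width * np.arange(n_bins + 1)
    counts, _ = np.histogram(areas, bins=edges)
    return edges, counts / counts.sum()


# ---------------------------------------------------------------------------
# tabular I/O

_RECORD_COLUMNS = [
    "entry_id", "interface_id", "sequence_a", "sequence_b", "area",
    "operator_code", "resolution", "method", "crystal_form_id",
    "protcid_cluster_id", "n_crystal_forms_in_cluster",
    "fraction_forms_present", "biounit_symmetry", "nmr_matched",
]


def write_records_tsv(records: list, path) -> None:
    rows = []
    for r in records:
        d = {c: getattr(r, c) for c in _RECORD_COLUMNS if c not in
             ("operator_code",)}
        d["operator_code"] = r.operator_code
        rows.append(d)
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(path, sep="\t", index=False)


def read_records_tsv(path) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"protcid_cluster_id": str,
                                            "crystal_form_id": str,
                                            "biounit_symmetry": str},
                     keep_default_na=True)
    records = []
    for _, row in df.iterrows():
        cluster = row.get("protcid_cluster_id")
        if pd.isna(cluster):
            cluster = None
        res = row.get("resolution")
        records.append(InterfaceRecord(
            entry_id=str(row["entry_id"]),
            interface_id=int(row["interface_id"]),
            sequence_a=str(row["sequence_a"]),
            sequence_b=str(row["sequence_b"]),
            area=float(row["area"]),
            operator_code=str(row["operator_code"]),
            resolution=None if pd.isna(res) else float(res),
            method=str(row.get("method", "XRAY")),
            crystal_form_id="" if pd.isna(row.get("crystal_form_id")) else str(row["crystal_form_id"]),
            protcid_cluster_id=cluster,
            n_crystal_forms_in_cluster=int(row.get("n_crystal_forms_in_cluster", 0)),
            fraction_forms_present=float(row.get("fraction_forms_present", 0.0)),
            biounit_symmetry="" if pd.isna(row.get("biounit_symmetry")) else str(row["biounit_symmetry"]),
            nmr_matched=bool(row.get("nmr_matched", False)),
        ))
    return records


def write_labels_tsv(labels: list, path) -> None:
    rows = [{
        "entry_id": lb.record.entry_id,
        "interface_id": lb.record.interface_id,
        "label": lb.label,
        "provenance": lb.provenance.value,
        "cluster_representative": lb.cluster_representative,
    } for lb in labels]
    pd.DataFrame(rows, columns=["entry_id", "interface_id", "label",
                                "provenance", "cluster_representative"]
                 ).to_csv(path, sep="\t", index=False)
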