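"""Comparing per-interface calls across methods and benchmark metrics.

Assembly-level predictions (e.g. from a thermodynamic stability estimator
like PISA, or from author biological-unit annotations) are reduced to
per-interface BIO/XTAL calls: unstable assemblies are discarded; an entry
left with only gray-region assemblies gets "no prediction" everywhere;
otherwise the largest stable assembly wins (first encountered on ties) and
its member interfaces — matched by crystallographic operator fingerprint —
are biological, all remaining interfaces crystal contacts.

Benchmark quality is summarized by the usual confusion-matrix statistics
with BIO as the positive class: sensitivity, specificity, accuracy and the
Matthews correlation coefficient
``MCC = (tp tn - fp fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn))``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .classifier import Call

__all__ = [
    "Stability",
    "Assembly",
    "AssemblyPrediction",
    "ConfusionMetrics",
    "assembly_to_interface_calls",
    "compare_calls",
    "confusion_metrics",
    "read_assembly_json",
    "read_pisa_xml",
]


class Stability(str, Enum):
    STABLE = "STABLE"
    GRAY = "GRAY"
    UNSTABLE = "UNSTABLE"


@dataclass
class Assembly:
    stability: Stability
    size: int                       # number of chains in the assembly
    member_interfaces: list         # operator fingerprints

    def __post_init__(self):
        if self.size < 1:
            raise ValueError("assembly size must be >= 1")


@dataclass
class AssemblyPrediction:
    entry_id: str
    assemblies: list


def assembly_to_interface_calls(pred: AssemblyPrediction,
                                interfaces: list) -> list:
    """Per-interface calls from an assembly list.

    ``interfaces`` is the package's interface list; matching uses each
    interface's unordered operator fingerprint.  Multiple copies of the
    same assembly (one per asymmetric-unit copy) merge naturally because
    congruent interfaces share a fingerprint.
    """
    if not pred.assemblies:
        return [Call.NOPRED] * len(interfaces)
    stable = [a for a in pred.assemblies if a.stability == Stability.STABLE]
    gray = [a for a in pred.assemblies if a.stability == Stability.GRAY]
    if not stable:
        if gray:
            return [Call.NOPRED] * len(interfaces)
        # only unstable assemblies: a monomer prediction, lattice contacts
        return [Call.XTAL] * len(interfaces)
    best = max(stable, key=lambda a: a.size)  # max() keeps the first on ties
    members = set(best.member_interfaces)
    calls = []
    for iface in interfaces:
        fp = getattr(iface, "fingerprint", None) or str(iface)
        calls.append(Call.BIO if fp in members else Call.XTAL)
    return calls


def compare_calls(calls_a: list, calls_b: list, areas: list,
                  bin_width: float = 200.0) -> pd.DataFrame:
    """Agreement between two call vectors as a function of interface area.

    Returns a table with one row per area bin: counts of (BIO,BIO),
    (XTAL,XTAL), (BIO,XTAL), (XTAL,BIO), pairs involving NOPRED, and the
    agreement fraction among both-predicted pairs.  A summary row labelled
    ``overall`` aggregates all bins.
    """
    if not (len(calls_a) == len(calls_b) == len(areas)):
        raise ValueError("call vectors and areas must have equal length")
    rows = []
    data = list(zip(calls_a, calls_b, areas))

    def tally(sub):
        both_bio = sum(1 for a, b, _ in sub if a == Call.BIO and b == Call.BIO)
        both_xtal = sum(1 for a, b, _ in sub if a == Call.XTAL and b == Call.XTAL)
        a_bio_b_xtal = sum(1 for a, b, _ in sub if a == Call.BIO and b == Call.XTAL)
        a_xtal_b_bio = sum(1 for a, b, _ in sub if a == Call.XTAL and b == Call.BIO)
        nopred = sum(1 for a, b, _ in sub if Call.NOPRED in (a, b))
        predicted = both_bio + both_xtal + a_bio_b_xtal + a_xtal_b_bio
        agreement = (both_bio + both_xtal) / predicted if predicted else math.nan
        return both_bio, both_xtal, a_bio_b_xtal, a_xtal_b_bio, nopred, agreement

    max_area = max(areas) if areas else 0.0
    n_bins = int(max_area // bin_width) + 1
    for k in range(n_bins):
        lo, hi = k * bin_width, (k + 1) * bin_width
        sub = [d for d in data if lo <= d[2] < hi]
        if not sub:
            continue
        bb, xx, bx, xb, np_, agr = tally(sub)
        rows.append({"bin_lo": lo, "bin_hi": hi, "n": len(sub),
                     "bio_bio": bb, "xtal_xtal": xx, "bio_xtal": bx,
                     "xtal_bio": xb, "nopred": np_, "agreement": agr})
    bb, xx, bx, xb, np_, agr = tally(data)
    rows.append({"bin_lo": 0.0, "bin_hi": math.inf, "n": len(data),
                 "bio_bio": bb, "xtal_xtal": xx, "bio_xtal": bx,
                 "xtal_bio": xb, "nopred": np_, "agreement": agr})
    return pd.DataFrame(rows)


@dataclass
class ConfusionMetrics:
    tp: int
    tn: int
    fp: int
    fn: int
    n_excluded: int = 0      # NOPRED calls left out of the counts
    mcc_degenerate: bool = False

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else math.nan

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else math.nan

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else math.nan

    @property
    def mcc(self) -> float:
        denom = math.sqrt(float(self.tp + self.fp) * (self.tp + self.fn)
                          * (self.tn + self.fp) * (self.tn + self.fn))
        if denom == 0:
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / denom


def confusion_metrics(truth: list, calls: list) -> ConfusionMetrics:
    """Confusion-matrix statistics with BIO as the positive class.

    ``truth`` holds "BIO"/"XTAL" labels (or Call values); NOPRED calls are
    excluded from the counts and reported in ``n_excluded``.
    """
    if len(truth) != len(calls):
        raise ValueError("label and call vectors must have equal length")
    tp = tn = fp = fn = excl = 0
    for t, c in zip(truth, calls):
        t = Call(t) if not isinstance(t, Call) else t
        c = Call(c) if not isinstance(c, Call) else c
        if c == Call.NOPRED:
            excl += 1
            continue
        if t == Call.BIO:
            if c == Call.BIO:
                tp += 1
            else:
                fn += 1
        else:
            if c == Call.XTAL:
                tn += 1
            else:
                fp += 1
    if tp + tn + fp + fn == 0:
        raise ValueError("no evaluable label/call pairs")
    m = ConfusionMetrics(tp, tn, fp, fn, n_excluded=excl)
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    m.mcc_degenerate = denom == 0
    return m


# ---------------------------------------------------------------------------
# input adapters

def read_assembly_json(path) -> AssemblyPrediction:
    """Canonical neutral format::

        {"entry_id": "XXXX",
         "assemblies": [{"stability": "STABLE", "size": 2,
                         "member_interfaces": ["-x,y+1/2,-z|0,0,0", ...]}]}
    """
    data = json.loads(Path(path).read_text())
    assemblies = [Assembly(Stability(a["stability"].upper()), int(a["size"]),
                           list(a.get("member_interfaces", [])))
                  for a in data.get("assemblies", [])]
    return AssemblyPrediction(str(data.get("entry_id", "")), assemblies)


def read_pisa_xml(path) -> AssemblyPrediction:
    """Best-effort reader for PISA-style assembly XML.

    Looks for ``<asm_set>``/``<assembly>`` elements carrying a size
    (``mmsize``/``size``), a stability/dissociation indicator and member
    interface operators; dialects vary across versions, hence the neutral
    JSON format is canonical for tests.
    """
    from lxml import etree

    tree = etree.parse(str(path))
    root = tree.getroot()
    entry = root.findtext(".//pdb_code") or root.findtext(".//name") or ""
    assemblies = []
    for asm in root.iter("assembly"):
        size_text = asm.findtext("mmsize") or asm.findtext("size") or "1"
        size = max(1, int(float(size_text)))
        diss = asm.findtext("diss_energy")
        stab_text = (asm.findtext("stability") or "").upper()
        if stab_text in ("STABLE", "GRAY", "UNSTABLE"):
            stability = Stability(stab_text)
        elif diss is not None:
            e = float(diss)
            stability = (Stability.STABLE if e > 2.0
                         else Stability.GRAY if e > 0.0
                         else Stability.UNSTABLE)
        else:
            stability = Stability.STABLE
        members = [el.text.strip() for el in asm.iter("operator")
                   if el.text and el.text.strip()]
        assemblies.append(Assembly(stability, size, members))
    return AssemblyPrediction(entry.strip(), assemblies)
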