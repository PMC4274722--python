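"""Interface classification: geometry and evolutionary indicators.

Three indicators judge whether a lattice interface is biological or a
crystal contact:

* **geometry** — the number of core residues (burial >= 0.95) summed over
  both partners; six or more indicate a biological interface.
* **core-rim** — the ratio of mean sequence entropy in the core residues
  (burial >= 0.70) to that in the rim; a conserved core (ratio below the
  cutoff, default 0.75) indicates a biological interface.
* **core-surface** — a z-score of the core's mean entropy against the
  distribution of means of random surface-residue subsets of the same
  size; strongly negative (below the cutoff, default -1.0) indicates a
  core more conserved than the surface, i.e. a biological interface.

The consensus is a majority vote; chains without enough homologs make the
evolutionary indicators abstain (NOPRED), leaving the geometry call.  A
separate robust-call filter retains only unanimous calls on well-determined
structures (resolution < 2.5 Å, Rfree < 0.3, >= 30 homologs) with extreme
core-surface scores (< -3.3 for BIO, > 0.15 for XTAL).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

import numpy as np

from .evolution import EntropyProfile
from .interfaces import (
    CORE_THRESHOLD_EVOLUTION,
    CORE_THRESHOLD_GEOMETRY,
    Interface,
    Region,
)
from .structure_io import CrystalStructure

__all__ = [
    "Call",
    "Verdict",
    "InterfaceCall",
    "geometry_indicator",
    "core_rim_indicator",
    "core_surface_indicator",
    "consensus_call",
    "robust_filter",
    "entry_verdict",
    "classify_interface",
    "classify_structure",
    "GEOMETRY_CORE_CUTOFF",
    "CORE_RIM_CALL_CUTOFF",
    "CORE_SURFACE_CALL_CUTOFF",
    "ROBUST_MAX_RESOLUTION",
    "ROBUST_MAX_RFREE",
    "ROBUST_MIN_HOMOLOGS",
    "ROBUST_BIO_SCORE",
    "ROBUST_XTAL_SCORE",
]

GEOMETRY_CORE_CUTOFF = 6         # core residues at/above which the call is BIO
CORE_RIM_CALL_CUTOFF = 0.75      # ratio below which the call is BIO
CORE_SURFACE_CALL_CUTOFF = -1.0  # z-score below which the call is BIO
DEFAULT_N_SAMPLES = 10_000

ROBUST_MAX_RESOLUTION = 2.5      # Å, strictly better required
ROBUST_MAX_RFREE = 0.3           # strictly lower required
ROBUST_MIN_HOMOLOGS = 30
ROBUST_BIO_SCORE = -3.3          # core-surface below this for robust BIO
ROBUST_XTAL_SCORE = 0.15         # core-surface above this for robust XTAL


class Call(str, Enum):
    BIO = "BIO"
    XTAL = "XTAL"
    NOPRED = "NOPRED"


class Verdict(str, Enum):
    MONOMERIC = "MONOMERIC"
    MULTIMERIC = "MULTIMERIC"


@dataclass
class InterfaceCall:
    interface_id: int
    chain_a: str
    chain_b: str
    operator: str
    operator_class: str
    area: float
    n_core_geom: int
    core_rim_ratio: Optional[float]
    core_surface_score: Optional[float]
    call_geometry: Call
    call_corerim: Call
    call_coresurface: Call
    consensus: Call
    robust: bool = False


# ---------------------------------------------------------------------------
# indicators

def geometry_indicator(interface: Interface,
                       core_call_cutoff: int = GEOMETRY_CORE_CUTOFF,
                       burial_threshold: float = CORE_THRESHOLD_GEOMETRY):
    """Core-residue count over both partners; BIO iff count >= cutoff."""
    n_core = interface.core_count(burial_threshold)
    call = Call.BIO if n_core >= core_call_cutoff else Call.XTAL
    return n_core, call


def _partner_entropies(interface: Interface, profiles: dict,
                       burial_threshold: float):
    """Entropy values of CORE / RIM / SURFACE residues, pooled per region.

    ``profiles`` maps partner ('A'/'B') to that partner's EntropyProfile.
    Residues with no entropy value (unmapped columns) are skipped.
    Surface entropies are kept per partner for the core-surface sampling.
    """
    regs = interface.regions(burial_threshold)
    pooled = {Region.CORE: [], Region.RIM: []}
    per_partner = {}
    for partner in ("A", "B"):
        prof = profiles[partner]
        ent = prof.entropies
        core, surf = [], []
        for i, lab in enumerate(regs[partner]):
            v = ent[i] if i < len(ent) else np.nan
            if not np.isfinite(v):
                continue
            if lab == Region.CORE:
                pooled[Region.CORE].append(v)
                core.append(v)
            elif lab == Region.RIM:
                pooled[Region.RIM].append(v)
            elif lab == Region.SURFACE:
                surf.append(v)
        per_partner[partner] = (np.array(core), np.array(surf))
    return pooled, per_partner


def core_rim_indicator(interface: Interface, profile_a: EntropyProfile,
                       profile_b: EntropyProfile,
                       call_cutoff: float = CORE_RIM_CALL_CUTOFF,
                       burial_threshold: float = CORE_THRESHOLD_EVOLUTION):
    """Mean core entropy over mean rim entropy (partners pooled).

    BIO iff ratio < cutoff (a conserved core has lower entropy than the
    rim).  NOPRED when either profile is insufficient, a region is empty,
    or the rim mean is zero.
    """
    if profile_a.insufficient or profile_b.insufficient:
        return None, Call.NOPRED
    pooled, _ = _partner_entropies(interface, {"A": profile_a, "B": profile_b},
                                   burial_threshold)
    core, rim = pooled[Region.CORE], pooled[Region.RIM]
    if not core or not rim:
        return None, Call.NOPRED
    rim_mean = float(np.mean(rim))
    if rim_mean <= 0:
        return None, Call.NOPRED
    ratio = float(np.mean(core)) / rim_mean
    return ratio, (Call.BIO if ratio < call_cutoff else Call.XTAL)


def core_surface_indicator(interface: Interface, profile_a: EntropyProfile,
                           profile_b: EntropyProfile,
                           n_samples: int = DEFAULT_N_SAMPLES,
                           seed: int = 0,
                           call_cutoff: float = CORE_SURFACE_CALL_CUTOFF,
                           burial_threshold: float = CORE_THRESHOLD_EVOLUTION):
    """Z-score of core conservation against random surface subsets.

    For each partner with a non-empty core, ``n_samples`` random subsets of
    its surface residues of the core's size are drawn; sample means are
    pooled across partners (weighted by core sizes) and the score is
    ``(mean_core - mean_of_sample_means) / std_of_sample_means``.  BIO iff
    score < cutoff.  NOPRED when a surface pool is smaller than its core,
    or the sampling distribution is degenerate (zero spread).
    """
    if n_samples < 100:
        raise ValueError("n_samples must be >= 100")
    if profile_a.insufficient or profile_b.insufficient:
        return None, Call.NOPRED
    pooled, per_partner = _partner_entropies(
        interface, {"A": profile_a, "B": profile_b}, burial_threshold)
    cores_all = pooled[Region.CORE]
    if not cores_all:
        return None, Call.NOPRED

    rng = np.random.default_rng(seed)
    total_core = len(cores_all)
    # pooled sample mean: concatenation of per-partner subsets, sizes = core sizes
    sums = np.zeros(n_samples)
    for partner in ("A", "B"):
        core, surf = per_partner[partner]
        k = len(core)
        if k == 0:
            continue
        if len(surf) < k:
            return None, Call.NOPRED
        # vectorised sampling without replacement: argpartition of random keys
        keys = rng.random((n_samples, len(surf)))
        idx = np.argpartition(keys, k - 1, axis=1)[:, :k]
        sums += surf[idx].sum(axis=1)
    sample_means = sums / total_core
    spread = float(sample_means.std())
    if spread <= 0:
        return None, Call.NOPRED
    score = (float(np.mean(cores_all)) - float(sample_means.mean())) / spread
    return score, (Call.BIO if score < call_cutoff else Call.XTAL)


# ---------------------------------------------------------------------------
# consensus and aggregation

def consensus_call(call_geometry: Call, call_corerim: Call,
                   call_coresurface: Call) -> Call:
    """Majority vote over the non-abstaining indicators.

    Both evolutionary indicators NOPRED -> the geometry call stands alone.
    A one-against-one tie (third indicator NOPRED) is broken by the
    core-surface indicator when it voted, else by geometry: core-surface is
    consistently the most discriminating of the three.
    """
    votes = [c for c in (call_geometry, call_corerim, call_coresurface)
             if c != Call.NOPRED]
    if not votes:
        return Call.NOPRED
    n_bio = sum(1 for c in votes if c == Call.BIO)
    n_xtal = len(votes) - n_bio
    if n_bio > n_xtal:
        return Call.BIO
    if n_xtal > n_bio:
        return Call.XTAL
    # tie: one BIO, one XTAL, one NOPRED
    if call_coresurface != Call.NOPRED:
        return call_coresurface
    return call_geometry


def robust_filter(entry: CrystalStructure, call: InterfaceCall,
                  n_homologs: int,
                  max_resolution: float = ROBUST_MAX_RESOLUTION,
                  max_rfree: float = ROBUST_MAX_RFREE,
                  min_homologs: int = ROBUST_MIN_HOMOLOGS,
                  bio_score: float = ROBUST_BIO_SCORE,
                  xtal_score: float = ROBUST_XTAL_SCORE) -> bool:
    """Whether a call qualifies as a robust (safest) prediction.

    Requires a well-determined crystal structure, a deep alignment, a
    unanimous call by all three indicators (an abstention breaks
    unanimity), and an extreme core-surface score.
    """
    if entry.resolution is None or entry.r_free is None:
        return False
    if not (entry.resolution < max_resolution and entry.r_free < max_rfree):
        return False
    if n_homologs < min_homologs:
        return False
    calls = (call.call_geometry, call.call_corerim, call.call_coresurface)
    if any(c == Call.NOPRED for c in calls):
        return False
    if len(set(calls)) != 1:
        return False
    if call.core_surface_score is None:
        return False
    if call.consensus == Call.BIO:
        return call.core_surface_score < bio_score
    if call.consensus == Call.XTAL:
        return call.core_surface_score > xtal_score
    return False


def entry_verdict(calls: list) -> Verdict:
    """MULTIMERIC iff at least one interface is classified biological."""
    if any(c.consensus == Call.BIO for c in calls):
        return Verdict.MULTIMERIC
    return Verdict.MONOMERIC


# ---------------------------------------------------------------------------
# drivers

def classify_interface(interface: Interface, profile_a, profile_b,
                       seed: int = 0,
                       core_call_cutoff: int = GEOMETRY_CORE_CUTOFF,
                       core_rim_cutoff: float = CORE_RIM_CALL_CUTOFF,
                       core_surface_cutoff: float = CORE_SURFACE_CALL_CUTOFF,
                       n_samples: int = DEFAULT_N_SAMPLES) -> InterfaceCall:
    """All three indicators plus consensus for one interface.

    ``profile_a`` / ``profile_b`` may be None (no alignment for that chain):
    the evolutionary indicators then abstain.
    """
    from .symmetry import operator_fingerprint

    n_core, g_call = geometry_indicator(interface, core_call_cutoff)
    if profile_a is None or profile_b is None:
        ratio, cr_call = None, Call.NOPRED
        score, cs_call = None, Call.NOPRED
    else:
        ratio, cr_call = core_rim_indicator(interface, profile_a, profile_b,
                                            core_rim_cutoff)
        score, cs_call = core_surface_indicator(interface, profile_a, profile_b,
                                                n_samples, seed,
                                                core_surface_cutoff)
    return InterfaceCall(
        interface_id=interface.id,
        chain_a=interface.chain_a,
        chain_b=interface.chain_b,
        operator=operator_fingerprint(interface.op_b),
        operator_class=interface.operator_class.code,
        area=interface.area,
        n_core_geom=n_core,
        core_rim_ratio=ratio,
        core_surface_score=score,
        call_geometry=g_call,
        call_corerim=cr_call,
        call_coresurface=cs_call,
        consensus=consensus_call(g_call, cr_call, cs_call),
    )


def classify_structure(structure: CrystalStructure, interfaces: list,
                       profiles: dict, seed: int = 0, **kwargs) -> list:
    """Classify every interface of a structure.

    ``profiles`` maps chain_id -> EntropyProfile (or None).  The robust
    flag is set using the smaller homolog count of the two partners.
    """
    calls = []
    for iface in interfaces:
        pa = profiles.get(iface.chain_a)
        pb = profiles.get(iface.chain_b)
        call = classify_interface(iface, pa, pb, seed=seed + iface.id, **kwargs)
        if pa is not None and pb is not None:
            n_hom = min(pa.n_homologs_used, pb.n_homologs_used)
            call.robust = robust_filter(structure, call, n_hom)
        calls.append(call)
    return calls
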