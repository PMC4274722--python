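"""Sequence-entropy profiles from multiple sequence alignments.

The conservation of each alignment column is measured by its Shannon
entropy ``s = -sum_g p_g log2 p_g`` over the amino-acid frequencies of the
column (gaps and unknown symbols excluded).  Low entropy means a conserved
position.  Profiles are computed from homologs at or above an identity
cutoff to the query (default 50%), and are flagged insufficient when fewer
than ``min_homologs`` (default 10) survive — downstream evolutionary
indicators then abstain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .structure_io import Alignment, ChainModel

__all__ = [
    "EntropyProfile",
    "MappingError",
    "STANDARD_AA",
    "filter_homologs",
    "map_alignment_to_chain",
    "column_entropy",
    "entropy_profile",
    "DEFAULT_IDENTITY_CUTOFF",
    "DEFAULT_MIN_HOMOLOGS",
]

DEFAULT_IDENTITY_CUTOFF = 0.50
DEFAULT_MIN_HOMOLOGS = 10

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_GAPS = set("-.")


class MappingError(ValueError):
    """Alignment query and chain sequence cannot be reconciled."""


@dataclass
class EntropyProfile:
    """Per-residue sequence entropy mapped onto a chain.

    ``entropies[i]`` is NaN where residue i maps to no alignment column or
    the column holds no counted symbols.
    """

    entropies: np.ndarray
    n_homologs_used: int
    identity_cutoff: float
    insufficient: bool = False

    def entropy_at(self, residue_index: int) -> float:
        return float(self.entropies[residue_index])


def filter_homologs(aln: Alignment, identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF) -> Alignment:
    """Keep homolog rows with identity to the query >= cutoff (inclusive).

    The query row is always retained and row order is preserved.
    """
    kept_rows = [aln.rows[0]]
    kept_ids = []
    for row, ident in zip(aln.rows[1:], aln.identity_to_query):
        if ident >= identity_cutoff:
            kept_rows.append(row)
            kept_ids.append(ident)
    return Alignment(aln.query_id, kept_rows, kept_ids)


def map_alignment_to_chain(aln: Alignment, chain: ChainModel,
                           max_mismatches: int = 0) -> list:
    """Map each observed chain residue to an alignment column index.

    The query's ungapped sequence must contain the chain's observed sequence
    (the chain may be missing terminal residues present in the alignment).
    Returns a list of column indices (or None) per chain residue, strictly
    increasing over mapped residues.
    """
    query_cols = [i for i, ch in enumerate(aln.query_seq) if ch not in _GAPS]
    query_ungapped = "".join(aln.query_seq[i] for i in query_cols)
    target = chain.sequence

    offset = query_ungapped.find(target)
    if offset < 0 and max_mismatches > 0:
        best = None
        for off in range(len(query_ungapped) - len(target) + 1):
            mm = sum(1 for a, b in zip(query_ungapped[off:off + len(target)], target)
                     if a != b)
            if mm <= max_mismatches and (best is None or mm < best[1]):
                best = (off, mm)
        if best is not None:
            offset = best[0]
    if offset < 0:
        raise MappingError(
            f"chain {chain.chain_id} sequence not found in alignment query "
            f"{aln.query_id}")
    return [query_cols[offset + i] for i in range(len(target))]


def column_entropy(column, alphabet_groups: Optional[dict] = None) -> float:
    """Shannon entropy (bits) of one alignment column.

    ``alphabet_groups`` maps each symbol to a group label; symbols absent
    from the map (and gaps) are excluded from the frequency counts.  With
    the default 20-letter alphabet every standard amino acid is its own
    group.  Returns NaN for a column with no counted symbols.
    """
    if alphabet_groups is None:
        alphabet_groups = {a: a for a in STANDARD_AA}
    counts = {}
    for sym in column:
        sym = sym.upper()
        if sym in _GAPS:
            continue
        g = alphabet_groups.get(sym)
        if g is None:
            continue
        counts[g] = counts.get(g, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return math.nan
    s = 0.0
    for c in counts.values():
        p = c / total
        s -= p * math.log2(p)
    return s


def entropy_profile(aln: Alignment, chain: ChainModel,
                    identity_cutoff: float = DEFAULT_IDENTITY_CUTOFF,
                    min_homologs: int = DEFAULT_MIN_HOMOLOGS,
                    alphabet_groups: Optional[dict] = None,
                    max_mismatches: int = 0) -> EntropyProfile:
    """Entropy per observed chain residue from filtered homologs.

    When fewer than ``min_homologs`` rows pass the identity cutoff the
    profile is flagged insufficient and downstream evolutionary indicators
    abstain (NOPRED); entropies are still reported for inspection.
    """
    filtered = filter_homologs(aln, identity_cutoff)
    mapping = map_alignment_to_chain(filtered, chain, max_mismatches)
    n_hom = filtered.n_homologs
    entropies = np.full(chain.n_residues, np.nan)
    # columns sampled over all retained rows (query included)
    seqs = [seq for _, seq in filtered.rows]
    for res_idx, col in enumerate(mapping):
        if col is None:
            continue
        entropies[res_idx] = column_entropy([s[col] for s in seqs], alphabet_groups)
    return EntropyProfile(
        entropies=entropies,
        n_homologs_used=n_hom,
        identity_cutoff=identity_cutoff,
        insufficient=n_hom < min_homologs,
    )


def write_entropy_tsv(profile: EntropyProfile, chain: ChainModel, path) -> None:
    """Entropy profile as TSV: residue index, author number, entropy."""
    import pandas as pd

    rows = [
        {"residue_index": i,
         "author_seq_num": chain.residues[i].seq_num,
         "entropy_bits": round(float(profile.entropies[i]), 5)
         if np.isfinite(profile.entropies[i]) else ""}
        for i in range(chain.n_residues)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
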