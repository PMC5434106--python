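"""Sequence pre-processing: dereplication, 97%-identity OTU clustering,
template-based alignment and gap-column filtering.

The clustering dialect is deterministic greedy centroid clustering: records
are processed in descending abundance (ties broken lexicographically by id)
and each record joins the first centroid it matches at or above the identity
threshold, else founds a new OTU.  The representative of an OTU is its
centroid, which by construction is the most abundant unique sequence in it.

Identity between two sequences is computed from a global pairwise alignment
(match +1, mismatch -1, gap open -2, gap extend -1) as
matches / alignment columns, excluding terminal-gap columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from Bio import Align

from .core_io import MultipleAlignment, ReferenceSequence

__all__ = [
    "OTU",
    "dereplicate",
    "pairwise_identity",
    "cluster_otus",
    "align_to_template",
    "filter_gap_columns",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OTU:
    """An operational taxonomic unit from greedy centroid clustering."""

    representative_id: str
    member_ids: frozenset[str]
    threshold: float = 0.97

    def __post_init__(self) -> None:
        if self.representative_id not in self.member_ids:
            raise ValueError("OTU representative must be a member")


def dereplicate(records: Sequence[ReferenceSequence]) -> list[ReferenceSequence]:
    """Collapse identical sequence strings into single records.

    The merged record keeps the id/taxonomy/description of the first-seen
    duplicate, sums abundances, and is flagged as a type strain if any of the
    merged duplicates was one (so that anchor sequences survive collapse).
    Output order is descending abundance, ties broken lexicographically by id.
    Idempotent.
    """
    merged: dict[str, ReferenceSequence] = {}
    for rec in records:
        prev = merged.get(rec.sequence)
        if prev is None:
            merged[rec.sequence] = rec
        else:
            merged[rec.sequence] = replace(
                prev,
                abundance=prev.abundance + rec.abundance,
                is_type_strain=prev.is_type_strain or rec.is_type_strain,
            )
    return sorted(merged.values(), key=lambda r: (-r.abundance, r.id))


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    return aligner


_ALIGNER = _make_aligner()


def _gapped_rows(a: str, b: str) -> tuple[str, str]:
    aln = _ALIGNER.align(a, b)[0]
    return aln[0], aln[1]


def pairwise_identity(a: str, b: str) -> float:
    """Global-alignment identity in [0, 1], terminal-gap columns excluded."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    ra, rb = _gapped_rows(a, b)
    n = len(ra)
    first = max(next(i for i in range(n) if ra[i] != "-"),
                next(i for i in range(n) if rb[i] != "-"))
    last = min(next(i for i in reversed(range(n)) if ra[i] != "-"),
               next(i for i in reversed(range(n)) if rb[i] != "-"))
    cols = last - first + 1
    if cols <= 0:
        return 0.0
    matches = sum(1 for i in range(first, last + 1) if ra[i] == rb[i] and ra[i] != "-")
    return matches / cols


def cluster_otus(
    records: Sequence[ReferenceSequence],
    threshold: float = 0.97,
    assign: str = "first",
) -> list[OTU]:
    """Greedy centroid clustering of dereplicated records at an identity threshold.

    ``assign="first"`` (default) joins the first centroid, in founding order,
    reaching the threshold; ``assign="best"`` joins the highest-identity
    centroid among those reaching it (ties to the earlier centroid).  OTUs are
    returned in founding order.
    """
    if assign not in ("first", "best"):
        raise ValueError(f"unknown assignment dialect {assign!r}")
    ordered = sorted(records, key=lambda r: (-r.abundance, r.id))
    centroids: list[ReferenceSequence] = []
    members: list[set[str]] = []
    for rec in ordered:
        chosen = None
        best_ident = -1.0
        for ci, cen in enumerate(centroids):
            ident = pairwise_identity(cen.sequence, rec.sequence)
            if ident >= threshold:
                if assign == "first":
                    chosen = ci
                    break
                if ident > best_ident:
                    best_ident = ident
                    chosen = ci
        if chosen is None:
            centroids.append(rec)
            members.append({rec.id})
        else:
            members[chosen].add(rec.id)
    return [
        OTU(representative_id=cen.id, member_ids=frozenset(mem), threshold=threshold)
        for cen, mem in zip(centroids, members)
    ]


def align_to_template(
    records: Sequence[ReferenceSequence],
    template: MultipleAlignment,
    min_alignable: float = 0.5,
) -> tuple[MultipleAlignment, dict[str, int], list[str]]:
    """Align records against a fixed-coordinate template reference.

    Each record is globally aligned to the ungapped first row of ``template``;
    record bases are projected onto template columns, and record positions
    that fall in insertions relative to the template are discarded (their
    count is reported per record).  Records with fewer than ``min_alignable``
    of their bases placed on template positions are dropped with a warning.

    Returns ``(alignment, discarded_counts, dropped_ids)``; the alignment has
    exactly the template's width.
    """
    if len(template) < 1:
        raise ValueError("template must contain at least one row")
    ref_row = template.rows[0]
    ref = ref_row.replace("-", "")
    if not ref:
        raise ValueError("template reference row is all gaps")
    # template column index of each ungapped reference position
    ref_cols = [i for i, c in enumerate(ref_row) if c != "-"]

    ids: list[str] = []
    rows: list[str] = []
    discarded: dict[str, int] = {}
    dropped: list[str] = []
    for rec in records:
        aln = _ALIGNER.align(ref, rec.sequence)[0]
        placed = np.full(len(ref), "-", dtype="<U1")
        n_placed = 0
        n_match = 0
        for (t0, t1), (q0, q1) in zip(aln.aligned[0], aln.aligned[1]):
            for k in range(t1 - t0):
                placed[t0 + k] = rec.sequence[q0 + k]
                if rec.sequence[q0 + k] == ref[t0 + k]:
                    n_match += 1
            n_placed += t1 - t0
        # "alignable" means identical to the template base: a record that
        # mostly mismatches is junk relative to this template
        if n_match < min_alignable * len(rec.sequence):
            log.warning("dropping %s: only %d/%d bases alignable to template",
                        rec.id, n_match, len(rec.sequence))
            dropped.append(rec.id)
            continue
        discarded[rec.id] = len(rec.sequence) - n_placed
        row = ["-"] * template.width
        for pos, col in enumerate(ref_cols):
            row[col] = placed[pos]
        ids.append(rec.id)
        rows.append("".join(row))
    return MultipleAlignment(ids=tuple(ids), rows=tuple(rows)), discarded, dropped


def filter_gap_columns(
    aln: MultipleAlignment,
    max_gap_fraction: float = 0.90,
) -> tuple[MultipleAlignment, list[int]]:
    """Remove alignment columns that are gaps in at least ``max_gap_fraction`` of rows.

    The boundary is inclusive: a column with gap fraction exactly equal to the
    threshold is removed.  Returns the filtered alignment and the 0-based
    indices of the removed columns.  Raises if every column would be removed.
    """
    if len(aln) == 0:
        raise ValueError("empty alignment")
    mat = np.array([list(r) for r in aln.rows])
    gap_frac = (mat == "-").mean(axis=0)
    removed = [int(i) for i in np.flatnonzero(gap_frac >= max_gap_fraction)]
    keep = np.flatnonzero(gap_frac < max_gap_fraction)
    if keep.size == 0:
        raise ValueError("degenerate alignment: all columns at or above the gap threshold")
    new_rows = tuple("".join(row[keep]) for row in mat)
    return MultipleAlignment(ids=aln.ids, rows=new_rows), removed
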