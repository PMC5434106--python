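"""Perfect-match evaluation of degenerate 16S rRNA gene primer pairs.

A primer pair "covers" a reference sequence when both primers have a
zero-mismatch (perfect) binding site on it, with the forward site upstream of
the reverse binding site and a plausible amplicon span in between.  Primer
degeneracies (IUPAC codes) match any base in their set; ambiguity codes in the
*target* never satisfy a perfect match — a conservative convention, since an
ambiguous reference base gives no guarantee the real template matches.  The
permissive alternative (set intersection) is available via
``target_ambig="compatible"``.

Coverage of a taxon is the fraction of its reference sequences with a valid
amplicon, the quantity tabulated per primer pair and amplicon size class
(small 100-400 bp, medium >400-<1000 bp, large >=1000 bp).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import ReferenceSequence, TaxonSet

__all__ = [
    "IUPAC_SETS",
    "reverse_complement",
    "iupac_compatible",
    "parse_primer_name",
    "Primer",
    "PrimerPair",
    "AmpliconRecord",
    "nominal_amplicon_length",
    "assign_size_class",
    "find_sites",
    "evaluate_pair",
    "coverage_by_taxon",
    "overall_coverage",
    "filter_min_coverage",
    "coverage_histogram",
]

#: Base set denoted by each IUPAC nucleotide code.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


def reverse_complement(seq: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, S/W/N fixed)."""
    return seq.translate(_COMPLEMENT)[::-1]


def iupac_compatible(primer_base: str, target_base: str, target_ambig: str = "strict") -> bool:
    """True iff ``target_base`` is perfectly matched by ``primer_base``.

    Strict (default) semantics: the target base must be a concrete A/C/G/T
    inside the primer code's set.  ``target_ambig="compatible"`` instead
    accepts any non-empty intersection of the two codes' base sets.
    """
    pset = IUPAC_SETS[primer_base]
    if target_ambig == "compatible":
        return bool(pset & IUPAC_SETS[target_base])
    return target_base in "ACGT" and target_base in pset


_NAME_RE = re.compile(r"^S-D-Bact-(\d+)-[A-Za-z0-9]+-([SA])-(\d+)$")


def parse_primer_name(name: str) -> tuple[int, str, int] | None:
    """Parse standardized primer nomenclature ``S-D-Bact-<pos>-<variant>-<S|A>-<len>``.

    Returns ``(nominal_position, orientation, nominal_length)`` with
    orientation ``"sense"`` or ``"antisense"``; ``None`` for names that do not
    follow the pattern (e.g. ``27F``), which is a soft outcome, not an error.
    """
    m = _NAME_RE.match(name)
    if m is None:
        return None
    pos, strand, length = int(m.group(1)), m.group(2), int(m.group(3))
    return pos, ("sense" if strand == "S" else "antisense"), length


@dataclass(frozen=True)
class Primer:
    """A degenerate primer, 5'->3'.

    ``orientation`` is the strand the primer anneals in: sense (forward) or
    antisense (reverse).  ``nominal_position``/``nominal_length`` are parsed
    from standardized names where available; for antisense primers the nominal
    position is the 5'-most reference coordinate of the binding site on the
    sense strand.
    """

    name: str
    seq: str
    orientation: str  # "sense" | "antisense"
    nominal_position: int | None = None
    nominal_length: int | None = None

    def __post_init__(self) -> None:
        if self.orientation not in ("sense", "antisense"):
            raise ValueError(f"primer {self.name!r}: bad orientation {self.orientation!r}")
        bad = set(self.seq) - set(IUPAC_SETS)
        if bad:
            raise ValueError(
                f"primer {self.name!r}: non-IUPAC character(s) {sorted(bad)!r}"
            )
        if not self.seq:
            raise ValueError(f"primer {self.name!r}: empty sequence")

    @classmethod
    def from_name(cls, name: str, seq: str, orientation: str) -> "Primer":
        seq = seq.upper().replace("U", "T")
        parsed = parse_primer_name(name)
        pos = length = None
        if parsed is not None:
            pos, _, length = parsed
            # nomenclature length must agree with the actual oligo; otherwise
            # the name is treated as non-conforming and metadata stays unset
            if length != len(seq):
                pos = length = None
        return cls(name=name, seq=seq, orientation=orientation,
                   nominal_position=pos, nominal_length=length)


@dataclass(frozen=True)
class PrimerPair:
    """A forward (sense) / reverse (antisense) primer pair."""

    pair_id: str
    forward: Primer
    reverse: Primer
    size_class: str = "unknown"  # small | medium | large | unknown

    def __post_init__(self) -> None:
        if self.forward.orientation != "sense":
            raise ValueError(f"pair {self.pair_id!r}: forward primer must be sense")
        if self.reverse.orientation != "antisense":
            raise ValueError(f"pair {self.pair_id!r}: reverse primer must be antisense")

    @classmethod
    def from_sequences(cls, pair_id: str, fwd_name: str, fwd_seq: str,
                       rev_name: str, rev_seq: str) -> "PrimerPair":
        fwd = Primer.from_name(fwd_name, fwd_seq, "sense")
        rev = Primer.from_name(rev_name, rev_seq, "antisense")
        pair = cls(pair_id=pair_id, forward=fwd, reverse=rev)
        nominal = nominal_amplicon_length(pair)
        return cls(pair_id=pair_id, forward=fwd, reverse=rev,
                   size_class=assign_size_class(nominal))


@dataclass(frozen=True)
class AmpliconRecord:
    """An in-silico amplicon, 1-based inclusive coordinates on the sense strand.

    The span runs from the forward primer's 5' position through the 3' end of
    the reverse-primer binding site, so both primer-binding regions are part
    of the amplicon.
    """

    seq_id: str
    pair_id: str
    start: int
    end: int
    amplicon_seq: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.amplicon_seq):
            raise ValueError("amplicon coordinates inconsistent with sequence length")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def nominal_amplicon_length(pair: PrimerPair) -> int | None:
    """Designed amplicon span from name-encoded positions, or None if unparsed.

    Inclusive reference-coordinate span from the forward primer's start
    through the reverse primer's 3'-terminal position
    (``rev_pos + rev_len - 1``); e.g. positions 343/908 with lengths 15/18
    give 583 bp.
    """
    f, r = pair.forward, pair.reverse
    if f.nominal_position is None or r.nominal_position is None:
        return None
    return (r.nominal_position + r.nominal_length - 1) - f.nominal_position + 1


def assign_size_class(length: int | None) -> str:
    """Amplicon size class: small 100-400, medium 401-999, large >=1000.

    The published grouping leaves exactly 1000 bp unassigned ("<1000" vs
    ">1000"); it is placed in ``large`` here.  Lengths under 100 or unknown
    lengths map to ``unknown``.
    """
    if length is None or length < 100:
        return "unknown"
    if length <= 400:
        return "small"
    if length < 1000:
        return "medium"
    return "large"


def _site_regex(probe: str, target_ambig: str) -> re.Pattern:
    parts = []
    for c in probe:
        if target_ambig == "compatible":
            allowed = {t for t in IUPAC_SETS if IUPAC_SETS[c] & IUPAC_SETS[t]}
        else:
            allowed = IUPAC_SETS[c]
        parts.append("[" + "".join(sorted(allowed)) + "]")
    # lookahead so overlapping sites are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def find_sites(primer: Primer, target: str, target_ambig: str = "strict") -> list[int]:
    """1-based start positions of perfect binding sites of ``primer`` on ``target``.

    Antisense primers are scanned as their IUPAC reverse complement against
    the given (sense) strand; positions refer to the 5'-most base of the
    binding site on that strand.  Overlapping sites are all returned, in
    ascending order.
    """
    probe = primer.seq if primer.orientation == "sense" else reverse_complement(primer.seq)
    pat = _site_regex(probe, target_ambig)
    return [m.start() + 1 for m in pat.finditer(target)]


def evaluate_pair(
    pair: PrimerPair,
    target: ReferenceSequence,
    min_len: int = 50,
    max_len: int = 3000,
    target_ambig: str = "strict",
) -> AmpliconRecord | None:
    """Extract the amplicon the pair would produce from ``target``, if any.

    Candidate amplicons pair a forward site strictly upstream of (and not
    overlapping) a reverse binding site, with total span within
    ``[min_len, max_len]``.  When several candidates exist the shortest span
    wins (shorter products amplify preferentially), ties broken by the
    smallest forward position.  Returns ``None`` when either primer has no
    site or no site pair yields a valid span.
    """
    seq = target.sequence
    fwd_sites = find_sites(pair.forward, seq, target_ambig)
    if not fwd_sites:
        return None
    rev_sites = find_sites(pair.reverse, seq, target_ambig)
    if not rev_sites:
        return None
    len_f, len_r = len(pair.forward.seq), len(pair.reverse.seq)
    best: tuple[int, int] | None = None  # (span, fwd_start)
    for f in fwd_sites:
        for r in rev_sites:
            if r < f + len_f:
                continue
            span = (r + len_r - 1) - f + 1
            if span < min_len or span > max_len:
                continue
            if best is None or (span, f) < best:
                best = (span, f)
    if best is None:
        return None
    span, f = best
    end = f + span - 1
    return AmpliconRecord(
        seq_id=target.id,
        pair_id=pair.pair_id,
        start=f,
        end=end,
        amplicon_seq=seq[f - 1 : end],
    )


def coverage_by_taxon(
    pair: PrimerPair,
    taxa: Sequence[TaxonSet],
    refs: Mapping[str, ReferenceSequence],
    min_len: int = 50,
    max_len: int = 3000,
    target_ambig: str = "strict",
) -> pd.DataFrame:
    """Perfect-match pair coverage per taxon.

    Returns a frame with columns ``pair_id, taxon, n_targets, n_matched,
    coverage`` where coverage is the matched fraction of the taxon's members.
    """
    if not taxa:
        raise ValueError("no taxa given")
    rows = []
    for taxon in taxa:
        if not taxon.member_ids:
            raise ValueError(f"taxon {taxon.name!r} is empty")
        members = sorted(taxon.member_ids)
        missing = [m for m in members if m not in refs]
        if missing:
            raise KeyError(
                f"taxon {taxon.name!r}: member ids not in reference set: {missing}"
            )
        n_matched = sum(
            evaluate_pair(pair, refs[m], min_len, max_len, target_ambig) is not None
            for m in members
        )
        rows.append(
            {
                "pair_id": pair.pair_id,
                "taxon": taxon.name,
                "n_targets": len(members),
                "n_matched": n_matched,
                "coverage": n_matched / len(members),
            }
        )
    return pd.DataFrame(rows, columns=["pair_id", "taxon", "n_targets", "n_matched", "coverage"])


def overall_coverage(
    pair: PrimerPair,
    all_refs: Mapping[str, ReferenceSequence] | Iterable[ReferenceSequence],
    min_len: int = 50,
    max_len: int = 3000,
    target_ambig: str = "strict",
) -> float:
    """Coverage against one taxon spanning the entire reference set.

    Mirrors the re-check of high-coverage pairs against all bacteria: the same
    perfect-match computation, run on the full set instead of a target genus.
    """
    if isinstance(all_refs, Mapping):
        refs = dict(all_refs)
    else:
        refs = {r.id: r for r in all_refs}
    if not refs:
        raise ValueError("empty reference set")
    taxon = TaxonSet(name="__all__", member_ids=frozenset(refs))
    table = coverage_by_taxon(pair, [taxon], refs, min_len, max_len, target_ambig)
    return float(table["coverage"].iloc[0])


def filter_min_coverage(table: pd.DataFrame, min_cov: float = 0.95) -> list[str]:
    """Pair ids whose coverage is >= ``min_cov`` for EVERY taxon in the table.

    The boundary is inclusive ("at least 95% coverage" keeps 0.95 exactly).
    Order of first appearance in the table is preserved.
    """
    ok = table.groupby("pair_id", sort=False)["coverage"].min() >= min_cov
    return [pid for pid in table["pair_id"].unique() if bool(ok[pid])]


def coverage_histogram(
    table: pd.DataFrame,
    size_classes: Mapping[str, str],
    bin_width: int = 10,
) -> pd.DataFrame:
    """Histogram of pair coverage per (taxon, size class) in percent bins.

    Bins are half-open ``[0,10), [10,20), ..., [90,100]`` with the top bin
    closed, so a pair at exactly 100% lands in the last bin.  Counts within
    each (taxon, size_class) panel sum to the number of pairs tabulated there.
    """
    n_bins = 100 // bin_width
    rows = []
    for _, rec in table.iterrows():
        pct = rec["coverage"] * 100.0
        b = min(int(pct // bin_width), n_bins - 1)
        rows.append(
            {
                "taxon": rec["taxon"],
                "size_class": size_classes.get(rec["pair_id"], "unknown"),
                "bin_low": b * bin_width,
            }
        )
    if not rows:
        return pd.DataFrame(columns=["taxon", "size_class", "bin_low", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["taxon", "size_class", "bin_low"], sort=True)
        .size()
        .reset_index(name="count")
    )
    return out
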