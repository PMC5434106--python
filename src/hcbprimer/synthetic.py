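"""Synthetic 16S-like reference sets with known taxonomy and engineered primer sites.

The generator emulates the statistical structure the downstream analysis
assumes: a star-like genus phylogeny (one ancestor per genus derived from a
common root, tips derived from their ancestor), conserved primer-binding
motifs at fixed coordinates, and genus-labeled type strains.  Primer sites
are shielded from background substitutions and indels, so whether a tip
carries a perfect binding site is controlled *exactly* by the configured
per-genus perfect-match fraction — coverage becomes an engineered, checkable
quantity with a truth table.

Evolution model: per-site independent substitutions, uniform over the three
alternative bases (Jukes-Cantor-like), applied with probability equal to the
branch's divergence fraction; optional 1-3 nt indels on tip branches outside
primer sites.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .core_io import (
    ReferenceSequence,
    write_fasta,
    write_taxonomy_table,
)
from .primers import IUPAC_SETS, reverse_complement

__all__ = [
    "HCB_GENERA",
    "PrimerSite",
    "SynthConfig",
    "SiteTruth",
    "TruthTable",
    "generate_reference_set",
    "expected_pairwise_identity",
    "write_synthetic_set",
    "load_synth_config",
]

#: The eight obligate hydrocarbon-degrading genera used as default labels.
HCB_GENERA = (
    "Alcanivorax",
    "Cycloclasticus",
    "Marinobacter",
    "Neptunomonas",
    "Oleiphilus",
    "Oleispira",
    "Thalassolituus",
    "Thalassospira",
)

_BASES = "ACGT"
_BASE_IDX = {c: i for i, c in enumerate(_BASES)}

#: Default engineered sites mirror a V3-V5 medium amplicon: a forward motif
#: at reference position 201 and a reverse-primer binding site at 766, giving
#: a 583-bp span including both binding regions.
DEFAULT_FORWARD_MOTIF = "TACGGRAGGCAGCAG"  # 15 nt, one R degeneracy
DEFAULT_REVERSE_PRIMER = "CCGTCAATTCMTTTGAGT"  # 18 nt, annealing antisense


@dataclass(frozen=True)
class PrimerSite:
    """A conserved motif written into the root at a fixed 1-based position.

    ``motif`` is given on the sense strand (for a reverse primer this is the
    reverse complement of the oligo).  ``perfect_fraction`` is the fraction
    of tips per genus that keep a perfect-match site; either a single float
    for all genera or a genus -> fraction map.
    """

    motif: str
    start: int  # 1-based on the root sequence
    perfect_fraction: float | Mapping[str, float] = 1.0

    def fraction_for(self, genus: str) -> float:
        if isinstance(self.perfect_fraction, Mapping):
            return float(self.perfect_fraction.get(genus, 1.0))
        return float(self.perfect_fraction)

    @property
    def end(self) -> int:
        return self.start + len(self.motif) - 1


def _default_sites() -> tuple[PrimerSite, ...]:
    return (
        PrimerSite(motif=DEFAULT_FORWARD_MOTIF, start=201),
        PrimerSite(motif=reverse_complement(DEFAULT_REVERSE_PRIMER), start=766),
    )


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for one synthetic reference set."""

    n_genera: int = 5
    seqs_per_genus: int = 40
    seq_length: int = 1500
    between_genus_divergence: float = 0.15
    within_genus_divergence: float = 0.02
    indel_rate: float = 0.005
    primer_sites: tuple[PrimerSite, ...] = field(default_factory=_default_sites)
    n_type_strains_per_genus: int = 1
    seed: int = 0
    genus_names: tuple[str, ...] | None = None

    def validate(self) -> None:
        if self.n_genera < 2:
            raise ValueError("n_genera must be >= 2")
        if self.seqs_per_genus < 1:
            raise ValueError("seqs_per_genus must be >= 1")
        if self.n_type_strains_per_genus < 1:
            raise ValueError("n_type_strains_per_genus must be >= 1")
        if self.n_type_strains_per_genus > self.seqs_per_genus:
            raise ValueError("more type strains than sequences per genus")
        for frac in (self.between_genus_divergence, self.within_genus_divergence,
                     self.indel_rate):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("divergence/indel fractions must lie in [0, 1]")
        intervals = []
        for site in self.primer_sites:
            bad = set(site.motif) - set(IUPAC_SETS)
            if bad:
                raise ValueError(f"site motif has non-IUPAC characters {sorted(bad)}")
            if site.start < 1 or site.end > self.seq_length:
                raise ValueError(
                    f"site [{site.start}, {site.end}] outside [1, {self.seq_length}]"
                )
            fr = site.perfect_fraction
            values = fr.values() if isinstance(fr, Mapping) else [fr]
            if any(not 0.0 <= float(v) <= 1.0 for v in values):
                raise ValueError("perfect fractions must lie in [0, 1]")
            intervals.append((site.start, site.end))
        intervals.sort()
        for (s1, e1), (s2, e2) in zip(intervals, intervals[1:]):
            if s2 <= e1:
                raise ValueError("primer site intervals must be disjoint")

    def genera(self) -> tuple[str, ...]:
        if self.genus_names is not None:
            if len(self.genus_names) != self.n_genera:
                raise ValueError("genus_names length must equal n_genera")
            return tuple(self.genus_names)
        if self.n_genera <= len(HCB_GENERA):
            return HCB_GENERA[: self.n_genera]
        extra = tuple(f"Genus{i:02d}" for i in range(len(HCB_GENERA), self.n_genera))
        return HCB_GENERA + extra


@dataclass(frozen=True)
class SiteTruth:
    """Known state of one engineered site on one generated sequence."""

    perfect: bool
    start: int  # 1-based, after indels
    end: int


@dataclass(frozen=True)
class TruthTable:
    """Ground truth for a generated set: genus labels and site states."""

    genus_of: dict[str, str]
    sites: dict[tuple[str, int], SiteTruth]  # (seq_id, site_index) -> state
    site_motifs: tuple[str, ...]  # instantiated (concrete) site sequences
    site_starts: tuple[int, ...]  # root coordinates, 1-based
    root_sequence: str

    def pair_perfect(self, seq_id: str) -> bool:
        """True iff every engineered site on the sequence is a perfect match."""
        return all(
            self.sites[(seq_id, si)].perfect for si in range(len(self.site_motifs))
        )

    def expected_coverage(self, genus: str) -> float:
        ids = [sid for sid, g in self.genus_of.items() if g == genus]
        if not ids:
            raise KeyError(f"unknown genus {genus!r}")
        return sum(self.pair_perfect(sid) for sid in ids) / len(ids)


def _mutate(codes: np.ndarray, rate: float, free: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Substitute each free position with probability ``rate`` (uniform over the
    three alternative bases)."""
    out = codes.copy()
    if rate <= 0 or free.size == 0:
        return out
    hits = free[rng.random(free.size) < rate]
    if hits.size:
        out[hits] = (out[hits] + rng.integers(1, 4, size=hits.size)) % 4
    return out


def _codes_to_str(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


def generate_reference_set(
    config: SynthConfig,
) -> tuple[list[ReferenceSequence], TruthTable]:
    """Generate a genus-labeled reference set with engineered primer sites.

    Fully deterministic given ``config`` (including its seed).  Within each
    genus, exactly ``round(fraction * seqs_per_genus)`` tips keep a perfect
    site; the remaining tips get one substitution inside the site, chosen to
    fall outside the motif's degeneracy set so the perfect match is
    guaranteed broken.  The same per-genus tip permutation orders breakage
    across sites, so sites with equal fractions break the same tips and a
    primer *pair* built from two sites has engineered coverage
    ``min(fractions)``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    L = config.seq_length

    root = rng.integers(0, 4, size=L)
    # instantiate degenerate motif positions to one concrete base, recorded
    inst_motifs: list[str] = []
    shield = np.zeros(L, dtype=bool)
    for site in config.primer_sites:
        s0 = site.start - 1
        inst = []
        for off, code in enumerate(site.motif):
            choices = sorted(IUPAC_SETS[code])
            base = choices[rng.integers(0, len(choices))]
            root[s0 + off] = _BASE_IDX[base]
            inst.append(base)
        inst_motifs.append("".join(inst))
        shield[s0 : s0 + len(site.motif)] = True
    free = np.flatnonzero(~shield)
    site_intervals = [(s.start - 1, s.end) for s in config.primer_sites]  # [s0, e0)

    genera = config.genera()
    records: list[ReferenceSequence] = []
    genus_of: dict[str, str] = {}
    site_states: dict[tuple[str, int], SiteTruth] = {}

    for genus in genera:
        ancestor = _mutate(root, config.between_genus_divergence, free, rng)
        n = config.seqs_per_genus
        perm = rng.permutation(n)
        broken_by_site: list[set[int]] = []
        for site in config.primer_sites:
            n_perfect = int(round(site.fraction_for(genus) * n))
            broken_by_site.append(set(perm[: n - n_perfect].tolist()))
        for t in range(n):
            tip = _mutate(ancestor, config.within_genus_divergence, free, rng)
            perfect_flags: list[bool] = []
            for si, site in enumerate(config.primer_sites):
                broken = t in broken_by_site[si]
                perfect_flags.append(not broken)
                if broken:
                    # substitute one site position to a base outside its
                    # degeneracy set, guaranteeing the perfect match breaks
                    breakable = [
                        off for off, code in enumerate(site.motif)
                        if len(IUPAC_SETS[code]) < 4
                    ]
                    if not breakable:
                        raise ValueError(
                            f"site {si}: motif is all-N, cannot break a perfect match"
                        )
                    off = breakable[rng.integers(0, len(breakable))]
                    outside = sorted(set(_BASES) - IUPAC_SETS[site.motif[off]])
                    tip[site.start - 1 + off] = _BASE_IDX[
                        outside[rng.integers(0, len(outside))]
                    ]
            seq_str, shifts = _apply_indels(tip, config.indel_rate, site_intervals, rng)
            seq_id = f"{genus}_{t + 1:03d}"
            genus_of[seq_id] = genus
            for si, site in enumerate(config.primer_sites):
                new_start = site.start + shifts[si]
                site_states[(seq_id, si)] = SiteTruth(
                    perfect=perfect_flags[si],
                    start=new_start,
                    end=new_start + len(site.motif) - 1,
                )
            records.append(
                ReferenceSequence(
                    id=seq_id,
                    sequence=seq_str,
                    taxonomy=("Bacteria", "Proteobacteria", "Gammaproteobacteria",
                              "SynthOrder", "SynthFamily", genus),
                    is_type_strain=t < config.n_type_strains_per_genus,
                )
            )

    truth = TruthTable(
        genus_of=genus_of,
        sites=site_states,
        site_motifs=tuple(inst_motifs),
        site_starts=tuple(s.start for s in config.primer_sites),
        root_sequence=_codes_to_str(root),
    )
    return records, truth


def _apply_indels(
    codes: np.ndarray,
    rate: float,
    site_intervals: Sequence[tuple[int, int]],
    rng: np.random.Generator,
) -> tuple[str, list[int]]:
    """Apply 1-3 nt indels outside primer sites; return sequence and per-site
    coordinate shifts."""
    L = codes.size
    if rate <= 0:
        return _codes_to_str(codes), [0] * len(site_intervals)
    hits = np.flatnonzero(rng.random(L) < rate)
    events: list[tuple[int, str, np.ndarray | int]] = []
    deleted: list[tuple[int, int]] = []

    def in_site(p: int) -> bool:
        return any(s0 <= p < e0 for s0, e0 in site_intervals)

    def overlaps_site(p: int, q: int) -> bool:
        return any(s0 < q and p < e0 for s0, e0 in site_intervals)

    for p in hits:
        p = int(p)
        if any(d0 <= p < d1 for d0, d1 in deleted):
            continue
        is_ins = rng.random() < 0.5
        size = int(rng.integers(1, 4))
        if is_ins:
            # insertion lands between p and p+1; skip if that splits a site
            if any(s0 <= p < e0 - 1 for s0, e0 in site_intervals):
                continue
            events.append((p, "I", rng.integers(0, 4, size=size)))
        else:
            if p + size > L or overlaps_site(p, p + size) or in_site(p):
                continue
            if any(d0 < p + size and p < d1 for d0, d1 in deleted):
                continue
            events.append((p, "D", size))
            deleted.append((p, p + size))

    events.sort(key=lambda e: e[0])
    parts: list[np.ndarray] = []
    cursor = 0
    shifts = [0] * len(site_intervals)
    for p, kind, payload in events:
        for si, (s0, _e0) in enumerate(site_intervals):
            if kind == "I" and p < s0:
                shifts[si] += len(payload)  # type: ignore[arg-type]
            elif kind == "D" and p + payload <= s0:  # type: ignore[operator]
                shifts[si] -= int(payload)  # type: ignore[arg-type]
        if kind == "I":
            parts.append(codes[cursor : p + 1])
            parts.append(np.asarray(payload))
            cursor = p + 1
        else:
            parts.append(codes[cursor:p])
            cursor = p + int(payload)
    parts.append(codes[cursor:])
    return _codes_to_str(np.concatenate(parts)), shifts


def _transition(d: float) -> np.ndarray:
    """4x4 per-site substitution matrix for one branch of divergence ``d``."""
    return (1.0 - d) * np.eye(4) + (d / 3.0) * (np.ones((4, 4)) - np.eye(4))


def expected_pairwise_identity(config: SynthConfig) -> dict[str, float]:
    """Closed-form expected pairwise identity (within / between genus).

    Valid only for ``indel_rate == 0`` (identity is then ungapped per-site
    agreement) and assumes perfect primer sites (sites are invariant).  The
    per-site match probability is computed exactly from the substitution
    transition matrices; shielded site positions contribute identity 1.
    """
    if config.indel_rate != 0:
        raise ValueError("closed form requires indel_rate == 0")
    config.validate()
    L = config.seq_length
    n_shielded = sum(len(s.motif) for s in config.primer_sites)
    n_free = L - n_shielded

    def p_match(T: np.ndarray) -> float:
        # both lineages evolve independently from the same start base;
        # rows are identical up to permutation, so row 0 suffices
        return float((T[0] ** 2).sum())

    Tw = _transition(config.within_genus_divergence)
    Tb = _transition(config.between_genus_divergence) @ Tw
    within = (n_shielded + n_free * p_match(Tw)) / L
    between = (n_shielded + n_free * p_match(Tb)) / L
    return {"within": within, "between": between}


def write_synthetic_set(
    records: Sequence[ReferenceSequence],
    truth: TruthTable,
    config: SynthConfig,
    out_dir: str | Path,
) -> dict[str, Path]:
    """Write FASTA + taxonomy TSV + truth TSV + template FASTA + primer TSV.

    The template is the root sequence (one-row alignment at generation
    coordinates); the primer table pairs every upstream site (as forward
    primer) with every downstream site (as reverse primer, i.e. the reverse
    complement of the embedded sense motif), named in standardized
    nomenclature so nominal amplicon lengths are well-defined.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": out / "reference.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.tsv",
        "template": out / "template.fasta",
        "primers": out / "primers.tsv",
    }
    write_fasta(records, paths["fasta"])
    write_taxonomy_table(records, paths["taxonomy"])
    with paths["truth"].open("w") as fh:
        for si, (motif, start) in enumerate(zip(truth.site_motifs, truth.site_starts)):
            fh.write(f"#site\t{si}\t{motif}\t{start}\n")
        fh.write("#seq_id\tgenus\tsite\tperfect\tstart\tend\n")
        for sid in sorted(truth.genus_of):
            for si in range(len(truth.site_motifs)):
                st = truth.sites[(sid, si)]
                fh.write(
                    f"{sid}\t{truth.genus_of[sid]}\t{si}\t{int(st.perfect)}\t"
                    f"{st.start}\t{st.end}\n"
                )
    write_fasta(
        [ReferenceSequence(id="template", sequence=truth.root_sequence)],
        paths["template"],
    )
    sites = config.primer_sites
    with paths["primers"].open("w") as fh:
        fh.write("#pair_id\tfwd_name\tfwd_seq\trev_name\trev_seq\n")
        for i in range(len(sites)):
            for j in range(i + 1, len(sites)):
                f, r = sites[i], sites[j]
                fwd_name = f"S-D-Bact-{f.start:04d}-s-S-{len(f.motif)}"
                rev_name = f"S-D-Bact-{r.start:04d}-s-A-{len(r.motif)}"
                fh.write(
                    f"pair_{i}_{j}\t{fwd_name}\t{f.motif}\t{rev_name}\t"
                    f"{reverse_complement(r.motif)}\n"
                )
    return paths


def load_synth_config(path: str | Path) -> SynthConfig:
    """Read a flat ``key = value`` config file (one key per SynthConfig field).

    ``primer_sites`` uses ``MOTIF@START[:FRAC[,FRAC...]]`` items separated by
    ``;`` — one fraction applies to all genera, a comma list maps onto the
    genus order.  ``genus_names`` is a comma list.
    """
    kv: dict[str, str] = {}
    with Path(path).open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            kv[key.strip()] = val.strip()
    cfg = SynthConfig()
    ints = {"n_genera", "seqs_per_genus", "seq_length", "n_type_strains_per_genus", "seed"}
    floats = {"between_genus_divergence", "within_genus_divergence", "indel_rate"}
    updates: dict = {}
    for key, val in kv.items():
        if key in ints:
            updates[key] = int(val)
        elif key in floats:
            updates[key] = float(val)
        elif key == "genus_names":
            updates[key] = tuple(v.strip() for v in val.split(","))
        elif key == "primer_sites":
            sites = []
            for item in val.split(";"):
                motif, _, rest = item.strip().partition("@")
                start_s, _, frac_s = rest.partition(":")
                if frac_s:
                    fracs = [float(x) for x in frac_s.split(",")]
                    frac = fracs[0] if len(fracs) == 1 else fracs
                else:
                    frac = 1.0
                sites.append((motif, int(start_s), frac))
            updates["primer_sites"] = sites  # resolved below once genera known
        else:
            raise ValueError(f"unknown config key {key!r}")
    raw_sites = updates.pop("primer_sites", None)
    cfg = replace(cfg, **updates)
    if raw_sites is not None:
        genera = cfg.genera()
        resolved = []
        for motif, start, frac in raw_sites:
            if isinstance(frac, list):
                if len(frac) != len(genera):
                    raise ValueError("per-genus fraction list must match n_genera")
                frac = dict(zip(genera, frac))
            resolved.append(PrimerSite(motif=motif, start=start, perfect_fraction=frac))
        cfg = replace(cfg, primer_sites=tuple(resolved))
    cfg.validate()
    return cfg
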