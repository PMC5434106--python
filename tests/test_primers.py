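"""Degenerate primer matching, amplicon extraction, coverage and histograms."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from hcbprimer.core_io import ReferenceSequence, TaxonSet
from hcbprimer.primers import (
    IUPAC_SETS,
    AmpliconRecord,
    Primer,
    PrimerPair,
    assign_size_class,
    coverage_by_taxon,
    coverage_histogram,
    evaluate_pair,
    filter_min_coverage,
    find_sites,
    iupac_compatible,
    nominal_amplicon_length,
    parse_primer_name,
    reverse_complement,
)

from _oracles import IUPAC as ORACLE_IUPAC
from _oracles import rc as oracle_rc
from _oracles import sites_by_expansion


class TestParsePrimerName:
    @pytest.mark.parametrize(
        "name,expected",
        [
            ("S-D-Bact-0343-a-S-15", (343, "sense", 15)),
            ("S-D-Bact-0908-a-A-18", (908, "antisense", 18)),
            ("S-D-Bact-0341-b-S-17", (341, "sense", 17)),
        ],
    )
    def test_standardized_names(self, name, expected):
        assert parse_primer_name(name) == expected

    @pytest.mark.parametrize("name", ["27F", "1492R", "S-D-Bact-x-a-S-15", ""])
    def test_non_conforming_names_yield_none(self, name):
        assert parse_primer_name(name) is None


def _pair(fwd_name, fwd_seq, rev_name, rev_seq, pair_id="p"):
    return PrimerPair.from_sequences(pair_id, fwd_name, fwd_seq, rev_name, rev_seq)


class TestNominalAmpliconLength:
    def test_recommended_pair_span(self):
        pair = _pair("S-D-Bact-0343-a-S-15", "TACGGRAGGCAGCAG",
                     "S-D-Bact-0908-a-A-18", "CCGTCAATTCMTTTGAGT")
        assert nominal_amplicon_length(pair) == 583

    def test_degenerate_same_position_span(self):
        pair = _pair("S-D-Bact-0343-a-S-15", "TACGGRAGGCAGCAG",
                     "S-D-Bact-0343-a-A-15", "CTGCTGCCTYCCGTA")
        assert nominal_amplicon_length(pair) == 15

    def test_simple_arithmetic(self):
        pair = _pair("S-D-Bact-0001-a-S-10", "ACGTACGTAC",
                     "S-D-Bact-0991-a-A-10", "ACGTACGTAC")
        assert nominal_amplicon_length(pair) == 1000

    def test_unparsed_name_gives_none(self):
        pair = _pair("27F", "AGAGTTTGATCMTGGCTCAG", "1492R", "TACGGYTACCTTGTTACGACTT")
        assert nominal_amplicon_length(pair) is None


class TestAssignSizeClass:
    @pytest.mark.parametrize(
        "length,cls",
        [(583, "medium"), (100, "small"), (400, "small"), (401, "medium"),
         (999, "medium"), (1000, "large"), (1500, "large"), (99, "unknown"),
         (None, "unknown")],
    )
    def test_published_boundaries(self, length, cls):
        assert assign_size_class(length) == cls


class TestIupacCompatible:
    def test_degenerate_primer_base(self):
        assert iupac_compatible("R", "A")
        assert not iupac_compatible("R", "C")

    def test_ambiguous_target_never_matches(self):
        assert not iupac_compatible("N", "N")
        assert not iupac_compatible("A", "R")

    def test_exhaustive_table_matches_set_membership_oracle(self):
        codes = sorted(IUPAC_SETS)
        for p in codes:
            for t in codes:
                expected = t in "ACGT" and t in ORACLE_IUPAC[p]
                assert iupac_compatible(p, t) == expected, (p, t)

    def test_compatible_semantics_accept_set_intersection(self):
        assert iupac_compatible("R", "N", target_ambig="compatible")
        assert not iupac_compatible("R", "Y", target_ambig="compatible")


class TestReverseComplement:
    @given(st.text(alphabet="ACGTRYSWKMBDHVN", max_size=40))
    def test_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", max_size=40))
    def test_agrees_with_oracle(self, s):
        assert reverse_complement(s) == oracle_rc(s)


class TestFindSites:
    def test_sense_simple(self):
        p = Primer(name="f", seq="ACGT", orientation="sense")
        assert find_sites(p, "GGACGTGG") == [3]

    def test_antisense_palindrome(self):
        p = Primer(name="r", seq="ACGT", orientation="antisense")
        assert find_sites(p, "GGACGTGG") == [3]

    def test_antisense_scans_reverse_complement(self):
        # primer 5'-AACCG-3' antisense binds sense-strand CGGTT
        p = Primer(name="r", seq="AACCG", orientation="antisense")
        assert find_sites(p, "TTCGGTTAA") == [3]

    def test_overlapping_sites_all_reported(self):
        p = Primer(name="f", seq="AAA", orientation="sense")
        assert find_sites(p, "AAAAA") == [1, 2, 3]

    def test_ambiguous_target_base_blocks_match(self):
        p = Primer(name="f", seq="ACGT", orientation="sense")
        assert find_sites(p, "GGACGNGG") == []

    def test_matches_expansion_oracle_on_random_cases(self):
        rng = np.random.default_rng(99)
        alphabet = np.array(sorted(IUPAC_SETS))
        bases = np.array(list("ACGTN"))
        n_checked = 0
        while n_checked < 300:
            plen = int(rng.integers(3, 11))
            probe = "".join(rng.choice(alphabet, size=plen))
            if np.prod([len(IUPAC_SETS[c]) for c in probe]) > 4 ** 6:
                continue
            target = "".join(rng.choice(bases, size=int(rng.integers(20, 200)),
                                        p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            p = Primer(name="f", seq=probe, orientation="sense")
            assert find_sites(p, target) == sites_by_expansion(probe, target)
            n_checked += 1


def _target(seq: str, rid: str = "t") -> ReferenceSequence:
    return ReferenceSequence(id=rid, sequence=seq)


class TestEvaluatePair:
    FWD = "ACGTACGTAC"  # 10 nt
    REV_BIND = "GGATCCGGATCCGGATCC"  # 18 nt binding region on sense strand

    def _mk(self, pair_id="p"):
        return PrimerPair.from_sequences(
            pair_id, "f", self.FWD, "r", reverse_complement(self.REV_BIND))

    def test_amplicon_coordinates_arithmetic(self):
        # forward at 11, reverse binding region at 93..110 -> span 100
        seq = "T" * 10 + self.FWD + "C" * 72 + self.REV_BIND + "T" * 10
        amp = evaluate_pair(self._mk(), _target(seq))
        assert (amp.start, amp.end, amp.length) == (11, 110, 100)
        assert amp.amplicon_seq == seq[10:110]
        assert amp.amplicon_seq.startswith(self.FWD)
        assert amp.amplicon_seq.endswith(self.REV_BIND)

    def test_missing_reverse_site_gives_none(self):
        seq = "T" * 10 + self.FWD + "C" * 100
        assert evaluate_pair(self._mk(), _target(seq)) is None

    def test_shortest_span_preferred(self):
        seq = ("T" * 10 + self.FWD + "C" * 72 + self.REV_BIND
               + "A" * 30 + self.REV_BIND + "T" * 5)
        amp = evaluate_pair(self._mk(), _target(seq))
        assert amp.end == 110

    def test_span_guards(self):
        seq = "T" * 10 + self.FWD + "C" * 72 + self.REV_BIND + "T" * 10
        assert evaluate_pair(self._mk(), _target(seq), min_len=150) is None
        assert evaluate_pair(self._mk(), _target(seq), max_len=90) is None

    def test_truth_table_coordinates_on_synthetic_data(self, small_set):
        cfg, records, truth = small_set
        fwd = cfg.primer_sites[0].motif
        rev = reverse_complement(cfg.primer_sites[1].motif)
        pair = PrimerPair.from_sequences("sp", "f", fwd, "r", rev)
        for rec in records:
            amp = evaluate_pair(pair, rec)
            assert (amp is not None) == truth.pair_perfect(rec.id)
            if amp is not None:
                assert amp.start == truth.sites[(rec.id, 0)].start
                assert amp.end == truth.sites[(rec.id, 1)].end

    def test_amplicon_record_invariant(self):
        with pytest.raises(ValueError):
            AmpliconRecord(seq_id="s", pair_id="p", start=1, end=5,
                           amplicon_seq="ACG")


class TestCoverage:
    def _fixture(self):
        fwd = "ACGTACGTAC"
        rev_bind = "GGATCCGGATCCGGATCC"
        pair = PrimerPair.from_sequences("p", "f", fwd, "r",
                                         reverse_complement(rev_bind))
        good = "T" * 5 + fwd + "C" * 80 + rev_bind + "T" * 5
        bad = "T" * 5 + fwd + "C" * 90  # reverse site absent
        refs = {}
        ids = []
        for i in range(9):
            refs[f"g{i}"] = _target(good, f"g{i}")
            ids.append(f"g{i}")
        refs["b0"] = _target(bad, "b0")
        ids.append("b0")
        taxon = TaxonSet(name="Alcanivorax", member_ids=frozenset(ids))
        return pair, taxon, refs

    def test_nine_of_ten_engineered_coverage(self):
        pair, taxon, refs = self._fixture()
        table = coverage_by_taxon(pair, [taxon], refs)
        row = table.iloc[0]
        assert row["n_targets"] == 10 and row["n_matched"] == 9
        assert row["coverage"] == pytest.approx(0.9)

    def test_bounds_zero_and_one(self):
        pair, taxon, refs = self._fixture()
        all_good = TaxonSet(name="g", member_ids=frozenset(
            i for i in taxon.member_ids if i.startswith("g")))
        none_match = TaxonSet(name="n", member_ids=frozenset({"b0"}))
        table = coverage_by_taxon(pair, [all_good, none_match], refs)
        cov = dict(zip(table["taxon"], table["coverage"]))
        assert cov == {"g": 1.0, "n": 0.0}

    def test_empty_taxon_is_rejected_at_construction(self):
        with pytest.raises(ValueError, match="no members"):
            TaxonSet(name="empty", member_ids=frozenset())

    def test_unresolvable_member_raises(self):
        pair, taxon, refs = self._fixture()
        bad_taxon = TaxonSet(name="ghost", member_ids=frozenset({"nope"}))
        with pytest.raises(KeyError, match="ghost"):
            coverage_by_taxon(pair, [bad_taxon], refs)


class TestFilterMinCoverage:
    def _table(self, rows):
        return pd.DataFrame(
            [{"pair_id": p, "taxon": t, "n_targets": 100,
              "n_matched": int(c * 100), "coverage": c} for p, t, c in rows])

    def test_boundary_inclusive(self):
        table = self._table([("p1", "a", 1.0), ("p1", "b", 0.96), ("p1", "c", 0.95)])
        assert filter_min_coverage(table, 0.95) == ["p1"]

    def test_one_low_taxon_excludes_pair(self):
        table = self._table([("p1", "a", 1.0), ("p1", "b", 0.94)])
        assert filter_min_coverage(table, 0.95) == []

    def test_zero_threshold_keeps_all(self):
        table = self._table([("p1", "a", 0.0), ("p2", "a", 0.5)])
        assert filter_min_coverage(table, 0.0) == ["p1", "p2"]


class TestCoverageHistogram:
    def test_full_coverage_lands_in_top_bin(self):
        table = pd.DataFrame([{"pair_id": "p", "taxon": "a", "n_targets": 10,
                               "n_matched": 10, "coverage": 1.0}])
        hist = coverage_histogram(table, {"p": "small"})
        assert hist.iloc[0]["bin_low"] == 90 and hist.iloc[0]["count"] == 1

    def test_exact_ten_percent_goes_to_second_bin(self):
        table = pd.DataFrame([{"pair_id": "p", "taxon": "a", "n_targets": 10,
                               "n_matched": 1, "coverage": 0.1}])
        hist = coverage_histogram(table, {"p": "small"})
        assert hist.iloc[0]["bin_low"] == 10

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_counts_conserved(self, coverages):
        table = pd.DataFrame(
            [{"pair_id": f"p{i}", "taxon": "a", "n_targets": 1,
              "n_matched": 0, "coverage": c} for i, c in enumerate(coverages)])
        hist = coverage_histogram(table, {f"p{i}": "small"
                                          for i in range(len(coverages))})
        assert hist["count"].sum() == len(coverages)
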