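"""Query grammar, fragment matching semantics, options, filters, ordering."""

import datetime

import pytest

from rnafrag import fixtures as fx
from rnafrag.search import (
    Filters,
    PatternError,
    SearchOptions,
    entry_from_dotbracket,
    entry_from_structure,
    match_entry,
    parse_query,
    search_library,
)

from oracle import hits_as_sets, oracle_hits


class TestParseQuery:
    def test_sequence_only_with_modification_constraints(self):
        q = parse_query(">strand1GAcUgAAgAuc")
        (s,) = q.strands
        assert s.sequence == "GAcUgAAgAuc"
        assert s.structure is None
        assert s.length == 11
        assert sum(1 for c in s.sequence if c.islower()) == 5

    def test_decamer_duplex_all_anchors_and_pairs(self):
        q = parse_query(">strand1^(((((((((($>strand2^))))))))))$")
        assert all(s.anchor5 and s.anchor3 for s in q.strands)
        assert len(q.pairs) == 10
        assert q.pairs[0] == (1, 20)

    def test_structure_wildcards_keep_sequence_constraints(self):
        q = parse_query(">strand1 NNNGNRANNN((?....?))")
        (s,) = q.strands
        assert s.structure[2] == "?" and s.structure[7] == "?"
        assert s.sequence[5] == "R"
        assert q.pairs == [(1, 10), (2, 9)]

    @pytest.mark.parametrize(
        "text",
        [
            ">s1(.^.)",                 # anchor inside the strand
            ">s1GAC(....)",             # length mismatch
            ">s1((((",                  # unbalanced brackets
            ">s1N?N>s2(?)",             # internal '?' in multi-strand pattern
            ">s1GAC!",                  # unknown character
        ],
    )
    def test_invalid_patterns_rejected(self, text):
        with pytest.raises(PatternError):
            parse_query(text)

    def test_terminal_question_marks_allowed_in_multi_strand(self):
        q = parse_query(">s1?((((>s2))))?")
        assert q.strands[0].structure == "?(((("
        assert q.strands[1].structure == "))))?"


class TestMatching:
    def test_anchored_decamer_matches_exact_duplex_only(self, entries_by_id):
        q = parse_query(">strand1^(((((((((($>strand2^))))))))))$")
        assert len(match_entry(q, entries_by_id["DUP10"])) == 1
        assert len(match_entry(q, entries_by_id["DUP12"])) == 0

    def test_unanchored_decamer_slides_over_longer_duplex(self, entries_by_id):
        q = parse_query(">strand1((((((((((>strand2))))))))))")
        hits = match_entry(q, entries_by_id["DUP12"])
        assert len(hits) == 3
        starts = sorted(h.segments[0].start for h in hits)
        assert starts == [1, 2, 3]

    def test_gnra_pattern_matches_gnra_hairpin(self, entries_by_id):
        q = parse_query(">strand1 NNNGNRANNN(((....)))")
        assert len(match_entry(q, entries_by_id["HPGNRA"])) == 1
        # UUCG loop violates the GNRA sequence constraint
        assert len(match_entry(q, entries_by_id["HPUUCG"])) == 0

    def test_through_space_relaxes_externally_paired_dots(self):
        st_ = fx.build_structure(
            "TS", [("A", "GCGGAAACGC"), ("B", "GGUCC")],
            [(1, 10), (2, 9), (3, 8), (5, 13)],
        )
        e = entry_from_structure(st_)
        q = parse_query(">strand1(((....)))")
        assert len(match_entry(q, e)) == 0
        hits = match_entry(q, e, SearchOptions(through_space=True))
        assert len(hits) == 1
        external = [p for p in hits[0].pairs if p.location == "one_in_fragment"]
        assert [(p.i, p.j) for p in external] == [(5, 13)]

    def test_strand_shift_finds_rotated_junction(self, entries_by_id):
        q = parse_query(">strand1((.......((>strand2))....((>strand3))..))")
        rot = q.rotated(1)
        jct = entries_by_id["JCT3"]
        assert len(match_entry(q, jct)) == 1
        assert len(match_entry(rot, jct)) == 0
        assert len(match_entry(rot, jct, SearchOptions(strand_shift=True))) == 1

    def test_kissing_pattern_hits_complex_not_decoy(self, entries_by_id):
        q = parse_query(">strand1(((.[[[[[[)))>strand2(((.]]]]]])))")
        assert len(match_entry(q, entries_by_id["KISS"])) == 1
        assert len(match_entry(q, entries_by_id["KISSDECOY"])) == 0

    def test_question_mark_matches_missing_residue(self):
        # hairpin with two coordinate-less loop residues: '(((.--.)))'
        st_ = fx.inject_missing(
            fx.build_hairpin("GCG", "GAAA", "QM"), [("A", 5), ("A", 6)]
        )
        e = entry_from_structure(st_)
        assert e.models[0].ssdb.strands[0].structure == "(((.--.)))"
        assert len(match_entry(parse_query(">s1(((....)))"), e)) == 0
        hits = match_entry(parse_query(">s1(((.??.)))"), e)
        assert len(hits) == 1
        assert hits[0].qmark_count == 2
        # the gap's identity is declared, so sequence constraints still apply
        assert len(match_entry(parse_query(">s1GCGGAAACGC(((.??.)))"), e)) == 1
        assert len(match_entry(parse_query(">s1GCGGUUACGC(((.??.)))"), e)) == 0

    def test_lowercase_letters_require_modified_residues(self, entries_by_id):
        e = entries_by_id["ANTICODON"]
        assert len(match_entry(parse_query(">strand1GAcUgAAgAuc"), e)) == 1
        # all-uppercase letters demand unmodified residues -> no hit
        assert len(match_entry(parse_query(">strand1GACUGAAGAUC"), e)) == 0

    def test_two_query_strands_may_share_one_chain(self, entries_by_id):
        # acceptor-stem-like pattern: both halves live on one hairpin strand
        q = parse_query(">strand1^(((>strand2)))....$")
        e = entry_from_structure(
            fx.build_structure(
                "ACC", [("A", "GCGAAAACGCAAAA")],
                [(1, 10), (2, 9), (3, 8)],
            )
        )
        hits = match_entry(q, e)
        assert len(hits) == 1
        segs = [(s.start, s.end) for s in hits[0].segments]
        assert segs == [(1, 3), (8, 14)]

    def test_hit_ordering_is_deterministic(self, entries_by_id):
        q = parse_query(">s1((((((>s2))))))")
        hits1 = match_entry(q, entries_by_id["DUP12"])
        hits2 = match_entry(q, entries_by_id["DUP12"])
        assert [h.sort_key() for h in hits1] == [h.sort_key() for h in hits2]
        assert hits1 == sorted(hits1, key=lambda h: h.sort_key())


TABLE_PATTERNS = [
    ">strand1GAcUgAAgAuc",
    ">strand1GAcUgAAgAuc(.........)",
    ">strand1 NNNGNRANNN(((....)))",
    ">strand1 NNNGNRANNN((?....?))",
    ">strand1^(((((((((($>strand2^))))))))))$",
    ">strand1^(((((((>strand2)))))))....$",
    ">strand1NNNANNN(((.(((>strand2NNNNNN))))))",
    ">strand1(......(>strand2).....)",
    ">strand1((.......((>strand2))....((>strand3))..))",
    ">strand1(((....).((>strand2))...((>strand3)).))",
    ">strand1(((.[[[[[[)))>strand2(((.]]]]]])))",
]

OPTION_SETS = [
    SearchOptions(),
    SearchOptions(through_space=True),
    SearchOptions(strand_shift=True),
    SearchOptions(through_space=True, strand_shift=True),
]


class TestOracleEquivalence:
    @pytest.mark.parametrize("pattern_text", TABLE_PATTERNS)
    def test_matcher_equals_brute_force_on_library(
        self, pattern_text, library_entries
    ):
        pattern = parse_query(pattern_text)
        for entry in library_entries:
            for options in OPTION_SETS:
                got = hits_as_sets(match_entry(pattern, entry, options))
                want = oracle_hits(pattern, entry, options)
                assert got == want, (entry.entry_id, options)

    def test_matcher_equals_brute_force_on_dotbracket_entries(self):
        records = [
            ">a\nGGGGAAAACCCC\n((((....))))",
            ">a\nGCCGAAAGGCAAAGC\n.((..(...)..)).",
            ">x\nGGGGG\n((((( \n>y\nCCCCCAAA\n)))))...",
        ]
        entries = [
            entry_from_dotbracket(f"E{k}", text) for k, text in enumerate(records)
        ]
        patterns = [">s1((((....))))", ">s1(...)", ">s1(((((>s2)))))...",
                    ">s1??(?)", ">s1N"]
        for text in patterns:
            pattern = parse_query(text)
            for entry in entries:
                for options in OPTION_SETS:
                    got = hits_as_sets(match_entry(pattern, entry, options))
                    want = oracle_hits(pattern, entry, options)
                    assert got == want, (entry.entry_id, text, options)


class TestMonotonicity:
    @pytest.mark.parametrize(
        "pattern_text",
        [">strand1 NNNGNRANNN(((....)))",
         ">strand1((((((((((>strand2))))))))))",
         ">strand1(((.[[[[[[)))>strand2(((.]]]]]])))"],
    )
    def test_replacing_any_position_with_wildcard_never_loses_hits(
        self, pattern_text, library_entries
    ):
        from dataclasses import replace

        from rnafrag.search import QueryPattern

        base = parse_query(pattern_text)
        base_hits = {
            e.entry_id: hits_as_sets(match_entry(base, e))
            for e in library_entries
        }
        # wildcard one structure position at a time, dropping any pair that
        # touches it (patterns are built directly so the check covers interior
        # positions of multi-strand patterns as well)
        for pos in range(1, base.length + 1):
            strands, off = [], 0
            for s in base.strands:
                if s.structure is not None and off < pos <= off + s.length:
                    chars = list(s.structure)
                    chars[pos - off - 1] = "?"
                    strands.append(replace(s, structure="".join(chars)))
                else:
                    strands.append(s)
                off += s.length
            relaxed = QueryPattern(
                strands,
                [p for p in base.pairs if pos not in p],
            )
            for e in library_entries:
                got = hits_as_sets(match_entry(relaxed, e))
                assert base_hits[e.entry_id] <= got, (pos, e.entry_id)

    def test_options_never_reduce_hits(self, library_entries):
        for text in TABLE_PATTERNS:
            pattern = parse_query(text)
            for e in library_entries:
                off = hits_as_sets(match_entry(pattern, e))
                for options in OPTION_SETS[1:]:
                    on = hits_as_sets(match_entry(pattern, e, options))
                    assert off <= on, (text, e.entry_id, options)

    def test_strand_shift_equals_union_over_rotations(self, library_entries):
        for text in TABLE_PATTERNS:
            pattern = parse_query(text)
            n = len(pattern.strands)
            for e in library_entries:
                union = set()
                for r in range(n):
                    union |= hits_as_sets(match_entry(pattern.rotated(r), e))
                shifted = hits_as_sets(
                    match_entry(pattern, e, SearchOptions(strand_shift=True))
                )
                assert shifted == union, (text, e.entry_id)


class TestAnchors:
    def test_anchored_windows_touch_their_terminus(self, library_entries):
        q5 = parse_query(">s1^(((>s2)))")
        q3 = parse_query(">s1(((>s2)))$")
        for e in library_entries:
            for h in match_entry(q5, e):
                assert h.segments[0].start_local == 1
            for h in match_entry(q3, e):
                seg = h.segments[1]
                strand = e.models[0].ssdb.strands[seg.strand_index]
                assert seg.start_local + seg.length - 1 == len(strand)
        # at least one anchored hit exists in the library (duplex termini)
        assert any(match_entry(q5, e) for e in library_entries)


class TestSearchLibrary:
    def test_method_filter_excludes_other_methods(self, library_entries):
        q = parse_query(">s1(((....)))")
        hits = search_library(q, library_entries, filters=Filters(methods={"NMR"}))
        nmr_ids = {e.entry_id for e in library_entries if e.method == "NMR"}
        assert {h.entry_id for h in hits} <= nmr_ids
        assert hits  # NMR entries with stems exist

    def test_resolution_and_date_filters(self, library_entries):
        q = parse_query(">s1(((>s2)))")
        strict = search_library(
            q, library_entries, filters=Filters(max_resolution=2.0)
        )
        for h in strict:
            e = next(x for x in library_entries if x.entry_id == h.entry_id)
            assert e.resolution is None or e.resolution <= 2.0
        dated = search_library(
            q, library_entries,
            filters=Filters(date_from=datetime.date(2008, 1, 1)),
        )
        for h in dated:
            e = next(x for x in library_entries if x.entry_id == h.entry_id)
            assert e.deposition_date >= datetime.date(2008, 1, 1)

    def test_modified_filter_skips_modified_entries(self, library_entries):
        q = parse_query(">s1N")
        hits = search_library(
            q, library_entries, filters=Filters(allow_modified=False)
        )
        assert "ANTICODON" not in {h.entry_id for h in hits}
        assert "HPMOD" not in {h.entry_id for h in hits}

    def test_all_models_multiplies_identical_model_hits(self, entries_by_id):
        q = parse_query(">strand1 NNNGNRANNN(((....)))")
        e = entries_by_id["HPGNRA"]  # three identical NMR models
        off = search_library(q, [e])
        on = search_library(q, [e], SearchOptions(all_models=True))
        assert len(off) == 1
        assert len(on) == 3
        assert sorted({h.model_number for h in on}) == [1, 2, 3]

    def test_search_is_deterministic(self, library_entries):
        q = parse_query(">s1(((>s2)))")
        a = search_library(q, library_entries, SearchOptions(all_models=True))
        b = search_library(q, library_entries, SearchOptions(all_models=True))
        assert [(h.entry_id, h.model_number, h.positions) for h in a] == \
               [(h.entry_id, h.model_number, h.positions) for h in b]
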