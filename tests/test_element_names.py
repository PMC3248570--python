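import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from agnc import element_names as en
from agnc.errors import DomainError, GrammarError, SequenceError

from conftest import oracle_scan


class TestConservedSequenceNames:
    def test_worked_example(self):
        desc = en.ConservedSequenceDescriptor(
            species_code="Acar",
            index=1000,
            length_bp=600,
            conservation_pct=100,
            taxa=frozenset("SMB"),
        )
        assert en.cs_name(desc) == "Acar1000l1SMB"

    @pytest.mark.parametrize(
        "index, length, pct, taxa, expected",
        [
            (1, 99, 95, "S", "Acar1s1S"),
            (7, 250, 90, "M", "Acar7m2M"),
            (3, 100, 89, "B", "Acar3m3B"),
            (4, 500, 94, "G", "Acar4l2G"),
        ],
    )
    def test_class_boundaries(self, index, length, pct, taxa, expected):
        desc = en.ConservedSequenceDescriptor(
            "Acar", index, length, pct, frozenset(taxa)
        )
        assert en.cs_name(desc) == expected

    def test_below_class_floor_rejected(self):
        desc = en.ConservedSequenceDescriptor("Acar", 2, 50, 80, frozenset("S"))
        with pytest.raises(DomainError):
            en.cs_name(desc)

    def test_fractional_conservation_rounds_half_up(self):
        assert en.conservation_class(94.5) == 1
        assert en.conservation_class(94.4) == 2
        assert en.conservation_class(89.5) == 2
        assert en.conservation_class(84.5) == 3
        with pytest.raises(DomainError):
            en.conservation_class(84.4)

    def test_taxa_always_serialized_in_canonical_order(self):
        desc = en.ConservedSequenceDescriptor(
            "Acar", 5, 600, 97, frozenset(["B", "S", "M"])
        )
        assert en.cs_name(desc).endswith("SMB")

    def test_empty_taxa_rejected(self):
        with pytest.raises(DomainError):
            en.ConservedSequenceDescriptor("Acar", 5, 600, 97, frozenset())


class TestCSParse:
    def test_worked_name(self):
        f = en.cs_parse("Acar1000l1SMB")
        assert f.species_code == "Acar"
        assert f.index == 1000
        assert f.length_class == "l" and f.length_bounds == (500, None)
        assert f.conservation_class == 1 and f.conservation_bounds == (95, 100)
        assert f.taxa == frozenset("SMB")

    def test_boundary_round_trip(self):
        f = en.cs_parse("Acar1s1S")
        assert (f.species_code, f.index, f.length_class, f.conservation_class) == (
            "Acar",
            1,
            "s",
            1,
        )

    @pytest.mark.parametrize(
        "bad", ["Acar1x1S", "acar1s1S", "Acar1s4S", "Acar1s1Z", "Acar1s1SS", "Acars1S"]
    )
    def test_grammar_errors(self, bad):
        with pytest.raises(GrammarError):
            en.cs_parse(bad)

    @settings(max_examples=100, deadline=None)
    @given(
        index=st.integers(min_value=1, max_value=10**6),
        length=st.integers(min_value=1, max_value=2000),
        pct=st.integers(min_value=85, max_value=100),
        taxa=st.sets(st.sampled_from("SMBG"), min_size=1),
    )
    def test_parse_inverts_name(self, index, length, pct, taxa):
        desc = en.ConservedSequenceDescriptor(
            "Acar", index, length, pct, frozenset(taxa)
        )
        f = en.cs_parse(en.cs_name(desc))
        assert f.index == index
        assert f.length_class == en.length_class(length)
        assert f.conservation_class == en.conservation_class(pct)
        assert f.taxa == frozenset(taxa)
        lo, hi = f.length_bounds
        assert lo <= length and (hi is None or length <= hi)
        clo, chi = f.conservation_bounds
        assert clo <= pct <= chi


class TestSTRNames:
    @pytest.mark.parametrize(
        "code, index, expected",
        [("Acar", 8, "Acar_str_8"), ("Acar", 1, "Acar_str_1"), ("Asag", 3, "Asag_str_3")],
    )
    def test_name_grammar(self, code, index, expected):
        assert en.str_name(code, index) == expected
        assert en.str_parse(expected) == (code, index)

    def test_zero_index_rejected(self):
        with pytest.raises(DomainError):
            en.str_name("Acar", 0)

    def test_bad_names_rejected(self):
        for bad in ("Acar_str_0", "Acar_STR_1", "acar_str_1", "Acar_str_"):
            with pytest.raises(GrammarError):
                en.str_parse(bad)


class TestScanSTRs:
    def test_dinucleotide_run(self):
        records = en.scan_strs("ACACACAC", min_unit=2, max_unit=2, min_copies=3)
        assert len(records) == 1
        rec = records[0]
        assert (rec.unit, rec.copies, rec.start, rec.end) == ("AC", 4, 0, 8)
        assert rec.name == "Acar_str_1"

    def test_no_repeat(self):
        assert en.scan_strs("ACGT") == []

    def test_two_runs_indexed_in_scan_order(self):
        records = en.scan_strs("AAAACGTGCATTTTTT", min_copies=3)
        assert [r.index for r in records] == [1, 2]
        assert records[0].unit == "A" and records[0].copies == 4
        assert records[1].unit == "T" and records[1].copies == 6

    def test_unit_reported_in_minimal_rotation(self):
        records = en.scan_strs("GATGATGATGAT", min_unit=3, max_unit=3, min_copies=3)
        assert records[0].unit == "ATG"

    def test_invalid_alphabet(self):
        with pytest.raises(SequenceError):
            en.scan_strs("ACGU")

    @settings(max_examples=100, deadline=None)
    @given(
        seq=st.text(alphabet="ACGT", min_size=0, max_size=120),
        min_copies=st.integers(min_value=2, max_value=4),
    )
    def test_matches_quadratic_oracle(self, seq, min_copies):
        got = [
            (r.start, r.end, r.copies)
            for r in en.scan_strs(seq, min_copies=min_copies)
        ]
        assert got == oracle_scan(seq, min_copies=min_copies)

    def test_random_long_sequences_match_oracle(self):
        rng = random.Random(5)
        for _ in range(20):
            seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(100, 500)))
            got = [(r.start, r.end, r.copies) for r in en.scan_strs(seq)]
            assert got == oracle_scan(seq)


class TestSTRRegistry:
    def test_indices_gap_free_and_persistent(self, tmp_path):
        registry = en.STRRegistry("Acar")
        registry.extend(en.scan_strs("AAAACGTGCATTTTTT", min_copies=3))
        registry.add("AG", 5, seq_id="scaf1", start=40, end=50)
        assert [r.index for r in registry.records] == [1, 2, 3]
        path = tmp_path / "strs.tsv"
        registry.to_tsv(path)
        reloaded = en.STRRegistry.from_tsv(path)
        assert reloaded.records == registry.records
        assert reloaded.by_name("Acar_str_3").unit == "AG"

    def test_reload_rejects_index_gaps(self, tmp_path):
        path = tmp_path / "strs.tsv"
        path.write_text(
            "name\tunit\tcopies\tseq_id\tstart\tend\n"
            "Acar_str_2\tAC\t3\ts\t0\t6\n"
        )
        with pytest.raises(GrammarError):
            en.STRRegistry.from_tsv(path)


class TestTENames:
    @pytest.mark.parametrize(
        "fields, expected",
        [
            (en.TEName("Helitron", 1, "Acar"), "Helitron-1_Acar"),
            (en.TEName("Helitron", 1, "Acar", nonautonomous_id=1), "Helitron-1N1_Acar"),
            (
                en.TEName("hAT", 1, "Acar", horizontally_transferred=True),
                "hAT-HT1_Acar",
            ),
            (en.TEName("hobo", 1, "Acar"), "hobo-1_Acar"),
        ],
    )
    def test_worked_examples_round_trip(self, fields, expected):
        assert en.te_name(fields) == expected
        assert en.te_parse(expected) == fields

    def test_parse_extracts_lineage_and_family(self):
        t = en.te_parse("hobo-1_Acar")
        assert (t.lineage, t.family_id) == ("hobo", 1)
        assert not t.horizontally_transferred and t.nonautonomous_id is None

    @pytest.mark.parametrize(
        "bad",
        ["Helitron_1_Acar", "Helitron-0_Acar", "Heli-tron-1_Acar",
         "Helitron-1_acar", "Helitron-N1_Acar", "1-1_Acar"],
    )
    def test_grammar_errors(self, bad):
        with pytest.raises(GrammarError):
            en.te_parse(bad)

    @settings(max_examples=100, deadline=None)
    @given(
        lineage=st.from_regex(r"[A-Za-z][A-Za-z0-9]{0,9}", fullmatch=True),
        family=st.integers(min_value=1, max_value=999),
        nonauto=st.one_of(st.none(), st.integers(min_value=1, max_value=99)),
        ht=st.booleans(),
    )
    def test_round_trip_identity(self, lineage, family, nonauto, ht):
        t = en.TEName(
            lineage=lineage,
            family_id=family,
            species_code="Acar",
            nonautonomous_id=nonauto,
            horizontally_transferred=ht,
        )
        assert en.te_parse(en.te_name(t)) == t
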