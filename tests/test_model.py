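"""Table readers/writers, record invariants and world assembly."""

from __future__ import annotations

import logging

import pytest
from hypothesis import given
from hypothesis import strategies as st

from vaultgap.model import (
    UNKNOWN,
    AccessionRecord,
    DepositRecord,
    HoldingsRecord,
    InstitutionRecord,
    IntegrityError,
    SchemaError,
    assemble_world,
    normalize_country,
    read_deposits,
    read_holdings_summary,
    read_institution_registry,
    read_passport_table,
    write_deposits,
    write_holdings_summary,
    write_institution_registry,
    write_passport_table,
)


def _write(tmp_path, name, text):
    path = tmp_path / name
    path.write_text(text)
    return path


class TestPassportReader:
    def test_row_count_and_sentinel(self, tmp_path):
        path = _write(
            tmp_path,
            "p.csv",
            "INSTCODE,ACCENUMB,GENUS,SPECIES,ORIGCTY\n"
            "NOR001,A1,Hordeum,vulgare,NOR\n"
            "NOR001,A2,Hordeum,vulgare,\n"
            "NOR001,A3,Avena,,ETH\n",
        )
        records = read_passport_table(path)
        assert len(records) == 3
        assert records[1].origin_country == UNKNOWN
        assert records[2].species_epithet == ""

    def test_hand_enumerated_toy_file(self, tmp_path):
        """A 20-row file read field-by-field against a hand-built list."""
        genera = ["Triticum", "Oryza", "Zea", "Phaseolus"]
        lines = ["INSTCODE,ACCENUMB,GENUS,SPECIES,ORIGCTY"]
        expected = []
        for i in range(20):
            inst = f"INS{i % 3}"
            genus = genera[i % 4]
            origin = ["NOR", "ETH", ""][i % 3]
            lines.append(f"{inst},ACC{i},{genus},sp{i},{origin}")
            expected.append(
                AccessionRecord(inst, f"ACC{i}", genus, f"sp{i}",
                                origin or UNKNOWN)
            )
        records = read_passport_table(_write(tmp_path, "t.csv", "\n".join(lines)))
        assert records == expected

    def test_missing_column_names_it(self, tmp_path):
        path = _write(tmp_path, "p.csv", "INSTCODE,GENUS,ORIGCTY\nA,B,NOR\n")
        with pytest.raises(SchemaError, match="accession_id"):
            read_passport_table(path)

    def test_duplicate_pair_lists_offenders(self, tmp_path):
        path = _write(
            tmp_path,
            "p.csv",
            "INSTCODE,ACCENUMB,GENUS,SPECIES,ORIGCTY\n"
            "X,A1,Zea,mays,MEX\nX,A1,Zea,mays,MEX\n",
        )
        with pytest.raises(IntegrityError, match="X/A1"):
            read_passport_table(path)

    def test_alpha2_codes_translated(self, tmp_path):
        path = _write(
            tmp_path,
            "p.csv",
            "INSTCODE,ACCENUMB,GENUS,SPECIES,ORIGCTY\nX,A1,Zea,mays,mx\n",
        )
        assert read_passport_table(path)[0].origin_country == "MEX"


class TestRegistryReader:
    def test_flags_parsed(self, tmp_path):
        path = _write(
            tmp_path,
            "r.csv",
            "institute_code,country,inst_type,article15,sda_signed,sgsv_depositor\n"
            "IRRI,PHL,international_IARC,yes,true,1\n"
            "NOR001,NOR,national,0,no,false\n",
        )
        iarc, nat = read_institution_registry(path)
        assert iarc.article15 and iarc.sda_signed and iarc.sgsv_depositor
        assert not (nat.article15 or nat.sda_signed or nat.sgsv_depositor)

    def test_article15_on_national_warns_but_accepts(self, tmp_path, caplog):
        path = _write(
            tmp_path,
            "r.csv",
            "institute_code,country,inst_type,article15,sda_signed,sgsv_depositor\n"
            "N1,NOR,national,1,0,0\n",
        )
        with caplog.at_level(logging.WARNING, logger="vaultgap.model"):
            records = read_institution_registry(path)
        assert records[0].article15
        assert "article15" in caplog.text

    def test_empty_file_with_header(self, tmp_path):
        path = _write(
            tmp_path,
            "r.csv",
            "institute_code,country,inst_type,article15,sda_signed,sgsv_depositor\n",
        )
        assert read_institution_registry(path) == []

    @pytest.mark.parametrize(
        "row,error",
        [
            ("N1,NOR,megabank,0,0,0", SchemaError),
            ("N1,NOR,national,maybe,0,0", SchemaError),
        ],
    )
    def test_bad_tokens(self, tmp_path, row, error):
        path = _write(
            tmp_path,
            "r.csv",
            "institute_code,country,inst_type,article15,sda_signed,sgsv_depositor\n"
            + row + "\n",
        )
        with pytest.raises(error):
            read_institution_registry(path)

    def test_duplicate_code(self, tmp_path):
        path = _write(
            tmp_path,
            "r.csv",
            "institute_code,country,inst_type,article15,sda_signed,sgsv_depositor\n"
            "N1,NOR,national,0,0,0\nN1,SWE,national,0,0,0\n",
        )
        with pytest.raises(IntegrityError, match="N1"):
            read_institution_registry(path)


class TestHoldingsReader:
    def test_counts_and_absent_indigenous(self, tmp_path):
        path = _write(
            tmp_path,
            "h.csv",
            "institute_code,genus,n_total,n_indigenous\n"
            "K001,Eleusine,100,40\nK001,Sorghum,50,\n",
        )
        a, b = read_holdings_summary(path)
        assert (a.n_total, a.n_indigenous) == (100, 40)
        assert b.n_indigenous is None  # absent, not zero

    def test_hand_tally_per_genus(self, tmp_path):
        rows = [("I0", "Zea", 5), ("I1", "Zea", 7), ("I0", "Oryza", 3),
                ("I2", "Zea", 11), ("I1", "Oryza", 2), ("I3", "Avena", 9),
                ("I2", "Oryza", 6), ("I3", "Zea", 1), ("I0", "Avena", 4),
                ("I1", "Avena", 8)]
        text = "institute_code,genus,n_total\n" + "\n".join(
            f"{i},{g},{n}" for i, g, n in rows
        )
        records = read_holdings_summary(_write(tmp_path, "h.csv", text))
        tally = {}
        for _, g, n in rows:
            tally[g] = tally.get(g, 0) + n
        got = {}
        for r in records:
            got[r.genus] = got.get(r.genus, 0) + r.n_total
        assert got == tally == {"Zea": 24, "Oryza": 11, "Avena": 21}

    def test_negative_count_rejected(self, tmp_path):
        path = _write(tmp_path, "h.csv",
                      "institute_code,genus,n_total\nK,Zea,-3\n")
        with pytest.raises(ValueError):
            read_holdings_summary(path)

    def test_indigenous_exceeding_total_rejected(self, tmp_path):
        path = _write(tmp_path, "h.csv",
                      "institute_code,genus,n_total,n_indigenous\nK,Zea,5,9\n")
        with pytest.raises(IntegrityError):
            read_holdings_summary(path)


def test_deposits_duplicate_pair_rejected(tmp_path):
    path = _write(tmp_path, "d.csv",
                  "depositor_code,genus,n_deposited\nX,Zea,5\nX,Zea,2\n")
    with pytest.raises(IntegrityError, match="X/Zea"):
        read_deposits(path)


def test_normalize_country_unmappable_is_unknown():
    assert normalize_country("XQZ9") == UNKNOWN
    assert normalize_country("") == UNKNOWN
    assert normalize_country("nor") == "NOR"


# ---------------------------------------------------------------------------
# round-trip properties

_code = st.text(alphabet="ABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789", min_size=1, max_size=8)
_genus = st.sampled_from(["Zea", "Oryza", "Triticum", "Phaseolus", "Eleusine"])
_country = st.sampled_from(["NOR", "ETH", "MEX", "IND", UNKNOWN])


@given(
    st.lists(
        st.tuples(_code, _code, _genus, st.sampled_from(["", "mays", "sativa"]),
                  _country),
        max_size=20,
        unique_by=lambda t: (t[0], t[1]),
    )
)
def test_passport_round_trip(tmp_path_factory, rows):
    records = [AccessionRecord(*row) for row in rows]
    path = tmp_path_factory.mktemp("rt") / "p.csv"
    write_passport_table(records, path)
    assert read_passport_table(path) == records


@given(
    st.lists(
        st.tuples(_code, _country, st.sampled_from(
            ["national", "subnational", "regional", "international_IARC", "other"]),
            st.booleans(), st.booleans(), st.booleans()),
        max_size=15,
        unique_by=lambda t: t[0],
    )
)
def test_registry_round_trip(tmp_path_factory, rows):
    records = [
        InstitutionRecord(code, c, t, a15 and t == "international_IARC", sda, dep)
        for code, c, t, a15, sda, dep in rows
    ]
    path = tmp_path_factory.mktemp("rt") / "r.csv"
    write_institution_registry(records, path)
    assert read_institution_registry(path) == records


@given(
    st.lists(
        st.tuples(_code, _genus, st.integers(0, 10_000),
                  st.one_of(st.none(), st.integers(0, 10_000))),
        max_size=20,
    )
)
def test_holdings_round_trip(tmp_path_factory, rows):
    records = [
        HoldingsRecord(code, g, max(total, indig or 0), indig)
        for code, g, total, indig in rows
    ]
    path = tmp_path_factory.mktemp("rt") / "h.csv"
    write_holdings_summary(records, path)
    assert read_holdings_summary(path) == records


@given(
    st.lists(
        st.tuples(_code, _genus, st.integers(0, 10_000)),
        max_size=20,
        unique_by=lambda t: (t[0], t[1]),
    )
)
def test_deposits_round_trip(tmp_path_factory, rows):
    records = [DepositRecord(*row) for row in rows]
    path = tmp_path_factory.mktemp("rt") / "d.csv"
    write_deposits(records, path)
    assert read_deposits(path) == records


# ---------------------------------------------------------------------------
# assembly


class TestAssembleWorld:
    def test_empty_world_zero_counts(self):
        world, report = assemble_world([], [], [], [])
        assert world.accessions == () and world.deposits == ()
        assert (report.n_accessions, report.n_holdings, report.n_institutions,
                report.n_deposits) == (0, 0, 0, 0)

    def test_unresolved_code_named(self):
        deposit = DepositRecord("GHOST1", "Zea", 5)
        with pytest.raises(IntegrityError, match="GHOST1"):
            assemble_world([], [], [], [deposit])

    def test_report_counts_match_inputs(self):
        registry = [InstitutionRecord("A", "NOR", "national")]
        accs = [AccessionRecord("A", f"x{i}", "Zea") for i in range(4)]
        holds = [HoldingsRecord("A", "Zea", 4)]
        deps = [DepositRecord("A", "Zea", 2)]
        world, report = assemble_world(accs, holds, registry, deps)
        assert report.n_accessions == len(world.accessions) == 4
        assert report.n_holdings == 1 and report.n_deposits == 1

    def test_synthetic_world_round_trip(self, tmp_path):
        """Write a generated world's tables, re-read, re-assemble: identity."""
        from vaultgap.synthetic import SyntheticWorldConfig, generate_world

        world, _ = generate_world(SyntheticWorldConfig(), seed=11)
        write_passport_table(world.accessions, tmp_path / "p.csv")
        write_institution_registry(world.registry, tmp_path / "r.csv")
        write_holdings_summary(world.holdings, tmp_path / "h.csv")
        write_deposits(world.deposits, tmp_path / "d.csv")
        again, _ = assemble_world(
            read_passport_table(tmp_path / "p.csv"),
            read_holdings_summary(tmp_path / "h.csv"),
            read_institution_registry(tmp_path / "r.csv"),
            read_deposits(tmp_path / "d.csv"),
        )
        assert again == world
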