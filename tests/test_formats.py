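"""Strict-dialect readers and writers: normalization, referential integrity,
round trips on generated data."""

import numpy as np
import pytest

from remotethread import formats as fm
from remotethread.fixtures import random_sequence


@pytest.fixture
def rng():
    return np.random.default_rng(42)


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nACDE\n")
        recs = fm.read_fasta(p)
        assert recs == [fm.SequenceRecord(id="p1", residues="ACDE")]

    def test_normalization_drops_stop_and_uppercases(self, tmp_path, caplog):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nacde*\n")
        recs = fm.read_fasta(p)
        assert recs[0].residues == "ACDE"

    def test_nonstandard_letters_become_x(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nABZUO-C\n")
        assert fm.read_fasta(p)[0].residues == "AXXXXXC"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fasta"
        p.write_text("")
        with pytest.raises(fm.FormatError, match="no records"):
            fm.read_fasta(p)

    def test_duplicate_ids_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">p1\nAC\n>p1\nDE\n")
        with pytest.raises(fm.FormatError, match="duplicate"):
            fm.read_fasta(p)

    def test_round_trip_50_random_records(self, tmp_path, rng):
        recs = [
            fm.SequenceRecord(id=f"p{i}", residues=random_sequence(rng, int(rng.integers(5, 80))))
            for i in range(50)
        ]
        path = tmp_path / "rt.fasta"
        fm.write_fasta(recs, path)
        back = fm.read_fasta(path)
        assert [(r.id, r.residues) for r in back] == [(r.id, r.residues) for r in recs]


class TestProfiles:
    def _random_profile(self, rng, acc, length, calibrated=True):
        scores = np.round(rng.normal(size=(length, 20)), 6)
        cal = (float(rng.normal()), float(rng.uniform(0.1, 1.0))) if calibrated else None
        return fm.DomainProfile(
            accession=acc, name=f"fam_{acc}", clan="CL001" if rng.random() < 0.5 else None,
            length=length, match_scores=scores, calibration=cal, db_version="vT",
        )

    def test_round_trip(self, tmp_path, rng):
        profiles = [self._random_profile(rng, f"PF{i:03d}", int(rng.integers(3, 30)))
                    for i in range(10)]
        path = tmp_path / "db.tsv"
        fm.write_profiles(profiles, path)
        back = fm.read_profiles(path)
        assert len(back) == len(profiles)
        for a, b in zip(profiles, back):
            assert (a.accession, a.name, a.clan, a.length, a.db_version) == (
                b.accession, b.name, b.clan, b.length, b.db_version)
            np.testing.assert_allclose(a.match_scores, b.match_scores, atol=1e-6)
            assert b.calibration == pytest.approx(a.calibration, rel=1e-6)

    def test_row_count_mismatch_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text(">PF1 length=2\n" + "\t".join(["0.0"] * 20) + "\n")
        with pytest.raises(fm.FormatError, match="declares"):
            fm.read_profiles(path)

    def test_negative_calibration_scale_rejected(self):
        with pytest.raises(fm.FormatError, match="scale"):
            fm.DomainProfile(
                accession="PF1", name="x", length=1,
                match_scores=np.zeros((1, 20)), calibration=(0.0, -1.0),
            )


class TestStructureTables:
    def test_map_groups_structures(self, tmp_path):
        lib = [fm.StructureEntry(s, "f", 10) for s in ("s1", "s2", "s3")]
        path = tmp_path / "map.tsv"
        path.write_text("PF_A\ts1\nPF_A\ts2\nPF_B\ts3\nPF_A\ts1\n")
        assert fm.read_structure_map(path, lib) == {"PF_A": {"s1", "s2"}, "PF_B": {"s3"}}

    def test_unknown_structure_named_in_error(self, tmp_path):
        lib = [fm.StructureEntry("s1", "f", 10)]
        path = tmp_path / "map.tsv"
        path.write_text("PF_A\ts9\n")
        with pytest.raises(fm.FormatError, match="s9"):
            fm.read_structure_map(path, lib)

    def test_map_round_trip_generated(self, tmp_path, rng):
        lib = [fm.StructureEntry(f"s{i:04d}", "f", 10) for i in range(1000)]
        mapping = {}
        for i in range(200):
            ids = rng.choice(1000, size=int(rng.integers(1, 6)), replace=False)
            mapping[f"PF{i:04d}"] = {f"s{j:04d}" for j in ids}
        path = tmp_path / "map.tsv"
        fm.write_structure_map(mapping, path)
        assert fm.read_structure_map(path, lib) == mapping

    def test_manifest_round_trip(self, tmp_path, rng):
        entries = [fm.StructureEntry(f"d{i}", f"fold{i % 5}", int(rng.integers(20, 200)))
                   for i in range(50)]
        path = tmp_path / "m.tsv"
        fm.write_structure_manifest(entries, path)
        assert fm.read_structure_manifest(path) == entries


class TestAuxTables:
    def test_ortholog_table_round_trip(self, tmp_path):
        table = {"q1": {"sp1": "q1_sp1", "sp2": "q1_sp2"}, "q2": {"sp1": "q2_sp1"}}
        path = tmp_path / "o.tsv"
        fm.write_ortholog_table(table, path)
        assert fm.read_ortholog_table(path) == table

    def test_essential_residue_positions_are_one_based_on_disk(self, tmp_path):
        path = tmp_path / "e.tsv"
        fm.write_essential_residues({"PF_A": [(0, "K"), (9, "R")]}, path)
        text = path.read_text()
        assert "PF_A\t1\tK" in text and "PF_A\t10\tR" in text
        assert fm.read_essential_residues(path) == {"PF_A": [(0, "K"), (9, "R")]}

    def test_background_round_trip(self, tmp_path, rng):
        vals = np.round(rng.normal(size=500), 6)
        path = tmp_path / "z.txt"
        fm.write_background_zscores(vals, path)
        np.testing.assert_allclose(fm.read_background_zscores(path), vals, atol=1e-6)


class TestHitsReport:
    def _rows(self, rng, n):
        rows = []
        for i in range(n):
            level = int(rng.integers(0, 4))
            scored = rng.random() < 0.7
            rows.append(fm.ReportRow(
                protein_id=f"p{i}", profile_accession=f"PF{i % 7}",
                start=int(rng.integers(0, 50)), end=int(rng.integers(60, 120)),
                evalue=float(np.round(rng.uniform(1e-6, 40), 6)),
                tier="remote_validated" if scored else "significant",
                p_cdf=0.001 if scored else None,
                p_hyper=0.02 if scored else None,
                p_combined=2e-5 if scored else None,
                validation_level=level if scored else None,
                no_validation_data=False,
                short_domain=bool(rng.random() < 0.2),
            ))
        return rows

    def test_empty_call_list_gives_header_only(self, tmp_path):
        path = tmp_path / "r.tsv"
        fm.write_hits_report([], path)
        lines = path.read_text().splitlines()
        assert lines and all(l.startswith("#") for l in lines)
        assert "1-based inclusive" in "\n".join(lines)

    def test_level_two_uses_species_tag(self, tmp_path):
        row = fm.ReportRow("p1", "PF_A", 9, 40, 2.0, "remote_validated",
                           p_cdf=1e-3, p_hyper=1e-2, p_combined=1e-5,
                           validation_level=2)
        path = tmp_path / "r.tsv"
        fm.write_hits_report([row], path)
        assert "2-species" in path.read_text()

    def test_round_trip_100_calls(self, tmp_path):
        rng = np.random.default_rng(5)
        rows = self._rows(rng, 100)
        path = tmp_path / "r.tsv"
        fm.write_hits_report(rows, path)
        back = fm.parse_hits_report(path)
        assert len(back) == len(rows)
        for a, b in zip(rows, back):
            assert (a.protein_id, a.profile_accession, a.start, a.end, a.tier,
                    a.validation_level, a.short_domain) == (
                b.protein_id, b.profile_accession, b.start, b.end, b.tier,
                b.validation_level, b.short_domain)
            assert b.evalue == pytest.approx(a.evalue, rel=1e-5)

    def test_json_twin_written(self, tmp_path):
        import json
        path = tmp_path / "r.tsv"
        fm.write_hits_report(self._rows(np.random.default_rng(6), 5), path)
        twin = json.loads((tmp_path / "r.tsv.json").read_text())
        assert twin["coordinates"] == "1-based inclusive"
        assert len(twin["calls"]) == 5
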