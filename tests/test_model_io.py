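"""Domain types and tabular IO: fingerprints, readers, round-trips."""

import numpy as np
import pytest

from drugsig.errors import FormatError, ValidationError
from drugsig.model import Compound, Fingerprint, GoldStandardTargets, SignatureMatrix
from drugsig import io
from drugsig.simulate import SyntheticConfig, generate, write_fixture


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text, encoding="utf-8")
    return p


class TestFingerprint:
    def test_sparse_round_trip(self):
        fp = Fingerprint(frozenset({3, 1, 17}), 32)
        assert fp.to_sparse() == "1;3;17"
        assert Fingerprint.from_sparse("1;3;17", 32) == fp
        assert Fingerprint.from_sparse("", 32).bits == frozenset()

    def test_bit_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            Fingerprint(frozenset({32}), 32)

    def test_smiles_determinism_and_failure(self):
        a = Fingerprint.from_smiles("c1ccccc1O", 128)
        b = Fingerprint.from_smiles("c1ccccc1O", 128)
        assert a == b and a.n_bits > 0
        assert Fingerprint.from_smiles("not-a-smiles", 128) is None


class TestCompoundLibrary:
    def test_three_valid_rows_all_fingerprinted(self, tmp_path):
        p = _write(tmp_path, "c.tsv",
                   "id\tname\tsmiles\tapproved\n"
                   "D1\tmethane\tC\t1\n"
                   "D2\tphenol\tc1ccccc1O\t0\n"
                   "D3\tethanol\tCCO\t1\n")
        comps = io.read_compound_library(p, fingerprint_width=128)
        assert len(comps) == 3
        assert all(c.scoreable for c in comps)
        assert comps[0].heavy_atoms == 1          # methane: one non-hydrogen atom
        assert comps[0].approved and not comps[1].approved

    def test_unparseable_smiles_flagged_not_dropped(self, tmp_path):
        p = _write(tmp_path, "c.tsv",
                   "id\tname\tsmiles\tapproved\nD1\tbad\tC((C\t1\nD2\tok\tCCO\t0\n")
        comps = io.read_compound_library(p, 128)
        assert len(comps) == 2
        bad = comps[0]
        assert bad.flagged and bad.fingerprint is None and not bad.scoreable

    def test_sparse_fingerprint_column_bypasses_chemistry(self, tmp_path):
        p = _write(tmp_path, "c.tsv",
                   "id\tname\tsmiles\tapproved\tfingerprint\theavy_atoms\n"
                   "D1\tsynthetic\t\t1\t0;5;9\t12\n")
        (c,) = io.read_compound_library(p, 32)
        assert c.fingerprint.bits == frozenset({0, 5, 9})
        assert c.heavy_atoms == 12

    def test_duplicate_ids_rejected(self, tmp_path):
        p = _write(tmp_path, "c.tsv",
                   "id\tname\tsmiles\tapproved\nD1\ta\tC\t1\nD1\tb\tC\t1\n")
        with pytest.raises(ValidationError, match="duplicate"):
            io.read_compound_library(p, 64)

    def test_missing_column_rejected(self, tmp_path):
        p = _write(tmp_path, "c.tsv", "id\tsmiles\nD1\tC\n")
        with pytest.raises(FormatError, match="missing required columns"):
            io.read_compound_library(p, 64)


class TestBindingSiteTable:
    def test_rows_grouped_by_protein(self, tmp_path):
        p = _write(tmp_path, "b.tsv",
                   "protein_id\tsite_id\tligand\tconfidence\n"
                   "P1\tS0\t0;1\t0.9\nP1\tS1\t2;3\t0.4\nP2\tS0\t1;2\t0.5\n")
        prots = io.read_binding_site_table(p, 32)
        assert [pr.id for pr in prots] == ["P1", "P2"]
        assert len(prots[0].predictions) == 2
        assert prots[0].predictions[0].confidence == 0.9

    def test_empty_table_gives_empty_library(self, tmp_path):
        p = _write(tmp_path, "b.tsv", "protein_id\tsite_id\tligand\tconfidence\n")
        assert io.read_binding_site_table(p, 32) == []

    def test_confidence_out_of_range_names_row(self, tmp_path):
        p = _write(tmp_path, "b.tsv",
                   "protein_id\tsite_id\tligand\tconfidence\nP1\tS0\t0;1\t1.2\n")
        with pytest.raises(ValidationError, match="row 2"):
            io.read_binding_site_table(p, 32)


class TestIndicationMapping:
    COMPS = [Compound(id=f"D{i}") for i in range(1, 6)]

    def test_association_count_preserved(self, tmp_path):
        p = _write(tmp_path, "m.tsv",
                   "indication_id\tindication_name\tcompound_id\n"
                   "I1\tflu\tD1\nI1\tflu\tD2\nI1\tflu\tD3\nI2\tcold\tD4\nI2\tcold\tD5\n")
        maps = io.read_indication_mapping(p, self.COMPS)
        assert len(maps) == 2
        assert sum(m.n_approved for m in maps) == 5

    def test_duplicate_associations_deduplicated(self, tmp_path):
        p = _write(tmp_path, "m.tsv",
                   "indication_id\tindication_name\tcompound_id\n"
                   "I1\tflu\tD1\nI1\tflu\tD1\nI1\tflu\tD2\n")
        (m,) = io.read_indication_mapping(p, self.COMPS)
        assert m.approved_compound_ids == frozenset({"D1", "D2"})

    def test_unknown_compound_skipped_single_drug_flagged(self, tmp_path, caplog):
        p = _write(tmp_path, "m.tsv",
                   "indication_id\tindication_name\tcompound_id\n"
                   "I1\tflu\tD1\nI1\tflu\tDX\n")
        with caplog.at_level("WARNING"):
            (m,) = io.read_indication_mapping(p, self.COMPS)
        assert m.n_approved == 1 and not m.benchmarkable
        assert "not in library" in caplog.text


class TestMatrixIO:
    def test_round_trip_at_precision(self, tmp_path, rng):
        vals = np.round(rng.random((3, 4)), 6)
        mat = SignatureMatrix(vals, ["C1", "C2", "C3"], ["P1", "P2", "P3", "P4"])
        path = tmp_path / "m.tsv"
        io.write_matrix(mat, path, header_comments=["stage=test"])
        back = io.read_matrix(path)
        assert back.compound_ids == mat.compound_ids
        assert back.protein_ids == mat.protein_ids
        np.testing.assert_array_equal(back.values, vals)

    def test_fixed_precision_serialization(self, tmp_path):
        mat = SignatureMatrix(np.array([[0.85]]), ["C1"], ["P1"])
        path = tmp_path / "m.tsv"
        io.write_matrix(mat, path)
        assert "0.850000" in path.read_text()

    def test_empty_matrix_round_trips(self, tmp_path):
        mat = SignatureMatrix(np.zeros((0, 2)), [], ["P1", "P2"])
        path = tmp_path / "m.tsv"
        io.write_matrix(mat, path)
        back = io.read_matrix(path)
        assert back.shape == (0, 2) and back.protein_ids == ["P1", "P2"]

    def test_label_mismatch_rejected(self, tmp_path):
        mat = SignatureMatrix(np.zeros((1, 1)), ["C1"], ["P1"])
        path = tmp_path / "m.tsv"
        io.write_matrix(mat, path)
        with pytest.raises(FormatError):
            io.read_matrix(path, expected_compounds=["C2"])

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValidationError):
            SignatureMatrix(np.array([[1.5]]), ["C1"], ["P1"])


def test_gold_standard_requires_nonempty():
    with pytest.raises(ValidationError):
        GoldStandardTargets("empty", frozenset())


def test_synthetic_fixture_passes_all_readers(tmp_path):
    """Round-trip identity: generated files load back to equivalent objects."""
    data = generate(SyntheticConfig(n_compounds=20, n_proteins=10, n_indications=2,
                                    drugs_per_indication=3, theme_size=2, seed=7))
    paths = write_fixture(data, tmp_path)
    comps = io.read_compound_library(paths["compounds"],
                                     data.config.fingerprint_width)
    assert [c.id for c in comps] == [c.id for c in data.compounds]
    assert all(a.fingerprint == b.fingerprint for a, b in zip(comps, data.compounds))
    prots = io.read_binding_site_table(paths["binding_sites"],
                                       data.config.fingerprint_width)
    assert [p.id for p in prots] == [p.id for p in data.proteins]
    assert all(len(a.predictions) == len(b.predictions)
               for a, b in zip(prots, data.proteins))
    maps = io.read_indication_mapping(paths["mapping"], comps)
    assert {m.indication_id: m.approved_compound_ids for m in maps} == \
           {m.indication_id: m.approved_compound_ids for m in data.mappings}
    gold = io.read_gold_standards(paths["gold"])
    assert {g.source_label: g.protein_ids for g in gold} == \
           {g.source_label: g.protein_ids for g in data.gold_standards}


def test_similarity_list_round_trip(tmp_path):
    from drugsig import build_signature_matrix, rank_all

    data = generate(SyntheticConfig(n_compounds=12, n_proteins=6, n_indications=2,
                                    drugs_per_indication=2, theme_size=2, seed=3))
    lists = rank_all(build_signature_matrix(data.compounds, data.proteins))
    path = tmp_path / "sim.tsv"
    io.write_similarity_lists(lists, path)
    back = io.read_similarity_lists(path)
    assert set(back) == {sl.query_id for sl in lists}
    for sl in lists:
        got = back[sl.query_id].entries
        assert [(e.compound_id, e.rank) for e in got] == \
               [(e.compound_id, e.rank) for e in sl.entries]
        assert all(abs(a.distance - b.distance) < 1e-9
                   for a, b in zip(got, sl.entries))
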