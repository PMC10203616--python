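import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from itcep.alphabet import AA_INDEX, AMINO_ACIDS
from itcep.encoders import (
    AAPPTable,
    build_aapp_table,
    compute_aac,
    encode_onehot_pair,
    encode_phychem_pair,
    fuse_pair,
    load_phychem_table,
    lookup_aapp,
)
from itcep.io_data import PairRecord
from itcep.nearest_peptide import edit_distance

PEPTIDE = "NLVPMVATV"
CDR3 = "CASSQWSNEKLFF"

seq_strategy = st.text(alphabet=AMINO_ACIDS, min_size=1, max_size=21)


@pytest.fixture(scope="module")
def table():
    return load_phychem_table()


@pytest.fixture(scope="module")
def tables():
    aapp = build_aapp_table([PairRecord(PEPTIDE, c, 1) for c in ("CASSLGQF", "CASSPGQF")])
    return aapp, load_phychem_table()


class TestOnehot:
    def test_example_pair_geometry(self):
        fm = encode_onehot_pair(PEPTIDE, CDR3)
        assert fm.values.shape == (32, 20)
        assert fm.n_entries == 640
        assert int(fm.values.sum()) == len(PEPTIDE) + len(CDR3) == 22
        zero_rows = int(np.sum(~fm.values.any(axis=1)))
        assert zero_rows == (11 - len(PEPTIDE)) + (21 - len(CDR3)) == 10

    def test_blocks_are_peptide_then_cdr3(self):
        fm = encode_onehot_pair(PEPTIDE, CDR3)
        # First peptide residue N and first CDR3 residue C at their rows.
        assert fm.values[0, AA_INDEX["N"]] == 1.0
        assert fm.values[11, AA_INDEX["C"]] == 1.0

    def test_max_lengths_no_zero_rows(self):
        fm = encode_onehot_pair("A" * 11, "C" + "A" * 20)
        assert not np.any(~fm.values.any(axis=1))

    def test_row_sums_zero_or_one(self):
        fm = encode_onehot_pair(PEPTIDE, CDR3)
        assert set(np.unique(fm.values.sum(axis=1))) <= {0.0, 1.0}

    def test_column_sums_count_residues(self):
        fm = encode_onehot_pair(PEPTIDE, CDR3)
        combined = PEPTIDE + CDR3
        for aa in AMINO_ACIDS:
            assert fm.values[:, AA_INDEX[aa]].sum() == combined.count(aa)

    @pytest.mark.parametrize("peptide,cdr3", [("NLVPMVA", CDR3), (PEPTIDE, "CASSQW"), ("X" * 9, CDR3)])
    def test_invalid_inputs_raise(self, peptide, cdr3):
        with pytest.raises(ValueError):
            encode_onehot_pair(peptide, cdr3)

    def test_purity(self):
        a = encode_onehot_pair(PEPTIDE, CDR3)
        b = encode_onehot_pair(PEPTIDE, CDR3)
        np.testing.assert_array_equal(a.values, b.values)


class TestPhychem:
    def test_21_scales(self, table):
        assert table.n_scales == 21

    def test_standardization(self, table):
        np.testing.assert_allclose(table.values.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(table.values.var(axis=0), 1.0, rtol=1e-12)

    def test_rows_are_scale_values(self, table):
        fm = encode_phychem_pair(PEPTIDE, CDR3, table)
        assert fm.values.shape == (32, 21)
        np.testing.assert_array_equal(fm.values[0], table.row("N"))
        np.testing.assert_array_equal(fm.values[11], table.row("C"))

    def test_identical_residues_identical_rows(self, table):
        fm = encode_phychem_pair("AAAAAAAA", "CASSAAAF", table)
        np.testing.assert_array_equal(fm.values[0], fm.values[1])

    def test_padding_rows_zero(self, table):
        fm = encode_phychem_pair(PEPTIDE, CDR3, table)
        assert np.all(fm.values[9:11] == 0)  # peptide block padding
        assert np.all(fm.values[11 + 13 :] == 0)  # CDR3 block padding


class TestAAC:
    def test_homopolymer(self):
        v = compute_aac("AAAA").frequencies
        assert v[AA_INDEX["A"]] == 1.0
        assert v.sum() == 1.0

    def test_cass(self):
        v = compute_aac("CASS").frequencies
        assert v[AA_INDEX["C"]] == 0.25
        assert v[AA_INDEX["A"]] == 0.25
        assert v[AA_INDEX["S"]] == 0.5

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            compute_aac("")

    @given(seq_strategy)
    @settings(max_examples=100, deadline=None)
    def test_sums_to_one_entries_in_unit_interval(self, seq):
        v = compute_aac(seq).frequencies
        assert np.isclose(v.sum(), 1.0)
        assert np.all((v >= 0) & (v <= 1))


def _records(peptide, cdr3s):
    return [PairRecord(peptide, c, 1) for c in cdr3s]


class TestAAPP:
    def test_spec_repertoire(self):
        table = build_aapp_table(_records("NLVPMVATV", ["CASSLGQF", "CASSPGQF"]))
        m = table.maps["NLVPMVATV"]
        # position 2 (row 0): both CDR3s have A
        assert m[0, AA_INDEX["A"]] == 1.0
        # position 5 (row 3): one L, one P
        assert m[3, AA_INDEX["L"]] == 0.5
        assert m[3, AA_INDEX["P"]] == 0.5
        # position 9 (row 7): both CDR3s have length 8 -> all zero
        assert np.all(m[7] == 0.0)

    def test_column_sum_law(self, small_dataset):
        records, _ = small_dataset
        positives = [r for r in records if r.label == 1]
        table = build_aapp_table(positives)
        by_pep = {}
        for r in positives:
            by_pep.setdefault(r.peptide, []).append(r.cdr3)
        for pep, m in table.maps.items():
            cdr3s = by_pep[pep]
            n_t = len(cdr3s)
            for row in range(20):
                x = row + 2  # 1-based CDR3 position
                expected = sum(1 for c in cdr3s if len(c) >= x) / n_t
                assert np.isclose(m[row].sum(), expected)
            assert np.isclose(m[0].sum(), 1.0)  # position 2 always present

    def test_entries_in_unit_interval(self, small_dataset):
        records, _ = small_dataset
        table = build_aapp_table([r for r in records if r.label == 1])
        for m in table.maps.values():
            assert np.all((m >= 0) & (m <= 1))

    def test_repertoire_of_one_is_binary(self):
        table = build_aapp_table(_records("NLVPMVATV", ["CASSLGQF"]))
        m = table.maps["NLVPMVATV"]
        assert set(np.unique(m)) <= {0.0, 1.0}

    def test_rejects_negative_records(self):
        with pytest.raises(ValueError):
            build_aapp_table([PairRecord("NLVPMVATV", "CASSLGQF", 0)])

    def test_roundtrip_exact(self, tmp_path, small_dataset):
        records, _ = small_dataset
        table = build_aapp_table([r for r in records if r.label == 1])
        path = tmp_path / "aapp.json"
        table.save(path)
        back = AAPPTable.load(path)
        assert back.tcr_counts == table.tcr_counts
        for pep in table.maps:
            np.testing.assert_array_equal(back.maps[pep], table.maps[pep])


class TestLookupAAPP:
    def test_present_peptide_returns_own_map(self):
        table = build_aapp_table(_records("NLVPMVATV", ["CASSLGQF"]))
        fm = lookup_aapp("NLVPMVATV", table)
        np.testing.assert_array_equal(fm.values, table.maps["NLVPMVATV"])
        assert fm.n_entries == 400

    def test_single_substitution_routes_to_neighbor(self):
        recs = _records("NLVPMVATV", ["CASSLGQF"]) + _records("GILGFVFTL", ["CASSPGQF"])
        table = build_aapp_table(recs)
        fm = lookup_aapp("NLVPMVATI", table)  # one substitution from NLVPMVATV
        np.testing.assert_array_equal(fm.values, table.maps["NLVPMVATV"])

    def test_matches_brute_force_argmin(self, small_dataset):
        records, _ = small_dataset
        positives = [r for r in records if r.label == 1]
        table = build_aapp_table(positives)
        assert len(table) <= 50
        query = "WWWWWWWW"
        fm = lookup_aapp(query, table)
        dists = {p: edit_distance(query, p) for p in table.peptides}
        best = min(sorted(dists), key=lambda p: (dists[p], p))
        np.testing.assert_array_equal(fm.values, table.maps[best])

    def test_empty_table_raises(self):
        with pytest.raises(ValueError):
            lookup_aapp("NLVPMVATV", AAPPTable({}, {}))


class TestFusePair:
    def test_onehot_aapp_shapes(self, tables):
        aapp, _ = tables
        fused = fuse_pair(PEPTIDE, CDR3, "onehot-aapp", aapp_table=aapp)
        assert fused.module1_map.values.shape == (32, 20)
        assert fused.module1_map.n_entries == 640
        assert fused.module2_map.values.shape == (20, 20)
        assert fused.module2_map.n_entries == 400

    def test_onehot_aac_stacks_vectors(self, tables):
        fused = fuse_pair(PEPTIDE, CDR3, "onehot-aac")
        assert fused.module2_map.values.shape == (2, 20)
        np.testing.assert_array_equal(fused.module2_map.values[0], compute_aac(PEPTIDE).frequencies)
        np.testing.assert_array_equal(fused.module2_map.values[1], compute_aac(CDR3).frequencies)

    def test_phychem_aapp_shapes(self, tables):
        aapp, phychem = tables
        fused = fuse_pair(PEPTIDE, CDR3, "phychem-aapp", aapp_table=aapp, phychem_table=phychem)
        assert fused.module1_map.values.shape == (32, 21)
        assert fused.module2_map.values.shape == (20, 20)

    def test_unknown_scheme_raises(self, tables):
        with pytest.raises(ValueError):
            fuse_pair(PEPTIDE, CDR3, "onehot-blosum")

    def test_aapp_ignores_cdr3(self, tables):
        aapp, _ = tables
        a = fuse_pair(PEPTIDE, "CASSLGQFF", "onehot-aapp", aapp_table=aapp)
        b = fuse_pair(PEPTIDE, "CASSPGQFF", "onehot-aapp", aapp_table=aapp)
        np.testing.assert_array_equal(a.module2_map.values, b.module2_map.values)

    def test_purity(self, tables):
        aapp, _ = tables
        a = fuse_pair(PEPTIDE, CDR3, "onehot-aapp", aapp_table=aapp)
        b = fuse_pair(PEPTIDE, CDR3, "onehot-aapp", aapp_table=aapp)
        np.testing.assert_array_equal(a.module1_map.values, b.module1_map.values)
        np.testing.assert_array_equal(a.module2_map.values, b.module2_map.values)
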