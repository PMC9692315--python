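"""Record I/O, dose-range labeling, filtering, splitting, oversampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from smitox import (ChemicalRecord, filter_records, label_binary,
                    label_multiclass, oversample, random_split, read_chemicals)


def make_records(ld50s):
    return [ChemicalRecord(id=f"c{i}", smiles="CCO", ld50=x)
            for i, x in enumerate(ld50s)]


class TestRecordInvariants:
    def test_empty_smiles_rejected(self):
        with pytest.raises(ValueError):
            ChemicalRecord(id="x", smiles="")

    def test_nonpositive_ld50_rejected(self):
        with pytest.raises(ValueError):
            ChemicalRecord(id="x", smiles="C", ld50=0.0)

    def test_route_normalized_via_synonyms(self):
        assert ChemicalRecord(id="x", smiles="C", route="Intraperitoneal").route == "ip"
        assert ChemicalRecord(id="x", smiles="C", route="PO").route == "oral"


class TestReadChemicals:
    def test_csv_all_valid(self, tmp_path):
        p = tmp_path / "chems.csv"
        p.write_text("id,smiles,ld50,route,species\n"
                     "a,CCO,120,oral,rat\nb,c1ccccc1,900,iv,mouse\nc,CC(=O)O,3300,oral,rat\n")
        records = read_chemicals(p)
        assert len(records) == 3
        assert records[0].ld50 == 120 and records[1].route == "iv"

    def test_csv_unparsable_smiles_skipped(self, tmp_path, caplog):
        p = tmp_path / "chems.csv"
        p.write_text("smiles,ld50\nCCO,10\nC(((,20\nCN,30\n")
        with caplog.at_level("WARNING"):
            records = read_chemicals(p)
        assert len(records) == 2
        assert any("unparsable" in r.message for r in caplog.records)

    def test_csv_without_smiles_column_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("name,ld50\nfoo,1\n")
        with pytest.raises(ValueError, match="smiles"):
            read_chemicals(p)

    def test_missing_file_rejected(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_chemicals(tmp_path / "absent.csv")

    def test_smi_round_trip(self, tmp_path):
        p = tmp_path / "mols.smi"
        p.write_text("CCO ethanol\nc1ccccc1 benzene\n")
        records = read_chemicals(p)
        assert [r.id for r in records] == ["ethanol", "benzene"]

    def test_sdf_with_ld50_property(self, tmp_path):
        """Write an SDF through RDKit, read it back field-by-field."""
        from rdkit import Chem

        mol = Chem.MolFromSmiles("CCO")
        mol.SetProp("_Name", "ethanol")
        mol.SetProp("LD50_mgkg", "7060")
        mol.SetProp("route", "oral")
        p = tmp_path / "one.sdf"
        with Chem.SDWriter(str(p)) as w:
            w.write(mol)
        records = read_chemicals(p)
        assert len(records) == 1
        rec = records[0]
        assert rec.id == "ethanol"
        assert rec.ld50 == pytest.approx(7060.0)
        assert rec.route == "oral"
        assert Chem.CanonSmiles(rec.smiles) == Chem.CanonSmiles("CCO")


class TestBinaryLabeling:
    def test_below_cutoff_is_toxic(self):
        ds = label_binary(make_records([100.0]), cutoff=500)
        assert ds.labels.tolist() == [1]

    def test_boundary_value_is_nontoxic(self):
        ds = label_binary(make_records([500.0]), cutoff=500)
        assert ds.labels.tolist() == [0]

    def test_elementwise_comparison(self):
        ds = label_binary(make_records([10, 400, 600, 2000]), cutoff=750)
        assert ds.labels.tolist() == [1, 1, 1, 0]

    def test_missing_ld50_rejected(self):
        with pytest.raises(ValueError, match="missing LD50"):
            label_binary([ChemicalRecord(id="x", smiles="C")], cutoff=500)

    def test_monotone_nesting_across_cutoffs(self):
        rng = np.random.default_rng(0)
        records = make_records(10 ** rng.uniform(0, 4, size=200))
        toxic_sets = []
        for cutoff in (250, 500, 750, 1000):
            ds = label_binary(records, cutoff=cutoff)
            toxic_sets.append({r.id for r, y in zip(ds.records, ds.labels) if y})
        for smaller, larger in zip(toxic_sets, toxic_sets[1:]):
            assert smaller <= larger

    def test_scheme_metadata_recomputes_labels(self):
        ds = label_binary(make_records([10, 400, 600, 2000]), cutoff=750)
        np.testing.assert_array_equal(ds.recompute_labels(), ds.labels)


class TestMulticlassLabeling:
    @pytest.mark.parametrize("ld50,expected", [
        (49.9, 0),   # below the first boundary -> most toxic class
        (50.0, 1),   # boundary belongs to the upper interval
        (499.9, 1),
        (500.0, 2),
        (1000.0, 3),  # top interval closed below
    ])
    def test_interval_assignment(self, ld50, expected):
        ds = label_multiclass(make_records([ld50]))
        assert ds.labels.tolist() == [expected]

    def test_counts_partition_records(self):
        rng = np.random.default_rng(1)
        records = make_records(10 ** rng.uniform(0, 4, size=300))
        ds = label_multiclass(records)
        assert sum(ds.class_counts().values()) == 300
        np.testing.assert_array_equal(ds.recompute_labels(), ds.labels)

    def test_nonincreasing_boundaries_rejected(self):
        with pytest.raises(ValueError):
            label_multiclass(make_records([10.0]), boundaries=(500, 50, 1000))

    def test_binary_500_coarsens_four_class_scheme(self):
        """Merging multiclass {a,b} vs {c,d} equals binary at 500 mg/kg."""
        rng = np.random.default_rng(2)
        records = make_records(10 ** rng.uniform(0, 4, size=1000))
        four = label_multiclass(records)
        two = label_binary(records, cutoff=500)
        np.testing.assert_array_equal((four.labels <= 1).astype(int), two.labels)


class TestFilterRecords:
    def test_route_filter(self, ten_records):
        out = filter_records(ten_records, route={"oral"})
        assert all(r.route == "oral" for r in out)

    def test_no_filters_identity(self, ten_records):
        assert filter_records(ten_records) == list(ten_records)

    def test_enumerated_matching_subset(self, ten_records):
        out = filter_records(ten_records, route={"oral"}, species={"rat", "mouse"})
        assert [r.id for r in out] == ["r0", "r1", "r5", "r7", "r9"]

    def test_filter_synonyms_match(self, ten_records):
        assert filter_records(ten_records, route={"PO"}) == \
            filter_records(ten_records, route={"oral"})


class TestRandomSplit:
    def test_fraction_gives_exact_sizes(self):
        ds = label_binary(make_records(np.linspace(10, 2000, 100)), cutoff=500)
        train, test = random_split(ds, 0.2, seed=0)
        assert (len(train), len(test)) == (80, 20)

    def test_fixed_count_test_set(self):
        ds = label_binary(make_records(np.linspace(10, 2000, 100)), cutoff=500)
        train, test = random_split(ds, 30, seed=0)
        assert (len(train), len(test)) == (70, 30)

    def test_same_seed_identical_partitions(self):
        ds = label_binary(make_records(np.linspace(10, 2000, 50)), cutoff=500)
        a = random_split(ds, 0.2, seed=7)
        b = random_split(ds, 0.2, seed=7)
        assert [r.id for r in a[0].records] == [r.id for r in b[0].records]
        assert [r.id for r in a[1].records] == [r.id for r in b[1].records]

    def test_out_of_range_sizes_rejected(self):
        ds = label_binary(make_records([10, 20, 30]), cutoff=500)
        for bad in (0, 3, 5):
            with pytest.raises(ValueError):
                random_split(ds, bad, seed=0)

    @given(n=st.integers(min_value=2, max_value=1000),
           seed=st.integers(min_value=0, max_value=2**16))
    @settings(max_examples=40, deadline=None)
    def test_partition_property(self, n, seed):
        """Disjoint, exhaustive, deterministic for every size 2 <= n <= 1000."""
        ds = label_binary(make_records(np.linspace(1, 2000, n)), cutoff=500)
        n_test = max(1, n // 5)
        train, test = random_split(ds, n_test, seed=seed)
        ids_train = {r.id for r in train.records}
        ids_test = {r.id for r in test.records}
        assert ids_train | ids_test == {r.id for r in ds.records}
        assert not ids_train & ids_test
        train2, test2 = random_split(ds, n_test, seed=seed)
        assert [r.id for r in test2.records] == [r.id for r in test.records]


class TestOversample:
    @staticmethod
    def dataset_with_counts(counts):
        ld50s, labels = [], []
        # classes: 0 -> [0,50), 1 -> [50,500), 2 -> [500,1000)
        doses = {0: 10.0, 1: 100.0, 2: 600.0}
        for cls, count in counts.items():
            ld50s += [doses[cls]] * count
        return label_multiclass(make_records(ld50s))

    def test_reaches_targets_exactly(self):
        ds = self.dataset_with_counts({0: 40, 1: 150, 2: 60})
        out = oversample(ds, {0: 100, 1: 200, 2: 100}, seed=0)
        assert out.class_counts() == {0: 100, 1: 200, 2: 100}

    def test_added_rows_duplicate_existing_rows(self):
        ds = self.dataset_with_counts({0: 40, 1: 150, 2: 60})
        out = oversample(ds, {0: 100, 1: 200, 2: 100}, seed=0)
        original_ids = {r.id for r in ds.records}
        assert {r.id for r in out.records} <= original_ids
        # no feature value was modified: every row equals its original
        by_id = {r.id: r for r in ds.records}
        assert all(r == by_id[r.id] for r in out.records)

    def test_targets_equal_counts_is_identity_up_to_order(self):
        ds = self.dataset_with_counts({0: 5, 1: 7})
        out = oversample(ds, {0: 5, 1: 7}, seed=3)
        assert sorted(r.id for r in out.records) == sorted(r.id for r in ds.records)

    def test_target_below_count_rejected(self):
        ds = self.dataset_with_counts({0: 5, 1: 7})
        with pytest.raises(ValueError, match="below current count"):
            oversample(ds, {0: 3}, seed=0)

    def test_absent_class_rejected(self):
        ds = self.dataset_with_counts({0: 5})
        with pytest.raises(ValueError, match="absent"):
            oversample(ds, {3: 10}, seed=0)
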