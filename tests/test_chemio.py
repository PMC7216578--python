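"""Readers, preprocessing filters, balancing, splits and folds."""

import numpy as np
import pytest
from rdkit import Chem

import molgcn as mg
from molgcn.errors import (
    BalanceError,
    EmptyDatasetError,
    InputError,
    SchemaError,
    SplitError,
    ValueCoercionError,
)

from conftest import record_from_smiles


def write_sdf(path, smiles_list, corrupt_at=None):
    blocks = []
    for i, smi in enumerate(smiles_list):
        mol = Chem.MolFromSmiles(smi)
        mol.SetProp("_Name", f"mol{i}")
        blocks.append(Chem.MolToMolBlock(mol) + "$$$$\n")
    if corrupt_at is not None:
        # structurally SDF-shaped record whose bond references a missing atom
        bad = Chem.MolToMolBlock(Chem.MolFromSmiles("CC")).replace(
            "  1  2  1  0", "  1  9  1  0"
        )
        blocks.insert(corrupt_at, bad + "$$$$\n")
    path.write_text("".join(blocks))
    return str(path)


class TestReadSDF:
    def test_valid_blocks_all_read(self, tmp_path):
        p = write_sdf(tmp_path / "in.sdf", ["CCO", "c1ccccc1", "CC(=O)NO"])
        records, report = mg.read_sdf(p)
        assert [r.id for r in records] == ["mol0", "mol1", "mol2"]
        assert report.n_skipped == 0
        assert records[0].n_heavy_atoms == 3

    def test_corrupt_block_skipped_and_counted(self, tmp_path):
        p = write_sdf(tmp_path / "in.sdf", ["CCO", "c1ccccc1"], corrupt_at=1)
        records, report = mg.read_sdf(p)
        assert len(records) == 2
        assert report.n_skipped == 1

    def test_empty_file_is_an_error(self, tmp_path):
        p = tmp_path / "empty.sdf"
        p.write_text("")
        with pytest.raises(EmptyDatasetError):
            mg.read_sdf(str(p))

    def test_missing_file_is_an_input_error(self):
        with pytest.raises(InputError):
            mg.read_sdf("/nonexistent/foo.sdf")


class TestReadSmiles:
    def test_line_order_and_heavy_atom_counts(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("CCO\nc1ccccc1\n")
        records, report = mg.read_smiles(str(p))
        assert [r.n_heavy_atoms for r in records] == [3, 6]
        assert [r.id for r in records] == ["0", "1"]

    def test_invalid_line_skipped_with_report(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("CCO\nnot_a_smiles\nCC\n")
        records, report = mg.read_smiles(str(p))
        assert len(records) == 2
        assert report.n_skipped == 1 and report.skipped == [1]

    def test_second_token_becomes_id(self, tmp_path):
        p = tmp_path / "in.smi"
        p.write_text("C mol1\n")
        records, _ = mg.read_smiles(str(p))
        assert records[0].id == "mol1"


class TestReadLabelsCSV:
    def test_empty_cell_is_masked(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("id,a,b\nm0,1,0\nm1,0,\nm2,1,1\nm3,0,1\n")
        table = mg.read_labels_csv(str(p), "id", ["a", "b"])
        assert table.values.shape == (4, 2)
        assert table.mask.sum() == 7
        assert np.isnan(table.values[1, 1])

    def test_non_binary_cell_is_an_error(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("id,a\nm0,2\n")
        with pytest.raises(ValueCoercionError, match="m0"):
            mg.read_labels_csv(str(p), "id", ["a"])

    def test_duplicate_id_is_a_schema_error(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("id,a\nm0,1\nm0,0\n")
        with pytest.raises(SchemaError, match="m0"):
            mg.read_labels_csv(str(p), "id", ["a"])

    def test_missing_column_is_a_schema_error(self, tmp_path):
        p = tmp_path / "labels.csv"
        p.write_text("id,a\nm0,1\n")
        with pytest.raises(SchemaError, match="b"):
            mg.read_labels_csv(str(p), "id", ["a", "b"])


class TestAtomFilter:
    def test_boundary_at_50_heavy_atoms(self):
        records = [record_from_smiles("C" * n, f"n{n}") for n in (12, 50, 51)]
        kept = mg.filter_by_atom_count(records)
        assert [r.n_heavy_atoms for r in kept] == [12, 50]

    def test_empty_input_gives_empty_output(self):
        assert mg.filter_by_atom_count([]) == []

    def test_methane_survives_max_atoms_one(self):
        assert len(mg.filter_by_atom_count([record_from_smiles("C")], max_atoms=1)) == 1

    def test_filter_is_idempotent(self):
        records = [record_from_smiles("C" * n, f"n{n}") for n in (3, 49, 50, 51, 60)]
        once = mg.filter_by_atom_count(records)
        assert mg.filter_by_atom_count(once) == once


def _dataset(n_pos, n_neg):
    smiles, values = [], []
    for i in range(n_pos + n_neg):
        smiles.append("C" * (i + 2))
        values.append([1.0 if i < n_pos else 0.0])
    records = [record_from_smiles(s, f"c{i}") for i, s in enumerate(smiles)]
    table = mg.LabelTable([r.id for r in records], ["assay"], np.asarray(values))
    return mg.assemble_dataset(records, table)


class TestBalanceNegatives:
    def pool(self, n):
        return [record_from_smiles("CC" + "O" * (i % 3 + 1), f"pool{i}") for i in range(n)]

    def test_negatives_drawn_until_parity(self):
        ds = mg.balance_negatives(_dataset(10, 4), "assay", self.pool(20), seed=0)
        obs = ds.label_mask[:, 0] == 1
        assert (ds.labels[obs, 0] == 0).sum() == 10
        assert (ds.labels[obs, 0] == 1).sum() == 10

    def test_already_balanced_unchanged(self):
        ds = _dataset(5, 5)
        assert mg.balance_negatives(ds, "assay", self.pool(20), seed=0) is ds

    def test_same_seed_draws_identical_ids(self):
        a = mg.balance_negatives(_dataset(10, 4), "assay", self.pool(20), seed=3)
        b = mg.balance_negatives(_dataset(10, 4), "assay", self.pool(20), seed=3)
        assert a.ids == b.ids

    def test_short_pool_reports_shortfall(self):
        with pytest.raises(BalanceError, match="shortfall"):
            mg.balance_negatives(_dataset(10, 4), "assay", self.pool(3), seed=0)


class TestSplitsAndFolds:
    def test_split_sizes_follow_rounding(self):
        tr, te = mg.split_dataset(_dataset(5, 5), 0.2, seed=0)
        assert (len(tr), len(te)) == (8, 2)
        assert set(tr.ids).isdisjoint(te.ids)
        assert set(tr.ids) | set(te.ids) == set(_dataset(5, 5).ids)

    def test_split_same_seed_identical_membership(self):
        a = mg.split_dataset(_dataset(5, 5), 0.3, seed=9)
        b = mg.split_dataset(_dataset(5, 5), 0.3, seed=9)
        assert a[0].ids == b[0].ids and a[1].ids == b[1].ids

    def test_degenerate_split_is_an_error(self):
        with pytest.raises(SplitError):
            mg.split_dataset(_dataset(1, 0), 0.5, seed=0)

    def test_five_folds_of_two(self):
        ds = mg.make_cv_folds(_dataset(5, 5), k=5, seed=0)
        sizes = sorted(np.bincount(ds.fold_assignment))
        assert sizes == [2, 2, 2, 2, 2]

    def test_balanced_remainder_fold_sizes(self):
        ds = mg.make_cv_folds(_dataset(4, 3), k=5, seed=0)
        assert sorted(np.bincount(ds.fold_assignment), reverse=True) == [2, 2, 1, 1, 1]

    def test_k_of_one_is_an_error(self):
        with pytest.raises(SplitError):
            mg.make_cv_folds(_dataset(5, 5), k=1, seed=0)


class TestDatasetArchive:
    def test_roundtrip_preserves_everything(self, tmp_path):
        ds = mg.make_cv_folds(_dataset(4, 4), k=2, seed=1)
        path = str(tmp_path / "data.npz")
        mg.chemio.save_dataset(ds, path)
        back = mg.chemio.load_dataset(path)
        assert back.ids == ds.ids and back.tasks == ds.tasks
        assert np.array_equal(back.labels, ds.labels)
        assert np.array_equal(back.label_mask, ds.label_mask)
        assert np.array_equal(back.fold_assignment, ds.fold_assignment)
        for a, b in zip(ds.graphs, back.graphs):
            assert np.array_equal(a.features, b.features)
            for t in a.adjacency:
                assert np.array_equal(a.adjacency[t], b.adjacency[t])
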