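"""Sinusoid/molecular task generators and score-table IO."""

import numpy as np
import pytest

from molnp.molrep import InvalidSmilesError
from molnp.synthetic_tasks import (DockstringMatrix, SinusoidFamily,
                                   SyntheticMolTaskSpec, fixture_smiles,
                                   make_fsl_split, make_molecular_metadataset,
                                   random_smiles, read_dockstring_table,
                                   sample_sinusoid_task,
                                   target_max_correlation,
                                   write_dockstring_table)


class TestSinusoids:
    def test_exact_value_at_quarter_period(self):
        fam = SinusoidFamily(A_range=(1.0, 1.0), B_range=(0.0, 0.0),
                             rho=1.0, x_range=(np.pi / 2, np.pi / 2))
        task = sample_sinusoid_task(fam, 1, np.random.default_rng(0))
        assert task.y[0] == pytest.approx(1.0)

    def test_amplitude_bound(self):
        fam = SinusoidFamily(noise_sd=0.05)
        rng = np.random.default_rng(1)
        for _ in range(20):
            task, (A, B) = sample_sinusoid_task(fam, 100, rng,
                                                return_params=True)
            assert np.abs(task.y).max() <= abs(A) + 5 * 0.05

    def test_seeded_identical(self):
        fam = SinusoidFamily(noise_sd=0.1)
        a = sample_sinusoid_task(fam, 30, np.random.default_rng(9))
        b = sample_sinusoid_task(fam, 30, np.random.default_rng(9))
        assert np.array_equal(a.x, b.x) and np.array_equal(a.y, b.y)


class TestRandomSmiles:
    def test_unique_valid_and_reproducible(self):
        from rdkit import Chem

        a = random_smiles(30, np.random.default_rng(3))
        b = random_smiles(30, np.random.default_rng(3))
        assert a == b
        assert len(set(a)) == 30
        assert all(Chem.MolFromSmiles(s) is not None for s in a)

    def test_fixture_list_is_valid(self):
        from rdkit import Chem

        smis = fixture_smiles()
        assert len(smis) == 200
        assert all(Chem.MolFromSmiles(s) is not None for s in smis)


class TestMolecularMetadataset:
    def _tasks(self, lam, n_mols=300, n_tasks=8, noise=0.0, seed=0):
        smiles = fixture_smiles()[:200] + random_smiles(
            max(0, n_mols - 200), np.random.default_rng(1))
        spec = SyntheticMolTaskSpec(n_tasks=n_tasks,
                                    shared_weight_fraction=lam,
                                    noise_sd=noise)
        return make_molecular_metadataset(smiles[:n_mols], spec,
                                          np.random.default_rng(seed))

    def test_full_sharing_gives_perfect_correlation(self):
        tasks = self._tasks(lam=1.0)
        ys = np.stack([t.y for t in tasks])
        corr = np.corrcoef(ys)
        off_diag = corr[~np.eye(len(tasks), dtype=bool)]
        assert off_diag.min() >= 0.999

    def test_no_sharing_gives_low_correlation(self):
        tasks = self._tasks(lam=0.0, n_mols=300, n_tasks=10)
        ys = np.stack([t.y for t in tasks])
        corr = np.corrcoef(ys)
        off_diag = np.abs(corr[~np.eye(len(tasks), dtype=bool)])
        assert off_diag.mean() <= 0.2

    def test_seeded_identical(self):
        a = self._tasks(lam=0.5, n_mols=50, noise=0.1)
        b = self._tasks(lam=0.5, n_mols=50, noise=0.1)
        for ta, tb in zip(a, b):
            assert np.array_equal(ta.y, tb.y)

    def test_invalid_smiles_reported(self):
        spec = SyntheticMolTaskSpec(n_tasks=2)
        with pytest.raises(InvalidSmilesError, match="C\\("):
            make_molecular_metadataset(["CCO", "C(", "CCN"], spec,
                                       np.random.default_rng(0))

    def test_correlation_increases_with_lambda(self):
        meds = []
        for lam in (0.0, 0.5, 1.0):
            tasks = self._tasks(lam=lam, n_mols=150, n_tasks=6, noise=0.05)
            ys = np.stack([t.y for t in tasks])
            corr = np.corrcoef(ys)
            meds.append(np.median(corr[~np.eye(6, dtype=bool)]))
        assert meds[0] < meds[1] < meds[2]


class TestDockstringIO:
    def _write(self, tmp_path, text, name="table.tsv"):
        p = tmp_path / name
        p.write_text(text)
        return p

    def test_small_fixture_roundtrip(self, tmp_path):
        path = self._write(tmp_path,
                           "smiles\tsplit\tPARP1\tESR2\n"
                           "CCO\ttrain\t-7.1\t-6.2\n"
                           "CCN\ttrain\t-6.9\t-5.8\n"
                           "c1ccccc1\ttest\t-8.0\t-7.5\n")
        m = read_dockstring_table(path)
        assert m.scores.shape == (3, 2)
        assert m.target_names == ["PARP1", "ESR2"]
        assert list(m.split) == ["train", "train", "test"]
        out = tmp_path / "echo.tsv"
        write_dockstring_table(m, out)
        again = read_dockstring_table(out)
        assert again.smiles == m.smiles
        assert np.allclose(again.scores, m.scores)

    def test_blank_cell_policy(self, tmp_path):
        path = self._write(tmp_path,
                           "smiles\tT1\tT2\nCCO\t-7.1\t\nCCN\t-6.9\t-5.8\n")
        with pytest.raises(ValueError, match="missing"):
            read_dockstring_table(path)
        m = read_dockstring_table(path, on_missing="drop")
        assert m.smiles == ["CCN"]

    def test_errors_name_row_and_column(self, tmp_path):
        bad_num = self._write(tmp_path,
                              "smiles\tT1\nCCO\t-7.1\nCCN\tabc\n", "a.tsv")
        with pytest.raises(ValueError, match="T1.*row 1"):
            read_dockstring_table(bad_num)
        dup = self._write(tmp_path,
                          "smiles\tT1\nCCO\t-7.1\nCCO\t-6.9\n", "b.tsv")
        with pytest.raises(ValueError, match="duplicate"):
            read_dockstring_table(dup)
        no_smiles = self._write(tmp_path, "mol\tT1\nCCO\t-7.1\n", "c.tsv")
        with pytest.raises(ValueError, match="smiles"):
            read_dockstring_table(no_smiles)


class TestTargetCorrelation:
    def _matrix(self, scores, names):
        n = len(scores)
        return DockstringMatrix(smiles=[f"C{'C' * i}O" for i in range(n)],
                                target_names=names,
                                scores=np.asarray(scores, float))

    def test_duplicated_column_scores_one(self):
        col = [1.0, 2.0, 4.0, 3.0]
        m = self._matrix(np.stack([col, col, [0, 5, 1, 2]], axis=1),
                         ["A", "B", "C"])
        out = target_max_correlation(m)
        assert out["A"] == pytest.approx(1.0)
        assert out["B"] == pytest.approx(1.0)

    def test_negation_only_partner(self):
        col = np.array([1.0, 2.0, 4.0, 3.0])
        rng = np.random.default_rng(0)
        indep = rng.normal(size=4)
        m = self._matrix(np.stack([col, -col, indep], axis=1),
                         ["A", "B", "C"])
        out = target_max_correlation(m)
        expected_ac = np.corrcoef(col, indep)[0, 1]
        assert out["A"] == pytest.approx(max(-1.0, expected_ac))

    def test_three_column_hand_computed(self):
        a = [0.0, 1.0, 2.0, 3.0]
        b = [0.0, 1.0, 1.0, 2.0]
        c = [3.0, 1.0, 2.0, 0.0]
        m = self._matrix(np.stack([a, b, c], axis=1), ["A", "B", "C"])
        out = target_max_correlation(m)
        r_ab = np.corrcoef(a, b)[0, 1]
        r_ac = np.corrcoef(a, c)[0, 1]
        r_bc = np.corrcoef(b, c)[0, 1]
        assert out["A"] == pytest.approx(max(r_ab, r_ac))
        assert out["B"] == pytest.approx(max(r_ab, r_bc))
        assert out["C"] == pytest.approx(max(r_ac, r_bc))

    def test_constant_column_warns(self):
        m = self._matrix(np.stack([[1.0, 1, 1, 1], [0, 1, 2, 3]], axis=1),
                         ["A", "B"])
        with pytest.warns(UserWarning, match="constant"):
            out = target_max_correlation(m)
        assert np.isnan(out["A"])


class TestFslSplit:
    @pytest.fixture
    def matrix(self):
        rng = np.random.default_rng(2)
        n = 40
        return DockstringMatrix(
            smiles=[f"{'C' * (i + 1)}O" for i in range(n)],
            target_names=["A", "B", "C", "D"],
            scores=rng.normal(size=(n, 4)),
            split=np.array(["train"] * 25 + ["test"] * 15))

    def test_task_partition(self, matrix):
        s = make_fsl_split(matrix, ["B"], 10, 10, np.random.default_rng(0))
        assert set(s.ftrain) | set(s.ftest) == {"A", "B", "C", "D"}
        assert not set(s.ftrain) & set(s.ftest)

    def test_molecule_sets_disjoint(self, matrix):
        s = make_fsl_split(matrix, ["B"], 20, 10, np.random.default_rng(0))
        assert not set(s.dtrain_idx) & set(s.dtest_idx)
        assert all(matrix.split[i] == "train" for i in s.dtrain_idx)
        assert all(matrix.split[i] == "test" for i in s.dtest_idx)

    def test_seeded_identical(self, matrix):
        a = make_fsl_split(matrix, ["B"], 10, 10, np.random.default_rng(5))
        b = make_fsl_split(matrix, ["B"], 10, 10, np.random.default_rng(5))
        assert np.array_equal(a.dtrain_idx, b.dtrain_idx)

    def test_insufficient_rows(self, matrix):
        with pytest.raises(ValueError, match="train-split rows"):
            make_fsl_split(matrix, ["B"], 30, 10, np.random.default_rng(0))

    def test_missing_split_labels(self, matrix):
        matrix.split = None
        with pytest.raises(ValueError, match="split"):
            make_fsl_split(matrix, ["B"], 5, 5, np.random.default_rng(0))
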