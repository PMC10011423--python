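"""QC filtering, normalization, concordance, splitting, pseudo-bulk."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from ctdeconv import (
    CellCounts,
    QCThresholds,
    lognormalize,
    make_pseudobulk,
    qc_filter,
    split_balanced,
    technical_concordance,
)


def _counts(matrix, genes=None, cells=None):
    matrix = np.asarray(matrix)
    genes = genes or [f"g{i}" for i in range(matrix.shape[0])]
    cells = cells or [f"c{i}" for i in range(matrix.shape[1])]
    return CellCounts(sparse.csr_matrix(matrix), pd.Index(genes), pd.Index(cells))


def _meta(cells, **overrides):
    n = len(cells)
    base = {
        "donor": ["D0"] * n,
        "batch": ["B0"] * n,
        "origin": ["fetal"] * n,
        "sex": ["female"] * n,
        "technical_replicate": ["D0_repA"] * n,
        "cell_type": ["type0"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base, index=pd.Index(cells, name="cell_id"))


class TestQCFilter:
    def test_low_umi_cell_excluded(self):
        # one cell at 499 total UMIs across 300 detected genes, one healthy
        mat = np.zeros((400, 2), dtype=int)
        mat[:300, 0] = 1
        mat[99, 0] = 200  # total 499
        mat[:250, 1] = 3  # total 750
        counts = _counts(mat)
        assert mat[:, 0].sum() == 499
        filtered, meta, report = qc_filter(counts, _meta(counts.cells), QCThresholds())
        assert list(filtered.cells) == ["c1"]
        assert report["n_removed_umi"] == 1

    def test_mito_mad_cutoff_hand_computed(self):
        """Batch mito rates {1,2,2,3,3,3,4,50}% with mito_mads = 4: median 3,
        MAD 1, cutoff 3 + 4 * 1.4826 * 1 = 8.93 => only the 50% cell drops."""
        rates = np.array([1, 2, 2, 3, 3, 3, 4, 50]) / 100.0
        total = 1000
        mat = np.zeros((3, 8), dtype=int)
        mat[0] = (rates * total).astype(int)  # mito gene
        mat[1] = total - mat[0]
        counts = _counts(mat, genes=["MT-1", "other1", "other2"])
        th = QCThresholds(min_umis=10, min_genes=1, mito_mads=4.0, mito_gene_set=("MT-1",))
        filtered, meta, report = qc_filter(counts, _meta(counts.cells), th)
        assert report["n_removed_mito"] == 1
        assert "c7" not in filtered.cells
        assert report["mito_cutoffs"]["B0"] == pytest.approx(0.03 + 4 * 1.4826 * 0.01)

    def test_all_pass_identity(self, small_sc):
        counts, meta, _ = small_sc
        th = QCThresholds(min_umis=1, min_genes=1)
        filtered, fmeta, report = qc_filter(counts, meta, th)
        assert report["n_removed_unique"] == 0
        assert (filtered.matrix != counts.matrix).nnz == 0

    def test_idempotent(self, small_sc):
        counts, meta, _ = small_sc
        th = QCThresholds(min_umis=1800, min_genes=100)
        once_c, once_m, _ = qc_filter(counts, meta, th)
        twice_c, twice_m, rep = qc_filter(once_c, once_m, th)
        assert rep["n_removed_unique"] == 0
        assert once_c.cells.equals(twice_c.cells)

    def test_missing_mito_genes_warns_and_skips(self):
        mat = np.full((3, 4), 300, dtype=int)
        counts = _counts(mat)
        th = QCThresholds(min_umis=10, min_genes=1, mito_gene_set=("MT-ABSENT",))
        with pytest.warns(UserWarning, match="mitochondrial"):
            _, _, report = qc_filter(counts, _meta(counts.cells), th)
        assert report["n_removed_mito"] == 0

    def test_empty_result_errors(self):
        mat = np.ones((10, 3), dtype=int)
        counts = _counts(mat)
        with pytest.raises(ValueError, match="no cells remain"):
            qc_filter(counts, _meta(counts.cells), QCThresholds())


class TestLogNormalize:
    def test_stated_formula(self):
        # count 2 in a cell of total 2000 -> ln(1 + 1e4 * 2/2000) = ln(11)
        mat = np.zeros((3, 1), dtype=int)
        mat[0, 0] = 2
        mat[1, 0] = 1998
        norm = lognormalize(_counts(mat))
        got = norm.matrix.toarray()
        assert got[0, 0] == pytest.approx(np.log(11.0), abs=1e-9)
        assert got[2, 0] == 0.0  # zeros map to zeros

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(2.0, size=(50, 4))
        mat[:, 0] = np.maximum(mat[:, 0], 1)
        doubled = mat.copy()
        doubled[:, 0] *= 2
        a = lognormalize(_counts(mat)).matrix.toarray()
        b = lognormalize(_counts(doubled)).matrix.toarray()
        np.testing.assert_allclose(a[:, 0], b[:, 0], atol=1e-12)

    def test_zero_total_cell_named(self):
        mat = np.zeros((3, 2), dtype=int)
        mat[0, 0] = 5
        with pytest.raises(ValueError, match="c1"):
            lognormalize(_counts(mat))


class TestTechnicalConcordance:
    def _two_rep_setup(self, values_b):
        rng = np.random.default_rng(1)
        n_genes, n_cells = 60, 20
        a = rng.poisson(5.0, size=(n_genes, n_cells // 2))
        mat = np.hstack([a, values_b(a)])
        counts = _counts(mat)
        meta = _meta(
            counts.cells,
            technical_replicate=["D0_repA"] * (n_cells // 2) + ["D0_repB"] * (n_cells // 2),
        )
        return lognormalize(counts), meta

    def test_exact_copy_gives_rho_one(self):
        norm, meta = self._two_rep_setup(lambda a: a)
        table, summary = technical_concordance(norm, meta)
        assert summary["mean_rho"] == pytest.approx(1.0)

    def test_monotone_transform_gives_rho_one(self):
        # one cell per replicate; squaring counts is strictly monotone, and
        # per-cell normalization/log are monotone too, so gene ranks agree
        rng = np.random.default_rng(1)
        a = rng.poisson(5.0, size=(80, 1))
        counts = _counts(np.hstack([a, a**2]))
        meta = _meta(counts.cells, technical_replicate=["D0_repA", "D0_repB"])
        table, _ = technical_concordance(lognormalize(counts), meta)
        assert table["rho"].iloc[0] == pytest.approx(1.0)

    def test_permuted_genes_near_zero(self):
        """Replicate B with gene values permuted: |rho| small under the
        permutation null (5000 genes)."""
        rng = np.random.default_rng(2)
        n_genes = 5000
        a = rng.poisson(4.0, size=(n_genes, 6))
        b = a[rng.permutation(n_genes)]
        counts = _counts(np.hstack([a, b]))
        meta = _meta(counts.cells,
                     technical_replicate=["D0_repA"] * 6 + ["D0_repB"] * 6)
        table, _ = technical_concordance(lognormalize(counts), meta)
        assert abs(table["rho"].iloc[0]) < 0.05

    def test_cluster_in_one_replicate_skipped(self):
        rng = np.random.default_rng(3)
        mat = rng.poisson(5.0, size=(30, 8))
        counts = _counts(mat)
        meta = _meta(
            counts.cells,
            technical_replicate=["D0_repA"] * 4 + ["D0_repB"] * 4,
            cell_type=["type0"] * 4 + ["type0", "type0", "type1", "type1"],
        )
        with pytest.warns(UserWarning, match="only one replicate"):
            table, _ = technical_concordance(lognormalize(counts), meta)
        assert set(table["cluster"]) == {"type0"}


class TestSplitBalanced:
    def test_floor_convention_101_cells(self):
        meta = _meta([f"c{i}" for i in range(101)])
        train, test = split_balanced(meta, 0.5, seed=0)
        assert len(train) == 50 and len(test) == 51

    def test_partition(self, small_sc):
        _, meta, _ = small_sc
        train, test = split_balanced(meta, 0.5, seed=1)
        assert len(set(train) & set(test)) == 0
        assert set(train) | set(test) == set(meta.index)
        # per-type balance within one cell
        for t, grp in meta.groupby("cell_type"):
            n_tr = len(set(grp.index) & set(train))
            assert abs(n_tr - len(grp) * 0.5) <= 1

    def test_seeded_reproducibility(self, small_sc):
        _, meta, _ = small_sc
        t1 = split_balanced(meta, 0.5, seed=42)
        t2 = split_balanced(meta, 0.5, seed=42)
        assert t1[0].equals(t2[0]) and t1[1].equals(t2[1])

    def test_tiny_type_goes_to_train(self):
        meta = _meta([f"c{i}" for i in range(11)],
                     cell_type=["type0"] * 10 + ["rare"])
        with pytest.warns(UserWarning, match="rare"):
            train, test = split_balanced(meta, 0.5, seed=0)
        assert "c10" in train


class TestMakePseudobulk:
    def _mixed_meta(self, cells):
        # 30 female fetal, 50 male fetal, 20 maternal
        origin = ["fetal"] * 80 + ["maternal"] * 20
        sex = ["female"] * 30 + ["male"] * 50 + ["female"] * 20
        ctype = (["type0"] * 30 + ["type1"] * 50 + ["typeM"] * 20)
        return _meta(cells, origin=origin, sex=sex, cell_type=ctype)

    def test_female_fetal_downsampling_rule(self):
        rng = np.random.default_rng(0)
        mat = rng.poisson(3.0, size=(40, 100))
        counts = _counts(mat)
        meta = self._mixed_meta(counts.cells)
        bulk, props = make_pseudobulk(counts, meta, "female_fetal", seed=0)
        # male fetal excluded entirely; maternal at baseline share 20/80 of 30
        assert props["type1"] == 0.0
        n_mat_expected = round(20 * 30 / 80)
        n_sel = 30 + n_mat_expected
        assert props["typeM"] == pytest.approx(n_mat_expected / n_sel)

    def test_proportions_sum_to_one_and_additivity(self, small_sc):
        counts, meta, _ = small_sc
        bulk, props = make_pseudobulk(counts, meta, "all", seed=0)
        assert props.sum() == pytest.approx(1.0)
        assert bulk.sum() == counts.matrix.sum()

    def test_all_scenario_matches_tallies(self, small_sc):
        counts, meta, _ = small_sc
        _, props = make_pseudobulk(counts, meta, "all", seed=0)
        expected = meta["cell_type"].value_counts(normalize=True)
        for t in props.index:
            assert props[t] == pytest.approx(expected.get(t, 0.0))

    def test_maternal_only_has_no_fetal(self, small_sc):
        counts, meta, _ = small_sc
        _, props = make_pseudobulk(counts, meta, "maternal_only", seed=0)
        fetal_types = set(meta.loc[meta["origin"] == "fetal", "cell_type"])
        assert props[sorted(fetal_types)].sum() == 0.0

    def test_unknown_scenario_rejected(self, small_sc):
        counts, meta, _ = small_sc
        with pytest.raises(ValueError, match="unknown scenario"):
            make_pseudobulk(counts, meta, "everything", seed=0)
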