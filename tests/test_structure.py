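import numpy as np
import pandas as pd
import pytest

from rohscape import GenotypeDataset, PruneParams, ibs_matrix, ld_prune, pca, remove_related
from rohscape.structure import _pair_r2

from conftest import make_dataset, random_dataset


class TestLdPrune:
    def test_duplicated_snp_one_removed(self):
        rng = np.random.default_rng(2)
        col = rng.integers(0, 3, size=10).astype(np.int8)
        calls = np.column_stack([col, col, rng.integers(0, 3, size=10)]).astype(np.int8)
        ds = make_dataset(calls)
        kept = ld_prune(ds, PruneParams(window_snps=3, step_snps=1))
        assert sum(1 for j in kept if j in (0, 1)) == 1

    def test_independent_snps_untouched(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(60, 12)).astype(np.int8)
        ds = make_dataset(calls)
        # verify the fixture truly has no high-LD pair, then prune
        for i in range(12):
            for j in range(i + 1, 12):
                assert _pair_r2(calls[:, i], calls[:, j]) <= 0.5
        kept = ld_prune(ds, PruneParams(window_snps=6, step_snps=2, r2_max=0.5))
        assert list(kept) == list(range(12))

    def test_postcondition_no_high_ld_pair_in_windows(self):
        rng = np.random.default_rng(7)
        base = rng.integers(0, 3, size=(40, 25)).astype(np.int8)
        # add correlated copies to force pruning
        noisy = base.copy()
        for j in range(0, 25, 3):
            k = min(j + 1, 24)
            noisy[:, k] = base[:, j]
        ds = make_dataset(noisy)
        params = PruneParams(window_snps=10, step_snps=3, r2_max=0.5)
        kept = list(ld_prune(ds, params))
        for w0 in range(0, 25, params.step_snps):
            wnd = [j for j in kept if w0 <= j < w0 + params.window_snps]
            for a in range(len(wnd)):
                for b in range(a + 1, len(wnd)):
                    r2 = _pair_r2(ds.calls[:, wnd[a]], ds.calls[:, wnd[b]])
                    assert not (np.isfinite(r2) and r2 > 0.5)


class TestIbs:
    def test_identical_samples_one(self):
        rng = np.random.default_rng(3)
        row = rng.integers(0, 3, size=30).astype(np.int8)
        ds = make_dataset(np.vstack([row, row]))
        m = ibs_matrix(ds)
        assert m.iloc[0, 1] == 1.0

    def test_opposite_homozygotes_zero(self):
        ds = make_dataset(np.vstack([np.zeros(20), np.full(20, 2)]).astype(np.int8))
        assert ibs_matrix(ds).iloc[0, 1] == 0.0

    def test_matches_direct_computation_and_symmetry(self):
        rng = np.random.default_rng(9)
        ds = random_dataset(rng, n_samples=6, n_snps=50)
        m = ibs_matrix(ds)
        assert np.allclose(m.to_numpy(), m.to_numpy().T, equal_nan=True)
        assert np.allclose(np.diag(m.to_numpy()), 1.0)
        i, j = 1, 4
        a, b = ds.calls[i], ds.calls[j]
        ok = (a != -1) & (b != -1)
        direct = np.mean((2 - np.abs(a[ok].astype(float) - b[ok])) / 2)
        assert m.iloc[i, j] == pytest.approx(direct, abs=1e-12)

    def test_invariant_to_snp_order(self):
        rng = np.random.default_rng(10)
        ds = random_dataset(rng, n_samples=5, n_snps=30)
        perm = rng.permutation(30)
        shuffled = GenotypeDataset(
            snps=ds.snps.iloc[np.sort(perm)].reset_index(drop=True),
            samples=ds.samples.copy(),
            calls=ds.calls[:, np.sort(perm)],
        )
        # same SNP set, different construction path
        pd.testing.assert_frame_equal(ibs_matrix(ds), ibs_matrix(shuffled))


class TestRemoveRelated:
    def test_duplicate_sample_reduced_to_one(self):
        rng = np.random.default_rng(5)
        row = rng.integers(0, 3, size=60).astype(np.int8)
        other = rng.integers(0, 3, size=60).astype(np.int8)
        ds = make_dataset(np.vstack([row, row, other]))
        out = remove_related(ds, 0.65)
        assert out.n_samples == 2
        assert "s3" in set(out.samples["sample_id"])

    def test_unrelated_unchanged(self):
        rng = np.random.default_rng(6)
        ds = random_dataset(rng, n_samples=5, n_snps=80, missing_rate=0.0)
        out = remove_related(ds, 0.99)
        assert out.n_samples == 5

    def test_clone_pair_with_outlier_hand_traced(self):
        rng = np.random.default_rng(8)
        clone = rng.integers(0, 3, size=100).astype(np.int8)
        clone2 = clone.copy()
        clone2[0] = -1  # lower call rate -> removed first
        outlier = 2 - clone  # maximally dissimilar
        ds = make_dataset(np.vstack([clone, clone2, outlier]))
        out = remove_related(ds, 0.9)
        assert list(out.samples["sample_id"]) == ["s1", "s3"]


class TestPca:
    def test_identical_samples_identical_coordinates(self):
        rng = np.random.default_rng(11)
        row = rng.integers(0, 3, size=50).astype(np.int8)
        others = rng.integers(0, 3, size=(4, 50)).astype(np.int8)
        ds = make_dataset(np.vstack([row, row, others]))
        res = pca(ds, k=2)
        c = res.coordinates
        assert np.allclose(
            c.loc[0, ["PC1", "PC2"]].to_numpy(dtype=float),
            c.loc[1, ["PC1", "PC2"]].to_numpy(dtype=float),
        )

    def test_eigenvalues_match_dense_decomposition(self):
        rng = np.random.default_rng(12)
        ds = random_dataset(rng, n_samples=20, n_snps=100, missing_rate=0.0)
        res = pca(ds, k=5)
        # independent dense eigendecomposition of the same scaled matrix
        d = ds.calls.astype(float)
        p = d.mean(axis=0) / 2
        keep = (p > 0) & (p < 1)
        z = (d[:, keep] - 2 * p[keep]) / np.sqrt(2 * p[keep] * (1 - p[keep]))
        cov = z @ z.T / z.shape[1]
        evals = np.sort(np.linalg.eigvalsh(cov))[::-1]
        assert np.allclose(res.eigenvalues, evals[:5], atol=1e-9)

    def test_k_too_large_errors(self):
        rng = np.random.default_rng(13)
        ds = random_dataset(rng, n_samples=4, n_snps=20)
        with pytest.raises(ValueError, match="exceeds"):
            pca(ds, k=4)

    def test_pc1_separates_diverged_populations(self):
        rng = np.random.default_rng(14)
        n_snps = 200
        p1 = rng.uniform(0.2, 0.8, n_snps)
        shift = rng.choice([-0.3, 0.3], n_snps)
        p2 = np.clip(p1 + shift, 0.05, 0.95)
        def draw(p, n):
            return (rng.random((n, n_snps)) < p).astype(int) + (rng.random((n, n_snps)) < p).astype(int)
        calls = np.vstack([draw(p1, 15), draw(p2, 15)]).astype(np.int8)
        ds = make_dataset(calls, populations=["A"] * 15 + ["B"] * 15)
        res = pca(ds, k=2)
        pc1 = res.coordinates["PC1"].to_numpy()
        a, b = pc1[:15], pc1[15:]
        # group separation: gap between group means exceeds within-group spread
        assert abs(a.mean() - b.mean()) > 2 * (a.std() + b.std()) / 2

    def test_sample_order_invariance_up_to_sign(self):
        rng = np.random.default_rng(15)
        ds = random_dataset(rng, n_samples=10, n_snps=60, missing_rate=0.0)
        perm = rng.permutation(10)
        shuffled = ds.subset(sample_idx=perm)
        r1 = pca(ds, k=2)
        r2 = pca(shuffled, k=2)
        c1 = r1.coordinates.set_index("sample_id")[["PC1", "PC2"]]
        c2 = r2.coordinates.set_index("sample_id")[["PC1", "PC2"]]
        for pc in ("PC1", "PC2"):
            v1 = c1[pc].loc[c2.index].to_numpy()
            v2 = c2[pc].to_numpy()
            assert np.allclose(v1, v2, atol=1e-8) or np.allclose(v1, -v2, atol=1e-8)
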