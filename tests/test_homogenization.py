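import numpy as np
import pandas as pd
import pytest

from tdrscan.core_data import DataError
from tdrscan.homogenization import (
    HomogenizationSpec,
    combat_location_estimates,
    homogenize,
    homogenize_combat,
    homogenize_limma,
    homogenize_none,
    homogenize_quantile,
    homogenize_ruv4,
    homogenize_ruv_custom,
    homogenize_yugene,
)


def make_pair(n_genes=50, n_train=30, n_test=20, shift=0.0, seed=0):
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    train = pd.DataFrame(
        rng.normal(5, 1, (n_genes, n_train)),
        index=genes,
        columns=[f"t{i}" for i in range(n_train)],
    )
    test = pd.DataFrame(
        rng.normal(5 + shift, 1, (n_genes, n_test)),
        index=genes,
        columns=[f"p{i}" for i in range(n_test)],
    )
    return train, test


class TestNoneAndShapes:
    def test_identity(self):
        train, test = make_pair()
        out_train, out_test = homogenize_none(train, test)
        assert out_train is train and out_test is test

    @pytest.mark.parametrize(
        "method", ["quantile", "combat", "limma", "ruv", "ruv4", "yugene"]
    )
    def test_shape_and_order_preserved(self, method):
        train, test = make_pair(seed=2)
        spec = HomogenizationSpec(
            method=method,
            control_genes=frozenset(f"g{i}" for i in range(15)),
            n_unwanted_factors=3,
        )
        out_train, out_test = homogenize(train, test, spec)
        assert list(out_train.index) == list(train.index)
        assert list(out_train.columns) == list(train.columns)
        assert out_test.shape == test.shape


class TestQuantile:
    def test_hand_worked_two_samples(self):
        train = pd.DataFrame({"t1": [1.0, 3.0, 5.0]}, index=["a", "b", "c"])
        test = pd.DataFrame({"p1": [2.0, 4.0, 8.0]}, index=["a", "b", "c"])
        out_train, out_test = homogenize_quantile(train, test)
        np.testing.assert_allclose(out_train["t1"], [1.5, 3.5, 6.5])
        np.testing.assert_allclose(out_test["p1"], [1.5, 3.5, 6.5])

    def test_identical_samples_unchanged(self):
        col = [1.0, 2.0, 7.0]
        train = pd.DataFrame({"t1": col, "t2": col}, index=["a", "b", "c"])
        test = pd.DataFrame({"p1": col}, index=["a", "b", "c"])
        out_train, out_test = homogenize_quantile(train, test)
        np.testing.assert_allclose(out_train["t1"], col)
        np.testing.assert_allclose(out_test["p1"], col)

    def test_all_sorted_vectors_identical(self):
        train, test = make_pair(shift=2.0, seed=3)
        out_train, out_test = homogenize_quantile(train, test)
        pooled = pd.concat([out_train, out_test], axis=1)
        ref = np.sort(pooled.iloc[:, 0].to_numpy())
        for j in range(pooled.shape[1]):
            np.testing.assert_allclose(np.sort(pooled.iloc[:, j].to_numpy()), ref)

    def test_gene_mismatch_errors(self):
        train, test = make_pair()
        with pytest.raises(DataError):
            homogenize_quantile(train, test.iloc[::-1])


class TestLimma:
    def test_closed_form_centering(self):
        train = pd.DataFrame(
            [[4.0, 6.0]], index=["g"], columns=["t1", "t2"]
        )  # train mean 5
        test = pd.DataFrame([[6.0, 8.0]], index=["g"], columns=["p1", "p2"])  # mean 7
        out_train, out_test = homogenize_limma(train, test)
        assert out_train.loc["g"].mean() == pytest.approx(6.0)
        assert out_test.loc["g"].mean() == pytest.approx(6.0)

    def test_batch_means_exactly_equal(self):
        train, test = make_pair(shift=1.5, seed=4)
        out_train, out_test = homogenize_limma(train, test)
        np.testing.assert_allclose(
            out_train.mean(axis=1), out_test.mean(axis=1), atol=1e-12
        )

    def test_shift_invariance_up_to_global_constant(self):
        # A constant added to the test batch is absorbed into the fitted
        # batch term; outputs change only by one global constant (which no
        # downstream stage can see), never by a gene- or sample-specific
        # amount.
        train, test = make_pair(seed=5)
        base = homogenize_limma(train, test)
        shifted = homogenize_limma(train, test + 3.7)
        for a, b in zip(base, shifted):
            diff = (b - a).to_numpy()
            assert np.allclose(diff, diff.flat[0], atol=1e-10)
        # and the batch-mean gap stays removed in both cases
        np.testing.assert_allclose(
            shifted[0].mean(axis=1), shifted[1].mean(axis=1), atol=1e-12
        )


class TestCombat:
    def test_matches_reference_implementation(self):
        # Frozen oracle: output of the Bioconductor sva::ComBat reference
        # implementation on a small synthetic fixture (both files generated
        # for this test; see the *_synthetic.tsv names).
        import pathlib

        data_dir = pathlib.Path(__file__).parent / "data"
        d = pd.read_csv(data_dir / "combat_input_synthetic.tsv", sep="\t", index_col=0)
        ref = pd.read_csv(
            data_dir / "combat_reference_synthetic.tsv", sep="\t", index_col=0
        )
        out_train, out_test = homogenize_combat(d.iloc[:, :8], d.iloc[:, 8:])
        mine = pd.concat([out_train, out_test], axis=1)
        np.testing.assert_allclose(mine, ref, atol=1e-5)

    def test_planted_shift_removed(self):
        # Residual per-gene batch gap after EB adjustment is bounded by the
        # sampling noise of the batch means, which shrinks with batch size.
        train, test = make_pair(n_genes=200, n_train=200, n_test=200, shift=2.0, seed=6)
        out_train, out_test = homogenize_combat(train, test)
        delta = (out_train.mean(axis=1) - out_test.mean(axis=1)).abs()
        assert delta.median() < 0.05

    def test_no_batch_limit_near_identity(self):
        train, test = make_pair(n_genes=100, n_train=60, n_test=60, shift=0.0, seed=7)
        out_train, out_test = homogenize_combat(train, test)
        assert (out_train - train).abs().to_numpy().max() < 0.5
        # batch means still closer than a real correction would move them
        assert (out_train.mean(axis=1) - train.mean(axis=1)).abs().max() < 0.2

    def test_location_shrinkage_direction(self):
        train, test = make_pair(n_genes=100, shift=1.0, seed=8)
        diag = combat_location_estimates(train, test)
        lo = np.minimum(diag["g_hat"], diag["g_bar"])
        hi = np.maximum(diag["g_hat"], diag["g_bar"])
        assert ((diag["g_star"] >= lo - 1e-9) & (diag["g_star"] <= hi + 1e-9)).all()

    def test_single_sample_batch_errors(self):
        train, test = make_pair()
        with pytest.raises(DataError):
            homogenize_combat(train, test.iloc[:, :1])

    def test_zero_variance_gene_passthrough(self):
        train, test = make_pair(n_genes=10, seed=9)
        train.iloc[0] = 3.0
        test.iloc[0] = 3.0
        with pytest.warns(UserWarning, match="zero-variance"):
            out_train, out_test = homogenize_combat(train, test)
        assert (out_train.iloc[0] == 3.0).all()


def plant_factor_pair(n_genes=120, n_controls=30, n=40, strength=3.0, seed=10):
    """Batch factor loaded on every gene, controls carrying only the factor."""
    rng = np.random.default_rng(seed)
    genes = [f"g{i}" for i in range(n_genes)]
    batch = np.r_[np.zeros(n), np.ones(n)]  # pooled batch labels
    loadings = rng.normal(1.0, 0.2, n_genes) * strength
    base = rng.normal(5, 1, (n_genes, 2 * n))
    data = base + loadings[:, None] * batch[None, :]
    pooled = pd.DataFrame(
        data, index=genes, columns=[f"s{i}" for i in range(2 * n)]
    )
    train = pooled.iloc[:, :n]
    test = pooled.iloc[:, n:]
    controls = frozenset(genes[:n_controls])
    return train, test, controls, batch


class TestRUV:
    def test_residuals_orthogonal_to_factors(self):
        train, test, controls, _ = plant_factor_pair()
        spec = HomogenizationSpec(method="ruv", control_genes=controls, n_unwanted_factors=5)
        out_train, out_test = homogenize_ruv_custom(train, test, spec)
        pooled_in = pd.concat([train, test], axis=1)
        pooled_out = pd.concat([out_train, out_test], axis=1)
        sub = pooled_in.loc[list(controls)].to_numpy().T
        centered = sub - sub.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        w = u[:, :5] * s[:5]
        resid = pooled_out.to_numpy() - pooled_out.to_numpy().mean(axis=1, keepdims=True)
        dots = np.abs(resid @ w)
        assert dots.max() < 1e-8

    def test_planted_batch_factor_removed(self):
        train, test, controls, batch = plant_factor_pair()
        spec = HomogenizationSpec(method="ruv", control_genes=controls, n_unwanted_factors=5)

        def top_pc_auc(train_df, test_df):
            pooled = pd.concat([train_df, test_df], axis=1).to_numpy().T
            pooled = pooled - pooled.mean(axis=0)
            u, s, _ = np.linalg.svd(pooled, full_matrices=False)
            pc1 = u[:, 0]
            from tdrscan.evaluation import roc_auc

            auc = roc_auc(pd.Series(pc1), pd.Series(batch.astype(int)))
            return max(auc, 1 - auc)

        assert top_pc_auc(train, test) > 0.95
        out_train, out_test = homogenize_ruv_custom(train, test, spec)
        assert top_pc_auc(out_train, out_test) < 0.6

    def test_ruv4_agrees_with_ruv_on_control_only_factor(self):
        train, test, controls, _ = plant_factor_pair(seed=11)
        spec = HomogenizationSpec(method="ruv4", control_genes=controls, n_unwanted_factors=5)
        a_train, a_test = homogenize_ruv_custom(train, test, spec)
        b_train, b_test = homogenize_ruv4(train, test, spec)
        rms = np.sqrt(((a_train - b_train) ** 2).to_numpy().mean())
        assert rms < 0.05

    def test_too_many_factors_errors(self):
        train, test, controls, _ = plant_factor_pair(n=4)
        spec = HomogenizationSpec(method="ruv", control_genes=controls, n_unwanted_factors=10)
        with pytest.raises(DataError, match="factors"):
            homogenize_ruv_custom(train, test, spec)

    def test_too_few_controls_errors(self):
        train, test, _, _ = plant_factor_pair()
        spec = HomogenizationSpec(
            method="ruv", control_genes=frozenset(["g0"]), n_unwanted_factors=2
        )
        with pytest.raises(DataError, match="control"):
            homogenize_ruv_custom(train, test, spec)


class TestYuGene:
    def test_hand_worked_sample(self):
        train = pd.DataFrame({"t1": [3.0, 1.0, 2.0]}, index=["a", "b", "c"])
        test = pd.DataFrame({"p1": [3.0, 1.0, 2.0]}, index=["a", "b", "c"])
        out_train, _ = homogenize_yugene(train, test)
        np.testing.assert_allclose(out_train["t1"], [0.5, 0.0, 1 / 6], atol=1e-12)

    def test_scale_invariance(self):
        train, test = make_pair(seed=12)
        train = train.abs()
        test = test.abs()
        a, _ = homogenize_yugene(train, test)
        b, _ = homogenize_yugene(train * 7.0, test)
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_constant_sample_tie_rule(self):
        train = pd.DataFrame({"t1": [1.0, 1.0, 1.0]}, index=["a", "b", "c"])
        test = train.rename(columns={"t1": "p1"})
        out_train, _ = homogenize_yugene(train, test)
        np.testing.assert_allclose(out_train["t1"], [2 / 3, 1 / 3, 0.0])

    def test_negative_values_error_and_shift_flag(self):
        train = pd.DataFrame({"t1": [-1.0, 2.0]}, index=["a", "b"])
        test = pd.DataFrame({"p1": [1.0, 2.0]}, index=["a", "b"])
        with pytest.raises(DataError, match="non-negative"):
            homogenize_yugene(train, test)
        out_train, _ = homogenize_yugene(train, test, shift_negative=True)
        assert (out_train >= 0).all().all()
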