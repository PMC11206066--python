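import itertools

import numpy as np
import pytest

from ecoassembly.ordination import (
    clr_transform,
    envfit,
    envfit_all,
    rda,
    variance_partition,
)

from conftest import make_table


class TestCLR:
    def test_uniform_sample_is_zero(self):
        table = make_table(np.ones((4, 3), dtype=int))
        clr = clr_transform(table)
        np.testing.assert_allclose(clr, 0.0, atol=1e-12)

    def test_rows_sum_to_zero(self, random_table):
        clr = clr_transform(random_table)
        np.testing.assert_allclose(clr.sum(axis=1), 0.0, atol=1e-10)

    def test_hand_computed_no_zeros(self):
        table = make_table(np.array([[1, 1], [10, 10], [100, 100]]))
        clr = clr_transform(table)
        logs = np.log([1.0, 10.0, 100.0])
        np.testing.assert_allclose(clr[0], logs - logs.mean(), atol=1e-12)

    def test_pseudocount_validation(self):
        table = make_table(np.ones((2, 2), dtype=int))
        with pytest.raises(ValueError, match="pseudocount"):
            clr_transform(table, pseudocount=0.0)

    def test_pseudocount_only_touches_zeros(self):
        table = make_table(np.array([[4, 1], [0, 3]]))
        clr = clr_transform(table, pseudocount=0.5)
        expected0 = np.log([4.0, 0.5])
        np.testing.assert_allclose(clr[0], expected0 - expected0.mean())


class TestRDA:
    def test_orthogonal_predictors_near_zero(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(200, 8))
        x = rng.normal(size=(200, 2))
        res = rda(y, x)
        assert res.proportion_constrained < 0.05

    def test_perfect_linear_map(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(30, 3))
        b = rng.normal(size=(3, 6))
        y = x @ b
        res = rda(y, x)
        assert res.proportion_constrained == pytest.approx(1.0, abs=1e-10)

    def test_trace_r2_oracle(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=(20, 10))
        x = rng.normal(size=(20, 3))
        res = rda(y, x)
        # independent oracle: classical multivariate regression trace R2
        yc = y - y.mean(axis=0)
        xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
        hat = xs @ np.linalg.solve(xs.T @ xs, xs.T @ yc)
        oracle = np.square(hat).sum() / np.square(yc).sum()
        assert res.proportion_constrained == pytest.approx(oracle, abs=1e-10)

    def test_eigenvalue_total_equals_variance(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(25, 7))
        x = rng.normal(size=(25, 3))
        res = rda(y, x)
        yc = y - y.mean(axis=0)
        total = np.square(yc).sum() / (25 - 1)
        assert res.constrained_eigenvalues.sum() + res.unconstrained_eigenvalues.sum() == pytest.approx(total, abs=1e-8)

    def test_eigenvalues_non_increasing(self):
        rng = np.random.default_rng(4)
        res = rda(rng.normal(size=(30, 9)), rng.normal(size=(30, 4)))
        assert (np.diff(res.constrained_eigenvalues) <= 1e-12).all()
        assert (np.diff(res.unconstrained_eigenvalues) <= 1e-12).all()

    def test_collinear_predictors_dropped(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(20, 2))
        x3 = np.column_stack([x, x[:, 0] + x[:, 1]])
        with pytest.warns(UserWarning, match="aliased"):
            res = rda(rng.normal(size=(20, 5)), x3, ["a", "b", "c"])
        assert res.aliased == ["c"]
        assert res.predictor_names == ["a", "b"]


class TestEnvfit:
    def test_perfect_alignment(self):
        rng = np.random.default_rng(0)
        scores = rng.normal(size=(50, 2))
        r2, p = envfit(scores, scores[:, 0], n_perm=999, seed=1)
        assert r2 == pytest.approx(1.0)
        assert p == pytest.approx(1.0 / 1000.0)

    def test_constant_variable(self):
        scores = np.random.default_rng(0).normal(size=(20, 2))
        r2, p = envfit(scores, np.full(20, 3.0))
        assert (r2, p) == (0.0, 1.0)

    def test_determinism(self):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=(40, 2))
        v = rng.normal(size=40)
        assert envfit(scores, v, seed=9) == envfit(scores, v, seed=9)

    def test_envfit_all_frame(self):
        import pandas as pd

        rng = np.random.default_rng(2)
        scores = rng.normal(size=(30, 2))
        df = pd.DataFrame({"a": scores[:, 0], "b": rng.normal(size=30)})
        out = envfit_all(scores, df, n_perm=99, seed=0)
        assert list(out["variable"]) == ["a", "b"]
        assert out.loc[0, "r2"] > 0.99
        assert out.loc[1, "p"] > 0.05


class TestVPA:
    @staticmethod
    def _reconstruct(result, union):
        total = 0.0
        names = result.block_names
        for r in (1, 2, 3):
            for subset in itertools.combinations(names, r):
                if not set(subset) & set(union):
                    continue
                if len(subset) == 1:
                    key = f"pure_{subset[0]}"
                elif len(subset) == 2:
                    key = f"joint_{subset[0]}_{subset[1]}"
                else:
                    key = "joint_all"
                total += result.fractions[key]
        return total

    def test_inclusion_exclusion_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=(60, 10))
        z = rng.normal(size=60)
        blocks = {
            "topography": np.column_stack([z + rng.normal(size=60), rng.normal(size=60)]),
            "light": np.column_stack([z + rng.normal(size=60)] * 1),
            "soil": rng.normal(size=(60, 2)),
        }
        y[:, 0] += z
        res = variance_partition(y, blocks)
        for r in (1, 2, 3):
            for union in itertools.combinations(res.block_names, r):
                assert self._reconstruct(res, union) == pytest.approx(
                    res.adjusted_r2_by_union[union], abs=1e-8
                )
        assert res.residual == pytest.approx(
            1.0 - res.adjusted_r2_by_union[res.block_names], abs=1e-12
        )

    def test_duplicated_blocks_share_everything(self):
        rng = np.random.default_rng(1)
        z = rng.normal(size=(80, 2))
        y = np.column_stack([z @ rng.normal(size=(2, 4))]) + rng.normal(scale=0.3, size=(80, 4))
        blocks = {"topography": z, "light": z.copy(), "soil": z.copy()}
        res = variance_partition(y, blocks)
        for name in res.block_names:
            assert abs(res.fractions[f"pure_{name}"]) < 0.02
        assert res.fractions["joint_all"] > 0.5

    def test_orthogonal_blocks_pure_fractions(self):
        rng = np.random.default_rng(2)
        n = 300
        a = rng.normal(size=(n, 1))
        b = rng.normal(size=(n, 1))
        c = rng.normal(size=(n, 1))
        y = np.column_stack([a, b, c]) + rng.normal(scale=1.0, size=(n, 3))
        res = variance_partition(y, {"topography": a, "light": b, "soil": c})
        for name in res.block_names:
            assert res.fractions[f"pure_{name}"] > 0.05
        for key in ("joint_topography_light", "joint_topography_soil",
                    "joint_light_soil", "joint_all"):
            assert abs(res.fractions[key]) < 0.02

    def test_block_validation(self):
        rng = np.random.default_rng(3)
        y = rng.normal(size=(10, 3))
        with pytest.raises(ValueError, match="three"):
            variance_partition(y, {"a": rng.normal(size=(10, 1))})
        with pytest.raises(ValueError, match="columns"):
            variance_partition(
                y,
                {
                    "topography": rng.normal(size=(10, 10)),
                    "light": rng.normal(size=(10, 1)),
                    "soil": rng.normal(size=(10, 1)),
                },
            )
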