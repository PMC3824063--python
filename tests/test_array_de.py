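"""Microarray DE: normalization, SNR statistic, permutation p-values
and the significance gate."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirnforge.array_de import (
    de_table,
    gate_and_intersect,
    median_polish,
    normalize,
    permutation_pvalues,
    quantile_normalize,
    signed_fold_change,
    snr_statistic,
)
from mirnforge.synth import simulate_expression_matrix


class TestSNR:
    def test_textbook_value(self):
        assert snr_statistic([3, 4, 5], [1, 2, 3]) == pytest.approx(1.0)

    def test_identical_groups_zero(self):
        assert snr_statistic([2, 3, 4], [2, 3, 4]) == 0.0

    def test_sd_floor_on_replicate_identical_groups(self):
        assert snr_statistic([10, 10], [2, 2]) == pytest.approx(400.0)

    def test_error_when_floor_disabled_and_variance_zero(self):
        with pytest.raises(ValueError):
            snr_statistic([10, 10], [2, 2], eps=0.0)

    def test_antisymmetric_under_group_swap(self):
        a, b = [3.0, 4.5, 5.1], [1.2, 2.0, 2.9]
        assert snr_statistic(a, b) == pytest.approx(-snr_statistic(b, a))

    def test_needs_two_replicates(self):
        with pytest.raises(ValueError):
            snr_statistic([1], [2, 3])


class TestQuantileNormalize:
    def test_identical_columns_are_fixed_point(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 3.0], "b": [1.0, 5.0, 3.0]})
        assert np.allclose(quantile_normalize(df), df)

    def test_columns_share_sorted_vectors(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(size=(50, 4)))
        out = quantile_normalize(df)
        sorted_cols = np.sort(out.to_numpy(), axis=0)
        for j in range(1, 4):
            assert np.allclose(sorted_cols[:, 0], sorted_cols[:, j])

    def test_permuted_columns_become_identical_multisets(self):
        rng = np.random.default_rng(1)
        col = rng.normal(size=30)
        df = pd.DataFrame({"a": col, "b": rng.permutation(col)})
        out = quantile_normalize(df)
        assert np.allclose(np.sort(out["a"]), np.sort(out["b"]))
        assert np.allclose(np.sort(out["a"]), np.sort(col))


class TestMedianPolish:
    def test_hand_iterated_oracle(self):
        # one sweep by hand: row medians [1.5, 3.5, 7]; median of row
        # effects 3.5 folds into the overall; column medians of the
        # residuals [-0.5, 0.5]; second sweep changes nothing
        m = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 9.0]])
        overall, row, col, resid = median_polish(m)
        assert overall == pytest.approx(3.5)
        assert row == pytest.approx([-2.0, 0.0, 3.5])
        assert col == pytest.approx([-0.5, 0.5])
        assert np.allclose(resid, [[0.0, 0.0], [0.0, 0.0], [-1.5, 1.5]])

    def test_decomposition_reconstructs_matrix(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(6, 4))
        overall, row, col, resid = median_polish(m, max_iter=20)
        assert np.allclose(overall + row[:, None] + col[None, :] + resid, m)


class TestNormalize:
    def test_multirow_probe_summarized(self):
        raw = pd.DataFrame(
            2.0 ** np.array([[8.0, 9.0], [8.2, 9.2], [5.0, 6.0]]),
            index=["pA", "pA", "pB"],
            columns=["s1", "s2"],
        )
        out = normalize(raw)
        assert list(out.index) == ["pA", "pB"]
        assert out.shape == (2, 2)

    def test_nonpositive_intensity_rejected(self):
        raw = pd.DataFrame({"s1": [1.0, -2.0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            normalize(raw)


class TestPermutationPvalues:
    def _matrix(self, seed=0, n_probes=12):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            rng.normal(8, 1, size=(n_probes, 6)),
            index=[f"p{i}" for i in range(n_probes)],
            columns=list("abcdef"),
        )

    GROUPS = ["control"] * 3 + ["treated"] * 3

    def test_exhaustive_matches_independent_enumeration(self):
        matrix = self._matrix()
        out = permutation_pvalues(matrix, self.GROUPS, exhaustive=True, pool_probes=False)
        arr = matrix.to_numpy()

        def snr(vals, t_idx, c_idx):
            t, c = vals[list(t_idx)], vals[list(c_idx)]
            return (t.mean() - c.mean()) / (
                max(t.std(ddof=1), 0.01) + max(c.std(ddof=1), 0.01)
            )

        for i, probe in enumerate(matrix.index):
            obs = snr(arr[i], [3, 4, 5], [0, 1, 2])
            null = [
                snr(arr[i], combo, [k for k in range(6) if k not in combo])
                for combo in combinations(range(6), 3)
            ]
            assert len(null) == 20
            p_right = sum(v >= obs for v in null) / 20
            p_left = sum(v <= obs for v in null) / 20
            assert out.loc[probe, "p_right"] == pytest.approx(p_right)
            assert out.loc[probe, "p_left"] == pytest.approx(p_left)

    def test_null_probe_has_two_sided_p_near_one(self):
        matrix = self._matrix()
        matrix.iloc[0] = [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]  # snr exactly 0
        out = permutation_pvalues(matrix, self.GROUPS, exhaustive=True, pool_probes=False)
        assert out.iloc[0]["snr"] == 0.0
        assert out.iloc[0]["p_two"] == pytest.approx(1.0)

    def test_deterministic_given_seed(self):
        matrix = self._matrix()
        a = permutation_pvalues(matrix, self.GROUPS, n_perm=200, seed=42)
        b = permutation_pvalues(matrix, self.GROUPS, n_perm=200, seed=42)
        assert a.equals(b)

    def test_pseudocount_keeps_p_positive(self):
        matrix = self._matrix()
        matrix.iloc[0, 3:] += 100  # overwhelming effect
        out = permutation_pvalues(matrix, self.GROUPS, n_perm=100, seed=0, pool_probes=False)
        # only relabelings that reproduce the true treated set can tie the
        # observed SNR; the +1 pseudocount keeps the estimate positive
        assert 1 / 101 <= out.iloc[0]["p_right"] <= 0.2

    def test_pvalues_uniform_under_null(self):
        # label-exchangeable data: per-probe permutation p-values should
        # be ~U(0,1); KS test must not reject at alpha = 0.01
        rng = np.random.default_rng(3)
        matrix = pd.DataFrame(rng.normal(size=(150, 6)), columns=list("abcdef"))
        out = permutation_pvalues(
            matrix, self.GROUPS, n_perm=1000, seed=1, pool_probes=True
        )
        ks = sps.kstest(out["p_right"], "uniform")
        assert ks.pvalue > 0.01

    def test_invalid_n_perm(self):
        with pytest.raises(ValueError):
            permutation_pvalues(self._matrix(), self.GROUPS, n_perm=0)


class TestGate:
    def _stats(self):
        return pd.DataFrame(
            {
                "p_two": [0.009, 0.009, 0.02, 0.01],
                "fold_change": [1.25, 1.1, 2.0, -1.2],
            },
            index=["g1", "g2", "g3", "g4"],
        ).assign(significant=lambda d: (d.p_two <= 0.01) & (d.fold_change.abs() >= 1.2))

    def test_boundary_behavior(self):
        sig, _ = gate_and_intersect(self._stats())
        # g1: both thresholds met; g2: |FC| below 1.2; g3: p above 0.01;
        # g4: boundary values on both (p == 0.01, |FC| == 1.2) -> in
        assert sig == {"g1", "g4"}

    def test_list_intersections(self):
        sig, inter = gate_and_intersect(
            self._stats(), {"A": ["g1", "g2"], "B": ["g2", "g4"]}
        )
        assert inter == {"A": {"g1"}, "B": {"g4"}}

    def test_fold_change_sign_folding(self):
        matrix = pd.DataFrame(
            [[1.0, 1.0, 1.0, 3.0, 3.0, 3.0], [3.0, 3.0, 3.0, 1.0, 1.0, 1.0]],
            columns=list("abcdef"),
        )
        fc = signed_fold_change(matrix, ["control"] * 3 + ["treated"] * 3)
        assert fc.iloc[0] == pytest.approx(4.0)
        assert fc.iloc[1] == pytest.approx(-4.0)


class TestEndToEndArray:
    def test_de_table_recovers_planted_effects(self):
        raw, groups = simulate_expression_matrix(
            n_probes=200, n_de=20, effect=1.5, seed=4
        )
        matrix = normalize(raw)
        stats = de_table(matrix, groups, n_perm=2000, seed=5)
        planted = {f"p{i + 1}" for i in range(20)}
        sig, _ = gate_and_intersect(stats)
        # most planted effects found, few nulls called
        assert len(sig & planted) >= 12
        assert len(sig - planted) <= 6
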