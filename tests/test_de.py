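"""Dispersion estimation, NB exact test, FDR, contrasts and Venn logic."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from oracles import bh_stepup_oracle, binomial_conditional_pvalue
from rnadeg.de import (
    Contrast,
    bh_adjust,
    estimate_common_dispersion,
    exact_test_pvalue,
    intersect_de_sets,
    nb_exact_test,
    run_contrast,
    threshold_de,
)
from rnadeg.normalization import NormalizationResult


def _nb(rng, mu, phi, size):
    if phi == 0:
        return rng.poisson(mu, size=size)
    r = 1.0 / phi
    return rng.negative_binomial(r, r / (r + mu), size=size)


def _frame(arr, prefix="s"):
    return pd.DataFrame(
        np.asarray(arr, dtype=float),
        index=[f"g{i}" for i in range(len(arr))],
        columns=[f"{prefix}{j}" for j in range(len(arr[0]))],
    )


def _norm_from(pseudo: pd.DataFrame) -> NormalizationResult:
    return NormalizationResult(
        factors=pd.DataFrame(1.0, index=[0], columns=pseudo.columns),
        bins=pd.Series(0, index=pseudo.index),
        pseudo=pseudo,
        effective_lib_size=float(pseudo.sum(axis=0).mean()),
        covariate="none",
    )


class TestDispersion:
    def test_recovers_planted_dispersion(self):
        rng = np.random.default_rng(1)
        mu = np.exp(rng.uniform(np.log(30), np.log(400), 2000))
        y = _nb(rng, mu[:, None], 0.2, (2000, 6))
        est = estimate_common_dispersion(_frame(y), [["s0", "s1", "s2"], ["s3", "s4", "s5"]])
        assert est.phi == pytest.approx(0.2, rel=0.2)

    def test_poisson_data_estimates_near_zero(self):
        rng = np.random.default_rng(2)
        mu = rng.uniform(50, 300, 1500)
        y = _nb(rng, mu[:, None], 0.0, (1500, 6))
        est = estimate_common_dispersion(_frame(y), [[f"s{j}" for j in range(6)]])
        assert est.phi <= 0.01

    def test_equal_counts_push_to_lower_bound(self):
        # a single gene with identical replicate counts shows no
        # overdispersion: likelihood is monotone decreasing in phi
        y = _frame([[50, 50, 50, 50]])
        est = estimate_common_dispersion(y, [["s0", "s1", "s2", "s3"]])
        assert est.phi == pytest.approx(1e-4, rel=0.05)
        from rnadeg.de import _group_conditional_loglik

        vals = [
            _group_conditional_loglik(np.array([[50.0, 50, 50, 50]]), p)[0]
            for p in (1e-4, 1e-3, 0.01, 0.1, 1.0)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            estimate_common_dispersion(pd.DataFrame(), [["a", "b"]])


class TestExactTest:
    def test_modal_split_gives_p_one(self):
        assert exact_test_pvalue(30, 30, 3, 3, 0.1) == pytest.approx(1.0)
        assert exact_test_pvalue(0, 0, 3, 3, 0.1) == 1.0

    @pytest.mark.parametrize("n1,n2", [(3, 3), (2, 4)])
    def test_poisson_limit_matches_binomial_enumeration(self, n1, n2):
        rng = np.random.default_rng(3)
        for _ in range(60):
            s = int(rng.integers(1, 200))
            a = int(rng.integers(0, s + 1))
            ours = exact_test_pvalue(a, s - a, n1, n2, 0.0)
            oracle = binomial_conditional_pvalue(a, s - a, n1, n2)
            assert ours == pytest.approx(oracle, abs=1e-8)

    def test_group_label_swap_symmetry(self):
        for a, b in [(10, 40), (0, 12), (33, 35)]:
            assert exact_test_pvalue(a, b, 3, 3, 0.15) == pytest.approx(
                exact_test_pvalue(b, a, 3, 3, 0.15), abs=1e-12
            )

    def test_p_monotone_nondecreasing_in_dispersion(self):
        for a, b in [(10, 30), (0, 15), (60, 20)]:
            grid = [0.0, 0.01, 0.05, 0.1, 0.3, 1.0]
            ps = [exact_test_pvalue(a, b, 3, 3, phi) for phi in grid]
            assert all(p2 >= p1 - 1e-12 for p1, p2 in zip(ps, ps[1:]))

    def test_normal_approximation_continuous_at_switchover(self):
        # compare the approximation against full enumeration just above
        # the cap (enumeration forced by max_enumeration=None)
        for a, b, phi in [(3300, 2900, 0.05), (2600, 3600, 0.1), (3100, 3100, 0.2)]:
            exact = exact_test_pvalue(a, b, 3, 3, phi, max_enumeration=None)
            approx = exact_test_pvalue(a, b, 3, 3, phi, max_enumeration=5000)
            assert approx == pytest.approx(exact, abs=0.02)

    def test_null_calibration_known_phi(self):
        rng = np.random.default_rng(4)
        mu = np.exp(rng.uniform(np.log(20), np.log(500), 1000))
        y = _frame(_nb(rng, mu[:, None], 0.1, (1000, 6)))
        p = nb_exact_test(y, ["s0", "s1", "s2"], ["s3", "s4", "s5"], phi=0.1)
        assert 0.03 <= (p < 0.05).mean() <= 0.07


class TestBhAdjust:
    def test_hand_stepup_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_independent_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(0, 1, 50)
        assert np.allclose(bh_adjust(p), bh_stepup_oracle(p.tolist()))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_adjust([0.1, 1.5])


class TestRunContrast:
    @staticmethod
    def _design(n=6):
        return pd.DataFrame(
            {
                "genotype": ["Tg"] * (n // 2) + ["NTg"] * (n // 2),
                "sex": "M",
                "age": "young",
                "replicate": list(range(1, n // 2 + 1)) * 2,
            },
            index=pd.Index([f"s{j}" for j in range(n)], name="sample_id"),
        )

    @staticmethod
    def _contrast():
        return Contrast("tg_vs_ntg", {"genotype": "NTg"}, {"genotype": "Tg"})

    def test_null_pvalues_near_uniform(self):
        rng = np.random.default_rng(5)
        mu = np.exp(rng.uniform(np.log(30), np.log(500), 2000))
        pseudo = _frame(_nb(rng, mu[:, None], 0.08, (2000, 6)))
        res = run_contrast(_norm_from(pseudo), self._design(), self._contrast())
        assert kstest(res.table["pvalue"], "uniform").statistic < 0.05

    def test_recovers_spiked_log2fc(self):
        rng = np.random.default_rng(6)
        n, n_de = 1000, 100
        mu = np.exp(rng.uniform(np.log(50), np.log(500), n))
        mu_mat = np.tile(mu[:, None], (1, 6)).astype(float)
        mu_mat[:n_de, :3] *= 4.0  # Tg samples s0..s2 up 2 log2 units
        pseudo = _frame(_nb(rng, mu_mat, 0.05, (n, 6)))
        res = run_contrast(_norm_from(pseudo), self._design(), self._contrast())
        spiked = res.table.iloc[:n_de]
        assert spiked["log2fc"].mean() == pytest.approx(2.0, abs=0.15)
        assert (spiked["fdr"] < 0.05).mean() > 0.9

    def test_swapping_groups_negates_log2fc_keeps_p(self):
        rng = np.random.default_rng(7)
        pseudo = _frame(rng.poisson(100, (200, 6)))
        fwd = run_contrast(_norm_from(pseudo), self._design(), self._contrast(), phi=0.1)
        rev = run_contrast(
            _norm_from(pseudo),
            self._design(),
            Contrast("r", {"genotype": "Tg"}, {"genotype": "NTg"}),
            phi=0.1,
        )
        assert np.allclose(fwd.table["pvalue"], rev.table["pvalue"], atol=1e-12)
        assert np.allclose(fwd.table["log2fc"], -rev.table["log2fc"], atol=1e-12)

    def test_deterministic(self):
        rng = np.random.default_rng(8)
        pseudo = _frame(rng.poisson(80, (100, 6)))
        r1 = run_contrast(_norm_from(pseudo), self._design(), self._contrast())
        r2 = run_contrast(_norm_from(pseudo), self._design(), self._contrast())
        pd.testing.assert_frame_equal(r1.table, r2.table)

    def test_small_group_rejected(self):
        rng = np.random.default_rng(9)
        pseudo = _frame(rng.poisson(80, (50, 4)))
        design = self._design(4)
        design.loc["s0", "genotype"] = "other"
        with pytest.raises(ValueError, match=">=2 samples"):
            run_contrast(_norm_from(pseudo), design, self._contrast())

    def test_fdr_never_below_p(self):
        rng = np.random.default_rng(10)
        pseudo = _frame(rng.poisson(60, (300, 6)))
        res = run_contrast(_norm_from(pseudo), self._design(), self._contrast())
        assert (res.table["fdr"] >= res.table["pvalue"] - 1e-12).all()


class TestThresholdAndVenn:
    @staticmethod
    def _result(log2fc, pvalue):
        table = pd.DataFrame(
            {
                "log2fc": log2fc,
                "logcpm": 5.0,
                "pvalue": pvalue,
                "fdr": bh_adjust(pvalue),
            },
            index=pd.Index([f"g{i}" for i in range(len(log2fc))], name="gene_id"),
        )
        from rnadeg.de import DEResult

        return DEResult("c", table, 0.1)

    def test_hand_filter(self):
        res = self._result([2.1, 1.0, -2.5], [0.01, 0.01, 0.2])
        out = threshold_de(res, min_abs_log2fc=2.0, max_p=0.05)
        assert list(out.index) == ["g0"]
        assert out.loc["g0", "direction"] == "up"

    def test_zero_cutoffs_keep_everything(self):
        res = self._result([0.5, -0.1, 0.0], [0.5, 0.9, 0.99])
        assert len(threshold_de(res, 0.0, 1.0)) == 3

    def test_empty_result_empty_set(self):
        res = self._result([], [])
        assert threshold_de(res, 1.0, 0.05).empty

    def test_constructed_four_set_intersection(self):
        shared = {f"core{i}" for i in range(19)}
        sets = {
            name: shared | {f"{name}_{i}" for i in range(5)}
            for name in ("TgM", "TgF", "NTgM", "NTgF")
        }
        out = intersect_de_sets(sets)
        allway = out[out["region"] == "TgM&TgF&NTgM&NTgF"]
        assert int(allway["n_genes"].iloc[0]) == 19

    def test_disjoint_and_identical_sets(self):
        disjoint = intersect_de_sets({"a": {"x"}, "b": {"y"}})
        assert set(disjoint["region"]) == {"a", "b"}
        identical = intersect_de_sets({"a": {"x", "y"}, "b": {"x", "y"}})
        assert list(identical["region"]) == ["a&b"]
        assert int(identical["n_genes"].iloc[0]) == 2

    def test_fewer_than_two_sets_rejected(self):
        with pytest.raises(ValueError, match="2 sets"):
            intersect_de_sets({"a": {"x"}})
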