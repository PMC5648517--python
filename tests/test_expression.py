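"""Normalisation, filtering and the negative-binomial Wald test."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mirlink import expression as ex
from mirlink.ioformats import CountMatrix

from conftest import brute_force_bh


def _cm(matrix, stages=None):
    df = pd.DataFrame(matrix)
    df.index = [f"f{i}" for i in range(df.shape[0])]
    df.columns = [f"s{i}" for i in range(df.shape[1])]
    if stages is None:
        stages = ["immature"] * df.shape[1]
    return CountMatrix(df, pd.Series(stages, index=df.columns))


class TestLowCountFilter:
    def test_maxima_rule(self):
        cm = _cm([[9, 9], [10, 3], [1000, 0]])
        kept = ex.low_count_filter(cm, 10)
        assert list(kept.counts.index) == ["f1", "f2"]

    def test_all_zero_matrix_empties(self):
        assert ex.low_count_filter(_cm([[0, 0], [0, 0]]), 10).n_features == 0

    def test_threshold_zero_keeps_all(self):
        assert ex.low_count_filter(_cm([[0, 0], [5, 1]]), 0).n_features == 2

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        cm = _cm(rng.poisson(8, size=(50, 4)))
        sizes = [ex.low_count_filter(cm, t).n_features for t in range(0, 30, 3)]
        assert sizes == sorted(sizes, reverse=True)


class TestSizeFactors:
    def test_doubled_sample_hand_computation(self):
        cm = _cm([[10, 20], [20, 40], [40, 80]])
        sf = ex.size_factors(cm)
        assert sf.iloc[0] == pytest.approx(1 / math.sqrt(2))
        assert sf.iloc[1] == pytest.approx(math.sqrt(2))

    def test_identical_samples_give_unit_factors(self):
        cm = _cm([[10, 10, 10], [55, 55, 55]])
        assert np.allclose(ex.size_factors(cm), 1.0)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(3)
        mat = rng.poisson(50, size=(30, 4)) + 1
        sf = ex.size_factors(_cm(mat))
        perm = [2, 0, 3, 1]
        sf_p = ex.size_factors(_cm(mat[:, perm]))
        assert np.allclose(sf_p.values, sf.values[perm])

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(4)
        sf = ex.size_factors(_cm(rng.poisson(100, size=(40, 6)) + 1))
        assert np.exp(np.mean(np.log(sf))) == pytest.approx(1.0, abs=1e-9)

    def test_no_all_positive_feature_rejected(self):
        with pytest.raises(ValueError, match="pseudocount"):
            ex.size_factors(_cm([[0, 5], [5, 0]]))


class TestNormalizeLog:
    def test_zero_count_with_default_pseudocount(self):
        cm = _cm([[0]])
        sf = pd.Series([1.0], index=cm.counts.columns)
        assert ex.normalize_log(cm, sf).normalized_log.iloc[0, 0] == -1.0

    def test_known_value(self):
        cm = _cm([[31]])       # 31/1 + 0.5 = 31.5 -> not 32; use sf to land on 32
        sf = pd.Series([31 / 31.5], index=cm.counts.columns)
        assert ex.normalize_log(cm, sf).normalized_log.iloc[0, 0] == pytest.approx(5.0)

    def test_scale_invariance(self):
        cm1 = _cm([[10, 20], [5, 9]])
        cm2 = _cm([[20, 40], [10, 18]])
        sf1 = pd.Series([1.0, 1.0], index=cm1.counts.columns)
        sf2 = pd.Series([2.0, 2.0], index=cm2.counts.columns)
        a = ex.normalize_log(cm1, sf1).normalized_log
        b = ex.normalize_log(cm2, sf2).normalized_log
        assert np.allclose(a.values, b.values)


class TestBH:
    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(12)
        for n in (1, 5, 50, 500):
            p = rng.uniform(size=n)
            assert np.allclose(ex.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_over_p_ranks(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(size=100)
        adj = ex.bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestDETest:
    def _stages(self):
        return ["immature"] * 3 + ["pubertal"] * 3

    def test_identical_groups_give_zero_lfc(self):
        mat = np.tile(np.array([[10], [100], [7]]), (1, 6))
        cm = _cm(mat, self._stages())
        sf = pd.Series(1.0, index=cm.counts.columns)
        res = ex.de_test(cm, sf, cm.samples[:3], cm.samples[3:])
        assert np.allclose(res["log2fc"], 0.0)

    def test_group_swap_flips_sign(self):
        rng = np.random.default_rng(21)
        cm = _cm(rng.poisson(80, size=(30, 6)), self._stages())
        sf = pd.Series(1.0, index=cm.counts.columns)
        ab = ex.de_test(cm, sf, cm.samples[:3], cm.samples[3:])
        ba = ex.de_test(cm, sf, cm.samples[3:], cm.samples[:3])
        assert np.allclose(ab["log2fc"], -ba["log2fc"])
        assert np.allclose(ab["p"], ba["p"])

    def test_overlapping_groups_rejected(self):
        cm = _cm(np.ones((2, 6), dtype=int), self._stages())
        sf = pd.Series(1.0, index=cm.counts.columns)
        with pytest.raises(ValueError, match="overlap"):
            ex.de_test(cm, sf, cm.samples[:3], cm.samples[2:])

    def test_rank_agreement_with_permutation_oracle(self):
        """Wald p-values should order features like an exact 3v3 label
        permutation test (Spearman >= 0.9 on a 50-feature toy)."""
        rng = np.random.default_rng(31)
        n = 50
        base = rng.uniform(50, 300, size=n)
        # a third of the features carry modest fold changes; effects are kept
        # small enough that the 20-split permutation null retains resolution
        lfc = np.where(np.arange(n) % 3 == 0,
                       rng.uniform(0.3, 1.0, size=n), 0.0)
        mu = np.empty((n, 6))
        mu[:, :3] = base[:, None]
        mu[:, 3:] = (base * 2.0 ** lfc)[:, None]
        counts = rng.poisson(rng.gamma(50.0, mu / 50.0))
        cm = _cm(counts, self._stages())
        sf = pd.Series(1.0, index=cm.counts.columns)
        res = ex.de_test(cm, sf, cm.samples[:3], cm.samples[3:])

        q = counts.astype(float)
        obs = np.abs(np.log2(q[:, 3:].mean(1) + 0.5)
                     - np.log2(q[:, :3].mean(1) + 0.5))
        perm_ge = np.zeros(n)
        splits = [c for c in itertools.combinations(range(6), 3)]
        for grp_a in splits:
            grp_b = [i for i in range(6) if i not in grp_a]
            stat = np.abs(np.log2(q[:, grp_b].mean(1) + 0.5)
                          - np.log2(q[:, list(grp_a)].mean(1) + 0.5))
            perm_ge += stat >= obs - 1e-12
        perm_p = perm_ge / len(splits)
        rho = sps.spearmanr(res["p"], perm_p).statistic
        assert rho >= 0.9


class TestApplyThresholds:
    def _results(self, padj, lfc):
        return pd.DataFrame({"log2fc": [lfc], "p": [padj], "padj": [padj]},
                            index=["f0"])

    def test_boundary_values_retained_inclusively(self):
        res = self._results(0.05, 0.5)
        assert ex.apply_thresholds(res, 0.05, 0.5) == {"f0"}

    def test_padj_just_over_excluded(self):
        res = self._results(0.051, 2.0)
        assert ex.apply_thresholds(res, 0.05, 0.5) == set()

    def test_mirna_mode_ignores_fold_change(self):
        res = self._results(0.04, 0.0)
        assert ex.apply_thresholds(res, 0.05, 0.0) == {"f0"}
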