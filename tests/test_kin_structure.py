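"""Permutation tests for kin association."""

import numpy as np
import pytest

from gorillakin.kin_structure import (
    focal_male_relatedness_test,
    group_mean_relatedness_test,
    partition_relatedness_test,
    significant_pair_summary,
)
from gorillakin.relatedness import RelatednessMatrix, matrix_from_size_arrays
from gorillakin.simdata import dyad_arrays


def unrelated_matrix(n, founder_freqs, sim_config, seed):
    gx, _, _ = dyad_arrays(sim_config, "U", n, seed=seed, freqs=founder_freqs)
    return matrix_from_size_arrays([f"i{k}" for k in range(n)], gx, founder_freqs)


class TestGroupTest:
    def test_sib_group_detected(self, founder_freqs, sim_config):
        """One group of full sibs among unrelated groups is flagged."""
        gx, gy, _ = dyad_arrays(sim_config, "FS", 3, seed=8, freqs=founder_freqs)
        sibs = np.concatenate([gx[:3], gy[:3]])  # 6 full sibs (3 sibships)
        # actually take one sibship of 5: draw FS repeatedly from same parents
        from gorillakin.simdata import _draw_founders, _freq_arrays, _mendelian

        rng = np.random.default_rng(8)
        sizes, probs = _freq_arrays(founder_freqs)
        gm = np.repeat(_draw_founders(rng, 1, sizes, probs), 5, axis=0)
        gf = np.repeat(_draw_founders(rng, 1, sizes, probs), 5, axis=0)
        sibs = _mendelian(rng, gm, gf)
        others, _, _ = dyad_arrays(sim_config, "U", 15, seed=9, freqs=founder_freqs)
        geno = np.concatenate([sibs, others])
        ids = [f"i{k}" for k in range(20)]
        m = matrix_from_size_arrays(ids, geno, founder_freqs)
        labels = {f"i{k}": f"g{k // 5}" for k in range(20)}
        res = group_mean_relatedness_test(m, labels, n_perm=1000, seed=4)
        assert res["g0"].p_value <= 0.01
        assert res["g1"].p_value > 0.01

    def test_null_calibration(self, founder_freqs, sim_config):
        rng = np.random.default_rng(0)
        labels = {f"i{k}": f"g{k // 5}" for k in range(20)}
        rej = tot = 0
        for rep in range(150):
            m = unrelated_matrix(20, founder_freqs, sim_config,
                                 seed=int(rng.integers(2**31)))
            res = group_mean_relatedness_test(m, labels, n_perm=200,
                                              seed=int(rng.integers(2**31)))
            for r in res.values():
                tot += 1
                rej += r.p_value < 0.05
        assert abs(rej / tot - 0.05) < 0.03

    def test_seed_reproducibility(self, founder_freqs, sim_config):
        m = unrelated_matrix(12, founder_freqs, sim_config, seed=3)
        labels = {f"i{k}": f"g{k // 4}" for k in range(12)}
        a = group_mean_relatedness_test(m, labels, n_perm=300, seed=11)
        b = group_mean_relatedness_test(m, labels, n_perm=300, seed=11)
        for g in a:
            assert a[g].p_value == b[g].p_value
            np.testing.assert_array_equal(a[g].null_means, b[g].null_means)

    def test_null_centers_on_grand_mean(self, founder_freqs, sim_config):
        m = unrelated_matrix(20, founder_freqs, sim_config, seed=6)
        labels = {f"i{k}": f"g{k // 5}" for k in range(20)}
        res = group_mean_relatedness_test(m, labels, n_perm=2000, seed=2)
        iu, ju = np.triu_indices(20, 1)
        grand = np.nanmean(m.values[iu, ju])
        for r in res.values():
            assert float(np.mean(r.null_means)) == pytest.approx(grand, abs=0.02)

    def test_single_group_errors(self, founder_freqs, sim_config):
        m = unrelated_matrix(6, founder_freqs, sim_config, seed=3)
        with pytest.raises(ValueError):
            group_mean_relatedness_test(m, {f"i{k}": "g0" for k in range(6)},
                                        n_perm=10, seed=0)

    def test_corrected_p_never_zero(self, founder_freqs, sim_config):
        m = unrelated_matrix(12, founder_freqs, sim_config, seed=3)
        labels = {f"i{k}": f"g{k // 4}" for k in range(12)}
        res = group_mean_relatedness_test(m, labels, n_perm=200, seed=1)
        for r in res.values():
            assert r.p_corrected() > 0


class TestFocalMale:
    def test_daughters_of_silverback_significant(self, founder_freqs, sim_config):
        gx, gy, _ = dyad_arrays(sim_config, "PO", 10, seed=12, freqs=founder_freqs)
        # gx are fathers, gy their daughters; add unrelated male pool
        other, _, _ = dyad_arrays(sim_config, "U", 6, seed=13, freqs=founder_freqs)
        geno = np.concatenate([gy, gx, other[:6]])
        females = [f"f{k}" for k in range(10)]
        males = [f"m{k}" for k in range(16)]
        m = matrix_from_size_arrays(females + males, geno, founder_freqs)
        own = {f"f{k}": f"m{k}" for k in range(10)}
        r = focal_male_relatedness_test(m, females, own, males, n_perm=2000, seed=3)
        assert r.p_value <= 0.001

    def test_null_calibration(self, founder_freqs, sim_config):
        rng = np.random.default_rng(1)
        rej = 0
        n_rep = 200
        for rep in range(n_rep):
            m = unrelated_matrix(28, founder_freqs, sim_config,
                                 seed=int(rng.integers(2**31)))
            females = [f"i{k}" for k in range(20)]
            males = [f"i{k}" for k in range(20, 28)]
            own = {f: males[int(rng.integers(8))] for f in females}
            r = focal_male_relatedness_test(m, females, own, males, n_perm=200,
                                            seed=int(rng.integers(2**31)))
            rej += r.p_value < 0.05
        assert abs(rej / n_rep - 0.05) < 0.04

    def test_pool_of_one_gives_p_one(self, founder_freqs, sim_config):
        m = unrelated_matrix(5, founder_freqs, sim_config, seed=3)
        females, males = ["i0", "i1"], ["i4"]
        own = {"i0": "i4", "i1": "i4"}
        r = focal_male_relatedness_test(m, females, own, males, n_perm=100, seed=0)
        assert r.p_value == 1.0

    def test_empty_pool_errors(self, founder_freqs, sim_config):
        m = unrelated_matrix(4, founder_freqs, sim_config, seed=3)
        with pytest.raises(ValueError, match="pool"):
            focal_male_relatedness_test(m, ["i0"], {"i0": "i1"}, [], n_perm=10,
                                        seed=0)


class TestPartitionTest:
    def test_one_country_errors(self, founder_freqs, sim_config):
        m = unrelated_matrix(8, founder_freqs, sim_config, seed=3)
        with pytest.raises(ValueError):
            partition_relatedness_test(m, {f"i{k}": "X" for k in range(8)},
                                       n_perm=10, seed=0)

    def test_philopatric_region_detected(self, founder_freqs, sim_config):
        from gorillakin.simdata import _draw_founders, _freq_arrays, _mendelian

        rng = np.random.default_rng(20)
        sizes, probs = _freq_arrays(founder_freqs)
        # region A: two sibships of 4; region B: unrelated
        fams = []
        for _ in range(2):
            gm = np.repeat(_draw_founders(rng, 1, sizes, probs), 4, axis=0)
            gf = np.repeat(_draw_founders(rng, 1, sizes, probs), 4, axis=0)
            fams.append(_mendelian(rng, gm, gf))
        others = _draw_founders(rng, 8, sizes, probs)
        geno = np.concatenate(fams + [others])
        ids = [f"i{k}" for k in range(16)]
        m = matrix_from_size_arrays(ids, geno, founder_freqs)
        labels = {f"i{k}": ("A" if k < 8 else "B") for k in range(16)}
        res = partition_relatedness_test(m, labels, n_perm=1000, seed=5)
        assert res["A"].p_value <= 0.05
        assert res["B"].p_value > 0.05


class TestSignificantPairSummary:
    def _matrix_with_p(self, n, p_flags):
        V = np.zeros((n, n))
        P = np.ones((n, n))
        for (i, j) in p_flags:
            P[i, j] = P[j, i] = 0.01
        np.fill_diagonal(V, np.nan)
        return RelatednessMatrix(ids=[f"i{k}" for k in range(n)], estimator="QG",
                                 values=V, n_shared=np.full((n, n), 10), p=P)

    def test_counts_and_proportions(self):
        # 2 of the within-group pairs flagged, none among
        m = self._matrix_with_p(10, [(0, 1), (0, 2)])
        labels = {f"i{k}": ("g0" if k < 5 else "g1") for k in range(10)}
        out = significant_pair_summary(m, labels).set_index("scope")
        assert out.loc["within", "n_significant"] == 2
        assert out.loc["within", "n_pairs"] == 20
        assert out.loc["within", "proportion"] == pytest.approx(0.10)
        assert out.loc["among", "n_significant"] == 0
        assert out.loc["among", "n_pairs"] == 25

    def test_all_or_none(self):
        m = self._matrix_with_p(6, [])
        labels = {f"i{k}": ("a" if k < 3 else "b") for k in range(6)}
        out = significant_pair_summary(m, labels)
        assert (out["n_significant"] == 0).all()
        m2 = self._matrix_with_p(6, [(i, j) for i in range(6) for j in range(i + 1, 6)])
        out2 = significant_pair_summary(m2, labels)
        assert (out2["proportion"] == 1.0).all()

    def test_requires_p_values(self, founder_freqs, sim_config):
        m = unrelated_matrix(6, founder_freqs, sim_config, seed=3)
        with pytest.raises(ValueError, match="p-values"):
            significant_pair_summary(m, {f"i{k}": "a" for k in range(6)})
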