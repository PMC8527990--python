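"""Correlation and permutation statistics against closed forms and oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from skbio import DistanceMatrix

from distdecay.model import DataModelError
from distdecay.mstats import (
    _chi_square_matrix,
    _constrained_inertia,
    amova,
    amova_exhaustive_p,
    cca_varpart,
    mantel,
    spearman,
    wilcoxon_ranksum,
)


class TestSpearman:
    def test_monotone_maximum(self):
        x = np.arange(10.0)
        rho, p = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_partial_controlling_for_itself_is_zero(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        rho, p = spearman(x, y, control=y)
        assert rho == pytest.approx(0.0, abs=1e-6)

    def test_partial_with_independent_control_matches_plain(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=2000)
        y = x + rng.normal(size=2000)
        z = rng.normal(size=2000)  # independent of both
        plain, _ = spearman(x, y)
        partial, _ = spearman(x, y, control=z)
        assert partial == pytest.approx(plain, abs=0.05)

    def test_pairwise_deletion_of_missing(self):
        x = np.array([1, 2, 3, 4, np.nan, 6.0])
        y = np.array([2, 4, 6, 8, 10, 12.0])
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_constant_vector_rejected(self):
        with pytest.raises(DataModelError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestMantel:
    def _random_dm(self, n, seed, ids=None):
        rng = np.random.default_rng(seed)
        x = rng.uniform(0.1, 1.0, (n, n))
        m = (x + x.T) / 2
        np.fill_diagonal(m, 0)
        return DistanceMatrix(m, ids=ids or [f"e{i}" for i in range(n)])

    def test_identity_gives_minimal_p(self):
        dm = self._random_dm(8, 0)
        res = mantel(dm, dm, n_perm=99, seed=1)
        assert res.rho_s == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1 / 100)

    def test_deterministic_given_seed(self):
        a, b = self._random_dm(8, 2), self._random_dm(8, 3)
        r1 = mantel(a, b, n_perm=199, seed=5)
        r2 = mantel(a, b, n_perm=199, seed=5)
        assert r1.p_value == r2.p_value and r1.rho_s == r2.rho_s

    def test_alignment_on_shared_labels(self):
        a = self._random_dm(8, 2)
        b = self._random_dm(6, 3, ids=[f"e{i}" for i in range(6)])
        res = mantel(a, b, n_perm=99, seed=0)
        assert res.n_entities == 6
        with pytest.raises(DataModelError):
            mantel(a, b, strict=True)

    def test_rho_matches_direct_spearman_of_triangles(self):
        a, b = self._random_dm(9, 4), self._random_dm(9, 5)
        res = mantel(a, b, n_perm=0 or 9, seed=0)
        iu = np.triu_indices(9, k=1)
        want = stats.spearmanr(a.data[iu], b.data[iu]).statistic
        assert res.rho_s == pytest.approx(want, abs=1e-12)


class TestAmova:
    def test_perfect_separation(self):
        m = np.ones((6, 6))
        m[:3, :3] = 0
        m[3:, 3:] = 0
        dm = DistanceMatrix(m, ids=list("abcdef"))
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        res = amova(dm, groups, n_perm=2000, seed=0)
        assert res.ss_within == pytest.approx(0.0)
        # the smallest achievable p under label permutation: exactly the
        # partition-preserving permutations, 3!*3!*2 / 6! = 0.1
        assert res.p_value == pytest.approx(0.1, abs=0.03)

    def test_sum_of_squares_decomposition(self):
        rng = np.random.default_rng(6)
        x = rng.uniform(0.1, 1, (10, 10))
        m = (x + x.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(m, ids=[f"e{i}" for i in range(10)])
        groups = pd.Series((["a"] * 5) + (["b"] * 5), index=dm.ids)
        res = amova(dm, groups, n_perm=9, seed=0)
        d2 = dm.data**2
        ss_total = d2.sum() / 2 / 10
        assert res.ss_among + res.ss_within == pytest.approx(ss_total, abs=1e-9)

    def test_sampled_p_close_to_exhaustive_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0.1, 1, (6, 6))
        m = (x + x.T) / 2
        np.fill_diagonal(m, 0)
        dm = DistanceMatrix(m, ids=list("abcdef"))
        groups = pd.Series(["g1"] * 3 + ["g2"] * 3, index=list("abcdef"))
        exact = amova_exhaustive_p(dm, groups)
        sampled = amova(dm, groups, n_perm=2000, seed=1).p_value
        assert sampled == pytest.approx(exact, abs=0.02)

    def test_singleton_group_rejected(self):
        dm = DistanceMatrix(np.array([[0, 1, 1], [1, 0, 1], [1, 1, 0]], float),
                            ids=list("abc"))
        with pytest.raises(DataModelError, match="singleton"):
            amova(dm, pd.Series(["g1", "g1", "g2"], index=list("abc")))


class TestCcaVarpart:
    def _fixture(self):
        rng = np.random.default_rng(42)
        y = rng.integers(1, 50, size=(8, 6)).astype(float)
        env = rng.normal(0, 1, (8, 2))
        space = rng.normal(0, 1, (8, 2))
        idx = [f"F{i}" for i in range(8)]
        return (pd.DataFrame(y, index=idx),
                pd.DataFrame(env, index=idx, columns=["e1", "e2"]),
                pd.DataFrame(space, index=idx, columns=["s1", "s2"]))

    def test_inertia_components_match_vegan_oracle(self):
        """Frozen reference values computed with vegan::cca on this fixture."""
        comm, env, space = self._fixture()
        qbar, r, total = _chi_square_matrix(comm.to_numpy())
        both = np.hstack([env.to_numpy(), space.to_numpy()])
        assert total == pytest.approx(0.2286176, abs=1e-6)
        assert _constrained_inertia(qbar, r, both)[0] == pytest.approx(
            0.1098662, abs=1e-6)
        assert _constrained_inertia(qbar, r, env.to_numpy())[0] == pytest.approx(
            0.05083086, abs=1e-7)
        assert _constrained_inertia(qbar, r, space.to_numpy())[0] == pytest.approx(
            0.05482665, abs=1e-7)
        assert _constrained_inertia(
            qbar, r, env.to_numpy(), space.to_numpy())[0] == pytest.approx(
            0.05503951, abs=1e-7)
        assert _constrained_inertia(
            qbar, r, space.to_numpy(), env.to_numpy())[0] == pytest.approx(
            0.05903530, abs=1e-7)

    def test_fractions_sum_to_one(self):
        comm, env, space = self._fixture()
        vp = cca_varpart(comm, env, space, n_perm=49, seed=0)
        total = vp.pure_space + vp.pure_env + vp.shared + vp.unexplained
        assert total == pytest.approx(1.0, abs=1e-9)

    def test_duplicated_predictors_have_no_pure_fractions(self):
        comm, env, _ = self._fixture()
        vp = cca_varpart(comm, env, env.copy(), n_perm=49, seed=0)
        assert vp.pure_space == pytest.approx(0.0, abs=1e-9)
        assert vp.pure_env == pytest.approx(0.0, abs=1e-9)
        assert vp.shared > 0

    def test_constrained_inertia_monotone_in_predictors(self):
        comm, env, space = self._fixture()
        qbar, r, _ = _chi_square_matrix(comm.to_numpy())
        i1 = _constrained_inertia(qbar, r, env.to_numpy()[:, :1])[0]
        i2 = _constrained_inertia(qbar, r, env.to_numpy())[0]
        i3 = _constrained_inertia(
            qbar, r, np.hstack([env.to_numpy(), space.to_numpy()]))[0]
        assert i1 <= i2 + 1e-12 <= i3 + 1e-12

    def test_rank_one_community_is_degenerate(self):
        idx = [f"F{i}" for i in range(4)]
        row = np.array([4.0, 2.0, 1.0])
        comm = pd.DataFrame(np.outer([1, 2, 3, 4], row), index=idx)
        env = pd.DataFrame(np.random.default_rng(0).normal(size=(4, 1)), index=idx)
        with pytest.raises(DataModelError, match="degenerate|inertia"):
            cca_varpart(comm, env, env, n_perm=9, seed=0)

    def test_too_many_predictors_rejected(self):
        comm, env, space = self._fixture()
        wide = pd.concat([env] * 4, axis=1)
        with pytest.raises(DataModelError, match="predictors"):
            cca_varpart(comm, wide, space, n_perm=9, seed=0)


class TestWilcoxon:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        z, p = wilcoxon_ranksum(x, x)
        assert z == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_complete_separation_closed_form(self):
        # n = m = 12, no ties: W = Σ(13..24) = 222, μ = 150, σ² = 300
        x = np.arange(13, 25, dtype=float)
        y = np.arange(1, 13, dtype=float)
        z, p = wilcoxon_ranksum(x, y)
        assert z == pytest.approx((222 - 150) / np.sqrt(300))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(10)
        for _ in range(20):
            x = rng.integers(0, 6, 15).astype(float)
            y = rng.integers(1, 7, 12).astype(float)
            z, p = wilcoxon_ranksum(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic",
                                     use_continuity=False)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_normal_approximation_close_to_exact(self):
        # exhaustive rank-sum null distribution at n = m = 4
        import itertools
        x = [8.0, 9.0, 11.0, 14.0]
        y = [1.0, 3.0, 4.0, 7.0]
        z, p_normal = wilcoxon_ranksum(x + [2.0], y + [5.0])  # n = m = 5
        combined = x + [2.0] + y + [5.0]
        ranks = stats.rankdata(combined)
        w_obs = ranks[:5].sum()
        mu = 5 * 11 / 2
        count = total = 0
        for combo in itertools.combinations(range(10), 5):
            w = ranks[list(combo)].sum()
            total += 1
            if abs(w - mu) >= abs(w_obs - mu) - 1e-12:
                count += 1
        assert p_normal == pytest.approx(count / total, abs=0.03)

    def test_all_tied_degenerate(self):
        z, p = wilcoxon_ranksum([2.0] * 5, [2.0] * 5)
        assert (z, p) == (0.0, 1.0)

    def test_small_groups_rejected(self):
        with pytest.raises(DataModelError):
            wilcoxon_ranksum([1.0, 2.0], [1.0, 2.0, 3.0])
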