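"""Pairwise dependence scorers against brute-force oracles and closed forms."""

from __future__ import annotations

import numpy as np
import pytest

from mirank.datatypes import MirankError, Ordering
from mirank.pairwise import (
    dcov,
    distance_correlation,
    hoeffding,
    hoeffding_d,
    kendall,
    mutual_information,
    pearson,
    rdc,
    rdc_pair,
    spearman,
    zscore,
)

from conftest import make_dataset
from _oracles import (
    dcor_brute,
    hoeffding_brute,
    kendall_taub_brute,
    pearson_brute,
    spearman_brute,
)


def _pair_ds(x, y):
    return make_dataset(np.asarray(x, dtype=float)[:, None],
                        np.asarray(y, dtype=float)[:, None])


def _score(sm):
    return float(sm.values.iloc[0, 0])


class TestCorrelations:
    def test_perfect_anti_linear(self):
        assert _score(pearson(_pair_ds([1, 2, 3], [6, 4, 2]))) == \
            pytest.approx(-1.0, abs=1e-12)

    def test_identity(self):
        assert _score(pearson(_pair_ds([1, 2, 3], [1, 2, 3]))) == \
            pytest.approx(1.0, abs=1e-12)

    def test_monotone_decreasing_rank_measures(self):
        ds = _pair_ds([1, 2, 3], [9, 4, 1])
        assert _score(spearman(ds)) == pytest.approx(-1.0, abs=1e-12)
        assert _score(kendall(ds)) == pytest.approx(-1.0, abs=1e-12)

    def test_kendall_enumerated_example(self):
        # pairs: (1,2)-(2,1) discordant, (1,2)-(3,3) concordant,
        # (2,1)-(3,3) concordant -> tau = (2-1)/3
        ds = _pair_ds([1, 2, 3], [2, 1, 3])
        assert _score(kendall(ds)) == pytest.approx(1 / 3, abs=1e-12)

    def test_orderings(self):
        ds = _pair_ds([1, 2, 3], [1, 2, 3])
        assert pearson(ds).ordering is Ordering.ASC_SIGNED
        assert spearman(ds).ordering is Ordering.ASC_SIGNED
        assert kendall(ds).ordering is Ordering.ASC_SIGNED

    def test_zero_variance_scores_zero(self):
        ds = _pair_ds([1, 2, 3], [5, 5, 5])
        with pytest.warns(UserWarning):
            assert _score(pearson(ds)) == 0.0

    def test_spearman_equals_pearson_on_ranks(self, rng):
        from scipy.stats import rankdata
        x = rng.integers(0, 5, size=(30, 3)).astype(float)  # with ties
        y = rng.integers(0, 5, size=(30, 4)).astype(float)
        sp = spearman(make_dataset(x, y)).values.to_numpy()
        ranked = make_dataset(
            np.apply_along_axis(rankdata, 0, x),
            np.apply_along_axis(rankdata, 0, y))
        pe = pearson(ranked).values.to_numpy()
        np.testing.assert_allclose(sp, pe, atol=1e-12)


class TestBruteForceOracles:
    """All five classical measures against direct-formula oracles."""

    @pytest.mark.parametrize("with_ties", [False, True])
    def test_random_instances(self, with_ties):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n = int(rng.integers(8, 31))
            if with_ties:
                x = rng.integers(0, 6, n).astype(float)
                y = rng.integers(0, 6, n).astype(float)
            else:
                x = rng.standard_normal(n)
                y = rng.standard_normal(n)
            ds = _pair_ds(x, y)
            assert _score(pearson(ds)) == pytest.approx(
                pearson_brute(x, y), abs=1e-10)
            assert _score(spearman(ds)) == pytest.approx(
                spearman_brute(x, y), abs=1e-10)
            assert _score(kendall(ds)) == pytest.approx(
                kendall_taub_brute(x, y), abs=1e-10)
            assert distance_correlation(x, y) == pytest.approx(
                dcor_brute(x, y), abs=1e-10)
            if not with_ties:
                assert hoeffding_d(x, y) == pytest.approx(
                    hoeffding_brute(x, y), abs=1e-10)

    def test_hoeffding_with_ties_matches_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            n = int(rng.integers(6, 13))
            x = rng.integers(0, 4, n).astype(float)
            y = rng.integers(0, 4, n).astype(float)
            assert hoeffding_d(x, y) == pytest.approx(
                hoeffding_brute(x, y), abs=1e-10)


class TestDcov:
    def test_linear_dependence_attains_one(self):
        x = np.array([0.3, 1.2, -0.5, 2.0, 0.0, 1.5])
        ds = _pair_ds(x, 2 * x + 1)
        assert _score(dcov(ds)) == pytest.approx(1.0, abs=1e-10)

    def test_small_under_independence(self):
        rng = np.random.default_rng(11)
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        assert distance_correlation(x, y) < 0.1

    def test_symmetric(self, rng):
        for _ in range(10):
            x = rng.standard_normal(15)
            y = rng.standard_normal(15)
            assert distance_correlation(x, y) == pytest.approx(
                distance_correlation(y, x), abs=1e-12)

    def test_ordering_and_constant_warns(self):
        with pytest.warns(UserWarning):
            sm = dcov(_pair_ds([1, 2, 3, 4], [5, 5, 5, 5]))
        assert sm.ordering is Ordering.DESC_VALUE
        assert _score(sm) == 0.0


class TestHoeffding:
    def test_too_few_samples_rejected(self):
        with pytest.raises(MirankError):
            hoeffding(_pair_ds([1, 2, 3, 4], [1, 2, 3, 4]))

    def test_small_under_independence(self):
        rng = np.random.default_rng(5)
        x = rng.standard_normal(2000)
        y = rng.standard_normal(2000)
        assert abs(hoeffding_d(x, y)) < 0.01

    def test_matrix_ordering(self):
        sm = hoeffding(_pair_ds([1, 2, 3, 4, 5], [5, 3, 1, 4, 2]))
        assert sm.ordering is Ordering.DESC_VALUE


class TestRdc:
    def test_strong_dependence(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(200)
        assert rdc_pair(x, x, rng=np.random.default_rng(2)) > 0.95

    def test_independence(self):
        rng = np.random.default_rng(4)
        x = rng.standard_normal(500)
        y = rng.standard_normal(500)
        assert rdc_pair(x, y, rng=np.random.default_rng(6)) < 0.3

    def test_deterministic_given_seed(self, rng):
        ds = make_dataset(rng.standard_normal((30, 2)),
                          rng.standard_normal((30, 3)))
        a = rdc(ds, seed=42).values
        b = rdc(ds, seed=42).values
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_row_permutation_invariant(self, rng):
        ds = make_dataset(rng.standard_normal((30, 2)),
                          rng.standard_normal((30, 3)))
        perm = rng.permutation(30)
        ds_perm = ds.with_data(ds.data.iloc[perm].reset_index(drop=True))
        a = rdc(ds, seed=9).values.to_numpy()
        b = rdc(ds_perm, seed=9).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestMutualInformation:
    def test_diagonal_joint_closed_form(self):
        # y = x with n divisible by B gives a diagonal joint and log2(B)
        for b in (2, 4, 5):
            n = 40
            x = np.arange(n, dtype=float)
            ds = _pair_ds(x, x)
            sm = mutual_information(ds, bins=b)
            assert _score(sm) == pytest.approx(np.log2(b), abs=1e-12)

    def test_non_negative(self, rng):
        ds = make_dataset(rng.standard_normal((25, 3)),
                          rng.standard_normal((25, 4)))
        assert (mutual_information(ds, bins=3).values.to_numpy()
                >= -1e-12).all()

    def test_small_under_independence(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(size=5000)
        y = rng.uniform(size=5000)
        sm = mutual_information(_pair_ds(x, y), bins=8)
        assert _score(sm) < 0.05

    def test_symmetric_under_role_swap(self, rng):
        x = rng.standard_normal(60)
        y = x + rng.standard_normal(60)
        a = _score(mutual_information(_pair_ds(x, y), bins=4))
        b = _score(mutual_information(_pair_ds(y, x), bins=4))
        assert a == pytest.approx(b, abs=1e-12)

    def test_bad_bins_rejected(self, small_dataset):
        with pytest.raises(MirankError):
            mutual_information(small_dataset, bins=1)


class TestZscore:
    def test_hand_computed(self):
        sm = zscore(_pair_ds([5, 1, 3], [2, 8, 5]))
        assert _score(sm) == pytest.approx(1.0, abs=1e-12)

    def test_constant_mrna_scores_zero(self):
        with pytest.warns(UserWarning):
            sm = zscore(_pair_ds([5, 1, 3], [4, 4, 4]))
        assert _score(sm) == 0.0

    def test_tied_minimum_uses_first_sample(self):
        # miRNA minimum tied at samples 0 and 2; sample 0 must be used
        sm = zscore(_pair_ds([1, 5, 1], [10, 4, 7]))
        y = np.array([10.0, 4.0, 7.0])
        expected = abs(y[0] - y.mean()) / y.std(ddof=1)
        assert _score(sm) == pytest.approx(expected, abs=1e-12)


class TestRowPermutationInvariance:
    @pytest.mark.parametrize("scorer", [pearson, spearman, kendall, dcov,
                                        hoeffding, zscore])
    def test_invariant(self, scorer, rng):
        ds = make_dataset(rng.standard_normal((20, 2)),
                          rng.standard_normal((20, 3)))
        perm = rng.permutation(20)
        ds_perm = ds.with_data(ds.data.iloc[perm].reset_index(drop=True))
        a = scorer(ds).values.to_numpy()
        b = scorer(ds_perm).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_mi_invariant_up_to_tie_splitting(self, rng):
        # ordinal rank tie-splitting depends on row order, so only
        # tie-free data is exactly invariant
        ds = make_dataset(rng.standard_normal((24, 2)),
                          rng.standard_normal((24, 3)))
        perm = rng.permutation(24)
        ds_perm = ds.with_data(ds.data.iloc[perm].reset_index(drop=True))
        a = mutual_information(ds, bins=4).values.to_numpy()
        b = mutual_information(ds_perm, bins=4).values.to_numpy()
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestPlantedSignal:
    def test_pearson_separates_true_edges(self):
        """Planted negative regulation scores below the non-edge mean."""
        from mirank.synthetic import SynthConfig, generate

        wins = 0
        for seed in range(20):
            cfg = SynthConfig(n_samples=300, n_mirna=5, n_mrna=40,
                              n_edges=10, seed=seed)
            ds, truth, _ = generate(cfg)
            sm = pearson(ds)
            edge_scores, non_edge_scores = [], []
            for mirna in sm.mirna_names:
                for mrna in sm.mrna_names:
                    score = float(sm.values.loc[mrna, mirna])
                    if (mirna, mrna) in truth.pairs:
                        edge_scores.append(score)
                    else:
                        non_edge_scores.append(score)
            if np.mean(edge_scores) < np.mean(non_edge_scores):
                wins += 1
        assert wins == 20
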