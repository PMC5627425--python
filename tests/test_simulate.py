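import dataclasses

import numpy as np
import pytest
from scipy.stats import chi2

from profilebin import SimConfig, simulate_community, sweep
from profilebin.simulate import abundance_correlation, match_components

from conftest import make_config


class TestGenerator:
    def test_same_seed_bit_identical(self):
        cfg = make_config(4, 6, 150, 150, seed=42, missing_fraction=0.2)
        cm1, t1 = simulate_community(cfg)
        cm2, t2 = simulate_community(cfg)
        assert (cm1.counts == cm2.counts).all()
        assert (cm1.lengths == cm2.lengths).all()
        assert (t1.labels == t2.labels).all()
        assert (t1.A_true == t2.A_true).all()

    def test_structure_invariants(self):
        cm, truth = simulate_community(make_config(3, 5, 200, 100, seed=0))
        assert (cm.row_totals > 0).all()
        assert truth.labels.min() >= 0 and truth.labels.max() < 3
        assert np.abs(truth.A_true.sum(axis=1) - 1).max() < 1e-12
        assert len(truth.labels) == cm.n_contigs

    def test_empirical_profiles_converge_to_truth(self):
        cm, truth = simulate_community(make_config(5, 20, 2000, 200, seed=1))
        for k in range(5):
            pooled = cm.counts[truth.labels == k].sum(axis=0)
            emp = pooled / pooled.sum()
            assert np.abs(emp - truth.A_true[k]).max() < 0.03

    def test_missing_fraction_zeroes_profile_cells(self):
        cfg = make_config(10, 20, 100, 100, seed=3, missing_fraction=0.4)
        _, truth = simulate_community(cfg)
        assert (truth.A_true == 0).mean() > 0.2
        assert np.abs(truth.A_true.sum(axis=1) - 1).max() < 1e-12

    def test_counts_follow_conditional_multinomial(self):
        """Chi-square GOF of x_i | z_i against Multinomial(n_i, a_z).

        Cells with small expectation are pooled; at alpha=0.01 at least 95%
        of contigs must not reject.
        """
        cm, truth = simulate_community(make_config(3, 6, 400, 600, seed=8))
        rejected = 0
        tested = 0
        for i in range(cm.n_contigs):
            a = truth.A_true[truth.labels[i]]
            n = cm.row_totals[i]
            expect = n * a
            order = np.argsort(-expect)
            exp_sorted, obs_sorted = expect[order], cm.counts[i][order]
            # pool trailing cells so every expected count is >= 5
            while len(exp_sorted) > 2 and exp_sorted[-1] < 5:
                exp_sorted = np.concatenate(
                    [exp_sorted[:-2], [exp_sorted[-2] + exp_sorted[-1]]]
                )
                obs_sorted = np.concatenate(
                    [obs_sorted[:-2], [obs_sorted[-2] + obs_sorted[-1]]]
                )
            if len(exp_sorted) < 2 or exp_sorted[-1] < 5:
                continue
            stat = ((obs_sorted - exp_sorted) ** 2 / exp_sorted).sum()
            tested += 1
            rejected += stat > chi2.ppf(0.99, df=len(exp_sorted) - 1)
        assert tested > 300
        assert rejected / tested <= 0.05

    def test_explicit_profiles_override_dirichlet(self):
        A = np.array([[0.7, 0.3], [0.2, 0.8]])
        cfg = make_config(2, 2, 100, 200, seed=1, profiles=A)
        _, truth = simulate_community(cfg)
        assert np.allclose(truth.A_true, A)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(K=0, P=2, N=10)
        with pytest.raises(ValueError):
            SimConfig(K=2, P=2, N=10, missing_fraction=1.0)
        with pytest.raises(ValueError):
            SimConfig(K=2, P=2, N=10, depth=0.0)


class TestHelpers:
    def test_match_components_unscrambles_permutation(self, rng):
        A = rng.dirichlet(np.ones(6), size=4)
        perm = np.array([2, 0, 3, 1])
        order = match_components(A[perm], A)
        assert (A[perm][order] == A).all()

    def test_abundance_correlation_perfect_on_identical(self, rng):
        b = rng.gamma(1.0, size=(5, 4))
        assert np.allclose(abundance_correlation(b, b), 1.0)


class TestSweep:
    def test_single_config_produces_valid_row(self):
        df = sweep([make_config(3, 8, 150, 200, seed=0)])
        assert len(df) == 1
        row = df.iloc[0]
        assert -1 <= row["ari"] <= 1
        assert 0 < row["precision"] <= 1
        assert 0 < row["recall"] <= 1
        assert row["error"] == ""

    def test_failures_recorded_not_raised(self):
        # N < K makes the fit impossible; the sweep must continue
        bad = make_config(5, 4, 3, 100, seed=0)
        good = make_config(3, 8, 150, 200, seed=0)
        df = sweep([bad, good])
        assert df.iloc[0]["error"] != ""
        assert np.isnan(df.iloc[0]["ari"])
        assert df.iloc[1]["error"] == ""

    def test_identical_profile_species_are_not_separable(self):
        """Two species sharing a profile collapse into one bin (a known
        limitation: proportional abundances are indistinguishable)."""
        rng = np.random.default_rng(5)
        A = rng.dirichlet(np.ones(12), size=2)
        A3 = np.vstack([A, A[0]])  # species 2 duplicates species 0
        cfg = make_config(3, 12, 400, 300, seed=5, profiles=A3)
        from profilebin import MultinomialMixtureBinner

        cm, truth = simulate_community(cfg)
        est = MultinomialMixtureBinner(k_max=6).fit(cm)
        assert est.n_components_ == 2
        merged = est.labels_[truth.labels == 0]
        dup = est.labels_[truth.labels == 2]
        # the duplicated pair lands in the same fitted bin
        assert np.bincount(merged).argmax() == np.bincount(dup).argmax()
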