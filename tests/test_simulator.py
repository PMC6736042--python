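"""Substitution-model machinery and replicate simulation."""

import numpy as np
import pytest

import absfit as af
from absfit.simulator import (
    SimulationSpec,
    SubstitutionModel,
    discrete_gamma_rates,
    simulate_alignment,
    simulate_replicate_set,
    transition_matrix,
)

JC = SubstitutionModel(scheme="JC")


class TestSubstitutionModel:
    def test_k80_forces_equal_freqs(self):
        m = SubstitutionModel(scheme="K80", kappa=3.0, base_freqs=(0.4, 0.2, 0.2, 0.2))
        assert m.base_freqs == (0.25, 0.25, 0.25, 0.25)

    def test_rate_matrix_normalised(self):
        for m in (JC,
                  SubstitutionModel(scheme="HKY", kappa=4.0,
                                    base_freqs=(0.35, 0.15, 0.2, 0.3)),
                  SubstitutionModel(scheme="GTR", base_freqs=(0.3, 0.2, 0.2, 0.3),
                                    exchangeabilities=(1, 3, 0.5, 0.8, 4, 1))):
            Q = m.rate_matrix()
            pi = np.asarray(m.base_freqs)
            assert np.allclose(Q.sum(axis=1), 0, atol=1e-12)
            assert -(pi * np.diag(Q)).sum() == pytest.approx(1.0)
            # detailed balance (reversibility)
            assert np.allclose(pi[:, None] * Q, (pi[:, None] * Q).T, atol=1e-12)

    def test_gtr_requires_six_rates(self):
        with pytest.raises(ValueError):
            SubstitutionModel(scheme="GTR", exchangeabilities=(1, 2, 3))

    def test_free_rates_must_be_mean_one(self):
        with pytest.raises(ValueError):
            SubstitutionModel(scheme="JC", free_rates=((2.0, 0.5), (2.0, 0.5)))
        m = SubstitutionModel(scheme="JC", free_rates=((0.5, 0.5), (1.5, 0.5)))
        rates, wts = m.site_rate_classes()
        assert rates @ wts == pytest.approx(1.0)


class TestTransitionMatrix:
    def test_zero_length_is_identity(self):
        assert np.allclose(transition_matrix(JC, 0.0), np.eye(4), atol=1e-12)

    def test_long_branch_reaches_stationarity(self):
        P = transition_matrix(JC, 500.0)
        assert np.allclose(P, 0.25, atol=1e-10)

    @pytest.mark.parametrize("t", [0.01, 0.1, 0.5, 2.0])
    def test_jc_closed_form_diagonal(self, t):
        P = transition_matrix(JC, t)
        diag = 0.25 + 0.75 * np.exp(-4 * t / 3)
        off = 0.25 - 0.25 * np.exp(-4 * t / 3)
        assert np.allclose(np.diag(P), diag, atol=1e-12)
        assert P[0, 1] == pytest.approx(off)

    @pytest.mark.parametrize("t", [0.0, 0.05, 1.0, 10.0])
    def test_rows_sum_to_one(self, t):
        m = SubstitutionModel(scheme="GTR", base_freqs=(0.31, 0.19, 0.21, 0.29),
                              exchangeabilities=(1.4, 4, 1.2, 1.1, 5, 1))
        P = transition_matrix(m, t)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-10
        assert (P >= 0).all()


class TestDiscreteGamma:
    @pytest.mark.parametrize("alpha", [0.1, 0.4, 1.0, 5.0])
    def test_mean_rate_is_one(self, alpha):
        r = discrete_gamma_rates(alpha, 4)
        assert r.mean() == pytest.approx(1.0, abs=1e-6)
        assert (np.diff(r) > 0).all()

    def test_large_alpha_approaches_homogeneity(self):
        r = discrete_gamma_rates(500.0, 4)
        assert np.allclose(r, 1.0, atol=0.1)


class TestSimulateAlignment:
    def test_seed_determinism(self, fig1_trees):
        t1, _ = fig1_trees
        spec = SimulationSpec(tree=t1, model=JC, k=200, seed=77)
        a = simulate_alignment(spec)
        b = simulate_alignment(spec)
        assert a.taxa == b.taxa and np.array_equal(a.codes, b.codes)

    def test_fully_invariant_sites(self):
        tree = af.tree_from_newick("((a:0.5,b:0.5):0.1,(c:0.5,d:0.5):0.1);")
        model = SubstitutionModel(scheme="JC", p_invariant=0.999999999)
        msa = simulate_alignment(SimulationSpec(tree=tree, model=model, k=300, seed=3))
        assert (msa.codes == msa.codes[0]).all()

    def test_star_tree_stationary_frequencies(self):
        star = af.ModelTree(
            tree=__import__("dendropy").Tree.get(
                data="(a:5.0,b:5.0,c:5.0,d:5.0);", schema="newick"),
            label="star")
        msa = simulate_alignment(SimulationSpec(tree=star, model=JC, k=10_000, seed=9))
        freqs = np.bincount(msa.codes.ravel(), minlength=4) / msa.codes.size
        assert np.abs(freqs - 0.25).max() < 0.02

    def test_jc_two_taxon_mismatch_calibration(self):
        # expected mismatch fraction 3/4 (1 - e^{-4t/3}) at pairwise distance t
        t = 0.3
        tree = af.tree_from_newick(f"(x:{t / 2},y:{t / 2});")
        k = 20_000
        msa = simulate_alignment(SimulationSpec(tree=tree, model=JC, k=k, seed=13))
        p = 0.75 * (1 - np.exp(-4 * t / 3))
        se = np.sqrt(p * (1 - p) / k)
        observed = (msa.codes[0] != msa.codes[1]).mean()
        assert abs(observed - p) < 3 * se


class TestReplicateSet:
    def test_counts_match_alignments(self, fig1_trees):
        t1, _ = fig1_trees
        spec = SimulationSpec(tree=t1, model=JC, k=100, q=4, seed=21)
        msas, reps = simulate_replicate_set(spec)
        assert reps.q == 4
        for i, m in enumerate(msas):
            assert np.array_equal(
                reps.counts[i], af.count_pair_alignments(m).counts)

    def test_replicates_differ(self, fig1_trees):
        t1, _ = fig1_trees
        msas, _ = simulate_replicate_set(
            SimulationSpec(tree=t1, model=JC, k=100, q=2, seed=21))
        assert not np.array_equal(msas[0].codes, msas[1].codes)

    def test_fit_favours_generating_model(self):
        # data under HKY fits HKY-based replicates better than JC-based ones
        tree = af.tree_from_newick(
            "((a:0.2,b:0.15):0.05,(c:0.25,d:0.1):0.05,(e:0.3,f:0.2):0.04);")
        hky = SubstitutionModel(scheme="HKY", kappa=6.0,
                                base_freqs=(0.35, 0.15, 0.15, 0.35))
        obs = af.count_pair_alignments(simulate_alignment(
            SimulationSpec(tree=tree, model=hky, k=5000, seed=30)))
        _, reps_hky = simulate_replicate_set(
            SimulationSpec(tree=tree, model=hky, k=5000, q=20, seed=31))
        _, reps_jc = simulate_replicate_set(
            SimulationSpec(tree=tree, model=JC, k=5000, q=20, seed=32))
        assert af.ggg(obs, reps_hky) < af.ggg(obs, reps_jc)
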