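"""D values per node-specific subset and the rank-correlation component B."""

import numpy as np
import pytest
from scipy.stats import rankdata

import absfit as af
from absfit.errors import OrderMismatchError, SubsetSizeError
from absfit.tree_fit import RS_CLAMP, SubsetDProfile
from conftest import random_msa


def make_m(msa, P=10_000.0):
    return af.scoring_matrix(af.frequencies(af.count_pair_alignments(msa)), P)


def make_profile(values, order=None):
    values = np.asarray(values, float)
    order = tuple(order or (f"s{i}" for i in range(values.size)))
    return SubsetDProfile(subset_order=order, d_values=values)


class TestColumnScores:
    def test_v1_single_pair(self, tiny_msa):
        m = make_m(tiny_msa)
        assert af.column_v1(["A", "A"], m) == pytest.approx(m["A", "A"])

    def test_v1_three_members(self, tiny_msa):
        m = make_m(tiny_msa)
        expected = (m["A", "C"] + m["A", "G"] + m["C", "G"]) / 3
        assert af.column_v1(["A", "C", "G"], m) == pytest.approx(expected)

    def test_v1_invariant_under_reordering(self, tiny_msa):
        m = make_m(tiny_msa)
        assert af.column_v1(["A", "C", "G"], m) == pytest.approx(
            af.column_v1(["G", "A", "C"], m)
        )

    def test_v1_rejects_singleton(self, tiny_msa):
        with pytest.raises(SubsetSizeError):
            af.column_v1(["A"], make_m(tiny_msa))

    def test_v2_identical_cross_pairs(self, tiny_msa):
        m = make_m(tiny_msa)
        assert af.column_v2(["A", "A"], ["C", "C"], m) == pytest.approx(m["A", "C"])

    def test_v2_four_distinct_cross_pairs(self, tiny_msa):
        m = make_m(tiny_msa)
        expected = (m["A", "G"] + m["A", "T"] + m["C", "G"] + m["C", "T"]) / 4
        assert af.column_v2(["A", "C"], ["G", "T"], m) == pytest.approx(expected)

    def test_v2_strictly_positive_for_own_msa_columns(self):
        # every co-occurring pair in a column contributed >= 1 count to the
        # msa's own scoring matrix, so the cross mean can never be zero
        rng = np.random.default_rng(17)
        for _ in range(20):
            msa = random_msa(rng, n=6, k=15)
            m = make_m(msa)
            for c in range(msa.k):
                col = msa.codes[:, c]
                assert af.column_v2(col[:3], col[3:], m) > 0


class TestDValue:
    def test_constant_msa_gives_unity(self):
        msa = af.msa_from_sequences([(f"t{i}", "AAAA") for i in range(6)])
        m = make_m(msa)
        sub = af.TaxonSubset(members=frozenset({"t0", "t1"}), complement_size=4)
        assert af.d_value(msa, sub, m) == pytest.approx(1.0)

    def test_single_column_ratio(self):
        # rows: t1=A t2=A t3=C t4=C; subset {t1,t2}: D = m_AA / m_AC
        msa = af.msa_from_sequences([("t1", "A"), ("t2", "A"), ("t3", "C"), ("t4", "C")])
        m = make_m(msa)
        sub = af.TaxonSubset(members=frozenset({"t1", "t2"}), complement_size=2)
        assert af.d_value(msa, sub, m) == pytest.approx(m["A", "A"] / m["A", "C"])

    def test_matches_column_loop(self):
        rng = np.random.default_rng(23)
        msa = random_msa(rng, n=6, k=30)
        m = make_m(msa)
        members = frozenset({"t0", "t3", "t4"})
        sub = af.TaxonSubset(members=members, complement_size=3)
        rows = msa.row_indices(members)
        other = np.setdiff1d(np.arange(msa.n), rows)
        expected = np.mean([
            af.column_v1(msa.codes[rows, c], m) / af.column_v2(
                msa.codes[rows, c], msa.codes[other, c], m)
            for c in range(msa.k)
        ])
        assert af.d_value(msa, sub, m) == pytest.approx(expected)

    def test_true_split_has_larger_d_than_under_rival_tree(self, fig1_trees):
        # data simulated on Tree I: D for the A|B split is larger than D for
        # the same split under data simulated on Tree II (which lacks it)
        from absfit.simulator import SimulationSpec
        from absfit.workflows import GTR_G_MODEL, TREE_I_NEWICK, TREE_II_NEWICK

        t1 = af.tree_from_newick(TREE_I_NEWICK)
        t2 = af.tree_from_newick(TREE_II_NEWICK)
        subsets = af.extract_subsets([t1, t2])
        msa1 = af.simulate_alignment(
            SimulationSpec(tree=t1, model=GTR_G_MODEL, k=5000, seed=101))
        msa2 = af.simulate_alignment(
            SimulationSpec(tree=t2, model=GTR_G_MODEL, k=5000, seed=202))
        p1 = af.profile(msa1, subsets)
        p2 = af.profile(msa2, subsets)
        i_ab = p1.subset_order.index("A|B")
        i_ac = p1.subset_order.index("A|C")
        assert p1.d_values[i_ab] > p2.d_values[i_ab]
        assert p2.d_values[i_ac] > p1.d_values[i_ac]


class TestSpearman:
    def test_self_comparison_is_clamped(self):
        p = make_profile([3.0, 1.0, 2.0, 5.0])
        assert af.spearman_rs(p, p) == RS_CLAMP

    def test_reversed_ranks(self):
        a = make_profile([1.0, 2.0, 3.0, 4.0])
        b = make_profile([9.0, 7.0, 5.0, 3.0])
        assert af.spearman_rs(a, b) == pytest.approx(-1.0, abs=1e-15)

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_rank_then_pearson_oracle_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        a = rng.integers(0, 4, size=n).astype(float)  # ties likely
        b = rng.integers(0, 4, size=n).astype(float)
        if np.unique(a).size < 2 or np.unique(b).size < 2:
            return  # undefined correlation handled elsewhere
        expected = np.corrcoef(rankdata(a), rankdata(b))[0, 1]
        got = af.spearman_rs(make_profile(a), make_profile(b))
        assert got == pytest.approx(np.clip(expected, -RS_CLAMP, RS_CLAMP))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        a = rng.random(8)
        b = rng.random(8)
        base = af.spearman_rs(make_profile(a), make_profile(b))
        assert af.spearman_rs(make_profile(np.exp(a)), make_profile(b ** 3)) == \
            pytest.approx(base)

    def test_order_mismatch_rejected(self):
        a = make_profile([1.0, 2.0], order=("x", "y"))
        b = make_profile([1.0, 2.0], order=("y", "x"))
        with pytest.raises(OrderMismatchError):
            af.spearman_rs(a, b)

    def test_constant_profile_yields_zero(self):
        a = make_profile([1.0, 1.0, 1.0])
        b = make_profile([1.0, 2.0, 3.0])
        assert af.spearman_rs(a, b) == 0.0


class TestFitB:
    def test_single_replicate_is_one_minus_rs(self):
        obs = make_profile([1.0, 3.0, 2.0, 4.0])
        rep = make_profile([1.5, 2.5, 2.0, 5.0])
        rs = af.spearman_rs(obs, rep)
        res = af.fit_B(obs, [rep])
        assert res.B == pytest.approx(1 - rs)

    def test_mean_zero_correlation_gives_one(self):
        # one perfectly agreeing and one perfectly reversed replicate:
        # r_s = +clamp and -clamp, mean z = 0, hence B = 1
        obs = make_profile([1.0, 2.0, 3.0, 4.0])
        rep_pos = make_profile([10.0, 20.0, 30.0, 40.0])
        rep_neg = make_profile([40.0, 30.0, 20.0, 10.0])
        res = af.fit_B(obs, [rep_pos, rep_neg])
        assert res.B == pytest.approx(1.0)

    def test_equal_rs_replicates(self):
        obs = make_profile([1.0, 3.0, 2.0, 4.0])
        rep = make_profile([2.0, 6.0, 4.0, 8.0])  # same ranks -> clamped rs
        res = af.fit_B(obs, [rep, rep, rep])
        assert res.B == pytest.approx(1 - RS_CLAMP)

    def test_b_equals_one_minus_tanh_mean_z(self):
        rng = np.random.default_rng(8)
        obs = make_profile(rng.random(6))
        reps = [make_profile(rng.random(6)) for _ in range(5)]
        res = af.fit_B(obs, reps)
        assert res.B == pytest.approx(1 - np.tanh(res.z_mean))
        assert 0 <= res.B <= 2
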