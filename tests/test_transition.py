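"""Transition-matrix construction: normalization, bias, crosstalk mixing."""

import networkx as nx
import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings
from hypothesis import strategies as st

from amend.diffusion import build_seed_vector, rwr
from amend.graph_model import build_index
from amend.synthetic import ComponentSpec, LayerSpec, SyntheticSpec, generate_graph, monoplex
from amend.transition import (
    BiasVector,
    TransitionOptions,
    apply_bias,
    assemble_transition,
    column_normalize,
    penalized_normalize,
)

from conftest import random_weighted_graph


def colsums(M):
    return np.asarray(M.sum(axis=0)).ravel()


class TestColumnNormalize:
    def test_permutation_matrix_is_fixed_point(self):
        P = sp.csc_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        assert np.allclose(column_normalize(P).toarray(), P.toarray())

    def test_column_divided_by_its_sum(self):
        A = sp.csc_matrix(np.array([[2.0], [6.0], [2.0]]))
        out = column_normalize(A).toarray().ravel()
        assert np.allclose(out, [0.2, 0.6, 0.2])

    def test_zero_column_stays_zero(self):
        A = sp.csc_matrix(np.array([[1.0, 0.0], [1.0, 0.0]]))
        out = column_normalize(A)
        assert colsums(out)[1] == 0.0

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            column_normalize(sp.csc_matrix(np.array([[-1.0]])))


class TestPenalizedNormalize:
    def test_k_zero_equals_plain_normalization(self):
        rng = np.random.default_rng(0)
        A = sp.csc_matrix(np.abs(rng.normal(size=(6, 6))))
        A = A + A.T
        assert np.allclose(
            penalized_normalize(A, 0.0).toarray(), column_normalize(A).toarray()
        )

    def test_regular_graph_unaffected_for_any_k(self):
        A = nx.to_scipy_sparse_array(nx.cycle_graph(8), format="csc").astype(float)
        for k in (0.1, 0.5, 2.0):
            assert np.allclose(
                penalized_normalize(A, k).toarray(), column_normalize(A).toarray()
            )

    def test_star_hand_derived_values(self):
        # K_{1,3}: hub degree 3, leaves degree 1; k_pen = 1.
        # A leaf's only neighbor is the hub -> its column is forced to 1;
        # the hub's column penalizes nothing (all leaf degrees equal) -> 1/3.
        star = nx.star_graph(3)  # node 0 is the hub
        A = nx.to_scipy_sparse_array(star, format="csc").astype(float)
        M = penalized_normalize(A, 1.0).toarray()
        for leaf in (1, 2, 3):
            assert M[0, leaf] == pytest.approx(1.0)
        assert np.allclose(M[1:, 0], 1.0 / 3.0)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            penalized_normalize(sp.eye(2, format="csc"), -0.5)


class TestApplyBias:
    def test_identity_bias_is_noop(self):
        rng = np.random.default_rng(1)
        A = sp.csc_matrix(np.abs(rng.normal(size=(5, 5))))
        assert np.allclose(apply_bias(A, np.ones(5)).toarray(), A.toarray())

    def test_path_column_split_two_thirds(self):
        # source j adjacent to i and k with equal weights; mu = (2, 1)
        # -> m_ij = 2/3, m_kj = 1/3
        A = sp.csc_matrix(np.array([[0.0, 1.0, 0.0], [0.0, 0.0, 0.0], [0.0, 1.0, 0.0]]))
        mu = np.array([2.0, 1.0, 1.0])
        M = column_normalize(apply_bias(A, mu)).toarray()
        assert M[0, 1] == pytest.approx(2.0 / 3.0)
        assert M[2, 1] == pytest.approx(1.0 / 3.0)

    def test_doubling_mu_strictly_increases_incoming_rates(self):
        rng = np.random.default_rng(2)
        G = random_weighted_graph(12, 0.4, rng)
        A = nx.to_scipy_sparse_array(G, weight="weight", format="csc")
        mu = np.ones(12)
        base = column_normalize(apply_bias(A, mu)).toarray()
        mu[3] = 2.0
        boosted = column_normalize(apply_bias(A, mu)).toarray()
        for j in G.neighbors(3):
            assert boosted[3, j] > base[3, j]

    def test_matches_elementwise_formula_on_random_graphs(self):
        # oracle: m_ij = mu_i a_ij / sum_l mu_l a_lj, evaluated densely
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = int(rng.integers(4, 20))
            G = random_weighted_graph(n, 0.3, rng)
            A = nx.to_scipy_sparse_array(G, weight="weight", format="csc").astype(float)
            mu = rng.uniform(0.1, 3.0, size=n)
            M = column_normalize(apply_bias(A, mu)).toarray()
            Ad = A.toarray()
            expect = np.zeros_like(Ad)
            for j in range(n):
                denom = (mu * Ad[:, j]).sum()
                if denom > 0:
                    expect[:, j] = mu * Ad[:, j] / denom
            assert np.allclose(M, expect, atol=1e-12)

    def test_zero_mu_neighborhood_falls_back_unbiased(self):
        A = sp.csc_matrix(np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.warns(UserWarning, match="all-zero biased neighborhood"):
            out = apply_bias(A, np.array([0.0, 1.0]))
        # column 1 (whose only target had mu=0) reverts to the raw column
        assert out.toarray()[0, 1] == 1.0


class TestAssembly:
    def test_single_layer_reduces_to_column_normalize(self):
        G = random_weighted_graph(15, 0.3, np.random.default_rng(4))
        g = monoplex(G)
        A = nx.to_scipy_sparse_array(
            G, nodelist=sorted(G.nodes), weight="weight", format="csc"
        )
        expect = column_normalize(A).toarray()
        for lam, delta in [(0.0, 0.0), (0.5, 0.5), (1.0, 0.3), (0.2, 1.0)]:
            tm = assemble_transition(
                g, TransitionOptions(lambda_switch=lam, delta_jump=delta)
            )
            assert np.allclose(tm.M.toarray(), expect, atol=1e-14)

    def test_zero_crosstalk_gives_block_diagonal(self, two_component_graph):
        tm = assemble_transition(
            two_component_graph, TransitionOptions(lambda_switch=0.0, delta_jump=0.0)
        )
        index = tm.index
        M = tm.M.toarray()
        for (cid, lid), sl in index.layer_slices.items():
            block = np.zeros_like(M, dtype=bool)
            block[sl, sl] = True
            outside = M[~block & (M != 0.0)]
            M_masked = M.copy()
            M_masked[sl, sl] = 0.0
            # no mass may leave the (component, layer) block of its column
            assert np.all(M_masked[:, sl] == 0.0)

    def test_column_class_masses_follow_crosstalk_split(self, two_component_graph):
        tm = assemble_transition(two_component_graph)
        index = tm.index
        lam, delta = tm.lambda_switch, tm.delta_jump
        # replica of node b in (c1, l1): has intra ('a','c'), inter-layer
        # (b in l2), and inter-component (x in c2) targets
        j = index.index("c1", "l1", "b")
        masses = tm.column_class_mass(j)
        assert masses["intra"] == pytest.approx((1 - delta) * (1 - lam), abs=1e-12)
        assert masses["inter_layer"] == pytest.approx((1 - delta) * lam, abs=1e-12)
        assert masses["inter_component"] == pytest.approx(delta, abs=1e-12)

    def test_missing_class_mass_redistributed(self, two_component_graph):
        tm = assemble_transition(two_component_graph)
        index = tm.index
        # replica of 'a' in (c1, l1): no inter-layer replica, no bipartite
        # edges -> all mass stays intra-layer
        j = index.index("c1", "l1", "a")
        masses = tm.column_class_mass(j)
        assert masses["intra"] == pytest.approx(1.0, abs=1e-12)

    def test_columns_sum_to_one(self, two_component_graph):
        tm = assemble_transition(two_component_graph)
        s = colsums(tm.M)
        assert np.all(np.abs(s[~tm.dangling] - 1.0) <= 1e-12)

    def test_isolated_replica_is_dangling_zero_column(self):
        import networkx as nx

        G = nx.Graph()
        G.add_edge("a", "b", weight=1.0)
        G.add_node("iso")
        g = monoplex(G)
        tm = assemble_transition(g)
        j = tm.index.index("c1", "l1", "iso")
        assert tm.dangling[j]
        assert colsums(tm.M)[j] == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        lam=st.floats(0.0, 1.0),
        delta=st.floats(0.0, 1.0),
        k_pen=st.floats(0.0, 2.0),
        seed=st.integers(0, 100),
        biased=st.booleans(),
    )
    def test_stochasticity_over_random_configurations(self, lam, delta, k_pen, seed, biased):
        spec = SyntheticSpec(
            components=[
                ComponentSpec("c1", [LayerSpec("l1", 25), LayerSpec("l2", 20)], overlap=0.4),
                ComponentSpec("c2", [LayerSpec("l1", 15, model="erdos_renyi", density=0.2)]),
            ],
            bipartite_density=0.02,
            seed=seed,
        )
        g = generate_graph(spec)
        index = build_index(g)
        rng = np.random.default_rng(seed)
        opts = TransitionOptions(
            lambda_switch=lam,
            delta_jump=delta,
            normalization="penalized",
            k_pen=k_pen,
            bias=BiasVector(rng.uniform(0.1, 2.0, index.n)) if biased else None,
        )
        tm = assemble_transition(g, opts, index=index)
        s = colsums(tm.M)
        assert np.all(np.abs(s[~tm.dangling] - 1.0) <= 1e-12)
        assert np.all(s[tm.dangling] == 0.0)
        assert tm.M.data.min() >= 0.0


class TestCrosstalkLinearity:
    def test_class_mass_affine_in_lambda_and_delta(self, two_component_graph):
        index = build_index(two_component_graph)
        j = index.index("c1", "l1", "b")  # has all three target classes
        grid = np.linspace(0.0, 1.0, 11)

        def masses(lam, delta):
            tm = assemble_transition(
                two_component_graph,
                TransitionOptions(lambda_switch=lam, delta_jump=delta),
                index=index,
            )
            return tm.column_class_mass(j)

        for cls, expect in [
            ("intra", lambda lam: (1 - 0.3) * (1 - lam)),
            ("inter_layer", lambda lam: (1 - 0.3) * lam),
        ]:
            ys = np.array([masses(lam, 0.3)[cls] for lam in grid])
            line = np.array([expect(lam) for lam in grid])
            assert np.max(np.abs(ys - line)) <= 1e-12
        ys = np.array([masses(0.4, d)["inter_component"] for d in grid])
        assert np.max(np.abs(ys - grid)) <= 1e-12


def test_rwr_runs_on_assembled_heterogeneous_matrix(two_component_graph):
    tm = assemble_transition(two_component_graph)
    sv = build_seed_vector(two_component_graph, {"c1": {"a": 1.0}}, index=tm.index)
    res = rwr(tm, sv, r=0.5)
    assert res.p.sum() == pytest.approx(1.0, abs=1e-10)
    assert res.p.min() >= 0.0
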