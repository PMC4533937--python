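"""State space, classification and kernel construction."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from kmtchain import (
    AttachmentClass,
    AttachmentState,
    ModelParams,
    ParameterError,
    StateSpace,
    build_kernel,
    classify,
    enumerate_states,
)
from kmtchain.chain_model import (
    EVENT_ORDER,
    Event,
    apply_event,
    event_probability,
    scaling_factor,
)

from brute_oracle import oracle_classify, oracle_kernel, oracle_states


class TestStateSpace:
    @pytest.mark.parametrize("n,size", [(2, 36), (3, 100), (10, 4356)])
    def test_size_matches_enumeration(self, n, size):
        space = enumerate_states(n)
        assert len(space) == size == ((n + 1) * (n + 2) // 2) ** 2
        assert len(space) == len(oracle_states(n))

    def test_single_kinetochore_configurations_n2(self):
        space = enumerate_states(2)
        singles = {(s.i1, s.j1) for s in space}
        assert singles == {(0, 0), (1, 0), (0, 1), (2, 0), (1, 1), (0, 2)}

    def test_index_round_trips(self, space_n2):
        for k, s in enumerate(space_n2):
            assert space_n2.index(s) == k
            assert space_n2.state(k) == s

    def test_order_is_lexicographic(self, space_n2):
        assert list(space_n2.states) == sorted(space_n2.states)

    def test_rejects_n_below_two(self):
        with pytest.raises(ParameterError):
            enumerate_states(1)

    def test_state_capacity_validation(self):
        with pytest.raises(ParameterError):
            AttachmentState(2, 1, 0, 0).validate(2)
        with pytest.raises(ParameterError):
            AttachmentState(-1, 0, 0, 0).validate(2)


class TestClassify:
    @pytest.mark.parametrize(
        "state,cls",
        [
            ((0, 0, 0, 0), AttachmentClass.FREE),
            ((1, 0, 0, 1), AttachmentClass.AMPHITELIC),
            ((0, 2, 3, 0), AttachmentClass.AMPHITELIC),
            ((1, 1, 0, 0), AttachmentClass.MEROTELIC),
            ((2, 0, 1, 0), AttachmentClass.SYNTELIC),
            ((0, 0, 0, 2), AttachmentClass.MONOTELIC),
            ((1, 1, 1, 0), AttachmentClass.MEROTELIC),  # merotelic precedence
            ((1, 0, 1, 1), AttachmentClass.MEROTELIC),
        ],
    )
    def test_known_configurations(self, state, cls):
        assert classify(AttachmentState(*state)) is cls

    def test_partition_and_oracle_agreement(self, space_n10):
        for s, c in zip(space_n10.states, space_n10.class_of):
            assert int(c) == oracle_classify(s)

    def test_symmetry_of_classification(self, space_n10):
        for s in space_n10:
            c = classify(s)
            assert classify(s.mirror()) == c
            assert classify(s.swap_kinetochores()) == c


class TestModelParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n=1),
            dict(p=0.3),
            dict(q=0.06),      # above 1/(2n) for n = 10
            dict(alpha=1.5),
            dict(beta=-0.1),
        ],
    )
    def test_bounds_are_enforced(self, kwargs):
        base = dict(n=10, p=0.05, q=0.05, alpha=0.0, beta=0.0, gamma=1.0,
                    mode="meiosis_I")
        base.update(kwargs)
        with pytest.raises(ParameterError):
            ModelParams(**base)

    def test_mode_constraints(self):
        with pytest.raises(ParameterError):
            ModelParams(n=10, p=0.05, q=0.05, alpha=0.5, beta=0.0,
                        gamma=0.1, mode="mitosis")
        with pytest.raises(ParameterError):
            ModelParams(n=10, p=0.05, q=0.05, alpha=0.0, beta=0.0,
                        gamma=0.5, mode="meiosis_I")
        assert ModelParams.mitosis().alpha == 0.0
        assert ModelParams.meiosis_I().gamma == 1.0


class TestEventProbability:
    def test_attach_to_empty_kinetochore(self):
        params = ModelParams.meiosis_I(n=10, p=0.05)
        p = event_probability(
            AttachmentState(0, 0, 3, 2), Event("attach", 1, "left"), params
        )
        assert p == pytest.approx(0.05)

    def test_attach_blocked_at_capacity(self):
        params = ModelParams.meiosis_I(n=10)
        assert event_probability(
            AttachmentState(4, 6, 0, 0), Event("attach", 1, "right"), params
        ) == 0.0

    def test_detach_scales_with_count(self):
        params = ModelParams.meiosis_I(n=10, q=0.05)
        p = event_probability(
            AttachmentState(3, 1, 0, 0), Event("detach", 1, "left"), params
        )
        assert p == pytest.approx(0.15)


class TestScalingFactor:
    def setup_method(self):
        self.params = ModelParams(n=10, p=0.05, q=0.05, alpha=0.3, beta=0.6,
                                  gamma=1.0, mode="meiosis_I")

    def test_amphitelic_to_merotelic_attachment_scales_with_alpha(self):
        f = scaling_factor(
            AttachmentState(1, 0, 0, 1), AttachmentState(1, 1, 0, 1), self.params
        )
        assert f == self.params.alpha

    def test_amphitelic_detachment_scales_with_beta(self):
        # leaving the amphitelic class...
        assert scaling_factor(
            AttachmentState(1, 0, 0, 1), AttachmentState(0, 0, 0, 1), self.params
        ) == self.params.beta
        # ...and staying inside it are both tension-stabilised
        assert scaling_factor(
            AttachmentState(2, 0, 0, 1), AttachmentState(1, 0, 0, 1), self.params
        ) == self.params.beta

    def test_amphitelic_correct_pole_attachment_unscaled(self):
        assert scaling_factor(
            AttachmentState(1, 0, 0, 1), AttachmentState(2, 0, 0, 1), self.params
        ) == 1.0

    def test_monotelic_attachments_scale_with_gamma(self):
        params = ModelParams.mitosis(gamma=0.1)
        # monotelic -> syntelic
        assert scaling_factor(
            AttachmentState(1, 0, 0, 0), AttachmentState(1, 0, 1, 0), params
        ) == params.gamma
        # monotelic -> merotelic
        assert scaling_factor(
            AttachmentState(1, 0, 0, 0), AttachmentState(1, 1, 0, 0), params
        ) == params.gamma
        # monotelic -> amphitelic is the unscaled, correct capture
        assert scaling_factor(
            AttachmentState(1, 0, 0, 0), AttachmentState(1, 0, 0, 1), params
        ) == 1.0

    def test_non_adjacent_pair_is_a_contract_error(self):
        with pytest.raises(ValueError):
            scaling_factor(
                AttachmentState(0, 0, 0, 0), AttachmentState(1, 1, 0, 0),
                self.params,
            )


class TestKernel:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=2**32 - 1))
    def test_rows_stochastic_for_random_valid_parameters(self, entropy):
        from conftest import random_params

        params = random_params(np.random.default_rng(entropy))
        kernel = build_kernel(params)
        rowsums = np.asarray(kernel.matrix.sum(axis=1)).ravel()
        assert np.abs(rowsums - 1.0).max() < 1e-12
        assert kernel.matrix.data.min() >= 0.0
        assert kernel.matrix.data.max() <= 1.0

    def test_offdiagonal_entries_are_single_events(self, meiosis_random):
        coo = meiosis_random.matrix.tocoo()
        counts = meiosis_random.space.counts
        off = coo.row != coo.col
        d = counts[coo.col[off]] - counts[coo.row[off]]
        assert (np.abs(d).sum(axis=1) == 1).all()

    def test_diagonal_nonnegative_at_extreme_corner(self):
        params = ModelParams.meiosis_I(n=10, p=0.25, q=1 / 20)
        kernel = build_kernel(params)
        assert kernel.matrix.diagonal().min() >= 0.0

    def test_fully_occupied_amphitelic_states_absorb_when_alpha_beta_zero(self):
        kernel = build_kernel(ModelParams.meiosis_I(n=10))
        space = kernel.space
        expected = {
            space.index(AttachmentState(10, 0, 0, 10)),
            space.index(AttachmentState(0, 10, 10, 0)),
        }
        assert set(kernel.absorbing_indices()) == expected
        diag = kernel.matrix.diagonal()
        for k in expected:
            assert diag[k] == 1.0

    def test_pole_mirror_symmetry(self, meiosis_random):
        space = meiosis_random.space
        perm = np.array([space.index(s.mirror()) for s in space])
        M = meiosis_random.matrix.toarray()
        assert np.allclose(M, M[np.ix_(perm, perm)], atol=1e-15)
        assert (space.class_of == space.class_of[perm]).all()

    def test_kinetochore_exchange_symmetry(self, meiosis_random):
        space = meiosis_random.space
        perm = np.array([space.index(s.swap_kinetochores()) for s in space])
        M = meiosis_random.matrix.toarray()
        assert np.allclose(M, M[np.ix_(perm, perm)], atol=1e-15)

    def test_class_transition_graph_matches_taxonomy(self):
        """One-step class adjacency: amphitelic exits only to monotelic,
        merotelic, or itself; free reaches only monotelic."""
        params = ModelParams(n=4, p=0.1, q=0.1, alpha=0.5, beta=0.5,
                             gamma=1.0, mode="meiosis_I")
        kernel = build_kernel(params)
        cls = kernel.space.class_of
        coo = kernel.matrix.tocoo()
        adj = set()
        for u, v in zip(cls[coo.row], cls[coo.col]):
            if u != v:
                adj.add((int(u), int(v)))
        assert {v for (u, v) in adj if u == 5} == {2, 4}
        assert {v for (u, v) in adj if u == 1} == {2}
        assert adj == {
            (1, 2), (2, 1), (2, 3), (2, 4), (2, 5), (3, 2), (3, 4),
            (4, 2), (4, 3), (4, 5), (5, 2), (5, 4),
        }

    @pytest.mark.parametrize(
        "alpha,beta,gamma,mode",
        [
            (0.0, 0.0, 1.0, "meiosis_I"),
            (1.0, 1.0, 1.0, "meiosis_I"),
            (0.7, 0.3, 1.0, "meiosis_I"),
            (0.0, 0.5, 0.1, "mitosis"),
        ],
    )
    def test_n2_kernel_equals_brute_force_oracle(self, alpha, beta, gamma, mode):
        params = ModelParams(n=2, p=0.1, q=0.2, alpha=alpha, beta=beta,
                             gamma=gamma, mode=mode)
        kernel = build_kernel(params)
        o_states, o_K = oracle_kernel(2, 0.1, 0.2, alpha, beta, gamma)
        assert list(kernel.space.states) == o_states
        assert np.abs(kernel.matrix.toarray() - o_K).max() < 1e-14

    def test_apply_event_round_trip(self):
        s = AttachmentState(1, 0, 2, 1)
        t = apply_event(s, EVENT_ORDER[0])
        assert t == AttachmentState(2, 0, 2, 1)
        assert apply_event(t, EVENT_ORDER[4]) == s
        assert apply_event(AttachmentState(0, 0, 0, 0), EVENT_ORDER[4]) is None

    def test_kernel_coo_export_round_trips(self, tmp_path):
        from scipy import sparse

        kernel = build_kernel(ModelParams.meiosis_I(n=2))
        path = tmp_path / "kernel.tsv"
        kernel.write_coo(path)
        rows, cols, vals = [], [], []
        for line in path.read_text().splitlines()[2:]:
            r, c, v = line.split("\t")
            rows.append(int(r)); cols.append(int(c)); vals.append(float(v))
        M = sparse.csr_matrix((vals, (rows, cols)), shape=kernel.matrix.shape)
        assert np.abs((M - kernel.matrix).toarray()).max() == 0.0
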