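"""Unit and property tests of the one-step kernel and its marginals."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microhost import (
    FocalTarget,
    HostState,
    MarginalClosureError,
    ModelParams,
    marginal_step_probabilities,
    replacement_distribution,
)


class TestModelParamsValidation:
    def test_accepts_valid_neutral_params(self):
        params = ModelParams(N=100, m=0.1, tau=0.01, p=np.array([0.3, 0.7]))
        assert params.M == 2
        assert np.array_equal(params.alpha, np.zeros(3))
        assert params.pool_with_empty[0] == 0.0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"N": 1},
            {"N": 100, "m": -0.1},
            {"N": 100, "m": 1.5},
            {"N": 100, "tau": 2.0},
            {"N": 100, "p": [1.2]},
            {"N": 100, "p": [-0.1]},
            {"N": 100, "alpha": [-1.0, 0.0]},
            {"N": 100, "alpha": [0.0, 0.0, 0.0]},  # wrong length for M=1
        ],
    )
    def test_rejects_invalid_params(self, kwargs):
        defaults = {"N": 100, "m": 0.1, "tau": 0.0, "p": [1.0]}
        defaults.update(kwargs)
        with pytest.raises((ValueError, TypeError)):
            ModelParams(**defaults)

    def test_community_pool_requires_unit_sum(self):
        ModelParams(N=10, m=0.1, tau=0.0, p=[0.5, 0.5]).require_community_pool()
        with pytest.raises(ValueError, match="sum"):
            ModelParams(N=10, m=0.1, tau=0.0, p=[0.5, 0.4]).require_community_pool()

    def test_marginal_pool_needs_no_unit_sum(self):
        # a focal taxon may carry any pool frequency on its own
        ModelParams(N=10, m=0.1, tau=0.0, p=[0.25])


class TestHostState:
    def test_microbe_free_and_frequencies(self):
        s = HostState.microbe_free(20, 3)
        assert s.N == 20
        assert s.x[0] == 1.0 and np.all(s.x[1:] == 0.0)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            HostState(np.array([5, -1]))

    def test_capacity_mismatch_detected(self):
        params = ModelParams(N=10, m=0.1, tau=0.0, p=[1.0])
        with pytest.raises(ValueError):
            HostState(np.array([5, 4])).check_capacity(params)


class TestReplacementDistribution:
    def test_empty_host_splits_between_migration_and_empty_reproduction(self):
        # only empty space can reproduce locally in a sterile host
        params = ModelParams(N=10, m=0.3, tau=0.0, p=[1.0])
        w = replacement_distribution(HostState.microbe_free(10, 1), params)
        assert w == pytest.approx([0.7, 0.3], abs=1e-15)

    def test_pure_immigration_returns_pool(self):
        params = ModelParams(N=10, m=1.0, tau=0.0, p=[0.2, 0.8])
        w = replacement_distribution(HostState(np.array([3, 3, 4])), params)
        assert w == pytest.approx([0.0, 0.2, 0.8], abs=1e-15)

    def test_fitness_weighted_local_reproduction(self):
        # N=4, half empty with alpha_0 = -0.5: empty weight 0.25/(0.25+0.5)=1/3
        params = ModelParams(N=4, m=0.0, tau=0.0, p=[1.0], alpha=[-0.5, 0.0])
        w = replacement_distribution(HostState(np.array([2, 2])), params)
        assert w == pytest.approx([1.0 / 3.0, 2.0 / 3.0], abs=1e-15)

    @given(
        m=st.floats(0.0, 1.0),
        alpha0=st.floats(-0.99, 5.0),
        counts=st.lists(st.integers(0, 30), min_size=3, max_size=5).filter(
            lambda c: sum(c) >= 2
        ),
    )
    @settings(deadline=None, max_examples=100)
    def test_sums_to_one(self, m, alpha0, counts):
        M = len(counts) - 1
        alpha = np.zeros(M + 1)
        alpha[0] = alpha0
        params = ModelParams(
            N=int(sum(counts)), m=m, tau=0.0, p=np.full(M, 1.0 / M), alpha=alpha
        )
        w = replacement_distribution(HostState(np.array(counts)), params)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(w >= 0.0)


class TestMarginalStepProbabilities:
    def test_certain_immigration_from_empty(self):
        params = ModelParams(N=10, m=1.0, tau=0.0, p=[1.0])
        quad = marginal_step_probabilities(0.0, FocalTarget.taxon(1, 1.0), params)
        assert quad == pytest.approx((0.0, 1.0, 0.0, 0.0), abs=1e-15)

    def test_no_increase_at_full_occupancy(self):
        for m, tau in [(0.3, 0.1), (1.0, 0.0), (0.0, 0.9)]:
            params = ModelParams(N=10, m=m, tau=tau, p=[0.6])
            _, up, _, _ = marginal_step_probabilities(
                1.0, FocalTarget.taxon(1, 0.6), params
            )
            assert up == 0.0

    def test_hand_evaluated_quadruple(self):
        # tau=0.5, m=0, x=0.5: up = 0.5 * 0.5 * 0.5 = 0.125 = down
        params = ModelParams(N=10, m=0.0, tau=0.5, p=[0.5])
        quad = marginal_step_probabilities(0.5, FocalTarget.taxon(1, 0.5), params)
        assert quad == pytest.approx((0.5, 0.125, 0.125, 0.25), abs=1e-15)

    @pytest.mark.parametrize("kind", ["taxon", "empty_space"])
    @pytest.mark.parametrize("m", [0.0, 0.01, 0.5, 1.0])
    @pytest.mark.parametrize("tau", [0.0, 1e-6, 0.3, 1.0])
    def test_probabilities_sum_to_one_on_dense_grid(self, kind, m, tau):
        x = np.linspace(0.0, 1.0, 201)
        if kind == "taxon":
            params = ModelParams(N=200, m=m, tau=tau, p=[0.37])
            target = FocalTarget.taxon(1, 0.37)
        else:
            params = ModelParams(N=200, m=m, tau=tau, p=[1.0], alpha=[-0.8, 0.0])
            target = FocalTarget.empty_space()
        reset, up, down, stay = marginal_step_probabilities(x, target, params)
        total = reset + up + down + stay
        assert np.max(np.abs(total - 1.0)) < 1e-12
        for arr in (reset, up, down, stay):
            assert np.all(arr >= -1e-15) and np.all(arr <= 1.0 + 1e-15)

    def test_pure_neutral_drift_is_symmetric(self):
        # m=0, tau=0, all alpha 0: up(x) = down(x) everywhere
        params = ModelParams(N=100, m=0.0, tau=0.0, p=[0.5])
        x = np.arange(101) / 100
        _, up, down, _ = marginal_step_probabilities(
            x, FocalTarget.taxon(1, 0.5), params
        )
        assert up == pytest.approx(down, abs=1e-15)

    def test_taxon_closure_violation_is_refused(self):
        params = ModelParams(N=10, m=0.1, tau=0.0, p=[1.0], alpha=[-0.5, 0.0])
        with pytest.raises(MarginalClosureError, match="closure unavailable"):
            marginal_step_probabilities(0.5, FocalTarget.taxon(1, 1.0), params)

    def test_empty_space_closure_requires_neutral_taxa(self):
        params = ModelParams(N=10, m=0.1, tau=0.0, p=[1.0], alpha=[0.0, 0.5])
        with pytest.raises(MarginalClosureError, match="closure unavailable"):
            marginal_step_probabilities(0.5, FocalTarget.empty_space(), params)

    def test_empty_space_marginal_allows_any_alpha0(self):
        params = ModelParams(N=10, m=0.1, tau=0.1, p=[1.0], alpha=[3.0, 0.0])
        reset, up, down, stay = marginal_step_probabilities(
            0.4, FocalTarget.empty_space(), params
        )
        assert reset + up + down + stay == pytest.approx(1.0, abs=1e-14)
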