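"""Tests of summary statistics, modality classification and lifespan sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microhost import (
    FocalTarget,
    HostState,
    MarginalDistribution,
    ModelParams,
    build_reset_chain,
    classify_modality,
    colonization_probabilities,
    empirical_distribution,
    sample_at_host_death,
    simulate_population,
    stationary_distribution,
    total_variation,
)
from microhost.master_equation import GridMismatchError


def _dist(mass):
    mass = np.asarray(mass, dtype=float)
    return MarginalDistribution(np.arange(mass.size) / (mass.size - 1), mass)


class TestTotalVariation:
    def test_identical_distributions_differ_by_zero(self):
        d = _dist([0.2, 0.3, 0.5])
        assert total_variation(d, d) == 0.0

    def test_disjoint_point_masses_differ_by_one(self):
        a = _dist([1.0, 0.0, 0.0])
        b = _dist([0.0, 0.0, 1.0])
        assert total_variation(a, b) == 1.0

    def test_hand_value(self):
        a = _dist([0.5, 0.5, 0.0])
        b = _dist([0.0, 0.5, 0.5])
        assert total_variation(a, b) == pytest.approx(0.5)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridMismatchError):
            total_variation(_dist([0.5, 0.5]), _dist([0.3, 0.3, 0.4]))

    @given(
        raw=st.lists(
            st.tuples(
                st.floats(0.0, 1.0), st.floats(0.0, 1.0), st.floats(0.0, 1.0)
            ),
            min_size=3,
            max_size=3,
        )
    )
    @settings(deadline=None, max_examples=60)
    def test_metric_properties(self, raw):
        dists = []
        for triple in raw:
            v = np.asarray(triple) + 1e-6
            dists.append(_dist(v / v.sum()))
        a, b, c = dists
        assert total_variation(a, b) == pytest.approx(total_variation(b, a))
        assert total_variation(a, a) == 0.0
        assert (
            total_variation(a, c)
            <= total_variation(a, b) + total_variation(b, c) + 1e-12
        )
        assert 0.0 <= total_variation(a, b) <= 1.0


class TestColonizationProbabilities:
    def test_point_mass_at_zero(self):
        probs = colonization_probabilities(
            _dist([1.0, 0.0, 0.0]), FocalTarget.taxon(1, 0.5)
        )
        assert (probs.p_absent, probs.p_present, probs.p_full) == (1.0, 0.0, 0.0)

    def test_uniform_mass_over_eleven_states(self):
        probs = colonization_probabilities(
            _dist(np.full(11, 1 / 11)), FocalTarget.taxon(1, 0.5)
        )
        assert probs.p_absent == pytest.approx(1 / 11)
        assert probs.p_full == pytest.approx(1 / 11)

    def test_tau_one_stationary_is_fully_absent(self):
        params = ModelParams(N=20, m=0.5, tau=1.0, p=[0.5])
        dist = stationary_distribution(
            build_reset_chain(FocalTarget.taxon(1, 0.5), params)
        )
        probs = colonization_probabilities(dist, FocalTarget.taxon(1, 0.5))
        assert probs.p_absent == pytest.approx(1.0)

    def test_empty_space_labels_are_swapped(self):
        # all mass at x_0 = 1: microbe-free hosts, not full colonization
        probs = colonization_probabilities(
            _dist([0.0, 0.0, 1.0]), FocalTarget.empty_space()
        )
        assert probs.p_absent == 1.0  # no microbes at all
        assert probs.p_full == 0.0


class TestClassifyModality:
    def test_boundary_point_masses(self):
        assert classify_modality(_dist([1, 0, 0, 0])).category == "unimodal_at_0"
        assert classify_modality(_dist([0, 0, 0, 1])).category == "unimodal_at_1"

    def test_internal_maximum(self):
        label = classify_modality(_dist([0.1, 0.2, 0.4, 0.2, 0.1]))
        assert label.category == "unimodal_internal"
        assert label.maxima[0][0] == 2

    def test_bimodal_boundary_pair(self):
        label = classify_modality(_dist([0.45, 0.05, 0.0, 0.05, 0.45]))
        assert label.category == "bimodal_0_and_1"

    def test_bimodal_zero_and_internal(self):
        label = classify_modality(_dist([0.4, 0.1, 0.3, 0.15, 0.05]))
        assert label.category == "bimodal_0_and_internal"

    def test_plateau_counts_once_at_first_index(self):
        label = classify_modality(_dist([0.1, 0.25, 0.25, 0.25, 0.15]))
        assert label.category == "unimodal_internal"
        assert label.maxima[0][0] == 1

    def test_vanishing_tails_are_zeroed_before_search(self):
        # the 1e-12 blip at the right boundary is below threshold: unimodal
        mass = np.array([1.0 - 2e-12, 1e-12, 0.0, 1e-12])
        label = classify_modality(_dist(mass))
        assert label.category == "unimodal_at_0"

    def test_retained_maxima_exceed_threshold(self):
        mass = np.array([0.5, 0.0, 0.5 - 1e-12, 0.0, 1e-12])
        label = classify_modality(_dist(mass))
        assert all(m >= 1e-9 for _, m in label.maxima)

    def test_invariant_to_positive_rescaling(self):
        import warnings

        rng = np.random.default_rng(0)
        mass = rng.dirichlet(np.ones(21))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            base = classify_modality(_dist(mass)).category
            scaled = mass * 7.3
            again = classify_modality(_dist(scaled / scaled.sum())).category
        assert base == again

    def test_more_than_two_maxima_truncates_to_largest(self):
        mass = np.array([0.3, 0.0, 0.25, 0.0, 0.2, 0.0, 0.25])
        with pytest.warns(RuntimeWarning, match="maxima"):
            label = classify_modality(_dist(mass))
        assert label.truncated
        assert len(label.maxima) == 2
        assert label.maxima[0][1] == pytest.approx(0.3)


@pytest.fixture(scope="module")
def trajectory():
    params = ModelParams(N=40, m=0.05, tau=0.0, p=[1.0])
    return simulate_population(
        params, n_hosts=400, n_steps=4000, sample_every=10, seed=13
    )


class TestLifespanSampling:

    def test_tau_one_samples_the_initial_state(self, trajectory):
        states = sample_at_host_death(trajectory, 1.0, seed=0)
        assert all(np.array_equal(s.n, trajectory.counts[h, 0]) for h, s in enumerate(states))

    def test_mean_sampled_time_matches_geometric_mean(self, trajectory):
        tau = 0.01
        _, times = sample_at_host_death(trajectory, tau, seed=1, return_times=True)
        mean, n = (1 - tau) / tau, len(times)
        se = np.sqrt((1 - tau) / tau**2 / n)
        assert abs(times.mean() - mean) <= 3 * se

    def test_rejects_nonpositive_tau(self, trajectory):
        with pytest.raises(ValueError):
            sample_at_host_death(trajectory, 0.0, seed=0)

    def test_warns_when_horizon_truncates_lifespans(self, trajectory):
        with pytest.warns(RuntimeWarning, match="horizon"):
            sample_at_host_death(trajectory, 1e-4, seed=0)

    def test_warns_for_resetting_trajectory(self):
        params = ModelParams(N=20, m=0.05, tau=0.01, p=[1.0])
        traj = simulate_population(params, n_hosts=5, n_steps=200, sample_every=10, seed=0)
        with pytest.warns(RuntimeWarning, match="reset-free"):
            sample_at_host_death(traj, 0.01, seed=0)

    def test_sampled_histogram_approximates_resetting_stationary_law(self):
        # scaled-down model-vs-simulation agreement through Eq-6-style sampling
        N, m, tau = 100, 0.01, 1e-3
        params = ModelParams(N=N, m=m, tau=0.0, p=[0.5, 0.5])
        traj = simulate_population(
            params, n_hosts=1000, n_steps=20_000, sample_every=10, seed=17
        )
        states = sample_at_host_death(traj, tau, seed=18)
        target = FocalTarget.taxon(1, 0.5)
        hist = empirical_distribution(states, target)
        solver = stationary_distribution(
            build_reset_chain(
                target, ModelParams(N=N, m=m, tau=tau, p=[0.5])
            )
        )
        assert total_variation(hist, solver) < 0.1


class TestEmpiricalDistribution:
    def test_single_state_gives_point_mass(self):
        dist = empirical_distribution(
            [HostState(np.array([6, 4]))], FocalTarget.taxon(1, 1.0)
        )
        assert dist.mass[4] == 1.0

    def test_duplication_leaves_histogram_unchanged(self):
        states = [HostState(np.array([6, 4])), HostState(np.array([2, 8]))]
        a = empirical_distribution(states, FocalTarget.taxon(1, 1.0))
        b = empirical_distribution(states * 3, FocalTarget.taxon(1, 1.0))
        assert np.array_equal(a.mass, b.mass)

    def test_spread_states_give_uniform_mass(self):
        states = [HostState(np.array([9 - k, k])) for k in range(10)]
        dist = empirical_distribution(states, FocalTarget.taxon(1, 1.0))
        assert dist.mass == pytest.approx(np.full(10, 0.1))

    def test_empty_space_target_uses_vacancy_counts(self):
        dist = empirical_distribution(
            [HostState(np.array([3, 7]))], FocalTarget.empty_space()
        )
        assert dist.mass[3] == 1.0

    def test_empty_collection_rejected(self):
        with pytest.raises(ValueError):
            empirical_distribution([], FocalTarget.taxon(1, 1.0))
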