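"""Tests for the stochastic community-assembly kernels."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from holosim.community import (
    Community,
    SourceSpec,
    allocate_counts,
    assemble_offspring,
    draw_from_sources,
    initial_colonization,
    renew_environment,
    sampling_probabilities,
    select_parents,
    within_host_update,
)

NEUTRAL_S = 1e12


class TestSamplingProbabilities:
    def test_uniform_fitness_gives_relative_abundance(self):
        p = sampling_probabilities(Community(np.array([2, 2])), np.array([1.0, 1.0]))
        assert p == pytest.approx([0.5, 0.5])

    def test_fitness_weighted(self):
        w = np.array([1.0, math.exp(-1.0)])
        p = sampling_probabilities(Community(np.array([1, 1])), w)
        expect = w / w.sum()
        assert p == pytest.approx(expect)
        assert p[0] == pytest.approx(0.7310585786, abs=1e-9)

    def test_single_taxon_degenerate(self):
        p = sampling_probabilities(Community(np.array([0, 5, 0])), np.ones(3))
        assert p == pytest.approx([0.0, 1.0, 0.0])

    def test_zero_weight_fallback_to_abundance(self):
        """If every fitness x abundance product underflows to zero, sampling
        falls back to relative abundance alone."""
        p = sampling_probabilities(Community(np.array([3, 1])), np.zeros(2))
        assert p == pytest.approx([0.75, 0.25])

    def test_empty_community_rejected(self):
        with pytest.raises(ValueError):
            sampling_probabilities(Community(np.array([0, 0])), np.ones(2))


class TestAllocateCounts:
    @pytest.mark.parametrize(
        "total, props, expected",
        [
            (100, [0.98, 0.02], [98, 2]),
            (10**8, [0.8, 0.05, 0.15], [8 * 10**7, 5 * 10**6, 15 * 10**6]),
            (3, [0.5, 0.5], [2, 1]),  # tie broken towards the first source
            (10, [1.0, 0.0], [10, 0]),
        ],
    )
    def test_examples(self, total, props, expected):
        assert allocate_counts(total, props).tolist() == expected

    @given(
        total=st.integers(0, 10**6),
        weights=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=6).filter(
            lambda w: sum(w) > 1e-6),
    )
    def test_sums_exactly_and_within_one(self, total, weights):
        p = np.array(weights) / sum(weights)
        alloc = allocate_counts(total, p)
        assert alloc.sum() == total
        assert np.all(np.abs(alloc - total * p) < 1.0 + 1e-9)

    def test_negative_proportions_rejected(self):
        with pytest.raises(ValueError):
            allocate_counts(10, [-0.1, 1.1])


class TestDrawFromSources:
    def test_single_taxon_monoculture(self, rng):
        out = draw_from_sources(
            [SourceSpec(Community(np.array([5])), np.ones(1), 42)], rng)
        assert out.counts.tolist() == [42]

    def test_disjoint_sources_conserve_per_source(self, rng):
        a = Community(np.array([10, 10, 0, 0]))
        b = Community(np.array([0, 0, 7, 3]))
        out = draw_from_sources(
            [SourceSpec(a, np.ones(4), 30), SourceSpec(b, np.ones(4), 70)], rng)
        assert out.counts[:2].sum() == 30
        assert out.counts[2:].sum() == 70

    def test_positive_allocation_from_empty_source_rejected(self, rng):
        with pytest.raises(ValueError):
            draw_from_sources(
                [SourceSpec(Community(np.array([0, 0])), np.ones(2), 5)], rng)

    def test_determinism(self):
        src = [SourceSpec(Community(np.array([3, 5, 2])), np.array([1.0, 0.5, 0.1]), 50)]
        a = draw_from_sources(src, np.random.default_rng(9))
        b = draw_from_sources(src, np.random.default_rng(9))
        assert np.array_equal(a.counts, b.counts)


class TestWithinHostUpdate:
    def test_full_retention_blocks_recruitment(self, rng):
        """P = 1: taxa absent from the host can never appear."""
        host = Community(np.array([50, 50, 0]))
        env = Community(np.array([0, 0, 100]))
        out = within_host_update(host, env, 1.0, 0.0, 0.0, np.zeros(3), 1.0, rng)
        assert out.counts[2] == 0
        assert out.total == 100

    def test_two_percent_environmental_acquisition(self, rng):
        """P = 0.98 with n_MH = 10^4 draws exactly 200 individuals from the
        environment source (visible via disjoint taxon sets)."""
        host = Community(np.array([5000, 5000, 0, 0]))
        env = Community(np.array([0, 0, 600, 400]))
        out = within_host_update(host, env, 0.98, 0.0, 0.0, np.zeros(4), 1.0, rng)
        assert out.counts[2:].sum() == 200
        assert out.counts[:2].sum() == 9800

    def test_source_context_switch_changes_env_weighting(self):
        """Under source-context fitness the environment source is weighted at
        E_tM rather than the within-host E_tMh."""
        phi = np.array([-2.0, 2.0])
        host = Community(np.array([1, 1]))
        env = Community(np.array([1, 1]))
        rng_a, rng_b = np.random.default_rng(1), np.random.default_rng(1)
        dest = within_host_update(host, env, 0.0, -2.0, 2.0, phi, 0.5, rng_a,
                                  fitness_context="destination")
        src = within_host_update(host, env, 0.0, -2.0, 2.0, phi, 0.5, rng_b,
                                 fitness_context="source")
        # destination context favours taxon 0 (matches E_tMh = -2);
        # source context favours taxon 1 (matches E_tM = +2)
        assert dest.counts[0] > dest.counts[1]
        assert src.counts[1] > src.counts[0]

    def test_binomial_allocation_mode_conserves_total(self, rng):
        host = Community(np.array([600, 400]))
        env = Community(np.array([500, 500]))
        out = within_host_update(host, env, 0.7, 0.0, 0.0, np.zeros(2), 1.0, rng,
                                 allocation_mode="binomial")
        assert out.total == 1000


class TestRenewEnvironment:
    def test_pure_persistence_keeps_support(self, rng):
        env = Community(np.array([900, 100, 0]))
        hosts = np.zeros((2, 3), dtype=np.int64)
        hosts[:, 2] = 50
        out = renew_environment(env, hosts, 1.0, 0.0, 0.0, np.zeros(3), NEUTRAL_S, rng)
        assert out.total == 1000
        assert out.counts[2] == 0  # Z = 1: no shedding, no fixed input

    def test_fixed_pool_only_tracks_fitness(self, rng):
        """Z = Y = 0: expected counts proportional to environmental fitness."""
        phi = np.array([0.0, 1.0])
        env = Community(np.array([500, 500]))
        hosts = np.array([[1, 1]], dtype=np.int64)
        n = 200
        totals = np.zeros(2)
        for _ in range(n):
            out = renew_environment(env, hosts, 0.0, 0.0, 0.0, phi, 1.0, rng)
            totals += out.counts
        w = np.exp(-phi**2)
        expect = w / w.sum()
        freq = totals / totals.sum()
        assert freq == pytest.approx(expect, abs=0.01)

    def test_invalid_zy_rejected(self, rng):
        with pytest.raises(ValueError):
            renew_environment(Community(np.array([10])), np.array([[1]]),
                              0.9, 0.2, 0.0, np.zeros(1), 1.0, rng)


class TestOffspringAssembly:
    def test_complete_vertical_inheritance(self, rng):
        parent = Community(np.array([70, 30, 0]))
        env = Community(np.array([0, 0, 100]))
        out = assemble_offspring(parent, env, 1.0, 0.0, 0.0, np.zeros(3), 1.0, rng)
        assert out.counts[2] == 0 and out.total == 100

    def test_fully_horizontal(self, rng):
        parent = Community(np.array([100, 0]))
        env = Community(np.array([0, 100]))
        out = assemble_offspring(parent, env, 0.0, 0.0, 0.0, np.zeros(2), 1.0, rng)
        assert out.counts.tolist() == [0, 100]

    def test_even_split_with_disjoint_sources(self, rng):
        # allocation is deterministic: exactly half from each disjoint source
        out = assemble_offspring(
            Community(np.array([10_000, 0])), Community(np.array([0, 10_000])),
            0.5, 0.0, 0.0, np.zeros(2), 1.0, rng)
        assert out.counts.tolist() == [5000, 5000]


class TestInitialColonization:
    def test_monoculture(self, rng):
        assert initial_colonization(17, 1, rng).counts.tolist() == [17]

    def test_counts_near_binomial_expectation(self, rng):
        n, k = 10**6, 200
        comm = initial_colonization(n, k, rng)
        sd = math.sqrt(n * (1 / k) * (1 - 1 / k))
        within = np.abs(comm.counts - n / k) <= 4 * sd
        assert within.mean() >= 0.9999 or within.sum() >= k - 1
        assert comm.total == n


class TestSelectParents:
    def test_uniform_fitness_is_neutral(self, rng):
        idx = select_parents(np.ones(100), rng)
        assert idx.shape == (100,)
        assert idx.min() >= 0 and idx.max() < 100

    def test_dominant_host_takes_all(self, rng):
        w = np.zeros(5)
        w[3] = 1.0
        assert np.all(select_parents(w, rng) == 3)

    def test_sampling_frequency_matches_fitness(self, rng):
        """Two hosts with fitness 1 and e^-1: host 0 is chosen with
        probability 1/(1 + e^-1) ~ 0.731."""
        w = np.array([1.0, math.exp(-1.0)])
        draws = np.concatenate([select_parents(w, rng) for _ in range(5000)])
        freq = np.mean(draws == 0)
        assert freq == pytest.approx(0.7310585786, abs=0.015)

    def test_all_zero_fitness_falls_back_to_uniform(self, rng):
        idx = select_parents(np.zeros(50), rng)
        assert len(np.unique(idx)) > 1


@given(
    n_taxa=st.integers(1, 8),
    host_total=st.integers(1, 300),
    env_total=st.integers(1, 300),
    P=st.floats(0.0, 1.0),
    E=st.floats(-2.5, 2.5),
)
def test_kernels_conserve_totals(n_taxa, host_total, env_total, P, E):
    """Every assembly kernel returns a community of exactly the declared size."""
    rng = np.random.default_rng(7)
    phi = rng.uniform(-2.5, 2.5, n_taxa)
    host = Community(rng.multinomial(host_total, np.full(n_taxa, 1 / n_taxa)))
    env = Community(rng.multinomial(env_total, np.full(n_taxa, 1 / n_taxa)))
    assert within_host_update(host, env, P, E, E, phi, 1.0, rng).total == host_total
    assert assemble_offspring(host, env, P, E, E, phi, 1.0, rng).total == host_total
    assert renew_environment(env, host.counts[None, :], 0.8, 0.05, E, phi, 1.0,
                             rng).total == env_total
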