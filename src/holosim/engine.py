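"""Simulation orchestration.

One host generation comprises ``T_M`` microbial generations followed by
host reproduction.  The birth of the generation counts as the first
microbial generation: the environmental pool is renewed at the first
microbial-resolution condition, and the generation's starting host
communities are the offspring microbiomes assembled at the end of the
previous generation.  Microbial generations 2..T_M each renew the
environmental pool and then resample every host's microbiome (retention
``P`` from the host, ``1 - P`` recruited from the environment).  With
``T_M = 1`` no within-host updates occur, so complete vertical
inheritance (``X = 1``) gives a host lineage no opportunity to recruit
new microbes at all.

After the last microbial generation, host phenotypes and fitnesses are
evaluated at the final microbial-resolution environmental value of the
generation (the most recent condition the holobiont experienced; equal
to the host-resolution value when ``T_M = 1``), metrics are recorded
prior to reproduction, parents are sampled with probability
proportional to fitness, and offspring microbiomes are assembled with
vertical proportion ``X`` from the post-renewal environmental pool.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .community import (
    Community,
    assemble_offspring,
    initial_colonization,
    renew_environment,
    select_parents,
    within_host_update,
)
from .config import SimulationConfig
from .environment import EnvironmentScenario, interpolate_series
from .fitness import gaussian_fitness, host_phenotype, internal_environment
from .metrics import MetricsRecord, mean_microbial_fitness, mean_scaled_shannon

__all__ = [
    "PopulationState",
    "initialize",
    "run_host_generation",
    "run_replicate",
    "neutral_coalescence_time",
    "mean_neutral_coalescence_time",
    "effective_inheritance_experiment",
]


@dataclass
class PopulationState:
    """Full mutable simulation state."""

    host_counts: np.ndarray      # (N_H, N_M) integer microbiome counts
    env_counts: np.ndarray       # (N_M,) environmental pool counts
    phi_m: np.ndarray            # (N_M,) microbial trait values
    phi_hg: np.ndarray           # (N_H,) host genetic traits
    generation: int = 0
    parent_indices: Optional[np.ndarray] = None  # parents of the current hosts

    @property
    def n_hosts(self) -> int:
        return self.host_counts.shape[0]


def initialize(config: SimulationConfig, rng: np.random.Generator) -> PopulationState:
    """Draw traits and colonize the first generation.

    Microbial trait values are drawn once, uniformly on
    ``[trait_min, trait_max]``.  The environmental pool starts with all
    taxa at approximately equal abundances, and each first-generation
    host acquires its microbiome from it multinomially with equal
    sampling probabilities — the only fitness-free sampling events in a
    simulation.
    """
    phi_m = rng.uniform(config.trait_min, config.trait_max, size=config.N_M)
    env = Community.uniform(config.n_ME, config.N_M, rng)
    hosts = np.empty((config.N_H, config.N_M), dtype=np.int64)
    for i in range(config.N_H):
        hosts[i] = initial_colonization(config.n_MH, config.N_M, rng).counts
    phi_hg = np.full(config.N_H, float(config.phi_hg))
    return PopulationState(host_counts=hosts, env_counts=env.counts,
                           phi_m=phi_m, phi_hg=phi_hg)


def run_host_generation(
    state: PopulationState,
    E_slice,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> MetricsRecord:
    """Advance the population by one host generation (mutates ``state``).

    ``E_slice`` holds the ``T_M`` microbial-resolution environmental
    values for this generation.  Returns the metrics recorded prior to
    reproduction; afterwards ``state`` holds the offspring generation
    and ``state.parent_indices`` the sampled parents.
    """
    E_slice = np.asarray(E_slice, dtype=float)
    if E_slice.size != config.T_M:
        raise ValueError(f"expected {config.T_M} environmental values, got {E_slice.size}")
    if not np.isfinite(E_slice).all():
        raise ValueError("environmental values must be finite")
    kw = dict(fitness_context=config.fitness_context, allocation_mode=config.allocation_mode)

    for k, E in enumerate(E_slice):
        env = renew_environment(
            Community(state.env_counts), state.host_counts,
            config.Z, config.Y, E, state.phi_m, config.s, rng,
            allocation_mode=config.allocation_mode,
        )
        state.env_counts = env.counts
        if k > 0:
            new_hosts = np.empty_like(state.host_counts)
            for i in range(state.n_hosts):
                e_h = internal_environment(state.phi_hg[i], E, config.I)
                new_hosts[i] = within_host_update(
                    Community(state.host_counts[i]), env,
                    config.P, e_h, E, state.phi_m, config.s, rng, **kw,
                ).counts
            state.host_counts = new_hosts

    E_sel = E_slice[-1] if config.selection_env == "final" else E_slice[0]
    totals = state.host_counts.sum(axis=1)
    phi_hM = state.host_counts @ state.phi_m / totals
    phi_h = host_phenotype(state.phi_hg, phi_hM, config.G)
    w_h = gaussian_fitness(phi_h, E_sel, config.s)
    e_tmh = internal_environment(state.phi_hg, E_sel, config.I)

    record = MetricsRecord(
        replicate=-1,
        scenario=config.scenario,
        X=config.X,
        T_M=config.T_M,
        host_generation=state.generation,
        is_burn_in=state.generation < config.burn_in,
        E_value=float(E_sel),
        mean_host_fitness=float(np.mean(w_h)),
        mean_microbe_fitness=mean_microbial_fitness(
            state.host_counts, state.phi_m, e_tmh, config.s),
        mean_alpha=mean_scaled_shannon(state.host_counts, config.N_M),
    )

    parents = select_parents(w_h, rng)
    env = Community(state.env_counts)
    offspring = np.empty_like(state.host_counts)
    for i, p in enumerate(parents):
        offspring[i] = assemble_offspring(
            Community(state.host_counts[p]), env,
            config.X, float(e_tmh[p]), E_sel, state.phi_m, config.s, rng, **kw,
        ).counts
    state.host_counts = offspring
    state.phi_hg = state.phi_hg[parents]
    state.parent_indices = parents
    state.generation += 1
    return record


def run_replicate(
    config: SimulationConfig,
    scenario: EnvironmentScenario,
    seed=None,
    rng: Optional[np.random.Generator] = None,
    replicate: int = 0,
    state: Optional[PopulationState] = None,
):
    """Run one full simulation replicate and return per-generation metrics.

    Burn-in generations (where the environmental series holds its
    stationary baseline behaviour) are included in the output and
    flagged via ``is_burn_in`` rather than discarded, so community
    stabilization can be inspected.
    """
    if len(scenario) != config.T_H:
        raise ValueError(
            f"scenario length {len(scenario)} does not match T_H={config.T_H}")
    if rng is None:
        rng = np.random.default_rng(seed)
    e_tm = interpolate_series(scenario.values, config.T_M)
    if state is None:
        state = initialize(config, rng)
    records = []
    for t in range(config.T_H):
        e_slice = e_tm[t * config.T_M:(t + 1) * config.T_M]
        rec = run_host_generation(state, e_slice, config, rng)
        rec.replicate = replicate
        records.append(rec)
    return records


def neutral_coalescence_time(n_hosts: int, rng: np.random.Generator,
                             max_generations: int = 100_000) -> int:
    """Generations until all hosts descend from a single founder under neutrality.

    Runs fitness-proportional parent selection with uniform fitness
    (neutral Wright-Fisher reproduction) forward in time, propagating
    founder labels, and returns the first generation at which only one
    founder label survives.  For a haploid population of size ``N`` the
    expectation is approximately ``2 N`` generations — the rationale for
    a burn-in of twice the host population size.
    """
    uniform = np.ones(n_hosts)
    labels = np.arange(n_hosts)
    for t in range(1, max_generations + 1):
        labels = labels[select_parents(uniform, rng)]
        if (labels == labels[0]).all():
            return t
    raise RuntimeError(f"no coalescence within {max_generations} generations")


def mean_neutral_coalescence_time(n_hosts: int, replicates: int,
                                  rng: np.random.Generator) -> float:
    """Mean of :func:`neutral_coalescence_time` over independent replicates."""
    times = [neutral_coalescence_time(n_hosts, rng) for _ in range(replicates)]
    return float(np.mean(times))


def effective_inheritance_experiment(
    *,
    n_hosts: int,
    n_taxa: int,
    n_MH: int,
    n_ME: int,
    X: float,
    P: float,
    T_M: int,
    s: float,
    E: float = 0.0,
    I: float = 0.5,
    phi_hg: float = 0.0,
    rng: np.random.Generator,
    trait_min: float = -2.5,
    trait_max: float = 2.5,
) -> np.ndarray:
    """Track parental-origin microbes through one host generation.

    Each host is born with proportion ``X`` of its microbiome drawn from
    a parent community (tagged) and ``1 - X`` from the environment
    (untagged), then undergoes ``T_M - 1`` within-host generations with
    retention ``P``.  Tags propagate by treating tagged and untagged
    copies of each taxon as separate sampling categories, so the tagged
    fraction at the end is the realized effective vertical inheritance.
    The environmental pool is held static (uniform) for the duration.

    Returns the per-host tagged-count matrix of shape
    ``(n_hosts, 2 * n_taxa)``: first block parent-descended, second
    block environment-descended.  Under neutral sampling the expected
    tagged fraction is ``X * P**(T_M - 1)``.
    """
    phi_m = rng.uniform(trait_min, trait_max, size=n_taxa)
    ext_phi = np.concatenate([phi_m, phi_m])
    env = Community.uniform(n_ME, n_taxa, rng)
    env_ext = Community(np.concatenate([np.zeros(n_taxa, dtype=np.int64), env.counts]))
    e_h = internal_environment(phi_hg, E, I)
    out = np.empty((n_hosts, 2 * n_taxa), dtype=np.int64)
    for h in range(n_hosts):
        parent = initial_colonization(n_MH, n_taxa, rng)
        parent_ext = Community(
            np.concatenate([parent.counts, np.zeros(n_taxa, dtype=np.int64)]))
        comm = assemble_offspring(parent_ext, env_ext, X, e_h, E, ext_phi, s, rng)
        for _ in range(T_M - 1):
            comm = within_host_update(comm, env_ext, P, e_h, E, ext_phi, s, rng)
        out[h] = comm.counts
    return out
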