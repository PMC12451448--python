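"""Stochastic community-assembly kernels.

Communities are fixed-size multisets over ``N_M`` microbial taxa,
represented as integer count vectors.  Every assembly event in the model
is a fitness-weighted multinomial draw: the probability of sampling taxon
``m`` from a source community is proportional to the product of its
fitness (in the *destination* context, by default) and its relative
abundance in the source.  A destination built from several sources draws
a fixed integer allocation from each (largest-remainder rounding of the
stated proportions) so that the community total is conserved exactly.

Kernels provided:

- :func:`renew_environment` — environmental pool renewal from its own
  previous state (``Z``), host shedding (``Y``) and a fixed uniform pool
  (``1 - Z - Y``);
- :func:`within_host_update` — one within-host microbial generation,
  retaining proportion ``P`` from the host and ``1 - P`` from the
  environment;
- :func:`assemble_offspring` — microbiome acquisition at host birth,
  ``X`` from the parent and ``1 - X`` from the environment;
- :func:`initial_colonization` — fitness-free uniform colonization of
  the very first generation;
- :func:`select_parents` — fitness-proportional Wright-Fisher host
  reproduction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .fitness import gaussian_fitness

logger = logging.getLogger(__name__)

__all__ = [
    "Community",
    "SourceSpec",
    "sampling_probabilities",
    "allocate_counts",
    "draw_from_sources",
    "renew_environment",
    "within_host_update",
    "assemble_offspring",
    "initial_colonization",
    "select_parents",
]


@dataclass
class Community:
    """Integer abundance vector over the global taxon pool.

    The community size (``total``) is fixed by construction: every
    kernel returns a community whose counts sum exactly to the declared
    destination size.
    """

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.ndim != 1:
            raise ValueError("community counts must be a 1-D vector")
        if (self.counts < 0).any():
            raise ValueError("community counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def richness(self) -> int:
        """Number of taxa with non-zero abundance."""
        return int((self.counts > 0).sum())

    @classmethod
    def uniform(cls, total: int, n_taxa: int, rng: np.random.Generator) -> "Community":
        """Multinomial draw of ``total`` individuals with equal taxon probabilities."""
        if total < 1 or n_taxa < 1:
            raise ValueError("total and n_taxa must be >= 1")
        return cls(rng.multinomial(total, np.full(n_taxa, 1.0 / n_taxa)))


@dataclass
class SourceSpec:
    """One source feeding a multinomial assembly event.

    ``fitness`` is the per-taxon fitness vector evaluated in the
    destination context; ``allocation`` is the integer number of
    individuals to draw from this source.
    """

    community: Community
    fitness: np.ndarray
    allocation: int = field(default=0)


def sampling_probabilities(community: Community, fitness) -> np.ndarray:
    """Per-taxon sampling probabilities: fitness x relative abundance, normalized.

    If every product underflows to zero (extreme trait-environment
    mismatch), sampling falls back to relative abundance alone so the
    process stays defined without favouring any taxon.
    """
    counts = community.counts
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot sample from an empty community")
    fitness = np.asarray(fitness, dtype=float)
    if (fitness < 0).any():
        raise ValueError("fitness values must be non-negative")
    weights = fitness * (counts / total)
    wsum = weights.sum()
    if wsum <= 0 or not np.isfinite(wsum):
        logger.warning(
            "all fitness x abundance weights are zero; falling back to relative abundance"
        )
        weights = counts / total
        wsum = weights.sum()
    return weights / wsum


def allocate_counts(total: int, proportions) -> np.ndarray:
    """Convert source proportions into integers summing exactly to ``total``.

    Largest-remainder rounding: each allocation is within 1 of
    ``total * proportion``; remainder units go to the largest fractional
    parts, ties broken by ascending source index (host/parent source
    first, by argument order).
    """
    p = np.asarray(proportions, dtype=float)
    if (p < 0).any():
        raise ValueError("proportions must be non-negative")
    psum = p.sum()
    if not np.isclose(psum, 1.0, atol=1e-9):
        raise ValueError(f"proportions must sum to 1, got {psum}")
    exact = total * p
    base = np.floor(exact).astype(np.int64)
    remainder = int(total - base.sum())
    if remainder > 0:
        frac = exact - base
        # descending fractional part; ascending index breaks ties
        order = np.lexsort((np.arange(p.size), -frac))
        base[order[:remainder]] += 1
    return base


def draw_from_sources(sources, rng: np.random.Generator) -> Community:
    """Multinomial draw of each source's allocation, summed across sources."""
    out = None
    for src in sources:
        if src.allocation < 0:
            raise ValueError("allocations must be non-negative")
        if src.allocation == 0:
            if out is None:
                out = np.zeros(src.community.counts.size, dtype=np.int64)
            continue
        if src.community.total == 0:
            raise ValueError("cannot draw a positive allocation from an empty source")
        p = sampling_probabilities(src.community, src.fitness)
        draw = rng.multinomial(src.allocation, p / p.sum())
        out = draw if out is None else out + draw
    if out is None:
        raise ValueError("no sources given")
    return Community(out)


def _allocations(total, proportions, rng, mode):
    if mode == "deterministic":
        return allocate_counts(total, proportions)
    if mode == "binomial":
        return rng.multinomial(total, np.asarray(proportions, dtype=float))
    raise ValueError(f"unknown allocation mode {mode!r}")


def renew_environment(
    env: Community,
    host_counts,
    Z: float,
    Y: float,
    E_tM: float,
    phi_m,
    s: float,
    rng: np.random.Generator,
    allocation_mode: str = "deterministic",
) -> Community:
    """Renew the environmental pool for one microbial generation.

    The new pool of size ``n_ME`` is assembled from three sources, in
    this order: the previous pool (proportion ``Z``), the pooled sum of
    all current host microbiomes (``Y``, host shedding), and a fixed
    pool with all taxa equally abundant (``1 - Z - Y``).  All three
    sources are weighted by microbial fitness in the environment at the
    current condition ``E_tM``.

    Parameters
    ----------
    host_counts : array_like, shape (N_H, N_M) or (N_M,)
        Current host community counts; summed over hosts for shedding.
    """
    if Z < 0 or Y < 0 or Z + Y > 1 + 1e-12:
        raise ValueError(f"need Z, Y >= 0 and Z + Y <= 1, got Z={Z}, Y={Y}")
    n_me = env.total
    n_taxa = env.counts.size
    w = gaussian_fitness(phi_m, E_tM, s)
    pooled = np.asarray(host_counts, dtype=np.int64)
    if pooled.ndim == 2:
        pooled = pooled.sum(axis=0)
    alloc = _allocations(n_me, [Z, Y, 1.0 - Z - Y], rng, allocation_mode)
    sources = [
        SourceSpec(env, w, int(alloc[0])),
        SourceSpec(Community(pooled), w, int(alloc[1])),
        SourceSpec(Community(np.ones(n_taxa, dtype=np.int64)), w, int(alloc[2])),
    ]
    return draw_from_sources(sources, rng)


def within_host_update(
    host: Community,
    env: Community,
    P: float,
    E_tMh: float,
    E_tM: float,
    phi_m,
    s: float,
    rng: np.random.Generator,
    fitness_context: str = "destination",
    allocation_mode: str = "deterministic",
) -> Community:
    """One within-host microbial generation.

    The new microbiome of size ``n_MH`` draws proportion ``P`` from the
    host's previous community and ``1 - P`` from the environment.  Under
    the default destination-context weighting both sources use microbial
    fitness at the composite within-host condition ``E_tMh`` (the host
    filters environmental colonizers).  With ``fitness_context='source'``
    the environmental source is instead weighted at the external
    condition ``E_tM``.
    """
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"retention proportion must be in [0, 1], got {P}")
    if fitness_context not in ("destination", "source"):
        raise ValueError(f"unknown fitness context {fitness_context!r}")
    phi_m = np.asarray(phi_m, dtype=float)
    w_host_ctx = gaussian_fitness(phi_m, E_tMh, s)
    w_env_src = w_host_ctx if fitness_context == "destination" else gaussian_fitness(phi_m, E_tM, s)
    alloc = _allocations(host.total, [P, 1.0 - P], rng, allocation_mode)
    sources = [
        SourceSpec(host, w_host_ctx, int(alloc[0])),
        SourceSpec(env, w_env_src, int(alloc[1])),
    ]
    return draw_from_sources(sources, rng)


def assemble_offspring(
    parent: Community,
    env: Community,
    X: float,
    E_tMh: float,
    E_tM: float,
    phi_m,
    s: float,
    rng: np.random.Generator,
    fitness_context: str = "destination",
    allocation_mode: str = "deterministic",
) -> Community:
    """Microbiome acquisition at host birth.

    Identical mechanics to :func:`within_host_update` with the vertical
    inheritance proportion ``X`` in place of ``P`` and the parent as the
    host-side source.
    """
    if not 0.0 <= X <= 1.0:
        raise ValueError(f"vertical inheritance proportion must be in [0, 1], got {X}")
    return within_host_update(
        parent, env, X, E_tMh, E_tM, phi_m, s, rng,
        fitness_context=fitness_context, allocation_mode=allocation_mode,
    )


def initial_colonization(n: int, n_taxa: int, rng: np.random.Generator) -> Community:
    """Fitness-free uniform multinomial colonization (first generation only)."""
    return Community.uniform(n, n_taxa, rng)


def select_parents(host_fitnesses, rng: np.random.Generator) -> np.ndarray:
    """Fitness-proportional parent sampling with replacement.

    Returns ``N_H`` parent indices drawn with probability proportional
    to fitness (Wright-Fisher reproduction; uniform fitness gives the
    neutral model).  If every fitness underflows to zero, sampling falls
    back to uniform.
    """
    w = np.asarray(host_fitnesses, dtype=float)
    if (w < 0).any():
        raise ValueError("host fitnesses must be non-negative")
    n = w.size
    total = w.sum()
    if total <= 0 or not np.isfinite(total):
        logger.warning("all host fitnesses are zero; falling back to uniform reproduction")
        p = np.full(n, 1.0 / n)
    else:
        p = w / total
    return rng.choice(n, size=n, replace=True, p=p)
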