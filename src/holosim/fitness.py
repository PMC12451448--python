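"""Fitness and phenotype equations.

All selection in the model is Gaussian stabilizing selection towards an
environmental optimum: an individual (microbe or host) with trait value
``phi`` in an environment with condition ``E`` has fitness

    w = exp(-(phi - E)^2 / s)

where ``s > 0`` sets the strength of selection (small ``s`` = strong
selection; very large ``s`` approaches neutrality).  The same functional
form is used for microbes inside hosts, microbes in the environmental
pool, and hosts themselves; only the relevant environmental condition
changes.

Host-level quantities are convex combinations: the within-host
environment mixes the host genetic trait with the external condition
(weight ``I``), and the host phenotype mixes the host genetic trait with
the mean trait of its microbiome (weight ``G``).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "gaussian_fitness",
    "internal_environment",
    "host_phenotype",
    "mean_microbiome_trait",
]


def gaussian_fitness(phi, E, s):
    """Stabilizing-selection fitness ``exp(-(phi - E)^2 / s)``.

    Parameters
    ----------
    phi : float or array_like
        Trait value(s).
    E : float or array_like
        Environmental condition (the trait value that maximizes fitness).
    s : float
        Selection parameter, strictly positive.  Smaller values mean
        stronger selection; very large values approach neutrality.

    Returns
    -------
    float or ndarray
        Fitness in ``(0, 1]``; equals 1 iff ``phi == E``.
    """
    if s <= 0:
        raise ValueError(f"selection parameter s must be > 0, got {s}")
    phi = np.asarray(phi, dtype=float)
    E = np.asarray(E, dtype=float)
    out = np.exp(-((phi - E) ** 2) / s)
    return float(out) if out.ndim == 0 else out


def internal_environment(phi_hg, E_tM, I):
    """Composite within-host environment ``I*phi_hg + (1 - I)*E_tM``.

    ``I`` weights the host genetic trait against the current external
    condition; ``I = 0`` exposes within-host microbes to the external
    environment directly, ``I = 1`` isolates them entirely behind the
    host genotype.
    """
    if not 0.0 <= I <= 1.0:
        raise ValueError(f"internal-environment weighting I must be in [0, 1], got {I}")
    return I * np.asarray(phi_hg, dtype=float) + (1.0 - I) * np.asarray(E_tM, dtype=float)


def host_phenotype(phi_hg, phi_hM, G):
    """Host phenotype ``G*phi_hg + (1 - G)*phi_hM``.

    ``G = 0`` makes host fitness depend only on the microbiome's mean
    trait; ``G = 1`` makes it depend only on the host's own genetic
    trait (the microbiome-independent baseline).
    """
    if not 0.0 <= G <= 1.0:
        raise ValueError(f"host-genetic weighting G must be in [0, 1], got {G}")
    return G * np.asarray(phi_hg, dtype=float) + (1.0 - G) * np.asarray(phi_hM, dtype=float)


def mean_microbiome_trait(community, phi_m):
    """Abundance-weighted mean microbial trait of a community.

    Each microbial individual contributes equally, so the mean is
    ``sum(n_m * phi_m) / sum(n_m)`` over taxa.
    """
    counts = np.asarray(getattr(community, "counts", community), dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot compute mean trait of an empty community")
    return float(counts @ np.asarray(phi_m, dtype=float) / total)
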