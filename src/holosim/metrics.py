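"""Diversity and fitness summaries, vertical-inheritance accounting, tidy output.

Per host generation the simulation records, immediately prior to host
reproduction: mean host fitness, mean within-host microbial fitness
(abundance-weighted, then averaged over hosts), and mean within-host
alpha diversity as the scaled Shannon-Wiener index
``H / ln(N_M)`` where ``H = -sum p_m ln p_m``.  The scaling denominator
is the log of the *global* taxon pool size, so permanent taxon loss
lowers the index even if the surviving taxa are perfectly even.

"Effective vertical inheritance" is the fraction of a host's microbiome
at reproduction that descends from the parentally acquired microbes.
Under neutral sampling its expectation has the closed form
``X * P**(T_M - 1)``: the birth draw contributes ``X``, and each of the
``T_M - 1`` within-host generations retains proportion ``P``.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import entropy

from .fitness import gaussian_fitness

__all__ = [
    "MetricsRecord",
    "scaled_shannon",
    "mean_microbial_fitness",
    "expected_effective_vertical_inheritance",
    "realized_vertical_inheritance",
    "records_to_frame",
    "write_metrics",
    "read_metrics",
]

METRICS_COLUMNS = (
    "replicate", "scenario", "X", "T_M", "host_generation", "is_burn_in",
    "E_value", "mean_host_fitness", "mean_microbe_fitness", "mean_alpha",
)


@dataclass
class MetricsRecord:
    """Per-host-generation summary row."""

    replicate: int
    scenario: str
    X: float
    T_M: int
    host_generation: int
    is_burn_in: bool
    E_value: float
    mean_host_fitness: float
    mean_microbe_fitness: float
    mean_alpha: float


def scaled_shannon(community, N_M: int) -> float:
    """Shannon entropy of taxon relative abundances, scaled to [0, 1].

    ``H = -sum_{m: n_m > 0} p_m ln p_m`` divided by its maximum
    ``ln(N_M)`` over the global pool of ``N_M`` taxa.  A perfectly even
    community over all taxa scores 1; a monoculture scores 0; any
    community missing taxa scores strictly below 1.
    """
    counts = np.asarray(getattr(community, "counts", community), dtype=float)
    if counts.sum() <= 0:
        raise ValueError("cannot compute diversity of an empty community")
    if N_M < 2:
        raise ValueError(f"N_M must be >= 2, got {N_M}")
    return float(entropy(counts) / np.log(N_M))


def mean_scaled_shannon(host_counts, N_M: int) -> float:
    """Mean scaled Shannon index over hosts (rows of a count matrix)."""
    counts = np.asarray(host_counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    return float(np.mean(entropy(counts, axis=1) / np.log(N_M)))


def mean_microbial_fitness(host_counts, phi_m, E_tMh, s: float) -> float:
    """Mean within-host microbial fitness, averaged over hosts.

    Per host: ``sum_m n_m * w_m / n_MH`` with ``w_m`` the Gaussian
    fitness of taxon ``m`` at that host's composite internal condition.

    Parameters
    ----------
    host_counts : array_like, shape (N_H, N_M) or (N_M,)
    E_tMh : float or array_like of shape (N_H,)
        Composite within-host environmental condition per host.
    """
    counts = np.asarray(host_counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all host communities must be non-empty")
    e = np.broadcast_to(np.asarray(E_tMh, dtype=float), (counts.shape[0],))
    w = gaussian_fitness(np.asarray(phi_m, dtype=float)[None, :], e[:, None], s)
    return float(np.mean((counts * w).sum(axis=1) / totals))


def expected_effective_vertical_inheritance(X: float, P: float, T_M: int) -> float:
    """Closed-form expected parental-origin fraction at host reproduction.

    ``X * P**(T_M - 1)`` under neutral sampling: the birth draw takes
    proportion ``X`` from the parent, and each of the ``T_M - 1``
    subsequent within-host generations retains proportion ``P`` of the
    standing community in expectation.
    """
    if not 0.0 <= X <= 1.0 or not 0.0 <= P <= 1.0:
        raise ValueError("X and P must be proportions in [0, 1]")
    if T_M < 1:
        raise ValueError(f"T_M must be >= 1, got {T_M}")
    return X * P ** (T_M - 1)


def realized_vertical_inheritance(tagged_counts, n_taxa: int) -> float:
    """Mean parental-origin fraction from tagged community counts.

    ``tagged_counts`` holds one row per host over ``2 * n_taxa``
    categories: the first ``n_taxa`` are parent-descended (tagged)
    copies of each taxon, the second ``n_taxa`` environment-descended
    copies.  Returns the mean tagged fraction over hosts.
    """
    counts = np.asarray(tagged_counts, dtype=float)
    if counts.ndim == 1:
        counts = counts[None, :]
    if counts.shape[1] != 2 * n_taxa:
        raise ValueError("tagged counts must have 2 * n_taxa categories")
    totals = counts.sum(axis=1)
    if (totals <= 0).any():
        raise ValueError("all host communities must be non-empty")
    return float(np.mean(counts[:, :n_taxa].sum(axis=1) / totals))


def records_to_frame(records) -> pd.DataFrame:
    """Convert MetricsRecord rows to a tidy DataFrame with fixed column order."""
    if not records:
        raise ValueError("no records to convert")
    df = pd.DataFrame([
        {f.name: getattr(r, f.name) for f in fields(MetricsRecord)} for r in records
    ])
    return df[list(METRICS_COLUMNS)]


def write_metrics(records, path) -> None:
    """Write records as tidy delimited text; numbers round-trip at full precision."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    df.to_csv(path, index=False, float_format="%.17g")


def read_metrics(path) -> pd.DataFrame:
    """Read a metrics file written by :func:`write_metrics`."""
    return pd.read_csv(path, float_precision="round_trip")
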