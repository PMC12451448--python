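"""Environmental-scenario generation and microbial-resolution interpolation.

Six scenarios of environmental change are supported, crossed from three
trajectories of the per-generation mean/variance and two noise types:

====  ==========================================================
kind  description
====  ==========================================================
1A    unchanging mean, autocorrelated (predictable) fluctuations
1B    unchanging mean, independent (random) fluctuations
2A    mean ramps linearly upward after burn-in, autocorrelated
2B    mean ramps linearly upward after burn-in, random
3A    variance ramps linearly upward after burn-in, autocorrelated
3B    variance ramps linearly upward after burn-in, random
====  ==========================================================

Type A series follow an AR(1) process around the (possibly moving)
mean, ``E_t = mu_t + rho * (E_{t-1} - mu_{t-1}) + eps_t`` with
``eps_t ~ Normal(0, sigma_t^2 * (1 - rho^2))`` so that the marginal
standard deviation is ``sigma_t``; type B draws each deviation
independently with the same marginal SD.  A and B therefore differ only
in predictability, not in the amount of variation.

During burn-in every scenario behaves like scenario 1 (mean 0, SD
``sigma0``); trend and variance ramps begin after burn-in.

An environmental series has one value per *host* generation.  When a
host generation contains ``T_M`` microbial generations, the series is
linearly interpolated so microbes experience environmental change at
their own timescale: within host generation ``t`` the microbial values
are ``E[t] + k * (E[t+1] - E[t]) / T_M`` for ``k = 0 .. T_M - 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

SCENARIO_KINDS = ("1A", "1B", "2A", "2B", "3A", "3B")

#: Default scenario parameters.  rho is the lag-1 autocorrelation of
#: type-A series; sigma0 the baseline fluctuation SD; mu_max the final
#: mean under scenario 2; sigma_max the final SD under scenario 3.
#: Series are clipped to the trait range by default so environmental
#: optima stay inside the range of simulated microbial trait values.
DEFAULT_PARAMS = {
    "rho": 0.9,
    "sigma0": 0.5,
    "mu_max": 2.0,
    "sigma_max": 1.5,
    "clip": True,
    "clip_min": -2.5,
    "clip_max": 2.5,
}

__all__ = [
    "SCENARIO_KINDS",
    "DEFAULT_PARAMS",
    "EnvironmentScenario",
    "scenario_moments",
    "generate_series",
    "interpolate_series",
    "write_series",
    "read_series",
]


@dataclass
class EnvironmentScenario:
    """A host-resolution environmental series and how it was generated."""

    kind: str
    values: np.ndarray
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in SCENARIO_KINDS:
            raise ValueError(f"unknown scenario kind {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)

    def __len__(self) -> int:
        return self.values.size


def scenario_moments(kind, T_H, burn_in, sigma0, mu_max, sigma_max):
    """Per-generation mean and SD targets for a scenario.

    Burn-in generations always use mean 0 and SD ``sigma0``; scenario 2
    ramps the mean linearly from 0 (end of burn-in) to ``mu_max`` (last
    generation), scenario 3 ramps the SD from ``sigma0`` to
    ``sigma_max`` over the same interval.
    """
    if kind not in SCENARIO_KINDS:
        raise ValueError(f"unknown scenario kind {kind!r}")
    if not 0 <= burn_in <= T_H:
        raise ValueError(f"need 0 <= burn_in <= T_H, got burn_in={burn_in}, T_H={T_H}")
    mu = np.zeros(T_H)
    sigma = np.full(T_H, float(sigma0))
    span = T_H - 1 - burn_in
    if span > 0:
        ramp = (np.arange(burn_in, T_H) - burn_in) / span
    elif T_H > burn_in:
        ramp = np.ones(T_H - burn_in)
    else:
        ramp = np.zeros(0)
    if kind[0] == "2":
        mu[burn_in:] = mu_max * ramp
    elif kind[0] == "3":
        sigma[burn_in:] = sigma0 + (sigma_max - sigma0) * ramp
    return mu, sigma


def generate_series(kind, T_H, burn_in, params=None, rng=None) -> EnvironmentScenario:
    """Generate a host-resolution environmental series for one scenario.

    Parameters
    ----------
    kind : str
        One of ``1A, 1B, 2A, 2B, 3A, 3B``.
    T_H : int
        Number of host generations (series length); burn-in generations
        are included within it.
    burn_in : int
        Host generations before trend/variance ramps begin.
    params : dict, optional
        Overrides of :data:`DEFAULT_PARAMS`.
    rng : numpy.random.Generator
    """
    if rng is None:
        rng = np.random.default_rng()
    p = dict(DEFAULT_PARAMS)
    if params:
        unknown = set(params) - set(DEFAULT_PARAMS)
        if unknown:
            raise ValueError(f"unknown scenario parameters: {sorted(unknown)}")
        p.update(params)
    rho = float(p["rho"])
    sigma0 = float(p["sigma0"])
    if not 0.0 <= rho < 1.0:
        raise ValueError(f"autocorrelation rho must be in [0, 1), got {rho}")
    if sigma0 < 0 or p["sigma_max"] < 0:
        raise ValueError("fluctuation SDs must be non-negative")
    mu, sigma = scenario_moments(kind, T_H, burn_in, sigma0, p["mu_max"], p["sigma_max"])

    autocorrelated = kind[1] == "A"
    e = np.empty(T_H)
    if autocorrelated:
        innov_scale = np.sqrt(1.0 - rho * rho)
        # initialize at the stationary marginal distribution
        dev = rng.normal(0.0, sigma[0]) if T_H else 0.0
        for t in range(T_H):
            if t > 0:
                dev = rho * dev + rng.normal(0.0, sigma[t] * innov_scale)
            e[t] = mu[t] + dev
    else:
        e = mu + rng.normal(0.0, 1.0, size=T_H) * sigma
    if p["clip"]:
        np.clip(e, p["clip_min"], p["clip_max"], out=e)
    return EnvironmentScenario(kind=kind, values=e, params=p)


def interpolate_series(E_tH, T_M: int) -> np.ndarray:
    """Linearly interpolate a host-resolution series to microbial resolution.

    For each host generation ``t`` the microbial values are the
    arithmetic progression from ``E[t]`` with step
    ``(E[t+1] - E[t]) / T_M`` (``T_M`` values, endpoint exclusive).  The
    final host generation has no successor and is held constant.  For
    ``T_M = 1`` the output equals the input.

    Returns an array of length ``len(E_tH) * T_M``.
    """
    if T_M < 1:
        raise ValueError(f"microbial generation count must be >= 1, got {T_M}")
    e = np.asarray(E_tH, dtype=float)
    if e.ndim != 1 or e.size < 1:
        raise ValueError("series must be a non-empty 1-D array")
    steps = np.append(np.diff(e), 0.0) / T_M
    k = np.arange(T_M, dtype=float)
    return (e[:, None] + steps[:, None] * k[None, :]).ravel()


def write_series(path, scenario: EnvironmentScenario) -> None:
    """Write a series as two-column delimited text (index, value) at full precision."""
    idx = np.arange(len(scenario))
    header = f"kind={scenario.kind}\ngeneration\tE"
    np.savetxt(
        path,
        np.column_stack([idx, scenario.values]),
        fmt=("%d", "%.17g"),
        delimiter="\t",
        header=header,
    )


def read_series(path) -> EnvironmentScenario:
    """Read a series written by :func:`write_series`."""
    with open(path) as fh:
        first = fh.readline().strip()
    kind = first.lstrip("# ").split("=", 1)[1] if "kind=" in first else "1A"
    data = np.loadtxt(path, delimiter="\t", skiprows=2, ndmin=2)
    return EnvironmentScenario(kind=kind, values=data[:, 1])
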