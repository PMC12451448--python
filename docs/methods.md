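# Methods

## Model structure

The simulator couples two Wright–Fisher-style processes. Hosts form a
constant-sized haploid population of `N_H` individuals with non-overlapping
generations and clonal, fitness-proportional reproduction. Microbes form
fixed-size communities — `n_MH` individuals per host, `n_ME` in a shared
environmental pool — over a global pool of `N_M` taxa, also with
non-overlapping generations. There is no mutation and no within-taxon
variation: taxa are characterized entirely by a fixed trait value `phi_m`
drawn once per replicate from U(`trait_min`, `trait_max`).

All selection is Gaussian stabilizing selection,
`w = exp(-(phi - E)^2 / s)`, towards the current environmental condition.
Microbes in the environmental pool are selected on the external condition
`E_tM`; microbes inside a host on the composite condition
`E_tMh = I*phi_hg + (1 - I)*E_tM`; hosts on the match between their
phenotype `phi_h = G*phi_hg + (1 - G)*phi_hM` and the environment. With the
default `G = 0` and `phi_hg = 0`, host fitness derives entirely from the
abundance-weighted mean trait of the microbiome, so hosts have no adaptive
capacity of their own — the configuration used throughout unless a
microbiome-free baseline (`G = 1`) is wanted.

Every assembly event is a multinomial draw in which taxon `m`'s sampling
probability is proportional to `fitness_m x relative abundance_m` in the
source. A destination fed by several sources (e.g. the environmental pool
from persistence `Z`, host shedding `Y`, and the fixed pool `1 - Z - Y`)
draws a fixed integer allocation from each.

## Generation accounting

The birth of a host generation counts as its first microbial generation:
offspring assembly (proportion `X` from the parent, `1 - X` from the
environment) is microbial generation 1, and within-host updates (retention
`P`, recruitment `1 - P`) run `T_M - 1` times. This is the only accounting
under which complete vertical inheritance with `T_M = 1` gives a host
lineage literally no opportunity to recruit microbes — the regime in which
diversity can only decline — which the model treats as a defining boundary
case. The environmental pool is renewed once per microbial generation,
including the birth step, and host shedding uses the communities from the
previous microbial step (pool renewal precedes host updates within a step).

Host selection evaluates fitness at the final microbial-resolution
environmental value of the generation — the most recent condition the
holobiont experienced — which coincides with the host-resolution value when
`T_M = 1`. A `selection_env="start"` switch exposes the alternative for
sensitivity analysis.

## Fitness context of sampling

When sampling into a host, both the host-side and environment-side sources
are weighted by within-host fitness at `E_tMh` (destination context): the
host "filters" environmental colonizers by its internal conditions. The
alternative — weighting each source by fitness in that source's own context
— is available as `fitness_context="source"`. Destination weighting is the
default because recruitment into a host is survival in the host, and host
filtering of colonizers over multiple microbial generations is the
mechanism the model is built to express.

## Integer allocation

Stated proportions (`X`, `P`, `Z`, `Y`) are converted to integer source
allocations by largest-remainder rounding, ties broken towards the
first-listed source (host/parent first). This makes the source split
deterministic and exact — with `P = 0.98` and `n_MH = 10^4`, exactly 200
individuals per update come from the environment — and keeps community
totals conserved without rejection steps. A `allocation_mode="binomial"`
switch draws allocations multinomially instead, for checking that results
do not hinge on the deterministic split.

If every `fitness x abundance` product in a source underflows to zero
(extreme trait-environment mismatch at strong selection), sampling falls
back to relative abundance alone and a warning is logged; this keeps the
process defined without biasing among taxa.

## Environmental scenarios

Six scenarios cross three mean/variance trajectories with two noise types.
Each series has one value per host generation; burn-in generations always
behave like the stationary scenario (mean 0, SD `sigma0`), with trend or
variance ramps starting after burn-in and reaching their final value
(`mu_max`, `sigma_max`) at the last generation. Type A series are AR(1),
`E_t = mu_t + rho*(E_{t-1} - mu_{t-1}) + eps_t` with innovation variance
`sigma_t^2 (1 - rho^2)` so the marginal SD equals `sigma_t`; type B draws
deviations independently with the same marginal SD. A and B therefore
differ only in predictability, which is the contrast of interest.

Defaults: `rho = 0.9`, `sigma0 = 0.5`, `mu_max = 2.0`, `sigma_max = 1.5`,
values clipped to the trait range [−2.5, 2.5] (so environmental optima stay
attainable by some taxon). These are package choices of a plausible
parameterization — fluctuations at 10% of the trait range, a mean shift
spanning most of the positive half-range — and are fully configurable;
conclusions about A-vs-B contrasts should be read relative to this
parameterization. Burn-in generations are included within `T_H` (the first
`burn_in` of them), and series are interpolated to microbial resolution by
exact linear interpolation with `T_M` steps per host generation, the final
generation held constant (no successor to interpolate towards; this affects
only the last `T_M` microbial steps).

Series are generated per (scenario, replicate) from a seed that ignores
`X` and `T_M`, so every transmission setting of a replicate experiences the
identical environment — the sharing design that makes settings comparable
within a replicate.

## Diversity metric

Alpha diversity is the Shannon entropy of within-host relative abundances
scaled by its maximum over the *global* taxon pool, `H / ln(N_M)`, averaged
over hosts. Scaling by `ln(N_M)` rather than by observed richness makes
permanent taxon loss depress the index even when the survivors are even —
the behaviour needed for loss-only regimes to register as diversity
decline. Natural log; the scaling cancels the base.

## Effective vertical inheritance

The expected fraction of a host's microbiome at reproduction descending
from the parental inoculum is `X * P^(T_M - 1)` under neutral sampling (the
birth draw contributes `X`; each within-host update retains `P` in
expectation). The realized fraction is measured by a tagged-lineage
experiment that doubles the category space to (taxon x origin) — tagged
categories for parent-descended copies, untagged for environment-descended
— and runs the ordinary kernels on the extended vectors with a static
uniform environmental pool. Tag tracking is kept out of ordinary runs so
they stay at `N_M` categories. Under selection the realized fraction may
deviate from the closed form; no claim is made there.

## Seeds and determinism

All randomness flows through `numpy.random.Generator`. A single master seed
yields per-run seeds by SHA-256 hashing of
(master, purpose, scenario, replicate, X, T_M) truncated to 31 bits, so any
run is reproducible in isolation and independent of execution order.
Identical (config, scenario, seed) triples give byte-identical metric
series.

## Problem sizes used in validation

The full-scale reference configuration (100 hosts, 200 taxa, 10^6 microbes per
host, 10^8 in the environment, 1500 generations, 15 120-run grid) is
supported but not exercised by the test suite. The behavioural test suite
uses a reduced scale chosen to preserve the regime that drives the
qualitative results — strong selection relative to drift, community sizes
large enough that sampling noise does not swamp selection differentials,
and a post-burn-in environmental shift spanning multiple trait SDs: 50
hosts, 50 taxa, 10^4 microbes per host, 10^5 in the environment, 400 host
generations (burn-in 100), scenario 2B, 5 replicates per setting. At this
scale the suite reproduces the host/microbe fitness antagonism across
vertical-inheritance levels at `T_M = 1`, the buffering of both fitnesses
at `T_M = 50`, and diversity collapse under `X = 1, T_M = 1`. Passing at
reduced scale demonstrates the mechanisms, not full-scale effect sizes;
figure-scale trajectories require the full configuration.

## Known limitations

- Purely ecological: no host or microbe mutation, no genetic variance
  (`phi_hg` is uniform and constant), so host evolution per se is outside
  scope.
- Fixed community sizes and non-overlapping generations (Wright–Fisher
  framing); no density dependence or demographic stochasticity in totals.
- One global selection strength `s` shared by host-level and microbe-level
  selection.
- The synthetic environments are Gaussian AR(1)/i.i.d. processes; real
  environmental series have heavier tails, seasonality and multi-scale
  autocorrelation that these generators do not emulate, so quantitative
  A-vs-B contrasts depend on the chosen `rho` and SDs.
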