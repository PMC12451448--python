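# holosim

Agent-based simulation of hosts and their microbiomes — holobionts — under
environmental change.

`holosim` is for researchers studying host-microbiome eco-evolutionary
dynamics: how the mode of microbial transmission (vertical from parent vs.
horizontal from the environment), the number of microbial generations per
host generation, and the predictability of environmental change jointly
shape the fitness of hosts, the fitness of their microbes, and within-host
microbial diversity.

## The model

A constant population of *N_H* haploid hosts each carries a microbial
community of fixed size *n_MH* drawn from a global pool of *N_M* taxa; a
shared environmental pool holds *n_ME* microbes. Each microbial taxon *m*
has a trait value *φ_m* ~ U(−2.5, 2.5), and all selection is Gaussian
stabilizing selection towards the current environmental condition *E*:

    ω = exp(−(φ − E)² / s)

with selection parameter *s* > 0 (small *s* = strong selection). Every
community-assembly event is a fitness-weighted multinomial draw: the
probability of sampling taxon *m* from a source is proportional to
ω_m × (relative abundance of *m* in that source).

Each host generation contains *T_M* microbial generations. Per microbial
generation:

- the **environmental pool** is rebuilt from its previous state (proportion
  *Z*), microbes shed by hosts (*Y*), and a fixed uniform pool (1 − *Z* − *Y*),
  all weighted by environmental fitness ω_m,env;
- each **host microbiome** is resampled with retention *P* from itself and
  1 − *P* recruited from the environmental pool, weighted by within-host
  fitness ω_m,host evaluated at the composite condition
  *E_tMh* = *I·φ_hg* + (1 − *I*)·*E_tM* (the birth of the generation counts
  as the first microbial generation, so *T_M* − 1 such updates occur).

At the end of the generation each host's phenotype
*φ_h* = *G·φ_hg* + (1 − *G*)·*φ_hM* (with *φ_hM* the abundance-weighted mean
microbiome trait) determines its fitness ω_h,env; parents are sampled with
replacement proportionally to fitness (Wright–Fisher reproduction), and each
offspring draws proportion *X* of its microbiome from its parent and
1 − *X* from the environment.

The environmental condition follows one of six scenarios — stationary (1),
increasing mean (2), or increasing variance (3), each with autocorrelated
(A, AR(1) with ρ = 0.9) or independent (B) noise — generated at host
resolution and linearly interpolated to microbial resolution, so microbes
experience change at their own timescale.

Recorded per host generation (prior to reproduction): mean host fitness,
mean within-host microbial fitness, and mean alpha diversity as the scaled
Shannon–Wiener index H/ln(*N_M*).

## Worked example

`examples/transmission_tradeoff.py` runs a small increasing-mean (2B)
experiment at one microbial generation per host generation across three
levels of vertical inheritance:

```
    X  host fitness  microbe fitness
 0.00         0.794            0.634
 0.50         0.729            0.679
 0.99         0.353            0.872
```

Final-generation means over 3 replicates. As vertical inheritance *X* rises,
within-host microbial fitness rises (communities persist across host
generations, so within-host selection accumulates) while host fitness falls
(hosts tracking a moving environmental optimum do better by re-sampling
environmentally adapted microbes each birth): the transmission-mode tradeoff
between the two levels of selection. The other scripts in `examples/`
demonstrate the environmental scenarios, the ~2·*N_H* neutral coalescence
time behind the burn-in length, and effective vertical inheritance
(*X·P^(T_M−1)*, e.g. only ~13% of a fully vertically acquired microbiome
still descends from the parent after 100 within-host generations at
*P* = 0.98).

A thin CLI mirrors the library for batch use:

```sh
holosim run --scenario 2B --x 0.5 --tm 10 --replicates 5 --seed 1 --out out/
holosim grid --config config.yaml --out grid_out/   # full Cartesian sweep
```

Each run writes one tidy per-generation metrics CSV plus a `manifest.json`
of resolved parameters and derived seeds.

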