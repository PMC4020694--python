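# Methods

## Model overview

`plastisim` simulates a metapopulation of diploid, hermaphroditic
individuals arranged on a linear gradient of `D` demes. A single
quantitative trait determines survival. Three additive locus classes, 5
diploid loci each, build the trait at development:

| class | symbol | role | units |
|---|---|---|---|
| nonplastic | `N` | reaction-norm intercept | trait units |
| plastic | `P` | cue coefficient (slope / cue slope) | trait units per cue unit |
| instability | `D` | sd of one developmental-noise draw | trait-sd units |

Phenotype at development in natal deme *i*:
`T = ΣN + E_i·ΣP + R`, with `R ~ Normal(0, ΣD)` drawn exactly once per
lifetime; the phenotype is never recomputed after dispersal, which is what
makes the timing of environmental change relative to development and
selection matter. When the noise sd is zero the draw is skipped and `R = 0`
exactly.

Any locus class can be switched off (e.g. plasticity-only or
instability-only populations). In the **pleiotropic variant** the
instability class is removed entirely and the noise sd is
`(S/10)·|ΣP|`: instability is then an unavoidable side effect of
plasticity, with `S` (range 0–4) chosen so that a genotype at the optimal
reaction norm (`ΣP = 10`) realizes noise sd `S`. The prose description of
this scaling admits more than one constant; we pin it by requiring the
reported strength to equal the realized sd at the optimal slope, which is
how the strength axis of the pleiotropic result surfaces is labelled.
The absolute value makes opposite-signed slopes of equal magnitude
equivalent.

## Environment

Mean optima and mean cues are linear in deme position with a fixed ratio
`optimum_step / cue_slope = 0.4 / 0.04 = 10` (the optimal reaction-norm
slope). Defaults: 50 demes spanning −9.8..+9.8 (about five selection
widths), or a single deme centred at 0 for temporal-only runs.

Among-generation change perturbs the realized optimum at development
(`θ_dev`), at selection (`θ_sel`), or both, under four patterns: selection
only (P1), development only (P2), both independently (P3 — an unreliable
cue), and development carrying over to selection (P4 — a fully reliable
cue). Deviations follow a stationary AR(1) process

    dev_t = ρ·dev_{t−1} + τ·√(1−ρ²)·z_t,   z_t ~ N(0,1)

so that τ is the *stationary* sd for every ρ ∈ (−1, 1); the innovation
variance is scaled accordingly, and the initial deviation is drawn from the
stationary distribution `N(0, τ²)`. (The alternative convention — innovation
sd τ, stationary sd τ/√(1−ρ²) — would make the effective magnitude of
variation depend on ρ, confounding the autocorrelation comparisons, so we
reject it.) In synchronized mode all demes share one `z_t` per generation;
otherwise each deme has its own. τ may be configured directly (optimum
units), as a percentage of the gradient span (multi-deme convention), or as
a multiple of σ (single-deme convention).

The developmental cue is the realized developmental optimum rescaled by
`cue_slope / optimum_step`. This choice makes a slope-10 genotype track a
P4 perturbation exactly — required for P4 to behave as a fully trackable
environment — and reduces to the fixed `E_i` whenever development is
unperturbed.

## Life cycle and demography

Per generation: environment step → development (natal-deme cue) →
dispersal and selection in the configured order (*move first*: disperse
then select; *select first*: select then disperse) → reproduction.

**Selection** is an independent Bernoulli survival trial per individual
with `W = exp(−(T − θ)²/(2σ²))`, σ = 2, against the realized optimum of the
individual's *current* deme. **Dispersal** is cost-free and uses one of two
kernels at the same per-capita rate: *stepping-stone* — displacement
`round(N(0, s))` demes with `s` calibrated so `P(move at all) = rate`
(2·Φ(−0.5/s) = rate), so higher rates also mean longer moves, and
over-shooting individuals stop in the terminal deme; *island* — move with
probability `rate` to a uniformly chosen *other* deme. Calibrating the
stepping-stone kernel on the movement probability keeps the configured rate
comparable across kernels. **Reproduction** is soft selection: every deme
with ≥ 1 adult recruits exactly `K` juveniles (100/deme on the gradient,
1000 in a single deme), each from a mother and father drawn independently,
uniformly, with replacement from the deme's adults (selfing allowed; the
pair is re-drawn for every offspring rather than cycling a fixed mating
list). Empty demes recruit nothing that generation but can be recolonized.
Extinction means zero individuals anywhere.

**Inheritance** is diploid Mendelian segregation with free recombination:
at each locus the offspring receives one allele drawn uniformly from the
mother's two copies and one from the father's, independently across loci.
The transmission rule is a modelling choice (only "diploid loci" is given);
unlinked multilocus Mendelian transmission is the standard choice for
additive individual-based models. Every allele of every newborn then
mutates with probability 0.10, adding `N(0, 0.1)` (infinite-alleles);
instability alleles are truncated at zero from below, which together with
the truncation creates the net upward mutation pressure that selection must
balance.

**Initialization**: every deme filled to `K` with newborns whose
nonplastic and plastic alleles are drawn uniformly from {−2, −1, 0, 1, 2}
(mean 0) and whose instability alleles are all zero; values become
continuous after one round of mutation.

## Runs, replication, seeding

Default runs last 10,000 generations — past the point where the reported
statistics show no directional trend — with 20 replicates per parameter
combination; extinct replicates are discarded and re-run until 20 succeed
or 60 total attempts are exhausted (an all-extinct cell is a reported
outcome, not an error). Attempt `a` uses root seed `base_seed + a`, from
which independent generator streams are spawned for initialization, the
environment, developmental noise, and demography; a run is bit-reproducible
from `(config, base_seed)`.

Statistics are recorded on the juvenile cohort after reproduction, when
every occupied deme holds exactly `K` individuals, so the plain mean over
individuals equals the equal-weight-per-deme mean. Because reported means
are equilibrium values, each replicate reports both the final-generation
snapshot and the mean over the last `report_window` generations (default
100, capped at the run length); the window average is the headline number
since it reduces sampling noise at equilibrium. **Relative plasticity** is
the replicate-averaged mean `ΣP` divided by the optimal slope;
**mean instability** is the corresponding average of `ΣD`, or of the
realized pleiotropic sd `(S/10)|ΣP|` in the pleiotropic variant (where `ΣD`
does not exist); among-replicate spread is a coefficient of variation in
percent (sample sd / |mean|, undefined at mean 0).

## Numerical and scale choices

* Allele matrices are stored per locus class as `(n, 10)` arrays;
  the whole generation loop is vectorized (a 50-deme default run is a few
  ms per generation).
* Test and acceptance runs use reduced problem sizes chosen to leave the
  qualitative outcomes intact: the mutation–selection-balance check uses 5
  replicates × 5,000 generations (averaging the last 1,000) in the
  single-deme setting, and the directional spatial/temporal scenario checks
  use 20 demes × 100 individuals × 2,000 generations × 5 replicates. At
  these scales equilibria are reached but per-cell Monte-Carlo error is
  larger than at the default scale, so the scenario checks assert orderings
  between conditions rather than surface values.
* Deme indices are 0-based internally; the 1-based cue formula
  `E_i = 0.04(i − 25.5)` is reproduced exactly by centring on `(D−1)/2`.
* Dispersal with rate 0 (or a single deme) bypasses the kernel; a
  single-deme config rejects nonzero dispersal at validation time, as does
  |ρ| ≥ 1 or a pleiotropic config that also asks for instability loci.

## What the simulator does and does not capture

The generator *is* the study system: all inputs are parameters, no
biological data is consumed. Deliberate idealizations: no dominance,
epistasis, linkage maps, or sex differences; no dispersal cost or
density-dependent dispersal; hard selection, mate choice, and fecundity
selection are out of scope; gradients are linear and temporal variation
stationary. Conclusions drawn from passing tests are therefore about the
model's internal logic — e.g. that plasticity suppresses selection for
instability when the cue is reliable and selection precedes dispersal — not
about any particular empirical system. Near the high-τ, high-dispersal
corner of the pleiotropic variant, replicate-to-replicate variation grows
several-fold and 10,000 generations may not reach equilibrium; results
there should be read as distributions over replicates, not point values.
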