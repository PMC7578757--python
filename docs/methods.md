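# Methods

## The genetic system

Sex determination is female-heterogametic: males are ZZ, females WZ, and —
because WZ × WZ matings occur — homogametic WW females exist and are
viable. The unusual ingredient is intersexuality: a fraction α of
WZ-genotype progeny develop as functional males carrying both male and
female gonopores. The model treats α as a constant of the population
(intersex emergence is taken as genetically programmed, not environmentally
induced), and treats intersex animals as fully fertile males with no
selfing path. WW sires are rejected outright: functional WW males are not
part of the system modelled here. Gonopore sub-configurations are carried
as free-text metadata and never influence classification beyond the
male/female/intersex phenotype itself.

Cross tables are exact outer products of gamete distributions (each parent
transmits each of its two sex chromosomes with probability ½). Genotype
calls from the W/Z PCR bands are deterministic: both bands → WZ, Z only →
ZZ, W only → WW; a blank lane is a genotyping failure and raises an error
rather than returning a genotype.

## The projection model

State: abundances (N_ZZ, N_IS, N_WZ, N_WW) of the four functional classes.
One time step is one generation, nominally 6 months (`step_months`
converts steps to years). Per step:

1. Every functional female (WZ + WW) mates once, with her sire's class
   drawn proportional to male-class abundances (polygyny is implicit: male
   counts only set sire-class frequencies; IS and ZZ males are equally
   fertile). The newborn class distribution **p** is the α-partition of
   the resulting mixture of cross tables.
2. Each female contributes σ₀·φ surviving recruits in expectation;
   recruits mature in one step (no juvenile age class — σ₀ simply scales
   φ, which is why the package exposes their product as `recruitment`).
3. Adults survive with probability σ_a, identically across classes.

So N'_k = σ_a·N_k + σ₀·φ·F·p_k. Because survival and fecundity are
class-independent, stationary class fractions must equal the newborn
distribution's fixed point; hence the long-term stable distribution (LTSD)
is a function of α alone, verified numerically across σ_a ∈ {0…0.9} and
σ₀·φ ∈ {0.5…3}. Default parameters are α = 0.04, σ_a = 0.6, σ₀·φ = 1.2
(λ∞ = σ_a + σ₀·φ/2 = 1.2); survival/fecundity defaults are declared
choices that shape only transients and growth rates, not structure.

Two further operators: a constant-N variant in which exactly (1−σ_a)·N
recruits replace the adults that die (total conserved to machine
precision; it reaches the same structural fixed point), and a stochastic
mode drawing Poisson recruit totals per female, multinomial class
assignment, and binomial survivors from a seeded generator. A stochastic
population reaching N = 0 yields a truncated trajectory flagged extinct.
Degenerate states (no males or no females) recruit nothing and decay
geometrically; class fractions are undefined at N = 0.

### Solvers and numerical choices

The LTSD solver iterates the projection on class fractions (renormalising
each step) from ZZ = WZ = 50% until the maximum fraction change is below
`tol` (default 1e-10), with a 10,000-step cap. An independent route —
Newton iteration (scipy) on the two scalar fixed-point equations for the
IS share among males and the WW share among females — is exposed as
`stable_distribution_fixed_point` and agrees with the iterative solver to
1e-8; the acceptance script asserts this cross-check on every run.
"Generations to convergence" counts steps until every class fraction is
within `tol_pp` (default 0.1 percentage points) of the LTSD; the criterion
is an explicit tolerance, so reported counts are upper-bound-comparable
with eyeball judgements of "about converged".

### The ½α rule is approximate

At the fixed point IS∞ = α·(WZ-genotype total fraction). The WZ total is
51.0% at α = 0.04 — giving IS∞ = 2.04%, i.e. IS∞/α = 0.510 — and grows
roughly as 0.5 + 0.25α, reaching ≈0.525 at α = 0.1. "IS ≈ ½α" is therefore
accurate to ~2% at small α but is not exact, and any band tighter than
that on IS∞/α will fail at larger α. The α estimator `2 × IS fraction`
inherits the same ~+2% deterministic offset: its exact estimand is 2·IS∞,
and tests assert sharp unbiasedness for that estimand plus the bounded
offset from α, rather than pretending the rule is exact.

## Cohort statistics

The progeny test pools WZ and ZZ offspring into a single "not-WW" category
(the W marker distinguishes WW from Z-carriers), testing observed counts
against 3:1 with the uncorrected χ² statistic, df = 1, upper-tail p from
scipy. No Yates correction: the uncorrected statistic reproduces the
reference p-values (0.34/0.16/0.27 for counts (66,17)/(56,12)/(42,19));
the corrected one would not. A 3-category 1:2:1 test is available when
genotypes are fully resolved. Ratios in tallies are reported both as exact
quotients and in the field's "k:1" nearest-integer style; F:M is undefined
(flagged "—") only when no males were sampled. Records whose genotype
cannot be determined stay in phenotype counts and are excluded, with a
logged count, from genotype tallies. No multiple-testing correction is
applied across progenies (few tests, reported raw).

## Marker screening

Input is a binary tags × samples matrix (counts are binarized at ≥1 read
by default). The W-screen selects tags present in strictly more than 60%
of female samples and in zero males; the male criterion is absolute
because a W-derived tag has no template in a ZZ animal, while the female
threshold absorbs RAD dropout. Missing calls count as absences by default
(conservative for the zero-male rule), with an option to drop them from
female denominators instead. The selected set is monotone non-increasing
in the threshold. A symmetric Z-screen (present in males and WZ females,
absent in WW females) is provided but needs genotype labels and is off by
default in pipelines. The false-positive rate of the W-screen for a
background tag with uniform presence frequency is the integral of
(1−f)¹² · P(Bin(12, f) ≥ 8) — about 10⁻⁴ per tag for the 12♂/12♀ design —
and the generator tests verify the realised rate against this closed form.

## Synthetic data: what it does and does not emulate

Generators cover the four study designs: multinomial cross progenies with
optional independent per-band genotyping-error flips (default 0; flips can
produce blank, undetermined calls, exercising that path); ponds stocked
with chosen phenotype compositions, where each female's brood (default 100
offspring, optionally negative-binomially overdispersed) follows her own
sire draw and the sampled cohort is a multivariate-hypergeometric draw
from the pooled progeny; native populations drawn multinomially at the
α-LTSD (a trajectory-based route exists via `simulate_trajectory` for
transient studies); and RAD matrices with W-linked tags present in
W-carriers at 1−dropout, in ZZ males at the false-presence rate, and
background tags at i.i.d. uniform per-tag frequencies.

Not emulated: brood-size and survival realism in ponds (true
distributions are unreported; equal broods are a declared default),
geographic/population structure, sequence-level artefacts (reads,
restriction sites, allelic dropout correlated across tags), and
environmental modulation of α. Passing tests therefore demonstrate
internal consistency of the method chain under the stated sampling models,
not robustness to those real-data complications.

## Problem sizes

Deterministic results (LTSD, cross tables, convergence, thresholds) are
exact at machine precision and run in milliseconds. Simulation-based
checks use cohorts of 10⁴–10⁵ individuals, 200–500 replicates for
estimator calibration, 300 replicates for stochastic-vs-deterministic
tracking, and 2,000–4,000-tag matrices for the screen — sizes at which
binomial/multinomial standard errors are small enough to resolve the
effects being tested.

## Known limitations

No density dependence beyond the constant-N variant; no age or size
structure; one-step maturation; proportional (frequency-based) siring is
an assumption, not an observation; α is assumed spatially and temporally
constant; the marker screen takes the labelled female set as given and
does not model batch effects between sequencing runs.
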