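# Methods

## Model

`ilshmm` models a four-way genome alignment of three focal species A, B,
C and an outgroup D as a hidden Markov chain along the alignment whose
hidden states are rooted three-leaf genealogies.  A state is a topology
label plus two discretised coalescent times:

* **V0** — species topology ((A,B),C) with the A–B coalescence between
  the two speciation events, in one of `n_AB` intervals of the AB
  ancestor, and the second coalescence in one of `n_ABC` intervals of
  the deep ancestor;
* **V1** — species topology with both coalescences in the deep ancestor;
* **V2** ((A,C),B) and **V3** ((B,C),A) — the incomplete-lineage-sorting
  topologies, necessarily deep.

The state count is `n_AB·n_ABC + 3·n_ABC·(n_ABC+1)/2` (27 at 3/3).
The demography is parameterised by tip times `t_A, t_B, t_C`, the
inter-speciation time `t_2`, the outgroup offset `t_upper`, ancestral
effective sizes `N_AB, N_ABC` and the recombination/mutation ratio
`rho_over_mu`.  Only products of rates and times are identifiable, so
the mutation rate is fixed to 1 and everything is carried in mutation
units; `rescale` maps to natural units.  A pair of lineages coalesces at
rate `1/(ploidy_scale·N)` per generation (`ploidy_scale = 2` is the
diploid 1/(2N) convention; 1 reads sizes as haploid).  Under this model
the probability that A and B fail to coalesce in the AB ancestor is
`exp(-T2)` with `T2 = t_2/(ploidy_scale·N_AB)`, giving the familiar ILS
fraction `(2/3)·exp(-T2)` split equally between V2 and V3.

## Transition probabilities

Transitions derive from the two-locus coalescent with recombination.  A
chain state is a set of lineage blocks, each carrying the subset of
sample labels it is ancestral to at the left and at the right site; a
block with material at both sites splits at the recombination rate, and
any two blocks merge (site-wise unions) at the coalescence rate.
Completed material is retained, and states with both sites fully
coalesced absorb.  The chain has 2, 15 and 203 states for one, two and
three sequences (asserted at import).

The pipeline mirrors the speciation tree: each tip evolves the
two-state one-sequence chain for its tip time (re-linking of split
sites uses `N_tip`, default `N_AB` — the model itself never pins this
quantity, so it is exposed as configuration); A and B are merged into
the 15-state chain for the AB epoch; the result is merged with C into
the three-sequence chain for the deep epoch.  Interval matrices
`exp(Q·Δ)` are sliced at the grid cutpoints, and the final infinite
interval is handled by an exact absorption solve, never by truncation.

Because coalescence only coarsens a site's label partition, comparing
the chain state at consecutive cutpoints reveals exactly which
coalescences each site underwent in each interval.  One ambiguity
remains: when both coalescences of a site fall inside a single
interval, the endpoints no longer show which pair merged first — which
decides the topology.  The implementation therefore augments the
internal three-sequence chain with a per-site *first-merged-pair* tag
(271 tagged states); the joint (left genealogy, right genealogy) matrix
is accumulated by propagating event-labelled probability vectors
through the masked interval matrices.  Row-normalising the joint matrix
gives the transition matrix; its row sums are the stationary law.

Two structural subtleties are worth recording.  First, inside the AB
epoch the both-sites-coalesced states must *not* be frozen: the merged
A–B lineage keeps recombining and re-linking, which shapes the joint
left/right law downstream; the public `build_rate_matrix` still seals
absorbing rows, as the classical presentation of the process does.
Second, the one-sequence chain has no absorbing state at all (its two
states cycle), so "absorbing" is defined only for two or more
sequences.

Validation: the stationary topology masses reproduce the closed-form
ILS split to machine precision; the first coalescent follows the
truncated rate-1 exponential on the AB grid; the cumulative second
coalescent equals the phase-type law below at every cutpoint; and the
full joint matrix agrees with 10^5 independent two-adjacent-site
coalescent simulations within three binomial standard errors per cell.

## Time discretisation

Grids live in per-epoch coalescent units.  The default scheme takes
equal-probability quantiles of the density of the *first* coalescent:
a truncated rate-1 exponential on [0, T2] for the AB epoch and a rate-1
exponential for the deep epoch, whose last cutpoint is infinite.  Two
alternative deep-epoch schemes serve posterior decoding: rate-3
exponential quantiles (first coalescent conditional on being deep —
three lineages present) and quantiles of the phase-type distribution of
the second coalescent, with sub-intensity matrix

    S = [[-1, 0, 0],
         [ 0,-3, 3],
         [ 0, 0,-1]]

and initial vector `pi = (1 - e^-T2, e^-T2, 0)`: a mixture of a rate-1
exponential (first coalescent was shallow) with the convolution of
rate-3 and rate-1 exponentials (three lineages survive the second
speciation).  Phase-type quantiles are found by monotone root
bracketing to 1e-10 and verified against numeric integration of the
survival function.  User-supplied cutpoint lists are accepted
unchanged.  One convention had to be fixed where usage is mixed in the
field: grids are built in `ploidy_scale·N` units, consistent with the
coalescence-rate convention above.

The first-coalescent track spans `n_AB` shallow plus `n_ABC` deep
intervals; the second-coalescent track spans the `n_ABC` deep
intervals.

## Emission probabilities

Each hidden state implies a rooted four-leaf tree.  Within-interval
coalescent times are replaced by their conditional expectations under
the governing density (truncated Exp(1) between speciation events,
Exp(3)/Exp(1) components deep in time, conditional tail means `a + 1/λ`
for the infinite interval; when both events share one interval the
second time is the conditional mean of Exp(1) truncated to start at the
first).  Integrating the emission over the full within-interval law by
quadrature was evaluated during development and moved the likelihood
surface negligibly, so the simpler point-time choice is kept.

The outgroup joins the ingroup root deterministically at the second
speciation plus `t_upper`; its tip branch is `t_C + t_upper` (clock-like
on the C timeline).  Should a representative second-coalescent time
exceed `t_upper` (possible only for extreme grids), the root branch is
clamped at zero rather than made negative.  Site patterns over the 256
ordered quadruples follow from pruning under Jukes–Cantor with a
uniform root distribution; rows sum to one exactly.  Any non-ACGT
character marks a tip missing and is marginalised out; columns with A,
B and C all missing emit probability 1 so coordinates are preserved.

The forward pass uses per-column scaling (not log-sum-exp — adequate
for a few hundred states) and is JIT-compiled with numba when
available, with a pure-numpy fallback.  Modal-state ties break to the
lowest state index.

## Estimation

`fit` maximises the forward log-likelihood with bound-constrained
Nelder–Mead (default) or L-BFGS-B.  Free parameters are
`(t_1, t_2, t_upper, N_AB, N_ABC, log10 rho)` in ultrametric mode (the
molecular clock ties `t_A = t_B = t_C − t_2`), with the three tip times
freed in non-ultrametric mode.  The recombination ratio is optimised on
a log scale because it spans orders of magnitude; the other coordinates
are rescaled by their starting values.  Default bounds are a factor of
[0.1, 10] around the start, the log-likelihood tolerance is 1e-5
relative, and every evaluation is recorded.  Simulation studies start
from normal jitter around the truth with standard deviation one fifth
of the true value.  Parametric-bootstrap confidence intervals refit
replicates simulated from the fitted model and report mean ± 1.96 sd of
a per-parameter normal fit; individual replicate failures are tolerated
while at least half succeed.

## Synthetic data

The neutral generator delegates to msprime: the species tree with
populations A, B, C, D, AB, ABC and ABCD, one haploid lineage per
species, recombination along the sequence, and Jukes–Cantor mutations.
Population sizes are passed so that pairwise coalescence rates match
the analytical model under the configured ploidy convention.  The
outgroup-ancestor size (`N_out`, default `N_ABC`) is not part of the
analytical model — there the outgroup joins deterministically — so
fitted `t_upper` absorbs its mean (about `+N_out` generations) and the
join-time variance remains unmodelled; profile checks showed this does
not measurably bias the other parameters.  Truth tracks (topology and
both coalescence times per site) come from the tree sequence through
the same labelling function the model uses.

The default generator parameters are the validation demography used
throughout: `t1 = 200,000` generations, `t2 = 25,501`, outgroup offset
`1,000,000`, haploid-convention `N_AB = 80,000`, `N_ABC = 70,000`,
`rho = 0.5e-8`, `mu = 1.5e-8`.  Its ILS fraction is 48.5%.

The sweep fixture conditions on the fixation of a single beneficial
variant in the AB ancestor: msprime's genic-selection model
(deterministic logistic trajectory, structured coalescence around the
swept site) is spliced between neutral phases, completing at the first
speciation by default.  msprime's sweep machinery supports a single
population and assigns selective backgrounds correctly only to lineages
alive before the sweep phase begins, so species isolation is expressed
differently here: A and B are contemporary samples kept apart before
the first speciation by an effectively infinite population size, while
C and D enter at their speciation times (after the sweep has ended) and
receive their tip-branch mutations analytically.  Consequently the
fixture requires the sweep to finish inside the AB epoch, which bounds
the weakest usable selection at roughly 2Ns ≈ 60 under the default
demography; the neutral limit of weak selection is therefore checked at
sites unlinked to the sweep, where hitchhiking vanishes, rather than at
the swept site, which any conditioning on fixation perturbs.

What the generator does not emulate: alignment error, indels and
missing data, mutation-rate and recombination-rate variation, selection
outside the single-sweep fixture, and demographic change within
branches.  Tests passing on this generator therefore certify the
inference machinery under the model's own assumptions, not robustness
to real-data artefacts.

## Problem sizes and identifiability

Test-suite and acceptance-script experiments run at desk scale, chosen
once: 10^5 replicates for the two-site Monte-Carlo oracle; posterior
decoding on 100–200 kb; parameter recovery on five 1-Mb genomes (three
600-kb genomes in the acceptance script) with Nelder–Mead evaluation
budgets of 200–450, beyond the iteration counts at which the fits
plateau.

A caveat established during development: at megabase scale `N_AB` and
`t_2` sit on a shallow, correlated likelihood ridge (together with the
recombination ratio).  Profiling the log-likelihood around the truth
shows a drop of only ~2 units within ±25–35% of `N_AB` on 1 Mb of
data, and the decisive control is self-consistency: fitting 1 Mb of
data generated from the package's *own* HMM — where no model mismatch
is possible — still returns `N_AB` about 20% off at convergence while
`t_1` and `N_ABC` come back within ~2%.  The information floor for
`N_AB` at 1 Mb is therefore roughly a fifth of its value per
replicate; tens of megabases are needed to pin it within a few
percent.  On coalescent-simulated (non-Markovian) data the drift is
larger still, and with converged optimisation a fine-grid fit can land
further from the truth than a coarse one on the same realisation —
the extra likelihood is spent tracking the ridge, not the parameter.
Recovery results at desk scale must be read against this limit.

## Known limitations

* Markov approximation along the sequence (the true ancestral
  recombination graph is long-range correlated); tends to bias the
  recombination-rate estimate.
* Three focal species only; one outgroup, joined deterministically.
* Jukes–Cantor substitution; no rate variation across sites.
* Constant `N` within each ancestral branch; no migration or
  introgression states.
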