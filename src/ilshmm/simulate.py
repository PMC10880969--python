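"""Synthetic four-species alignments and brute-force validation oracles.

The neutral generator delegates the coalescent with recombination to
msprime under the species tree ((A,B),C),D with ancestral sizes N_AB
and N_ABC, overlays Jukes-Cantor mutations, and records per-site truth
tracks (topology and both coalescence times) from the tree sequence.
Simulation requires clock-like sampling (all tips at time 0).

Population sizes are passed to msprime so that a pair of lineages
coalesces at rate 1/(ploidy_scale * N), matching the analytical model
for any ploidy convention.

The default parameter set is the validation demography used throughout
the package: t1 = 200,000 generations between present and the first
speciation, t2 = 25,501 generations between speciations, t3 = 1,000,000
generations to the outgroup, haploid-convention N_AB = 80,000 and
N_ABC = 70,000, rho = 0.5e-8 and mu = 1.5e-8 per site per generation.

The sweep fixture models a single positively selected variant fixing in
the A-B ancestral population: a deterministic logistic trajectory with
structured coalescence around the selected site (msprime's genic
selection model), spliced between neutral phases.  Species isolation is
expressed by sampling each lineage at its speciation time in a single
ancestral population - exactly equivalent for one lineage per species -
and tip-branch mutations are laid down separately.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import msprime
import numpy as np

from .demography import DemographyParams, coalescent_units
from .discretization import TimeGrid
from .transitions import (
    classify_genealogy,
    enumerate_hidden_states,
    hidden_state_index,
    topology_label,
)

__all__ = [
    "SimTruth",
    "TreeRecord",
    "default_simulation_params",
    "DEFAULT_MU",
    "species_tree_demography",
    "simulate_alignment",
    "two_site_oracle",
    "TwoSiteOracleResult",
    "simulate_sweep",
]

SPECIES = ("A", "B", "C", "D")
DEFAULT_MU = 1.5e-8

_PAIRS = {frozenset({0, 1}): 0, frozenset({0, 2}): 1, frozenset({1, 2}): 2}
_TOPO_CODE = {"V0": 0, "V1": 1, "V2": 2, "V3": 3}


def default_simulation_params() -> DemographyParams:
    """The validation demography, in natural units (haploid sizes)."""
    return DemographyParams.ultrametric(
        t_1=200_000.0,
        t_2=25_501.0,
        t_upper=1_000_000.0,
        N_AB=80_000.0,
        N_ABC=70_000.0,
        rho_over_mu=0.5e-8,
        ploidy_scale=1.0,
    )


@dataclass(frozen=True)
class TreeRecord:
    """One marginal genealogy: reference interval plus coalescence data."""

    left: int
    right: int
    pair: int  # 0 = (A,B), 1 = (A,C), 2 = (B,C)
    t_first: float
    t_second: float


@dataclass
class SimTruth:
    """A simulated alignment plus its per-site true genealogy."""

    alignment: dict[str, str]
    topology: np.ndarray  # int8 per site, V0..V3 -> 0..3
    t_first: np.ndarray
    t_second: np.ndarray
    trees: list[TreeRecord]
    seed: int
    params: DemographyParams  # natural units
    mu: float

    @property
    def length(self) -> int:
        return len(self.topology)

    def codes(self) -> np.ndarray:
        """Alignment columns encoded for the HMM."""
        from .alignment_io import encode_alignment

        return encode_alignment([self.alignment[s] for s in SPECIES])


def _require_clocklike(p: DemographyParams) -> None:
    if abs(p.t_B - p.t_A) > 1e-6 * p.t_A or abs(p.t_C - p.t_A - p.t_2) > 1e-6 * p.t_C:
        raise ValueError(
            "simulation requires clock-like sampling: t_A = t_B, t_C = t_A + t_2"
        )


def species_tree_demography(
    params: DemographyParams, N_out: float | None = None
) -> msprime.Demography:
    """msprime demography of the four-species speciation tree.

    ``N_out`` sizes the outgroup-ancestral population (beyond the model's
    deterministic-join horizon); defaults to N_ABC.
    """
    _require_clocklike(params)
    p = params
    ps = p.ploidy_scale
    if N_out is None:
        N_out = p.N_ABC
    dem = msprime.Demography()
    for name in SPECIES:
        dem.add_population(name=name, initial_size=ps * p.tip_Ne)
    dem.add_population(name="AB", initial_size=ps * p.N_AB)
    dem.add_population(name="ABC", initial_size=ps * p.N_ABC)
    dem.add_population(name="ABCD", initial_size=ps * N_out)
    t1 = p.t_A
    dem.add_population_split(time=t1, derived=["A", "B"], ancestral="AB")
    dem.add_population_split(time=t1 + p.t_2, derived=["AB", "C"], ancestral="ABC")
    dem.add_population_split(
        time=t1 + p.t_2 + p.t_upper, derived=["ABC", "D"], ancestral="ABCD"
    )
    return dem


def _truth_from_ts(ts, params: DemographyParams):
    length = int(ts.sequence_length)
    topo = np.empty(length, dtype=np.int8)
    t_first = np.empty(length)
    t_second = np.empty(length)
    trees = []
    for tree in ts.trees():
        tab = tree.tmrca(0, 1)
        tac = tree.tmrca(0, 2)
        tbc = tree.tmrca(1, 2)
        times = {frozenset({0, 1}): tab, frozenset({0, 2}): tac, frozenset({1, 2}): tbc}
        pair = min(times, key=times.get)
        tf, tsec = times[pair], max(tab, tac, tbc)
        lo, hi = int(tree.interval.left), int(tree.interval.right)
        trees.append(TreeRecord(lo, hi, _PAIRS[pair], tf, tsec))
        topo[lo:hi] = _TOPO_CODE[topology_label(pair, tf, params)]
        t_first[lo:hi] = tf
        t_second[lo:hi] = tsec
    return topo, t_first, t_second, trees


def _alignment_from_ts(ts, length: int, rng: np.random.Generator) -> np.ndarray:
    """Per-species base codes (4 x length, 0..3), uniform ancestral
    bases at invariant sites."""
    arr = np.tile(rng.integers(0, 4, length, dtype=np.int8), (4, 1))
    base_code = {"A": 0, "C": 1, "G": 2, "T": 3}
    for var in ts.variants():
        pos = int(var.site.position)
        codes = np.array([base_code[a] for a in var.alleles if a is not None], dtype=np.int8)
        arr[:, pos] = codes[var.genotypes]
    return arr


_BASES = np.array(list("ACGT"))


def _to_strings(arr: np.ndarray) -> dict[str, str]:
    return {sp: "".join(_BASES[row]) for sp, row in zip(SPECIES, arr)}


def simulate_alignment(
    params: DemographyParams,
    length: int,
    mu: float = DEFAULT_MU,
    seed: int = 1,
    N_out: float | None = None,
) -> SimTruth:
    """Neutral coalescent-with-recombination alignment with truth tracks.

    ``params`` is in natural units (generations, individuals, rho per
    generation in ``rho_over_mu``).  The same seed and parameters give
    byte-identical output.
    """
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = np.random.default_rng(seed)
    s_anc, s_mut = (int(x) for x in rng.integers(1, 2**31 - 1, 2))
    dem = species_tree_demography(params, N_out=N_out)
    ts = msprime.sim_ancestry(
        samples=[msprime.SampleSet(1, population=sp, ploidy=1) for sp in SPECIES],
        demography=dem,
        ploidy=1,
        sequence_length=length,
        recombination_rate=params.rho_over_mu,
        discrete_genome=True,
        random_seed=s_anc,
    )
    mts = msprime.sim_mutations(ts, rate=mu, model="jc69", random_seed=s_mut)
    arr = _alignment_from_ts(mts, length, rng)
    topo, t1, t2, trees = _truth_from_ts(ts, params)
    return SimTruth(
        alignment=_to_strings(arr),
        topology=topo,
        t_first=t1,
        t_second=t2,
        trees=trees,
        seed=seed,
        params=params,
        mu=mu,
    )


@dataclass
class TwoSiteOracleResult:
    """Empirical joint genealogy law of two adjacent sites."""

    counts: np.ndarray
    n_reps: int
    states: tuple

    @property
    def joint(self) -> np.ndarray:
        return self.counts / self.n_reps

    @property
    def se(self) -> np.ndarray:
        p = self.joint
        return np.sqrt(p * (1.0 - p) / self.n_reps)


def two_site_oracle(
    params: DemographyParams,
    grid: TimeGrid,
    n_reps: int,
    seed: int = 1,
    N_out: float | None = None,
) -> TwoSiteOracleResult:
    """Monte-Carlo joint law of the genealogies at two adjacent sites.

    Simulates ``n_reps`` independent two-site ancestries, classifies each
    site's genealogy against ``grid`` and tabulates joint frequencies.
    Validates the analytical transition construction.
    """
    dem = species_tree_demography(params, N_out=N_out)
    states = enumerate_hidden_states(grid.n_ab, grid.n_abc)
    counts = np.zeros((len(states), len(states)))
    reps = msprime.sim_ancestry(
        samples=[msprime.SampleSet(1, population=sp, ploidy=1) for sp in SPECIES],
        demography=dem,
        ploidy=1,
        sequence_length=2,
        recombination_rate=params.rho_over_mu,
        discrete_genome=True,
        num_replicates=n_reps,
        random_seed=seed,
    )
    n_ab, n_abc = grid.n_ab, grid.n_abc
    for ts in reps:
        idx = [None, None]
        for tree in ts.trees():
            tab, tac, tbc = tree.tmrca(0, 1), tree.tmrca(0, 2), tree.tmrca(1, 2)
            times = {
                frozenset({0, 1}): tab,
                frozenset({0, 2}): tac,
                frozenset({1, 2}): tbc,
            }
            pair = min(times, key=times.get)
            h = classify_genealogy(
                tuple(pair), times[pair], max(tab, tac, tbc), params, grid
            )
            k = hidden_state_index(h, n_ab, n_abc)
            lo, hi = int(tree.interval.left), int(tree.interval.right)
            for site in range(lo, hi):
                idx[site] = k
        counts[idx[0], idx[1]] += 1.0
    return TwoSiteOracleResult(counts=counts, n_reps=n_reps, states=states)


def simulate_sweep(
    params: DemographyParams,
    length: int,
    sweep_pos: float,
    two_Ne_s: float,
    seed: int = 1,
    mu: float = DEFAULT_MU,
    fix_time: float | None = None,
    N_out: float | None = None,
) -> SimTruth:
    """Alignment with a selective sweep in the A-B ancestral population.

    The beneficial variant at ``sweep_pos`` follows msprime's genic
    selection trajectory (deterministic logistic frequency path) with
    selection coefficient s = two_Ne_s / (ploidy_scale * N_AB), reaching
    fixation at ``fix_time`` (default: the first speciation time, so the
    sweep runs just above the species merge).  Neutral coalescence
    applies outside the sweep phase.

    Species isolation is expressed in a single population: A and B are
    ordinary contemporary samples kept from coalescing before the first
    speciation by an effectively infinite population size on [0, t1)
    (msprime's sweep machinery requires one population and assigns
    selective backgrounds correctly only to lineages alive before the
    sweep phase starts); C and D enter at their speciation times, after
    the sweep has completed, and their tip-branch mutations are laid
    down analytically afterwards.
    """
    if not (0 <= sweep_pos < length):
        raise ValueError("sweep position must lie within [0, length)")
    if two_Ne_s <= 0:
        raise ValueError("two_Ne_s must be > 0")
    _require_clocklike(params)
    p = params
    ps = p.ploidy_scale
    if N_out is None:
        N_out = p.N_ABC
    t1 = p.t_A
    t_abc = t1 + p.t_2
    t_out = t_abc + p.t_upper
    if fix_time is None:
        fix_time = t1
    if not (t1 <= fix_time < t_abc):
        raise ValueError("fix_time must lie in the AB-ancestral epoch")
    rng = np.random.default_rng(seed)
    s_anc, s_mut = (int(x) for x in rng.integers(1, 2**31 - 1, 2))

    isolation_size = 1e12  # no coalescence while the species are separate
    dem = msprime.Demography()
    dem.add_population(name="anc", initial_size=isolation_size)
    dem.add_population_parameters_change(time=t1 - 1.0, initial_size=ps * p.N_AB)
    dem.add_population_parameters_change(time=t_abc, initial_size=ps * p.N_ABC)
    dem.add_population_parameters_change(time=t_out, initial_size=ps * N_out)
    size_at_sweep = ps * p.N_AB
    sweep = msprime.SweepGenicSelection(
        position=sweep_pos,
        start_frequency=1.0 / size_at_sweep,
        end_frequency=1.0 - 1.0 / size_at_sweep,
        s=two_Ne_s / size_at_sweep,
        dt=1.0 / (40.0 * size_at_sweep),
    )
    sample_times = (0.0, 0.0, t_abc, t_out)
    ts = msprime.sim_ancestry(
        samples=[
            msprime.SampleSet(1, population="anc", time=t, ploidy=1)
            for t in sample_times
        ],
        demography=dem,
        ploidy=1,
        sequence_length=length,
        recombination_rate=p.rho_over_mu,
        discrete_genome=True,
        model=[
            msprime.StandardCoalescent(duration=fix_time),
            sweep,
            msprime.StandardCoalescent(),
        ],
        random_seed=s_anc,
    )
    mts = msprime.sim_mutations(ts, rate=mu, model="jc69", random_seed=s_mut)
    arr = _alignment_from_ts(mts, length, rng)
    # tip branches are absent from the tree sequence; mutate them directly
    for row, t_tip in enumerate(sample_times):
        p_sub = 0.75 * -np.expm1(-4.0 * mu * t_tip / 3.0)
        hit = rng.random(length) < p_sub
        arr[row, hit] = (arr[row, hit] + rng.integers(1, 4, int(hit.sum()))) % 4
    topo, tf, tsec, trees = _truth_from_ts(ts, params)
    return SimTruth(
        alignment=_to_strings(arr.astype(np.int8)),
        topology=topo,
        t_first=tf,
        t_second=tsec,
        trees=trees,
        seed=seed,
        params=params,
        mu=mu,
    )
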