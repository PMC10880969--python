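"""HMM hidden states and transition probabilities from chained CTMCs.

A hidden state is a rooted three-leaf genealogy: a topology label plus
the discretised time intervals of its two coalescent events.  V0 is the
species topology with the first (A,B) coalescence between the speciation
events; V1 is the species topology with both coalescences in the deep
ancestor; V2 ((A,C),B) and V3 ((B,C),A) are the incomplete-lineage-
sorting topologies, necessarily deep.

The joint law of the genealogies at two adjacent sites is computed by
propagating the two-locus ancestral process through the speciation
tree: each tip evolves a one-sequence chain until its speciation time,
A and B are merged into the 15-state two-sequence chain for the AB
epoch, the result is merged with C into the (tagged) three-sequence
chain for the deep epoch, and the interval matrices exp(Q * dt) are
sliced at the grid cutpoints.  Because coalescence only ever coarsens a
site's label partition, comparing the chain state at consecutive
cutpoints identifies exactly which coalescences each site underwent in
each interval; the first-pair tags resolve the topology when both
events of a site fall inside one interval.  Summing the resulting path
probabilities into (left genealogy, right genealogy) cells yields the
joint matrix, whose row-normalisation is the HMM transition matrix and
whose row sums are the stationary distribution.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .demography import DemographyParams, coalescent_units
from .discretization import TimeGrid
from . import state_spaces as ss

__all__ = [
    "HiddenState",
    "JointGenealogyMatrix",
    "enumerate_hidden_states",
    "hidden_state_index",
    "joint_genealogy_probabilities",
    "transition_matrix",
    "topology_label",
    "classify_genealogy",
]

TOPOLOGIES = ("V0", "V1", "V2", "V3")

# first-merged-pair tag -> deep topology
_PAIR_TO_TOPO = {
    frozenset({0, 1}): "V1",
    frozenset({0, 2}): "V2",
    frozenset({1, 2}): "V3",
}


@dataclass(frozen=True)
class HiddenState:
    """Topology plus 1-based first/second coalescent interval indices.

    For V0 the first index counts AB-epoch intervals and the second
    counts deep-epoch intervals; for V1-V3 both count deep-epoch
    intervals with first <= second.
    """

    topology: str
    first: int
    second: int

    def __post_init__(self):
        if self.topology not in TOPOLOGIES:
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.first < 1 or self.second < 1:
            raise ValueError("interval indices are 1-based")
        if self.topology != "V0" and self.second < self.first:
            raise ValueError("deep states need first <= second")

    def label(self) -> str:
        return f"{self.topology}_{self.first}_{self.second}"


def enumerate_hidden_states(n_AB: int, n_ABC: int) -> tuple[HiddenState, ...]:
    """Canonical ordering: V0 block first, then V1, V2, V3; interval
    pairs lexicographic.  Count is n_AB*n_ABC + 3*n_ABC*(n_ABC+1)/2."""
    if n_AB < 1 or n_ABC < 1:
        raise ValueError("interval counts must be >= 1")
    states = [
        HiddenState("V0", i, j)
        for i in range(1, n_AB + 1)
        for j in range(1, n_ABC + 1)
    ]
    for topo in ("V1", "V2", "V3"):
        states += [
            HiddenState(topo, m1, m2)
            for m1 in range(1, n_ABC + 1)
            for m2 in range(m1, n_ABC + 1)
        ]
    return tuple(states)


def hidden_state_index(state: HiddenState, n_AB: int, n_ABC: int) -> int:
    """Position of ``state`` in the canonical ordering, O(1)."""
    if state.topology == "V0":
        return (state.first - 1) * n_ABC + (state.second - 1)
    base = n_AB * n_ABC
    tri = n_ABC * (n_ABC + 1) // 2
    t = TOPOLOGIES.index(state.topology) - 1
    a, b = state.first, state.second
    pair = (a - 1) * (2 * n_ABC - a + 2) // 2 + (b - a)
    return base + t * tri + pair


@dataclass(frozen=True)
class JointGenealogyMatrix:
    """Joint probability that the left site carries genealogy u and the
    right site genealogy v, over the canonical hidden-state ordering.
    Entries are non-negative, the grand total is 1 and the matrix is
    symmetric (the sequence can be read in either direction)."""

    states: tuple[HiddenState, ...]
    matrix: np.ndarray
    n_AB: int
    n_ABC: int


# ---------------------------------------------------------------------------
# Event-labelled propagation
#
# A DP key is a pair (left label, right label) where a site label is
#   ()                : no coalescence yet
#   ("AB", i)         : first coalescence in AB-epoch interval i, second pending
#   ("ABC", m)        : first coalescence in deep interval m, second pending
#   (epoch, i, m2)    : complete, second coalescence in deep interval m2
# Interval indices never influence future dynamics, so vectors sharing a
# chain state but different labels evolve identically and are advanced
# with the same masked interval matrices.

_PATTERNS_BY_PHASE_AB = {0: (ss.EV_NONE, ss.EV_FIRST), 1: (ss.EV_NONE,), 2: (ss.EV_NONE,)}
_PATTERNS_BY_PHASE_ABC = {
    0: (ss.EV_NONE, ss.EV_FIRST, ss.EV_BOTH),
    1: (ss.EV_NONE, ss.EV_SECOND),
    2: (ss.EV_NONE,),
}


def _phase(label: tuple) -> int:
    return 0 if len(label) == 0 else (1 if len(label) == 2 else 2)


def _apply_event(label: tuple, ev: int, epoch: str, idx: int) -> tuple:
    if ev == ss.EV_NONE:
        return label
    if ev == ss.EV_FIRST:
        return (epoch, idx)
    if ev == ss.EV_BOTH:
        return (epoch, idx, idx)
    if ev == ss.EV_SECOND:
        return label + (idx,)
    raise AssertionError(ev)


def _advance(keys: dict, P: np.ndarray, chain, epoch: str, idx: int,
             patterns_by_phase: dict) -> dict:
    """One interval step: split every labelled vector by the site-event
    classification of the interval matrix ``P`` and relabel."""
    out: dict = {}
    cache: dict = {}
    for (lp, rp), vec in keys.items():
        for el in patterns_by_phase[_phase(lp)]:
            for er in patterns_by_phase[_phase(rp)]:
                M = cache.get((el, er))
                if M is None:
                    mask = chain.ev_masks[(el, er)]
                    if not mask.any():
                        cache[(el, er)] = False
                        continue
                    M = np.where(mask, P, 0.0)
                    cache[(el, er)] = M
                elif M is False:
                    continue
                nv = vec @ M
                if not nv.any():
                    continue
                nk = (_apply_event(lp, el, epoch, idx), _apply_event(rp, er, epoch, idx))
                if nk in out:
                    out[nk] += nv
                else:
                    out[nk] = nv
    return out


def _evolve_tip(t: float, gamma: float, rho: float) -> np.ndarray:
    """One-sequence chain from the fully linked start, over the tagged
    one-sequence state ordering."""
    chain = ss.one_sequence_chain()
    Q = chain.rate_matrix(gamma, rho, seal=False)
    start = np.zeros(len(chain.states))
    linked = [i for i, s in enumerate(chain.states) if len(s.blocks) == 1]
    start[linked[0]] = 1.0
    return start @ expm(Q * t)


def _absorption_matrix(Q: np.ndarray, absorbing: np.ndarray) -> np.ndarray:
    """Limit of exp(Q t) as t -> inf for a sealed generator: transient
    states distribute onto the absorbing set."""
    n = Q.shape[0]
    B = np.zeros((n, n))
    t_idx = np.where(~absorbing)[0]
    a_idx = np.where(absorbing)[0]
    Qtt = Q[np.ix_(t_idx, t_idx)]
    Qta = Q[np.ix_(t_idx, a_idx)]
    B[np.ix_(t_idx, a_idx)] = np.linalg.solve(-Qtt, Qta)
    B[a_idx, a_idx] = 1.0
    return B


def joint_genealogy_probabilities(
    params: DemographyParams, grid: TimeGrid
) -> JointGenealogyMatrix:
    """Joint (left genealogy, right genealogy) law at two adjacent sites.

    With rho_over_mu = 0 the matrix is diagonal; its grand total is 1
    within numerical tolerance and it is symmetric.
    """
    cu = coalescent_units(params)
    rho = params.rho_over_mu
    n_ab, n_abc = grid.n_ab, grid.n_abc
    if abs(grid.T2 - cu.T2) > 1e-8 * max(1.0, cu.T2):
        raise ValueError(
            f"grid AB epoch ends at {grid.T2}, demography implies T2={cu.T2}"
        )

    # tip branches: independent one-sequence chains
    g_tip = 1.0 / cu.tip_scale
    vA = _evolve_tip(params.t_A, g_tip, rho)
    vB = _evolve_tip(params.t_B, g_tip, rho)
    vC = _evolve_tip(params.t_C, g_tip, rho)

    # AB epoch: merge A and B, slice at the AB cutpoints
    chain2 = ss.two_sequence_chain()
    cmap11 = ss.combine_map("one_one")
    v2 = np.zeros(len(chain2.states))
    np.add.at(v2, cmap11.ravel(), np.outer(vA, vB).ravel())
    Q2 = chain2.rate_matrix(1.0 / cu.ab_scale, rho, seal=False)
    keys = {((), ()): v2}
    ab_times = cu.ab_scale * np.asarray(grid.ab)
    for i in range(1, n_ab + 1):
        P = expm(Q2 * (ab_times[i] - ab_times[i - 1]))
        keys = _advance(keys, P, chain2, "AB", i, _PATTERNS_BY_PHASE_AB)

    # second speciation: merge with C into the tagged three-sequence chain
    chain3 = ss.three_sequence_chain()
    cmap21 = ss.combine_map("two_one")
    n3 = len(chain3.states)
    keys3 = {}
    for key, vec in keys.items():
        v3 = np.zeros(n3)
        np.add.at(v3, cmap21.ravel(), np.outer(vec, vC).ravel())
        keys3[key] = v3

    Q3 = chain3.rate_matrix(1.0 / cu.abc_scale, rho, seal=True)
    abc_times = cu.abc_scale * np.asarray(grid.abc)
    for m in range(1, n_abc):
        P = expm(Q3 * (abc_times[m] - abc_times[m - 1]))
        keys3 = _advance(keys3, P, chain3, "ABC", m, _PATTERNS_BY_PHASE_ABC)
    B = _absorption_matrix(Q3, chain3.absorbing)
    keys3 = _advance(keys3, B, chain3, "ABC", n_abc, _PATTERNS_BY_PHASE_ABC)

    # read off genealogies from complete labels and absorbing-state tags
    states = enumerate_hidden_states(n_ab, n_abc)
    J = np.zeros((len(states), len(states)))
    a_idx = np.where(chain3.absorbing)[0]
    lf_tags = [chain3.states[i].lf for i in a_idx]
    rf_tags = [chain3.states[i].rf for i in a_idx]
    for (lp, rp), vec in keys3.items():
        if len(lp) != 3 or len(rp) != 3:
            # incomplete labels carry no mass after absorption
            if float(np.abs(vec).sum()) > 1e-12:
                raise AssertionError("incomplete genealogy retained mass")
            continue
        va = vec[a_idx]
        for pos, p in enumerate(va):
            if p == 0.0:
                continue
            hl = _label_to_state(lp, lf_tags[pos])
            hr = _label_to_state(rp, rf_tags[pos])
            J[
                hidden_state_index(hl, n_ab, n_abc),
                hidden_state_index(hr, n_ab, n_abc),
            ] += p

    J[J < 1e-300] = 0.0
    total = float(J.sum())
    if abs(total - 1.0) > 1e-8:
        raise AssertionError(f"joint genealogy mass is {total}, expected 1")
    return JointGenealogyMatrix(states=states, matrix=J, n_AB=n_ab, n_ABC=n_abc)


def _label_to_state(label: tuple, tag: frozenset) -> HiddenState:
    epoch, first, second = label
    if epoch == "AB":
        return HiddenState("V0", first, second)
    return HiddenState(_PAIR_TO_TOPO[tag], first, second)


def transition_matrix(joint: JointGenealogyMatrix):
    """Row-normalise the joint matrix into the HMM transition matrix.

    Returns (T, pi): row u of T is joint[u, :] / marginal[u]; pi is the
    marginal (stationary) vector.  A vanishing marginal for a reachable
    state signals a degenerate grid and raises.
    """
    J = joint.matrix
    pi = J.sum(axis=1)
    bad = pi < 1e-12
    if bad.any():
        names = [joint.states[i].label() for i in np.where(bad)[0]]
        raise ValueError(
            "degenerate grid: vanishing marginal for state(s) " + ", ".join(names)
        )
    T = J / pi[:, None]
    return T, pi


def write_transition_tsv(T: np.ndarray, pi: np.ndarray, states, path) -> None:
    """Dump a labelled transition matrix and stationary vector."""
    labels = [s.label() for s in states]
    with open(path, "w") as fh:
        fh.write("state\tstationary\t" + "\t".join(labels) + "\n")
        for lab, p, row in zip(labels, pi, T):
            fh.write(lab + f"\t{p:.10g}\t" + "\t".join(f"{x:.10g}" for x in row) + "\n")


def topology_label(
    pair: tuple[int, int] | frozenset, t_first: float, params_natural: DemographyParams
) -> str:
    """Topology of a genealogy from its first-coalescing species pair
    and first coalescence time (generations, tips at sampling times).
    The single source of the V0-V3 convention for simulation truth
    tracks and model states alike."""
    pair = frozenset(pair)
    if pair == frozenset({0, 1}) and t_first < params_natural.t_A + params_natural.t_2:
        return "V0"
    return _PAIR_TO_TOPO[pair]


def classify_genealogy(
    pair: tuple[int, int],
    t_first: float,
    t_second: float,
    params_natural: DemographyParams,
    grid: TimeGrid,
) -> HiddenState:
    """Label a simulated genealogy with the hidden-state convention.

    ``pair`` holds the two species indices (0=A, 1=B, 2=C) of the first
    coalescence, ``t_first``/``t_second`` the coalescence times in
    generations on the sample timeline (tips at their sampling times,
    first speciation at t_A).  Shared by the simulator's truth tracks so
    that simulation and model use one labelling function.
    """
    p = params_natural
    cu = coalescent_units(p)
    t_split1 = p.t_A
    t_split2 = p.t_A + p.t_2
    pair = frozenset(pair)
    topo = topology_label(pair, t_first, p)
    if topo == "V0":
        c = (t_first - t_split1) / cu.ab_scale
        first = int(np.searchsorted(grid.ab, c, side="right"))
        first = min(max(first, 1), grid.n_ab)
    else:
        u = (t_first - t_split2) / cu.abc_scale
        first = int(np.searchsorted(grid.abc, u, side="right"))
        first = min(max(first, 1), grid.n_abc)
    u2 = (t_second - t_split2) / cu.abc_scale
    second = int(np.searchsorted(grid.abc, u2, side="right"))
    second = min(max(second, 1), grid.n_abc)
    if topo != "V0":
        second = max(second, first)
    return HiddenState(topo, first, second)
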