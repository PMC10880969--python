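"""Jukes-Cantor emissions, forward likelihood and posterior decoding.

Each hidden state implies a rooted four-leaf tree: the three-leaf
genealogy of (A, B, C) with its two coalescent events placed at
representative times inside their intervals, rooted by the outgroup D
joining deterministically at the second speciation time plus t_upper.
Site-pattern probabilities for the 256 ordered nucleotide quadruples
follow from pruning under the Jukes-Cantor model with a uniform root
distribution.  Representative times are conditional expectations of the
coalescent time given the interval under the governing density (a
truncated rate-1 exponential between the speciation events; rate-3 /
rate-1 exponential components deep in time; conditional tail means for
the final infinite interval), which avoids truncation artefacts.

Observed alignment columns are encoded as integers: 0..255 for complete
(A, B, C, D) columns in base 4 with A=0, C=1, G=2, T=3, and
256 + 256*mask + partial_code for columns with missing data, where bit
i of ``mask`` flags species i as present (bit 0 = A ... bit 3 = D).
Missing tips are marginalised out of the emission; columns where A, B
and C are all missing emit probability 1 so that coordinates are kept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import cached_property

import numpy as np

from . import _kernels
from .demography import DemographyParams, coalescent_units
from .discretization import TimeGrid
from .transitions import (
    HiddenState,
    enumerate_hidden_states,
    joint_genealogy_probabilities,
    transition_matrix,
)

__all__ = [
    "jc69_transition",
    "emission_distribution",
    "emission_table",
    "forward_loglik",
    "posterior_decode",
    "HmmModel",
    "PosteriorTrack",
    "N_PATTERNS",
    "MISSING_BASE",
]

N_PATTERNS = 256
MISSING_BASE = 256  # codes >= this carry a presence mask
_ABC_PRESENT = 0b0111


def jc69_transition(t: float) -> np.ndarray:
    """Jukes-Cantor substitution probabilities after t expected
    substitutions: same base 1/4 + 3/4 e^(-4t/3), different 1/4 (1 - e^(-4t/3))."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    e = np.exp(-4.0 * t / 3.0)
    P = np.full((4, 4), 0.25 * (1.0 - e))
    np.fill_diagonal(P, 0.25 + 0.75 * e)
    return P


def _trunc_exp_mean(a: float, b: float, rate: float) -> float:
    """E[X | a < X < b] for X ~ Exponential(rate)."""
    if np.isposinf(b):
        return a + 1.0 / rate
    ra, rb = rate * a, rate * b
    den = np.exp(-ra) - np.exp(-rb)
    if den <= 0:
        return 0.5 * (a + b)
    num = (a + 1.0 / rate) * np.exp(-ra) - (b + 1.0 / rate) * np.exp(-rb)
    return num / den


def representative_times(state: HiddenState, grid: TimeGrid) -> tuple[float, float]:
    """Conditional-mean coalescent times (in epoch coalescent units) of
    the two events of a hidden state within their intervals."""
    if state.topology == "V0":
        tau1 = _trunc_exp_mean(grid.ab[state.first - 1], grid.ab[state.first], 1.0)
        tau2 = _trunc_exp_mean(grid.abc[state.second - 1], grid.abc[state.second], 1.0)
    else:
        tau1 = _trunc_exp_mean(grid.abc[state.first - 1], grid.abc[state.first], 3.0)
        if state.second > state.first:
            tau2 = _trunc_exp_mean(grid.abc[state.second - 1], grid.abc[state.second], 1.0)
        else:
            tau2 = _trunc_exp_mean(tau1, grid.abc[state.second], 1.0)
    return tau1, tau2


def _branch_lengths(state: HiddenState, params: DemographyParams, grid: TimeGrid):
    """Six branch lengths (mutation units) of the rooted four-leaf tree.

    Returns (first_pair, la, lb, lc, l_n1, l_n2_root, ld) where la/lb/lc
    are tip-to-first-coalescence or tip-to-second-coalescence lengths as
    dictated by the topology.
    """
    cu = coalescent_units(params)
    tau1, tau2 = representative_times(state, grid)
    p = params
    if state.topology == "V0":
        t1 = tau1 * cu.ab_scale  # within the AB epoch
        t2 = tau2 * cu.abc_scale  # after the second speciation
        la = p.t_A + t1
        lb = p.t_B + t1
        l_n1 = (p.t_2 - t1) + t2
        lc = p.t_C + t2
        pair = ("A", "B")
    else:
        t1 = tau1 * cu.abc_scale
        t2 = tau2 * cu.abc_scale
        if state.topology == "V1":
            la, lb = p.t_A + p.t_2 + t1, p.t_B + p.t_2 + t1
            lc = p.t_C + t2
            pair = ("A", "B")
        elif state.topology == "V2":
            la, lb = p.t_A + p.t_2 + t1, p.t_C + t1
            lc = p.t_B + p.t_2 + t2
            pair = ("A", "C")
        else:  # V3
            la, lb = p.t_B + p.t_2 + t1, p.t_C + t1
            lc = p.t_A + p.t_2 + t2
            pair = ("B", "C")
        l_n1 = t2 - t1
    l_root = max(p.t_upper - t2, 0.0)
    ld = p.t_C + p.t_upper
    return pair, la, lb, lc, l_n1, l_root, ld


def emission_distribution(
    state: HiddenState, params: DemographyParams, grid: TimeGrid
) -> np.ndarray:
    """Pattern probabilities (length 256, summing to 1) for one state."""
    pair, la, lb, lc, l_n1, l_root, ld = _branch_lengths(state, params, grid)
    Pa, Pb, Pc = jc69_transition(la), jc69_transition(lb), jc69_transition(lc)
    P1, Pr, Pd = jc69_transition(l_n1), jc69_transition(l_root), jc69_transition(ld)
    # cherry = (x -> two cherry tips), then y joins the third tip, root joins D
    cherry = np.einsum("xa,xb->xab", Pa, Pb)
    upper = np.einsum("yx,xab->yab", P1, cherry)
    three = np.einsum("yab,yc->yabc", upper, Pc)
    rooted = np.einsum("ry,yabc->rabc", Pr, three)
    full = 0.25 * np.einsum("rabc,rd->abcd", rooted, Pd)
    # map cherry/third positions back onto the fixed (A, B, C, D) order
    if pair == ("A", "B"):
        pat = full  # a=A, b=B, c=C
    elif pair == ("A", "C"):
        pat = np.transpose(full, (0, 2, 1, 3))  # a=A, b=C, c=B
    else:  # ("B", "C")
        pat = np.transpose(full, (2, 0, 1, 3))  # a=B, b=C, c=A
    return pat.reshape(N_PATTERNS)


def emission_table(params: DemographyParams, grid: TimeGrid) -> np.ndarray:
    """Hidden-state x 256 emission matrix; rows sum to 1."""
    states = enumerate_hidden_states(grid.n_ab, grid.n_abc)
    E = np.empty((len(states), N_PATTERNS))
    for i, s in enumerate(states):
        E[i] = emission_distribution(s, params, grid)
    return E


def masked_emission_table(E: np.ndarray) -> np.ndarray:
    """Extend an (S, 256) table over the missing-data code space.

    Output shape (S, 256 * 17): codes < 256 are complete patterns; code
    256 + 256*mask + c marginalises the absent species out.  Masks with
    A, B and C all absent emit 1.
    """
    S = E.shape[0]
    out = np.empty((S, N_PATTERNS * 17))
    out[:, :N_PATTERNS] = E
    E4 = E.reshape(S, 4, 4, 4, 4)
    for mask in range(16):
        block = slice(MISSING_BASE + mask * N_PATTERNS, MISSING_BASE + (mask + 1) * N_PATTERNS)
        if mask & _ABC_PRESENT == 0:
            out[:, block] = 1.0
            continue
        M = E4
        for species in range(4):
            if not (mask >> species) & 1:
                M = M.sum(axis=1 + species, keepdims=True)
        out[:, block] = np.broadcast_to(M, (S, 4, 4, 4, 4)).reshape(S, N_PATTERNS)
    return out


@dataclass
class PosteriorTrack:
    """Per-column posterior over hidden states with grouped summaries.

    ``topology`` sums states sharing a topology (columns V0..V3);
    ``first`` groups by first-coalescent interval (n_AB shallow then
    n_ABC deep columns); ``second`` groups by second-coalescent interval.
    """

    states: tuple[HiddenState, ...]
    n_AB: int
    n_ABC: int
    posterior: np.ndarray
    loglik: float

    def __len__(self) -> int:
        return self.posterior.shape[0]

    @cached_property
    def topology(self) -> np.ndarray:
        out = np.zeros((len(self), 4))
        for i, s in enumerate(self.states):
            out[:, int(s.topology[1])] += self.posterior[:, i]
        return out

    @cached_property
    def first(self) -> np.ndarray:
        out = np.zeros((len(self), self.n_AB + self.n_ABC))
        for i, s in enumerate(self.states):
            col = s.first - 1 if s.topology == "V0" else self.n_AB + s.first - 1
            out[:, col] += self.posterior[:, i]
        return out

    @cached_property
    def second(self) -> np.ndarray:
        out = np.zeros((len(self), self.n_ABC))
        for i, s in enumerate(self.states):
            out[:, s.second - 1] += self.posterior[:, i]
        return out

    @cached_property
    def modal_state(self) -> np.ndarray:
        """Index of the most probable state per column (ties -> lowest)."""
        return self.posterior.argmax(axis=1)


class HmmModel:
    """Transition, stationary and emission structure for one parameter
    set and grid; the workhorse behind the public functions."""

    def __init__(self, params: DemographyParams, grid: TimeGrid):
        self.params = params
        self.grid = grid
        joint = joint_genealogy_probabilities(params, grid)
        self.states = joint.states
        self.transition, self.stationary = transition_matrix(joint)
        self.emission = emission_table(params, grid)
        self._ext_T: np.ndarray | None = None
        self._plain_T: np.ndarray | None = None

    def _emission_rows(self, codes: np.ndarray) -> np.ndarray:
        """Code-indexed emission lookup, extended over the missing-data
        code space only when the observations need it."""
        if codes.max() >= MISSING_BASE:
            if self._ext_T is None:
                self._ext_T = np.ascontiguousarray(
                    masked_emission_table(self.emission).T
                )
            return self._ext_T
        if self._ext_T is not None:
            return self._ext_T
        if self._plain_T is None:
            self._plain_T = np.ascontiguousarray(self.emission.T)
        return self._plain_T

    def loglik(self, codes: np.ndarray) -> float:
        codes = np.asarray(codes, dtype=np.int64)
        if codes.size == 0:
            warnings.warn("empty observation sequence; log-likelihood is 0")
            return 0.0
        E = self._emission_rows(codes)
        return float(_kernels.loglik(self.stationary, self.transition, E, codes))

    def posterior(self, codes: np.ndarray) -> PosteriorTrack:
        codes = np.asarray(codes, dtype=np.int64)
        if codes.size == 0:
            warnings.warn("empty observation sequence; empty posterior")
            return PosteriorTrack(self.states, self.grid.n_ab, self.grid.n_abc,
                                  np.zeros((0, len(self.states))), 0.0)
        E = self._emission_rows(codes)
        alpha, scale = _kernels.forward(self.stationary, self.transition, E, codes)
        gamma = _kernels.backward_posterior(self.transition, E, codes, alpha, scale)
        ll = float(np.log(scale).sum())
        return PosteriorTrack(self.states, self.grid.n_ab, self.grid.n_abc, gamma, ll)


def forward_loglik(
    observations: np.ndarray, params: DemographyParams, grid: TimeGrid
) -> float:
    """Log-likelihood of an encoded column sequence under the HMM
    (scaled forward recursion)."""
    return HmmModel(params, grid).loglik(observations)


def posterior_decode(
    observations: np.ndarray, params: DemographyParams, grid: TimeGrid
) -> PosteriorTrack:
    """Forward-backward posterior decoding with grouped summaries."""
    return HmmModel(params, grid).posterior(observations)
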