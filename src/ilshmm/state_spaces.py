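"""Two-locus ancestral-process state spaces and CTMC rate matrices.

The coalescent with recombination restricted to two contiguous sites is a
finite continuous-time Markov chain.  A state is a set of lineage
*blocks*; each block carries the subset of sample labels whose left-site
material it is ancestral to, and likewise for the right site.  Backwards
in time a block carrying material at both sites splits into a left-only
and a right-only block at the recombination rate, and any two blocks
merge (site-wise label union) at the pairwise coalescence rate.  Material
that has fully coalesced (one block carries every label at that site) is
retained, and states in which *both* sites have fully coalesced are
absorbing.  Under this convention the chain has 2 states for one
sequence, 15 for two (the Simonsen-Churchill process) and 203 for three,
with exactly two absorbing states for k >= 2 (both sites coalesced in
the same block, or in two different blocks).

The public functions expose the plain state space.  The private
:class:`AncestralChain` additionally tags each site with the identity of
the first pair of labels that merged, which the transition-probability
pipeline needs to resolve the gene-tree topology when both coalescences
of a site fall inside a single discretised time interval.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np

__all__ = [
    "TwoLocusState",
    "RateMatrix",
    "enumerate_two_locus_states",
    "build_rate_matrix",
    "combine_lineage_distributions",
]

_EXPECTED_COUNTS = {1: 2, 2: 15, 3: 203}

# Site-event classes for endpoint pairs of an interval (per site).
EV_NONE = 0   # no coalescence at this site
EV_FIRST = 1  # first coalescence (singletons -> one pair)
EV_BOTH = 2   # first and second coalescence within the interval
EV_SECOND = 3  # second coalescence (pair -> fully merged)
EV_IMPOSSIBLE = -1

Block = tuple[frozenset, frozenset]


def _canon_blocks(blocks) -> frozenset:
    return frozenset(blocks)


def _block_sort_key(block: Block, k: int):
    L, R = block
    return (min(L) if L else k, min(R) if R else k)


def _encode(blocks: frozenset, k: int) -> str:
    """Canonical string form: blocks sorted by (min left, min right)."""
    parts = []
    for L, R in sorted(blocks, key=lambda b: _block_sort_key(b, k)):
        ls = "".join(str(i + 1) for i in sorted(L)) or "."
        rs = "".join(str(i + 1) for i in sorted(R)) or "."
        parts.append(f"{ls}|{rs}")
    return ";".join(parts)


def _site_partition(blocks: frozenset, side: int) -> frozenset:
    return frozenset(b[side] for b in blocks if b[side])


@dataclass(frozen=True)
class TwoLocusState:
    """A plain (untagged) state of the two-locus ancestral process."""

    blocks: frozenset
    k: int

    @property
    def encoding(self) -> str:
        return _encode(self.blocks, self.k)

    def partition(self, side: int) -> frozenset:
        """Partition of labels induced at a site (0 = left, 1 = right)."""
        return _site_partition(self.blocks, side)

    @property
    def left_coalesced(self) -> bool:
        labels = frozenset(range(self.k))
        return any(b[0] == labels for b in self.blocks)

    @property
    def right_coalesced(self) -> bool:
        labels = frozenset(range(self.k))
        return any(b[1] == labels for b in self.blocks)

    @property
    def is_absorbing(self) -> bool:
        # For a single sequence "full coalescence" is vacuous: Eq-style
        # one-sequence chains keep cycling between linked and unlinked.
        return self.k >= 2 and self.left_coalesced and self.right_coalesced

    def __repr__(self) -> str:  # pragma: no cover
        return f"TwoLocusState({self.encoding})"


def _moves(blocks: frozenset, labels: frozenset, absorbing: bool):
    """Yield (target_blocks, kind, detail) for every single event.

    kind is "rec" or "coal"; for coalescences detail is the pair of
    merged blocks (used by the tagged chain to update first-pair tags).
    """
    if absorbing:
        return
    bl = list(blocks)
    for b in bl:
        L, R = b
        if L and R:
            nb = [x for x in bl if x != b]
            nb += [(L, frozenset()), (frozenset(), R)]
            yield _canon_blocks(nb), "rec", None
    for b1, b2 in combinations(bl, 2):
        nb = [x for x in bl if x not in (b1, b2)]
        nb.append((b1[0] | b2[0], b1[1] | b2[1]))
        yield _canon_blocks(nb), "coal", (b1, b2)


def _is_absorbing_blocks(blocks: frozenset, k: int) -> bool:
    if k < 2:
        return False
    labels = frozenset(range(k))
    return any(b[0] == labels for b in blocks) and any(b[1] == labels for b in blocks)


@lru_cache(maxsize=None)
def enumerate_two_locus_states(k: int) -> tuple[TwoLocusState, ...]:
    """All states of the k-sequence two-locus process, canonically ordered.

    Reachability closure from the fully linked start (every sequence a
    single block carrying both its sites), ordered by the canonical
    string encoding.  Counts are 2, 15 and 203 for k = 1, 2, 3.
    """
    if k not in (1, 2, 3):
        raise ValueError(f"k must be in {{1, 2, 3}}, got {k!r}")
    labels = frozenset(range(k))
    start = _canon_blocks((frozenset([i]), frozenset([i])) for i in range(k))
    seen = {start}
    stack = [start]
    while stack:
        blocks = stack.pop()
        for target, _, _ in _moves(blocks, labels, _is_absorbing_blocks(blocks, k)):
            if target not in seen:
                seen.add(target)
                stack.append(target)
    states = sorted(
        (TwoLocusState(blocks=b, k=k) for b in seen), key=lambda s: s.encoding
    )
    return tuple(states)


@dataclass(frozen=True)
class RateMatrix:
    """CTMC generator over an ordered two-locus state list.

    Rows sum to zero, off-diagonals are non-negative and absorbing-state
    rows are identically zero.
    """

    states: tuple[TwoLocusState, ...]
    matrix: np.ndarray
    coal_rate: float
    rec_rate: float


def build_rate_matrix(
    states: tuple[TwoLocusState, ...], coal_rate: float, rec_rate: float
) -> RateMatrix:
    """Generator of the two-locus coalescent-with-recombination CTMC.

    Every block carrying material at both sites recombines at
    ``rec_rate``; every unordered pair of blocks coalesces at
    ``coal_rate`` (site-wise unions).  For one sequence this is exactly
    the 2x2 generator [[-coal, coal], [rec, -rec]] over
    (unlinked, linked).
    """
    if coal_rate < 0 or rec_rate < 0:
        raise ValueError("rates must be non-negative")
    k = states[0].k
    index = {s.blocks: i for i, s in enumerate(states)}
    n = len(states)
    Q = np.zeros((n, n))
    labels = frozenset(range(k))
    for i, s in enumerate(states):
        for target, kind, _ in _moves(s.blocks, labels, s.is_absorbing):
            Q[i, index[target]] += rec_rate if kind == "rec" else coal_rate
    np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
    return RateMatrix(states=states, matrix=Q, coal_rate=coal_rate, rec_rate=rec_rate)


def combine_lineage_distributions(p_left: np.ndarray, p_right: np.ndarray) -> np.ndarray:
    """Merge final distributions of two independent chains into one.

    At a speciation event (backwards in time) the lineages of two
    previously isolated populations enter a common ancestral population;
    the state of the merged chain is the disjoint union of the component
    blocks, with the second chain's labels shifted.  Probabilities are
    over the canonical orderings of :func:`enumerate_two_locus_states`.
    """
    k1 = _k_from_len(len(p_left))
    k2 = _k_from_len(len(p_right))
    if k1 + k2 > 3:
        raise ValueError("combined chain supports at most 3 sequences")
    for name, p in (("p_left", p_left), ("p_right", p_right)):
        if abs(float(np.sum(p)) - 1.0) > 1e-9:
            raise ValueError(f"{name} must sum to 1 within 1e-9")
    states1 = enumerate_two_locus_states(k1)
    states2 = enumerate_two_locus_states(k2)
    out_states = enumerate_two_locus_states(k1 + k2)
    out_index = {s.blocks: i for i, s in enumerate(out_states)}
    out = np.zeros(len(out_states))
    for i, s1 in enumerate(states1):
        if p_left[i] == 0:
            continue
        for j, s2 in enumerate(states2):
            if p_right[j] == 0:
                continue
            merged = _canon_blocks(
                list(s1.blocks) + [_shift_block(b, k1) for b in s2.blocks]
            )
            out[out_index[merged]] += p_left[i] * p_right[j]
    return out


def _shift_block(block: Block, offset: int) -> Block:
    L, R = block
    return (frozenset(x + offset for x in L), frozenset(x + offset for x in R))


def write_states_tsv(k: int, path) -> None:
    """Dump the canonical state list for debugging."""
    with open(path, "w") as fh:
        fh.write("index\tencoding\tn_blocks\tabsorbing\n")
        for i, s in enumerate(enumerate_two_locus_states(k)):
            fh.write(f"{i}\t{s.encoding}\t{len(s.blocks)}\t{int(s.is_absorbing)}\n")


def _k_from_len(n: int) -> int:
    for k, count in _EXPECTED_COUNTS.items():
        if count == n:
            return k
    raise ValueError(f"no {{1,2,3}}-sequence chain has {n} states")


# ---------------------------------------------------------------------------
# Tagged chain used by the transition-probability pipeline


@dataclass(frozen=True)
class TaggedState:
    """Plain state plus per-site first-merged-pair tags.

    ``lf``/``rf`` record which pair of labels was the first to coalesce
    at the left/right site (None while the site is still fully
    unresolved).  The tag equals the unique non-singleton class of the
    site partition while only one merge has happened, and keeps that
    information once the partition has fully collapsed - which is what
    the genealogy bookkeeping needs.
    """

    blocks: frozenset
    lf: frozenset | None
    rf: frozenset | None


class AncestralChain:
    """Tagged two-locus chain over k sequences, with event bookkeeping.

    Attributes
    ----------
    states : list of TaggedState, canonically ordered
    coal, rec : structural count matrices; the generator for rates
        (gamma, rho) is ``gamma * coal + rho * rec`` with the diagonal
        set to minus the row sums (absorbing rows optionally zeroed).
    cls_left, cls_right : per ordered state pair, the site-event class
        of any within-interval path between them (EV_*); impossible
        pairs are EV_IMPOSSIBLE.
    """

    def __init__(self, k: int, roots: list[TaggedState]):
        self.k = k
        labels = frozenset(range(k))
        seen = set(roots)
        stack = list(seen)
        edges: list[tuple[TaggedState, TaggedState, str]] = []
        while stack:
            s = stack.pop()
            absorbing = _is_absorbing_blocks(s.blocks, k)
            for target_blocks, kind, detail in _moves(s.blocks, labels, absorbing):
                lf, rf = s.lf, s.rf
                if kind == "coal":
                    b1, b2 = detail
                    if lf is None and b1[0] and b2[0]:
                        lf = b1[0] | b2[0]
                    if rf is None and b1[1] and b2[1]:
                        rf = b1[1] | b2[1]
                t = TaggedState(target_blocks, lf, rf)
                edges.append((s, t, kind))
                if t not in seen:
                    seen.add(t)
                    stack.append(t)

        def sort_key(s: TaggedState):
            return (
                _encode(s.blocks, k),
                tuple(sorted(s.lf)) if s.lf else (),
                tuple(sorted(s.rf)) if s.rf else (),
            )

        self.states = sorted(seen, key=sort_key)
        self.index = {s: i for i, s in enumerate(self.states)}
        n = len(self.states)
        self.coal = np.zeros((n, n))
        self.rec = np.zeros((n, n))
        for s, t, kind in edges:
            mat = self.coal if kind == "coal" else self.rec
            mat[self.index[s], self.index[t]] += 1.0
        self.absorbing = np.array(
            [_is_absorbing_blocks(s.blocks, k) for s in self.states]
        )
        self.cls_left = self._classify(side=0)
        self.cls_right = self._classify(side=1)
        self.ev_masks = {
            (el, er): (self.cls_left == el) & (self.cls_right == er)
            for el in (EV_NONE, EV_FIRST, EV_BOTH, EV_SECOND)
            for er in (EV_NONE, EV_FIRST, EV_BOTH, EV_SECOND)
        }

    def _classify(self, side: int) -> np.ndarray:
        k = self.k
        n = len(self.states)
        parts = [_site_partition(s.blocks, side) for s in self.states]
        merges = np.array([k - len(p) for p in parts])
        tags = [(s.lf if side == 0 else s.rf) for s in self.states]
        cls = np.full((n, n), EV_IMPOSSIBLE, dtype=np.int8)
        for i in range(n):
            for j in range(n):
                d = merges[j] - merges[i]
                if d < 0:
                    continue
                if tags[i] is not None and tags[j] != tags[i]:
                    continue
                if d == 0:
                    if parts[i] == parts[j]:
                        cls[i, j] = EV_NONE
                elif d == 1:
                    cls[i, j] = EV_FIRST if merges[i] == 0 else EV_SECOND
                elif d == 2:
                    cls[i, j] = EV_BOTH
        return cls

    def rate_matrix(self, coal_rate: float, rec_rate: float, seal: bool = True) -> np.ndarray:
        """Generator; with ``seal`` absorbing rows are zeroed (the public
        convention), without it fully coalesced lineages keep
        recombining/re-linking, which matters mid-pipeline."""
        Q = coal_rate * self.coal + rec_rate * self.rec
        if seal:
            Q[self.absorbing, :] = 0.0
        np.fill_diagonal(Q, Q.diagonal() - Q.sum(axis=1))
        return Q


@lru_cache(maxsize=None)
def one_sequence_chain() -> AncestralChain:
    start = TaggedState(
        _canon_blocks([(frozenset([0]), frozenset([0]))]), None, None
    )
    return AncestralChain(1, [start])


@lru_cache(maxsize=None)
def two_sequence_chain() -> AncestralChain:
    """Chain over labels {0, 1}, rooted at all products of one-sequence
    states (every configuration two isolated sequences can arrive in)."""
    one = one_sequence_chain()
    roots = []
    for s1 in one.states:
        for s2 in one.states:
            blocks = list(s1.blocks) + [_shift_block(b, 1) for b in s2.blocks]
            roots.append(TaggedState(_canon_blocks(blocks), None, None))
    return AncestralChain(2, roots)


@lru_cache(maxsize=None)
def three_sequence_chain() -> AncestralChain:
    """Tagged chain over labels {0, 1, 2} (species A, B, C), rooted at all
    products of two-sequence states with a one-sequence state for C."""
    two = two_sequence_chain()
    one = one_sequence_chain()
    roots = []
    for s2 in two.states:
        for s1 in one.states:
            blocks = list(s2.blocks) + [_shift_block(b, 2) for b in s1.blocks]
            roots.append(TaggedState(_canon_blocks(blocks), s2.lf, s2.rf))
    return AncestralChain(3, roots)


@lru_cache(maxsize=None)
def combine_map(which: str) -> np.ndarray:
    """Index map for merging chains at a speciation event.

    "one_one": (i, j) over one-sequence states -> two-sequence index.
    "two_one": (i, j) over (two-sequence, one-sequence) -> three-sequence
    index, carrying the AB chain's first-pair tags.
    """
    if which == "one_one":
        a, b, out, offset = one_sequence_chain(), one_sequence_chain(), two_sequence_chain(), 1
    elif which == "two_one":
        a, b, out, offset = two_sequence_chain(), one_sequence_chain(), three_sequence_chain(), 2
    else:  # pragma: no cover
        raise ValueError(which)
    m = np.zeros((len(a.states), len(b.states)), dtype=np.int64)
    for i, sa in enumerate(a.states):
        for j, sb in enumerate(b.states):
            blocks = list(sa.blocks) + [_shift_block(blk, offset) for blk in sb.blocks]
            t = TaggedState(_canon_blocks(blocks), sa.lf, sa.rf)
            m[i, j] = out.index[t]
    return m


for _k, _expected in _EXPECTED_COUNTS.items():
    _n = len(enumerate_two_locus_states(_k))
    if _n != _expected:  # pragma: no cover - structural self-check
        raise AssertionError(
            f"two-locus state space for k={_k} has {_n} states, expected {_expected}"
        )
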