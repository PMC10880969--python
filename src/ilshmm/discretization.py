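"""Time grids that discretise coalescent times into HMM intervals.

The AB-ancestral epoch spans [0, T2] in AB coalescent units and is cut
into ``n_AB`` intervals; the deep (ABC) epoch spans [0, inf) in ABC
coalescent units and is cut into ``n_ABC`` intervals, the last one
infinite.  The default scheme takes equal-probability quantiles of the
density governing the *first* coalescent in each epoch: a truncated
rate-1 exponential between the speciation events, and a rate-1
exponential deep in time.  Two alternative deep-epoch schemes target the
first coalescent conditional on deep coalescence (rate-3 exponential -
three lineages are present) and the second coalescent (a phase-type
distribution: a mixture of a rate-1 exponential with the convolution of
rate-3 and rate-1 exponentials).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm
from scipy.optimize import brentq

__all__ = [
    "TimeGrid",
    "default_cutpoints",
    "rate3_cutpoints",
    "phase_type_cutpoints",
    "custom_grid",
    "phase_type_cdf",
    "phase_type_mean",
    "second_coalescent_phase_type",
]

SCHEMES = ("default", "rate3", "phase_type", "custom")


@dataclass(frozen=True)
class TimeGrid:
    """Cutpoints for both ancestral epochs, in per-epoch coalescent units.

    ``ab`` has length n_AB + 1 running from 0 to T2 exactly; ``abc`` has
    length n_ABC + 1 running from 0 to +inf.
    """

    ab: np.ndarray
    abc: np.ndarray
    scheme: str = "default"

    def __post_init__(self):
        ab = np.asarray(self.ab, dtype=float)
        abc = np.asarray(self.abc, dtype=float)
        object.__setattr__(self, "ab", ab)
        object.__setattr__(self, "abc", abc)
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for name, cuts in (("ab", ab), ("abc", abc)):
            if cuts.ndim != 1 or len(cuts) < 2:
                raise ValueError(f"{name} cutpoints need at least one interval")
            if cuts[0] != 0.0:
                raise ValueError(f"{name} cutpoints must start at 0")
            if not np.all(np.diff(cuts) > 0):
                raise ValueError(f"{name} cutpoints must be strictly increasing")
        if not np.isposinf(abc[-1]):
            raise ValueError("last ABC cutpoint must be +inf")
        if not np.isfinite(ab[-1]):
            raise ValueError("last AB cutpoint must be finite (T2)")

    @property
    def n_ab(self) -> int:
        return len(self.ab) - 1

    @property
    def n_abc(self) -> int:
        return len(self.abc) - 1

    @property
    def T2(self) -> float:
        return float(self.ab[-1])


def default_cutpoints(n_AB: int, n_ABC: int, T2: float) -> TimeGrid:
    """Equal-probability quantile grid for the first coalescent.

    AB cutpoint i solves (1 - e^-c) / (1 - e^-T2) = i / n_AB (truncated
    rate-1 exponential); ABC cutpoint j is -log(1 - j/n_ABC).
    """
    if n_AB < 1 or n_ABC < 1:
        raise ValueError("interval counts must be >= 1")
    if not (T2 > 0):
        raise ValueError("T2 must be > 0")
    i = np.arange(n_AB + 1)
    ab = -np.log1p(-(i / n_AB) * (-np.expm1(-T2)))
    ab[-1] = T2  # exact endpoint
    j = np.arange(n_ABC + 1)
    with np.errstate(divide="ignore"):
        abc = -np.log1p(-j / n_ABC)
    return TimeGrid(ab=ab, abc=abc, scheme="default")


def rate3_cutpoints(n: int) -> np.ndarray:
    """Deep-epoch cutpoints from rate-3 exponential quantiles.

    Appropriate for the first coalescent conditional on happening deep
    in time, where three lineages are present.  Returns the ABC
    cutpoints only; combine with an AB grid via :func:`custom_grid`.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    j = np.arange(n + 1)
    with np.errstate(divide="ignore"):
        return -np.log1p(-j / n) / 3.0


def second_coalescent_phase_type(T2: float):
    """Sub-intensity matrix S and initial vector pi of the second
    coalescent time (measured from the second speciation, in ABC
    coalescent units).

    With probability 1 - e^-T2 the first coalescent happened between the
    speciation events and the second is a rate-1 exponential; otherwise
    three lineages survive and the second coalescent is the convolution
    of rate-3 and rate-1 exponentials.
    """
    S = np.array([[-1.0, 0.0, 0.0], [0.0, -3.0, 3.0], [0.0, 0.0, -1.0]])
    p_v0 = -np.expm1(-T2)
    pi = np.array([p_v0, 1.0 - p_v0, 0.0])
    return S, pi


def phase_type_cdf(t, S: np.ndarray, pi: np.ndarray):
    """CDF(t) = 1 - pi . exp(tS) . 1 of a phase-type distribution."""
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    out = np.empty(np.atleast_1d(t).shape)
    for idx, ti in enumerate(np.atleast_1d(t)):
        if np.isposinf(ti):
            out[idx] = 1.0
        else:
            out[idx] = 1.0 - pi @ expm(ti * S) @ np.ones(len(pi))
    return float(out[0]) if scalar else out


def phase_type_mean(S: np.ndarray, pi: np.ndarray) -> float:
    """Mean absorption time -pi . S^-1 . 1."""
    return float(-pi @ np.linalg.solve(S, np.ones(len(pi))))


def phase_type_cutpoints(
    n: int,
    t2_gens: float | None = None,
    N_AB: float | None = None,
    ploidy_scale: float = 2.0,
    T2: float | None = None,
    tol: float = 1e-10,
) -> np.ndarray:
    """Deep-epoch cutpoints from second-coalescent phase-type quantiles.

    The epoch length between speciations can be given either directly in
    AB coalescent units (``T2``) or as generations plus a population
    size (``t2_gens``, ``N_AB``), with the 1/(ploidy_scale*N) rate
    convention.  Quantiles are found by monotone root bracketing to
    |CDF - q| < tol; non-convergence raises rather than clamping.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if T2 is None:
        if t2_gens is None or N_AB is None:
            raise ValueError("give either T2 or (t2_gens, N_AB)")
        if t2_gens <= 0 or N_AB <= 0:
            raise ValueError("t2_gens and N_AB must be > 0")
        T2 = t2_gens / (ploidy_scale * N_AB)
    S, pi = second_coalescent_phase_type(T2)
    cuts = [0.0]
    hi = 1.0
    for j in range(1, n):
        q = j / n
        while phase_type_cdf(hi, S, pi) < q:
            hi *= 2.0
            if hi > 1e6:  # pragma: no cover
                raise RuntimeError("phase-type quantile bracketing failed")
        c = brentq(lambda t: phase_type_cdf(t, S, pi) - q, 0.0, hi, xtol=tol)
        if abs(phase_type_cdf(c, S, pi) - q) > max(100 * tol, 1e-8):
            raise RuntimeError(f"phase-type quantile {q} did not converge")
        cuts.append(c)
    cuts.append(np.inf)
    return np.array(cuts)


def custom_grid(ab_cutpoints, abc_cutpoints, scheme: str = "custom") -> TimeGrid:
    """Wrap user-supplied cutpoint lists (validated) into a TimeGrid."""
    return TimeGrid(ab=np.asarray(ab_cutpoints, float),
                    abc=np.asarray(abc_cutpoints, float), scheme=scheme)
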