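"""Demographic model for a three-species-plus-outgroup speciation tree.

The model is a species tree ((A,B),C) rooted by an outgroup D, with two
ancestral populations: the A-B ancestor (effective size ``N_AB``, lasting
``t_2`` generations between the two speciation events) and the deeper
A-B-C ancestor (size ``N_ABC``, unbounded).  Because only the products of
rates and times are identifiable, the mutation rate is fixed to 1 and all
parameters are expressed in mutation units: times are generations times
the per-site per-generation mutation rate, population sizes are
individuals times the mutation rate, and recombination enters as the
ratio rho/mu.  :func:`rescale` converts to and from natural units.

Coalescence of a pair of lineages happens at rate ``1/(ploidy_scale * N)``
per generation.  The default ``ploidy_scale = 2`` is the usual diploid
convention (rate 1/(2N)); setting it to 1 reads sizes as haploid.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

MODES = ("ultrametric", "non-ultrametric")

_REL_TOL = 1e-9


@dataclass(frozen=True)
class DemographyParams:
    """Full parameter vector of the speciation model, in mutation units.

    Parameters
    ----------
    t_A, t_B, t_C
        Tip sampling-to-speciation times: A and B run to the first
        speciation event, C to the second.
    t_2
        Time between the first and the second speciation event.
    t_upper
        Time from the second speciation to the outgroup divergence; the
        outgroup lineage joins the ingroup root deterministically there.
    N_AB, N_ABC
        Ancestral effective population sizes.
    rho_over_mu
        Recombination/mutation rate ratio (dimensionless).
    mode
        "ultrametric" enforces the molecular clock t_A = t_B = t_C - t_2;
        "non-ultrametric" leaves the three tip branches free.
    ploidy_scale
        Pairwise coalescence rate is 1/(ploidy_scale*N) per generation.
    N_tip
        Effective size governing re-linking of recombined sites on tip
        branches (not an optimised parameter). Defaults to N_AB.
    """

    t_A: float
    t_B: float
    t_C: float
    t_2: float
    t_upper: float
    N_AB: float
    N_ABC: float
    rho_over_mu: float
    mode: str = "ultrametric"
    ploidy_scale: float = 2.0
    N_tip: float | None = None

    def __post_init__(self) -> None:
        for name in ("t_A", "t_B", "t_C", "t_2", "t_upper", "N_AB", "N_ABC"):
            v = getattr(self, name)
            if not (v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        if self.rho_over_mu < 0:
            raise ValueError("rho_over_mu must be >= 0")
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.ploidy_scale <= 0:
            raise ValueError("ploidy_scale must be > 0")
        if self.N_tip is not None and self.N_tip <= 0:
            raise ValueError("N_tip must be > 0 when given")
        if self.mode == "ultrametric":
            t1 = self.t_A
            if not (_close(self.t_B, t1) and _close(self.t_C - self.t_2, t1)):
                raise ValueError(
                    "ultrametric mode requires t_A = t_B = t_C - t_2; got "
                    f"t_A={self.t_A}, t_B={self.t_B}, t_C - t_2={self.t_C - self.t_2}"
                )

    @classmethod
    def ultrametric(
        cls,
        t_1: float,
        t_2: float,
        t_upper: float,
        N_AB: float,
        N_ABC: float,
        rho_over_mu: float,
        **kwargs,
    ) -> "DemographyParams":
        """Build a clock-like parameter set from the shared tip time t_1."""
        return cls(
            t_A=t_1,
            t_B=t_1,
            t_C=t_1 + t_2,
            t_2=t_2,
            t_upper=t_upper,
            N_AB=N_AB,
            N_ABC=N_ABC,
            rho_over_mu=rho_over_mu,
            mode="ultrametric",
            **kwargs,
        )

    @property
    def t_1(self) -> float:
        """Shared tip time in ultrametric mode (t_A by convention)."""
        return self.t_A

    @property
    def tip_Ne(self) -> float:
        return self.N_AB if self.N_tip is None else self.N_tip

    def replace(self, **changes) -> "DemographyParams":
        return dataclasses.replace(self, **changes)


def _close(a: float, b: float) -> bool:
    return abs(a - b) <= _REL_TOL * max(abs(a), abs(b), 1.0)


def rescale(params: DemographyParams, mu: float) -> DemographyParams:
    """Convert parameters between mutation units and natural units.

    Dividing every time and size by ``mu`` and multiplying the
    recombination ratio by ``mu`` maps mutation-unit parameters (times in
    generations x mu, sizes in individuals x mu, rho/mu) to natural units
    (generations, individuals, rho per generation).  ``mu = 1`` is the
    identity, and ``rescale(rescale(p, mu), 1/mu)`` round-trips exactly.
    """
    if not (mu > 0):
        raise ValueError(f"mu must be strictly positive, got {mu!r}")
    if mu == 1.0:
        return params
    return params.replace(
        t_A=params.t_A / mu,
        t_B=params.t_B / mu,
        t_C=params.t_C / mu,
        t_2=params.t_2 / mu,
        t_upper=params.t_upper / mu,
        N_AB=params.N_AB / mu,
        N_ABC=params.N_ABC / mu,
        rho_over_mu=params.rho_over_mu * mu,
        N_tip=None if params.N_tip is None else params.N_tip / mu,
    )


@dataclass(frozen=True)
class EpochUnits:
    """Time scalings of the two ancestral epochs.

    One coalescent unit of an epoch is ``ploidy_scale * N_epoch`` of
    whatever time unit the parameters are in; pairwise coalescence then
    has rate 1 per unit.  ``T2`` is the AB-epoch length in its own units;
    the deep epoch is unbounded.
    """

    T2: float
    ab_scale: float
    abc_scale: float
    tip_scale: float

    def ab_to_time(self, c: float) -> float:
        return c * self.ab_scale

    def abc_to_time(self, c: float) -> float:
        return c * self.abc_scale


def coalescent_units(params: DemographyParams) -> EpochUnits:
    """Express the epochs of ``params`` in per-epoch coalescent units."""
    ps = params.ploidy_scale
    ab = ps * params.N_AB
    abc = ps * params.N_ABC
    return EpochUnits(
        T2=params.t_2 / ab,
        ab_scale=ab,
        abc_scale=abc,
        tip_scale=ps * params.tip_Ne,
    )


# ---------------------------------------------------------------------------
# Flat key/value configuration files

_PARAM_KEYS = (
    "t_A",
    "t_B",
    "t_C",
    "t_2",
    "t_upper",
    "N_AB",
    "N_ABC",
    "rho_over_mu",
    "ploidy_scale",
    "N_tip",
)


def read_config(path: str | Path) -> dict:
    """Parse a flat ``key = value`` config file ('#' starts a comment)."""
    cfg: dict = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {raw!r}")
        key, value = (part.strip() for part in line.split("=", 1))
        cfg[key] = _coerce(value)
    return cfg


def _coerce(value: str):
    for cast in (int, float):
        try:
            return cast(value)
        except ValueError:
            continue
    return value


def params_from_config(cfg: dict) -> DemographyParams:
    mode = cfg.get("mode", "ultrametric")
    kwargs = {k: cfg[k] for k in _PARAM_KEYS if k in cfg}
    if "t_1" in cfg and "t_A" not in cfg:
        t1 = float(cfg["t_1"])
        kwargs.update(t_A=t1, t_B=t1, t_C=t1 + float(cfg["t_2"]))
    return DemographyParams(mode=mode, **kwargs)
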