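"""Posterior summarisation, windowed statistics and closed-form utilities.

Windowed means of the grouped posterior give genome-scale views of
incomplete lineage sorting and coalescent depth; interval indices are
numbered 1..K chronologically backwards in time and summarised as
posterior-weighted means.  The neutrality scan compares per-interval
mean posteriors of the second coalescent against the flat expectation
1/K that holds, by construction, on an equal-probability grid.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .emissions import PosteriorTrack

__all__ = [
    "window_summaries",
    "window_correlations",
    "sweep_scan",
    "ils_probability",
    "expected_fixation_time",
    "neutral_fixation_time",
    "EULER_GAMMA",
]

EULER_GAMMA = 0.5772156649015329


def window_summaries(
    track: PosteriorTrack,
    window: int = 100_000,
    clip_percentiles: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Mean grouped posteriors per window.

    Per window: mean posterior of each topology (summing to 1), the ILS
    proxy mean(V2) + mean(V3), and posterior-weighted mean interval
    indices for the first and second coalescent.  Optional percentile
    clipping (e.g. (1, 99)) masks outlier windows of the index columns
    for plotting.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    L = len(track)
    if L == 0:
        raise ValueError("empty track")
    starts = np.arange(0, L, window)
    rows = []
    f_idx = np.arange(1, track.first.shape[1] + 1)
    s_idx = np.arange(1, track.second.shape[1] + 1)
    for s in starts:
        e = min(s + window, L)
        topo = track.topology[s:e].mean(axis=0)
        fmean = track.first[s:e].mean(axis=0)
        smean = track.second[s:e].mean(axis=0)
        rows.append(
            {
                "start": int(s),
                "end": int(e),
                "V0": topo[0], "V1": topo[1], "V2": topo[2], "V3": topo[3],
                "ils": topo[2] + topo[3],
                "first_index": float(f_idx @ (fmean / fmean.sum())),
                "second_index": float(s_idx @ (smean / smean.sum())),
            }
        )
    df = pd.DataFrame(rows)
    if clip_percentiles is not None:
        lo_p, hi_p = clip_percentiles
        for col in ("ils", "first_index", "second_index"):
            lo, hi = np.percentile(df[col], [lo_p, hi_p])
            df[col] = df[col].where((df[col] >= lo) & (df[col] <= hi))
    return df


def window_correlations(df: pd.DataFrame) -> dict:
    """Pearson correlations of the ILS proxy with the coalescent-depth
    indices across windows."""
    sub = df.dropna()
    return {
        "ils_vs_first": float(np.corrcoef(sub["ils"], sub["first_index"])[0, 1]),
        "ils_vs_second": float(np.corrcoef(sub["ils"], sub["second_index"])[0, 1]),
    }


def sweep_scan(track: PosteriorTrack, window: int | None = None) -> pd.DataFrame:
    """Per-interval mean second-coalescent posterior vs flat expectation.

    On an equal-probability grid the neutral expectation for every
    interval is 1/K; the excess statistic observed - 1/K flags
    localised surpluses of coalescence (e.g. a selective sweep in the
    earliest deep interval).  With ``window`` set, one row per window
    and interval; otherwise one row per interval over the whole track.
    """
    K = track.second.shape[1]
    flat = 1.0 / K
    if window is None:
        spans = [(0, len(track))]
    else:
        if window < 1:
            raise ValueError("window must be >= 1")
        starts = np.arange(0, len(track), window)
        spans = [(int(s), int(min(s + window, len(track)))) for s in starts]
    rows = []
    for s, e in spans:
        means = track.second[s:e].mean(axis=0)
        for k in range(K):
            rows.append(
                {
                    "start": s, "end": e, "interval": k + 1,
                    "mean_posterior": means[k], "excess": means[k] - flat,
                }
            )
    return pd.DataFrame(rows)


def check_equal_probability_grid(track_or_scheme) -> None:
    """Warn when a scan runs on a grid without equal interval masses."""
    scheme = getattr(track_or_scheme, "scheme", track_or_scheme)
    if scheme not in ("rate3", "phase_type"):
        warnings.warn(
            "sweep scan expects an equal-probability (rate3/phase_type) "
            f"second-coalescent grid; got scheme {scheme!r}"
        )


def ils_probability(
    t2_generations: float, N_AB_individuals: float, ploidy_scale: float = 2.0
) -> float:
    """Probability of incomplete lineage sorting,
    (2/3) exp(-t2 / (ploidy_scale * N_AB)).

    The complement of AB-epoch coalescence times the 2/3 chance that the
    first deep coalescence is a discordant pair.
    """
    if t2_generations < 0 or N_AB_individuals <= 0:
        raise ValueError("t2 must be >= 0 and N_AB > 0")
    return (2.0 / 3.0) * np.exp(-t2_generations / (ploidy_scale * N_AB_individuals))


def expected_fixation_time(two_Ne_s: float, Ne: float) -> float:
    """Expected fixation time of a strongly selected variant,
    (4/s) (ln(2 Ne s) + gamma - 1/(2 Ne s)) generations with
    s = two_Ne_s / (2 Ne)."""
    if two_Ne_s <= 0 or Ne <= 0:
        raise ValueError("two_Ne_s and Ne must be > 0")
    s = two_Ne_s / (2.0 * Ne)
    return (4.0 / s) * (np.log(two_Ne_s) + EULER_GAMMA - 1.0 / two_Ne_s)


def neutral_fixation_time(Ne: float) -> float:
    """Expected fixation time of a neutral variant, 4 Ne generations."""
    if Ne <= 0:
        raise ValueError("Ne must be > 0")
    return 4.0 * Ne
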