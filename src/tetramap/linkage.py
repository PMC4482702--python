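"""Genetic distance and crossover-interference statistics from tetrad counts.

Perkins' estimator converts a (PD, TT, NPD) tally into a map distance,

    cM = 100 (TT/2 + 3 NPD) / n,

where the 3 NPD term corrects for the four-strand double crossovers that
produce NPDs.  Interference is assessed two ways:

* the NPD ratio: observed NPDs over the number expected from the tetratype
  fraction under a random (no-interference) crossover distribution
  (Papazian's expectation); ratios below 1 indicate positive interference;
* the adjacent-interval interference ratio: the map distance of a test
  interval among tetrads recombinant for a neighbouring reference interval,
  divided by its distance among tetrads parental there, backed by a
  chi-square test on tetrad-type distributions and a normal test on the two
  map distances.
"""

from __future__ import annotations

import enum
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DegenerateTableError, UndefinedStatisticError
from .tetrads import (
    IntervalCounts,
    MarkerMap,
    ScoringPolicy,
    STRICT_POLICY,
    Tetrad,
    IntervalClass,
    classify_interval,
    tabulate_interval,
)

# per-tetrad Perkins scores: a PD contributes no recombinant spores, a TT
# half, and an NPD (four-strand double crossover) three map-unit equivalents
_SCORE = {"pd": 0.0, "tt": 0.5, "npd": 3.0}


class MapSource(enum.Enum):
    TETRAD = "tetrad"
    RANDOM_SPORE = "random_spore"


@dataclass
class MapEstimate:
    cM: float
    se: float
    n: int
    source: MapSource = MapSource.TETRAD


def perkins_map_distance(counts: IntervalCounts) -> MapEstimate:
    """Perkins map distance with a standard error from the per-tetrad score
    variance (each tetrad scores 0, 1/2 or 3 for PD, TT, NPD)."""
    n = counts.n
    if n == 0:
        raise UndefinedStatisticError("no scorable tetrads: map distance undefined")
    mean = (0.5 * counts.tt + 3.0 * counts.npd) / n
    if n > 1:
        sq = (0.25 * counts.tt + 9.0 * counts.npd) / n
        var = (sq - mean * mean) * n / (n - 1)
        se = 100.0 * math.sqrt(max(var, 0.0) / n)
    else:
        se = 0.0
    return MapEstimate(cM=100.0 * mean, se=se, n=n, source=MapSource.TETRAD)


def papazian_expected_fraction(f_tt: float) -> float:
    """Expected NPD fraction under no interference, from the tetratype
    fraction fTT:

        E[fNPD] = (1/2) (1 - fTT - (1 - 3 fTT / 2)^(2/3)).

    Undefined (NaN, with a warning) when fTT exceeds 2/3, where the inner
    base turns negative.
    """
    inner = 1.0 - 1.5 * f_tt
    if inner < 0.0:
        warnings.warn(
            f"tetratype fraction {f_tt:.3f} exceeds 2/3; expected NPD undefined",
            stacklevel=2,
        )
        return math.nan
    return 0.5 * (1.0 - f_tt - inner ** (2.0 / 3.0))


def papazian_expected_npd(counts: IntervalCounts) -> tuple[float, float]:
    """Expected NPD fraction and count under no interference (see
    :func:`papazian_expected_fraction`)."""
    n = counts.n
    if n == 0:
        raise UndefinedStatisticError("no scorable tetrads: expected NPD undefined")
    fraction = papazian_expected_fraction(counts.tt / n)
    return (fraction, fraction * n)


class NPDSEMethod(enum.Enum):
    """How the NPD-ratio standard error is propagated.

    POISSON treats the observed NPD count as Poisson with the expectation
    held fixed; DELTA additionally propagates sampling noise in the
    tetratype fraction through Papazian's formula.
    """

    POISSON = "poisson"
    DELTA = "delta"


@dataclass
class NPDInterference:
    f_tt: float
    npd_obs: int
    npd_exp: float
    ratio: float  # NaN when undefined ("n.d.")
    se: float  # NaN when undefined
    flag_low_npd: bool


def npd_interference_ratio(
    counts: IntervalCounts, se_method: NPDSEMethod = NPDSEMethod.POISSON
) -> NPDInterference:
    """Observed/expected NPD ratio; < 1 reflects positive interference.

    With zero observed NPDs the ratio is undefined (reported "n.d.") and
    ``flag_low_npd`` is set — interference measurements are not robust at
    low NPD counts.
    """
    fraction, expected = papazian_expected_npd(counts)
    n = counts.n
    f_tt = counts.tt / n
    obs = counts.npd
    if obs == 0 or not math.isfinite(expected) or expected <= 0.0:
        return NPDInterference(f_tt, obs, expected, math.nan, math.nan, True)
    ratio = obs / expected
    var_rel = 1.0 / obs  # Poisson: Var(obs)/obs^2
    if se_method is NPDSEMethod.DELTA:
        # d E[fNPD] / d fTT, propagated through Var(fTT) = fTT(1-fTT)/n
        inner = 1.0 - 1.5 * f_tt
        deriv = 0.5 * (-1.0 + inner ** (-1.0 / 3.0)) if inner > 0 else 0.0
        var_exp = (n * deriv) ** 2 * f_tt * (1.0 - f_tt) / n
        var_rel += var_exp / expected**2
    return NPDInterference(f_tt, obs, expected, ratio, ratio * math.sqrt(var_rel), False)


def percent_of_reference(map_test: MapEstimate, map_ref: MapEstimate) -> float:
    """Map distance as a percentage of a reference strain's distance
    (the %WT column of a mapping report); unrounded."""
    if map_ref.cM <= 0:
        raise UndefinedStatisticError("reference map distance must be positive")
    return 100.0 * map_test.cM / map_ref.cM


def random_spore_map_distance(r: int, t: int) -> MapEstimate:
    """Map distance from random-spore counts: cM = 100 r/t with the binomial
    standard error 100 sqrt((r/t)(1 - r/t)/t)."""
    if t <= 0:
        raise UndefinedStatisticError("total spore count must be positive")
    if not 0 <= r <= t:
        raise UndefinedStatisticError(f"recombinant count {r} outside [0, {t}]")
    p = r / t
    return MapEstimate(
        cM=100.0 * p,
        se=100.0 * math.sqrt(p * (1.0 - p) / t),
        n=t,
        source=MapSource.RANDOM_SPORE,
    )


def chi_square_tetrad_distribution(
    counts_a: IntervalCounts,
    counts_b: IntervalCounts,
    pool_threshold: float = 5.0,
) -> tuple[float, float]:
    """Pearson chi-square on the 2 x k contingency of (PD, TT, NPD) counts.

    NPDs are pooled into the TT column whenever any expected NPD cell falls
    below ``pool_threshold`` (NPDs are rare); no continuity correction.
    """
    if counts_a.n == 0 or counts_b.n == 0:
        raise DegenerateTableError("both tetrad tallies must be nonzero")
    table = np.array(
        [[counts_a.pd, counts_a.tt, counts_a.npd], [counts_b.pd, counts_b.tt, counts_b.npd]],
        dtype=float,
    )
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / table.sum()
    if (expected[:, 2] < pool_threshold).any():
        table = np.column_stack([table[:, 0], table[:, 1] + table[:, 2]])
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        raise DegenerateTableError("all tetrads in a single class: chi-square undefined")
    stat, p, _, _ = stats.chi2_contingency(table, correction=False)
    return (float(stat), float(p))


def map_difference_test(est_a: MapEstimate, est_b: MapEstimate) -> tuple[float, float]:
    """Two-tailed normal test for a difference between two map estimates:
    z = (cM_a - cM_b) / sqrt(se_a^2 + se_b^2)."""
    denom = math.hypot(est_a.se, est_b.se)
    if denom == 0.0:
        raise UndefinedStatisticError("both standard errors are zero: test undefined")
    z = (est_a.cM - est_b.cM) / denom
    return (z, 2.0 * stats.norm.sf(abs(z)))


@dataclass
class InterferenceRatioResult:
    reference_interval: tuple[str, str]
    test_interval: tuple[str, str]
    counts_ref_pd: IntervalCounts
    counts_ref_rec: IntervalCounts
    cm_pd: Optional[MapEstimate]
    cm_rec: Optional[MapEstimate]
    ratio: float
    chi2_stat: float
    chi2_p: float
    map_diff_p: float
    interference_called: bool
    diagnostic: Optional[str] = None


def interference_ratio_analysis(
    tetrads: Sequence[Tetrad],
    marker_map: MarkerMap,
    reference_interval: tuple[str, str],
    test_interval: tuple[str, str],
    alpha: float = 0.05,
    policy: ScoringPolicy = STRICT_POLICY,
) -> InterferenceRatioResult:
    """Adjacent-interval interference test.

    Tetrads are partitioned by their class in the reference interval — PD
    (no crossover there) versus TT or NPD (one or more crossovers) — and the
    test interval is mapped separately in each partition.  The interference
    ratio is cM(recombinant partition) / cM(PD partition); positive
    interference is called only when the tetrad-type distributions differ by
    chi-square, the map distances differ by the normal test, and the ratio
    is below 1, all at level ``alpha``.
    """
    ref = marker_map.interval(*reference_interval)
    tst = marker_map.interval(*test_interval)
    pd_part: list[Tetrad] = []
    rec_part: list[Tetrad] = []
    for tetrad in tetrads:
        cls = classify_interval(tetrad, marker_map, *ref, policy)
        if cls is IntervalClass.PD:
            pd_part.append(tetrad)
        elif cls in (IntervalClass.TT, IntervalClass.NPD):
            rec_part.append(tetrad)
    counts_pd = tabulate_interval(pd_part, marker_map, *tst, policy)
    counts_rec = tabulate_interval(rec_part, marker_map, *tst, policy)

    def _undefined(reason: str) -> InterferenceRatioResult:
        return InterferenceRatioResult(
            ref, tst, counts_pd, counts_rec, None, None,
            math.nan, math.nan, math.nan, math.nan, False, diagnostic=reason,
        )

    if counts_pd.n == 0:
        return _undefined("no scorable tetrads in the PD-reference partition")
    if counts_rec.n == 0:
        return _undefined("no scorable tetrads in the recombinant-reference partition")
    est_pd = perkins_map_distance(counts_pd)
    est_rec = perkins_map_distance(counts_rec)
    if est_pd.cM <= 0:
        return _undefined("test interval shows no recombination in the PD-reference partition")
    ratio = est_rec.cM / est_pd.cM
    try:
        chi2_stat, chi2_p = chi_square_tetrad_distribution(counts_pd, counts_rec)
    except DegenerateTableError:
        chi2_stat, chi2_p = 0.0, 1.0
    _, map_p = map_difference_test(est_pd, est_rec)
    called = (chi2_p < alpha) and (map_p < alpha) and (ratio < 1.0)
    return InterferenceRatioResult(
        ref, tst, counts_pd, counts_rec, est_pd, est_rec,
        ratio, chi2_stat, chi2_p, map_p, called,
    )


# --- reporting conventions -------------------------------------------------
# Applied only when formatting output, never internally: map distances to one
# decimal, interference ratios to two decimals, percent-of-reference to the
# nearest integer (half away from zero, as in conventional hand-rounding).


def _round_half_up(x: float, ndigits: int) -> float:
    scaled = x * 10**ndigits
    return math.floor(scaled + 0.5) / 10**ndigits


def report_cm(x: float) -> float:
    return _round_half_up(x, 1)


def report_ratio(x: float) -> float:
    return math.nan if not math.isfinite(x) else _round_half_up(x, 2)


def report_percent(x: float) -> int:
    return int(_round_half_up(x, 0))
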