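"""Meiosis simulator with tunable crossover interference.

Crossover events on each bivalent are drawn from a stationary gamma renewal
process on the genetic scale, with an event rate of 2 per Morgan (two
crossovers per Morgan per bivalent, so that the expected recombinant-spore
fraction per Morgan matches the mapping definition: each event involves half
the chromatids).  The gamma shape parameter sets interference strength:
shape 1 reduces exactly to a homogeneous Poisson process (no interference),
while larger shapes space events more evenly (positive interference, the
"counting model" behaviour).  Each event exchanges the distal segments of
one chromatid from each homolog, chosen uniformly — the standard
no-chromatid-interference assumption underlying both the Perkins and
Papazian formulas.

On top of the crossover machinery the simulator layers gene conversion
(per-locus call flips on one chromatid, producing 3:1 / 1:3 segregation) and
a spore-viability model: independent random spore death plus optional
meiosis-I nondisjunction of crossover-less chromosomes.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import InputError
from .tetrads import Locus, MarkerMap, MISSING, SporeRecord, Tetrad

_EVENT_RATE = 2.0  # crossover events per Morgan per bivalent


class NondisjunctionMode:
    """How meiosis-I nondisjunction of a crossover-less chromosome kills spores.

    MI_LETHAL (default): both homologs segregate to one pole, leaving two
    disomic and two nullisomic spores; all four are marked dead (a 0-sv
    outcome from that chromosome's contribution).  NULLISOMIC_ONLY is a
    milder aneuploidy model in which only the two spores receiving zero
    copies die (a 2-sv outcome).
    """

    MI_LETHAL = "mi_lethal"
    NULLISOMIC_ONLY = "nullisomic_only"


@dataclass
class SimParams:
    marker_map: MarkerMap
    n_tetrads: int
    seed: int
    interference_shape: float = 1.0
    obligate_crossover: bool = False
    conversion_rate: float = 0.0
    p_random_spore_death: float = 0.0
    p_nondisjunction_if_no_crossover: float = 0.0
    nondisjunction_mode: str = NondisjunctionMode.MI_LETHAL

    def __post_init__(self) -> None:
        if self.interference_shape <= 0:
            raise InputError("interference_shape must be positive")
        if self.n_tetrads <= 0:
            raise InputError("n_tetrads must be positive")
        for name in ("conversion_rate", "p_random_spore_death", "p_nondisjunction_if_no_crossover"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InputError(f"{name} must lie in [0, 1]")
        for locus in self.marker_map.loci:
            if locus.position_m is None:
                raise InputError(f"locus {locus.name!r} has no genetic position; required for simulation")

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "marker_map"}
        d["marker_map"] = [
            {"name": l.name, "chromosome": l.chromosome, "position_m": l.position_m}
            for l in self.marker_map.loci
        ]
        return d


@dataclass
class TetradTruth:
    """Realized generating events of one simulated meiosis."""

    events: dict[str, list[tuple[float, int, int]]]  # chrom -> [(pos, strand_p, strand_m)]
    conversions: list[tuple[str, int]]  # (locus name, flipped chromatid)
    deaths: dict[int, str]  # spore index -> cause


@dataclass
class SimTruth:
    """Generating parameters and per-tetrad realizations of a cohort."""

    params: SimParams
    tetrads: list[TetradTruth] = field(default_factory=list)

    def interval_true_length(self, locus_a: str, locus_b: str) -> float:
        """True map length (Morgans) between two loci on one chromosome."""
        a = self.params.marker_map.locus(locus_a)
        b = self.params.marker_map.locus(locus_b)
        if a.chromosome != b.chromosome:
            raise InputError("interval endpoints lie on different chromosomes")
        return abs(b.position_m - a.position_m)

    def to_json(self) -> str:
        payload = {
            "params": self.params.to_dict(),
            "tetrads": [asdict(t) for t in self.tetrads],
        }
        return json.dumps(payload, sort_keys=True)


@lru_cache(maxsize=32)
def _equilibrium_grid(shape: float, scale: float) -> tuple[np.ndarray, np.ndarray]:
    """Inverse-CDF grid for the stationary (equilibrium) first-arrival
    distribution of a gamma renewal process with rate 1/(shape*scale):
    F_e(t) = r t S(t) + F_{shape+1}(t)."""
    rate = 1.0 / (shape * scale)

    def cdf(t: np.ndarray) -> np.ndarray:
        return rate * t * stats.gamma.sf(t, shape, scale=scale) + stats.gamma.cdf(
            t, shape + 1, scale=scale
        )

    upper = 4.0 * shape * scale
    while 1.0 - cdf(np.array([upper]))[0] > 1e-12:
        upper *= 2.0
    t_grid = np.linspace(0.0, upper, 4097)
    f_grid = cdf(t_grid)
    return f_grid, t_grid


def place_crossovers(
    chromosome_length: float, shape: float, rng: np.random.Generator
) -> list[float]:
    """Draw crossover event positions (Morgans) on one bivalent.

    Events form a stationary gamma renewal process with rate 2 per Morgan
    and the given shape; the first event uses the equilibrium inter-arrival
    distribution, so shape 1 is exactly a homogeneous Poisson process.
    """
    if chromosome_length <= 0:
        raise InputError("chromosome length must be positive")
    if shape <= 0:
        raise InputError("interference shape must be positive")
    scale = 1.0 / (_EVENT_RATE * shape)
    if shape == 1.0:
        # Poisson special case (equilibrium == exponential inter-arrival)
        k = rng.poisson(_EVENT_RATE * chromosome_length)
        return sorted(rng.random(k) * chromosome_length)
    f_grid, t_grid = _equilibrium_grid(shape, scale)
    t = float(np.interp(rng.random(), f_grid, t_grid))
    positions: list[float] = []
    while t < chromosome_length:
        positions.append(t)
        t += rng.gamma(shape, scale)
    return positions


def _chromosome_layout(marker_map: MarkerMap) -> list[tuple[str, list[int], list[float], float]]:
    """Per chromosome: (name, locus indices in map order, positions, length)."""
    layout = []
    for chrom in marker_map.chromosomes():
        loci = marker_map.loci_on(chrom)
        idxs = [marker_map.index(l.name) for l in loci]
        poss = [l.position_m for l in loci]
        layout.append((chrom, idxs, poss, max(poss)))
    return layout


def simulate_tetrad(
    params: SimParams, rng: np.random.Generator, _layout=None
) -> tuple[Tetrad, TetradTruth]:
    """Simulate one meiosis: crossover placement, chromatid choice, call
    propagation, gene conversion, then viability."""
    layout = _layout if _layout is not None else _chromosome_layout(params.marker_map)
    m = len(params.marker_map)
    # strand-major genotype: rows are chromatids P0,P1,M0,M1; 0 = P, 1 = M
    geno = [[0] * m, [0] * m, [1] * m, [1] * m]
    truth_events: dict[str, list[tuple[float, int, int]]] = {}
    no_crossover_chroms: list[str] = []
    for chrom, idxs, poss, length in layout:
        events = place_crossovers(length, params.interference_shape, rng)
        if params.obligate_crossover:
            while not events:
                events = place_crossovers(length, params.interference_shape, rng)
        ev_records = []
        for x in events:
            i = 0 if rng.random() < 0.5 else 1
            j = 2 if rng.random() < 0.5 else 3
            ev_records.append((x, i, j))
        # A spore chromatid is the path from a centromere through the CO
        # junctions; the genotype at a locus composes the junction
        # transpositions proximal to it in path order.  Applying the distal
        # exchange first realizes that composition with plain segment swaps.
        for x, i, j in reversed(ev_records):
            gi, gj = geno[i], geno[j]
            for t, pos in enumerate(poss):
                if pos > x:
                    k = idxs[t]
                    gi[k], gj[k] = gj[k], gi[k]
        truth_events[chrom] = ev_records
        if not events:
            no_crossover_chroms.append(chrom)

    conversions: list[tuple[str, int]] = []
    if params.conversion_rate > 0.0:
        for k, name in enumerate(params.marker_map.names):
            if rng.random() < params.conversion_rate:
                c = int(rng.random() * 4)
                geno[c][k] ^= 1
                conversions.append((name, c))

    deaths: dict[int, str] = {}
    if params.p_random_spore_death > 0.0:
        for s in range(4):
            if rng.random() < params.p_random_spore_death:
                deaths[s] = "random"
    if params.p_nondisjunction_if_no_crossover > 0.0:
        for chrom in no_crossover_chroms:
            if rng.random() < params.p_nondisjunction_if_no_crossover:
                if params.nondisjunction_mode == NondisjunctionMode.MI_LETHAL:
                    victims = (0, 1, 2, 3)
                else:
                    # one randomly oriented pole pair receives zero copies
                    victims = (0, 1) if rng.random() < 0.5 else (2, 3)
                for s in victims:
                    deaths.setdefault(s, f"nondisjunction:{chrom}")

    spores = []
    for s in range(4):
        if s in deaths:
            calls = (MISSING,) * m
            viable = False
        else:
            calls = tuple("P" if g == 0 else "M" for g in geno[s])
            viable = True
        spores.append(SporeRecord(spore_id=f"s{s + 1}", viable=viable, calls=calls))
    tetrad = Tetrad(tetrad_id="t", spores=tuple(spores))
    return tetrad, TetradTruth(truth_events, conversions, deaths)


def simulate_cohort(
    params: SimParams, out_dir: Optional[Path] = None
) -> tuple[list[Tetrad], SimTruth]:
    """Simulate ``params.n_tetrads`` independent meioses.

    Fully deterministic given (params, seed).  If ``out_dir`` is given the
    tetrad table, marker map and truth sidecar are written there.
    """
    rng = np.random.default_rng(params.seed)
    layout = _chromosome_layout(params.marker_map)
    tetrads: list[Tetrad] = []
    truth = SimTruth(params=params)
    width = len(str(params.n_tetrads))
    for i in range(params.n_tetrads):
        tetrad, t_truth = simulate_tetrad(params, rng, _layout=layout)
        tetrad.tetrad_id = f"T{i + 1:0{width}d}"
        for s, spore in enumerate(tetrad.spores):
            spore.spore_id = f"{tetrad.tetrad_id}.{s + 1}"
        tetrads.append(tetrad)
        truth.tetrads.append(t_truth)
    if out_dir is not None:
        from . import io as tmio

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        header = [f"# seed={params.seed}"]
        tmio.write_tetrads(out_dir / "tetrads.tsv", tetrads, params.marker_map, comments=header)
        tmio.write_marker_map(out_dir / "markers.tsv", params.marker_map, comments=header)
        (out_dir / "truth.json").write_text(truth.to_json() + "\n")
    return tetrads, truth


# --- analytic oracle -------------------------------------------------------

_CLASS_TRANSITION = np.array(
    [
        [0.0, 1.0, 0.0],  # PD: any event recombines two chromatids -> TT
        [0.25, 0.5, 0.25],  # TT: 2-/3-/4-strand double relation
        [0.0, 1.0, 0.0],  # NPD: any event returns two chromatids to parental -> TT
    ]
)


def closed_form_tetrad_probs(x: float) -> tuple[float, float, float]:
    """Exact (P_PD, P_TT, P_NPD) for an interval of ``x`` Morgans under no
    interference and no chromatid interference.

    The event count is Poisson(2x); conditional class probabilities follow
    the Markov chain over {PD, TT, NPD} induced by uniform non-sister
    chromatid choice, summed over the event count to numerical convergence.
    Satisfies P_TT(x) = (2/3)(1 - exp(-3x)) and is exactly consistent with
    Papazian's no-interference NPD expectation.
    """
    if x < 0:
        raise InputError("map length must be non-negative")
    if x == 0.0:
        return (1.0, 0.0, 0.0)
    mean = _EVENT_RATE * x
    k_max = int(stats.poisson.ppf(1.0 - 1e-15, mean)) + 2
    weights = stats.poisson.pmf(np.arange(k_max + 1), mean)
    v = np.array([1.0, 0.0, 0.0])
    out = weights[0] * v
    for k in range(1, k_max + 1):
        v = v @ _CLASS_TRANSITION
        out = out + weights[k] * v
    out = out / out.sum()  # renormalize the truncated Poisson tail
    return (float(out[0]), float(out[1]), float(out[2]))


def expected_perkins_cm(x: float) -> float:
    """Expected value of the Perkins estimator (cM) for a true interval
    length of ``x`` Morgans under no interference — includes the estimator's
    slight downward bias from triple and higher crossover classes."""
    _, tt, npd = closed_form_tetrad_probs(x)
    return 100.0 * (0.5 * tt + 3.0 * npd)
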