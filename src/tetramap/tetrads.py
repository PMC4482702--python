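"""Core data model for tetrad analysis.

A yeast tetrad is the set of four haploid spores produced by one meiosis.
Each spore carries, at every scored locus, an allele inherited from one of
the two parents; calls are coded ``P``/``M`` (paternal/maternal phase) with
``-`` for missing.  Two-locus tetrad classes — parental ditype (PD),
tetratype (TT) and non-parental ditype (NPD) — are the atoms of tetrad-based
linkage mapping: a tetrad is PD when all four spores carry a parental
two-locus combination, NPD when all four are recombinant, and TT when two
are parental and two recombinant.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .errors import InputError

P_CALL = "P"
M_CALL = "M"
MISSING = "-"
VALID_CALLS = frozenset({P_CALL, M_CALL, MISSING})


@dataclass(frozen=True)
class Locus:
    """One genetic marker: a name, a chromosome, and (optionally, needed only
    for simulation) a genetic position in Morgans."""

    name: str
    chromosome: str
    position_m: Optional[float] = None


class MarkerMap:
    """Ordered collection of loci.

    Locus order is map order: the order given at construction, which must
    place loci of a chromosome at strictly increasing genetic positions
    whenever positions are present.
    """

    def __init__(self, loci: Sequence[Locus]):
        loci = list(loci)
        names = [l.name for l in loci]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate locus name(s): {', '.join(dupes)}")
        by_chrom: dict[str, list[Locus]] = {}
        for locus in loci:
            by_chrom.setdefault(locus.chromosome, []).append(locus)
        for chrom, group in by_chrom.items():
            pos = [l.position_m for l in group if l.position_m is not None]
            if any(b <= a for a, b in zip(pos, pos[1:])):
                raise InputError(
                    f"genetic positions on chromosome {chrom!r} must be strictly increasing in map order"
                )
        self._loci = tuple(loci)
        self._index = {l.name: i for i, l in enumerate(loci)}
        self._by_chrom = {c: tuple(g) for c, g in by_chrom.items()}

    @property
    def loci(self) -> tuple[Locus, ...]:
        return self._loci

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(l.name for l in self._loci)

    def __len__(self) -> int:
        return len(self._loci)

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise InputError(f"unknown locus {name!r}") from None

    def locus(self, name: str) -> Locus:
        return self._loci[self.index(name)]

    def chromosomes(self) -> tuple[str, ...]:
        return tuple(self._by_chrom)

    def loci_on(self, chromosome: str) -> tuple[Locus, ...]:
        try:
            return self._by_chrom[chromosome]
        except KeyError:
            raise InputError(f"unknown chromosome {chromosome!r}") from None

    def interval(self, locus_a: str, locus_b: str) -> tuple[str, str]:
        """Canonical interval identity: the two locus names in map order."""
        ia, ib = self.index(locus_a), self.index(locus_b)
        if ia == ib:
            raise InputError(f"interval endpoints must differ (got {locus_a!r} twice)")
        return (locus_a, locus_b) if ia < ib else (locus_b, locus_a)


@dataclass
class SporeRecord:
    spore_id: str
    viable: bool
    calls: tuple[str, ...]

    def __post_init__(self) -> None:
        bad = set(self.calls) - VALID_CALLS
        if bad:
            raise InputError(f"invalid allele symbol(s) {sorted(bad)} in spore {self.spore_id!r}")


@dataclass
class Tetrad:
    tetrad_id: str
    spores: tuple[SporeRecord, SporeRecord, SporeRecord, SporeRecord]

    def __post_init__(self) -> None:
        if len(self.spores) != 4:
            raise InputError(
                f"tetrad {self.tetrad_id!r} has {len(self.spores)} spores; exactly 4 required"
            )
        lengths = {len(s.calls) for s in self.spores}
        if len(lengths) > 1:
            raise InputError(f"tetrad {self.tetrad_id!r}: spores have unequal call-vector lengths")

    @property
    def n_viable(self) -> int:
        return sum(s.viable for s in self.spores)


class IntervalClass(enum.Enum):
    PD = "PD"
    TT = "TT"
    NPD = "NPD"
    UNSCORABLE = "UNSCORABLE"


class SegregationClass(enum.Enum):
    """Allele segregation at one locus across the four spores.

    2:2 is Mendelian; 3:1, 1:3, 4:0 and 0:4 indicate gene conversion
    (non-reciprocal information transfer during recombination)."""

    TWO_TWO = "2:2"
    THREE_ONE = "3:1"
    ONE_THREE = "1:3"
    FOUR_ZERO = "4:0"
    ZERO_FOUR = "0:4"
    INCOMPLETE = "INCOMPLETE"

    @property
    def is_conversion(self) -> bool:
        return self not in (SegregationClass.TWO_TWO, SegregationClass.INCOMPLETE)


@dataclass(frozen=True)
class ScoringPolicy:
    """Which tetrads enter two-locus tallies.

    The strict default admits only four-spore-viable tetrads whose interval
    loci are fully called and 2:2, and that show no gene conversion at any
    other fully-called locus.  Setting ``exclude_conversion_anywhere`` to
    False relaxes the last condition so that conversion at a locus outside
    the interval no longer disqualifies the tetrad.
    """

    exclude_conversion_anywhere: bool = True


STRICT_POLICY = ScoringPolicy()
RELAXED_POLICY = ScoringPolicy(exclude_conversion_anywhere=False)


@dataclass
class IntervalCounts:
    """(PD, TT, NPD) tally for one interval over a tetrad set."""

    interval: tuple[str, str]
    pd: int = 0
    tt: int = 0
    npd: int = 0
    n_unscorable: int = 0

    @property
    def n(self) -> int:
        return self.pd + self.tt + self.npd

    def __post_init__(self) -> None:
        if min(self.pd, self.tt, self.npd, self.n_unscorable) < 0:
            raise InputError("tetrad counts must be non-negative")


def segregation_class(tetrad: Tetrad, marker_map: MarkerMap, locus: str) -> SegregationClass:
    """Classify allele segregation at one locus; INCOMPLETE if any spore is
    dead or uncalled there."""
    idx = marker_map.index(locus)
    n_p = n_m = 0
    for spore in tetrad.spores:
        call = spore.calls[idx]
        if not spore.viable or call == MISSING:
            return SegregationClass.INCOMPLETE
        if call == P_CALL:
            n_p += 1
        else:
            n_m += 1
    return {
        (2, 2): SegregationClass.TWO_TWO,
        (3, 1): SegregationClass.THREE_ONE,
        (1, 3): SegregationClass.ONE_THREE,
        (4, 0): SegregationClass.FOUR_ZERO,
        (0, 4): SegregationClass.ZERO_FOUR,
    }[(n_p, n_m)]


def classify_interval(
    tetrad: Tetrad,
    marker_map: MarkerMap,
    locus_a: str,
    locus_b: str,
    policy: ScoringPolicy = STRICT_POLICY,
) -> IntervalClass:
    """Two-locus tetrad class (PD/TT/NPD), or UNSCORABLE.

    Under the strict default policy a tetrad is scorable only when all four
    spores are viable, both interval loci are fully called and segregate
    2:2, and no other fully-called locus shows gene conversion.
    """
    ia, ib = marker_map.index(locus_a), marker_map.index(locus_b)
    if ia == ib:
        raise InputError(f"interval endpoints must differ (got {locus_a!r} twice)")
    if tetrad.n_viable != 4:
        return IntervalClass.UNSCORABLE
    for locus in (locus_a, locus_b):
        if segregation_class(tetrad, marker_map, locus) is not SegregationClass.TWO_TWO:
            return IntervalClass.UNSCORABLE
    if policy.exclude_conversion_anywhere:
        for locus in marker_map.names:
            if locus in (locus_a, locus_b):
                continue
            if segregation_class(tetrad, marker_map, locus).is_conversion:
                return IntervalClass.UNSCORABLE
    n_recombinant = sum(1 for s in tetrad.spores if s.calls[ia] != s.calls[ib])
    # 2:2 at both loci forces an even recombinant count (0, 2 or 4)
    return {0: IntervalClass.PD, 2: IntervalClass.TT, 4: IntervalClass.NPD}[n_recombinant]


def tabulate_interval(
    tetrads: Iterable[Tetrad],
    marker_map: MarkerMap,
    locus_a: str,
    locus_b: str,
    policy: ScoringPolicy = STRICT_POLICY,
) -> IntervalCounts:
    """Apply :func:`classify_interval` over a tetrad set and tally classes."""
    counts = IntervalCounts(marker_map.interval(locus_a, locus_b))
    for tetrad in tetrads:
        cls = classify_interval(tetrad, marker_map, locus_a, locus_b, policy)
        if cls is IntervalClass.PD:
            counts.pd += 1
        elif cls is IntervalClass.TT:
            counts.tt += 1
        elif cls is IntervalClass.NPD:
            counts.npd += 1
        else:
            counts.n_unscorable += 1
    return counts


def count_breakpoints(
    spore: SporeRecord, marker_map: MarkerMap, chromosome: str
) -> Optional[int]:
    """Number of adjacent-locus call changes along one chromosome — the
    spore's crossover class (0 = non-recombinant chromatid, 1 = single, ...).

    Returns None (incomplete) for a dead spore or any missing call on the
    chromosome.
    """
    if not spore.viable:
        return None
    calls = [spore.calls[marker_map.index(l.name)] for l in marker_map.loci_on(chromosome)]
    if MISSING in calls:
        return None
    return sum(1 for a, b in zip(calls, calls[1:]) if a != b)


def crossover_class_distribution(
    spores: Iterable[SporeRecord], marker_map: MarkerMap, chromosome: str
) -> Counter:
    """Histogram of breakpoint counts over viable, fully-called spores.

    Spores from any viability class of tetrad may be pooled; incomplete
    spores are excluded from the tally.
    """
    hist: Counter = Counter()
    for spore in spores:
        k = count_breakpoints(spore, marker_map, chromosome)
        if k is not None:
            hist[k] += 1
    return hist


@dataclass
class AsciCounts:
    """Externally supplied sporulation counts: cells that formed 2-, 3- or
    4-spore asci out of all cells examined."""

    n_sporulated: int
    n_cells: int


@dataclass
class ViabilitySummary:
    n_tetrads: int
    sv_counts: Mapping[int, int] = field(default_factory=dict)  # viable-spore class -> tetrads
    sporulation_efficiency: Optional[float] = None  # percent

    @property
    def overall_viability(self) -> float:
        """Percent of all dissected spores that were viable."""
        viable = sum(k * n for k, n in self.sv_counts.items())
        return 100.0 * viable / (4 * self.n_tetrads)


def viability_summary(
    tetrads: Sequence[Tetrad], asci_counts: Optional[AsciCounts] = None
) -> ViabilitySummary:
    """Tally the 4-sv/3-sv/2-sv/1-sv/0-sv tetrad distribution and overall
    spore viability; sporulation efficiency only when asci counts are given."""
    if not tetrads:
        raise InputError("empty tetrad set")
    sv = Counter(t.n_viable for t in tetrads)
    efficiency = None
    if asci_counts is not None:
        if asci_counts.n_cells <= 0:
            raise InputError("asci_counts.n_cells must be positive")
        efficiency = 100.0 * asci_counts.n_sporulated / asci_counts.n_cells
    return ViabilitySummary(
        n_tetrads=len(tetrads),
        sv_counts={k: sv.get(k, 0) for k in range(5)},
        sporulation_efficiency=efficiency,
    )
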