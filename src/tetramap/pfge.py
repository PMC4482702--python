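"""Quantification of physical recombination assays from densitometry tables.

Circle–linear pulsed-field assay: a strain carries one linear and one
circular chromosome III.  Circular chromatids never enter the gel; linear
chromatids run as monomer (non-recombinant), dimer (single crossover with
the circle) or trimer (double crossover involving three chromatids) bands.
Percent recombination weights the trimer band twice, as each trimer records
two crossover events:

    %rec = 100 (2 * trimer + dimer) / (monomer + dimer + trimer).

Joint-molecule (JM) 2D-gel assay: branched recombination intermediates
migrate off the linear arc; the statistic is simply the JM signal as a
percentage of total hybridizing DNA.  Intensities are assumed
background-corrected by the caller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class BandIntensities:
    sample_id: str
    strain: str
    timepoint_h: float
    monomer: float
    dimer: float
    trimer: float

    def __post_init__(self) -> None:
        if min(self.monomer, self.dimer, self.trimer) < 0:
            raise InputError(f"negative band intensity in sample {self.sample_id!r}")


@dataclass(frozen=True)
class SpotIntensities:
    sample_id: str
    timepoint_h: float
    jm_signal: float
    total_signal: float

    def __post_init__(self) -> None:
        if self.jm_signal < 0:
            raise InputError(f"negative JM signal in sample {self.sample_id!r}")
        if self.jm_signal > self.total_signal:
            raise InputError(f"JM signal exceeds total signal in sample {self.sample_id!r}")


def percent_recombination(band: BandIntensities) -> float:
    """100 * (2*trimer + dimer) / (monomer + dimer + trimer); ranges 0-200
    because a trimer chromatid carries two crossovers."""
    total = band.monomer + band.dimer + band.trimer
    if total <= 0:
        raise InputError(f"lane {band.sample_id!r} has no signal; unquantifiable")
    # divide before scaling so the all-trimer lane hits 200 exactly
    return 100.0 * ((2.0 * band.trimer + band.dimer) / total)


def jm_fraction(spot: SpotIntensities) -> float:
    """Joint-molecule signal as percent of total DNA signal."""
    if spot.total_signal <= 0:
        raise InputError(f"sample {spot.sample_id!r} has no total signal; unquantifiable")
    return 100.0 * (spot.jm_signal / spot.total_signal)


def summarize_timecourse(samples: Iterable[BandIntensities]) -> pd.DataFrame:
    """Per (strain, timepoint) mean and range of percent recombination over
    replicate lanes (gel experiments are typically run at least twice)."""
    rows = [
        {
            "strain": b.strain,
            "timepoint_h": b.timepoint_h,
            "percent_recombination": percent_recombination(b),
        }
        for b in samples
    ]
    if not rows:
        raise InputError("no quantifiable lanes supplied")
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["strain", "timepoint_h"], sort=True)["percent_recombination"]
        .agg(mean="mean", min="min", max="max", n_replicates="count")
        .reset_index()
    )
    return out
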