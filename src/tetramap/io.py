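"""Readers and writers for the plain-text table formats.

All tables are TSV/CSV with explicit headers; lines starting with ``#`` are
comments and are skipped.  The tetrad table has one row per spore::

    tetrad_id  spore_id  viable  <locus1>  <locus2> ...

with ``viable`` in {1, 0} and calls in {P, M, -}.  An optional allele-name
dictionary translates real marker allele symbols (e.g. drug-resistance vs
sensitive) to the canonical P/M coding at read time.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ParseError
from .pfge import BandIntensities, SpotIntensities
from .tetrads import Locus, MarkerMap, MISSING, SporeRecord, Tetrad, VALID_CALLS


def _rows(path: Path, delimiter: str) -> Iterable[tuple[int, list[str]]]:
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter=delimiter), start=1):
            if not row or (row[0].startswith("#")):
                continue
            yield lineno, [c.strip() for c in row]


def read_marker_map(path: str | Path) -> MarkerMap:
    """Read a marker-map TSV with columns name, chromosome, position_morgans
    (the position column may be absent or empty)."""
    path = Path(path)
    rows = iter(_rows(path, "\t"))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty marker-map file") from None
    required = ["name", "chromosome"]
    if header[: len(required)] != required:
        raise ParseError(f"{path}: header must start with {required}, got {header}")
    has_pos = len(header) > 2 and header[2] == "position_morgans"
    loci = []
    for lineno, row in rows:
        if len(row) < 2:
            raise ParseError(f"{path}:{lineno}: expected at least 2 columns")
        pos = None
        if has_pos and len(row) > 2 and row[2] != "":
            try:
                pos = float(row[2])
            except ValueError:
                raise ParseError(f"{path}:{lineno}: bad position {row[2]!r}") from None
        loci.append(Locus(name=row[0], chromosome=row[1], position_m=pos))
    return MarkerMap(loci)


def write_marker_map(
    path: str | Path, marker_map: MarkerMap, comments: Sequence[str] = ()
) -> None:
    lines = list(comments)
    lines.append("name\tchromosome\tposition_morgans")
    for locus in marker_map.loci:
        pos = "" if locus.position_m is None else repr(locus.position_m)
        lines.append(f"{locus.name}\t{locus.chromosome}\t{pos}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_tetrads(
    path: str | Path,
    marker_map: MarkerMap,
    allele_names: Optional[Mapping[str, str]] = None,
    allow_missing_dead: bool = False,
) -> list[Tetrad]:
    """Read and validate a tetrad table against a marker map.

    Rows are grouped by ``tetrad_id`` into exactly four spores; with
    ``allow_missing_dead`` a tetrad with fewer rows is padded with dead,
    all-missing spores instead of raising.
    """
    path = Path(path)
    rows = iter(_rows(path, "\t"))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty tetrad file") from None
    if header[:3] != ["tetrad_id", "spore_id", "viable"]:
        raise ParseError(f"{path}: header must start with tetrad_id, spore_id, viable")
    loci = header[3:]
    for name in loci:
        if name not in marker_map:
            raise ParseError(f"{path}: column locus {name!r} not in the marker map")
    if list(loci) != list(marker_map.names):
        raise ParseError(
            f"{path}: locus columns {loci} do not match the marker map order {list(marker_map.names)}"
        )
    translate = dict(allele_names) if allele_names else {}
    for sym in (str(c) for c in VALID_CALLS):
        translate.setdefault(sym, sym)

    grouped: dict[str, list[tuple[int, SporeRecord]]] = {}
    order: list[str] = []
    for lineno, row in rows:
        if len(row) != 3 + len(loci):
            raise ParseError(f"{path}:{lineno}: expected {3 + len(loci)} columns, got {len(row)}")
        tetrad_id, spore_id, viable_s = row[:3]
        if viable_s not in ("0", "1"):
            raise ParseError(f"{path}:{lineno}: viable must be 0 or 1, got {viable_s!r}")
        calls = []
        for sym in row[3:]:
            if sym not in translate:
                raise ParseError(f"{path}:{lineno}: unknown allele symbol {sym!r}")
            calls.append(translate[sym])
        spore = SporeRecord(spore_id=spore_id, viable=viable_s == "1", calls=tuple(calls))
        if tetrad_id not in grouped:
            grouped[tetrad_id] = []
            order.append(tetrad_id)
        grouped[tetrad_id].append((lineno, spore))

    tetrads = []
    for tetrad_id in order:
        members = grouped[tetrad_id]
        spores = [s for _, s in members]
        if len(spores) < 4 and allow_missing_dead:
            pad = 4 - len(spores)
            for i in range(pad):
                spores.append(
                    SporeRecord(
                        spore_id=f"{tetrad_id}.dead{i + 1}",
                        viable=False,
                        calls=(MISSING,) * len(loci),
                    )
                )
        if len(spores) != 4:
            first = members[0][0]
            raise ParseError(
                f"{path}:{first}: tetrad {tetrad_id!r} has {len(members)} spore rows; exactly 4 required"
            )
        tetrads.append(Tetrad(tetrad_id=tetrad_id, spores=tuple(spores)))
    return tetrads


def write_tetrads(
    path: str | Path,
    tetrads: Sequence[Tetrad],
    marker_map: MarkerMap,
    comments: Sequence[str] = (),
) -> None:
    """Write the tetrad TSV; dead spores are written with all-missing calls."""
    lines = list(comments)
    lines.append("\t".join(["tetrad_id", "spore_id", "viable"] + list(marker_map.names)))
    for tetrad in tetrads:
        for spore in tetrad.spores:
            calls = spore.calls if spore.viable else (MISSING,) * len(marker_map)
            lines.append(
                "\t".join([tetrad.tetrad_id, spore.spore_id, "1" if spore.viable else "0", *calls])
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_band_table(path: str | Path) -> list[BandIntensities]:
    """Read a gel band-intensity CSV: sample_id, strain, timepoint_h,
    monomer, dimer, trimer."""
    path = Path(path)
    rows = iter(_rows(path, ","))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty band table") from None
    expected = ["sample_id", "strain", "timepoint_h", "monomer", "dimer", "trimer"]
    if header != expected:
        raise ParseError(f"{path}: header must be {expected}, got {header}")
    out = []
    for lineno, row in rows:
        if len(row) != 6:
            raise ParseError(f"{path}:{lineno}: expected 6 columns")
        try:
            out.append(
                BandIntensities(row[0], row[1], float(row[2]), float(row[3]), float(row[4]), float(row[5]))
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out


def read_spot_table(path: str | Path) -> list[SpotIntensities]:
    """Read a 2D-gel spot-intensity CSV: sample_id, timepoint_h, jm_signal,
    total_signal."""
    path = Path(path)
    rows = iter(_rows(path, ","))
    try:
        _, header = next(rows)
    except StopIteration:
        raise ParseError(f"{path}: empty spot table") from None
    expected = ["sample_id", "timepoint_h", "jm_signal", "total_signal"]
    if header != expected:
        raise ParseError(f"{path}: header must be {expected}, got {header}")
    out = []
    for lineno, row in rows:
        if len(row) != 4:
            raise ParseError(f"{path}:{lineno}: expected 4 columns")
        try:
            out.append(SpotIntensities(row[0], float(row[1]), float(row[2]), float(row[3])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: {exc}") from None
    return out
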