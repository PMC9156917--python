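"""Occurrence records with dominance-aware genotype-class calls.

Each record is one georeferenced butterfly scored at up to three Mendelian
colour-pattern loci (A: hindwing white/orange, B: light/dark background,
C: forewing black tip). Heterozygotes are not reliably scorable, so every
locus carries a two-class call: homozygous recessive (e.g. ``aa``) or the
combined dominant class (e.g. ``A-``), or missing. The dominant class is
never split into ``AA``/``Aa``.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

logger = logging.getLogger(__name__)

LOCI = ("A", "B", "C")

RECORD_COLUMNS = [
    "record_id", "source", "date", "lat", "lon", "locusA", "locusB", "locusC",
]


class ClassCall(str, enum.Enum):
    """Genotype-class call at one locus under full dominance."""

    RECESSIVE_HOM = "rec"
    DOMINANT_CLASS = "dom"
    MISSING = "NA"


class Source(str, enum.Enum):
    RESEARCH = "research"
    CITIZEN = "citizen"


@dataclass(frozen=True)
class ColourRecord:
    """One georeferenced butterfly with per-locus genotype-class calls."""

    record_id: str
    source: Source
    latitude: float
    longitude: float
    calls: dict  # locus letter -> ClassCall, always all of A, B, C
    date: str | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if not -180.0 <= self.longitude < 180.0:
            raise ValueError(f"longitude out of range: {self.longitude}")
        if set(self.calls) != set(LOCI):
            raise ValueError(f"calls must cover loci {LOCI}, got {set(self.calls)}")

    def scored(self, locus: str) -> bool:
        return self.calls[locus] is not ClassCall.MISSING

    def all_missing(self) -> bool:
        return all(c is ClassCall.MISSING for c in self.calls.values())


@dataclass
class Dataset:
    """An ordered collection of validated records plus provenance text."""

    records: list[ColourRecord]
    provenance: str = ""
    rejected: list[tuple[int, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def subset(self, source: Source | str) -> "Dataset":
        source = Source(source)
        return Dataset(
            records=[r for r in self.records if r.source is source],
            provenance=f"{self.provenance} [subset source={source.value}]",
        )


def _parse_call(raw: str) -> ClassCall:
    raw = (raw or "").strip()
    if raw == "" or raw.upper() == "NA":
        return ClassCall.MISSING
    return ClassCall(raw)  # raises ValueError on anything else


def parse_row(row: dict, row_number: int) -> ColourRecord:
    """Validate one CSV row; raises ValueError with a reason on failure."""
    try:
        lat = float(row["lat"])
    except (TypeError, ValueError):
        raise ValueError("unparseable latitude")
    try:
        lon = float(row["lon"])
    except (TypeError, ValueError):
        raise ValueError("unparseable longitude")
    if lon == 180.0:  # normalize the antimeridian to the canonical half-open range
        lon = -180.0
    if not -90.0 <= lat <= 90.0:
        raise ValueError("latitude out of range")
    if not -180.0 <= lon < 180.0:
        raise ValueError("longitude out of range")
    try:
        source = Source(row["source"].strip())
    except (KeyError, ValueError, AttributeError):
        raise ValueError(f"unknown source {row.get('source')!r}")
    try:
        calls = {loc: _parse_call(row[f"locus{loc}"]) for loc in LOCI}
    except ValueError as e:
        raise ValueError(f"bad locus call: {e}")
    date = (row.get("date") or "").strip() or None
    return ColourRecord(
        record_id=str(row["record_id"]).strip(),
        source=source,
        latitude=lat,
        longitude=lon,
        calls=calls,
        date=date,
    )


def read_records(path, provenance: str | None = None) -> Dataset:
    """Read a record CSV into a validated :class:`Dataset`.

    Rows failing validation are logged with their row number and collected in
    ``Dataset.rejected`` rather than aborting the read; a missing mandatory
    column is a hard failure.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        missing = [c for c in RECORD_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"missing mandatory column(s): {missing}")
        records: list[ColourRecord] = []
        rejected: list[tuple[int, str]] = []
        seen_ids: set[str] = set()
        for i, row in enumerate(reader, start=2):  # 1-based incl. header
            try:
                rec = parse_row(row, i)
                if rec.record_id in seen_ids:
                    raise ValueError(f"duplicate record_id {rec.record_id!r}")
                seen_ids.add(rec.record_id)
            except ValueError as e:
                logger.warning("row %d rejected: %s", i, e)
                rejected.append((i, str(e)))
                continue
            records.append(rec)
    return Dataset(
        records=records,
        provenance=provenance or str(path),
        rejected=rejected,
    )


def write_records(ds: Dataset | Iterable[ColourRecord], path) -> None:
    """Write records in the record-CSV dialect (round-trips with read_records)."""
    records: Sequence[ColourRecord] = list(ds)
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(RECORD_COLUMNS)
        for r in records:
            writer.writerow([
                r.record_id,
                r.source.value,
                r.date or "",
                repr(r.latitude),
                repr(r.longitude),
                r.calls["A"].value,
                r.calls["B"].value,
                r.calls["C"].value,
            ])


def summarize_sources(ds: Dataset) -> dict:
    """Per-source record counts and per-locus scored counts.

    Returns ``{"counts": {source: n}, "scored": {source: {locus: n}},
    "total": n}``; counts partition the dataset and scored counts are per
    locus, independent of missingness at the other loci.
    """
    counts = {s.value: 0 for s in Source}
    scored = {s.value: {loc: 0 for loc in LOCI} for s in Source}
    for r in ds:
        counts[r.source.value] += 1
        for loc in LOCI:
            if r.scored(loc):
                scored[r.source.value][loc] += 1
    return {"counts": counts, "scored": scored, "total": len(ds)}
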