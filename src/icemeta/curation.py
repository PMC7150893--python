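"""Curation of tabular homology-search hits.

Consumes the 11-field comma-separated hit layout

    qseqid,sacc,sgi,length,sstart,send,pident,evalue,staxid,sskingdom,ssciname

(headerless, one high-scoring pair per row, as produced by a tabular
nucleotide homology search capped at 20 targets per query) and applies
the curation chain, in this fixed order:

1. identity/e-value thresholds (pident >= 97 inclusive, e-value < 1e-6
   strict);
2. negative-control subtraction: any subject GI seen in the control at
   >= 97% identity is removed from the sample wholesale;
3. read enumeration: per accession (or GI), the number of DISTINCT query
   reads hitting it — multiple HSPs of one read count once;
4. best-hit deduplication: one record per GI, keeping the lowest
   e-value, then the highest percent identity, then the longest
   alignment, then first-seen;
5. molecule classification of the retained records into rRNA / mRNA /
   other via accession metadata.

The result is a :class:`CuratedProfile`: per-sample map of retained GIs
to their best hit, read count and molecule class, plus a provenance
block that records thresholds, removed GIs and the no-hit fraction.
"""
from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

logger = logging.getLogger(__name__)

N_HIT_FIELDS = 11
DEFAULT_MIN_PIDENT = 97.0
DEFAULT_MAX_EVALUE = 1e-6

MOLECULE_CLASSES = ("rRNA", "mRNA", "other")


class HitTableParseError(ValueError):
    """Malformed hit-table row, reported with the row number."""


class CurationError(ValueError):
    """Invalid curation input."""


@dataclass(frozen=True)
class HitRecord:
    """One homology hit row (one HSP)."""

    qseqid: str
    sacc: str
    sgi: int
    length: int
    sstart: int
    send: int
    pident: float
    evalue: float
    staxid: int
    sskingdom: str
    ssciname: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise CurationError(f"pident {self.pident} outside [0, 100]")
        if self.evalue < 0:
            raise CurationError(f"negative evalue {self.evalue}")
        if self.sstart < 1 or self.send < 1:
            raise CurationError("alignment coordinates are 1-based (>= 1)")

    def to_row(self) -> list[str]:
        return [
            self.qseqid,
            self.sacc,
            str(self.sgi),
            str(self.length),
            str(self.sstart),
            str(self.send),
            f"{self.pident:.3f}".rstrip("0").rstrip("."),
            repr(self.evalue),
            str(self.staxid),
            self.sskingdom,
            self.ssciname,
        ]


_NUMERIC_FIELDS = (
    ("sgi", int, 2),
    ("length", int, 3),
    ("sstart", int, 4),
    ("send", int, 5),
    ("pident", float, 6),
    ("evalue", float, 7),
    ("staxid", int, 8),
)


def parse_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a comma-separated, headerless 11-field hit table.

    Scientific names must not contain embedded commas in this dialect;
    wrong field counts and unparseable numerics raise
    :class:`HitTableParseError` naming the row (and field).
    """
    records: list[HitRecord] = []
    with open(path, newline="") as fh:
        for i, row in enumerate(csv.reader(fh), start=1):
            if not row:
                continue
            records.append(_parse_row(row, i))
    return records


def parse_hit_rows(rows: Iterable[Sequence[str]]) -> list[HitRecord]:
    return [_parse_row(list(row), i) for i, row in enumerate(rows, start=1)]


def _parse_row(row: list[str], rownum: int) -> HitRecord:
    if len(row) != N_HIT_FIELDS:
        raise HitTableParseError(
            f"row {rownum}: expected {N_HIT_FIELDS} fields, got {len(row)}"
        )
    values: dict[str, object] = {
        "qseqid": row[0],
        "sacc": row[1],
        "sskingdom": row[9],
        "ssciname": row[10],
    }
    for name, conv, idx in _NUMERIC_FIELDS:
        try:
            values[name] = conv(row[idx])
        except ValueError as exc:
            raise HitTableParseError(
                f"row {rownum}: cannot parse field {name!r} from {row[idx]!r}"
            ) from exc
    return HitRecord(**values)  # type: ignore[arg-type]


def write_hit_table(records: Iterable[HitRecord], path: str | Path) -> int:
    """Write records back to the 11-field comma-separated layout."""
    n = 0
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        for rec in records:
            w.writerow(rec.to_row())
            n += 1
    return n


# ---------------------------------------------------------------------------
# Curation operations
# ---------------------------------------------------------------------------

def apply_thresholds(
    hits: Iterable[HitRecord],
    min_pident: float = DEFAULT_MIN_PIDENT,
    max_evalue: float = DEFAULT_MAX_EVALUE,
) -> list[HitRecord]:
    """Keep hits with pident >= ``min_pident`` AND evalue < ``max_evalue``.

    The identity cutoff is inclusive, the e-value cutoff strict: a hit at
    exactly the e-value ceiling is removed, one at exactly the identity
    floor is retained.
    """
    return [h for h in hits if h.pident >= min_pident and h.evalue < max_evalue]


def subtract_control(
    sample_hits: Iterable[HitRecord],
    control_hits: Iterable[HitRecord],
    min_pident: float = DEFAULT_MIN_PIDENT,
) -> tuple[list[HitRecord], dict[int, int]]:
    """Remove sample hits whose subject GI occurs in the negative control.

    A control hit implicates its GI when its own identity is >=
    ``min_pident``; every sample hit with that GI is then removed,
    without re-checking the sample-side identity.  Returns the retained
    hits plus a report mapping each removed GI to the number of sample
    rows it accounted for.
    """
    contaminated = {h.sgi for h in control_hits if h.pident >= min_pident}
    kept: list[HitRecord] = []
    removed: dict[int, int] = {}
    for h in sample_hits:
        if h.sgi in contaminated:
            removed[h.sgi] = removed.get(h.sgi, 0) + 1
        else:
            kept.append(h)
    return kept, removed


def enumerate_reads(hits: Iterable[HitRecord], key: str = "sacc") -> dict:
    """Count, per accession (``key="sacc"``) or GI (``key="sgi"``), the
    number of distinct query reads hitting it.

    A read with several HSP rows against one subject counts once for
    that subject; a read hitting several subjects counts once per
    subject, so the total over subjects can exceed the number of reads.
    """
    if key not in ("sacc", "sgi", "ssciname"):
        raise CurationError(f"unsupported enumeration key {key!r}")
    seen: dict[object, set[str]] = {}
    for h in hits:
        seen.setdefault(getattr(h, key), set()).add(h.qseqid)
    return {k: len(v) for k, v in seen.items()}


def dedupe_best_hit(hits: Sequence[HitRecord]) -> list[HitRecord]:
    """One record per subject GI: lowest e-value, then highest identity,
    then longest alignment, then first-seen (stable).  Idempotent."""
    best: dict[int, tuple[tuple, HitRecord]] = {}
    order: list[int] = []
    for i, h in enumerate(hits):
        rank = (h.evalue, -h.pident, -h.length, i)
        if h.sgi not in best:
            best[h.sgi] = (rank, h)
            order.append(h.sgi)
        elif rank < best[h.sgi][0]:
            best[h.sgi] = (rank, h)
    return [best[gi][1] for gi in order]


def classify_molecule(
    record: HitRecord, reference_metadata: Mapping[str, str]
) -> str:
    """rRNA / mRNA / other classification via accession metadata.

    Accessions absent from the metadata fall back to ``"other"`` with a
    logged warning.
    """
    cls = reference_metadata.get(record.sacc)
    if cls is None:
        logger.warning(
            "accession %s absent from molecule metadata; classified as 'other'",
            record.sacc,
        )
        return "other"
    if cls not in MOLECULE_CLASSES:
        raise CurationError(f"unknown molecule class {cls!r} for {record.sacc}")
    return cls


# ---------------------------------------------------------------------------
# Curated profile
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CuratedRecord:
    best: HitRecord
    read_count: int
    molecule_class: str


@dataclass
class CuratedProfile:
    """Per-sample map of retained GIs to best hit, read count and class."""

    sample_label: str
    records: dict[int, CuratedRecord]
    min_pident: float = DEFAULT_MIN_PIDENT
    max_evalue: float = DEFAULT_MAX_EVALUE

    def validate(self) -> None:
        for gi, rec in self.records.items():
            if rec.best.sgi != gi:
                raise CurationError(f"record keyed {gi} holds GI {rec.best.sgi}")
            if rec.read_count < 1:
                raise CurationError(f"GI {gi}: read_count {rec.read_count} < 1")
            if rec.best.pident < self.min_pident or rec.best.evalue >= self.max_evalue:
                raise CurationError(f"GI {gi}: stored hit violates thresholds")
            if rec.molecule_class not in MOLECULE_CLASSES:
                raise CurationError(f"GI {gi}: bad class {rec.molecule_class!r}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def total_reads(self) -> int:
        return sum(r.read_count for r in self.records.values())

    def counts_by(self, key: str = "sgi") -> dict:
        """Read counts aggregated by sgi, sacc or ssciname."""
        out: dict[object, int] = {}
        for rec in self.records.values():
            k = getattr(rec.best, key)
            out[k] = out.get(k, 0) + rec.read_count
        return out


def curate(
    sample_hits: Sequence[HitRecord],
    control_hits: Sequence[HitRecord] = (),
    sample_label: str = "sample",
    min_pident: float = DEFAULT_MIN_PIDENT,
    max_evalue: float = DEFAULT_MAX_EVALUE,
    reads_searched: Optional[int] = None,
    molecule_metadata: Optional[Mapping[str, str]] = None,
) -> tuple[CuratedProfile, dict]:
    """Full curation chain: thresholds -> control subtraction ->
    enumeration -> dedup -> classification.

    ``reads_searched`` (number of reads submitted to the search) enables
    the no-hit fraction: 1 - (reads with any hit at any identity) /
    (reads searched).  Returns the profile plus a provenance dict.
    """
    reads_with_hit = len({h.qseqid for h in sample_hits})
    no_hit_fraction: Optional[float] = None
    if reads_searched is not None:
        if reads_searched < reads_with_hit:
            raise CurationError(
                f"reads_searched={reads_searched} < reads with hits={reads_with_hit}"
            )
        no_hit_fraction = 1.0 - reads_with_hit / reads_searched if reads_searched else 0.0

    thresholded = apply_thresholds(sample_hits, min_pident, max_evalue)
    decontaminated, removed = subtract_control(thresholded, control_hits, min_pident)
    counts = enumerate_reads(decontaminated, key="sgi")
    unique = dedupe_best_hit(decontaminated)
    metadata = molecule_metadata or {}
    records = {
        h.sgi: CuratedRecord(
            best=h,
            read_count=counts[h.sgi],
            molecule_class=classify_molecule(h, metadata),
        )
        for h in unique
    }
    profile = CuratedProfile(
        sample_label=sample_label,
        records=records,
        min_pident=min_pident,
        max_evalue=max_evalue,
    )
    profile.validate()
    provenance = {
        "sample": sample_label,
        "min_pident": min_pident,
        "max_evalue": max_evalue,
        "hits_parsed": len(sample_hits),
        "hits_after_thresholds": len(thresholded),
        "hits_after_control_subtraction": len(decontaminated),
        "unique_gis": len(unique),
        "removed_gis": {str(k): v for k, v in sorted(removed.items())},
        "reads_searched": reads_searched,
        "reads_with_any_hit": reads_with_hit,
        "no_hit_fraction": no_hit_fraction,
        "max_target_seqs": 20,  # property of the upstream search, recorded only
    }
    return profile, provenance


_PROFILE_COLUMNS = (
    "gi",
    "sacc",
    "ssciname",
    "staxid",
    "pident",
    "evalue",
    "read_count",
    "molecule_class",
)


def write_profile(profile: CuratedProfile, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(_PROFILE_COLUMNS)
        for gi in sorted(profile.records):
            rec = profile.records[gi]
            h = rec.best
            w.writerow(
                [
                    gi,
                    h.sacc,
                    h.ssciname,
                    h.staxid,
                    f"{h.pident:.3f}",
                    repr(h.evalue),
                    rec.read_count,
                    rec.molecule_class,
                ]
            )


def read_profile(path: str | Path, sample_label: Optional[str] = None) -> CuratedProfile:
    """Load a profile TSV written by :func:`write_profile`.

    Alignment-level fields not stored in the TSV (query id, alignment
    length/coordinates, super-kingdom) come back as placeholders; the
    taxonomic and count fields round-trip exactly.
    """
    records: dict[int, CuratedRecord] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            gi = int(row["gi"])
            best = HitRecord(
                qseqid="-",
                sacc=row["sacc"],
                sgi=gi,
                length=1,
                sstart=1,
                send=1,
                pident=float(row["pident"]),
                evalue=float(row["evalue"]),
                staxid=int(row["staxid"]),
                sskingdom="",
                ssciname=row["ssciname"],
            )
            records[gi] = CuratedRecord(
                best=best,
                read_count=int(row["read_count"]),
                molecule_class=row["molecule_class"],
            )
    label = sample_label or Path(path).stem.removeprefix("profile_")
    profile = CuratedProfile(sample_label=label, records=records)
    profile.validate()
    return profile


def write_provenance(provenance: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
        fh.write("\n")
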