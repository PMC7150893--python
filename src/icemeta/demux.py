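"""Multiplex-identifier demultiplexing and primer clipping.

Reads produced by the two-stage tagging protocol are decorated as

    <platform adapter A> + <10-nt MID> + <EcoRI/NotI linker> + insert

where the MID (multiplex identifier) assigns each read to its source
sample.  This module converts FASTQ to FASTA, splits reads into
per-sample bins by locating the MID in a 5' search window, clips the
adapter/MID/linker decoration (and a 3' linker/adapter occurrence when
one is found), and drops reads shorter than a minimum insert length.

Every input read lands in exactly one of: a sample bin, the unassigned
bin, the fully-clipped discard list, or the short-read discard list.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

# Ion Torrent library adapters (A and P1) and the EcoRI/NotI linker that
# sits between the MID and the insert.
ION_ADAPTER_A = "CCATCTCATCCCTGCGTGTCTCCGACTCAG"
ION_ADAPTER_P1 = "CCTCTCTATGGGCAGTCGGTGAT"
ECORI_NOTI_LINKER = "AATTCGCGGCCGCGTCGAC"

# MIDs used for the five multiplexed groups (four ice-core depth pools
# plus the sterile-water negative control).
DEFAULT_MIDS: dict[str, str] = {
    "2149m": "ACGCTCGACA",        # glacial ice
    "3501_3520m": "AGCACTGTAG",   # basal ice
    "3540_3569m": "ATCAGACACG",   # west embayment accretion ice
    "3585m": "ATATCGCGAG",        # east embayment accretion ice
    "control": "TCTCTATGCG",      # sterile water control
}

MID_LENGTH = 10
DEFAULT_MID_WINDOW = 45  # 5' window (bases) in which the MID must lie
DEFAULT_MIN_LENGTH = 50


class DemuxError(ValueError):
    """Invalid demultiplexing input (manifest or sequence records)."""


class FastqParseError(DemuxError):
    """Malformed FASTQ, reported with the offending record/line."""


@dataclass(frozen=True)
class SequenceRead:
    """One sequencing read: identifier, bases, optional Phred qualities."""

    read_id: str
    bases: str
    qualities: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.bases:
            raise DemuxError(f"read {self.read_id!r} has empty bases")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise DemuxError(
                f"read {self.read_id!r}: {len(self.qualities)} qualities for "
                f"{len(self.bases)} bases"
            )

    def __len__(self) -> int:
        return len(self.bases)


@dataclass(frozen=True)
class MIDEntry:
    """Per-sample tag definition: MID, linker and platform adapters."""

    sample_label: str
    mid: str
    linker: str = ECORI_NOTI_LINKER
    platform_adapters: tuple[str, str] = (ION_ADAPTER_A, ION_ADAPTER_P1)


@dataclass(frozen=True)
class MIDManifest:
    """The set of MID assignments for one sequencing run."""

    entries: tuple[MIDEntry, ...]

    def __post_init__(self) -> None:
        mids = [e.mid for e in self.entries]
        if len(set(mids)) != len(mids):
            dupes = sorted({m for m in mids if mids.count(m) > 1})
            raise DemuxError(f"duplicate MID(s) in manifest: {dupes}")
        labels = [e.sample_label for e in self.entries]
        if len(set(labels)) != len(labels):
            raise DemuxError("duplicate sample labels in manifest")
        for e in self.entries:
            if len(e.mid) != MID_LENGTH:
                raise DemuxError(
                    f"MID for {e.sample_label!r} has length {len(e.mid)}, "
                    f"expected {MID_LENGTH}"
                )

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, sample_label: str) -> MIDEntry:
        for e in self.entries:
            if e.sample_label == sample_label:
                return e
        raise KeyError(sample_label)

    @property
    def sample_labels(self) -> tuple[str, ...]:
        return tuple(e.sample_label for e in self.entries)


def default_manifest() -> MIDManifest:
    """Manifest for the five-group run (four depth pools + water control)."""
    return MIDManifest(
        tuple(MIDEntry(sample_label=label, mid=mid) for label, mid in DEFAULT_MIDS.items())
    )


# ---------------------------------------------------------------------------
# FASTQ / FASTA I/O
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[SequenceRead]:
    """Parse a Phred+33 FASTQ file into :class:`SequenceRead` records."""
    reads: list[SequenceRead] = []
    try:
        for i, rec in enumerate(SeqIO.parse(str(path), "fastq")):
            reads.append(
                SequenceRead(
                    read_id=rec.id,
                    bases=str(rec.seq),
                    qualities=tuple(rec.letter_annotations["phred_quality"]),
                )
            )
    except ValueError as exc:
        # Biopython reports the record, not the file line; derive the line
        # from the 4-line record structure.
        line = len(reads) * 4 + 1
        raise FastqParseError(
            f"malformed FASTQ near record {len(reads) + 1} (line ~{line}): {exc}"
        ) from exc
    return reads


def read_fasta(path: str | Path) -> list[SequenceRead]:
    return [
        SequenceRead(read_id=rec.id, bases=str(rec.seq))
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_fasta(reads: Iterable[SequenceRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.bases}\n")
            n += 1
    return n


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            quals = r.qualities if r.qualities is not None else (40,) * len(r.bases)
            qline = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qline}\n")
            n += 1
    return n


def convert_fastq_to_fasta(fastq_path: str | Path, fasta_path: str | Path) -> int:
    """FASTQ -> FASTA, preserving identifiers and bases, dropping qualities.

    Returns the number of records converted (conserved by construction).
    """
    reads = read_fastq(fastq_path)
    return write_fasta(reads, fasta_path)


# ---------------------------------------------------------------------------
# MID assignment
# ---------------------------------------------------------------------------

def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _best_mid_occurrence(
    bases: str, mid: str, window: int, max_mismatch: int
) -> Optional[tuple[int, int]]:
    """Best (mismatches, end_position) of ``mid`` fully inside ``bases[:window]``.

    Returns ``None`` when no occurrence has <= ``max_mismatch`` substitutions.
    """
    if max_mismatch == 0:
        pos = bases.find(mid, 0, window)
        if pos < 0:
            return None
        return (0, pos + len(mid))
    best: Optional[tuple[int, int]] = None
    limit = min(window, len(bases)) - len(mid)
    for start in range(0, limit + 1):
        mm = _hamming(bases[start : start + len(mid)], mid)
        if mm <= max_mismatch and (best is None or mm < best[0]):
            best = (mm, start + len(mid))
            if mm == 0:
                break
    return best


@dataclass
class DemuxResult:
    """Partition of the input reads plus per-read MID match metadata."""

    bins: dict[str, list[SequenceRead]]
    unassigned: list[SequenceRead]
    fully_clipped: list[SequenceRead] = field(default_factory=list)
    short: list[SequenceRead] = field(default_factory=list)
    # read_id -> (sample_label, mid_end_position, mismatches)
    matches: dict[str, tuple[str, int, int]] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return (
            sum(len(v) for v in self.bins.values())
            + len(self.unassigned)
            + len(self.fully_clipped)
            + len(self.short)
        )

    def report(self) -> dict[str, dict[str, int]]:
        return {
            "assigned": {k: len(v) for k, v in self.bins.items()},
            "unassigned": {"": len(self.unassigned)},
            "fully_clipped": {"": len(self.fully_clipped)},
            "short": {"": len(self.short)},
        }


def assign_by_mid(
    reads: Sequence[SequenceRead],
    manifest: MIDManifest,
    max_mismatch: int = 0,
    window: int = DEFAULT_MID_WINDOW,
) -> DemuxResult:
    """Bin reads by the best MID occurrence in the 5' search window.

    A read goes to the unique manifest entry with the fewest MID
    mismatches (<= ``max_mismatch``); ties between two or more MIDs send
    the read to the unassigned bin rather than guessing, so ambiguous
    tags never bleed across samples.
    """
    bins: dict[str, list[SequenceRead]] = {e.sample_label: [] for e in manifest}
    result = DemuxResult(bins=bins, unassigned=[])
    for read in reads:
        candidates: list[tuple[int, str, int]] = []
        for entry in manifest:
            hit = _best_mid_occurrence(read.bases, entry.mid, window, max_mismatch)
            if hit is not None:
                candidates.append((hit[0], entry.sample_label, hit[1]))
        if not candidates:
            result.unassigned.append(read)
            continue
        best_mm = min(c[0] for c in candidates)
        winners = [c for c in candidates if c[0] == best_mm]
        if len(winners) > 1:
            result.unassigned.append(read)
            continue
        mm, label, end = winners[0]
        bins[label].append(read)
        result.matches[read.read_id] = (label, end, mm)
    return result


# ---------------------------------------------------------------------------
# Clipping and length filtering
# ---------------------------------------------------------------------------

def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def clip_decoration(
    read: SequenceRead,
    entry: MIDEntry,
    mid_end: Optional[int] = None,
    max_mismatch: int = 0,
    window: int = DEFAULT_MID_WINDOW,
) -> Optional[SequenceRead]:
    """Remove the 5' adapter+MID+linker decoration (and any 3' remnant).

    Everything through the end of the matched MID is removed; a linker
    immediately following the MID (within the mismatch tolerance) is
    removed too.  A 3' occurrence of the linker or either platform
    adapter — forward or reverse-complement — truncates the read at
    that point.  Returns ``None`` when clipping leaves nothing (the
    caller routes such reads to a fully-clipped discard list).  The
    returned bases are always a contiguous substring of the input.
    """
    bases = read.bases
    if mid_end is None:
        hit = _best_mid_occurrence(bases, entry.mid, window, max_mismatch)
        if hit is None:
            raise DemuxError(
                f"read {read.read_id!r} has no MID match for sample "
                f"{entry.sample_label!r}; assign before clipping"
            )
        mid_end = hit[1]
    start = mid_end
    linker = entry.linker
    if linker and len(bases) >= start + len(linker):
        if _hamming(bases[start : start + len(linker)], linker) <= max_mismatch:
            start += len(linker)
    remainder = bases[start:]
    # 3' cleanup: earliest occurrence of a linker/adapter motif truncates.
    motifs = {linker, _revcomp(linker)}
    for ad in entry.platform_adapters:
        motifs.add(ad)
        motifs.add(_revcomp(ad))
    cut = len(remainder)
    for motif in motifs:
        if not motif:
            continue
        j = remainder.find(motif)
        if j >= 0:
            cut = min(cut, j)
    remainder = remainder[:cut]
    if not remainder:
        return None
    quals = None
    if read.qualities is not None:
        quals = read.qualities[start : start + cut]
    return SequenceRead(read_id=read.read_id, bases=remainder, qualities=quals)


def filter_min_length(
    reads: Sequence[SequenceRead], min_len: int = DEFAULT_MIN_LENGTH
) -> tuple[list[SequenceRead], int]:
    """Keep reads with length >= ``min_len`` (order preserved).

    Returns (retained reads, number discarded).
    """
    retained = [r for r in reads if len(r) >= min_len]
    return retained, len(reads) - len(retained)


def mean_quality_filter(
    reads: Sequence[SequenceRead], min_mean_phred: float = 20.0
) -> tuple[list[SequenceRead], int]:
    """Optional pre-filter: drop reads whose mean Phred score is below a floor.

    Off by default in the pipeline; reads without qualities pass.
    """
    kept = [
        r
        for r in reads
        if r.qualities is None or sum(r.qualities) / len(r.qualities) >= min_mean_phred
    ]
    return kept, len(reads) - len(kept)


def demux_reads(
    reads: Sequence[SequenceRead],
    manifest: MIDManifest,
    max_mismatch: int = 0,
    min_len: int = DEFAULT_MIN_LENGTH,
    window: int = DEFAULT_MID_WINDOW,
) -> DemuxResult:
    """Full demultiplex: assign, clip, length-filter; partition preserved."""
    assigned = assign_by_mid(reads, manifest, max_mismatch=max_mismatch, window=window)
    out_bins: dict[str, list[SequenceRead]] = {e.sample_label: [] for e in manifest}
    result = DemuxResult(bins=out_bins, unassigned=assigned.unassigned, matches=assigned.matches)
    for entry in manifest:
        for read in assigned.bins[entry.sample_label]:
            _, mid_end, _ = assigned.matches[read.read_id]
            clipped = clip_decoration(
                read, entry, mid_end=mid_end, max_mismatch=max_mismatch, window=window
            )
            if clipped is None:
                result.fully_clipped.append(read)
            elif len(clipped) < min_len:
                result.short.append(clipped)
            else:
                out_bins[entry.sample_label].append(clipped)
    return result


def write_demux_report(result: DemuxResult, path: str | Path) -> None:
    """TSV demux report: per-sample assigned counts plus discard tallies."""
    with open(path, "w") as fh:
        fh.write("category\tsample\tcount\n")
        for label in sorted(result.bins):
            fh.write(f"assigned\t{label}\t{len(result.bins[label])}\n")
        fh.write(f"unassigned\t-\t{len(result.unassigned)}\n")
        fh.write(f"short\t-\t{len(result.short)}\n")
        fh.write(f"fully_clipped\t-\t{len(result.fully_clipped)}\n")
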