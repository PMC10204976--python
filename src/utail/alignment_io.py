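"""Reading SAM/BAM alignments and normalising them for tail extraction.

Only mapped primary alignments can carry a trustworthy 3' soft clip:
secondary (0x100) and supplementary (0x800) records repeat or split the
read, and unmapped records have no reference context. This module filters
to the primary mapped set, tallies what it skipped, and exposes each kept
record as a plain :class:`AlignmentRecord` so downstream code never touches
pysam objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import pysam

# CIGAR operation codes per the SAM specification.
CIGAR_OPS = "MIDNSHP=X"
QUERY_CONSUMING = frozenset("MIS=X")
REFERENCE_CONSUMING = frozenset("MDN=X")


class AlignmentInputError(Exception):
    """Input file missing or unreadable."""


class AlignmentParseError(Exception):
    """Malformed header or record; message names the record ordinal."""


class RegionLookupError(Exception):
    """Requested region names a reference absent from the header."""


@dataclass(frozen=True)
class AlignmentRecord:
    """One primary alignment, decomposed from its SAM representation.

    ``seq`` is stored exactly as in the SAM file, i.e. in reference
    orientation; ``pos`` is the 1-based leftmost mapping coordinate.
    ``mate_index`` is 1 or 2 for paired reads and 0 for unpaired.
    """

    query_name: str
    is_primary: bool
    is_reverse: bool
    mate_index: int
    reference_name: str
    pos: int
    cigar: tuple[tuple[int, str], ...]
    seq: str
    mapq: int
    is_duplicate: bool = False
    qualities: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.cigar:
            raise ValueError("mapped record requires a non-empty CIGAR")
        query_len = sum(n for n, op in self.cigar if op in QUERY_CONSUMING)
        if self.seq and query_len != len(self.seq):
            raise ValueError(
                f"CIGAR query length {query_len} != seq length {len(self.seq)} "
                f"for read {self.query_name!r}"
            )


@dataclass
class SkipTally:
    """Counts of records excluded while streaming a file."""

    secondary: int = 0
    supplementary: int = 0
    unmapped: int = 0
    no_sequence: int = 0
    duplicate: int = 0
    low_mapq: int = 0
    kept: int = 0

    def total_skipped(self) -> int:
        return (
            self.secondary
            + self.supplementary
            + self.unmapped
            + self.no_sequence
            + self.duplicate
            + self.low_mapq
        )

    def as_dict(self) -> dict[str, int]:
        return {
            "kept": self.kept,
            "secondary": self.secondary,
            "supplementary": self.supplementary,
            "unmapped": self.unmapped,
            "no_sequence": self.no_sequence,
            "duplicate": self.duplicate,
            "low_mapq": self.low_mapq,
        }


def _mate_index(aln: pysam.AlignedSegment) -> int:
    if not aln.is_paired:
        return 0
    return 1 if aln.is_read1 else 2


def _to_record(aln: pysam.AlignedSegment) -> AlignmentRecord:
    cigar = tuple((int(n), CIGAR_OPS[op]) for op, n in aln.cigartuples)
    quals = tuple(aln.query_qualities) if aln.query_qualities is not None else None
    return AlignmentRecord(
        query_name=aln.query_name,
        is_primary=not (aln.is_secondary or aln.is_supplementary),
        is_reverse=aln.is_reverse,
        mate_index=_mate_index(aln),
        reference_name=aln.reference_name,
        pos=aln.reference_start + 1,
        cigar=cigar,
        seq=aln.query_sequence or "",
        mapq=aln.mapping_quality,
        is_duplicate=aln.is_duplicate,
        qualities=quals,
    )


def read_alignments(
    path: str | Path,
    region: Optional[str] = None,
    *,
    drop_duplicates: bool = False,
    min_mapq: int = 0,
    tally: Optional[SkipTally] = None,
) -> Iterator[AlignmentRecord]:
    """Stream mapped, primary, non-supplementary alignments in file order.

    Records that are unmapped, secondary, supplementary, sequence-less
    (SEQ ``*``), duplicate-marked (only when ``drop_duplicates``), or below
    ``min_mapq`` are skipped silently but counted in ``tally``.

    Parameters
    ----------
    path
        SAM or BAM file with a header. BAM needs an index only for
        region queries.
    region
        Optional samtools-style region string; its reference must be in
        the header.
    tally
        A caller-supplied :class:`SkipTally`, updated in place so skip
        counts are available after the stream is exhausted.
    """
    path = Path(path)
    if not path.exists():
        raise AlignmentInputError(f"alignment file not found: {path}")
    if tally is None:
        tally = SkipTally()

    try:
        handle = pysam.AlignmentFile(str(path), "r")
    except (ValueError, OSError) as exc:
        raise AlignmentParseError(f"cannot open {path}: {exc}") from exc

    with handle:
        if region is not None:
            ref = region.split(":")[0]
            if ref not in handle.references:
                raise RegionLookupError(f"region reference {ref!r} not in header")
            iterator = handle.fetch(region=region)
        else:
            iterator = handle
        ordinal = 0
        for aln in iterator:
            ordinal += 1
            try:
                if aln.is_unmapped:
                    tally.unmapped += 1
                    continue
                if aln.is_secondary:
                    tally.secondary += 1
                    continue
                if aln.is_supplementary:
                    tally.supplementary += 1
                    continue
                if aln.query_sequence is None:
                    tally.no_sequence += 1
                    continue
                if drop_duplicates and aln.is_duplicate:
                    tally.duplicate += 1
                    continue
                if aln.mapping_quality < min_mapq:
                    tally.low_mapq += 1
                    continue
                rec = _to_record(aln)
            except ValueError as exc:
                raise AlignmentParseError(f"malformed record #{ordinal}: {exc}") from exc
            tally.kept += 1
            yield rec


def aligned_reference_span(rec: AlignmentRecord) -> tuple[int, int]:
    """Return the 1-based inclusive reference interval covered by ``rec``.

    The last reference base is ``pos + (sum of M/D/N/=/X lengths) - 1``;
    soft/hard clips and insertions consume no reference.
    """
    ref_len = sum(n for n, op in rec.cigar if op in REFERENCE_CONSUMING)
    if ref_len == 0:
        raise ValueError(f"CIGAR of {rec.query_name!r} has no reference-consuming op")
    return rec.pos, rec.pos + ref_len - 1
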