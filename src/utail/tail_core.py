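"""Extraction and classification of 3'-end soft-clipped tails.

The biological 3' end of a read sits at the right CIGAR terminus for a
plus-strand alignment and at the left terminus for a minus-strand alignment
(SAM stores sequence in reference orientation). A terminal soft clip there
is a candidate non-templated extension; once reverse-complemented into the
read's own 5'→3' orientation it is classified by a four-way grammar:

======== ==========================================
poly(A)  only adenosines                  (``A+``)
poly(AU) an A-run then a U-run            (``A+U+``)
oligo(U) only uridines                    (``U+``)
mixed    any other A/U-only arrangement
======== ==========================================

Tails containing any base outside {A, U} are rejected outright. Sequencers
report uridine as T; the internal alphabet is DNA and user-facing output
rewrites T to U.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Iterator, Optional, TextIO

from utail.alignment_io import AlignmentRecord, aligned_reference_span

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_MIN_TAIL_LEN = 4
DEFAULT_MIN_ANCHOR = 20


class TailCategory(str, Enum):
    POLYA = "POLYA"
    POLYAU = "POLYAU"
    OLIGOU = "OLIGOU"
    MIXED = "MIXED"

    @property
    def display(self) -> str:
        """Field vocabulary: poly(A), poly(A)U, oligo(U), mixed."""
        return {
            TailCategory.POLYA: "poly(A)",
            TailCategory.POLYAU: "poly(A)U",
            TailCategory.OLIGOU: "oligo(U)",
            TailCategory.MIXED: "mixed",
        }[self]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class RawTail:
    """An oriented 3' extension before classification.

    ``tail_seq`` is written 5'→3' in the read's biological orientation
    (DNA alphabet); ``junction`` is the 1-based genomic coordinate of the
    last templated base, i.e. the base the tail hangs off.
    """

    read_id: str
    tail_seq: str
    junction: int
    junction_strand: str
    reference_name: str


@dataclass(frozen=True)
class TailCall:
    """A classified tail."""

    raw: RawTail
    category: TailCategory
    a_run: int
    u_run: int
    tail_len: int

    @property
    def tail_seq_u(self) -> str:
        """Tail sequence in the RNA (U) alphabet for output."""
        return self.raw.tail_seq.replace("T", "U")


def extract_three_prime_clip(
    rec: AlignmentRecord, *, min_anchor: int = DEFAULT_MIN_ANCHOR
) -> Optional[RawTail]:
    """Pull the soft-clipped 3' extension off one alignment, if present.

    Plus strand: the suffix of ``seq`` under a terminal right-end S op,
    taken as-is; junction is the last aligned reference base. Minus
    strand: the reverse complement of the prefix under a terminal left-end
    S op; junction is ``pos``. A clip at the read's biological 5' end is
    ignored. Hard clips outside the soft clip are tolerated per the SAM
    spec and carry no sequence.

    Records whose aligned reference span is shorter than ``min_anchor``
    are skipped: a tail hanging off a tiny anchor is unreliable.
    """
    if not rec.seq:
        return None
    first_ref, last_ref = aligned_reference_span(rec)
    if last_ref - first_ref + 1 < min_anchor:
        return None

    cigar = rec.cigar
    if rec.is_reverse:
        # biological 3' end = left CIGAR terminus (skip a leading H)
        idx = 1 if cigar[0][1] == "H" and len(cigar) > 1 else 0
        n, op = cigar[idx]
        if op != "S":
            return None
        clipped = rec.seq[:n]
        return RawTail(
            read_id=rec.query_name,
            tail_seq=reverse_complement(clipped),
            junction=rec.pos,
            junction_strand="-",
            reference_name=rec.reference_name,
        )
    idx = len(cigar) - 2 if cigar[-1][1] == "H" and len(cigar) > 1 else len(cigar) - 1
    n, op = cigar[idx]
    if op != "S":
        return None
    clipped = rec.seq[len(rec.seq) - n :]
    return RawTail(
        read_id=rec.query_name,
        tail_seq=clipped,
        junction=last_ref,
        junction_strand="+",
        reference_name=rec.reference_name,
    )


_POLYA_RE = re.compile(r"^A+$")
_OLIGOU_RE = re.compile(r"^T+$")
_POLYAU_RE = re.compile(r"^A+T+$")
_AU_ONLY_RE = re.compile(r"^[AT]+$")


def classify_tail(tail_seq: str) -> Optional[tuple[TailCategory, int, int, int]]:
    """Classify an oriented tail; return None for rejected (non-A/U) tails.

    Returns ``(category, a_run, u_run, tail_len)`` where ``a_run`` is the
    maximal leading A-run and ``u_run`` the maximal trailing T-run. Input
    T is read as U. Any other character (including N) rejects the tail.
    """
    if not tail_seq:
        raise ValueError("cannot classify an empty tail")
    seq = tail_seq.upper()
    if not _AU_ONLY_RE.match(seq):
        return None
    a_run = len(seq) - len(seq.lstrip("A"))
    u_run = len(seq) - len(seq.rstrip("T"))
    if _POLYA_RE.match(seq):
        category = TailCategory.POLYA
    elif _OLIGOU_RE.match(seq):
        category = TailCategory.OLIGOU
    elif _POLYAU_RE.match(seq):
        category = TailCategory.POLYAU
    else:
        category = TailCategory.MIXED
    return category, a_run, u_run, len(seq)


def passes_length(call: TailCall, min_len: int = DEFAULT_MIN_TAIL_LEN) -> bool:
    """True iff the tail is long enough to be trusted (default >= 4 nt).

    Short clips are frequently sequencing artefacts; requiring at least
    four A/U bases keeps the false-positive rate down.
    """
    if min_len < 1:
        raise ValueError(f"min_len must be >= 1, got {min_len}")
    return call.tail_len >= min_len


def call_tails(
    records: Iterable[AlignmentRecord],
    *,
    min_tail_len: int = DEFAULT_MIN_TAIL_LEN,
    min_anchor: int = DEFAULT_MIN_ANCHOR,
    min_clip_qual: int = 0,
    dedup_fragments: bool = False,
    tally: Optional[dict[str, int]] = None,
) -> list[TailCall]:
    """Run extract → classify → length-filter over a record stream.

    With ``min_clip_qual`` > 0, clip bases whose base quality falls below
    the threshold are masked to N, which rejects the tail. With
    ``dedup_fragments``, at most one call per query name is kept,
    preferring the longer tail, ties broken in favour of mate 1.
    """
    counts = {"scanned": 0, "no_clip": 0, "rejected": 0, "short": 0, "accepted": 0}
    best: dict[str, tuple[TailCall, tuple[int, int]]] = {}
    out: list[TailCall] = []
    for rec in records:
        counts["scanned"] += 1
        raw = extract_three_prime_clip(rec, min_anchor=min_anchor)
        if raw is None:
            counts["no_clip"] += 1
            continue
        tail_seq = raw.tail_seq
        if min_clip_qual > 0 and rec.qualities is not None:
            tail_seq = _mask_low_quality(rec, raw, min_clip_qual)
        result = classify_tail(tail_seq)
        if result is None:
            counts["rejected"] += 1
            continue
        category, a_run, u_run, tail_len = result
        call = TailCall(raw=raw, category=category, a_run=a_run, u_run=u_run, tail_len=tail_len)
        if not passes_length(call, min_tail_len):
            counts["short"] += 1
            continue
        counts["accepted"] += 1
        if dedup_fragments:
            key = rec.query_name
            # longer tail wins; on a tie, mate 1 wins
            rank = (call.tail_len, 1 if rec.mate_index == 1 else 0)
            if key not in best or rank > best[key][1]:
                best[key] = (call, rank)
        else:
            out.append(call)
    if dedup_fragments:
        out = [call for call, _ in best.values()]
        counts["accepted"] = len(out)
    if tally is not None:
        tally.update(counts)
    return out


def _mask_low_quality(rec: AlignmentRecord, raw: RawTail, min_qual: int) -> str:
    if rec.is_reverse:
        clip_quals = rec.qualities[: len(raw.tail_seq)][::-1]
    else:
        clip_quals = rec.qualities[len(rec.qualities) - len(raw.tail_seq) :]
    return "".join(
        base if q >= min_qual else "N" for base, q in zip(raw.tail_seq, clip_quals)
    )


# ---------------------------------------------------------------------------
# tail-call table I/O

TAIL_TSV_COLUMNS = (
    "read_id",
    "reference",
    "junction",
    "strand",
    "tail_seq",
    "category",
    "a_run",
    "u_run",
    "tail_len",
)


def write_tail_tsv(calls: Iterable[TailCall], handle: TextIO, *, header_lines: Iterable[str] = ()) -> None:
    """Write the tab-separated tail-call table (U alphabet in tail_seq)."""
    for line in header_lines:
        handle.write(f"# {line}\n")
    handle.write("\t".join(TAIL_TSV_COLUMNS) + "\n")
    for c in calls:
        handle.write(
            "\t".join(
                (
                    c.raw.read_id,
                    c.raw.reference_name,
                    str(c.raw.junction),
                    c.raw.junction_strand,
                    c.tail_seq_u,
                    c.category.value,
                    str(c.a_run),
                    str(c.u_run),
                    str(c.tail_len),
                )
            )
            + "\n"
        )


def read_tail_tsv(handle: TextIO) -> Iterator[TailCall]:
    """Read a table written by :func:`write_tail_tsv`."""
    header_seen = False
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        fields = line.split("\t")
        raw = RawTail(
            read_id=fields[0],
            tail_seq=fields[4].replace("U", "T"),
            junction=int(fields[2]),
            junction_strand=fields[3],
            reference_name=fields[1],
        )
        yield TailCall(
            raw=raw,
            category=TailCategory(fields[5]),
            a_run=int(fields[6]),
            u_run=int(fields[7]),
            tail_len=int(fields[8]),
        )
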