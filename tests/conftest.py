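"""Shared fixtures: synthetic alignment records, SAM files, and sim bundles."""

from __future__ import annotations

from pathlib import Path

import pytest

from utail.alignment_io import AlignmentRecord
from utail.feature_assign import AssignedTail
from utail.simulate import SimSpec, make_genome_and_annotation, simulate_reads
from utail.tail_core import RawTail, TailCall, TailCategory, classify_tail, reverse_complement


def make_record(
    *,
    query_name: str = "r1",
    is_reverse: bool = False,
    reference_name: str = "chr1",
    pos: int = 100,
    cigar: tuple[tuple[int, str], ...] = ((20, "M"),),
    seq: str = "",
    mapq: int = 60,
    mate_index: int = 0,
) -> AlignmentRecord:
    if not seq:
        seq = "C" * sum(n for n, op in cigar if op in "MIS=X")
    return AlignmentRecord(
        query_name=query_name,
        is_primary=True,
        is_reverse=is_reverse,
        mate_index=mate_index,
        reference_name=reference_name,
        pos=pos,
        cigar=cigar,
        seq=seq,
        mapq=mapq,
    )


def records_for_fragment(anchor: str, tail: str, pos: int = 1000) -> tuple[AlignmentRecord, AlignmentRecord]:
    """Emit one biological fragment as a plus- and a minus-strand record.

    The biological read is ``anchor + tail`` (5'->3'). The plus-strand
    record stores it as-is with the clip on the right; the minus-strand
    record stores the reverse complement with the clip on the left, per
    SAM convention.
    """
    read = anchor + tail
    plus = make_record(
        query_name="frag+",
        is_reverse=False,
        pos=pos,
        cigar=((len(anchor), "M"), (len(tail), "S")),
        seq=read,
    )
    minus = make_record(
        query_name="frag-",
        is_reverse=True,
        pos=pos,
        cigar=((len(tail), "S"), (len(anchor), "M")),
        seq=reverse_complement(read),
    )
    return plus, minus


def make_call(
    tail_seq: str,
    *,
    read_id: str = "r1",
    junction: int = 1000,
    strand: str = "+",
    reference_name: str = "chr1",
) -> TailCall:
    result = classify_tail(tail_seq)
    assert result is not None, f"test helper got a rejected tail {tail_seq!r}"
    category, a_run, u_run, tail_len = result
    raw = RawTail(
        read_id=read_id,
        tail_seq=tail_seq,
        junction=junction,
        junction_strand=strand,
        reference_name=reference_name,
    )
    return TailCall(raw=raw, category=category, a_run=a_run, u_run=u_run, tail_len=tail_len)


def make_assigned(
    tail_seq: str,
    *,
    feature_id: str = "gene0001",
    biotype: str = "mRNA",
    tes_distance: int = 0,
    read_id: str = "r1",
    junction: int = 1000,
    strand: str = "+",
) -> AssignedTail:
    return AssignedTail(
        call=make_call(tail_seq, read_id=read_id, junction=junction, strand=strand),
        feature_id=feature_id,
        biotype=biotype,
        tes_distance=tes_distance,
    )


@pytest.fixture(scope="session")
def default_bundle(tmp_path_factory) -> dict:
    """One deterministic simulation shared by read-only tests."""
    spec = SimSpec(seed=11, n_fragments=10_000)
    genome, features = make_genome_and_annotation(spec)
    result = simulate_reads(spec, genome, features)
    outdir = tmp_path_factory.mktemp("bundle")
    sam = outdir / "reads.sam"
    sam.write_text(result.sam_text)
    return {
        "spec": spec,
        "genome": genome,
        "features": features,
        "result": result,
        "sam": sam,
        "dir": outdir,
    }
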