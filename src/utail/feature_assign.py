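"""Annotation loading, closest-feature assignment, and TES distances.

Tail junctions are assigned to annotated transcripts the way ``bedtools
closest`` assigns reads to genes: a feature overlapping the junction wins
outright; otherwise the feature with the smallest genomic distance is
taken, by default restricted to features on the same strand (a tail
derives from its own transcript's 3' end). The signed distance to the
feature's transcription end site (TES) is reported in the feature's
orientation: 0 means the junction sits exactly on the TES, positive means
downstream of it, negative upstream.

Internal coordinates are 0-based half-open; GFF3 (1-based inclusive) and
BED (already half-open) are converted at the I/O boundary.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional, TextIO

from intervaltree import IntervalTree

from utail.tail_core import TAIL_TSV_COLUMNS, RawTail, TailCall, TailCategory

BIOTYPES = (
    "mRNA",
    "ncRNA_antisense",
    "ncRNA_bidirectional",
    "ncRNA_intergenic",
    "ncRNA_overlapping",
    "rRNA",
    "tRNA",
    "snoRNA",
    "snRNA",
    "other",
)

# maps common annotation biotype spellings onto the closed vocabulary
DEFAULT_BIOTYPE_MAP = {
    "mrna": "mRNA",
    "protein_coding": "mRNA",
    "ncrna_antisense": "ncRNA_antisense",
    "antisense": "ncRNA_antisense",
    "ncrna_bidirectional": "ncRNA_bidirectional",
    "bidirectional": "ncRNA_bidirectional",
    "ncrna_intergenic": "ncRNA_intergenic",
    "intergenic": "ncRNA_intergenic",
    "ncrna_overlapping": "ncRNA_overlapping",
    "overlapping": "ncRNA_overlapping",
    "rrna": "rRNA",
    "trna": "tRNA",
    "snorna": "snoRNA",
    "snrna": "snRNA",
}

DEFAULT_MAX_DISTANCE = 1000


class AnnotationError(Exception):
    """Malformed annotation line or duplicate feature id."""


@dataclass(frozen=True)
class Feature:
    """An annotated genomic interval (0-based half-open internally)."""

    feature_id: str
    reference_name: str
    start: int
    end: int
    strand: str
    biotype: str = "other"

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.feature_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.feature_id}: strand must be + or -")
        if self.biotype not in BIOTYPES:
            raise ValueError(f"{self.feature_id}: unknown biotype {self.biotype!r}")


@dataclass(frozen=True)
class AssignedTail:
    """A tail call joined to its closest feature."""

    call: TailCall
    feature_id: str
    biotype: str
    tes_distance: int


def tes_of(f: Feature) -> int:
    """1-based genomic coordinate of the feature's 3'-most base.

    Plus strand: the last base of the interval; minus strand: the first.
    """
    return f.end if f.strand == "+" else f.start + 1


def _normalise_biotype(value: Optional[str], mapping: dict[str, str]) -> str:
    if value is None:
        return "other"
    return mapping.get(value.strip().lower(), "other")


def _parse_gff3_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        if "=" in part:
            key, value = part.split("=", 1)
            attrs[key.strip()] = value.strip()
    return attrs


def load_annotation(
    path: str | Path,
    dialect: str = "gff3",
    *,
    biotype_attribute: str = "biotype",
    biotype_map: Optional[dict[str, str]] = None,
    feature_types: Optional[set[str]] = None,
) -> list[Feature]:
    """Load features from GFF3 or BED6 into the internal convention.

    GFF3 start/end (1-based inclusive) become 0-based half-open; BED is
    taken as-is. The biotype is read from ``biotype_attribute`` in the
    GFF3 attribute column (falling back to the feature type column) and
    mapped through ``biotype_map``; unmapped values become ``other``. For
    BED the biotype is parsed from the name field as ``id|biotype`` when
    a pipe is present.
    """
    path = Path(path)
    mapping = dict(DEFAULT_BIOTYPE_MAP)
    if biotype_map:
        mapping.update({k.lower(): v for k, v in biotype_map.items()})
    features: list[Feature] = []
    seen: set[str] = set()

    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                if dialect == "gff3":
                    if len(fields) < 9:
                        raise ValueError(f"expected 9 GFF3 columns, got {len(fields)}")
                    ref, _source, ftype, start, end, _score, strand, _phase, attr_text = fields[:9]
                    if feature_types is not None and ftype not in feature_types:
                        continue
                    attrs = _parse_gff3_attributes(attr_text)
                    fid = attrs.get("ID") or attrs.get("Name")
                    if fid is None:
                        raise ValueError("no ID attribute")
                    raw_biotype = attrs.get(biotype_attribute, ftype)
                    feature = Feature(
                        feature_id=fid,
                        reference_name=ref,
                        start=int(start) - 1,
                        end=int(end),
                        strand=strand,
                        biotype=_normalise_biotype(raw_biotype, mapping),
                    )
                elif dialect == "bed":
                    if len(fields) < 6:
                        raise ValueError(f"expected 6 BED columns, got {len(fields)}")
                    ref, start, end, name, _score, strand = fields[:6]
                    fid, _, raw_biotype = name.partition("|")
                    feature = Feature(
                        feature_id=fid,
                        reference_name=ref,
                        start=int(start),
                        end=int(end),
                        strand=strand,
                        biotype=_normalise_biotype(raw_biotype or None, mapping),
                    )
                else:
                    raise ValueError(f"unknown dialect {dialect!r}")
            except ValueError as exc:
                raise AnnotationError(f"{path}:{lineno}: {exc}") from exc
            if feature.feature_id in seen:
                raise AnnotationError(f"{path}:{lineno}: duplicate feature_id {feature.feature_id!r}")
            seen.add(feature.feature_id)
            features.append(feature)
    return features


class FeatureIndex:
    """Per-reference interval tree plus sorted boundaries for nearest lookup."""

    def __init__(self, features: Iterable[Feature]):
        self._trees: dict[tuple[str, str], IntervalTree] = {}
        self._sorted: dict[tuple[str, str], list[tuple[int, int, Feature]]] = {}
        self._starts: dict[tuple[str, str], list[int]] = {}
        self._max_len: dict[tuple[str, str], int] = {}
        by_key: dict[tuple[str, str], list[Feature]] = {}
        self.references: set[str] = set()
        for f in features:
            self.references.add(f.reference_name)
            for strand_key in (f.strand, "*"):
                by_key.setdefault((f.reference_name, strand_key), []).append(f)
        for key, feats in by_key.items():
            tree = IntervalTree()
            for f in feats:
                tree[f.start : f.end] = f
            self._trees[key] = tree
            # sorted by start for bisect-based nearest-neighbour search
            self._sorted[key] = sorted(
                ((f.start, f.end, f) for f in feats), key=lambda t: (t[0], t[1], t[2].feature_id)
            )
            self._starts[key] = [e[0] for e in self._sorted[key]]
            self._max_len[key] = max(f.end - f.start for f in feats)

    def query(
        self, reference_name: str, junction: int, strand: str, same_strand: bool
    ) -> tuple[list[Feature], list[tuple[int, Feature]]]:
        """Return (overlapping features, candidate (distance, feature) pairs).

        ``junction`` is 1-based; a feature overlaps when junction-1 falls
        inside its half-open interval.
        """
        key = (reference_name, strand if same_strand else "*")
        tree = self._trees.get(key)
        if tree is None:
            return [], []
        point = junction - 1
        overlapping = [iv.data for iv in tree[point]]
        if overlapping:
            return overlapping, []
        entries = self._sorted[key]
        starts = self._starts[key]
        idx = bisect.bisect_left(starts, point)
        candidates: list[tuple[int, Feature]] = []
        # nearest features starting at/after the point (all sharing the
        # minimal start, so ties stay available for the caller's tie rule)
        if idx < len(entries):
            s0 = entries[idx][0]
            j = idx
            while j < len(entries) and entries[j][0] == s0:
                candidates.append((s0 - point, entries[j][2]))
                j += 1
        # features starting before the point: distance is to their end;
        # ends are not ordered, so walk left until starts alone rule the
        # rest out against the best distance found so far
        best = candidates[0][0] if candidates else None
        for s, e, f in reversed(entries[:idx]):
            d = point - e + 1  # e is half-open; last base is e-1
            if d < 0:
                d = 0
            candidates.append((d, f))
            if best is None or d < best:
                best = d
            if point - s > best + self._max_len[key]:
                break
        return [], candidates


def assign_closest(
    tail: TailCall,
    index: FeatureIndex,
    same_strand: bool = True,
    max_distance: Optional[int] = DEFAULT_MAX_DISTANCE,
) -> Optional[AssignedTail]:
    """Assign a tail to its overlapping or nearest feature.

    Overlap beats proximity. Ties on distance are broken by the
    lexicographically smallest feature id. Returns None when no feature
    lies within ``max_distance`` (None = unlimited) or the reference is
    absent from the annotation.
    """
    junction = tail.raw.junction
    overlapping, candidates = index.query(
        tail.raw.reference_name, junction, tail.raw.junction_strand, same_strand
    )
    if overlapping:
        chosen = min(overlapping, key=lambda f: f.feature_id)
    elif candidates:
        best_distance = min(d for d, _ in candidates)
        if max_distance is not None and best_distance > max_distance:
            return None
        chosen = min((f for d, f in candidates if d == best_distance), key=lambda f: f.feature_id)
    else:
        return None
    tes = tes_of(chosen)
    tes_distance = junction - tes if chosen.strand == "+" else tes - junction
    return AssignedTail(
        call=tail, feature_id=chosen.feature_id, biotype=chosen.biotype, tes_distance=tes_distance
    )


def assign_all(
    tails: Iterable[TailCall],
    features: Iterable[Feature],
    *,
    same_strand: bool = True,
    max_distance: Optional[int] = DEFAULT_MAX_DISTANCE,
    tally: Optional[dict[str, int]] = None,
) -> list[AssignedTail]:
    """Assign every tail; unassignable tails are dropped and tallied."""
    index = FeatureIndex(features)
    counts = {"assigned": 0, "unassigned": 0, "missing_reference": 0}
    out = []
    for tail in tails:
        if tail.raw.reference_name not in index.references:
            counts["missing_reference"] += 1
            continue
        assigned = assign_closest(tail, index, same_strand=same_strand, max_distance=max_distance)
        if assigned is None:
            counts["unassigned"] += 1
        else:
            counts["assigned"] += 1
            out.append(assigned)
    if tally is not None:
        tally.update(counts)
    return out


# ---------------------------------------------------------------------------
# assigned-tail table I/O

ASSIGNED_TSV_COLUMNS = TAIL_TSV_COLUMNS + ("feature_id", "biotype", "tes_distance")


def write_assigned_tsv(
    assigned: Iterable[AssignedTail], handle: TextIO, *, header_lines: Iterable[str] = ()
) -> None:
    """Write the tail-call table extended with assignment columns."""
    for line in header_lines:
        handle.write(f"# {line}\n")
    handle.write("\t".join(ASSIGNED_TSV_COLUMNS) + "\n")
    for a in assigned:
        c = a.call
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
                    a.feature_id,
                    a.biotype,
                    str(a.tes_distance),
                )
            )
            + "\n"
        )


def read_assigned_tsv(handle: TextIO) -> Iterator[AssignedTail]:
    """Read a table written by :func:`write_assigned_tsv`.

    ``#``-prefixed provenance lines are skipped; ``# total_aligned: N`` is
    recoverable via :func:`read_total_aligned`.
    """
    header_seen = False
    for line in handle:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if not header_seen:
            header_seen = True
            continue
        f = line.split("\t")
        raw = RawTail(
            read_id=f[0],
            tail_seq=f[4].replace("U", "T"),
            junction=int(f[2]),
            junction_strand=f[3],
            reference_name=f[1],
        )
        call = TailCall(
            raw=raw,
            category=TailCategory(f[5]),
            a_run=int(f[6]),
            u_run=int(f[7]),
            tail_len=int(f[8]),
        )
        yield AssignedTail(call=call, feature_id=f[9], biotype=f[10], tes_distance=int(f[11]))


def read_total_aligned(path: str | Path) -> Optional[int]:
    """Recover the ``total_aligned`` provenance header from a TSV, if any."""
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                return None
            if line.startswith("# total_aligned:"):
                return int(line.split(":", 1)[1].strip())
    return None
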