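"""Deterministic simulator for tailed-read RNA-seq alignment fixtures.

Generates a synthetic genome, a single-exon gene annotation, and SAM
alignments with authoritative CIGARs (no aligner involved), together with
a ground-truth table of every simulated tail. The default parameters
emulate a wild-type ligation-based library: about 1.5% of reads carry an
A/U extension, poly(A) and poly(A)U dominate the tailed set (93% combined,
with 11% of poly(A)-bearing tails uridylated), uridine runs are mostly 1–2
nt, poly(A)/poly(A)U junctions sit at the annotated TES with small jitter,
and oligo(U)/mixed tails scatter over gene bodies.

All randomness flows from a single seed; the same spec reproduces the SAM
byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from utail.feature_assign import Feature, tes_of
from utail.tail_core import TailCall, TailCategory, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass
class SimSpec:
    """Parameters of one simulated library.

    ``category_mixture`` gives the probabilities of the four tail classes
    among tailed reads; ``u_run_probs`` the distribution of terminal
    uridine-run lengths for poly(A)U tails; ``a_run_mean`` the mean of the
    geometric adenosine-run length. ``tes_jitter_sd`` (nt) spreads
    poly(A)/poly(A)U junctions around the TES, while oligo(U) and mixed
    tails land uniformly in gene bodies. ``antisense_fraction`` flips that
    share of tailed reads onto the strand opposite their gene.
    """

    seed: int = 1
    n_genes: int = 60
    gene_length_range: tuple[int, int] = (300, 900)
    genome_padding: int = 200
    n_fragments: int = 20_000
    expression_sigma: float = 1.0
    tailed_read_probability: float = 0.015
    category_mixture: dict[str, float] = field(
        default_factory=lambda: {
            "POLYA": 0.828,
            "POLYAU": 0.102,
            "OLIGOU": 0.040,
            "MIXED": 0.030,
        }
    )
    a_run_mean: float = 8.0
    u_run_probs: dict[int, float] = field(default_factory=lambda: {1: 0.6, 2: 0.3, 3: 0.1})
    tes_jitter_sd: float = 20.0
    antisense_fraction: float = 0.0
    sequencing_error_rate: float = 0.0
    read_length: int = 60
    mrna_fraction: float = 0.9
    reference_name: str = "chrSim"

    def validate(self) -> None:
        mix = sum(self.category_mixture.values())
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"category mixture sums to {mix}, expected 1")
        for name, p in [
            ("tailed_read_probability", self.tailed_read_probability),
            ("antisense_fraction", self.antisense_fraction),
            ("sequencing_error_rate", self.sequencing_error_rate),
            ("mrna_fraction", self.mrna_fraction),
        ]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if abs(sum(self.u_run_probs.values()) - 1.0) > 1e-9:
            raise ValueError("u_run_probs must sum to 1")
        if self.gene_length_range[0] < self.read_length:
            raise ValueError("genes must be at least one read long")


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated tailed read."""

    read_id: str
    category: str
    a_run: int
    u_run: int
    gene: str
    junction: int
    strand: str


@dataclass
class SimResult:
    """Everything one simulation run produced."""

    sam_text: str
    truth: list[TruthRecord]
    gene_read_counts: dict[str, int]
    n_records: int


def make_genome_and_annotation(spec: SimSpec) -> tuple[str, list[Feature]]:
    """Build a random genome and non-overlapping single-exon genes.

    Genes alternate between strands at random, separated by
    ``genome_padding`` nt of intergenic sequence. The ten genomic bases
    immediately downstream of every TES (in the gene's orientation) are
    forced to C/G so that a soft-clip boundary at the TES is unambiguous
    for any aligner run on the fixture.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.gene_length_range
    lengths = rng.integers(lo, hi + 1, size=spec.n_genes)
    strands = np.where(rng.random(spec.n_genes) < 0.5, "+", "-")
    is_mrna = rng.random(spec.n_genes) < spec.mrna_fraction

    features: list[Feature] = []
    cursor = spec.genome_padding
    for i in range(spec.n_genes):
        start, end = cursor, cursor + int(lengths[i])
        features.append(
            Feature(
                feature_id=f"gene{i + 1:04d}",
                reference_name=spec.reference_name,
                start=start,
                end=end,
                strand=str(strands[i]),
                biotype="mRNA" if is_mrna[i] else "ncRNA_intergenic",
            )
        )
        cursor = end + spec.genome_padding
    genome_len = cursor

    genome = rng.integers(0, 4, size=genome_len)
    seq = _BASES[genome]
    # non-A/T decamer downstream of each TES (C or G only)
    for f in features:
        if f.strand == "+":
            window = slice(f.end, f.end + 10)
        else:
            window = slice(max(f.start - 10, 0), f.start)
        n = window.stop - window.start
        seq[window] = np.where(rng.random(n) < 0.5, "C", "G")
    return "".join(seq), features


def _sample_u_run(rng: np.random.Generator, probs: Mapping[int, float]) -> int:
    ks = sorted(probs)
    return int(rng.choice(ks, p=[probs[k] for k in ks]))


def _sample_tail(spec: SimSpec, rng: np.random.Generator, category: str) -> tuple[str, int, int]:
    """Return (tail DNA string, a_run, u_run); length always >= 4."""
    max_tail = spec.read_length - 25  # keep a solid aligned anchor
    if category == "POLYA":
        a = min(max(4, int(rng.geometric(1.0 / spec.a_run_mean))), max_tail)
        return "A" * a, a, 0
    if category == "POLYAU":
        u = _sample_u_run(rng, spec.u_run_probs)
        a = min(max(3, int(rng.geometric(1.0 / spec.a_run_mean))), max_tail - u)
        return "A" * a + "T" * u, a, u
    if category == "OLIGOU":
        u = min(max(4, int(rng.geometric(0.4)) + 2), max_tail)
        return "T" * u, 0, u
    # MIXED: an A/U-only string rejected by the three pure grammars
    while True:
        length = min(max(4, int(rng.geometric(0.25)) + 2), max_tail)
        tail = "".join(rng.choice(["A", "T"], size=length))
        stripped_a = tail.lstrip("A")
        if stripped_a and stripped_a.strip("T") and set(tail) == {"A", "T"}:
            a = length - len(stripped_a)
            u = length - len(tail.rstrip("T"))
            return tail, a, u


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0.0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[int(rng.integers(0, 3))]
    return "".join(arr)


def draw_expression_rates(spec: SimSpec, n_genes: Optional[int] = None) -> np.ndarray:
    """Log-normal per-gene expression rates, seeded by the spec.

    Replicates of the same strain share a transcriptome: draw rates once
    and pass them to several :func:`simulate_reads` calls with different
    read seeds.
    """
    rng = np.random.default_rng(spec.seed + 2)
    return rng.lognormal(mean=0.0, sigma=spec.expression_sigma, size=n_genes or spec.n_genes)


def simulate_reads(
    spec: SimSpec,
    genome: str,
    features: Sequence[Feature],
    expression_rates: Optional[np.ndarray] = None,
) -> SimResult:
    """Simulate single-end primary alignments with known tails.

    Untailed reads are fully matched (``xM``); tailed reads carry the tail
    in a terminal soft clip (``xM yS`` for plus-strand records, ``yS xM``
    with the stored sequence reverse-complemented for minus strand, per
    SAM convention). One truth row is written per tailed read.
    ``expression_rates`` (one positive rate per feature) lets replicates
    share per-gene expression; omitted, rates are drawn from the spec seed.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed + 1)
    genome_len = len(genome)
    if expression_rates is None:
        rates = rng.lognormal(mean=0.0, sigma=spec.expression_sigma, size=len(features))
    else:
        rates = np.asarray(expression_rates, dtype=float)
        if rates.size != len(features) or np.any(rates <= 0):
            raise ValueError("expression_rates must hold one positive rate per feature")
    probs = rates / rates.sum()
    gene_idx = rng.choice(len(features), size=spec.n_fragments, p=probs)

    lines = [
        "@HD\tVN:1.6\tSO:coordinate",
        f"@SQ\tSN:{spec.reference_name}\tLN:{genome_len}",
        "@PG\tID:utail-sim\tPN:utail-sim",
    ]
    records: list[tuple[int, str]] = []  # (pos, sam line) for coordinate sort
    truth: list[TruthRecord] = []
    gene_read_counts: dict[str, int] = {f.feature_id: 0 for f in features}

    for i in range(spec.n_fragments):
        gene = features[int(gene_idx[i])]
        gene_read_counts[gene.feature_id] += 1
        read_id = f"sim{i + 1:07d}"
        tailed = rng.random() < spec.tailed_read_probability
        read_strand = gene.strand
        if tailed and spec.antisense_fraction > 0 and rng.random() < spec.antisense_fraction:
            read_strand = "-" if gene.strand == "+" else "+"

        if not tailed:
            start0 = int(rng.integers(gene.start, gene.end - spec.read_length + 1))
            # SAM stores sequence in reference orientation regardless of strand
            seq = genome[start0 : start0 + spec.read_length]
            flag = 0 if read_strand == "+" else 16
            seq = _apply_errors(seq, spec.sequencing_error_rate, rng)
            records.append(
                (
                    start0 + 1,
                    _sam_line(read_id, flag, spec.reference_name, start0 + 1,
                              f"{spec.read_length}M", seq),
                )
            )
            continue

        cats = sorted(spec.category_mixture)
        category = str(rng.choice(cats, p=[spec.category_mixture[c] for c in cats]))
        tail, a_run, u_run = _sample_tail(spec, rng, category)
        anchor = spec.read_length - len(tail)

        if category in ("POLYA", "POLYAU"):
            tes = tes_of(gene) if read_strand == gene.strand else (
                gene.end if read_strand == "+" else gene.start + 1
            )
            jitter = int(round(rng.normal(0.0, spec.tes_jitter_sd)))
            junction = tes + (jitter if read_strand == "+" else -jitter)
        else:
            junction = int(rng.integers(gene.start + 1, gene.end + 1))
        junction = max(anchor, min(junction, genome_len - anchor + 1))

        if read_strand == "+":
            pos = junction - anchor + 1
            seq = genome[pos - 1 : junction] + tail
            cigar = f"{anchor}M{len(tail)}S"
            flag = 0
        else:
            pos = junction
            seq = reverse_complement(tail) + genome[junction - 1 : junction + anchor - 1]
            cigar = f"{len(tail)}S{anchor}M"
            flag = 16
        seq = _apply_errors(seq, spec.sequencing_error_rate, rng)
        records.append((pos, _sam_line(read_id, flag, spec.reference_name, pos, cigar, seq)))
        truth.append(
            TruthRecord(
                read_id=read_id,
                category=category,
                a_run=a_run,
                u_run=u_run,
                gene=gene.feature_id,
                junction=junction,
                strand=read_strand,
            )
        )

    records.sort(key=lambda t: t[0])
    lines.extend(line for _, line in records)
    return SimResult(
        sam_text="\n".join(lines) + "\n",
        truth=truth,
        gene_read_counts=gene_read_counts,
        n_records=spec.n_fragments,
    )


def _sam_line(qname: str, flag: int, rname: str, pos: int, cigar: str, seq: str) -> str:
    qual = "I" * len(seq)
    return "\t".join((qname, str(flag), rname, str(pos), "60", cigar, "*", "0", "0", seq, qual))


# ---------------------------------------------------------------------------
# evaluation against truth

def evaluate_calls(
    calls: Iterable[TailCall], truth: Sequence[TruthRecord]
) -> dict:
    """Per-category precision/recall and a truth × called confusion matrix.

    A call is a true positive for its category when a truth row with the
    same read id carries the same category. Truth rows without any call
    are counted in the ``MISSED`` column; calls whose read id is absent
    from the truth (spurious) in the ``SPURIOUS`` truth row.
    """
    truth_by_id = {t.read_id: t for t in truth}
    if len(truth_by_id) != len(truth):
        raise ValueError("duplicate read_ids in truth")
    calls = list(calls)
    seen: set[str] = set()
    for c in calls:
        if c.raw.read_id in seen:
            raise ValueError(f"duplicate read_id in calls: {c.raw.read_id}")
        seen.add(c.raw.read_id)

    categories = [c.value for c in TailCategory]
    confusion = pd.DataFrame(
        0, index=categories + ["SPURIOUS"], columns=categories + ["MISSED"], dtype=int
    )
    for c in calls:
        t = truth_by_id.get(c.raw.read_id)
        row = t.category if t is not None else "SPURIOUS"
        confusion.loc[row, c.category.value] += 1
    for t in truth:
        if t.read_id not in seen:
            confusion.loc[t.category, "MISSED"] += 1

    precision: dict[str, Optional[float]] = {}
    recall: dict[str, Optional[float]] = {}
    for cat in categories:
        called = int(confusion[cat].sum())
        true_n = int(confusion.loc[cat].sum())
        tp = int(confusion.loc[cat, cat])
        precision[cat] = tp / called if called else None
        recall[cat] = tp / true_n if true_n else None
    return {"precision": precision, "recall": recall, "confusion": confusion}


# ---------------------------------------------------------------------------
# fixture bundle writers

def write_fasta(genome: str, spec: SimSpec, path: Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        fh.write(f">{spec.reference_name}\n")
        for i in range(0, len(genome), width):
            fh.write(genome[i : i + width] + "\n")


def write_gff3(features: Sequence[Feature], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            fh.write(
                "\t".join(
                    (
                        f.reference_name,
                        "utail-sim",
                        "gene",
                        str(f.start + 1),
                        str(f.end),
                        ".",
                        f.strand,
                        ".",
                        f"ID={f.feature_id};biotype={f.biotype}",
                    )
                )
                + "\n"
            )


def write_bed(features: Sequence[Feature], path: Path) -> None:
    with open(path, "w") as fh:
        for f in features:
            fh.write(
                "\t".join(
                    (
                        f.reference_name,
                        str(f.start),
                        str(f.end),
                        f"{f.feature_id}|{f.biotype}",
                        "0",
                        f.strand,
                    )
                )
                + "\n"
            )


def write_truth_tsv(truth: Sequence[TruthRecord], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\tcategory\ta_run\tu_run\tgene\tjunction\tstrand\n")
        for t in truth:
            fh.write(
                f"{t.read_id}\t{t.category}\t{t.a_run}\t{t.u_run}\t"
                f"{t.gene}\t{t.junction}\t{t.strand}\n"
            )


def read_truth_tsv(path: Path) -> list[TruthRecord]:
    frame = pd.read_csv(path, sep="\t")
    return [
        TruthRecord(
            read_id=row.read_id,
            category=row.category,
            a_run=int(row.a_run),
            u_run=int(row.u_run),
            gene=row.gene,
            junction=int(row.junction),
            strand=row.strand,
        )
        for row in frame.itertuples()
    ]


def write_expression_tsv(gene_read_counts: Mapping[str, int], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tcount\n")
        for gene in sorted(gene_read_counts):
            fh.write(f"{gene}\t{gene_read_counts[gene]}\n")


def write_bundle(spec: SimSpec, outdir: str | Path) -> SimResult:
    """Run the full simulation and write every fixture file to ``outdir``.

    Writes genome.fa, genes.gff3, genes.bed, reads.sam, truth.tsv and
    expression.tsv; returns the in-memory result as well.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome, features = make_genome_and_annotation(spec)
    result = simulate_reads(spec, genome, features)
    write_fasta(genome, spec, outdir / "genome.fa")
    write_gff3(features, outdir / "genes.gff3")
    write_bed(features, outdir / "genes.bed")
    (outdir / "reads.sam").write_text(result.sam_text)
    write_truth_tsv(result.truth, outdir / "truth.tsv")
    write_expression_tsv(result.gene_read_counts, outdir / "expression.tsv")
    return result
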