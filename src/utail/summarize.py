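"""Per-sample and per-gene summary statistics over assigned tails.

Covers the quantities a uridylation survey reports: category counts and
fractions of total aligned reads, biotype breakdown, TES-distance
cumulative curves, uridine-run histograms, per-gene poly(A)/poly(A)U count
tables with a detection threshold, expression correlations, and relative
uridylation loss between strains (e.g. wild type versus a
uridyltransferase deletion).

Every fraction is reported together with its numerator and denominator so
results remain auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from utail.feature_assign import AssignedTail
from utail.tail_core import TailCategory

CATEGORIES = (
    TailCategory.POLYA,
    TailCategory.POLYAU,
    TailCategory.OLIGOU,
    TailCategory.MIXED,
)

DEFAULT_MIN_TOTAL = 5
DEFAULT_CDF_WINDOW = 1000


@dataclass
class SampleSummary:
    """Category and biotype counts for one sample."""

    sample_id: str
    total_aligned: int
    category_counts: dict[TailCategory, int]
    biotype_counts: dict[str, int] = field(default_factory=dict)
    uridylation_frequency: Optional[float] = None

    @property
    def accepted_tails(self) -> int:
        return sum(self.category_counts.values())

    @property
    def tailed_fraction(self) -> float:
        return self.accepted_tails / self.total_aligned

    def category_fraction(self, category: TailCategory) -> float:
        """Share of this category among tailed reads (0 when no tails)."""
        total = self.accepted_tails
        if total == 0:
            return 0.0
        return self.category_counts.get(category, 0) / total


@dataclass
class GeneTailTable:
    """Per-gene poly(A)/poly(A)U counts per replicate plus expression.

    ``counts`` is indexed by gene, with one (replicate, category) column
    per replicate and category; ``expression`` maps gene to its total read
    count (all reads overlapping the gene, tailed or not).
    """

    counts: pd.DataFrame
    expression: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    def polya_polyau_total(self) -> pd.Series:
        """Summed poly(A)+poly(A)U count per gene over all replicates."""
        cols = [
            c
            for c in self.counts.columns
            if c[1] in (TailCategory.POLYA.value, TailCategory.POLYAU.value)
        ]
        return self.counts[cols].sum(axis=1)

    def tailed_total(self) -> pd.Series:
        return self.counts.sum(axis=1)

    def both_categories_observed(self) -> pd.Series:
        """Per gene, whether both poly(A) and poly(A)U reads were seen."""
        a_cols = [c for c in self.counts.columns if c[1] == TailCategory.POLYA.value]
        u_cols = [c for c in self.counts.columns if c[1] == TailCategory.POLYAU.value]
        return (self.counts[a_cols].sum(axis=1) > 0) & (self.counts[u_cols].sum(axis=1) > 0)


@dataclass
class StrainComparison:
    """Relative uridylation loss per strain against a baseline."""

    baseline: str
    baseline_frequency: float
    strain_frequencies: dict[str, float]
    loss_percent: dict[str, float]


def category_fractions(
    tails: Sequence[AssignedTail],
    total_aligned: int,
    *,
    sample_id: str = "sample",
) -> SampleSummary:
    """Count tails per category and per biotype for one sample.

    ``total_aligned`` is the number of primary mapped reads in the sample
    and anchors the tailed fraction; the tails are assumed already
    length-filtered.
    """
    if total_aligned <= 0:
        raise ValueError("total_aligned must be a positive count")
    category_counts = {cat: 0 for cat in CATEGORIES}
    biotype_counts: dict[str, int] = {}
    for t in tails:
        category_counts[t.call.category] += 1
        biotype_counts[t.biotype] = biotype_counts.get(t.biotype, 0) + 1
    summary = SampleSummary(
        sample_id=sample_id,
        total_aligned=total_aligned,
        category_counts=category_counts,
        biotype_counts=biotype_counts,
    )
    freq = uridylation_frequency(tails)
    summary.uridylation_frequency = freq
    return summary


def uridylation_frequency(
    tails: Iterable[AssignedTail],
    biotype_filter: Optional[str] = "mRNA",
    *,
    denominator: str = "polyA+polyAU",
) -> Optional[float]:
    """Uridylated share of poly(A)-bearing tails, by default on mRNA only.

    With ``denominator='polyA+polyAU'`` (default) the frequency is
    poly(A)U / (poly(A) + poly(A)U); with ``'all-tailed'`` the denominator
    includes oligo(U) and mixed tails as well. Returns None (undefined,
    never 0) when the denominator is empty.
    """
    if denominator not in ("polyA+polyAU", "all-tailed"):
        raise ValueError(f"unknown denominator choice {denominator!r}")
    n_polyau = 0
    n_denom = 0
    for t in tails:
        if biotype_filter is not None and t.biotype != biotype_filter:
            continue
        if t.call.category == TailCategory.POLYAU:
            n_polyau += 1
            n_denom += 1
        elif t.call.category == TailCategory.POLYA:
            n_denom += 1
        elif denominator == "all-tailed":
            n_denom += 1
    if n_denom == 0:
        return None
    return n_polyau / n_denom


def strain_loss(
    summaries: Sequence[SampleSummary],
    baseline: str,
    *,
    strain_of: Optional[Mapping[str, str]] = None,
) -> StrainComparison:
    """Percent loss of uridylation per strain relative to a baseline.

    ``strain_of`` maps sample_id to strain name so biological replicates
    can be averaged before the ratio (identity when omitted). Loss is
    ``100 * (1 - freq_strain / freq_baseline)``: 0 for the baseline
    itself, 100 when uridylation vanishes.
    """
    groups: dict[str, list[float]] = {}
    for s in summaries:
        if s.uridylation_frequency is None:
            continue
        strain = strain_of.get(s.sample_id, s.sample_id) if strain_of else s.sample_id
        groups.setdefault(strain, []).append(s.uridylation_frequency)
    if baseline not in groups:
        raise ValueError(f"baseline {baseline!r} has no defined uridylation frequency")
    freqs = {strain: float(np.mean(vals)) for strain, vals in groups.items()}
    base = freqs[baseline]
    if base == 0:
        raise ValueError("baseline uridylation frequency is zero; loss undefined")
    loss = {strain: 100.0 * (1.0 - f / base) for strain, f in freqs.items()}
    return StrainComparison(
        baseline=baseline,
        baseline_frequency=base,
        strain_frequencies=freqs,
        loss_percent=loss,
    )


def tes_distance_cdf(
    tails: Sequence[AssignedTail],
    category: TailCategory,
    window: int = DEFAULT_CDF_WINDOW,
    *,
    signed: bool = False,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Cumulative frequency of TES distances for one tail category.

    Returns ``(distances, cumulative_fraction, n_outside)`` where the
    curve is evaluated at the sorted distinct distances within the window
    and reaches 1 at the window edge for the in-window tails. Distances
    are absolute by default; ``signed=True`` keeps the sign (negative =
    upstream of the TES).
    """
    values = [
        t.tes_distance if signed else abs(t.tes_distance)
        for t in tails
        if t.call.category == category
    ]
    if not values:
        return np.array([]), np.array([]), 0
    arr = np.asarray(values)
    lo = -window if signed else 0
    inside = arr[(arr >= lo) & (arr <= window)]
    n_outside = int(arr.size - inside.size)
    if inside.size == 0:
        return np.array([]), np.array([]), n_outside
    xs, counts = np.unique(inside, return_counts=True)
    cdf = np.cumsum(counts) / inside.size
    return xs, cdf, n_outside


def u_run_histogram(tails: Iterable[AssignedTail]) -> dict[int, int]:
    """Histogram of terminal uridine-run lengths over poly(A)U tails."""
    hist: dict[int, int] = {}
    for t in tails:
        if t.call.category != TailCategory.POLYAU:
            continue
        hist[t.call.u_run] = hist.get(t.call.u_run, 0) + 1
    return dict(sorted(hist.items()))


def per_gene_table(
    tails_per_replicate: Mapping[str, Sequence[AssignedTail]],
    expression: Mapping[str, int],
    min_total: int = DEFAULT_MIN_TOTAL,
) -> GeneTailTable:
    """Per-gene poly(A)/poly(A)U counts, thresholded on summed detections.

    A gene is retained when its poly(A)+poly(A)U count summed over all
    replicates is at least ``min_total`` (default 5, the detection
    threshold for calling a transcript uridylation-informative).
    """
    if not tails_per_replicate:
        raise ValueError("at least one replicate required")
    rows: dict[str, dict[tuple[str, str], int]] = {}
    for rep_id, tails in tails_per_replicate.items():
        for t in tails:
            if t.call.category not in (TailCategory.POLYA, TailCategory.POLYAU):
                continue
            key = (rep_id, t.call.category.value)
            cells = rows.setdefault(t.feature_id, {})
            cells[key] = cells.get(key, 0) + 1
    columns = pd.MultiIndex.from_product(
        [sorted(tails_per_replicate), [TailCategory.POLYA.value, TailCategory.POLYAU.value]],
        names=["replicate", "category"],
    )
    counts = pd.DataFrame(0, index=sorted(rows), columns=columns, dtype=int)
    for gene, cells in rows.items():
        for key, n in cells.items():
            counts.loc[gene, key] = n
    keep = counts.sum(axis=1) >= min_total
    counts = counts.loc[keep]
    expr = pd.Series(
        [int(expression.get(g, 0)) for g in counts.index],
        index=counts.index,
        dtype=int,
        name="expression",
    )
    return GeneTailTable(counts=counts, expression=expr)


def expression_correlation(table: GeneTailTable) -> float:
    """Pearson r between log10(expression+1) and log10(tailed count+1).

    The log transform tames count data spanning orders of magnitude.
    Raises when fewer than 3 genes or either side has zero variance.
    """
    if len(table.genes) < 3:
        raise ValueError("need at least 3 genes for a correlation")
    x = np.log10(table.expression.to_numpy(dtype=float) + 1.0)
    y = np.log10(table.polya_polyau_total().to_numpy(dtype=float) + 1.0)
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance; correlation undefined")
    r, _p = stats.pearsonr(x, y)
    return float(r)


def correlation_matrix(
    tables: Mapping[str, GeneTailTable],
    read_classes: Sequence[str] = ("all", "POLYA", "POLYAU"),
) -> pd.DataFrame:
    """Pearson correlations between samples and read classes.

    Gene sets are intersected across samples first; each (sample, class)
    column is the per-gene log10(count+1) vector, with class ``all``
    meaning the gene's total expression count. The result is symmetric
    with a unit diagonal.
    """
    common: Optional[set[str]] = None
    for table in tables.values():
        genes = set(table.genes)
        common = genes if common is None else common & genes
    if common is None or len(common) < 3:
        raise ValueError("fewer than 3 genes shared across samples")
    genes_sorted = sorted(common)
    vectors: dict[str, np.ndarray] = {}
    for sample_id, table in tables.items():
        sub = table.counts.loc[genes_sorted]
        for cls in read_classes:
            if cls == "all":
                v = table.expression.loc[genes_sorted].to_numpy(dtype=float)
            else:
                cols = [c for c in sub.columns if c[1] == cls]
                v = sub[cols].sum(axis=1).to_numpy(dtype=float)
            vectors[f"{sample_id}:{cls}"] = np.log10(v + 1.0)
    frame = pd.DataFrame(vectors, index=genes_sorted)
    return frame.corr(method="pearson")


def biotype_breakdown(
    tails: Sequence[AssignedTail],
) -> dict[str, dict[str, float]]:
    """Counts and fractions of assigned tails per biotype.

    Fractions are over assigned tails only; unassigned tails never reach
    this function and are reported separately by the caller's tally.
    """
    counts: dict[str, int] = {}
    for t in tails:
        counts[t.biotype] = counts.get(t.biotype, 0) + 1
    total = sum(counts.values())
    return {
        bt: {"count": n, "fraction": (n / total if total else 0.0)}
        for bt, n in sorted(counts.items(), key=lambda kv: -kv[1])
    }


def summary_as_dict(summary: SampleSummary) -> dict:
    """JSON-ready dump of a sample summary with audit numerators."""
    accepted = summary.accepted_tails
    return {
        "sample_id": summary.sample_id,
        "total_aligned": summary.total_aligned,
        "accepted_tails": accepted,
        "tailed_fraction": {
            "value": summary.tailed_fraction,
            "numerator": accepted,
            "denominator": summary.total_aligned,
        },
        "categories": {
            cat.value: {
                "count": summary.category_counts.get(cat, 0),
                "fraction_of_tailed": summary.category_fraction(cat),
            }
            for cat in CATEGORIES
        },
        "biotypes": summary.biotype_counts,
        "uridylation_frequency": summary.uridylation_frequency,
    }
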