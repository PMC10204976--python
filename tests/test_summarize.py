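"""Sample summaries, per-gene tables, CDFs, correlations and strain loss."""

import numpy as np
import pytest

from utail.summarize import (
    GeneTailTable,
    SampleSummary,
    biotype_breakdown,
    category_fractions,
    correlation_matrix,
    expression_correlation,
    per_gene_table,
    strain_loss,
    tes_distance_cdf,
    u_run_histogram,
    uridylation_frequency,
)
from utail.tail_core import TailCategory

from conftest import make_assigned


class TestCategoryFractions:
    def test_counts_and_tailed_fraction(self):
        tails = [
            make_assigned("AAAA"),
            make_assigned("AAAAA"),
            make_assigned("AAATT"),
            make_assigned("TTTT"),
        ]
        s = category_fractions(tails, total_aligned=400)
        assert s.category_counts[TailCategory.POLYA] == 2
        assert s.tailed_fraction == pytest.approx(0.01)
        polya_au = s.category_fraction(TailCategory.POLYA) + s.category_fraction(TailCategory.POLYAU)
        assert polya_au == pytest.approx(0.75)

    def test_empty_tail_set_gives_zero_fractions(self):
        s = category_fractions([], total_aligned=100)
        assert s.accepted_tails == 0
        assert s.tailed_fraction == 0.0
        assert all(s.category_fraction(c) == 0.0 for c in TailCategory)

    def test_zero_total_aligned_is_a_contract_error(self):
        with pytest.raises(ValueError):
            category_fractions([], total_aligned=0)

    def test_binomial_recovery_of_simulated_mixture(self):
        """Sampled category fractions land within 3 binomial SDs."""
        mixture = {"POLYA": 0.80, "POLYAU": 0.13, "OLIGOU": 0.04, "MIXED": 0.03}
        tail_for = {"POLYA": "AAAA", "POLYAU": "AAATT", "OLIGOU": "TTTT", "MIXED": "ATAT"}
        rng = np.random.default_rng(12)
        n = 50_000
        draws = rng.choice(sorted(mixture), size=n, p=[mixture[k] for k in sorted(mixture)])
        tails = [make_assigned(tail_for[d], read_id=f"r{i}") for i, d in enumerate(draws)]
        s = category_fractions(tails, total_aligned=n * 10)
        for name, p in mixture.items():
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(s.category_fraction(TailCategory(name)) - p) < 3 * sd


class TestUridylationFrequency:
    def test_simple_ratio(self):
        tails = [make_assigned("AAAA", read_id=f"a{i}") for i in range(90)]
        tails += [make_assigned("AAATT", read_id=f"u{i}") for i in range(10)]
        assert uridylation_frequency(tails) == pytest.approx(0.10)

    def test_zero_polyau_gives_zero(self):
        tails = [make_assigned("AAAA")]
        assert uridylation_frequency(tails) == 0.0

    def test_empty_denominator_is_missing_not_zero(self):
        assert uridylation_frequency([]) is None
        assert uridylation_frequency([make_assigned("TTTT")]) is None

    def test_biotype_filter_restricts_to_mrna(self):
        tails = [
            make_assigned("AAATT", biotype="mRNA"),
            make_assigned("AAAA", biotype="mRNA", read_id="r2"),
            make_assigned("AAATT", biotype="ncRNA_intergenic", read_id="r3"),
        ]
        assert uridylation_frequency(tails) == pytest.approx(0.5)
        assert uridylation_frequency(tails, biotype_filter=None) == pytest.approx(2 / 3)

    def test_all_tailed_denominator(self):
        tails = [
            make_assigned("AAATT"),
            make_assigned("AAAA", read_id="r2"),
            make_assigned("TTTT", read_id="r3"),
            make_assigned("ATAT", read_id="r4"),
        ]
        assert uridylation_frequency(tails, denominator="all-tailed") == pytest.approx(0.25)

    def test_binomial_recovery_at_realistic_rate(self):
        """p=0.11 at n=20,000 tails is recovered within 3 binomial SDs."""
        rng = np.random.default_rng(11)
        n = 20_000
        is_u = rng.random(n) < 0.11
        tails = [
            make_assigned("AAATT" if u else "AAAA", read_id=f"r{i}") for i, u in enumerate(is_u)
        ]
        freq = uridylation_frequency(tails)
        assert abs(freq - 0.11) < 3 * np.sqrt(0.11 * 0.89 / n)


def _summary(sample_id, freq):
    s = SampleSummary(sample_id=sample_id, total_aligned=1, category_counts={})
    s.uridylation_frequency = freq
    return s


class TestStrainLoss:
    def test_printed_frequencies_reproduce_the_ratio(self):
        """0.11 baseline vs 0.053 mutant is a 51.8% loss."""
        cmp = strain_loss([_summary("WT", 0.11), _summary("cid1", 0.053)], baseline="WT")
        assert cmp.loss_percent["cid1"] == pytest.approx(51.8, abs=0.05)
        assert cmp.loss_percent["WT"] == 0.0

    def test_equal_strain_has_zero_loss_and_zero_freq_full_loss(self):
        cmp = strain_loss([_summary("WT", 0.1), _summary("m1", 0.1), _summary("m2", 0.0)], "WT")
        assert cmp.loss_percent["m1"] == pytest.approx(0.0)
        assert cmp.loss_percent["m2"] == pytest.approx(100.0)

    def test_replicates_average_before_ratio(self):
        summaries = [
            _summary("WT_r1", 0.10),
            _summary("WT_r2", 0.12),
            _summary("mut_r1", 0.055),
        ]
        strain_of = {"WT_r1": "WT", "WT_r2": "WT", "mut_r1": "mut"}
        cmp = strain_loss(summaries, "WT", strain_of=strain_of)
        assert cmp.baseline_frequency == pytest.approx(0.11)
        assert cmp.loss_percent["mut"] == pytest.approx(50.0)

    def test_zero_baseline_is_a_contract_error(self):
        with pytest.raises(ValueError):
            strain_loss([_summary("WT", 0.0)], "WT")


class TestTesDistanceCdf:
    def test_all_at_tes_is_a_unit_step(self):
        tails = [make_assigned("AAAA", tes_distance=0, read_id=f"r{i}") for i in range(5)]
        xs, cdf, outside = tes_distance_cdf(tails, TailCategory.POLYA)
        assert list(xs) == [0] and list(cdf) == [1.0] and outside == 0

    def test_known_distances(self):
        tails = [
            make_assigned("AAAA", tes_distance=0, read_id="a"),
            make_assigned("AAAA", tes_distance=-10, read_id="b"),
            make_assigned("AAAA", tes_distance=100, read_id="c"),
        ]
        xs, cdf, _ = tes_distance_cdf(tails, TailCategory.POLYA)
        assert list(xs) == [0, 10, 100]
        assert list(cdf) == pytest.approx([1 / 3, 2 / 3, 1.0])

    def test_monotone_and_bounded(self):
        rng = np.random.default_rng(3)
        tails = [
            make_assigned("AAAA", tes_distance=int(d), read_id=f"r{i}")
            for i, d in enumerate(rng.integers(-2000, 2000, size=500))
        ]
        xs, cdf, outside = tes_distance_cdf(tails, TailCategory.POLYA, window=1000)
        assert np.all(np.diff(cdf) >= 0)
        assert cdf[-1] == pytest.approx(1.0)
        assert outside == sum(1 for t in tails if abs(t.tes_distance) > 1000)

    def test_empty_category_is_flagged(self):
        xs, cdf, outside = tes_distance_cdf([], TailCategory.OLIGOU)
        assert xs.size == 0 and cdf.size == 0


class TestURunHistogram:
    def test_counts(self):
        tails = [
            make_assigned("AAAT", read_id="a"),
            make_assigned("AATT", read_id="b"),
            make_assigned("AAAT", read_id="c"),
            make_assigned("AAAA", read_id="d"),  # not POLYAU, ignored
        ]
        assert u_run_histogram(tails) == {1: 2, 2: 1}

    def test_empty(self):
        assert u_run_histogram([]) == {}

    def test_multinomial_recovery(self):
        probs = {1: 0.6, 2: 0.3, 3: 0.1}
        rng = np.random.default_rng(9)
        n = 10_000
        runs = rng.choice([1, 2, 3], size=n, p=[0.6, 0.3, 0.1])
        tails = [make_assigned("AAA" + "T" * int(u), read_id=f"r{i}") for i, u in enumerate(runs)]
        hist = u_run_histogram(tails)
        assert sum(hist.values()) == n
        for u, p in probs.items():
            sd = np.sqrt(p * (1 - p) / n)
            assert abs(hist[u] / n - p) < 3 * sd


class TestPerGeneTable:
    def _tails(self):
        reps = {
            "rep1": [make_assigned("AAAA", feature_id="g1", read_id=f"r{i}") for i in range(2)],
            "rep2": (
                [make_assigned("AAAA", feature_id="g1", read_id=f"s{i}") for i in range(2)]
                + [make_assigned("AAATT", feature_id="g1", read_id="s9")]
                + [make_assigned("AAAA", feature_id="g2", read_id=f"t{i}") for i in range(4)]
            ),
        }
        return reps

    def test_threshold_boundary(self):
        table = per_gene_table(self._tails(), expression={"g1": 100, "g2": 50}, min_total=5)
        # g1 sums to 5 across replicates -> retained; g2 sums to 4 -> dropped
        assert table.genes == ["g1"]
        assert table.expression["g1"] == 100
        assert bool(table.both_categories_observed()["g1"]) is True

    def test_filter_commutes_with_manual_filtering(self):
        full = per_gene_table(self._tails(), expression={}, min_total=0)
        for k in range(0, 7):
            direct = per_gene_table(self._tails(), expression={}, min_total=k)
            manual = full.polya_polyau_total()[full.polya_polyau_total() >= k].index
            assert list(direct.counts.index) == sorted(manual)

    def test_oligou_and_mixed_never_count(self):
        reps = {"r": [make_assigned("TTTT", feature_id="g1", read_id=f"r{i}") for i in range(9)]}
        table = per_gene_table(reps, expression={}, min_total=5)
        assert table.genes == []

    def test_requires_a_replicate(self):
        with pytest.raises(ValueError):
            per_gene_table({}, expression={})


class TestExpressionCorrelation:
    def test_proportional_counts_give_r_of_one(self):
        reps = {
            "r": [
                t
                for g, n in [("g1", 2), ("g2", 4), ("g3", 8), ("g4", 16)]
                for t in [
                    make_assigned("AAAA", feature_id=g, read_id=f"{g}x{i}") for i in range(n)
                ]
            ]
        }
        expr = {"g1": 20, "g2": 40, "g3": 80, "g4": 160}
        table = per_gene_table(reps, expression=expr, min_total=0)
        # the +1 pseudocount perturbs exact log-linearity only slightly
        assert expression_correlation(table) == pytest.approx(1.0, abs=1e-3)

    def test_binomial_sampling_keeps_strong_correlation(self):
        """Tailed ~ Binomial(expression, p) over a 100x range gives r > 0.8."""
        rng = np.random.default_rng(21)
        genes = {f"g{i:03d}": int(e) for i, e in enumerate(np.geomspace(50, 5000, 80))}
        reps = {"r": []}
        for g, e in genes.items():
            k = rng.binomial(e, 0.02)
            reps["r"] += [make_assigned("AAAA", feature_id=g, read_id=f"{g}_{i}") for i in range(k)]
        table = per_gene_table(reps, expression=genes, min_total=0)
        assert expression_correlation(table) > 0.8

    def test_constant_counts_are_undefined(self):
        reps = {
            "r": [
                make_assigned("AAAA", feature_id=g, read_id=f"{g}x{i}")
                for g in ("g1", "g2", "g3")
                for i in range(3)
            ]
        }
        table = per_gene_table(reps, expression={"g1": 10, "g2": 20, "g3": 30}, min_total=0)
        with pytest.raises(ValueError):
            expression_correlation(table)

    def test_needs_three_genes(self):
        reps = {"r": [make_assigned("AAAA", feature_id="g1")]}
        with pytest.raises(ValueError):
            expression_correlation(per_gene_table(reps, expression={"g1": 5}, min_total=0))


class TestCorrelationMatrix:
    def _table_pair(self, seed, n_genes=60, depth=40):
        """Two samples drawn from identical per-gene rates."""
        rng = np.random.default_rng(seed)
        rates = rng.lognormal(3.0, 0.8, size=n_genes)
        tables = {}
        for sample in ("s1", "s2"):
            reps = {sample: []}
            expr = {}
            for i, rate in enumerate(rates):
                g = f"g{i:03d}"
                k = rng.poisson(rate * depth / rates.mean())
                ku = rng.binomial(k, 0.11) if k else 0
                expr[g] = max(k * 10, 1)
                reps[sample] += [
                    make_assigned("AAAA", feature_id=g, read_id=f"{sample}{g}_{j}")
                    for j in range(k - ku)
                ] + [
                    make_assigned("AAATT", feature_id=g, read_id=f"{sample}{g}_u{j}")
                    for j in range(ku)
                ]
            tables[sample] = per_gene_table(reps, expression=expr, min_total=0)
        return tables

    def test_symmetric_unit_diagonal(self):
        tables = self._table_pair(seed=2)
        corr = correlation_matrix(tables)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_identical_rates_correlate_strongly(self):
        tables = self._table_pair(seed=4)
        corr = correlation_matrix(tables, read_classes=("POLYA",))
        assert corr.loc["s1:POLYA", "s2:POLYA"] > 0.9

    def test_permuted_labels_kill_correlation(self):
        tables = self._table_pair(seed=6)
        shuffled = tables["s2"].counts.copy()
        rng = np.random.default_rng(0)
        shuffled.index = list(rng.permutation(shuffled.index))
        tables["s2"] = GeneTailTable(counts=shuffled, expression=tables["s2"].expression)
        corr = correlation_matrix(tables, read_classes=("POLYA",))
        assert abs(corr.loc["s1:POLYA", "s2:POLYA"]) < 0.4

    def test_too_small_intersection_errors(self):
        tables = self._table_pair(seed=2)
        tables["s2"] = GeneTailTable(
            counts=tables["s2"].counts.iloc[:2], expression=tables["s2"].expression.iloc[:2]
        )
        with pytest.raises(ValueError):
            correlation_matrix(tables)


class TestBiotypeBreakdown:
    def test_all_mrna(self):
        tails = [make_assigned("AAAA", read_id=f"r{i}") for i in range(4)]
        out = biotype_breakdown(tails)
        assert out["mRNA"]["count"] == 4 and out["mRNA"]["fraction"] == 1.0

    def test_fractions_sum_to_one(self):
        tails = [make_assigned("AAAA", biotype="mRNA", read_id=f"a{i}") for i in range(9)]
        tails += [make_assigned("AAAA", biotype="ncRNA_intergenic", read_id="b0")]
        out = biotype_breakdown(tails)
        assert sum(v["count"] for v in out.values()) == 10
        assert sum(v["fraction"] for v in out.values()) == pytest.approx(1.0)
        assert out["mRNA"]["fraction"] == pytest.approx(0.9)
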