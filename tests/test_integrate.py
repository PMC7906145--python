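import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lncm6a.integrate import (
    bin_lengths,
    call_differential_peaks,
    chromosome_distribution,
    correlate_levels,
    cumulative_log2fc,
    ddct_fold_change,
    enrichment_test,
    join_methylation_expression,
    mean_fold_change_by_class,
    round_pct,
    summarize_regulation,
)
from lncm6a.model import (
    DiffPeakRecord,
    ExpressionRecord,
    GeneSetCollection,
    GenomicInterval,
    PeakRecord,
    PositionalClass,
    TranscriptCatalog,
    ValidationError,
)

from conftest import make_transcript


def diff(chrom="chr1", start=100, end=200, fc=2.0, direction="hypermethylated", lnc=None):
    return DiffPeakRecord(GenomicInterval(chrom, start, end), fc, direction, lnc)


def peak(start, end, fe, chrom="chr1"):
    return PeakRecord(GenomicInterval(chrom, start, end), fe)


def expr(tid, fc, regulation, fpkm=None, biotype="lncRNA"):
    fpkm = fpkm or {"CRC_1": 1.0, "NC_1": 1.0}
    cond = {s: s.split("_")[0] for s in fpkm}
    return ExpressionRecord(
        transcript_id=tid, fpkm=fpkm, sample_condition=cond,
        fold_change=fc, regulation=regulation, biotype=biotype,
    )


class TestDifferentialCalling:
    def test_matched_pair_ratio(self):
        called = call_differential_peaks([peak(0, 100, 10.0)], [peak(50, 150, 2.0)])
        assert called[0].fold_change == 5.0
        assert called[0].direction == "hypermethylated"

    def test_equal_enrichment_gives_unit_fold(self):
        called = call_differential_peaks([peak(0, 100, 3.0)], [peak(0, 100, 3.0)])
        assert called[0].fold_change == 1.0

    def test_unmatched_peaks_get_infinite_fold(self):
        called = call_differential_peaks([peak(0, 100, 3.0)], [peak(5000, 5100, 4.0)])
        directions = sorted((c.direction, math.isinf(c.fold_change)) for c in called)
        assert directions == [("hypermethylated", True), ("hypomethylated", True)]

    def test_planted_labels_recovered(self, small_config, small_study):
        from lncm6a.simulate import GroundTruth, generate_peak_sets

        catalog, _ = small_study
        a, b, planted, truth = generate_peak_sets(small_config, catalog, GroundTruth())
        called = {
            (c.interval.chrom, c.interval.start, c.interval.end): c.direction
            for c in call_differential_peaks(a, b)
            if c.fold_change > 1.0 and not math.isinf(c.fold_change)
        }
        for rec in planted:
            key = (rec.interval.chrom, rec.interval.start, rec.interval.end)
            assert called[key] == rec.direction
        assert len(called) == len(planted)


class TestRegulationSummary:
    @pytest.mark.parametrize(
        "n_total,n_neg,pct_pos,pct_neg",
        [(396, 261, 34.1, 65.9), (383, 251, 34.5, 65.5)],
    )
    def test_published_percentages(self, n_total, n_neg, pct_pos, pct_neg):
        records = [diff(direction="hypermethylated")] * (n_total - n_neg)
        records += [diff(direction="hypomethylated")] * n_neg
        summary = summarize_regulation(records)
        assert (summary.n_total, summary.n_hypo) == (n_total, n_neg)
        assert summary.pct_hyper == pct_pos
        assert summary.pct_hypo == pct_neg

    def test_expression_counts_conserved(self):
        records = [expr(f"u{i}", 3.0, "up") for i in range(44)]
        records += [expr(f"d{i}", 3.0, "down") for i in range(119)]
        summary = summarize_regulation(records)
        assert (summary.n_total, summary.n_hyper, summary.n_hypo) == (163, 44, 119)

    def test_empty_input_gives_nan_percentages(self):
        summary = summarize_regulation([])
        assert summary.n_total == 0 and math.isnan(summary.pct_hyper)

    @given(st.integers(0, 500), st.integers(0, 500))
    @settings(derandomize=True, max_examples=100)
    def test_percentages_sum_to_100(self, n_pos, n_neg):
        if n_pos + n_neg == 0:
            return
        records = [diff(direction="hypermethylated")] * n_pos + [
            diff(direction="hypomethylated")
        ] * n_neg
        summary = summarize_regulation(records)
        assert summary.pct_hyper + summary.pct_hypo == pytest.approx(100, abs=0.1)


class TestLengthBinning:
    @pytest.fixture
    def catalog(self):
        return TranscriptCatalog(
            [
                make_transcript("l500", "chr1", [(1000, 1300), (1400, 1600)]),
                make_transcript("l100", "chr2", [(0, 100)]),
                make_transcript("l1500", "chr3", [(0, 1500)]),
            ]
        )

    def test_fine_bin_placement(self, catalog):
        binning = bin_lengths({"l500": "hypermethylated"}, catalog)
        row = binning.fine.iloc[0]
        assert (row.bin_start, row.bin_end, row["count"]) == (401, 600, 1)

    def test_coarse_fractions(self, catalog):
        binning = bin_lengths(
            {"l100": "hypomethylated", "l1500": "hypomethylated"}, catalog
        )
        coarse = binning.coarse.set_index("bin_start")
        assert coarse.loc[1, "fraction"] == 0.5
        assert coarse.loc[1001, "fraction"] == 0.5

    def test_missing_lncrna_reported_not_dropped(self, catalog):
        binning = bin_lengths({"ghost": "hypermethylated", "l100": "hypermethylated"}, catalog)
        assert binning.unresolved == ["ghost"]
        assert binning.coarse["count"].sum() == 1

    def test_totals_match_numpy_histogram(self):
        rng = np.random.default_rng(13)
        records = [
            make_transcript(f"l{i}", "chr1", [(j * 10_000, j * 10_000 + int(rng.integers(50, 4000)))])
            for i, j in enumerate(range(40))
        ]
        catalog = TranscriptCatalog(records)
        mapping = {r.transcript_id: "hypomethylated" for r in records}
        binning = bin_lengths(mapping, catalog)
        lengths = np.array([r.exonic_length for r in records])
        edges = np.arange(0, lengths.max() + 1001, 1000)
        hist, _ = np.histogram(lengths - 1, bins=edges)  # length 1 in first bin
        got = dict(zip(binning.coarse.bin_start, binning.coarse["count"]))
        for k, count in enumerate(hist):
            if count:
                assert got[k * 1000 + 1] == count


class TestChromosomeDistribution:
    def test_single_chrom(self):
        frame = chromosome_distribution([diff(chrom="chr1")] * 4)
        assert frame.fraction.tolist() == [1.0]

    def test_fraction_arithmetic(self):
        records = [diff(chrom="chr19", direction="hypomethylated")] * 3
        records += [diff(chrom="chr2", direction="hypomethylated")] * 17
        frame = chromosome_distribution(records).set_index("chrom")
        assert frame.loc["chr19", "fraction"] == pytest.approx(0.15)

    def test_matches_pandas_groupby(self):
        rng = np.random.default_rng(29)
        records = [
            diff(
                chrom=f"chr{rng.integers(1, 6)}",
                direction="hypermethylated" if rng.random() < 0.4 else "hypomethylated",
            )
            for _ in range(300)
        ]
        frame = chromosome_distribution(records)
        raw = pd.DataFrame(
            {"chrom": [r.interval.chrom for r in records], "dir": [r.direction for r in records]}
        )
        expected = raw.groupby(["dir", "chrom"]).size() / raw.groupby("dir").size()
        for _, row in frame.iterrows():
            assert row.fraction == pytest.approx(expected[(row.direction, row.chrom)])


class TestMeanFoldChangeByClass:
    def test_mean_and_sem(self):
        records = [diff(fc=2.0, lnc="a"), diff(fc=4.0, lnc="b")]
        mapping = {"a": PositionalClass.INTERGENIC, "b": PositionalClass.INTERGENIC}
        frame = mean_fold_change_by_class(records, mapping).set_index(["class", "direction"])
        row = frame.loc[("intergenic", "hypermethylated")]
        assert row.mean_fold_change == 3.0 and row["sem"] == 1.0

    def test_all_infinite_class_is_nan(self):
        records = [diff(fc=math.inf, lnc="a")]
        frame = mean_fold_change_by_class(records, {"a": PositionalClass.BIDIRECTIONAL})
        row = frame.set_index(["class", "direction"]).loc[("bidirectional", "hypermethylated")]
        assert row.n == 0 and math.isnan(row.mean_fold_change)

    def test_matches_direct_computation(self):
        rng = np.random.default_rng(37)
        classes = list(PositionalClass)
        mapping = {f"l{i}": classes[i % 6] for i in range(24)}
        records = [
            diff(
                fc=float(rng.uniform(1, 30)),
                direction="hypermethylated" if rng.random() < 0.5 else "hypomethylated",
                lnc=f"l{rng.integers(24)}",
            )
            for _ in range(150)
        ]
        frame = mean_fold_change_by_class(records, mapping).set_index(["class", "direction"])
        for cls in classes:
            for direction in ("hypermethylated", "hypomethylated"):
                values = [
                    r.fold_change
                    for r in records
                    if mapping[r.lncrna_id] == cls and r.direction == direction
                ]
                row = frame.loc[(cls.value, direction)]
                if values:
                    assert row.mean_fold_change == pytest.approx(np.mean(values))
                else:
                    assert math.isnan(row.mean_fold_change)


class TestJoin:
    def test_disjoint_sets_have_empty_intersections(self):
        table = join_methylation_expression(
            {"a": "hypermethylated"}, {"b": "up"}
        )
        assert table.loc["hypermethylated", "up"] == 0
        assert table.loc["hypermethylated", "not_differential"] == 1
        assert table.loc["not_differential", "up"] == 1

    def test_published_overlap_cell(self):
        """251 hypomethylated lncRNAs of which 5 are also down-expressed."""
        meth = {f"h{i}": "hypomethylated" for i in range(251)}
        expr_map = {f"h{i}": "down" for i in range(5)}
        expr_map.update({f"x{i}": "down" for i in range(10)})
        table = join_methylation_expression(meth, expr_map)
        assert table.loc["hypomethylated", "down"] == 5
        assert table.loc["hypomethylated", "not_differential"] == 246
        assert table.to_numpy().sum() == 261

    def test_matches_set_intersections(self):
        rng = np.random.default_rng(43)
        ids = [f"l{i}" for i in range(200)]
        meth = {l: ("hypermethylated" if rng.random() < 0.5 else "hypomethylated")
                for l in ids if rng.random() < 0.4}
        expr_map = {l: ("up" if rng.random() < 0.3 else "down")
                    for l in ids if rng.random() < 0.3}
        table = join_methylation_expression(meth, expr_map)
        for m in ("hypermethylated", "hypomethylated"):
            for e in ("up", "down"):
                expected = len(
                    {l for l in meth if meth[l] == m} & {l for l in expr_map if expr_map[l] == e}
                )
                assert table.loc[m, e] == expected


class TestCorrelation:
    def test_perfect_monotone(self):
        x = {f"l{i}": float(i) for i in range(10)}
        rho, p, n = correlate_levels(x, x)
        assert rho == pytest.approx(1.0) and n == 10
        y = {k: -v for k, v in x.items()}
        assert correlate_levels(x, y)[0] == pytest.approx(-1.0)

    def test_infinite_pairs_dropped(self):
        x = {"a": 1.0, "b": 2.0, "c": 3.0, "d": math.inf}
        y = {"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0}
        assert correlate_levels(x, y)[2] == 3

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValidationError):
            correlate_levels({"a": 1.0, "b": 2.0}, {"a": 1.0, "b": 2.0})

    def test_matches_manual_rank_correlation(self):
        rng = np.random.default_rng(47)
        x = {f"l{i}": float(rng.uniform(0, 100)) for i in range(20)}
        y = {f"l{i}": float(rng.uniform(0, 100)) for i in range(20)}
        rho, _, _ = correlate_levels(x, y, method="spearman")
        keys = sorted(x)
        rx = pd.Series([x[k] for k in keys]).rank().to_numpy()
        ry = pd.Series([y[k] for k in keys]).rank().to_numpy()
        manual = np.corrcoef(rx, ry)[0, 1]
        assert rho == pytest.approx(manual)


class TestCumulativeCurve:
    def test_identical_groups_have_zero_distance(self):
        records = [expr(f"a{i}", 2.0 ** (i + 1), "up") for i in range(5)]
        records += [expr(f"b{i}", 2.0 ** (i + 1), "up") for i in range(5)]
        curve = cumulative_log2fc(records, m6a_ids=[f"a{i}" for i in range(5)])
        assert curve.ks_statistic == 0.0

    def test_full_separation(self):
        records = [expr("a", 1.0, "unchanged"), expr("b", 4.0, "up")]
        curve = cumulative_log2fc(records, m6a_ids=["a"])
        assert curve.ks_statistic == 1.0

    def test_empty_group_errors(self):
        with pytest.raises(ValidationError, match="non-m6A"):
            cumulative_log2fc([expr("a", 2.0, "up")], m6a_ids=["a"])

    def test_curve_matches_ecdf_at_sample_points(self):
        rng = np.random.default_rng(53)
        fcs = [float(2 ** rng.uniform(-4, 4)) for i in range(60)]
        records = [expr(f"l{i}", fc, "up") for i, fc in enumerate(fcs)]
        m6a = {f"l{i}" for i in range(30)}
        curve = cumulative_log2fc(records, m6a)
        values = np.array([abs(math.log2(fc)) for fc in fcs[:30]])
        for v, frac in zip(curve.m6a_values, curve.m6a_fractions):
            assert frac == pytest.approx((values <= v).mean())
        assert curve.m6a_fractions[-1] == 1.0
        assert (np.diff(curve.m6a_fractions) >= 0).all()

    def test_infinite_values_clamped_not_dropped(self):
        records = [expr("a", math.inf, "up"), expr("b", 2.0, "up"),
                   expr("c", 4.0, "down"), expr("d", 0.0, "unchanged")]
        curve = cumulative_log2fc(records, m6a_ids=["a", "b"])
        assert curve.n_clamped == 2
        assert len(curve.m6a_values) == 2 and len(curve.non_m6a_values) == 2


class TestDdct:
    def test_identity(self):
        assert ddct_fold_change(20, 18, 22, 20) == 1.0

    def test_known_quadruple(self):
        assert ddct_fold_change(20, 18, 24, 18) == 16.0

    def test_matches_formula_on_random_inputs(self):
        rng = np.random.default_rng(59)
        for _ in range(50):
            ct = rng.uniform(10, 35, size=4)
            expected = 2 ** -((ct[0] - ct[1]) - (ct[2] - ct[3]))
            assert ddct_fold_change(*ct) == pytest.approx(expected)


class TestEnrichment:
    def test_query_equals_universe_set(self):
        sets = GeneSetCollection(sets={"S": frozenset("abcde")})
        result = enrichment_test(list("abcde"), sets, universe=list("abcde"))
        assert result.loc[0, "p"] == 1.0

    def test_closed_form_extreme_overlap(self):
        """k=K=n=5 in a 10-gene universe: p = 1/C(10,5)."""
        sets = GeneSetCollection(sets={"S": frozenset("abcde")})
        universe = list("abcdefghij")
        result = enrichment_test(list("abcde"), sets, universe=universe)
        assert result.loc[0, "p"] == pytest.approx(1 / math.comb(10, 5))

    def test_empty_universe_errors(self):
        with pytest.raises(ValidationError):
            enrichment_test(["a"], GeneSetCollection(sets={"S": frozenset("a")}), universe=[])

    def test_matches_exhaustive_enumeration_small_universe(self):
        """Hypergeometric tails equal enumeration over all query draws."""
        rng = np.random.default_rng(61)
        universe = [f"g{i}" for i in range(12)]
        for _ in range(10):
            K = int(rng.integers(1, 10))
            members = frozenset(rng.choice(universe, size=K, replace=False))
            n = int(rng.integers(1, 10))
            query = list(rng.choice(universe, size=n, replace=False))
            sets = GeneSetCollection(sets={"S": members})
            p = enrichment_test(query, sets, universe=universe).loc[0, "p"]
            k = len(set(query) & members)
            hits = total = 0
            for draw in itertools.combinations(universe, n):
                total += 1
                if len(set(draw) & members) >= k:
                    hits += 1
            assert p == pytest.approx(hits / total)

    def test_combinatorial_tail_for_random_sets(self):
        rng = np.random.default_rng(67)
        universe = [f"g{i}" for i in range(20)]
        sets = {}
        for i in range(50):
            K = int(rng.integers(1, 15))
            sets[f"S{i:02d}"] = frozenset(rng.choice(universe, size=K, replace=False))
        query = list(rng.choice(universe, size=8, replace=False))
        result = enrichment_test(query, GeneSetCollection(sets=sets), universe=universe)
        N, n = 20, 8
        for _, row in result.iterrows():
            members = sets[row["set"]]
            k, K = len(set(query) & members), len(members)
            expected = sum(
                math.comb(K, j) * math.comb(N - K, n - j) for j in range(k, min(K, n) + 1)
            ) / math.comb(N, n)
            assert row.p == pytest.approx(expected)

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(71)
        for _ in range(1000):
            p = rng.uniform(size=10)
            from scipy.stats import false_discovery_control

            adj = false_discovery_control(p, method="bh")
            order = np.argsort(p, kind="mergesort")
            assert (np.diff(adj[order]) >= -1e-12).all()

    def test_output_sorted_by_p_then_name(self):
        sets = GeneSetCollection(
            sets={"B": frozenset("ab"), "A": frozenset("ab"), "C": frozenset("xy")}
        )
        result = enrichment_test(["a", "b"], sets, universe=list("abxy"))
        assert result["set"].tolist() == ["A", "B", "C"]


class TestRounding:
    @pytest.mark.parametrize(
        "num,den,expected",
        [(261, 396, 65.9), (135, 396, 34.1), (251, 383, 65.5), (132, 383, 34.5)],
    )
    def test_printed_identities(self, num, den, expected):
        assert round_pct(num, den) == expected

    def test_half_rounds_away_from_zero(self):
        assert round_pct(1, 1000, 1) == 0.1
        assert round_pct(45, 10000, 1) == 0.5  # 0.45% -> 0.5
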