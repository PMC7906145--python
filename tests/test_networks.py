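import math

import numpy as np
import pandas as pd
import pytest

from lncm6a.datasets import load_cerna_screen_table
from lncm6a.model import (
    BindingPrediction,
    ConfigError,
    TranscriptCatalog,
    ValidationError,
)
from lncm6a.networks import (
    ScreenCriteria,
    build_cerna_network,
    build_cnc_network,
    find_cis_targets,
    find_trans_targets,
    screen_cerna_candidates,
)

from conftest import make_transcript


class TestCisTargets:
    def _catalog(self, gap):
        lnc = make_transcript("lnc", "chr1", [(100_000, 101_000)])
        mrna = make_transcript(
            "mrna", "chr1", [(101_000 + gap, 102_000 + gap)], "+", "mRNA"
        )
        return lnc, TranscriptCatalog([lnc, mrna])

    def test_gap_strictly_less_than_window(self):
        lnc, catalog = self._catalog(gap=9_999)
        assert find_cis_targets(lnc, catalog) == ["mrna"]
        lnc, catalog = self._catalog(gap=10_000)
        assert find_cis_targets(lnc, catalog) == []

    def test_isolated_lncrna_has_no_targets(self):
        lnc, catalog = self._catalog(gap=50_000)
        assert find_cis_targets(lnc, catalog) == []

    def test_strand_agnostic(self):
        lnc = make_transcript("lnc", "chr1", [(100_000, 101_000)], "+")
        mrna = make_transcript("m", "chr1", [(95_000, 96_000)], "-", "mRNA")
        assert find_cis_targets(lnc, TranscriptCatalog([lnc, mrna])) == ["m"]

    def test_negative_window_rejected(self):
        lnc, catalog = self._catalog(gap=0)
        with pytest.raises(ConfigError):
            find_cis_targets(lnc, catalog, window=-1)

    def test_matches_brute_force_distance_scan(self):
        rng = np.random.default_rng(73)
        mrnas = []
        for i in range(50):
            start = int(rng.integers(0, 400_000))
            mrnas.append(
                make_transcript(f"m{i}", "chr1", [(start, start + int(rng.integers(500, 5000)))], "+", "mRNA")
            )
        lnc = make_transcript("lnc", "chr1", [(200_000, 201_000)])
        catalog = TranscriptCatalog(mrnas + [lnc])
        expected = sorted(
            m.transcript_id
            for m in mrnas
            if max(m.interval.start - lnc.interval.end, lnc.interval.start - m.interval.end) < 10_000
        )
        assert find_cis_targets(lnc, catalog) == expected


class TestTransTargets:
    def _frame(self, rows):
        return pd.DataFrame(rows, columns=[f"s{i}" for i in range(6)])

    def test_identical_profile_included(self):
        x = {f"s{i}": float(v) for i, v in enumerate([1, 5, 2, 8, 3, 9])}
        table = self._frame([[1, 5, 2, 8, 3, 9]])
        table.index = ["m"]
        assert find_trans_targets(x, table) == [("m", pytest.approx(1.0))]

    def test_negated_profile_keeps_sign(self):
        x = {f"s{i}": float(v) for i, v in enumerate([1, 5, 2, 8, 3, 9])}
        table = self._frame([[-1, -5, -2, -8, -3, -9]])
        table.index = ["m"]
        hits = find_trans_targets(x, table)
        assert hits == [("m", pytest.approx(-1.0))]
        assert find_trans_targets(x, table, positive_only=True) == []

    def test_too_few_samples_errors(self):
        x = {"s0": 1.0, "s1": 2.0}
        table = pd.DataFrame([[1.0, 2.0]], columns=["s0", "s1"], index=["m"])
        with pytest.raises(ValidationError):
            find_trans_targets(x, table)


class TestScreening:
    def test_published_methylation_rows_pass_default_screen(self):
        table = load_cerna_screen_table()
        meth = {
            row.transcript_id: row.fold_change
            for row in table.itertuples()
            if "methyl" in row.regulation
        }
        result = screen_cerna_candidates(meth, {}, disease_flags=meth)
        assert len(result) == 8
        assert set(result.criterion) == {"meth"}

    def test_published_expression_rows_pass_default_screen(self):
        table = load_cerna_screen_table()
        expr = {
            row.transcript_id: row.fold_change
            for row in table.itertuples()
            if "expression" in row.regulation
        }
        result = screen_cerna_candidates({}, expr, disease_flags=expr)
        assert len(result) == 8
        assert math.isinf(result.set_index("lncrna_id").loc["ENST00000566997", "expr_fc"])

    def test_infinite_thresholds_keep_only_infinite_fold_changes(self):
        criteria = ScreenCriteria(meth_fc_threshold=math.inf, expr_fc_threshold=math.inf)
        result = screen_cerna_candidates(
            {"a": math.inf, "b": 1e9}, {"c": math.inf, "d": 50.0},
            disease_flags=["a", "b", "c", "d"], criteria=criteria,
        )
        assert result.lncrna_id.tolist() == ["a", "c"]

    def test_disease_flag_required_by_default(self):
        result = screen_cerna_candidates({"a": 100.0, "b": 100.0}, {}, disease_flags=["a"])
        assert result.lncrna_id.tolist() == ["a"]

    def test_monotone_in_thresholds(self):
        rng = np.random.default_rng(79)
        meth = {f"l{i}": float(rng.uniform(0, 20)) for i in range(50)}
        flags = list(meth)
        previous = None
        for threshold in (2.0, 5.0, 8.0, 12.0):
            criteria = ScreenCriteria(meth_fc_threshold=threshold)
            kept = set(screen_cerna_candidates(meth, {}, flags, criteria).lncrna_id)
            if previous is not None:
                assert kept <= previous
            previous = kept


def bindings(pairs, layer):
    return [BindingPrediction(s, t, score, layer) for s, t, score in pairs]


class TestCeRNA:
    def test_minimal_one_lncrna_network(self):
        lnc_mi = bindings([("L", f"mi{i}", 10 - i) for i in range(5)], "lncRNA-miRNA")
        mi_mrna = bindings(
            [(f"mi{i}", f"m{i}_{j}", 10 - j) for i in range(5) for j in range(5)],
            "miRNA-mRNA",
        )
        net = build_cerna_network(["L"], lnc_mi, mi_mrna, k=5)
        assert len(net.nodes_by_layer("lncRNA")) == 1
        assert len(net.nodes_by_layer("miRNA")) == 5
        assert len(net.nodes_by_layer("mRNA")) == 25

    def test_shortfall_logged_not_fatal(self):
        lnc_mi = bindings([("L", f"mi{i}", i) for i in range(3)], "lncRNA-miRNA")
        mi_mrna = bindings([(f"mi{i}", "m", 1.0) for i in range(3)], "miRNA-mRNA")
        net = build_cerna_network(["L"], lnc_mi, mi_mrna, k=5)
        assert len(net.nodes_by_layer("miRNA")) == 3
        assert net.shortfalls["L"] == 2

    def test_tie_break_by_partner_id(self):
        lnc_mi = bindings(
            [("L", "mi_b", 1.0), ("L", "mi_a", 1.0), ("L", "mi_c", 1.0)], "lncRNA-miRNA"
        )
        mi_mrna = bindings(
            [(m, "t", 1.0) for m in ("mi_a", "mi_b", "mi_c")], "miRNA-mRNA"
        )
        net = build_cerna_network(["L"], lnc_mi, mi_mrna, k=2)
        assert net.nodes_by_layer("miRNA") == ["mi_a", "mi_b"]

    def test_topk_matches_sort_oracle(self):
        rng = np.random.default_rng(83)
        for _ in range(25):
            scores = rng.permutation(20).astype(float)
            lnc_mi = bindings(
                [("L", f"mi{i:02d}", float(scores[i])) for i in range(20)], "lncRNA-miRNA"
            )
            mi_mrna = bindings(
                [(f"mi{i:02d}", "t", 1.0) for i in range(20)], "miRNA-mRNA"
            )
            net = build_cerna_network(["L"], lnc_mi, mi_mrna, k=5)
            expected = sorted(
                [f"mi{i:02d}" for i in range(20)],
                key=lambda m: (-scores[int(m[2:])], m),
            )[:5]
            assert net.nodes_by_layer("miRNA") == sorted(expected)

    def test_node_count_law_with_shared_partners(self):
        """Shared partners can only shrink the miRNA/mRNA node counts below
        k*L and k^2*L."""
        rng = np.random.default_rng(89)
        lncs = [f"L{i}" for i in range(6)]
        mirnas = [f"mi{i}" for i in range(12)]
        lnc_mi, mi_mrna = [], []
        for l in lncs:
            for m in rng.choice(mirnas, size=7, replace=False):
                lnc_mi.append(BindingPrediction(l, str(m), float(rng.random()), "lncRNA-miRNA"))
        for m in mirnas:
            for t in rng.choice([f"t{i}" for i in range(30)], size=7, replace=False):
                mi_mrna.append(BindingPrediction(m, str(t), float(rng.random()), "miRNA-mRNA"))
        net = build_cerna_network(lncs, lnc_mi, mi_mrna, k=5)
        assert len(net.nodes_by_layer("miRNA")) <= 5 * len(lncs)
        assert len(net.nodes_by_layer("mRNA")) <= 25 * len(lncs)
        net.validate()


class TestCNC:
    def _tables(self, lnc_rows, mrna_rows, samples=6):
        cols = [f"s{i}" for i in range(samples)]
        lnc = pd.DataFrame(lnc_rows).T if isinstance(lnc_rows, dict) else None
        lnc = pd.DataFrame.from_dict(lnc_rows, orient="index", columns=cols)
        mrna = pd.DataFrame.from_dict(mrna_rows, orient="index", columns=cols)
        return lnc, mrna

    def test_identical_profile_gives_positive_edge(self):
        profile = [1.0, 4.0, 2.0, 8.0, 3.0, 9.0]
        lnc, mrna = self._tables({"L": profile}, {"M": profile})
        net = build_cnc_network(lnc, mrna)
        assert net.graph.has_edge("L", "M")
        assert net.graph.edges["L", "M"]["sign"] == "+"

    def test_negated_profile_gives_negative_edge(self):
        profile = np.array([1.0, 4.0, 2.0, 8.0, 3.0, 9.0])
        lnc, mrna = self._tables({"L": profile}, {"M": (-profile).tolist()})
        net = build_cnc_network(lnc, mrna)
        assert net.graph.edges["L", "M"]["sign"] == "-"

    def test_independent_noise_yields_almost_no_edges(self):
        rng = np.random.default_rng(97)
        cols = [f"s{i}" for i in range(10)]
        lnc = pd.DataFrame(rng.normal(size=(20, 10)), index=[f"L{i}" for i in range(20)], columns=cols)
        mrna = pd.DataFrame(rng.normal(size=(20, 10)), index=[f"M{i}" for i in range(20)], columns=cols)
        net = build_cnc_network(lnc, mrna, threshold=0.95)
        assert net.graph.number_of_edges() <= 1

    def test_row_shuffle_invariance(self):
        rng = np.random.default_rng(101)
        cols = [f"s{i}" for i in range(8)]
        lnc = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"L{i}" for i in range(10)], columns=cols)
        mrna = pd.DataFrame(rng.normal(size=(10, 8)), index=[f"M{i}" for i in range(10)], columns=cols)
        net1 = build_cnc_network(lnc, mrna, threshold=0.3)
        net2 = build_cnc_network(lnc.sample(frac=1, random_state=0), mrna.sample(frac=1, random_state=1), threshold=0.3)
        edges1 = {(u, v): round(d["r"], 12) for u, v, d in net1.graph.edges(data=True)}
        edges2 = {(u, v): round(d["r"], 12) for u, v, d in net2.graph.edges(data=True)}
        assert edges1 == edges2

    def test_too_few_samples_errors(self):
        lnc = pd.DataFrame([[1.0, 2.0]], index=["L"], columns=["s0", "s1"])
        mrna = pd.DataFrame([[1.0, 2.0]], index=["M"], columns=["s0", "s1"])
        with pytest.raises(ValidationError):
            build_cnc_network(lnc, mrna)

    def test_planted_hub_degree_recovered(self, small_config):
        """A lncRNA planted with 10 highly correlated mRNAs has degree 10."""
        from lncm6a.simulate import (
            expression_frame,
            generate_annotation,
            generate_expression_matrix,
            generate_peak_sets,
        )

        catalog, truth = generate_annotation(small_config)
        _, _, diff, truth = generate_peak_sets(small_config, catalog, truth)
        expr, truth = generate_expression_matrix(small_config, catalog, diff, truth)
        lnc = expression_frame(expr, biotype="lncRNA")
        mrna = expression_frame(expr, biotype="mRNA")
        net = build_cnc_network(lnc, mrna, threshold=0.97)
        assert net.degree(truth.hub_lncrna) == small_config.hub_targets == 10
        assert set(net.graph.neighbors(truth.hub_lncrna)) == set(truth.hub_mrnas)
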