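import numpy as np
import pytest

from minimotif.annotations import AliasTable
from minimotif.filters import (
    FilterConfig,
    FilterDecision,
    FilterResources,
    Verdict,
    apply_filter,
    combine_either_or,
    frequency_filter,
    function_filter,
)
from minimotif.motifs import BackgroundFrequencies, Minimotif, parse_pattern

from conftest import build_graph

UNIFORM = BackgroundFrequencies.uniform()


def motif(source="S", target="T", pattern="AC"):
    return Minimotif(source=source, pattern=parse_pattern(pattern),
                     activity="binds", target=target)


class TestFunctionFilter:
    def test_threshold_separates_cousins(self, toy_dag):
        rejected = function_filter({"A1"}, {"A2"}, toy_dag, t=1)
        assert rejected.verdict is Verdict.REJECTED
        assert rejected.min_distance == 2
        retained = function_filter({"A1"}, {"A2"}, toy_dag, t=2)
        assert retained.verdict is Verdict.RETAINED

    def test_shared_term_retained_at_zero(self, toy_dag):
        d = function_filter({"A", "B1"}, {"A"}, toy_dag, t=0)
        assert d.verdict is Verdict.RETAINED
        assert d.min_distance == 0

    def test_empty_side_not_evaluable(self, toy_dag):
        d = function_filter({"A1"}, set(), toy_dag, t=5)
        assert d.verdict is Verdict.NOT_EVALUABLE
        assert d.min_distance is None and not d.has_distance

    def test_no_common_ancestor_counts_as_failure(self):
        g = build_graph({"A1": ["A"], "B1": ["B"]})
        d = function_filter({"A1"}, {"B1"}, g, t=100)
        assert d.verdict is Verdict.REJECTED
        assert d.min_distance is None and d.has_distance

    def test_closest_pair_is_lexicographically_smallest(self, toy_dag):
        # A1-A2 and A2-A1 both at distance 2: report the sorted-first pair
        d = function_filter({"A1", "A2"}, {"A1", "A2"}, toy_dag, t=0)
        assert d.closest_pair == ("A1", "A1")

    def test_t0_equals_intersection_oracle(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(3)
        terms = ds.graph.terms
        for _ in range(200):
            a = {terms[int(i)] for i in rng.integers(len(terms), size=3)}
            b = {terms[int(i)] for i in rng.integers(len(terms), size=3)}
            got = function_filter(a, b, ds.graph, t=0).verdict is Verdict.RETAINED
            assert got == bool(a & b)


class TestFrequencyFilter:
    SEQS = {"S": "A" * 11}

    def test_threshold_boundary(self):
        # score("AC", L=11) = 10 * (1/20)^2 = 0.025
        m = motif()
        low = frequency_filter(m, self.SEQS, UNIFORM, threshold=0.02)
        high = frequency_filter(m, self.SEQS, UNIFORM, threshold=0.03)
        assert low.verdict is Verdict.REJECTED
        assert high.verdict is Verdict.RETAINED
        assert low.score == pytest.approx(0.025)

    def test_wildcard_pattern_always_rejected(self):
        m = motif(pattern="xx")
        d = frequency_filter(m, self.SEQS, UNIFORM, threshold=0.04)
        assert d.verdict is Verdict.REJECTED and d.score >= 1.0

    def test_missing_sequence_not_evaluable(self):
        d = frequency_filter(motif(source="GHOST"), self.SEQS, UNIFORM, 0.02)
        assert d.verdict is Verdict.NOT_EVALUABLE and d.score is None

    def test_source_resolved_through_alias(self):
        aliases = AliasTable({"ALIAS": "S"})
        d = frequency_filter(motif(source="ALIAS"), self.SEQS, UNIFORM, 0.03,
                             aliases=aliases)
        assert d.verdict is Verdict.RETAINED


def decision(verdict, component="x"):
    return FilterDecision(Verdict(verdict), component=component)


class TestCombineEitherOr:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("retained", "rejected", "retained"),
            ("rejected", "retained", "retained"),
            ("retained", "retained", "retained"),
            ("rejected", "rejected", "rejected"),
            ("not_evaluable", "rejected", "rejected"),
            ("not_evaluable", "retained", "retained"),
            ("not_evaluable", "not_evaluable", "not_evaluable"),
        ],
    )
    def test_truth_table(self, a, b, expected):
        out = combine_either_or(decision(a, "fn"), decision(b, "fq"))
        assert out.verdict is Verdict(expected)

    def test_component_records_winners(self):
        out = combine_either_or(decision("retained", "fn"), decision("retained", "fq"))
        assert out.component == "either_or:fn+fq"


class TestApplyFilter:
    @pytest.fixture
    def resources(self, toy_dag, toy_annotations):
        return FilterResources(graph=toy_dag, annotations=toy_annotations,
                               sequences={"SRC": "A" * 11, "SHARED1": "A" * 300})

    @pytest.fixture
    def motifs(self):
        return [
            motif("SHARED1", "SHARED2"),   # shared term "A": retained at t=0
            motif("SRC", "TGT"),           # A1 vs A2: distance 2, rejected at t=0
            motif("SRC", "NOWHERE"),       # unannotated target: not evaluable
        ]

    def test_summary_excludes_not_evaluable(self, resources, motifs):
        config = FilterConfig(distance_threshold=0)
        decisions, summary = apply_filter(motifs, config, resources)
        assert [d.verdict.value for d in decisions] == [
            "retained", "rejected", "not_evaluable"]
        assert (summary.total_evaluable, summary.retained, summary.not_evaluable) == (2, 1, 1)

    def test_invert_swaps_only_evaluable(self, resources, motifs):
        config = FilterConfig(distance_threshold=0, invert=True)
        decisions, summary = apply_filter(motifs, config, resources)
        assert [d.verdict.value for d in decisions] == [
            "rejected", "retained", "not_evaluable"]
        assert (summary.total_evaluable, summary.retained) == (2, 1)

    def test_invert_is_an_involution(self, resources, motifs):
        plain, _ = apply_filter(motifs, FilterConfig(distance_threshold=0), resources)
        twice, _ = apply_filter(motifs, FilterConfig(distance_threshold=0), resources)
        from minimotif.filters import _invert
        assert [_invert(_invert(d)) for d in plain] == twice

    def test_retained_sets_nested_in_t(self, small_dataset, small_resources):
        ds = small_dataset
        retained_by_t = []
        for t in range(6):
            config = FilterConfig(namespace=ds.config.namespace, distance_threshold=t)
            decisions, _ = apply_filter(ds.positives, config, small_resources)
            retained_by_t.append({i for i, d in enumerate(decisions) if d.retained})
        for a, b in zip(retained_by_t, retained_by_t[1:]):
            assert a <= b

    def test_retained_sets_nested_in_frequency_threshold(self, small_dataset, small_resources):
        ds = small_dataset
        previous: set[int] = set()
        for thr in (0.0005, 0.005, 0.05, 0.5):
            config = FilterConfig(namespace=ds.config.namespace,
                                  mode="frequency_only", frequency_threshold=thr)
            decisions, _ = apply_filter(ds.positives, config, small_resources)
            current = {i for i, d in enumerate(decisions) if d.retained}
            assert previous <= current
            previous = current

    def test_either_or_retains_superset_of_components(self, small_dataset, small_resources):
        ds = small_dataset
        base = dict(namespace=ds.config.namespace, distance_threshold=1,
                    frequency_threshold=0.005)
        combined_cfg = FilterConfig(mode="either_or", **base)
        fn_cfg = FilterConfig(mode="function_only", **base)
        fq_cfg = FilterConfig(mode="frequency_only", **base)
        combined, _ = apply_filter(ds.positives, combined_cfg, small_resources)
        fn, _ = apply_filter(ds.positives, fn_cfg, small_resources)
        fq, _ = apply_filter(ds.positives, fq_cfg, small_resources)
        comb_idx = {i for i, d in enumerate(combined) if d.retained}
        fn_idx = {i for i, d in enumerate(fn) if d.retained}
        # frequency retention only counts inside the function-evaluable universe
        fq_idx = {i for i, d in enumerate(fq) if d.retained and fn[i].evaluable}
        assert fn_idx <= comb_idx
        assert fq_idx <= comb_idx
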