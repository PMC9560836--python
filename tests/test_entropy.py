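"""Weight schemes, indices and the entropy functional: worked values,
analytic limits, and the classed-vs-per-edge equivalence oracle."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from benzentropy import (DEGREE, DEGREE_SUM, EdgePartition, FamilySpec,
                         WeightScheme, edge_weight, entropy,
                         entropy_from_graph, index_value,
                         line_graph_of_subdivision, partition_edges,
                         printed_partition)
from benzentropy.errors import (BasisMismatchError, DomainError,
                                ParameterError)


def edgewise_entropy(g, scheme):
    """Per-edge brute-force evaluation of the entropy functional, with no
    classing at all — the independent oracle for the classed path."""
    if scheme.basis == DEGREE:
        label = g.degree
    else:
        label = g.neighbor_degree_sum
    weights = [edge_weight(scheme, tuple(sorted((label(u), label(v)))))
               for u, v in g.edges]
    total = sum(weights)
    return math.log(total) - sum(w * math.log(w) for w in weights) / total


SCHEMES = [WeightScheme("randic", 1.0), WeightScheme("randic", -1.0),
           WeightScheme("randic", 0.5), WeightScheme("randic", -0.5),
           WeightScheme("abc"), WeightScheme("ga"),
           WeightScheme("abc4"), WeightScheme("ga5")]


class TestEdgeWeight:
    def test_closed_form_values(self):
        assert edge_weight(WeightScheme("ga"), (3, 3)) == pytest.approx(1.0)
        assert edge_weight(WeightScheme("abc"), (2, 2)) == pytest.approx(math.sqrt(0.5))
        assert edge_weight(WeightScheme("randic", -1.0), (2, 3)) == pytest.approx(1 / 6)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            edge_weight(WeightScheme("abc"), (1, 1))
        with pytest.raises(DomainError):
            edge_weight(WeightScheme("ga"), (0, 2))

    def test_scheme_validation(self):
        with pytest.raises(ParameterError):
            WeightScheme("randic")  # missing alpha
        with pytest.raises(ParameterError):
            WeightScheme("abc", alpha=1.0)
        with pytest.raises(ParameterError):
            WeightScheme("zagreb")


class TestIndexValue:
    def test_uniform_randic(self):
        p = EdgePartition.build(DEGREE, {(2, 2): 12})
        assert index_value(p, WeightScheme("randic", 1.0)) == pytest.approx(48.0)

    def test_table6_randic_at_s12(self):
        p = printed_partition(FamilySpec("ZCS", 4, 4, 4), DEGREE)
        assert index_value(p, WeightScheme("randic", 1.0)) == pytest.approx(2445.0)

    def test_abc4_worked_example(self):
        # nine (4,4) edges: ABC4 = 9*sqrt(6)/4
        p = EdgePartition.build(DEGREE_SUM, {(4, 4): 9})
        assert index_value(p, WeightScheme("abc4")) == pytest.approx(9 * math.sqrt(6) / 4)

    def test_basis_mismatch(self):
        p = EdgePartition.build(DEGREE, {(2, 2): 1})
        with pytest.raises(BasisMismatchError):
            index_value(p, WeightScheme("abc4"))

    def test_empty_partition_rejected(self):
        p = EdgePartition.build(DEGREE, {})
        with pytest.raises(DomainError):
            index_value(p, WeightScheme("ga"))


class TestEntropy:
    def test_single_class_gives_log_count(self):
        p = EdgePartition.build(DEGREE, {(2, 2): 12})
        for scheme in SCHEMES[:6]:
            r = entropy(p, scheme)
            assert r.entropy_value == pytest.approx(math.log(12), abs=1e-12)

    def test_table14_444_randic1(self):
        p = printed_partition(FamilySpec("ZCS", 4, 4, 4), DEGREE)
        r = entropy(p, WeightScheme("randic", 1.0))
        assert r.entropy_value == pytest.approx(5.7200, abs=5e-4)

    def test_abc4_single_class_worked_example(self):
        p = EdgePartition.build(DEGREE_SUM, {(4, 4): 9})
        r = entropy(p, WeightScheme("abc4"))
        assert r.entropy_value == pytest.approx(math.log(9), abs=1e-12)
        assert r.entropy_value == pytest.approx(2.1972, abs=5e-4)

    def test_probabilities_sum_to_one(self):
        p = printed_partition(FamilySpec("H", 3, 4), DEGREE)
        for scheme in SCHEMES[:6]:
            r = entropy(p, scheme)
            assert sum(c.probability for c in r.per_class) == pytest.approx(1.0, abs=1e-9)

    def test_zero_count_classes_ignored(self):
        a = EdgePartition.build(DEGREE, {(2, 2): 5, (2, 3): 0})
        b = EdgePartition.build(DEGREE, {(2, 2): 5})
        s = WeightScheme("abc")
        assert entropy(a, s).entropy_value == entropy(b, s).entropy_value


class TestEntropyFromGraph:
    def test_c12_uniform(self, benzene):
        c12 = benzene.subdivision()
        r = entropy_from_graph(c12, WeightScheme("ga"))
        assert r.entropy_value == pytest.approx(math.log(12), abs=1e-12)

    def test_h22_abc_and_ga_printed_values(self):
        ls = line_graph_of_subdivision(FamilySpec("H", 2, 2))
        assert entropy_from_graph(ls, WeightScheme("abc")).entropy_value == \
            pytest.approx(3.8497, abs=5e-4)
        assert entropy_from_graph(ls, WeightScheme("ga")).entropy_value == \
            pytest.approx(3.8501, abs=5e-4)

    def test_empty_graph_rejected(self):
        from benzentropy import MolecularGraph

        with pytest.raises(DomainError):
            entropy_from_graph(MolecularGraph.from_edges([], isolated=[1]),
                               WeightScheme("ga"))


class TestAnalyticProperties:
    def test_classed_equals_edgewise_on_families(self):
        specs = [FamilySpec("T", 3), FamilySpec("H", 2, 3),
                 FamilySpec("ZCS", 4, 4, 4)]
        for spec in specs:
            ls = line_graph_of_subdivision(spec)
            for scheme in SCHEMES:
                classed = entropy_from_graph(ls, scheme).entropy_value
                assert classed == pytest.approx(edgewise_entropy(ls, scheme),
                                                abs=1e-12)

    def test_classed_equals_edgewise_on_fixtures(self, oracle_fixtures):
        ga = WeightScheme("ga")
        for g in oracle_fixtures[:40]:
            if g.n_edges == 0:
                continue
            assert entropy_from_graph(g, ga).entropy_value == \
                pytest.approx(edgewise_entropy(g, ga), abs=1e-12)

    def test_entropy_bounded_by_log_edges(self, oracle_fixtures):
        for g in oracle_fixtures:
            if g.n_edges == 0:
                continue
            for scheme in (WeightScheme("ga"), WeightScheme("randic", 1.0)):
                r = entropy_from_graph(g, scheme)
                assert r.entropy_value <= math.log(g.n_edges) + 1e-9
                assert r.entropy_value >= -1e-12

    def test_randic_alpha0_is_uniform(self):
        p = printed_partition(FamilySpec("H", 4, 7), DEGREE)
        r = entropy(p, WeightScheme("randic", 0.0))
        assert r.entropy_value == pytest.approx(math.log(p.total), abs=1e-12)

    def test_scale_invariance_of_randic_entropy(self):
        # multiplying every weight by c > 0 leaves the entropy unchanged;
        # for a partition with only classes (2,2) and (3,3) ... use direct
        # manual scaling on arbitrary class weights
        p = printed_partition(FamilySpec("T", 4), DEGREE)
        base = entropy(p, WeightScheme("randic", 1.0)).entropy_value
        # manual evaluation with weights scaled by c
        for c in (0.25, 7.0):
            weights = {k: c * (k[0] * k[1]) for k in p.nonzero()}
            total = sum(n * weights[k] for k, n in p.nonzero().items())
            acc = sum(n * weights[k] * math.log(weights[k])
                      for k, n in p.nonzero().items())
            assert math.log(total) - acc / total == pytest.approx(base, abs=1e-12)


@st.composite
def partitions(draw):
    pairs = draw(st.lists(
        st.tuples(st.integers(1, 9), st.integers(1, 9)).map(lambda t: tuple(sorted(t))),
        min_size=1, max_size=6, unique=True))
    counts = draw(st.lists(st.integers(1, 500), min_size=len(pairs),
                           max_size=len(pairs)))
    return EdgePartition.build(DEGREE, dict(zip(pairs, counts)))


class TestPropertyBased:
    @settings(max_examples=200, derandomize=True)
    @given(partitions(), st.sampled_from([1.0, -1.0, 0.5, -0.5]))
    def test_entropy_bounds_hold_for_random_partitions(self, p, alpha):
        r = entropy(p, WeightScheme("randic", alpha))
        assert -1e-9 <= r.entropy_value <= math.log(p.total) + 1e-9
        assert sum(c.probability for c in r.per_class) == pytest.approx(1.0, abs=1e-9)

    @settings(max_examples=100, derandomize=True)
    @given(partitions())
    def test_uniform_weight_collapse(self, p):
        r = entropy(p, WeightScheme("randic", 0.0))
        assert r.entropy_value == pytest.approx(math.log(p.total), abs=1e-12)
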