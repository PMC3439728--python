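"""Pair assessment, recall stratification, random/analytic nulls, BW screening,
Fisher's exact test and ATC enrichment."""

from fractions import Fraction
from math import comb

import numpy as np
import pytest
from scipy import stats

import setopics as st
from setopics.distance import NearestNeighborTable
from setopics.evaluate import overall_recall

from conftest import make_record


def nn_from_pairs(pairs):
    return NearestNeighborTable([(a, b, 0.1) for a, b in pairs])


def exact_fisher_oracle(a, b, c, d):
    """Two-sided Fisher p-value in exact rational arithmetic.

    Enumerates all tables with the observed margins; integer comparison of
    unnormalized hypergeometric weights avoids any floating-point ties.
    """
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if min(r1, r2, c1, n - c1) == 0:
        return Fraction(1)
    w_obs = comb(r1, a) * comb(r2, c1 - a)
    total = sum(
        comb(r1, x) * comb(r2, c1 - x)
        for x in range(max(0, c1 - r2), min(r1, c1) + 1)
        if comb(r1, x) * comb(r2, c1 - x) <= w_obs
    )
    return Fraction(total, comb(n, c1))


class TestEvaluatePairs:
    def test_universal_shared_indication(self):
        records = [make_record(f"d{i}", {"pain"}) for i in range(3)]
        nn = nn_from_pairs([("d0", "d1"), ("d1", "d2"), ("d2", "d0")])
        a = st.evaluate_pairs(nn, records)
        assert all(x.success for x in a)
        assert overall_recall(a) == 1.0

    def test_disjoint_indications(self):
        records = [make_record(f"d{i}", {f"ind{i}"}) for i in range(3)]
        nn = nn_from_pairs([("d0", "d1"), ("d1", "d2"), ("d2", "d0")])
        assert overall_recall(st.evaluate_pairs(nn, records)) == 0.0

    def test_shared_sets_match_hand_intersections(self):
        records = [
            make_record("d1", {"pain", "fever"}),
            make_record("d2", {"pain", "rash"}),
            make_record("d3", {"rash"}),
            make_record("d4", {"cough"}),
        ]
        nn = nn_from_pairs([("d1", "d2"), ("d2", "d3"), ("d3", "d2"), ("d4", "d1")])
        got = {a.drug_id: a.shared_indications for a in st.evaluate_pairs(nn, records)}
        assert got == {
            "d1": frozenset({"pain"}),
            "d2": frozenset({"rash"}),
            "d3": frozenset({"rash"}),
            "d4": frozenset(),
        }

    def test_missing_record_rejected(self):
        with pytest.raises(ValueError, match="no record"):
            st.evaluate_pairs(nn_from_pairs([("d1", "dX")]), [make_record("d1")])


class TestRecallCurve:
    def test_constant_when_all_drugs_rich(self):
        records = [make_record(f"d{i}", {"a", "b", "c"}) for i in range(4)]
        nn = nn_from_pairs([("d0", "d1"), ("d1", "d0"), ("d2", "d3"), ("d3", "d2")])
        curve = st.recall_curve(st.evaluate_pairs(nn, records), 3)
        assert all(curve.points[m].recall == 1.0 for m in (1, 2, 3))

    def test_undefined_beyond_max_indications(self):
        records = [make_record("d1", {"a"}), make_record("d2", {"a"})]
        a = st.evaluate_pairs(nn_from_pairs([("d1", "d2"), ("d2", "d1")]), records)
        curve = st.recall_curve(a, 4)
        assert curve.points[1].recall == 1.0
        assert curve.points[2].recall is None
        assert curve.points[2].n_eligible == 0

    def test_matches_direct_subset_recomputation(self):
        records = [
            make_record("d1", {"a"}),
            make_record("d2", {"a", "b"}),
            make_record("d3", {"b", "c", "d"}),
            make_record("d4", {"b", "c", "x", "y"}),
        ]
        nn = nn_from_pairs([("d1", "d4"), ("d2", "d3"), ("d3", "d4"), ("d4", "d3")])
        a = st.evaluate_pairs(nn, records)
        curve = st.recall_curve(a, 4)
        for m in range(1, 5):
            subset = [x for x in a if x.n_indications >= m]
            assert curve.points[m].n_eligible == len(subset)
            if subset:
                assert curve.points[m].recall == pytest.approx(
                    sum(x.success for x in subset) / len(subset)
                )
        # only multi-indication drugs succeed -> recall increases with m
        recalls = [curve.points[m].recall for m in (1, 2, 3)]
        assert recalls == sorted(recalls)


def random_records(n, rng, pool=8, k=3):
    inds = [f"i{j}" for j in range(pool)]
    return [
        make_record(f"d{i:02d}", set(rng.choice(inds, size=rng.integers(1, k + 1),
                                                replace=False)))
        for i in range(n)
    ]


class TestNulls:
    def test_universal_indication_gives_one(self):
        records = [make_record(f"d{i}", {"pain"}) for i in range(5)]
        assert st.analytic_null(records, 1)[1] == 1.0
        null = st.random_null(records, 1, n_trials=50, seed=0)
        assert null.mean[1] == 1.0

    def test_disjoint_gives_zero(self):
        records = [make_record(f"d{i}", {f"i{i}"}) for i in range(5)]
        assert st.analytic_null(records, 1)[1] == 0.0
        assert st.random_null(records, 1, n_trials=50, seed=0).mean[1] == 0.0

    def test_single_sharing_pair_enumeration(self):
        records = [
            make_record("d1", {"pain"}),
            make_record("d2", {"pain"}),
            make_record("d3", {"other"}),
        ]
        assert st.analytic_null(records, 1)[1] == pytest.approx(1 / 3)

    def test_analytic_equals_full_enumeration(self, rng):
        """Oracle: average success over all ordered (drug, partner) pairs."""
        records = random_records(15, rng)
        expected = {}
        D = len(records)
        for m in (1, 2, 3):
            eligible = [r for r in records if len(r.indications) >= m]
            if not eligible:
                expected[m] = None
                continue
            tot = 0.0
            for r in eligible:
                hits = sum(
                    1 for o in records if o.drug_id != r.drug_id and r.indications & o.indications
                )
                tot += hits / (D - 1)
            expected[m] = tot / len(eligible)
        got = st.analytic_null(records, 3)
        for m in (1, 2, 3):
            assert got[m] == pytest.approx(expected[m], abs=1e-12)

    def test_random_null_within_three_standard_errors(self, rng):
        records = random_records(50, rng)
        null = st.random_null(records, 3, n_trials=10_000, seed=7)
        exact = st.analytic_null(records, 3)
        for m in (1, 2, 3):
            se = null.std[m] / np.sqrt(null.n_trials)
            assert abs(null.mean[m] - exact[m]) <= 3 * se + 1e-12

    def test_reproducible_from_seed(self, rng):
        records = random_records(10, rng)
        n1 = st.random_null(records, 2, n_trials=200, seed=3)
        n2 = st.random_null(records, 2, n_trials=200, seed=3)
        assert n1 == n2


class TestBwReplacements:
    def test_no_bw_drugs(self):
        records = [make_record("d1", {"a"}), make_record("d2", {"a"})]
        a = st.evaluate_pairs(nn_from_pairs([("d1", "d2"), ("d2", "d1")]), records)
        report = st.bw_replacements(a, records)
        assert report.n_bw_drugs == 0
        assert report.replacements == []

    def test_safer_alternative_pattern(self):
        records = [
            make_record("cefazolin", {"urinary tract infection"}, bw=True),
            make_record("cefuroxime", {"urinary tract infection"}, bw=False),
        ]
        a = st.evaluate_pairs(
            nn_from_pairs([("cefazolin", "cefuroxime"), ("cefuroxime", "cefazolin")]),
            records,
        )
        report = st.bw_replacements(a, records)
        assert report.n_bw_drugs == 1
        assert report.replacements == [
            ("cefazolin", "cefuroxime", frozenset({"urinary tract infection"}))
        ]

    def test_matches_independent_filter(self, rng):
        records = [
            make_record(f"d{i}", set(rng.choice(["a", "b", "c"], size=2, replace=False)),
                        bw=bool(rng.integers(0, 2)))
            for i in range(10)
        ]
        ids = [r.drug_id for r in records]
        pairs = [(ids[i], ids[(i + 1) % 10]) for i in range(10)]
        a = st.evaluate_pairs(nn_from_pairs(pairs), records)
        report = st.bw_replacements(a, records)
        by_id = {r.drug_id: r for r in records}
        expected = [
            (x.drug_id, x.neighbor_id, x.shared_indications)
            for x in a
            if by_id[x.drug_id].has_boxed_warning
            and not by_id[x.neighbor_id].has_boxed_warning
            and x.success
        ]
        assert report.replacements == expected
        assert report.n_bw_drugs == sum(r.has_boxed_warning for r in records)


class TestFisherExact:
    def test_balanced_table(self):
        assert st.fisher_exact_two_sided([[5, 5], [5, 5]]) == pytest.approx(1.0, abs=1e-12)

    def test_hand_enumerated_value(self):
        assert st.fisher_exact_two_sided([[8, 2], [1, 9]]) == pytest.approx(
            920 / 167960, abs=1e-12
        )

    def test_zero_margin_gives_one(self):
        assert st.fisher_exact_two_sided([[0, 0], [3, 4]]) == 1.0
        assert st.fisher_exact_two_sided([[2, 0], [3, 0]]) == 1.0

    def test_invalid_tables_rejected(self):
        with pytest.raises(ValueError):
            st.fisher_exact_two_sided([[0, 0], [0, 0]])
        with pytest.raises(ValueError):
            st.fisher_exact_two_sided([[-1, 1], [1, 1]])

    def test_symmetries(self, rng):
        for _ in range(20):
            a, b, c, d = (int(x) for x in rng.integers(0, 10, size=4))
            if a + b + c + d == 0:
                continue
            p = st.fisher_exact_two_sided([[a, b], [c, d]])
            assert st.fisher_exact_two_sided([[a, c], [b, d]]) == pytest.approx(p, abs=1e-12)
            assert st.fisher_exact_two_sided([[d, c], [b, a]]) == pytest.approx(p, abs=1e-12)

    def test_matches_scipy_cross_check(self, rng):
        for _ in range(25):
            a, b, c, d = (int(x) for x in rng.integers(0, 12, size=4))
            if a + b + c + d == 0:
                continue
            ours = st.fisher_exact_two_sided([[a, b], [c, d]])
            theirs = stats.fisher_exact([[a, b], [c, d]]).pvalue
            assert ours == pytest.approx(theirs, rel=1e-9, abs=1e-12)

    def test_matches_exact_rational_enumeration(self, rng):
        for _ in range(30):
            a, b, c, d = (int(x) for x in rng.integers(0, 8, size=4))
            if a + b + c + d == 0:
                continue
            assert st.fisher_exact_two_sided([[a, b], [c, d]]) == pytest.approx(
                float(exact_fisher_oracle(a, b, c, d)), abs=1e-12
            )


class TestAtcEnrichment:
    def test_single_category_p_one(self):
        records = [make_record(f"d{i}", {"a"}, atc="M") for i in range(4)]
        pairs = [(f"d{i}", f"d{(i + 1) % 4}") for i in range(4)]
        a = st.evaluate_pairs(nn_from_pairs(pairs), records)
        (res,) = st.atc_enrichment(a, records)
        assert res.category == "M"
        assert res.p_value == 1.0

    def test_enriched_category_table_assembly(self):
        # category M all succeed; category X all fail -> global rate 50%
        records = [make_record(f"m{i}", {"pain"}, atc="M") for i in range(10)]
        records += [make_record(f"x{i}", {f"u{i}"}, atc="X") for i in range(10)]
        pairs = [(f"m{i}", f"m{(i + 1) % 10}") for i in range(10)]
        pairs += [(f"x{i}", f"x{(i + 1) % 10}") for i in range(10)]
        a = st.evaluate_pairs(nn_from_pairs(pairs), records)
        results = {r.category: r for r in st.atc_enrichment(a, records)}
        m = results["M"]
        assert (m.n_success_in, m.n_fail_in, m.n_success_out, m.n_fail_out) == (10, 0, 0, 10)
        assert m.p_value == pytest.approx(
            st.fisher_exact_two_sided([[10, 0], [0, 10]]), abs=1e-15
        )
        assert m.p_value == pytest.approx(float(exact_fisher_oracle(10, 0, 0, 10)), abs=1e-12)

    def test_proportions_match_recount_and_sorted(self, rng):
        atcs = ["M", "J", "N"]
        records = [
            make_record(f"d{i:02d}", set(rng.choice(["a", "b", "c", "d"], size=2, replace=False)),
                        atc=atcs[i % 3])
            for i in range(18)
        ]
        ids = [r.drug_id for r in records]
        pairs = [(ids[i], ids[(i + 5) % 18]) for i in range(18)]
        a = st.evaluate_pairs(nn_from_pairs(pairs), records)
        results = st.atc_enrichment(a, records)
        by_id = {r.drug_id: r for r in records}
        for res in results:
            subset = [x for x in a if by_id[x.drug_id].atc_level1 == res.category]
            assert res.proportion == pytest.approx(
                sum(x.success for x in subset) / len(subset)
            )
        props = [r.proportion for r in results]
        assert props == sorted(props, reverse=True)

    def test_drugs_without_atc_excluded(self):
        records = [
            make_record("d1", {"a"}, atc="M"),
            make_record("d2", {"a"}, atc=None),
        ]
        a = st.evaluate_pairs(nn_from_pairs([("d1", "d2"), ("d2", "d1")]), records)
        results = st.atc_enrichment(a, records)
        assert [r.category for r in results] == ["M"]
        assert results[0].n_success_in + results[0].n_fail_in == 1
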