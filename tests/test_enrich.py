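import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from orthoenrich.enrich import (
    ContingencyTable,
    Correction,
    DETable,
    Direction,
    Method,
    Tail,
    adjust_pvalues,
    build_contingency,
    enrich_collection,
    fisher_pvalue,
    hypergeom_point_prob,
    logistic_fit,
    pct_sig_genes,
    read_de_table,
    wald_test,
)
from orthoenrich.genesets import GeneSet, GeneSetCollection
from orthoenrich.idmap import Namespace
from orthoenrich.simdata import SimConfig, gen_collection, gen_de_table


# ---------------------------------------------------------------------------
# independent oracles


def exact_point_prob(a, b, c, d) -> Fraction:
    """Big-integer hypergeometric point probability."""
    n = a + b + c + d
    return Fraction(math.comb(a + b, a) * math.comb(c + d, d), math.comb(n, a + c))


def exact_tail(a, b, c, d, tail) -> Fraction:
    """Exhaustive enumeration of all feasible tables at fixed margins."""
    n, s, k = a + b + c + d, a + b, a + c
    lo, hi = max(0, s + k - n), min(s, k)
    total = Fraction(0)
    for a2 in range(lo, hi + 1):
        if (tail == "over" and a2 >= a) or (tail == "under" and a2 <= a):
            total += exact_point_prob(a2, s - a2, k - a2, n - s - k + a2)
    return total


# ---------------------------------------------------------------------------
# DE table and contingency counts


class TestDETable:
    def test_duplicates_collapse_to_min_pvalue(self):
        de = DETable(
            pd.DataFrame(
                {"gene": ["g1", "g1"], "pvalue": [0.5, 0.01], "log2fc": [1, -1]}
            )
        )
        assert len(de) == 1
        assert de.pvalues[0] == 0.01
        assert de.n_duplicates_collapsed == 1

    def test_zero_pvalue_clamped_positive(self):
        de = DETable(pd.DataFrame({"gene": ["g1"], "pvalue": [0.0], "log2fc": [1]}))
        assert de.pvalues[0] > 0

    def test_tsv_reader_ignores_extra_columns(self, tmp_path):
        path = tmp_path / "de.tsv"
        path.write_text("gene\tpvalue\tlog2fc\tbaseMean\ng1\t0.1\t2.0\t55\n")
        de = read_de_table(path)
        assert len(de) == 1


class TestBuildContingency:
    def test_hand_counted_four_gene_universe(self, toy_de, toy_set):
        # universe g1..g4; set {g1,g2}; significant {g1,g3}
        t = build_contingency(toy_de, toy_set, sig_threshold=0.05)
        assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)

    def test_up_direction_with_no_upregulated_sig_genes(self, toy_de):
        geneset = GeneSet("s", "s", frozenset({"g3", "g4"}))
        # only g3 is significant and it is downregulated
        t = build_contingency(toy_de, geneset, direction=Direction.UP)
        assert t.a == 0 and t.b == 1

    def test_zero_log2fc_counts_in_neither_direction(self):
        de = DETable(pd.DataFrame({"gene": ["g1"], "pvalue": [0.001], "log2fc": [0.0]}))
        s = GeneSet("s", "s", frozenset({"g1"}))
        assert build_contingency(de, s, direction=Direction.UP).a == 0
        assert build_contingency(de, s, direction=Direction.DOWN).a == 0

    def test_membership_restricted_to_universe(self, toy_de):
        s = GeneSet("s", "s", frozenset({"g1", "not_measured"}))
        t = build_contingency(toy_de, s)
        assert t.set_size == 1 and t.n == 4

    def test_matches_brute_force_double_loop(self, rng):
        cfg = SimConfig(n_zfish_genes=150, n_sets=10, set_size_range=(5, 30), seed=2)
        coll = gen_collection(cfg)
        de = gen_de_table(cfg, collection=coll)
        for s in coll.sets[:5]:
            for direction in Direction:
                t = build_contingency(de, s, 0.1, direction)
                a = b = c = d = 0
                for gene, p, fc in de.frame.itertuples(index=False):
                    sig = p < 0.1 and (
                        direction == Direction.NONDIRECTIONAL
                        or (direction == Direction.UP and fc > 0)
                        or (direction == Direction.DOWN and fc < 0)
                    )
                    member = gene in s.members
                    a += member and sig
                    b += (not member) and sig
                    c += member and not sig
                    d += (not member) and not sig
                assert (t.a, t.b, t.c, t.d) == (a, b, c, d)


# ---------------------------------------------------------------------------
# hypergeometric / Fisher


class TestHypergeomPointProb:
    def test_unit_table_is_two_thirds(self):
        assert hypergeom_point_prob(ContingencyTable(1, 1, 1, 1)) == pytest.approx(
            2 / 3, abs=1e-12
        )

    def test_whole_universe_set_has_probability_one(self):
        assert hypergeom_point_prob(ContingencyTable(3, 0, 2, 0)) == pytest.approx(1.0)

    def test_balanced_five_table_matches_big_integer_arithmetic(self):
        expected = Fraction(63504, 184756)  # = exact_point_prob(5,5,5,5)
        assert exact_point_prob(5, 5, 5, 5) == expected
        got = hypergeom_point_prob(ContingencyTable(5, 5, 5, 5))
        assert got == pytest.approx(float(expected), rel=1e-12)


class TestFisherPvalue:
    def test_a_zero_over_tail_is_one(self):
        assert fisher_pvalue(ContingencyTable(0, 5, 5, 10), Tail.OVER) == 1.0

    def test_whole_universe_set_is_one(self):
        assert fisher_pvalue(ContingencyTable(4, 0, 6, 0), Tail.OVER) == 1.0

    def test_enumeration_oracle_on_8_2_2_8(self):
        t = ContingencyTable(8, 2, 2, 8)
        expected = float(exact_tail(8, 2, 2, 8, "over"))
        assert fisher_pvalue(t, Tail.OVER) == pytest.approx(expected, rel=1e-12)

    def test_agrees_with_scipy_one_sided(self):
        from scipy.stats import fisher_exact

        t = ContingencyTable(7, 3, 12, 40)
        ref = fisher_exact([[t.a, t.b], [t.c, t.d]], alternative="greater")[1]
        assert fisher_pvalue(t, Tail.OVER) == pytest.approx(ref, rel=1e-9)


@given(
    st.integers(0, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15)
)
def test_fisher_tail_overlap_identity(a, b, c, d):
    """P_over + P_under = 1 + point probability on every table."""
    if a + b + c + d == 0:
        return
    t = ContingencyTable(a, b, c, d)
    total = fisher_pvalue(t, Tail.OVER) + fisher_pvalue(t, Tail.UNDER)
    assert total == pytest.approx(1 + hypergeom_point_prob(t), rel=1e-9)


@given(st.integers(2, 40), st.data())
def test_fisher_matches_enumeration_on_random_margins(n, data):
    s = data.draw(st.integers(0, n))
    k = data.draw(st.integers(0, n))
    lo, hi = max(0, s + k - n), min(s, k)
    a = data.draw(st.integers(lo, hi))
    t = ContingencyTable(a, s - a, k - a, n - s - k + a)
    for tail in ("over", "under"):
        assert fisher_pvalue(t, tail) == pytest.approx(
            float(exact_tail(t.a, t.b, t.c, t.d, tail)), rel=1e-11
        )


# ---------------------------------------------------------------------------
# logistic / Wald


class TestLogisticFit:
    def fixed_toy(self):
        x = np.array([0.1, 0.4, 0.9, 1.3, 2.2, 2.9, 3.4, 4.1, 5.0, 6.3])
        y = np.array([0, 0, 0, 1, 0, 1, 1, 0, 1, 1], dtype=float)
        return x, y

    def test_matches_reference_glm_on_fixed_toy(self):
        import statsmodels.api as sm

        x, y = self.fixed_toy()
        fit = logistic_fit(x, y)
        ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit(tol=1e-12)
        assert fit.beta == pytest.approx(ref.params[1], abs=1e-6)
        assert fit.se_beta == pytest.approx(ref.bse[1], abs=1e-6)

    def test_shift_absorbed_by_intercept(self):
        x, y = self.fixed_toy()
        f0 = logistic_fit(x, y)
        f1 = logistic_fit(x + 7.5, y)
        assert f1.beta == pytest.approx(f0.beta, abs=1e-8)
        assert f1.alpha == pytest.approx(f0.alpha - 7.5 * f0.beta, abs=1e-7)

    def test_symmetric_class_x_distributions_give_zero_beta(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        fit = logistic_fit(x, y)
        assert fit.beta == pytest.approx(0.0, abs=1e-8)

    def test_single_class_membership_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            logistic_fit([1.0, 2.0], [1, 1])

    def test_complete_separation_flagged_not_fitted(self):
        fit = logistic_fit([0.0, 1.0, 5.0, 6.0], [0, 0, 1, 1])
        assert not fit.converged
        assert "separation" in fit.message

    def test_reference_agreement_on_random_datasets(self, rng):
        import statsmodels.api as sm

        for _ in range(20):
            n = int(rng.integers(50, 300))
            x = -np.log(rng.random(n))
            y = np.zeros(n)
            y[rng.choice(n, max(3, n // 8), replace=False)] = 1
            fit = logistic_fit(x, y)
            ref = sm.GLM(y, sm.add_constant(x), family=sm.families.Binomial()).fit(
                tol=1e-12
            )
            assert fit.beta == pytest.approx(ref.params[1], abs=1e-6)
            assert fit.se_beta == pytest.approx(ref.bse[1], abs=1e-6)


class TestWaldTest:
    def test_zero_beta_gives_unit_pvalue(self):
        x = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        y = np.array([1, 1, 1, 0, 0, 0], dtype=float)
        W, p, enriched = wald_test(logistic_fit(x, y))
        assert W == pytest.approx(0.0, abs=1e-7)
        assert p == pytest.approx(1.0, abs=1e-6)
        assert not enriched

    def test_chi2_quantile_anchor(self):
        # a Wald ratio of 1.959964 is the two-sided 5% boundary
        from scipy.stats import chi2

        assert chi2.sf(1.959964 ** 2, 1) == pytest.approx(0.05, abs=1e-6)

    def test_pvalue_invariant_under_positive_scaling_and_shift(self, rng):
        x = -np.log(rng.random(120))
        y = np.zeros(120)
        y[rng.choice(120, 25, replace=False)] = 1
        p0 = logistic_fit(x, y).pvalue
        for transform in (lambda v: 3.7 * v, lambda v: v + 11.0, lambda v: 0.01 * v):
            assert logistic_fit(transform(x), y).pvalue == pytest.approx(p0, abs=1e-10)

    def test_nonconverged_fit_propagates_diagnostic(self):
        from orthoenrich.enrich import ConvergenceError

        fit = logistic_fit([0.0, 1.0, 5.0, 6.0], [0, 0, 1, 1])
        with pytest.raises(ConvergenceError, match="separation"):
            wald_test(fit)


# ---------------------------------------------------------------------------
# adjustment, percentages, collection-level contract


class TestAdjustPvalues:
    def test_single_pvalue_unchanged(self):
        for method in Correction:
            assert adjust_pvalues([0.03], method)[0] == pytest.approx(0.03)

    def test_equal_pvalues_unchanged_by_bh(self):
        out = adjust_pvalues([0.2, 0.2, 0.2], Correction.BH)
        assert np.allclose(out, 0.2)

    def test_bh_hand_step_up_oracle(self):
        out = adjust_pvalues([0.01, 0.02, 0.03, 0.04], Correction.BH)
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_output_dominates_input_and_stays_in_unit_interval(self, rng):
        p = rng.random(50) * 0.999 + 1e-6
        for method in (Correction.BH, Correction.BONFERRONI):
            out = adjust_pvalues(p, method)
            assert np.all(out >= p) and np.all(out <= 1.0)

    def test_empty_vector_passes_through(self):
        assert adjust_pvalues([], Correction.BH).size == 0

    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30))
    def test_bh_monotone_in_pointwise_order(self, p):
        p = np.asarray(p)
        larger = np.clip(p * 1.5, None, 1.0)
        assert np.all(adjust_pvalues(larger, "bh") >= adjust_pvalues(p, "bh") - 1e-12)


class TestPctSigGenes:
    def test_half_significant(self, toy_de, toy_set):
        assert pct_sig_genes(toy_de, toy_set) == pytest.approx(50.0)

    def test_zero_when_no_significant_members(self, toy_de):
        s = GeneSet("s", "s", frozenset({"g2", "g4"}))
        assert pct_sig_genes(toy_de, s) == 0.0

    def test_matches_recount_oracle(self, rng):
        cfg = SimConfig(n_zfish_genes=100, n_sets=5, set_size_range=(5, 20), seed=4)
        coll = gen_collection(cfg)
        de = gen_de_table(cfg, collection=coll)
        for s in coll:
            in_universe = [g for g in s.members if g in set(de.genes)]
            sig = {
                g
                for g, p, fc in de.frame.itertuples(index=False)
                if p < 0.05 and g in s.members
            }
            expected = 100 * len(sig) / len(in_universe) if in_universe else 0.0
            assert pct_sig_genes(de, s) == pytest.approx(expected)


class TestEnrichCollection:
    @pytest.fixture
    def setup(self):
        cfg = SimConfig(n_zfish_genes=400, n_sets=10, set_size_range=(10, 40), seed=6)
        coll = gen_collection(cfg)
        de = gen_de_table(cfg, collection=coll)
        return de, coll

    def test_single_set_adjustment_is_identity(self, setup):
        de, coll = setup
        sid = coll.ids[0]
        for correction in Correction:
            table = enrich_collection(de, coll, subset_ids=[sid], correction=correction)
            assert len(table) == 1
            assert table["adj_pvalue"].iloc[0] == pytest.approx(table["pvalue"].iloc[0])

    def test_subset_restricts_and_adjusts_within_subset(self, setup):
        de, coll = setup
        wanted = coll.ids[:3]
        table = enrich_collection(de, coll, subset_ids=wanted, correction=Correction.BH)
        assert sorted(table["set_id"]) == sorted(wanted)
        expected = adjust_pvalues(
            table.sort_values("pvalue")["pvalue"].to_numpy(), "bh"
        )
        assert np.allclose(np.sort(table["adj_pvalue"]), np.sort(expected))

    def test_unknown_subset_id_rejected(self, setup):
        de, coll = setup
        with pytest.raises(ValueError, match="not in collection"):
            enrich_collection(de, coll, subset_ids=["nope"])

    def test_output_sorted_by_pvalue_then_set_id(self, setup):
        de, coll = setup
        for method in Method:
            table = enrich_collection(de, coll, method=method)
            keys = list(zip(table["pvalue"], table["set_id"]))
            assert keys == sorted(keys)

    def test_degenerate_sets_skipped(self, setup):
        de, coll = setup
        phantom = GeneSet("dre99999", "absent", frozenset({"no_such_gene"}))
        extended = GeneSetCollection(
            coll.sets + [phantom], namespace=coll.namespace, organism=coll.organism
        )
        table = enrich_collection(de, extended)
        assert "dre99999" not in set(table["set_id"])

    def test_empty_after_filtering_raises(self, toy_de):
        phantom = GeneSetCollection(
            [GeneSet("s", "s", frozenset({"no_such_gene"}))], namespace=Namespace.SYMBOL
        )
        with pytest.raises(ValueError, match="no testable"):
            enrich_collection(toy_de, phantom)

    def test_adj_pvalue_never_below_raw(self, setup):
        de, coll = setup
        table = enrich_collection(de, coll, correction=Correction.BONFERRONI)
        assert np.all(table["adj_pvalue"].to_numpy() >= table["pvalue"].to_numpy())

    def test_directional_runs_use_masked_evidence(self, setup):
        de, coll = setup
        up = enrich_collection(de, coll, method=Method.LOGISTIC, direction=Direction.UP)
        down = enrich_collection(de, coll, method=Method.LOGISTIC, direction=Direction.DOWN)
        merged = up.merge(down, on="set_id", suffixes=("_up", "_down"))
        assert not np.allclose(merged["pvalue_up"], merged["pvalue_down"])
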