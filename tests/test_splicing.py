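"""Fisher exact test, Bayesian sign-error rate and the exon-variant
filter cascade."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import cardiosplice as cs
from cardiosplice.splicing import (FISHER_TIE_RTOL, build_contingency,
                                   call_exon_variants, exon_rpkm_filter,
                                   fisher_exact_two_sided_batch)


def fisher_oracle(a, b, c, d):
    """Exact-rational enumeration over all tables with the same margins."""
    n, r1, c1 = a + b + c + d, a + b, a + c
    if r1 in (0, n) or c1 in (0, n):
        return 1.0
    amin, amax = max(0, r1 + c1 - n), min(r1, c1)
    nums = [math.comb(r1, k) * math.comb(n - r1, c1 - k)
            for k in range(amin, amax + 1)]
    obs = nums[a - amin]
    total = sum(x for x in nums if Fraction(x, obs) <= 1 + Fraction(1, 10**7))
    return float(Fraction(total, math.comb(n, c1)))


# -- Fisher -----------------------------------------------------------------

def test_fisher_examples():
    assert cs.fisher_exact_two_sided(((5, 5), (5, 5))) == 1.0
    p = cs.fisher_exact_two_sided(((10, 0), (0, 10)))
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-12)
    assert cs.fisher_exact_two_sided(((0, 0), (3, 4))) == 1.0   # zero margin
    with pytest.raises(ValueError):
        cs.fisher_exact_two_sided(((-1, 2), (3, 4)))


@settings(deadline=None, derandomize=True, max_examples=200)
@given(st.tuples(*[st.integers(0, 25)] * 4))
def test_fisher_matches_enumeration_and_transpose(table):
    a, b, c, d = table
    p = cs.fisher_exact_two_sided(((a, b), (c, d)))
    assert p == pytest.approx(fisher_oracle(a, b, c, d), abs=1e-12)
    assert p == pytest.approx(cs.fisher_exact_two_sided(((a, c), (b, d))),
                              abs=1e-12)


def test_fisher_agrees_with_scipy_library():
    rng = np.random.default_rng(3)
    for _ in range(200):
        a, b, c, d = rng.integers(0, 40, size=4)
        ours = cs.fisher_exact_two_sided(((a, b), (c, d)))
        ref = stats.fisher_exact([[a, b], [c, d]])[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)


def test_fisher_upper_tail():
    # enrichment orientation: all hits in row 1
    assert cs.fisher_exact_upper(((10, 0), (0, 10))) == \
        pytest.approx(1 / math.comb(20, 10), rel=1e-9)
    assert cs.fisher_exact_upper(((0, 10), (10, 0))) == pytest.approx(1.0)


# -- Bayes error ------------------------------------------------------------

def test_bayes_error_symmetry_and_extremes():
    assert cs.bayes_error_rate(((7, 7), (13, 13))) == pytest.approx(0.5, abs=1e-6)
    assert cs.bayes_error_rate(((0, 50), (50, 0))) < 1e-10
    with pytest.raises(ValueError):
        cs.bayes_error_rate(((1, 1), (1, 1)), method="bogus")


@pytest.mark.parametrize("table", [
    ((30, 90), (270, 210)),
    ((12, 3), (40, 55)),
    ((120, 150), (1200, 1180)),
    ((5, 9), (20, 16)),
])
def test_bayes_quadrature_matches_monte_carlo(table):
    e_quad = cs.bayes_error_rate(table)
    e_mc = cs.bayes_error_rate(table, method="mc", n_draws=1_000_000, rng=99)
    assert e_quad == pytest.approx(e_mc, abs=0.01)


def test_bayes_error_direction_invariance():
    # swapping conditions swaps the apparent direction, not the error
    e1 = cs.bayes_error_rate(((12, 30), (90, 70)))
    e2 = cs.bayes_error_rate(((30, 12), (70, 90)))
    assert e1 == pytest.approx(e2, abs=1e-9)


# -- cascade ----------------------------------------------------------------

def test_exon_rpkm_filter_either_condition_suffices():
    rpkm = pd.DataFrame({"c1": [9.9, 3.0, 0.5], "c2": [9.9, 3.0, 0.5],
                         "t1": [9.9, 40.0, 0.1], "t2": [9.9, 40.0, 0.1]},
                        index=["low_both", "high_one_side", "silent"])
    keep = exon_rpkm_filter(rpkm, ["c1", "c2"], ["t1", "t2"])
    assert list(keep) == ["high_one_side"]
    assert len(exon_rpkm_filter(rpkm, ["c1", "c2"], ["t1", "t2"],
                                threshold=0.0)) == 3


def two_gene_counts():
    exon_counts = pd.DataFrame({
        "c1": [10, 90, 50], "c2": [12, 88, 50], "c3": [8, 92, 50],
        "t1": [30, 70, 50], "t2": [28, 72, 50], "t3": [32, 68, 50],
    }, index=["g1.e1", "g1.e2", "g2.e1"])
    gene_map = pd.Series({"g1.e1": "g1", "g1.e2": "g1", "g2.e1": "g2"})
    gene_counts = exon_counts.groupby(gene_map).sum()
    return exon_counts, gene_counts, gene_map


def test_build_contingency_pools_replicates():
    exon_counts, gene_counts, gene_map = two_gene_counts()
    tab = build_contingency(exon_counts, gene_counts, gene_map,
                            ["c1", "c2", "c3"], ["t1", "t2", "t3"])
    row = tab.loc["g1.e1"]
    assert (row.a, row.b, row.c, row.d) == (30, 90, 270, 210)
    # single-exon gene has no rest-of-gene and is not testable
    assert "g2.e1" not in tab.index


def test_build_contingency_degenerate_and_invalid():
    exon_counts = pd.DataFrame({"c1": [5, 5], "t1": [0, 0]},
                               index=["g.e1", "g.e2"])
    gene_map = pd.Series({"g.e1": "g", "g.e2": "g"})
    gene_counts = exon_counts.groupby(gene_map).sum()
    tab = build_contingency(exon_counts, gene_counts, gene_map, ["c1"], ["t1"])
    assert len(tab) == 0          # zero treatment margin
    with pytest.raises(ValueError):
        build_contingency(exon_counts, gene_counts * 0, gene_map,
                          ["c1"], ["t1"])


def test_call_exon_variants_filters_and_direction():
    exon_counts, gene_counts, gene_map = two_gene_counts()
    tab = build_contingency(exon_counts, gene_counts, gene_map,
                            ["c1", "c2", "c3"], ["t1", "t2", "t3"])
    alt = {"g1.e1": frozenset({"cassetteExon"}), "g1.e2": frozenset()}
    calls = call_exon_variants(tab, alt, "PAH")
    assert list(calls["exon_id"]) == ["g1.e1"]    # e2 lacks a knownAlt label
    assert calls.iloc[0]["direction"] == "inclusion"   # usage 0.1 -> 0.3
    assert calls.iloc[0]["fisher_p"] < 0.05
    assert calls.iloc[0]["bayes_e"] <= 0.1
    # the Bayes-error gate alone can veto a Fisher-significant exon
    assert len(call_exon_variants(tab, alt, "PAH", e_max=0.0)) == 0
    # and an exon with no knownAlt label is never reported
    assert len(call_exon_variants(tab, {"g1.e1": frozenset()}, "PAH")) == 0


def test_variant_calls_respect_all_gates(study_variants):
    calls = study_variants
    assert (calls["fisher_p"] < 0.05).all()
    assert (calls["bayes_e"] <= 0.1).all()
    assert (calls["alt_types"].str.len() > 0).all()
    assert set(calls["contrast"]) <= {"PAH", "PHH"}


def test_null_fisher_rate_is_nominal_or_below(null_study):
    fx = null_study
    mapped = fx.samples.set_index("sample_id")["mapped_reads_total"]
    rpkm_e = cs.compute_rpkm(fx.exon_counts, fx.annotation.exon_lengths(),
                             mapped)
    sam = fx.samples
    ctrl = sam.loc[sam.condition == "sham", "sample_id"].tolist()
    trt = sam.loc[sam.condition == "TAC", "sample_id"].tolist()
    testable = exon_rpkm_filter(rpkm_e, ctrl, trt)
    tab = build_contingency(fx.exon_counts, fx.gene_counts,
                            fx.annotation.exon_gene_map(), ctrl, trt,
                            exons=testable)
    p = fisher_exact_two_sided_batch(tab["a"].to_numpy(), tab["b"].to_numpy(),
                                     tab["c"].to_numpy(), tab["d"].to_numpy())
    n = len(p)
    band = 2.58 * np.sqrt(0.05 * 0.95 / n)
    assert (p < 0.05).mean() <= 0.05 + band


# -- summaries --------------------------------------------------------------

def test_summarize_variant_types():
    calls = pd.DataFrame({
        "exon_id": ["e1", "e2", "e3"], "gene_id": ["g1", "g2", "g3"],
        "direction": ["inclusion", "inclusion", "exclusion"],
        "alt_types": ["altPromoter", "altPromoter", "altPromoter"],
        "contrast": ["PAH"] * 3,
    })
    s = cs.summarize_variant_types(calls)
    assert s["proportion"].tolist() == [1.0]
    assert s.iloc[0][["n_inclusion", "n_exclusion"]].tolist() == [2, 1]
    # an exon with two labels splits its weight
    calls.loc[2, "alt_types"] = "cassetteExon,retainedIntron"
    s = cs.summarize_variant_types(calls)
    by_type = s.set_index("alt_type")["weight"]
    assert by_type["altPromoter"] == 2.0
    assert by_type["cassetteExon"] == by_type["retainedIntron"] == 0.5
    assert s["proportion"].sum() == pytest.approx(1.0)
    assert len(cs.summarize_variant_types(calls.iloc[:0])) == 0
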