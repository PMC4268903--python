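"""Confusion-count rates, Fisher's exact test and Pearson's chi-square."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st

from maskqc import (
    ConfusionCounts,
    DegenerateTableError,
    Table2x2,
    UndefinedRateError,
    chi_square,
    confusion_from_calls,
    fisher_exact,
    fn_rate,
    fp_rate,
    percent,
    round_p,
)

# --- rates ----------------------------------------------------------------------


def test_fp_rate_examples():
    assert fp_rate(ConfusionCounts(tp=35, fp=6, tn=80, fn=2)) == pytest.approx(6 / 86)
    assert percent(fp_rate(ConfusionCounts(35, 6, 80, 2))) == 7.0
    assert fp_rate(ConfusionCounts(35, 0, 86, 2)) == 0.0
    assert fp_rate(ConfusionCounts(0, 0, 1, 0)) == 0.0


def test_fn_rate_examples():
    # catalogue-scale counts: 104,858 recovered of 112,061 known positives
    c = ConfusionCounts(tp=104_858, fp=0, tn=0, fn=112_061 - 104_858)
    assert percent(fn_rate(c)) == 6.4
    assert fn_rate(ConfusionCounts(37, 0, 0, 0)) == 0.0
    assert fn_rate(ConfusionCounts(35, 0, 0, 2)) == pytest.approx(2 / 37)


def test_rates_undefined_on_zero_denominator():
    with pytest.raises(UndefinedRateError):
        fp_rate(ConfusionCounts(tp=1, fp=0, tn=0, fn=1))
    with pytest.raises(UndefinedRateError):
        fn_rate(ConfusionCounts(tp=0, fp=1, tn=1, fn=0))


@given(
    st.integers(0, 500), st.integers(0, 500), st.integers(0, 500),
    st.integers(0, 500), st.integers(1, 7),
)
def test_rates_bounded_and_scale_invariant(tp, fp, tn, fn, k):
    c = ConfusionCounts(tp, fp, tn, fn)
    scaled = ConfusionCounts(tp * k, fp * k, tn * k, fn * k)
    if c.negatives > 0:
        assert 0.0 <= fp_rate(c) <= 1.0
        assert fp_rate(scaled) == pytest.approx(fp_rate(c))
    if c.positives > 0:
        assert 0.0 <= fn_rate(c) <= 1.0
        assert fn_rate(scaled) == pytest.approx(fn_rate(c))


# --- Fisher's exact test ----------------------------------------------------------


@pytest.mark.parametrize(
    "table,p_printed",
    [
        ((6, 80, 0, 86), 0.014),
        ((2, 84, 0, 86), 0.25),
        ((6, 80, 2, 84), 0.14),
    ],
)
def test_fisher_one_sided_matches_published_comparisons(table, p_printed):
    result = fisher_exact(Table2x2(*table), "greater")
    assert round_p(result.p_value) == p_printed


def test_fisher_single_feasible_table():
    for sided in ("greater", "less", "two_sided"):
        assert fisher_exact(Table2x2(0, 86, 0, 86), sided).p_value == pytest.approx(1.0)


def test_fisher_rejects_all_zero_table():
    with pytest.raises(DegenerateTableError):
        Table2x2(0, 0, 0, 0)


table_strategy = st.tuples(
    st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30)
).filter(lambda t: sum(t) > 0)


@given(table_strategy, st.sampled_from(["greater", "less", "two_sided"]))
def test_fisher_matches_scipy(cells, sided):
    ours = fisher_exact(Table2x2(*cells), sided).p_value
    scipy_alt = {"greater": "greater", "less": "less", "two_sided": "two-sided"}[sided]
    ref = scipy.stats.fisher_exact(
        [[cells[0], cells[1]], [cells[2], cells[3]]], alternative=scipy_alt
    )[1]
    assert ours == pytest.approx(ref, rel=1e-8, abs=1e-12)


@given(table_strategy)
def test_fisher_tails_overlap_on_observed_mass(cells):
    t = Table2x2(*cells)
    assert (
        fisher_exact(t, "greater").p_value + fisher_exact(t, "less").p_value
        >= 1.0 - 1e-12
    )


@given(table_strategy, st.sampled_from(["greater", "less", "two_sided"]))
def test_fisher_invariant_under_row_and_column_swap(cells, sided):
    a, b, c, d = cells
    p1 = fisher_exact(Table2x2(a, b, c, d), sided).p_value
    p2 = fisher_exact(Table2x2(d, c, b, a), sided).p_value  # both rows and cols swapped
    assert p1 == pytest.approx(p2, rel=1e-10)


# --- chi-square --------------------------------------------------------------------


def test_chi_square_zero_statistic_iff_independent():
    r = chi_square([[10, 10], [10, 10]])
    assert r.statistic == 0.0 and r.p_value == pytest.approx(1.0) and r.df == 1


def test_chi_square_goodness_of_fit_closed_form():
    # observed [1,2,3] vs uniform mean 2: stat = (1+0+1)/2 = 1.0, df 2
    r = chi_square([1, 2, 3])
    assert r.statistic == pytest.approx(1.0)
    assert r.df == 2
    assert r.p_value == pytest.approx(scipy.stats.chi2.sf(1.0, 2))


@given(
    st.lists(
        st.lists(st.integers(1, 50), min_size=2, max_size=4),
        min_size=2, max_size=3,
    ).filter(lambda rows: len({len(r) for r in rows}) == 1)
)
def test_chi_square_matches_scipy_contingency(rows):
    ours = chi_square(rows)
    stat, p, df, _ = scipy.stats.chi2_contingency(rows, correction=False)
    assert ours.statistic == pytest.approx(stat)
    assert ours.df == df
    assert ours.p_value == pytest.approx(p)


def test_chi_square_yates_shrinks_statistic():
    plain = chi_square([[12, 5], [3, 14]])
    corrected = chi_square([[12, 5], [3, 14]], yates=True)
    assert corrected.statistic < plain.statistic
    assert corrected.p_value > plain.p_value


def test_chi_square_degenerate_tables():
    with pytest.raises(DegenerateTableError):
        chi_square([[0, 0], [1, 2]])
    with pytest.raises(DegenerateTableError):
        chi_square([[0, 0], [0, 0]])


def test_chi_square_p_monotone_in_statistic():
    weak = chi_square([[11, 9], [9, 11]])
    strong = chi_square([[18, 2], [2, 18]])
    assert strong.statistic > weak.statistic
    assert strong.p_value < weak.p_value


# --- confusion bookkeeping -----------------------------------------------------------


def test_confusion_from_calls_cases():
    pos, neg = {1, 2, 3}, {10, 11}
    perfect = confusion_from_calls({1, 2, 3}, pos, neg)
    assert (perfect.tp, perfect.fp, perfect.tn, perfect.fn) == (3, 0, 2, 0)

    nothing = confusion_from_calls(set(), pos, neg)
    assert (nothing.tp, nothing.fp, nothing.tn, nothing.fn) == (0, 0, 2, 3)

    pathological = confusion_from_calls(neg, pos, neg)
    assert (pathological.tp, pathological.fp) == (0, 2)

    ignored = confusion_from_calls({99}, pos, neg)  # outside both truth sets
    assert (ignored.tp, ignored.fp) == (0, 0)


def test_confusion_rejects_overlapping_truth():
    with pytest.raises(ValueError):
        confusion_from_calls(set(), {1, 2}, {2, 3})


def test_display_rounding():
    assert round_p(0.014278) == 0.014
    assert round_p(0.24853) == 0.25
    assert round_p(0.13868) == 0.14
    assert percent(6 / 86) == 7.0
    assert percent(0.0) == 0.0
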