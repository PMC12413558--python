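"""Kappa, banding, exact McNemar and t-intervals against independent oracles."""

import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.metrics import cohen_kappa_score
from statsmodels.stats.contingency_tables import mcnemar as sm_mcnemar

from planeqc import (
    PairedRatings2x2,
    UndefinedKappaError,
    categorize_kappa,
    cohen_kappa,
    concordance_table,
    mcnemar_exact,
    mean_ci_t,
)
from planeqc.io import ValidationError

tables = st.tuples(
    st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12)
).filter(lambda t: sum(t) >= 1)


def expand(t: PairedRatings2x2):
    """Reconstruct the paired rating vectors behind a 2x2 count table."""
    ref = [1] * t.a + [1] * t.b + [0] * t.c + [0] * t.d
    rater = [1] * t.a + [0] * t.b + [1] * t.c + [0] * t.d
    return ref, rater


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((19, 0, 0, 11), 1.0),  # perfect agreement
        ((18, 1, 1, 10), 0.8564593301435407),  # po=28/30, pe=482/900
        ((9, 9, 1, 1), 0.0),  # po equals chance agreement 0.5
    ],
)
def test_kappa_point_estimates(cells, expected):
    assert cohen_kappa(PairedRatings2x2(*cells)).kappa == pytest.approx(expected)


def test_kappa_undefined_when_both_raters_constant():
    with pytest.raises(UndefinedKappaError):
        cohen_kappa(PairedRatings2x2(30, 0, 0, 0))


@given(tables)
def test_kappa_matches_sklearn_on_expanded_vectors(cells):
    t = PairedRatings2x2(*cells)
    ref, rater = expand(t)
    try:
        result = cohen_kappa(t)
    except UndefinedKappaError:
        assert t.b == t.c == 0 and (t.a == 0 or t.d == 0)
        return
    assert result.kappa == pytest.approx(cohen_kappa_score(ref, rater), abs=1e-12)
    lo, hi = result.ci95
    assert lo <= result.kappa <= hi
    assert -1.0 <= lo <= hi <= 1.0
    assert result.category == categorize_kappa(max(-1.0, min(1.0, result.kappa)))


@given(tables)
def test_kappa_symmetries(cells):
    a, b, c, d = cells
    try:
        k1 = cohen_kappa(PairedRatings2x2(a, b, c, d)).kappa
    except UndefinedKappaError:
        return
    # swapping raters (b <-> c) and relabeling classes (a <-> d, b <-> c)
    assert cohen_kappa(PairedRatings2x2(a, c, b, d)).kappa == pytest.approx(k1)
    assert cohen_kappa(PairedRatings2x2(d, c, b, a)).kappa == pytest.approx(k1)
    if b == 0 and c == 0:
        assert k1 == pytest.approx(1.0)
    elif k1 == pytest.approx(1.0):
        assert b == 0 and c == 0


@pytest.mark.parametrize(
    "kappa, band",
    [
        (0.930, "very good"),
        (0.870, "very good"),
        (0.789, "good"),
        (0.783, "good"),
        (0.760, "good"),
        (0.667, "good"),
        (0.651, "good"),
        (0.615, "good"),
        (0.609, "good"),
        (0.516, "moderate"),
        (0.444, "moderate"),
        (0.429, "moderate"),
        (0.348, "weak"),
        (-0.047, "poor"),
        (0.20, "poor"),
        (0.80, "good"),
        (1.0, "very good"),
        (-1.0, "poor"),
    ],
)
def test_banding(kappa, band):
    assert categorize_kappa(kappa) == band


def test_banding_rejects_out_of_range():
    with pytest.raises(ValidationError):
        categorize_kappa(1.2)


@pytest.mark.parametrize(
    "cells, expected",
    [
        ((10, 0, 0, 5), 1.0),
        ((10, 1, 1, 5), 1.0),  # 2*P(X<=1 | n=2) caps at 1
        ((0, 5, 0, 25), 0.0625),  # 2*(1/2)^5
    ],
)
def test_mcnemar_exact_examples(cells, expected):
    assert mcnemar_exact(PairedRatings2x2(*cells)) == pytest.approx(expected)


@given(tables)
def test_mcnemar_matches_binomial_enumeration_and_statsmodels(cells):
    t = PairedRatings2x2(*cells)
    m = t.b + t.c
    if m == 0:
        expected = Fraction(1)
    else:
        tail = sum(
            Fraction(math.comb(m, x), 2**m) for x in range(min(t.b, t.c) + 1)
        )
        expected = min(Fraction(1), 2 * tail)
    got = mcnemar_exact(t)
    assert got == pytest.approx(float(expected), abs=1e-12)
    if m > 0:
        sm = sm_mcnemar([[t.a, t.b], [t.c, t.d]], exact=True).pvalue
        assert got == pytest.approx(float(sm), abs=1e-12)


def test_mcnemar_chi2_variant():
    p = mcnemar_exact(PairedRatings2x2(5, 12, 2, 5), method="chi2")
    sm = sm_mcnemar([[5, 12], [2, 5]], exact=False, correction=True).pvalue
    assert p == pytest.approx(float(sm))


@pytest.mark.parametrize(
    "n, mean, sd, expected",
    [
        (30, 46.1, 13.9, (40.9, 51.3)),  # age
        (30, 161.5, 5.9, (159.3, 163.7)),  # height
        (30, 1.5, 1.1, (1.1, 1.9)),  # parity
    ],
)
def test_mean_ci_t_reproduces_descriptive_intervals(n, mean, sd, expected):
    lo, hi = mean_ci_t(n, mean, sd)
    assert (round(lo, 1), round(hi, 1)) == expected


def test_mean_ci_t_degenerate_and_invalid():
    assert mean_ci_t(10, 2.5, 0.0) == (2.5, 2.5)
    with pytest.raises(ValidationError):
        mean_ci_t(1, 0.0, 1.0)


def _verdict_frame(values_by_endpoint):
    rows = [
        {"patient_id": f"P{i:03d}", "endpoint": endpoint, "verdict": v}
        for endpoint, values in values_by_endpoint.items()
        for i, v in enumerate(values)
    ]
    return pd.DataFrame(rows)


def _full_endpoints(n=12, flip=None):
    from planeqc.concordance import ENDPOINTS

    base = {e: [1] * (n // 2) + [0] * (n - n // 2) for e in ENDPOINTS}
    base["vagina"] = [1] * n  # constant endpoint, like the real tables
    if flip is not None:
        endpoint, idx = flip
        base[endpoint] = list(base[endpoint])
        base[endpoint][idx] ^= 1
    return base


def test_concordance_table_self_agreement():
    ref = _verdict_frame(_full_endpoints())
    table = concordance_table(ref, ref.copy())
    defined = table[table["agreement"].notna()]
    assert np.allclose(defined["kappa"], 1.0)
    vagina = table[table["endpoint"] == "vagina"].iloc[0]
    assert np.isnan(vagina["kappa"])  # both raters constant: not estimable
    assert vagina["rater_correct"] == 12


def test_concordance_table_composes_kappa_and_mcnemar():
    ref = _verdict_frame(_full_endpoints())
    rater = _verdict_frame(_full_endpoints(flip=("anus", 0)))
    table = concordance_table(ref, rater).set_index("endpoint")
    t = PairedRatings2x2.from_vectors(
        _full_endpoints()["anus"], _full_endpoints(flip=("anus", 0))["anus"]
    )
    direct = cohen_kappa(t)
    row = table.loc["anus"]
    assert row["kappa"] == pytest.approx(direct.kappa)
    assert row["mcnemar_p"] == pytest.approx(mcnemar_exact(t))
    assert row["agreement"] == direct.category


def test_concordance_table_rejects_mismatched_items():
    ref = _verdict_frame(_full_endpoints(n=12))
    rater = _verdict_frame(_full_endpoints(n=10))
    with pytest.raises(ValidationError):
        concordance_table(ref, rater)
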