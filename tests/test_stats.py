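"""Welch's t-test: closed-form checks, published-table reproduction,
an independent quadrature oracle, and simulation calibration."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad

from airwaykit import reference
from airwaykit.errors import InputError
from airwaykit.stats import (GroupSummary, comparison_report, welch_from_samples,
                             welch_from_summary, welch_from_summary_arrays)


def t_sf_quadrature(t_val: float, df: float) -> float:
    """Upper-tail t probability by direct numerical integration of the
    density (gamma-function form) — independent of any library t CDF."""
    c = math.gamma((df + 1) / 2) / (math.sqrt(df * math.pi) * math.gamma(df / 2))
    pdf = lambda x: c * (1 + x * x / df) ** (-(df + 1) / 2)
    val, _ = quad(pdf, t_val, np.inf)
    return val


# printed (mean, SD, n) rows and the P value each rounds to in the source
# tables; the small tolerance absorbs the rounding of the printed inputs
PRINTED_ROWS = [
    ("expiratory_time", (254.05, 28.25, 8), (218.26, 33.70, 8), 0.038),
    ("inspiratory_time", (80.61, 17.83, 8), (78.12, 8.03, 8), 0.727),
    ("vmax_nasal", (12.26, 4.28, 8), (14.76, 6.25, 8), 0.369),
    ("pmax", (-689.0, 134.0, 8), (-1085.0, 346.0, 8), 0.015),
    ("skull_f", (7.88, 0.19, 8), (7.53, 0.27, 7), 0.018),
    ("skull_m", (2.66, 0.09, 8), (2.51, 0.05, 7), 0.002),
    ("hyoid_z", (2.79, 0.12, 8), (2.79, 0.13, 7), 1.000),
]


@pytest.mark.parametrize("name,g1,g2,p_printed", PRINTED_ROWS)
def test_printed_p_values_reproduce(name, g1, g2, p_printed):
    res = welch_from_summary(GroupSummary(*g1), GroupSummary(*g2))
    assert res.p_two_sided == pytest.approx(p_printed, abs=3e-3)


def test_equal_means_give_t_zero_p_one():
    res = welch_from_summary(GroupSummary(5.0, 1.0, 8), GroupSummary(5.0, 2.5, 7))
    assert res.t_statistic == 0.0
    assert res.p_two_sided == 1.0


@pytest.mark.parametrize("g1,g2", [
    ((254.05, 28.25, 8), (218.26, 33.70, 8)),
    ((2.66, 0.09, 8), (2.51, 0.05, 7)),
    ((0.1, 3.0, 5), (-4.0, 0.2, 12)),
])
def test_p_matches_quadrature_oracle(g1, g2):
    res = welch_from_summary(GroupSummary(*g1), GroupSummary(*g2))
    p_oracle = 2.0 * t_sf_quadrature(abs(res.t_statistic), res.df)
    assert res.p_two_sided == pytest.approx(p_oracle, abs=1e-6)


def test_degenerate_variances():
    res = welch_from_summary(GroupSummary(1.0, 0.0, 4), GroupSummary(1.0, 0.0, 4))
    assert (res.t_statistic, res.p_two_sided) == (0.0, 1.0)
    with pytest.warns(UserWarning, match="zero variance"):
        res = welch_from_summary(GroupSummary(2.0, 0.0, 4), GroupSummary(1.0, 0.0, 4))
    assert res.p_two_sided == 0.0


def test_samples_route_equals_summary_route():
    rng = np.random.default_rng(42)
    x, y = rng.normal(0, 1, 11), rng.normal(0.7, 2, 9)
    rs = welch_from_samples(x, y)
    rsum = welch_from_summary(
        GroupSummary(x.mean(), x.std(ddof=1), 11),
        GroupSummary(y.mean(), y.std(ddof=1), 9),
    )
    assert rs.p_two_sided == pytest.approx(rsum.p_two_sided, abs=1e-12)
    assert welch_from_samples(x, x.copy()).p_two_sided == 1.0
    with pytest.raises(InputError):
        welch_from_samples([1.0], [1.0, 2.0])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    m1=st.floats(-10, 10), m2=st.floats(-10, 10),
    s1=st.floats(0.1, 5), s2=st.floats(0.1, 5),
    n1=st.integers(2, 50), n2=st.integers(2, 50),
    k=st.floats(0.01, 100),
)
def test_welch_invariances(m1, m2, s1, s2, n1, n2, k):
    """Antisymmetry under group swap and invariance under rescaling."""
    a = welch_from_summary(GroupSummary(m1, s1, n1), GroupSummary(m2, s2, n2))
    b = welch_from_summary(GroupSummary(m2, s2, n2), GroupSummary(m1, s1, n1))
    assert a.t_statistic == pytest.approx(-b.t_statistic, rel=1e-12, abs=1e-12)
    assert a.p_two_sided == pytest.approx(b.p_two_sided, rel=1e-12, abs=1e-12)
    c = welch_from_summary(
        GroupSummary(k * m1, k * s1, n1), GroupSummary(k * m2, k * s2, n2)
    )
    assert c.t_statistic == pytest.approx(a.t_statistic, rel=1e-9)
    assert c.p_two_sided == pytest.approx(a.p_two_sided, rel=1e-9, abs=1e-12)


def test_p_decreases_with_mean_separation():
    ps = [
        welch_from_summary(GroupSummary(d, 1.0, 8), GroupSummary(0.0, 1.2, 7)).p_two_sided
        for d in (0.5, 1.0, 2.0, 4.0)
    ]
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_comparison_report_flags_and_shape():
    table = {
        "sig": (1.0, 0.5, 8, 0.0, 0.5, 8),
        "weight": reference.BASELINE["weight_g"],
    }
    rep = comparison_report(table)
    assert len(rep) == 2
    assert bool(rep.loc[rep.metric == "weight", "significant"].iloc[0]) is False
    # alpha boundary behavior
    assert comparison_report({"x": (1, 1, 8, 0, 1, 8)}).loc[0, "p"] > 0
    rep_holm = comparison_report(table, holm=True)
    assert "p_holm" in rep_holm and (rep_holm["p_holm"] >= rep_holm["p"] - 1e-15).all()


def test_null_rejection_rate_calibrated():
    """Large-sample null: rejection at alpha = 0.05 within 0.05 +/- 0.01."""
    rng = np.random.default_rng(2026)
    reps, n = 2000, 5000
    x = rng.standard_normal((reps, n))
    y = rng.standard_normal((reps, n))
    _, _, p = welch_from_summary_arrays(
        x.mean(1), x.std(1, ddof=1), n, y.mean(1), y.std(1, ddof=1), n
    )
    rate = float((p < 0.05).mean())
    assert abs(rate - 0.05) <= 0.01


def test_power_on_published_frontal_bone_moments():
    """The frontal-bone length row (7.93+/-0.17 vs 7.33+/-0.20, n 8/7) is a
    large effect: >90% of replicate cohorts reject at p < 0.001."""
    rng = np.random.default_rng(7)
    reps = 200
    x = rng.normal(7.93, 0.17, (reps, 8))
    y = rng.normal(7.33, 0.20, (reps, 7))
    _, _, p = welch_from_summary_arrays(
        x.mean(1), x.std(1, ddof=1), 8, y.mean(1), y.std(1, ddof=1), 7
    )
    assert float((p < 0.001).mean()) > 0.9
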