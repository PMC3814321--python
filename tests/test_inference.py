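"""History and activation-probability estimators."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tloxtrace import (
    DataError,
    ModelError,
    SaturationError,
    beta_binomial_icc,
    estimate_activation_prob,
    estimate_divisions,
    fit_effective_p_timeseries,
    generate_label_counts,
    two_population_test,
)
from tloxtrace.inference import activation_from_fraction, divisions_from_fraction


def counts_at(f: float, n_mice: int = 3, n_total: int = 10_000) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "mouse": [f"m{i}" for i in range(n_mice)],
            "n_labeled": int(round(f * n_total)),
            "n_total": n_total,
        }
    )


@pytest.mark.parametrize(
    "f,p,k",
    [(0.25, 0.25, 1.0), (0.4375, 0.25, 2.0), (0.0, 0.25, 0.0), (0.19, 0.1, 2.0)],
)
def test_division_estimate_inverts_cumulative_curve(f, p, k):
    est = estimate_divisions(counts_at(f), p, seed=0)
    assert est.k_hat == pytest.approx(k, abs=1e-9)
    assert est.ci_low <= est.k_hat <= est.ci_high
    assert est.p_used == p


@pytest.mark.parametrize(
    "f,k,p",
    [
        (0.4375, 2.0, 0.25),
        (0.0, 3.0, 0.0),
        (0.24, 24 / 17, 0.17668),  # one-doubling-time culture observation
    ],
)
def test_activation_estimate_inverts_cumulative_curve(f, k, p):
    est = estimate_activation_prob(counts_at(f), k, seed=0)
    assert est.p_hat == pytest.approx(p, abs=5e-5)
    assert est.ci_low <= est.p_hat <= est.ci_high <= 1.0


def test_saturated_fraction_raises():
    with pytest.raises(SaturationError):
        estimate_divisions(counts_at(1.0), 0.25)
    with pytest.raises(SaturationError):
        estimate_activation_prob(counts_at(0.9995), 2.0)


def test_input_validation():
    with pytest.raises(DataError):
        estimate_divisions(counts_at(0.2).iloc[:0], 0.25)
    bad = counts_at(0.2).assign(n_total=0)
    with pytest.raises(DataError):
        estimate_divisions(bad, 0.25)
    with pytest.raises(DataError):
        estimate_divisions(counts_at(0.2).drop(columns=["n_labeled"]), 0.25)
    with pytest.raises(ModelError):
        estimate_divisions(counts_at(0.2), 1.5)
    with pytest.raises(ModelError):
        estimate_activation_prob(counts_at(0.2), 0.0)


def test_single_mouse_uses_cell_level_interval():
    est = estimate_divisions(counts_at(0.25, n_mice=1), 0.25, seed=0)
    assert "cell" in est.method
    assert est.ci_low < 1.0 < est.ci_high


@given(
    f1=st.floats(0.01, 0.9),
    gap=st.floats(0.01, 0.09),
    p=st.sampled_from([0.05, 0.1, 0.25]),
)
def test_k_hat_strictly_increasing_in_fraction(f1, gap, p):
    assert divisions_from_fraction(f1 + gap, p) > divisions_from_fraction(f1, p)


@given(f=st.floats(0.0, 0.99), p=st.sampled_from([0.05, 0.1, 0.25]))
def test_inversion_round_trip(f, p):
    k = divisions_from_fraction(f, p)
    assert 1 - (1 - p) ** k == pytest.approx(min(f, 0.999), abs=1e-9)
    assert activation_from_fraction(f, k if k > 0 else 1.0) <= 1.0


def test_round_trip_recovery_on_synthetic_cohort(rng):
    for k in (1, 3, 6):
        counts = generate_label_counts(k, 0.1, 3, 10_000, rho=0.02, rng=rng)
        est = estimate_divisions(counts, 0.1, seed=1)
        assert est.ci_low <= k <= est.ci_high
        assert est.k_hat > 0


def test_two_population_identical_groups():
    a = counts_at(0.25)
    res = two_population_test(a, a.copy(), 0.25, seed=0)
    assert res.effect_size == 0.0
    assert res.p_value == 1.0
    assert res.method.startswith("mouse permutation")


def test_two_population_resolution_floor_at_three_mice():
    """With 3 vs 3 mice the exhaustive permutation distribution has 20
    arrangements and the observed split ties its mirror image, so the
    smallest attainable p-value is 0.1."""
    rng = np.random.default_rng(5)
    a = generate_label_counts(2, 0.1, 3, 3000, rng=rng, group="a")
    b = generate_label_counts(6, 0.1, 3, 3000, rng=rng, group="b")
    res = two_population_test(a, b, 0.1, seed=0)
    assert res.method == "mouse permutation (exhaustive)"
    assert res.n_arrangements == 20
    assert res.p_value == pytest.approx(0.1)
    assert res.effect_size > 3.0


def test_two_population_power_at_resolution_limit():
    """At its attainable resolution (alpha = 0.1 for 3v3 mice) the
    permutation test separates a k = 6 vs k = 2 contrast almost always."""
    rng = np.random.default_rng(41)
    rejections = 0
    for rep in range(200):
        a = generate_label_counts(2, 0.1, 3, 3000, rho=0.02, rng=rng)
        b = generate_label_counts(6, 0.1, 3, 3000, rho=0.02, rng=rng)
        rejections += two_population_test(a, b, 0.1, seed=rep).p_value <= 0.1
    assert rejections >= 0.90 * 200


def test_two_population_separates_with_four_mice():
    rng = np.random.default_rng(6)
    a = generate_label_counts(2, 0.1, 4, 3000, rng=rng)
    b = generate_label_counts(6, 0.1, 4, 3000, rng=rng)
    res = two_population_test(a, b, 0.1, seed=0)
    assert res.p_value <= 0.05
    assert res.k_b > res.k_a


def test_two_population_single_mouse_falls_back_to_cells():
    a = counts_at(0.1, n_mice=1)
    b = counts_at(0.4, n_mice=2)
    with pytest.warns(UserWarning, match="cell-level"):
        res = two_population_test(a, b, 0.25, seed=0)
    assert res.method == "cell-level Fisher exact"
    assert res.p_value < 0.05


def test_two_population_empty_group_is_data_error():
    a = counts_at(0.2)
    with pytest.raises(DataError):
        two_population_test(a, a.iloc[:0], 0.25)


def test_overdispersion_estimate_recovers_icc(rng):
    rho = 0.1
    counts = generate_label_counts(3, 0.25, 400, 500, rho=rho, rng=rng)
    est = beta_binomial_icc(counts.n_labeled, counts.n_total)
    assert est == pytest.approx(rho, abs=0.03)
    assert np.isnan(beta_binomial_icc([5], [100]))


def test_timeseries_fit_single_point_is_exact_inverse():
    series = pd.DataFrame({"time_h": [17.0], "n_labeled": [2500], "n_total": [10_000]})
    fit = fit_effective_p_timeseries(series, doubling_time=17.0)
    assert fit.p_hat == pytest.approx(0.25, abs=1e-6)
    assert fit.ci_low < 0.25 < fit.ci_high


def test_timeseries_fit_recovers_generating_p(rng):
    t = np.array([12.0, 24.0, 36.0, 48.0])
    f = 1 - (1 - 0.15) ** (t / 17.0)
    series = pd.DataFrame(
        {"time_h": t, "n_labeled": rng.binomial(10_000, f), "n_total": 10_000}
    )
    fit = fit_effective_p_timeseries(series, doubling_time=17.0)
    assert fit.ci_low < 0.15 < fit.ci_high
    assert fit.p_hat == pytest.approx(0.15, abs=0.01)


def test_timeseries_fit_edge_cases():
    with pytest.raises(DataError):
        fit_effective_p_timeseries(pd.DataFrame(), 17.0)
    with pytest.raises(ModelError):
        fit_effective_p_timeseries(
            pd.DataFrame({"time_h": [17.0], "n_labeled": [1], "n_total": [10]}), 0.0
        )
    silent = pd.DataFrame({"time_h": [17.0, 34.0], "n_labeled": [0, 0], "n_total": [500, 500]})
    fit = fit_effective_p_timeseries(silent, 17.0)
    assert fit.p_hat == 0.0
    assert fit.ci_low == 0.0 and fit.ci_high > 0.0
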