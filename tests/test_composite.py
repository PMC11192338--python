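"""Min-max normalisation, CV weighting and the two composite indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cgmi.composite import (
    build_composite,
    cgmi_equal,
    cgmi_weighted,
    coefficient_of_variation,
    cv_weights,
    normalize_minmax,
    weights_from_cvs,
)


def test_minmax_endpoints_and_midpoint():
    scaled, (lo, hi) = normalize_minmax([33.50, 54.78, (33.50 + 54.78) / 2])
    assert (lo, hi) == (33.50, 54.78)
    np.testing.assert_allclose(scaled, [0.0, 1.0, 0.5])


def test_minmax_constant_column_is_error():
    with pytest.raises(ValueError, match="zero range"):
        normalize_minmax([2.0, 2.0, 2.0])


@given(st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=30, unique=True))
@settings(max_examples=100, deadline=None)
def test_minmax_is_affine_onto_unit_interval(values):
    scaled, (lo, hi) = normalize_minmax(values)
    assert scaled.min() == 0.0
    assert scaled.max() == 1.0
    # affinity: scaled differences proportional to raw differences
    arr = np.asarray(values)
    np.testing.assert_allclose(scaled * (hi - lo) + lo, arr, rtol=1e-9, atol=1e-9)


def _frame(cols):
    return pd.DataFrame(dict(zip(("spad", "ph", "lai", "agb"), cols)))


def test_cv_weights_from_raw_columns():
    rng = np.random.default_rng(3)
    cols = [rng.uniform(10, 20, 50), rng.uniform(1, 2, 50),
            rng.uniform(2, 5, 50), rng.uniform(1000, 9000, 50)]
    w = cv_weights(_frame(cols))
    manual_cv = [np.std(c) / np.mean(c) for c in cols]
    np.testing.assert_allclose(w.cv, manual_cv)
    np.testing.assert_allclose(w.weights, np.array(manual_cv) / np.sum(manual_cv))
    assert sum(w.weights) == pytest.approx(1.0, abs=1e-12)


def test_identical_cvs_give_equal_weights():
    base = np.array([1.0, 2.0, 3.0, 4.0])
    # scaling a column leaves its CV unchanged, so all four CVs coincide
    w = cv_weights(_frame([base, 2 * base, 5 * base, 100 * base]))
    np.testing.assert_allclose(w.weights, [0.25] * 4)


def test_weights_scale_invariant():
    rng = np.random.default_rng(11)
    cols = [rng.uniform(10, 20, 30) for _ in range(4)]
    w1 = cv_weights(_frame(cols))
    cols2 = [c * s for c, s in zip(cols, (1.0, 7.0, 0.01, 300.0))]
    w2 = cv_weights(_frame(cols2))
    np.testing.assert_allclose(w1.weights, w2.weights, rtol=1e-12)


def test_cv_zero_mean_is_error():
    with pytest.raises(ValueError, match="mean"):
        coefficient_of_variation(1.0, 0.0)


def test_cgmi_equal_bounds_and_mean():
    assert cgmi_equal([[1, 1, 1, 1]])[0] == 1.0
    assert cgmi_equal([[0, 0, 0, 0]])[0] == 0.0
    assert cgmi_equal([[0.2, 0.4, 0.6, 0.8]])[0] == pytest.approx(0.5)


def test_cgmi_weighted_convexity_and_reference_weights():
    w = (0.130514, 0.236403, 0.302251, 0.330832)
    assert cgmi_weighted([[1, 1, 1, 1]], w)[0] == pytest.approx(1.0, abs=2e-6)
    assert cgmi_weighted([[0.5] * 4], w)[0] == pytest.approx(0.5, abs=1e-6)
    assert cgmi_weighted([[1, 0, 0, 0]], w)[0] == pytest.approx(0.130514)


def test_cgmi_weighted_dimension_mismatch():
    with pytest.raises(ValueError, match="weights"):
        cgmi_weighted([[0.5] * 4], (0.5, 0.5))


@given(
    u=st.lists(st.floats(0, 1), min_size=4, max_size=4),
    bump=st.integers(0, 3),
    eps=st.floats(0.0, 0.5),
)
@settings(max_examples=100, deadline=None)
def test_cgmi_weighted_monotone_in_each_indicator(u, bump, eps):
    w = weights_from_cvs((0.09, 0.17, 0.22, 0.23))
    u2 = list(u)
    u2[bump] = min(1.0, u2[bump] + eps)
    assert cgmi_weighted([u2], w)[0] >= cgmi_weighted([u], w)[0] - 1e-12


def test_build_composite_table(default_plots):
    table, w, bounds = build_composite(default_plots)
    assert {"plot_id", "U1", "U2", "U3", "U4", "CGMI1", "CGMI2"} <= set(table.columns)
    for col in ("U1", "U2", "U3", "U4", "CGMI1", "CGMI2"):
        assert table[col].between(0, 1).all()
    # the plot attaining an indicator maximum scores U = 1 there
    assert table["U1"].max() == 1.0
    assert sum(w.weights) == pytest.approx(1.0, abs=1e-12)
    assert bounds["spad"][0] == default_plots["spad"].min()


def test_sample_sd_convention_switch(default_plots):
    w_pop = cv_weights(default_plots[["spad", "ph", "lai", "agb"]], ddof=0)
    w_samp = cv_weights(default_plots[["spad", "ph", "lai", "agb"]], ddof=1)
    assert w_pop.sd[0] < w_samp.sd[0]
    # at n = 66 the weights are nearly identical under either convention
    np.testing.assert_allclose(w_pop.weights, w_samp.weights, atol=1e-3)
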