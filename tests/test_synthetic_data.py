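"""Generator structure: moments, latent-factor coupling, determinism, I/O."""

import numpy as np
import pandas as pd
import pytest

from cgmi.composite import build_composite
from cgmi.synthetic_data import (
    INDICATOR_COLUMNS,
    PLOT_COLUMNS,
    SyntheticConfig,
    generate_plots,
    read_plot_table,
    write_plot_table,
)
from cgmi.vegindex import compute_all


def test_schema_and_physical_ranges(default_plots):
    assert list(default_plots.columns) == list(PLOT_COLUMNS)
    assert len(default_plots) == 66
    for band in ("b450", "g550", "r660", "re750", "nir840"):
        assert default_plots[band].between(0, 1).all()
    for ind in INDICATOR_COLUMNS:
        assert (default_plots[ind] > 0).all()


def test_same_seed_reproduces_table_bitwise():
    a = generate_plots(SyntheticConfig(seed=7))
    b = generate_plots(SyntheticConfig(seed=7))
    pd.testing.assert_frame_equal(a, b)


def test_different_seeds_differ():
    a = generate_plots(SyntheticConfig(seed=1))
    b = generate_plots(SyntheticConfig(seed=2))
    assert not np.allclose(a["spad"], b["spad"])


def test_spad_sample_mean_near_target(default_plots):
    # analytic standardisation leaves sqrt(n) sampling error on the mean
    se = 3.75 / np.sqrt(66)
    assert abs(default_plots["spad"].mean() - 40.18) < 3 * se


def test_indicator_cvs_match_targets_in_expectation():
    """Sample CVs across seeds should track (0.09, 0.17, 0.22, 0.24)."""
    targets = np.array([3.75 / 40.18, 0.20 / 1.18, 0.63 / 2.90, 1515.69 / 6347.70])
    cvs = []
    for seed in range(20):
        plots = generate_plots(SyntheticConfig(seed=seed))
        cvs.append(
            [plots[c].std(ddof=0) / plots[c].mean() for c in INDICATOR_COLUMNS]
        )
    assert np.all(np.abs(np.mean(cvs, axis=0) - targets) < 0.05)


def test_noise_free_indicators_perfectly_correlated(noise_free_config):
    plots = generate_plots(noise_free_config)
    corr = plots[list(INDICATOR_COLUMNS)].corr()
    assert np.allclose(corr.to_numpy(), 1.0, atol=1e-12)


def test_nir_rises_and_red_falls_with_vigor(noise_free_config):
    plots = generate_plots(noise_free_config)
    # noise-free: agb is a monotone image of vigor
    order = plots["agb"].to_numpy().argsort()
    nir = plots["nir840"].to_numpy()[order]
    red = plots["r660"].to_numpy()[order]
    assert np.all(np.diff(nir) >= 0)
    assert np.all(np.diff(red) <= 0)


def test_tcari_tracks_composite_index_across_seeds():
    """Mean TCARI-CGMI2 Pearson r over 20 seeds in the plausible band."""
    rs = []
    for seed in range(20):
        plots = generate_plots(SyntheticConfig(seed=seed))
        idx = compute_all(plots)
        table, _, _ = build_composite(plots)
        rs.append(np.corrcoef(idx["TCARI"], table["CGMI2"])[0, 1])
    assert 0.55 <= np.mean(rs) <= 0.90


def test_unphysical_reflectance_config_rejected():
    cfg = SyntheticConfig(seed=0)
    bad = cfg.replace(
        reflectance_params={**cfg.reflectance_params, "r660": (0.02, -0.5, 0.0)}
    )
    with pytest.raises(ValueError, match="r660"):
        generate_plots(bad)


def test_too_few_plots_rejected():
    with pytest.raises(ValueError, match="n_plots"):
        SyntheticConfig(n_plots=5)


def test_csv_round_trip_lossless(tmp_path, default_plots):
    path = tmp_path / "plots.csv"
    write_plot_table(default_plots, path)
    back = read_plot_table(path)
    assert list(back.columns) == list(PLOT_COLUMNS)
    for col in PLOT_COLUMNS[1:]:
        np.testing.assert_allclose(back[col], default_plots[col], rtol=1e-12)


def test_missing_column_named_in_error(tmp_path, default_plots):
    path = tmp_path / "broken.csv"
    default_plots.drop(columns=["nir840"]).to_csv(path, index=False)
    with pytest.raises(ValueError, match="nir840"):
        read_plot_table(path)


def test_non_numeric_cell_named_in_error(tmp_path, default_plots):
    path = tmp_path / "broken.csv"
    df = default_plots.copy()
    df["lai"] = df["lai"].astype(object)
    df.loc[3, "lai"] = "oops"
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="lai"):
        read_plot_table(path)


def test_empty_file_is_an_error(tmp_path):
    path = tmp_path / "empty.csv"
    path.write_text("")
    with pytest.raises(ValueError, match="empty"):
        read_plot_table(path)
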