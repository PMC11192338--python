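"""Synthetic plot-table generator.

Emulates a small plantation trial: ``n_plots`` sample plots, each carrying
five band-averaged canopy reflectances (blue 450 nm, green 550 nm,
red 660 nm, red edge 750 nm, NIR 840 nm) and four plot-level growth
indicators (SPAD chlorophyll reading, plant height in metres, leaf area
index, above-ground biomass).

The statistical backbone is a single latent "vigor" factor per plot:
every indicator is a loading on vigor plus Gaussian noise, affinely
mapped to a target mean/SD, and the red and NIR reflectances move down
and up with vigor respectively, so red/NIR contrast indices track the
composite growth index with realistic (not perfect) correlation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BAND_COLUMNS",
    "INDICATOR_COLUMNS",
    "PLOT_COLUMNS",
    "SyntheticConfig",
    "generate_plots",
    "write_plot_table",
    "read_plot_table",
]

BAND_COLUMNS = ("b450", "g550", "r660", "re750", "nir840")
INDICATOR_COLUMNS = ("spad", "ph", "lai", "agb")
PLOT_COLUMNS = ("plot_id",) + BAND_COLUMNS + INDICATOR_COLUMNS

#: target (mean, SD) per indicator: SPAD unitless, PH metres, LAI unitless,
#: AGB in grams of oven-dry mass per tree.
DEFAULT_INDICATOR_MOMENTS = {
    "spad": (40.18, 3.75),
    "ph": (1.18, 0.20),
    "lai": (2.90, 0.63),
    "agb": (6347.70, 1515.69),
}

#: residual SD per indicator, in latent (vigor) units.  Chosen so the
#: indicator-vigor correlations are strong for biomass-like indicators and
#: weak for height, mirroring the typical ordering of canopy-spectral
#: correlations (height is the least spectrally visible trait).
DEFAULT_NOISE_SD = {"spad": 0.78, "ph": 1.88, "lai": 0.86, "agb": 0.53}

DEFAULT_VIGOR_LOADINGS = {"spad": 1.0, "ph": 1.0, "lai": 1.0, "agb": 1.0}

#: per band: (baseline reflectance, slope per unit vigor, residual SD).
#: Healthy-canopy shape: low blue/red, moderate green, high red-edge/NIR;
#: vigor deepens red absorption and raises NIR/red-edge reflectance.
DEFAULT_REFLECTANCE_PARAMS = {
    "b450": (0.060, -0.006, 0.004),
    "g550": (0.120, 0.006, 0.008),
    "r660": (0.180, -0.022, 0.010),
    "re750": (0.320, 0.004, 0.008),
    "nir840": (0.460, 0.045, 0.055),
}

_CLAMP_LO, _CLAMP_HI = 0.01, 0.99


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the latent-vigor plot generator."""

    n_plots: int = 66
    seed: int = 0
    vigor_loadings: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_VIGOR_LOADINGS)
    )
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    reflectance_params: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REFLECTANCE_PARAMS)
    )
    indicator_moments: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_INDICATOR_MOMENTS)
    )

    def __post_init__(self) -> None:
        if self.n_plots < 10:
            raise ValueError(f"n_plots must be >= 10, got {self.n_plots}")
        for name in INDICATOR_COLUMNS:
            if name not in self.vigor_loadings:
                raise ValueError(f"vigor_loadings missing indicator {name!r}")
            if name not in self.noise_sd:
                raise ValueError(f"noise_sd missing indicator {name!r}")
            if self.noise_sd[name] < 0:
                raise ValueError(f"noise_sd[{name!r}] must be >= 0")
            if name not in self.indicator_moments:
                raise ValueError(f"indicator_moments missing indicator {name!r}")
        for band in BAND_COLUMNS:
            if band not in self.reflectance_params:
                raise ValueError(f"reflectance_params missing band {band!r}")

    def replace(self, **kwargs) -> "SyntheticConfig":
        return dataclasses.replace(self, **kwargs)


def generate_plots(config: SyntheticConfig | None = None) -> pd.DataFrame:
    """Draw a plot table with the configured latent-factor structure.

    Each indicator is ``loading * vigor + noise`` standardised analytically
    (so its population mean/SD equal the configured moments exactly, and
    the sample moments fluctuate with the usual sqrt(n) error).
    Reflectances are linear in vigor with Gaussian noise, clamped to
    (0.01, 0.99).  Deterministic for a given config.

    Raises
    ------
    ValueError
        If more than 10% of any band's samples hit the clamp, which means
        the configured slopes/noise push reflectance out of physical range.
    """
    config = config or SyntheticConfig()
    rng = np.random.default_rng(config.seed)
    n = config.n_plots
    vigor = rng.standard_normal(n)

    data: dict[str, np.ndarray] = {
        "plot_id": np.array([f"P{i + 1:03d}" for i in range(n)])
    }

    for band in BAND_COLUMNS:
        base, slope, sd = config.reflectance_params[band]
        raw = base + slope * vigor + rng.normal(0.0, sd, size=n)
        clamped = np.clip(raw, _CLAMP_LO, _CLAMP_HI)
        frac_clamped = np.mean(raw != clamped)
        if frac_clamped > 0.10:
            raise ValueError(
                f"band {band!r}: {frac_clamped:.0%} of samples fall outside "
                f"({_CLAMP_LO}, {_CLAMP_HI}); reflectance_params are unphysical"
            )
        data[band] = clamped

    for name in INDICATOR_COLUMNS:
        loading = config.vigor_loadings[name]
        noise = config.noise_sd[name]
        mean, sd = config.indicator_moments[name]
        raw = loading * vigor + rng.normal(0.0, noise, size=n) if noise > 0 else loading * vigor
        scale = float(np.hypot(loading, noise))
        z = raw / scale if scale > 0 else raw
        values = mean + sd * z
        # growth indicators are physically positive
        data[name] = np.maximum(values, 1e-6)

    return pd.DataFrame(data, columns=list(PLOT_COLUMNS))


def write_plot_table(records: pd.DataFrame, path) -> None:
    """Write a plot table to CSV with the canonical column order."""
    missing = [c for c in PLOT_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"plot table missing columns: {missing}")
    records.loc[:, list(PLOT_COLUMNS)].to_csv(path, index=False, float_format="%.15g")


def read_plot_table(path) -> pd.DataFrame:
    """Read a plot table CSV, validating schema and numeric content."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ValueError(f"plot table {path} is empty") from None
    missing = [c for c in PLOT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"plot table {path} missing columns: {missing}")
    for col in PLOT_COLUMNS[1:]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()]
        if len(bad) or coerced.isna().any():
            row = int(bad[0]) if len(bad) else int(coerced.index[coerced.isna()][0])
            raise ValueError(f"non-numeric value in column {col!r} at row {row}")
        df[col] = coerced.astype(float)
    return df.loc[:, list(PLOT_COLUMNS)]
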