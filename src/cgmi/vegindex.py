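"""Vegetation-index registry for five-band multispectral plot data.

Twelve broadband indices computed from blue (B, 450 nm), green (G, 550 nm),
red (R, 660 nm), red-edge (RE, 750 nm) and near-infrared (NIR, 840 nm)
plot-mean reflectance.

Several indices circulate in the applied literature in typographically
damaged forms (dropped exponents, misplaced parentheses).  The registry
therefore carries two formula modes:

``literature``
    The canonical definitions from the indices' original sources
    (default).
``as-printed``
    The garbled variants evaluated literally where they parse at all, for
    auditing how much the corruption matters.  Indices whose printed form
    is not syntactically recoverable fall back to the canonical form.

Every index carries a provenance flag (``as-printed`` when both modes
coincide, ``literature-corrected`` when the modes differ), retrievable via
:func:`formula_provenance`.
"""

from __future__ import annotations

from typing import Callable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "INDEX_NAMES",
    "compute_index",
    "compute_all",
    "formula_provenance",
]

ArrayLike = np.ndarray | float


def _ndvi(b, g, r, re, nir):
    return (nir - r) / (nir + r)


def _gndvi(b, g, r, re, nir):
    return (nir - g) / (nir + g)


def _msr(b, g, r, re, nir):
    ratio = nir / r
    return (ratio - 1.0) / (np.sqrt(ratio) + 1.0)


def _msr_printed(b, g, r, re, nir):
    # literal reading of "((NIR/R)-1)/(NIR/R)+1"
    ratio = nir / r
    return (ratio - 1.0) / ratio + 1.0


def _tcari(b, g, r, re, nir):
    return 3.0 * ((re - r) - 0.2 * (re - g) * (re / r))


def _ci_rededge(b, g, r, re, nir):
    return nir / re - 1.0


def _ci_rededge_printed(b, g, r, re, nir):
    # literal reading of "NIR/(RE-1)"
    return nir / (re - 1.0)


def _dvi(b, g, r, re, nir):
    return nir - r


def _osavi(b, g, r, re, nir):
    return (nir - r) / (nir + r + 0.16)


def _vdvi(b, g, r, re, nir):
    return (2.0 * g - r - b) / (2.0 * g + r + b)


def _sipi(b, g, r, re, nir):
    return (nir - b) / (nir + b)


def _mtvi(b, g, r, re, nir):
    # MTVI2 form; the hypotenuse term guards the soil line
    num = 1.5 * (1.2 * (nir - g) - 2.5 * (r - g))
    den = np.sqrt((2.0 * nir + 1.0) ** 2 - (6.0 * nir - 5.0 * np.sqrt(r)) - 0.5)
    return num / den


def _mnvi(b, g, r, re, nir):
    return 1.5 * (nir**2 - r) / (nir**2 + r + 0.5)


def _mnvi_printed(b, g, r, re, nir):
    # literal reading of "1.5(NIR2-2)/(NIR2+R+0.5)"
    return 1.5 * (nir**2 - 2.0) / (nir**2 + r + 0.5)


def _arvi(b, g, r, re, nir):
    rb = 2.0 * r - b
    return (nir - rb) / (nir + rb)


_Formula = Callable[..., ArrayLike]

#: name -> (literature formula, as-printed formula, provenance flag).
_REGISTRY: Mapping[str, tuple[_Formula, _Formula, str]] = {
    "NDVI": (_ndvi, _ndvi, "as-printed"),
    "GNDVI": (_gndvi, _gndvi, "as-printed"),
    "MSR": (_msr, _msr_printed, "literature-corrected"),
    "TCARI": (_tcari, _tcari, "as-printed"),
    "CIrededge": (_ci_rededge, _ci_rededge_printed, "literature-corrected"),
    "DVI": (_dvi, _dvi, "as-printed"),
    "OSAVI": (_osavi, _osavi, "as-printed"),
    "VDVI": (_vdvi, _vdvi, "as-printed"),
    "SIPI": (_sipi, _sipi, "as-printed"),
    "MTVI": (_mtvi, _mtvi, "literature-corrected"),
    "MNVI": (_mnvi, _mnvi_printed, "literature-corrected"),
    "ARVI": (_arvi, _arvi, "as-printed"),
}

INDEX_NAMES: tuple[str, ...] = tuple(_REGISTRY)

_BAND_ORDER = ("b450", "g550", "r660", "re750", "nir840")


def formula_provenance(name: str) -> str:
    """Return ``"as-printed"`` or ``"literature-corrected"`` for an index."""
    _check_name(name)
    return _REGISTRY[name][2]


def _check_name(name: str) -> None:
    if name not in _REGISTRY:
        raise KeyError(
            f"unknown vegetation index {name!r}; valid names: {', '.join(INDEX_NAMES)}"
        )


def compute_index(
    name: str,
    bands: Mapping[str, ArrayLike],
    formulas: str = "literature",
) -> ArrayLike:
    """Evaluate one vegetation index from band reflectances.

    Parameters
    ----------
    name
        Index name (see :data:`INDEX_NAMES`).
    bands
        Mapping with keys ``b450, g550, r660, re750, nir840`` holding
        scalars or equal-length arrays of reflectance in (0, 1].
    formulas
        ``"literature"`` (canonical, default) or ``"as-printed"``.
    """
    _check_name(name)
    if formulas not in ("literature", "as-printed"):
        raise ValueError(f"formulas must be 'literature' or 'as-printed', got {formulas!r}")
    vals = []
    for band in _BAND_ORDER:
        if band not in bands:
            raise ValueError(f"missing band {band!r}")
        arr = np.asarray(bands[band], dtype=float)
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ValueError(f"band {band!r} must be finite and > 0")
        vals.append(arr)
    func = _REGISTRY[name][0] if formulas == "literature" else _REGISTRY[name][1]
    with np.errstate(divide="raise", invalid="raise"):
        try:
            out = func(*vals)
        except FloatingPointError as exc:
            raise ZeroDivisionError(
                f"index {name!r}: singular denominator for supplied reflectances"
            ) from exc
    return out


def compute_all(records: pd.DataFrame, formulas: str = "literature") -> pd.DataFrame:
    """Compute all 12 indices for every plot row.

    Returns a DataFrame with ``plot_id`` plus one column per index.
    Division errors are re-raised with the offending plot identified.
    """
    if len(records) == 0:
        raise ValueError("empty plot table")
    bands = {band: records[band].to_numpy(dtype=float) for band in _BAND_ORDER}
    out = pd.DataFrame({"plot_id": records["plot_id"].to_numpy()})
    for name in INDEX_NAMES:
        try:
            out[name] = compute_index(name, bands, formulas=formulas)
        except ZeroDivisionError:
            # rerun row-wise to name the plot
            for i in range(len(records)):
                row = {b: bands[b][i] for b in _BAND_ORDER}
                try:
                    compute_index(name, row, formulas=formulas)
                except ZeroDivisionError as exc:
                    pid = records["plot_id"].iloc[i]
                    raise ZeroDivisionError(f"plot {pid!r}: {exc}") from None
            raise
    return out
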