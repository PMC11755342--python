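"""Aggregated isotopologue envelopes for window sizing.

For extraction-window construction we only need the *extent* and centroid of
a species' isotope envelope, not isotopologue fine structure, so isotopes
are aggregated by nucleon-number offset from the monoisotopic peak.  The
per-element distributions are convolved by exponentiation-by-squaring, which
stays fast even for ~150 kDa proteins (thousands of carbons).

Backbones defined only by a fixed mass get an averagine-scaled elemental
formula, the standard stand-in for an unknown protein composition.
"""

from __future__ import annotations

import numpy as np

__all__ = ["isotope_envelope", "averagine_formula", "envelope_extent"]

# relative isotope abundances per nucleon offset from the lightest isotope
_ISOTOPES = {
    "H": [0.999885, 0.000115],
    "C": [0.9893, 0.0107],
    "N": [0.99636, 0.00364],
    "O": [0.99757, 0.00038, 0.00205],
    "S": [0.9499, 0.0075, 0.0425, 0.0, 0.0001],
}

# average elemental composition of protein per residue (averagine),
# 111.1254 Da average residue mass
_AVERAGINE = {"C": 4.9384, "H": 7.7583, "N": 1.3577, "O": 1.4773, "S": 0.0417}
_AVERAGINE_MASS = 111.1254

#: mean mass spacing between successive aggregated isotopologues (Da)
NEUTRON_SPACING = 1.00235


def averagine_formula(avg_mass: float) -> dict[str, int]:
    """Integer elemental formula of an averagine pseudo-protein of the
    requested average mass."""
    n = avg_mass / _AVERAGINE_MASS
    return {e: max(0, round(k * n)) for e, k in _AVERAGINE.items()}


def _power_convolve(base: np.ndarray, n: int, trim: float) -> np.ndarray:
    """``base`` distribution convolved with itself ``n`` times."""
    result = np.array([1.0])
    term = base
    while n:
        if n & 1:
            result = np.convolve(result, term)
            result = _trim(result, trim)
        n >>= 1
        if n:
            term = _trim(np.convolve(term, term), trim)
    return result


def _trim(p: np.ndarray, floor: float) -> np.ndarray:
    keep = np.nonzero(p >= floor * p.max())[0]
    return p[: keep[-1] + 1] if keep.size else p[:1]


def isotope_envelope(
    formula: dict[str, int], floor: float = 1e-4
) -> tuple[np.ndarray, np.ndarray]:
    """Aggregated isotopologue distribution of an elemental formula.

    Returns ``(offsets, abundances)`` where offsets are integer nucleon
    counts above the monoisotopic peak and abundances are normalised to the
    most intense isotopologue; entries below ``floor`` (relative) at both
    tails are dropped.
    """
    dist = np.array([1.0])
    for elem, n in formula.items():
        if not n or elem not in _ISOTOPES:
            continue
        base = np.asarray(_ISOTOPES[elem], dtype=float)
        base = base / base.sum()
        dist = np.convolve(dist, _power_convolve(base, int(n), floor * 1e-3))
        dist = _trim(dist, floor * 1e-3)
    dist = dist / dist.max()
    keep = np.nonzero(dist >= floor)[0]
    lo, hi = keep[0], keep[-1]
    return np.arange(lo, hi + 1), dist[lo : hi + 1]


def envelope_extent(
    formula: dict[str, int], floor: float = 1e-4
) -> tuple[float, float, float]:
    """(mass below mono-ish start, mass above, centroid offset) in Da of the
    envelope relative to the monoisotopic mass."""
    offsets, ab = isotope_envelope(formula, floor)
    centroid = float((offsets * ab).sum() / ab.sum()) * NEUTRON_SPACING
    return (
        float(offsets[0]) * NEUTRON_SPACING,
        float(offsets[-1]) * NEUTRON_SPACING,
        centroid,
    )
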