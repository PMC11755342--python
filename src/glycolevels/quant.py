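"""Fractional-abundance quantification of glyco-species from raw spectra.

The core idea: skip deconvolution entirely.  For every candidate
glyco-species, extraction windows are placed at the m/z positions of its
charge states; the extracted ion current summed over windows and scans is
the species' signal, and dividing by the summed signal of all candidates
gives its *fractional abundance*.  This works identically at the peptide,
subunit (Fc/2, heavy chain), and intact-protein levels — only the mass mode
(monoisotopic vs average) and tolerances change with the resolution regime.

Window sizing uses an aggregated isotope-envelope model of the species'
elemental formula (averagine-scaled for fixed-mass backbones) truncated at a
relative-abundance floor, expanded by the user tolerance.  Windows of
distinct species that merely touch are flagged; only species whose windows
coincide exactly at every charge (true isobars) are rejected as
indistinguishable — their resolution belongs to the intact-level pair
annotation stage.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as _pmass

from .glycans import PROTON_MASS, Backbone, GlycoSpecies, species_mass
from .isotopes import averagine_formula, envelope_extent
from .spectra import MzWindow, SpectrumSeries, integrate_window

logger = logging.getLogger(__name__)

__all__ = [
    "ChargePlan",
    "AbundanceProfile",
    "WindowPlan",
    "IndistinguishableSpeciesError",
    "theoretical_mz",
    "build_windows",
    "quantify",
    "replicate_stats",
    "glycation_degree",
]


class IndistinguishableSpeciesError(ValueError):
    """All extraction windows of two or more species coincide exactly."""


@dataclass(frozen=True)
class ChargePlan:
    """Charge states and matching tolerance for one structural level.

    ``tolerance_unit`` is ``"ppm"`` (high-resolution peptide regime) or
    ``"Th"`` (absolute, subunit/intact regime); ``mass_mode`` selects
    monoisotopic or average masses to match what the resolution resolves.

    ``window_halfwidth_th`` optionally fixes the extraction half-width (Th,
    before tolerance expansion) instead of deriving it from the isotope
    envelope extent — the practical choice at the subunit levels, where
    isotope-resolved acquisition allows windows much narrower than the
    full envelope and neighbouring glycoforms sit only ~16 Da apart.
    """

    charges: tuple[int, ...]
    tolerance: float
    tolerance_unit: str = "ppm"
    mass_mode: str = "mono"
    window_halfwidth_th: float | None = None

    def __post_init__(self) -> None:
        charges = tuple(int(z) for z in self.charges)
        object.__setattr__(self, "charges", charges)
        if not charges or any(z < 1 for z in charges):
            raise ValueError("charges must be positive integers")
        if len(set(charges)) != len(charges):
            raise ValueError("duplicate charge states")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if self.tolerance_unit not in ("ppm", "Th"):
            raise ValueError("tolerance_unit must be 'ppm' or 'Th'")
        if self.mass_mode not in ("mono", "avg"):
            raise ValueError("mass_mode must be 'mono' or 'avg'")
        if self.window_halfwidth_th is not None and self.window_halfwidth_th <= 0:
            raise ValueError("window_halfwidth_th must be > 0")

    def tol_th(self, mz: float) -> float:
        return self.tolerance * mz * 1e-6 if self.tolerance_unit == "ppm" else self.tolerance


#: Tolerances and mass modes typical for the three resolution regimes.
#: Subunit levels use fixed narrow windows: at z = 16 (Fc/2) and z = 33
#: (heavy chain) glycoforms 16 Da apart are only ~1.0 / 0.48 Th apart, so
#: envelope-wide windows would swallow the neighbour.
DEFAULT_PLANS = {
    "peptide": dict(tolerance=10.0, tolerance_unit="ppm", mass_mode="mono"),
    "fc2": dict(
        tolerance=0.2, tolerance_unit="Th", mass_mode="avg", window_halfwidth_th=0.5
    ),
    "heavy_chain": dict(
        tolerance=0.1, tolerance_unit="Th", mass_mode="avg", window_halfwidth_th=0.25
    ),
    "intact": dict(tolerance=2.0, tolerance_unit="Th", mass_mode="avg"),
}


def default_plan(level: str, charges) -> ChargePlan:
    return ChargePlan(charges=tuple(charges), **DEFAULT_PLANS[level])


def theoretical_mz(species, charge: int, mode: str = "mono") -> float:
    """m/z of a species (or bare neutral mass) at the given protonation."""
    if charge < 1:
        raise ValueError("charge must be >= 1")
    m = species if isinstance(species, (int, float)) else species_mass(species, mode)
    return (m + charge * PROTON_MASS) / charge


@dataclass
class WindowPlan:
    windows: dict[str, list[MzWindow]]
    masses: dict[str, float]
    overlaps: list[tuple[str, str]] = field(default_factory=list)


def _species_formula(s: GlycoSpecies) -> dict[str, int]:
    bb = s.backbone
    if bb.sequence is not None:
        formula = dict(_pmass.Composition(sequence=bb.sequence))
    else:
        try:
            base = bb.mass("avg")
        except ValueError:
            base = bb.mass("mono")
        formula = averagine_formula(base)
    for g in s.glycans:
        for e, n in g.elemental_formula().items():
            formula[e] = formula.get(e, 0) + n
    return formula


def build_windows(
    species: list[GlycoSpecies],
    plan: ChargePlan,
    envelope_floor: float = 1e-4,
) -> WindowPlan:
    """Per-species extraction windows covering the isotope envelope.

    Raises :class:`IndistinguishableSpeciesError` when two species' windows
    coincide at every charge (equal masses — an isobaric group the raw
    spectrum cannot split).
    """
    names = [s.name for s in species]
    if len(set(names)) != len(names):
        raise ValueError("duplicate species names in library")
    windows: dict[str, list[MzWindow]] = {}
    masses: dict[str, float] = {}
    for s in species:
        m = species_mass(s, plan.mass_mode)
        if plan.window_halfwidth_th is None:
            lo_off, hi_off, centroid = envelope_extent(
                _species_formula(s), envelope_floor
            )
            if plan.mass_mode == "avg":
                # envelope offsets are relative to the monoisotopic mass;
                # shift so the configured (average) mass sits at the centroid
                lo_off, hi_off = lo_off - centroid, hi_off - centroid
        else:
            lo_off = hi_off = 0.0
        mass_lo, mass_hi = m + lo_off, m + hi_off
        wins = []
        for z in plan.charges:
            lo = (mass_lo + z * PROTON_MASS) / z
            hi = (mass_hi + z * PROTON_MASS) / z
            half = plan.window_halfwidth_th or 0.0
            tol = plan.tol_th(0.5 * (lo + hi)) + half
            wins.append(MzWindow(lo - tol, hi + tol))
        windows[s.name] = wins
        masses[s.name] = m

    # exact isobars: identical mass -> identical windows everywhere
    order = sorted(names, key=lambda n: masses[n])
    iso_group: list[str] = [order[0]] if order else []
    for prev, cur in zip(order, order[1:]):
        if abs(masses[cur] - masses[prev]) < 1e-9:
            iso_group.append(cur)
        else:
            if len(iso_group) > 1:
                raise IndistinguishableSpeciesError(
                    "species are isobaric and cannot be separated in the raw "
                    f"spectrum: {sorted(iso_group)}; merge them and resolve "
                    "the group by intact-level pair annotation"
                )
            iso_group = [cur]
    if len(iso_group) > 1:
        raise IndistinguishableSpeciesError(
            "species are isobaric and cannot be separated in the raw "
            f"spectrum: {sorted(iso_group)}; merge them and resolve the "
            "group by intact-level pair annotation"
        )

    overlaps = []
    flat = [(n, w) for n in names for w in windows[n]]
    flat.sort(key=lambda t: t[1].lower)
    for (na, wa), (nb, wb) in zip(flat, flat[1:]):
        if na != nb and wa.overlaps(wb):
            pair = tuple(sorted((na, nb)))
            if pair not in overlaps:
                overlaps.append(pair)
    for na, nb in overlaps:
        logger.warning(
            "extraction windows of %s and %s overlap; shared signal is "
            "counted for both species",
            na,
            nb,
        )
    return WindowPlan(windows=windows, masses=masses, overlaps=overlaps)


@dataclass
class AbundanceProfile:
    """Fractional abundances (summing to 1) and raw ion currents of the
    considered species at one structural level, one replicate."""

    level: str
    replicate: str | int
    abundances: dict[str, float]
    ion_currents: dict[str, float]

    def __post_init__(self) -> None:
        if self.abundances:
            total = sum(self.abundances.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(
                    f"fractional abundances sum to {total!r}, expected 1"
                )
        if set(self.abundances) != set(self.ion_currents):
            raise ValueError("abundances and ion currents list different species")

    @property
    def species(self) -> list[str]:
        return list(self.abundances)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "species": list(self.abundances),
                "ion_current": [self.ion_currents[s] for s in self.abundances],
                "frac_abundance": list(self.abundances.values()),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, level: str = "", replicate: str | int = 0):
        df = pd.read_csv(path)
        cur = dict(zip(df["species"], df["ion_current"].astype(float)))
        ab = dict(zip(df["species"], df["frac_abundance"].astype(float)))
        total = sum(ab.values())
        ab = {k: v / total for k, v in ab.items()}
        return cls(level, replicate, ab, cur)


def quantify(
    series: SpectrumSeries,
    species: list[GlycoSpecies],
    plan: ChargePlan,
    scans: tuple[int, int] | None = None,
    rt: tuple[float, float] | None = None,
    level: str = "",
    replicate: str | int = 0,
    envelope_floor: float = 1e-4,
) -> AbundanceProfile:
    """Fractional abundances of the listed species in the scan range.

    Each species' ion current is the sum of :func:`integrate_window` over
    its windows; species without signal are retained at 0.  Errors if the
    summed current of all species is zero ("no signal in scan range").
    """
    wp = build_windows(species, plan, envelope_floor)
    currents = {
        name: sum(integrate_window(series, w, scans=scans, rt=rt) for w in wins)
        for name, wins in wp.windows.items()
    }
    total = sum(currents.values())
    if total <= 0:
        raise ValueError("no signal in scan range for any listed species")
    abundances = {name: cur / total for name, cur in currents.items()}
    # guard against accumulated float error in the sum-to-one invariant
    norm = sum(abundances.values())
    abundances = {k: v / norm for k, v in abundances.items()}
    return AbundanceProfile(level, replicate, abundances, currents)


def replicate_stats(profiles: list[AbundanceProfile]) -> pd.DataFrame:
    """Per-species mean, sample SD (n-1), and RSD% across replicates.

    RSD is reported as missing (NaN) where the mean abundance is zero.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two replicate profiles")
    ref = set(profiles[0].abundances)
    for p in profiles[1:]:
        if set(p.abundances) != ref:
            raise ValueError("replicate profiles list different species sets")
    species = list(profiles[0].abundances)
    data = np.array([[p.abundances[s] for s in species] for p in profiles])
    mean = data.mean(axis=0)
    sd = data.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rsd = np.where(mean > 0, 100.0 * sd / mean, np.nan)
    return pd.DataFrame(
        {"mean": mean, "sd": sd, "rsd_pct": rsd}, index=pd.Index(species, name="species")
    )


@dataclass(frozen=True)
class GlycationDegree:
    """Fitted per-site glycation probability with the hexose-ladder profile."""

    g: float
    n_sites: int
    abundances: dict[int, float]


def glycation_degree(
    series: SpectrumSeries,
    backbone: Backbone,
    plan: ChargePlan,
    max_hexoses: int = 4,
    scans: tuple[int, int] | None = None,
    rt: tuple[float, float] | None = None,
) -> GlycationDegree:
    """Per-site glycation degree from a deglycosylated-protein run.

    Quantifies the hexose ladder backbone + k*Hex (k = 0..max) and fits the
    per-site probability under independent-site glycation: with unmodified
    fraction a0, g = 1 - a0 for one site and g = 1 - sqrt(a0) for two.
    """
    from .glycans import GlycanComposition  # local import to avoid cycle noise

    ladder = [
        GlycoSpecies(
            backbone,
            ()
            if k == 0
            else (GlycanComposition.from_dict({"Hex": k}, name=f"{k}Hex"),),
        )
        for k in range(max_hexoses + 1)
    ]
    # the ladder species' auto-names are the glycan names; map back to k
    profile = quantify(
        series, ladder, plan, scans=scans, rt=rt, level=backbone.level
    )
    by_k = {
        k: profile.abundances[s.name] for k, s in zip(range(max_hexoses + 1), ladder)
    }
    a0 = by_k[0]
    if a0 <= 0:
        raise ValueError(
            "unmodified species has zero abundance; glycation degree undefined"
        )
    n_sites = 2 if backbone.level == "intact" else 1
    g = 1.0 - a0 if n_sites == 1 else 1.0 - math.sqrt(a0)
    return GlycationDegree(g=g, n_sites=n_sites, abundances=by_k)
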