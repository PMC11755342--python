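"""Synthetic multi-charge electrospray spectra of glycoforms with known
ground truth.

The generator emulates the structure of the real experiments at every
structural level: a shared backbone carrying a site glycan profile (a pair
profile under site independence at the intact level), per-site glycation at
a stated degree, a series of scans with a chromatographic elution profile
(flat for direct infusion), Gaussian peaks at each charge state whose areas
are proportional to species abundance times charge response, and optional
multiplicative/additive noise.  Every spectrum comes with truth tables, and
identical seeds give bit-identical output.

The m/z axis is built from merged "islands" around the expected peaks
rather than one dense global grid; this keeps 60-scan intact-protein series
small while preserving trapezoid-exact peak areas (grids extend many sigma
beyond every extraction window).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .fixtures import intact_backbone, peptide_backbone, site_library, site_profile_20
from .glycans import (
    PROTON_MASS,
    Backbone,
    GlycanComposition,
    GlycoSpecies,
    _canonical_name,
    composition_mass,
    parse_oxford_name,
)
from .glycation import glycate_forward
from .spectra import Scan, SpectrumSeries

__all__ = [
    "LevelParams",
    "TruthSpec",
    "SimulatedLevel",
    "sample_pair_profile",
    "simulate_level",
    "nistmab_truth",
]

_LEVEL_CODE = {"peptide": 1, "fc2": 2, "heavy_chain": 3, "intact": 4}


@dataclass(frozen=True)
class LevelParams:
    """Instrument/acquisition emulation parameters for one level."""

    charges: tuple[int, ...]
    mass_mode: str = "avg"
    mz_sigma: float = 0.3  # Gaussian peak sigma, Th
    grid_step: float = 0.1  # m/z sampling step, Th
    #: peak placement above the nominal (mono/avg) mass, Da — emulates the
    #: isotope-envelope centroid sitting above the monoisotopic position
    mz_peak_offset_da: float = 0.0
    island_halfwidth: float = 15.0  # grid extent around each peak, Th
    n_scans: int = 60
    rt_start: float = 0.0
    rt_step: float = 0.02  # min
    chrom_center: float | None = None  # None = flat (direct infusion)
    chrom_sigma: float = 0.1  # min
    rt_offsets: dict[str, float] = field(default_factory=dict, hash=False)
    response: dict[int, float] = field(default_factory=dict, hash=False)
    noise_sd: float = 0.0  # multiplicative, relative
    noise_floor: float = 0.0  # additive, absolute (pre-scaling units)
    apply_glycation: bool = False
    base_intensity: float = 1e6


#: Acquisition emulation defaults per level, mirroring the resolution
#: regimes of the three measurement types (high-resolution LC-MS for the
#: glycopeptide, lower-resolution LC-MS for subunits, direct-infusion
#: native MS with 60 averaged scans for the intact protein).
DEFAULT_LEVEL_PARAMS = {
    "peptide": LevelParams(
        charges=(2, 3),
        mass_mode="mono",
        mz_sigma=0.04,
        grid_step=0.01,
        island_halfwidth=8.0,
        mz_peak_offset_da=1.5,
        n_scans=20,
        chrom_center=0.2,
        chrom_sigma=0.06,
    ),
    "fc2": LevelParams(
        charges=(16,),
        mz_sigma=0.05,
        grid_step=0.0125,
        island_halfwidth=4.0,
        n_scans=30,
        chrom_center=0.3,
        chrom_sigma=0.08,
        apply_glycation=True,
    ),
    "heavy_chain": LevelParams(
        charges=(33,),
        mz_sigma=0.02,
        grid_step=0.005,
        island_halfwidth=2.0,
        n_scans=30,
        chrom_center=0.3,
        chrom_sigma=0.08,
        apply_glycation=True,
    ),
    "intact": LevelParams(
        charges=(26, 27, 28),
        mz_sigma=0.3,
        grid_step=0.1,
        island_halfwidth=15.0,
        n_scans=60,
        apply_glycation=True,
    ),
}


@dataclass
class TruthSpec:
    """Ground truth for a simulated study: who is there and how much.

    ``site_profile`` is the per-site glycan distribution (fractions summing
    to one, "none" allowed); the intact level pairs sites independently.
    ``glycation_g`` is the per-site glycation degree applied wherever a
    level's parameters enable it.  ``seed`` is mandatory: all randomness
    derives from it.
    """

    site_profile: dict[str, float]
    backbones: dict[str, Backbone]
    seed: int
    glycation_g: float = 0.0
    levels: dict[str, LevelParams] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(self.site_profile.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"site profile sums to {total!r}, expected 1")
        if any(v < 0 for v in self.site_profile.values()):
            raise ValueError("site fractions must be >= 0")
        if not 0.0 <= self.glycation_g <= 0.5:
            raise ValueError("glycation degree must be in [0, 0.5]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        merged = dict(DEFAULT_LEVEL_PARAMS)
        merged.update(self.levels)
        self.levels = merged

    def compositions(self) -> dict[str, GlycanComposition]:
        return {name: parse_oxford_name(name) for name in self.site_profile}


def nistmab_truth(
    seed: int, glycation_g: float = 0.0, **overrides
) -> TruthSpec:
    """NISTmAb-like study conditions: the 20-species site profile on the
    standard backbones."""
    from .fixtures import fc2_backbone, heavy_chain_backbone

    return TruthSpec(
        site_profile=site_profile_20(),
        backbones={
            "peptide": peptide_backbone(),
            "fc2": fc2_backbone(),
            "heavy_chain": heavy_chain_backbone(),
            "intact": intact_backbone(),
        },
        seed=seed,
        glycation_g=glycation_g,
        **overrides,
    )


def sample_pair_profile(
    site_profile: dict[str, float], n_sites: int = 2
) -> dict[tuple[str, str], float]:
    """Pair distribution under site independence.

    P(g1, g2) = 2 a1 a2 for unordered heterodimers and a^2 for self-pairs;
    the marginals reproduce the site profile exactly.
    """
    if n_sites != 2:
        raise ValueError("pairing is defined for two sites")
    names = list(site_profile)
    out: dict[tuple[str, str], float] = {}
    for i, g1 in enumerate(names):
        for g2 in names[i:]:
            a = site_profile[g1] * site_profile[g2]
            pair = tuple(sorted((g1, g2)))
            out[pair] = a if g1 == g2 else 2.0 * a
    return out


@dataclass
class SimulatedLevel:
    """One simulated run: the spectra plus every layer of ground truth."""

    level: str
    series: SpectrumSeries
    species: pd.DataFrame  # name, mass, abundance (post-glycation = observed)
    true_profile: dict[str, float]  # pre-glycation species profile
    observed_profile: dict[str, float]  # what the spectrum actually encodes
    compositions: dict[str, GlycanComposition]
    pair_truth: pd.DataFrame | None = None  # intact only
    params: LevelParams | None = None


def _merged_islands(
    centers: list[float], halfwidth: float, step: float
) -> np.ndarray:
    intervals = sorted((c - halfwidth, c + halfwidth) for c in centers)
    merged = [list(intervals[0])]
    for lo, hi in intervals[1:]:
        if lo <= merged[-1][1] + 2 * step:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    parts = [np.arange(lo, hi + step, step) for lo, hi in merged]
    return np.concatenate(parts)


def _synthesise(
    species: list[tuple[str, float, float]],  # (name, mass, abundance)
    params: LevelParams,
    rng: np.random.Generator,
) -> SpectrumSeries:
    charges = params.charges
    resp = {z: params.response.get(z, 1.0) for z in charges}
    centers = [
        (name, (m + params.mz_peak_offset_da + z * PROTON_MASS) / z, z)
        for name, m, _ in species
        for z in charges
    ]
    grid = _merged_islands([c for _, c, _ in centers], params.island_halfwidth, params.grid_step)
    rts = params.rt_start + params.rt_step * np.arange(params.n_scans)

    abundance = {name: a for name, _, a in species}
    sigma = params.mz_sigma
    norm = params.base_intensity / (sigma * np.sqrt(2.0 * np.pi))
    scans = []
    for rt in rts:
        intensity = np.zeros_like(grid)
        for name, mzc, z in centers:
            if params.chrom_center is None:
                w = 1.0
            else:
                c = params.chrom_center + params.rt_offsets.get(name, 0.0)
                w = np.exp(-0.5 * ((rt - c) / params.chrom_sigma) ** 2)
            amp = abundance[name] * resp[z] * w * norm
            if amp == 0.0:
                continue
            lo, hi = np.searchsorted(grid, [mzc - 10 * sigma, mzc + 10 * sigma])
            seg = grid[lo:hi]
            intensity[lo:hi] += amp * np.exp(-0.5 * ((seg - mzc) / sigma) ** 2)
        if params.noise_sd > 0.0:
            intensity = intensity * (
                1.0 + params.noise_sd * rng.standard_normal(intensity.size)
            )
        if params.noise_floor > 0.0:
            intensity = intensity + params.noise_floor * np.abs(
                rng.standard_normal(intensity.size)
            )
        np.clip(intensity, 0.0, None, out=intensity)
        scans.append(Scan(rt_min=float(rt), mz=grid, intensity=intensity))
    return SpectrumSeries(scans)


def _intact_mass_groups(
    pair_profile: dict[tuple[str, str], float],
    comps: dict[str, GlycanComposition],
) -> tuple[dict[str, float], dict[str, GlycanComposition], pd.DataFrame]:
    """Merge exactly isobaric pairs into mass-group species (total glycan
    composition); the raw spectrum cannot split them."""
    groups: dict[tuple[int, ...], float] = {}
    members: dict[tuple[int, ...], list[tuple[str, float]]] = {}
    for (g1, g2), p in pair_profile.items():
        vec = tuple(
            a + b for a, b in zip(comps[g1].counts, comps[g2].counts)
        )
        groups[vec] = groups.get(vec, 0.0) + p
        members.setdefault(vec, []).append(("/".join(sorted((g1, g2))), p))
    profile: dict[str, float] = {}
    gcomps: dict[str, GlycanComposition] = {}
    rows = []
    for vec, p in groups.items():
        name = _canonical_name(vec)
        profile[name] = p
        gcomps[name] = GlycanComposition(vec, name)
        for pair_name, pp in members[vec]:
            rows.append(
                {"pair": pair_name, "mass_group": name, "abundance": pp}
            )
    truth = pd.DataFrame(rows).sort_values("pair").reset_index(drop=True)
    return profile, gcomps, truth


def simulate_level(
    truth: TruthSpec,
    level: str,
    replicate: int = 0,
    deglycosylated: bool = False,
    params: LevelParams | None = None,
) -> SimulatedLevel:
    """Simulate one run at one structural level.

    ``deglycosylated`` emulates the PNGase-F-treated control used to read
    off the glycation degree: the species are the bare backbone plus its
    glycation hexose ladder.  Otherwise the species are the site profile
    (paired independently and merged into isobaric mass groups at the
    intact level), with forward glycation applied when the level's
    parameters say so.
    """
    if level not in _LEVEL_CODE:
        raise ValueError(f"unknown level {level!r}")
    if params is None:
        params = truth.levels[level]
    backbone = truth.backbones[level]
    mode = params.mass_mode
    glyc_sites = 2 if level == "intact" else 1
    rng = np.random.default_rng(
        [truth.seed, _LEVEL_CODE[level], replicate, int(deglycosylated)]
    )

    pair_truth = None
    if deglycosylated:
        g = truth.glycation_g
        from math import comb

        profile = {
            f"{k}Hex": comb(glyc_sites, k) * g**k * (1 - g) ** (glyc_sites - k)
            for k in range(glyc_sites + 1)
        }
        comps = {
            f"{k}Hex": GlycanComposition.from_dict({"Hex": k}, name=f"{k}Hex")
            for k in range(glyc_sites + 1)
        }
        observed = dict(profile)
    else:
        site_comps = truth.compositions()
        if level == "intact":
            pairs = sample_pair_profile(truth.site_profile)
            profile, comps, pair_truth = _intact_mass_groups(pairs, site_comps)
        else:
            profile = dict(truth.site_profile)
            comps = dict(site_comps)
        if params.apply_glycation and truth.glycation_g > 0.0:
            fwd = glycate_forward(
                profile, truth.glycation_g, glyc_sites, comps, extend_library=True
            )
            observed = fwd.profile
        else:
            observed = dict(profile)

    base = backbone.mass(mode)
    rows = [
        (name, base + composition_mass(comps[name], mode), a)
        for name, a in observed.items()
    ]
    series = _synthesise(rows, params, rng)
    species = pd.DataFrame(rows, columns=["name", "mass", "abundance"]).sort_values(
        "mass", ignore_index=True
    )
    return SimulatedLevel(
        level=level,
        series=series,
        species=species,
        true_profile=profile,
        observed_profile=observed,
        compositions=comps,
        pair_truth=pair_truth,
        params=params,
    )


def intact_ladder(
    n_species: int = 20,
    profile_values: list[float] | None = None,
) -> tuple[dict[str, float], dict[str, GlycanComposition]]:
    """A 20-species intact glycoform ladder with well-separated masses.

    Species are total (two-site) glycan compositions starting from the
    doubly fucosylated biantennary pair (Hex6 HexNAc8 dHex2) and growing by
    alternating hexose / HexNAc steps — the galactosylation-and-antenna
    series that dominates real intact-IgG spectra, with consecutive masses
    162 or 203 Da apart.  Abundances default to the NISTmAb-like profile
    values (majors ~30 %, minors 0.3-3 %).
    """
    if profile_values is None:
        profile_values = list(site_profile_20().values())
    if len(profile_values) < n_species:
        raise ValueError("not enough profile values for the requested ladder")
    vec = [6, 8, 2, 0, 0]  # Hex, HexNAc, dHex, Neu5Ac, Neu5Gc
    profile: dict[str, float] = {}
    comps: dict[str, GlycanComposition] = {}
    for i in range(n_species):
        tvec = tuple(vec)
        name = _canonical_name(tvec)
        comps[name] = GlycanComposition(tvec, name)
        profile[name] = profile_values[i]
        vec[i % 2] += 1  # alternate Hex / HexNAc growth
    total = sum(profile.values())
    profile = {k: v / total for k, v in profile.items()}
    return profile, comps


def simulate_intact_ladder(
    seed: int,
    n_species: int = 20,
    noise_sd: float = 0.0,
    backbone: Backbone | None = None,
    params: LevelParams | None = None,
) -> SimulatedLevel:
    """Simulated intact-level run of the glycoform ladder (no glycation)."""
    if backbone is None:
        backbone = intact_backbone()
    if params is None:
        params = DEFAULT_LEVEL_PARAMS["intact"]
    if noise_sd:
        params = LevelParams(
            **{**params.__dict__, "noise_sd": noise_sd}
        )
    profile, comps = intact_ladder(n_species)
    rng = np.random.default_rng([seed, 99, n_species])
    base = backbone.mass(params.mass_mode)
    rows = [
        (name, base + composition_mass(comps[name], params.mass_mode), a)
        for name, a in profile.items()
    ]
    series = _synthesise(rows, params, rng)
    species = pd.DataFrame(rows, columns=["name", "mass", "abundance"]).sort_values(
        "mass", ignore_index=True
    )
    return SimulatedLevel(
        level="intact",
        series=series,
        species=species,
        true_profile=profile,
        observed_profile=dict(profile),
        compositions=comps,
        params=params,
    )


def library_species(
    backbone: Backbone, compositions: dict[str, GlycanComposition]
) -> list[GlycoSpecies]:
    """GlycoSpecies list for quantification, one per composition name
    ("none"/empty composition gives the unoccupied backbone); species are
    labelled with the composition-dict names so profiles line up with the
    truth tables."""
    out = []
    for name, comp in compositions.items():
        glycans = () if not any(comp.counts) else (comp,)
        out.append(GlycoSpecies(backbone, glycans, label=name))
    return out
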