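"""Machine-readable NISTmAb reference fixtures.

The reference-material IgG (NISTmAb, RM 8671) is the standard benchmark for
antibody glycosylation workflows.  This module ships, as data:

* the glycan detection groups of its four structural levels (released
  glycan, tryptic glycopeptide, Fc/2 subunit, heavy chain), keyed a-g by
  membership pattern;
* backbone definitions: the nine-residue tryptic glycopeptide EEQYNSTYR
  carrying Asn297, the Fc/2 and heavy-chain polypeptides (fixed average
  masses), and a synthetic deglycosylated intact backbone;
* a NISTmAb-like 20-glycan site profile (complex-type core-fucosylated
  majors, minors at 0.3 %-3 %) used as simulation ground truth;
* the worked isobaric-pair scoring example (FA2G0+FA2G2 vs FA2G1+FA2G1).

Only the group lists, the peptide sequence, and the Fc/2 / heavy-chain
masses are reference values; the intact backbone mass and the site profile
are synthetic stand-ins for simulation.
"""

from __future__ import annotations

from .glycans import Backbone, GlycanComposition, parse_oxford_name

__all__ = [
    "FIG_GROUPS",
    "LEVEL_REGIONS",
    "level_sets",
    "peptide_backbone",
    "fc2_backbone",
    "heavy_chain_backbone",
    "intact_backbone",
    "site_profile_20",
    "worked_scoring_example",
    "fixture_nistmab",
]

#: Detection groups by membership pattern (isomer-collapsed names).
FIG_GROUPS: dict[str, tuple[str, ...]] = {
    "a": (
        "A1G0",
        "FA1G0",
        "FA1G0-M5",
        "FA1G1",
        "FA1G1Sg1",
        "FA2G0",
        "FA2G1",
        "FA2G1Sg1",
        "FA2G2",
        "FA2G2Sg1",
        "FA2G3",
        "FA2G4",
        "M5",
    ),
    "b": ("FA1G1-M5", "M3"),
    "c": ("A1G0-M5", "A2G2", "FA1G2", "M6-U"),
    "d": ("M3-F",),
    "e": ("A1G1", "A2G0", "A2G1", "FA3G1", "M6"),
    "f": ("A1G1Sg1-M5", "M7", "none"),
    "g": ("A3G1", "FA2G3Sg1", "M4", "M9"),
}

#: Which levels each group belongs to — the unique assignment consistent
#: with the narrative: a = all four levels; b = released + both subunits;
#: c = released only; d = released + peptide; e = peptide only; f = peptide
#: + both subunits; g = subunits only.
LEVEL_REGIONS: dict[str, tuple[str, ...]] = {
    "released": ("a", "b", "c", "d"),
    "peptide": ("a", "d", "e", "f"),
    "fc2": ("a", "b", "f", "g"),
    "heavy_chain": ("a", "b", "f", "g"),
}


def level_sets() -> dict[str, set[str]]:
    """Detected-glycan sets per structural level (canonical names)."""
    return {
        level: {name for grp in groups for name in FIG_GROUPS[grp]}
        for level, groups in LEVEL_REGIONS.items()
    }


def peptide_backbone() -> Backbone:
    """Tryptic glycopeptide EEQYNSTYR (Asn297 site), mono mass 1188.505 Da."""
    return Backbone(identifier="EEQYNSTYR", level="peptide", sequence="EEQYNSTYR")


def fc2_backbone() -> Backbone:
    """Fc/2 polypeptide after IdeS cleavage (210 residues, avg 23,783 Da)."""
    return Backbone(identifier="NISTmAb-Fc/2", level="fc2", avg_mass=23783.0)


def heavy_chain_backbone() -> Backbone:
    """Heavy chain after disulfide reduction (449 residues, avg 49,454 Da)."""
    return Backbone(
        identifier="NISTmAb-HC", level="heavy_chain", avg_mass=49454.0
    )


def intact_backbone() -> Backbone:
    """Synthetic deglycosylated intact-IgG backbone, two glycan sites.

    145,140 Da average is a plausible aglycosylated tetramer mass for a
    NISTmAb-like IgG1; it is a simulation stand-in, not a measured value.
    """
    return Backbone(
        identifier="synthetic-intact-IgG", level="intact", avg_mass=145140.0
    )


#: NISTmAb-like site-level glycan profile: 20 species (including the
#: unoccupied site) with complex-type fucosylated majors and minors in the
#: 0.3-3 % range.  Chosen so that all pairwise mass gaps exceed ~16 Da and
#: no two species collide across the charge states used at any level, so
#: every species is individually resolvable.
SITE_PROFILE_20: dict[str, float] = {
    "FA2G0": 0.300,
    "FA2G1": 0.330,
    "FA2G2": 0.130,
    "M5": 0.035,
    "FA1G1": 0.030,
    "FA1G0": 0.022,
    "none": 0.020,
    "A1G1": 0.020,
    "A2G0": 0.015,
    "FA2G1Sg1": 0.013,
    "A2G1": 0.012,
    "M6": 0.012,
    "FA2G3": 0.012,
    "A1G0": 0.010,
    "FA1G0-M5": 0.009,
    "M7": 0.008,
    "FA2G2Sg1": 0.008,
    "FA2G4": 0.005,
    "A3G1": 0.005,
    "A1G1Sg1-M5": 0.004,
}


def site_profile_20() -> dict[str, float]:
    return dict(SITE_PROFILE_20)


def site_library(profile: dict[str, float] | None = None) -> dict[str, "GlycanComposition"]:
    """name -> composition for every glycan in a site profile."""
    prof = profile if profile is not None else SITE_PROFILE_20
    return {name: parse_oxford_name(name) for name in prof}


def worked_scoring_example() -> dict:
    """The canonical isobaric-pair apportionment example.

    With site abundances FA2G0 25 %, FA2G1 50 %, FA2G2 25 %, the pair mass
    shared by FA2G0+FA2G2 and FA2G1+FA2G1 splits 33.33 % / 66.67 %: the
    independence weights are 2 x 0.25 x 0.25 = 0.125 versus 0.5^2 = 0.25.
    """
    return {
        "site_abundances": {"FA2G0": 0.25, "FA2G1": 0.50, "FA2G2": 0.25},
        "candidates": [("FA2G0", "FA2G2"), ("FA2G1", "FA2G1")],
        "expected_scores_pct": (100.0 / 3.0, 200.0 / 3.0),
    }


def fixture_nistmab() -> dict:
    """Bundle of all NISTmAb fixtures (groups, level sets, backbones,
    site profile, worked scoring example)."""
    return {
        "groups": {k: list(v) for k, v in FIG_GROUPS.items()},
        "level_sets": level_sets(),
        "backbones": {
            "peptide": peptide_backbone(),
            "fc2": fc2_backbone(),
            "heavy_chain": heavy_chain_backbone(),
            "intact": intact_backbone(),
        },
        "site_profile": site_profile_20(),
        "worked_example": worked_scoring_example(),
    }
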