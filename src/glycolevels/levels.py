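"""Cross-level harmonisation: isomer collapsing, detection sets, Venn
regions, abundance matrices, and dispersion reports.

Released-glycan analysis distinguishes linkage isomers (FA2G1[6] versus
FA2G1[3]) that mass spectrometry cannot; before any cross-level comparison
such names are collapsed to one canonical composition.  Detection sets per
structural level are then compared by exhaustive Venn regions, and the
per-replicate abundance matrix supports the minor-species (< 5 %) report
and descriptive level-versus-level comparisons.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .glycans import GlycanParseError, parse_oxford_name

__all__ = [
    "LevelSet",
    "collapse_isomers",
    "venn_regions",
    "overlap_pct",
    "build_matrix",
    "minor_species_report",
    "compare_levels",
]


@dataclass(frozen=True)
class LevelSet:
    """Isomer-collapsed canonical glycan names detected at one level."""

    level: str
    names: frozenset[str]

    @classmethod
    def from_names(cls, level: str, names) -> "LevelSet":
        return cls(level, frozenset(collapse_isomers(names)))


def collapse_isomers(
    names, aliases: dict[str, dict[str, int]] | None = None
) -> set[str]:
    """Map names to canonical composition names, merging MS-isobaric isomer
    labels (arm/linkage decorations).  "none" passes through.  All parse
    failures are collected and reported together.
    """
    out: set[str] = set()
    failures: dict[str, str] = {}
    for name in names:
        try:
            out.add(parse_oxford_name(name, aliases).canonical_name)
        except GlycanParseError as exc:
            failures[str(name)] = str(exc)
    if failures:
        listing = "; ".join(f"{n!r}: {msg}" for n, msg in sorted(failures.items()))
        raise GlycanParseError(f"unparseable glycan name(s): {listing}")
    return out


def venn_regions(level_sets: dict[str, set]) -> dict[frozenset, set]:
    """Exhaustive partition of the union into 2^k - 1 membership regions.

    Keys are frozensets of level names (the membership signature); empty
    regions are present with empty member sets so counts always partition
    the union.
    """
    if len(level_sets) < 2:
        raise ValueError("need at least two level sets")
    levels = list(level_sets)
    regions: dict[frozenset, set] = {}
    for r in range(1, len(levels) + 1):
        for combo in itertools.combinations(levels, r):
            inside = set.intersection(*(set(level_sets[l]) for l in combo))
            outside = set.union(
                set(), *(set(level_sets[l]) for l in levels if l not in combo)
            )
            regions[frozenset(combo)] = inside - outside
    return regions


def overlap_pct(a: set, b: set) -> float:
    """Percentage overlap of two detection sets: 100 |A n B| / |A u B|."""
    a, b = set(a), set(b)
    if not a and not b:
        raise ValueError("both sets are empty; overlap undefined")
    return 100.0 * len(a & b) / len(a | b)


def build_matrix(profiles) -> pd.DataFrame:
    """Cross-level abundance matrix: rows glycans, columns (level,
    replicate), values fractional abundance (NaN where a species was not
    considered at a level)."""
    cols = {}
    for p in profiles:
        cols[(p.level, p.replicate)] = pd.Series(p.abundances)
    df = pd.DataFrame(cols)
    df.columns = pd.MultiIndex.from_tuples(df.columns, names=["level", "replicate"])
    df.index.name = "species"
    return df.sort_index()


def minor_species_report(
    matrix: pd.DataFrame, threshold: float = 0.05
) -> pd.DataFrame:
    """Glycans below the low-abundance threshold at every level where they
    were detected, with per-level means, RSDs and detection flags.

    Detection means a nonzero abundance in at least one replicate of the
    level.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    levels = matrix.columns.get_level_values("level").unique()
    rows = []
    for glycan, row in matrix.iterrows():
        rec: dict = {"species": glycan}
        minor_everywhere = True
        detected_anywhere = False
        for level in levels:
            vals = row[level].astype(float)
            detected = bool((vals.fillna(0) > 0).any())
            mean = float(vals.mean()) if detected else np.nan
            sd = float(vals.std(ddof=1)) if detected and vals.notna().sum() > 1 else np.nan
            rec[f"{level}_detected"] = detected
            rec[f"{level}_mean"] = mean
            rec[f"{level}_rsd_pct"] = (
                100.0 * sd / mean if detected and mean and not np.isnan(sd) else np.nan
            )
            if detected:
                detected_anywhere = True
                if mean >= threshold:
                    minor_everywhere = False
        if detected_anywhere and minor_everywhere:
            rows.append(rec)
    return pd.DataFrame(rows).set_index("species") if rows else pd.DataFrame(
        columns=["species"]
    ).set_index("species")


def compare_levels(
    matrix: pd.DataFrame, glycan: str, confidence: float = 0.95
) -> pd.DataFrame:
    """Pairwise mean differences of one glycan's abundance between levels,
    with Welch two-sample intervals (descriptive, not a hypothesis test).

    With a single replicate on either side the difference is reported
    without an interval.
    """
    if glycan not in matrix.index:
        raise KeyError(f"glycan {glycan!r} not in matrix")
    row = matrix.loc[glycan]
    levels = matrix.columns.get_level_values("level").unique()
    rows = []
    for la, lb in itertools.combinations(levels, 2):
        a = row[la].dropna().to_numpy(dtype=float)
        b = row[lb].dropna().to_numpy(dtype=float)
        if a.size == 0 or b.size == 0:
            continue
        diff = float(a.mean() - b.mean())
        rec = {
            "level_a": la,
            "level_b": lb,
            "mean_diff": diff,
            "n_a": a.size,
            "n_b": b.size,
            "ci_low": np.nan,
            "ci_high": np.nan,
        }
        if a.size > 1 and b.size > 1:
            se2 = a.var(ddof=1) / a.size + b.var(ddof=1) / b.size
            if se2 > 0:
                se = np.sqrt(se2)
                # Welch-Satterthwaite degrees of freedom
                df = se2**2 / (
                    (a.var(ddof=1) / a.size) ** 2 / (a.size - 1)
                    + (b.var(ddof=1) / b.size) ** 2 / (b.size - 1)
                )
                tcrit = stats.t.ppf(0.5 + confidence / 2, df)
                rec["ci_low"] = diff - tcrit * se
                rec["ci_high"] = diff + tcrit * se
            else:
                rec["ci_low"] = rec["ci_high"] = diff
        rows.append(rec)
    return pd.DataFrame(rows)
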