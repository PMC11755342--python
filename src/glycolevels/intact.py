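"""Glycan-pair annotation of intact-protein neutral-mass peaks.

An intact IgG carries one N-glycan per heavy chain, so every neutral-mass
peak corresponds to an *unordered pair* of glycans (either member may also
be "none", an unoccupied site).  Distinct pairs can be exactly isobaric —
e.g. FA2G0+FA2G2 versus FA2G1+FA2G1 — so a peak's intensity is apportioned
among its candidate pairs by a *permutation score*: the independence-model
pair probability built from site-level (glycopeptide) abundances,

    weight(g1, g2) = 2 a(g1) a(g2)   if g1 != g2,
    weight(g, g)   = a(g)^2,

normalised to 100% over the peak's candidates.  Manually annotated peaks
(those the deconvolution step missed) carry exactly one candidate and no
score.

A small charge-ladder least-squares estimator stands in for full spectral
deconvolution: given m/z values of consecutive charge states it recovers
the neutral mass.
"""

from __future__ import annotations

import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .glycans import (
    PROTON_MASS,
    Backbone,
    GlycanComposition,
    composition_mass,
)

logger = logging.getLogger(__name__)

__all__ = [
    "NeutralMassPeak",
    "PairCandidate",
    "PairAnnotation",
    "estimate_neutral_mass",
    "enumerate_pairs",
    "permutation_scores",
    "annotate",
    "read_peak_list",
    "write_annotations",
]


@dataclass(frozen=True)
class NeutralMassPeak:
    """A zero-charge peak: average neutral mass plus intensity (or fractional
    abundance); ``source`` records whether it came from deconvolution or was
    annotated manually."""

    mass_da: float
    intensity: float
    source: str = "deconvolved"

    def __post_init__(self) -> None:
        if self.mass_da <= 0:
            raise ValueError("peak mass must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be >= 0")
        if self.source not in ("deconvolved", "manual"):
            raise ValueError("source must be 'deconvolved' or 'manual'")


@dataclass(frozen=True)
class PairCandidate:
    pair: tuple[str, str]  # unordered, stored sorted
    mass_error_da: float
    score_pct: float | None = None

    @property
    def name(self) -> str:
        return "/".join(self.pair)


@dataclass
class PairAnnotation:
    peak: NeutralMassPeak
    candidates: list[PairCandidate] = field(default_factory=list)

    @property
    def annotated(self) -> bool:
        return bool(self.candidates)


def estimate_neutral_mass(
    mz_values, tol_da: float = 2.0, max_charge: int = 100
) -> tuple[float, list[int]]:
    """Neutral mass from m/z values of consecutive charge states.

    The m/z values (any order) are assumed to form a descending-m/z ladder
    of consecutive charges z0, z0+1, ....  For each admissible z0 the
    ladder's per-peak mass estimates are computed; the z0 with the most
    consistent ladder wins, and the least-squares mass over that ladder is
    returned together with the inferred charges.  Errors if no ladder's
    internal spread is within ``tol_da``.
    """
    mz = np.sort(np.asarray(mz_values, dtype=float))[::-1]
    if mz.size < 2:
        raise ValueError("need at least two m/z values from consecutive charges")
    best = None
    for z0 in range(1, max_charge + 1):
        z = z0 + np.arange(mz.size)
        masses = z * (mz - PROTON_MASS)
        spread = masses.max() - masses.min()
        if best is None or spread < best[0]:
            best = (spread, z)
    spread, z = best
    if spread > tol_da:
        raise ValueError(
            f"no consistent charge ladder: best spread {spread:.3g} Da "
            f"exceeds tolerance {tol_da} Da"
        )
    # least squares of mz_i = (M + z_i p)/z_i in the m/z residuals
    m_ls = float(np.sum((mz - PROTON_MASS) / z) / np.sum(1.0 / z**2))
    return m_ls, [int(v) for v in z]


def _pair_masses(
    library: dict[str, GlycanComposition], mode: str = "avg"
) -> dict[str, float]:
    masses = {name: composition_mass(c, mode) for name, c in library.items()}
    masses.setdefault("none", 0.0)
    return masses


def enumerate_pairs(
    peak_mass: float,
    library: dict[str, GlycanComposition],
    backbone: Backbone,
    tol_da: float = 2.0,
) -> list[tuple[tuple[str, str], float]]:
    """All unordered glycan pairs (self-pairs and "none" included) whose
    total mass matches the peak within ``tol_da``.

    Returns ``[(pair, mass_error_da), ...]`` with mass error = annotated
    minus observed, sorted by |error| then name.  The search sorts single-
    glycan masses and bisects the partner range, so it stays fast for
    larger libraries while remaining equivalent to the exhaustive double
    loop.
    """
    if tol_da < 0:
        raise ValueError("tolerance must be >= 0")
    if not library:
        raise ValueError("empty glycan library")
    masses = _pair_masses(library, "avg")
    base = backbone.mass("avg")
    names = sorted(masses, key=lambda n: (masses[n], n))
    mvals = [masses[n] for n in names]
    out = []
    for i, g1 in enumerate(names):
        # partner mass must fall in [target - tol, target + tol]
        target = peak_mass - base - mvals[i]
        lo = bisect_left(mvals, target - tol_da, lo=i)
        hi = bisect_right(mvals, target + tol_da, lo=i)
        for j in range(max(lo, i), hi):
            err = base + mvals[i] + mvals[j] - peak_mass
            if abs(err) <= tol_da:  # guard float edges of bisect
                out.append((tuple(sorted((g1, names[j]))), err))
    out.sort(key=lambda t: (abs(t[1]), t[0]))
    return out


def permutation_scores(
    candidates: list[tuple[str, str]],
    site_abundances: dict[str, float],
) -> list[float]:
    """Percentage apportionment of one peak among its candidate pairs.

    Uses the site-independence weights (2 a1 a2 for heterodimers, a^2 for
    self-pairs) normalised to 100.  Glycans missing from the site profile
    count as abundance 0 (warned); if every weight is zero the scores fall
    back to uniform (warned).
    """
    weights = []
    for g1, g2 in candidates:
        a1 = site_abundances.get(g1)
        a2 = site_abundances.get(g2)
        for g, a in ((g1, a1), (g2, a2)):
            if a is None:
                logger.warning(
                    "glycan %s has no site-level abundance; treating as 0", g
                )
        a1 = a1 or 0.0
        a2 = a2 or 0.0
        if a1 < 0 or a2 < 0:
            raise ValueError("site abundances must be >= 0")
        weights.append(a1 * a2 if g1 == g2 else 2.0 * a1 * a2)
    total = sum(weights)
    if total == 0.0:
        if not candidates:
            return []
        logger.warning(
            "all candidate pairs have zero site-level weight; uniform scores"
        )
        return [100.0 / len(candidates)] * len(candidates)
    return [100.0 * w / total for w in weights]


def annotate(
    peaks: list[NeutralMassPeak],
    library: dict[str, GlycanComposition],
    site_abundances: dict[str, float],
    backbone: Backbone,
    tol_da: float = 2.0,
) -> tuple[list[PairAnnotation], dict[str, float]]:
    """Annotate peaks with candidate pairs and apportion their abundance.

    Deconvolved peaks get the full candidate list with permutation scores;
    manual peaks keep exactly one (closest-mass) candidate and no score.
    The returned pair profile splits each peak's fractional abundance among
    its candidates proportionally to the scores; peaks without candidates
    are retained under an ``unannotated@<mass>`` key so total abundance is
    conserved exactly.
    """
    total_int = sum(p.intensity for p in peaks)
    if total_int <= 0:
        raise ValueError("peak list carries no intensity")
    annotations = []
    pair_profile: dict[str, float] = {}
    for peak in peaks:
        frac = peak.intensity / total_int
        cands = enumerate_pairs(peak.mass_da, library, backbone, tol_da)
        if not cands:
            annotations.append(PairAnnotation(peak, []))
            key = f"unannotated@{peak.mass_da:.1f}"
            pair_profile[key] = pair_profile.get(key, 0.0) + frac
            continue
        if peak.source == "manual":
            pair, err = cands[0]  # closest in mass; no score by convention
            ann = PairAnnotation(peak, [PairCandidate(pair, err, None)])
            name = ann.candidates[0].name
            pair_profile[name] = pair_profile.get(name, 0.0) + frac
        else:
            scores = permutation_scores([p for p, _ in cands], site_abundances)
            ann = PairAnnotation(
                peak,
                [
                    PairCandidate(pair, err, score)
                    for (pair, err), score in zip(cands, scores)
                ],
            )
            for cand in ann.candidates:
                pair_profile[cand.name] = (
                    pair_profile.get(cand.name, 0.0) + frac * cand.score_pct / 100.0
                )
        annotations.append(ann)
    return annotations, pair_profile


# ---------------------------------------------------------------------------
# external interfaces

def read_peak_list(path) -> list[NeutralMassPeak]:
    """Peak list CSV: columns mass_da, abundance, source(deconvolved|manual)."""
    df = pd.read_csv(path)
    required = {"mass_da", "abundance"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak list CSV needs columns {sorted(required)}")
    if "source" not in df.columns:
        df["source"] = "deconvolved"
    return [
        NeutralMassPeak(float(r.mass_da), float(r.abundance), str(r.source))
        for r in df.itertuples()
    ]


def write_annotations(
    annotations: list[PairAnnotation],
    pair_profile: dict[str, float],
    path,
) -> None:
    rows = []
    for ann in annotations:
        if not ann.candidates:
            rows.append(
                {
                    "peak_mass_da": ann.peak.mass_da,
                    "source": ann.peak.source,
                    "pair": f"unannotated@{ann.peak.mass_da:.1f}",
                    "mass_error_da": np.nan,
                    "permutation_score_pct": np.nan,
                }
            )
            continue
        for cand in ann.candidates:
            rows.append(
                {
                    "peak_mass_da": ann.peak.mass_da,
                    "source": ann.peak.source,
                    "pair": cand.name,
                    "mass_error_da": cand.mass_error_da,
                    "permutation_score_pct": cand.score_pct,
                }
            )
    df = pd.DataFrame(rows)
    # apportioned abundance is a per-pair total over all contributing peaks
    totals = pd.Series(pair_profile, name="apportioned_abundance")
    df = df.merge(
        totals.rename_axis("pair").reset_index(), on="pair", how="left"
    )
    df.to_csv(path, index=False)
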