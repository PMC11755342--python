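"""Hexosylation-bias correction for glycated glyco-species profiles.

Glycation — the non-enzymatic attachment of glucose (+162 Da) to the
protein — is mass-indistinguishable from an extra galactose or mannose on
the glycan.  An observed abundance profile is therefore a mixture: each true
species contributes to the species one, two, ... hexoses heavier.  The model
here is independent-site glycation: every molecule gains k hexoses with
Binomial(n_sites, g) probability, where g is the per-site glycation degree
(one site at the subunit level, two at the intact level).

``glycate_forward`` applies the mixture; ``correct`` inverts it by walking
the library in increasing hexose count, the correction workflow applied to
antibody subunit and intact profiles.  The inversion is exact in exact
arithmetic; on noisy inputs negative intermediate abundances are clamped to
zero (every clamp surfaced in the result) and the profile renormalised.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb

from .glycans import GlycanComposition, RESIDUES, _canonical_name

logger = logging.getLogger(__name__)

__all__ = ["GlycationResult", "CorrectionResult", "glycate_forward", "correct"]

_HEX = RESIDUES.index("Hex")


def _binom_weights(g: float, n_sites: int) -> list[float]:
    return [comb(n_sites, k) * g**k * (1.0 - g) ** (n_sites - k) for k in range(n_sites + 1)]


def _comp_key(c: GlycanComposition) -> tuple[int, ...]:
    return c.counts


def _shift_hex(key: tuple[int, ...], k: int) -> tuple[int, ...]:
    vec = list(key)
    vec[_HEX] += k
    return tuple(vec)


def _check_library(
    profile: dict[str, float], compositions: dict[str, GlycanComposition]
) -> dict[tuple[int, ...], str]:
    missing = set(profile) - set(compositions)
    if missing:
        raise ValueError(f"no composition given for species: {sorted(missing)}")
    by_comp: dict[tuple[int, ...], str] = {}
    for name in profile:
        key = _comp_key(compositions[name])
        if key in by_comp:
            raise ValueError(
                f"species {by_comp[key]!r} and {name!r} share one composition; "
                "merge isobars before glycation modelling"
            )
        by_comp[key] = name
    return by_comp


@dataclass
class GlycationResult:
    """Observed (biased) profile; hexose mass that landed on compositions
    outside the library is collected in ``unexplained``."""

    profile: dict[str, float]
    unexplained: float = 0.0
    g: float = 0.0
    n_sites: int = 1


@dataclass
class CorrectionResult:
    """Bias-corrected profile with the species whose exact inversion went
    negative and was clamped to zero."""

    profile: dict[str, float]
    clamped: list[str] = field(default_factory=list)
    g: float = 0.0
    n_sites: int = 1


def glycate_forward(
    true_profile: dict[str, float],
    g: float,
    n_sites: int,
    compositions: dict[str, GlycanComposition],
    extend_library: bool = False,
) -> GlycationResult:
    """Apply the glycation mixture to a true profile.

    Observed(s) = sum_k Binom(k; n_sites, g) * true(s minus k Hex).  Mass
    reaching compositions outside the library accrues to ``unexplained``
    unless ``extend_library`` is set, in which case those compositions
    become new named species (used by the spectrum simulator, where every
    glycated form produces a real peak).
    """
    if not 0.0 <= g < 1.0:
        raise ValueError("glycation degree must be in [0, 1)")
    if n_sites not in (1, 2):
        raise ValueError("n_sites must be 1 or 2")
    by_comp = dict(_check_library(true_profile, compositions))
    weights = _binom_weights(g, n_sites)
    observed: dict[str, float] = {}
    unexplained = 0.0
    for name, a in true_profile.items():
        key = _comp_key(compositions[name])
        for k, w in enumerate(weights):
            if w == 0.0:
                continue
            target_key = _shift_hex(key, k)
            target = by_comp.get(target_key)
            if target is None:
                if extend_library:
                    target = f"{name}+{k}Hex"
                    by_comp[target_key] = target
                    compositions[target] = GlycanComposition(
                        target_key, _canonical_name(target_key)
                    )
                else:
                    unexplained += w * a
                    continue
            observed[target] = observed.get(target, 0.0) + w * a
    # keep every input species visible even at zero observed abundance
    for name in true_profile:
        observed.setdefault(name, 0.0)
    return GlycationResult(
        profile=observed, unexplained=unexplained, g=g, n_sites=n_sites
    )


def correct(
    observed_profile: dict[str, float],
    g: float,
    n_sites: int,
    compositions: dict[str, GlycanComposition],
) -> CorrectionResult:
    """Invert :func:`glycate_forward` over the library.

    Species are processed in increasing hexose count;
    true(s) = [obs(s) - sum_{k>=1} Binom(k; n, g) * true(s - k Hex)] /
    Binom(0; n, g).  Negative intermediates are clamped to zero with a
    logged warning and the result renormalised to sum one.
    """
    if not 0.0 <= g < 1.0:
        raise ValueError("glycation degree must be in [0, 1)")
    if n_sites not in (1, 2):
        raise ValueError("n_sites must be 1 or 2")
    by_comp = _check_library(observed_profile, compositions)
    weights = _binom_weights(g, n_sites)
    w0 = weights[0]
    order = sorted(observed_profile, key=lambda n: compositions[n].counts[_HEX])
    true: dict[str, float] = {}
    clamped: list[str] = []
    for name in order:
        key = _comp_key(compositions[name])
        acc = observed_profile[name]
        for k in range(1, n_sites + 1):
            parent = by_comp.get(_shift_hex(key, -k))
            if parent is not None and parent in true:
                acc -= weights[k] * true[parent]
        if acc < 0.0:
            if acc < -1e-12:
                clamped.append(name)
                logger.warning(
                    "corrected abundance of %s is negative (%.3g); clamped to 0",
                    name,
                    acc / w0,
                )
            acc = 0.0
        true[name] = acc / w0
    total = sum(true.values())
    if total <= 0:
        raise ValueError("corrected profile has no mass left after clamping")
    profile = {name: true[name] / total for name in observed_profile}
    return CorrectionResult(profile=profile, clamped=clamped, g=g, n_sites=n_sites)
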