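"""Charge-ladder mass estimation, pair enumeration, and permutation scores."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycolevels.fixtures import intact_backbone, worked_scoring_example
from glycolevels.glycans import (
    PROTON_MASS,
    GlycanComposition,
    composition_mass,
    parse_oxford_name,
)
from glycolevels.intact import (
    NeutralMassPeak,
    annotate,
    enumerate_pairs,
    estimate_neutral_mass,
    permutation_scores,
)


class TestChargeLadder:
    def test_exact_ladder_recovers_mass(self):
        M = 148000.0
        mz = [(M + z * PROTON_MASS) / z for z in (26, 27, 28)]
        est, charges = estimate_neutral_mass(mz)
        assert est == pytest.approx(M, abs=0.1)
        assert charges == [26, 27, 28]

    def test_single_value_is_an_error(self):
        with pytest.raises(ValueError, match="at least two"):
            estimate_neutral_mass([5480.0])

    def test_jittered_ladder_within_one_dalton(self):
        rng = np.random.default_rng(13)
        M = 148000.0
        mz = [
            (M + z * PROTON_MASS) / z + rng.normal(0, 0.01) for z in range(25, 30)
        ]
        est, _ = estimate_neutral_mass(mz)
        assert est == pytest.approx(M, abs=1.0)

    def test_inconsistent_values_rejected(self):
        with pytest.raises(ValueError, match="charge ladder"):
            estimate_neutral_mass([5480.0, 5120.0, 4000.0], tol_da=1.0)


def _brute_force_pairs(peak_mass, library, backbone, tol):
    """Independent oracle: exhaustive double loop over ordered pairs."""
    masses = {n: composition_mass(c, "avg") for n, c in library.items()}
    masses.setdefault("none", 0.0)
    base = backbone.mass("avg")
    names = sorted(masses)
    found = set()
    for g1 in names:
        for g2 in names:
            if abs(base + masses[g1] + masses[g2] - peak_mass) <= tol:
                found.add(tuple(sorted((g1, g2))))
    return found


class TestEnumeratePairs:
    def test_isobaric_pair_example(self):
        lib = {n: parse_oxford_name(n) for n in ("FA2G0", "FA2G1", "FA2G2")}
        bb = intact_backbone()
        peak = (
            bb.mass("avg")
            + composition_mass(lib["FA2G0"], "avg")
            + composition_mass(lib["FA2G2"], "avg")
        )
        pairs = {p for p, _ in enumerate_pairs(peak, lib, bb, tol_da=0.5)}
        assert pairs == {("FA2G0", "FA2G2"), ("FA2G1", "FA2G1")}

    def test_off_mass_peak_yields_empty_list(self):
        lib = {n: parse_oxford_name(n) for n in ("FA2G0",)}
        bb = intact_backbone()
        assert enumerate_pairs(bb.mass("avg") + 50.0, lib, bb, tol_da=0.0) == []

    def test_none_participates_in_pairs(self):
        lib = {"none": parse_oxford_name("none"), "FA2G0": parse_oxford_name("FA2G0")}
        bb = intact_backbone()
        peak = bb.mass("avg") + composition_mass(lib["FA2G0"], "avg")
        pairs = {p for p, _ in enumerate_pairs(peak, lib, bb, tol_da=0.1)}
        assert ("FA2G0", "none") in pairs

    @given(seed=st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        """Bisection-based enumeration equals the exhaustive double loop on
        random libraries of random compositions."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        lib = {}
        for i in range(n):
            counts = {
                "Hex": int(rng.integers(0, 10)),
                "HexNAc": int(rng.integers(0, 8)),
                "dHex": int(rng.integers(0, 3)),
                "Neu5Ac": int(rng.integers(0, 3)),
            }
            lib[f"g{i}"] = GlycanComposition.from_dict(counts, name=f"g{i}")
        bb = intact_backbone()
        # aim near a random pair sum so hits are likely
        a, b = rng.choice(list(lib), size=2)
        peak = (
            bb.mass("avg")
            + composition_mass(lib[a], "avg")
            + composition_mass(lib[b], "avg")
            + rng.normal(0, 1.0)
        )
        tol = float(rng.uniform(0.1, 3.0))
        got = {p for p, _ in enumerate_pairs(peak, lib, bb, tol)}
        assert got == _brute_force_pairs(peak, lib, bb, tol)


class TestPermutationScores:
    def test_sole_candidate_scores_100(self):
        assert permutation_scores([("FA2G0", "FA2G1")], {"FA2G0": 0.5, "FA2G1": 0.5}) == [
            100.0
        ]

    def test_worked_isobaric_split(self):
        ex = worked_scoring_example()
        scores = permutation_scores(ex["candidates"], ex["site_abundances"])
        assert scores[0] == pytest.approx(100.0 / 3.0, abs=5e-3)
        assert scores[1] == pytest.approx(200.0 / 3.0, abs=5e-3)

    def test_scores_sum_to_100(self):
        cands = [("A", "B"), ("C", "C"), ("A", "C")]
        scores = permutation_scores(cands, {"A": 0.2, "B": 0.5, "C": 0.3})
        assert sum(scores) == pytest.approx(100.0, abs=1e-6)

    def test_invariant_to_rescaling_site_abundances(self):
        cands = [("A", "B"), ("C", "C")]
        ab = {"A": 0.2, "B": 0.5, "C": 0.3}
        scaled = {k: 7.3 * v for k, v in ab.items()}
        assert permutation_scores(cands, ab) == pytest.approx(
            permutation_scores(cands, scaled)
        )

    def test_missing_abundance_counts_as_zero(self, caplog):
        scores = permutation_scores(
            [("A", "B"), ("C", "C")], {"A": 0.5, "B": 0.5}
        )
        assert scores == [100.0, 0.0]

    def test_all_zero_weights_fall_back_to_uniform(self):
        scores = permutation_scores([("A", "A"), ("B", "B")], {"A": 0.0, "B": 0.0})
        assert scores == [50.0, 50.0]


class TestAnnotate:
    @staticmethod
    def _setup():
        lib = {n: parse_oxford_name(n) for n in ("none", "FA2G0", "FA2G1", "FA2G2")}
        bb = intact_backbone()
        site = {"none": 0.0, "FA2G0": 0.25, "FA2G1": 0.50, "FA2G2": 0.25}
        return lib, bb, site

    def _pair_mass(self, lib, bb, g1, g2):
        return (
            bb.mass("avg")
            + composition_mass(lib[g1], "avg")
            + composition_mass(lib[g2], "avg")
        )

    def test_proportional_split_of_peak_abundance(self):
        lib, bb, site = self._setup()
        iso_mass = self._pair_mass(lib, bb, "FA2G0", "FA2G2")
        other = self._pair_mass(lib, bb, "FA2G0", "FA2G0")
        peaks = [
            NeutralMassPeak(iso_mass, 0.10),
            NeutralMassPeak(other, 0.90),
        ]
        _, profile = annotate(peaks, lib, site, bb, tol_da=0.5)
        assert profile["FA2G0/FA2G2"] == pytest.approx(0.10 / 3, abs=1e-6)
        assert profile["FA2G1/FA2G1"] == pytest.approx(0.20 / 3, abs=1e-6)
        assert profile["FA2G0/FA2G0"] == pytest.approx(0.90)

    def test_single_candidate_peaks_pass_through(self):
        lib, bb, site = self._setup()
        peaks = [
            NeutralMassPeak(self._pair_mass(lib, bb, "FA2G0", "FA2G0"), 0.4),
            NeutralMassPeak(self._pair_mass(lib, bb, "FA2G2", "FA2G2"), 0.6),
        ]
        _, profile = annotate(peaks, lib, site, bb, tol_da=0.5)
        assert profile == pytest.approx(
            {"FA2G0/FA2G0": 0.4, "FA2G2/FA2G2": 0.6}
        )

    def test_manual_peak_keeps_one_unscored_candidate(self):
        lib, bb, site = self._setup()
        iso_mass = self._pair_mass(lib, bb, "FA2G0", "FA2G2")
        anns, profile = annotate(
            [NeutralMassPeak(iso_mass, 1.0, source="manual")], lib, site, bb, 0.5
        )
        (ann,) = anns
        assert len(ann.candidates) == 1
        assert ann.candidates[0].score_pct is None
        assert sum(profile.values()) == pytest.approx(1.0)

    def test_unannotated_peak_is_retained(self):
        lib, bb, site = self._setup()
        peaks = [
            NeutralMassPeak(self._pair_mass(lib, bb, "FA2G0", "FA2G0"), 0.7),
            NeutralMassPeak(bb.mass("avg") + 50.0, 0.3),
        ]
        anns, profile = annotate(peaks, lib, site, bb, tol_da=0.5)
        assert not anns[1].annotated
        unkeys = [k for k in profile if k.startswith("unannotated")]
        assert len(unkeys) == 1 and profile[unkeys[0]] == pytest.approx(0.3)

    def test_apportioning_conserves_total_abundance(self):
        lib, bb, site = self._setup()
        peaks = [
            NeutralMassPeak(self._pair_mass(lib, bb, "FA2G0", "FA2G2"), 3.0),
            NeutralMassPeak(self._pair_mass(lib, bb, "FA2G1", "FA2G2"), 2.0),
            NeutralMassPeak(bb.mass("avg") + 33.0, 1.0),
        ]
        _, profile = annotate(peaks, lib, site, bb, tol_da=0.5)
        assert sum(profile.values()) == pytest.approx(1.0, abs=1e-12)

    def test_score_normalisation_per_peak(self):
        lib, bb, site = self._setup()
        iso_mass = self._pair_mass(lib, bb, "FA2G0", "FA2G2")
        anns, _ = annotate([NeutralMassPeak(iso_mass, 1.0)], lib, site, bb, 0.5)
        total = sum(c.score_pct for c in anns[0].candidates)
        assert total == pytest.approx(100.0, abs=1e-6)
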