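"""Raw-spectrum fractional-abundance quantification."""

import numpy as np
import pytest

from glycolevels.fixtures import fc2_backbone, intact_backbone, peptide_backbone
from glycolevels.glycans import Backbone, GlycanComposition, GlycoSpecies, parse_oxford_name
from glycolevels.quant import (
    AbundanceProfile,
    ChargePlan,
    IndistinguishableSpeciesError,
    build_windows,
    default_plan,
    glycation_degree,
    quantify,
    replicate_stats,
    theoretical_mz,
)
from glycolevels.simulate import (
    LevelParams,
    library_species,
    nistmab_truth,
    simulate_intact_ladder,
    simulate_level,
)
from glycolevels.spectra import Scan, SpectrumSeries


class TestTheoreticalMz:
    def test_singly_protonated(self):
        assert theoretical_mz(1000.0, 1) == pytest.approx(1001.007276)

    def test_doubly_charged_glycopeptide(self):
        bb = peptide_backbone()
        sp = GlycoSpecies(bb, (parse_oxford_name("FA2G0"),))
        assert theoretical_mz(sp, 2, "mono") == pytest.approx(1317.527, abs=2e-3)

    def test_strictly_decreasing_in_charge(self):
        mzs = [theoretical_mz(148000.0, z) for z in range(20, 40)]
        assert all(a > b for a, b in zip(mzs, mzs[1:]))

    def test_charge_must_be_positive(self):
        with pytest.raises(ValueError):
            theoretical_mz(1000.0, 0)


class TestBuildWindows:
    def test_single_species_window_contains_theoretical_mz(self):
        bb = peptide_backbone()
        sp = GlycoSpecies(bb, (parse_oxford_name("FA2G0"),))
        plan = default_plan("peptide", (2,))
        wp = build_windows([sp], plan)
        (w,) = wp.windows[sp.name]
        assert w.lower <= theoretical_mz(sp, 2, "mono") <= w.upper

    def test_exactly_isobaric_pairs_are_rejected(self):
        bb = intact_backbone()
        a = GlycoSpecies(bb, (parse_oxford_name("FA2G0"), parse_oxford_name("FA2G2")))
        b = GlycoSpecies(bb, (parse_oxford_name("FA2G1"), parse_oxford_name("FA2G1")))
        with pytest.raises(IndistinguishableSpeciesError, match="isobaric"):
            build_windows([a, b], default_plan("intact", (26, 27, 28)))

    def test_charge_state_windows_of_one_big_species_are_disjoint(self):
        bb = intact_backbone()
        sp = GlycoSpecies(bb, (parse_oxford_name("FA2G0"), parse_oxford_name("FA2G0")))
        plan = default_plan("intact", tuple(range(24, 31)))
        wins = sorted(build_windows([sp], plan).windows[sp.name], key=lambda w: w.lower)
        for a, b in zip(wins, wins[1:]):
            assert a.upper < b.lower

    def test_partial_overlaps_are_flagged_not_merged(self):
        bb = fc2_backbone()
        close = [
            GlycoSpecies(bb, (GlycanComposition.from_dict({"Hex": k}, name=f"{k}Hex"),))
            for k in (1, 2)
        ]
        plan = ChargePlan(charges=(16,), tolerance=6.0, tolerance_unit="Th",
                          mass_mode="avg", window_halfwidth_th=5.0)
        wp = build_windows(close, plan)
        assert wp.overlaps == [("1Hex", "2Hex")]
        assert set(wp.windows) == {"1Hex", "2Hex"}


def _two_peak_series(ratio=3.0):
    """One scan, two well-separated Gaussians with area ratio ``ratio``."""
    mz = np.arange(1000.0, 1200.0, 0.01)
    sigma = 0.05
    y = ratio * np.exp(-0.5 * ((mz - 1050.0) / sigma) ** 2)
    y = y + np.exp(-0.5 * ((mz - 1150.0) / sigma) ** 2)
    return SpectrumSeries([Scan(0.0, mz, y)])


class TestQuantify:
    @staticmethod
    def _species_at(masses, level="fc2"):
        bbs = [
            Backbone(identifier=f"b{i}", level=level, avg_mass=m)
            for i, m in enumerate(masses)
        ]
        return [GlycoSpecies(bb, label=f"s{i}") for i, bb in enumerate(bbs)]

    def test_known_area_ratio(self):
        series = _two_peak_series(ratio=3.0)
        # single charge z=1: neutral masses put peaks at 1050 / 1150
        species = self._species_at([1050.0 - 1.007276, 1150.0 - 1.007276])
        plan = ChargePlan(charges=(1,), tolerance=0.2, tolerance_unit="Th",
                          mass_mode="avg", window_halfwidth_th=1.0)
        prof = quantify(series, species, plan)
        assert prof.abundances["s0"] == pytest.approx(0.75, abs=1e-6)
        assert prof.abundances["s1"] == pytest.approx(0.25, abs=1e-6)

    def test_single_species_gets_abundance_one(self):
        series = _two_peak_series()
        species = self._species_at([1050.0 - 1.007276])
        plan = ChargePlan(charges=(1,), tolerance=0.2, tolerance_unit="Th",
                          mass_mode="avg", window_halfwidth_th=1.0)
        prof = quantify(series, species, plan)
        assert prof.abundances["s0"] == 1.0

    def test_no_signal_errors(self):
        series = _two_peak_series()
        species = self._species_at([5000.0])
        plan = ChargePlan(charges=(1,), tolerance=0.2, tolerance_unit="Th",
                          mass_mode="avg", window_halfwidth_th=1.0)
        with pytest.raises(ValueError, match="no signal"):
            quantify(series, species, plan)

    def test_twenty_species_intact_profile_recovered_exactly(self):
        """Noise-free 20-glycoform intact simulation: parameter recovery to
        numerical precision across three charge states."""
        sim = simulate_intact_ladder(seed=3)
        species = library_species(intact_backbone(), sim.compositions)
        prof = quantify(sim.series, species, default_plan("intact", (26, 27, 28)))
        for name, truth in sim.true_profile.items():
            assert prof.abundances[name] == pytest.approx(truth, abs=1e-6)

    def test_scale_invariance(self):
        sim = simulate_intact_ladder(seed=3, n_species=5)
        species = library_species(intact_backbone(), sim.compositions)
        plan = default_plan("intact", (26, 27, 28))
        base = quantify(sim.series, species, plan)
        scaled = SpectrumSeries(
            [Scan(s.rt_min, s.mz, 7.5 * s.intensity) for s in sim.series]
        )
        rescaled = quantify(scaled, species, plan)
        for name in base.abundances:
            assert rescaled.abundances[name] == pytest.approx(
                base.abundances[name], abs=1e-12
            )

    def test_charge_subset_consistency(self):
        """With equal charge response, any single charge state quantifies
        the same as all charge states together."""
        sim = simulate_intact_ladder(seed=5)
        species = library_species(intact_backbone(), sim.compositions)
        full = quantify(sim.series, species, default_plan("intact", (26, 27, 28)))
        for z in (26, 27, 28):
            single = quantify(sim.series, species, default_plan("intact", (z,)))
            for name in full.abundances:
                assert single.abundances[name] == pytest.approx(
                    full.abundances[name], abs=1e-6
                )

    def test_profile_sums_to_one(self):
        sim = simulate_intact_ladder(seed=8, noise_sd=0.01)
        species = library_species(intact_backbone(), sim.compositions)
        prof = quantify(sim.series, species, default_plan("intact", (26, 27, 28)))
        assert sum(prof.abundances.values()) == pytest.approx(1.0, abs=1e-9)


class TestReplicateStats:
    @staticmethod
    def _profile(a, rep):
        ab = {"A": a, "B": 1.0 - a}
        return AbundanceProfile("fc2", rep, ab, {k: v * 100 for k, v in ab.items()})

    def test_identical_replicates_have_zero_rsd(self):
        stats = replicate_stats([self._profile(0.3, i) for i in range(5)])
        assert (stats["rsd_pct"] == 0.0).all()

    def test_hand_computed_example(self):
        stats = replicate_stats([self._profile(0.10, 0), self._profile(0.12, 1)])
        assert stats.loc["A", "mean"] == pytest.approx(0.11)
        assert stats.loc["A", "rsd_pct"] == pytest.approx(12.856, abs=1e-2)

    def test_mismatched_species_sets_rejected(self):
        p1 = self._profile(0.3, 0)
        p2 = AbundanceProfile("fc2", 1, {"A": 1.0}, {"A": 10.0})
        with pytest.raises(ValueError, match="different species"):
            replicate_stats([p1, p2])

    def test_noisy_replicates_yield_finite_rsds(self):
        profiles = []
        for rep in range(5):
            sim = simulate_intact_ladder(seed=100 + rep, noise_sd=0.01)
            species = library_species(intact_backbone(), sim.compositions)
            profiles.append(
                quantify(sim.series, species, default_plan("intact", (26, 27, 28)),
                         replicate=rep)
            )
        stats = replicate_stats(profiles)
        assert np.isfinite(stats["rsd_pct"]).all()
        assert (stats["rsd_pct"] >= 0).all()


class TestGlycationDegree:
    def test_single_site_matches_definition(self, truth_glycated):
        sim = simulate_level(truth_glycated, "fc2", deglycosylated=True)
        gd = glycation_degree(sim.series, fc2_backbone(), default_plan("fc2", (16,)))
        assert gd.n_sites == 1
        assert gd.g == pytest.approx(0.1, abs=1e-6)

    def test_two_sites_uses_square_root(self, truth_glycated):
        sim = simulate_level(truth_glycated, "intact", deglycosylated=True)
        gd = glycation_degree(
            sim.series, intact_backbone(), default_plan("intact", (26, 27, 28))
        )
        assert gd.n_sites == 2
        # binomial(2, 0.1): abundances 0.81 / 0.18 / 0.01 -> g = 1 - sqrt(0.81)
        assert gd.abundances[0] == pytest.approx(0.81, abs=1e-6)
        assert gd.g == pytest.approx(0.1, abs=1e-6)

    def test_unglycated_sample_gives_zero(self, truth_clean):
        sim = simulate_level(truth_clean, "fc2", deglycosylated=True)
        gd = glycation_degree(sim.series, fc2_backbone(), default_plan("fc2", (16,)))
        assert gd.g == pytest.approx(0.0, abs=1e-9)
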