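# Methods

## Mass bookkeeping

Glycans are residue-count vectors over {Hex, HexNAc, dHex, Neu5Ac,
Neu5Gc}. Residue masses are computed from elemental formulas (Hex C6H10O5,
HexNAc C8H13NO5, dHex C6H10O4, Neu5Ac C11H17NO8, Neu5Gc C11H17NO9) with
standard atomic masses, in three modes: monoisotopic, average, and nominal
(most-abundant-isotope integer masses, which yield the familiar 162 / 146 /
291 Da). Peptide masses (residues + one water, optional fixed
modifications) come from pyteomics. Glyco-species masses are strictly
additive: backbone + Σ glycan residue masses; the residue-mass convention
already accounts for the water of glycosidic bond formation.

The Oxford-style name grammar implemented: optional leading `F` (core
fucose, dHex = 1); `A<k>` → HexNAc = 2+k; `G<k>` → Hex = 3+k; `aG<k>`
(alpha-Gal) adds k hexoses; `S<k>`/`Sg<k>` → Neu5Ac/Neu5Gc = k; `M<k>` →
Hex = k on the HexNAc₂ core. Arm (`[3]`, `[6]`) and linkage (`(2,6)`)
decorations are parsed into an isomer label and do not affect identity:
MS cannot distinguish them, so FA2G1[6] and FA2G1[3] collapse to FA2G1.
Hybrid-type names (`FA1G0-M5`, `A1G1Sg1-M5`, `M3-F`, …) have no defined
arithmetic in the compact grammar; their compositions are fixed in an
explicit alias table (`glycans.OXFORD_ALIASES`) using the usual reading of
hybrid names (Man5 core plus one processed antenna). **This table is an
assumption** and is deliberately auditable data, not code.

Two naming subtleties are intentional. First, alias names keep their own
identity even when composition-isobaric with a grammar name (FA1G0-M5 vs
FA1G2): the reference detection sets list them as distinct species, and
collapsing them would change every set count. Second, the `-U` suffix
(a structure distinguished only by released-glycan analysis) likewise
stays distinct (M6-U ≠ M6), for the same reason.

## Raw-spectrum quantification

For each candidate species and charge z, the extraction window is centred
at (M + z·1.007276)/z. Window extent:

* **Envelope-based (peptide, intact).** The aggregated isotopologue
  distribution of the species' elemental formula (averagine-scaled,
  C4.9384 H7.7583 N1.3577 O1.4773 S0.0417 per 111.1254 Da, for fixed-mass
  backbones) is computed by exponentiation-by-squaring convolution and
  truncated at 1e-4 relative abundance; the window covers that extent,
  expanded by the tolerance (10 ppm peptide, 2 Th intact). In average-mass
  mode the envelope is anchored at its centroid.
* **Fixed half-width (subunits).** At z = 16 (Fc/2) and z = 33 (heavy
  chain), glycoforms 16 Da apart — e.g. FA2G0 vs A2G1 — are only ~1.0 /
  0.48 Th apart, narrower than the full envelope extent. Isotope-resolved
  acquisition at these levels permits narrow extracted-ion windows, so the
  defaults are fixed half-widths (0.5 / 0.25 Th) plus small absolute
  tolerances (0.2 / 0.1 Th).

Species whose windows coincide *exactly* at every charge (equal masses)
are rejected as an isobaric group — the raw spectrum cannot split them;
their resolution belongs to the intact-level pair annotation. Windows that
merely *overlap* are flagged with a warning but not merged: at the intact
level the window edges of single-hexose neighbours always touch, and
transitive merging would collapse the whole glycoform ladder into one
group. Shared signal in an overlap is counted for both species and is
visible in the flag list.

Ion current per species is the sum over its windows and the selected scans
(trapezoid on the native grid for profile data, stick sum for centroid);
fractional abundance divides by the summed current of all listed species.
Species without signal are retained at zero; an all-zero selection is an
error. Replicate dispersion is reported as mean, sample SD (n−1) and
RSD% (missing where the mean is zero).

The glycation degree is read from a deglycosylated control: quantify the
backbone + k·Hex ladder and fit per-site probability under independent
sites — g = 1 − a₀ (one site), g = 1 − √a₀ (two sites, intact).

## Glycation correction

Forward model: each molecule independently gains k hexoses with
Binomial(n_sites, g) probability; observed(s) = Σₖ B(k)·true(s − k·Hex),
mapped through the library's composition table (isobars must be merged
first; sharing a composition is an error). Mass landing outside the
library goes to an explicit unexplained bucket — or becomes a new named
species when the caller asks for library extension (the simulator does, so
every glycated form produces a real peak). Inversion walks species in
increasing hexose count: true(s) = [obs(s) − Σₖ≥₁ B(k)·true(s−k·Hex)] /
B(0). This is an exact algebraic inverse; on inconsistent (noisy) input,
negative intermediates are clamped to zero — every clamp is surfaced in
the result — and the profile renormalised. Glycation is assumed
independent of glycosylation state and site-symmetric; no uncertainty
propagation is attempted (point corrections only).

## Intact-level pair annotation

Candidate pairs for a neutral-mass peak are all unordered glycan pairs
(self-pairs and the unoccupied site "none" included) with |backbone +
m(g₁) + m(g₂) − peak| ≤ tolerance (default 2 Da, average masses). The
implementation sorts single-glycan masses and bisects the partner range;
tests pin it against the exhaustive double loop. The permutation score of
a candidate is its site-independence probability from glycopeptide-level
abundances — 2a₁a₂ for heterodimers, a² for self-pairs — normalised to
100 % over the peak's candidates. This is the unique symmetric
apportionment consistent with independent, exchangeable heavy chains; if
pairing were correlated in reality, the scores would mis-split isobaric
peaks (a known model limitation). Missing site abundances count as zero
(warned); an all-zero candidate set falls back to uniform scores (warned).
Manually annotated peaks carry exactly one (closest-mass) candidate and no
score. Apportioning multiplies each peak's fractional abundance by
score/100; unannotated peaks are retained under an explicit key so total
abundance is conserved exactly.

A least-squares charge-ladder estimator (m/z values of consecutive charge
states; the charge offset chosen by ladder consistency) provides neutral
masses where a deconvolved peak list is not available. It is deliberately
minimal plumbing, not a deconvolution algorithm.

## Cross-level integration

Detection sets per level hold isomer-collapsed canonical names; Venn
regions are the exhaustive 2ᵏ−1 membership partition (empty regions
reported). Overlap percentage is 100·|A∩B|/|A∪B|. The abundance matrix is
rows = glycans × columns = (level, replicate); the minor-species report
lists glycans below the 5 % threshold at every level where detected
(detection = nonzero in ≥ 1 replicate), with per-level means and RSDs.
Level comparisons are descriptive Welch intervals on per-glycan mean
differences, not hypothesis tests.

The shipped reference fixture maps the four NISTmAb detection sets through
membership groups a–g; the region-to-level assignment is the unique one
consistent with the published narrative and reproduces 13 species at all
four levels, 32 in the union, 22 per polypeptide level and 100 % Fc/2 vs
heavy-chain overlap. The released-glycan set reconstructed this way has
20 members although 21 unique moieties are quoted for that level; the
discrepancy is recorded as unresolved, and only the four counts above are
pinned by tests.

## Synthetic spectra: what they emulate, and what they do not

`simulate_level` builds, per level, a scan series with Gaussian m/z peaks
at each charge state whose *areas* are abundance × charge response ×
chromatographic weight, on an m/z grid of merged islands around the
expected peaks (grids extend ≥ 10 σ past every window, so trapezoid areas
are exact to machine precision). Study conditions, chosen once:

| level | charges | mass mode | peak σ (Th) | scans | elution |
|---|---|---|---|---|---|
| peptide | 2, 3 | mono | 0.04 | 20 | Gaussian, σ 0.06 min |
| Fc/2 | 16 | avg | 0.05 | 30 | Gaussian, σ 0.08 min |
| heavy chain | 33 | avg | 0.02 | 30 | Gaussian, σ 0.08 min |
| intact | 26–28 | avg | 0.3 | 60 | flat (direct infusion) |

Backbones: EEQYNSTYR (computed, mono 1188.505 Da); Fc/2 23,783 Da and
heavy chain 49,454 Da (average, reference values); intact 145,140 Da
average with two sites — a plausible aglycosylated IgG1 tetramer mass,
explicitly a synthetic stand-in. Peptide-level peaks sit 1.5 Da above the
monoisotopic mass, emulating the envelope centroid inside the mono-anchored
extraction windows. The default site profile has 20 species (majors
FA2G0/FA2G1/FA2G2, minors 0.3–3 %, including the unoccupied site); it was
screened so that no two species — including their +Hex glycated variants —
approach a foreign extraction window closer than 6 peak sigmas at any
level, because exact recovery of species that coincide in m/z is
impossible in principle. The intact level pairs sites independently
(correlated pairing is not modelled), merges exactly isobaric pairs into
mass groups, and applies forward glycation (two sites) before synthesis.
Noise is multiplicative Gaussian (relative SD) plus an optional additive
folded-normal floor, clipped at zero; every random draw comes from a
generator seeded by (seed, level, replicate).

Not emulated: isotopologue fine structure (peaks are single Gaussians),
co-elution and retention shifts between glycoforms (available via
`rt_offsets` but off by default), ionization-efficiency differences
between glycans, detector saturation, and MS2. Passing recovery tests
therefore demonstrates the correctness of the bookkeeping, integration,
correction and apportionment machinery — not robustness to those
instrument effects.

## Recovery ladder (computed by the tests and acceptance script)

* Noise-free 20-glycoform intact simulation: fractional abundances exact
  to < 1e-6 (measured ~5e-14; the residual is neighbouring-window tail
  overlap at 7 σ).
* 1 % multiplicative noise, 5 seeds: every species with truth ≥ 0.5 %
  within 0.5 percentage points (measured ~0.01 pp).
* Glycation forward → correct round trip: identity to 1e-12 for
  n_sites ∈ {1, 2}, g ∈ [0, 0.5] (clamp-free inputs).
* End-to-end (simulate → quantify → correct → annotate): two-site pair
  profile within 1 percentage point noise-free (measured ~5e-12 pp).

## Numerical choices

Averaging interpolates scans linearly onto the first selected scan's grid
(the instrument grid is stable in practice; any grid can be supplied).
Window integration interpolates the boundary ordinates so disjoint windows
partition the total ion current exactly. Isobar grouping is single-linkage
by sorted-mass chaining. Unsorted m/z arrays are repaired by sorting with
a warning; duplicate m/z values within a scan are an error. Profile
normalisation is re-applied after division to keep the sum-to-one
invariant at 1e-9 even for many species.
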