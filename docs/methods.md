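# Methods

## Scope and data model

The pipeline operates on centroided, per-sample peak lists
(m/z, intensity, ionization mode) from MALDI spectra of released
N-glycans, a sample manifest assigning each sample to one of three
groups (control strain, model strain, treated model), and a per-animal
behavior table. Raw spectrum processing (calibration, centroiding,
isotope deconvolution) and MS/MS structure confirmation are upstream of
this package and out of scope: compositions, not structures, are the
unit of analysis.

## Mass calculus

Residue masses are derived from IUPAC atomic masses at full precision
(Hex 162.0528234, HexNAc 203.0793725, Fuc 146.0579088, Neu5Ac
291.0954165, Neu5Gc 307.0903311, sulfate as SO₃ 79.9568149 Da; water
18.0105647). Full precision matters for one structural reason: Hex +
Neu5Ac and Fuc + Neu5Gc are the same elemental composition
(C₁₇H₂₇NO₁₃), and the search's tie-handling relies on this degeneracy
being exact rather than broken by rounding noise. Ion arithmetic uses
the proton mass for hydrogen transfers and Na⁺/K⁺ cation masses; the
electron mass is ignored (< 0.6 ppm at m/z 1000, far below the 10 ppm
working tolerance). "Fuc" denotes generic deoxyhexose and "S" counts
sulfates attached without additional water loss, both standard
composition-level conventions.

## Composition search

Candidates are enumerated exhaustively over a bounded residue lattice
(defaults Hex ≤ 15, HexNAc ≤ 10, Fuc ≤ 4, Neu5Ac ≤ 4, Neu5Gc ≤ 4,
S ≤ 2 — 66 000 points, pre-tabulated and queried by binary search; no
heuristic changes the result set). The default tolerance is 10 ppm,
matching internally calibrated FT-ICR accuracy; an absolute-Da override
exists because printed literature masses are often rounded beyond
10 ppm fidelity (the packaged tables deviate from theory by up to
~1.6 Da, so a 0.2 Da window is used when replaying them, and the
deviations themselves are reported, never corrected).

The biological filter is a deliberately minimal, pluggable rule set:
decorations (Fuc, Neu5Ac, Neu5Gc, sulfate) require at least one HexNAc;
sialic acids ≤ HexNAc + 1; fucoses ≤ HexNAc + 1; counts within bounds.
All 99 published compositions pass. The fucose-site rule earns its
place empirically: without it, bound-saturating (Fuc)₄ decoys outrank
true compositions in the ppm ordering.

Ranking is by |ppm error| quantized to 0.01 ppm, then total residues,
then decoration parsimony (fewer sulfates, then Neu5Gc, then Fuc), then
the canonical string. Quantization is required because exact isobars
(above) and near-exact cross-charge coincidences differ by far less
than instrument accuracy; distinguishing candidates by sub-0.01 ppm
float differences would be pseudo-precision. The parsimony preference
encodes that heavily decorated alternatives are the less likely reading
of the same mass; all candidates remain available to the caller in
ranked order.

Two adduct configurations are exposed. The full set ([M+H]⁺, [M+Na]⁺,
[M+K]⁺, [M+2Na]²⁺; [M−H]⁻, [M−2H]²⁻ and the sodium-exchanged forms)
covers everything the published tables contain and is the default. The
`instrument_primary` configuration restricts to [M+Na]⁺/[M−H]⁻, the
dominant species of NaCl-doped MALDI in positive/negative mode, and is
the right setting when assigning spectra known to be dominated by those
forms (it is also the CLI `quantify` discovery default). The
distinction matters quantitatively: on synthetic peaks with 2 ppm
Gaussian jitter the true composition is top-ranked in 100% of cases
under the primary configuration, but ~96% under the full set, because
distinct charge states can coincide within ~3 ppm — an ambiguity MS1
masses cannot resolve (instruments resolve it via isotope spacing,
which peak lists here do not carry).

## Quantification

Corrected intensity = 100 × raw / internal standard, per ionization
mode, using the most intense peak within ±0.5 Da of the working
β-cyclodextrin references (m/z 1157.25 positive, 1133.25 negative — the
study's stated reference values, which differ ~0.1 Da from theory; the
match window absorbs this). The factor 100 reproduces the magnitude
range (~1–150) of published relative-abundance columns. A sample whose
standard cannot be located is excluded with a logged reason, never
silently zeroed.

Group summaries use mean and sample SD (n−1) over all replicates with
zeros standing in for absences, and "detectable" means any replicate
> 0. This zeros-included convention is what the published cells imply:
a cell of 7.65 ± 13.24 at n = 3 is exactly one replicate at ~22.95 with
two zeros.

Dixon's Q (two-sided r₁₀ critical values, n = 3–10, α ∈ {0.10, 0.05,
0.01}) screens each (species, group) replicate vector; at most one
suspect per vector, flagged iff Q = gap/range exceeds Q(n, α). Flagged
values are reported; exclusion (replacement by the mean of the
remaining replicates) is opt-in because the original workflow does not
state what was done with detected outliers.

## Group comparison and modulation classes

Pooled-variance Student's t (df = n₁+n₂−2) and classical one-way ANOVA
are computed from summaries or raw replicates (the two entry points
agree to 1e-9; with two groups F = t²). Detectability categories are
exact set logic on the summary frame; mean-shift categories
("significantly different model vs control", "significantly changed by
treatment") come either from recomputed two-tailed tests at α = 0.05 or
from transcribed table markers. Both sources are first-class because
several published markers are reproducible only one-tailed at n = 3
(the reconciliation report lists each marker with both p-values);
table replay therefore uses marker mode, and a one-tailed option exists
rather than guessing the original tail convention. No multiplicity
correction is applied by default, mirroring the original analysis; a
Benjamini–Hochberg option is available.

## Behavior correlation

Correlations pool all animals across groups — the only reading
consistent with the study's stated correlation n of 8–9 against group
sizes of 3 — so a glycan whose abundance tracks group structure can
correlate with a behavior that does the same. p-values are two-tailed
via the t transform; the 95% CI is Fisher-z (degenerate at n = 3). The
number of screened pairs is reported; no multiplicity correction is
applied, again mirroring the original analysis.

## Synthetic cohorts

The generator emits exactly what the pipeline consumes. Each present
species contributes one peak at m/z = theoretical × (1 + ε·10⁻⁶),
ε ~ N(0, jitter²) with jitter 2 ppm (internally calibrated FT-ICR
scale), and raw intensity baseline × (IS/100) × exp(N(0, σ²)) with
σ_log = 0.4 — multiplicative log-normal noise, since MS intensities are
positive and their SDs scale with means, as the published tables show.
Per-species σ overrides exist because real replicate scatter is
species-dependent: the study's signature glycan shows CV ≈ 0.07 in the
model group, far tighter than the profile-wide scatter. An optional
per-replicate Bernoulli dropout (off by default) can emulate
one-nonzero-of-three cells.

Abundance patterns are structural: control-only {C}, model-only {M,T},
treatment-induced {T}, treatment-suppressed {C,M}, plus fold-change
patterns, including "treatment-rescued" (mean × f in the model group
only; f = 0.5 for the default signature species, matching the roughly
halved abundance in the published model group). The study-shaped
default glycome has 43 species: 9 control-only, 5 model-only, 15
induced, 5 suppressed, 1 treatment-rescued, 8 ubiquitous — the cortex
census by construction. The generator declares its designed mean shifts
as markers in the ground truth, the synthetic analogue of printed table
markers; the end-to-end census check classifies in marker mode for the
same reason the table replay does — at n = 3 with ~13 null tests, any
α = 0.05 recomputation adds a false positive to the modulated union
with ~50% probability per cohort, which would make a structural count
stochastic. A separate check verifies the recomputed t-test does flag
the designed fold-change species (power ≈ 0.97 at f = 2, σ = 0.1, from
an a-priori Monte Carlo).

Behavior values are group Gaussians truncated at zero (means/SDs chosen
as plausible magnitudes for a senescence-accelerated model with partial
treatment rescue: e.g. short-term discrimination index 65/45/62 ± 8%),
with platform crossings rounded to integers. One (species, measure, r)
correlation is planted through a bivariate Gaussian copula: the
species' log-intensity noise and the measure's group-mean deviation
share latent correlation r. Because the intensity margin is log-normal,
the Pearson correlation of emitted values is attenuated to
r·σ/√(e^σ² − 1) (≈ 0.96·r at σ = 0.4); `planted_pearson_r` exposes this
and calibration tests target it.

What the generator does **not** emulate: isotope envelopes, profile
spectra, instrument drift, ionization-efficiency differences between
glycan classes, and correlated multi-species biology. Passing tests on
synthetic cohorts therefore validate the statistical chain and the mass
calculus under the stated noise model, not robustness to raw-spectrum
artifacts.

## Problem sizes and numerical choices

The packaged table replay is exact arithmetic on 99 rows and runs in
milliseconds. Stochastic validations use: 1 075 jittered peaks for
top-rank recovery; ≥ 100 random instances against brute-force lattice
enumeration (small bounds, 25 ppm); 200 cohorts of 30 animals per
planted correlation level for CI coverage and type-I calibration.
Dixon's test requires 3 ≤ n ≤ 10 and returns an explicit no-test result
on zero range, as does ANOVA on identical constant groups. TSV writers
emit 10 significant digits (sub-0.001 ppm round-trip error on m/z) and
a version/config-hash header; fixture files are checksummed on load.

## Known limitations

- Exact isobars and near-coincident charge states are ranked by
  parsimony, not resolved; MS/MS or isotope spacing would be needed.
- The transcribed tables are data, not oracles: several printed masses
  are internally inconsistent (flagged in `data/table_flags.tsv`), two
  tissues contain duplicate (composition, adduct) rows, and one serum
  species satisfies the suppression rule while the narrative count
  omits it. The reconciliation report carries all of these; nothing is
  silently corrected.
- Pooled behavior correlations conflate within- and between-group
  association by design (that is what the original analysis measured);
  they are screening statistics, not causal estimates.
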