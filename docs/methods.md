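# Methods

## Model

The package treats an intact glycoprotein assembly as a backbone of fixed
average mass decorated by independent modification sites. Each site *s*
carries a normalized glycoform distribution *p_s(g)* (the unmodified form is
a glycoform with the empty composition); the intact proteoform distribution
is the product measure

    P(g_1, …, g_S) = Π_s p_s(g_s),   M = M_backbone + Σ_s m(g_s).

Site independence is the explicit modeling assumption. Where it is known to
fail within one peptide — C-mannosylation positional isomers of a WXXWXXW
motif, where the middle Trp is always modified and the second mannose sits
on either the first or third — the isomer-level joint distribution can be
convolved as a single pseudo-site instead of the per-site marginals
(`isomers_to_marginals` provides the marginals; convolving a joint
distribution over total Hex counts preserves the exclusivity constraint).

All masses are average masses: at ~150 kDa the isotopic envelope is
unresolved and the measured centroid corresponds to the average mass.
Monoisotopic arithmetic is out of scope.

### Constants

* Proton 1.00728 Da, hydrogen 1.00794 Da, water 18.0153 Da; standard
  average amino-acid residue masses to 4 decimals.
* Glycan monomers: Hex 162.1424, HexNAc 203.1950, NeuAc 291.2579 Da —
  the values used in intact-glycoprotein PTM assignment — plus dHex
  (fucose) 146.1412 Da, needed for the sub-percent core-fucosylated forms.
* Na/K adduct offsets: +21.9818 (Na−H) and +37.9559 Da (K−H).
* The γ-chain N-terminal Gln→pyroglutamate correction defaults to
  −18.01 Da. Chemically the conversion is an NH₃ loss (−17.03 Da), but the
  C8 backbone value this package ships (143,075.63 Da) is defined with the
  −18.01 convention, so that is the default; the correction is a per-chain
  configurable, not a hard-coded constant.

## Glycan-delta solver

`solve_delta` enumerates all compositions within per-class bounds whose
average mass lies within an **absolute** tolerance (default 1.0 Da) of the
target delta. Absolute, not ppm-of-delta: intact-mass accuracy is set by
the ~150 kDa precursor (≈1 Da at ~6–7 ppm), so a small PTM delta inherits
that absolute uncertainty; a ppm-of-delta criterion would reject correct
assignments (a 0.96 Da error on a 5548 Da delta is ≈170 ppm of the delta
but only ≈6.5 ppm of the precursor).

Plausibility rules: `n_glycan_core` (single-glycan deltas must contain the
chitobiose/trimannosyl core, HexNAc ≥ 2 and Hex ≥ 3), `aggregate`
(whole-protein PTM sums; no per-glycan constraint), `none`. Results are
sorted by |error| then lexicographic count vector (HexNAc, Hex, NeuAc,
dHex) for full determinism; a bound set generating more than 10⁸ candidates
is rejected with guidance rather than attempted. Linkage and branching are
never inferred — compositions only.

## Site profiles

XIC areas of one site in one run are normalized to sum to 1 (the peptide's
proteoform areas set to 100%); per-run profiles are averaged unweighted,
with a composition missing from a run contributing zero in that run, then
renormalized. Averaging is order-invariant and scale-invariant per run.

The packaged C8 occupancy fixture uses point values for glycoforms whose
abundance is only bounded in the peptide-level data ("<1%", "<0.5%"): each
such form enters at a configurable `minor_fraction` (default 0.5%) and the
site is renormalized. αW545, described as almost fully occupied, is carried
at 100%. The peptide-level O-glycoform bound (<0.5%) and the larger
intact-level O-glycan signal (>2%, an ionization-bias discrepancy) are kept
as alternative scenario settings rather than reconciled.

## Convolution bookkeeping

The product convolution accumulates species keyed by aggregate composition
(identical compositions merge exactly), pruning species below
`abundance_prune` (default 10⁻⁶) after each site to keep the species count
polynomial. Afterwards, species closer in mass than `merge_bin_da` (default
0.1 Da — far below anything native MS could separate) are merged to the
abundance-weighted mean mass under the dominant member's composition; merge
happens before pruning-sensitive reporting and before renormalization, in a
fixed order for determinism. Whether near-coincident species should merge
at all is a judgment call (e.g. NeuAc₁ vs Hex₂-combination species 33 Da
apart never merge at the default), so the bin width is configurable; with
`abundance_prune=0, merge_bin_da=0` the convolution equals brute-force
Cartesian enumeration exactly, which is the oracle the tests use.

The intensity cutoff used when reading the profile as a spectrum is
relative to the most intense species (that is how a "1% relative intensity"
peak cutoff is applied to a measured spectrum), and retained abundances are
not renormalized, keeping their scale interpretable against the original
profile. The cutoff is idempotent.

The number of occupied C-mannosylation sites is Poisson-binomial; it is
computed by exact dynamic programming (iterated convolution with
[1−p, p]), equivalent to the coefficient vector of Π(1−p_i+p_i·x).

## Spectrum simulation and deconvolution

Each species spreads its abundance over integer charges with discrete
Gaussian weights (fixture: z 21–26, center 24, width 1.5 — six visible
charge states with 24+ most intense). Peaks are Gaussian with
FWHM(mz) = mz/R_eff and R_eff = R₂₀₀·√(200/mz), an Orbitrap-like resolution
decay anchored at the instrument setting R₂₀₀ = 30,000; only the setting is
knowable from a method section, so the decay rule is a configurable choice.
The m/z grid defaults to 0.05; peak positions are refined by three-point
parabolic interpolation, and peak picking requires both height and
prominence above the relative threshold so baseline noise wiggles are not
reported as peaks.

Adduct satellites are an optional model: each species sheds the configured
intensity fractions into +Na−H and +K−H images (intensity conserved). They
exist so a synthetic "experimental" spectrum contains the unmatched
low-abundance signals real native ESI spectra show.

Charge assignment searches integer base charges z₀ ∈ [1, 100], assigns
consecutive descending charges to ascending m/z, and minimizes the
coefficient of variation of the implied neutral masses; the neutral mass is
the unweighted mean over the detected charge states (no weighting scheme is
assumed). Two peaks suffice in principle; one peak is rejected as
underdetermined. For multi-species spectra, `cluster_apexes` first selects
the most intense peak of each charge-state cluster (clusters are hundreds
of m/z apart; proteoform structure within a cluster is a few m/z), which is
the "follow the most abundant species across charge states" step of manual
analysis. Full-trace zero-charge deconvolution is a remap-and-sum:
I(M) = Σ_z I_mz((M+z·p)/z), which reinforces peaks supported by the whole
series.

## Comparison

Constructed-vs-experimental similarity is the Pearson correlation of the
two traces linearly resampled onto their overlapping range; by default the
comparison runs on the zero-charge axis (grid 1 Da; m/z comparison at 0.05
by flag). Intensities are not baseline-subtracted unless requested. Peak
matching is greedy nearest-neighbor within a tolerance (default 3 Da at
~150 kDa), each peak used once; unmatched experimental peaks are annotated
by solving their offset to the nearest constructed peak for a glycan
composition, falling back to "possible Na/K adduct".

## Synthetic data: what it emulates, and what it does not

Generators are seeded (`numpy.random.default_rng`); identical configuration
gives byte-identical outputs. The scenario emulates:

* multi-run glycopeptide XIC tables with multiplicative log-normal noise
  (σ = 0.2, 4 runs by default — log-normal is the standard model for
  LC-MS area variability);
* a native spectrum of the convolved profile with additive uniform noise
  and Na/K satellites. The calibrated "noisy" setting (noise 3% of base
  peak, Na 18%, K 9% satellite fractions) is chosen once so that the
  constructed-vs-synthetic-experimental correlation falls midway between
  the clean limit (R = 1) and a degraded regime — around R ≈ 0.96–0.97 —
  representative of what an annotated-but-imperfect match looks like.

It does not emulate: chromatographic separation, PNGase F/sialidase
kinetics, peptide ionization bias (the very effect that makes peptide-level
O-glycoform abundances underestimates), isotope structure, detector
saturation, or charge-state-dependent transmission. Passing round trips
therefore demonstrate internal consistency of the pipeline — truth in,
truth recovered through normalization, convolution, simulation and
deconvolution — not robustness to every artifact of real data.

## Degenerate inputs and numerical choices

* Empty sequences are rejected at chain construction; the empty peptide's
  residue sum is one water.
* All-zero XIC areas, mixed-site or mixed-run normalization inputs, and
  unnormalized profiles entering the convolution are rejected.
* Modal-species ties break to the lower mass; solver ties break
  lexicographically.
* Spectra axes must be strictly increasing; flat spectra yield no peaks.
* Abundance sums are validated to 1 ± 10⁻⁹; expectation linearity of the
  exact convolution holds to 10⁻⁶ Da in tests.

## Problem sizes

The default test suite and the acceptance script run the full scenario:
14 sites, ~130 proteoform species, six charge states on a 0.05 m/z grid
(~3×10⁴ points), 4-run XIC tables, and brute-force oracles up to 6 sites ×
4 glycoforms and 2⁵ C-Man enumerations. The whole suite completes in a few
seconds on one core.

## Known limitations

* Backbone masses for the real C8 chains require the mature UniProt
  sequences as user-supplied FASTA plus mature ranges; the package ships
  the resulting backbone constant, not the sequences.
* The −18.01 Da pyroglutamate convention is kept for consistency with the
  shipped backbone constant even though the chemical NH₃ loss is −17.03 Da
  (see Constants above).
* Charge assignment assumes one consecutive series from one species;
  heavily overlapped multi-species envelopes need the cluster-apex
  selection first, and fail gracefully (rejected, not guessed) below two
  peaks.
* The comparison never claims identity of grids or smoothing with any
  external software; grid, range and baseline handling are explicit
  configuration reported in the run log.
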