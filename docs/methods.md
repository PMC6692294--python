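# Methods

`sprekit` predicts and measures solvent paramagnetic relaxation
enhancements (sPREs) of intrinsically disordered proteins (IDPs) and uses
the comparison of the two to locate transient structure. This note
describes the models implemented, the numerical choices behind them, and
what the synthetic-data tests do and do not establish.

## The grid-based sPRE back-calculation

An inert paramagnetic co-solute such as Gd(DTPA-BMA) distributes uniformly
through the solvent and is excluded from the protein interior. To first
order, the relaxation enhancement it induces on a nucleus *i* is an
integral of the dipolar 1/d⁶ distance dependence over the solvent volume.
`grid_spre` discretizes this integral on a regular lattice:

    sPRE_i = c · Σ_j  d_ij⁻⁶      over accessible points j with d_ij < cutoff

with defaults: spacing 0.5 Å, probe exclusion radius 3.5 Å (a lattice
point is removed when it lies strictly closer than 3.5 Å to *any* atom
centre, with no per-element van-der-Waals augmentation), integration
cutoff 10 Å, lattice margin 10 Å beyond the protein bounding box, and an
arbitrary scale constant c = 1000. The raw value is a dimensionless
lattice sum times c; `volume_normalized=True` multiplies by spacing³ to
make values comparable across resolutions. Downstream normalization
absorbs either convention.

Numerical choices:

- **Lattice registration.** The lattice is anchored to the bounding-box
  minimum minus the margin, *offset by half a spacing* (midpoint-rule
  registration). Anchoring makes values exactly invariant under
  translation of the input; the half-spacing offset keeps quadrature nodes
  off atom positions, which is the worst case for the 1/d⁶ discretization
  error. With it, a lone atom reproduces the closed-form shell integral
  (c/spacing³)(4π/3)(3.5⁻³ − 10⁻³) to −2.5 % at 0.5 Å spacing and −0.4 %
  at 0.25 Å. Rotations re-register the lattice and move individual values
  by up to ~1.5 % at 0.5 Å spacing for peptide protons (more for bare
  isolated atoms, whose probe sits directly on the singularity's edge).
- **Boundary tie-breaks.** Both bounds are strict: a point at exactly the
  probe radius is retained, a point at exactly the cutoff does not
  contribute. Contributions beyond 10 Å would add < 2.5 % of the analytic
  total (the ratio cutoff⁻³/probe⁻³), so treating the cutoff as a physical
  bound rather than an artifact of the lattice extent is immaterial.
- **Equivalent paths.** The default evaluation enumerates only the lattice
  window inside each probe's cutoff sphere and tests accessibility with a
  k-d tree; it visits exactly the same points as the naive all-lattice sum
  (`method="naive"`), and the test suite holds the two equal to 1e-12
  relative on small systems.

## The fragment-ensemble prediction

A single conformer of an IDP is meaningless; the observable is a fast
population-weighted ensemble average. The predictor therefore slides a
5-residue window over the sequence, embeds each window in triple-alanine
flanks (AAA + core + AAA, an 11-mer), generates an ensemble of random-coil
conformers of that fragment, back-calculates the central residue's sPRE in
every conformer, and assigns the ensemble mean (± SD) to the central
residue. The first and last two residues of a chain are never window
centers and carry no prediction. Because local excluded volume dominates
the accessibility of a disordered chain, the flanked fragment is a good
local proxy for the full chain; the default ensemble size of 1500
conformers reproduces a 20,000-conformer master mean to well under 5 %
(see the acceptance script).

The coil generator is self-contained rather than a wrapper around an
external refinement pipeline:

- Backbone φ/ψ pairs are drawn per residue from a three-basin Gaussian
  mixture — PPII (weight 0.45, φ −75 ± 15°, ψ 145 ± 15°), β (0.30,
  −120 ± 25°, 135 ± 20°), α_R (0.25, −63 ± 10°, −43 ± 10°) — approximating
  coil-library statistics; ω is fixed at 180° (trans only, including
  proline, whose φ is pinned at −65 ± 8°).
- Residues are decorated from ideal full-atom templates (CCD geometry):
  the template is superimposed on the placed N/CA/C triad, the carbonyl O
  is rebuilt anti to the next amide nitrogen, the amide H in the peptide
  plane, and χ1 is set to a canonical rotamer (gauche−; trans for Val,
  gauche+ for Ser/Thr) with a ±15° uniform jitter.
- Conformers with any non-bonded heavy-atom pair (different residues,
  peptide bond exempt) closer than 2.0 Å are rejected, with a 100-attempt
  budget per conformer. All sampling is bit-reproducible under a seed.

Because no external refinement pipeline defines a canonical coil
distribution, absolute predicted values are generator-dependent. This is by construction harmless: predictions are
always mapped onto the experimental scale by a linear fit before
interpretation, and the *patterns* the method rests on — glycine-rich
fragments more accessible than bulky ones, helices less accessible than
extended chains — are properties of excluded volume that any reasonable
coil model reproduces (both are asserted in the test suite).

Fragment records are cached in a JSON library keyed by (core, ensemble
size, seed, grid parameters); a full-sequence prediction touches one
record per distinct 5-mer, so repeated and overlapping sequences are
cheap. Precomputing all 3.2 M possible cores is deliberately out of
scope; on-demand computation plus the cache covers practical use.

## From recovery curves to experimental sPREs

Saturation-recovery data enter as peak-intensity tables (peak, residue,
atom role, recovery delay, intensity, agent concentration, duplicate
flag). The pipeline is:

1. **Mono-exponential fit** I(t) = −A·e^(−R₁t) + C per curve
   (Levenberg–Marquardt via `scipy.optimize.curve_fit`, initialization
   A₀ = max−min, C₀ = max, R₁₀ = 1/median(delay), R₁ bounded positive).
   Degenerate curves set a `converged=False` flag instead of raising.
2. **Noise from duplicates**: ε = sqrt((1/2N) Σ δ_i²) over all duplicate
   pairs, the standard estimator whose expectation is the per-point
   intensity SD (one duplicate delay per curve in the default design).
   A dimensionally inconsistent variant without the square is available
   behind a flag for comparison only.
3. **Monte-Carlo R₁ errors**: Gaussian noise of SD ε is added to the
   *fitted* curve's predictions (parametric resampling, default 500
   resamples), each resample refit; σ_R1 is the SD of the resampled
   rates. A residual bootstrap would be the non-parametric alternative;
   parametric resampling is the default because the model class is exact
   for these data.
4. **Weighted regression** R₁(c) = sPRE·c + R₁⁰ across concentrations,
   weights 1/σ_R1², closed-form normal equations; concentration error is
   neglected. The slope is the sPRE (s⁻¹ mM⁻¹), its standard error comes
   from the weighted curvature. Peaks failing any stage, or observed at a
   single concentration, are excluded and logged.

## Normalization and deviation flagging

Predicted (arbitrary-unit) and experimental (s⁻¹ mM⁻¹) profiles are
reconciled by OLS of the experimental values on the predicted ones over
co-defined residues; the fitted slope/intercept then shift and scale the
whole prediction, with prediction errors scaled by |slope|. A robust
option iteratively trims points with |residual| > 2.5 robust-scale units
(1.4826·MAD — an SD-based threshold would be inflated by the very
outliers it should reject) and refits; it is the right choice when
extended deviating regions are expected, since those bias a plain fit.
The plain OLS remains the default.

A residue is flagged *buried* when the normalized prediction exceeds the
measurement by more than z · (experimental error), with z = 1.96, and
*exposed* for the opposite sign; only runs of ≥ 3 consecutive
same-direction flags are reported as regions. The z/run-length rule is
this package's explicit operationalization of "regions of strong
variation"; the defaults give a per-residue false-flag rate of ~5 % and a
negligible false-region rate on white noise (both measured in the test
suite). Amide-proton (HN) reports carry a caveat: solvent exchange
inflates experimental amide sPREs, so HN deviations are not clean
structure indicators. A Zimmerman-bulkiness profile is provided as the
crude sequence-only baseline for the same contrast.

## Synthetic data: what it emulates, what it does not

`synthetic_data` mirrors the acquisition design of the real experiments:
10 geometrically spaced recovery delays (0.03–3 s) plus one duplicate,
concentrations 0–5 mM, i.i.d. Gaussian intensity noise, amplitude and
plateau 1 a.u. Ground-truth rates are drawn uniformly (R₁⁰ ∈ [0.5, 1.5]
s⁻¹, sPRE ∈ [1, 6] s⁻¹ mM⁻¹, the range spanned by measured IDP Hα
values). Truth-profile generators implant multiplicative accessibility
depressions over chosen residue ranges; ideal helix (φ −57°, ψ −47°) and
extended (φ −120°, ψ +120°) builders provide the compact-vs-extended
contrast.

Passing tests on these fixtures establishes estimator correctness and
calibration *within the model class*: exact zero-noise round trips,
nominal 95 % coverage of slope confidence intervals, detection of ≥ 6
residue, ≥ 4-error-unit depressions with residue-level boundaries. They
do not establish robustness to what real spectra add — peak overlap,
baseline distortions, non-Gaussian or delay-correlated noise, exchange
contributions, or specific binding of the paramagnetic agent (which
raises experimental sPREs and must be excluded experimentally).

## Problem sizes and defaults used in the shipped checks

The acceptance script regenerates the fragment-convergence experiment at
a 20,000-conformer master ensemble with 100 subsets of 1500 (the package's
desk-scale rendition of the original 99,000-conformer version; the
without-replacement subset SE is ~0.4 % of the mean, so the 95th-percentile
deviation sits near 1 %, far inside the 5 % convergence claim). Test-suite
simulations use 100–200 replicates per calibration check and ensembles of
120–600 conformers where only means and variances matter.

## Known limitations

- Absolute predicted sPREs depend on the coil model and the scale
  constant; only normalized comparisons are meaningful.
- The coil model samples χ1 around a single canonical rotamer and keeps
  prolines trans; neighbor-dependent coil libraries and cis-proline are
  not modelled.
- R₂-based sPREs, spectral processing, and ensemble reweighting against
  sPRE restraints are out of scope; the pipeline starts at intensity
  tables and ends at flagged regions.
- Electron-spin relaxation theory (Solomon–Bloembergen) is deliberately
  absent: the geometric integral *is* the prediction, which is adequate
  for fast-tumbling co-solutes but not for slowly relaxing or binding
  probes.
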