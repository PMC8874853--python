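# Methods

## Model and procedure

The package analyzes steady-state fluorescence titrations of a protein with
a quenching ligand under the classical linearized framework.

**Inner filter effect.** When the sample absorbs at the excitation or
emission wavelength, the observed intensity underestimates the true one.
The correction `F_cor = F_obs · exp((A_ex + A_em)/2)` assumes a standard
1-cm cuvette with absorbance measured over the full path; geometry-dependent
variants are out of scope. Correction is opt-in per titration file (it is
applied exactly when per-point absorbance columns are present) and is the
identity at zero absorbance, strictly increasing in each absorbance.

**Stern–Volmer.** `F₀/F = 1 + K_SV[Q]` is fit by ordinary least squares of
F₀/F on [Q] in mol/L. The intercept is *fitted*, not constrained to its
theoretical value 1: the reported correlation then matches what an
unconstrained regression produces, and an intercept more than three
standard errors from 1 is surfaced as a warning (a diagnostic for curvature
or systematic error). Points with F ≥ F₀ (fluorescence enhancement) are
retained in this fit and flagged, never silently dropped. The bimolecular
quenching constant is k_q = K_SV/τ₀ with τ₀ = 10⁻⁸ s by default (typical
biopolymer lifetime, overridable); the identity holds to machine precision
in every result.

**Mechanism classification** is a two-criterion vote: (A) across ≥2
temperatures, strictly decreasing K_SV(T) votes static, strictly increasing
votes dynamic — strict monotonicity of point estimates, no significance
test; (B) all k_q above 2×10¹⁰ M⁻¹s⁻¹ (the diffusion-controlled ceiling)
votes static, all at or below votes dynamic. Agreement or a single
applicable criterion decides; conflict yields "ambiguous" with both
outcomes recorded.

**Double-log binding plot.** `log₁₀((F₀−F)/F) = log₁₀ K_b + n·log₁₀[Q]`,
OLS with [Q] in mol/L so K_b carries M⁻ⁿ. Base-10 logs here; natural logs
are reserved for the van't Hoff fit. Points with F ≥ F₀ leave the transform
undefined: they are excluded and the count reported. K_b's standard error
uses the delta method, `SD(K_b) = K_b · ln 10 · SE(intercept)`.

**van't Hoff.** `ln K_b = −ΔH°/(RT) + ΔS°/R` fit by OLS of ln K_b on 1/T
with R = 8.314 J·mol⁻¹·K⁻¹; ΔH° is reported in kJ·mol⁻¹ and ΔS° in
J·mol⁻¹·K⁻¹, with the factor 1000 reconciling the unit mix in exactly one
place (`gibbs`). ΔH° is assumed temperature-independent over the narrow
studied range (linear van't Hoff, no heat-capacity term). Duplicate
temperatures warn but do not abort. Force typing follows the sign rules
(ΔH<0, ΔS<0 → van der Waals + hydrogen bonding; both >0 → hydrophobic;
ΔH<0, ΔS>0 → electrostatic; ΔH>0, ΔS<0 → unfavorable/other), with driving
character and spontaneity judged at 298 K.

**Competition and site markers.** The binary-vs-ternary comparison reports
the K_b fold change, quench-percentage delta, and flags the pattern where
K_SV rises while K_b falls (increased quencher accessibility despite
weakened net binding). Site inference computes each marker's relative K_b
displacement |K_b,marker − K_b|/K_b; exactly one marker above the 0.30
threshold (configurable; the underlying judgment in the literature is
qualitative) assigns its mapped site, otherwise the result is undetermined
with evidence. The marker→site map is user-extensible (Site III has no
standard marker).

**Spectral features.** Emission peaks are located by grid argmax with
3-point parabolic refinement, which resolves sub-grid shifts (a 1-nm shift
on a 1-nm grid is not reliably resolvable by argmax alone); ties go to the
lowest wavelength, and flat or monotone (boundary-maximum) spectra are
flagged rather than reported as peaks. Synchronous spectra sample the EEM
along λ_em = λ_ex + Δλ with linear interpolation between emission grid
points. EEM taxonomy: cells within tolerance (default two emission grid
steps) of λ_em = k·λ_ex for k ∈ {1, 2} form the Rayleigh and second-order
scattering ridges; Peak I and Peak II are the off-ridge *local* maxima
inside the excitation windows 260–300 nm (Trp/Tyr fluorophores) and
210–250 nm (polypeptide backbone) — the local-maximum requirement stops
ridge tails that leak past the tolerance from masquerading as peaks. The
windows delimit regions the literature names but does not bound precisely.

## Units

Concentrations are stored in μM (the reporting unit of titration tables)
and converted to mol/L exactly once, at fit time, through the read-only
`TitrationSeries.ligand_conc_molar` property — since the series is frozen
and the property derives from the stored μM values on every access, a
double conversion cannot occur by construction. All fitted constants
therefore carry M⁻¹ (or M⁻ⁿ). Intensities are arbitrary units and are never
normalized before fitting; every fitted quantity depends only on intensity
ratios, and the fits are invariant to uniform rescaling (tested).

## Synthetic data: what it emulates and what it does not

The generator reproduces the standard albumin titration design: protein
fixed at 1.5 μM, quencher on an 11–12 point grid over 0–27.5 μM (the zero
point defining F₀), temperatures near physiological, an optional competitor
at fixed concentration (default study condition 5.5 μM), optional constant
inner-filter absorbances, and multiplicative Gaussian noise with CV 1% by
default (a shot/gain-noise approximation).

It generates data from the *linearized analysis equations themselves*:
static titrations satisfy (F₀−F)/F = K_b,app[Q]ⁿ exactly, with competitive
attenuation K_b,app = K_b/(1 + K_c[C]); dynamic titrations satisfy
F₀/F = 1 + K_SV(T)[Q] with K_SV rising 1%/K above 298 K. This makes
recovery exact at zero noise — by design, so round-trip tests are sharp —
but it means passing tests demonstrate correctness of the estimators, not
that real quenching data obey these laws. Real data add ligand depletion
(mass-balance effects at high affinity), mixed static/dynamic character,
photobleaching, drift, and wavelength-dependent noise, none of which are
modeled. The ternary model captures the direction of competitive
displacement, not the (mechanistically unexplained) simultaneous K_SV rise
observed in real ternary systems; an elevated-K_SV ternary series can be
constructed with sub-unit stoichiometry instead.

All randomness flows through `numpy.random.default_rng(seed)`; identical
seeds give bit-identical output.

## Numerical choices

- All lines are fit with `scipy.stats.linregress` (slope and intercept
  standard errors included); an independent brute-force grid-search
  least-squares oracle cross-checks the estimates in the test suite.
- Degenerate zero-quenching input (constant F₀/F) has no definable
  correlation; r is reported as 0 with a warning instead of NaN.
- Pearson r is clipped to [−1, 1] against floating-point overshoot.
- JSON reports use sorted keys and 6-significant-digit floats, so repeated
  runs are byte-identical and independent of input ordering.

## Known limitations

**The double-log intercept amplifies intensity noise.** K_b is 10^intercept
at log₁₀[Q] = 0, i.e. [Q] = 1 M — about five decades outside the sampled
2.5–27.5 μM window. An error δ in the fitted slope therefore shifts
log₁₀ K_b by ≈ 5δ. At 1% multiplicative noise the median relative error of
K_b is ~54% for a 2×10⁴ M⁻¹ binder over 200 replicates, and stays near 4%
even for strong binders where every point is deeply quenched, while K_SV
(no extrapolation) recovers to ~2% under the same conditions. Published
K_b uncertainties of a few percent from this plot imply effective
intensity noise well below 1%. Relatedly, weak binders whose maximal
quench falls below the noise floor (e.g. K_b ≈ 344 M⁻¹ quenches < 1% over
this grid) cannot be fit at 1% noise at all — roughly half the points show
F ≥ F₀ and the fit correctly refuses. The recovery study in
`scripts/acceptance.py` therefore uses a synthetic truth of ΔH° = −100
kJ·mol⁻¹, ΔS° = −200 J·mol⁻¹·K⁻¹, for which all three temperatures stay
well above the noise floor; with it, ΔH° recovers to ~3.5% and ΔS° to ~6%
(medians over 66 replicate sets).

**Problem sizes.** The recovery study uses 200 single-titration replicates
and 66 three-temperature sets at the 11-point design — large enough for
stable medians while keeping the whole study under a few seconds.

**Scope.** No modified (Lehrer) Stern–Volmer accessible-fraction analysis,
no Scatchard/Hill linearizations, no global nonlinear isotherm fitting, no
mass-balance (ligand-depletion) simulation, no docking or molecular
dynamics. Temperatures are always caller-supplied; the package never
assumes a particular temperature set.
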