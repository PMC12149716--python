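# Methods

This note documents the models, numerical choices and known limitations of
the package; the README gives the formulas and a worked example.

## Signal model and correction taxonomy

A raw reading is mapped to a quantity proportional to the mean dose in the
sensitive volume by two classes of corrections.  Factors independent of the
small beam-quality change between the reference and the clinical field
(temperature/pressure, humidity, electrometer, polarity, recombination,
drift, background, stem, positioning) multiply the reading directly; the
applicable set depends on the detector class (ionization chamber, solid
state, plastic scintillator), and `apply_type1` refuses a non-unit factor
outside its class rather than silently ignoring it.  Beam-quality-dependent
factors — for these detectors only the scintillator quenching ratio — enter
the output correction factor instead, so they never contaminate the corrected
reading ratio.  In ratio mode the factors equal on both sides contribute no
value; they are tracked by name so the budget can still carry their
uncertainty allowance (0.1% each for stem and "other influence quantities").

## Volume averaging and positional uncertainty

The 2-D relative dose near the axis is modelled as the product of two
second-order polynomials fitted to the cross-line and in-line profiles.  The
fit window defaults to 30% of the profile FWHM around the centre (the
quadratic approximation holds well inside the penumbrae; the window is
configurable) and is centred on the midpoint of the profile's 50% crossings,
which stays well defined on flat-topped wide fields where the sample argmax
does not.  The overall scale of the separable model is a gauge choice; only
per-axis coefficient ratios enter the correction factors.

The detector signal is the footprint convolution of this model with the
normalized height function of the sensitive volume.  Supported shapes are the
sphere, the cylinder and the hemisphere-tipped cylinder, with the symmetry
axis parallel or perpendicular to the beam; presets carry the geometries of
the six studied detectors (spherical micro-chambers of 1.0 and 1.65 mm
radius, a 1.0 mm × 2.6 mm tipped cylinder, a 0.3 mm × 0.02 mm diode disc, a
1.1 mm × 1 µm diamond disc, and the 0.5 mm × 1 mm scintillator).  For the
tipped cylinder in the perpendicular orientation the footprint is referenced
to the volume centroid (the cap pulls it 0.34 mm toward the tip for the
preset dimensions) so that first moments vanish and the "detector position"
means the same thing for every shape.  Whether a stem flat truncates the
spherical chamber volumes is not specified by the manufacturers' nominal
geometry; they are modelled as full spheres.

**Quadrature.**  The convolution integrals are evaluated with fixed-order
Gauss–Legendre product rules in mapped coordinates that remove the
square-root edge behaviour of circular footprints (ρ = r·sin t); for the
separable quadratic dose model the rules are exact to roundoff at any order
≥ 3 (default 48, configurable, which also keeps smooth non-polynomial models
accurate far beyond the 1e-8 target).  This is deterministic, fast and
extensible to new shapes.  Correctness is guarded by independent oracles:
hand-derived footprint moments (disk ⟨x²⟩ = r²/4, ⟨x²y²⟩ = r⁴/24; ball r²/5,
r⁴/35; perpendicular cylinder r²/4, L²/12, r²L²/48) and brute-force
midpoint-grid quadrature on 400×400 mapped grids.  The angular rule of the
hemispherical cap uses Gauss nodes because a uniform midpoint rule is only
exact over a full period, not the cap's half period.

The positioning window average and the signal variance use a 4-node Gauss
rule per axis — exact for the degree ≤ 4 polynomials involved — computed as
2-D integrals of the signal and its square, so Var = ⟨M²⟩ − ⟨M⟩² is
non-negative up to roundoff (clipped at zero).  kvol and kpos are evaluated
at the fitted maximum clamped into the fit window: measurement noise on a
flat field can flip the fitted curvature sign and send the nominal
stationary point to infinity, while the same-point signal ratios remain well
behaved at the beam axis.

## Polarity and recombination

Polarity corrections come from bias-paired readings; the convention is
relative to the stated operating polarity (published curves using the
opposite sign convention mirror about unity).  Recombination at a single
operating point uses the pulsed-beam Boag two-voltage formula
kion = (1 − V_H/V_L)/(M_H/M_L − V_H/V_L); the method choice matches a
flattened 6 MV beam at the usual 300/150 V pair.  Across field sizes the
recombination ratio follows the linear dose-per-pulse model with a single
detector parameter B, calibrated by rescaling the reference field at SSDs of
80–110 cm so the field size at the detector plane is constant while the dose
per pulse follows the inverse square law.  B is the mean of the inversions at
the two extreme SSDs; its uncertainty is quoted as the maximal variation
among all SSDs relative to the mean (stored both relative and absolute, as
the prescription is ambiguous between the two readings at the printed
precision).  Records with a unit reading ratio carry no dose-per-pulse lever
and are excluded from the inversion.

## Quenching

The Birks light yield integrates A/(1 + kB·L_Δ(E)) over each particle's
energy-deposition interval, adaptively in log energy (relative tolerance
1e-9); the ideal yield (kB = 0) reduces to the weighted interval lengths in
closed form.  Stopping-power tables are interpolated monotone-preserving
(PCHIP) in log energy, so monotone tabulations cannot oscillate or go
negative between nodes.  The integrator is table-agnostic; the shipped
polystyrene table is **synthetic** — computed from the standard restricted
Møller collision stopping-power formula (Z/A = 0.53768, I = 68.7 eV,
ρ = 1.06 g/cm³, cutoff 1 keV) without the density-effect term, which only
matters at the few-percent level above ~1 MeV where quenching is weakest.
kB defaults to 0.019 cm/MeV with 0.01 cm/MeV as the sensitivity alternative;
`kB_sensitivity` reports the spread.  The quenching correction is the
clin/msr ratio of ideal-to-quenched yields (the subscript order of the
correction factor), independent of the efficiency A and of particle ordering.

## Fitting

Reading ratios follow the saturation-plus-buildup curve
P∞·Sⁿ/(lⁿ+Sⁿ) + S∞(1−e^(−bS)), normalized to 1 at S = 10 cm; correction
factors follow the sigmoid-plus-linear curve that is algebraically 1 at
10 cm for any parameters (its parameters are named q1..q4 to avoid colliding
with the profile polynomial coefficients).  Fits use bounded
trust-region-reflective least squares with optional per-point weights;
default bounds keep the saturation parameters positive, the sigmoid width
positive, |slope| < 0.05 cm⁻¹ and |amplitude| < 10 — wide enough never to
bind on realistic data while excluding degenerate sign flips.
Non-convergence is reported, never silent; rank-deficient designs raise.
The reference probe's nearly flat correction curve is interpolated by a
weighted quadratic in log S: the field sizes span almost two decades
log-uniformly, and in log S the quadratic represents the tabulated curve
within half the printed rounding step, which a quadratic in S cannot.

## Uncertainty

All bookkeeping is k = 1, in percent, combined in quadrature.  The
output-factor budget composition is {correction-factor uncertainty,
statistical reading-ratio term for the scenario (single measurement, or
seven detectors × two readings), 0.1% stem, 0.1% other, field-size term};
the per-measurement sub-components (readout reproducibility, jaw
repositioning, positioning window) are already folded into the statistical
terms and are reported only informationally.  This composition reproduces
all printed combined values of the probe's budgets; the corresponding
transferred-detector budgets are *not* plain quadratures of their printed
components (shared terms between the reference and the measured detector are
presumably treated as correlated), so the builder applies the same rule
without forcing agreement — a known limitation.  The field-size term is the
numerical derivative of the fitted reading-ratio curve times the
equivalent-square size uncertainty, itself propagated first-order through
S = √(FSx·FSy).

The uncertainty band of a fitted correction curve uses two-level Monte-Carlo
resampling: per iteration one shared Gaussian draw scales the systematic
sigma and independent draws scale the per-point random sigmas; the perturbed
points are refitted and the band is the standard deviation of the refitted
curves on a 0.05 cm grid over 0.5–40 cm (1000 iterations by default;
non-convergent iterations are dropped and more than 5% dropped is an error).
Note the pinned-at-10 cm sigmoid cannot absorb a rigid scale shift — its
systematic-only band vanishes at 10 cm by construction — so the "band equals
the systematic sigma" identity is exercised with a scale-family curve.

## Synthetic data: what it emulates and what it does not

The generator reproduces the study conditions: twelve jaw-delimited square
fields (0.6–30 cm) with erf-difference penumbras (σ = 2 mm default — chosen
so a nominal 0.6 cm field measures ≈ 0.67 cm, as observed for flattened 6 MV
jaw fields), a reading-ratio truth curve tuned once to typical flattened
6 MV output factors (0.67 at 0.66 cm, 1.06 at 30 cm), 0.1% multiplicative
reading noise (short-term readout/machine reproducibility), three repeats
per field, a chamber-like polarity curve, dose-per-pulse recombination with
B in the published ±0.005 range made self-consistent with the linear
correction model, and two-component (hard ~MeV / soft tens-of-keV) electron
spectra whose soft energy fraction grows with field side so the quenching
ratio moves by a few tenths of a percent.  All randomness flows through one
integer seed (default 20240101).

The ground-truth output factor is defined by the same deterministic
noiseless path the pipeline follows (noiseless-profile kvol, fixture
interpolation, spectra quenching), so zero-noise recovery is exact by
construction and the recovery tests probe noise propagation and plumbing,
not convolution accuracy (which has its own oracles).  What passing tests do
*not* show about real data: real penumbras are not exactly Gaussian-blurred
edges, real spectra are continuous rather than two-component, detector-
perturbation fixtures here are smooth inventions of the right magnitude, and
no linac-head, phantom-scatter or optical-chain physics is modelled.
Agreement on synthetic data validates the analysis chain, not the physics
inputs.

## Degenerate inputs and tie-breaks

Non-positive field sizes, sigmas, factors and empty budgets raise typed
errors; penumbra samples that fail to bracket the 50% level (or are exactly
equal) raise a bracketing error; spectra intervals outside the
stopping-power grid raise range errors; a positive fitted curvature beyond
roundoff scale flags the model as non-concave with a warning but still
returns it.  Detector footprints larger than the fit window trigger an
extrapolation warning rather than an error — the quadratic is then used
slightly beyond its fitted support, which is the measured-profile reality
for millimetre chambers in sub-centimetre fields.
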