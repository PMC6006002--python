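# Methods

## Scope and model

`prrtdose` implements the per-cycle internal dosimetry workflow used to
manage patients receiving [¹⁷⁷Lu]-DOTA-TATE peptide receptor radionuclide
therapy (PRRT). The workflow has four stages, mirrored by the package
modules:

1. **Kinetics** (`kinetics`). Every tissue's activity concentration is
   modelled as a single decaying exponential, C(t) = c₀·e^(−λt), with λ the
   effective decay constant combining biological clearance and ¹⁷⁷Lu
   physical decay (half-life 6.647 d). After the first cycle, organs are
   sampled at 18, 25 and 168 h post-injection and blood at 18 and 25 h;
   later cycles contribute a single ~20 h point and reuse the first-cycle
   effective half-life (the curve is re-anchored through the new point).
   The concentration residence time is the curve's integral to infinity per
   unit administered activity, c₀·3600/(λ·A_adm), in (MBq·s)/(MBq·kg).

2. **Dose engine** (`dose_engine`). Absorbed dose to a target r_t follows
   the MIRD formalism,
   D(r_t) = A_adm·[t_rt·DF(r_t←r_t) + Σ_s t_rs·DF(r_t←r_s)],
   with dose factors tabulated on a reference phantom. Bone-marrow
   self-dose assumes the marrow concentration equals the blood
   concentration; the remainder-of-body→marrow factor is replaced by
   30.3 nGy·kg/(MBq·s) (male) / 35.8 (female), since the phantom value
   overestimates it without skeletal uptake. Tumor self-dose is
   A_adm·t_r·DCF with DCF = 0.0236 mGy·g/(MBq·s); tumors act as cross-dose
   sources using the liver's factors (lesions are predominantly hepatic).

3. **Management** (`management`). After p completed cycles the expected
   cumulative dose after one further cycle is cumulative·(p+1)/p. Therapy
   is withheld when that expectation strictly exceeds the safety limit plus
   a 10% margin — 23 Gy → 25.3 Gy for kidneys, 2 Gy → 2.2 Gy for marrow.
   Only kidneys and marrow enter the decision (configurable). The CT
   schedule model counts 3+(n−1) CTs for an n-cycle classical course versus
   1 for the single-CT protocol.

4. **Agreement** (`agreement`). Paired protocol results are summarised by
   Bland-Altman relative differences, d = (a−b)/((a+b)/2)·100, with mean,
   sample SD (n−1) and limits of agreement mean ± 1.96·SD; Pearson r with a
   two-sided t-based p; decision concordance; and the exact power of a
   one-sided binomial test with rejection region {X ≥ k*}, k* the smallest
   k with P(X ≥ k | p₀) ≤ α. Under the discordance null p₀ = 0 this
   reduces to 1−(1−p)^n.

## Mass-scaling convention

The dose factors come in two kinds to close the units against
concentration residence times. `organ_level` factors (mGy/(MBq·s)) pair
with a source mass: cross terms multiply the source residence time by its
VOI mass (tissue density 1.0 g/cm³). In the self term, rescaling the self
S-value by m_phantom/m_voi — the standard inverse-mass scaling of
self-absorbed fractions for a nonpenetrating-dominated emitter — cancels
the VOI mass, leaving A_adm·t_r·S_self·m_phantom. Consequently the
self-dose depends on the delineation only through the measured
concentration, consistent with the concentration-DCF tumor method.
`concentration` factors (mGy·kg/(MBq·s)) multiply residence times
directly (blood→marrow, remainder of body, tumor DCF).

## Two-point fits and the physical bound

Blood is sampled at only two close time points, so its fit is the exact
two-point solution; organ fits with ≥ 3 points use nonlinear least squares
in linear concentration space (log-space fitting biases the estimate under
multiplicative noise), initialised from the log-linear OLS solution. A
fitted λ below the ¹⁷⁷Lu physical decay constant is flagged with a warning
rather than clamped — noise can legitimately push estimates below the
bound. A rising curve (λ ≤ 0) is an error. No uncertainty is propagated
onto fitted parameters.

## Synthetic cohorts

The generator defines the study conditions the pipeline is validated
under: 24 patients, 1–4 cycles each, administered activity
7400 ± 250 MBq per cycle. Uptake concentration scales with the
administered activity, so true dose is linear in A_adm. Per-organ c₀ and
effective half-life ranges are invented fixtures with magnitudes typical of
this therapy (kidney doses span roughly 2–14 Gy per cycle with a mean near
5.4 Gy; marrow doses near 0.1 Gy); effective half-lives are truncated below
at the physical bound. Measurement noise is multiplicative lognormal with
unit mean (concentrations are positive with scale-proportional error):
5% SD for SPECT-derived samples and 1% for blood, because triplicate
well-counter measurements are substantially more precise than SPECT
quantification — with 5% blood noise the 7-hour lever arm of the two-point
blood fit would regularly produce non-physical rising curves, which the
well counter does not exhibit in practice.

The single-CT protocol's misregistration/attenuation-mismatch effect is
reduced to one multiplicative factor per cycle ≥ 2 (lognormal, 6% SD)
applied to organ samples only; blood counting involves no CT, which is why
marrow dose is nearly protocol-independent. The factor is drawn from the
same stream either way so that classical and single-CT simulations from
equal seeds share identical measurement noise.

Per-patient sub-seeds are split with `SeedSequence(master, spawn_key=(k,))`,
so patient k is reproducible in isolation and identical in any cohort of
size ≥ k.

What the generator does *not* emulate: bi-exponential or multi-compartment
kinetics, inter-cycle biological change (tumor response, receptor
saturation), delineation variability, organ-size anatomy, and reconstruction
physics. Passing tests therefore demonstrate correctness of the arithmetic
and robustness to measurement-scale noise, not clinical accuracy on real
images.

## Misregistration phantom

The sensitivity experiment uses a voxel phantom: a hot ellipsoid
(semi-axes 30 × 22 × 50 mm, activity 10) in unit background on a 2-mm grid,
blurred with an isotropic Gaussian of 10 mm FWHM approximating SPECT
resolution. Attenuation physics is deliberately reduced to this
VOI-displacement proxy. The emission map is shifted axially against the
anatomical frame; integer-voxel shifts are exact array translations, others
are linearly interpolated. Two VOI strategies are compared: a fixed
anatomy-drawn mask, and a threshold segmentation (voxels ≥ 50% of the
shifted map's maximum) that follows the activity. The reference value for
each strategy is its own recovery on the aligned map — matching the use of
inherently aligned acquisitions as the dosimetry reference — so the error
is exactly 0 at zero shift, grows in magnitude with shift for the fixed
VOI, and stays ≈ 0 for the threshold VOI. The published percentages for
this experiment derive from reconstructed patient data; only the
qualitative ordering is asserted here.

## Numerical choices

- Times in hours internally; ×3600 applied only when forming residence
  times. Doses in mGy internally; Gy only in thresholds and reports.
- Strict ">" at the withholding threshold ("will exceed"); equality
  continues treatment. An override flag exists for exceptional clinical
  setups but is never applied automatically.
- Bland-Altman is signed by default (the reported means in such studies
  include negative values); an unsigned mode exists. 1.96 is fixed for the
  limits of agreement; sample SD uses n−1.
- The shipped dose-factor table (`synthetic_dose_factor_table`) is a
  clearly-labelled synthetic fixture with plausible magnitudes, not
  reference phantom values; real tables are user-supplied JSON with strict
  schema validation.
- Degenerate inputs raise typed errors: < 2 samples, repeated times,
  non-positive concentrations/activities, zero pair means, zero variance,
  mismatched decision lists, shifts leaving the phantom grid.

## Problem sizes

The validation suite uses: 200 synthetic patients for the 5%-noise
recovery study (mean signed error of cumulative kidney dose within ±2%,
median absolute error < 10%); 100 seeded 24-patient cohorts for the
perturbation-vs-concordance ordering property; a 48×48×80 phantom grid for
the misregistration experiment. These sizes give stable statistics at
interactive runtimes.

## Known limitations

Mono-exponential kinetics understate early washout phases; the two-point
blood fit underestimates marrow cumulated activity when clearance is
multi-phasic. Remainder-of-body residence time is taken as an input rather
than derived as whole-body minus organs. Cross-dose to tumors, voxel-level
dosimetry, biologically effective dose, and attenuation/scatter physics are
out of scope.
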