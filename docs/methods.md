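# Methods

## Scope and model

`doseshift` quantifies the dosimetric shift introduced when a radiotherapy
department replaces its dose calculation engine. The comparison is built on
three plans per case: the reference plan (Plan 1, old engine, normalized so
the isocentre receives the prescription dose Dpr), the same beams re-planned
by the new engine to the same Dpr (Plan 2), and the new engine evaluated
with Plan 1's exact MUs (Plan 3). Plan 3 shows what historical treatments
actually delivered as seen by the new engine; it is the basis of the
suggested prescription.

Plan 3 cannot be recomputed here without a treatment planning system. It is
emulated by exact MU-linear rescaling of Plan 2's dose quantities with the
global factor k = ΣMU₁/ΣMU₂ (dose is proportional to delivered MU for fixed
geometry). This is exact for a global output change and an approximation
where the engines disagree spatially; per-beam scaling would need a
per-beam dose decomposition, which plan exports do not usually carry.

## DVH representation

A DVH stores unitless volume fractions against dose in Gy, cumulative
("fraction receiving ≥ D") or differential (bin left edges). Point queries
(Dq, Vd) interpolate the cumulative curve piecewise-linearly; queries beyond
the binned range clamp (D at q above the covered fraction → lowest bin, V
above the last bin → 0). On a plateau, Dq returns the highest dose still
covering q, matching the convention that a structure uniformly at D₀ has
Dq = D₀ for every q. Conversions are exact inverses: differential volumes
are successive decrements of the cumulative curve, with the residual
fraction kept in the last bin.

## Radiobiology

The generalized equivalent uniform dose is the power mean
EUD = (Σᵢ vᵢ Dᵢᵃ)^(1/a). The exponent a is tissue specific: negative for
tumors (cold spots dominate; a = −10 is the bundled target default), ≈1 for
parallel organs (EUD → Dmean), large for serial organs (EUD → near-maximum
dose). Response probabilities follow the logistic form in log dose,
P(EUD) = 1/(1 + (D₅₀/EUD)^(4γ₅₀)), evaluated via the log-odds so slopes up
to γ₅₀ ≈ 20 cannot overflow; P(D₅₀) = 1/2 is exact by construction.

Numerical choices:

* EUD factors out the extreme dose (max for a > 0, min positive dose for
  a < 0) and works in log space, keeping |a| up to 20 stable.
* Zero-volume bins are dropped before exponentiation; volume at exactly
  zero dose with a < 0 returns the mathematical limit EUD = 0 and emits
  `ZeroDoseWarning` instead of raising.
* When a cannot be calibrated, `eud_interval` brackets EUD with
  a ∈ [0.5, 3.0] (parallel) or [4.0, 15.0] (serial); EUD is non-decreasing
  in a (power-mean inequality), so evaluating the endpoints suffices.

The bundled thoracic parameter table carries D₅₀ and LKB-derived a = 1/n
values for conventional fractionation, plus EUD caps at 1% and 5%
complication probability. Because γ₅₀ slopes are rarely published alongside
such tables, the shipped slopes are recovered by inverting the 1% cap
through the logistic model (`derive_gamma50`), rounded to integers (lung 2,
heart 3, esophagus 4, spinal cord 4) and marked as derived in a provenance
column. With these slopes the spinal-cord caps (49.9/55.3 Gy) and the acute
esophagitis 5% cap (42.4 Gy) are exact at one-decimal rounding; the
remaining cells are internally consistent only to ≈0.1 Gy, and the tests
bound them at 0.15 Gy rather than pretending exactness. Slopes are an
explicit required parameter of the API; the derived defaults live only in
the table.

On the D98% ≤ EUD ≤ D2% ordering: it holds for clinically shaped target
distributions (bounded cold tail), which is where negative exponents are
used, and the test suite asserts it there over a ∈ [−10, 20]. It is *not* a
theorem for arbitrary DVHs: with appreciable volume in a low-dose tail and
a strongly negative exponent, EUD deliberately collapses toward the
cold-spot dose — far below D98% — because penalizing cold spots is exactly
what the negative exponent is for.

Range-style dose limits ("Dmean < 15–20 Gy") are checked against the
conservative (lower) bound by default, configurable.

## Gamma engine

γ(r) = min over evaluated positions e of
√(((Dₑ(e) − Dᵣ(r))/ΔD)² + (|e − r|/dta)²), with ΔD = dd% of a global
normalization dose (default: the reference prescription — the clinical
photon convention) or of the local reference dose. All points are evaluated
by default (low-dose cutoff 0); under local normalization, zero-dose
reference points are excluded because the criterion degenerates there.

The minimization interpolates the evaluated grid linearly and searches a
subsampled neighborhood: step dta/upsample (default dta/10) out to a cap of
3·dta. On 16×16 grids this agrees with an exhaustive fine-grained
brute-force search to within 0.02 in γ. A consequence of interpolated
search worth knowing: an isolated voxel raised by exactly the dose
criterion scores γ ≈ √½, not 1, because the interpolated falloff toward a
neighbour trades dose error for distance — any interpolating implementation
(and the brute-force oracle) behaves this way.

γ ≤ 1 counts as passing (boundary inclusive); the pixels-γ-histogram is the
cumulative fraction of evaluated points per γ edge and equals the pass rate
at edge 1.0 by construction. Failing points are split into over/underdose
masks by the sign of (eval − ref). Grids whose roughness against their own
smoothed trend greatly exceeds the reference's (Monte-Carlo-like noise) get
a warning — pass rates are then biased — but no correction is applied.
Both 2-D planes and full 3-D grids are accepted; 3-D searches at default
resolution are expensive and the plan pipeline uses 2-D planes.

## Statistics

Paired dosimetric data (same CT, same beams, only the engine changes) are
tested with the two-sided Wilcoxon signed-rank test. Zero differences are
discarded; ties receive average ranks. For n ≤ 25 the p-value is exact: the
null distribution of W⁺ is built by dynamic-programming convolution over
the doubled ranks, identical to enumerating all 2ⁿ sign assignments but
polynomial in n. Beyond 25 a normal approximation with tie-corrected
variance is used. The two-sided p is 2·min(P(W⁺ ≤ w), P(W⁺ ≥ w)), capped
at 1.

The bootstrap sample-size curve draws, for each n from 2 up to the sample
size m, B = 1000 resamples with replacement, computes the Wilcoxon p on
each (all-zero resamples score p = 1 — no detectable difference), and
records the mean p per n (median available as an option). The minimal
significant n is the first n whose mean p falls below α = 0.05. For a
constant-sign equal-magnitude difference the curve is the closed form
p(n) = 2/2ⁿ, crossing 0.05 at n = 6. Curves are bit-reproducible for a
given seed.

## Decision engine

The prescription is kept when all three hold: the paired MU Wilcoxon p ≥ α
(0.05), the target |ΔD95%| is strictly below 2% (a shift exactly at 2% is
actionable), and every gamma criterion (defaults 2%/2 mm and 3%/3 mm,
global) reaches the 95% pass goal. Otherwise the suggested new prescription
is the Plan 3 target EUD — the dose the historical MUs really deliver per
the new engine — with the percent change reported and flagged when it falls
in the 5–10% band typical of transitions from older algorithm generations.
(A D95%-based suggestion is available behind `suggestion_basis="d95"`.)
The ΔD95% flag is taken from the same-prescription comparison (Plan 2),
since that is what a planner re-normalizing to the new engine sees; the
same-MU (Plan 3) deltas are reported alongside. Missing evidence yields
`insufficient_evidence` rather than a guess. The decision is monotone:
worsening any input never flips an adjustment recommendation back to keep.

## Synthetic scenarios

The generator emulates the *statistical signature* of an engine transition,
not radiation transport: a global dose-per-MU ratio (`global_scale`), an
optional localized additive perturbation (heterogeneity regions), an extra
systematic MU shift, and per-beam Gaussian MU noise. Renormalizing Plan 2
to the same prescription makes MU₂ = MU₁·(1 + shift/100)/global_scale; with
a scale of 0.92 the pipeline recovers a suggested prescription within 1% of
0.92·Dpr, and the identity scenario returns "keep".

Default study conditions: Dpr = 60 Gy, 10 beams with reference MUs uniform
in [60, 160], a 32×32 grid at 3 mm with a flat target core and Gaussian
penumbra, and sigmoid DVHs (target at Dpr with steepness 2 /Gy — D95 within
≈2.5% of Dpr and EUD(a=−10) within 0.6% — lungs and cord at clinically
plausible fractions of Dpr). Bins start at 0.5 Gy so target EUDs with
negative exponents stay finite.

What passing the synthetic pipeline does **not** show: real engines differ
spatially in heterogeneous anatomy, DVH shapes change between engines (here
Plan 2 DVHs equal Plan 1's at the same prescription), MU differences are
not exactly proportional across beams, and clinical DVHs carry TPS binning
artifacts. Results on synthetic scenarios validate the machinery and sign
conventions, not clinical magnitudes.

## Problem sizes

The test suite and the acceptance script run at desk scale by design:
16×16–32×32 gamma grids (with the brute-force oracle on 16×16), bootstrap
samples of 8–20 pairs at B ≤ 1000, and 1000-DVH sweeps for the analytic
identities. All complete in well under two minutes on one CPU.

## Known limitations

* No contour handling: DVHs come from TPS exports, never from grid + RT
  Struct.
* Absolute-volume DVHs are normalized to fractions at import; cc arithmetic
  is out of scope.
* DICOM support is deliberately narrow: axial, axis-aligned RT Dose with
  uniform frame offsets, and RT Plan metersets only.
* The logistic EUD models carry no fractionation (EQD2) correction; the
  bundled D₅₀ values assume conventional fractionation.
* Suggested prescriptions are raw values; clinical rounding and
  fractionation are left to the oncologist.
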