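# Methods

## Signal model and conventions

A QCM-D record is a set of per-harmonic time series (Δf_n, ΔD_n) for odd
harmonics n ∈ {3, 5, 7, 9, 11}. Frequency shifts are stored
overtone-normalized (Δf_n/n), the scale on which a rigid film reads the same
shift on every harmonic and a complete bilayer sits near −26 Hz; an input
flag divides raw shifts by n at read time, since instrument exports differ
and plotted data rarely state the convention. Dissipation is stored in units
of 1×10⁻⁶ so that published thresholds (e.g. "rigid below 1×10⁻⁶") are the
plain numbers 1.0, 3.8, 0.6. Time is in minutes throughout. Baselines are
established by subtracting the per-series mean over a pre-flow buffer
window; this is a pure shift, so every difference-based descriptor is
unaffected and the operation is idempotent.

## Signature classification

All descriptors are evaluated on a single reference harmonic, the 3rd by
default (the conventional reporting harmonic), after a centered 5-sample
moving average; window widths and every decision threshold live in
`ClassifierConfig`. Plateaus are means over the final minute before the
rinse and before the end of record — published values are quoted as
"stabilized" without a stated window, so a fixed 60 s average is this
package's choice. A frequency minimum counts as real only when the
subsequent recovery exceeds a prominence threshold (default 10 Hz), which
noise at realistic levels (σ_f ≈ 0.5 Hz) cannot produce. Because smoothing
flattens the cusp at a true minimum, the reported (t_min, f_min) is refined
on the raw series within the smoothing neighborhood of the smoothed argmin.

Decision rules, in order: a non-rigid final film (ΔD ≥ 1×10⁻⁶) without a
minimum is a vesicle layer; a prominent minimum whose recovery exceeds
10 Hz, ending rigid, is a two-step bilayer; a monotone approach ending rigid
with |Δf| inside the bilayer band (default 24–30 Hz, bracketing the
published −26…−29 Hz plateau range) is a one-step bilayer; a rigid film
below the band whose rinse raises both Δf (> 1 Hz) and ΔD (> 0.1×10⁻⁶) is an
incomplete bilayer; anything else is reported as indeterminate with all
descriptors populated. These thresholds are decision boundaries chosen
around exemplar values, not published constants, and are exposed in config.
If both the vesicle-layer and incomplete-bilayer patterns could fire, the
final ΔD decides, since rigidity is the sharper physical criterion.

The initial adsorption slope is a least-squares fit of Δf against time from
flow start to the frequency minimum. Vesicle-layer traces have no minimum
yet still have a meaningful adsorption rate, so the window then ends where
Δf first covers 90% of its final plateau change — a surrogate endpoint that
keeps slopes comparable across outcomes; the fraction is configurable and
this is a package choice, not a published procedure.

Phase-trajectory reading: on the (−Δf, ΔD) plane, eastward motion is mass
gain and northward motion viscoelasticity gain; adsorption runs north-east,
rupture south-west, direct bilayer deposition mainly east. The two axes
carry different units, so compass octants are computed after scaling ΔD by
20 Hz per 1×10⁻⁶ — the aspect under which a full adsorption transient (tens
of Hz against a few 1×10⁻⁶) runs diagonally, matching how such plots are
drawn and read. Increments below a dead-band (0.1 Hz, 0.01×10⁻⁶) are
stationary.

## Packing geometry

The chain is Δm = −C·Δf with C = 17.8 ng/cm²/Hz (5 MHz crystal); water-layer
subtraction (default 102 ng/cm², the PC-on-silica estimate, assumed
transferable to anionic bilayers — an auditable config value, not a
validated fact); mole-fraction averaging of molecular weight and tail
volume; M_L = M̄/N_A with N_A = 6.02214×10²³; N_L = Δm_corrected/(2 M_L) per
nm²; a_L = 1/N_L; h_L = 2 v̄_L/a_L. Tail volumes are species constants
(PG 0.96, LPG 0.46, PC 0.96 nm³/molecule) averaged by mole fraction, which
reproduces every published mixture value. All intermediates are kept at full
precision; rounding is a rendering concern. The identities a_L·N_L = 1 and
h_L·a_L = 2 v̄_L hold to 1e−12 by construction and are property-tested
against an independent single-expression recomputation.

The Sauerbrey conversion assumes a thin rigid film. The rigidity criterion
(final ΔD strictly below 1×10⁻⁶) is advisory: the chain still computes for
softer films but attaches a warning, because the surface-averaged effective
mass remains interpretable (and packing for an incomplete bilayer is
explicitly labeled a surface average over patches and gaps). Viscoelastic
(Voigt-type) mass estimation is out of scope.

## DLS distributions

Distributions are discrete binned weights related by %I ∝ N_i d_i⁶,
%V ∝ N_i d_i³, %N ∝ N_i under the spherical-particle, Rayleigh-weighting
assumption; conversions multiply by the power ratio and renormalize to 100,
with no bin-width correction (the defining relations sum over bins
directly). Conversion is an exact bijection on positive distributions. Mode
detection finds peaks with at least 5% relative prominence (so sampling
noise does not split one population) and assigns each peak the mass between
the flanking minima. Stability assessment compares later time points to the
earliest: a primary-mode shift beyond 25% of diameter, or a new mode
carrying ≥ 5% of the mass, flags aggregation; both thresholds are config, as
published descriptions of aggregation are qualitative.

## Synthetic traces

The generator emulates the four outcome signatures with saturating
exponentials — shapes published as figures, not equations, so the functional
form is a modeling choice. Two-step runs descend to (t_min, f_min) along a
normalized (1 − e^{−kt}) curve with k·t_min = 1, a curvature under which the
least-squares initial slope stays within ~2% of f_min/t_min, then recover
exponentially to the plateau while ΔD peaks and relaxes. One-step and
vesicle-layer runs approach their plateaus monotonically (the latter slowly,
rate 0.075/min, so the plateau takes tens of minutes as observed for PG).
Incomplete-bilayer runs hold a shallow pre-rinse plateau, then the rinse
moves Δf and ΔD exponentially to their final values. Per-harmonic scaling
spans the configured overtone spread with the lowest harmonic carrying the
nominal curve; Gaussian noise is added per sample from a single integer
seed.

Preset parameter sets pin the published plateau/minimum/dissipation values
of each lipid system: PC (minimum −72 Hz at 2.5 min, plateau −26 Hz, ΔD peak
3.5 relaxing to 0.6×10⁻⁶), PG (plateau −52 Hz over ~40 min, ΔD 3.8×10⁻⁶,
6 Hz overtone spread), PG/LPG 10/20/30 (one-step plateaus −26/−27/−29 Hz,
low ΔD), PG/LPG 40 (pre-rinse −23 Hz, post-rinse −18 Hz, rinse ΔD rise to
0.8×10⁻⁶). Default sampling is 1 s over 20–52 min records. What the
generator does not emulate: mechanistic vesicle-deformation/rupture physics,
flow-cell hydrodynamics, drift and spikes in real baselines, or
harmonic-dependent noise. Passing closed-loop tests therefore shows the
classifier reads the canonical signatures correctly at realistic noise, not
that it is robust to every instrument artifact.

## Problem sizes and numerical choices

Tests and the acceptance script use 1 s sampling (1200–3100 samples per
trace) and 100 seeded replicates per scenario for the noisy-recovery check,
sizes at which all results are stable with respect to refinement. Property
tests run 1000 derandomized random draws. Degenerate inputs are rejected
with messages rather than coerced: non-monotonic time, empty mixtures,
corrected mass at or below zero (film lighter than the assumed water layer),
zero-weight distributions. Report JSON uses sorted keys and 12-significant-
digit floats, so identical inputs give byte-identical output.

## Known limitations

The water-layer correction and its transfer to anionic lipids is the
dominant systematic in every packing number. Classification thresholds are
tuned to the canonical signatures; intermediate real-world traces will
return `indeterminate` rather than a forced label. Δf/ΔD are surface
averages, so no spatial information (patch sizes, defects) is inferred.
Egg-derived PG and PC are acyl-chain mixtures treated as single species with
average constants.
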