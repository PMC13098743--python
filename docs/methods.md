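# Methods

`hybriddo` analyzes hybrid diffuse-optics monitoring of red-blood-cell
transfusion (RBCT) sessions: time-resolved near-infrared spectroscopy (TRS)
for absolute tissue optical properties and hemoglobin concentrations, and
diffuse correlation spectroscopy (DCS) for a microvascular blood-flow
index, combined with vitals and timed blood gases into per-subject
biomarker traces and a cohort-level pre/post statistical battery. This
note records the models, the defaults and their rationale, what the
synthetic generator does and does not emulate, and the numerical choices
that were genuinely open.

## Photon-transport forward models

**Time-domain reflectance.** The DTOF shape is the diffusion-approximation
solution for a homogeneous semi-infinite medium with an extrapolated
boundary: an isotropic source at depth `z0 = 1/musp'` and a negative image
source mirrored across the extrapolated plane at `-(z0 + 2*zb)`, with
`zb = 2D(1+Reff)/(1-Reff)`, `D = 1/(3*musp')`. `Reff` comes from the
standard polynomial approximation in the relative refractive index.
Defaults `n_tissue = 1.4`, `n_outside = 1.0` (config-exposed; devices
rarely publish their boundary condition). Curves are defined up to an
arbitrary amplitude; every fit treats scale as a nuisance.

The late tail decays as `exp(-mua*v*t)` only asymptotically: the `t^(-5/2)`
prefactor contributes `-2.5/t` to the log-slope, which at 8 ns is still
~15% of `mua*v` for brain-like properties. The absorption self-test
therefore regresses the log-slope on a window far in the analytic tail
(250–300 ns), where it agrees with `-mua*v` to better than 1%.

**DCS.** The normalized field autocorrelation solves the correlation
diffusion equation in the same geometry with Brownian scatterer dynamics,
mean-square displacement `6*BFI*tau` and wavenumber `k0 = 2*pi*n/lambda`
(785 nm). The measured intensity autocorrelation follows from the Siegert
relation `g2 = 1 + beta*g1^2`. Note that `g2` equals `1+beta` exactly only
at zero lag; at `tau = 1e-8 s` and `BFI = 1e-8 cm^2/s` the model itself has
already decayed by ~4e-4, so plateau checks evaluate the zero-lag limit.

## Inverse problems

**DTOF fit.** Poisson-weighted least squares of the forward curve convolved
with the measured IRF against the recorded histogram, inside a window from
80% of the peak on the rising edge to 1% of the peak on the tail (a common
TRS convention that excludes early non-diffusive photons; both fractions
config-exposed). Free parameters are `log mua` and `log musp'` (enforcing
positivity); the amplitude is profiled out in closed form each iteration
and a sub-bin temporal shift is fitted as a nuisance because device
IRF/DTOF timing offsets are rarely known. The dark-count floor, estimated
from the bins preceding the rising edge, is subtracted first — guarded to
apply only when the estimate is below 2% of the peak, since a larger value
means there is no pre-pulse baseline (e.g. an IRF at t = 0). An unmodeled
flat background of even a few counts per bin biases the late tail and
hence `mua` by ~0.5%, which matters because a bias that co-varies with the
transfusion-induced absorption change leaks into the Δ-traces.
Non-convergence and unphysical optima flag the record for exclusion; they
never raise.

**Chromophores.** Fitted absorptions at 690/830 nm invert the 2x2
Beer–Lambert system `mua = ln(10) * E c` using a bundled extinction table
(compiled Gratzer/Kollias tabulation; provenance in the data file header).
Concentrations are in mM; negative solutions are flagged and excluded, not
clipped, because clipping would bias the Δ-traces. Water/lipid background
absorption is neglected (the emulated device software's assumption is
unknown); the extinction table is replaceable.

**Hand-off to DCS.** The reduced scattering fed to the DCS model is the
arithmetic mean of the two TRS wavelengths; absorption at 785 nm is the
mean of the two fitted `mua` by default, with linear interpolation in
wavelength as a config alternative. `fit_g2` then runs joint least squares
over `(log BFI, log beta)` from the smallest lag to where the
plateau-normalized `g2-1` drops below 3%. The noiseless round trip of both
inversions recovers generating parameters to well under 1%; the residual
~1% systematic the TRS hand-off leaves in the recovered BFI cancels in the
baseline-relative traces.

## Quality control

TRS records pass when SNR — peak counts over the standard deviation of a
pre-curve background window (first 10% of bins, capped at the rising-edge
half-maximum crossing, minimum 20 bins) — strictly exceeds 10. DCS records
are rejected below 10 kHz averaged count rate **or** below beta = 0.4: the
criteria are disjunctive by default because either alone marks an unusable
curve; a conjunctive mode exists for the literal reading. Artifact
intervals (event marks, accelerometer flags, manual) are half-open
`[t0, t1)` and masking removes bins without altering survivors; gaps are
never interpolated.

## Derived biomarkers

* `Hgb [g/dL] = HCT/100 * MCHC/10`, MCHC = 340 g/L.
* `CaO2 = 1.36 * Hgb * SaO2` (mL O2/dL), SaO2 from pulse oximetry
  (percent-scale inputs auto-detected and converted).
* OEF via an assumed venous compartment fraction gamma = 0.75:
  `SvO2 = (StO2 - (1-gamma)*SaO2)/gamma`, `OEF = (SaO2-SvO2)/SaO2`. The
  emulated study derives OEF per its methodology literature without
  printing the formula; gamma is config-exposed and `gamma = 1` reduces to
  `(SaO2-StO2)/SaO2`.
* `MRO2 = BFI * OEF * CaO2`, with the hematocrit correction carried
  entirely by CaO2: HCT is held constant within each protocol period
  (pre before the transfusion-start mark, mid during, post from the end
  mark), switching at the marks. The BFI itself is deliberately left
  uncorrected for hematocrit; flow-index HCT corrections are still being
  validated in the field and the derived flow values should be read as
  preliminary.
* A missing post-transfusion draw is imputed as the mean post-HCT of
  cohort donors whose pre-HCT matched within ±0.5 points (fallback: cohort
  mean, with a warning).
* All streams fuse on half-open 10-s bins (bin value = mean of members;
  empty bins absent). Flow, OEF and MRO2 become r-traces (divided by the
  pre-transfusion baseline mean); hemoglobin concentrations become
  Δ-traces (baseline mean subtracted).

## Statistical battery

Per subject, the pre window is the entire baseline and the post window the
6 minutes after the transfusion-end mark; bins belong to windows by their
start times. Three tests per variable: a one-sample Wilcoxon signed-rank
of the per-subject (post − pre) means against zero, one-sided in the
physiologically expected direction (flow, MRO2, Δ[HbO2], Δ[HbT]: greater;
OEF, Δ[Hhb]: less — a config table); a paired signed-rank for blood-gas
analytes; and a paired two-sided cerebral-vs-peripheral contrast of post
means over subjects with both placements. The signed-rank null is exact
for n ≤ 25 via the shift-algorithm convolution over all sign assignments
(tied magnitudes handled with midranks — needed because real blood-gas
differences tie), and a normal approximation with continuity correction
above. Zeros are removed before ranking; all-zero differences report p = 1
flagged; fewer than 5 usable pairs refuses the test. p-values below 0.001
print as "<0.001"; no multiple-testing correction is applied (matching the
emulated analysis). Summaries are mean(SD) with sample SD and quartiles by
linear interpolation; table rounding is half-up.

## Synthetic session generator

The generator emulates the monitored-transfusion protocol: 30 min
baseline, 150 min transfusion (range 120–180), 30 min post, three arterial
draws (10 min into baseline, half-bag, 10 min into post). Ground truth per
location is baseline physiology plus a sigmoidal ramp spanning the
transfusion epoch (clamped to exactly 0/1 at its ends so windows are
clean) carrying per-subject effects drawn around the cohort defaults:

* peripheral blood flow +68% (SD 0.20), cerebral 0 (SD 0.08);
* OEF −7% cerebral / −8% peripheral (SD 30% of the mean — the cohort
  spread of these is not reported);
* Δ[Hhb] = 0 (SD 0.0004 mM);
* HCT +2.9 points (SD 0.8) from a pre level of 24.5% (SD 1.6); arterial
  Hgb follows HCT through the MCHC identity;
* PaCO2 essentially unchanged (+0.6 mmHg, SD 2.0).

The OEF drop and constant Hhb are the primitive dials; Δ[HbO2] and Δ[HbT]
emerge through `HbO2 = StO2/(1-StO2) * Hhb` and land at ≈ +0.0041 mM
cerebral and +0.0037 mM peripheral with the default baselines (cerebral
HbT 0.060 mM, StO2 0.65; peripheral HbT 0.048 mM, StO2 0.70; BFI 1.5e-8 /
0.8e-8 cm^2/s) — the magnitudes the emulated cohort reports. Dialing the
hemoglobin deltas directly instead is not equivalent: the cohort's printed
Δ[HbO2] spread (0.0053 mM) implies sign-flipping oxygenation effects in a
quarter of subjects, which is incompatible with the uniformly significant
extraction-fraction drop the same cohort shows; a single-driver Gaussian
model cannot reproduce both, and this package reproduces the
significance/direction pattern. AR(1) noise (phi = 0.9 per 10-s step) on
concentrations (0.0006 mM), flow (3% multiplicative) and SaO2 (0.003)
supplies within-subject variability; assay noise is 0.5 points (HCT) and
0.1 g/dL (Hgb).

Raw simulation per acquisition: concentrations → absorption via the same
extinction table → DTOF (IRF-convolved Gaussian IRF, sigma 100 ps, t0
1 ns; 25-ps bins, 400 bins; 5e5 total counts over a 2 counts/bin dark
floor; Poisson) and BFI → g2 (60 lags over 1e-7–1e-1 s, beta 0.5, additive
Gaussian noise 0.005 scaled with the inverse root count rate; 30/60 kHz
cerebral/peripheral). Vitals are generated at 1 Hz — the clinical
monitors' 400 Hz native rate is a source detail since fusion happens at
10-s bins. An optional missingness pattern drops the cerebral streams of
two subjects and the post draw of one, mirroring the emulated cohort
(12 of 14 with cerebral traces).

**What the generator does not emulate** — and hence what green tests do
not show about real data: scalp/skull partial-volume contamination (the
homogeneous model under-recovers cerebral changes on real heads), motion
artifacts beyond clean masked intervals, probe-repositioning drifts,
arterial-line events, inter-device clock drift beyond constant offsets,
and non-Gaussian between-subject physiology. Parameter-recovery results
certify the inverse machinery against its own forward model, not the
model's adequacy for layered tissue.

## Problem sizes and calibration checks

The packaged cohort runs (acceptance script and end-to-end tests) use the
full cohort size (n = 14) and the 0.1 Hz acquisition rate with a
time-compressed protocol of 10/30/10 min — the window structure (entire
baseline, 6-min post window) is preserved and five independent seeded
cohorts are processed through the full raw pipeline; the significance/
direction pattern (peripheral flow up, extraction down bilaterally,
Δ[Hhb] unchanged) must appear in at least 4 of 5. Type-I calibration runs
200 null cohorts (no programmed effects, physiological noise retained)
through the trace-level path; the pooled one-sided rejection rate at
alpha = 0.05 stays within [0.02, 0.09] (signed-rank tests at n = 14 are
slightly conservative because of the discrete null).

## Known limitations

* Homogeneous semi-infinite model only; no layered or Monte-Carlo
  transport, no multi-distance TRS/DCS, no absolute amplitude calibration.
* OEF rests on an assumed, constant venous fraction; gamma errors scale
  OEF and MRO2 multiplicatively (they cancel in r-traces but not in the
  cerebral-vs-peripheral contrast if the sites' true gammas differ).
* The BFI carries no hematocrit correction (deliberate, see above).
* Imputation assumes donors with equal pre-HCT respond alike.
* The exact engine's two-sided p doubles the smaller tail (capped at 1),
  the same convention as the R implementation the emulated analysis used.
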