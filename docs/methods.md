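# Methods

`myotrace` reimplements, as a tested pipeline over synthetic data with known
ground truth, an ex vivo analysis of right-ventricular-outflow-tract (RVOT)
myocardium: extraction and quality control of action-potential (AP) shape
properties from paced intracellular recordings, detection of pro-arrhythmic
tissue abnormalities, percent-fibrosis quantification from
picrosirius-red-stained sections, and linear mixed-effects association
modelling linking clinical covariates, AP shape and fibrosis. This note
documents the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic generators do and do not emulate.

## The AP waveform model

The generator (`synth.waveform`) produces a parametric piecewise curve, not a
biophysical ionic model: baseline at the resting membrane potential (RMP), a
half-cosine upstroke of configurable duration (default 1 ms), an optional
plateau at the peak, and a linear or half-cosine ("sigmoidal") repolarisation.
The parametrisation was chosen so that every property the extractor must
recover has a closed form — the generator is the oracle, which is the point:
the analysis measures AP *shape*, not currents.

Parameters (`APWaveformParams`): `rmp_mV` (default −80 mV), `apa_mV`
(amplitude, 100 mV), `upstroke_duration_ms` (1 ms), `apd90_ms` (duration at
90 % repolarisation, 250 ms at the 1 Hz reference), `plateau_fraction`
(0.25; scales the APD20/APD90 ratio), `repolarisation_shape`.

The *activation time* — the fiducial from which all APDs and the AUC are
measured — is the instant of maximum upstroke velocity (dV/dt_max), the
standard cardiac-EP convention and the midpoint of the half-cosine upstroke.
Analytic values of RMP, APA, dV/dt_max, APD20/50/90 and AUC90 are available
via `analytic_features`.

## Paced-train generation

`synth.recording.generate_recording` emulates the recording protocol: trains
of paced beats at 0.5/1/2/3/4 Hz, a biphasic stimulation artifact (one full
sine cycle, 2 ms wide, default 25 mV) placed at each stimulus, and the AP
upstroke following the stimulus at a configurable latency (default 6 ms —
outside the 5 ms blanking window, so that insufficient-separation QC cases
can be synthesised on demand by shortening the latency). The acquisition rate
defaults to 10 kHz, enough to resolve a ~1 ms upstroke to 1 % in slope.

Rate adaptation: the waveform's `apd90_ms` is the 1 Hz value; at other
frequencies APD90 shortens linearly at 41.46 ms/Hz (the frequency slope of
the reference cohort model below), floored at 60 ms. When impaired
shortening is configured, APD is frequency-invariant and the tissue follows
pacing 2:1 at the configured fast frequencies. Requests whose AP footprint
(latency + waveform duration + 25 ms diastolic baseline) exceeds the pacing
cycle without configured capture failure raise an error as physically
inconsistent.

Injected abnormalities (`AbnormalityConfig`), each logged with sample-exact
ground truth:

* **EAD** — raised-cosine depolarising hump (default +15 mV, 30 ms) centred
  uniformly between the APD20 and APD90 times of its beat;
* **extrasystole** — a full AP at a uniformly random diastolic phase at
  least 100 ms after the preceding APD90, fitted entirely inside the
  interval;
* **spontaneous couplet** — two stimulus-independent AP 250 ms apart;
* **APD alternans** — beat-to-beat APD90 alternation of configurable
  peak-to-peak depth;
* **capture failure** — 2:1 capture at listed frequencies.

An interval hosts at most one spontaneous event (couplet sampled before
extrasystole), so injected counts are unambiguous. Gaussian noise of
configurable SD is added last. Identical seeds give bit-identical traces.

## Feature extraction and QC

`apfeatures.segment_aps` detects AP as contiguous excursions above 40 % of
the trace amplitude lasting ≥ 4 ms (which suppresses the 2 ms artifact) and
reaching 60 % of the amplitude (which suppresses partial deflections such as
late EADs); the upstroke is located as the maximum discrete derivative near
the threshold crossing. An AP is *stimulated* iff its dV/dt_max falls within
50 ms after a stimulus, otherwise *spontaneous*.

Estimators: RMP is the median of the last 20 ms of baseline before the
stimulus (before the upstroke, with a 5 ms guard, for spontaneous AP); APA is
peak minus RMP; APD thresholds are crossed with linear interpolation between
samples (sub-sample precision); AUC90 is the trapezoidal integral of
(V − RMP) from activation to the APD90 crossing with fractional end
segments, in mV·s.

QC rejection reasons, applied in order: `no_baseline`,
`upstroke_in_artifact` (dV/dt_max inside the 5 ms post-stimulus blanking
window), `artifact` (|dV/dt| > 1000 V/s outside the upstroke, or voltage
above +60 mV), `low_amplitude` (APA strictly below 75 mV — the boundary
value 75.0 is accepted), `incomplete_repolarisation`. The amplitude
threshold and blanking are configurable; lowering the threshold can only
increase the accepted count.

Closure (verified in the acceptance tests over APD90 150–350 ms, APA
80–130 mV, all five frequencies): potentials are recovered within 0.5 mV and
durations within one sample period. dV/dt_max and AUC90 carry an inherent
finite-difference/trapezoid discretisation error (≤ ~2 % and ≤ 1 % at
10 kHz), which is the tolerance applied to them.

## Abnormality detection

* **EAD**: local maxima during repolarisation (between the APD20 time and
  the 90 % level) with prominence ≥ 5 mV on a 1 ms-smoothed segment and a
  preceding positive dV/dt ≥ 0.5 V/s. A hump riding a steep repolarisation
  slope loses roughly slope × half-width of apparent prominence, so the
  effective detection floor rises with short APDs; the default 15 mV
  injection is detected with 100 % sensitivity on the waveforms used here.
* **Extrasystole / couplet**: consecutive spontaneous AP separated by at
  most 500 ms form one couplet event; isolated spontaneous AP are
  extrasystoles. Every spontaneous AP contributes to exactly one event.
* **APD alternans**: within a per-frequency sequence of accepted APD90s,
  true iff some run of ≥ 6 beats has strictly alternating successive
  differences with mean |ΔAPD| ≥ max(5 ms, 5 % of mean APD); sequences
  shorter than 6 beats are indeterminate rather than negative.
* **Impaired APD shortening**: per location, flagged iff the capture ratio
  falls below 1 at any of 2/3/4 Hz or mean APD90 exceeds the cycle length
  there; indeterminate unless ≥ 2 frequencies including a fast one were
  measured. Patient-level flags are the OR over locations.

All thresholds are config-exposed defaults: the phenomena were originally
identified visually and no published numeric criteria exist to validate
against.

## Histology generation and fibrosis quantification

`synth.histology` renders red collagen speckle (Gaussian random field,
σ = 1.5 px, thresholded) on yellow myocardium with a near-white background,
interior background-coloured gaps (σ = 8 px field), and an optional
endocardial collagen band along the top edge. The collagen fraction within
the analysable area is imposed exactly by choosing the threshold as the
appropriate empirical quantile, so the label mask is exact ground truth. A
3 px myocardium margin separates interstitial speckle from the image border
and the band, keeping the exclusion rule's behaviour unambiguous.

`fibrosis.classify_pixels` works in HSV space: tissue requires saturation
≥ 0.25 and value < 0.95; hue in [330°, 25°] (wrapping) is collagen, hue in
(25°, 90°] myocardium; everything else is a background/gap candidate.
`build_exclusion_mask` removes background and gaps, and additionally any
collagen component that touches the tissue border (image edge or
edge-connected background) with local thickness ≥ 8 px — a morphological
stand-in for endocardium/non-myocardial collagen exclusion; interior gaps do
not define a tissue border, so dense interstitial fibrosis is never
discarded wholesale. Percent-fibrosis is 100 × collagen / (collagen +
myocardium) over the analysed area; patients are summarised as the
unweighted mean over usable sections, with a warning below 30 sections.

Recovery is within 1 percentage point of truth across fractions 0–0.6 and
stable (< 0.5 pp) under resolution doubling.

## Cohort generation and mixed models

`synth.cohort.generate_cohort` draws, per patient, binary covariates at the
reference cohort prevalences (22/25 TOF, 6/25 repaired, 9/25 cyanotic,
12/2/11 mild/moderate/severe RV–PA gradient, 9/25 beta blocker, 12/25 severe
proBNP, 6/25 clinical arrhythmia, 13/25 tissue arrhythmia, 6/25 impaired
shortening, 12/25 alternans), age in years log-normally (median 2.5 y,
σ = 1.4, clipped to 0.33–56 y — infants repaired early plus re-operated
adults), and emits one row per patient × location × frequency per dependent:

y = intercept + Σ βᵢxᵢ + b_patient + ε,  b ~ N(0, σ_p²), ε ~ N(0, σ_e²).

The default β are the published point estimates for all seven dependents
(e.g. APD90: intercept 217.62 ms, frequency slope −41.46 ms/Hz, cyanosis
+41.21 ms, impaired shortening +127.82 ms). σ_p/σ_e defaults are realistic
per-scale spreads (APD90: 30/18 ms; RMP: 3/2 mV; …); the source study does
not report variance components, so these are this package's own choices,
fixed once. Categorical coding is treatment coding against the reference
levels ASD / unrepaired / acyanotic / mild gradient / no beta blocker /
none-mild proBNP / no clinical arrhythmia. With both SDs set to zero the
responses equal the linear predictor exactly.

`assoc.fit_ap_mixed_model` fits a linear mixed model with patient random
intercept via REML (ML available), pacing frequency entered as a continuous
linear covariate, and the observation unit being the per-location
per-frequency mean. Conventions where no unique definition exists:

* **Adjusted R²** is the OLS adjusted R² of the fixed-effects-only fit — a
  documented convention, since adjusted R² is not defined for mixed models.
* **p-values** are Wald tests; by default the statistic is referred to a t
  distribution with *between-within* degrees of freedom (patient-level
  covariates: n_patients − #between-effects; within-patient covariates:
  n_obs − n_patients − #within-effects), the classic partition used by
  mixed-model software. This keeps the small-sample type-I error near
  nominal with 25 patients, where the asymptotic normal reference rejects at
  ~0.08–0.14. `p_value_method="wald-z"` restores the asymptotic version.
* Covariates constant in a given table (possible for low-prevalence
  binaries in a 25-patient cohort) are dropped with a warning and reported
  as NaN rather than producing a singular fit.
* No multiple-testing correction; significance is strictly p < 0.05.

Logistic regressions use maximum likelihood; (quasi-)separation is flagged
and the model refit with an L1 penalty, reported as penalised without
p-values. The drug-induced-vs-spontaneous comparison is a two-sided
two-sample t-test per property.

## Monte-Carlo validation

`simulate.recovery_simulation` (default 200 replicates of 25 × 3 × 5)
refits the APD90 model per replicate cohort; mean recovered coefficients are
unbiased for the generating truth with MC standard errors of ~0.05–2.6 ms
depending on the covariate. `simulate.type_i_error_simulation` (1000
replicates) uses an all-null generating model and a parsimonious three-
covariate fit; per-covariate rejection stays within 0.05 ± 0.02. These
problem sizes are the package's chosen validation scale and run in a few
minutes on one CPU.

## What the generators do not emulate

Synthetic traces have stationary Gaussian noise, a fixed artifact shape and
a single stereotyped waveform per recording — no baseline drift, impalement
loss, motion artifacts, cell-to-cell variability, or drug-provocation
dynamics (the provocation phase is a metadata label, not simulated).
Histology images lack staining-batch variation, uneven illumination and
out-of-plane structures; the colour classes are well separated by design, so
passing recovery tests demonstrates correctness of the segmentation logic,
not robustness to real stain variability. The cohort generator implements
exactly the linear mixed model that the analysis fits, so recovery tests
validate estimation, not model adequacy for real tissue. Conclusions about
real recordings therefore require the config-exposed thresholds to be
re-examined against real data.

## Known limitations

* Wald/REML inference with 25 clusters remains slightly anti-conservative
  even with between-within df (~6 % at nominal 5 %); Kenward–Roger or
  parametric-bootstrap inference is not implemented.
* The EAD detector's prominence criterion under-detects small humps on
  steep repolarisation slopes (physically inherent to prominence measures).
* The endocardium-exclusion rule is morphological (border contact +
  thickness); it is calibrated on the generator's geometry, not on a
  published segmentation procedure.
* `fit_fibrosis_model` expects section-level rows; with one row per patient
  the random intercept is unidentifiable and the fit will be rejected.
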