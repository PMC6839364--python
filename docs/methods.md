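# Methods

This note documents the models implemented in `cbctrisk`, the conventions and
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Dose-to-risk arithmetic

### Equivalent dose

`equivalent_dose` multiplies a mean absorbed organ dose (mGy) by the
radiation weighting factor; for photons `w_R = 1.0`, so the operation is a
unit relabelling mGy → mSv. Negative doses are rejected.

### Effective dose and the remainder rule

`effective_dose` implements the ICRP-103 weighted sum

    E = Σ_explicit w_T · H_T  +  w_rem · (Σ_remainder H_T) / 13

Two weighting schemes ship as configuration
(`src/cbctrisk/data/icrp103_weights.yaml`):

* **full** — the complete ICRP-103 scheme: 14 explicitly weighted tissues
  plus 13 remainder organs sharing `w_rem = 0.12`. The scheme sums to
  exactly 1.0, so a uniform whole-body dose `D` yields `E = D` (tested).
* **study_subset** — the scheme for dose tables covering the 15
  thoraco-abdominal organs typically contoured on a planning CT: eight
  explicitly weighted organs (lung/stomach/bone-marrow at 0.12,
  esophagus/liver/thyroid at 0.04, bone-surface/skin at 0.01) and seven
  measured remainder organs (adrenals, gallbladder, heart, intestine,
  kidney, pancreas, spleen).

Conventions that matter, each fixed by the requirement that a published
organ-dose table and its published effective dose be mutually consistent:

* The remainder divisor stays at the full ICRP count of **13** even when
  fewer remainder organs are supplied; unmeasured remainder organs count as
  zero dose.
* Organs absent from a dose table (e.g. thyroid outside a liver-protocol
  scan range) contribute zero; weights are **not** renormalised.
* An organ in the table that the scheme knows neither as explicit nor as
  remainder is an error naming the organ — silent dropping would bias E
  downward.

### BEIR VII excess absolute risk

`excess_absolute_risk` evaluates

    EAR = beta_{M/F} · D · exp(gamma · (e − 30) / 10) · (A / A0)^eta

with `D` converted mSv → Gy internally, `beta` tabulated per organ and sex in
cases per 10⁴ person-years per Gy, and the result rescaled to cases per 10⁶
person-years (the scale on which such risks are usually quoted). `A0 = 60 y`.

Choices:

* The exposure-age modifier is applied **as written for all e**, without the
  BEIR VII report's convention of clamping `e` at 30: the model here is used
  to study the 30–60 y exposure-age range, where the unclamped form is what
  reproduces the published risk-versus-time-since-exposure series.
* Organs lacking organ-specific incidence parameters (esophagus, thyroid,
  skin, kidney, pancreas, and any unlisted organ) resolve to the
  **other-solid-cancer** tuple (β_M/β_F = 5.1/4.2, γ = −0.39, η = 1.9); every
  organ therefore resolves to exactly one parameter tuple.
* EAR is computed per sex from cohort-mean organ doses, not per patient.
* Out of scope by design: excess relative risk, lifetime attributable risk,
  DDREF, risk transport between populations, and uncertainty propagation on
  (β, γ, η).

Parameter file: `src/cbctrisk/data/beir_parameters.tsv` (intestine uses the
colon incidence parameters).

### Protocol arithmetic

`total_mas = A · T_acq · F · T_pulse` per acquisition. Shipped protocols
(125 kV, 20 ms pulses): thorax 20 mA × 60 s × 15 f/s → 360 mAs; pelvis
80 mA × 60 s × 15 f/s → 1440 mAs; 4D 40 mA × 120 s × 7 f/s → 672 mAs.
`absolute_dose` multiplies a simulated dose by
`f_cal · N · total_mas`, so dose ratios between protocols equal
`N·mAs` ratios exactly, and calibrating then rescaling at the reference
conditions returns the measured dose identically. The calibration factor's
magnitude depends on the simulator's per-history normalisation; it is
carried as configuration (`BeamCalibration`), never recomputed. The
reference exposure time enters in seconds (777 ms → 0.777 s).

## Voxel grids and I/O

Coordinate convention: 0-based voxel-centred indices `[ix, iy, iz]`, +x
patient-right, +y anterior→posterior, +z inferior→superior; 2.5 mm isotropic
voxels by default.

* **portable** dialect: JSON header line + one `%.17g` value per line; 17
  significant digits round-trip IEEE float64 bit-exactly.
* **rtdose** dialect: a genuine DICOM RTDOSE dataset via pydicom — unsigned
  16-bit voxels with `DoseGridScaling` chosen as `max/65535` so the integer
  range is fully used; reconstruction error is at most half a scaling step
  (≤ max/2¹⁶). Grids are stored in Gy per the DICOM convention and
  converted back to mGy on read.

CT-number → material labelling uses three cut points (defaults −850/−200/
+120 HU for air|lung|tissue|bone) with values **at** a cut point assigned to
the upper class; the cut points are configuration defaults, not claims about
any particular scanner's calibration curve. Densities: 0.0012 / 0.26 / 1.0 /
1.85 g/cm³.

Organs partially outside a grid are averaged over in-grid voxels only — the
mean dose to such organs is biased toward the irradiated part, which is the
same overestimation caveat that applies to any finite scan range.

## The synthetic data generator

### What it emulates

* **Phantoms**: elliptic-cylinder trunk, ellipsoidal organs (two-component
  organs like lungs and kidneys merge into one mask), four materials, an
  optional one-voxel skin shell, and a posterior couch slab. Voxelised organ
  volumes agree with the analytic ellipsoid volume within 10% at 2.5 mm
  voxels.
* **Beam**: source-axis distance 100 cm; field 26.5 × 19.8 cm² at the
  isocenter with the asymmetric half-fan lateral offsets (23.9 cm on one
  side, 2.6 cm on the other) that let a full rotation cover the body, and
  symmetric ±9.9 cm longitudinal offsets. The half-bowtie filter and the
  anode heel effect are modelled as monotone linear transmission ramps
  across the lateral field axis (default strength 0.4) and along the patient
  axis (default 0.15); the defaults make mirrored profiles at 5 cm depth
  disagree by well over 2%, and setting a strength to 0 disables that
  asymmetry exactly.
* **Transport**: per gantry angle the attenuation volume is resampled into
  the beam frame (linear interpolation), the path integral of μ accumulated
  along the beam axis with half credit for the voxel itself, and dose
  deposited as `transmission × inverse-square × exp(−∫μ dl) × μ/ρ`. Angles
  default to the acquisition geometry (−180°…180° in 2° steps; coarser
  steps are used for desk-scale runs). Per-angle contributions share the
  protocol mAs equally, and output scales as
  `reference_dose_rate × N × total_mas` — exactly linear, by construction.
* **Cohorts**: height ~ truncated normal, BMI ~ truncated normal with weight
  derived as `BMI·(h/100)²`, sex Bernoulli; site presets (lung: height
  154.6 ± 10.3 cm, BMI 21.6 ± 3.1, 8/15 female; liver: 159.0 ± 7.7 cm,
  22.5 ± 4.3, 3/15 female) were fixed once from the corresponding published
  cohort tables. Trunk half-axes come from weight (unit density, 45% of body
  volume in a trunk 30% of height long, lateral:AP aspect 1.5). The seed is
  mandatory; all sampling is `numpy.random.default_rng(seed)`-deterministic.

### What it does not emulate

No scatter, no electron transport, no buildup (the depth curve decreases
from the surface), no energy spectrum, no detector, no image formation, and
no respiratory motion. Effective attenuation coefficients
(air/lung/tissue/bone = 2.5 × 10⁻⁵ / 0.0055 / 0.021 / 0.048 mm⁻¹) are
plausible for a ~125 kV beam but are configuration, not measurements, and
the reference dose rate (5 mGy per mAs per unit deposition) is an arbitrary
normalisation. Consequently, passing tests demonstrate the **structure** of
the dose-to-risk chain — linearity in mAs and N, attenuation monotonicity
(deeper organs receive less), rotational symmetry when the beam is
symmetric, measurable asymmetry when it is not, and the decrease of
effective dose with growing body size — but say nothing about absolute
dosimetric accuracy for real patients. Absolute accuracy enters only through
the calibration factor, which must come from measurement.

### BMI classification

`BMI = weight / (height/100)²`, WHO classes with inclusive floors
(underweight < 18.50, normal 18.50–24.99, overweight ≥ 25.00 kg/m²). The
class is assigned at the one-decimal reporting precision of clinical BMI
tables: a patient whose BMI prints as 18.5 is normal-weight even if the
unrounded value is 18.4997. This matches how published cohort tables count
their class memberships.

## Pipeline and reporting

`run_pipeline` composes cohort → phantom → simulation → organ doses →
effective dose → EAR into a `StudyReport` (tidy DataFrames serialising
losslessly to JSON). The simulator runs once per patient; other protocols
are exact mAs rescalings of the same primary field, which is an identity
under this transport model, not an approximation. Cohort summaries default
to the sample (n−1) standard deviation, with a flag for the population
form; published "±" values are compared on means only. Stage failures are
wrapped with the stage name and patient index. Default problem sizes
(5 mm voxels, 15° gantry steps, small cohorts) keep a run interactive;
the clinical-resolution geometry (2.5 mm, 2°) is a parameter change.

Hypothesis-based property tests are seeded/derandomised via pytest's
deterministic collection; the simulator itself contains no randomness.

## Known limitations

* Primary-photon-only transport underestimates dose at depth relative to a
  scattered beam and cannot model surface buildup.
* Organ layouts are schematic; organ volumes are parameterisable to realistic
  ranges but positions are fixed fractions of the trunk axes.
* The remainder-organ rule assumes the 13-organ divisor; dose tables from
  protocols measuring a different remainder set must supply their own
  scheme.
* EAR parameters are incidence parameters for a mixed Euro-American
  population baseline; no transport to other populations is attempted.
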