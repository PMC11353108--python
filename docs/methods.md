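# Methods

This note records the measurement model, the statistical conventions, the
synthetic-data design, and the numerical choices behind `livercond`, in
the order the pipeline applies them.

## Measurement model and calibration

A tetrapolar needle probe measures complex impedance Z(f) = R(f) + iX(f)
at 256 log-spaced frequencies spanning 3 kHz–1 MHz. Reactance is stored
as the signed imaginary part of Z (capacitive ⇒ X < 0); the conductance
G = R/(R²+X²) is sign-agnostic, so the convention only affects phase
plots. For an ideal (artifact-free) measurement, bulk conductivity and
conductance are related by the probe cell constant κ [1/m]:

    σ(f) = κ · G_ideal(f).

The instrument and leads superimpose a high-frequency artifact. The
calibration assumes:

1. the reference buffer is purely resistive (flat spectrum), so any
   frequency structure in its measured G_buffer(f) is artifact;
2. buffer and tissue are measured through the same probe and instrument
   path, so the conversion factor k(f) = σ_ref / G_buffer(f) transfers.

Under these assumptions σ_tissue(f) = k(f)·G_tissue(f) removes both κ and
the common artifact. Two identities follow and are enforced by tests:
calibrating the buffer against itself returns exactly σ_ref at every grid
point (machine precision, by construction), and with no parasitics at all
the calibration inverts the forward model exactly — the cell constant
cancels, so the choice among the 0.062 / 0.13 / 0.25 S/m buffers is
immaterial on clean data.

Assumption 2 is only approximate on real hardware: the parasitic network
interacts with the load, and buffer and tissue are different loads. The
residual is quantified rather than hidden: under the default simulated
parasitics, calibrating with the 0.062 S/m buffer instead of the 0.25 S/m
buffer shifts recovered σ at 1 MHz by ~0.1–0.2 %, while the recovered
*group means* at 1 MHz carry a +3–7 % load-dependent residual relative to
truth. At 3 kHz the residual is below 10⁻⁴ relative for every simulated
record. This is why the default calibration buffer is the 0.25 S/m
reference — its ~100 Ω impedance is closest to the tissue loads — and why
recovery claims at scale are made at the 3 kHz anchor.

The calibration refuses to interpolate between frequency grids
(tolerance: 10⁻⁹ relative per point, configurable). Buffer and tissue
come from the same instrument sweep by design; a mismatch indicates a
data-handling fault, and interpolation would silently bend k(f) exactly
where parasitics are steep. Duplicate frequency rows in input CSVs are
likewise an error, not averaged: silent averaging hides acquisition
faults.

Temperature is carried as metadata only (36 °C in vivo, 20 °C ex vivo in
the simulator); no conductivity–temperature correction is applied by
default, matching the measurement protocol this reproduces. A config hook
(`CalibrationConfig.temp_coeff_pct_per_c`) accepts a user-supplied linear
%/°C coefficient, off unless set.

Records whose sweeps cannot be converted (a frequency with R = X = 0,
grid mismatch, non-positive conductivity) are dropped with a reason code
and reported, never imputed — so per-condition n varies downstream, as it
does in practice.

## Cohort statistics

- **Analysis frequencies.** 3, 30, 300, 607, 1000 kHz by default. Each
  target maps to the nearest grid frequency; equidistant ties break
  toward the lower frequency, and the frequency actually used is reported
  alongside σ.
- **Summaries.** Sample mean and SD with the n−1 denominator per
  (tissue class, state) group; SD is omitted — not zero — for n = 1.
  Cirrhotic parenchyma is its own class and never pools with "normal".
  Values are sorted before aggregation so results are exactly invariant
  to record order.
- **Ratios.** Ratio of group means, not mean of per-patient ratios:
  groups are unequal and unpaired (15 / 16 / 16 / 3 in the reference
  cohort), so per-patient pairing does not exist in general. Raw ratios
  are reported next to the 1-decimal rendering (round half away from
  zero). The ratio-of-means definition is exactly transitive:
  ratio(A,C) = ratio(A,B)·ratio(B,C) before rounding.
- **Kruskal–Wallis.** Mid-ranks over the pooled sample,
  H = 12/(N(N+1)) Σ nᵢ(r̄ᵢ−(N+1)/2)², tie-corrected by
  H* = H / (1 − Σ(t³−t)/(N³−N)), p from the χ² upper tail with k−1
  degrees of freedom. All-identical data is a degenerate-ties error. The
  implementation is cross-checked in tests against an independent rank
  routine and a numerically integrated χ² tail.
- **No normality screening.** The analysis path is always nonparametric;
  the reference analysis also proceeded nonparametrically at every
  frequency after its normality screen, so a separate screening step
  would add a decision without changing any downstream result. No
  post-hoc pairwise tests or multiplicity corrections are produced: only
  the omnibus comparison is in scope.

### Bundled study tables

The published group summaries, ratio table, per-type breakdowns and the
per-patient 1 MHz case table are bundled (`livercond.study_tables`) as
fixtures for the worked numbers that are recomputable. Three printed
cells are obvious dropped-decimal typos ("012", "041", "043"); they are
stored verbatim together with a normalized numeric value and a
`typo_normalized` flag — no silent correction. Two internal
inconsistencies of the printed tables are reproduced, not repaired: the
in vivo tumor group prints n = 16 while its case table has 15 values, and
the printed tumor/cirrhotic ratio at 3 kHz (4.4) is not reproducible from
the printed group means (0.41/0.09 ≈ 4.6, the value this package
reports); the other eleven checkable ratio cells reproduce exactly under
ratio-of-means with half-away rounding.

## Synthetic cohorts

The simulator emulates the study conditions so every downstream stage is
testable without clinical data.

- **Tissue dispersion.** The Cole model
  Z(f) = R∞ + (R₀−R∞)/(1+(if/f_c)^α), the standard empirical description
  of the β-dispersion band. Per record, f_c ~ U(50, 500) kHz and
  α ~ U(0.70, 0.95), plausible for soft tissue in this band and spanning
  narrow-to-broad dispersions.
- **Group anchors.** Per record, conductivities at 3 kHz and 1 MHz are
  drawn from normal distributions truncated to (0, ∞), with per-group
  mean/SD defaulting to the published six-group summary (e.g. in vivo
  tumor, n = 16: 0.41 ± 0.10 S/m at 3 kHz, 0.78 ± 0.24 at 1 MHz); the
  pair is redrawn until σ(1 MHz) > σ(3 kHz). Truncated-normal-within-
  positivity is the minimal assumption given that only mean ± SD are
  published; small-sample non-normality then arises naturally. A
  configuration is rejected when the positive tail has probability
  < 10⁻³.
- **Anchor pinning.** The anchor map R₀ = κ/σ(3 kHz), R∞ = κ/σ(1 MHz)
  sets the Cole *limits*, so the raw curve misses the anchors by a few
  percent at the finite anchor frequencies. A real scaling Z → s(f)·Z
  with log s linear in log f pins both anchors exactly. Because
  G_cole(3 kHz) ≥ 1/R₀ and G_cole(1 MHz) ≤ 1/R∞ always, the endpoint
  corrections satisfy s(3 kHz) ≥ 1 ≥ s(1 MHz): the ramp only ever tilts
  the conductivity spectrum further upward, so σ(f) remains non-
  decreasing and *every* ordered anchor pair is representable. (An exact
  two-parameter (R₀, R∞) solve, by contrast, has no solution for the
  large σ-ratio tails that independent draws produce.)
- **Probe and parasitics.** Cell constant κ = 25 m⁻¹ by default —
  order-of-magnitude plausible for a 1 mm-spaced needle tetrapole, and
  shared by tissue and buffer simulations because one physical probe
  measures both; it places the 0.25 S/m buffer at 100 Ω. The parasitic
  network is the minimal two-element model reproducing the
  characteristic high-frequency artifact: series lead inductance
  L = 0.5 µH and parallel stray capacitance C = 0.2 nF around the load,
  Z_meas = iωL + Z/(1+iωC·Z). At 1 MHz this distorts |Z| of a ~100 Ω
  load by >5 % (visually material, as in pre-calibration spectra); at
  3 kHz it is negligible (<0.1 %). Published spectra plots print no axis
  values, so distortion magnitude is calibrated qualitatively, not to a
  figure.
- **Reproducibility.** One top-level seed; each group draws from a child
  stream keyed by a CRC of its label, so adding or removing a group does
  not perturb the others. Same seed ⇒ byte-identical cohorts.
- **Metadata.** Tumor records draw a type (HCC/MET/CCA weighted by the
  published per-type counts, or fixed per group) and dimensions with the
  largest axis log-uniform on 10–90 mm (the observed size range, kept
  ≥ 10 mm so the probe fits); in vivo records carry 36 °C, ex vivo 20 °C.

What the simulator deliberately does **not** model: instrument noise
(records differ only through biology and parasitics), electrode
polarization, within-patient correlation between a patient's normal and
tumor measurements (records are independent draws; the reference
analysis is also unpaired), tissue anisotropy, and spatial heterogeneity.
Passing recovery tests therefore demonstrate correctness of the
calibration algebra and the statistics under the stated generative
model — not robustness to noise sources the model excludes.

## Geometry estimates

E(r)/E₀ = r₀/r for an idealized infinite cylindrical electrode, with
r measured from the electrode **axis**; the worst-case clearance of a
centred array is (D − span)/2. The axis convention is a deliberate
choice: the published worked case (5 % at 3.5 mm for r₀ = 175 µm) is
reproduced exactly by 0.175/3.5, i.e. with axis-measured r, although the
accompanying wording says "from the electrode surface"
(0.175/3.675 = 4.8 % would follow from the surface convention). A tumor
smaller than the 3 mm array span is an error (probe does not fit), and a
clearance smaller than r₀ propagates an inside-electrode error. The 1/r
model is an analytical bound, not a field solver; no finite-element
modelling is attempted.

## Test and acceptance problem sizes

Statistical properties are exercised at sizes chosen to make the checks
sharp yet quick: the parasitic-free round-trip on a 50-record cohort
(tolerance 10⁻¹⁰ relative, dominated by float algebra); type-I error of
the omnibus test over 2 000 null cohorts of 4 × 15 values (rejection rate
within [0.03, 0.07] at α = 0.05, a ±4-standard-error band); and recovery
at scale with n = 200 per group, where calibrated group means at the
3 kHz anchor must sit within 3 standard errors of the generator's
configured truncated-normal means. The truncated mean — not the nominal
normal mean — is the correct recovery target: for low-mean groups
(0.12 ± 0.07 S/m) positivity truncation shifts the sampled mean by up to
+0.007 S/m, which is generator design, not recovery error.

## Known limitations

- The instrument's true 256-frequency grid is unpublished; the default
  grid is exactly log-spaced with both endpoints on-grid. Nearest-grid
  picking makes analyses robust to this choice.
- k(f) is applied raw (unsmoothed); smoothing would trade variance for
  bias in the steep parasitic region and is intentionally left to the
  user.
- Group-mean recovery at 1 MHz inherits the load-dependent calibration
  residual discussed above; headline recovery guarantees hold at low
  frequency.
- The CSV layer targets the package's own plain-text formats; proprietary
  instrument exports are out of scope.
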