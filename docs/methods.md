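# Methods

This note records the models, parameter choices and numerical decisions
behind `radnano`, and what the passing tests do and do not establish.

## Photon interaction coefficients (`radnano.photon_data`)

Water ships as an embedded reference table of standard mass
energy-absorption and attenuation coefficients (10 keV – 20 MeV) and is the
denominator of every dose-enhancement factor. Element coefficients (H, C,
N, O, Si, Ti, Hf, W, Au) are generated at import from a compact analytic
parameterization rather than copied tables:

* **Photoelectric.** τ/ρ = C·Z^4.15/A at a 30 keV anchor (C calibrated on
  oxygen), with a piecewise log–log energy slope (−3.05 below 150 keV,
  −2.5 to 600 keV, −1.9 to 2.5 MeV, −1.0 above), K/L shell availability
  factors below the edges (below-K factor 0.185, i.e. a K jump ratio
  ≈ 5.4), and a fluorescence-escape correction
  1 − f_K·ω_K·(0.85·E_K)/E for the energy-absorption variant.
* **Incoherent.** Klein–Nishina free-electron cross sections; the mean
  energy-transfer fraction is integrated numerically over the scattering
  angle and cached on a log grid.
* **Pair production.** A Bethe–Heitler-like Z²·ln(183·Z^(−1/3)) term with a
  logarithmic threshold shape (ln(E/1022 keV)/9, capped at 1) and charged
  particle energy fraction (E − 1022 keV)/E.
* Coherent scattering is excluded throughout (it deposits no energy and the
  engine does not track photon deflections).

Accuracy: H₂O reconstructed from the element model stays within 25% of the
embedded water reference over 10 keV – 20 MeV (asserted in tests; mostly
within 6%). Near the K edges of W/Hf/Au the parameterization is close to
quantitative (e.g. W at 60 keV: 3.25 vs ≈ 3.4 cm²/g). This level is
sufficient for what the package claims: spectrum-weighted coefficient
*ratios*, material orderings, and kV→MV reduction factors — not per-energy
reference values. Compound coefficients use the mass-weighted elemental
mixture rule; tables are sampled onto per-material grids (log-spaced plus
edge-bracketing points) and interpolated log–log; out-of-range energies
raise rather than extrapolate.

## Spectra (`radnano.beam_physics`)

* `kv150`: filtered Kramers model of a 150 kV tungsten tube — intensity
  ∝ (150 − E)/E hardened by 3 cm of PMMA-equivalent material; the 7 mm
  beryllium window is negligible above 10 keV; characteristic lines are not
  modelled. Mean energy ≈ 58 keV.
* `mv6`: a coarse 15-bin tabulation of a generic 6 MV linac fluence shape
  (peak near 0.5 MeV, tail to 6 MeV).
* Spectrum weighting of coefficients defaults to **energy fluence**
  (weight·E·μ), because collision kerma is energy fluence × μen/ρ; plain
  fluence weighting is switchable. Both are exposed since the appropriate
  choice depends on how a spectrum tabulation was normalized.
* `macroscopic_def` offers `as_printed` (1 + f·ratio, the conventional
  additive form, default) and `mixture` (1 + f·(ratio − 1), the exact
  two-component kerma rule). DEF ≥ 1 is guaranteed only for `as_printed`;
  in `mixture` mode low-Z oxides fall below 1 at MV energies because their
  μen/ρ is below water's there — this is physics, not a bug.
* Protons: intracellular physical dose enhancement is treated as the
  analytic null (DEF = 1). Stopping-power ratios of the relevant materials
  to water differ by a few percent at 100 MeV and the package makes no
  claim finer than that; proton transport is out of scope.

## Simplified Monte Carlo (`radnano.mc`)

Geometry is micrometres while photon mean free paths are centimetres, so
analog transport would waste ~10⁵ histories per interaction. The engine
instead uses a **forced-interaction (first-collision) estimator**: each
history samples one interaction site along its ray with density ∝ local μ,
carrying weight W = Σᵢ μᵢLᵢ (valid in the μL ≪ 1 linear regime, here
μL ≈ 10⁻⁷).

* **`local` mode** is a collision-kerma estimator: deposit
  W·E·(μen/μ)<sub>site</sub> at the site. On a homogeneous mixture this
  reproduces the analytic mixture DEF exactly for monoenergetic beams and
  to within sampling noise for spectra — the kerma-limit oracle.
* **`csda` mode** samples photoelectric vs incoherent by cross section;
  photoelectrons carry E − E_bind (K edge, or L3 below it) with the binding
  remainder deposited at the site; Compton electrons carry the mean KN
  transfer fraction; scattered photons and fluorescence escape. Electrons
  travel isotropically on straight lines over their water CSDA range
  (embedded range–energy table; nanoparticle regions treated as water for
  slowing) depositing energy uniformly per unit length, scored by exact
  segment–sphere overlap.
* **Correlated baseline.** Every DEF divides by a water run with the same
  seed and an identical draw sequence (the per-history draw count is fixed
  regardless of material, including the fixed-count rejection used for
  water-site sampling). Water-vs-water is bitwise the same run, so the null
  DEF is exactly 1; material runs benefit from common random numbers.
* **Scenes.** The vesicle scene carries 166 explicit non-overlapping 50 nm
  spheres (dart throwing with a deterministic jittered-FCC fallback; dart
  throwing up to 50 vol%, hard error above 74 vol%). The cell scene
  homogenizes each 400 nm vesicle to a 32.4 vol% mixture — at this
  engine's fidelity level the explicit spheres inside a 6 µm cell add cost
  but no information. Scoring masses are the nanoparticle-free water only,
  in both the material and baseline runs, so doses are comparable.
* Replicates run at seed, seed+1, seed+2 (default 3) and report the DEF
  spread; defaults are desk-scale (10⁴–10⁵ histories, seconds) rather than
  the 10⁸-history scale of track-structure codes.

**What the MC does and does not claim.** Verified properties: the water
null; kerma-limit agreement; the kV cytoplasm ordering
Au > HfO₂ > WO₃ > TiO₂ ≈ 1; DEF_cytoplasm ≥ DEF_nucleus ≥ 1; approximate
linearity of DEF in vesicle count (R² ≥ 0.95 over 1–10); monotone shell-DEF
decay with distance; replicate spread shrinking with history count. Not
claimed: absolute DEF magnitudes of track-structure codes, and — noted
explicitly — sub-micron convergence of the shell profile to DEF = 1. With
straight-line CSDA transport, kV photoelectrons (~40 µm range) carry all of
the nanoparticle-released energy far from the vesicle, so the measured
excess at 1 µm remains a few tenths of the thin-beam water baseline
(~0.4 for gold at 20 µm world, 4 µm beam), where cascade-resolved physics
whose short-range Auger secondaries dominate the near field reaches < 0.05.
The corresponding acceptance test is intentionally left failing to keep the
gap visible rather than papering over it with a widened tolerance.

## Survival pipeline (`radnano.survival`)

* The standard curve default is the printed linear conversion
  x = y·b/(a − b) with a = 3.872 × 10⁶, b = 3.431 × 10⁵ (`as_printed`);
  a `saturation` form x = y·b/(a − y) is provided because a luminescence
  plateau is the physically expected behaviour at high cell counts. The
  choice is recorded per run.
* LQ fits are unweighted nonlinear least squares **on the SF scale** with
  α, β ≥ 0 box constraints, seeded by a log-linear regression plus a fixed
  fallback; the exact boundary solution (0, 0) is checked explicitly so
  flat survival yields LD50 = ∞ rather than a spurious near-zero α.
  Zero-noise data are recovered to ≤ 10⁻⁸.
* LD50 uses the rationalized root 2·ln2/(α + √(α² + 4β·ln2)) — continuous
  at β = 0; values beyond the fitted dose range are flagged
  `extrapolated`, not suppressed. DMR uncertainty comes from per-batch
  refits (mean ± sd), matching how batch repeats are reported.
* SF > 1 is retained (flagged in QC) to keep estimators unbiased; the 60%
  sham-viability cutoff removes a concentration from DMR tables but never
  from the raw outputs.
* The toxicity sigmoid viability = 1 − 1/(1 + a·e^(−bx)) gives
  LC50 = ln(a)/b; when the data never fall below 50% viability and the
  fitted crossing extrapolates beyond the design, LC50 is reported as ∞.

## ROS assay (`radnano.ros`)

DEF_ROS uses replicate 12 Gy readings minus the *mean* 0 Gy reading of the
same condition over the mean blank gain, giving 3 levels × 6 replicates =
18 regression points. The regression pins the intercept at DEF_ROS = 1
(zero surface area cannot enhance); a free-intercept variant exists. The
`ros_slope` operation reports the textbook through-origin CI
(t, df = n − 1). The table-level `analyze_ros_plate` CI additionally
propagates two error sources that the residuals cannot see and that a
shared-blank design makes material: (i) the common blank-denominator error,
whose slope sensitivity is |slope| + Σx/Σx² because a denominator error
also acts as a spurious intercept that the pinned-intercept fit folds into
the slope; and (ii) heteroscedasticity from multiplicative plate noise,
via an HC1-robust standard error. Measured coverage at the design noise is
≈ 95% (naive: ≈ 55%). No outlier rejection is applied. Gold wells trigger
an interference warning — the DCF assay is not reliable for Au.

## Uptake (`radnano.uptake`)

Hill-type saturation f(x) = A·xᵖ/(Bᵖ + xᵖ) fitted by bounded least squares
(p ∈ [0.05, 20]); all-zero masses short-circuit to a flagged degenerate
fit. Volume fractions divide per-cell metal mass by the metal mass
fraction and bulk density, normalize to a 2800 µm³ cell (17.5 µm diameter),
and divide by sham viability — the reading of "corrected using the
viability fit" adopted here is that surviving cells carry the measured
load; the correction is switchable off.

## Synthetic data (`radnano.synth`)

Generators are pure functions of (config, seed) via per-stream
`SeedSequence`s. Defaults encode the study design: 2000 cells/well
48-well layout, triplicate NP wells, sextuplicate controls, doses
{0, 2, 4, 6, 8} Gy, DMSO grid {0, 0.11, 0.334, 0.667, 1} M in
quadruplicate over two batches, ROS surface-area grid {36.8, 368, 1840}
cm²/mL in sextuplicate, 5% multiplicative lognormal plate noise (the
with-adapter repeatability) and 15% for ICP-MS. The control
radiosensitivity α₀ = 0.03 Gy⁻¹, β₀ = 0.004 Gy⁻² puts the no-nanoparticle
SF(6 Gy) at ≈ 0.72, inside the observed 70–80% control band (an LD50
beyond the 8 Gy design, correctly flagged `extrapolated`). Nanoparticle
action is a dose-scaling factor k(conc), linear in concentration up to
k_max; DMSO scales the NP-attributable enhancement by
1 − φ·protection(c), with protection(c) = (1 − e^(−5c))/(1 − e^(−2.5))
capped at 1 — saturating exactly at 0.5 M, a generator choice, not a
mechanistic claim. `truth_for_ner_pair` inverts a published NER pair into
(k, φ) so quench plates can encode literature endpoints exactly.

**What passing round trips show** is that the pipeline inverts its own
generative model — estimator correctness, identifiability, calibrated
uncertainty. They do not validate the generative model against real plate
data: real assays add well-position effects, batch drifts, non-lognormal
outliers and toxicity–enhancement interactions the generator omits.

## Known limitations

* Coefficients are parameterized, not reference tabulations; mid-Z
  photoelectric values can be off by tens of percent between 100 and
  500 keV. Orderings and ratio classes are robust to this; per-energy
  values are not guaranteed.
* The MC has no Auger cascades, fluorescence transport, electron
  scattering or restricted energy loss; near-field dose around vesicles is
  correspondingly flattened (see the intentionally failing shell-decay
  threshold).
* The proton arm of the original comparison is represented only by the
  analytic null and the generators; nuclear activation channels are not
  modelled.
* DMR spread comes from batch repeats only; with a single batch the sd
  column is 0 rather than a bootstrap estimate. Fit covariances are
  reported for the LQ parameters themselves.
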