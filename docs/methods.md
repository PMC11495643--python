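# Methods

## Strain: endocardial area change

Regional strain is the fractional area change of each endocardial
triangle relative to end-diastole (frame 0, R-wave aligned):
`RS_CT(v,t) = A(v,t)/A(v,0) − 1`. It is unitless, exactly 0 at the
reference frame, invariant to rigid-body motion, and bounded below by −1.
Patches with zero reference area are excluded (logged) rather than
deleted, so patch indexing is stable across frames. Segmental curves are
the mean of patch strains within each AHA segment; we weight by
reference patch area so the average is independent of mesh resolution
(an unweighted mode exists for sensitivity checks — on near-uniform
meshes the two differ negligibly). No temporal smoothing is applied.

AHA parcellation uses fractional position along the apex–base axis
measured from the base (basal [0, 1/3), mid [1/3, 2/3), apical
[2/3, 0.95), apex cap ≥ 0.95) and 60°/90° azimuthal sectors from a
configurable anterior reference; septal segments are {2, 3, 8, 9, 14}.

## Stress surrogates

All pressures and stresses are kPa internally (1 mmHg = 0.133322 kPa).
Five per-segment stress time series can be formed on the strain time
base (linear interpolation of the pressure samples):

| method | definition |
|---|---|
| `P_LHC` | measured LV pressure applied to every segment |
| `WS_ED` | `σ_s(t) = P(t)·r_eff,s(ED) / (2 h_s(ED))` |
| `WS_TV` | as `WS_ED` with per-frame refit of `r_eff,s(t)`, `h_s(t)` |
| `P_gen` | generic normal-hemodynamics waveform (below) |
| `P_gen_scaled` | `P_gen` scaled multiplicatively to the patient's peak |

`r_eff = r_c·r_l/(r_c+r_l)` merges circumferential and longitudinal
curvature (curvatures add; radius is inverse curvature). Segmental radii
come from an axisymmetric ellipsoid fit centred on the long axis:
`ρ² = c₀ + c₁z + c₂z²` is linear in its coefficients and solved by
ordinary least squares; `r_c = a` and `r_l` is the meridional radius of
curvature `(a²cos²θ̄ + b²sin²θ̄)^{3/2}/(ab)` at the segment's mean polar
angle (which reduces to `b²/a` at the equator). Rank-deficient or
non-elliptic fits (e.g. near-coplanar equatorial bands) fall back to a
sphere centred on the axis and are flagged. Note that this effective-
radius convention yields *half* the textbook membrane stress on a sphere
(`P·r/4h` rather than `P·r/2h`); it is applied uniformly, and all
fraction/COVW metrics are invariant to such uniform scaling.

Wall thickness is supplied as a per-segment table (mm); in time-varying
mode it evolves under wall incompressibility, `h_s(t) = h_s(0)·A_s(0)/A_s(t)`.
Whether the original analysis refit shape per frame or scaled the
end-diastolic fit is not documented; per-frame refit is the default and
both are exposed.

The generic waveform is a parametric piecewise raised-cosine stand-in
for a digitized normal Wiggers diagram (the original digitization is not
reproducible): baseline at EDP, systolic rise to the peak, relaxation to
a diastolic minimum, refill to EDP, with defaults peak 16.0 kPa
(120 mmHg), EDP 1.07 kPa (8 mmHg), and timings onset 50 / peak 300 /
relaxation end 550 ms on an 800 ms RR, scaled proportionally for other
RR intervals. Any sampled waveform can be supplied by CSV instead. The
fraction and COVW metrics are insensitive to this choice because they
are invariant to uniform pressure scaling.

## Work

Work density is the signed area of the sampled stress–strain loop,
strain on the abscissa, counter-clockwise positive: `W = −∮σ dε`,
evaluated by the shoelace formula with the end-diastolic sample appended
to close the cycle (no resampling). Self-intersecting figure-8 loops —
the signature of early-activated myocardium — contribute the net signed
area of their lobes; no per-lobe decomposition is attempted because the
negative-work classification uses the net loop area. For the pressure
surrogates work density is in kPa ≡ kJ/m³.

Stroke work is the PV-loop area under the same signed-area rule
(kPa·mL = mJ). Total myocardial work integrates density over wall volume
(kPa·mm³ = µJ); surface-resolution maps are converted with
volume ≈ patch area × local thickness, a thin-wall approximation that is
flagged as an extension — the simplified estimates were designed for
fractions and heterogeneity, not for calibrated energetics (with the
effective-radius convention the surrogate total is ~½ the equilibrium
wall work, so η computed from it is not meaningful). Mechanical
efficiency η = stroke / total is reported for the generator's
ground-truth map (below).

## Regional metrics

* COVW: weighted population SD of work density divided by |weighted
  mean| within a region (volume-weighted when volume weights exist;
  unweighted mode available since the original weighting is not stated).
* Negative-work fractions: weight share of units with work strictly < 0
  (no tolerance band); volume weights give `V_f_LVNW`/`V_f_STNW`,
  surface weights `S_f_LVNW`/`S_f_STNW`. Septal metrics are evaluated
  over segments {2, 3, 8, 9, 14} only. Patch and segment resolutions are
  both supported; patch (the finer) is the default.
* High-work fraction `V_f_LVHW`: weight share strictly above the
  weighted 0.75-quantile of the same patient-state LV distribution
  (per-patient convention; lower-interpolation on the cumulative weight
  function, deterministic).
* Deltas are baseline − post, so a positive change is a reduction after
  CRT.

## Cohort statistics

Echo responders: ESV reduction strictly > 10 %. Clinical responders:
NYHA improvement ≥ 1 class — the published patient table labels
single-class improvements as responders even though the accompanying
text says "> 1", so ≥ 1 is the default and the strict reading is an
option. Combined (CRT) responders satisfy both. Group contrasts use
two-sided pooled-variance Student's t-tests (paired within patient for
state contrasts) and a standard two-factor fixed-effects ANOVA
(response × state, type-II SS) — the original factor/interaction
reporting is not detailed, so the conventional form is implemented.
Degenerate zero-variance comparisons return p = 1 with a flag. No
multiple-testing correction is applied. Regression is OLS with
R² = squared Pearson r and p from the t-test on r at n − 2 df
(equivalently the Pearson critical-value test).

The knock-out procedure replaces one pipeline input (geometry,
dyssynchrony, pressure, thickness) with its cohort mean for every
patient, reruns everything, and reports R²(metric, ΔESV) plus
nRMSD = RMSD(knock-out, specific)/range(specific). Range normalization
is the default (the original normalization is not defined); mean
normalization is available.

## Synthetic generator

The generator emulates the phenomenology that matters for the metrics,
not ventricular electrophysiology:

* **Geometry** — truncated prolate spheroid (apex pole to a basal plane
  at 3/4 of the spheroid height), default equatorial radius 30 mm and
  axis length 90 mm → EDV ≈ 188 mL, a dilated failing LV; ~650
  triangular patches, 25 frames over an 800 ms RR interval.
* **Activation field** — continuous azimuthal delay, earliest at the
  septal centre, latest at the lateral wall, up to
  `severity × 120 ms`; CRT compresses the dispersion (and every
  dyssynchrony-driven amplitude, via √factor) by a factor 0.3.
* **Strain curves** — raised-cosine basis: onset-delayed shortening with
  systolic hold and diastolic release (base amplitude 0.18 area strain →
  EF ≈ 28 %); early-wall rebound stretch during the high-pressure window
  (amplitude 0.25 × severity, spatially graded by azimuth⁴ × mid-wall
  weight so patches cross the negative-work threshold at different
  severities — this gradation is what makes `V_f_STNW` strictly
  monotone in severity); late-wall pre-stretch and shortening
  augmentation. Severity 0 is exactly synchronous.
* **Motion** — vertices move by a spatially varying homothety about a
  point on the long axis; per-frame per-segment scale corrections are
  fixed-point iterated until the area-weighted segmental strain matches
  the target curves to ~1e−12, so the analysis pipeline recovers the
  prescription exactly. Patch-level noise, when enabled, is per-vertex
  log-normal radial jitter (positive areas by construction): exact
  per-patch area noise cannot be imposed on a conforming mesh, and the
  vertex realization induces the intended multiplicative patch-area
  noise.
* **Pressure** — the parametric waveform with patient-varied peak/EDP,
  optional additive measurement noise.
* **Energy-consistent truth map** — per-patch stress is the local
  Laplace equilibrium stress plus a non-negative active-tension term
  whose deactivation completes *before* passive recoil re-lengthens the
  wall. Work done during shortening under active tension is then not
  returned during lengthening, so total wall work exceeds the PV work
  and η < 1 structurally (≈ 0.8 at defaults) — the physical reason real
  myocardium is less than 100 % efficient. For the purely kinematic
  surrogate maps the instantaneous local Laplace identity makes total
  wall work ≈ ∮P dV, so η would sit at 1 up to discretization; the
  active term is what breaks the tie in the physical direction.
* **Cohorts** — per-patient parameters (geometry ±6 %, thickness
  ±0.8 mm, peak pressure ±1.5 kPa, activation ±12 ms, severity uniform
  on [0.3, 0.95]) from RNG streams spawned off one master seed; all
  seeds are recorded in the outputs. Outcomes follow
  `ΔESV = β₀ + β₁·V_f_STNW(LBBB) + ε` (defaults β₀ = −20, β₁ = 150 %
  per unit fraction). When a target R² is configured the noise draw is
  orthogonalized against the metric and rescaled so the planted
  in-sample R² equals the target exactly; otherwise an explicit σ_ε is
  used as drawn. The planted value is the cohort's ground truth, so
  recovery tests measure pipeline fidelity rather than outcome-noise
  resampling.

What the generator does **not** emulate: real conduction physics,
infarct scar, RV mechanics, torsion/long-axis shortening asymmetries,
imaging artifacts, or inter-modality registration error. Passing the
recovery tests therefore shows the estimation chain is self-consistent
and sensitive to the planted structure under realistic magnitudes — not
that it reproduces any particular clinical cohort's values.

## Numerical choices and problem sizes

Loop closure appends the reference sample; degenerate triangles keep
zero area with a warning; cavity volume uses signed tetrahedra with a
basal-cap fan oriented from the shell's directed boundary edges (exactly
one boundary loop allowed); weighted quantiles use lower interpolation;
COVW uses |mean| so it stays non-negative. Validation suites use ~650-
patch meshes with 25 frames; cohort recovery uses n = 50 patients across
multiple master seeds and the knock-out analysis n = 10, sizes at which
the planted effects are resolved comfortably in seconds per cohort.

## Known limitations

Surface fractions are a proxy for the volume fractions a full
biomechanical model would give (the surface cannot see transmural
variation); the surrogate-map total work/η is a flagged extension (see
above); the catheter-to-frame synchronization is assumed R-wave aligned;
basal-plane motion is simplified (the cap moves with the homothety);
and the ellipsoid fit can fall back to a sphere on degenerate segment
clouds, which is flagged per segment.
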