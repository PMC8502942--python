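# Methods

## Measurement model

The imaged object is a thin tissue slab — dorsal skin, implanted fatty
tissue, and a developing tumor — compressed between two cover glasses to a
thickness `d` and raster scanned in transmission at 108 GHz. `thzvol`
models transmission as pure Beer–Lambert attenuation,

    I_s(x, y) = I_b · exp(−τ_skin − α(x, y) · d),

with `I_b` the background power through the cover glasses alone, `α` the
absorption coefficient of the fat/tumor slab (mm⁻¹) and `τ_skin` a
dimensionless skin optical depth. Reflections, scattering, diffraction and
fiber-coupling effects are deliberately outside the model: at these
frequencies and geometries they are treated as negligible, and the package
makes no attempt at physical-optics simulation.

Skin is parameterized as an optical depth rather than a thickness × α pair
because only its total, position-independent attenuation matters to the
analysis; that also makes the skin calibration an exact scalar subtraction
in α units, `α ← α − τ_skin / d`.

The inversion `α = ln(I_b / I_s) / d` is oriented so that an attenuating
sample yields positive α; this is the physically meaningful sign for
absorption maps whose reported values are all positive.

## Synthetic phantom and what it does (not) emulate

The generator reproduces the study conditions: a 10 × 10 mm² scan field, a
uniform fatty slab with α = 1.42 mm⁻¹ (inside the 1.400–1.450 mm⁻¹ fatty
band), disc-shaped tumor inclusions that raise α into the 1.450–1.600 mm⁻¹
cancer band, a uniform skin layer, three replicate scans per subject, and
multiplicative Gaussian detector noise with relative standard deviation
1/SNR (powers floored at the smallest positive float; at any realistic SNR
the floor is never reached). A pixel belongs to a disc iff its center lies
inside it; centers sit at `(i + 0.5, j + 0.5) · pitch`, row-major, origin
top-left. Overlapping discs take the maximum excess rather than stacking.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| field | 10 × 10 mm² | scan area of the reported images |
| pixel pitch | 0.1 mm | sub-millimeter sampling of a ~mm lesion; the true scan step is unreported, so it is fully configurable |
| slab thickness `d` | 0.5 mm phantom default | plausible compressed-sandwich thickness; **required** input when loading real rasters, never defaulted silently |
| fat α | 1.42 mm⁻¹ | mid fatty band |
| detector SNR | 10⁴ | visible-noise regime for recovery tests; the instrument's quoted ~10⁸:1 would make noise invisible |
| replicates | 3 | three scans per animal |

What the phantom does **not** emulate: partial-volume pixels at lesion
boundaries (discs are binary at pixel centers), spatially correlated noise,
drift between replicates, skin-thickness variation, or tumor α
heterogeneity. Passing the recovery tests therefore shows the *analysis
chain* is correct and noise-stable, not that real tissue meets the model's
assumptions.

## Segmentation and Δα

Band edges are half-open `[low, high)` so every pixel gets exactly one
label; a pixel exactly at 1.450 mm⁻¹ is classified cancer — the
conservative choice for detection. Saturated pixels (α ≥ 1.600) count with
cancer in all region statistics, so clipping of the display scale never
biases Δα.

Δα is defined here as mean(cancer ∪ saturated) − mean(background). The
source analysis reports a single Δα per animal without defining the
estimator; the region-mean difference was chosen because it matches the
"absorption change" reading and is invariant under any residual constant
offset left by an imperfect skin calibration (both means shift equally).
A connected-component minimum-size filter exists for noisy data but
defaults to off: the reference analysis is pure thresholding.

An empty background class is an error (no reference level); an empty cancer
class yields Δα = 0 with a warning flag rather than an error, since a
tumor-free image is a legitimate outcome.

## Volumetry calibration

The cross-section model gives V = (Δα / α_ref) · V_eff. Neither α_ref,
V_cell nor V_eff is printed in the source; they were fixed once from the
internal consistency of the three reported (Δα, V) pairs, whose ratio
V/Δα is constant to 0.04%. Defaults: α_ref = 1.5 mm⁻¹ (midpoint of the
1.400–1.600 mm⁻¹ color scale) and V_eff = ratio × α_ref = 8.0 mm³. Both are
plain configuration values. V_eff is treated as an opaque instrument
constant — no claim is made that it equals scan area × thickness.

V_cell (default 2 × 10⁻⁶ mm³, the order of magnitude of a ~15 µm breast
cancer cell) cancels out of V algebraically; the implementation computes V
in the cancelled form, so perturbing V_cell changes σ and N′ but leaves V
bit-identical. Volumes and Δα are reported to 3 decimal places, rounded
half-up.

The detection-limit calculator maps a minimum resolvable Δα through the
same linear law; the smallest measured Δα of 0.090 mm⁻¹ corresponds to
0.480 mm³, below 1 mm³. The penetration-depth helper,
`ln(dynamic_range)/α`, is a closed-form bound on the depth at which
transmitted power meets the noise floor; the instrument's quoted 8 cm
capability is not reproducible from first principles because the tissue α
assumed for that estimate is unstated, so the function is exercised only on
its closed form.

## Spectroscopy

Per-tissue spectra run over 108–143 GHz (default grid: 5 GHz steps, 8
points — only the band endpoints are fixed by the instrument). Error bars
are standard deviations of the mean (sample SD over animals / √n), recorded
explicitly because the two conventions are often conflated. The
separability statistic between two tissue spectra is the per-frequency
standardized gap `(m_a − m_b)/√(s_a² + s_b²)` with an overall flag when the
gap exceeds 2 everywhere; it is a package-defined diagnostic, not a
published statistic, and no spectral numbers are treated as reproducible
targets (the source figure prints none).

## Numerical choices and determinism

- Replicates are averaged in α-space (arithmetic mean of maps), matching
  the mean-absorption-coefficient presentation; by log-linearity this
  equals the α of the geometric power mean.
- Averaging then skin-correcting equals skin-correcting then averaging
  (both are affine); the pipeline averages first.
- Skin estimation from a reference region returns
  `max(0, d · (mean α − expected α))` — floored so noise cannot produce a
  negative optical depth. The pipeline's estimate mode uses a border frame
  (default 1 mm margin) as the tumor-free reference.
- All randomness flows through `numpy.random.default_rng` seeds carried in
  the configs; identical config + seed gives byte-identical reports. In
  multi-subject panels each subject's seed derives from
  `SeedSequence([master_seed, subject_index])`, so adding a subject never
  perturbs the others.
- Test problem sizes: recovery suites run the full 100 × 100 phantom with
  3 replicates over 20 seeds, and the noise-averaging check uses 300
  simulated replicates of a uniform slab — both complete in seconds.

## Known limitations

- The volumetry is linear by construction; it cannot capture saturation of
  contrast in large or necrotic tumors.
- Δα as a region-mean difference depends on the segmentation bands; a
  mis-set fatty band biases both the lesion mask and the reference mean.
- The skin model ignores any spatial skin-thickness variation; real maps
  with uneven skin will leak that structure into α.
- Volume accuracy inherits the calibration constants; α_ref and V_eff are
  internally consistent with the three reported animals but not traceable
  to an independent measurement.
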