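# thzvol — terahertz transmission-imaging tumor volumetry

`thzvol` implements the analysis chain behind in vivo tumor volumetry with a
fiber-scanned terahertz (THz) transmission imaging system, for researchers
evaluating THz imaging as a non-ionizing early-detection modality in
subcutaneous xenograft mouse models. The measurement geometry is a dorsal
skin/fat/tumor tissue stack sandwiched between two cover glasses and raster
scanned at 108 GHz; because cancer tissue carries more water than fat, it
absorbs more strongly, and that endogenous contrast alone is enough to
segment the lesion and estimate its volume.

## The model

Transmission follows the Beer–Lambert law. From a transmitted-power raster
`I_s` and the background power through the cover glasses `I_b`, the
per-pixel absorption coefficient of the sandwiched slab of thickness `d` is

    α = ln(I_b / I_s) / d        [mm⁻¹]

Replicate scans (three per animal) are averaged pixelwise in α-space. The
skin layer attenuates uniformly and position-independently, so its optical
depth `τ_skin` is removed as a scalar: `α ← α − τ_skin / d`. Pixels are then
classified by fixed α bands: fatty background for 1.400 ≤ α < 1.450 mm⁻¹,
cancer for 1.450 ≤ α < 1.600 mm⁻¹, saturated above. The absorption change

    Δα = mean α over cancer pixels − mean α over background pixels

feeds the absorption-cross-section volumetry. With σ = α_ref · V_cell the
per-cell cross-section (α_ref the reference cancer absorption coefficient,
V_cell a single cell's volume), the cancer-cell density is N′ = Δα / σ and
the total cancer volume inside the interrogated volume V_eff is

    V = N′ · V_cell · V_eff = (Δα / α_ref) · V_eff     [mm³]

V_cell cancels algebraically, so the volume depends only on Δα, α_ref
(default 1.5 mm⁻¹, the midpoint of the color scale) and V_eff (default
8 mm³). A synthetic phantom module simulates the whole forward process —
disc-shaped tumor inclusions in a fatty slab under skin, multiplicative
detector noise at a configurable SNR — so every stage is testable without
experimental data.

## Worked example

```python
from thzvol import (PhantomSpec, TumorRegion, AcquisitionConfig,
                    PipelineConfig, run_pipeline, round_half_up)

spec = PhantomSpec(                       # 10 x 10 mm field, 0.1 mm pitch
    fat_alpha=1.42,                       # fatty baseline, mm^-1
    skin_optical_depth=0.05,
    tumor_regions=(TumorRegion(5.0, 5.0, 1.5, 0.160),),  # 1.5 mm disc
)
cfg = PipelineConfig(
    subject_id="mouse-2",
    phantom=spec,
    acquisition=AcquisitionConfig(snr=1e4, n_replicates=3, rng_seed=7),
    skin_optical_depth=0.05,
)
report = run_pipeline(cfg)
print("delta_alpha =", round_half_up(report.region_summary.delta_alpha, 3), "mm^-1")
print("V =", round_half_up(report.volume_estimate.volume_mm3, 3), "mm^3")
```

prints

```
delta_alpha = 0.16 mm^-1
V = 0.853 mm^3
```

i.e. the pipeline recovers the generating 0.160 mm⁻¹ absorption excess from
the noisy simulated scans and converts it to 0.853 mm³ of cancer tissue —
one of the three measured mouse values (Δα = 0.090, 0.160, 0.132 mm⁻¹ map
to V = 0.480, 0.853, 0.704 mm³), all below the 1 mm³ detection limit.

The same chain is scriptable stage by stage from the shell:

```sh
thzvol phantom scan --config spec.yaml --seed 7 --out scans/
thzvol absorbance compute scans/raster_0.txt --thickness 0.5 --out a0.txt
thzvol absorbance average a0.txt a1.txt a2.txt --out mean.txt
thzvol absorbance skin-correct mean.txt --depth 0.05 --out corr.txt
thzvol segment classify corr.txt --bands 1.400,1.450,1.600 --out labels.txt
thzvol segment summarize corr.txt labels.txt
thzvol volumetry estimate --delta-alpha 0.160 --alpha-ref 1.5 --v-eff 8
```

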