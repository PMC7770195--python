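# shgquant

Quantitative image analysis of collagen quality and quantity in the
intervertebral-disk **annulus fibrosus (AF)**, from second-harmonic-generation
(SHG) multiphoton z-stacks and collagen-hybridizing-peptide (CHP)
fluorescence images — with the factorial statistics used by dietary and
organ-culture mouse studies, and a synthetic fibrous-tissue phantom generator
with known ground truth.

**Who it is for:** researchers quantifying early degenerative changes to
collagenous tissue (AGE accumulation, crosslinking, fibril disruption) who
need reproducible, scriptable versions of the standard SHG morphometry
pipeline and its group statistics.

## The measurements

For each SHG stack the pipeline computes, in order:

1. maximum intensity z-projection;
2. background subtraction (modal gray value by default), clamped at zero;
3. a 500 x 500 px region of interest in the central AF (auto-centered on the
   foreground centroid, or explicit);
4. **mean SHG intensity** I&#772; of the ROI — relates to collagen content and
   crosslinking; comparable across samples only under constant acquisition
   settings, and never normalized per image;
5. histogram equalization (CDF mapping), then **Shannon entropy**
   H = −Σᵢ pᵢ log₂ pᵢ of the equalized ROI — lower entropy means loss of
   fibrillar architectural complexity — plus the full set of gray-level
   co-occurrence (GLCM) features: entropy, energy ΣP², inertia Σ(i−j)²P,
   inverse difference moment ΣP/(1+(i−j)²), and correlation;
6. **Otsu threshold** t\* = argmax ω₀ω₁(μ₀−μ₁)² on the background-subtracted
   ROI and **percent area** = 100 · #{pixels > t\*}/N, a proxy for total
   collagen.

CHP damage is quantified as the background-subtracted mean green-channel
intensity in the same ROI geometry, tagged by acquisition batch (cross-batch
contrasts are refused).

The statistics layer implements two-tailed independent t tests, two-way
fixed-effects ANOVA with interaction (Type III, sum-to-zero contrasts — exact
against R `car::Anova` on unbalanced data), Bonferroni-adjusted planned 2x2
contrasts, and reference-group percent differences
100·(x&#772;ₑₓₚ − x&#772;ᵣₑ𝒻)/x&#772;ᵣₑ𝒻, with significance at P ≤ 0.05.

## Worked example

```python
from shgquant import PhantomParams, generate_shg_stack, quantify_sample

params = PhantomParams(seed=42, disruption=0.3, intensity_scale=0.8,
                       collagen_fraction=0.55)
stack = generate_shg_stack(params)          # 10 slices, 600 x 600, 16-bit
result = quantify_sample(stack, sample_id="phantom-42")
print(f"mean SHG intensity : {result.mean_intensity:.2f}")
print(f"entropy (bits)     : {result.entropy_bits:.3f}")
print(f"Otsu threshold     : {result.otsu_threshold}")
print(f"percent area       : {result.percent_area:.1f}")
print(f"GLCM entropy       : {result.glcm_features['entropy']:.3f}")
print(f"GLCM correlation   : {result.glcm_features['correlation']:.3f}")
```

prints

```
mean SHG intensity : 36.38
entropy (bits)     : 3.479
Otsu threshold     : 4
percent area       : 36.7
GLCM entropy       : 5.981
GLCM correlation   : 0.741
```

The mean intensity reflects the 0.8 intensity scale at photon gain 120; the
Otsu threshold sits just above the dark background, so the 36.7 % area
matches the phantom's ground truth (55 % collagen coverage with 30 % of
fibers ablated by disruption: 0.55 · 0.7 ≈ 38.5 %); the entropy sits between
the intact (~4.2 bits) and fully disrupted (~1 bit) ends of the scale.

A whole study runs from the shell:

```bash
shgquant pipeline --design aim2 --seed 7 --out run/   # simulate → quantify → compare
```

which writes the phantom TIFFs plus `truth.csv`, per-sample `results.csv`,
`comparison.csv`/`.json` with ANOVA and Bonferroni contrast p values, and a
`manifest.json` (config snapshot, checksums, seed) from which a rerun is
bitwise identical.

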