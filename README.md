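# vasquant

Quantification pipeline for fluorescence imaging of the zebrafish trunk
vasculature: à trous wavelet FISH spot detection inside annotated vessel
regions with an endothelial enrichment index, the manual vascular morphometry
scores used for venous/lymphatic phenotyping (thoracic duct extent,
parachordal lymphangioblast counts, intersegmental-vessel identity, secondary
sprout timing, filopodia density, cortical actin enrichment), single-cell
dotplot expression summaries, and the nonparametric group statistics that tie
them together. A synthetic-data module generates every input with known
ground truth, so the whole pipeline is testable without microscope data.

Intended users: imaging and developmental-biology groups who score trunk
vessel phenotypes and quantify transcript enrichment in the dorsal aorta (DA)
and posterior cardinal vein (PCV) from maximum-intensity projections.

## The core computations

**Spot detection.** The stationary ("à trous") wavelet transform with the
separable B3-spline kernel h = (1, 4, 6, 4, 1)/16 computes smooth planes
c_j = c_{j−1} ⊛ h_j (2^{j−1}−1 zeros inserted between taps at level j,
c_0 = image) and detail planes w_j = c_{j−1} − c_j, so that
Σ_j w_j + c_J = image exactly. Each w_j is a matched filter for round spots
of size ≈ 2^j px. Planes are hard-thresholded at k·σ_j with
σ_j = MAD(w_j)/0.6745, the plane matching the expected spot diameter is kept
(positive part), and a single global threshold plus 8-connected labeling with
intensity-based declumping yields the spot objects.

**Endothelial enrichment index.** With A_spot(R) the cumulative segmented
spot area in region R and A(R) its area,

    E_R = (A_spot(R)/A(R)) / (A_spot(out)/A(out)),    R ∈ {DA, PCV},

where "out" is the frame minus all vessel ROIs; E = 1 means no enrichment
over non-endothelial tissue.

**Morphometry.** Thoracic-duct extent is the merged length of visible TD
spans as a percentage of a 10-somite trunk span; sprout connection time is
(contact frame − first frame with a protrusion strictly longer than 15 μm) ×
20 min; filopodia density counts protrusions strictly longer than 5 μm per
40 μm of contour; cortical enrichment is mean intensity in a peripheral band
of the cell mask over the mean of its eroded interior.

**Statistics.** Mann–Whitney U (exact by small-sample null when n+m ≤ 12 and
tie-free, otherwise normal approximation with tie and continuity
corrections), Kruskal–Wallis, 2×2 χ² with Yates correction, pairwise
proportion tests with Holm step-down adjustment, Student/Welch t-tests, and
per-cluster percent-expressing / mean-expression dotplot summaries.

## Worked example

```python
import vasquant as vq

params = vq.FishSimParams(seed=3)          # 256x256 px, 0.2 um/px, SNR ~ 8
stack, annots, truth = vq.generate_fish_image(params)
spots = vq.detect_spots(stack.channel("FISH"), params.pixel_size,
                        spot_diameter=0.8)
enr = vq.enrichment_index(spots, annots)
print(truth.counts)
print(enr.per_region[["region", "n_spots", "enrichment_index"]])
```

prints

```
{'DA': 78, 'PCV': 96, 'outside': 77}
  region  n_spots  enrichment_index
0     DA       68          4.343255
1    PCV       85          5.193863
```

The generator planted spots at 10 per 1000 px² in each vessel band and 2 per
1000 px² outside — a density ratio of 5 — and the measured enrichment
indices recover that ratio from the segmented spot areas alone.

The same flow is scriptable from the shell:

```sh
vasquant simulate fish --seed 3 --out-dir scene
vasquant enrich scene/fish.tif scene/regions.json --out-dir scene/out
vasquant stats chi2 10 20 20 10      # -> chi2,5.4
```

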