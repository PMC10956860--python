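# dbotsu

Multi-level image thresholding for tapping-panel-dryness (TPD) diagnosis in
rubber trees: a restricted-range Otsu objective searched by the Dung Beetle
Optimizer (DBO), with severity grading from the latex-to-cut area ratio.

## The problem

Tapping Panel Dryness is a disorder of rubber trees in which latex flow from
the tapping cut declines; severity is graded 1 (mild) to 5 (severe).  In a
grayscale photograph of a panel, the tapping cut (scar) is a bright
curvilinear band and the latex along it is brighter still, but the image is
dominated by dark bark.  A global Otsu threshold — the gray level k
maximizing the between-class variance

    σ_B²(k) = P₁(k)·(m₁(k) − m_G)² + P₂(k)·(m₂(k) − m_G)²

is dragged toward the dark mass and cannot isolate the region of interest.

`dbotsu` therefore:

1. **Restricts the histogram** to gray levels above a first cut Th
   (default 150, where the latex/cut region lives), renormalizing the level
   probabilities to p_i / Σ_{i>Th} p_i.
2. **Maximizes the 5-class between-class variance** J(j,k,l,m) =
   Σ_c ω_c (μ_c − μ)² over four thresholds Th < j < k < l < m ≤ L−1.
   Exhaustive search is O(L⁴), so the maximization runs through the **Dung
   Beetle Optimizer**, a swarm metaheuristic whose agents take four roles
   (rollers, breeders, foragers, thieves) with role-specific position
   updates; positions are floored to integers, sorted, and scored by −J.
3. **Derives masks**: latex = pixels above the largest threshold m*, scar =
   pixels between the scar threshold and m*.  A morphological assessment
   checks whether the latex mask is curvilinear (elongation of its largest
   connected component); if not — the signature of a severe panel whose
   sparse latex no longer forms a histogram peak — the latex threshold
   falls back to the brightest occupied gray level.
4. **Grades severity** from λ = S1/S2 (latex area over cut area):
   grade 5 for λ ≤ 10%, 4 for 10% < λ ≤ 20%, 3 for 20% < λ ≤ 35%,
   2 for 35% < λ ≤ 45%, 1 above 45%.

Everything is exercisable without any photographic dataset: a synthetic
panel generator renders dark-bark images with a bright arc-shaped cut and a
latex streak of controllable area ratio, with exact ground-truth masks.

## Worked example

```sh
$ dbotsu synth --out demo --seed 5        # render a grade-2 panel (λ* = 0.40)
{"lambda": 0.40110395584176634, "latex_area": 436, "scar_area": 1087}

$ dbotsu grade demo/panel.png --seed 7
{"S1": 436, "S2": 1048, "fitness": -748.2793387925802, "grade": 2,
 "lambda": 0.41603053435114506, "latex_threshold": 233, "scar_threshold": 165,
 "schema_version": 1, "thresholds": [165, 176, 185, 233], "used_fallback": false}
```

The generator placed a latex streak covering 436 px against 1087 px of cut
(true λ = 0.401, grade 2).  The optimizer's four thresholds bracket the
bright-bark speckle (≤165), subdivide the scar band (176, 185) and separate
latex from scar at 233; the recovered ratio 0.416 falls in the same grade-2
band.  `used_fallback: false` records that the latex mask passed the
curvilinearity check, i.e. the low-severity path was taken.

The same objects are available as a library:

```python
from dbotsu import PanelSpec, PipelineConfig, generate_panel, segment_tpd
from dbotsu.grading import grade_segmentation

panel = generate_panel(PanelSpec(target_lambda=0.40, seed=5))
result = segment_tpd(panel.image, PipelineConfig(seed=7))
print(result.thresholds, grade_segmentation(result).grade)   # (165, 176, 185, 233) 2
```

Segmentation quality of the region-valued reconstruction can be scored with
the bundled metrics (`psnr`, `ssim_global`, `fsim_paper`, `detail_score`),
and `rank_table` / `wilcoxon_exact_one_sided` aggregate metric tables across
algorithms exactly as in the published comparison (`dbotsu compare`).

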