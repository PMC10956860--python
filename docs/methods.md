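# Methods

## Restricted-range multi-level Otsu

Let an M×N image have L gray levels with counts n_i and probabilities
p_i = n_i/MN.  A first cut Th splits the range into [0, Th] (background) and
[Th+1, L−1] (region of interest); within the upper range the conditional
probabilities are p_i^r = n_i / n_r with n_r the pixel count above Th.  Four
thresholds Th < j ≤ k ≤ l ≤ m ≤ L−1 partition the upper range into five
classes C₀…C₄ with weights ω_c = Σ p_i^r over the class and means
μ_c = (Σ i·p_i^r)/ω_c; the objective is the between-class variance

    J(j,k,l,m) = Σ_c ω_c (μ_c − μ)²,   μ = Σ_{i>Th} i·p_i^r.

Every class term is included and every class mean carries the i·p factor.
Empty classes (ω_c = 0) contribute zero, so duplicate thresholds are legal —
the optimizer can traverse degenerate tuples without special cases.  Th = −1
is accepted and means "no restriction", which makes the q = 1 case collapse
exactly to the classic global Otsu criterion.

Probabilities are formed from exact integer counts divided once at the end,
and all class sums use prefix arrays of p and i·p, so the objective is
bit-stable and O(1) per tuple after an O(L) setup.

**Exhaustive oracles.**  `exhaustive_otsu_single` scans all k;
`exhaustive_otsu_multi` enumerates all strictly increasing tuples
(vectorized over the full combination set) and refuses above a configurable
combination cap — it is meant for reduced level counts (64 levels with q = 4
is ~600k tuples).  Ties break to the smallest threshold /
lexicographically smallest tuple, making the oracles deterministic.

## Dung Beetle Optimizer

Population N = 60 split 20/20/25/35% into rollers, breeders, foragers and
thieves (largest-remainder rounding keeps the counts summing to N), run for
T_max = 200 iterations, minimizing −J over [Th+1, 256]⁴.  Update rules, with
X* the best position of the current iteration, X^b the global best and X^ω
the worst seen so far:

- **roll** (prob. 0.9): x ← x + α·k·x_prev + b·|x − X^ω|, with deflection
  k = 0.1, constant b = 0.3, and α = ±1 drawn with P(α=1) = 1−l (l = 0.5);
- **dance** (prob. 0.1): x ← x + tan(θ)·|x − x_prev|, θ ~ U(0, π); θ exactly
  0, π/2 or π (within 1e−12) leaves the position unchanged, so no overflow;
- **breed**: B ← X* + b₁(B − Lb*) + b₂(B − Ub*), clamped into the spawning
  area Lb* = max(X*(1−R), Lb), Ub* = min(X*(1+R), Ub), R = 1 − t/T_max;
- **forage**: x ← x + C₁(x − Lb^b) + C₂(x − Ub^b) with the same shrinking
  window around X^b; C₁ ~ N(0,1) scalar, C₂ ~ U(0,1)^D;
- **thieve**: x ← X^b + S·g·(|x − X*| + |x − X^b|), S = 0.5, g ~ N(0,1)^D.

Design choices the published description leaves open, fixed here:

- The spawning/foraging **upper bound as printed uses (1−R)**, which
  collapses the interval to a point; the default `bounds_convention =
  "corrected"` uses (1+R) (the standard form), and `"as_printed"` is kept
  behind the flag for auditing.
- **Greedy acceptance** per agent per move ("keep if better"), which makes
  the best-fitness trace non-increasing by construction.
- **X\*** is refreshed once per iteration as the best current position; X^ω
  is the worst-so-far.  All roles are clamped to the global bounds (the
  published pseudocode clamps only breeding balls; the thresholding domain
  requires all positions to stay in range).
- Scalar vs vector randomness: δ and C₁ are scalars per agent-iteration;
  b₁, b₂, C₂, g are D-vectors.
- T_max defaults to 200 (the published parameter table; the pseudocode's
  initialization line says 150 — the table wins, and the value is a plain
  parameter).

Continuous positions map to thresholds by floor → clamp to [Th+1, L−1] →
sort.  Floor maps each unit interval [g, g+1) to g uniformly; sorting
removes ordering constraints from the search space.

On separable quadratics in D ≤ 4 the optimizer reliably recovers the optimum
to machine precision (the shrinking breeding/foraging windows collapse onto
the best position as R → 0), and on 64-level quantized synthetic panels it
attains the exhaustive four-threshold optimum in 10/10 seeded runs.

## Level-dependent strategy and threshold roles

The largest threshold m* is the latex threshold (latex = pixels > m*).  The
**scar mask is (j\*, m\*]**, bounded below by the *smallest* threshold j*.
This is a deliberate reading of an ambiguity: published scar thresholds hug
the lower edge of the restricted range (e.g. 152.4 with Th = 150), which
only the smallest of four thresholds can do, and the interval reading keeps
the whole scar gray range in the scar class even when the optimizer spends
its middle thresholds subdividing the scar's own gray distribution — with a
(l*, m*] scar class the computed area ratio would inflate whenever that
happens.  `scar_role = "third"` switches to the (l*, m*] reading.

After the initial segmentation a **morphological assessment** checks the
latex mask (configurable to the scar mask): the largest 8-connected
component with area ≥ 50 px is fit with its second-moment ellipse and the
mask counts as curvilinear when major/minor ≥ E_min = 3.0.  Elongation is
cheap, rotation-invariant and monotone in band-likeness; the threshold is a
config parameter because no quantitative criterion is published.  A
curvilinear latex mask is kept (low-severity path).  Otherwise the image is
treated as high-severity: the latex threshold becomes the brightest occupied
gray level g_max and the latex mask the pixels at that level (a configurable
tolerance can widen it to ≥ g_max − tol; default 0, the strict reading).
The scar mask is unchanged, minus any pixels the fallback latex mask claims,
so the masks stay disjoint.

## Severity grading

λ = S1/S2 with S1 = latex pixel count, S2 = scar pixel count; S2 = 0 is an
error.  Bands are inclusive on their upper ends exactly as published, and
λ < 1% — left undefined by the published band table but graded 5 in its own
worked examples (λ = 0.00047 → grade 5) — is folded into grade 5.

## Quality metrics and comparison machinery

- `psnr`: 10·log₁₀(MAX²/MSE), +∞ sentinel at MSE = 0.
- `ssim_global`: the SSIM formula evaluated on whole-image moments
  (population variances), as the published evaluation defines it.
- `fsim_paper`: the published "FSIM" formula is a mean of local SSIM-form
  terms, not the phase-congruency FSIM of the wider literature; it is
  implemented exactly as printed (uniform w×w windows, stride 1, mean over
  all valid positions) and named to avoid claiming equivalence.  Window side
  w = 8 and stability constants C₁ = (0.01·MAX)², C₂ = (0.03·MAX)² are the
  smallest common conventions; both are configurable because neither is
  published.
- `detail_score`: ±1 per pixel with the inclusive boundary |Δ| ≤ 50.
- Region-valued reconstruction (for scoring a threshold set against the
  original) replaces each pixel by the rounded mean gray of its class,
  including the below-Th class — the standard choice that makes PSNR
  well-defined.
- `rank_table`: rank 1 = largest metric within each group; **ties share the
  midrank** (average method).  This is the convention the published average
  rankings actually follow — several comparators share identical printed
  metric values, and only midranks reproduce every published average;
  competition ("min") ranks are available as an option.
- `wilcoxon_exact_one_sided`: exact signed-rank by enumerating all 2ⁿ sign
  assignments of the midranked |differences| (n ≤ 20), one-sided "reference
  greater".  One-sided p-values reproduce every published cell.

## Synthetic panel generator

The generator emulates the gray structure that motivates the restricted
objective: a dominant dark background (N(60, 15²), ≥ 70% of pixels below
gray 120), a bright arc-shaped tapping cut (radius 170 px, 64° span, 8 px
wide, gray N(180, 8²)), a latex streak along the cut centerline (6 px wide,
gray N(245, 4²)) and sparse bright-bark speckle (6% of off-band pixels,
uniform gray 156–162).  Geometry is drawn first and noise second, so the
ground-truth masks are exact.  The latex run's angular length is solved by
bisection so the realized area ratio hits the requested target to within
pixel quantization (±20% is guaranteed for targets ≥ 0.05).  The speckle's
narrow gray band is what gives the threshold search a coherent cluster to
separate just below the scar range, mirroring the bright-bark sheen of real
panels.

What the generator does **not** emulate: bark texture correlation, uneven
illumination, JPEG artifacts, specular highlights off the cut, multiple or
branched cuts, and latex droplets detached from the cut.  Passing the
recovery tests therefore demonstrates that the pipeline's logic is correct
under the intended gray-structure assumptions, not that field accuracy on
photographs is reproduced.

All randomness in the generator and the optimizer flows through one seeded
NumPy generator each; identical seeds give bit-identical images and
segmentations.

## Problem sizes used by the test suite

Unit tests use reduced optimizer budgets (N = 30, T = 60) on 200×200 panels;
the acceptance checks run the full N = 60, T = 200 configuration on ten
seeded panels for the oracle-gap measurement (64-level quantization keeps
the exhaustive reference at ~600k tuples) and on the 5×10 severity grid
(targets 0.05–0.60, seeds 1–10) for grade recovery.  These sizes were chosen
as the smallest at which the stochastic acceptance margins (≥ 9/10 oracle
hits, ≥ 80% grade recovery) are comfortably stable across seeds.

## Known limitations

- Th is a fixed configuration parameter (default 150); no procedure for
  choosing it per image is published, and none is attempted here.
- The curvilinearity criterion (largest-component elongation ≥ 3) is one
  reasonable operationalization of "curvilinear"; panels whose latex forms
  several short parallel runs may be misrouted to the fallback path.
- The fallback latex mask at tolerance 0 contains only the single brightest
  occupied level, which under-counts latex in noisy images; raise
  `fallback_tol` for robustness at the cost of the strict reading.
- The comparator optimizers of the published evaluation are consumed as
  printed metric values only; they are not reimplemented.
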