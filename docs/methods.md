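# Methods

`mzlspatial` quantifies the spatial organisation of CD4+ T-cell subsets in
lymphoma tissue sections from per-cell coordinates and marker intensities.
Because the original per-cell coordinate data for marginal zone lymphoma
are not publicly deposited, every stage is exercised on synthetic marked
point patterns whose construction is described below; all statements made
by the test suite and the analysis scripts are statements about these
synthetic study conditions.

## Phenotype gating

Cells carry staining intensities for CD4, PD1, FOXP3 and Ki67. The subset
rule table is:

| CD4 | PD1 | FOXP3 | call |
|---|---|---|---|
| + | high | − | Tfh |
| + | high | + | Tfr |
| + | low | + | Treg |
| otherwise | | | other |

Ki67 positivity is flagged independently of the subset call; the
single-marker surrogate populations PD1hi (PD1 ≥ τ_PD1 regardless of the
other markers) and FOXP3+ are exposed as flags so the surrogate-marker
analysis mode can be compared with the multi-marker calls.

Threshold conventions are fixed and documented rather than inferred:
a marker is positive/high when intensity ≥ threshold (boundary cells are
positive), negative when below. Quantiles use linear interpolation between
order statistics.

The PD1-high threshold τ_PD1 can be calibrated as a low quantile (default
`reference_quantile = 0.05`) of a reference PD1-high population emulating
follicular-helper cells of tonsillar germinal centres, so that ~95% of the
reference population is called PD1-high. Note the statistical consequence:
any cell drawn from the same PD1-high intensity model has a ~5% chance of
falling below an in-sample 5th-percentile threshold, so reference
calibration cannot achieve perfect recovery of PD1-high cells by
construction. For that reason, when no reference and no explicit threshold
are supplied, every channel — PD1 included — defaults to a bimodality
split: the midpoint (in log intensity) between the two largest modes of a
Gaussian kernel density estimate of the channel. With well-separated
intensity models this split sits between the class supports and gating is
exact. Channels that do not look bimodal are rejected with an instruction
to supply an explicit threshold.

## Ripley's K and the cluster score

For n cells of one phenotype in a rectangular window A,

    K̂(r) = |A| / (n(n−1)) · Σ_{i≠j} w_ij · 1(d_ij ≤ r)

with translation edge-correction weights
w_ij = |A| / ((W−|dx_ij|)(H−|dy_ij|)) by default (exact for rectangles);
`correction="none"` (w_ij = 1) exists for oracle comparisons. Under
complete spatial randomness (CSR) K(r) = πr². The radius grid defaults to
50 evenly spaced radii from 0 to one quarter of the shorter window side;
larger radii are refused because the correction degrades.

The deviation from CSR is reduced to a single dimensionless cluster score

    score = ∫ (K̂(r) − πr²) dr / ∫ πr² dr   (trapezoidal over the grid),

zero in expectation under CSR, positive for clustering (exactly 1 when
K̂ = 2πr²), negative for regularity, and window-scale-free thanks to the
normalisation. No canonical definition of a K-based scalar "cluster
score" exists; this normalised integrated deviation is this package's
definition, so published patient-level score values are comparable to it
only directionally. Groups of case-level scores are compared with a
two-sided Mann-Whitney rank-sum test (tie-corrected; identical groups
report p = 1).

Implementation: pair distances are gathered with a dense `pdist` when
n(n−1)/2 ≤ 8·10⁶ and a k-d tree restricted to the largest radius
otherwise; both paths are exact and feed a weighted bin-count cumulative
sum with `d ≤ r` boundary semantics, so results equal the O(n²) oracle to
the last bit.

## Quadrat interaction

The window is tessellated into equal squares of side s anchored at the
lower-left corner; sides default to 100/200/400 μm. The side is a length:
a quadrat of *area* 200 μm² (side ≈ 14 μm) could never contain the >50
cells required by the high-interaction rule, so the length reading is the
only consistent one. Partial edge strips are dropped (quadrats must be
equally sized) and cells within them are excluded; assignment uses
half-open intervals so boundary cells are counted exactly once.

Per phenotype pair (x_i, y_i counts over quadrats):

* **Morisita-Horn**: MH = 2Σx_i y_i / [(Σx_i²/X² + Σy_i²/Y²)·X·Y],
  computed over *all* retained quadrats (it is a whole-tessellation
  overlap index); 1 for proportional vectors, 0 for disjoint support.
* **Pearson correlation** over quadrats passing a display filter (at
  least one population ≥ `min_cells`, default 5); fewer than three
  passing quadrats is an error, a constant filtered vector leaves the
  correlation undefined (flagged).
* **High-interaction fraction**: share of *filter-passing* quadrats where
  both counts strictly exceed `high_threshold` (default 50). The
  denominator choice (analysed = filter-passing quadrats) is deliberate
  and overridable.

Whether published interaction indices were pooled across all quadrats of
all cases or averaged per case is not generally stated; the pipeline
computes per-case values and labels any pooling it performs.

## Nearest-neighbour analysis

For each query cell (by default restricted to Ki67− members of the query
phenotype, so a proliferating query never measures the distance to
itself), the exact Euclidean distance to the nearest target cell is
computed with a k-d tree (verified identical to the O(n·m) brute force).
Distances are computed per case and pooled afterwards, never across
tissue-section boundaries. Query populations larger than 10⁵ are
subsampled without replacement, seeded, optionally with proportional
stratification across cases (floors first, remainders by largest
fractional part, ties by case order). Two pooled distance samples are
compared with a two-sided Mann-Whitney test plus a shared-bin histogram
summary.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes,
not tissue images:

* **CSR phenotype** (Treg/FOXP3+ analogue): homogeneous Poisson with
  intensity λ (cells/μm²).
* **Clustered phenotype** (Tfh/PD1hi analogue): Thomas (Neyman–Scott)
  process — parents Poisson(κ) per μm², each with Poisson(μ_c) offspring
  displaced by isotropic Gaussian(σ). Parents are simulated on the window
  expanded by 4σ per side and offspring clipped to the window, so the
  retained pattern is an unbiased restriction of the stationary process
  (no edge-depleted clusters).
* **Proliferating population** (Ki67+ B-cell analogue): offspring of the
  *same* parent set as the clustered phenotype ("linked") or of an
  independently drawn parent set ("independent"); the linked construction
  is the mechanism hypothesised for proliferating B-cells around
  follicular-helper T-cells.
* **Marker intensities**: log-normal per channel per phenotype
  (strictly positive, right-skewed, matching immunohistochemical signal).
  Defaults put "low" at meanlog 1.0 and "high" at meanlog 4.0 with
  sdlog 0.25 — 12 scale units of separation, so threshold gating is
  essentially exact and the PD1 channel is bimodal whenever PD1-high and
  PD1-low phenotypes coexist.

The default `full_tissue` scenario is one synthetic "case": a
1500×1500 μm window (2.25 mm²) containing a clustered Tfh analogue
(κ = 2·10⁻⁵/μm², μ_c = 25, σ = 20 μm ⇒ ~1100 cells), a CSR Treg analogue
(λ = 5·10⁻⁴ ⇒ ~1100 cells), a linked Ki67+ class (μ_c = 40, σ = 25 μm ⇒
~1800 cells) and a CD4+ CSR background (λ = 5.1·10⁻³ ⇒ ~11500 cells).
The background is sized so the Tfh+Treg share of CD4+ cells is ≈16%, the
subset-share scale reported for this tissue type; the window is two
orders of magnitude smaller than whole tissue sections (4.8–112 mm²) to
keep desk-scale runtimes, which scales every absolute count down but
leaves the intensive quantities (K, scores, MH, NN medians) comparable.

All randomness flows through `numpy` `SeedSequence` substreams spawned
from one seed: fixed seed ⇒ bit-identical patterns, labels and intensity
tables, and adding a stage does not perturb earlier draws.

What the generator does **not** emulate: irregular tissue masks (windows
are rectangles; edge corrections assume this), within-slide intensity
gradients (no inhomogeneous Poisson), nucleus-segmentation and
registration noise, marker spillover, and cell-size exclusion effects.
Passing tests therefore demonstrate correctness of the estimators and the
directional behaviour of the pipeline under its assumed data model — not
performance on real stained sections.

## Benchmark studies

`mzlspatial.studies` fixes four characterisation studies on a 1 mm²
window with ~10³ cells per pattern (problem sizes chosen for desk-scale
runtime):

1. **CSR calibration** — 100 CSR replicates (λ = 10⁻³): mean K̂ vs πr²
   over 20–100 μm and mean cluster score vs 0.
2. **Clustering detection** — case-control suites of 15 Thomas
   (κ = 5·10⁻⁵, μ_c = 20, σ = 20 μm) vs 15 CSR cases at equal expected
   abundance, repeated 100 times; a detection is a higher Thomas median
   with Mann-Whitney p < 0.01.
3. **σ response** — mean cluster score at σ ∈ {10, 20, 40, 80} μm,
   50 replicates per level, using common random numbers across levels
   (shared parents, offspring counts and standardized displacements, with
   the parent buffer sized for the largest σ): the standard
   variance-reduction design for a monotone dose-response comparison,
   without which the small σ=10 vs σ=20 gap (~0.02, consistent with the
   Thomas closed form K(r) = πr² + (1−e^{−r²/4σ²})/κ) is of the order of
   the Monte-Carlo standard error at this replicate count.
4. **Linked vs independent contrast** — 100 paired bivariate simulations
   (κ = 5·10⁻⁵, μ = 30 per class, σ = 20 μm; the same seed drives both
   members of a pair): Morisita-Horn at each quadrat side,
   high-interaction fraction at 200 μm, and per-pair plus pooled
   nearest-neighbour medians.

## Numerical and degenerate-input conventions

* Quantiles: linear interpolation; boundary comparisons: ≥ for
  positive/high.
* K estimation requires ≥2 points inside the window and refuses radius
  grids beyond the quarter-side guard; K̂(0) = 0 for distinct points.
* Cluster score requires a common grid with ≥2 radii; the CSR integral
  must be positive.
* Morisita-Horn is undefined (error) when either count vector sums to
  zero; Pearson is undefined (NaN, flagged) for constant filtered
  vectors; the high-interaction fraction is undefined (error) when no
  quadrat passes the display filter. Inside the multiscale summary these
  per-index failures are flagged rather than aborting the other indices.
* Subset fractions are NaN (undefined, not zero) when no cell is CD4+;
  the PD1hi:FOXP3+ ratio is +inf when FOXP3+ is empty but PD1hi is not.
* Identical groups in rank tests report p = 1; ties use the corrected
  asymptotic statistic.
* Equidistant nearest-target ties are irrelevant for distances; when a
  target identity is needed it would break ties by lowest cell id (not
  exposed in the current API).
* Cell tables are CSV (UTF-8, header, comma, decimal point) with floats
  at 9 significant digits; an optional `# window:` sidecar header
  declares the observation rectangle, else the bounding rectangle of the
  coordinates is used. Image-convention input (y downward) is converted
  by a flag; all statistics are orientation-invariant.
* Raw p-values are reported with an explicit no-multiplicity-adjustment
  note; optional Benjamini-Hochberg is available in the pipeline config.

## Known limitations

* Rectangular windows only; irregular section outlines are approximated
  by bounding rectangles, which biases the translation correction near
  concave boundaries.
* The cluster score definition is package-specific (see above);
  published score magnitudes are directional references only.
* The KDE bimodality split assumes genuinely bimodal channels; gradual
  marker expression would need externally supplied thresholds.
* Synthetic windows are far smaller than whole tissue sections; absolute
  counts (e.g. per-quadrat totals) scale accordingly.
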