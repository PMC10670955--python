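# Methods

`uroquant` quantifies readouts of the urothelial blood–urine barrier as they
are measured in ex vivo mouse bladder studies: epithelial hyperplasia as
nuclei per micrometre of urothelium, transepithelial electrical resistance
(TEER) from Ussing-chamber readings, ROI fluorescence densitometry, and the
small-sample statistics these assays are analysed with. A synthetic-data
module generates all inputs with exact ground truth, so every stage is
testable without animal data.

## Nuclear density (hyperplasia)

**Model.** Hyperplasia is quantified as the linear nuclear density
`rho = N / L`, where `N` is the number of nucleus objects inside the
segmented urothelial band and `L` is the band's centerline length. The
density is reported per micrometre.

**Band segmentation.** The marker channel (e.g., Cytokeratin 7) is smoothed
(Gaussian, `smoothing_sigma_um`, default 1 µm), thresholded with global
Otsu, morphologically closed (`closing_radius_um`, default 2 µm), hole
filled, and reduced to its largest 8-connected component. A trainable
random-forest pixel classifier over a multiscale feature stack (intensity,
edges, texture at 3 scales) is available behind the same contract for data
where a global threshold fails; the deterministic route is the default
because it needs no annotations and is exactly reproducible.

**Nucleus segmentation.** Otsu threshold on the nuclear channel, then
watershed on the distance transform with seeds at local maxima separated by
at least `min_seed_distance_um` (default 2 µm) to split touching nuclei.
Components whose seed was suppressed by a larger neighbour are labelled
separately rather than dropped. Smoothing is off by default: on
high-contrast nuclear stains Otsu does not need it, and any smoothing
erases the sub-µm² debris that the area filter is designed to handle.
A nucleus belongs to the band iff its centroid lies inside the band mask —
the simplest rule that is stable under partial occlusion at band edges.

**Area filter.** Objects with area < `A_min` (default 2.5 µm², valid range
0–5 µm²) are discarded; the median area `A_med` of the survivors defines an
upper bound `A_max = factor × A_med` (factor default 4.0, valid range
3–5), above which objects are excluded. `A_med` is computed after both the
in-band restriction and the `A_min` cut so that debris cannot bias it.
Oversized objects are excluded rather than split; an optional
`split_oversized` mode counts them as `round(area / A_med)` merged nuclei.

**Band length.** The band mask is skeletonized with the medial axis.
Side branches shorter than the band thickness (estimated as mask area /
skeleton length, re-estimated once after a first prune) are pruned. When
the pruned skeleton is a single curve, the curve ends are additionally
trimmed where the medial radius falls below 95% of the median radius
(corner spurs taper toward radius 1), and the length is measured as a
chord sum over every 5th skeleton pixel — per-pixel step sums (1 px
orthogonal, √2 px diagonal) overestimate obliquely heading smooth curves
by up to ~8% from staircase quantization, while chord resampling is exact
on straight runs and unbiased on smooth curves. Finally, because the
medial axis of a ribbon retracts by the local half-thickness at each open
end, `2 × (mean medial radius − 1 px)` is added back; for a one-pixel-wide
curve this correction is exactly zero, so a 41-pixel line measures exactly
40 px. With these choices the rectangle, half-circle and phantom fixtures
recover their analytic centerline lengths to well within 1%.

**Sensitivity analysis.** Segmentation and length are computed once; the
area filter is re-applied over the grid `A_min ∈ {0, 1.25, 2.5, 3.75, 5}`
µm² × `factor ∈ {3.25, 3.75, 4.25, 4.75}`, and the spread is summarized as
`(max − min) / median` of the grid densities. On clean tissue with
unimodal nucleus areas the deviation is ~0 (the thresholds never bite);
debris below 1 µm² makes the density strictly decreasing in `A_min`.

**Manual comparison.** Automated vs. manual counts are compared by mean
signed difference, mean absolute difference, and Lin's concordance
correlation coefficient (undefined, reported as NaN, for a single pair).

## TEER processing

Net resistance per reading is `R_total − R_blank` (blank = fluid
resistance without tissue, stored per chamber); absolute TEER is the net
resistance × exposed window area in cm² (circular window, default diameter
2 mm → 0.0314 cm²). Raw potential/current pairs are converted by Ohm's law
(`R = ΔV/ΔI`, magnitudes). Because absolute TEER varies strongly between
preparations, each series is expressed as a percentage of its reading at
the end of the 30 min equilibration period; if that exact reading is
missing the nearest earlier one is used with a warning.

Group comparisons at fixed time points use a two-tailed Mann–Whitney U
test. For combined n ≤ 12 the test is exact: all C(n1+n2, n1) assignments
of the pooled mid-ranks are enumerated and both tails at least as extreme
as the observed U are summed (the null distribution of U is symmetric
about n1·n2/2 even under ties), capped at 1. The threshold 12 covers all
group sizes of 2–6 per group with exact enumeration; larger samples fall
back to the tie-corrected normal approximation. Under complete separation
the exact two-sided p equals `2 / C(n1+n2, n1)` — e.g., 2/70 ≈ 0.0286 at
4 vs 4 and 2/462 ≈ 0.0043 at 5 vs 6.

## ROI fluorescence

A pixel belongs to a polygonal ROI when its center lies strictly inside
the polygon. The rule is deterministic and additive when an ROI is split
along lines between pixel centers, which makes the densitometric readout
invariant under splitting and area-weighted recombination. Two readouts:
the arithmetic mean intensity (with fold change against the
negative-control mean, which must be positive), and the summed gray value
per ROI area scaled to 10,000 µm². "Gray value" is interpreted as the
densitometric total (sum) by default; a mean-based mode is provided since
source conventions differ.

## Assay statistics

- qPCR: relative expression is `−ΔCt = −(mean Ct_target − mean Ct_control)`
  against an endogenous control (e.g., L32), with technical duplicates
  plain-averaged (no outlier handling — none is defined for this assay).
- Urine: K⁺ (mmol/L) divided by creatinine (g/L), giving mmol/g.
- Two-group testing: Shapiro–Wilk per group at α = 0.05; both normal →
  unpaired pooled-variance t test (the conventional reading of "unpaired
  Student's t"); otherwise Mann–Whitney (conservative when only one group
  is non-normal). Routing needs n ≥ 3 per group, the minimum for
  Shapiro–Wilk.
- Differential-expression tables: significance is `p_adj < 0.05` as given
  (the adjustment is upstream and out of scope); direction is the sign of
  log2FC; genes with log2FC = 0 belong to neither set and are counted
  separately. With exactly two contrasts, shared and per-contrast unique
  deregulated genes are reported.

## Synthetic data: what it emulates, and what not

The tissue phantom renders a curved urothelial band (straight, sinusoidal,
or circular-arc centerline) of known analytic length and elliptical nuclei
placed at deterministic arc-length spacing `1/density` with seeded,
bounded jitter — bounded so that nuclei never overlap after rasterization
and never leave the band, which makes the true density exact rather than a
Poisson expectation and keeps parameter-recovery tests sharp. The band is
rasterized with square-cut ends so its ideal centerline length equals the
analytic curve length. Optional debris (< 1 µm², inside the band, inside
the `A_min` sweep range) and nucleus-like out-of-band clutter exercise the
area filter and the in-band rule. Noise is additive Gaussian on grey
levels, clipped to the bit depth — the simplest model that measurably
degrades Otsu thresholds.

Defaults describe a 20× fluorescence acquisition of a mouse bladder
section: 0.5 µm/px, 16 µm band thickness, nuclei with 3 × 2 µm semi-axes
(≈19 µm² area, far above the 0–5 µm² `A_min` sweep, hence the "negligible
effect" behaviour on clean tissue), density 0.12 nuclei/µm, 8-bit
intensities 10/200/220 (background/band/nuclei). Moderate noise in the
tests is sd 20, i.e. ~10% of the nucleus contrast.

The Ussing simulator holds baseline TEER (default 150 Ω·cm²) through a
30 min equilibration, declines linearly to `1 − drop` (default drop 0.6)
of baseline during a 15 min polycation exposure ending at 45 min, then
recovers exponentially (half-time 60 min) toward a plateau fraction
(default 0.85 of baseline). Readings follow the standard schedule (every
10 min to 30, every 5 to 60, every 10 to 120, every 20 to 360) and are
emitted as total resistances (TEER/area + blank) with multiplicative
noise.

Assay-table generators plant exact truths: a Ct shift on one group's
target gene, a K⁺/creatinine ratio between groups, or a chosen number of
up/down deregulated genes with `p_adj < 0.05` by construction.

Not emulated: optical PSF and photorealistic histology, stain variability,
3D sections, chamber drift or electrode offsets, and real RNA-seq noise
structure. A green test therefore establishes correctness of the
quantification algorithms on well-posed inputs, not robustness to every
acquisition artifact; the trainable segmentation route exists for data the
global threshold cannot handle.

## Numerical choices and edge cases

- All randomness flows through one `numpy.random.Generator` per generator
  call; same parameters + seed → bit-identical outputs.
- Areas are pixel counts × pixel_size²; coordinates are 0-based (row, col);
  connectivity is 8-neighbour throughout.
- Constant nuclear channel → empty record list; constant band channel →
  error (no foreground).
- `A_med` undefined (nothing passes `A_min`) → explicit error rather than a
  silent zero.
- Skeleton step dedup: a diagonal step is not counted when its endpoints
  share an orthogonal skeleton neighbour (an L-corner is one step, not a
  triangle).
- Exact-test tie handling uses mid-ranks with a 1e-9 tolerance when
  comparing enumerated U values.

## Known limitations

- The end-retraction correction assumes open ribbon ends; on a mask with
  naturally rounded (cap-shaped) ends it adds about one band thickness.
  Closed-loop bands (full rings) are measured without correction.
- Very tortuous bands whose medial axis genuinely branches fall back to
  the step-sum measure over the pruned skeleton, which can overestimate by
  a few percent.
- The exact Mann–Whitney enumerates C(n1+n2, n1) tables and is intended
  for the small group sizes of ex vivo work (combined n ≤ 12).
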