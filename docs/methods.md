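# Methods

## Statistical model of the proteomic screen

A protein's abundance ratio between a test and a reference condition is
estimated from per-peptide reporter ratios. Within one biological
replicate the protein ratio is the geometric mean of its peptide ratios —
equivalently the exponential of the mean log ratio, so the estimate is
symmetric under inversion of the comparison (a 2-fold increase and a
2-fold decrease are equally far from 1). The per-replicate p-value is a
two-sided one-sample t-test of the log2 peptide ratios against 0. This
test is a stand-in for the proprietary per-protein significance produced
by commercial identification software; it assumes peptide log-ratios are
exchangeable and approximately normal around the protein's log fold
change. A replicate needs at least `min_peptides` peptides (default 2,
emulating upstream identification stringency) to yield a p-value; with
zero variance the p-value is 1 when all log ratios are exactly 0 and 0
otherwise (the t statistic diverges).

Across replicates the pooled ratio is the geometric mean of the replicate
ratios. Each replicate's two-sided p-value is converted to a signed
z-score, `z_i = sign(log r_i) · Φ⁻¹(1 − p_i/2)`, so replicates that
disagree in direction cancel, and the replicate z-scores are combined with
the weighted Stouffer–Liptak statistic `Z = Σ w_i z_i / √(Σ w_i²)` with
the peptide count as weight. The denominator `√(Σ w_i²)` is what keeps Z
standard normal under the null; the plain weighted mean `Σ w z / Σ w` is
not a calibrated z-statistic and is available only behind
`StatsConfig(z_normalization="mean")` for comparison. The pooled two-sided
p-value `2(1 − Φ(|Z|))` is Bonferroni-corrected within each comparison
(family = proteins tested in that comparison; a global integer family is
available via config). Direction calls at `alpha` (default 0.05):
DECREASED / INCREASED when the adjusted p is below alpha and the pooled
ratio is below / above 1; a pooled ratio of exactly 1 is UNCHANGED
regardless of p (its direction is undefined). Proteins with fewer than
`min_replicates` (default 2) p-value-carrying replicates are reported with
their pooled ratio but never tested. P-values are floored at 1e-300 before
the normal quantile so that underflow cannot produce infinite z-scores.

## Two-tier screen

Tier 1 classifies each protein on the CHX-vs-control comparison. Tier 2 is
evaluated for every tier-1-affected protein on each arrestin-deletion
comparison: an INCREASED call there means the deletion left more protein
at the PM than in the wild type (STABILIZED — an internalization defect),
DECREASED means DEPLETED, otherwise UNAFFECTED; proteins missing from a
comparison are UNAFFECTED with a "not quantified" flag. The
arrestin→target map keeps only proteins that are both tier-1 DECREASED and
STABILIZED in that deletion: a rise of an already-CHX-resistant protein is
not evidence of blocked endocytosis. Output tables are ordered by tier-1
effect, greatest decrease first.

The packaged reference tables can drive the same classifier directly
("fixture mode") using their recorded significance flags; when a full
peptide dataset is available the pipeline-computed significance is used
instead. The per-arrestin table's flags are recorded only where the
source's narrative states them; cells whose significance could not be
established are flagged `none` and the affected rows are listed in
`reference_tables.TABLE2_AMBIGUOUS_ROWS`.

## Synthetic data generator

The generator emulates the screen's design: one CHX-vs-control comparison
with 6 biological replicates, twelve arrestin-deletion comparisons with 3
replicates each, 33 proteins, and a fixed peptide-count table spanning
1–40 peptides so that both the weighting and the minimum-evidence filter
are exercised. The noise model is explicit, since no raw data exist to fit
one: each (protein, comparison, replicate) draws a log2 offset
~ N(0, `replicate_effect_sd`²) representing shared biological and labeling
variation, then each peptide draws log2(ratio) ~ N(log2(fold change) +
offset, `peptide_noise_sd`²). Defaults `peptide_noise_sd = 0.5` and
`replicate_effect_sd = 0.1` (log2 units) reflect typical isobaric-label
peptide-level scatter and a modest between-replicate component. Randomness
follows a single top-level seed with one CRC-32-keyed substream per
(protein, comparison, replicate), so identical seeds are bit-reproducible
and adding proteins never perturbs existing draws.

What the generator does *not* emulate: reporter-channel effects (isotope
impurity, ratio compression at high complexity), missing peptides,
shared/razor peptides, and retention-time or identification artifacts.
Passing tests therefore demonstrate the statistics behave correctly under
the stated noise model, not that the pipeline is robust to every artifact
of real spectra.

A consequence worth knowing: the per-replicate t-test sees only peptide
scatter, so the replicate-level offset inflates per-replicate z-scores for
peptide-rich proteins, and the combined statistic over-rejects slightly on
null comparisons (measured ≈1.4% per protein–arrestin pair after
Bonferroni at the defaults, against a nominal ≈0.25%). The null
calibration bound (≤5% of proteins called) still holds with a wide margin,
but the planted-screen false-discovery proportion sits near 0.10–0.13
rather than near zero. A between-replicate variance component (e.g. a
random-effects combination) would fix this but is deliberately out of
scope: the point is to reproduce the published pipeline's behavior, not to
improve on it.

Simulation sizes used by the test suite and the acceptance script — a
200-protein single-comparison null screen, 200 single-protein power runs
at fold 0.14, and 50 planted screens of 20 proteins across all 12
arrestins — are the package's chosen balance between Monte-Carlo error and
convenience; all are reproducible from their seeds.

## Imaging quantification

Pixel membership uses the pixel-center convention on a 0-based grid: pixel
(row, col) belongs to an ellipse when its center point (x=col, y=row)
satisfies the ellipse inequality. The PM region is the annulus between the
outer (whole-cell) and inner (interior) ellipses; the inner ellipse must
be strictly contained in the outer, and an annulus that captures no pixel
center is an error rather than a silent zero. The internal/PM ratio is
invariant under multiplicative gain but **not** under an additive offset —
a camera pedestal compresses it toward 1 — so images should be dark-level
corrected before quantification (a regression test documents the effect).

Condition summaries report the median ratio with a 95% bootstrap
percentile CI of the median (2,000 resamples by default, seeded); the
bootstrap was chosen because no distributional CI for the median is
standard at these sample sizes. Time-course data can be normalized per
variant by the median ratio of that variant's time-0 group.

Pairwise comparisons use the two-sided Wilcoxon rank-sum test. When both
groups have ≤ 10 observations the permutation null of the rank sum is
enumerated exhaustively using midranks, which makes the p-value exact even
with ties (this is slightly stronger than switching to the approximation
whenever ties occur: identical groups then give p = 1 exactly, as the
symmetric null demands); the two-sided p is `min(1, 2·min(P(W ≤ w),
P(W ≥ w)))`. Larger groups use the normal approximation with tie-corrected
variance and no continuity correction. Families of comparisons belonging
to one figure panel are Holm-adjusted.

The synthetic field renderer places non-overlapping cells with constant
interior and ring levels plus Gaussian noise; its ground-truth ratio is
interior/ring. The convenience detector thresholds at an intensity
quantile and fits second-order-moment ellipses to connected components,
shrinking the semi-axes by a configurable PM-thickness margin (default 2
px) for the inner ellipse; it is intended for synthetic or well-separated
cells, not as a segmentation method for crowded micrographs (budding cells
in particular should be drawn by hand, as in the original workflow).

## Known limitations

- Per-replicate p-values are a declared stand-in for the original
  software's proprietary test; absolute pooled p-values are therefore not
  comparable to the original analysis, though the combination, correction
  and calls are.
- No between-replicate variance component (see above).
- The per-arrestin reference table records significance flags only for
  narrative-anchored cells; fixture-mode tier-2 calls for other cells
  default to UNAFFECTED.
- The imaging arm quantifies given or detected ellipses; it does not
  segment vacuoles, correct illumination fields, or handle overlapping
  cells.
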