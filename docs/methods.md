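# Methods

This note documents the models, conventions and design choices behind
`miaqsar`, in the order the pipeline runs them.

## Coordinates and image handling

Pixels are 0-based `(row, col)` internally, scanned row-major when
unfolding.  Drawing-convention coordinates (anchor sidecars) are 1-based and
width-first `(col, row)` — the convention in which the standard workspace is
quoted as "240 × 160" and the anchor as "110 × 80" — and are converted at
the I/O boundary, so the default internal anchor is `(79, 109)`.

Binarization thresholds the luminance at 0.5 of the intensity range and
then inverts polarity if the foreground would be the majority class, so
both dark-on-light exports and light-on-dark rasters end up with strokes as
foreground.  Anchors are supplied explicitly (generator metadata or a
sidecar CSV), never inferred by registration: anchoring on a chosen atom is
part of the method's definition, and automatic registration would be a
different algorithm.

Alignment is pure translation: pixels shifted out of frame are dropped,
vacated pixels become background, output dimensions are unchanged.

## Zero-variance filtering and centering

Columns constant across compounds carry no information and are removed
before modeling.  By default the filter is judged on the **training rows
only** and the same columns are dropped from prediction rows, so held-out
compounds never influence preprocessing; `filter_scope="all"` reproduces
the older convention of filtering the full matrix before splitting.
Columns are mean centered but not autoscaled, and the response is centered
but not scaled — binary pixels share a natural scale, and autoscaling would
blow up barely-varying columns.

## Kennard–Stone splitting

Classical maximin selection on Euclidean distances.  The pipeline computes
the split on the raw unfolded matrix: all-constant columns contribute
nothing to pairwise distances, so the split is identical to one computed on
the filtered matrix, while letting the filter itself remain training-only.
Ties (farthest pair, greedy step) go to the lowest row index, making the
split reproducible without a seed.  Centering does not change Euclidean
distances, so raw and centered splits coincide as well.

## SPA pixel selection

`build_chain` implements the projection chains by sequential deflation:
the residual matrix is deflated by the normalized residual direction of the
newest chain member, which is algebraically Gram–Schmidt; the test suite
checks it against an explicit QR-based oracle.  Chains stop early, with a
warning, at the matrix rank.  Columns with norm below 1e-12 are excluded as
starts.

`spa_select` scores every `(start, N)` candidate, `N ∈ [n_min, n_max]`, by
the validation RMSE of an intercept-included ordinary multiple linear
regression — the classical SPA scorer — and the winner minimizes that
score, ties resolved toward smaller `N` then smaller start index.  The
final reported model refits PLS on the winning columns (SPA-PLS).
Validation data for scoring is an inner Kennard–Stone split of the training
set (default 70/30), so the external prediction set is never touched by
selection.  Defaults `n_min = 2` and `n_max = min(20, n_inner − 2, p)`
(with `n_inner` the inner-training size) keep the regression determined
with a couple of residual degrees of freedom.

## PCR and PLS

Both calibrations are single-response and operate on centered data.  PCR
regresses the centered response on the leading principal-component scores
(SVD-based; the closed-form coefficients use the scores' orthogonality)
and folds the coefficients back to pixel space.  PLS is NIPALS with x- and
y-deflation; for a single response the weight of each component is the
covariance direction `X'y` in closed form, so the fit is deterministic with
no convergence tolerance.  If the response residual becomes orthogonal to
every column while predictors remain, the fit truncates with a warning and
the regression vector from the completed components (zero if none); true
rank exhaustion raises.  At full rank both methods coincide with ordinary
least squares, which the tests use as an oracle.  Exploratory PCA is
delegated to scikit-learn behind the same module surface.

Model selection is leave-one-out RMSECV (each fold re-centers on its 
remaining rows) followed by the Haaland–Thomas rule: among LV counts below
the curve's argmin, choose the smallest whose F = (RMSECV_h/RMSECV_min)²
falls below the F(n, n) quantile at 1 − α, default α = 0.25; otherwise the
argmin.  LOO is used because at ~23 training samples it is the standard
choice and removes a free parameter; candidates an individual fold cannot
support are skipped with a warning.

## Validation statistics

RMSEP and RSEP(%) follow their standard definitions (see README).  Q² for
the external set uses the **prediction-set mean** in its denominator; this
convention reproduces the published benchmark value shipped in
`miaqsar.benchmark` exactly, whereas the training-mean variant does not.
Percent errors are signed, negative meaning under-prediction.  Full
precision is kept internally; printed tables round to three significant
figures.  Note that statistics recomputed from the benchmark's printed
two-decimal predictions can differ from the study's own full-precision
values in the last digit (the recomputed SPA-PLS RMSEP is 0.159 against a
printed 0.160), and the benchmark's printed "REP (%)" row is not the RSEP
of the formula implemented here; the formula is authoritative.

## The synthetic generator

The generator emulates the statistical structure of a hand-drawn congeneric
series rather than chemically valid depictions:

- **Scaffold** — fused six- and four-membered ring perimeters plus two
  exocyclic bonds, rendered once per dataset geometry and stamped
  identically into every image, so scaffold pixels have exactly zero
  variance and the filtering stage is exercised deterministically.  The
  anchor pixel sits on the ring system and is foreground in every image.
- **Substituent regions** — three disjoint 16 × 16 boxes clear of the
  scaffold.  Per compound, each region receives one binary glyph from a
  seeded alphabet.
- **Glyphs = coverage levels × decorative variants.**  Each stamp is built
  from three disjoint layers: *feature strokes* — `ceil(log2(levels))`
  small cell groups (sizes `unit·2^j`) whose on/off pattern binary-encodes
  the stamp's coverage level, so the stroke cell count is exactly
  `unit × level`; a *decoration* of constant cell count (`round(lo·area)`)
  redrawn at random for every stamp; and background.  The realized fill
  fraction is therefore exactly affine in the coverage level, and the
  activity `y_i = Σ_r w_r · frac(i, r) + ε_i`, `ε ~ N(0, noise_sd)`, is a
  literal linear function of pixels whose noise-free value is recomputable
  from the stored truth.
- **Why this glyph design.**  It reproduces the regime that makes pixel
  selection worthwhile in real drawings: a handful of heteroatom-scale
  strokes carry the entire activity signal (as a single halogen dominates a
  pKa shift), while most pixel variance comes from activity-neutral
  drawing variation.  Six decorative variants per level push the matrix
  rank far above the training-set size, so an all-pixel latent-variable
  model faces an underdetermined, mostly irrelevant column space; the
  dense decoration (fills 0.82–0.94 of the box) keeps decoration-pixel
  variance well below feature-stroke variance, so SPA's norm-driven chains
  find the informative strokes.  With evenly spread fills or a low-rank
  alphabet, every varying pixel is informative, all-pixel PLS is
  near-optimal, and *no* selection method could beat it — a regime unlike
  the data this method is for.
- **Defaults as study conditions** — 31 compounds, 23/8 split, activity
  noise SD 0.05, three active regions with weights (10, 13.3, 8.3); the
  middle region is deliberately the most influential.  Weights are large
  because the coverage span per region is narrow (0.12), giving pKa-like
  activity spreads.

What the generator does **not** emulate: chemically meaningful shapes,
antialiasing or grayscale strokes, rotation/scale misregistration, and
activity contributions that are nonlinear in pixel coverage.  Passing tests
therefore demonstrate the pipeline's correctness and the selection
advantage in the linear-coverage regime, not performance on arbitrary real
drawings.

## Numerical conventions

- Rank decisions use a relative tolerance of 1e-12 on singular values;
  chain truncation uses 1e-10 of the largest column norm.
- Singular candidate regressions in SPA score +∞ rather than erroring.
- All randomness flows from a single integer seed through
  `numpy.random.default_rng`; reruns are byte-identical.
- Degenerate inputs (all-constant matrices, constant responses, zero-norm
  start columns, empty validation sets) raise informative `ValueError`s.

## Problem sizes

The shipped tests and the acceptance script run the full study design (31
compounds, 38 400 pixel columns, ~500–600 retained, 20 replicate seeds) —
the method's native scale; a replicate takes on the order of a second.
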