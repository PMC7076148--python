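# Methods

This note documents the statistical model behind `gridsurvey`, the
parameters that matter, the numerical choices made where the design was
genuinely open, what the synthetic generator does and does not emulate, and
the package's known limitations.

## The sampling frame as a random field

The frame is the set of settled grid cells on a regular geographic grid
(default resolution 3 arc-seconds = 1/1200 degree, roughly 90 m at the
equator). Cells are indexed `(i, j)`, 0-based, row-major from the
north-west corner; the cell rectangle is half-open —
`[x0 + j s, x0 + (j+1) s) x (y0 - (i+1) s, y0 - i s]` — so any point of the
plane belongs to at most one cell. A cell is *settled* when at least one
settlement polygon intersects its rectangle with positive area; a polygon
touching only an edge does not settle it (zero-area contact is not
evidence of habitation). Centroid-containment was the alternative rule; the
positive-area intersection was chosen because "presence of a settlement in
the cell" is the semantic being encoded, and it is monotone in the polygon
set.

Population counts are copied from a gridded population raster.
No-data population at a settled cell becomes 0 with a warning rather than
dropping the cell: the cell's settled status rests on the settlement layer,
and a zero count simply removes it from PPS draws (`pi(PPS) = 0`, weight
undefined) without breaking frame completeness. Negative counts are an
error.

## Contextual stratification

Covariate values are extracted at settled cells. Categorical variables are
expanded to *full* one-hot indicators (no dropped reference level): PCA is
insensitive to the induced collinearity and the symmetry across levels is
preserved. Missing continuous values are imputed by the column mean,
missing categories by the modal level — the simplest schemes that keep
every settled cell stratifiable; imputations are logged.

PCA is performed on standardized columns (correlation PCA). Covariates mix
units — meters, radiance, millimetres of rainfall — so covariance PCA
would let the widest-unit variable dominate. Zero-variance columns are
dropped with a warning before standardization. The retained count q is the
smallest number of components whose cumulative explained variance reaches
the threshold (default 0.9). Each loading vector's largest-magnitude entry
is made positive, fixing the sign indeterminacy so scores are reproducible
across library versions.

k-means (Lloyd's algorithm, k-means++ initialization, `n_starts = 25`
restarts) clusters the retained scores. The elbow scan reports, for each k,
the best WSS over the restarts *plus* one hierarchical candidate — the
previous best (k−1) centroids augmented with the farthest point, refined by
Lloyd iterations. Adding a centroid at a data point cannot increase the
optimum and Lloyd never increases WSS, so the scan is exactly
non-increasing in k rather than only up to restart noise. Elbow candidates
are ranked by perpendicular distance below the chord joining the endpoints
of the normalized WSS curve; an exactly linear curve yields no candidates.
The suggestion is advisory: the stratum count is a config input (default
k = 3), because the realism of the spatial pattern of the strata is a
judgement the analyst must make on a map, not a statistic.

Final strata are relabelled by descending mean cell population, so stratum
0 is always the most urban context and downstream reports are stable under
re-clustering.

## Probability scheme and draws

Within stratum S with m_S cells, n_S of which will be sampled:

    pi_i(S)    = n_S / m_S
    pi_i(PPS)  = X_i / sum_{j in S} X_j
    pi_i(SPPS) = pi_i(S) * pi_i(PPS)
    W_i        = 1 / pi_i(SPPS)

The PPS denominator is the *stratum* population total, so `pi(PPS)` sums to
1 within each stratum — sampling is performed per stratum independently. A
config switch (`denominator="frame"`) restores a whole-frame denominator
for designs written with a single global total. The composite `pi(SPPS)`
is used literally for the weights; note it is a probability scheme, not
necessarily the exact inclusion probability of any one draw mechanism (for
the classical stratified-PPS inclusion probability `n_S X_i / sum X`, scale
`pi(PPS)` by n_S).

Two mechanisms are provided. *Systematic PPS* (default for the field
design): cells ordered by cell id (row-major, giving implicit spatial
spreading; a flag randomizes the order), cumulative population computed,
and n_S equally spaced points with a random start select cells — without
replacement, since a survey team cannot visit a cell twice. A cell whose
population is at least the step `total/n_S` is selected with certainty, and
may legitimately be hit more than once; multiplicity is recorded, and the
number of draw points per stratum always equals n_S. *Multinomial PPS*
(used by the size simulation): n_S independent draws with replacement,
matching the single-draw probability exactly and allowing n beyond the
distinct-cell count.

## Estimator

The population ECDF and the design-weighted ECDF of a sample are

    F_m(x) = (1/m) sum_i I{X_i <= x}
    G_n(x) = sum_draws W_i I{X_i <= x} / sum_draws W_i     (normalized)

The literal inverse-probability form with a 1/n factor and raw weights
(`mode="as_printed"`) is retained for inspection, but it terminates at
`sum W / n`, which generally differs from 1 (vastly, when weights are
large); all KS computations therefore use the self-normalized (Hájek) form,
so D lives in [0, 1]. The Hájek mean over replicated draws is consistent
for F but carries O(1/n) ratio bias that grows with weight dispersion: on a
50-cell lognormal(2, 0.5) population the pointwise bias of the mean WECDF
at n = 10 is under 0.02, while at lognormal(2, 0.8) it reaches 0.035. The
pure Horvitz–Thompson form `(1/m) sum c_i W'_i I` with `W'_i = 1/(n p_i)`
is exactly unbiased at every n — the test suite verifies this against an
enumerated single-draw expectation — at the cost of not being a CDF
draw-by-draw.

The KS distance between two step functions is computed exactly: both
functions and their left limits are evaluated on the union of the two knot
sets. No grid approximation is used in the product path; dense-grid scans
appear only as independent test oracles.

## Sample-size simulation

For each stratum and candidate n, `reps` multinomial PPS draws are made,
the normalized WECDF of each draw is compared with the stratum's full ECDF,
and the arithmetic mean and sd of D across replications are recorded.
Defaults follow survey practice for this design: n scanned to 1000,
reps = 1000; the bundled tests and the acceptance script use a scaled-down
grid (n ≤ 500, reps = 100) with a thinned n-grid, dense where the curve
moves fast. Random substreams are derived deterministically per
(stratum, n), so any sub-curve is reproducible in isolation.

Selection takes the smallest n, *strictly after the argmax of the mean
curve*, whose mean distance meets the threshold (default D* = 0.15, within
the sensible 0.10–0.20 band). The argmax rule is the simplest reproducible
formalization of "discard very low sample sizes". If no post-peak n
qualifies, an explicit not-achievable result reports the minimum attained
mean distance — it is never silently clamped.

One finding is worth documenting. Mean-KS curves are often reported as
deceptively *low* at extremely small n, spiking, then decaying. With the
exact supremum this dip cannot occur: at n = 1 the normalized WECDF is a
one-point ECDF, so `D_1 = max(F(v-), 1 - F(v)) >= 1/2`, and empirically the
exact mean curve decreases from n = 1 at every skew level we tested. The
dip appears exactly when the supremum is restricted to the sampled values
(a common idiom: evaluating both CDFs only at sample points). A single PPS
draw almost surely lands on a high-population cell where both curves are
near 1, so the restricted maximum is tiny; as n grows, more of the support
enters the sample and the restricted maximum spikes before decaying.
`simulate_ks_curve(..., sup_mode="sampled_knots")` reproduces this
behaviour as a diagnostic; the product path always uses the exact sup. The
post-peak selection rule is robust under either mode.

When the selected n exceeds what a stratum can supply (small strata under
a strict threshold), the pipeline takes the stratum as a census — every
positive-population cell, `pi(S) = 1` — with a warning and a manifest
entry, since a field design cannot draw more cells than exist.

## Synthetic landscapes

The generator produces the statistical structure the design assumes:

- *autocorrelation*: log population intensity includes a stationary
  Gaussian random field, simulated as kernel-smoothed white noise
  (smoothing length = `correlation_range / 2` cells, periodic boundary);
- *trend/heterogeneity*: Gaussian urban-core kernels (`core_intensity`
  log-units at the centre, sd `core_decay` cells) create an urban–rural
  gradient;
- *discreteness*: settlement is per-cell Bernoulli with logistic
  probability in log intensity; population is `exp(log intensity)` on
  settled cells and 0 elsewhere;
- *context*: continuous covariates are `rho z(log intensity) +
  sqrt(1-rho^2) noise` with configurable correlation `rho` (default 0.6,
  alternating sign and heterogeneous scales across covariates);
  categoricals are quantile-binned smooth latent fields.

Each cell carries a ground-truth regime label (core / periphery / rural,
thresholded on the kernel field at 1/2 and 1/20 of the core intensity)
used as a clustering reference. Two fixtures are bundled: `tiny` (30×30,
~150 settled cells, 2 covariates) for unit-test speed, and `medium`
(200×200, ~8,000 settled cells, 8 continuous + 2 four-level categorical
covariates = 16 attribute columns, mirroring a ten-dataset covariate suite
across socio-economic, infrastructural, environmental, physical and
climatic classes). Settlement-logistic centres were set so the fixtures hit
those scales.

What the generator does *not* emulate: real settlement geography
(road-following ribbons, nucleated villages), covariate interactions beyond
a single latent intensity, measurement error in population rasters, and
the extreme skew of real city-block counts. Passing tests therefore show
the machinery is correct under the assumed structure, not that any specific
real frame would behave identically — in particular, real strata are
usually far more dispersed, which (as the tests show directly) increases
the sample size needed at a given KS threshold.

## Numerical and engineering choices

- Grid rasters are single-band WGS84 GeoTIFFs written and parsed via
  standard GeoTIFF tags (ModelPixelScale, ModelTiepoint, EPSG:4326 key
  directory) with `tifffile`; vector products are GeoJSON. Frame tables are
  CSV with a JSON sidecar holding the grid geometry, and round-trip
  exactly.
- k-means ties and convergence follow scikit-learn's Lloyd implementation
  (assignment-stability / 300-iteration cap).
- All pipeline stages draw from named substreams of one master seed
  (`stage_seed`), so identical config + seed yields byte-identical CSV
  artifacts and any stage can be replayed alone; the run manifest echoes
  config, seed, versions and row counts.
- Degenerate inputs are explicit: empty frames are rejected by every
  downstream operation, one-distinct-value strata are flagged on their KS
  curve, zero-population cells are flagged unsampleable, and an empty
  settlement collection yields an all-false mask.

## Limitations

- Second-stage (within-cell household) sampling, cell aggregation to
  enforce minimum population per unit, and spatially balanced or
  joint-inclusion-variance designs are out of scope.
- The composite weight `1/pi(SPPS)` is applied to systematic draws as the
  design prescribes even though the true inclusion probability of
  systematic PPS differs from the multinomial single-draw probability for
  cells near or above the step size.
- Stratification quality is bounded by what PCA + k-means can see; no
  spatial-contiguity post-processing is applied, so strata may be
  spatially fragmented ("salt and pepper") on noisy covariates.
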