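# Methods

This note documents the models and procedures `polycontact` implements, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the synthetic-data tests do and do not demonstrate.

## Polygon derivation

An individual's body (or visual field) is modeled as a rigid template — a
*planar model* with reference point `loc*` (the tag's position on the body),
forward direction `η*` (degrees counter-clockwise from +x, as are all angles
in the package) and one or more simple vertex rings with at least three
vertices. At each fix the template is mapped rigidly onto the plane: vertex
offsets `V* − loc*` are rotated by `η_it − η*` and added to the fix
location. This is algebraically the same as placing each vertex at distance
`d_l = ‖V*_l − loc*‖` and bearing `(θ*_l + η_it − η*) mod 360`, where
`θ*_l` is the angle of the vector from the reference point to the template
vertex; the rotation-matrix form is used because it makes the identity case
`η_it = η*` an exact translation in floating point and conserves edge
lengths to machine precision. Rigidity (edge lengths and area equal to the
template's) and rotation equivariance are enforced by tests at 1e-9 m and
1e-6 m respectively.

### Headings and the immobility threshold

Without gyroscopic data, the heading at time `t` is the angle of the vector
from the *anchor* — the location at which the pose was last updated — to the
current fix. The pose (position and orientation used for polygons) updates
only when that displacement is strictly positive and at least the immobility
threshold; otherwise the previous polygons are re-emitted unchanged. The
threshold discounts jitter such as head shaking or positional noise; 0.1 m
is a sensible default for livestock-scale RTLS, while 0.0 m (every observed
movement reorients the polygon) suits high-accuracy collar data driving
visual fields.

Two interpretation choices were open and are resolved as follows:

* **Anchor-based immobility.** The displacement is measured from the last
  *update* point, not the previous fix. Consecutive-step thresholds would let
  an animal drift arbitrarily far in sub-threshold steps without ever
  updating its pose; the anchor rule cannot.
* **Re-estimation after a freeze.** When a freeze ends, the heading is
  re-estimated from the anchor to the new fix (rather than reusing any
  pre-freeze heading); the anchor is precisely "the most recent previous
  location with a different coordinate pair" once sub-threshold fixes are
  discounted.

No heading — hence no polygon — exists before the first qualifying
relocation, so oriented series start at the second distinct fix at the
earliest. A single-fix track yields no polygons at all. Externally supplied
headings (e.g. from gyroscopes) can be passed by constructing the
heading-state table directly; nothing downstream distinguishes the source.

### Bundled models

`calf.json` is a three-part calf template: 0.333 m × 0.333 m head,
1 m × 1 m anterior and posterior body squares laid out along the forward
axis, with the reference point on the left ear (0.25 m left of the body
axis at the head/anterior junction). The along-axis arrangement and the ear
position are an approximation — the source imagery for calf body-section
layout is not numerically specified — so layout-sensitive analyses should
supply their own model JSON; all layout-sensitive tests in this repository
construct their models explicitly. `visual_100m_120deg.json` is the
binocular visual-field triangle: apex at the collar, 100 m height along the
forward direction, 120° apex angle (base half-width `100·tan 60° ≈ 173.2`
m, base angles 30° each), patterned on human binocular vision parameters.

## Threshold calibration

RTLS accuracy enters as a containment statement: a fraction `p` of fixes
fall within `δ` meters of the true location. Treating errors as independent
zero-mean Gaussians per coordinate, `σ = δ / Φ⁻¹((1+p)/2)`. Note the
quantile is one-dimensional and two-sided: `σ` is calibrated so each
*coordinate* is within `±δ` with probability `p`. The implied *radial*
containment is `1 − exp(−z²/2)` (≈ 0.74 for `p = 0.90`), not `p` itself —
an internal property of this conventional error model worth knowing when
comparing against field-measured accuracies. The synthetic generator uses
the same convention, and the test suite asserts the per-coordinate law.

Hypothetical in-contact pairs are sampled as `[x1, y1, x2, y2] ~
N([0, 0, 0, SpTh], σ²I)` and summarized by the observed pair distance. Two
estimator modes are provided because the natural-language definition of the
adjusted threshold ("upper 99% of the expected distance distribution") is
ambiguous:

* `mean_distribution_quantile` (default): the 0.99 quantile of the
  per-replicate *mean* distances (1,000 replicates × 1,000 pairs). Under the
  0.5 m / 90% model this concentrates tightly around 0.559 m (CLT: mean
  `s√(π/2)` plus 2.33 standard errors of a 1,000-draw mean, `s = σ√2`) and
  rounds to 0.56 m for every seed.
* `distance_quantile`: the 0.99 quantile of all pooled distances — the
  operational reading "a threshold capturing 99% of in-contact
  observations". For zero true separation this is the Rayleigh quantile
  `s√(2 ln 100) ≈ 1.31` m under the calf model.

The two differ by design: the first describes where the *expected* distance
lies, the second where *individual* observations lie. The coverage guarantee
("≥99% of true contacts captured") is a property of the second mode and is
tested as such. For the near-certain-containment GPS case (`δ = 0.26` m,
`p = 0.9999`, `z = 3.89`) the replicate-mean mode gives ≈0.123 m; the
published value for that system (0.109 m) is not reproducible under either
mode with `σ = 0.26/3.89` — the two published thresholds are not
proportional to their σ values, so no single procedure can satisfy both.
The discrepancy is documented rather than papered over: tests anchor each
mode to its own closed form (Rayleigh/Rice means and quantiles, the Rice
mean obtained by numerical quadrature) within three Monte Carlo standard
errors, and no assertion targets 0.109 m.

## Contacts, bouts and networks

Distances are minimum Euclidean separations between shapely geometries
(zero on intersection or containment), computed per timestep for the
requested part pairings; self-pairs are excluded, and for asymmetric
undirected pairings (head↔posterior) both part-to-part combinations are
evaluated and later folded into one undirected edge. Contact is inclusive
(`distance ≤ SpTh`), which makes the SpTh = 0 "precise" definition exactly
polygon intersection and guarantees the nesting precise ⊆ expected. The
"expected" network is realized by enlarging SpTh rather than buffering
polygons — the two framings are equivalent for distance-based contact and
the distance form is exact.

A missing fix yields no distance record (never a zero), and by default
breaks any ongoing bout; `max_gap > 0` merges runs separated by at most that
many absent/non-contact timesteps, in which case a bout's `n_timesteps`
counts its in-contact timesteps only. Edge weights are total in-contact
timesteps (not bout counts): at 10-s resolution over 24 h this is the only
reading that yields per-capita sums in the thousands, i.e. "contact
frequency" at grid resolution. Degree counts distinct partners within the
given network; daily degree splits on UTC calendar days. Sample standard
deviations (ddof = 1) are reported throughout. The directed visual network
adds an instantaneous out-degree time series (individuals visible per
timestep).

## Null models and comparisons

`randomize_paths` cuts each individual's series into consecutive blocks of
`block_length` timesteps and permutes the block order uniformly; timestamps
stay on the grid while location (or polygon) blocks move, so each
individual's location multiset, record count and timestamp set are exactly
preserved. This is one member of the family of trajectory-permutation
null models in the movement-ecology literature; a second variant permutes
same-time-of-day blocks across days (preserving diel structure; it assumes
equal per-day record counts). Stage matters for polygons: permuting fixes
*before* derivation randomizes the recomputed orientations, permuting the
derived series *after* keeps empirical orientations — both are implemented
and the choice is an a-priori analysis decision.

The Mantel test correlates off-diagonal entries under simultaneous
row/column permutation, two-sided, with the +1 correction
`p = (#{|r_perm| ≥ |r_obs|} + 1)/(n_perm + 1)` so p is never zero; a
zero-variance matrix returns a flagged NaN rather than an arbitrary sign.
The implementation is seeded and is cross-checked against an independent
library implementation of the statistic in the tests. The χ² goodness-of-fit
test pools non-positive-expectation cells into the smallest valid cell and
uses df = k−1 after pooling; its type-I calibration is verified under a
conserved-total (multinomial) null, the sampling model for which that df is
exact.

## Synthetic data

The generator emulates: fixed-interval fixes (1–10 s grids), correlated
random walks (wrapped-normal turning parameterized by mean resultant length,
normal step lengths truncated at zero, reflective arena boundaries),
Gaussian positional error with the containment parameterization above, and
scripted events that hold a pair at a fixed separation over a known window.
It does not emulate behavioral realism — no social attraction, foraging
states, habitat preference, or autocorrelated/spatially correlated error —
so passing tests demonstrate correctness of the geometry, calibration and
aggregation machinery, not ecological validity on real herds or troops.

Four scripted scenarios have closed-form ground truth and drive the
end-to-end tests: `converge_pair` (one 500-step point-contact bout,
seconds 200–699 of a 1,200-step run, with 0.5 m/90% noise), `parallel_walk`
(two walkers 0.4 m apart for 600 steps, threshold 0.5 m), `head_to_tail`
(nose-to-tail followers 2.6 m apart; at the 0.56 m threshold contact occurs
only in the head↔posterior pairing, 499 oriented timesteps) and
`visual_crossing` (a leader 50 m ahead is inside the follower's 100-m visual
triangle at all 299 oriented timesteps; the reverse edge never exists). The
recovery property — calibrate at the 99% distance quantile, then detect on
noisy data and recover ≥99% of scripted contact timesteps (within binomial
error) — is tested on `converge_pair`.

Problem sizes in the test and acceptance runs (10⁶ calibration pairs, 10⁵
coverage draws, scenario runs of 300–1,200 timesteps, Mantel tests at
10²–10³ permutations with the full 10⁴ used only where the p-value precision
is asserted) were chosen so the Monte Carlo error is far below every
asserted tolerance while the whole suite runs in well under a minute.

## Numerical conventions and edge cases

* Angles: degrees, CCW-positive, 0° = +x, reduced mod 360.
* Timestamps: UTC, integer epoch seconds; grids are `[start + k·interval)`.
* Planar projection: spherical azimuthal equidistant, mean Earth radius
  6,371,000 m, centered on the data centroid by default; preserves
  center distances exactly (verified against a haversine oracle at 0.01%),
  and rejects records at the poles or the center's antipode where the
  projection is singular.
* Duplicate fixes: first occurrence by file order wins. Speed filter:
  single forward pass anchored at the last retained fix, so one bad fix
  does not cascade. Confinement: boundary-inclusive.
* Quantiles: NumPy's default linear interpolation on order statistics.
* All stochastic routines accept either an integer seed or a
  `numpy.random.Generator`; identical seeds give identical results.

## Known limitations

* Rigid templates only: no shape morphing or per-timestep model switching;
  multi-part models share one reference point and heading.
* 2-D only; no visual-obstruction modeling (a visual "contact" is a
  point-in-triangle event, not confirmed gaze).
* Great-circle distances are supported for point data only; polygon
  workflows require projected planar coordinates.
* The across-days randomization variant assumes equal per-day record
  counts per individual.
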