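# Methods

This note documents the models and procedures `forestcc` implements, the
parameters that matter, what the synthetic scene generator does and does
not emulate, and the numerical choices made where the design was open.

## Grid model and area accounting

All rasters live on an abstract equal-area grid: square pixels of side
`pixel_size_m`, row-major from the top-left, pixel-center coordinates,
one band per calendar year for annual stacks. Equal area is what licenses
the two accounting conventions:

* **binary** — area = labelled-pixel count × pixel area (km²), used for
  products that label whole pixels changed;
* **sub-pixel fractional** — area = Σ |Δcover|/100 × pixel area, used for
  percent-cover products and for fine binary products aggregated to
  percent-of-change.

The two conventions meet exactly at scale changes: aggregating a fine
binary map to a percent map with `aggregate_fraction` and accounting it
fractionally reproduces the fine binary accounting to machine precision
(same summands regrouped). The same regrouping argument makes provincial
tables conserve national totals exactly; pixels with no province ID are
reported in an explicit `unassigned` row rather than dropped. National
coverage percentages divide by a configurable land area, default
9.6 × 10⁶ km² (the conventional land area of China); reported values are
rounded to the printed precision with Python's round-half-even.

## Temporal segmentation detector

For each pixel the annual index series is processed in three stages.

**Despiking.** An interior point is replaced by the mean of its two
neighbours when (i) it pokes above or below both neighbours, (ii) its
deviation from their mean exceeds `despike_threshold` × the local 3-point
range, and (iii) the two neighbours agree with each other to within the
same fraction of the local range. Condition (iii) is the package's
dampening guard: a genuine one-year spike returns to its level, so its
neighbours are similar, whereas at the edge of a persistent step the
neighbours straddle the step and the point is preserved. Without the
guard, the last pre-disturbance year of an abrupt loss is frequently
"corrected" halfway down the step whenever noise makes its predecessor dip,
which blurs the fitted edge and costs several points of recall. Endpoints
are never touched; series shorter than 3 pass through.

**Fitting.** The model is a continuous piecewise-linear function anchored
at a vertex-year subset that always includes both endpoints. For a fixed
vertex set the optimal vertex values are a linear least-squares problem on
"hat" (tent) basis functions, solved by pseudo-inverse; operators are
cached per vertex set. Vertices are chosen greedily top-down: starting
from the endpoints-only line, each step adds the interior year whose
inclusion most reduces the SSE, stopping at `max_segments` segments, or
when the relative SSE improvement falls below `mse_improvement_min`, or
when the fit is already exact. A refinement pass then improves the vertex
*positions*: coordinate descent relocates each interior vertex within its
neighbour span, and a remove-and-reinsert move drops one vertex and
re-adds the globally best replacement (letting a vertex jump across its
neighbours). Both moves strictly decrease SSE, so the loop terminates.
Plain greedy alone is not exact on all noiseless piecewise-linear inputs —
the first split can land between two true breakpoints and trap the later
ones — and the refinement repairs exactly that failure mode: on the
enumerated family of all noiseless piecewise-linear series of length 14
with ≤ 3 segments, the refined greedy fit matches exhaustive search (SSE
0) on every case, at a small fraction of exhaustive cost. On noisy input
greedy remains an upper bound on the optimal SSE, which is the property
the classifier needs. An exhaustive-enumeration fitter is retained as the
test oracle and is never used in the pipeline path.

**Classification.** Segments with fitted |Δvalue| ≥ `change_threshold`
are change candidates; the largest-magnitude candidate (earliest on exact
ties, for reproducibility) decides the label. A negative candidate is
**loss** only if its start value is ≥ `forest_threshold` (it was forest);
a positive candidate is **gain** only if its end value is ≥
`forest_threshold` (it became forest); otherwise the pixel is unchanged.
The change year is the decisive segment's end for loss and start for gain.
Because the decisive candidate is the global maximum-magnitude segment,
raising `change_threshold` can only remove labels, never add or alter
them — the monotonicity the sweep tests assert is exact, not statistical.

**Cube processing.** Missing years are linearly interpolated when no gap
exceeds 2 consecutive years and both endpoints are present; otherwise the
pixel is labelled unchanged and flagged in a QA layer. The independent
forest mask suppresses loss labels outside the forest domain. Gain labels
are kept outside the mask by default, since afforestation occurs on
previously non-forest land; a `mask_filters_gain` flag applies the mask to
both directions for users who read the mask's role strictly.

### Detector defaults

| parameter | default | units | rationale |
|---|---|---|---|
| `forest_threshold` | 0.40 | index | mid-range between the bare (0.05) and forest (0.60) index levels |
| `change_threshold` | 0.15 | index | ≈ 27% of the forest–bare contrast; well above noise (σ ≈ 0.02), well below real events |
| `max_segments` | 4 | — | one disturbance plus recovery plus margins within a 14-year series |
| `despike_threshold` | 0.5 | fraction | a spike must claim half the local range |
| `mse_improvement_min` | 0.01 | fraction | stop splitting when a vertex buys < 1% SSE |

These are exposed in configuration and swept by the sensitivity module;
results are parameter-sensitive by nature and the defaults claim only to
be reasonable mid-range choices for an NBR-like index.

## The three map-based recipes

* **Categorical (post-classification).** Stable maps are per-pixel modes
  over a window (defaults 2001–2003 and 2010–2012); ties break to the
  class observed latest in the window (favouring recency; a lowest-code
  rule is selectable). Loss is forest→non-forest between the two stable
  maps under a class-set definition; gain is the reverse. Forest codes
  default to the five standard IGBP forest classes (codes 1–5); the
  widened definition adds woody savanna (code 8).
* **Fractional.** Period means over windows (defaults 2000–2002 and
  2011–2013) ignoring missing years; change is the signed difference,
  any strictly non-zero delta counting as change (an epsilon guard is
  configurable, default 0).
* **Annual-loss accumulation.** Logical OR of fine binary loss layers over
  the span, aggregated to percent-of-change at the analysis resolution;
  gain arrives as a single whole-period layer and is aggregated the same
  way.

## Scaling and resampling

Only block-aligned integer-factor changes are supported: a coarse cell
covers exactly factor × factor fine pixels, which is how the products in
this analysis nest and avoids sub-pixel registration questions. Five
kernels: nearest (sample at the coarse-cell centre), average (block mean,
nodata-aware), mode (block majority, ties to the smallest code), bilinear
and cubic (separable interpolation at coarse-cell centres; the cubic is
Catmull-Rom, a = −0.5, edge-clamped and clipped to the input range — any
standard cubic would serve, and the tests pin this one against an
independent naive implementation). Bilinear, average and cubic are
rejected for categorical data with an explicit error.

The scaling experiment runs both orderings. *Change-then-scale* resamples
per-direction binary change maps as 0–1 fractions and accounts them
fractionally; averaging is then exactly area-preserving by linearity.
*Scale-then-change* resamples the period cover maps first and extracts
change from the resampled maps; gross loss and gain are rectified (one-
sided) sums, so co-located gain and loss cancel inside coarse blocks and
the estimates move substantially across kernels. This asymmetry — not any
property of a particular kernel — is what makes the ordering matter, and
it only appears when scenes contain both signs of change. Block majority
collapses scattered change in either ordering and is reported but not
informative in that regime.

## Agreement and correlation

Per-direction binary maps (label maps pass through; fractional maps flag
strictly non-zero deltas of the requested sign) are summed per pixel into
agreement levels 0–n, banded none (0) / low (1–2) / high (3–4), with
level n = 4 additionally marked full. Composition tables report, for each
dataset, the share of its flagged pixels at each level.

Provincial correlations use coverage percentages (areas divided by
provincial land area). Significance is a two-sided t-test at the 90%
level, t = r√((n−2)/(1−r²)) with df = n−2; two-sided is the conservative
reading of an unspecified sidedness and is configurable. The weighted
variant uses weights normalised to sum 1 in the means, covariance and
variances, and takes its degrees of freedom from the Kish effective
sample size n_eff = (Σw)²/Σw², so the result is invariant to rescaling
all weights; with equal weights it reduces to the plain r to machine
precision. Provinces missing from either table are excluded pairwise. An
inventory-style dataset that reports only net change participates only in
net-change matrices.

## Synthetic scene generator

The generator's role is to provide ground truth for every downstream
stage, with the event classes the detector is meant to distinguish:
stable forest, stable non-forest, abrupt loss (cover drops by `magnitude`
at the event year), gradual gain (cover ramps at `ramp_rate` per year
until saturation), and loss-then-recovery (drop, then linear regrowth).
Event kinds are i.i.d. per pixel with configured proportions; event years
are uniform over the interior of the span, never at the endpoints, so a
detector always has an observation on each side. Default magnitudes
(loss 0.8, gain 0.7 of cover), ramp (0.07/yr ≈ a decade to regrow), index
levels (forest 0.60, bare 0.05), and noise (index σ 0.02, cover σ 3%,
label flip 5%) are plausible mid-range values for an NBR-like index over
temperate forest; tests depend on clear separation, not on the specific
numbers.

Rendering: the index cube is affine in true cover plus i.i.d. Gaussian
noise, clipped to [−1, 1]; the categorical series thresholds cover at 60%
(the canopy-cover convention of the IGBP forest classes) with independent
label flips; the percent-cover product replicates truth to a finer grid
(default 2×) with Gaussian noise clipped to [0, 100]; the fine binary
product (default 16× finer) flags loss in the year a parent first crosses
below the forest threshold and gain as a single whole-period layer, plus a
baseline first-year cover layer. Provinces are a rectangular block
partition with land areas from pixel counts.

Deliberately **not** emulated: spatial autocorrelation of noise or of
events (every statistic exercised here is pixel-wise or sum-based), cloud
and gap patterns, sensor-specific radiometry and BRDF effects, and
classification confusion structure beyond symmetric label flips. Passing
tests therefore demonstrate algorithmic correctness and the scaling/
definition mechanisms on known truth — they do not certify accuracy on
real imagery, where autocorrelated noise and systematic classifier errors
can violate the i.i.d. assumptions.

## Numerical choices and degenerate inputs

* Piecewise-linear fits use `numpy.linalg.pinv`; an exactly fit series
  (SSE ≤ 1e-24) stops vertex addition immediately, so constant and
  single-line series return one segment.
* Vertex-set operators are cached (`lru_cache`, 4096 entries) keyed by
  series length and vertex tuple.
* Zero-variance vectors make Pearson r undefined: reported as NaN and
  not significant rather than raising.
* Mode ties resolve to the smallest class code; stable-map ties to the
  most recent class (both documented, both configurable where exposed).
* All-missing aggregation cells propagate as NaN/nodata; means never
  invent data.
* Seeds: every stochastic stage takes an explicit seed; the pipeline
  derives stage seeds from the run seed by a fixed affine map modulo
  2³¹ − 1, so runs are bit-reproducible and stages are decoupled.

## Problem sizes

Tests and the acceptance script use scenes from 10×10 to 100×100 pixels
over 14 years, with the segmentation oracle family enumerated at series
length 14 and ≤ 3 segments (237 cases). These sizes were chosen so the
full suite exercises every code path in a few minutes on a single CPU;
all statistics of interest (recall, false-positive rate, conservation,
monotonicity) are already stable at these sizes under the fixed seeds.

## Known limitations

* The detector fits one index; multi-index or multi-season fitting is out
  of scope.
* Only block-aligned integer resampling factors are supported; no
  arbitrary-CRS warping.
* The greedy-plus-refinement fitter is exact on noiseless piecewise-linear
  input and an upper bound otherwise; it does not guarantee the global
  optimum on noisy series (the classifier only needs the decisive-segment
  geometry, which is robust to that gap).
* Significance tests assume independent provinces; no spatial
  autocorrelation correction is applied.
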