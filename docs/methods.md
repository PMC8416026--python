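# Methods

## Contact probability decay, P(s)

For a binned contact matrix, the curve is computed per log-spaced distance
bin *k* as P_k = (O_k / N_k) / Z: O_k is the summed (optionally balanced)
contact weight at bin separations s = (j − i) · bin_width falling in the
bin, N_k the total possible number of locus pairs at those separations
(matrix elements; restricted to bins with valid balancing weights when
weights are applied), and Z = Σ O_k the total interaction count, so curves
from different sequencing depths are directly comparable.  Chromosomes are
pooled (O and N summed) before dividing, giving the genome-wide average
curve; per-chromosome curves are available by passing a chromosome subset.
In pair mode the same formula runs at bp resolution, with
N_k = Σ_c Σ_{s∈bin} (len_c − s) evaluated in closed form.

Distance bins are geometric, e_k = s_min · 10^(k / bins_per_decade), default
8 bins per decade over 1 kb – 100 Mb.  Each bin also carries an *effective*
separation — the possible-pair-weighted mean s within the bin — used as the
derivative abscissa; at small s, where a log bin holds at most one matrix
diagonal, this removes the systematic wiggle that geometric midpoints would
introduce.  Log bins narrower than the matrix bin width are simply empty and
flagged invalid rather than rejected, since the canonical 1 kb lower edge is
useful for pair-level input at the same call site.

### Balancing

Iterative correction equalizes the matrix marginals: counts are repeatedly
divided by their row/column marginal factors until the variance of the
scaled nonzero marginals around 1 falls below `tol` (default 1e-5, max 200
iterations).  The first two diagonals are masked by default — excluded from
the marginals and dropped from balanced output — to avoid re-ligation
artifacts near the main diagonal; bins with zero marginal get NaN weights.
Balancing is per chromosome, since every downstream quantity here is
cis-only.  Non-convergence returns `converged=False` with a warning rather
than raising, so long pipelines can log and continue.

## Derivative and the loop/layer estimators

The raw slope is the central difference of log₁₀ P versus log₁₀ s over
consecutive valid bins, which is exact for power laws regardless of bin
spacing.  The smoothed slope is a locally weighted linear regression
(tricube weights, degree 1) of the raw slope over log₁₀ s, window fraction
`loess_span` (default 0.3; no span is canonical for this analysis, and 0.3
suppresses bin-level noise without flattening the layer drop).

* **Loop size L**: s at the maximum of the smoothed slope within
  10 kb – 1 Mb.  Ties break toward smaller s (the conservative estimate);
  a flatness flag is raised when (max − median) of the windowed slope is
  below `flat_eps` (default 0.02), since a flattened peak — expected when
  loop sizes are broadly dispersed — makes the point estimate coarse.
* **Layer size D**: s at the minimum of the smoothed slope within
  1 – 100 Mb, the point of steepest log-log decay at the inter-layer
  falloff.  A minimum at the window boundary (as for a monotone power law)
  is flagged unreliable.
* **Loops per layer**: n = D / L, reported only when both are detected.

Grid extrema are refined with a three-point parabola in log₁₀ s, so
estimates are not quantized to the 1/8-decade bin grid; extrema at window
edges are returned unrefined with the boundary flag set.

## The loop-layer contact-map generator

The simulator provides ground-truth calibration targets for the estimators.
Rather than stitching power-law segments — whose log-log slope is a monotone
staircase with no localizable extrema — the model parameterizes the slope
directly in the shape observed for rod-like mitotic chromosomes:

σ(x) = −α_layer + (α_layer − α_loop) · G(x; log₁₀ L, w_L)
              − (α_inter − α_layer) · G(x; log₁₀ D, w_D),

with x = log₁₀ s and G a unit-height Gaussian.  The slope equals −α_loop
(default 0.5) exactly at the mean loop size, −α_layer (0.6) on the
intra-layer plateau, and −α_inter (3.0) exactly at the layer size D = n·L,
recovering toward the plateau beyond the drop as measured curves do when
they flatten onto the background contact floor.  The knee widths (decades of
s) stand in for loop-length dispersion: an exponential loop-length
distribution spreads its log-scale density by roughly a third of a decade,
hence the default w_L = 0.30; w_D defaults to 0.20.  Because the extrema of
σ sit exactly at (L, D), parameter recovery is well defined: the estimators
are judged against the model's stated knees, not against a quantity that
itself needs estimating.

P*(s) follows by integrating σ on a fine log grid and normalizing.
Contacts are drawn by inverse-CDF sampling of P*(s) × (number of admissible
locus pairs at s) — P* is a per-pair contact probability, so the observed
count density must carry the (len − s) availability factor; omitting it
would make the estimated P(s) = O/N diverge from P* at large s — and a
uniform admissible position.  Sampling is reproducible bit-for-bit under a
fixed seed.

What the generator does **not** emulate: bin-level coverage biases (so
balancing is exercised on separate fixtures, not needed for recovery runs),
trans contacts, compartments/TADs, sister-chromatid structure, and
mechanistic loop extrusion.  Passing recovery tests therefore demonstrates
that the estimators read the knee scales out of a three-regime decay at
realistic depth and noise — not that any particular biological sample has
those scales.

Default study conditions for recovery runs: one 100 Mb chromosome, 5 × 10⁶
contacts, 10 kb bins, exponents 0.5 / 0.6 / 3.0, ten seeds per condition;
medians are reported across seeds.  These sizes keep a full recovery run in
minutes on one CPU while leaving per-bin counting noise in the loop decade
well below the bump height.

## Imaging quantifications

**Segmentation** is Otsu's threshold (between-class variance maximization
over a 256-bin histogram) with the most permissive connectivity
(8-neighbor in 2D, 26 in 3D), merging touching chromatids into one mass as
the cluster concept implies.

**Immunofluorescence ratios**: the z-slice with maximal total DNA intensity
is selected; the background — the median intensity outside a 10-px-dilated
provisional DNA mask, a parameter-free robust choice — is subtracted from
both channels (clamped at 0); the DNA mask is rebuilt by Otsu; each
connected mass reports mean(marker)/mean(DNA).  Ratios are invariant to
common rescaling of both channels.

**3D surface area**: the DNA volume is linearly interpolated along z to
67 nm slice spacing (a stack of nz slices spanning (nz−1)·z_nm yields
ceil(span/67)+1 slices), Otsu-thresholded, and labeled; components of
10,000 voxels or fewer (interpolated-grid voxels) are discarded.  Surface
area is the marching-cubes mesh area of the mildly Gaussian-smoothed binary
mask (σ = 1 voxel) in physical units — the smoothing recovers sub-voxel
isosurface accuracy, bringing a digital sphere within ~1% of 4πr² where the
raw binary mesh overestimates by ~8%.  An exposed-voxel-face mode is
available as an upper-bound fallback.  The headline statistic is surface
area per unit integrated DNA intensity, making clusters of different DNA
content comparable.

**CENP-A foci / individualization**: DNA and CENP-A are thresholded
independently; foci are connected components of the spot mask, with
centroids closer than 3 px merged so a sister-centromere doublet counts
once; each focus is assigned to the DNA mass containing its centroid
(centroid membership avoids double assignment at touching boundaries).  A
mass with fewer than four foci is individualized; the individualization
frequency is 100 × (individualized / total), per replicate when replicate
ids are present.  Foci were counted on the maximal-DNA 2D slice by default
(a 3D mode exists), matching how such coverslip data are scored.

Three detection-hygiene defaults make the spot counter robust at realistic
noise: the spot channel is pre-smoothed with a 1-px Gaussian before
thresholding (read noise is pixel-scale, foci span several pixels),
components under 2 px are rejected as specks, and candidate foci must peak
at least 5 robust (MAD-based) noise standard deviations above the channel
median — without this, Otsu on a signal-free channel splits the noise floor
and reports spurious foci.  All three are exposed as parameters.

## Synthetic image scenes

Masses are ellipsoids or curved tubes (spheres swept along a smooth spline,
mimicking elongated chromosomes); foci are 3D Gaussian spots planted inside
a named mass; the marker channel is the DNA signal scaled by a known
per-mass ratio; noise is Gaussian read noise (clamped at zero) with optional
Poisson shot noise.  Scenes that would place two masses in the same voxel
are rejected, since ground-truth labels would be ambiguous.  The truth table
carries voxel counts, analytic ellipsoid volumes and Knud-Thomsen surface
areas, planted focus counts, and marker ratios.  Default spacings mirror
wide-field acquisition at 100×: 200 nm z-sections, 65 nm xy pixels, so the
67 nm interpolation path is exercised.  SNR is amplitude over noise sigma;
at SNR 10 with foci separated by ≥ 3 detection sigmas, counting is exact;
at lower SNR detection degrades by missing or merging spots rather than
hallucinating them (the significance floor removes noise-only candidates).

## Grouped statistics

Within a replicate, conditions are compared by a two-tailed Mann-Whitney
U test: U = min(U_a, U_b) (stated in output headers); with ≤ 20 values per
group and no ties the p-value is exact — the permutation probability that
min(U) is at most the observed value, computed from the exact U null
distribution — otherwise a normal approximation with tie and continuity
corrections is used.  Across replicates, values are first normalized so the
control median is exactly 1 in every replicate (idempotent), each replicate
contributes its median, and conditions are compared with an unpaired
equal-variance Student's t-test on those medians ("Student's" rather than
Welch, as is conventional for this design; the equal-variance choice is a
documented toggle away in scipy if needed).  Degenerate inputs are handled
explicitly: identical pooled samples give p = 1, and zero pooled variance
with unequal means is flagged rather than reported as an infinite t.

## Numerical conventions and degenerate inputs

* Bins are 0-based half-open; pairs positions are 1-based (the pairs-text
  standard); conversion is (pos − 1) // bin_width.  Strand fields are
  parsed and discarded.
* Multi-resolution cooler containers are rejected with the resolution path
  named; single-resolution containers round-trip losslessly, including
  weights and the masked-diagonal count.
* Curve tables round-trip at 12 significant digits.
* `derivative` requires ≥ 3 valid bins; windows without valid points raise;
  empty masks raise in `quantify_if` but yield zero-count records in foci
  counting (a mass with no foci is simply individualized).
* The interpolated-volume voxel budget (default 4e8) guards against
  accidental memory blowups from very fine z-interpolation targets.

## Known limitations

* The generator's knee widths are free parameters of the calibration, not
  measured biology; estimates on real data inherit whatever dispersion the
  sample has, and a flattened peak (flagged) means the loop-size point
  estimate is coarse.
* Layer-size detection assumes the derivative recovers after the drop
  within the search window; a chromosome-scale drop at the window edge is
  flagged unreliable rather than silently reported.
* Surface areas use a mesh estimator; absolute values differ by a bounded
  factor from voxel-face or region-properties conventions, so comparisons
  should stay within one convention (relative comparisons are what the
  assays use).
* The Mann-Whitney exact path requires tie-free data; tied data fall back
  to the corrected normal approximation regardless of sample size.
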