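# Methods

## Scope and model

`dmnconnect` implements the ICA + template-matching workflow for
resting-state default-mode-network (DMN) connectivity: per-participant
spatial ICA of conditioned BOLD series, automated selection of the DMN
component by a goodness-of-fit statistic against a group template, and
between-group voxel-wise inference with empirical (Monte-Carlo)
cluster-extent family-wise-error control. Because raw human scans are not
part of the package, a synthetic-data module generates cohorts whose
generative structure matches the assumptions of the analysis, so that
selection accuracy, calibration and power are measurable quantities.

All images live on one common grid (default 30×36×30 voxels at 3 mm
isotropic — an analysis-resolution, desk-scale stand-in for a normalized
brain volume) with a RAS+ affine; world coordinates are reported as
X left→right, Y posterior→anterior, Z inferior→superior, in mm.
Registration, slice-timing and motion *estimation* are out of scope:
synthetic data are generated already aligned, and motion enters only as a
known confound table.

## Synthetic cohorts

Each participant's series is a linear mixture

    y(x,t) = Σ_k a_k · w_k · M_k(x) · c_k(t)  +  Σ_j g_j(x) · m_j(t)  +  ε(x,t)

- `M_k`: nonnegative network weight maps, unions of Gaussian lobes placed
  in separated sub-regions of an ellipsoidal brain mask. Map 0 is
  "DMN-like": seven disjoint lobes (posterior-cingulate-, medial-
  prefrontal-, bilateral-parietal-, hippocampus-, dACC- and caudate-like
  nodes). Lobe centres get a sub-voxel seeded jitter, widths ±10 %.
  Pairwise spatial correlation between network maps stays below 0.2.
- `c_k`: band-limited (0.01–0.08 Hz) unit-variance courses, built by hard
  band-passing white noise and QR-orthogonalizing, so they are mutually
  orthogonal and entirely in-band.
- `w_k ~ N(1, 0.1)`: per-subject multiplicative weight jitter, which makes
  between-subject variances non-degenerate.
- Motion: six smooth random walks (translations mm, rotations deg). They
  leak into the data as motion-correlated drift with near-uniform spatial
  gain (0.30·σ_noise per regressor, modulated ±25 % by a smooth random
  field, random sign). The leak scales with the noise level, so the
  noiseless limit is an exact low-rank mixture.
- `ε`: i.i.d. Gaussian noise, SD 2.0 by default.
- Group effect: inside named target regions (the cores of the
  hippocampus-, dACC- and caudate-like lobes), cohort A's DMN map is
  scaled by (1 + direction·magnitude); defaults +0.5, −0.5, −0.5.

Default cohort design: 14 vs 13 participants, 180 frames at TR 2 s (a
six-minute run), target ICA model order 25.

### Why these noise defaults

Two error mechanisms bound how well any analysis can recover `M_k` from a
*variance-normalized* series:

1. **Saturation.** After per-voxel normalization the recoverable map shape
   is `a·M(x)/σ_tot(x)`; where the signal dominates the denominator the
   map saturates toward a support indicator. Mild saturation requires the
   non-signal variance to stay comparable to the signal's.
2. **Estimation floor.** The per-voxel map-estimation error is
   `√(white-noise fraction of voxel variance) / √n_frames` — notably
   *independent* of the absolute noise level, because normalization pins
   total variance at 1.

The floor is lowered only by shrinking the white fraction of the voxel
variance with structure that the pipeline can remove exactly — which is
precisely what the dominant, regressable motion/drift term provides. Its
spatial gain is kept near-uniform because a strongly spatially varying
nuisance variance would warp the normalization denominator and hence the
recovered map shape. With these defaults the best-fit linear
reconstruction of the DMN map from a smoothed series correlates > 0.9
with the planted map, and ICA reaches that bound to within 1–3 %.

What the generator does **not** emulate: physiological (cardiac/
respiratory) noise, scanner physics (k-space, slice timing,
susceptibility), nonlinear hemodynamics, spatial non-stationarity of
noise, inter-subject anatomical variability or registration error.
Passing tests therefore demonstrate correctness of the *procedure* under
its own model assumptions, not performance on real scans.

## Preprocessing

Order: spatial smoothing → temporal normalization → nuisance regression →
band-pass of the residuals.

- **Smoothing**: frame-wise isotropic Gaussian, FWHM 6 mm (field-standard
  at 3 mm voxels; configurable). FWHM is converted per axis via the
  affine's voxel sizes, so anisotropic grids smooth isotropically in
  world space. Boundary handling is plain zero-padded convolution;
  reflective padding (which preserves the frame-wise sum) is available
  via `mode="reflect"`.
- **Temporal normalization**: per-voxel z-scoring (mean 0, sample SD 1).
  A percent-signal-change variant is exposed as `normalize.mode = psc`.
  Zero-variance voxels are set to zero and logged, never NaN.
- **Nuisance regression**: least-squares residual on
  [intercept | motion table] per masked voxel, via a QR projection. The
  operation is idempotent and its output orthogonal to every design
  column; rank-deficient designs fail with the collinear columns named.
- **Band-pass**: discrete-Fourier hard cutoff — every rFFT bin outside
  [0.01, 0.08] Hz, including DC, is zeroed. Exactly linear, phase-free,
  testable bin by bin; a 0.04 Hz sinusoid at TR 2 s/180 frames is
  preserved to within 1 % amplitude, a 0.2 Hz sinusoid suppressed below
  1 % power.

## Spatial ICA

The masked series (t×V) is reduced to the requested model order by PCA
and whitened; the fraction of variance retained is reported (≥ 0.7 on
synthetic data at defaults). Unmixing is a **deflationary one-unit
fixed-point iteration with the kurtosis (cube) contrast**, voxels as
samples:

    w ← E[y (wᵀy)³] − 3w,   Gram-Schmidt against extracted rows, normalize

Each component has its own convergence test (|⟨w⁺, w⟩| within 1e-4 of 1,
at most 200 iterations) and a budget of 3 random restarts. Extraction
stops when a component exhausts its restarts; the achieved model order
`n_realized` is the number of converged components, and every attempt is
logged. An error (carrying the log) is raised only if fewer than two
components converge.

Design rationale, recorded because the obvious alternative fails here:

- A *symmetric* fixed-point update cannot converge on this data class.
  For an exactly Gaussian direction the fixed-point attraction vanishes
  (E[z·g(z)] − E[g′(z)] = 0 for z ~ N(0,1), any even contrast), and with
  ~5 real sources in a 25-dimensional whitened space the joint rotation
  is dominated by directionless noise axes: the convergence limit
  plateaus around 0.2 indefinitely (scikit-learn's parallel FastICA
  stalls identically). Deflation turns this physics into the observed
  behavior of ICA software on real data — a realized model order that
  varies with the input — instead of a hard failure.
- The *kurtosis* contrast is used instead of log-cosh because one-unit
  log-cosh iterations occasionally converge to a stable mixture of two
  networks (~8 % of subjects, recovered |r| dropping to ~0.7); for
  sources sharing the sign of their excess kurtosis — sparse spatial
  maps are strongly super-Gaussian — the kurtosis contrast's stable
  points are single sources.
- The iteration runs in float32 (the whitened matrix fits cache; the
  tolerance is far above float32 rounding), which keeps a 27-subject
  cohort's decompositions near 3 s on one core.

Conventions: components are ordered by explained series variance
(‖c_k‖²·‖s_k‖², ties by solver index); each map is z-scored over the
brain mask with the *sample* SD (an explicit, simple convention — no
mixture-model or residual-noise normalization); each map is sign-flipped
so its spatial skewness is ≥ 0. Scale invariance holds: scaling the
input series leaves z-maps unchanged.

## Template and best-fit selection

Two passes, byte-identical code for both cohorts:

1. **Bootstrap pass.** Per subject, the candidate component maximizes
   |spatial correlation| with a prior map — the simulator's ground-truth
   DMN map in simulation mode, or a user-supplied prior mask on real
   data. (This replaces a manual visual-inspection step, which is not
   implementable; the second, formula-defined pass is unchanged.) The
   pooled candidates of *all* subjects enter a voxel-wise one-sample
   t-test (t = mean/(SD/√n), df = n−1, zero-variance voxels flagged);
   voxels with one-sided p < 0.005 in clusters of at least the
   Monte-Carlo extent form the binary template. An empty template is
   returned with a warning, not an error.
2. **Goodness-of-fit pass.** Every component is scored by mean z inside
   the template minus mean z outside it; the "outside" mean is over the
   brain mask (not the full image) — the bounded, interpretable choice.
   The top score is the best fit, ties broken deterministically by lower
   component index (logged). The score is shift-invariant and positively
   homogeneous, so the z-scoring convention does not bias selection.

Because all synthetic data share one space, the per-subject template
back-transformation is the identity.

## Group inference

- **Two-sample test**: pooled-variance t (group A − group B), two-sided,
  df = n_A + n_B − 2, restricted to the OR of the two group DMN masks.
  The voxel threshold p < 0.005 is interpreted as total two-sided mass
  (configurable). Zero-variance voxels are flagged non-significant.
- **Monte-Carlo extent**: each iteration draws white noise on the grid,
  smooths it with the *applied* smoothing FWHM (smoothness is not
  re-estimated from residuals — the simple, stated choice),
  re-standardizes within the mask, thresholds at the voxel p, and
  records the largest suprathreshold cluster. The returned extent is the
  smallest k with empirical P(max ≥ k) ≤ α; the achieved level is always
  reported beside it. Defaults: 1000 iterations, face-adjacency
  (6-neighborhood) clustering (18/26 configurable), mandatory seed.
  The extent is monotone in both voxel-p strictness and smoothness.
  The one-sided whole-mask extent is calibrated once and reused for the
  template and both group maps (identical mask, smoothness and threshold
  ⇒ identical calibration problem); the two-sample extent is calibrated
  separately on the OR mask.
- **Cluster table**: connected components above threshold and extent,
  with voxel/mm³ size, peak = maximum |t| (ties to the first voxel in
  x-fastest scan order, logged), world-mm peak coordinates, and the
  per-group mean ± SD of subject-level cluster-averaged z. Rows are
  sorted by size, descending. Anatomical labels are out of scope; on
  synthetic data regions are named from the generator's manifest.

## Calibration and validation results computed by the suite

- The extent threshold calibrated at α = 0.05 achieves a family-wise
  false-positive proportion within ±0.02 of 0.05 on 1000 independent
  null volumes (`scripts/acceptance.py`; slightly conservative because
  discrete extents enforce P(max ≥ k) ≤ α).
- Cluster extraction agrees exactly with a brute-force BFS flood fill on
  random grids at 6/18/26-connectivity; all t and goodness-of-fit
  statistics match closed-form oracles at 1e-10.
- On a 27-subject cohort at default conditions, ICA recovers every
  planted network (per-network mean matched |r| > 0.9), the selector
  picks the planted DMN component in ≥ 95 % of subjects, the best score
  strictly exceeds the second best in every subject, and the template
  overlaps the planted DMN support (Dice > 0.7).
- Over replicate 14-vs-13 datasets (50 with the default effect, 20
  null — sizes chosen once as the package's replication design), each
  planted region is detected with the correct sign in ≥ 80 % of effect
  datasets, while per-region detections on null datasets stay within
  5 % + 2·SE.

## Numerical and degenerate-input choices

- Seeds are explicit everywhere; a pipeline configuration without seeds
  fails validation before any compute. Identical configuration + data
  reproduce identical output checksums (recorded in the run record,
  along with realized model orders and every warning that fired).
- Data payloads flow as float32 (synthesis, smoothing, filtering, ICA
  iteration); statistics (t-maps, goodness of fit, cluster summaries)
  are computed in float64.
- Zero-variance voxels: flagged and excluded (normalization, t-maps),
  never NaN-propagating. Empty template / empty OR mask / empty cluster
  table are warnings or legitimate outputs, not crashes — except where
  selection becomes undefined (goodness of fit with an empty template
  raises).
- Config files are flat `dotted.key = value` text; round-tripping
  through serialization is identity.

## Known limitations

- Realized ICA orders at the default conditions can fall well below the
  requested 25 when few noise directions carry stable sample structure;
  only the recovery of planted networks, not the realized order, is a
  contract.
- The Monte-Carlo null assumes homogeneous, known smoothness; on real
  data smoothness estimation from residuals would be required.
- The generator's realism limits (above) mean power figures here do not
  transfer to real cohorts; they validate the machinery, not effect
  sizes.
- Problem sizes in the replicate suites (replicate counts, Monte-Carlo
  iterations per replicate) are the package's chosen replication design;
  larger designs sharpen the proportions but do not change the
  procedures.
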