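# Methods

This note documents the models, parameter choices and numerical conventions
behind `mosswave`, and what the synthetic benchmark does and does not show
about real microscopy data.

## Pipeline model and conventions

**Coordinates and units.** Arrays are `(frame, row, col)`; reported stack
shapes are `(m, n, t)` with m = image height. Time in seconds is frame
index × frame interval (default 1 s). Default pixel size is 2.9 µm
(0.345 px/µm, a 4×/0.28 NA objective with 2× binning).

**Masking.** The colony footprint is found on the maximum z-projection.
Rolling-ball background subtraction (default radius 25 px ≈ 72 µm; up to
90 px ≈ 260 µm for large colonies) flattens illumination, a disk median
filter (r = 2.5 px ≈ 7.2 µm) suppresses shot noise while keeping edges, and
the triangle threshold picks the cutoff automatically: on a 256-bin
histogram over the data range, the threshold bin maximizes the perpendicular
distance to the chord from the histogram peak to the far tail endpoint
(peak ties break toward the lower bin). Components are 8-connected so thin
diagonal filaments do not fragment. Component filtering always removes areas
< 200 px² (~1600 µm²); the circularity rule is configurable because its two
readings conflict for filamentous shapes: the default `exclude_round` mode
removes components that are both rounder than 0.9 and smaller than twice the
minimum area (round specks are noise; filaments are never round), while
`include_round` keeps only round components and `off` disables the rule.
Circularity 4πA/P² is computed with two perimeter conventions: the exact
pixel-edge perimeter (a digital square scores π/4 — the convention's
compact-shape maximum) for reporting, and the smoothed contour perimeter
(compact blobs ≈ 0.95–1.0) for the 0.9 rule, which presumes it.

**Deconvolution and background.** Each frame is Richardson–Lucy deconvolved
(10 iterations — enough to sharpen without amplifying noise at typical
calcium-imaging SNR) with a normalized Gaussian PSF whose FWHM is the Abbe
limit 0.61 λ/NA; with λ = 0.51 µm (GCaMP emission) and NA = 0.28 this is
1.1 µm. At 2.9 µm/pixel that FWHM is sub-pixel, so the kernel is nearly a
delta and deconvolution is close to inert — the step matters at finer
sampling. Edge tapering (border blended toward its Gaussian-smoothed version
over twice the PSF FWHM) suppresses ringing; it is skipped for sub-half-pixel
PSFs, which cannot ring. The background field is estimated per frame by
grayscale opening with a disk of radius 15 px, which removes bright
structures narrower than the disk and keeps broad gradients; it is
subtracted and negatives are clipped. `background_stride` may interpolate
the field between every N-th frame when the background is static; the
default (1) recomputes it per frame.

**Z-scores.** Per pixel over time, sample SD (n−1); the difference from the
population SD is immaterial at thousands of frames but the convention is
fixed for reproducibility. σ = 0 pixels map to all-zero traces rather than
NaN so the clustering matrix stays dense; such rows carry no cosine
direction and are assigned to the nearest centroid by Euclidean fallback,
then typically pruned. Z-scoring is exactly invariant to per-pixel affine
intensity transforms, which is its purpose: pixels with the same dynamics
cluster together regardless of brightness.

**Clustering.** Cosine k-means on unit-normalized Z-trace rows. For unit
rows the objective is J = N − Σ_c ‖s_c‖ with s_c the per-cluster vector
sum, which makes both phases cheap and exact: the batch phase is Lloyd
iteration against normalized mean centroids; the online phase then accepts
single-point moves only when ‖s_a − x‖ + ‖s_b + x‖ > ‖s_a‖ + ‖s_b‖
(an exact decrease of J), passing over points in random order until no move
helps. Ten replicates with random initializations keep the best J. Empty
clusters are dropped rather than reseeded — the split/prune step dominates
the final count anyway. Initial k = foreground area / 150 px² (≈ 1260 µm²,
an empirical mean ROI size of one to a few per cell). After clustering,
each spatially connected (8-connectivity) component of a cluster becomes an
ROI, components < 12 px (≈ 101 µm²) are pruned as noise, and labels are
renumbered 1..K in raster order of their centroids for reproducibility.

**Traces and baseline.** Per-ROI trace = mean background-subtracted
intensity per frame. Baseline F₀ is the 1st percentile of the trace rather
than the strict minimum — a robust minimum that one noisy frame cannot set
(percentile configurable; 0 gives the strict minimum). ΔF/F₀ = (F − F₀)/F₀.
ROIs whose peak ΔF/F₀ within 300 s of the first stimulus onset is below 1.0
are excluded as non-responsive (typical driven responses peak near 2.5).

**Wave detection.** Threshold = max(0.35 × MAD, 0.3) on the ΔF/F₀ trace.
The MAD is unscaled (no 1.4826 factor) and computed on the full trace. The
absolute floor of 0.3 ΔF/F₀ is needed because the MAD of a mostly-quiet
trace reflects baseline noise, and near-threshold noise or neighbour
bleed-through would otherwise be called waves; 0.3 sits well below the
smallest real wave class (~0.7 spontaneous) and far below driven waves
(~2.5). Prominence is topographic (height above the higher flanking
minimum); the 10%/90% levels are fractions of prominence above the peak's
base, located by linear interpolation, giving FW10 = end − onset and
rise/fall between the 10% and 90% crossings. For a noiseless Gaussian wave
these are FW10 = 4.29193 σ and rise = fall = 1.68692 σ, used as closed-form
oracles in the tests. Peaks closer than 10 s are merged keeping the higher
(far below the shortest plausible inter-wave interval of ~59 s). A wave is
flagged `truncated` when a recording boundary cuts its tail (detected as an
elevated base at the boundary sample); truncated FW10 values are lower
bounds and should be excluded from duration statistics.

**Synchrony and entrainment.** The cross-correlation matrix holds, per ROI
pair, the maximum Pearson correlation of the overlapping mean-centered
segments over lags up to ±120 s (about two wave durations) — synchrony
insensitive to fixed phase shifts. Zero-variance traces yield NaN entries,
never a silent 0. Wave probability at time t is the fraction of ROIs whose
FW10 span covers t (the in-wave criterion is the FW10 span by definition
here). Pulse metrics use windows from each onset to the next (the last to
the recording end): waves per ROI, trapezoidal AUC of the colony-mean
ΔF/F₀ normalized to the first window (1 by construction), response-latency
mean ± SD, and the median peak-to-peak interval pooled across ROIs.
Intervals are peak-to-peak (onset-to-onset differs only by onset jitter for
symmetric waves).

## The synthetic colony model

The generator emulates the statistical structure of chitin-stimulated
protonemal imaging; its defaults are the emulated study conditions and are
not tuned per experiment.

* **Geometry.** Filaments radiate from a common origin as slightly wiggly
  polylines; each is a chain of cells (45–75 µm, caulonemal 1.2× longer and
  thinner: ~13 vs ~17 µm wide). Tips are typed CA or CH (p = 0.5),
  interior cells CAs/CHs, branch-bearing cells B; each CA tip's apical
  15 µm is a separate CA\* region. Every cell is one ROI region (CA tips:
  two), matching the observation of 1–3 dynamically distinct ROIs per cell.
* **Rasterization.** Cells are thick rounded-end polylines; emission weight
  is 1 in the core and falls to 0 over 2 px with a cosine profile
  (intensity greatest at the cell centre, lowest at borders, which has no
  reported functional form). Each pixel emits its owning region's program
  only, so ROI-trace cross-talk is PSF-only and the ground-truth label map
  is exact; the rendered footprint and label map cover identical pixels.
* **Waves.** Gaussian in time — the observed shape is bell-like with
  symmetric onset/offset — parameterized by FW10 via σ = FW10/2√(2 ln 10)
  so shape metrics are analytically checkable. Driven FW10 ~72 s,
  spontaneous ~61 s (lognormal, CV 0.15, clipped to 30–120 s); amplitudes
  ~2.5 ΔF/F₀ driven vs 0.7 spontaneous (lognormal, CV 0.25).
* **Timing.** Each region draws one characteristic driven interval
  (lognormal, mean 159.7 s, across-ROI CV 0.40; CA\* regions median
  144.6 s — chitin slows the fast tips); within-ROI jitter CV 19.2%.
  During each pulse a responsive region (p = 0.985 per pulse) fires at
  onset + latency and recurs at its characteristic interval while the
  stimulus lasts. Latency is Gaussian (SD 24 s, clipped at 0) with a mean
  drifting linearly across the protocol's pulses from 25 s to 64 s
  (endpoints reported for repeated stimulation; an explicit per-pulse drift
  can be configured instead). Spontaneous activity — CA\* oscillation at
  median 85.5 s and rare waves elsewhere (mean interval ~1385 s ≈ 1.3 per
  30 min) — runs until the first stimulus onset; stimulation entrains and
  slows it thereafter, which is what repeated-pulse recordings show
  (near-universal locking, intervals at the stimulation period). A 30 s
  refractory period suppresses wave initiation after each wave (shortest
  observed intervals ~59–63 s imply initiation suppression; the exact value
  is unreported).
* **Baseline and noise.** Per-region baseline F₀ is lognormal (mean 120
  counts, CV 0.3), optionally with a slow post-onset elevation
  (`baseline_boost`, default off). Acquisition: Gaussian PSF blur, Poisson
  shot noise (gain 1.2 counts) plus Gaussian read noise (SD 3 counts) over
  a dim sloped background (20 counts ± 20%), giving per-pixel SNR ≈ 10 at
  baseline; the camera's absolute scales and noise statistics are free
  parameters chosen once at realistic values. Rendering is bit-deterministic
  for a fixed seed; stacks are 16-bit.

**What the benchmark does not emulate:** photobleaching, focus drift, stage
movement, cell growth during the recording, wave propagation *within* a
region (each region's pixels share one program, scaled by the taper), and
multi-channel imaging. Passing recovery tests on these colonies therefore
shows the algorithmic chain is correct and well-conditioned at realistic
SNR and geometry — not that it is robust to drift, bleaching or
morphological change in real recordings.

## Problem sizes and tolerances in the test suite

The benchmark colony is 6 primary filaments × 4 cells with 25% branching
(~40 regions, ~3800 foreground pixels, 900 frames) — large enough for the
count-robustness and recovery properties while keeping a full pipeline run
to ~2 minutes. The entrainment experiment runs at trace level (the
detector consumes ground-truth-normalized traces directly), with five
replicate colonies of ≥ 50 regions and ten 60 s pulses at a 240 s period
over 44 min. Closed-form wave-shape checks allow one frame interval of
interpolation error; render-fidelity checks allow for PSF bleed and 16-bit
quantization (achieved error ~0.003 ΔF/F₀, asserted < 0.05); recovery
properties assert wave recall/precision ≥ 0.9 (±15 s match window),
segmentation mean best-match IoU ≥ 0.5 with ≥ 80% of true regions matched
at IoU ≥ 0.3, and ROI-count variation ≤ 10% across initial k in 50–150% of
the estimate.

## Known limitations

* The online k-means phase caps at 5 passes; pathological instances could
  stop short of a local optimum (the batch phase has already converged).
* CA\* regions are small (~20 px); at coarser pixel sizes they can fall
  under the 12 px prune threshold and merge into the parent CA region.
* The exclusion rule keys on the *first* stimulus onset only, as specified;
  colonies that become responsive late are excluded.
* `wave_probability` and interval statistics treat truncated waves like any
  other for occupancy but their durations are lower bounds.
* The triangle threshold assumes a dominant background mode; images that
  are mostly foreground need the `include_round`/`off` component modes and
  a manual threshold review.
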