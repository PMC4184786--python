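# Methods

## Trajectory model

Cluster motion is modelled as 2D fractional Brownian motion (fBm): each axis
receives stationary fractional-Gaussian-noise increments with Hurst exponent
H = α/2 and per-step variance 2·D·Δt^α, so the drift- and noise-free ensemble
MSD is exactly 4·D·t^α — the same power law the fits assume. α is restricted
to (0, 2]; outside that range the fGn covariance

    γ(k) = D·Δt^α · (|k+1|^α − 2|k|^α + |k−1|^α)

is not positive semi-definite and the process does not exist.

Increments are generated by Davies–Harte circulant embedding (O(n log n),
exact covariance when the embedding's eigenvalues are non-negative) with an
automatic fallback to a Cholesky factorisation of the full Toeplitz covariance
for lengths where the embedding fails. Both paths are exact; the choice is
deterministic given (n, α), so seed determinism holds either way. Confinement
is represented only through α < 1 — there is no explicit reflecting boundary —
because the fitted model is the power law itself.

Optional additions:

- **drift** `v·t` per axis, modelling directionally transported clusters
  (fits α ≈ 2, flagged superdiffusive);
- **static localization error**, iid Gaussian per position, which adds a
  constant 4·σ_loc² to the expected 2D MSD at every positive lag. Because the
  fit model carries no offset term, localization error biases fitted α
  downward at short lags; the bias is monotone in σ_loc and is documented and
  tested rather than corrected.

Default parameters are the reported live-imaging conditions: D = 0.0045 µm²/s,
α = 0.74, 300 frames at 0.5 s.

## Image model

Clusters are rendered as filled disks (indicator height 1) rasterised on an
8× supersampled grid, block-averaged to pixel resolution, convolved with a
Gaussian PSF and scaled so a disk much larger than the PSF plateaus at
`peak_intensity` photons above `background`; shot noise is Poisson, optionally
plus Gaussian read noise. For a pulse-chase pair the red channel holds a disk
of `core_diameter` and the green channel a concentric disk larger by
`shell_growth_fraction` (a filled disk by default — the FWHM of a filled disk
is what the growth statistic compares — with an annulus mode for visual
fidelity to the onion-like appearance of real aggregates).

Defaults: pixel size 0.1 µm/px and PSF σ = 0.085 µm (≈ 200 nm FWHM, typical
lateral confocal resolution). The source study states neither its pixel size
nor its exact PSF; both are stated assumptions, live in the config, and are
never hard-coded inside algorithms.

**What the generator does not emulate:** cell background structure (ER
texture, neighbouring clusters, autofluorescence gradients), photobleaching
(verified negligible in the original acquisitions), axial (3D) extent, motion
blur within a frame, per-cluster heterogeneity of D and α, and any kinetics of
aggregate nucleation or growth. A green test therefore establishes that the
measurement chain is unbiased and precise under the stated imaging physics —
not that it is robust to every nuisance of real cells.

## FWHM sizing and the growth statistic

A profile is sampled at the pixel pitch by bilinear interpolation along a line
through the cluster center; the background is the median of the outer 10% of
samples at each end (a local, robust choice — no background rule is stated in
the original method). The half-maximum level is background + (peak −
background)/2; crossings are located by linear interpolation between
bracketing samples and the two crossings nearest the peak are used, which
tolerates neighbouring structures on the line. Interpolation contributes up to
half a sample spacing of error per edge.

Where the original analysis had the user choose the diameter by eye, the
diameter here is the mean FWHM over K = 8 evenly spaced angles through the
intensity-weighted centroid (configurable to a single fixed angle). This
removes operator dependence and is unbiased for round clusters. The growth
statistic (d_g − d_r)/d_r is computed per cluster; since both channels share
the PSF, blur largely cancels in the ratio (recovery of a 16% shell on
1 µm cores is accurate to ~0.003 noise-free).

SEM is computed over clusters by default (matching the reported per-cluster
count); per-cell aggregation is available because the original report counts
both cells and clusters without stating the SEM unit.

## Detection and linking

Detection: scale-normalised negated Laplacian of Gaussian at σ = r/√2 (the
scale maximising the response of a disk of radius r), local maxima above a
quality threshold (default mean + 5·SD of the response, which returns nothing
on a blank frame), per-axis quadratic sub-pixel refinement, and suppression of
detections closer than half the expected diameter to a stronger one.

Linking: per-frame optimal bipartite assignment (Hungarian) on squared
displacement with a hard gate `max_displacement`; gated pairs are never
linked, unmatched spots start new tracks, and a track not extended in the next
frame terminates (no gap closing — no gap parameters exist in the original
protocol and bright clusters rarely blink). Track-length filtering is strict:
"longer than L frames" keeps tracks with ≥ L+1 points (default L = 150).

## MSD and fitting

The per-track MSD is time-averaged with overlapping pairs (the standard,
lower-variance choice; the original does not state overlapping vs independent
pairs), up to `max_lag_fraction` (default 0.25) of the track length. The model
MSD = 4Dt^α is fit by OLS of log MSD on log t over the first 20 lags: exact on
noiseless power laws, scale-free, with no fitting hyper-parameters; weighted
nonlinear least squares was deliberately not made the default since the
original fitting method is unstated and log-log OLS is reproducible. Tracks
with a non-positive MSD value inside the fit window are dropped and counted,
never imputed. α is soft-capped at 2.5 and values at or above 2 (up to
roundoff) are flagged superdiffusive so drifting clusters remain visible.

Population SEMs are over tracks. Note that for homogeneous ideal fBm
populations (one true α, no localization error) the SEM of α over 115 tracks
is ≈ 0.006–0.007; empirical reports of ≈ 0.02 at the same n additionally
reflect biological spread of α across clusters, which the generator
intentionally does not model.

Group comparisons use two-sided Mann–Whitney U per parameter (D is
right-skewed and the original names no test; Welch's t-test is available via
`method="welch"`). Because groups are unpaired, the effect size is reported
both as the ratio of group means and the ratio of group medians.

## Pipeline and reproducibility

`RunConfig` carries every constant (0.5 s frame interval, 20 fit points,
150-frame filter, condition labels, seeds) and is echoed verbatim into each
run's output directory; the report includes a config hash, SHA-256 manifest of
artifacts, and per-stage counts that must reconcile (kept + dropped = in).
Identical configs produce byte-identical CSV outputs. Population seeds are
derived from a single base seed via `numpy.random.SeedSequence.spawn`, keeping
every derived seed below 2³¹.

## Numerical choices and degenerate inputs

- fGn embedding non-PSD → exact Cholesky fallback (tolerance 1e-8 relative on
  the most negative eigenvalue; tiny negative eigenvalues from roundoff are
  clipped to zero).
- FWHM: peak at the profile edge or half level never crossed → "unbounded
  peak" error; zero-variance profile → "flat profile" error; peak not above
  background → error.
- Spearman size–mobility correlation on constant input → "degenerate ranks"
  error rather than a NaN.
- Linking ties are resolved by the assignment solver deterministically; with
  a gate below half the minimum inter-spot distance the assignment is forced
  and algorithm-independent.
- Sub-pixel quadratic refinement offsets are clipped to ±0.5 px.

## Known limitations

- No 3D/axial information; diameters and MSDs are in-plane quantities.
- Localization error is a documented bias on α, not a fitted parameter.
- The renderer's Gaussian PSF and shot-noise model are idealisations; no
  camera gain, dark current or structured background.
- No splitting/merging of tracks and no gap closing; dense fields with
  frequent crossings will fragment.
- The growth statistic assumes one isolated cluster per measurement line;
  overlapping clusters must be excluded upstream (the renderer records
  overlap warnings for exactly this purpose).
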