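# Methods

## The quantifiers

`itquant` characterises the *dynamics* of a univariate, regularly sampled
time series through the probability distribution of its ordinal patterns.
A window of `D` values taken `tau` samples apart,
`(x_j, x_{j+tau}, ..., x_{j+(D-1)tau})`, is reduced to the permutation of
time offsets that sorts the values ascending.  Over all windows this yields a
"causal" PDF `P = {p_i}` on the `N = D!` possible patterns — causal because,
unlike a value histogram, it retains the temporal ordering of the data.  The
symbolization is invariant under strictly increasing transformations of the
measurements, which makes the derived quantifiers robust to calibration
drift and unit changes.

From `P` we compute:

* **Permutation entropy** `H[P] = S[P] / ln N`, `S[P] = -sum p_i ln p_i`
  (natural logarithms; `H` is base-invariant).  `H ~ 1` for uncorrelated
  noise, `H ~ 0` for fully regular series.
* **Statistical complexity** `C[P] = Q_J[P, Pe] * H[P]`, where
  `Q_J = Q0 * {S[(P+Pe)/2] - S[P]/2 - S[Pe]/2}` is the Jensen-Shannon
  disequilibrium to the uniform PDF `Pe` and
  `Q0 = -2 * {(N+1)/N ln(N+1) - 2 ln(2N) + ln N}^{-1}` normalizes it so a
  delta PDF gives exactly `Q_J = 1` (verified to 1e-12 in the tests; the
  derivation is the closed form of the divergence between a delta and the
  uniform PDF).  `C` vanishes both for perfect order and for pure
  randomness and peaks for structured dynamics.
* **Fisher information** `F[P] = F0 * sum (sqrt(p_{i+1}) - sqrt(p_i))^2`,
  built from probability *amplitudes*; `F0 = 1` for a delta at either end
  of the ordering, `1/2` otherwise, so that `F(delta) = 1` and
  `F(uniform) = 0`.  `F` is local in distribution space and depends on the
  pattern ordering; we use the Lehmer rank of the sorting permutation as
  the canonical ordering (a user-supplied ordering table is accepted — the
  literature also uses other sorting schemes whose exact index maps are not
  always published).
* **Rényi entropy** `H_q = log2(sum p_i^q) / (1-q)` in bits, as a
  single-exponent alternative to variance weighting.  Convergence to the
  Shannon limit as `q -> 1` is first-order in `|q-1|`; the tests check the
  symmetric mean at `q = 1 +/- 1e-4`, which converges at second order.
* **Jensen-Shannon divergence** `J[P,Q] = S[(P+Q)/2] - S[P]/2 - S[Q]/2`
  between two pattern distributions (same `D`, `tau`, ordering): the
  model-benchmark distance.  Symmetric, bounded by `ln 2`, and exactly zero
  when the pattern counts coincide — in particular for any strictly
  increasing transformation between model and data.

### Weighted variants

Environmental series have strongly seasonal signal-to-noise ratios; ordinal
patterns from low-amplitude (dormant-season, night-time) windows are mostly
noise.  The weighted pattern distribution assigns each window its embedded
vector's population variance as weight; `H_w`, `C_w`, `F_w` are then the
same functionals of the weighted PDF.  For `tau > 1` the variance is taken
over the embedded vector itself, so weighting and symbolization see the same
points.  Weighted mode is the default throughout the applied interfaces.
A series whose every window is constant has zero total weight and is
rejected as degenerate.

### Ties, gaps, length

Measured series can contain exact ties; the default resolves them stably in
favour of the earlier time offset (deterministic, reproducible), and a
`reject` mode drops tied windows instead.  Windows containing missing values
are always skipped.  `validate_series` reports tied and skipped fractions,
errors when fewer than `D!` windows remain and warns below `5 * D!` —
practical floors for populating the pattern space; weak stationarity of the
ordinal statistics is an assumption, not a tested property.  Default
parameters for applied analyses are `D = 4`, `tau = 1` (pattern lengths of
4-6 suit typical series lengths; `D = 6` is used for the long synthetic
reference series).

## Limit curves

For fixed `H`, `C` is confined between curves `Cmin(H)` and `Cmax(H)`.
Both are traced by one-parameter families: the lower by the full-support
family `{p, (1-p)/(N-1), ...}`, the upper by the envelope over families with
`m = 0..N-2` components exactly zero and the remainder `{p, equal shares}`.
Each family is sampled on 2000-point parameter grids per monotone branch
(cosine-clustered toward the ends), and the envelope is resampled onto a
regular `H` grid by linear interpolation; endpoint values at `H = 0, 1` are
pinned to their exact value 0.  Containment checks use a 1e-6 tolerance; a
Monte-Carlo test with 10^4 Dirichlet(1) PDFs over 24 states shows margins
above 1e-2 on both sides, so interpolation error is immaterial there.

## Synthetic processes

The generators reproduce the canonical geography of the causal planes and
stand in for flux-tower and gridded land-surface data:

* `white_noise`: iid standard Gaussian.
* `k_noise`: spectral synthesis of `1/f^k` noise — amplitudes `f^(-k/2)`,
  iid uniform phases, zero DC, inverse FFT, standardized to zero mean and
  unit variance.  Periodogram slopes verify the target exponent.
* `logistic_map`: `x_{t+1} = r x_t (1 - x_t)` with a 1000-iteration warm-up
  discarded (standard transient removal); the representative chaotic map.
* `harmonic`: sinusoid plus optional Gaussian noise.
* `gpp_site` / `gpp_grid`: GPP-like fixtures — a seasonal sinusoid
  (peak amplitude 10 flux units), an optional daylight half-sine diurnal
  modulation at sub-daily resolutions, an optional mid-summer depression
  ("bimodal" regime, the water-limited two-peak seasonal shape), and AR(1)
  noise (lag-1 correlation 0.6, sd 1, i.e. 10% of the seasonal peak —
  a plausible signal-to-noise ratio for monthly ecosystem fluxes).  The
  grid variant assigns regimes by latitude band, creating spatial gradients
  in the quantifiers.

What these fixtures do *not* emulate: weather-driven interannual anomalies,
trends and disturbances, heteroscedastic observation error, or spatial
correlation of noise between cells.  Tests passing on them demonstrate the
correctness and qualitative behaviour of the estimators, not performance on
real observational archives.

## Resolution analysis

`aggregate` takes non-overlapping block means (a block with any missing
member is missing; a trailing partial block is dropped, keeping block
statistics unbiased); `decimate` thins.  On correlated series aggregation
lowers `H` and raises `C`, decimation the reverse — tested as mean shifts
over replicates.  An oscillation of period `P` samples is "detected" when
one window spans the cycle, i.e. at aggregation factor `P / D`.  For a
*noise-free* sampled sinusoid this detection raises rather than lowers `H`:
at fine resolution two monotone patterns dominate (H ≈ 0.40 for a
24-sample/day sine with `D = 4`) while the cycle-spanning resolution gives
exactly four equiprobable phase patterns (H = ln 4 / ln 24 ≈ 0.44).  The
entropy *drop* at the detecting resolution is a property of noisy cyclic
series — fine-resolution windows are noise-dominated and high-entropy,
aggregation averages the noise away and lets the cycle take over.  The
resolution-sweep tests therefore use a daily cycle plus Gaussian noise with
sd = 0.3 of the amplitude, which shows the effect robustly across seeds.

## Gridded benchmarking

`itq_map` applies the suite cell-wise; cells with less than 90% valid time
steps (default) or degenerate series are missing.  `rgb_composite` encodes
(H, C, F) as (R, G, B) scaled linearly over the theoretical [0, 1] range —
not per-map min-max — so composites are comparable across datasets; missing
cells are transparent.  `jsd_map` and `rmse_map` are the complementary
mismatch metrics: a constant model offset gives RMSE > 0 everywhere and
JSD = 0 everywhere (exactly so for unweighted counts; the variance weights
are offset-invariant up to floating-point round-off, below 1e-12), while a
dynamics mismatch with matched magnitudes does the reverse.
`metric_correlation` reports their Pearson correlation across cells.
Quantifiers on model *residuals* are deliberately out of scope: white-noise
residuals of a bad high-variance model would masquerade as low complexity.

## Structure diagnostics

Each run's plane point cloud is rasterized on a fixed 25x25 grid over
[0,1]^2 (half-open pixels, top edge closed; bounds fixed rather than
data-driven so rasters are comparable across runs) and normalized to sum 1,
absorbing differences in spatial resolution.  Pixels empty across all runs —
in H x C many are unreachable above `Cmax(H)` — are dropped before a PCA
with mean centering only (the vectors already share a scale; no variance
scaling).  Time-windowed slicing (`windowed_runs`) reproduces the
30-year-window, fixed-stride protocol used for century-scale simulation
archives; window and stride are explicit parameters.

The separation experiment builds two "model families" (1/f^1 vs 1/f^3 noise
cells) under two "scenarios" (linear trends of 0 and 1 amplitude over the
record) with two ensemble members each: the first principal component
separates families with purity 1 on every tested seed, while the best
single split on PC1 cannot separate scenarios — the fingerprint responds to
structure, not forcing.

## Numerical choices

* Natural logarithms for `S`, `H`, `C`, `J`; Rényi entropy in bits.
* Probability vectors validated to sum 1 within 1e-8 on input; constructed
  distributions are normalized and checked to 1e-12.
* `J(P, P)` returns exactly 0 via an equality short-circuit (the three-term
  evaluation would leave ~1e-16 of round-off).
* Fisher's edge-delta test uses a 1e-12 tolerance on `p = 1`.
* CSV output uses 12 significant digits, enough for bitwise-stable
  round-trips of double-precision values through text.
* NetCDF I/O goes through xarray's scipy backend (netCDF3 classic).

## Problem sizes

Reference computations use n = 10^5 (white noise, `D = 6`), n = 10^4
(chaotic map and coloured noise, 50 seeds per exponent), 10^4 random PDFs
for containment, a 64-day half-hourly series for the resolution sweep,
4x4x360-month grids for the benchmark metrics, and 20 replicates of the
16-run structure ensemble — sizes at which every stochastic claim in the
acceptance checks is stable across seeds.

## Known limitations

* Symbolization assumes regular sampling; irregular series must be
  regularized upstream.  Multivariate patterns are out of scope.
* No formal stationarity test; strongly nonstationary series yield
  well-defined but hard-to-interpret pattern distributions.
* The H x F plane has no known limit curves; none are computed.
* Tied data shift mass toward the identity pattern under the stable tie
  rule; heavily quantized series should be checked via the tied-fraction
  report (or analysed with `tie_rule="reject"`).
* No regridding: gridded comparisons require pre-aligned grids.
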