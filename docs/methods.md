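# Methods

This note records the models burstkin implements, the conventions and
numerical choices behind them, and what the synthetic-data tests do and do
not establish about real imaging data.

## Signal model

The transcribed sequence is divided into `r` sites of one polymerase
footprint (150 bp), traversed in `step_time_s` seconds each. The default
step time of 6 s is the promoter *blocking time* τ_block: a newly initiated
polymerase occupies the initiation site for one step, so initiation events
cannot be closer than τ_block. The loop function `L_i` gives the cumulative
number of MS2 loops produced by a polymerase at site `i`: zero before the
cassette, a linear ramp of `loops_total / cassette_steps` per step across it
(fractional values allowed — loop spacing and polymerase footprint do not
coincide), then constant. With promoter occupancy `X(t) ∈ {0, 1}`,

    F(t) = Σ_{i=1..r} L_i · X(t − i·τ_block),

i.e. the polymerase at site `i` reports the promoter state `i` steps ago.
Elongation speed is assumed constant and enters only through `step_time_s`;
splicing, polymerase traffic and MCP binding kinetics are not modeled
(loops are taken to fluoresce as soon as they are made). The stationary
mean is `⟨F⟩ = P_on Σ_i L_i`, and the signal (cross-)covariance between two
loop functions A, B on the same gene is

    C_AB(τ) = Σ_{i,j} L^A_i L^B_j · g(τ + (i − j) τ_block),

where `g(t) = P_on (A(t) − P_on)` is the autocovariance of the ON indicator
and `A(t)` the ON→ON propagator. The double sum is evaluated as a
correlation kernel over the site offset `d = i − j` (cost `O(r · n_lags)`),
with `g` a continuous function of the lag in seconds, so curves can be
evaluated at any sampling interval without interpolation.

## Promoter models

All rates are stored in s⁻¹; ON dwells are exponential with rate `k_off`
for every family.

* **two-state (telegraph)** — OFF dwells exponential with rate `k_on`;
  `P_on = k_on/(k_on + k_off)`, `g(t) = P_on(1 − P_on) e^{−(k_on+k_off)t}`.
  This is the continuous-time exponential form of the printed per-step
  propagator `e^{(δ−1)n}`, `δ = 1 − (k_on+k_off)τ_block`; the exact
  discrete chain `δ^n` agrees to second order in the per-step rates and is
  kept as a test oracle (the gap peaks at ≈0.02 for per-step rates of 0.1).
* **cycle** — the OFF period is an irreversible chain of K sub-states with
  exit rates `k_1..k_K` (canonically sorted ascending; the ordering is not
  identifiable from one color). `P_on = k_off⁻¹ / (k_off⁻¹ + Σ_m k_m⁻¹)`;
  `A(t)` is the (ON, ON) entry of the matrix exponential of the chain
  generator, evaluated through its eigen-expansion. K = 1 reduces exactly
  to the telegraph. The effective ON rate is `k_on_eff = (Σ_m 1/k_m)⁻¹`.
* **gamma** — an effective two-state process whose OFF dwells follow
  Gamma(α, β) (mean α/β); `P_on = (1 + α k_off / β)⁻¹`. For integer α and
  equal cycle rates the two descriptions coincide exactly (Erlang), which
  is the main validation oracle of the spectral route below.
* **poisson-like** — memoryless initiation: Poisson firing at rate `r`,
  blocked for τ_block after each event, giving `r_eff = (τ_block + 1/r)⁻¹`
  and `P_on = τ_block · r_eff`. For the correlation analysis the occupancy
  of distinct blocking steps is taken as uncorrelated (`A(n) = P_on` for
  n ≥ 1); as a continuous-lag kernel this is the triangle
  `g(t) = P_on(1−P_on) max(0, 1 − |t|/τ_block)`, the autocovariance of a
  step-wise independent occupancy sampled at real lags. The normalized
  autocorrelation then depends on the probe geometry only — the defining
  feature of this model.

### Gamma autocovariance by spectral inversion

The gamma family has no closed-form propagator. Its ON-indicator spectrum
follows from alternating-renewal theory,

    S(ω) = 2 / ((μ_on + μ_off) ω²) · Re[(1 − f_on)(1 − f_off) / (1 − f_on f_off)],

with `f` the dwell-time Laplace transforms at `s = iω`. `g(t)` is recovered
by a trapezoidal cosine transform up to a cutoff of 80× the fastest rate —
where the spectrum matches its `2/(μω²)` asymptote to better than 10⁻⁴ —
plus the analytic tail `∫_{ω₁}^∞ cos(ωt)/ω² dω = cos(ω₁t)/ω₁ − t(π/2 −
Si(ω₁t))`, so the high-frequency truncation error is far below the 10⁻⁶
target at no grid cost; `g(0)` is pinned to the exact variance
`P_on(1 − P_on)`. A guard raises if rates and lag span would require an
unreasonable grid. Validated against the telegraph (α = 1) and the
equal-rate cycle (α = 2) to ≈10⁻⁵ absolute on a 0.22–0.25 scale. Inside
fit loops the family's scaling symmetry is exploited: at fixed (α, P_on)
the covariance depends on the dimensionless lag βt only, so one tabulated
reference curve serves every candidate β.

## Simulation

Switching paths are simulated exactly in continuous time by drawing
alternating dwell sequences (exponential ON; exponential, hypoexponential
or Gamma OFF), with a stationarily chosen initial state and a burn-in of
six mean cycles for the non-Markovian OFF laws. Fluorescence is evaluated
directly at the observation times through the delayed-readout formula, with
the path extended `r` steps before the first sample so every returned
sample is steady state. Because the sampled process is exactly stationary,
the empirical correlation at lag `k·dt` estimates `C(k·dt)` for *any*
sampling interval, commensurate with the polymerase step or not. (An
alternative convention — binarize `X` on the step grid, then sample by
nearest-step lookup — makes the sampled correlation non-stationary in the
sample index whenever `dt` is not a multiple of τ_block and shifts it by
several percent at `dt = 4 s`; the exact evaluation was chosen so that the
analytic curves are the true expectations of the simulated estimator at
every study sampling rate.) Poisson-like paths are iid Bernoulli(P_on)
occupancies per blocking step, matching the uncorrelated-step convention
above. One master seed spawns independent per-trace substreams, so trace
sets are reproducible and individual traces can be regenerated.

## Empirical connected autocorrelation and the finite-trace correction

For traces `v_α` of K samples the per-trace empirical mean is subtracted
and the lag-r covariance sum is formed with the `(K − r)/K` pair
normalization. The variance denominator is **pooled** across traces by
default: the finite-trace correction below is the exact expectation of the
numerator divided by a constant variance, and simulation shows that the
pooled estimator matches it to within one across-trace SE at M = 4000,
whereas averaging per-trace *ratios* (each trace divided by its own noisy,
covariance-correlated short-window variance) is biased by ~0.1 at
intermediate lags under study conditions. Per-trace variance normalization
remains available (`variance='per-trace'`) for strongly heterogeneous
uncalibrated data, with this caveat documented. Curves are normalized to 1
at the second time point (lag 1): lag 0 carries temporally uncorrelated
noise and is never used downstream, and the normalization removes the
(arbitrary) variance scale from both data and theory. Constant traces are
excluded with a warning — under pooled normalization this leaves the curve
unchanged (they contribute zero to numerator and denominator alike) and
only affects the across-trace standard errors.

For a stationary process with autocovariance `G_k`, the expectation of the
empirical numerator at lag r is

    E[Σ_i (v_i − m)(v_{i+r} − m)] / (K − r)
      = G_r + Var(m) − (1/(K−r)) Σ_i [Cov(v_i, m) + Cov(v_{i+r}, m)],

with `Var(m)` and `Cov(v_i, m)` assembled from the `G_k` Toeplitz matrix
(`O(K²)`, exact — an additive constant in `G` cancels identically, so
connected and non-connected inputs give the same curve). These mean-bias
terms force the corrected curve's area toward zero and reproduce the
negative valley of short traces; as K → ∞ the corrected curve converges to
the normalized infinite-trace one. The implementation is verified against
an independent Gaussian covariance-algebra oracle to 10⁻¹⁰ and against
short-trace simulations of an Ornstein–Uhlenbeck process (λ = 2 s⁻¹,
γ = 4 s⁻¹ᐟ², 5-s traces) and of the telegraph reporter at several window
lengths, always within three across-trace SE.

## Inference

1. **Calibration.** `I0 = ⟨max_t I(t)⟩ / Σ_i L_i` (mean of per-trace maxima,
   robust against overestimating the maximum); traces are divided by `I0`.
   At low occupancy the gene rarely saturates within a short window, so
   `I0` is biased low and `P_on` high; for spatially structured data the
   recommended practice (used in the embryo examples) is to calibrate on
   the high-expression anterior and transfer the scale, since intensity per
   loop is a property of the optics, not the region.
2. **Occupancy.** `P_on = ⟨F⟩ / Σ_i L_i` over the steady-state window; it
   fixes the within-family rate ratios (`k_on/k_off`; `k_off` vs `Σ 1/k_m`;
   `k_off` vs `α/β`). The poisson-like model is fully determined here.
3. **Rate scale.** The remaining scale — `k_on + k_off`, the cycle's
   `k_on_eff + k_off` together with the ratio `k_1/k_2 ∈ (0, 1]`, or the
   gamma β at each α on a small shape grid (default 1..3 in halves) —
   minimizes the pair-count-weighted MSE between the empirical curve and
   the finite-trace-corrected model curve over lags 1..min(K − 2, three
   probe buffering times). The pair-count weights implement the
   down-weighting of poorly sampled large lags; the lag cap keeps the fit
   in the well-sampled regime (sensitivity checks showed longer ranges add
   noise without information for the studied rates, and shorter ones
   discard shape). Optimization is a log-spaced scan over the physical
   window [10⁻⁴, 1] s⁻¹ refined by bounded scalar minimization (cheap,
   monotone-robust, avoids local minima); the cycle's two free parameters
   use a coarse grid plus Nelder–Mead in (log scale, logit ratio). Fits
   hitting the rate bounds raise a boundary warning. Inference refuses
   trace sets without a marked steady-state window.

Uncertainties are SDs over re-fits on 20 random subsets of 60% of the
traces; the per-trace correlation curves are computed once and subset
averages reuse them. Two-vs-three-state discrimination reports the fitted
`k_1/k_2` with its subset distribution, plus a continuous evidence score —
the log ratio of the best constrained-fit MSEs with the ratio pinned near 0
versus at 1 — which is a steadier statistic than the location of the
bimodal ratio estimate on noisy short-trace data. No information-criterion
comparison across model families is attempted: the number of independent
points in a correlation curve is ill-defined, so models of different
complexity are compared only through their fit quality and through
independent statistics (the readout precision below).

## Readout precision

The mRNA produced in a window T is proportional to the time-averaged
occupancy, so the readout precision is its coefficient of variation.
For the telegraph, the large-T variance of the time average is exactly
`2 P_on(1 − P_on) τ_i / T` with `τ_i = 1/(k_on + k_off)`, giving

    δmRNA/⟨mRNA⟩ = sqrt( 2 τ_i (1 − P_on) / (T P_on) ),

the square-root form being fixed by that variance calculation and confirmed
against the Monte-Carlo estimator. The poisson-like counterpart is
`sqrt(τ_block (1 − P_on)/T)`.
A consistency note: a renewal-CLT estimate from the firing statistics
(`n_P = T/(τ_block + 1/r)` independent inter-arrival measurements of CV
`1 − P_on`) gives `sqrt(τ_block (1 − P_on)²/(P_on T))`, which coincides with
the printed formula at `P_on = 1/2` and diverges from it at small
occupancy; the Monte-Carlo cross-check of the poisson-like formula is
therefore run at `P_on = 1/2`. The cycle model's finite-T error has no
closed form here and is always computed by Monte-Carlo (vectorized exact
dwell simulation of the time-averaged indicator; the poisson-like MC uses
the physical firing process, deterministic τ_block occupancy with
exponential gaps). Across matched parameter grids the orderings hold:
poisson-like < two-state at equal `P_on`, and the three-state cycle <
two-state at equal `k_on_eff + k_off` — more regular OFF periods mean more
effective independent measurements.

Empirical estimators compute the SD/mean over nuclei of the time-averaged
calibrated activity per AP bin (default 10% egg-length strips, bins with
fewer than 3 nuclei skipped), a binary ever-active variant, and the
lineage-integrated total (own integral + ½ mother + ¼ grandmother, assuming
equal partitioning of mRNA at division). `integration_time_factor` converts
an error ratio into a required integration-time factor via the T^(−1/2)
law.

## Synthetic embryo datasets

`generate_embryo_dataset` emulates the *structure* of the study data: four
embryos at sampling intervals 13.1/10.2/5.1/4.3 s; cycles 11–13 with
interphases of 360/540/780 s (within the observed 6–15 min range, the last
~60 s transcriptionally silent before division); nuclei doubling between
cycles with lineage links and positional jitter; and
`k_on(x) = k_anterior · exp(−(x − 0.175) L/λ)` with λ = 100 µm on a 500-µm
embryo — an activator gradient giving a ≈5-fold drop in the mean ON rate
between the anterior ([0, 0.35] egg length) and boundary ([0.45, 0.55])
regions. Defaults `k_anterior = k_off = 0.015 s⁻¹` put the anterior at
`P_on ≈ 0.5` with a ≈33-s switching timescale; with a single,
position-independent `k_off` the 5-fold `k_on` drop places the boundary at
`P_on ≈ 0.15` (an exactly 0.1 boundary would require the OFF rate to rise
toward the posterior as well — a deliberate simplification). Steady state
within a cycle is genuine: the promoter is silent outside the interphase,
the signal ramps up over one buffering time after mitosis and decays after
shutdown, and the plateau window is marked on the generated sets (and
recoverable by the detector). Mitosis appears only as the gap between
cycle windows; nuclear movement, photobleaching, detection noise and real
activator dynamics are *not* modeled — passing tests on these fixtures
validate the estimators' statistics, not robustness to imaging artifacts.

The steady-state detector smooths the ensemble-mean intensity with a
3-sample moving average and takes the contiguous stretch above 0.8 of the
maximum; both knobs are exposed, the criterion is scale invariant, and a
window touching the first or last sample is rejected (no plateau) with a
pointer to explicit manual bounds.

## Known limitations

* The calibration bias at low occupancy (Step 1 above) propagates to
  `P_on` and hence to the `k_on/k_off` split, though not to the fitted
  timescale `k_on + k_off`, whose normalized curve shape is occupancy
  independent for the telegraph.
* Because the simulator, the analytic curves and the empirical estimator
  form a consistent triple, two-state inference here remains *consistent*
  at fast switching: at M = 1000 nuclei the median recovered `k_on + k_off`
  stays within a few percent even at 0.18–0.20 s⁻¹, with the data
  requirement (variance at fixed M) exploding as the rates approach the
  blocking limit 1/τ_block ≈ 0.167 s⁻¹. Analyses whose generative process,
  fitted propagator or estimator normalization are mutually mismatched
  instead show a bias at fast rates that more data cannot remove; the
  acceptance scan therefore reports the rate at which recovery at the
  study size (M = 200) leaves the 15% band, which lies near the blocking
  limit rather than below it.
* The poisson-like precision formula coincides with the firing-statistics
  estimate only near `P_on = 1/2`; see the consistency note above.
* Non-steady-state correlation analysis and the finite-size correction to
  the variance (small effect, heavy numerics) are out of scope.
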