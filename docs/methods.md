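# Methods

This note records the models implemented in `mesoflow`, the estimator and
design choices that were genuinely open, the synthetic regimes the test
suite runs at, and the known limitations.

## Race-model behavior

Stop-trial behavior is the independent horse-race of a GO process (finish
time drawn from the Go-RT distribution) and a STOP process of fixed latent
duration `ssrt_true`, started `SSD` after the Go signal.  A response occurs
iff the GO finish precedes `SSD + ssrt_true`.  The SSD follows a
one-up/one-down staircase: +100 ms after a correct Stop, −100 ms after a
wrong Stop, floored at 0 ms with no ceiling; this drives p(response)
towards 1/2.  The Go-RT family is a truncated normal (mean 650 ms, SD
130 ms, support > 0 by default) — only summary statistics constrain it, so
any positive unimodal family would do and the family is configurable.

**SSRT estimation.**  The integration method is applied per SSD: with
`n = round(p_response · #GoRTs)` (half-up rounding, clamped to
[1, #GoRTs]), the SSD's estimate is the nth smallest Go RT minus the SSD.
SSDs with p(response) ∈ {0, 1} carry no timing information and are dropped
with a warning.  The overall SSRT is the stop-trial-count-weighted mean of
the per-SSD estimates — the staircase concentrates trials on few SSD
levels, and count weighting keeps the pooled estimate unbiased under that
uneven sampling.  A mean-SSD variant (single subtraction from the overall
response rate) is available behind a switch.  Note the rounding rule makes
the estimate only *approximately* invariant to duplicating every Go RT:
the duplicated rank can land one order statistic away, so the property
holds up to one inter-RT gap.

**Race check.**  The race model's identifiability assumption (the GO
process is the same in Go and Stop trials) predicts wrong-Stop RTs are the
censored fast tail of the Go-RT distribution; a one-sided Mann–Whitney test
(wrong-Stop < Go, α = 0.05) is reported, "untestable" below 10 RTs a side.

## Spectral MUA

MUA is the band-average (0.2–1.5 kHz) of the relative spectrogram
R(ω,t) = P(ω,t)/P_ref(ω): short-time Fourier power in 5-ms Hann windows
hopped every 1 ms (the taper and hop are not dictated by the measure; Hann
controls leakage, and the 1-ms hop makes the later interpolation to a 1-ms
grid nearly lossless), with P_ref the time-average over the first 30
minutes (the whole recording when shorter).  The ratio cancels the unknown
spike-waveform spectrum and any per-channel gain — MUA is exactly invariant
to amplitude rescaling of the raw signal — and acts as the baseline
correction, so no further detrending is applied.  Log-MUA is then smoothed
by a 40-ms moving average evaluated every 5 ms and linearly interpolated to
1 ms; interpolation is the adopted reading of a 5-ms-step average yielding
a 1-ms series.

One physical caveat: a 5-ms window resolves ~200 Hz, so a strong
low-frequency component (e.g. 50 Hz line noise) leaks into the lower edge
of the analysis band.  The ratio normalization suppresses any *stationary*
component regardless of frequency; for nonstationary interference the
suppression is relative (tested as: an amplitude-stepped 50 Hz tone
perturbs band MUA by less than 30 % of the same tone placed in band).

**Outlier trials.**  A trial is excluded iff in any epoch time bin its MUA
exceeds the per-channel mean + 2 SD on strictly more than 80 % of channels.
Mean and SD are computed within condition and epoch (across that tensor's
trials and time), which keeps exclusions condition-fair; with SD = 0 the
strict inequality never fires.  **Epochs** are 400 ms, half-open, 1-ms
bins: [movement onset − 400, movement onset) for Go and wrong Stop,
[Stop + SSRT − 400, Stop + SSRT) for correct Stop.

## Multivariate transfer entropy

TE_{X→Y|Z} = H(Y_n | Y⁻, Z⁻) − H(Y_n | Y⁻, X⁻, Z⁻), in nats.  Trials are
treated as stationary realizations: TE is estimated per trial over the
400-ms epoch and trial-averaged per condition (no time-resolved ensemble
estimation).  Conditioning uses all remaining channels.

**Estimator.**  Entropies use the Heaviside (step) kernel under the
Chebyshev norm — the sample-entropy estimator: Ĥ = −(1/n) Σ_i ln((1/n) Σ_j
Θ(r − ‖p_i − p_j‖_∞)), self-match included so Ĥ is finite, ties (distance
exactly r) counted as neighbours.  Series are standardized per trial
(population SD), so the radius r is a fraction of the SD.  Because the
Chebyshev indicator factorises across coordinates, the implementation
precomputes per-(series, lag) boolean neighbour matrices bit-packed into
uint64 words; every conditional entropy is then an AND + popcount, and a
circularly time-shifted surrogate is just a different window offset into
the same packed rows.  The packed path is tested to 1e-9 against a plain
`cdist` implementation and an independent double-loop oracle.

**Radius.**  Default r = 0.2·SD.  At 400-sample epochs the conditional
neighbour counts after two or three selected terms fall to single digits at
r = 0.2, which destroys both the power and the calibration of the
candidate tests; the structure-recovery analyses therefore run at
r = 0.5·SD, where per-trial edge sensitivity is 30–60 % while per-pair
false positives stay below 1 %.  The dimensional bias of the estimator
(entropies of higher-dimensional spaces are underestimated more) largely
cancels between the two conditional entropies of TE only when counts are
adequate: the linear-Gaussian benchmark (closed-form TE of a VAR(1))
is matched within ~10 % at r = 0.5 and n = 2000, but overestimated ~3×
at r = 0.2.  Radius, α, surrogate count and shift bounds are all exposed
in `KernelConfig`.

**Nonuniform embedding.**  Candidates are the pasts of every channel at
lags 1..l (l = 50 ms by default, embedding lag and offset 1).  Greedily,
the candidate maximizing the decrease of H(Y_n | selected ∪ {candidate})
is tested against surrogates obtained by circularly shifting that candidate
by a uniform offset in [20, n − 20] samples; the first rejection
terminates the selection.  Two test statistics are implemented:

* `max-z` (default): the winning gain is compared with a Gaussian fit
  (mean + z·SD) of its own surrogate gains at the Bonferroni-corrected
  level α/#candidates.  The correction matters: the winner is the argmax
  over hundreds of candidates, and comparing it against the uncorrected
  (1−α) surrogate quantile of a single candidate admits a false term for
  the majority of null targets (measured ~70 %).  With the correction the
  per-target false-selection rate on independent noise is at or below the
  nominal α (measured 0/60 targets at α = 0.01).
* `quantile`: the uncorrected empirical-quantile convention, kept as an
  option for comparison with toolbox implementations.

A pair whose selection admitted no source past is assigned TE exactly 0 —
the hard-zero rule that makes the median TE over independent channels
exactly zero.  Computed TE values are floored at 0.  Greedy ties break by
(lower lag, lower series index); per-target seeds derive from a spawned
`SeedSequence` tree so the matrix is reproducible and independent of
evaluation order.

## Network topology

The trial-averaged TE matrix is a weighted digraph without self-loops.
**Percolation**: thresholds sweep {0} ∪ {distinct positive weights}; the
graph at threshold t keeps links with weight strictly above t; the curve
records |GSCC|/N (largest strongly connected component, Tarjan via
networkx, ties by smallest member index, validated against a
transitive-closure oracle).  The **descent point** is the smallest
threshold where the fraction first drops below its initial value; the
**slope** is the secant magnitude of the descending segment
(fraction lost per unit TE; a least-squares variant is available).  The
**analysis graph** keeps links with weight ≥ the descent point — the last
configuration before fragmentation begins, balancing spurious-link removal
against information loss; degenerate curves with no descent retain all
positive links with a warning.

**Hubs** are nodes with out-degree > mean + 2·SD (sample SD, strict
comparison) of the out-degree distribution of the analysis graph, computed
per condition.  **Clusters**: C1 = Go-only hubs, C2 = correct-Stop-only,
C3 = both, C4 = never; wrong-Stop-only hubs are flagged as anomalies
rather than classified (none are expected).  With the 2-SD rule, a single
planted hub among 10 nodes is detectable (z ≈ 2.85) but two equal hubs
among 10 are not (z ≈ 1.9 each — the hubs inflate the SD themselves); the
synthetic recovery designs therefore plant at most one hub per condition
at 10 nodes, and shared-hub recovery into C3 is exercised both
end-to-end (one shared hub) and at the degree-profile level (20 nodes).

**Robustness curves** track each cluster's mean out-degree along the
percolation sweep.  **Group comparisons** use Kruskal–Wallis with
Bonferroni-corrected pairwise Mann–Whitney follow-ups at α = 0.01.

## Interaction measure

I_ij = (1/|C_i|) Σ_{m∈C_i} Σ_{n∈C_j} TE(m→n), self-pairs excluded (the TE
diagonal is zero), diagonal entries I_ii computed and reported.  The
summation reading — over node pairs between two fixed clusters, normalized
by the source-cluster size — is the one under which I equals node
out-strength on the cluster-quotient graph, and duplication of every
source-cluster node leaves I_ij (i≠j) unchanged; both properties are
tested.  Empty clusters yield *undefined* (NaN) rows/columns, not zeros:
an absent cluster is not a zero-flow cluster.  Session aggregation reports
mean ± SEM per entry (SEM absent for a single session).

## Null model

Null hypothesis: the observed topology follows from the marginal MUA
distributions and series length alone.  Per repetition, every channel of
every trial is independently permuted in time (exact histogram
preservation, all temporal structure destroyed), single-trial TE matrices
are recomputed, each surrogate single-trial graph is thinned to the link
count of its empirical counterpart (k strongest links, ties by node-index
order; significant-link count is the adopted density-matching currency),
and the matrices are trial-averaged.  Metrics (descent point, slope) are
collected per repetition; the empirical value is ranked with the add-one
correction p = (1 + #{null ≥ emp})/(1 + reps).  The paper-faithful setting
is 500 repetitions; desk-scale analyses in the test suite use 20–50.

## Synthetic generators

`simulate_coupled_network` evolves each node as
x_i[t] = a·x_i[t−1] + tanh(Σ_e strength_e · x_src[t−lag_e]) + σ·ε, with
self-decay a = 0.5, unit innovations, couplings only through the
condition-active edges of a `GroundTruthNetwork` (lags 1–10 ms, the range
of causal interactions the analysis targets), 100-sample burn-in,
per-channel standardization.  The tanh squash makes interactions nonlinear
— the regime TE is meant for.  The default `hub_network` places a weakly
coupled ring (strength 0.6, lag 1) as a strongly connected backbone plus
condition-specific hubs (strength 0.7, lag 3) driving all other nodes:
node 0 in Go, the diametrically opposite node in correct Stop, so no
static ring edge joins the two hubs and the hub-to-hub flow direction is
purely condition-dependent.  Wrong-Stop wiring is the stated mixture: Go
edges at full strength plus Stop edges at half strength.  These strengths
are free parameters of the synthetic regime (no quantitative couplings
exist for real tissue); they were fixed once so that the stated recovery
regime (strengths ≥ 0.5 detectable at 400 samples × 40 trials) is
realizable, and recovery targets are claims about this regime only.

What the generator does *not* emulate: volume conduction / shared-electrode
crosstalk, nonstationary task-locked transients inside the epoch, slow
drifts across trials, realistic MUA autocorrelation from the 40-ms
smoothing, and excitatory/inhibitory asymmetries.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery, not
real-data performance.

`simulate_race_session` and `simulate_raw_broadband` (inhomogeneous
Poisson spikes convolved with a stereotyped ~1-ms biphasic waveform plus
white noise, 24.4 kHz) close the loop for the behavioral and spectral
stages.

## Problem sizes in the test suite

Structure recovery runs 20 end-to-end sessions (10 nodes, 400-sample
epochs, 40 trials per condition, 2 conditions, surrogates 100, r = 0.5,
max lag 20) — 13 with disjoint Go/Stop hubs and 7 with a shared hub — plus
a 50-repetition permutation null on one session; estimator benchmarks use
n = 2000; the staircase target uses 1000 Stop trials.  These sizes keep
the suite at desk scale while leaving every acceptance margin
(≥ 80 % recovery, sensitivity ≥ 0.8, FPR ≤ 0.1, ±25 ms SSRT) comfortably
cleared at the measured operating points.

## Numerical choices and degenerate inputs

Constant channels are rejected at standardization.  All-zero TE matrices
(no significant link) yield no percolation curve and empty hub sets rather
than errors at the pipeline level, while the percolation operation itself
rejects an empty graph.  Surrogate-gain SDs are floored at 1e-12.  Seeds
everywhere derive from `numpy.random.SeedSequence` spawn trees keyed by
stage, condition, trial and target, making every result reproducible
bit-for-bit under a fixed master seed.

## Known limitations

* The sample-entropy kernel estimator is biased when neighbour counts are
  sparse; TE magnitudes at the r = 0.2 default should be read as detection
  statistics, not calibrated information rates.
* Full conditioning on all remaining channels is implemented; at many more
  channels than samples the embedding selection will simply stop early
  rather than overfit, but no dimensionality reduction is attempted.
* The `max-z` candidate test extrapolates the surrogate null Gaussianly to
  the α/#candidates tail; its measured calibration is at-or-below nominal
  on i.i.d. noise, slightly conservative.
* Percolation metrics on very sparse averaged graphs (few links) are
  dominated by detection noise; the complexity comparison between
  conditions is meaningful only when both conditions retain a giant
  component.
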