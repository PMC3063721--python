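# Methods

## Point-process model

Spike trains are treated as realisations of discrete-time point processes on
a regular grid of bins of width δ (default 1 ms, small enough that a neuron
spikes at most once per bin; duplicate spikes in a bin are a hard error
unless the caller opts into collapsing them).  The conditional intensity of
target neuron *i* is log-linear in the ensemble spiking history,

    log(λᵢ[k] δ) = β₀ + Σⱼ Σᵣ γⱼᵣ nⱼᵣ[k],

with covariates nⱼᵣ[k] = spike count of source *j* in the half-open causal
window [tₖ − rW, tₖ − (r−1)W), r = 1..R.  Windows never include bin k itself.
A single order R governs all sources of one target; R is selected per neuron
by AIC (−2 logL + 2p, p = 1 + N·R), with all candidates evaluated on the
common fittable range implied by the largest candidate so their likelihoods
are comparable, and ties broken toward the smaller order.

The discrete point-process log-likelihood Σₖ ΔNₖ log(λₖδ) − λₖδ coincides
with a Poisson log-likelihood for 0/1 responses (the higher-order term for
multiple spikes per bin vanishes by construction), so fitting is a log-link
count regression.  It is maximised by a damped Newton iteration
(equivalently IRLS): deterministic start at β₀ = log(mean rate), γ = 0;
backtracking line search on the log-likelihood; convergence when the step
falls below 1e-8 relative; at most 100 iterations.  The per-bin intensity is
floored at 1e-12 inside logarithms, and any coefficient exceeding 30 in
magnitude flags the fit as non-converged (perfect-separation guard).  A
ridge jitter of 1e-8·tr(H)/p is added only if the observed information is
numerically singular.  The solver was validated against statsmodels' Poisson
GLM (agreement to ~1e-13 in the coefficients); it is implemented in-package
because the pairwise analysis performs hundreds of 100,000 × ~30 fits per
Monte-Carlo replicate and the dedicated Newton loop is an order of magnitude
faster per fit.

## Causality measure and significance

For each ordered pair *j → i* the reduced model structurally removes *j*'s R
columns and re-optimises all remaining coefficients (never merely zeroing),
warm-started from the full fit.  The log-likelihood ratio logΛ =
logL_red − logL_full is non-positive up to solver tolerance; values in
(0, 1e-6·|logL_full|] are clipped to zero, larger positive values mark the
pair as a failed re-fit (reported NA).  The signed strength is Γ = sign ×
(−logΛ), where the sign is the unweighted mean of the trigger's R full-model
coefficients; for self-pairs the first window is omitted because the
absolute refractory period forces it negative regardless of the true
self-interaction (when R = 1 the lone coefficient is used).  The deviance
difference −2 logΛ is referred to χ²(R) — R coefficients are removed, so the
degrees of freedom equal the target's order — and the N² p-values (self-tests
included) enter a Benjamini–Hochberg step-up at level q (default 0.05).
Non-converged fits propagate as NA entries that are excluded from the FDR
ranking and never rejected.  Γ[j→i] and Γ[i→j] are independent quantities;
no symmetry is assumed.

## Simulator

The generator draws one uniform per neuron per bin and emits a spike when
the draw falls below λδ = min(1, exp(β₀ + Σ lag terms)) and the neuron has
not spiked within the absolute refractory period (1 ms, i.e. no spikes in
adjacent bins).  Interaction kernels are per-lag coefficient vectors: entry
m acts on the source's spike indicator m bins (milliseconds) in the past.
The thinning stream and the noise stream are split from one seed, so
enabling noise never perturbs the thinning draws and the infinite-SNR limit
reproduces the noiseless run bit for bit.  Clamping of λδ at 1 is counted
and warned about above 1% of bins.

Gaussian log-intensity noise at a requested SNR uses the uncentred
time-average power of the unperturbed log(λδ) as the signal power: a
noiseless companion run with the same thinning draws measures P_signal, the
noise variance is then σ² = P_signal/10^(SNR/10).  This is the literal
"ratio of the unperturbed log-intensity to the perturbation"; realised SNR
is reported in the simulation metadata so alternative power conventions can
be compared.

### Preset networks

The nine-neuron benchmark consists of three sub-networks of three neurons.
Every neuron is self-inhibitory (kernel [−0.6, −0.5, −0.4] over lags
1–3 ms) and receives exactly one other inhibitory input and one or two
excitatory inputs.  Within a sub-network, excitation [1, 2, 2] runs around a
cycle and inhibition [−0.8, −0.6, −0.3] around the complementary cycle;
between sub-networks, three excitatory ([0, 0, 0, 1, 2, 1], lags 4–6 ms) and
three inhibitory ([0, 0, 0, −0.8, −0.9, −0.5]) long-lag edges target neurons
1, 5, 9 and 3, 4, 8 respectively.  All baselines are 18 Hz.  With these
kernels the per-neuron totals over 100,000 bins fall in roughly 2100–2800
spikes and the AIC-selected orders split into R = 3 (6 ms) for the
cross-connected neurons {1, 3, 4, 5, 8, 9} and R = 2 (4 ms) for the
within-only neurons {2, 6, 7}: the short kernels span 3 ms ≤ 4 ms, the long
ones 6 ms.  The exact adjacency beyond these degree constraints is a design
choice of this package; a variant with a cross-excitation 3-cycle was
rejected during design because its 12–18 ms positive feedback loop induced
self-sign misclassifications, and a chain-only variant because it
undershoots the intended spike-count scale.

Density variants with 8, 16, 32 and 64 interactions (counting
self-interactions) serve the FDR calibration experiments; the 8-interaction
network leaves several neurons without any interaction — homogeneous Poisson
units.  Neurons declared to have no self-interaction are exempted from the
absolute refractory period: a refractory neuron is not homogeneous Poisson,
and the pipeline would (correctly) flag its refractoriness as a
self-inhibitory interaction, which the false-positive accounting of the
Monte-Carlo experiment would then miscount.

The five-neuron hidden-feedback ensemble observes only neurons 1–3 (wiring:
2 inhibits 1, 3 excites 1 and 2, 2 excites 3) while hidden neurons 4 and 5
form positive feedback loops with neuron 1 (1→4 and the returns 4→1, 5→1
with the long kernel [0, 0, 1, 2, 2, 1]; the forward drive 1→5 with the
short kernel).  The loops elevate neuron 1 to ~40 Hz (≈3950 spikes per
100,000 bins vs ~2250 for neurons 2–3), and because the feedback returns at
4–12 ms lags, neuron 1's own history remains informative far beyond its
3-ms self-kernel: AIC selects a modal order of 5 (10 ms) for neuron 1
against 2 (4 ms) for neurons 2–3, and the pipeline classifies neuron 1 as
self-*excitatory* although its direct self-kernel is inhibitory — the
signature by which hidden positive feedback masquerades as self-excitation.
Tight loops carrying the long kernel on both directions of both branches
are supercritical (rates run to the refractory-limited ceiling), which
constrains the adopted wiring.

## Monte-Carlo FDR experiment

Each replicate simulates a fresh realisation, selects orders by AIC
(candidates 1–4; the generator's true orders are ≤ 3) and runs the full
inference once, re-thresholding the p-value matrix at each nominal level.  A
detection is a false positive when the generator has no edge for that
ordered pair among observed neurons.  The observed FDR is the mean over
replicates of FP/(detections), with zero-detection replicates contributing 0.
Replicates that fail are skipped; the experiment errors if fewer than half
survive.

At q = 0.05 with ~30 detections over 81 tests, a perfectly calibrated
procedure still admits ~1 borderline false positive per run (the
Benjamini–Hochberg threshold sits near 0.017 with ~54 true nulls), so exact
81-entry recovery is expected in only a minority-to-half of runs even though
every true edge is detected with the correct sign and the FDR itself is
controlled.  Residual miscalibration beyond this comes from window
aggregation: the fitted 2-ms-window model is a slight coarsening of the
per-millisecond generator, and at 10⁵ bins the likelihood-ratio test has
power against these tiny projection effects.

## Goodness of fit

Time rescaling integrates the fitted λδ over each interspike interval
(bins strictly after the previous spike through the spike bin); z = 1 −
exp(−τ) is compared to uniform quantiles (k − ½)/n with the KS statistic and
a 95% bound of 1.36/√n (exact Kolmogorov critical values below n = 36).
With λδ ≈ 0.02 on 1-ms bins the naive discrete sum is adequate; no
discreteness correction is applied, which becomes a limitation only for
rates approaching the bin rate.

## What the synthetic data does and does not show

The generator realises the same model family the analysis fits (up to window
aggregation), with stationary baselines and noiseless observation.  Passing
tests therefore demonstrate correctness of the estimator, the test
calibration and the FDR machinery under the model's assumptions — not
robustness to nonstationarity, common input from unrecorded populations
(except the explicit hidden-feedback construction), spike-sorting errors, or
strongly non-Poisson firing, all of which real recordings contain.

## Problem sizes and determinism

Default experiment sizes follow the benchmark conditions: 100,000 bins of
1 ms, 18-Hz baselines, W = 2 ms, FDR q = 0.05; the Monte-Carlo FDR check
uses 20 replicates (12 for the sparse density variant in the test suite) and
the null-calibration check 200 replicates of a two-neuron ensemble over
10,000 bins, sizes chosen to keep a full run of the suite and the acceptance
script in the tens of minutes on one core.  All randomness flows through
numpy SeedSequence spawning: a single seed determines every simulation,
and identical seeds give bit-identical spike trains.
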