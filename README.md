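# ppgranger

Granger-causality inference for ensembles of simultaneously recorded neural
spike trains, using point-process (conditional-intensity) generalized linear
models.

Cross-correlation style methods detect associations between neurons but say
little about direction, handle inhibition poorly, and ignore the point-process
nature of spike trains.  `ppgranger` instead asks the Granger question
directly at the spike-train level: does the spiking history of neuron *j*
improve the prediction of neuron *i*'s spiking beyond everything else we
observe?  It is aimed at systems neuroscientists who record ensembles of
units (microelectrode arrays, silicon probes) and want a signed, statistically
controlled functional-connectivity map.

## The model and the measure

Each neuron's spiking is a discrete-time point process on 1-ms bins with
conditional intensity λᵢ[k], modelled log-linearly in the ensemble history:

    log(λᵢ[k] δ) = β₀ + Σⱼ Σᵣ γⱼᵣ · nⱼᵣ[k]

where nⱼᵣ[k] counts neuron *j*'s spikes in the *r*-th non-overlapping causal
window of width W (default 2 ms) before bin *k*, and the order R (windows per
source) is chosen per neuron by AIC.  The model is fit by maximising the
discrete point-process log-likelihood Σₖ ΔNₖ log(λₖδ) − λₖδ.

For every ordered pair *j → i* the model is re-fit with *j*'s history
structurally excluded, giving the log-likelihood ratio logΛ = logL_reduced −
logL_full ≤ 0.  The signed causality strength is

    Γⱼ→ᵢ = sign(mean γⱼ·) × (−logΛ),

positive for excitatory, negative for inhibitory influence (for
self-interactions the first window's coefficient is omitted from the sign,
since the absolute refractory period forces it negative).  Significance uses
the deviance difference −2 logΛ, asymptotically χ²(R) under the null of no
influence, with Benjamini–Hochberg FDR control over all N² ordered pairs; the
result is a trichotomous connectivity matrix C ∈ {−1, 0, +1}.  Model adequacy
is checked by the time-rescaling theorem: rescaled interspike intervals of a
well-fit neuron are uniform, assessed with a Kolmogorov–Smirnov plot and 95%
bounds.

A network simulator generates ground-truth spike trains by per-bin Bernoulli
thinning of the same log-linear intensity (with absolute refractoriness and
optional Gaussian log-intensity noise at a controlled SNR), and ships preset
benchmark networks: a nine-neuron, three-sub-network topology, density
variants with 8–64 interactions, and a five-neuron ensemble in which two
hidden neurons form positive feedback loops with an observed one.

## Worked example

```python
import ppgranger as pg

spec = pg.preset_fig1()                      # nine-neuron benchmark
ens = pg.simulate(spec, 100_000, seed=2)     # 100 s at 1-ms resolution
binned = pg.bin_spikes(ens)

orders = [pg.select_order_aic(binned, t, W=0.002, candidates=range(1, 7))[0]
          for t in range(binned.n_neurons)]
print(orders)

result = pg.GrangerAnalysis(binned, orders, W=0.002, q=0.05).fit()
print(result.summary())
```

This prints the AIC-selected history orders

```
[3, 2, 3, 3, 3, 2, 2, 3, 3]
```

— neurons 1, 3, 4, 5, 8, 9 receive long-lag cross-sub-network input and need
a 6-ms history (R=3), while neurons 2, 6, 7 interact only within their
sub-network and need 4 ms (R=2) — followed by

```
Point-process Granger causality
  neurons:            9 [1, 2, 3, 4, 5, 6, 7, 8, 9]
  history orders:     [3, 2, 3, 3, 3, 2, 2, 3, 3] (W = 2 ms)
  FDR level q:        0.05
  significant pairs:  30 / 81
  failed pairs (NA):  0

  connectivity (rows = trigger, columns = target; +1 excitatory, -1 inhibitory):
      1   2   3   4   5   6   7   8   9
  1  -1  +1   0   0   0   0   0   0   0
  2  -1  -1  +1   0  +1   0   0   0   0
  3  +1  -1  -1   0   0   0   0  -1   0
  4   0   0   0  -1  +1  -1   0   0   0
  5   0   0   0   0  -1  +1   0   0  +1
  6   0   0  -1  +1  -1  -1   0   0   0
  7  +1   0   0   0   0   0  -1  +1  -1
  8   0   0   0   0   0   0  -1  -1  +1
  9   0   0   0  -1   0   0  +1   0  -1
```

which reproduces the generator's wiring exactly: all 30 true edges (9
self-interactions, 15 within-sub-network and 6 cross-sub-network edges) are
detected with the correct excitatory/inhibitory sign and nothing else is
flagged (at q = 0.05 an occasional borderline false positive can appear in
other realisations).  The same pipeline is available from the shell:

```sh
ppgranger simulate --network fig1 --bins 100000 --seed 1 --out spikes.csv
ppgranger infer --spikes spikes.csv --out-dir results/
```

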