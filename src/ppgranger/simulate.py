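"""Generative network simulator for ensemble spike trains.

Spike trains are generated from a known ground-truth interaction network by
per-bin Bernoulli thinning of a log-linear conditional intensity: at every
1-ms bin the per-bin spike probability of neuron ``i`` is

.. math::

    \\lambda_i \\delta = \\min\\Big(1, \\exp\\big(\\beta_0
        + \\textstyle\\sum_{j} \\sum_{m \\ge 1} c_{j \\to i}[m]\\,
        \\Delta N_j[k - m]\\big)\\Big),

where :math:`\\beta_0 = \\log(\\text{baseline rate} \\times \\delta)` and
``c`` is the per-lag coefficient vector of each directed edge (entry ``m``
acts on the spike indicator ``m`` bins in the past, so a length-3 vector
spans 3 ms of history).  A spike occurs when an independent uniform draw
falls below :math:`\\lambda_i\\delta` and the neuron has not spiked within
its absolute refractory period.  Optionally, i.i.d. Gaussian noise at a
controlled signal-to-noise ratio is added to the log-intensity per neuron
and bin.

Preset networks (nine-neuron three-sub-network topologies at several
interaction densities, and a five-neuron ensemble with a hidden positive
feedback loop) are shipped as JSON files under ``ppgranger/networks`` and
loaded with :func:`preset_fig1`, :func:`preset_fig4` and
:func:`preset_fig11`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
from numba import njit

from .data import SpikeTrainEnsemble

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Edge:
    """Directed interaction with one coefficient per 1-bin lag."""

    source: int  # 1-based neuron id
    target: int
    coefficients: tuple

    def sign(self):
        s = sum(self.coefficients)
        return 1 if s > 0 else (-1 if s < 0 else 0)


@dataclass(frozen=True)
class NetworkSpec:
    """Ground-truth generative network.

    Neuron ids are 1-based.  ``observed`` lists the ids exposed in simulated
    ensembles; any others are hidden neurons that shape the dynamics but are
    dropped from the returned spike trains.
    """

    n_neurons: int
    edges: tuple
    baseline_rate: float = 18.0  # spikes/s
    delta: float = 0.001  # s
    refractory: float = 0.001  # s
    observed: tuple = ()
    refractory_exempt: tuple = ()  # neurons meant to be homogeneous Poisson
    noise_snr_db: float | None = None
    name: str = "custom"

    def __post_init__(self):
        if not self.observed:
            object.__setattr__(self, "observed",
                               tuple(range(1, self.n_neurons + 1)))
        for e in self.edges:
            if not (1 <= e.source <= self.n_neurons
                    and 1 <= e.target <= self.n_neurons):
                raise ValueError(f"edge {e} references an unknown neuron")

    @property
    def hidden(self):
        return tuple(i for i in range(1, self.n_neurons + 1)
                     if i not in self.observed)

    @property
    def n_interactions(self):
        return len(self.edges)

    def coefficient_tensor(self):
        """Dense ``(N, N, max_lag)`` array ``C[j-1, i-1, m-1]`` of lag weights."""
        max_lag = max((len(e.coefficients) for e in self.edges), default=1)
        C = np.zeros((self.n_neurons, self.n_neurons, max_lag))
        for e in self.edges:
            C[e.source - 1, e.target - 1, : len(e.coefficients)] = e.coefficients
        return C

    def ground_truth(self, observed_only=True):
        """Signed adjacency matrix ``[trigger, target]`` of the generator.

        With ``observed_only`` the matrix is restricted to (and ordered by)
        the observed neurons; edges through hidden neurons do not appear.
        """
        ids = self.observed if observed_only else tuple(range(1, self.n_neurons + 1))
        pos = {nid: k for k, nid in enumerate(ids)}
        A = np.zeros((len(ids), len(ids)), dtype=int)
        for e in self.edges:
            if e.source in pos and e.target in pos:
                A[pos[e.source], pos[e.target]] = e.sign()
        return A

    # -- (de)serialisation -------------------------------------------------
    def to_json(self, path=None):
        doc = {
            "name": self.name,
            "n_neurons": self.n_neurons,
            "baseline_rate_hz": self.baseline_rate,
            "delta_s": self.delta,
            "refractory_s": self.refractory,
            "observed": list(self.observed),
            "refractory_exempt": list(self.refractory_exempt),
            "noise_snr_db": self.noise_snr_db,
            "edges": [
                {"source": e.source, "target": e.target,
                 "coefficients": list(e.coefficients)}
                for e in self.edges
            ],
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_json(cls, source):
        """Load from a JSON document (path or already-parsed dict)."""
        if isinstance(source, dict):
            doc = source
        else:
            with open(source) as fh:
                doc = json.load(fh)
        edges = tuple(
            Edge(e["source"], e["target"], tuple(e["coefficients"]))
            for e in doc["edges"]
        )
        return cls(
            n_neurons=doc["n_neurons"], edges=edges,
            baseline_rate=doc.get("baseline_rate_hz", 18.0),
            delta=doc.get("delta_s", 0.001),
            refractory=doc.get("refractory_s", 0.001),
            observed=tuple(doc.get("observed", ())),
            refractory_exempt=tuple(doc.get("refractory_exempt", ())),
            noise_snr_db=doc.get("noise_snr_db"),
            name=doc.get("name", "custom"),
        )


def _load_preset(name):
    path = resources.files("ppgranger.networks").joinpath(f"{name}.json")
    return NetworkSpec.from_json(json.loads(path.read_text()))


def preset_fig1():
    """Nine-neuron, three-sub-network benchmark topology."""
    return _load_preset("nine_neuron")


def preset_fig4(n_interactions):
    """Nine-neuron networks with 8, 16, 32 or 64 interactions."""
    if n_interactions not in (8, 16, 32, 64):
        raise ValueError("n_interactions must be one of 8, 16, 32, 64")
    return _load_preset(f"nine_neuron_{n_interactions}")


def preset_fig11():
    """Five-neuron ensemble whose neurons 4 and 5 form hidden positive
    feedback loops with neuron 1; only neurons 1-3 are observed."""
    return _load_preset("five_neuron_hidden")


PRESETS = {
    "fig1": preset_fig1,
    "fig4-8": lambda: preset_fig4(8),
    "fig4-16": lambda: preset_fig4(16),
    "fig4-32": lambda: preset_fig4(32),
    "fig4-64": lambda: preset_fig4(64),
    "fig11": preset_fig11,
}


def add_log_cif_noise(spec, snr_db):
    """Return a copy of ``spec`` with Gaussian log-intensity noise attached.

    The noise is i.i.d. zero-mean per neuron and bin; its variance is set at
    simulation time so that ``10*log10(P_signal / var)`` equals ``snr_db``,
    with ``P_signal`` the uncentred time-average power of the unperturbed
    ``log(lambda*delta)`` measured on a noiseless companion run.
    """
    if not np.isfinite(snr_db) and snr_db != np.inf:
        raise ValueError("snr_db must be finite (or +inf for no noise)")
    return replace(spec, noise_snr_db=float(snr_db))


@njit(cache=True)
def _simulate_core(base_eta, C, refr_bins, u, noise, spikes, eta_power):
    N, n_bins = u.shape
    max_lag = C.shape[2]
    for k in range(n_bins):
        for i in range(N):
            eta = base_eta[i]
            lo = k - max_lag
            if lo < 0:
                lo = 0
            for j in range(N):
                for b in range(lo, k):
                    if spikes[j, b]:
                        eta += C[j, i, k - b - 1]
            eta_power[i] += eta * eta
            eta += noise[i, k]
            lam = np.exp(eta)
            if lam > 1.0:
                lam = 1.0
                eta_power[i + N] += 1.0  # clamp counter block
            if u[i, k] < lam:
                ok = True
                b0 = k - refr_bins[i]
                if b0 < 0:
                    b0 = 0
                for b in range(b0, k):
                    if spikes[i, b]:
                        ok = False
                        break
                if ok:
                    spikes[i, k] = 1
    return spikes


def _run_core(spec, n_bins, u, noise):
    N = spec.n_neurons
    base_eta = np.full(N, np.log(spec.baseline_rate * spec.delta))
    C = spec.coefficient_tensor()
    n_refr = int(np.ceil(spec.refractory / spec.delta)) if spec.refractory else 0
    refr_bins = np.full(N, n_refr, dtype=np.int64)
    for nid in spec.refractory_exempt:
        refr_bins[nid - 1] = 0
    spikes = np.zeros((N, n_bins), dtype=np.int8)
    acc = np.zeros(2 * N)
    _simulate_core(base_eta, C, refr_bins, u, noise, spikes, acc)
    eta_power = acc[:N] / n_bins
    clamp_frac = acc[N:] / n_bins
    return spikes, eta_power, clamp_frac


def simulate(spec, n_bins, seed, include_hidden=False):
    """Generate an ensemble of ``n_bins`` bins from a network specification.

    The same seed always produces the same output, and the uniform thinning
    draws come from a stream that is independent of the noise stream, so
    enabling noise does not perturb the thinning randomness.

    Returns a :class:`~ppgranger.data.SpikeTrainEnsemble` of the observed
    neurons (all neurons when ``include_hidden``).  Spike times are placed at
    bin centres.  The realised log-intensity signal power, noise variance and
    clamp fraction are attached as ``ensemble.simulation_info``.
    """
    C = spec.coefficient_tensor()
    if n_bins <= C.shape[2]:
        raise ValueError("n_bins must exceed the maximum history lag")
    ss = np.random.SeedSequence(seed)
    thin_ss, noise_ss = ss.spawn(2)
    N = spec.n_neurons
    u = np.random.default_rng(thin_ss).random((N, n_bins))

    noise = np.zeros((N, n_bins))
    noise_var = 0.0
    if spec.noise_snr_db is not None and np.isfinite(spec.noise_snr_db):
        # calibrate the noise power against a noiseless companion run
        _, eta_power, _ = _run_core(spec, n_bins, u, noise)
        p_signal = float(eta_power.mean())
        noise_var = p_signal / 10.0 ** (spec.noise_snr_db / 10.0)
        noise = np.random.default_rng(noise_ss).normal(
            0.0, np.sqrt(noise_var), (N, n_bins))

    spikes, eta_power, clamp_frac = _run_core(spec, n_bins, u, noise)
    if clamp_frac.max() > 0.01:
        logger.warning("intensity clamped at 1 in %.1f%% of bins for some "
                       "neuron", 100 * clamp_frac.max())

    ids = list(range(1, N + 1)) if include_hidden else list(spec.observed)
    trains = [
        (np.nonzero(spikes[i - 1])[0] + 0.5) * spec.delta for i in ids
    ]
    ens = SpikeTrainEnsemble(trains, 0.0, n_bins * spec.delta, neuron_ids=ids)
    ens.simulation_info = {
        "seed": seed,
        "n_bins": n_bins,
        "signal_power": float(eta_power.mean()),
        "noise_variance": noise_var,
        "clamp_fraction": float(clamp_frac.max()),
        "network": spec.name,
    }
    return ens


@dataclass
class MCResult:
    """Observed false-discovery rates of the full pipeline over replicates."""

    nominal_levels: list
    observed_fdr: list
    replicate_count: int
    per_replicate: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"nominal_q": self.nominal_levels,
                             "observed_fdr": self.observed_fdr,
                             "replicates": self.replicate_count})


def mc_fdr_experiment(spec, n_replicates, levels, seed, n_bins=100_000,
                      W=0.002, candidate_orders=(1, 2, 3, 4)):
    """Monte-Carlo check that the pipeline controls the FDR.

    For each replicate a fresh realisation of ``spec`` is simulated, history
    orders are selected by AIC and the network is inferred at every nominal
    level ``q``.  A detection counts as a false positive when the generator
    has no edge for that ordered (trigger, target) pair among the observed
    neurons.  Replicates with zero detections contribute 0 to the average
    ratio.
    """
    from .data import bin_spikes
    from .glm import select_order_aic
    from .granger import GrangerAnalysis, fdr_correct

    levels = list(levels)
    truth = spec.ground_truth(observed_only=True) != 0
    ratios = {q: [] for q in levels}
    n_failed = 0
    child_seeds = np.random.SeedSequence(seed).generate_state(n_replicates)
    for rep, s in enumerate(child_seeds):
        try:
            ens = simulate(spec, n_bins, int(s) % 2**31)
            binned = bin_spikes(ens, spec.delta)
            orders = [
                select_order_aic(binned, t, W, candidate_orders)[0]
                for t in range(binned.n_neurons)
            ]
            # the fits are level-independent: fit once, re-threshold per q
            res = GrangerAnalysis(binned, orders, W, q=min(levels)).fit()
            signs = np.sign(np.nan_to_num(res.gamma_matrix))
            for q in levels:
                det = fdr_correct(res.p_values, q) & (signs != 0)
                n_det = int(det.sum())
                fp = int((det & ~truth).sum())
                ratios[q].append(fp / n_det if n_det else 0.0)
        except Exception as exc:
            n_failed += 1
            logger.warning("replicate %d failed and was skipped: %s", rep, exc)
    n_ok = n_replicates - n_failed
    if n_ok < (n_replicates + 1) // 2:
        raise RuntimeError(
            f"{n_failed}/{n_replicates} Monte-Carlo replicates failed")
    return MCResult(
        nominal_levels=levels,
        observed_fdr=[float(np.mean(ratios[q])) for q in levels],
        replicate_count=n_ok,
        per_replicate={q: ratios[q] for q in levels},
    )
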