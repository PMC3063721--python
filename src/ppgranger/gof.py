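"""Time-rescaling goodness-of-fit for fitted conditional-intensity models.

If a fitted CIF is close to the true intensity of the point process, the
rescaled interspike intervals

.. math:: \\tau_m = \\sum_{k \\in (s_{m-1}, s_m]} \\hat\\lambda[k]\\,\\delta

are approximately unit-rate exponential, so :math:`z_m = 1 - e^{-\\tau_m}`
are approximately Uniform(0, 1).  Sorting the ``z`` values and plotting them
against the uniform quantiles ``(m - 1/2)/n`` gives a Kolmogorov-Smirnov
plot; the maximum deviation is compared against the 95% KS band
(``1.36/sqrt(n)`` for ``n > 35``, the exact small-sample critical value
otherwise).

With 1-ms bins and per-bin spike probabilities around 0.02 the naive
discrete sum is an adequate approximation of the integrated intensity; no
discreteness correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class RescaledTimes:
    """Sorted rescaled interspike values with their KS assessment."""

    z: np.ndarray
    ks_stat: float
    ks_bound: float
    within_95: bool

    @property
    def n(self):
        return int(self.z.size)

    def uniform_quantiles(self):
        return (np.arange(1, self.n + 1) - 0.5) / self.n


def ks_bound_95(n):
    """95% KS acceptance bound: asymptotic ``1.36/sqrt(n)`` for ``n > 35``,
    the exact Kolmogorov critical value for smaller samples."""
    if n < 1:
        raise ValueError("need at least one rescaled interval")
    if n > 35:
        return 1.36 / np.sqrt(n)
    return float(stats.kstwo.ppf(0.95, n))


def rescale_times(results, binned=None):
    """Rescale the target neuron's interspike intervals under a fitted model.

    For each interspike interval the integrated intensity ``tau`` accumulates
    the fitted ``lambda*delta`` over the bins strictly after the previous
    spike up to and including the spike bin; ``z = 1 - exp(-tau)``.  Requires
    at least two spikes in the fittable range.

    Parameters
    ----------
    results : CIFResults
        A fitted model; its stored design provides both the response and the
        fitted intensity (``binned`` is accepted for symmetry but the
        model's own binned data is used).
    """
    y = results.model.data.y
    lam = results.fitted_intensity()
    spike_bins = np.nonzero(y)[0]
    if spike_bins.size < 2:
        raise ValueError("need at least 2 spikes in the fittable range to "
                         "rescale interspike intervals")
    csum = np.concatenate(([0.0], np.cumsum(lam)))
    # tau over (previous spike bin, spike bin]
    tau = csum[spike_bins[1:] + 1] - csum[spike_bins[:-1] + 1]
    z = np.sort(1.0 - np.exp(-tau))
    n = z.size
    ks = float(np.max(np.abs(z - (np.arange(1, n + 1) - 0.5) / n)))
    bound = ks_bound_95(n)
    return RescaledTimes(z=z, ks_stat=ks, ks_bound=bound,
                         within_95=bool(ks < bound))


@dataclass
class KSReport:
    """Quantile pairs and pass/fail summary of one KS comparison."""

    model_quantiles: np.ndarray
    uniform_quantiles: np.ndarray
    ks_stat: float
    ks_bound: float
    passed: bool
    n: int

    def plot(self, ax=None):
        """KS plot with the 45-degree line and 95% confidence band."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        u = self.uniform_quantiles
        ax.plot(u, self.model_quantiles, "k-", lw=1)
        ax.plot([0, 1], [0, 1], "b-", lw=0.8)
        ax.plot([0, 1], [self.ks_bound, 1 + self.ks_bound], "b--", lw=0.8)
        ax.plot([0, 1], [-self.ks_bound, 1 - self.ks_bound], "b--", lw=0.8)
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel("uniform quantiles")
        ax.set_ylabel("rescaled-time quantiles")
        return ax


def ks_report(rescaled):
    """Build the quantile-pair report for a :class:`RescaledTimes`."""
    n = rescaled.n
    u = rescaled.uniform_quantiles()
    ks = float(np.max(np.abs(rescaled.z - u)))
    bound = rescaled.ks_bound
    return KSReport(model_quantiles=rescaled.z.copy(), uniform_quantiles=u,
                    ks_stat=ks, ks_bound=bound, passed=bool(ks < bound), n=n)


def ks_table(binned, orders, W):
    """Fit each neuron's full model and tabulate its KS goodness-of-fit.

    Returns a DataFrame with columns (neuron, n, ks_stat, bound, passed).
    """
    import pandas as pd

    from .data import HistoryWindows
    from .glm import CIFGLM

    if np.isscalar(orders):
        orders = [int(orders)] * binned.n_neurons
    rows = []
    for t, nid in enumerate(binned.neuron_ids):
        try:
            res = CIFGLM(binned, t, HistoryWindows(W=W, R=orders[t])).fit()
            rt = rescale_times(res)
            rows.append((nid, rt.n, rt.ks_stat, rt.ks_bound, rt.within_95))
        except ValueError as exc:
            rows.append((nid, 0, np.nan, np.nan, False))
    return pd.DataFrame(rows, columns=["neuron", "n", "ks_stat", "bound",
                                       "passed"])
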