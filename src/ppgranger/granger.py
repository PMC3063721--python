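"""Pairwise Granger-causality analysis of ensemble spike trains.

A trigger neuron ``j`` Granger-causes a target ``i`` if removing ``j``'s
spiking history from the target's conditional-intensity GLM significantly
reduces the point-process likelihood.  For every ordered pair the reduced
model is re-fit with the trigger's history structurally excluded, giving the
log-likelihood ratio

.. math:: \\log\\Lambda_{j \\to i} = \\log L_{reduced} - \\log L_{full} \\le 0.

The signed causality strength is :math:`\\Gamma_{j \\to i} =
\\mathrm{sign} \\times (-\\log\\Lambda)`, where the sign is the mean of the
trigger's fitted history coefficients in the full model (excitatory
positive, inhibitory negative).  Significance uses the deviance difference
:math:`-2\\log\\Lambda`, asymptotically :math:`\\chi^2_R` under the null of
no influence, with Benjamini-Hochberg FDR control across all ``N^2`` ordered
pairs.  The result is a trichotomous connectivity matrix: +1 excitatory,
-1 inhibitory, 0 no detected interaction (NaN where a fit failed).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .data import HistoryWindows
from .glm import CIFGLM

logger = logging.getLogger(__name__)

#: relative tolerance for "positive log-likelihood ratio" anomalies
LLR_POSITIVE_RTOL = 1e-6


def log_likelihood_ratio(full_results, reduced_results):
    """``logL(reduced) - logL(full)`` for a nested pair of CIF fits.

    The reduced model must be the full model re-fit with exactly one source
    structurally excluded.  Values within solver tolerance above zero are
    clipped to zero; larger positive values indicate a failed re-fit and
    raise.
    """
    full_data, red_data = full_results.model.data, reduced_results.model.data
    if red_data.excluded is None or full_data.excluded is not None:
        raise ValueError("expected a full model and a one-source-reduced model")
    if red_data.hw != full_data.hw or red_data.target != full_data.target:
        raise ValueError("models are not nested: window structure or target differ")
    llr = reduced_results.llf - full_results.llf
    if llr > 0:
        tol = LLR_POSITIVE_RTOL * abs(full_results.llf)
        if llr > tol:
            raise ValueError(
                f"log-likelihood ratio {llr:.3e} > 0 beyond tolerance: the "
                "reduced re-fit failed to reach its optimum"
            )
        llr = 0.0
    return float(llr)


def causal_sign(full_results, trigger, target):
    """Sign of the trigger's averaged history influence in the full model.

    Uses the unweighted mean of the trigger's ``R`` coefficients.  For a
    self-interaction (``trigger == target``) the first window's coefficient
    is omitted: the absolute refractory period forces it negative regardless
    of the true self-interaction (when ``R == 1`` the lone coefficient is
    used as-is).  A zero mean maps to +1 with a warning.
    """
    g = full_results.gamma(trigger)
    if trigger == target and g.size > 1:
        g = g[1:]
    m = float(g.mean())
    if m == 0.0:
        logger.warning("exactly zero mean coefficient for trigger %d -> target "
                       "%d; reporting +1", trigger, target)
        return 1
    return 1 if m > 0 else -1


def causality_measure(llr, sign):
    """Signed causality strength ``Gamma = sign * (-llr)``."""
    if llr > 0:
        raise ValueError("log-likelihood ratio must be <= 0")
    if sign not in (-1, 1):
        raise ValueError("sign must be -1 or +1")
    return float(sign * (-llr))


def deviance_test(llr, dof):
    """Upper-tail chi-squared p-value for the deviance difference ``-2*llr``."""
    if dof < 1:
        raise ValueError("degrees of freedom must be >= 1")
    stat = -2.0 * llr
    if stat < -1e-9:
        raise ValueError(f"negative deviance difference {stat:.3e}: failed re-fit")
    return float(stats.chi2.sf(max(stat, 0.0), dof))


def fdr_correct(p_values, q):
    """Benjamini-Hochberg step-up rejection mask over all finite p-values.

    NaN entries (failed fits) are never rejected and are excluded from the
    ranking; the number of hypotheses is the number of finite entries.
    """
    if not 0 < q < 1:
        raise ValueError("FDR level q must be in (0, 1)")
    p = np.asarray(p_values, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    finite = np.isfinite(p)
    if finite.any():
        rej, *_ = multipletests(p[finite], alpha=q, method="fdr_bh")
        mask[finite] = rej
    return mask


class GrangerAnalysis:
    """Ensemble-wide pairwise causality model.

    Parameters
    ----------
    binned : BinnedEnsemble
    orders : int or sequence of int
        History order ``R`` per target neuron (a scalar applies to all);
        typically chosen beforehand by :func:`~ppgranger.glm.select_order_aic`.
    W : float
        History window duration in seconds.
    q : float
        FDR level for the connectivity matrix (default 0.05).
    """

    def __init__(self, binned, orders, W, q=0.05):
        self.binned = binned
        N = binned.n_neurons
        if np.isscalar(orders):
            orders = [int(orders)] * N
        if len(orders) != N:
            raise ValueError("need one history order per neuron")
        self.orders = [int(r) for r in orders]
        self.W = float(W)
        if not 0 < q < 1:
            raise ValueError("FDR level q must be in (0, 1)")
        self.q = float(q)

    def fit(self):
        """Fit all full and reduced models and assemble the causality result."""
        N = self.binned.n_neurons
        gamma = np.full((N, N), np.nan)
        dev = np.full((N, N), np.nan)
        dof = np.zeros((N, N), dtype=int)
        pvals = np.full((N, N), np.nan)
        signs = np.zeros((N, N), dtype=int)

        for i in range(N):
            hw = HistoryWindows(W=self.W, R=self.orders[i])
            dof[:, i] = self.orders[i]
            try:
                full = CIFGLM(self.binned, i, hw).fit()
            except ValueError as exc:
                logger.warning("target %d skipped: %s", i, exc)
                continue
            if not full.converged:
                logger.warning("target %d: full model did not converge; "
                               "column reported as NA", i)
                continue
            for j in range(N):
                try:
                    reduced = self._fit_reduced(full, j)
                    if not reduced.converged:
                        raise RuntimeError("reduced fit did not converge")
                    llr = log_likelihood_ratio(full, reduced)
                except Exception as exc:
                    logger.warning("pair %d -> %d reported as NA: %s", j, i, exc)
                    continue
                s = causal_sign(full, j, i)
                signs[j, i] = s
                gamma[j, i] = causality_measure(llr, s)
                dev[j, i] = -2.0 * llr
                pvals[j, i] = deviance_test(llr, self.orders[i])

        rejected = fdr_correct(pvals, self.q)
        connectivity = np.where(rejected, signs, 0).astype(float)
        connectivity[~np.isfinite(pvals)] = np.nan
        return CausalityResult(
            neuron_ids=self.binned.neuron_ids, gamma_matrix=gamma,
            deviance_diff=dev, dof=dof, p_values=pvals,
            connectivity=connectivity, fdr_level=self.q,
            orders=self.orders, W=self.W,
        )

    def _fit_reduced(self, full, j):
        """Re-optimise the full model with source ``j`` structurally removed.

        Warm-started from the full fit with ``j``'s coefficients dropped; the
        remaining coefficients are re-optimised, never merely zeroed.
        """
        model = CIFGLM(self.binned, full.model.target, full.model.hw,
                       excluded=j, first_bin=full.model.data.first_bin)
        R = full.model.hw.R
        pos = full.model.data.sources.index(j)
        keep = np.ones(full.params.size, dtype=bool)
        keep[1 + pos * R : 1 + (pos + 1) * R] = False
        return model.fit(start_params=full.params[keep])


def infer_network(binned, orders, W, q=0.05):
    """One-call pairwise causality inference; see :class:`GrangerAnalysis`."""
    return GrangerAnalysis(binned, orders, W, q=q).fit()


class CausalityResult:
    """Signed strengths, test statistics and connectivity for all pairs.

    All matrices are indexed ``[trigger, target]``.  ``connectivity`` holds
    +1 (excitatory), -1 (inhibitory), 0 (no detected interaction) or NaN
    (fit failure for that ordered pair).
    """

    def __init__(self, neuron_ids, gamma_matrix, deviance_diff, dof, p_values,
                 connectivity, fdr_level, orders, W):
        self.neuron_ids = list(neuron_ids)
        self.gamma_matrix = gamma_matrix
        self.deviance_diff = deviance_diff
        self.dof = dof
        self.p_values = p_values
        self.connectivity = connectivity
        self.fdr_level = fdr_level
        self.orders = list(orders)
        self.W = W

    @property
    def n_neurons(self):
        return len(self.neuron_ids)

    @property
    def rejected(self):
        """Boolean mask of significant ordered pairs after FDR control."""
        conn = self.connectivity
        return np.isfinite(conn) & (conn != 0)

    def n_significant(self):
        return int(self.rejected.sum())

    # -- export ------------------------------------------------------------
    def _frame(self, matrix):
        return pd.DataFrame(matrix, index=self.neuron_ids, columns=self.neuron_ids)

    def to_csv(self, directory, prefix=""):
        """Write gamma/deviance/p/connectivity matrices as CSV files.

        Connectivity is written with integer entries and the string ``NA``
        for failed pairs.
        """
        import os

        paths = {}
        for name, mat in [("gamma", self.gamma_matrix),
                          ("deviance", self.deviance_diff),
                          ("p_values", self.p_values)]:
            path = os.path.join(directory, f"{prefix}{name}.csv")
            self._frame(mat).to_csv(path, index_label="trigger")
            paths[name] = path
        conn = self._frame(self.connectivity)
        conn = conn.map(lambda v: "NA" if not np.isfinite(v) else str(int(v)))
        path = os.path.join(directory, f"{prefix}connectivity.csv")
        conn.to_csv(path, index_label="trigger")
        paths["connectivity"] = path
        return paths

    def summary(self):
        n_na = int((~np.isfinite(self.p_values)).sum())
        lines = [
            "Point-process Granger causality",
            f"  neurons:            {self.n_neurons} {self.neuron_ids}",
            f"  history orders:     {self.orders} (W = {self.W * 1e3:g} ms)",
            f"  FDR level q:        {self.fdr_level}",
            f"  significant pairs:  {self.n_significant()} / "
            f"{self.n_neurons ** 2}",
            f"  failed pairs (NA):  {n_na}",
            "",
            "  connectivity (rows = trigger, columns = target; "
            "+1 excitatory, -1 inhibitory):",
        ]
        frame = self._frame(self.connectivity)
        frame = frame.map(lambda v: "NA" if not np.isfinite(v) else f"{int(v):+d}"
                          if v else "0")
        lines.append("  " + frame.to_string().replace("\n", "\n  "))
        return "\n".join(lines)

    def plot_connectivity(self, ax=None):
        """Heat-map of the trichotomous connectivity matrix."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = np.where(np.isfinite(self.connectivity), self.connectivity, 0)
        ax.imshow(data.T, cmap="bwr_r", vmin=-1, vmax=1, origin="upper")
        ax.set_xlabel("trigger neuron")
        ax.set_ylabel("target neuron")
        ax.set_xticks(range(self.n_neurons), self.neuron_ids)
        ax.set_yticks(range(self.n_neurons), self.neuron_ids)
        return ax

    def plot_gamma(self, ax=None):
        """Heat-map of the signed causality strengths."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        data = np.where(np.isfinite(self.gamma_matrix), self.gamma_matrix, 0)
        lim = max(np.abs(data).max(), 1e-12)
        ax.imshow(data.T, cmap="bwr_r", vmin=-lim, vmax=lim, origin="upper")
        ax.set_xlabel("trigger neuron")
        ax.set_ylabel("target neuron")
        return ax
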