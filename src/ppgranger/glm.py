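"""Conditional-intensity GLMs for single neurons.

The spiking of a target neuron is modelled as a discrete-time point process
with conditional intensity :math:`\\lambda_i[k]` whose logarithm is linear in
the ensemble spiking history,

.. math::

    \\log(\\lambda_i[k]\\,\\delta) = \\beta_0
        + \\sum_j \\sum_{r=1}^{R} \\gamma_{j,r}\\, n_{j,r}[k],

where :math:`n_{j,r}[k]` is the spike count of source neuron :math:`j` in the
``r``-th causal history window before bin ``k``.  With 0/1 responses on small
bins the point-process log-likelihood

.. math::

    \\log L = \\sum_k \\Delta N_k \\log(\\lambda_k \\delta) - \\lambda_k \\delta

coincides with a Poisson log-likelihood under a log link, so the model is fit
by Newton-Raphson (equivalently iteratively reweighted least squares), which
is globally well behaved here because the log-likelihood is concave.

:class:`CIFGLM` follows the model/results split used by statsmodels:
construct the model from a :class:`~ppgranger.data.BinnedEnsemble`, call
:meth:`~CIFGLM.fit`, and read estimates and diagnostics off the returned
:class:`CIFResults`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .data import BinnedEnsemble, HistoryWindows

logger = logging.getLogger(__name__)

#: floor applied to the per-bin intensity inside logarithms
INTENSITY_FLOOR = 1e-12
#: coefficients beyond this magnitude flag a divergent (non-converged) fit
COEF_CAP = 30.0


@dataclass
class FitData:
    """Response vector and design matrix for one target neuron.

    Rows correspond one-to-one to the bins ``first_bin .. K-1`` of the binned
    ensemble (bins with a full causal history).  Columns are an intercept
    followed by ``R`` history-window counts per included source neuron, in
    source order.
    """

    y: np.ndarray
    X: np.ndarray
    target: int
    hw: HistoryWindows | None
    excluded: int | None
    sources: list = field(default_factory=list)
    first_bin: int = 0

    @property
    def n_params(self):
        return self.X.shape[1]

    def column_labels(self):
        labels = ["const"]
        if self.hw is not None:
            for j in self.sources:
                labels += [f"src{j}_w{r + 1}" for r in range(self.hw.R)]
        return labels


def build_design(binned, target, hw, excluded=None, first_bin=None):
    """Assemble the point-process regression problem for ``target``.

    Parameters
    ----------
    binned : BinnedEnsemble
    target : int
        Row index of the target neuron.
    hw : HistoryWindows or None
        Covariate structure; ``None`` builds a baseline-only (intercept)
        design.
    excluded : int, optional
        Source row index whose history columns are structurally omitted
        (the reduced model of the causality test).  May equal ``target``.
    first_bin : int, optional
        First fittable bin; defaults to the full history depth ``R*W/delta``.
        A larger value lets nested or competing models share a common range.
    """
    N, K = binned.counts.shape
    if not 0 <= target < N:
        raise IndexError(f"target index {target} out of range for N={N}")
    if excluded is not None and not 0 <= excluded < N:
        raise IndexError(f"excluded index {excluded} out of range for N={N}")
    if hw is None:
        k0 = int(first_bin or 0)
        y = binned.counts[target, k0:].astype(float)
        return FitData(y=y, X=np.ones((y.size, 1)), target=target, hw=None,
                       excluded=excluded, sources=[], first_bin=k0)

    w = hw.window_bins(binned.delta)
    depth = hw.R * w
    k0 = depth if first_bin is None else int(first_bin)
    if k0 < depth:
        raise ValueError(f"first_bin={k0} leaves incomplete history (< {depth})")
    if k0 >= K:
        raise ValueError("no bins with full history: increase K or decrease R*W")

    ks = np.arange(k0, K)
    sources = [j for j in range(N) if j != excluded]
    X = np.empty((ks.size, 1 + len(sources) * hw.R))
    X[:, 0] = 1.0
    col = 1
    for j in sources:
        csum = np.concatenate(([0], np.cumsum(binned.counts[j], dtype=np.int64)))
        for r in range(hw.R):
            X[:, col] = csum[ks - r * w] - csum[ks - (r + 1) * w]
            col += 1
    y = binned.counts[target, k0:].astype(float)
    return FitData(y=y, X=X, target=target, hw=hw, excluded=excluded,
                   sources=sources, first_bin=k0)


def log_likelihood(params, fit_data):
    """Discrete point-process log-likelihood at ``params``.

    Evaluates ``sum_k dN_k log(lambda_k delta) - lambda_k delta`` with the
    per-bin intensity floored at a small positive guard inside the logarithm.
    """
    params = np.asarray(params, dtype=float)
    if params.size != fit_data.n_params:
        raise ValueError(
            f"parameter vector of length {params.size} does not match design "
            f"with {fit_data.n_params} columns"
        )
    mu = np.exp(fit_data.X @ params)
    return float(fit_data.y @ np.log(np.maximum(mu, INTENSITY_FLOOR)) - mu.sum())


def _newton_poisson(X, y, start=None, tol=1e-8, max_iter=100):
    """Maximise the Poisson/point-process log-likelihood by damped Newton.

    Deterministic start: intercept at log(mean response), history
    coefficients at zero.  Returns (params, llf, n_iter, converged, hessian).
    """
    n, p = X.shape
    if start is None:
        beta = np.zeros(p)
        beta[0] = np.log(max(y.mean(), INTENSITY_FLOOR))
    else:
        beta = np.asarray(start, dtype=float).copy()
    eta = X @ beta
    mu = np.exp(eta)
    ll = float(y @ eta - mu.sum())
    H = None
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        grad = X.T @ (y - mu)
        H = X.T @ (X * mu[:, None])
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            # singular information matrix (e.g. collinear or empty columns):
            # ridge jitter keeps the iteration defined
            jitter = 1e-8 * (np.trace(H) / p + 1.0)
            step = np.linalg.solve(H + jitter * np.eye(p), grad)
        t = 1.0
        while True:  # backtracking line search on the log-likelihood
            cand = beta + t * step
            eta_c = X @ cand
            with np.errstate(over="ignore"):
                mu_c = np.exp(np.minimum(eta_c, 700.0))
            ll_c = float(y @ eta_c - mu_c.sum())
            if np.isfinite(ll_c) and ll_c >= ll - 1e-12:
                break
            t *= 0.5
            if t < 1e-10:
                break
        beta, eta, mu, ll = cand, eta_c, mu_c, ll_c
        if np.max(np.abs(t * step)) <= tol * (1.0 + np.max(np.abs(beta))):
            converged = True
            break
    if np.max(np.abs(beta)) > COEF_CAP:
        converged = False  # perfect-separation style divergence
    return beta, ll, it, converged, H


class CIFGLM:
    """Point-process GLM for one target neuron's conditional intensity.

    Parameters
    ----------
    binned : BinnedEnsemble
    target : int
        Row index of the neuron being modelled.
    hw : HistoryWindows or None
        History structure shared by all source neurons; ``None`` gives the
        baseline-only model whose MLE is the mean spike probability per bin.
    excluded : int, optional
        Source neuron structurally removed from the covariates (the reduced
        model used by the causality test).
    first_bin : int, optional
        Override of the first fittable bin (for common-range comparisons).
    """

    def __init__(self, binned, target, hw, excluded=None, first_bin=None):
        self.binned = binned
        self.target = int(target)
        self.hw = hw
        self.excluded = excluded
        self.data = build_design(binned, target, hw, excluded=excluded,
                                 first_bin=first_bin)
        if self.data.y.sum() == 0:
            raise ValueError(
                f"degenerate response: neuron index {target} has no spikes in "
                "the fittable range"
            )

    def loglike(self, params):
        return log_likelihood(params, self.data)

    def fit(self, start_params=None, tol=1e-8, max_iter=100):
        params, llf, n_iter, converged, H = _newton_poisson(
            self.data.X, self.data.y, start=start_params, tol=tol,
            max_iter=max_iter,
        )
        # evaluate with the guarded likelihood so results are consistent
        llf = self.loglike(params)
        if not converged:
            logger.warning(
                "CIF fit for target index %d (excluded=%s) did not converge "
                "after %d iterations", self.target, self.excluded, n_iter,
            )
        return CIFResults(self, params, llf, n_iter, converged, H)


class CIFResults:
    """Fitted conditional-intensity model.

    Attributes
    ----------
    params : ndarray
        Intercept followed by history coefficients in design order.
    llf : float
        Maximised point-process log-likelihood.
    converged : bool
        Newton convergence and coefficient-magnitude diagnostics.
    """

    def __init__(self, model, params, llf, n_iter, converged, hessian=None):
        self.model = model
        self.params = np.asarray(params, dtype=float)
        self.llf = float(llf)
        self.n_iter = int(n_iter)
        self.converged = bool(converged)
        self._hessian = hessian

    # -- parameter views ---------------------------------------------------
    @property
    def beta0(self):
        return float(self.params[0])

    def gamma(self, source):
        """History coefficient vector of one included source neuron."""
        data = self.model.data
        if data.hw is None:
            raise ValueError("baseline-only model has no history coefficients")
        try:
            pos = data.sources.index(source)
        except ValueError:
            raise KeyError(
                f"source index {source} is structurally absent from this model"
            ) from None
        R = data.hw.R
        return self.params[1 + pos * R : 1 + (pos + 1) * R]

    @property
    def df_model(self):
        """Number of free parameters ``p = 1 + n_sources * R``."""
        return int(self.params.size)

    @property
    def aic(self):
        return -2.0 * self.llf + 2.0 * self.df_model

    @property
    def bse(self):
        """Asymptotic standard errors from the observed information matrix."""
        if self._hessian is None:
            raise ValueError("no Hessian stored for this fit")
        return np.sqrt(np.diag(np.linalg.inv(self._hessian)))

    def fitted_intensity(self):
        """Per-bin fitted ``lambda*delta`` over the fittable range."""
        return np.exp(self.model.data.X @ self.params)

    # -- reporting ---------------------------------------------------------
    def summary(self):
        data = self.model.data
        lines = [
            "Point-process CIF GLM",
            f"  target index:   {self.model.target}",
            f"  excluded:       {data.excluded}",
            f"  windows:        R={data.hw.R}, W={data.hw.W}" if data.hw
            else "  baseline-only model",
            f"  n bins fit:     {data.y.size}",
            f"  log-likelihood: {self.llf:.4f}",
            f"  AIC:            {self.aic:.4f}",
            f"  converged:      {self.converged} ({self.n_iter} iterations)",
            "",
            f"  {'coef':>12}  {'estimate':>12}",
        ]
        for name, value in zip(data.column_labels(), self.params):
            lines.append(f"  {name:>12}  {value:>12.6f}")
        return "\n".join(lines)

    def to_json(self, path=None):
        data = self.model.data
        doc = {
            "target": self.model.target,
            "excluded": data.excluded,
            "W": data.hw.W if data.hw else None,
            "R": data.hw.R if data.hw else None,
            "first_bin": data.first_bin,
            "params": self.params.tolist(),
            "columns": data.column_labels(),
            "llf": self.llf,
            "aic": self.aic,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }
        text = json.dumps(doc, indent=1)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text


def aic(results):
    """Akaike information criterion ``-2 logL + 2p`` of a fitted model."""
    return results.aic


def select_order_aic(binned, target, W, candidates, first_bin=None):
    """Choose the history order ``R`` for one neuron by AIC.

    All candidate models are evaluated on the common fittable range implied
    by the largest candidate so their likelihoods are comparable; ties break
    toward the smaller order.  Candidates whose fit fails are skipped with a
    warning.

    Returns
    -------
    (int, dict)
        The selected order and a ``{R: aic}`` table of the candidates that
        were successfully fit.
    """
    candidates = sorted(set(int(r) for r in candidates))
    if not candidates:
        raise ValueError("empty candidate list")
    r_max = max(candidates)
    hw_max = HistoryWindows(W=W, R=r_max)
    k0 = hw_max.history_bins(binned.delta) if first_bin is None else first_bin
    table = {}
    for r in candidates:
        try:
            res = CIFGLM(binned, target, HistoryWindows(W=W, R=r),
                         first_bin=k0).fit()
            if not res.converged:
                raise RuntimeError("fit did not converge")
            table[r] = res.aic
        except Exception as exc:  # pragma: no cover - defensive
            logger.warning("order candidate R=%d skipped for target %d: %s",
                           r, target, exc)
    if not table:
        raise RuntimeError(f"all order candidates failed for target {target}")
    best = min(table, key=lambda r: (table[r], r))
    return best, table
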