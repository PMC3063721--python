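"""Containers for ensemble spike trains and their discrete-time representation.

Spike trains are kept in two forms.  :class:`SpikeTrainEnsemble` stores the
raw event times (in seconds) of every neuron over a common observation
interval ``[t_start, t_end)``.  :class:`BinnedEnsemble` is the discrete-time
view used by all model fitting: the observation interval is partitioned into
``K`` half-open bins of width ``delta`` (1 ms by default) and each bin holds a
0/1 spike indicator.  The bin width is assumed small enough that a neuron
never fires twice inside one bin; violating inputs are rejected (or optionally
collapsed with a warning).

:class:`HistoryWindows` describes the covariate structure of the
conditional-intensity GLM: the recent past of each neuron is summarised by
spike counts in ``R`` non-overlapping causal windows of duration ``W``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: columns of the spike CSV interchange format
CSV_COLUMNS = ("neuron_id", "spike_time_s")


class SpikeTrainEnsemble:
    """Event-time spike trains of ``N`` neurons on ``[t_start, t_end)``.

    Parameters
    ----------
    spike_times : sequence of array-like
        One strictly increasing array of spike times (seconds) per neuron.
    t_start, t_end : float
        Observation interval bounds in seconds; every spike must lie in
        ``[t_start, t_end)``.
    neuron_ids : sequence of int, optional
        Labels for the neurons; defaults to ``1..N``.
    """

    def __init__(self, spike_times, t_start, t_end, neuron_ids=None):
        if len(spike_times) < 1:
            raise ValueError("an ensemble needs at least one neuron")
        if not t_end > t_start:
            raise ValueError(f"empty observation interval [{t_start}, {t_end})")
        self.spike_times = [np.asarray(st, dtype=float) for st in spike_times]
        self.t_start = float(t_start)
        self.t_end = float(t_end)
        if neuron_ids is None:
            neuron_ids = list(range(1, len(spike_times) + 1))
        if len(neuron_ids) != len(spike_times):
            raise ValueError("neuron_ids and spike_times length mismatch")
        self.neuron_ids = list(neuron_ids)
        self._validate()

    def _validate(self):
        for nid, st in zip(self.neuron_ids, self.spike_times):
            if st.ndim != 1:
                raise ValueError(f"neuron {nid}: spike times must be 1-D")
            if st.size and (st[0] < self.t_start or st[-1] >= self.t_end):
                raise ValueError(
                    f"neuron {nid}: spike times outside "
                    f"[{self.t_start}, {self.t_end})"
                )
            if st.size > 1 and np.any(np.diff(st) <= 0):
                raise ValueError(f"neuron {nid}: spike times not strictly increasing")

    @property
    def n_neurons(self):
        return len(self.spike_times)

    @property
    def total_spikes(self):
        return int(sum(st.size for st in self.spike_times))

    def spike_counts(self):
        """Per-neuron total spike counts, in neuron order."""
        return np.array([st.size for st in self.spike_times])

    def to_dataframe(self):
        frames = [
            pd.DataFrame({CSV_COLUMNS[0]: nid, CSV_COLUMNS[1]: st})
            for nid, st in zip(self.neuron_ids, self.spike_times)
        ]
        return pd.concat(frames, ignore_index=True)

    @classmethod
    def from_dataframe(cls, df, t_start, t_end, neuron_ids=None):
        """Build an ensemble from a two-column (neuron_id, spike_time_s) frame.

        ``neuron_ids`` fixes the neuron order (and admits silent neurons that
        have no row in the frame); by default the sorted set of ids present
        in the frame is used.
        """
        extra = set(df.columns) - set(CSV_COLUMNS)
        if extra or list(df.columns) != list(CSV_COLUMNS):
            raise ValueError(
                f"expected columns {list(CSV_COLUMNS)}, got {list(df.columns)}"
            )
        if df.empty:
            raise ValueError("no spikes: cannot build an ensemble with zero neurons")
        if neuron_ids is None:
            neuron_ids = sorted(df[CSV_COLUMNS[0]].unique())
        groups = {k: g[CSV_COLUMNS[1]].to_numpy(float) for k, g in df.groupby(CSV_COLUMNS[0])}
        trains = []
        for nid in neuron_ids:
            st = groups.get(nid, np.empty(0))
            if st.size > 1 and np.any(np.diff(st) <= 0):
                raise ValueError(f"neuron {nid}: spike times not sorted in input")
            trains.append(st)
        return cls(trains, t_start, t_end, neuron_ids=neuron_ids)

    def bin(self, delta=0.001, collapse_duplicates=False):
        return bin_spikes(self, delta, collapse_duplicates=collapse_duplicates)

    def __eq__(self, other):
        if not isinstance(other, SpikeTrainEnsemble):
            return NotImplemented
        return (
            self.t_start == other.t_start
            and self.t_end == other.t_end
            and self.neuron_ids == other.neuron_ids
            and all(
                a.size == b.size and np.array_equal(a, b)
                for a, b in zip(self.spike_times, other.spike_times)
            )
        )

    def __repr__(self):
        return (
            f"SpikeTrainEnsemble(n_neurons={self.n_neurons}, "
            f"t=[{self.t_start}, {self.t_end}), spikes={self.total_spikes})"
        )


class BinnedEnsemble:
    """0/1 spike indicators on a regular grid of ``K`` bins of width ``delta``.

    Bin ``k`` covers the half-open interval
    ``[t_start + k*delta, t_start + (k+1)*delta)`` (0-based).
    """

    def __init__(self, counts, delta, t_start=0.0, neuron_ids=None):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D (neurons x bins) array")
        if not np.isin(counts, (0, 1)).all():
            raise ValueError("bin counts must be 0/1 spike indicators")
        self.counts = counts.astype(np.int8)
        self.delta = float(delta)
        self.t_start = float(t_start)
        if neuron_ids is None:
            neuron_ids = list(range(1, counts.shape[0] + 1))
        self.neuron_ids = list(neuron_ids)

    @property
    def n_neurons(self):
        return self.counts.shape[0]

    @property
    def n_bins(self):
        return self.counts.shape[1]

    @property
    def t_end(self):
        return self.t_start + self.n_bins * self.delta

    def index_of(self, neuron_id):
        try:
            return self.neuron_ids.index(neuron_id)
        except ValueError:
            raise KeyError(f"unknown neuron id {neuron_id}") from None

    def to_csv(self, path):
        """Dense (neurons x bins) export, mainly for debugging."""
        df = pd.DataFrame(self.counts, index=self.neuron_ids)
        df.index.name = "neuron_id"
        df.to_csv(path)

    def __repr__(self):
        return (
            f"BinnedEnsemble(n_neurons={self.n_neurons}, n_bins={self.n_bins}, "
            f"delta={self.delta})"
        )


@dataclass(frozen=True)
class HistoryWindows:
    """Causal history structure of the CIF model.

    ``W`` is the window duration in seconds and ``R`` the number of
    non-overlapping windows per source neuron (the GLM spike order), so each
    source contributes ``R`` spike-count covariates spanning ``R*W`` seconds
    of strictly causal history.
    """

    W: float
    R: int

    def __post_init__(self):
        if self.W <= 0:
            raise ValueError("window duration W must be positive")
        if self.R < 1:
            raise ValueError("order R must be >= 1")

    def window_bins(self, delta):
        """Window width in bins; ``W`` must be an integer multiple of ``delta``."""
        w = self.W / delta
        if abs(w - round(w)) > 1e-9 * max(1.0, w):
            raise ValueError(
                f"W={self.W} s is not an integer multiple of delta={delta} s"
            )
        return int(round(w))

    def history_bins(self, delta):
        """Total causal history depth in bins (``R * W / delta``)."""
        return self.R * self.window_bins(delta)


def bin_spikes(ensemble, delta=0.001, collapse_duplicates=False):
    """Discretise an ensemble to 0/1 indicators at resolution ``delta``.

    A spike at time ``t`` lands in bin ``floor((t - t_start)/delta)``; a spike
    exactly on a bin boundary therefore belongs to the later bin.  Two spikes
    of one neuron in the same bin are an error unless
    ``collapse_duplicates=True``, in which case one spike is kept per bin and
    the number of collapsed events is logged.
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    span = ensemble.t_end - ensemble.t_start
    k_float = span / delta
    n_bins = int(round(k_float))
    if abs(k_float - n_bins) > 1e-6 * max(1.0, k_float):
        raise ValueError(
            f"observation interval of {span} s is not a whole number of "
            f"{delta}-s bins"
        )
    counts = np.zeros((ensemble.n_neurons, n_bins), dtype=np.int8)
    n_collapsed = 0
    for row, (nid, st) in enumerate(zip(ensemble.neuron_ids, ensemble.spike_times)):
        if st.size == 0:
            continue
        idx = np.floor((st - ensemble.t_start) / delta).astype(np.int64)
        np.clip(idx, 0, n_bins - 1, out=idx)  # guard float round-off at t_end
        uniq, n_per = np.unique(idx, return_counts=True)
        if (n_per > 1).any():
            if not collapse_duplicates:
                bad = int(uniq[n_per > 1][0])
                raise ValueError(
                    f"neuron {nid}: {int(n_per.max())} spikes fall in bin {bad} "
                    f"(delta={delta} s); use collapse_duplicates=True to keep one"
                )
            n_collapsed += int((n_per - 1).sum())
        counts[row, uniq] = 1
    if n_collapsed:
        logger.warning("collapsed %d duplicate spikes during binning", n_collapsed)
    binned = BinnedEnsemble(counts, delta, ensemble.t_start, ensemble.neuron_ids)
    binned.n_collapsed = n_collapsed
    return binned


def window_counts(binned, source, k, hw):
    """Spike counts of ``source`` in the ``R`` causal windows preceding bin ``k``.

    Element ``r`` (1-based ``r = 1..R``) counts source spikes in the bins
    covering ``[t_k - r*W, t_k - (r-1)*W)`` where ``t_k`` is the left edge of
    bin ``k``; the windows never include bin ``k`` itself.
    """
    w = hw.window_bins(binned.delta)
    if k < hw.R * w:
        raise ValueError(
            f"bin {k} has incomplete history (need k >= {hw.R * w} "
            f"for R={hw.R}, W={hw.W})"
        )
    row = binned.counts[source]
    return np.array(
        [int(row[k - (r + 1) * w : k - r * w].sum()) for r in range(hw.R)]
    )


def read_spike_csv(path):
    """Read a two-column spike CSV written by :func:`write_spike_csv`.

    The file must carry the header ``neuron_id,spike_time_s``.  Comment lines
    starting with ``#`` may define ``t_start``/``t_end`` metadata (seconds);
    without them the interval defaults to ``[0, max spike time + 1 ms)``.
    """
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for key in ("t_start", "t_end"):
                if f"{key}=" in line:
                    meta[key] = float(line.split(f"{key}=")[1].split()[0])
            if "neuron_ids=" in line:
                ids = line.split("neuron_ids=")[1].split()[0]
                meta["neuron_ids"] = [int(x) for x in ids.split(",")]
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    if df.empty:
        raise ValueError(f"{path}: no spikes; an ensemble needs at least one neuron")
    t_start = meta.get("t_start", 0.0)
    t_end = meta.get("t_end")
    if t_end is None:
        t_end = float(df[CSV_COLUMNS[1]].max()) + 1e-3
    return SpikeTrainEnsemble.from_dataframe(
        df, t_start, t_end, neuron_ids=meta.get("neuron_ids")
    )


def write_spike_csv(ensemble, path, header_comments=()):
    """Write an ensemble as CSV with interval metadata in ``#`` comments."""
    with open(path, "w") as fh:
        ids = ",".join(str(i) for i in ensemble.neuron_ids)
        fh.write(f"# t_start={ensemble.t_start!r} t_end={ensemble.t_end!r}\n")
        fh.write(f"# neuron_ids={ids}\n")
        for line in header_comments:
            fh.write(f"# {line}\n")
        ensemble.to_dataframe().to_csv(fh, index=False, lineterminator="\n")
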