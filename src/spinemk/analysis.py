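"""Spike-train and trace analysis.

Instantaneous firing rates are estimated by convolving spike trains with
unit-area Gaussian kernels; because each kernel integrates to one, the
resulting trace has units of 1/s (Hz) and integrates to the spike count.
Selection in the basal-ganglia fixtures is read out by thresholding the
output-nucleus trace: a channel counts as selected at t when its value is
strictly below the threshold (0.1 for the normalised rate model, 10 Hz for
the spiking one).
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .simulator import AnalogTrace, EventTrace, LogSet

__all__ = [
    "RateTrace",
    "gaussian_rate",
    "channel_rates",
    "detect_selection",
    "export_csv",
    "write_csv",
    "plot_lines",
    "plot_raster",
]

#: Kernel width used throughout the spiking analyses (s).
DEFAULT_SIGMA = 0.1

#: Selection thresholds: normalised rate-model output and spiking rate (Hz).
RATE_MODEL_THRESHOLD = 0.1
SPIKING_THRESHOLD_HZ = 10.0


@dataclass(frozen=True)
class RateTrace:
    """Per-channel rate (or activation) traces on a common time grid."""

    times: np.ndarray  # s
    values: np.ndarray  # (n_times, n_channels)

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values, dtype=np.float64))
        if values.shape[0] != len(self.times):
            values = values.T
        object.__setattr__(self, "values", values)
        object.__setattr__(
            self, "times", np.asarray(self.times, dtype=np.float64))

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]


def gaussian_rate(spike_times, sigma: float, grid) -> RateTrace:
    """Sum of unit-area Gaussian kernels centred on the spikes (Hz).

    An empty spike list yields an all-zero trace; the estimate is linear in
    the spike train and integrates to the spike count over a wide grid.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    grid = np.asarray(grid, dtype=np.float64)
    spikes = np.asarray(list(spike_times), dtype=np.float64)
    if spikes.size == 0:
        return RateTrace(grid, np.zeros((len(grid), 1)))
    values = norm.pdf(grid[:, None], loc=spikes[None, :], scale=sigma).sum(axis=1)
    return RateTrace(grid, values[:, None])


def channel_rates(events: EventTrace, n_channels: int,
                  neurons_per_channel: int, sigma: float,
                  grid) -> RateTrace:
    """Per-channel mean single-neuron rate (Hz) from a population event log
    whose neuron index c*m + i belongs to channel c."""
    grid = np.asarray(grid, dtype=np.float64)
    out = np.zeros((len(grid), n_channels))
    for c in range(n_channels):
        lo, hi = c * neurons_per_channel, (c + 1) * neurons_per_channel
        mask = (events.indices >= lo) & (events.indices < hi)
        trace = gaussian_rate(events.times[mask], sigma, grid)
        out[:, c] = trace.values[:, 0] / neurons_per_channel
    return RateTrace(grid, out)


def detect_selection(trace: RateTrace, threshold: float) -> np.ndarray:
    """Boolean (n_times, n_channels): channel selected where the value is
    strictly below the threshold."""
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    return trace.values < threshold


# ---------------------------------------------------------------------------
# Export and plotting
# ---------------------------------------------------------------------------

def export_csv(logset: LogSet) -> dict[str, str]:
    """CSV text per logger: analog as time,channel0,channel1,...; events as
    time,index."""
    out = {}
    for name, trace in logset.analog.items():
        buf = io.StringIO()
        header = ",".join(["time"] + [f"channel{i}"
                                      for i in range(trace.data.shape[1])])
        buf.write(header + "\n")
        for t, row in zip(trace.times, trace.data):
            buf.write(",".join([repr(float(t))]
                               + [repr(float(v)) for v in row]) + "\n")
        out[f"{name}.csv"] = buf.getvalue()
    for name, trace in logset.events.items():
        buf = io.StringIO()
        buf.write("time,index\n")
        for t, i in zip(trace.times, trace.indices):
            buf.write(f"{float(t)!r},{int(i)}\n")
        out[f"{name}.csv"] = buf.getvalue()
    return out


def write_csv(logset: LogSet, out_dir: str) -> list[str]:
    os.makedirs(out_dir, exist_ok=True)
    written = []
    for filename, text in export_csv(logset).items():
        with open(os.path.join(out_dir, filename), "w", encoding="utf-8") as fh:
            fh.write(text)
        written.append(filename)
    return written


def _figure():
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    return plt


def plot_lines(trace: AnalogTrace | RateTrace, title: str = "",
               out_path: str | None = None):
    """Line plot of an analog trace; returns the figure (the plotted data
    is accessible through the line artists)."""
    plt = _figure()
    if isinstance(trace, RateTrace):
        times, data = trace.times, trace.values
        labels = [f"channel {i}" for i in range(trace.n_channels)]
    else:
        times, data = trace.times, trace.data
        labels = [f"index {i}" for i in trace.indices]
    fig, ax = plt.subplots()
    for col, label in zip(data.T, labels):
        ax.plot(times, col, label=label)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("value")
    if title:
        ax.set_title(title)
    if data.shape[1] <= 12:
        ax.legend(loc="best", fontsize="small")
    if out_path:
        fig.savefig(out_path)
    return fig


def plot_raster(events: EventTrace, title: str = "",
                out_path: str | None = None):
    """Raster of an event log: one mark per spike, neuron index on y."""
    plt = _figure()
    fig, ax = plt.subplots()
    ax.plot(events.times, events.indices, linestyle="none", marker="|",
            markersize=4, color="black")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neuron index")
    if title:
        ax.set_title(title)
    if out_path:
        fig.savefig(out_path)
    return fig
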