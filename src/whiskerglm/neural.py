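"""Spike-train binning at 1 ms and Gaussian rate smoothing.

The smoothed rate is the plain Gaussian-kernel sum

    r(t) = 1/sqrt(2 pi sigma^2) * sum_j exp(-(t - t_j)^2 / (2 sigma^2))

evaluated on the 1 ms grid, in spikes/ms.  The kernel is truncated at
+/- 5 sigma and not renormalized at the trial edges, so the rate integrates
to the spike count up to boundary truncation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

__all__ = ["SpikeTrain", "SmoothedRate", "bin_spikes", "smooth_rate", "DEFAULT_SIGMA_MS"]

log = logging.getLogger(__name__)

DEFAULT_SIGMA_MS = 15.0  # optimal smoothing width for contact-driven units


@dataclass(frozen=True)
class SpikeTrain:
    """Binary spike indicator on the 1 ms grid plus the retained spike times."""

    binary: np.ndarray        # uint8, one bin per ms
    spike_times_ms: np.ndarray  # integer ms, after rounding and collapsing
    duration_ms: int
    n_collapsed: int = 0      # coincident spikes merged into one bin

    @property
    def n_spikes(self) -> int:
        return int(self.binary.sum())

    @property
    def mean_rate(self) -> float:
        """Spikes per 1 ms bin."""
        return float(self.binary.mean())


@dataclass(frozen=True)
class SmoothedRate:
    rate: np.ndarray          # spikes/ms on the 1 ms grid
    sigma_ms: float
    spike_times_ms: np.ndarray


def bin_spikes(spike_times_ms, duration_ms: float) -> SpikeTrain:
    """Round spike times to the nearest ms (ties to even) and mark 1 ms bins.

    Spikes that round into the same bin collapse to a single spike; the
    number of collapsed events is recorded and logged.
    """
    times = np.asarray(spike_times_ms, dtype=float)
    n_bins = int(round(duration_ms))
    if times.size == 0:
        return SpikeTrain(np.zeros(n_bins, dtype=np.uint8), np.empty(0, dtype=int), n_bins)
    bad = (times < 0) | (times > duration_ms)
    if np.any(bad):
        raise ValueError(f"spike times outside [0, {duration_ms}] ms: {times[bad]}")
    rounded = np.rint(times).astype(int)  # numpy rounds half to even
    rounded = np.clip(rounded, 0, n_bins - 1)
    binary = np.zeros(n_bins, dtype=np.uint8)
    uniq = np.unique(rounded)
    binary[uniq] = 1
    n_collapsed = rounded.size - uniq.size
    if n_collapsed:
        log.info("bin_spikes: %d coincident spikes collapsed", n_collapsed)
    return SpikeTrain(binary, uniq, n_bins, n_collapsed)


def smooth_rate(spikes: SpikeTrain, sigma_ms: float = DEFAULT_SIGMA_MS) -> SmoothedRate:
    """Gaussian-kernel smoothed firing rate in spikes/ms."""
    if sigma_ms <= 0:
        raise ValueError("sigma must be positive")
    half = int(np.ceil(5 * sigma_ms))
    x = np.arange(-half, half + 1, dtype=float)
    kernel = np.exp(-(x**2) / (2 * sigma_ms**2)) / np.sqrt(2 * np.pi * sigma_ms**2)
    rate = np.convolve(spikes.binary.astype(float), kernel, mode="same")
    return SmoothedRate(rate, sigma_ms, spikes.spike_times_ms)
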