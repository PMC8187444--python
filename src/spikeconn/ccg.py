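"""Cross-correlograms and per-unit spike-train statistics.

A cross-correlogram (CCG) is the histogram of time lags between the
spikes of a reference unit and those of a target unit; a monosynaptic
connection shows up as a short-latency peak (excitatory) or trough
(inhibitory) on the causal (positive-lag) side.  Defaults follow the
estimation pipeline's convention: window ±50 ms, 1 ms bins, hence 100
integer counts, or 96 after removing the ±2 ms centre to suppress the
spike-sorting shadowing artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._kernels import ccg_counts
from .netsim import SpikeTrainSet

__all__ = [
    "Correlogram",
    "UnitStats",
    "compute_correlogram",
    "shadow_trim",
    "rescale_augment",
    "firing_rate",
    "local_variation",
    "unit_stats",
    "filter_low_rate_units",
]

#: half-window of the trimmed interval around lag zero, ms
SHADOW_HALF_MS = 2.0


@dataclass(frozen=True)
class Correlogram:
    """Spike-count histogram over lag bins [-W, W), bin width ``delta``.

    Orientation: positive lags are target spikes *after* reference
    spikes, so the causal impact of the reference (presynaptic
    candidate) unit appears in the right half.
    """

    counts: np.ndarray
    bin_width: float = 1.0  # ms
    window: float = 50.0  # ms
    trimmed: bool = False
    n_ref: int = 0
    pair: tuple[int, int] = (-1, -1)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if np.any(counts < 0):
            raise ValueError("correlogram counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        n_expected = int(round(2 * self.window / self.bin_width))
        if self.trimmed:
            n_expected -= int(round(2 * SHADOW_HALF_MS / self.bin_width))
        if len(counts) != n_expected:
            raise ValueError(
                f"expected {n_expected} bins, got {len(counts)}"
            )

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    def lag_centers(self) -> np.ndarray:
        """Bin-centre lags in ms (of the retained bins, if trimmed)."""
        edges = np.arange(-self.window, self.window + self.bin_width / 2,
                          self.bin_width)
        centers = (edges[:-1] + edges[1:]) / 2
        if self.trimmed:
            keep = (centers < -SHADOW_HALF_MS) | (centers > SHADOW_HALF_MS)
            centers = centers[keep]
        return centers

    def reversed(self) -> "Correlogram":
        """The same histogram seen from the other unit (lag negation)."""
        return replace(self, counts=self.counts[::-1],
                       pair=(self.pair[1], self.pair[0]))


@dataclass(frozen=True)
class UnitStats:
    rate: float  # Hz
    lv: float  # NaN when fewer than 3 spikes
    n_spikes: int


def compute_correlogram(ref: np.ndarray, tgt: np.ndarray,
                        window: float = 50.0, bin_width: float = 1.0,
                        pair: tuple[int, int] = (-1, -1)) -> Correlogram:
    """Cross-correlogram of two sorted spike trains (times in seconds).

    ``counts[k]`` is the number of spike pairs whose lag t_tgt - t_ref
    falls in the half-open bin [-W + kΔ, -W + (k+1)Δ) ms.
    """
    if round(window / bin_width, 9) % 1 != 0:
        raise ValueError("window must be a multiple of the bin width")
    ref = np.ascontiguousarray(ref, dtype=np.float64) * 1000.0  # -> ms
    tgt = np.ascontiguousarray(tgt, dtype=np.float64) * 1000.0
    counts = ccg_counts(ref, tgt, float(window), float(bin_width))
    return Correlogram(counts, bin_width, window, False, len(ref), pair)


def shadow_trim(cc: Correlogram) -> Correlogram:
    """Remove the bins covering lag ±2 ms and concatenate the rest.

    Mitigates the spike-sorting shadowing effect, in which
    near-synchronous spikes are missed and the correlogram shows a
    spurious notch at the origin.  100 bins become 96 at defaults.
    """
    if cc.trimmed:
        raise ValueError("correlogram is already trimmed")
    centers = cc.lag_centers()
    keep = (centers < -SHADOW_HALF_MS) | (centers > SHADOW_HALF_MS)
    return replace(cc, counts=cc.counts[keep], trimmed=True)


def rescale_augment(spikes: SpikeTrainSet, factor: float) -> SpikeTrainSet:
    """Dilate time by ``factor``: all spike times (and the duration) are
    multiplied, so every rate scales by 1/factor while spike counts and
    connectivity labels are unchanged.  Used for data augmentation:
    correlogram features at lag τ move to lag factor·τ."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    trains = [t * factor for t in spikes.trains]
    return SpikeTrainSet(spikes.unit_ids, trains, spikes.duration * factor,
                         spikes.meta)


def firing_rate(train: np.ndarray, duration: float) -> float:
    """Spike count divided by duration (Hz)."""
    if duration <= 0:
        raise ValueError("duration must be positive")
    return len(train) / duration


def local_variation(train: np.ndarray) -> float:
    """Local variation Lv of the inter-spike intervals.

    Lv = 3/(n-1) · Σ [(I_k − I_{k+1}) / (I_k + I_{k+1})]² over the n-1
    consecutive interval pairs; 0 for a perfectly regular train, ≈1 for
    Poisson.  Returns NaN for trains with fewer than 3 spikes.
    """
    train = np.asarray(train)
    if len(train) < 3:
        return float("nan")
    isi = np.diff(train)
    num = (isi[:-1] - isi[1:]) ** 2
    den = (isi[:-1] + isi[1:]) ** 2
    ratio = np.divide(num, den, out=np.zeros_like(num), where=den > 0)
    return float(3.0 * np.mean(ratio))


def unit_stats(train: np.ndarray, duration: float) -> UnitStats:
    return UnitStats(firing_rate(train, duration), local_variation(train),
                     len(train))


def filter_low_rate_units(spikes: SpikeTrainSet,
                          min_rate: float = 1.0) -> SpikeTrainSet:
    """Drop units firing at or below ``min_rate`` Hz (strictly greater
    retained), the usual preprocessing step before connectivity
    estimation."""
    if min_rate < 0:
        raise ValueError("min_rate must be >= 0")
    keep = spikes.unit_ids[spikes.rates() > min_rate]
    return spikes.subset(keep)
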