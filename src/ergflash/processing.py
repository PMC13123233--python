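"""Sweep averaging, spectra, and frequency-domain OP isolation.

The OP split is a zero-phase partition of DFT bins: bins strictly below the
cutoff reconstruct the slow (OP-removed) waveform, bins at/above the cutoff
reconstruct the oscillatory potentials. The removed record mean is folded
back into the slow component, so ``slow + ops`` equals the input exactly up
to floating tolerance and the two components carry orthogonal energy.

No taper is applied before the DFT; records are short and baseline-anchored,
and an untapered transform keeps spectra bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .data_model import (
    AveragedWaveform,
    FilteredPair,
    OpSplitConfig,
    RunConfig,
    SweepSet,
)
from .errors import ConfigurationError

__all__ = [
    "SpectralDecomposition",
    "reject_artifacts",
    "average_sweeps",
    "compute_baseline",
    "spectrum",
    "isolate_ops",
    "process_sweepset",
]

MAD_SCALE = 1.4826  # consistency factor for Gaussian data


@dataclass
class SpectralDecomposition:
    """Single-sided amplitude spectrum (peak-amplitude convention).

    ``magnitudes[k]`` is the amplitude in µV of the sinusoid at
    ``frequencies[k]``: interior bins are scaled by 2/N, the DC and Nyquist
    bins by 1/N.
    """

    frequencies: np.ndarray  # Hz
    magnitudes: np.ndarray  # µV

    @property
    def resolution_hz(self) -> float:
        return float(self.frequencies[1] - self.frequencies[0])


def reject_artifacts(
    sweeps: SweepSet, mad_k: float = 5.0
) -> tuple[np.ndarray, np.ndarray]:
    """Flag sweeps whose peak-to-peak range is a robust outlier.

    A sweep is rejected iff ``range > median(ranges) + mad_k * 1.4826 *
    MAD(ranges)``. A zero MAD rejects nothing, and at least one sweep is
    always kept. Returns ``(kept_indices, rejected_indices)``.
    """
    if mad_k <= 0:
        raise ConfigurationError("mad_k must be positive")
    n = sweeps.n_sweeps
    if n < 2:
        warnings.warn("single-sweep set: artifact rejection skipped", stacklevel=2)
        return np.arange(n), np.array([], dtype=int)
    ranges = sweeps.traces.max(axis=1) - sweeps.traces.min(axis=1)
    med = np.median(ranges)
    mad = MAD_SCALE * np.median(np.abs(ranges - med))
    if mad == 0:
        return np.arange(n), np.array([], dtype=int)
    bad = ranges > med + mad_k * mad
    if bad.all():  # pathological: keep the most typical sweep
        keep_one = int(np.argmin(np.abs(ranges - med)))
        bad[keep_one] = False
    idx = np.arange(n)
    return idx[~bad], idx[bad]


def average_sweeps(sweeps: SweepSet, kept: np.ndarray | None = None) -> AveragedWaveform:
    """Pointwise arithmetic mean over the kept sweeps."""
    if kept is None:
        kept = np.arange(sweeps.n_sweeps)
    kept = np.asarray(kept, dtype=int)
    if kept.size == 0:
        raise ConfigurationError("cannot average an empty set of sweeps")
    mean = sweeps.traces[kept].mean(axis=0)
    return AveragedWaveform(
        eye_id=sweeps.eye_id,
        animal_id=sweeps.animal_id,
        genotype=sweeps.genotype,
        condition=sweeps.condition,
        trace=mean,
        onset_index=sweeps.onset_index,
        sampling_rate=sweeps.sampling_rate,
        n_sweeps_used=int(kept.size),
        n_sweeps_rejected=int(sweeps.n_sweeps - kept.size),
    )


def baseline_window_slice(
    onset_index: int, sampling_rate: float, window_ms: float
) -> slice:
    """Pre-onset window ``[onset - window, onset)``; fractional counts floor."""
    n_win = int(math.floor(window_ms * sampling_rate / 1000.0))
    if n_win < 1 or onset_index - n_win < 0:
        raise ConfigurationError(
            f"baseline window of {window_ms} ms does not fit before onset "
            f"(onset_index={onset_index}, fs={sampling_rate})"
        )
    return slice(onset_index - n_win, onset_index)


def compute_baseline(w: AveragedWaveform, window_ms: float = 16.0) -> float:
    """Mean voltage over the pre-onset baseline window."""
    sl = baseline_window_slice(w.onset_index, w.sampling_rate, window_ms)
    return float(w.trace[sl].mean())


def _single_sided(trace: np.ndarray, sampling_rate: float) -> SpectralDecomposition:
    n = trace.size
    spec = np.fft.rfft(trace)
    mags = np.abs(spec) * 2.0 / n
    mags[0] /= 2.0
    if n % 2 == 0:
        mags[-1] /= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return SpectralDecomposition(frequencies=freqs, magnitudes=mags)


def spectrum(w: AveragedWaveform) -> SpectralDecomposition:
    """Single-sided amplitude spectrum of the mean-removed trace."""
    if w.n_samples < 8:
        raise ConfigurationError("need at least 8 samples for a spectrum")
    trace = w.trace - w.trace.mean()
    return _single_sided(trace, w.sampling_rate)


def _adaptive_cutoff(
    detrended: np.ndarray, sampling_rate: float, split: OpSplitConfig
) -> float:
    """Spectral-minimum cutoff in the search band, fixed-cutoff fallback.

    The fallback fires when the single-sided magnitude is strictly monotone
    across the band (no trough separating slow-wave energy from OP energy).
    """
    sd = _single_sided(detrended, sampling_rate)
    lo, hi = split.adaptive_search_hz
    in_band = (sd.frequencies >= lo) & (sd.frequencies <= hi)
    mags = sd.magnitudes[in_band]
    freqs = sd.frequencies[in_band]
    if mags.size < 3:
        return split.fixed_cutoff_hz
    d = np.diff(mags)
    if np.all(d > 0) or np.all(d < 0):
        return split.fixed_cutoff_hz
    return float(freqs[int(np.argmin(mags))])


def isolate_ops(w: AveragedWaveform, split: OpSplitConfig | None = None) -> FilteredPair:
    """Split an averaged trace into slow and OP components in the frequency domain.

    Bins with centre frequency strictly below the cutoff go to ``slow``;
    all remaining bins (up to Nyquist) go to ``ops``. The split is zero-phase
    by construction (symmetric bin masking via the real FFT) and exactly
    conservative: ``slow + ops`` reproduces the input trace.
    """
    split = split or OpSplitConfig()
    nyquist = w.sampling_rate / 2.0
    mean = w.trace.mean()
    detrended = w.trace - mean
    if split.mode == "fixed":
        cutoff = split.fixed_cutoff_hz
    else:
        cutoff = _adaptive_cutoff(detrended, w.sampling_rate, split)
    if cutoff >= nyquist:
        raise ConfigurationError(f"cutoff {cutoff} Hz is not below Nyquist {nyquist}")
    n = detrended.size
    spec = np.fft.rfft(detrended)
    freqs = np.fft.rfftfreq(n, d=1.0 / w.sampling_rate)
    low_mask = freqs < cutoff
    slow = np.fft.irfft(np.where(low_mask, spec, 0.0), n=n) + mean
    ops = np.fft.irfft(np.where(low_mask, 0.0, spec), n=n)
    return FilteredPair(source=w, slow=slow, ops=ops, cutoff_hz=float(cutoff))


def process_sweepset(sweeps: SweepSet, config: RunConfig) -> FilteredPair:
    """Reject artifacts (if enabled), average, and OP-split one sweep set."""
    if config.artifact_rejection.enabled and sweeps.n_sweeps >= 2:
        kept, _ = reject_artifacts(sweeps, config.artifact_rejection.mad_k)
    else:
        kept = np.arange(sweeps.n_sweeps)
    avg = average_sweeps(sweeps, kept)
    return isolate_ops(avg, config.op_split)
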