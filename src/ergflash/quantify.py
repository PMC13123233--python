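"""a-wave, b-wave and OP quantification on OP-removed traces.

Measurement rules:

* baseline = mean of the 16 ms pre-onset window of the averaged trace;
* a-wave trough = global minimum of the slow trace within 50 ms after onset,
  amplitude = baseline − trough, implicit time = time of the trough;
* b-wave peak = global maximum after the a-trough (or after onset + 10 ms
  when no a-wave is detected), amplitude = peak − trough (or peak − baseline
  without an a-wave), implicit time = time of the peak;
* OP amplitude = maximal single-sided spectral magnitude in 60–100 Hz.

Extrema are located at sample resolution and refined by a three-point
parabolic fit (standard sub-sample peak interpolation), so implicit times
are not quantized to the 1/fs grid. Ties between equal samples resolve to
the earliest time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .data_model import (
    Adaptation,
    ComponentMeasures,
    FilteredPair,
    RunConfig,
)
from .errors import ConfigurationError
from .processing import (
    SpectralDecomposition,
    baseline_window_slice,
    compute_baseline,
    spectrum,
)

__all__ = [
    "AWaveResult",
    "BWaveResult",
    "measure_a_wave",
    "measure_b_wave",
    "measure_op_amplitude",
    "quantify_pair",
    "quantify_eye",
]


@dataclass
class AWaveResult:
    detected: bool
    amplitude: float | None  # µV, baseline − trough
    implicit_time: float | None  # ms from onset
    trough_value: float | None  # µV (refined)
    trough_index: int | None  # sample index of the discrete minimum


@dataclass
class BWaveResult:
    amplitude: float  # µV
    implicit_time: float  # ms from onset
    at_record_edge: bool


def _refine(y: np.ndarray, k: int, minimum: bool) -> tuple[float, float]:
    """Sub-sample extremum location via a local least-squares parabola.

    A quadratic is fitted over up to ±2 samples around the discrete extremum
    ``k`` and its vertex gives the refined time offset (in samples, clipped
    to the window). The *value* returned is always the discrete sample
    ``y[k]``: amplitudes are read off the trace, only times are refined.
    Falls back to offset 0 at record edges or degenerate curvature.
    """
    value = float(y[k])
    half = min(2, k, y.size - 1 - k)
    if half < 1:
        return 0.0, value
    x = np.arange(-half, half + 1, dtype=float)
    w = y[k - half : k + half + 1]
    b2, b1, _ = np.polyfit(x, w, 2)
    if (minimum and b2 <= 0) or (not minimum and b2 >= 0) or b2 == 0:
        return 0.0, value
    delta = float(np.clip(-b1 / (2.0 * b2), -half, half))
    return delta, value


def _prestim_residual_sd(slow: np.ndarray, onset_index: int, sampling_rate: float,
                         window_ms: float) -> float:
    sl = baseline_window_slice(onset_index, sampling_rate, window_ms)
    seg = slow[sl]
    return float(seg.std(ddof=0))


def measure_a_wave(
    slow: np.ndarray,
    baseline: float,
    onset_index: int,
    sampling_rate: float,
    search_ms: float = 50.0,
    detect_threshold: float | None = None,
    baseline_window_ms: float = 16.0,
    detect_sd_mult: float = 3.0,
    detect_min_uv: float = 5.0,
) -> AWaveResult:
    """Locate the a-wave trough within ``search_ms`` after stimulus onset.

    ``detect_threshold`` (µV) overrides the default rule of
    ``detect_sd_mult`` × SD of the pre-stimulus residuals of the slow trace,
    floored at ``detect_min_uv`` (sub-µV filter ringing alone must not
    trigger a detection). The trough is treated as undetected when the
    amplitude does not exceed the threshold or the minimum sits on the far
    edge of the search window.
    """
    n_search = int(np.floor(search_ms * sampling_rate / 1000.0))
    start = onset_index + 1
    stop = onset_index + n_search + 1  # inclusive of onset + search_ms
    if stop > slow.size:
        raise ConfigurationError("a-wave search window exceeds the record")
    window = slow[start:stop]
    k_rel = int(np.argmin(window))
    k = start + k_rel
    if detect_threshold is None:
        detect_threshold = max(
            detect_sd_mult
            * _prestim_residual_sd(slow, onset_index, sampling_rate, baseline_window_ms),
            detect_min_uv,
        )
    delta, trough_val = _refine(slow, k, minimum=True)
    amplitude = baseline - trough_val
    at_edge = k_rel == window.size - 1
    if amplitude <= detect_threshold or at_edge:
        return AWaveResult(False, None, None, None, None)
    it = (k + delta - onset_index) / sampling_rate * 1000.0
    return AWaveResult(True, float(amplitude), float(it), trough_val, k)


def measure_b_wave(
    slow: np.ndarray,
    baseline: float,
    onset_index: int,
    sampling_rate: float,
    a_result: AWaveResult | None = None,
    b_search_start_ms: float = 10.0,
) -> BWaveResult:
    """Locate the b-wave peak after the a-trough (or after onset + 10 ms)."""
    if a_result is not None and a_result.detected:
        start = a_result.trough_index + 1
        ref = a_result.trough_value
    else:
        start = onset_index + int(np.floor(b_search_start_ms * sampling_rate / 1000.0)) + 1
        ref = baseline
    if start >= slow.size:
        start = slow.size - 1
    window = slow[start:]
    k = start + int(np.argmax(window))
    # edge flag also fires on ties: a final sample indistinguishable from the
    # detected peak means the real peak may lie beyond the record
    at_edge = k == slow.size - 1 or window[-1] == window.max()
    delta, peak_val = _refine(slow, k, minimum=False)
    amplitude = max(peak_val - ref, 0.0)
    it = (k + delta - onset_index) / sampling_rate * 1000.0
    return BWaveResult(float(amplitude), float(it), at_edge)


def measure_op_amplitude(
    spec: SpectralDecomposition, band_hz: tuple[float, float] = (60.0, 100.0)
) -> float:
    """Maximal single-sided magnitude over bins whose centre lies in the band."""
    lo, hi = band_hz
    mask = (spec.frequencies >= lo) & (spec.frequencies <= hi)
    if not mask.any():
        raise ConfigurationError(
            f"no spectral bins inside {band_hz} Hz (resolution "
            f"{spec.resolution_hz} Hz)"
        )
    return float(spec.magnitudes[mask].max())


def quantify_pair(pair: FilteredPair, config: RunConfig) -> ComponentMeasures:
    """Measure one filtered eye × condition record.

    DA records carry a/b/OP measures; LA records carry the b-wave only
    (photopic a-waves and OPs are not analyzed).
    """
    w = pair.source
    baseline = compute_baseline(w, config.baseline_window_ms)
    flags: set[str] = set()
    adaptation = w.condition.adaptation

    a_res: AWaveResult | None = None
    op_amp: float | None = None
    if adaptation is Adaptation.DA:
        a_res = measure_a_wave(
            pair.slow,
            baseline,
            w.onset_index,
            w.sampling_rate,
            search_ms=config.a_search_ms,
            baseline_window_ms=config.baseline_window_ms,
            detect_sd_mult=config.a_detect_sd_mult,
            detect_min_uv=config.a_detect_min_uv,
        )
        if not a_res.detected:
            flags.add("a_undetected")
        op_amp = measure_op_amplitude(spectrum(w), config.op_band_hz)

    b_res = measure_b_wave(
        pair.slow,
        baseline,
        w.onset_index,
        w.sampling_rate,
        a_result=a_res,
        b_search_start_ms=config.b_search_start_ms,
    )
    if b_res.at_record_edge:
        flags.add("b_at_record_edge")

    return ComponentMeasures(
        eye_id=w.eye_id,
        animal_id=w.animal_id,
        genotype=w.genotype,
        adaptation=adaptation,
        flash_strength=w.condition.flash_strength,
        baseline=baseline,
        a_amplitude=a_res.amplitude if (a_res and a_res.detected) else None,
        a_implicit_time=a_res.implicit_time if (a_res and a_res.detected) else None,
        b_amplitude=b_res.amplitude,
        b_implicit_time=b_res.implicit_time,
        op_spectral_amplitude=op_amp,
        flags=frozenset(flags),
    )


def quantify_eye(
    pairs: Sequence[FilteredPair], config: RunConfig
) -> list[ComponentMeasures]:
    """Quantify all available conditions of one eye; rows are never fabricated
    for missing conditions."""
    out = []
    for pair in sorted(
        pairs,
        key=lambda p: (
            p.source.condition.adaptation.value,
            p.source.condition.flash_strength,
        ),
    ):
        out.append(quantify_pair(pair, config))
    return out
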