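"""Sensor-space preprocessing: filtering, resampling, montage, epoching.

The chain mirrors standard neonatal EEG practice: a broad prefilter
(0.4-45 Hz), decimation to 100 Hz, conversion to the average montage,
zero-phase Butterworth band filtering into the bands of interest, and
selection of six equidistant 30-second windows per sleep state (3 min of
data per state).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .config import BandSpec

logger = logging.getLogger(__name__)


class InvalidBandError(ValueError):
    """Band edges incompatible with the sampling rate."""


class SubjectExclusionError(RuntimeError):
    """Recording lacks enough annotated data for the requested epochs."""


@dataclass
class SensorRecording:
    """Multichannel sensor time series with sleep-state annotations.

    ``annotations`` is a list of ``(state, start_s, end_s)`` tuples;
    states are free labels (typically ``"AS"`` / ``"QS"``) and intervals
    within one state must not overlap.
    """

    data: np.ndarray  # channels x samples
    sampling_rate: float
    channel_names: list[str] = field(default_factory=list)
    annotations: list[tuple[str, float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be channels x samples")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("data contains NaN/Inf")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if not self.channel_names:
            self.channel_names = [f"ch{i:02d}" for i in range(self.data.shape[0])]
        by_state: dict[str, list[tuple[float, float]]] = {}
        for state, t0, t1 in self.annotations:
            if t1 <= t0:
                raise ValueError("annotation with non-positive duration")
            by_state.setdefault(state, []).append((t0, t1))
        for state, ivals in by_state.items():
            ivals = sorted(ivals)
            for (a0, a1), (b0, _) in zip(ivals, ivals[1:]):
                if b0 < a1:
                    raise ValueError(f"overlapping annotations in state {state}")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def state_segments(self, state: str) -> list[tuple[float, float]]:
        return sorted((t0, t1) for s, t0, t1 in self.annotations if s == state)


@dataclass
class EpochSet:
    """Selected analysis windows, ``(state, start_s, end_s)`` each."""

    windows: list[tuple[str, float, float]]
    window_length: float

    @property
    def total_per_state(self) -> dict[str, float]:
        tot: dict[str, float] = {}
        for state, t0, t1 in self.windows:
            tot[state] = tot.get(state, 0.0) + (t1 - t0)
        return tot

    def n_windows(self, state: str) -> int:
        return sum(1 for s, _, _ in self.windows if s == state)


#: transition band as a fraction of each cut-off; narrow enough that the
#: four band outputs stay nearly incoherent (cross-band coherence < 0.1)
TRANSITION_FRACTION = 0.125


def _butter_sos(kind: str, cutoff: float, fs: float,
                gpass: float = 1.0, gstop: float = 20.0):
    """Minimum-order Butterworth designed from an attenuation spec.

    Transition band is 12.5% of the cut-off (stop edge at 0.875x cutoff
    for a high-pass, 1.125x for a low-pass); stop-band attenuation 20 dB
    per pass (>=40 dB after forward-backward application).
    """
    nyq = fs / 2.0
    if cutoff >= nyq:
        raise InvalidBandError(f"cutoff {cutoff} Hz >= Nyquist {nyq} Hz")
    frac = TRANSITION_FRACTION
    if kind == "highpass":
        wp, ws = cutoff / nyq, (1 - frac) * cutoff / nyq
    elif kind == "lowpass":
        wp, ws = cutoff / nyq, min((1 + frac) * cutoff / nyq, 0.999)
    else:  # pragma: no cover
        raise ValueError(kind)
    order, wn = sps.buttord(wp, ws, gpass, gstop)
    order = max(order, 1)
    logger.debug("butter %s @%.3g Hz: order %d", kind, cutoff, order)
    return sps.butter(order, wn, btype=kind.replace("pass", ""), output="sos")


def bandpass_zero_phase(rec: SensorRecording, band: BandSpec) -> SensorRecording:
    """Zero-phase band filtering as a high-pass/low-pass Butterworth pair.

    Each filter is applied forward-backward (``sosfiltfilt``) so the net
    phase response is zero and the effective stop-band attenuation
    doubles.
    """
    band.validate(rec.sampling_rate)
    hp = _butter_sos("highpass", band.low, rec.sampling_rate)
    lp = _butter_sos("lowpass", band.high, rec.sampling_rate)
    out = sps.sosfiltfilt(hp, rec.data, axis=1)
    out = sps.sosfiltfilt(lp, out, axis=1)
    return replace(rec, data=out)


def prefilter(rec: SensorRecording, low: float = 0.4,
              high: float = 45.0) -> SensorRecording:
    """Broad-band prefilter applied before decimation."""
    high = min(high, 0.45 * rec.sampling_rate)
    return bandpass_zero_phase(rec, BandSpec("prefilter", low, high))


def resample_to(rec: SensorRecording, target: float) -> SensorRecording:
    """Anti-aliased rational-ratio resampling (polyphase) to `target` Hz."""
    if target > rec.sampling_rate:
        raise ValueError("upsampling not supported")
    if target == rec.sampling_rate:
        return rec
    frac = Fraction(target / rec.sampling_rate).limit_denominator(1000)
    out = sps.resample_poly(rec.data, frac.numerator, frac.denominator, axis=1)
    return replace(rec, data=out, sampling_rate=target)


def average_reference(rec: SensorRecording) -> SensorRecording:
    """Convert to the average montage (channel mean removed per sample)."""
    if rec.n_channels < 2:
        raise ValueError("average reference needs >=2 channels")
    return replace(rec, data=rec.data - rec.data.mean(axis=0, keepdims=True))


def select_epochs(rec: SensorRecording, state: str, n_windows: int = 6,
                  window_length: float = 30.0) -> EpochSet:
    """Equidistant fixed-length windows across a sleep state's span.

    Window onsets are spaced evenly over the annotated span of `state`
    (concatenating within-state segments when the state is interrupted),
    rounded down to the sample grid. With exactly ``n_windows *
    window_length`` seconds available the windows are back-to-back.

    Raises
    ------
    SubjectExclusionError
        If the annotated duration for `state` is shorter than
        ``n_windows * window_length`` — the subject cannot contribute.
    """
    segs = rec.state_segments(state)
    total = sum(t1 - t0 for t0, t1 in segs)
    needed = n_windows * window_length
    if total + 1e-9 < needed:
        raise SubjectExclusionError(
            f"state {state}: {total:.1f} s available < {needed:.1f} s required")
    dt = 1.0 / rec.sampling_rate
    # Equidistant onsets on the concatenated within-state timeline.
    span = total - window_length
    if n_windows == 1:
        onsets = [span / 2.0]
    else:
        onsets = [k * span / (n_windows - 1) for k in range(n_windows)]
    # Segment offsets on the concatenated timeline.
    starts = np.cumsum([0.0] + [t1 - t0 for t0, t1 in segs[:-1]])
    windows: list[tuple[str, float, float]] = []
    prev_end = -np.inf
    for onset in onsets:
        i = int(np.searchsorted(starts, onset + 1e-12) - 1)
        i = max(i, 0)
        seg_t0, seg_t1 = segs[i]
        abs_start = seg_t0 + (onset - starts[i])
        # Keep the window inside one contiguous segment.
        abs_start = min(abs_start, seg_t1 - window_length)
        if abs_start < seg_t0:
            raise SubjectExclusionError(
                f"state {state}: segment too short for a {window_length:.0f} s window")
        abs_start = np.floor(abs_start / dt) * dt
        if abs_start < prev_end - 1e-9:
            abs_start = prev_end
            if abs_start + window_length > seg_t1 + 1e-9:
                raise SubjectExclusionError(
                    f"state {state}: cannot place non-overlapping windows")
        windows.append((state, float(abs_start), float(abs_start + window_length)))
        prev_end = abs_start + window_length
    return EpochSet(windows=windows, window_length=window_length)


def extract_windows(rec: SensorRecording, epochs: EpochSet,
                    state: str | None = None) -> list[np.ndarray]:
    """Slice the recording into the selected windows (channels x samples)."""
    out = []
    n_win = int(round(epochs.window_length * rec.sampling_rate))
    for s, t0, _t1 in epochs.windows:
        if state is not None and s != state:
            continue
        i0 = int(round(t0 * rec.sampling_rate))
        seg = rec.data[:, i0:i0 + n_win]
        if seg.shape[1] < n_win:
            raise SubjectExclusionError("window extends past end of recording")
        out.append(seg)
    return out
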