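"""Cleaning and filtering of raw electrodermal activity recordings.

The fixed preprocessing order is: artifact removal -> zero-phase Butterworth
low-pass -> moving average -> integer-stride downsampling.  All filters are
linear and leave units (microsiemens) and phase structure untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage, signal

PHASE_NAMES = ("REST", "MAT", "REC1", "RLX", "REC2")


class UnusableRecordingError(ValueError):
    """A recording too corrupted to analyse (e.g. >50% artifact in a phase)."""


@dataclass
class EDARecording:
    """One subject's conductance time series with phase annotation.

    samples are in microsiemens at ``sampling_rate_hz``; ``phase_bounds``
    are five contiguous half-open ``[start_s, end_s)`` intervals in the
    order REST, MAT, REC1, RLX, REC2.  ``artifact_mask`` marks corrupted
    samples (True = corrupted) when present.
    """

    subject_id: str
    group: str
    sampling_rate_hz: float
    samples: np.ndarray
    phase_bounds: tuple[tuple[float, float], ...]
    phase_names: tuple[str, ...] = PHASE_NAMES
    artifact_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.group not in ("control", "case"):
            raise ValueError(f"group must be 'control' or 'case', got {self.group!r}")
        if len(self.phase_bounds) != 5 or len(self.phase_names) != 5:
            raise ValueError("exactly five phases are required")
        for (s0, e0), (s1, e1) in zip(self.phase_bounds, self.phase_bounds[1:]):
            if not (e0 == s1 and e0 > s0 and e1 > s1):
                raise ValueError("phase intervals must be contiguous, ordered and non-empty")
        expected = int(round(self.duration_s * self.sampling_rate_hz))
        if len(self.samples) != expected:
            raise ValueError(
                f"sample count {len(self.samples)} does not match "
                f"{self.duration_s}s at {self.sampling_rate_hz}Hz ({expected})"
            )
        if self.artifact_mask is not None:
            self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
            if self.artifact_mask.shape != self.samples.shape:
                raise ValueError("artifact_mask must match samples in length")

    @property
    def duration_s(self) -> float:
        return self.phase_bounds[-1][1] - self.phase_bounds[0][0]

    def phase_slice(self, phase: str) -> slice:
        i = self.phase_names.index(phase)
        s, e = self.phase_bounds[i]
        r = self.sampling_rate_hz
        return slice(int(round(s * r)), int(round(e * r)))


@dataclass(frozen=True)
class FilterSpec:
    """Preprocessing parameters: filter orders, cutoffs and analysis rate."""

    butter_order: int = 2
    butter_cutoff_hz: float = 1.0
    ma_window_s: float = 0.25
    target_rate_hz: float = 8.0

    def __post_init__(self) -> None:
        if self.ma_window_s <= 0:
            raise ValueError("ma_window_s must be > 0")
        if self.target_rate_hz <= 0:
            raise ValueError("target_rate_hz must be > 0")


def detect_artifacts(
    samples: np.ndarray, max_step_uS: float = 1.0, rate_hz: float | None = None
) -> np.ndarray:
    """Flag motion artifacts: conductance jumps larger than ``max_step_uS``
    between neighbouring samples, plus samples deviating from a one-second
    rolling median by the same threshold (catches short plateau spikes whose
    interior has no jump).

    Sudomotor activity cannot move conductance by a full microsiemens within
    one sample at typical rates; such excursions are treated as artifact.
    """
    x = np.asarray(samples, dtype=float)
    mask = np.zeros(x.shape, dtype=bool)
    jumps = np.abs(np.diff(x)) > max_step_uS
    mask[1:] |= jumps
    mask[:-1] |= jumps
    if rate_hz is not None and len(x) > 3:
        w = max(3, int(round(rate_hz)) | 1)
        med = ndimage.median_filter(x, size=min(w, len(x) | 1), mode="nearest")
        mask |= np.abs(x - med) > max_step_uS
    return mask


def remove_artifacts(recording: EDARecording, max_step_uS: float = 1.0) -> EDARecording:
    """Replace artifact spans by linear interpolation between clean samples.

    Uses the recording's own mask when present, otherwise the step-detection
    fallback.  A phase with more than half its samples masked renders the
    recording unusable (``UnusableRecordingError``).
    """
    mask = recording.artifact_mask
    if mask is None:
        mask = detect_artifacts(recording.samples, max_step_uS, recording.sampling_rate_hz)
    if not mask.any():
        return replace(recording, artifact_mask=None)
    for phase in recording.phase_names:
        sl = recording.phase_slice(phase)
        frac = mask[sl].mean()
        if frac > 0.5:
            raise UnusableRecordingError(
                f"subject {recording.subject_id}: {frac:.0%} of phase {phase} is artifact"
            )
    x = recording.samples.copy()
    idx = np.arange(len(x))
    clean = ~mask
    x[mask] = np.interp(idx[mask], idx[clean], x[clean])
    return replace(recording, samples=x, artifact_mask=None)


def butterworth_lowpass(
    samples: np.ndarray, rate_hz: float, order: int = 2, cutoff_hz: float = 1.0
) -> np.ndarray:
    """Zero-phase (forward-backward) Butterworth low-pass filter."""
    if cutoff_hz >= rate_hz / 2:
        raise ValueError(f"cutoff {cutoff_hz}Hz must be below Nyquist ({rate_hz / 2}Hz)")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=rate_hz, output="sos")
    return signal.sosfiltfilt(sos, np.asarray(samples, dtype=float))


def moving_average(samples: np.ndarray, rate_hz: float, window_s: float) -> np.ndarray:
    """Centred uniform smoothing with reflective edge padding."""
    x = np.asarray(samples, dtype=float)
    w = int(round(window_s * rate_hz))
    if w < 2:
        raise ValueError(f"window of {window_s}s is shorter than 2 samples at {rate_hz}Hz")
    if w > len(x):
        raise ValueError("moving-average window longer than the signal")
    return ndimage.uniform_filter1d(x, size=w, mode="reflect")


def downsample(samples: np.ndarray, rate_hz: float, target_hz: float) -> np.ndarray:
    """Decimate by an integer stride (low-pass filtering must precede this)."""
    stride = rate_hz / target_hz
    if abs(stride - round(stride)) > 1e-9:
        raise ValueError(f"target rate {target_hz}Hz must divide the current rate {rate_hz}Hz")
    return np.asarray(samples, dtype=float)[:: int(round(stride))]


def preprocess(recording: EDARecording, spec: FilterSpec = FilterSpec()) -> EDARecording:
    """Full cleaning pipeline: artifacts -> Butterworth -> moving average -> decimate.

    Phase boundaries stay expressed in seconds, so they survive the rate
    change unchanged; conductance is clipped at zero from below after
    filtering.
    """
    rec = remove_artifacts(recording)
    rate = rec.sampling_rate_hz
    x = butterworth_lowpass(rec.samples, rate, spec.butter_order, spec.butter_cutoff_hz)
    x = moving_average(x, rate, spec.ma_window_s)
    if spec.target_rate_hz != rate:
        x = downsample(x, rate, spec.target_rate_hz)
        rate = spec.target_rate_hz
    x = np.clip(x, 0.0, None)
    return EDARecording(
        subject_id=rec.subject_id,
        group=rec.group,
        sampling_rate_hz=rate,
        samples=x,
        phase_bounds=rec.phase_bounds,
        phase_names=rec.phase_names,
    )
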