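"""From raw trace segments to per-eye regional epoch RMS.

Processing chain, in recording order: two-pass artifact rejection on the 16
recording segments, zero-phase 1-200 Hz band-pass per segment, first-order
kernel extraction by cross-correlation with the +/-1-recoded m-sequence, and
root-mean-square amplitudes over three post-step epochs:

* DC  (direct component)        15-45 ms
* IC1 (first induced component) 45-75 ms
* IC2 (second induced component) 75-105 ms

Per-hexagon RMS values are then averaged over the central 7 (10 deg) and
central 19 (15 deg) hexagons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import ConfigurationError, DataError, DegenerateInputError, RangeError
from .geometry import HexLayout, RegionMask
from .stimulus import FrameSchedule, MSequence

#: Epoch windows in ms after the m-frame onset (half-open intervals).
DEFAULT_WINDOWS: dict[str, tuple[float, float]] = {
    "dc": (15.0, 45.0), "ic1": (45.0, 75.0), "ic2": (75.0, 105.0),
}

#: Kernel epoch span in ms; covers all three analysis windows.
EPOCH_MS = 105.0


@dataclass(frozen=True)
class KernelWaveform:
    """First-order response of one hexagon on the 0-105 ms post-step grid."""

    hexagon_id: int
    samples: np.ndarray
    sample_rate: float

    def __post_init__(self):
        s = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(s)):
            raise DataError(f"non-finite samples in kernel {self.hexagon_id}")
        if len(s) / self.sample_rate * 1000.0 < EPOCH_MS - 1e-6:
            raise DataError("kernel shorter than the 105 ms analysis span")
        object.__setattr__(self, "samples", s)

    @property
    def duration_ms(self) -> float:
        return len(self.samples) / self.sample_rate * 1000.0


@dataclass(frozen=True)
class EpochRMS:
    """Per-eye DC/IC1/IC2 RMS averages over the 10 and 15 degree regions (µV)."""

    eye_id: str
    dc10: float
    ic1_10: float
    ic2_10: float
    dc15: float
    ic1_15: float
    ic2_15: float
    windows: dict = field(default_factory=lambda: dict(DEFAULT_WINDOWS))

    def __post_init__(self):
        vals = (self.dc10, self.ic1_10, self.ic2_10,
                self.dc15, self.ic1_15, self.ic2_15)
        if any(v < 0 for v in vals):
            raise DataError("RMS values must be non-negative")

    def value(self, epoch: str, region: str) -> float:
        key = {"10": "10", "central10": "10",
               "15": "15", "central15": "15"}[region]
        attr = f"dc{key}" if epoch == "dc" else f"{epoch}_{key}"
        return getattr(self, attr)

    def as_dict(self) -> dict:
        return {"dc10": self.dc10, "ic1_10": self.ic1_10, "ic2_10": self.ic2_10,
                "dc15": self.dc15, "ic1_15": self.ic1_15, "ic2_15": self.ic2_15}


# ---------------------------------------------------------------------------
# Artifact rejection
# ---------------------------------------------------------------------------

def reject_artifacts(segments: list[np.ndarray], z_threshold: float = 3.0,
                     passes: int = 2):
    """Two-pass peak-amplitude outlier rejection over recording segments.

    In each pass, a segment is flagged when the z-score of its peak absolute
    amplitude relative to the remaining (unflagged, leave-one-out) segments
    exceeds ``z_threshold``; flagged segments are replaced by the mean of
    their nearest surviving neighbours in recording order.  A second pass
    catches borderline artifacts whose z-score was masked by a gross outlier
    in the first pass.

    Returns ``(cleaned_segments, log)`` where ``log[p]`` lists the segment
    indices flagged in pass ``p``.
    """
    if len(segments) < 2:
        raise DataError("need at least 2 segments")
    cleaned = [np.asarray(s, dtype=float).copy() for s in segments]
    n = len(cleaned)
    ever_flagged: set[int] = set()
    log: list[list[int]] = []

    for _ in range(passes):
        peaks = np.array([np.max(np.abs(s)) for s in cleaned])
        flagged_now = []
        for i in range(n):
            others = [peaks[j] for j in range(n) if j != i and j not in ever_flagged]
            if len(others) < 2:
                continue
            mu, sd = float(np.mean(others)), float(np.std(others, ddof=1))
            if sd < 1e-12:
                z = np.inf if peaks[i] > mu + 1e-12 else 0.0
            else:
                z = (peaks[i] - mu) / sd
            if z > z_threshold:
                flagged_now.append(i)
        log.append(flagged_now)
        ever_flagged.update(flagged_now)
        if len(ever_flagged) == n:
            raise DegenerateInputError("all segments flagged as artifacts")
        for i in flagged_now:
            left = next((j for j in range(i - 1, -1, -1)
                         if j not in ever_flagged), None)
            right = next((j for j in range(i + 1, n)
                          if j not in ever_flagged), None)
            m = len(cleaned[i])
            neighbours = [_conform(cleaned[j], m) for j in (left, right)
                          if j is not None]
            cleaned[i] = np.mean(neighbours, axis=0)
    return cleaned, log


def _conform(seg: np.ndarray, length: int) -> np.ndarray:
    """Crop or edge-pad a segment to the target length (segments at the
    recording boundaries can differ by one m-step)."""
    if len(seg) == length:
        return seg
    if len(seg) > length:
        return seg[:length]
    return np.concatenate([seg, np.full(length - len(seg), seg[-1])])


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------

def bandpass(trace: np.ndarray, sample_rate: float,
             low: float = 1.0, high: float = 200.0, order: int = 2) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass (1-200 Hz by default).

    Applied forward-backward (sosfiltfilt) so epoch windows are not shifted
    by filter delay and the magnitude response is squared.  The 1 Hz
    high-pass removes DC offset and slow drift.
    """
    if sample_rate <= 2 * high:
        raise ConfigurationError(
            f"sample rate {sample_rate} must exceed twice the upper edge {high}")
    if not 0 < low < high:
        raise ConfigurationError("need 0 < low < high")
    sos = sps.butter(order, [low, high], btype="bandpass", fs=sample_rate,
                     output="sos")
    return sps.sosfiltfilt(sos, np.asarray(trace, dtype=float))


# ---------------------------------------------------------------------------
# Kernel extraction
# ---------------------------------------------------------------------------

def extract_first_order_kernels(trace, mseq: MSequence, schedule: FrameSchedule,
                                layout: HexLayout, sample_rate: float,
                                epoch_ms: float = EPOCH_MS) -> list[KernelWaveform]:
    """First-order kernels by circular cross-correlation.

    The kernel of hexagon h is the cross-correlation of the +/-1-recoded
    m-sequence, circularly shifted by h's offset, with the recorded trace,
    sampled on the 0-``epoch_ms`` grid after each step onset.  The result is
    scaled by 2/(period+1) so that on clean input the recovered kernel equals
    the per-hexagon response in µV (the raw correlation yields half the
    response because the 0/1 stimulus is the +/-1 code shifted and halved).

    ``trace`` may be the full continuous record or the list of segments,
    which are concatenated; extraction is circular in the step sequence.
    """
    if isinstance(trace, (list, tuple)):
        trace = np.concatenate([np.asarray(s, float) for s in trace])
    trace = np.asarray(trace, dtype=float)

    L = len(mseq)
    sps_step = schedule.samples_per_step(sample_rate)
    if len(trace) != L * sps_step:
        raise DataError(
            f"trace length {len(trace)} != {L} steps x {sps_step} samples")
    if not mseq.per_hexagon_shift:
        raise ConfigurationError("m-sequence has no per-hexagon shifts assigned")
    n_hex = layout.n_hexagons
    shifts = np.array([mseq.per_hexagon_shift[h] for h in range(n_hex)])

    epoch_n = int(round(epoch_ms / 1000.0 * sample_rate))
    epoch_steps = int(np.ceil(epoch_n / sps_step))
    if len(shifts) > 1:
        gaps = np.diff(np.sort(shifts))
        min_gap = min(int(gaps.min()), int(L - np.sort(shifts)[-1] + np.sort(shifts)[0]))
        if min_gap < epoch_steps:
            raise ConfigurationError(
                f"shift spacing {min_gap} steps < epoch length {epoch_steps} steps; "
                "first-order kernels are not separable")

    # epoch matrix: row s = trace samples in [s*sps, s*sps + epoch_n), circular
    idx = (np.arange(L)[:, None] * sps_step + np.arange(epoch_n)[None, :]) % len(trace)
    epochs = trace[idx]
    a0 = mseq.recoded.astype(np.float64)
    # row h = a0 shifted by shifts[h]: code value of hexagon h at step s
    code = a0[(np.arange(L)[None, :] - shifts[:, None]) % L]
    kernels = code @ epochs * (2.0 / (L + 1))
    return [KernelWaveform(hexagon_id=h, samples=kernels[h], sample_rate=sample_rate)
            for h in range(n_hex)]


def averaging_oracle_kernel(trace, mseq: MSequence, schedule: FrameSchedule,
                            hexagon_id: int, sample_rate: float,
                            epoch_ms: float = EPOCH_MS) -> np.ndarray:
    """Reference kernel by direct epoch averaging: the mean of epochs
    following the hexagon's on-steps minus the mean following its off-steps.

    Independent of the cross-correlation path; used as a test oracle.
    """
    if isinstance(trace, (list, tuple)):
        trace = np.concatenate([np.asarray(s, float) for s in trace])
    L = len(mseq)
    sps_step = schedule.samples_per_step(sample_rate)
    epoch_n = int(round(epoch_ms / 1000.0 * sample_rate))
    bits = mseq.shifted_bits(hexagon_id).astype(bool)
    idx = (np.arange(L)[:, None] * sps_step + np.arange(epoch_n)[None, :]) % len(trace)
    epochs = np.asarray(trace, float)[idx]
    return epochs[bits].mean(axis=0) - epochs[~bits].mean(axis=0)


# ---------------------------------------------------------------------------
# Epoch RMS
# ---------------------------------------------------------------------------

def rms_epoch(waveform: KernelWaveform, window: tuple[float, float]) -> float:
    """RMS of the kernel within the half-open window [t0, t1) ms.

    No local baseline subtraction: the analysis windows abut and the 1 Hz
    high-pass has already removed offset.
    """
    t0, t1 = window
    if not t0 < t1:
        raise RangeError("window must satisfy t0 < t1")
    if t0 < 0 or t1 > waveform.duration_ms + 1e-9:
        raise RangeError(f"window {window} outside kernel span "
                         f"0-{waveform.duration_ms:.1f} ms")
    i0 = int(round(t0 / 1000.0 * waveform.sample_rate))
    i1 = int(round(t1 / 1000.0 * waveform.sample_rate))
    if i1 <= i0:
        raise RangeError("window contains no samples")
    seg = waveform.samples[i0:i1]
    return float(np.sqrt(np.mean(seg ** 2)))


def regional_rms(kernels: list[KernelWaveform], masks: dict[str, RegionMask],
                 windows: dict[str, tuple[float, float]] | None = None,
                 eye_id: str = "") -> EpochRMS:
    """Average per-hexagon epoch RMS over the central-10 and central-15 masks.

    RMS is computed per hexagon first, then arithmetically averaged over the
    mask members, for each of the three epochs.
    """
    windows = windows or DEFAULT_WINDOWS
    by_id = {k.hexagon_id: k for k in kernels}
    values: dict[str, float] = {}
    for label, suffix in (("central10", "10"), ("central15", "15")):
        mask = masks[label]
        missing = [i for i in mask.member_ids if i not in by_id]
        if missing:
            raise DataError(f"mask {label} references missing hexagons {missing}")
        for epoch, win in windows.items():
            per_hex = [rms_epoch(by_id[i], win) for i in mask.member_ids]
            key = f"{epoch}{suffix}" if epoch == "dc" else f"{epoch}_{suffix}"
            values[key] = float(np.mean(per_hex))
    return EpochRMS(eye_id=eye_id, windows=dict(windows), **values)
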