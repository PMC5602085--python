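"""Maximal-length sequence generation and the two-global-flash frame schedule.

Each stimulus hexagon flickers according to a circularly shifted copy of one
binary m-sequence (period 2^n - 1, generated by a linear-feedback shift
register with primitive feedback taps).  Every m-sequence step is followed by
two full-field "global" flashes; the responses they evoke, as modulated by
the preceding focal flash, carry the inner-retinal adaptation signal this
paradigm targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError

#: Feedback tap positions (1-based, XOR form) of primitive polynomials over
#: GF(2) for register lengths 2..16.  Each yields the full period 2^n - 1;
#: generation verifies the period explicitly.
PRIMITIVE_TAPS: dict[int, tuple[int, ...]] = {
    2: (2, 1), 3: (3, 2), 4: (4, 3), 5: (5, 3), 6: (6, 5), 7: (7, 6),
    8: (8, 6, 5, 4), 9: (9, 5), 10: (10, 7), 11: (11, 9), 12: (12, 6, 4, 1),
    13: (13, 4, 3, 1), 14: (14, 5, 3, 1), 15: (15, 14), 16: (16, 15, 13, 4),
}

DEFAULT_LUMINANCES = {"M_on": 100.0, "M_off": 0.5, "GF": 200.0, "B": 0.5}


@dataclass(frozen=True)
class MSequence:
    """A maximal-length binary sequence with optional per-hexagon shifts."""

    order: int
    taps: tuple
    bits: np.ndarray  # uint8, length 2^order - 1
    per_hexagon_shift: dict = field(default_factory=dict)

    def __post_init__(self):
        bits = np.asarray(self.bits, dtype=np.uint8)
        L = 2 ** self.order - 1
        if len(bits) != L:
            raise ConfigurationError(f"sequence length {len(bits)} != 2^{self.order}-1")
        if int(bits.sum()) != 2 ** (self.order - 1):
            raise ConfigurationError("sequence is not balanced")
        shifts = list(self.per_hexagon_shift.values())
        if len(set(shifts)) != len(shifts):
            raise ConfigurationError("per-hexagon shifts must be distinct")
        object.__setattr__(self, "bits", bits)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def recoded(self) -> np.ndarray:
        """+/-1 recoding (1 -> +1, 0 -> -1) used for kernel extraction."""
        return self.bits.astype(np.int8) * 2 - 1

    def shifted_bits(self, hexagon_id: int) -> np.ndarray:
        """The bit stream actually displayed by one hexagon."""
        return np.roll(self.bits, self.per_hexagon_shift[hexagon_id])


def generate_msequence(order: int, taps: tuple | None = None,
                       seed_state: int = 1,
                       n_channels: int | None = None,
                       shift_spacing: int | None = None) -> MSequence:
    """Generate an m-sequence by Fibonacci LFSR iteration.

    Parameters
    ----------
    order : register length n; the sequence period is 2^n - 1.
    taps : 1-based feedback tap positions; defaults to a shipped primitive
        polynomial.  Non-primitive taps are detected by an explicit period
        check and rejected.
    seed_state : nonzero initial register contents (only the phase of the
        output changes with the seed).
    n_channels : if given, assign distinct circular shifts to this many
        stimulus channels, spaced ``shift_spacing`` steps apart
        (default ceil(period / n_channels)).
    """
    if order < 2 or order > 24:
        raise ConfigurationError("order must be in 2..24")
    if taps is None:
        try:
            taps = PRIMITIVE_TAPS[order]
        except KeyError:
            raise ConfigurationError(f"no shipped taps for order {order}") from None
    taps = tuple(sorted(taps, reverse=True))
    if max(taps) != order or min(taps) < 1:
        raise ConfigurationError("taps must include the register length and be >= 1")
    L = 2 ** order - 1
    if not (0 < seed_state <= L):
        raise DegenerateInputError("seed_state must be a nonzero register value")

    state = seed_state
    bits = np.empty(L, dtype=np.uint8)
    tap_mask = 0
    for t in taps:
        tap_mask |= 1 << (t - 1)
    reg_mask = (1 << order) - 1
    for i in range(L):
        fb = (state & tap_mask).bit_count() & 1
        bits[i] = fb
        state = ((state << 1) | fb) & reg_mask
        if state == seed_state and i < L - 1:
            raise ConfigurationError(
                f"taps {taps} are not primitive: period {i + 1} < {L}")
    if state != seed_state:
        raise ConfigurationError(f"taps {taps} are not primitive (no period {L})")

    shifts: dict[int, int] = {}
    if n_channels is not None:
        spacing = shift_spacing or math.ceil(L / n_channels)
        shifts = {h: (h * spacing) % L for h in range(n_channels)}
        if len(set(shifts.values())) != n_channels:
            raise ConfigurationError(
                f"{n_channels} channels at spacing {spacing} collide within period {L}")
    return MSequence(order=order, taps=taps, bits=bits, per_hexagon_shift=shifts)


# ---------------------------------------------------------------------------
# Frame schedule
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FrameSchedule:
    """Display timing for one multifocal run.

    The per-step frame pattern for the two-flash paradigm is
    M, dark, GF, dark, GF, dark: the m-sequence frame, then two global
    flashes two frames apart (26.7 ms at 75 Hz).
    """

    mseq: MSequence
    frame_rate: float
    frames_per_step: int
    pattern: tuple
    luminances: dict
    global_flash_interval_ms: float | None
    n_segments: int

    @property
    def n_steps(self) -> int:
        return len(self.mseq)

    @property
    def step_duration_s(self) -> float:
        return self.frames_per_step / self.frame_rate

    @property
    def total_duration_s(self) -> float:
        return self.n_steps * self.frames_per_step / self.frame_rate

    @property
    def segment_step_slices(self) -> list[tuple[int, int]]:
        """Near-equal partition of the step sequence into recording segments."""
        edges = np.linspace(0, self.n_steps, self.n_segments + 1).round().astype(int)
        return [(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]

    def samples_per_step(self, sample_rate: float) -> int:
        sps = self.step_duration_s * sample_rate
        if abs(sps - round(sps)) > 1e-9:
            raise ConfigurationError(
                f"sample rate {sample_rate} does not tile the {self.step_duration_s*1e3:.3f} ms step")
        return int(round(sps))

    def to_frame(self) -> pd.DataFrame:
        """Frame-by-frame export (frame_index, time_s, role, luminance)."""
        n_frames = self.n_steps * self.frames_per_step
        idx = np.arange(n_frames)
        roles = np.array(self.pattern, dtype=object)[idx % self.frames_per_step].copy()
        m_frames = idx % self.frames_per_step == self.pattern.index("M")
        on = np.repeat(self.mseq.bits.astype(bool), self.frames_per_step) & m_frames
        roles[m_frames & ~on] = "M_off"
        roles[m_frames & on] = "M_on"
        lum = np.array([self.luminances.get(r, 0.0) for r in roles])
        return pd.DataFrame({"frame_index": idx, "time_s": idx / self.frame_rate,
                             "role": roles, "luminance": lum})


def build_frame_schedule(mseq: MSequence, frame_rate: float = 75.0,
                         frames_per_step: int = 6, n_segments: int = 16,
                         luminances: dict | None = None,
                         two_flash: bool = True) -> FrameSchedule:
    """Lay out the frame roles of each m-sequence step.

    With the defaults (75 Hz, 6 frames per step) an order-13 sequence runs
    8191 x 80 ms = 655.3 s, i.e. 10 min 55 s, split into 16 recording
    segments.  ``two_flash=False`` produces a focal-only schedule (no global
    flashes), useful for small fixtures.
    """
    if frame_rate <= 0:
        raise ConfigurationError("frame_rate must be positive")
    if frames_per_step < 1:
        raise ConfigurationError("frames_per_step must be >= 1")
    if two_flash:
        if frames_per_step < 5:
            raise ConfigurationError(
                "two-flash pattern (M,_,GF,_,GF) needs frames_per_step >= 5")
        pattern = ["M", "B", "GF", "B", "GF"] + ["B"] * (frames_per_step - 5)
        gf_interval = 2.0 / frame_rate * 1000.0
    else:
        pattern = ["M"] + ["B"] * (frames_per_step - 1)
        gf_interval = None
    if n_segments < 1 or n_segments > len(mseq):
        raise ConfigurationError("n_segments must be in 1..n_steps")
    return FrameSchedule(
        mseq=mseq, frame_rate=frame_rate, frames_per_step=frames_per_step,
        pattern=tuple(pattern), luminances=dict(luminances or DEFAULT_LUMINANCES),
        global_flash_interval_ms=gf_interval, n_segments=n_segments,
    )
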