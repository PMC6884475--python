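"""Binaural encoding of vehicle lateral position.

The conversion rule maps the signed lateral deviation ``d`` (m, positive =
leftward) to per-ear white-noise levels, in dB of attenuation relative to
the maximum tolerable level:

    left  = base + gain * d
    right = base - gain * d

with ``base = -50 dB`` and ``gain = 25 dB/m`` by default, each ear clamped
to ``[clamp_floor, clamp_ceiling]``.  On the lane centre both ears sit at
the base level; drifting left raises the left ear and lowers the right ear
symmetrically, a "natural" panning rule.  dB values are amplitude-referenced
(a level L corresponds to an amplitude factor ``10**(L/20)``).

:func:`decode` inverts the rule (the percept of a listener who has learned
the mapping); :func:`render_wav` produces an audible stereo rendering for
diagnostics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.io import wavfile

__all__ = [
    "EncoderParams",
    "BinauralLevel",
    "encode",
    "decode",
    "render",
    "render_wav",
    "write_wav",
]


@dataclass(frozen=True)
class EncoderParams:
    """Parameters of the deviation-to-binaural-level conversion rule.

    ``base_level`` is the common per-ear level on the lane centre (dB,
    attenuation from the maximum tolerable level); ``gain`` is the per-ear
    level slope in dB per metre of lateral deviation.  With the defaults the
    unclamped (linear, invertible) range is |d| < 2 m, which covers a 3.5 m
    lane.
    """

    base_level: float = -50.0
    gain: float = 25.0
    clamp_floor: float = -100.0
    clamp_ceiling: float = 0.0

    def __post_init__(self):
        if not self.gain > 0:
            raise ValueError("gain must be positive")
        if not (self.clamp_floor <= self.base_level <= self.clamp_ceiling):
            raise ValueError("base_level must lie within the clamp range")

    @property
    def linear_range(self) -> float:
        """Largest |deviation| (m) encoded without clamping either ear."""
        return (
            min(self.clamp_ceiling - self.base_level, self.base_level - self.clamp_floor)
            / self.gain
        )


@dataclass(frozen=True)
class BinauralLevel:
    """Per-ear levels in dB (attenuation from the maximum tolerable level)."""

    left: float
    right: float

    def swapped(self) -> "BinauralLevel":
        return BinauralLevel(self.right, self.left)


def encode(deviation: float, params: EncoderParams = EncoderParams()) -> BinauralLevel:
    """Encode a lateral deviation (m, positive = leftward) as ear levels.

    Mirror-symmetric: ``encode(-d)`` swaps the ears.
    """
    if not math.isfinite(deviation):
        raise ValueError("deviation must be finite")
    lo, hi = params.clamp_floor, params.clamp_ceiling
    left = max(lo, min(params.base_level + params.gain * deviation, hi))
    right = max(lo, min(params.base_level - params.gain * deviation, hi))
    return BinauralLevel(left, right)


def decode(
    level: BinauralLevel, params: EncoderParams = EncoderParams()
) -> tuple[float, bool]:
    """Invert the conversion rule: ``(deviation, saturated)``.

    In the unclamped range the interaural difference is ``2 * gain * d``, so
    ``d = (left - right) / (2 * gain)`` and the round trip is exact.  If
    either ear is clamped the estimate saturates at the edge of the linear
    range (with the interaural sign) and ``saturated`` is True.
    """
    lo, hi = params.clamp_floor, params.clamp_ceiling
    saturated = level.left in (lo, hi) or level.right in (lo, hi)
    d = (level.left - level.right) / (2.0 * params.gain)
    if saturated:
        d = math.copysign(params.linear_range, d if d != 0.0 else 1.0)
    return d, saturated


def render(
    levels: np.ndarray,
    dt: float = 1.0 / 60.0,
    sample_rate: int = 44100,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Render a level time series as a float stereo white-noise buffer.

    ``levels`` is an ``(n_frames, 2)`` array of (left, right) dB levels
    sampled at the simulation rate; each frame's amplitude factor
    ``10**(dB/20)`` is held for the frame's samples (zero-order hold, no
    interpolation — the rendering is a diagnostic, not a calibrated
    stimulus).  The carrier is Gaussian white noise, independent per
    channel, scaled so that a 0 dB frame has RMS 0.25 of full scale.

    Returns an ``(n_samples, 2)`` float64 array in [-1, 1] with
    ``n_samples = round(n_frames * dt * sample_rate)``.
    """
    levels = np.asarray(levels, dtype=float)
    if levels.ndim != 2 or levels.shape[1] != 2 or len(levels) == 0:
        raise ValueError("levels must be a nonempty (n_frames, 2) array")
    if dt <= 0 or sample_rate <= 0:
        raise ValueError("dt and sample_rate must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_frames = len(levels)
    n_samples = round(n_frames * dt * sample_rate)
    # sample -> frame map (handles non-integer samples-per-frame)
    frame_of = np.minimum(
        (np.arange(n_samples) / (dt * sample_rate)).astype(np.intp), n_frames - 1
    )
    amp = 10.0 ** (levels[frame_of] / 20.0)
    noise = rng.standard_normal((n_samples, 2))
    out = 0.25 * amp * noise
    return np.clip(out, -1.0, 1.0)


def render_wav(
    levels: np.ndarray,
    dt: float = 1.0 / 60.0,
    sample_rate: int = 44100,
    seed: int | np.random.Generator | None = 0,
) -> np.ndarray:
    """Render a level time series as 16-bit stereo PCM samples."""
    out = render(levels, dt=dt, sample_rate=sample_rate, seed=seed)
    return (out * 32767.0).astype(np.int16)


def write_wav(
    path,
    levels: np.ndarray,
    dt: float = 1.0 / 60.0,
    sample_rate: int = 44100,
    seed: int | np.random.Generator | None = 0,
) -> None:
    """Write the rendering of a level time series to a RIFF/WAVE file."""
    wavfile.write(path, sample_rate, render_wav(levels, dt, sample_rate, seed))
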