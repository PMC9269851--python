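"""Raw sensor-frame acceleration to gravity-free earth-frame AP/ML/V.

Processing order follows the standard lumbar-sensor chain: zero-phase
low-pass filtering, static-tilt estimation from the trial-mean acceleration
direction, rotation into the earth frame, subtraction of gravity, and
extraction of the anterior-posterior component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import signal

G = 9.81


class PreprocessError(ValueError):
    pass


@dataclass
class RawTrace:
    """Triaxial sensor-frame acceleration at a fixed sampling rate (m/s^2)."""

    fs: float
    data: np.ndarray  # (n, 3) columns ax, ay, az

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 3:
            raise PreprocessError("trace data must be an (n, 3) array")
        if self.fs <= 0:
            raise PreprocessError("fs must be positive")
        if not np.all(np.isfinite(self.data)):
            raise PreprocessError("trace contains non-finite samples")

    def __len__(self):
        return self.data.shape[0]


@dataclass
class EarthTrace:
    """Gravity-removed earth-frame acceleration: columns AP, ML, V (m/s^2)."""

    fs: float
    data: np.ndarray  # (n, 3) columns ap, ml, v

    @property
    def ap(self) -> np.ndarray:
        return self.data[:, 0]

    @property
    def ml(self) -> np.ndarray:
        return self.data[:, 1]

    @property
    def v(self) -> np.ndarray:
        return self.data[:, 2]

    def __len__(self):
        return self.data.shape[0]


@dataclass
class TiltEstimate:
    """Static sensor inclination: gravity direction in the sensor frame."""

    pitch: float  # rad
    roll: float  # rad
    gravity_vector: np.ndarray  # unit vector, sensor frame

    def rotation(self) -> np.ndarray:
        """Rotation matrix sensor -> earth (R @ gravity_vector = e_z)."""
        cp, sp = math.cos(self.pitch), math.sin(self.pitch)
        cr, sr = math.cos(self.roll), math.sin(self.roll)
        ry = np.array([[cp, 0, sp], [0, 1, 0], [-sp, 0, cp]])
        rx = np.array([[1, 0, 0], [0, cr, -sr], [0, sr, cr]])
        return ry @ rx


def lowpass_filter(trace: RawTrace, cutoff_hz: float = 10.0, order: int = 4) -> RawTrace:
    """Two-pass (zero-phase) Butterworth low-pass on every axis.

    The forward-backward pass squares the filter's magnitude response and
    cancels its phase, so below-cutoff content is preserved without lag.
    """
    if cutoff_hz >= trace.fs / 2:
        raise PreprocessError(
            f"cutoff {cutoff_hz} Hz must be below Nyquist ({trace.fs / 2} Hz)")
    padlen = 3 * order
    min_len = padlen + 1
    if len(trace) < min_len:
        raise PreprocessError(
            f"trace too short for two-pass filtering: need at least {min_len} "
            f"samples, got {len(trace)}")
    sos = signal.butter(order, cutoff_hz, btype="low", fs=trace.fs, output="sos")
    out = signal.sosfiltfilt(sos, trace.data, axis=0, padtype="odd", padlen=padlen)
    return RawTrace(fs=trace.fs, data=out)


def estimate_tilt(trace: RawTrace, window: slice | None = None) -> TiltEstimate:
    """Static tilt from the mean acceleration direction over ``window``.

    Over whole strides the periodic gait components average to zero, leaving
    the gravity reaction; the normalized mean is therefore the sensor-frame
    gravity direction.  Pitch/roll parameterize the rotation ``Ry(pitch) @
    Rx(roll)`` that takes that direction onto earth vertical.
    """
    data = trace.data if window is None else trace.data[window]
    if data.shape[0] == 0:
        raise PreprocessError("empty window for tilt estimation")
    mean = data.mean(axis=0)
    norm = float(np.linalg.norm(mean))
    if norm < 0.1 * G:
        raise PreprocessError(
            "mean acceleration norm is near zero; cannot estimate gravity "
            "direction (free-fall-like input)")
    u = mean / norm
    # u = (Ry(p) Rx(r))^T e_z = (-sin p, cos p sin r, cos p cos r)
    pitch = float(-math.asin(np.clip(u[0], -1.0, 1.0)))
    roll = float(math.atan2(u[1], u[2]))
    return TiltEstimate(pitch=pitch, roll=roll, gravity_vector=u)


def to_earth_frame(trace: RawTrace, tilt: TiltEstimate, g: float = G) -> EarthTrace:
    """Rotate into the earth frame and subtract static gravity.

    The rotation is an isometry (per-sample norms preserved); gravity
    ``(0, 0, g)`` is subtracted afterwards.  Output columns are AP, ML, V.
    """
    rot = tilt.rotation()
    earth = trace.data @ rot.T
    earth[:, 2] -= g
    return EarthTrace(fs=trace.fs, data=earth)


def extract_ap(trace: EarthTrace) -> np.ndarray:
    """The anterior-posterior component, unchanged (pure projection)."""
    return trace.ap
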