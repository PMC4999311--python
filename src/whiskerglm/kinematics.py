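"""Kinematic variables of whisker contact and the preprocessing chain.

The kinematic description of a contact is purely geometric: the radial
distance r from the basepoint to the contact point, a contact angle theta,
and its temporal derivative V.  Two angle conventions apply.  For passive
(manual) deflections the contact point moves over the whisker, and
theta_deflection is the angle between the basepoint-to-initial-contact and
basepoint-to-current-contact segments.  For active whisking against a pole
the contact point is fixed in space, and theta_push is the angle swept by
the whisker's tangent at its base since contact onset.  Both read zero at
every contact onset and are positive for rostral (+y / counterclockwise)
motion, matching the Fy sign convention.  Kinematic variables are undefined
(NaN) during non-contact.

Preprocessing mirrors the standard chain for tracked-whisker signals:
median filtering to kill single-frame tracker glitches, linear interpolation
to the common 1 kHz grid, central-difference differentiation, and a
zero-phase 85 Hz low-pass on the velocity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt

from .trial import TrialRecording

__all__ = [
    "KinematicSignals",
    "extract_kinematics",
    "preprocess_signals",
    "resample_mask",
    "compute_velocity",
]


@dataclass
class KinematicSignals:
    """r/theta(/V) series with contact mask; NaN marks undefined bins."""

    t_ms: np.ndarray
    r_mm: np.ndarray
    theta_deg: np.ndarray
    contact: np.ndarray
    mode: str
    v_degps: np.ndarray | None = None


def _contact_episodes(contact: np.ndarray):
    """(start, stop) index pairs of contiguous contact runs, stop exclusive."""
    c = np.asarray(contact, dtype=bool).astype(int)
    dc = np.diff(np.concatenate([[0], c, [0]]))
    starts = np.flatnonzero(dc == 1)
    stops = np.flatnonzero(dc == -1)
    return list(zip(starts, stops))


def _signed_angle_deg(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Signed angle from u to v, CCW positive, degrees."""
    cross = u[..., 0] * v[..., 1] - u[..., 1] * v[..., 0]
    dot = u[..., 0] * v[..., 0] + u[..., 1] * v[..., 1]
    return np.degrees(np.arctan2(cross, dot))


def extract_kinematics(trial: TrialRecording, mode: str | None = None) -> KinematicSignals:
    """Per-frame r and theta from tracked shapes and contact annotations.

    theta resets to zero at each contact onset.  Non-contact frames carry
    NaN.  Raises if a contact frame lacks a contact point.
    """
    mode = mode or trial.mode
    contact = np.asarray(trial.contact, dtype=bool)
    cp = np.asarray(trial.contact_point_mm, dtype=float)
    base = trial.shapes_mm[:, 0, :]
    if np.any(~np.isfinite(base)):
        raise ValueError("missing basepoint in tracked shapes")
    if np.any(contact & ~np.isfinite(cp).all(axis=1)):
        raise ValueError("contact flagged on frames without a contact point")

    n = trial.n_frames
    r = np.full(n, np.nan)
    theta = np.full(n, np.nan)
    vec = cp - base
    r[contact] = np.hypot(vec[contact, 0], vec[contact, 1])

    if mode == "passive":
        for i0, i1 in _contact_episodes(contact):
            v0 = vec[i0]
            theta[i0:i1] = _signed_angle_deg(np.broadcast_to(v0, (i1 - i0, 2)), vec[i0:i1])
    elif mode == "active":
        # tangent angle at the base from the two most proximal nodes
        d = trial.shapes_mm[:, 1, :] - trial.shapes_mm[:, 0, :]
        base_ang = np.degrees(np.arctan2(d[:, 1], d[:, 0]))
        for i0, i1 in _contact_episodes(contact):
            theta[i0:i1] = base_ang[i0:i1] - base_ang[i0]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return KinematicSignals(trial.t_frames_ms, r, theta, contact, mode)


def preprocess_signals(series, native_rate_hz: float, median_window: int = 5) -> np.ndarray:
    """Median filter then linearly interpolate a series onto the 1 ms grid.

    The returned series has one sample per ms spanning the native time range;
    first and last values are preserved.
    """
    x = np.asarray(series, dtype=float)
    if x.size < median_window:
        raise ValueError("series shorter than the median filter window")
    # edge-replicating median: preserves ramp endpoints, kills point outliers
    x = median_filter(x, size=median_window, mode="nearest")
    t_native = np.arange(x.size) / native_rate_hz * 1000.0
    t_out = np.arange(0.0, t_native[-1] + 0.5, 1.0)
    t_out = t_out[t_out <= t_native[-1] + 1e-9]
    return np.interp(t_out, t_native, x)


def resample_mask(mask, native_rate_hz: float) -> np.ndarray:
    """Nearest-neighbor resampling of a boolean per-frame mask to 1 kHz."""
    m = np.asarray(mask, dtype=bool)
    t_native = np.arange(m.size) / native_rate_hz * 1000.0
    t_out = np.arange(0.0, t_native[-1] + 0.5, 1.0)
    t_out = t_out[t_out <= t_native[-1] + 1e-9]
    idx = np.clip(np.rint(t_out * native_rate_hz / 1000.0).astype(int), 0, m.size - 1)
    return m[idx]


def compute_velocity(theta_deg: np.ndarray, cutoff_hz: float = 85.0,
                     fs_hz: float = 1000.0) -> np.ndarray:
    """Angular velocity in deg/s: central difference + zero-phase low-pass.

    Endpoints use one-sided differences.  The low-pass is a 4th-order
    Butterworth at ``cutoff_hz`` applied forward-backward (zero phase).
    """
    th = np.asarray(theta_deg, dtype=float)
    if th.size < 3:
        raise ValueError("need at least 3 samples to differentiate")
    dt_s = 1.0 / fs_hz
    v = np.empty_like(th)
    v[1:-1] = (th[2:] - th[:-2]) / (2 * dt_s)
    v[0] = (th[1] - th[0]) / dt_s
    v[-1] = (th[-1] - th[-2]) / dt_s
    b, a = butter(4, cutoff_hz / (fs_hz / 2))
    return filtfilt(b, a, v)
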