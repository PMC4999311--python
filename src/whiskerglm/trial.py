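"""Core per-trial container: tracked whisker shapes, contact, loads, spikes."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TrialRecording"]


@dataclass
class TrialRecording:
    """One trial of frame-by-frame whisker data.

    ``shapes_mm`` holds ordered node coordinates per frame, (F, nodes, 2), in
    the whisker frame for passive trials and the head frame for active ones.
    ``loads`` are the per-frame base reactions (Fx uN, Fy uN, M uN*m) —
    exactly zero on non-contact frames.  ``contact_point_mm`` is NaN where
    there is no contact.
    """

    frame_rate_hz: float
    mode: str  # "passive" | "active"
    shapes_mm: np.ndarray
    contact: np.ndarray
    contact_point_mm: np.ndarray
    loads: np.ndarray
    spike_times_ms: np.ndarray | None = None
    base_angle_deg: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        f = self.shapes_mm.shape[0]
        if not (self.contact.shape == (f,) and self.loads.shape == (f, 3)
                and self.contact_point_mm.shape == (f, 2)):
            raise ValueError("per-frame arrays disagree on frame count")
        if self.mode not in ("passive", "active"):
            raise ValueError("mode must be 'passive' or 'active'")

    @property
    def n_frames(self) -> int:
        return self.shapes_mm.shape[0]

    @property
    def duration_ms(self) -> float:
        return self.n_frames / self.frame_rate_hz * 1000.0

    @property
    def t_frames_ms(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz * 1000.0
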