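"""Aligned 1 kHz predictor signals for the encoding models.

The six contact predictors, in canonical column order, are the mechanical
triplet (Fx, Fy, M) — base reactions of the bent whisker — and the kinematic
triplet (r, theta, V).  Mechanical signals are exactly zero during
non-contact; kinematic signals are undefined there and are imputed to zero
before entering a design matrix (configurable, mirroring the mechanical
zeros).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import WhiskerGeometry
from .kinematics import compute_velocity, extract_kinematics, preprocess_signals, resample_mask
from .mechanics import base_reactions_from_shape
from .trial import TrialRecording

__all__ = [
    "PREDICTOR_NAMES",
    "MECHANICAL",
    "KINEMATIC",
    "PredictorSet",
    "predictors_from_trial",
]

PREDICTOR_NAMES = ("Fx", "Fy", "M", "r", "theta", "V")
MECHANICAL = ("Fx", "Fy", "M")
KINEMATIC = ("r", "theta", "V")


@dataclass
class PredictorSet:
    """Six aligned 1 kHz signals with a contact mask.

    ``values`` is (n_bins, 6) in PREDICTOR_NAMES order: Fx uN, Fy uN,
    M uN*m, r mm, theta deg, V deg/s.
    """

    t_ms: np.ndarray
    values: np.ndarray
    contact: np.ndarray
    mode: str = "passive"

    def __post_init__(self) -> None:
        if self.values.shape != (self.t_ms.size, len(PREDICTOR_NAMES)):
            raise ValueError("values must be (n_bins, 6)")
        if self.contact.shape != (self.t_ms.size,):
            raise ValueError("contact mask length mismatch")

    @property
    def n_bins(self) -> int:
        return self.t_ms.size

    def column(self, name: str) -> np.ndarray:
        return self.values[:, PREDICTOR_NAMES.index(name)]

    def subset_values(self, names) -> np.ndarray:
        idx = [PREDICTOR_NAMES.index(n) for n in names]
        return self.values[:, idx]


def predictors_from_trial(
    trial: TrialRecording,
    geometry: WhiskerGeometry | None = None,
    mechanics: str = "stored",
    impute_kinematics: bool = True,
) -> PredictorSet:
    """Build the aligned 1 kHz predictor set for one trial.

    mechanics="stored" takes the per-frame base reactions carried by the
    trial (the forward solver's output); mechanics="inverse" recomputes them
    from each tracked contact shape with ``base_reactions_from_shape``.
    Either way the standard chain is applied per signal: median filter,
    linear interpolation to 1 kHz, central-difference velocity with an 85 Hz
    zero-phase low-pass.  Mechanical signals are forced to exact zeros on
    non-contact bins; kinematic signals are NaN there unless
    ``impute_kinematics`` replaces the sentinel with zeros.
    """
    rate = trial.frame_rate_hz
    if mechanics == "stored":
        loads = np.asarray(trial.loads, dtype=float)
    elif mechanics == "inverse":
        if geometry is None:
            raise ValueError("mechanics='inverse' needs the whisker geometry")
        loads = np.zeros((trial.n_frames, 3))
        for i in range(trial.n_frames):
            if trial.contact[i]:
                reactions, _diag = base_reactions_from_shape(
                    geometry, trial.shapes_mm[i], trial.contact_point_mm[i]
                )
                loads[i] = reactions.as_array()
    else:
        raise ValueError("mechanics must be 'stored' or 'inverse'")

    kin = extract_kinematics(trial)
    # zero-impute kinematics at the frame level so the median filter and
    # interpolation see finite values; re-masked below
    r_f = np.nan_to_num(kin.r_mm, nan=0.0)
    th_f = np.nan_to_num(kin.theta_deg, nan=0.0)

    cols = {}
    for name, series in (
        ("Fx", loads[:, 0]), ("Fy", loads[:, 1]), ("M", loads[:, 2]),
        ("r", r_f), ("theta", th_f),
    ):
        cols[name] = preprocess_signals(series, rate)
    mask = resample_mask(trial.contact, rate)
    n = mask.size
    # exact zeros for mechanics off contact (quasi-static contract)
    for name in MECHANICAL:
        cols[name] = cols[name][:n]
        cols[name][~mask] = 0.0
    for name in ("r", "theta"):
        cols[name] = cols[name][:n]
        cols[name][~mask] = 0.0 if impute_kinematics else np.nan
    theta_for_v = np.nan_to_num(cols["theta"], nan=0.0)
    v = compute_velocity(theta_for_v)
    if not impute_kinematics:
        v = np.where(mask, v, np.nan)
    cols["V"] = v

    values = np.column_stack([cols[name] for name in PREDICTOR_NAMES])
    t_ms = np.arange(n, dtype=float)
    return PredictorSet(t_ms=t_ms, values=values, contact=mask, mode=trial.mode)
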