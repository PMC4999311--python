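"""Reading and writing trials, predictor tables, and results.

HDF5 layout for a trial: /frames/xy (frame x node x 2, mm), /contact (bool
per frame), /contact_point (frame x 2, mm; NaN off contact), /loads
(frame x 3: Fx uN, Fy uN, M uN*m), /spikes (ms), plus frame_rate_hz and mode
attributes.  A plain-text dialect (frame, node, x, y) is provided for
interoperability with tracked-whisker tooling.
"""

from __future__ import annotations

import h5py
import numpy as np
import pandas as pd

from .predictors import PREDICTOR_NAMES, PredictorSet
from .trial import TrialRecording

__all__ = [
    "write_trial_h5", "read_trial_h5",
    "write_tracked_text", "read_tracked_text",
    "predictor_table", "write_predictors", "read_predictors",
    "results_table", "write_fit_json", "read_fit_json",
]


def write_trial_h5(trial: TrialRecording, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["frame_rate_hz"] = trial.frame_rate_hz
        f.attrs["mode"] = trial.mode
        f.create_dataset("frames/xy", data=trial.shapes_mm)
        f.create_dataset("contact", data=trial.contact.astype(bool))
        f.create_dataset("contact_point", data=trial.contact_point_mm)
        f.create_dataset("loads", data=trial.loads)
        if trial.spike_times_ms is not None:
            f.create_dataset("spikes", data=np.asarray(trial.spike_times_ms, dtype=float))
        if trial.base_angle_deg is not None:
            f.create_dataset("base_angle_deg", data=trial.base_angle_deg)


def read_trial_h5(path) -> TrialRecording:
    with h5py.File(path, "r") as f:
        return TrialRecording(
            frame_rate_hz=float(f.attrs["frame_rate_hz"]),
            mode=str(f.attrs["mode"]),
            shapes_mm=f["frames/xy"][...],
            contact=f["contact"][...].astype(bool),
            contact_point_mm=f["contact_point"][...],
            loads=f["loads"][...],
            spike_times_ms=f["spikes"][...] if "spikes" in f else None,
            base_angle_deg=f["base_angle_deg"][...] if "base_angle_deg" in f else None,
        )


def write_tracked_text(trial: TrialRecording, path) -> None:
    """Per-frame delimited text: frame, node, x_mm, y_mm."""
    n_frames, n_nodes, _ = trial.shapes_mm.shape
    frame = np.repeat(np.arange(n_frames), n_nodes)
    node = np.tile(np.arange(n_nodes), n_frames)
    xy = trial.shapes_mm.reshape(-1, 2)
    pd.DataFrame({"frame": frame, "node": node,
                  "x": xy[:, 0], "y": xy[:, 1]}).to_csv(path, sep="\t", index=False)


def read_tracked_text(path) -> np.ndarray:
    """Shapes (frame, node, 2) from the tracked-whisker text dialect."""
    df = pd.read_csv(path, sep="\t")
    n_frames = df["frame"].max() + 1
    n_nodes = df["node"].max() + 1
    shapes = np.full((n_frames, n_nodes, 2), np.nan)
    shapes[df["frame"], df["node"], 0] = df["x"]
    shapes[df["frame"], df["node"], 1] = df["y"]
    return shapes


def predictor_table(predictors: PredictorSet) -> pd.DataFrame:
    cols = {"t_ms": predictors.t_ms}
    units = {"Fx": "Fx_uN", "Fy": "Fy_uN", "M": "M_uNm",
             "r": "r_mm", "theta": "theta_deg", "V": "V_degps"}
    for name in PREDICTOR_NAMES:
        cols[units[name]] = predictors.column(name)
    cols["contact"] = predictors.contact.astype(int)
    return pd.DataFrame(cols)


def write_predictors(predictors: PredictorSet, path) -> None:
    predictor_table(predictors).to_csv(path, sep="\t", index=False)


def read_predictors(path) -> PredictorSet:
    df = pd.read_csv(path, sep="\t")
    vals = df[["Fx_uN", "Fy_uN", "M_uNm", "r_mm", "theta_deg", "V_degps"]].to_numpy()
    return PredictorSet(
        t_ms=df["t_ms"].to_numpy(dtype=float),
        values=vals,
        contact=df["contact"].to_numpy(dtype=bool),
    )


def write_fit_json(fit, path) -> None:
    """Serialize a GLM fit (coefficients, filters, whitening, basis layout)."""
    import json

    payload = {
        "subset": fit.subset,
        "predictor_names": list(fit.predictor_names),
        "coef": fit.coef.tolist(),
        "se": None if fit.se is None else fit.se.tolist(),
        "ridge": fit.ridge,
        "log_likelihood": fit.log_likelihood,
        "converged": fit.converged,
        "whiten_mean": None if fit.whiten_mean is None else fit.whiten_mean.tolist(),
        "whiten_sd": None if fit.whiten_sd is None else fit.whiten_sd.tolist(),
        "basis": {
            "n_funcs": fit.basis.n_funcs,
            "peak_times_ms": list(fit.basis.peak_times_ms),
            "support_ms": fit.basis.support_ms,
        },
        "filters": {k: v.tolist() for k, v in fit.filters().items()},
    }
    with open(path, "w") as f:
        json.dump(payload, f)


def read_fit_json(path):
    """Rebuild a GLMFit from its JSON serialization."""
    import json

    from .glm import GLMFit, make_basis

    with open(path) as f:
        d = json.load(f)
    basis = make_basis(d["basis"]["n_funcs"], d["basis"]["peak_times_ms"],
                       d["basis"]["support_ms"])
    return GLMFit(
        coef=np.asarray(d["coef"]),
        predictor_names=tuple(d["predictor_names"]),
        basis=basis,
        subset=d["subset"],
        log_likelihood=d["log_likelihood"],
        converged=d["converged"],
        n_iter=0,
        se=None if d["se"] is None else np.asarray(d["se"]),
        ridge=d["ridge"],
        whiten_mean=None if d["whiten_mean"] is None else np.asarray(d["whiten_mean"]),
        whiten_sd=None if d["whiten_sd"] is None else np.asarray(d["whiten_sd"]),
    )


def results_table(results) -> pd.DataFrame:
    """Per-neuron comparison table (one row per neuron)."""
    return pd.DataFrame([
        {
            "neuron_id": r.neuron_id,
            "R2_mech_vs_full": r.r2_mech_vs_full,
            "R2_kin_vs_full": r.r2_kin_vs_full,
            "preparation": r.preparation,
            "R_full": r.r_full,
            "R_mech": r.r_mech,
            "R_kin": r.r_kin,
        }
        for r in results
    ])
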