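"""Synthetic whisker-deflection experiments with ground-truth neurons.

This module makes the whole analysis pipeline testable without recordings.
It generates two stimulation regimes and renders them frame by frame through
the quasi-static mechanics solver:

* passive manual deflections — ramp-hold-release pushes of a point probe at
  variable radial distances along the whisker, two directions and two speed
  classes, emulating hand-delivered stimulation under anesthesia (300 fps);
* active whisking against a rigid vertical pole — a sinusoidal base-angle
  trajectory that brings the whisker into contact once per protraction
  (1000 fps).

Sampling push amplitudes of a few millimetres over a wide range of radial
distances decouples the contact angle from the bending moment; a single
radial distance with small pushes leaves them nearly collinear.  Ground
truth neurons are linear-nonlinear Bernoulli spikers whose filters live in
the raised-cosine basis, so the fitted model class can represent them
exactly and filter recovery is well defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import WhiskerGeometry
from .glm import CosineBasis, sigmoid
from .mechanics import ContactConstraint, ContactLost, deflect_whisker
from .predictors import PREDICTOR_NAMES, PredictorSet
from .trial import TrialRecording

__all__ = [
    "PassiveDeflection",
    "PassiveProtocol",
    "ActiveProtocol",
    "GroundTruthNeuron",
    "gen_passive_protocol",
    "gen_active_protocol",
    "render_trial",
    "simulate_spikes",
    "gen_noise_predictors",
]

# ramp durations for the two speed classes (the field reports only
# "fast" and "slow" hand-delivered deflections)
FAST_RAMP_S = 0.05
SLOW_RAMP_S = 0.25


@dataclass(frozen=True)
class PassiveDeflection:
    onset_s: float
    radial_fraction: float      # contact location as a fraction of whisker length
    direction: int              # +1 rostral (+y), -1 caudal
    speed: str                  # "fast" | "slow"
    amplitude_mm: float         # peak perpendicular push displacement
    hold_s: float               # plateau duration at peak

    @property
    def ramp_s(self) -> float:
        return FAST_RAMP_S if self.speed == "fast" else SLOW_RAMP_S

    @property
    def duration_s(self) -> float:
        return 2 * self.ramp_s + self.hold_s

    def displacement_mm(self, t_s: float) -> float:
        """Probe displacement at time since onset: half-cosine ramp, hold,
        half-cosine release; zero outside the event."""
        tr = self.ramp_s
        if t_s < 0 or t_s > self.duration_s:
            return 0.0
        if t_s < tr:
            return self.amplitude_mm * 0.5 * (1 - np.cos(np.pi * t_s / tr))
        if t_s < tr + self.hold_s:
            return self.amplitude_mm
        return self.amplitude_mm * 0.5 * (1 - np.cos(np.pi * (self.duration_s - t_s) / tr))


@dataclass(frozen=True)
class PassiveProtocol:
    deflections: tuple
    frame_rate_hz: float
    duration_s: float
    seed: int

    def __post_init__(self) -> None:
        events = sorted(self.deflections, key=lambda d: d.onset_s)
        for d1, d2 in zip(events, events[1:]):
            if d1.onset_s + d1.duration_s > d2.onset_s:
                raise ValueError("deflection intervals overlap")
        for d in events:
            if d.hold_s < 0 or d.amplitude_mm <= 0:
                raise ValueError("deflection durations and amplitudes must be positive")


@dataclass(frozen=True)
class ActiveProtocol:
    whisk_freq_hz: float
    amplitude_deg: float
    base_offset_deg: float
    pole_xy_mm: tuple           # pole center, head frame (basepoint at origin)
    pole_radius_mm: float
    frame_rate_hz: float
    duration_s: float
    seed: int

    def __post_init__(self) -> None:
        if self.frame_rate_hz < 2 * self.whisk_freq_hz:
            raise ValueError("frame rate must be at least twice the whisk frequency")


def gen_passive_protocol(
    geometry: WhiskerGeometry,
    n_deflections: int = 30,
    radial_range=(0.4, 0.9),
    seed: int = 0,
    frame_rate_hz: float = 300.0,
    amplitude_range_mm=(1.0, 4.0),
    long_hold_fraction: float = 0.2,
) -> PassiveProtocol:
    """Random manual-stimulation protocol.

    Radial contact fractions are uniform over ``radial_range``; directions
    and speed classes are random; a ``long_hold_fraction`` of deflections get
    ~3 s holds (adaptation probes), the rest brief holds.  Deterministic
    given the seed.
    """
    lo, hi = radial_range
    if not (0 < lo <= hi <= 0.9):
        raise ValueError("radial_range must lie within (0, 0.9]")
    if n_deflections < 1:
        raise ValueError("need at least one deflection")
    rng = np.random.default_rng(seed)
    t = 0.5
    events = []
    for _ in range(n_deflections):
        frac = float(rng.uniform(lo, hi))
        direction = int(rng.choice([-1, 1]))
        speed = str(rng.choice(["fast", "slow"]))
        amp = float(rng.uniform(*amplitude_range_mm))
        hold = float(rng.uniform(2.5, 3.5)) if rng.random() < long_hold_fraction \
            else float(rng.uniform(0.05, 0.3))
        ev = PassiveDeflection(t, frac, direction, speed, amp, hold)
        events.append(ev)
        t += ev.duration_s + float(rng.uniform(0.3, 0.8))
    return PassiveProtocol(tuple(events), frame_rate_hz, t + 0.2, seed)


def gen_active_protocol(
    geometry: WhiskerGeometry,
    pole_distance_fraction: float = 0.6,
    whisk_freq_hz: float = 8.0,
    amplitude_deg: float = 20.0,
    duration_s: float = 2.0,
    seed: int = 0,
    pole_radius_mm: float = 1.5,
    frame_rate_hz: float = 1000.0,
    pole_angle_deg: float | None = None,
) -> ActiveProtocol:
    """Whisking-against-a-pole protocol.

    The pole (default 3 mm diameter peg) is placed at ``pole_distance_fraction``
    of the whisker length, at an angle inside the upper half of the whisk
    sweep (overridable via ``pole_angle_deg``) so that contact occurs during
    part of each protraction.
    """
    if not (0 < pole_distance_fraction < 1):
        raise ValueError("pole_distance_fraction must be in (0, 1)")
    if duration_s <= 0 or whisk_freq_hz <= 0 or amplitude_deg <= 0:
        raise ValueError("duration, frequency and amplitude must be positive")
    d_pole = pole_distance_fraction * geometry.length_mm
    offset = 0.0
    # default: inside the protraction half of the sweep
    pole_angle = 0.4 * amplitude_deg if pole_angle_deg is None else pole_angle_deg
    theta_touch = pole_angle - np.degrees(np.arcsin(min(pole_radius_mm / d_pole, 1.0)))
    if theta_touch >= offset + amplitude_deg:
        raise ValueError("pole is outside the whisker's sweep at every phase")
    pole_xy = (d_pole * np.cos(np.radians(pole_angle)),
               d_pole * np.sin(np.radians(pole_angle)))
    return ActiveProtocol(whisk_freq_hz, amplitude_deg, offset, pole_xy,
                          pole_radius_mm, frame_rate_hz, duration_s, seed)


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def _bandlimited_noise(n: int, rate_hz: float, rng, cutoff_hz: float = 25.0) -> np.ndarray:
    """Unit-RMS low-pass-filtered Gaussian noise (hand/whisking tremor band)."""
    if n < 12:
        return np.zeros(n)
    from scipy.signal import butter, filtfilt

    b, a = butter(2, min(cutoff_hz / (rate_hz / 2), 0.99))
    x = filtfilt(b, a, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _render_passive(protocol: PassiveProtocol, geometry: WhiskerGeometry) -> TrialRecording:
    rate = protocol.frame_rate_hz
    n_frames = int(round(protocol.duration_s * rate))
    rest = geometry.undeflected_nodes_mm()
    shapes = np.tile(rest, (n_frames, 1, 1))
    contact = np.zeros(n_frames, dtype=bool)
    cpoint = np.full((n_frames, 2), np.nan)
    loads = np.zeros((n_frames, 3))

    events = sorted(protocol.deflections, key=lambda d: d.onset_s)
    for k_ev, ev in enumerate(events):
        i0 = int(np.ceil(ev.onset_s * rate))
        i1 = min(int(np.floor((ev.onset_s + ev.duration_s) * rate)) + 1, n_frames)
        s0 = ev.radial_fraction * geometry.length_mm
        # resting contact location and its normal (straight whisker: +y)
        p0 = np.array([s0, 0.0])
        n0 = np.array([0.0, 1.0])
        # hand-held probe wobble: multiplicative band-limited jitter (~5%)
        # gives each deflection naturalistic variability while keeping the
        # displacement continuous through contact onset and release
        rng_ev = np.random.default_rng([protocol.seed, k_ev])
        jit = _bandlimited_noise(i1 - i0, rate, rng_ev) * 0.05
        warm = None
        for i in range(i0, i1):
            t_ev = i / rate - ev.onset_s
            d = ev.displacement_mm(t_ev) * max(1.0 + jit[i - i0], 0.0)
            c = p0 + ev.direction * d * n0
            if d <= 1e-9:
                contact[i] = True
                cpoint[i] = p0
                continue  # probe at the rest line: zero loads, rest shape
            try:
                res = deflect_whisker(geometry, ContactConstraint(tuple(c)),
                                      warm_start=warm)
            except ContactLost:
                warm = None
                continue  # whisker slipped off the probe: free, non-contact
            warm = res
            shapes[i] = res.shape_mm
            contact[i] = True
            cpoint[i] = c
            loads[i] = res.reactions.as_array()
    return TrialRecording(rate, "passive", shapes, contact, cpoint, loads)


def _render_active(protocol: ActiveProtocol, geometry: WhiskerGeometry) -> TrialRecording:
    rate = protocol.frame_rate_hz
    n_frames = int(round(protocol.duration_s * rate))
    t = np.arange(n_frames) / rate
    # cycle-to-cycle amplitude variability of natural whisking
    cycle = np.floor(protocol.whisk_freq_hz * t).astype(int)
    rng = np.random.default_rng(protocol.seed)
    amp_fac = 1.0 + 0.08 * rng.standard_normal(cycle.max() + 1)
    base_ang = protocol.base_offset_deg + protocol.amplitude_deg * amp_fac[cycle] * np.sin(
        2 * np.pi * protocol.whisk_freq_hz * t)
    pole = np.asarray(protocol.pole_xy_mm, dtype=float)
    d_pole = float(np.hypot(*pole))
    pole_ang = np.degrees(np.arctan2(pole[1], pole[0]))
    theta_touch = pole_ang - np.degrees(
        np.arcsin(min(protocol.pole_radius_mm / d_pole, 1.0)))

    rest = geometry.undeflected_nodes_mm()
    shapes = np.empty((n_frames, geometry.n_nodes, 2))
    contact = np.zeros(n_frames, dtype=bool)
    cpoint = np.full((n_frames, 2), np.nan)
    loads = np.zeros((n_frames, 3))
    reachable = d_pole <= geometry.length_mm

    warm = None
    for i in range(n_frames):
        ang = np.radians(base_ang[i])
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        if not reachable or base_ang[i] <= theta_touch:
            shapes[i] = rest @ rot.T  # free whisking: rigid rotation
            warm = None
            continue
        # whisker swept past the pole: solve the bent equilibrium in the
        # whisker frame, with the pole (radius folded) as the constraint
        c_wf = rot.T @ pole
        try:
            res = deflect_whisker(
                geometry,
                ContactConstraint(tuple(c_wf), protocol.pole_radius_mm),
                warm_start=warm,
            )
        except ContactLost:
            shapes[i] = rest @ rot.T
            warm = None
            continue
        warm = res
        shapes[i] = res.shape_mm @ rot.T
        contact[i] = True
        arc_idx = res.contact_arc_mm / geometry.ds_mm
        k = min(int(arc_idx), geometry.n_nodes - 2)
        frac = arc_idx - k
        p_c = (1 - frac) * res.shape_mm[k] + frac * res.shape_mm[k + 1]
        cpoint[i] = rot @ p_c
        loads[i] = res.reactions.as_array()
    return TrialRecording(rate, "active", shapes, contact, cpoint, loads,
                          base_angle_deg=base_ang)


def render_trial(protocol, geometry: WhiskerGeometry) -> TrialRecording:
    """Render a protocol into a frame-by-frame trial via the forward solver.

    Non-contact frames carry the undeflected (or rigidly rotated) shape and
    exactly zero loads.
    """
    if isinstance(protocol, PassiveProtocol):
        return _render_passive(protocol, geometry)
    if isinstance(protocol, ActiveProtocol):
        return _render_active(protocol, geometry)
    raise TypeError("protocol must be a PassiveProtocol or ActiveProtocol")


# ---------------------------------------------------------------------------
# ground-truth neurons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroundTruthNeuron:
    """Linear-nonlinear Bernoulli spiker with known temporal filters.

    ``filters`` maps driven predictor names to alpha_j(t') arrays (1 ms
    resolution); ``beta`` optionally records the basis coefficients that
    generated them, for direct comparison with fitted coefficients.

    ``noise_sd`` adds slow private excitability fluctuations (an AR(1)
    process with time constant ``noise_tau_ms``) to the input of the
    nonlinearity.  Zero gives an exactly realizable model (used for
    estimator-recovery oracles); a positive value emulates the unmodeled
    rate variability of real sensory neurons, whose stimulus models predict
    far less than all of the observed spiking.
    """

    filters: dict
    bias: float
    seed: int
    beta: dict | None = field(default=None)
    noise_sd: float = 0.0
    noise_tau_ms: float = 50.0

    def __post_init__(self) -> None:
        if not self.filters:
            raise ValueError("need at least one driven predictor")
        for name in self.filters:
            if name not in PREDICTOR_NAMES:
                raise ValueError(f"unknown predictor {name!r}")
        p0 = sigmoid(self.bias)
        if not (0 < p0 < 0.5):
            raise ValueError("bias must give baseline firing probability in (0, 0.5)")

    @classmethod
    def from_basis(cls, basis: CosineBasis, weights: dict, bias: float,
                   seed: int = 0, noise_sd: float = 0.0,
                   noise_tau_ms: float = 50.0) -> "GroundTruthNeuron":
        """Build a neuron whose filters are basis-weighted sums, so exact
        recovery by the fitted model class is representable."""
        filters = {}
        for name, w in weights.items():
            w = np.asarray(w, dtype=float)
            if w.shape != (basis.n_funcs,):
                raise ValueError("one weight per basis function required")
            filters[name] = basis.functions.T @ w
        return cls(filters=filters, bias=float(bias), seed=seed,
                   beta={k: np.asarray(v, dtype=float) for k, v in weights.items()},
                   noise_sd=noise_sd, noise_tau_ms=noise_tau_ms)


def simulate_spikes(neuron: GroundTruthNeuron, predictors: PredictorSet) -> np.ndarray:
    """Bernoulli spike train (1 ms bins) from the neuron's LNL model.

    Filters are applied to whitened predictors (whole-recording mean/SD),
    matching the convention of the model fit.  Deterministic given the
    neuron's seed.
    """
    n = predictors.n_bins
    eta = np.full(n, neuron.bias)
    for name, alpha in neuron.filters.items():
        x = predictors.column(name)
        if np.any(~np.isfinite(x[predictors.contact])):
            raise ValueError(f"NaN in driven predictor {name!r} within the contact mask")
        x = np.nan_to_num(x, nan=0.0)
        z = (x - x.mean()) / x.std()
        eta += np.convolve(z, alpha)[:n]
    rng = np.random.default_rng(neuron.seed)
    if neuron.noise_sd > 0:
        # slow private excitability fluctuations, unit variance then scaled
        rho = float(np.exp(-1.0 / neuron.noise_tau_ms))
        from scipy.signal import lfilter

        eps = rng.standard_normal(n)
        eta += neuron.noise_sd * lfilter([1.0], [1.0, -rho], eps) * np.sqrt(1 - rho**2)
    p = sigmoid(eta)
    return (rng.random(n) < p).astype(np.uint8)


def gen_noise_predictors(n_bins: int, seed: int = 0, rho: float = 0.95) -> PredictorSet:
    """Six independent AR(1) noise channels, all bins in 'contact'.

    A stimulus-agnostic predictor set for exercising the GLM machinery
    (filter recovery, STA nulls) with a well-conditioned design.
    """
    rng = np.random.default_rng(seed)
    eps = rng.standard_normal((n_bins, len(PREDICTOR_NAMES)))
    from scipy.signal import lfilter

    vals = lfilter([1.0], [1.0, -rho], eps, axis=0) * np.sqrt(1 - rho**2)
    return PredictorSet(
        t_ms=np.arange(n_bins, dtype=float),
        values=vals,
        contact=np.ones(n_bins, dtype=bool),
        mode="passive",
    )
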