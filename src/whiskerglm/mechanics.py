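"""Quasi-static, frictionless elastic bending of a tapered whisker in 2D.

The whisker is modeled as a discrete elastica: rigid segments of uniform arc
length joined by elastic hinges whose stiffness follows the Euler-Bernoulli
moment-curvature law M(s) = E I(s) (kappa(s) - kappa0(s)).  A single point
force, oriented perpendicular to the local whisker tangent at the contact
point (frictionless contact), deforms the whisker so that it passes through a
geometric constraint point (the probe or pole surface).  The solver relaxes
the curvature profile to equilibrium while adjusting the force magnitude and
the contact arc position, so the contact point is free to slide along the
whisker as it bends.

The forward problem maps a constraint point to the deflected shape and the
reactions at the whisker base; the inverse problem recovers the base
reactions from an observed (tracked) shape plus the contact point, by finding
the point load whose forward solution best matches the observation.

Sign conventions (whisker frame, right-handed): x = base tangent pointing
tipward, y = rostral, moments positive counterclockwise about +z.  The
reported axial force Fx is positive pointing out of the follicle, i.e. it is
the -x component of the applied contact force; Fy is the +y (rostral)
component of the applied force.  Fx, Fy are in uN and M in uN*m, matching the
scales whisker-contact forces are conventionally reported on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .geometry import WhiskerGeometry, second_moment

__all__ = [
    "ContactConstraint",
    "BaseReactions",
    "DeflectionResult",
    "SolverError",
    "ContactLost",
    "deflect_whisker",
    "base_reactions_from_shape",
]

MM = 1e-3  # mm -> m

# solver tolerances: constraint residual 1e-3 mm, force residual 1e-3 uN
_TOL_POS = 1e-6  # m
_TOL_FORCE = 1e-9  # N
_MAX_ITER = 10_000


class SolverError(RuntimeError):
    """Equilibrium iteration failed to converge within the iteration budget."""


class ContactLost(RuntimeError):
    """The constraint slid beyond the whisker tip at equilibrium."""


@dataclass(frozen=True)
class ContactConstraint:
    """Geometric contact constraint in the whisker frame.

    ``point_mm`` is the probe/pole center; a non-zero ``probe_radius_mm``
    folds the radius into the constraint by moving the effective contact to
    the surface point nearest the undeflected whisker.
    """

    point_mm: tuple[float, float]
    probe_radius_mm: float = 0.0

    def __post_init__(self) -> None:
        if np.hypot(*self.point_mm) < 1e-9:
            raise ValueError("constraint point coincides with the basepoint")
        if self.probe_radius_mm < 0:
            raise ValueError("probe radius must be non-negative")


@dataclass(frozen=True)
class BaseReactions:
    """Forces and moment at the whisker base during contact.

    All three are exactly zero when there is no contact.
    """

    fx_uN: float
    fy_uN: float
    m_uNm: float

    @classmethod
    def zero(cls) -> "BaseReactions":
        return cls(0.0, 0.0, 0.0)

    def as_array(self) -> np.ndarray:
        return np.array([self.fx_uN, self.fy_uN, self.m_uNm])


@dataclass
class DeflectionResult:
    shape_mm: np.ndarray          # (n_nodes, 2) deflected node coordinates
    contact_arc_mm: float         # arc position of the contact point
    force_uN: np.ndarray          # applied force vector (2,), whisker frame
    reactions: BaseReactions
    converged: bool
    n_iter: int
    residual_mm: float
    kappa: np.ndarray | None = None  # internal state, reusable as warm start


# ---------------------------------------------------------------------------
# discrete elastica primitives (SI units internally)
# ---------------------------------------------------------------------------

def _beam_arrays(geometry: WhiskerGeometry):
    """Per-segment midpoint arc positions, EI, and intrinsic curvature (SI)."""
    n_seg = geometry.n_nodes - 1
    ds = geometry.ds_mm * MM
    s_mid_mm = (np.arange(n_seg) + 0.5) * geometry.ds_mm
    ei = geometry.youngs_modulus_pa * second_moment(geometry, s_mid_mm) * MM**4
    if geometry.intrinsic_curvature is None:
        kappa0 = np.zeros(n_seg)
    else:
        kmid = 0.5 * (geometry.intrinsic_curvature[:-1] + geometry.intrinsic_curvature[1:])
        kappa0 = kmid / MM  # 1/mm -> 1/m
    return ds, s_mid_mm * MM, ei, kappa0


def _integrate(kappa: np.ndarray, ds: float):
    """Node positions and segment angles from per-segment curvature.

    The base is clamped: the tangent of the first segment starts at angle 0.
    """
    n_seg = kappa.size
    # tangent angle at segment midpoints
    phi_end = np.cumsum(kappa * ds)
    phi_mid = phi_end - 0.5 * kappa * ds
    pos = np.zeros((n_seg + 1, 2))
    pos[1:, 0] = np.cumsum(ds * np.cos(phi_mid))
    pos[1:, 1] = np.cumsum(ds * np.sin(phi_mid))
    return pos, phi_mid


def _point_at(pos: np.ndarray, phi_mid: np.ndarray, ds: float, a: float):
    """Interpolated point, tangent, and left normal at arc length ``a``."""
    n_seg = phi_mid.size
    idx = min(int(a / ds), n_seg - 1)
    frac = a - idx * ds
    t_hat = np.array([np.cos(phi_mid[idx]), np.sin(phi_mid[idx])])
    p = pos[idx] + frac * t_hat
    n_hat = np.array([-t_hat[1], t_hat[0]])
    return p, t_hat, n_hat


def _nearest_arc(pos: np.ndarray, ds: float, c: np.ndarray):
    """Arc position and distance of the polyline point nearest to ``c``."""
    seg = pos[1:] - pos[:-1]
    rel = c[None, :] - pos[:-1]
    seg_len2 = np.einsum("ij,ij->i", seg, seg)
    t = np.clip(np.einsum("ij,ij->i", rel, seg) / seg_len2, 0.0, 1.0)
    proj = pos[:-1] + t[:, None] * seg
    d2 = np.einsum("ij,ij->i", (c - proj), (c - proj))
    k = int(np.argmin(d2))
    return (k + t[k]) * ds, float(np.sqrt(d2[k])), proj[k]


def _compliance(geometry: WhiskerGeometry, ei: np.ndarray, ds: float, a: float):
    """Small-deflection cantilever compliance at arc ``a`` (m/N): integral of
    (a-s)^2 / EI over [0, a].  Used as the Newton gain on the force magnitude."""
    n_seg = ei.size
    s_mid = (np.arange(n_seg) + 0.5) * ds
    w = np.clip(a - s_mid, 0.0, None)
    inside = s_mid < a
    return float(np.sum(w[inside] ** 2 / ei[inside]) * ds)


def _equilibrium_kappa(pos, ds, ei, kappa0, a, f_vec):
    """Target curvature profile for a point force ``f_vec`` applied at arc a."""
    n_seg = ei.size
    p_mid = 0.5 * (pos[:-1] + pos[1:])
    idx = min(int(a / ds), n_seg - 1)
    frac = a - idx * ds
    t = pos[idx + 1] - pos[idx]
    p_c = pos[idx] + (frac / ds) * t
    lever = p_c[None, :] - p_mid
    m = lever[:, 0] * f_vec[1] - lever[:, 1] * f_vec[0]
    s_mid = (np.arange(n_seg) + 0.5) * ds
    m[s_mid >= a] = 0.0
    return kappa0 + m / ei


# ---------------------------------------------------------------------------
# forward solver
# ---------------------------------------------------------------------------

def deflect_whisker(
    geometry: WhiskerGeometry,
    constraint: ContactConstraint,
    warm_start: DeflectionResult | None = None,
    damping: float = 0.7,
    max_iter: int = _MAX_ITER,
) -> DeflectionResult:
    """Solve the frictionless point-contact equilibrium for one frame.

    Returns the deflected shape, the arc position where the whisker touches
    the constraint, the applied force vector, and the base reactions.  If the
    constraint point lies on the undeflected whisker the solution is the
    trivial one with exactly zero force and reactions.

    A cold start far from the resting shape can defeat the relaxation; in
    that case the solver ramps the constraint outward from the resting
    whisker in substeps, warm-starting each one (displacement continuation).

    Raises ``SolverError`` on non-convergence and ``ContactLost`` when the
    constraint cannot be held by any point of the whisker.
    """
    try:
        return _deflect_attempt(geometry, constraint, warm_start, damping, max_iter)
    except SolverError:
        pass
    # adaptive continuation: approach the constraint point from the resting
    # whisker, bisecting the step and lowering the damping on failure
    ds_mm = geometry.ds_mm
    rest = geometry.undeflected_nodes_mm()
    c_mm = np.asarray(constraint.point_mm, dtype=float)
    _a, _d, p_near = _nearest_arc(rest * MM, ds_mm * MM, c_mm * MM)
    p_near_mm = p_near / MM
    warm = None
    frac, step = 0.0, 0.2
    while frac < 1.0 - 1e-9:
        frac_try = min(frac + step, 1.0)
        target = p_near_mm + frac_try * (c_mm - p_near_mm)
        cc = ContactConstraint(tuple(target), constraint.probe_radius_mm)
        try:
            warm = _deflect_attempt(geometry, cc, warm, damping, max_iter)
        except SolverError:
            try:
                warm = _deflect_attempt(geometry, cc, warm, 0.05, max_iter)
            except SolverError:
                step *= 0.5
                if step < 1e-3:
                    raise
                continue
        frac = frac_try
        step = min(step * 1.5, 0.25)
    return warm


def _deflect_attempt(
    geometry: WhiskerGeometry,
    constraint: ContactConstraint,
    warm_start: DeflectionResult | None,
    damping: float,
    max_iter: int,
) -> DeflectionResult:
    ds, _s_mid, ei, kappa0 = _beam_arrays(geometry)
    L = geometry.length_mm * MM
    rest_mm = geometry.undeflected_nodes_mm()
    rest_pos = rest_mm * MM

    c = np.asarray(constraint.point_mm, dtype=float) * MM
    a0, dist0, p_near = _nearest_arc(rest_pos, ds, c)
    if constraint.probe_radius_mm > 0 and dist0 > 1e-12:
        u = (c - p_near) / dist0
        c = c - constraint.probe_radius_mm * MM * u
        a0, dist0, p_near = _nearest_arc(rest_pos, ds, c)

    if np.hypot(*c) > L + 1e-12:
        raise ContactLost("constraint point beyond whisker reach")

    if dist0 < _TOL_POS:
        # constraint on the resting whisker: null deflection, exact zeros
        return DeflectionResult(
            shape_mm=rest_mm.copy(),
            contact_arc_mm=a0 / MM,
            force_uN=np.zeros(2),
            reactions=BaseReactions.zero(),
            converged=True,
            n_iter=0,
            residual_mm=0.0,
            kappa=kappa0.copy(),
        )

    # push side: which side of the resting whisker the constraint lies on
    _, t0, n0 = _point_at(rest_pos, np.zeros(ei.size) if geometry.intrinsic_curvature is None
                          else _integrate(kappa0, ds)[1], ds, a0)
    sigma = 1.0 if float(np.dot(c - p_near, n0)) >= 0 else -1.0

    if warm_start is not None and warm_start.kappa is not None:
        kappa = warm_start.kappa.copy()
        a = min(warm_start.contact_arc_mm * MM, L - 0.5 * ds)
        f_mag = float(np.hypot(*warm_start.force_uN)) * 1e-6
    else:
        kappa = kappa0.copy()
        a = a0
        f_mag = dist0 / _compliance(geometry, ei, ds, max(a0, ds))

    pos, phi_mid = _integrate(kappa, ds)
    converged = False
    err = np.inf
    err_prev = np.inf
    lam = damping
    at_tip = 0
    for it in range(1, max_iter + 1):
        p_a, t_hat, n_hat = _point_at(pos, phi_mid, ds, a)
        e = c - p_a
        err = float(np.hypot(*e))
        err_tan = float(np.dot(e, t_hat))
        err_perp = float(np.dot(e, n_hat))

        # oscillation guard: shrink the relaxation factor when the residual grows
        if err > 1.5 * err_prev and lam > 0.02:
            lam *= 0.5
        err_prev = err

        a_new = float(np.clip(a + lam * err_tan, 0.5 * ds, L - 1e-12))
        comp = _compliance(geometry, ei, ds, max(a_new, ds))
        df = lam * sigma * err_perp / comp
        f_new = max(f_mag + df, 0.0)

        f_vec = sigma * f_new * n_hat
        kappa_t = _equilibrium_kappa(pos, ds, ei, kappa0, a_new, f_vec)
        dk = lam * (kappa_t - kappa)
        # trust region: never rotate any hinge by more than 0.1 rad per sweep
        max_dphi = float(np.max(np.abs(dk))) * ds
        if max_dphi > 0.1:
            dk *= 0.1 / max_dphi
        kappa = kappa + dk
        pos, phi_mid = _integrate(kappa, ds)

        a, f_mag = a_new, f_new
        # contact sliding off the free end: no equilibrium holds the constraint
        at_tip = at_tip + 1 if a >= L - 1.5 * ds else 0
        if at_tip > 50 and err > 10 * _TOL_POS:
            raise ContactLost("contact point slid beyond the whisker tip")
        if (
            err < _TOL_POS
            and abs(df) < _TOL_FORCE
            and float(np.max(np.abs(dk))) * ds < 1e-7
        ):
            converged = True
            break

    if not converged:
        raise SolverError(
            f"equilibrium not reached in {max_iter} iterations "
            f"(constraint residual {err / MM:.3g} mm)"
        )
    if a >= L - ds:
        # converged with the contact at the last segment: treat as slipped off
        if err > _TOL_POS:
            raise ContactLost("constraint slid beyond the whisker tip")

    p_a, t_hat, n_hat = _point_at(pos, phi_mid, ds, a)
    f_vec = sigma * f_mag * n_hat
    if f_mag == 0.0:
        reactions = BaseReactions.zero()
        f_rep = np.zeros(2)
    else:
        m_base = p_a[0] * f_vec[1] - p_a[1] * f_vec[0]  # N*m, CCW positive
        reactions = BaseReactions(
            fx_uN=-f_vec[0] * 1e6,  # positive pointing out of the follicle
            fy_uN=f_vec[1] * 1e6,
            m_uNm=m_base * 1e6,
        )
        f_rep = f_vec * 1e6
    return DeflectionResult(
        shape_mm=pos / MM,
        contact_arc_mm=a / MM,
        force_uN=f_rep,
        reactions=reactions,
        converged=True,
        n_iter=it,
        residual_mm=err / MM,
        kappa=kappa,
    )


# ---------------------------------------------------------------------------
# inverse solver: observed shape -> base reactions
# ---------------------------------------------------------------------------

def _solve_shape_for_force(
    geometry: WhiskerGeometry,
    a: float,
    f_mag: float,
    sigma: float,
    damping: float = 0.7,
    max_iter: int = 2000,
):
    """Relax the elastica under a force of fixed magnitude applied at fixed
    arc position, direction perpendicular to the (current) tangent there."""
    ds, _s, ei, kappa0 = _beam_arrays(geometry)
    kappa = kappa0.copy()
    pos, phi_mid = _integrate(kappa, ds)
    for _ in range(max_iter):
        _, _t, n_hat = _point_at(pos, phi_mid, ds, a)
        f_vec = sigma * f_mag * n_hat
        kappa_t = _equilibrium_kappa(pos, ds, ei, kappa0, a, f_vec)
        dk = damping * (kappa_t - kappa)
        max_dphi = float(np.max(np.abs(dk))) * ds
        if max_dphi > 0.1:
            dk *= 0.1 / max_dphi
        kappa = kappa + dk
        pos, phi_mid = _integrate(kappa, ds)
        if float(np.max(np.abs(dk))) * ds < 1e-9:
            break
    p_a, t_hat, n_hat = _point_at(pos, phi_mid, ds, a)
    return pos, sigma * f_mag * n_hat, p_a


def _register_shape(shape_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rigidly register an observed shape to the base frame.

    Translation puts the most proximal node at the origin; rotation aligns the
    least-squares direction of the most proximal 10% of nodes with +x.
    Returns the registered shape plus (rotation matrix, translation).
    """
    shape = np.asarray(shape_mm, dtype=float)
    n_prox = max(4, shape.shape[0] // 10)
    base = shape[0]
    prox = shape[:n_prox] - base
    # tangent at the base from a quadratic fit in arc length over the
    # proximal nodes: a straight-line fit would be biased by proximal bending
    t = np.concatenate([[0.0], np.cumsum(np.hypot(*np.diff(prox, axis=0).T))])
    cx = np.polyfit(t, prox[:, 0], 2)
    cy = np.polyfit(t, prox[:, 1], 2)
    ang = np.arctan2(np.polyval(np.polyder(cy), 0.0), np.polyval(np.polyder(cx), 0.0))
    rot = np.array([[np.cos(-ang), -np.sin(-ang)], [np.sin(-ang), np.cos(-ang)]])
    return (shape - base) @ rot.T, rot, base


def base_reactions_from_shape(
    geometry: WhiskerGeometry,
    shape_mm: np.ndarray,
    contact_point_mm,
    contact: bool = True,
) -> tuple[BaseReactions, dict]:
    """Recover base reactions from an observed whisker shape.

    Finds the single point load (direction perpendicular to the whisker
    tangent at contact) whose quasi-static forward solution best matches the
    observed node positions in least squares, and returns the base reactions
    of that load.  Returns exact zeros when ``contact`` is False.

    The second return value is a diagnostics dict with the fitted force, the
    shape-residual RMS (mm) and a ``low_confidence`` flag.
    """
    if not contact:
        return BaseReactions.zero(), {"low_confidence": False, "rms_mm": 0.0}
    shape = np.asarray(shape_mm, dtype=float)
    if shape.shape[0] < 10:
        raise ValueError("observed shape needs at least 10 nodes")
    if contact_point_mm is None:
        raise ValueError("contact flagged but no contact point given")

    reg, rot, base = _register_shape(shape)
    c = (np.asarray(contact_point_mm, dtype=float) - base) @ rot.T

    ds, _s, ei, kappa0 = _beam_arrays(geometry)
    reg_m = reg * MM
    c_m = c * MM
    a_obs, _dist, _proj = _nearest_arc(reg_m, ds, c_m)
    a_obs = float(np.clip(a_obs, ds, geometry.length_mm * MM - 1e-12))

    rest = geometry.undeflected_nodes_mm() * MM
    # perpendicular displacement of the observed contact point from rest
    a_rest, d_rest, p_rest = _nearest_arc(rest, ds, c_m)
    if d_rest < _TOL_POS:
        return BaseReactions.zero(), {"low_confidence": False, "rms_mm": 0.0}
    pos0, phi0 = _integrate(kappa0, ds)
    _, _t0, n0 = _point_at(pos0, phi0, ds, a_rest)
    sigma = 1.0 if float(np.dot(c_m - p_rest, n0)) >= 0 else -1.0
    f0 = d_rest / _compliance(geometry, ei, ds, max(a_rest, ds))

    # resample the observed polyline onto the model's node arc grid
    def _resample(p):
        seg = np.hypot(*np.diff(p, axis=0).T)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        grid = np.linspace(0.0, arc[-1], geometry.n_nodes)
        return np.column_stack(
            [np.interp(grid, arc, p[:, 0]), np.interp(grid, arc, p[:, 1])]
        )

    obs = _resample(reg_m)

    def objective(f_mag: float) -> float:
        pos, _f, _pa = _solve_shape_for_force(geometry, a_obs, f_mag, sigma)
        return float(np.mean(np.sum((pos - obs) ** 2, axis=1)))

    # bracket with a coarse grid first: at forces far above the optimum the
    # relaxation can return shapes that defeat a blind line search
    grid = np.linspace(0.0, 6.0 * f0, 25)
    vals = [objective(fm) for fm in grid]
    k = int(np.argmin(vals))
    lo = grid[max(k - 1, 0)]
    hi = grid[min(k + 1, grid.size - 1)]
    res = minimize_scalar(
        objective, bounds=(lo, hi), method="bounded",
        options={"xatol": max(f0 * 1e-8, 1e-16)},
    )
    f_mag = float(res.x)
    rr = objective(f_mag)
    pos, f_vec, p_a = _solve_shape_for_force(geometry, a_obs, f_mag, sigma)
    rms_mm = float(np.sqrt(rr)) / MM
    m_base = p_a[0] * f_vec[1] - p_a[1] * f_vec[0]
    reactions = BaseReactions(
        fx_uN=-f_vec[0] * 1e6,
        fy_uN=f_vec[1] * 1e6,
        m_uNm=m_base * 1e6,
    )
    return reactions, {
        "low_confidence": rms_mm > 0.05,
        "rms_mm": rms_mm,
        "force_uN": f_vec * 1e6,
        "contact_arc_mm": a_obs / MM,
    }
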