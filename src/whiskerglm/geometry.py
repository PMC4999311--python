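"""Whisker geometry: a tapered 2D cantilever discretized into uniform arc segments.

The whisker frame has its origin at the basepoint with the base tangent along
+x (pointing tipward) and +y pointing rostrally.  Lengths are in mm, radii in
micrometres, and the Young's modulus in Pa.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["WhiskerGeometry", "second_moment", "default_geometry"]

MM = 1e-3  # mm -> m
UM = 1e-6  # um -> m


@dataclass(frozen=True)
class WhiskerGeometry:
    """Undeflected tapered whisker.

    Parameters
    ----------
    length_mm : total arc length L.
    base_radius_um, tip_radius_um : radii of the linearly tapered circular
        cross-section at the base and tip.
    youngs_modulus_pa : Young's modulus E.
    n_nodes : number of nodes of the uniform arc-length discretization.
    intrinsic_curvature : per-node curvature (1/mm) of the resting shape;
        zero (straight whisker) by default.
    """

    length_mm: float = 25.0
    base_radius_um: float = 70.0
    tip_radius_um: float = 3.0
    youngs_modulus_pa: float = 3.3e9
    n_nodes: int = 100
    intrinsic_curvature: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.length_mm <= 0:
            raise ValueError("length_mm must be positive")
        if self.tip_radius_um <= 0 or self.base_radius_um < self.tip_radius_um:
            raise ValueError("radii must satisfy base >= tip > 0")
        if self.n_nodes < 10:
            raise ValueError("need at least 10 nodes")
        if self.intrinsic_curvature is not None:
            kappa = np.asarray(self.intrinsic_curvature, dtype=float)
            if kappa.shape != (self.n_nodes,):
                raise ValueError("intrinsic_curvature must have one value per node")
            object.__setattr__(self, "intrinsic_curvature", kappa)

    @property
    def ds_mm(self) -> float:
        """Arc spacing between adjacent nodes."""
        return self.length_mm / (self.n_nodes - 1)

    @property
    def arc_mm(self) -> np.ndarray:
        """Arc-length coordinate of each node, 0 at the base."""
        return np.linspace(0.0, self.length_mm, self.n_nodes)

    def radius_um(self, s_mm) -> np.ndarray:
        """Cross-section radius at arc position(s) ``s_mm``, linear taper."""
        s = np.asarray(s_mm, dtype=float)
        if np.any(s < -1e-12) or np.any(s > self.length_mm + 1e-12):
            raise ValueError("arc position outside [0, L]")
        frac = np.clip(s / self.length_mm, 0.0, 1.0)
        return self.base_radius_um + frac * (self.tip_radius_um - self.base_radius_um)

    def undeflected_nodes_mm(self) -> np.ndarray:
        """Resting node coordinates (n_nodes, 2) in the whisker frame."""
        if self.intrinsic_curvature is None:
            xy = np.zeros((self.n_nodes, 2))
            xy[:, 0] = self.arc_mm
            return xy
        # integrate the intrinsic curvature (evaluated at segment midpoints)
        kappa_mid = 0.5 * (self.intrinsic_curvature[:-1] + self.intrinsic_curvature[1:])
        phi = np.concatenate([[0.0], np.cumsum(kappa_mid * self.ds_mm)])
        seg_phi = 0.5 * (phi[:-1] + phi[1:])
        xy = np.zeros((self.n_nodes, 2))
        xy[1:, 0] = np.cumsum(self.ds_mm * np.cos(seg_phi))
        xy[1:, 1] = np.cumsum(self.ds_mm * np.sin(seg_phi))
        return xy


def second_moment(geometry: WhiskerGeometry, s_mm) -> np.ndarray:
    """Second moment of area I(s) = pi r(s)^4 / 4, in mm^4.

    ``s_mm`` may be a scalar or array of arc positions in [0, L].
    """
    r_mm = geometry.radius_um(s_mm) * 1e-3
    return np.pi * r_mm**4 / 4.0


def default_geometry(**overrides) -> WhiskerGeometry:
    """Literature-typical rat whisker: 25 mm, 70→3 um taper, E = 3.3 GPa."""
    return WhiskerGeometry(**overrides)
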