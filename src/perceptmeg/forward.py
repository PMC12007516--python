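"""Analytic single-sphere forward model for MEG sensors.

Implements the closed-form magnetic field of a current dipole inside a
spherically symmetric conductor.  In this model radially oriented
dipoles are magnetically silent, and the field outside the conductor
does not depend on the sphere radius or conductivity profile — only on
the sphere centre.

Lead fields are expressed in fT per nA*m of dipole moment for
magnetometers and axial gradiometers, and fT/(mm * nA*m) for planar
gradiometers (finite difference over the physical baseline).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .profiles import ChannelInfo, GRAD_AXIAL, GRAD_PLANAR, MAG

__all__ = ["LeadField", "dipole_field", "sphere_leadfield"]

_MU0_4PI = 1e-7  # T*m/A
# dipole moment unit nA*m (1e-9 A*m), field unit fT (1e15 T)
_UNIT_SCALE = 1e-9 * 1e15


def dipole_field(r0: np.ndarray, q: np.ndarray, sensors: np.ndarray,
                 center: np.ndarray | None = None) -> np.ndarray:
    """Magnetic field of a current dipole in a conducting sphere.

    Parameters
    ----------
    r0 : (3,) array
        Dipole position in metres.
    q : (3,) array
        Dipole moment in nA*m.
    sensors : (n, 3) array
        Field evaluation points in metres (outside the conductor).
    center : (3,) array, optional
        Sphere centre; origin by default.

    Returns
    -------
    (n, 3) array
        Magnetic field vectors in fT.
    """
    r0 = np.asarray(r0, float)
    q = np.asarray(q, float)
    r = np.atleast_2d(np.asarray(sensors, float))
    if center is not None:
        r0 = r0 - center
        r = r - center

    a_vec = r - r0  # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)
    R = np.linalg.norm(r, axis=1)
    if np.any(a < 1e-12):
        raise ValueError("field point coincides with the dipole position")

    ar = np.einsum("ij,ij->i", a_vec, r)
    r0r = r0 @ r.T
    F = a * (R * a + R**2 - r0r)
    # gradient of F with respect to the field point
    c1 = a**2 / R + ar / a + 2.0 * a + 2.0 * R
    c2 = a + 2.0 * R + ar / a
    gradF = c1[:, None] * r - c2[:, None] * r0[None, :]

    qxr0 = np.cross(q, r0)
    num = F[:, None] * qxr0[None, :] - (r @ qxr0)[:, None] * gradF
    B = _MU0_4PI * num / (F**2)[:, None]
    return B * _UNIT_SCALE


def _channel_response(r0: np.ndarray, q: np.ndarray,
                      channels: tuple[ChannelInfo, ...],
                      center: np.ndarray,
                      axial_baseline: float,
                      planar_baseline: float) -> np.ndarray:
    """Response of every channel to one dipole, respecting channel types."""
    out = np.empty(len(channels))
    # group evaluation points to limit formula calls
    for i, ch in enumerate(channels):
        if ch.ctype == MAG:
            B = dipole_field(r0, q, ch.position[None, :], center)
            out[i] = B[0] @ ch.orientation
        elif ch.ctype == GRAD_AXIAL:
            pts = np.stack([ch.position,
                            ch.position + axial_baseline * ch.orientation])
            B = dipole_field(r0, q, pts, center)
            out[i] = (B[0] - B[1]) @ ch.orientation
        elif ch.ctype == GRAD_PLANAR:
            t = ch.tangential
            half = 0.5 * planar_baseline * t
            pts = np.stack([ch.position + half, ch.position - half])
            B = dipole_field(r0, q, pts, center)
            # field difference over the baseline, expressed per millimetre
            out[i] = (B[0] - B[1]) @ ch.orientation / (planar_baseline * 1e3)
        else:
            out[i] = 0.0
    return out


@dataclass(frozen=True)
class LeadField:
    """Forward fields for a dipole grid: (n_points, n_channels, 3)."""

    positions: np.ndarray  # (n_points, 3) m
    lf: np.ndarray  # (n_points, n_channels, 3)
    sphere_center: np.ndarray
    channel_names: tuple[str, ...]

    @property
    def n_points(self) -> int:
        return self.positions.shape[0]


def sphere_leadfield(grid: np.ndarray, channels: tuple[ChannelInfo, ...],
                     sphere_center: np.ndarray | None = None, *,
                     sphere_radius: float | None = None,
                     axial_baseline: float = 0.05,
                     planar_baseline: float = 0.0168) -> LeadField:
    """Lead field of every grid point for three orthogonal unit dipoles.

    Grid points must lie strictly inside the sensor array; a point at the
    sphere centre has no defined tangential basis and is dropped with a
    warning.
    """
    grid = np.atleast_2d(np.asarray(grid, float))
    center = (np.zeros(3) if sphere_center is None
              else np.asarray(sphere_center, float))
    sensor_r = min(np.linalg.norm(ch.position - center) for ch in channels)
    limit = sensor_r if sphere_radius is None else sphere_radius
    radii = np.linalg.norm(grid - center, axis=1)
    if np.any(radii >= limit):
        raise ValueError(
            f"{int(np.sum(radii >= limit))} grid point(s) lie outside the "
            f"sensor sphere (radius {limit:.3f} m)"
        )
    keep = radii > 1e-9
    if not np.all(keep):
        warnings.warn(
            "dropping grid point(s) at the sphere centre "
            "(dipole orientation basis undefined there)",
            stacklevel=2,
        )
        grid = grid[keep]

    basis = np.eye(3)
    lf = np.empty((grid.shape[0], len(channels), 3))
    for g, r0 in enumerate(grid):
        for k in range(3):
            lf[g, :, k] = _channel_response(
                r0, basis[k], channels, center, axial_baseline, planar_baseline
            )
    return LeadField(
        positions=grid,
        lf=lf,
        sphere_center=center,
        channel_names=tuple(ch.name for ch in channels),
    )
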