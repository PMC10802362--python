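"""Analytic forward model: current dipole in a conducting sphere (Sarvas).

For a spherically symmetric conductor the magnetic field outside the sphere
has a closed form that depends only on the sphere centre, not on the
conductivity profile.  Radially oriented dipoles and dipoles at the centre
are magnetically silent — both properties are exploited as physics checks.

Fields are in tesla per (A*m) of dipole moment; geometry in metres.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import GeometryError, HeadModel, SensorArray

__all__ = ["LeadField", "dipole_field", "sarvas_leadfield", "tangential_basis"]

_MU0_OVER_4PI = 1e-7  # T m / (A m)


def dipole_field(location: np.ndarray, moment: np.ndarray,
                 points: np.ndarray, origin: np.ndarray | None = None
                 ) -> np.ndarray:
    """Magnetic field of a current dipole inside a conducting sphere.

    Sarvas' closed-form solution evaluated at ``points`` (outside the
    conductor).  ``location``/``moment`` are the dipole position (m) and
    moment (A*m); ``origin`` is the sphere centre.

    Returns an array of shape ``(n_points, 3)`` in tesla.
    """
    r0 = np.asarray(location, dtype=float).reshape(3)
    q = np.asarray(moment, dtype=float).reshape(3)
    r = np.atleast_2d(np.asarray(points, dtype=float)).copy()
    if origin is not None:
        r0 = r0 - np.asarray(origin, dtype=float).reshape(3)
        r = r - np.asarray(origin, dtype=float).reshape(3)

    a_vec = r - r0                                   # (n, 3)
    a = np.linalg.norm(a_vec, axis=1)                # (n,)
    rn = np.linalg.norm(r, axis=1)                   # (n,)
    if np.any(a < 1e-12) or np.any(rn < 1e-12):
        raise GeometryError("field point coincides with source or origin")

    ar = np.einsum("ij,ij->i", a_vec, r)             # a_vec . r
    r0r = r @ r0                                     # r0 . r
    f = a * (rn * a + rn ** 2 - r0r)
    grad_f = ((a ** 2 / rn + ar / a + 2.0 * a + 2.0 * rn)[:, None] * r
              - (a + 2.0 * rn + ar / a)[:, None] * r0[None, :])

    qxr0 = np.cross(q, r0)                           # (3,)
    qxr0_r = r @ qxr0                                # (n,)
    b = (f[:, None] * qxr0[None, :] - qxr0_r[:, None] * grad_f)
    b *= _MU0_OVER_4PI / (f ** 2)[:, None]
    return b


def tangential_basis(locations: np.ndarray) -> np.ndarray:
    """Two orthonormal vectors spanning the tangential plane at each point.

    Only tangential dipole components produce external field in a spherical
    conductor, so lead fields are parameterised by this 2-basis.  At the
    sphere centre the plane is undefined; the x/y unit vectors are returned
    (the field there is identically zero regardless).
    """
    locs = np.atleast_2d(np.asarray(locations, dtype=float))
    n = locs.shape[0]
    basis = np.empty((n, 2, 3))
    for i, r0 in enumerate(locs):
        rn = np.linalg.norm(r0)
        if rn < 1e-12:
            basis[i, 0] = (1.0, 0.0, 0.0)
            basis[i, 1] = (0.0, 1.0, 0.0)
            continue
        radial = r0 / rn
        ref = np.array([0.0, 0.0, 1.0])
        if abs(radial[2]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        e1 = np.cross(ref, radial)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(radial, e1)
        basis[i, 0] = e1
        basis[i, 1] = e2
    return basis


@dataclass(frozen=True)
class LeadField:
    """Sensor topographies of two tangential unit dipoles per source.

    ``fields[v]`` is ``(n_channels, 2)``: the channel-projected field of a
    1 A*m dipole along ``basis[v, 0]`` and ``basis[v, 1]``.
    """

    source_locations: np.ndarray  # (n_src, 3)
    basis: np.ndarray             # (n_src, 2, 3)
    fields: np.ndarray            # (n_src, n_channels, 2) tesla / (A m)

    @property
    def n_sources(self) -> int:
        return self.source_locations.shape[0]

    @property
    def n_channels(self) -> int:
        return self.fields.shape[1]

    def oriented(self, v: int, orientation: np.ndarray) -> np.ndarray:
        """Channel topography of a unit dipole along a tangential direction."""
        u = np.asarray(orientation, dtype=float).reshape(3)
        coeff = self.basis[v] @ u              # components in the 2-basis
        return self.fields[v] @ coeff


def sarvas_leadfield(head: HeadModel, source_locations: np.ndarray,
                     array: SensorArray) -> LeadField:
    """Lead field of tangential unit dipoles at each source location.

    Raises if any source lies on or outside the conductor, or any sensor
    lies inside it.
    """
    locs = np.atleast_2d(np.asarray(source_locations, dtype=float))
    if not np.all(head.contains(locs)):
        raise GeometryError("all sources must lie inside the conductor")
    sens_r = np.linalg.norm(
        array.sensor_positions - head.sphere_origin, axis=1)
    if np.any(sens_r <= head.sphere_radius):
        raise GeometryError("all sensors must lie outside the conductor")

    basis = tangential_basis(locs - head.sphere_origin)
    ori = array.channel_orientations            # (n_ch, 3)
    pos = array.channel_positions               # (n_ch, 3)
    fields = np.empty((locs.shape[0], array.n_channels, 2))
    for v, r0 in enumerate(locs):
        for j in range(2):
            b = dipole_field(r0, basis[v, j], pos, origin=head.sphere_origin)
            fields[v, :, j] = np.einsum("ij,ij->i", b, ori)
    return LeadField(locs, basis, fields)
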