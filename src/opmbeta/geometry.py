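"""Sensor-array and head geometry for simulated triaxial OPM recordings.

Coordinates are head-centred SI metres: +x right, +y anterior, +z superior,
with the conducting sphere centred at the origin.  Each optically pumped
magnetometer (OPM) measures the magnetic field along three orthogonal axes
(one radial, two tangential), so an array of ``n`` sensors yields ``3 n``
channels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SensorArray", "HeadModel", "make_sensor_array", "fibonacci_cap"]

#: golden angle in radians, used for quasi-uniform spherical packing
_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


class GeometryError(ValueError):
    """Invalid sensor/head geometry."""


@dataclass(frozen=True)
class HeadModel:
    """Spherically symmetric volume conductor.

    The analytic conducting-sphere solution is used for the forward model;
    any dipolar source must lie strictly inside ``sphere_radius``.
    """

    sphere_origin: np.ndarray = field(
        default_factory=lambda: np.zeros(3))
    sphere_radius: float = 0.085
    conductor_kind: str = "spherical"

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sphere_origin",
            np.asarray(self.sphere_origin, dtype=float).reshape(3))
        if not self.sphere_radius > 0:
            raise GeometryError("sphere_radius must be positive")

    def contains(self, points: np.ndarray, margin: float = 0.0) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        r = np.linalg.norm(pts - self.sphere_origin, axis=1)
        return r < self.sphere_radius - margin


@dataclass(frozen=True)
class SensorArray:
    """Triaxial sensor geometry: positions plus per-sensor orthonormal axes.

    ``sensor_axes[i]`` is a 3x3 matrix whose rows are the radial (X) and two
    tangential (Y, Z) measurement directions of sensor ``i``.  Channels are
    ordered sensor-major: ``s0-X, s0-Y, s0-Z, s1-X, ...``.
    """

    sensor_positions: np.ndarray  # (n_sensors, 3) metres
    sensor_axes: np.ndarray       # (n_sensors, 3, 3) unit rows
    channel_labels: tuple
    scalp_offset: float

    def __post_init__(self) -> None:
        pos = np.asarray(self.sensor_positions, dtype=float)
        axes = np.asarray(self.sensor_axes, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3:
            raise GeometryError("sensor_positions must be (n, 3)")
        if axes.shape != (pos.shape[0], 3, 3):
            raise GeometryError("sensor_axes must be (n, 3, 3)")
        gram = np.einsum("nij,nkj->nik", axes, axes)
        if not np.allclose(gram, np.eye(3), atol=1e-10):
            raise GeometryError("sensor axes are not orthonormal")
        object.__setattr__(self, "sensor_positions", pos)
        object.__setattr__(self, "sensor_axes", axes)
        object.__setattr__(self, "channel_labels", tuple(self.channel_labels))
        if len(self.channel_labels) != 3 * pos.shape[0]:
            raise GeometryError("need 3 channel labels per sensor")

    @property
    def n_sensors(self) -> int:
        return self.sensor_positions.shape[0]

    @property
    def n_channels(self) -> int:
        return 3 * self.n_sensors

    @property
    def channel_positions(self) -> np.ndarray:
        """(n_channels, 3) position of each channel (sensor position)."""
        return np.repeat(self.sensor_positions, 3, axis=0)

    @property
    def channel_orientations(self) -> np.ndarray:
        """(n_channels, 3) unit measurement direction of each channel."""
        return self.sensor_axes.reshape(-1, 3)


def fibonacci_cap(n: int, cos_theta_min: float, phase: float = 0.0) -> np.ndarray:
    """Quasi-uniform unit vectors on the spherical cap z/r >= cos_theta_min.

    Fibonacci-spiral packing: points are equally spaced in cap area with
    azimuths advancing by the golden angle (plus a constant ``phase``).
    """
    if n < 1:
        raise GeometryError("need at least one point")
    i = np.arange(n)
    # equal-area spacing in z over [cos_theta_min, 1), cell-centred
    z = 1.0 - (1.0 - cos_theta_min) * (i + 0.5) / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    phi = _GOLDEN_ANGLE * i + phase
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def make_sensor_array(n_sensors: int = 64,
                      head_radius: float = 0.085,
                      scalp_offset: float = 0.01,
                      cap_fraction: float = 0.65,
                      seed: int = 0) -> SensorArray:
    """Build a triaxial array on the upper cap of a sphere around the head.

    Sensors are packed quasi-uniformly (Fibonacci spiral) over the upper
    ``cap_fraction`` of the sphere of radius ``head_radius + scalp_offset``;
    each carries one radial and two tangential orthonormal axes.  ``seed``
    only rotates the spiral in azimuth, so arrays are reproducible.
    """
    if n_sensors < 4:
        raise GeometryError("need at least 4 sensors")
    if head_radius <= 0 or scalp_offset <= 0:
        raise GeometryError("head_radius and scalp_offset must be positive")
    if not 0 < cap_fraction <= 1:
        raise GeometryError("cap_fraction must be in (0, 1]")

    rng = np.random.default_rng(seed)
    phase = rng.uniform(0.0, 2.0 * np.pi)
    radius = head_radius + scalp_offset
    # a cap covering fraction f of sphere area spans cos(theta) in [1-2f, 1]
    units = fibonacci_cap(n_sensors, 1.0 - 2.0 * cap_fraction, phase=phase)
    positions = radius * units

    axes = np.empty((n_sensors, 3, 3))
    for k, u in enumerate(units):
        radial = u / np.linalg.norm(u)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(radial[2]) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        t1 = np.cross(ref, radial)
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(radial, t1)
        axes[k] = np.vstack([radial, t1, t2])

    labels = tuple(f"s{k:03d}-{ax}" for k in range(n_sensors)
                   for ax in ("X", "Y", "Z"))
    return SensorArray(positions, axes, labels, scalp_offset)


def head_radius_for_age(age: float) -> float:
    """Linear head-growth map: 2 y -> 0.07 m, 34 y -> 0.09 m (clipped)."""
    r = 0.07 + (0.09 - 0.07) * (age - 2.0) / (34.0 - 2.0)
    return float(np.clip(r, 0.065, 0.095))
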