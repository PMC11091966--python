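"""Truncated-sphere geometry for adhered droplet pairs.

When two lipid-monolayer-coated aqueous microdroplets adhere in oil, a
bilayer forms at the contact zone and each droplet takes the shape of a
sphere truncated by the (shared) contact plane.  The bilayer is modeled as
a flat disc of radius ``r_c``; the droplet volume is the sphere volume
minus the spherical cap cut off by that plane.

All lengths are micrometres, areas μm², volumes μm³.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "DropletShape",
    "DropletObservationSeries",
    "truncated_sphere_volume",
    "sphere_volume",
    "contact_area",
    "radius_from_volume",
    "series_to_volumes",
    "GeometryError",
]


class GeometryError(ValueError):
    """Raised when droplet shape parameters are geometrically inconsistent."""


@dataclass(frozen=True)
class DropletShape:
    """A single truncated-sphere droplet.

    Parameters
    ----------
    radius : float
        Sphere radius ``R`` (μm), must be positive.
    contact_radius : float
        Radius ``r_c`` of the bilayer contact disc (μm); ``0 <= r_c <= R``.
    """

    radius: float
    contact_radius: float = 0.0

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise GeometryError(f"droplet radius must be positive, got {self.radius}")
        if self.contact_radius < 0 or self.contact_radius > self.radius:
            raise GeometryError(
                f"contact radius must satisfy 0 <= r_c <= R, got "
                f"r_c={self.contact_radius}, R={self.radius}"
            )

    @property
    def volume(self) -> float:
        return truncated_sphere_volume(self.radius, self.contact_radius)

    @property
    def bilayer_area(self) -> float:
        return contact_area(self.contact_radius)


@dataclass
class DropletObservationSeries:
    """Time-resolved contour parameters of an adhered droplet pair.

    Fields mirror what image analysis of a DIB recording yields per frame:
    the two apparent sphere radii and the contact (bilayer disc) radius.

    Invariants: strictly increasing time, >= 2 frames, positive radii,
    and ``r_c <= min(R1, R2)`` in every frame.
    """

    t: np.ndarray
    r1: np.ndarray
    r2: np.ndarray
    rc: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.r1 = np.asarray(self.r1, dtype=float)
        self.r2 = np.asarray(self.r2, dtype=float)
        self.rc = np.asarray(self.rc, dtype=float)
        n = len(self.t)
        if not (len(self.r1) == len(self.r2) == len(self.rc) == n):
            raise GeometryError("t, R1, R2, rc must have equal lengths")
        if n < 2:
            raise GeometryError(f"need at least 2 frames, got {n}")
        if not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 1
            raise GeometryError(f"time must be strictly increasing (violated at frame {bad})")
        if not (np.all(self.r1 > 0) and np.all(self.r2 > 0)):
            raise GeometryError("all droplet radii must be positive")
        if np.any(self.rc < 0):
            raise GeometryError("contact radius must be nonnegative")
        bad = np.flatnonzero(self.rc > np.minimum(self.r1, self.r2))
        if bad.size:
            raise GeometryError(
                f"contact radius exceeds droplet radius at frames {bad.tolist()}"
            )

    def __len__(self) -> int:
        return len(self.t)


def truncated_sphere_volume(radius, contact_radius):
    """Volume of a sphere of radius ``R`` truncated by a plane whose circular
    cut has radius ``r_c``.

    With ``d = sqrt(R^2 - r_c^2)`` the distance from the sphere centre to the
    cutting plane and cap height ``h = R - d``::

        V = (4/3) pi R^3 - pi h^2 (3R - h) / 3

    which ranges from the hemisphere ``(2/3) pi R^3`` (``r_c = R``) to the
    full sphere (``r_c = 0``).  Accepts scalars or arrays.
    """
    radius = np.asarray(radius, dtype=float)
    contact_radius = np.asarray(contact_radius, dtype=float)
    if np.any(radius <= 0):
        raise GeometryError("radius must be positive")
    if np.any(contact_radius < 0) or np.any(contact_radius > radius):
        raise GeometryError("contact radius must satisfy 0 <= r_c <= R")
    d = np.sqrt(radius**2 - contact_radius**2)
    h = radius - d
    v_cap = np.pi * h**2 * (3.0 * radius - h) / 3.0
    v = 4.0 / 3.0 * np.pi * radius**3 - v_cap
    return float(v) if v.ndim == 0 else v


def sphere_volume(radius):
    """Full-sphere volume, the alternative (untruncated) geometry convention."""
    radius = np.asarray(radius, dtype=float)
    if np.any(radius <= 0):
        raise GeometryError("radius must be positive")
    v = 4.0 / 3.0 * np.pi * radius**3
    return float(v) if v.ndim == 0 else v


def contact_area(contact_radius):
    """Bilayer contact area: planar disc, ``A = pi r_c^2`` (μm²)."""
    contact_radius = np.asarray(contact_radius, dtype=float)
    if np.any(contact_radius < 0):
        raise GeometryError("contact radius must be nonnegative")
    a = np.pi * contact_radius**2
    return float(a) if a.ndim == 0 else a


def radius_from_volume(volume, contact_radius, geometry: str = "truncated"):
    """Invert the volume model: sphere radius giving volume ``V`` at fixed r_c.

    The truncated-sphere volume is strictly increasing in R on ``[r_c, inf)``
    so the root is bracketed and unique (solved with Brent's method).
    Accepts scalar or array ``volume``.
    """
    vol = np.atleast_1d(np.asarray(volume, dtype=float))
    rc = np.broadcast_to(np.asarray(contact_radius, dtype=float), vol.shape)
    if np.any(vol <= 0):
        raise GeometryError("volume must be positive")
    out = np.empty_like(vol)
    for i, (v, r_c) in enumerate(zip(vol, rc)):
        if geometry == "sphere" or r_c == 0.0:
            out[i] = (3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0)
            continue
        lo = r_c
        if truncated_sphere_volume(lo * (1 + 1e-12) if lo > 0 else 1e-9, r_c) > v:
            raise GeometryError(
                f"volume {v} smaller than hemisphere volume at r_c={r_c}"
            )
        hi = max(2.0 * r_c, (3.0 * v / (2.0 * np.pi)) ** (1.0 / 3.0) + r_c)
        while truncated_sphere_volume(hi, r_c) < v:
            hi *= 2.0
        out[i] = brentq(
            lambda r: truncated_sphere_volume(r, r_c) - v, lo, hi, xtol=1e-12, rtol=1e-14
        )
    return float(out[0]) if np.ndim(volume) == 0 else out


def series_to_volumes(obs: DropletObservationSeries, geometry: str = "truncated"):
    """Per-frame droplet volumes and bilayer areas for an observation series.

    Returns ``(V1, V2, A)`` arrays (μm³, μm³, μm²).  ``geometry`` selects the
    truncated-sphere model (default) or the full-sphere convention that
    ignores the cap cut off by the contact plane.
    """
    if geometry == "truncated":
        v1 = truncated_sphere_volume(obs.r1, obs.rc)
        v2 = truncated_sphere_volume(obs.r2, obs.rc)
    elif geometry == "sphere":
        v1 = sphere_volume(obs.r1)
        v2 = sphere_volume(obs.r2)
    else:
        raise ValueError(f"unknown geometry mode {geometry!r}")
    a = contact_area(obs.rc)
    return v1, v2, a
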