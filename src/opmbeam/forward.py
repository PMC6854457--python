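"""Closed-form current-dipole forward model for a conducting sphere.

The external magnetic field of a current dipole inside a homogeneous
conducting sphere has the well-known closed form (Sarvas):

    B(r) = mu0 / (4 pi F^2) * ( F (Q x r0) - ((Q x r0) . r) grad F )

with r0 the dipole position and r the observation point (both relative to the
sphere centre), a = r - r0, F = a (r a + r^2 - r0.r), and

    grad F = (a^2/r + a.r/a + 2a + 2r) r - (a + 2r + a.r/a) r0.

Dipoles with a radial moment (Q parallel to r0) are externally silent, so the
lead field uses a two-column tangential basis at each source; the radial
direction is excluded by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import SensorArray, SourceGrid, SphereHeadModel

_MU0_OVER_4PI = 1e-7  # T m / (A m)


def _sarvas(r0: np.ndarray, q: np.ndarray, robs: np.ndarray) -> np.ndarray:
    """Field of dipole(s) ``q`` at ``r0`` observed at ``robs`` (broadcastable).

    All positions are relative to the sphere centre.  Shapes broadcast over a
    trailing axis of length 3.
    """
    a_vec = robs - r0
    an = np.linalg.norm(a_vec, axis=-1)
    rn = np.linalg.norm(robs, axis=-1)
    r0_dot_r = np.sum(r0 * robs, axis=-1)
    a_dot_r = np.sum(a_vec * robs, axis=-1)
    F = an * (rn * an + rn**2 - r0_dot_r)
    gF = (
        (an**2 / rn + a_dot_r / an + 2.0 * an + 2.0 * rn)[..., None] * robs
        - (an + 2.0 * rn + a_dot_r / an)[..., None] * r0
    )
    q_x_r0 = np.cross(q, r0)
    num = F[..., None] * q_x_r0 - np.sum(q_x_r0 * robs, axis=-1)[..., None] * gF
    return _MU0_OVER_4PI * num / (F**2)[..., None]


def dipole_field_sphere(
    dipole_pos,
    dipole_moment,
    obs_pos,
    head: SphereHeadModel,
) -> np.ndarray:
    """Full external field vector (tesla) of a current dipole in the sphere.

    ``obs_pos`` may be a single point or an (..., 3) stack of points, all of
    which must lie strictly outside the conductor; the dipole must lie
    strictly inside.  The result is linear in ``dipole_moment``; radial
    dipoles (and any dipole at the centre) give an exactly zero field.
    """
    c = head.center_arr
    r0 = np.asarray(dipole_pos, dtype=float) - c
    q = np.asarray(dipole_moment, dtype=float)
    robs = np.asarray(obs_pos, dtype=float) - c
    if np.linalg.norm(r0) >= head.radius:
        raise ValueError("dipole must lie strictly inside the head sphere")
    if np.any(np.linalg.norm(robs, axis=-1) <= head.radius):
        raise ValueError("observation points must lie strictly outside the head sphere")
    q_x_r0 = np.cross(q, r0)
    silent_scale = np.linalg.norm(q) * np.linalg.norm(r0)
    if np.linalg.norm(q_x_r0) <= 1e-12 * silent_scale or silent_scale == 0.0:
        # silent family: radial moment or dipole at the centre
        return np.zeros(np.shape(robs))
    return _sarvas(r0, np.broadcast_to(q, robs.shape), robs)


def tangential_basis(directions: np.ndarray) -> np.ndarray:
    """Orthonormal tangential pairs perpendicular to each radial direction.

    ``directions`` is (n, 3) of (not necessarily unit) radial vectors; returns
    (n, 2, 3).  A fixed fallback axis handles sources on/near the z axis; a
    source exactly at the centre (zero direction) gets the x/y plane.
    """
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    norms = np.linalg.norm(d, axis=1, keepdims=True)
    u_r = np.divide(d, norms, out=np.zeros_like(d), where=norms > 1e-15)
    z = np.array([0.0, 0.0, 1.0])
    e1 = np.cross(np.broadcast_to(z, u_r.shape), u_r)
    small = np.linalg.norm(e1, axis=1) < 1e-8
    if np.any(small):
        x = np.array([1.0, 0.0, 0.0])
        e1[small] = np.cross(np.broadcast_to(x, u_r[small].shape), u_r[small])
        center = np.linalg.norm(e1, axis=1) < 1e-8  # zero direction: arbitrary plane
        e1[center] = x
        u_r[center] = z
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(u_r, e1)
    return np.stack([e1, e2], axis=1)


@dataclass
class LeadFieldSet:
    """Per-source sensors x 2 lead-field matrices over a tangential basis."""

    L: np.ndarray        # (n_sources, n_sensors, 2) tesla per (A m)
    basis: np.ndarray    # (n_sources, 2, 3) tangential unit vectors
    grid: SourceGrid
    sensors: SensorArray
    head: SphereHeadModel

    @property
    def n_sources(self) -> int:
        return self.L.shape[0]


def lead_field_matrix(
    scalp: SensorArray,
    grid: SourceGrid,
    head: SphereHeadModel,
    chunk: int = 4096,
) -> LeadFieldSet:
    """Tangential lead fields for every in-mask grid voxel.

    Column ``c`` of source ``s`` is the field of a unit dipole along tangential
    basis vector ``c``, projected onto each sensor's sensitive axis.
    """
    c = head.center_arr
    sources = grid.in_mask_coords() - c
    if np.any(np.linalg.norm(sources, axis=1) >= head.radius):
        raise ValueError("in-mask sources must lie strictly inside the head sphere")
    sens = scalp.positions - c
    if np.any(np.linalg.norm(sens, axis=1) <= head.radius):
        raise ValueError("sensors must lie strictly outside the head sphere")
    orient = scalp.orientations
    ns, nc = sources.shape[0], sens.shape[0]
    basis = tangential_basis(sources)
    L = np.empty((ns, nc, 2))
    for start in range(0, ns, chunk):
        sl = slice(start, min(start + chunk, ns))
        r0 = sources[sl][:, None, :]          # (b, 1, 3)
        robs = sens[None, :, :]               # (1, nc, 3)
        for col in range(2):
            q = basis[sl, col][:, None, :]    # (b, 1, 3)
            B = _sarvas(r0, np.broadcast_to(q, (sl.stop - sl.start, nc, 3)),
                        np.broadcast_to(robs, (sl.stop - sl.start, nc, 3)))
            L[sl, :, col] = np.sum(B * orient[None, :, :], axis=-1)
    if not np.all(np.isfinite(L)):
        raise FloatingPointError("non-finite lead-field entries")
    return LeadFieldSet(L, basis, grid, scalp, head)
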