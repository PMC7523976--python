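"""Element-wise principal material directions for the arterial wall.

The collagen-fiber coordinate system of every wall element is built the way
locally structured hexahedral vessel meshes allow: the lumen-contour
centroids of consecutive cross-sections define a centerline; its two points
bracketing a section give the local axial basis e_z; the outward normal of
an element's inner face at the element centroid gives the radial basis e_r;
their cross product gives the circumferential basis e_theta.  The two fiber
families then lie at +/-phi from e_theta in the (e_theta, e_z) plane.

The plane-strain solver consumes only the in-plane angle of e_theta; the
full 3D frames are computed and exportable regardless.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Polygon

from .phantom import ContourStack, SectionMesh


class FrameError(RuntimeError):
    pass


def section_centerline(stack: ContourStack) -> np.ndarray:
    """(n_stations, 3) polyline of lumen-contour area centroids."""
    if stack.n_stations < 2:
        raise ValueError("need at least 2 stations for a centerline")
    pts = np.empty((stack.n_stations, 3))
    for k in range(stack.n_stations):
        poly = Polygon(stack.contour_xy("lumen", k))
        if poly.area <= 0:
            raise FrameError(f"degenerate lumen contour at station {k}")
        c = poly.centroid
        pts[k] = (c.x, c.y, stack.z[k])
    return pts


@dataclass
class LocalFrame:
    """Per-element orthonormal right-handed (e_r, e_theta, e_z) triads."""

    element_ids: np.ndarray  # (m,) element indices into the mesh
    e_r: np.ndarray  # (m, 3)
    e_theta: np.ndarray  # (m, 3)
    e_z: np.ndarray  # (m, 3)

    def basis_matrix(self, i: int) -> np.ndarray:
        """3x3 matrix with columns (e_r, e_theta, e_z) for local element i."""
        return np.column_stack([self.e_r[i], self.e_theta[i], self.e_z[i]])

    def inplane_angles(self) -> np.ndarray:
        """atan2 angle of e_theta in the section plane, per element."""
        return np.arctan2(self.e_theta[:, 1], self.e_theta[:, 0])


def _axial_basis(centerline: np.ndarray, z: float) -> np.ndarray:
    """Unit tangent from the two centerline points bracketing the section."""
    zs = centerline[:, 2]
    k = int(np.searchsorted(zs, z))
    k0 = max(0, min(k - 1, len(zs) - 2))
    d = centerline[k0 + 1] - centerline[k0]
    n = np.linalg.norm(d)
    if n == 0:
        raise FrameError("coincident centerline points")
    return d / n


def element_basis(
    mesh: SectionMesh,
    centerline: np.ndarray,
    elements: np.ndarray | None = None,
) -> LocalFrame:
    """Local material frames for the given (default: wall annulus) elements.

    e_z: centerline tangent at the section; e_r: outward normal of the
    element's inner (lumen-facing) edge at the element centroid; e_theta =
    e_z x e_r; the triad is re-orthonormalized so that [e_r e_theta e_z] is a
    proper rotation.
    """
    if elements is None:
        elements = np.flatnonzero(mesh.wall_mask())
    elements = np.asarray(elements, dtype=int)
    ez = _axial_basis(centerline, mesh.station_z)

    e_r = np.empty((len(elements), 3))
    e_t = np.empty_like(e_r)
    e_zs = np.empty_like(e_r)
    centroid2d = mesh.centroids()
    section_c = mesh.nodes[mesh.lumen_loop].mean(axis=0)
    for out_i, e in enumerate(elements):
        n0, n1 = mesh.quads[e, 0], mesh.quads[e, 3]  # inner edge nodes
        t = mesh.nodes[n1] - mesh.nodes[n0]
        nrm = np.array([t[1], -t[0]])
        ln = np.linalg.norm(nrm)
        if ln < 1e-14:
            raise FrameError(f"zero-length inner-face normal on element {e}")
        nrm /= ln
        # orient outward: away from the section centroid
        if nrm @ (centroid2d[e] - section_c) < 0:
            nrm = -nrm
        er = np.array([nrm[0], nrm[1], 0.0])
        et = np.cross(ez, er)
        et /= np.linalg.norm(et)
        er = np.cross(et, ez)  # re-orthonormalize
        er /= np.linalg.norm(er)
        e_r[out_i], e_t[out_i], e_zs[out_i] = er, et, ez
    return LocalFrame(element_ids=elements, e_r=e_r, e_theta=e_t, e_z=e_zs)


def fiber_directions(frame: LocalFrame, phi_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Unit fiber-family directions a+/- = cos(phi) e_theta +/- sin(phi) e_z."""
    phi = np.deg2rad(phi_deg)
    a_plus = np.cos(phi) * frame.e_theta + np.sin(phi) * frame.e_z
    a_minus = np.cos(phi) * frame.e_theta - np.sin(phi) * frame.e_z
    return a_plus, a_minus
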