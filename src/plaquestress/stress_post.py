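"""Stress recovery and extraction of the peak stress response indicators.

From a converged section solution, Cauchy stress tensors are recovered at
element centroids (a single recovery point per element; no nodal averaging
across region boundaries, which would smear the fibrous-tissue/lipid-core
stiffness jump).  The two scalar responses of the screening study are

* PPS (peak plaque stress): maximum first (largest) principal Cauchy stress
  over the plaque components — fibrous tissue, including the FT-like part of
  the wall annulus when the wall-thickness factor is below its maximum, and
  optionally the lipid core;
* PCS (peak cap stress): the same maximum restricted to the fibrous cap,
  the lumen-adjacent FT elements shielded by the lipid core, dilated by one
  element ring so the cap shoulders are included.

Stations within an exclusion length of the segment ends are skipped, since
near-boundary results are artefacts of the end constraints.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point
from shapely.ops import unary_union

from .fem_solver import PlaneStrainModel, Solution
from .fiber_frames import LocalFrame
from .phantom import SectionMesh
from . import _symdiff
from .constitutive import MediaAnisoParams

PLAQUE_REGIONS = ("ft", "ft_wall", "lc")


@dataclass
class StressField:
    """Centroid Cauchy stress tensors (kPa) of one solved section."""

    sigma: np.ndarray  # (n_elems, 3, 3)
    region: np.ndarray  # (n_elems,) region name strings
    centroids: np.ndarray  # (n_elems, 2) reference centroids [mm]
    station_z: float
    mesh: SectionMesh = field(repr=False)

    def __post_init__(self):
        if not np.all(np.isfinite(self.sigma)):
            raise ValueError("non-finite stress recovered")


def recover_stresses(
    model: PlaneStrainModel, solution: Solution, frames: LocalFrame | None = None
) -> StressField:
    """Centroid Cauchy stresses sigma = F S F^T / J + K(J0-1) I."""
    mesh = model.mesh
    _, F, J, F0, J0 = model.kinematics(solution.u)
    m = mesh.n_elems
    C3 = np.zeros((m, 3, 3))
    C3[:, :2, :2] = np.einsum("mkI,mkJ->mIJ", F0, F0)
    C3[:, 2, 2] = 1.0

    angles = np.zeros(m)
    if frames is not None:
        angles[frames.element_ids] = frames.inplane_angles()

    S3 = np.empty((m, 3, 3))
    names = mesh.region_names()
    for kind, sel, params in model.batches:
        if kind == "media":
            mu, k1, k2, rho, phi = params[:5]
            a = angles[sel]
            # rotate C into the local (r, theta, z) frame: columns (e_r, e_t, e_z)
            Q = np.zeros((len(sel), 3, 3))
            Q[:, 0, 0] = np.sin(a)  # e_r in plane, perpendicular to e_theta
            Q[:, 1, 0] = -np.cos(a)
            Q[:, 0, 1] = np.cos(a)
            Q[:, 1, 1] = np.sin(a)
            Q[:, 2, 2] = 1.0
            # right-handedness: e_r x e_theta = e_z requires e_r = e_theta x e_z
            Q[:, :, 0] = np.cross(Q[:, :, 1], Q[:, :, 2])
            Cl = np.einsum("mIi,mIJ,mJj->mij", Q, C3[sel], Q)
            _, Sl, _ = _symdiff.eval3d("media", Cl, (mu, k1, k2, rho, phi), 0.0)
            S3[sel] = np.einsum("miI,mIJ,mjJ->mij", Q, Sl, Q)
        else:
            _, S3[sel], _ = _symdiff.eval3d("yeoh", C3[sel], params, 0.0)

    F3 = np.zeros((m, 3, 3))
    F3[:, :2, :2] = F0
    F3[:, 2, 2] = 1.0
    sigma = np.einsum("miI,mIJ,mjJ->mij", F3, S3, F3) / J0[:, None, None]
    sigma += (model.K_bulk * (J0 - 1.0))[:, None, None] * np.eye(3)
    return StressField(
        sigma=sigma,
        region=names,
        centroids=mesh.centroids(),
        station_z=mesh.station_z,
        mesh=mesh,
    )


def principal_max(fld: StressField | np.ndarray) -> np.ndarray:
    """First (maximal) principal stress per element [kPa]."""
    sigma = fld.sigma if isinstance(fld, StressField) else np.asarray(fld)
    return np.linalg.eigvalsh(sigma)[..., -1]


def cap_region(mesh: SectionMesh) -> np.ndarray:
    """Element ids forming the fibrous cap (empty if the station has no LC).

    A lumen-adjacent FT element belongs to the cap when the radial ray from
    the section centroid through the element centroid crosses the lipid core
    before leaving the vessel; the set is dilated by one element ring to
    capture the cap shoulders.
    """
    names = mesh.region_names()
    lc_ids = np.flatnonzero(names == "lc")
    if len(lc_ids) == 0:
        return np.array([], dtype=int)
    lc_poly = unary_union([
        LineString(mesh.nodes[mesh.quads[e]]).convex_hull for e in lc_ids
    ])
    centre = mesh.nodes[mesh.lumen_loop].mean(axis=0)
    r_max = np.linalg.norm(mesh.nodes - centre, axis=1).max() * 1.5

    cand = np.flatnonzero(mesh.lumen_adjacent_mask() & (names == "ft"))
    cents = mesh.centroids()
    cap = []
    for e in cand:
        d = cents[e] - centre
        nd = np.linalg.norm(d)
        if nd < 1e-12:
            continue
        ray = LineString([cents[e], centre + d / nd * r_max])
        if ray.intersects(lc_poly) and not lc_poly.contains(Point(cents[e])):
            cap.append(e)
    if not cap:
        return np.array([], dtype=int)
    # one-ring dilation over FT elements sharing a node with the cap set
    cap_nodes = set(mesh.quads[cap].ravel())
    ft_ids = np.flatnonzero(np.isin(names, ["ft"]))
    extra = [e for e in ft_ids if e not in cap and cap_nodes & set(mesh.quads[e])]
    return np.array(sorted(set(cap) | set(extra)), dtype=int)


@dataclass
class StressSummary:
    """Peak plaque / cap stress with locations and the per-station table."""

    pps: float
    pcs: float
    pps_location: tuple[float, int]  # (station z, element id)
    pcs_location: tuple[float, int]
    table: pd.DataFrame  # per station: z, max plaque stress, max cap stress


def peak_stresses(
    fields: list[StressField],
    exclusion: float = 0.0,
    include_lc: bool = True,
) -> StressSummary:
    """Extract PPS and PCS over the solved stations.

    `exclusion` [mm] skips stations within that distance of either segment
    end; `include_lc=False` restricts the plaque search region to fibrous
    tissue only.
    """
    if not fields:
        raise ValueError("no stress fields supplied")
    zs = np.array([f.station_z for f in fields])
    z_lo, z_hi = zs.min() + exclusion, zs.max() - exclusion
    keep = [f for f in fields if z_lo - 1e-9 <= f.station_z <= z_hi + 1e-9]
    if not keep:
        raise ValueError("exclusion length removed every station")

    plaque_regions = ("ft", "ft_wall", "lc") if include_lc else ("ft", "ft_wall")
    rows = []
    pps, pcs = -np.inf, -np.inf
    pps_loc = pcs_loc = (np.nan, -1)
    for f in keep:
        s1 = principal_max(f)
        mask = np.isin(f.region, plaque_regions)
        station_pps = float(s1[mask].max())
        e_pps = int(np.flatnonzero(mask)[np.argmax(s1[mask])])
        cap = cap_region(f.mesh)
        if len(cap):
            station_pcs = float(s1[cap].max())
            e_pcs = int(cap[np.argmax(s1[cap])])
        else:
            station_pcs, e_pcs = np.nan, -1
        rows.append({"z": f.station_z, "max_plaque_stress": station_pps,
                     "max_cap_stress": station_pcs})
        if station_pps > pps:
            pps, pps_loc = station_pps, (f.station_z, e_pps)
        if np.isfinite(station_pcs) and station_pcs > pcs:
            pcs, pcs_loc = station_pcs, (f.station_z, e_pcs)
    return StressSummary(
        pps=pps,
        pcs=pcs if np.isfinite(pcs) else np.nan,
        pps_location=pps_loc,
        pcs_location=pcs_loc,
        table=pd.DataFrame(rows),
    )
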