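"""Synthetic idealized atherosclerotic vessel phantom.

Stand-in for a segmented ex vivo MRI reconstruction of a carotid plaque
segment: a straight tube of diseased fibrous tissue (FT) with an eccentric
plaque, an embedded lipid core (LC) separated from the lumen by a fibrous cap
whose thickness varies axially with a sharp local minimum (the "dip"), and an
outer arterial wall obtained by offsetting the FT surface equidistantly by
0.5 mm.  Cross-section contours are stored as radius-vs-angle profiles on a
fixed angular grid (256 rays, mirroring a 256x256 in-plane imaging matrix),
which makes every contour simple and star-shaped by construction.

The module also emulates the two geometry-degrading screening factors:

* slice thickness (ST): contours are sampled every ST mm along the axis and
  linearly interpolated back onto the master stations, as a reconstruction
  from sparse images would do;
* wall thickness (WT): the fixed 0.5 mm outer annulus is partitioned into
  adventitia (outer WT/2), media (next WT/2) and FT-like remainder, so the
  wall volume is always present but its material assignment varies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace, asdict
from typing import Iterator

import numpy as np
from shapely.geometry import Polygon

WALL_OFFSET = 0.5  # mm, fixed equidistant outer wall offset
LC_FLOOR = 0.05  # mm, band floor keeping the mesh layer non-degenerate
# elements are labelled lipid core only where the LC band is at least this
# thick; a blunter labelled tip keeps the soft-inclusion-tip stress
# concentration resolvable at the default element size
LC_LABEL_MIN = 0.15


class InvalidSpecError(ValueError):
    """Phantom specification violates a geometric invariant."""


class MeshError(RuntimeError):
    """Cross-section meshing failed."""


@dataclass(frozen=True)
class PhantomSpec:
    """Idealized eccentric-plaque carotid segment.

    Lengths in mm, angles in degrees.  The fibrous-cap axial profile is
    cap_thickness - dip_depth * bump((z - dip_center)/dip_width); the raised-
    cosine bump has unit peak and compact support of half-width `dip_width`.
    """

    length: float = 4.0
    axial_resolution: float = 0.2  # master station spacing
    n_theta: int = 256
    lumen_radius: float = 3.0  # healthy-side lumen radius
    ft_outer_radius: float = 4.0
    plaque_depth: float = 1.8  # extra FT thickness at plaque center
    plaque_extent_deg: float = 140.0
    lc_extent_deg: float = 100.0
    lc_thickness: float = 1.9  # large LC nearly filling the plaque body
    cap_thickness: float = 0.2  # nominal fibrous-cap thickness
    dip_depth: float = 0.12  # local cap minimum of 0.08 mm
    dip_width: float = 0.5
    dip_center: float | None = None  # default: segment midpoint
    jitter: float = 0.02  # smooth angular contour perturbation amplitude
    seed: int = 0

    def __post_init__(self):
        if self.axial_resolution > 0.25 + 1e-12:
            raise InvalidSpecError("master axial resolution must be <= 0.25 mm")
        if self.dip_depth >= self.cap_thickness:
            raise InvalidSpecError("cap dip depth must be smaller than the nominal cap thickness")
        if self.lc_extent_deg >= self.plaque_extent_deg:
            raise InvalidSpecError("LC angular extent must lie inside the plaque extent")
        min_lumen = self.lumen_radius - self.plaque_depth
        if min_lumen <= 0.3:
            raise InvalidSpecError("plaque depth leaves no lumen")
        room = self.ft_outer_radius - (min_lumen + self.cap_thickness + self.lc_thickness + LC_FLOOR)
        if room <= 0.1:
            raise InvalidSpecError("LC does not fit strictly inside the fibrous tissue")

    @property
    def z0(self) -> float:
        return self.length / 2 if self.dip_center is None else self.dip_center

    @classmethod
    def from_dict(cls, d: dict) -> "PhantomSpec":
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "PhantomSpec":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_dict(self) -> dict:
        return asdict(self)


_BUMP_FLAT = 0.4  # fraction of the support over which the bump is flat


def _bump(x: np.ndarray) -> np.ndarray:
    """Flat-top bump: 1 for |x| <= 0.4, quintic smoothstep to 0 at |x| = 1.

    The quintic falloff is C2 at both junctions, so plaque and lipid-core
    flanks join the healthy contour with continuous curvature (a curvature
    jump would concentrate surface stress in a mesh-sensitive way), while
    the flat top preserves the full plaque/core size over the interior.
    """
    x = np.clip((np.abs(x) - _BUMP_FLAT) / (1.0 - _BUMP_FLAT), 0.0, 1.0)
    s = x * x * x * (x * (6 * x - 15) + 10)  # smoothstep, 0 -> 1
    return 1.0 - s


SURFACES = ("lumen", "lc_inner", "lc_outer", "ft_outer", "wall_outer")


@dataclass
class ContourStack:
    """Axially ordered cross-section contours as radius(angle) profiles.

    radii maps surface name -> (n_stations, n_theta) array; lc_inner ==
    lc_outer where the lipid core is absent.
    """

    z: np.ndarray
    theta: np.ndarray
    radii: dict[str, np.ndarray]
    provenance: str = "master"
    spec: PhantomSpec | None = None

    @property
    def n_stations(self) -> int:
        return len(self.z)

    @property
    def axial_resolution(self) -> float:
        return float(self.z[1] - self.z[0])

    def validate(self) -> None:
        eps = 1e-9
        r = self.radii
        for name in SURFACES:
            if r[name].shape != (len(self.z), len(self.theta)):
                raise InvalidSpecError(f"surface {name} has wrong shape")
        if np.any(r["lumen"] <= 0):
            raise InvalidSpecError("lumen radius must be positive")
        if np.any(r["lc_inner"] < r["lumen"] - eps) or np.any(r["lc_outer"] > r["ft_outer"] + eps):
            raise InvalidSpecError("LC must lie strictly between lumen and FT outer boundary")
        t_lc = r["lc_outer"] - r["lc_inner"]
        if np.any((t_lc > eps) & ((r["lc_inner"] <= r["lumen"] + eps) | (r["lc_outer"] >= r["ft_outer"] - eps))):
            raise InvalidSpecError("LC touches the lumen or the outer FT boundary")
        if np.any(r["wall_outer"] <= r["ft_outer"]):
            raise InvalidSpecError("wall annulus collapsed")

    def contour_xy(self, surface: str, station: int) -> np.ndarray:
        """Closed (n_theta, 2) polyline of one surface at one station."""
        rr = self.radii[surface][station]
        return np.column_stack([rr * np.cos(self.theta), rr * np.sin(self.theta)])

    def polygon(self, surface: str, station: int) -> Polygon:
        return Polygon(self.contour_xy(surface, station))

    def lc_mask(self, station: int, floor: float = LC_FLOOR) -> np.ndarray:
        """Rays on which the lipid core is actually present."""
        t = self.radii["lc_outer"][station] - self.radii["lc_inner"][station]
        return t >= floor

    def cap_thickness_profile(self, floor: float = LC_FLOOR) -> np.ndarray:
        """Per-station minimum lumen-to-LC distance [mm]; NaN without LC."""
        out = np.full(self.n_stations, np.nan)
        for k in range(self.n_stations):
            m = self.lc_mask(k, floor)
            if m.any():
                out[k] = float((self.radii["lc_inner"][k] - self.radii["lumen"][k])[m].min())
        return out

    def iter_stations(self) -> Iterator[int]:
        return iter(range(self.n_stations))

    def save(self, directory) -> None:
        """Delimited text per station plus a JSON manifest."""
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "provenance": self.provenance,
            "z": self.z.tolist(),
            "n_theta": len(self.theta),
            "surfaces": list(SURFACES),
            "spec": self.spec.to_dict() if self.spec else None,
        }
        (d / "manifest.json").write_text(json.dumps(manifest, indent=1))
        for k in range(self.n_stations):
            arr = np.column_stack([self.theta] + [self.radii[s][k] for s in SURFACES])
            np.savetxt(d / f"station_{k:04d}.tsv", arr, delimiter="\t",
                       header="theta_rad\t" + "\t".join(SURFACES))

    @classmethod
    def load(cls, directory) -> "ContourStack":
        import pathlib

        d = pathlib.Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        z = np.asarray(manifest["z"], dtype=float)
        radii = {s: [] for s in SURFACES}
        theta = None
        for k in range(len(z)):
            arr = np.loadtxt(d / f"station_{k:04d}.tsv")
            theta = arr[:, 0]
            for i, s in enumerate(SURFACES):
                radii[s].append(arr[:, 1 + i])
        spec = PhantomSpec.from_dict(manifest["spec"]) if manifest.get("spec") else None
        return cls(z=z, theta=theta, radii={s: np.asarray(v) for s, v in radii.items()},
                   provenance=manifest["provenance"], spec=spec)


def build_phantom(spec: PhantomSpec) -> ContourStack:
    """Generate the master-resolution contour stack for a phantom spec.

    Deterministic for a fixed seed; the smooth angular jitter is applied
    identically to the lumen and the LC band so the realized cap-thickness
    profile matches the spec exactly.
    """
    nz = int(round(spec.length / spec.axial_resolution)) + 1
    z = np.linspace(0.0, spec.length, nz)
    theta = np.linspace(0.0, 2 * np.pi, spec.n_theta, endpoint=False)

    rng = np.random.default_rng(spec.seed)
    # smooth, 2pi-periodic radial jitter from a few low-order Fourier modes
    jit = np.zeros_like(theta)
    for mode in range(2, 6):
        a, b = rng.normal(0, 1, 2)
        jit += a * np.cos(mode * theta) + b * np.sin(mode * theta)
    if spec.jitter > 0 and np.abs(jit).max() > 0:
        jit *= spec.jitter / np.abs(jit).max()
    else:
        jit[:] = 0.0

    half_p = np.deg2rad(spec.plaque_extent_deg) / 2
    half_lc = np.deg2rad(spec.lc_extent_deg) / 2
    dtheta = np.angle(np.exp(1j * theta))  # wrapped to (-pi, pi], plaque at 0
    b_p = _bump(dtheta / half_p)
    b_lc = _bump(dtheta / half_lc)

    t_cap = spec.cap_thickness - spec.dip_depth * _bump((z - spec.z0) / spec.dip_width)

    r_lumen = np.empty((nz, spec.n_theta))
    r_lc_in = np.empty_like(r_lumen)
    r_lc_out = np.empty_like(r_lumen)
    base_lumen = spec.lumen_radius - spec.plaque_depth * b_p + jit
    for k in range(nz):
        r_lumen[k] = base_lumen
        r_lc_in[k] = base_lumen + t_cap[k]
        r_lc_out[k] = r_lc_in[k] + spec.lc_thickness * b_lc
    # collapse the LC where its thickness would be degenerate
    thin = (r_lc_out - r_lc_in) < LC_FLOOR
    r_lc_out[thin] = r_lc_in[thin]

    r_ft = np.broadcast_to(spec.ft_outer_radius + jit, (nz, spec.n_theta)).copy()
    stack = ContourStack(
        z=z,
        theta=theta,
        radii={
            "lumen": r_lumen,
            "lc_inner": r_lc_in,
            "lc_outer": r_lc_out,
            "ft_outer": r_ft,
            "wall_outer": r_ft + WALL_OFFSET,
        },
        provenance="master",
        spec=spec,
    )
    stack.validate()
    return stack


def resample_slices(stack: ContourStack, slice_thickness: float) -> ContourStack:
    """Emulate reconstruction from images with the given slice thickness.

    Contours are sampled every `slice_thickness` mm starting at the first
    station (values between master stations by linear interpolation, as the
    imaging plane need not coincide with a master station) and the sparse
    profiles are linearly interpolated back onto the master stations.
    Sampling at the master resolution is the identity.
    """
    dz = stack.axial_resolution
    if slice_thickness < dz - 1e-12:
        raise ValueError(
            f"slice thickness {slice_thickness} mm below master resolution {dz} mm"
        )
    if abs(slice_thickness - dz) < 1e-12:
        return replace(stack, provenance="resampled")
    z = stack.z
    z_samp = np.arange(z[0], z[-1] + 1e-9, slice_thickness)
    if z_samp[-1] < z[-1] - 1e-9:  # keep the segment end covered
        z_samp = np.append(z_samp, z[-1])
    radii = {}
    for name, arr in stack.radii.items():
        sampled = np.empty((len(z_samp), arr.shape[1]))
        for j in range(arr.shape[1]):
            sampled[:, j] = np.interp(z_samp, z, arr[:, j])
        back = np.empty_like(arr)
        for j in range(arr.shape[1]):
            back[:, j] = np.interp(z, z_samp, sampled[:, j])
        radii[name] = back
    out = ContourStack(z=z.copy(), theta=stack.theta.copy(), radii=radii,
                       provenance="resampled", spec=stack.spec)
    out.validate()
    return out


# --------------------------------------------------------------------------
# wall partitioning


@dataclass(frozen=True)
class WallPartition:
    """Material partition of the fixed 0.5 mm outer annulus.

    From the FT outer boundary outward: `ft_band` mm keeps FT properties,
    then media and adventitia of `wall_thickness`/2 each (the halving rule).
    """

    wall_thickness: float

    def __post_init__(self):
        if not 0.0 <= self.wall_thickness <= WALL_OFFSET:
            raise ValueError(f"wall thickness must lie in [0, {WALL_OFFSET}] mm")

    @property
    def ft_band(self) -> float:
        return WALL_OFFSET - self.wall_thickness

    @property
    def media_band(self) -> float:
        return self.wall_thickness / 2

    @property
    def adventitia_band(self) -> float:
        return self.wall_thickness / 2

    def bands(self) -> list[tuple[str, float]]:
        """(region, thickness) from the FT boundary outward, non-degenerate."""
        out = []
        if self.ft_band > 1e-12:
            out.append(("ft_wall", self.ft_band))
        if self.wall_thickness > 1e-12:
            out.append(("media", self.media_band))
            out.append(("adventitia", self.adventitia_band))
        return out


def partition_wall(stack: ContourStack, wall_thickness: float) -> WallPartition:
    """Region map of the outer annulus for the given wall-thickness factor."""
    del stack  # the partition is purely radial; kept for interface symmetry
    return WallPartition(wall_thickness=float(wall_thickness))


# --------------------------------------------------------------------------
# section meshing


@dataclass(frozen=True)
class MeshOptions:
    """Structured polar mesh resolution (element counts per band)."""

    n_theta: int = 64  # angular sectors; must divide the contour ray count
    n_cap: int = 2  # lumen -> LC inner
    n_lc: int = 2  # LC band
    n_ft_outer: int = 2  # LC outer -> FT boundary
    n_wall_layer: int = 2  # per media / adventitia layer
    n_wall_ft: int | None = None  # FT-like wall band; default by 0.125 mm rule

    def scaled(self, factor: int) -> "MeshOptions":
        return MeshOptions(
            n_theta=self.n_theta * factor,
            n_cap=self.n_cap * factor,
            n_lc=self.n_lc * factor,
            n_ft_outer=self.n_ft_outer * factor,
            n_wall_layer=self.n_wall_layer * factor,
            n_wall_ft=None if self.n_wall_ft is None else self.n_wall_ft * factor,
        )


REGION_CODES = {"ft": 0, "lc": 1, "ft_wall": 2, "media": 3, "adventitia": 4}
REGION_NAMES = {v: k for k, v in REGION_CODES.items()}


@dataclass
class SectionMesh:
    """Region-labelled conforming quad mesh of one cross-section.

    Structured polar topology: nodes on `n_theta` rays x (n_r+1) radial
    levels; element (i, j) spans rays i, i+1 and radial levels j, j+1.
    """

    nodes: np.ndarray  # (n_nodes, 2) mm
    quads: np.ndarray  # (n_elems, 4) CCW node ids
    region: np.ndarray  # (n_elems,) int codes, REGION_CODES
    n_theta: int
    n_radial: int
    station_z: float
    lumen_loop: np.ndarray  # node ids around the lumen, CCW
    band_id: np.ndarray  # (n_elems,) radial band index
    cap_band: int  # band index of the lumen-adjacent (cap) band
    lc_band: int  # band index of the LC band
    wall_rings: int  # element count across the 0.5 mm annulus
    wall_band_start: int = 3  # first radial band belonging to the annulus
    elem_theta: np.ndarray = field(default=None)  # (n_elems,) centroid angle

    @property
    def n_elems(self) -> int:
        return len(self.quads)

    def elem_index(self) -> tuple[np.ndarray, np.ndarray]:
        """(i_theta, j_radial) of every element."""
        idx = np.arange(self.n_elems)
        return idx // self.n_radial, idx % self.n_radial

    def centroids(self) -> np.ndarray:
        return self.nodes[self.quads].mean(axis=1)

    def areas(self) -> np.ndarray:
        p = self.nodes[self.quads]
        x, y = p[..., 0], p[..., 1]
        return 0.5 * np.abs(
            np.sum(x * np.roll(y, -1, axis=1) - np.roll(x, -1, axis=1) * y, axis=1)
        )

    def region_names(self) -> np.ndarray:
        return np.array([REGION_NAMES[c] for c in self.region])

    def wall_mask(self) -> np.ndarray:
        """Elements in the outer 0.5 mm annulus (any material)."""
        return self.band_id >= self.wall_band_start

    def lumen_adjacent_mask(self) -> np.ndarray:
        """Elements whose inner edge lies on the lumen boundary."""
        return self.band_id == self.cap_band


def mesh_section(
    stack: ContourStack,
    station: int,
    partition: WallPartition,
    options: MeshOptions = MeshOptions(),
) -> SectionMesh:
    """Mesh one cross-section with a conforming structured polar quad grid.

    Radial bands (inner to outer): cap band (lumen -> LC-inner line), LC band
    (floored to stay non-degenerate where the LC is absent; those elements are
    labelled FT), outer FT band, then the wall annulus split per `partition`
    with a configurable element count across the thickness.  The FT-wall
    interface is conforming by construction (shared nodes realize the bonded
    contact).
    """
    n_rays = len(stack.theta)
    if n_rays % options.n_theta != 0:
        raise MeshError(f"n_theta={options.n_theta} must divide the contour ray count {n_rays}")
    step = n_rays // options.n_theta
    sel = np.arange(0, n_rays, step)
    theta = stack.theta[sel]

    r_lum = stack.radii["lumen"][station][sel]
    r_in = stack.radii["lc_inner"][station][sel]
    r_out = stack.radii["lc_outer"][station][sel]
    r_ft = stack.radii["ft_outer"][station][sel]
    if np.any(r_in <= r_lum) or np.any(r_out >= r_ft):
        raise MeshError(f"station {station}: LC band violates nesting (LC touching lumen or wall)")
    # floor the LC band so the structured layer never degenerates
    r_out = np.maximum(r_out, r_in + LC_FLOOR)
    if np.any(r_out >= r_ft - 1e-9):
        raise MeshError(f"station {station}: floored LC band reaches the FT boundary")

    t_lc_actual = stack.radii["lc_outer"][station][sel] - stack.radii["lc_inner"][station][sel]

    bands: list[tuple[str, np.ndarray, np.ndarray, int]] = [
        ("cap", r_lum, r_in, options.n_cap),
        ("lcband", r_in, r_out, options.n_lc),
        ("ftout", r_out, r_ft, options.n_ft_outer),
    ]
    wall_start_band = len(bands)
    r_prev = r_ft
    for region, thick in partition.bands():
        if region == "ft_wall":
            # default: one element per 0.125 mm, scaled with the wall layers
            n = options.n_wall_ft or max(
                1, int(round(thick / 0.125)) * max(1, options.n_wall_layer // 2)
            )
        else:
            n = options.n_wall_layer
        r_next = r_prev + thick
        bands.append((region, r_prev, r_next, n))
        r_prev = r_next

    # radial node positions per ray
    cols = [r_lum[None, :]]
    band_of_layer: list[int] = []
    for b, (_, r0, r1, n) in enumerate(bands):
        frac = np.linspace(0, 1, n + 1)[1:]
        cols.append(r0[None, :] + frac[:, None] * (r1 - r0)[None, :])
        band_of_layer.extend([b] * n)
    R = np.vstack(cols).T  # (n_theta, n_r+1)
    n_r = R.shape[1] - 1
    if np.any(np.diff(R, axis=1) <= 0):
        raise MeshError(f"station {station}: non-monotone radial layering (degenerate contour)")

    nodes = np.empty((options.n_theta * (n_r + 1), 2))
    ct, st = np.cos(theta), np.sin(theta)
    for i in range(options.n_theta):
        sl = slice(i * (n_r + 1), (i + 1) * (n_r + 1))
        nodes[sl, 0] = R[i] * ct[i]
        nodes[sl, 1] = R[i] * st[i]

    def nid(i, j):
        return (i % options.n_theta) * (n_r + 1) + j

    quads = np.empty((options.n_theta * n_r, 4), dtype=np.int64)
    region = np.empty(options.n_theta * n_r, dtype=np.int64)
    band_id = np.empty_like(region)
    elem_theta = np.empty(len(quads))
    dth = 2 * np.pi / options.n_theta
    e = 0
    for i in range(options.n_theta):
        th_c = theta[i] + dth / 2
        # LC actually present around this sector?
        lc_here = min(t_lc_actual[i], t_lc_actual[(i + 1) % options.n_theta]) >= LC_LABEL_MIN
        for j in range(n_r):
            # CCW: inner edge is (node 0, node 3), outer edge (node 1, node 2)
            quads[e] = (nid(i, j), nid(i, j + 1), nid(i + 1, j + 1), nid(i + 1, j))
            b = band_of_layer[j]
            band_id[e] = b
            name = bands[b][0]
            if name in ("cap", "ftout"):
                reg = "ft"
            elif name == "lcband":
                reg = "lc" if lc_here else "ft"
            else:
                reg = name
            region[e] = REGION_CODES[reg]
            elem_theta[e] = np.angle(np.exp(1j * th_c))
            e += 1

    lumen_loop = np.array([nid(i, 0) for i in range(options.n_theta)])
    wall_rings = sum(n for (name, _, _, n) in bands[wall_start_band:])
    mesh = SectionMesh(
        nodes=nodes,
        quads=quads,
        region=region,
        n_theta=options.n_theta,
        n_radial=n_r,
        station_z=float(stack.z[station]),
        lumen_loop=lumen_loop,
        band_id=band_id,
        cap_band=0,
        lc_band=1,
        wall_rings=wall_rings,
        wall_band_start=wall_start_band,
        elem_theta=elem_theta,
    )
    return mesh


def _annular_polygon_area(r_in: np.ndarray, r_out: np.ndarray, closed: bool = True) -> float:
    """Area between two star-shaped polygonal profiles on a uniform ray fan.

    Exact polygon area (straight chords between consecutive rays):
    A = 1/2 sum (R_i R_{i+1} - r_i r_{i+1}) sin(dtheta).
    """
    n = len(r_in)
    if n < 2:
        return 0.0
    if closed:
        dth = 2 * np.pi / n
        Ro = np.roll(r_out, -1)
        ri = np.roll(r_in, -1)
        return float(0.5 * np.sin(dth) * np.sum(r_out * Ro - r_in * ri))
    dth = 2 * np.pi / 256  # open fan on the master angular grid spacing
    return float(0.5 * np.sin(dth) * np.sum(r_out[:-1] * r_out[1:] - r_in[:-1] * r_in[1:]))


def region_area(stack: ContourStack, station: int, region: str, n_theta: int | None = None) -> float:
    """Exact polygonal area [mm^2] of a region at the given angular sampling.

    `n_theta` subsamples the contour ray fan (must divide it) so the reference
    polygon uses the same chords as a mesh built at that resolution; default
    is the full contour resolution.
    """
    n_rays = len(stack.theta)
    n_theta = n_theta or n_rays
    if n_rays % n_theta != 0:
        raise ValueError("n_theta must divide the contour ray count")
    sel = np.arange(0, n_rays, n_rays // n_theta)
    r = {s: stack.radii[s][station][sel] for s in SURFACES}
    if region == "wall":
        return _annular_polygon_area(r["ft_outer"], r["wall_outer"])
    t_lc = r["lc_outer"] - r["lc_inner"]
    # LC sector rule used by the mesher: both bounding rays carry the label
    lc_sector = (t_lc >= LC_LABEL_MIN) & (np.roll(t_lc, -1) >= LC_LABEL_MIN)
    dth = 2 * np.pi / n_theta
    a_lc = float(0.5 * np.sin(dth) * np.sum(
        np.where(lc_sector, r["lc_outer"] * np.roll(r["lc_outer"], -1)
                 - r["lc_inner"] * np.roll(r["lc_inner"], -1), 0.0)))
    if region == "lc":
        return a_lc
    if region == "ft":
        return _annular_polygon_area(r["lumen"], r["ft_outer"]) - a_lc
    raise ValueError(f"unknown region {region!r}")
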