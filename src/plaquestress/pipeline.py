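"""Campaign orchestration: phantom -> FE solves -> responses -> ANOVA.

One call (or one CLI command) runs the whole screening study: generate the
master phantom, realize each design point's geometry (slice-thickness
resampling, wall partition) and materials (lipid-core / fibrous-tissue
stiffness, media behaviour), solve every evaluation station, extract PPS and
PCS, and fit the response surfaces with their ANOVA tables and the paired
iso/aniso comparison.  Failed solves are logged and excluded (never
imputed); the campaign aborts if more than 10% of runs fail.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from . import __version__, materials as mat
from .constitutive import ConstitutiveModel
from .doe_engine import (
    Factor,
    ResponseSurface,
    TTestResult,
    cross_with_categorical,
    default_factors,
    face_centred_ccd,
    fit_response_surface,
    paired_t_test,
)
from .fem_solver import LoadCase, NonConvergenceError, PlaneStrainModel, SolverSettings
from .fiber_frames import element_basis, section_centerline
from .phantom import (
    ContourStack,
    MeshOptions,
    PhantomSpec,
    build_phantom,
    mesh_section,
    partition_wall,
    resample_slices,
)
from .stress_post import StressSummary, peak_stresses, recover_stresses

log = logging.getLogger("plaquestress")


class CampaignError(RuntimeError):
    pass


@dataclass
class CampaignConfig:
    """Everything needed to reproduce a screening campaign."""

    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    factors: list[Factor] = field(default_factory=default_factors)
    media_levels: tuple[str, ...] = ("isotropic", "anisotropic")
    n_geometries: int = 1
    pressure: float = 13.0  # kPa, mean arterial
    exclusion: float = 0.6  # mm skipped at each segment end
    station_range: tuple[float, float] | None = None  # explicit z window
    mesh: MeshOptions = field(default_factory=MeshOptions)
    solver: SolverSettings = field(default_factory=SolverSettings)
    include_lc_in_pps: bool = True
    seed: int = 0
    output_dir: str | None = None

    def __post_init__(self):
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")
        if self.exclusion < 0:
            raise ValueError("exclusion must be non-negative")
        if self.n_geometries < 1:
            raise ValueError("need at least one geometry")
        for f in self.factors:
            _ = f.decode(0.0)  # validates limits
        known = {"WT", "ST", "LC", "FT"}
        if {f.name for f in self.factors} != known:
            raise ValueError(f"factors must be exactly {sorted(known)}")
        for mb in self.media_levels:
            mat.media(mb)  # validates level names

    # -- (de)serialization -------------------------------------------------

    def to_dict(self) -> dict:
        def listify(x):
            if isinstance(x, tuple):
                return [listify(v) for v in x]
            if isinstance(x, dict):
                return {k: listify(v) for k, v in x.items()}
            return x

        return listify(asdict(self))

    @classmethod
    def from_dict(cls, d: dict) -> "CampaignConfig":
        d = dict(d)
        if "phantom" in d and isinstance(d["phantom"], dict):
            d["phantom"] = PhantomSpec(**d["phantom"])
        if "factors" in d:
            d["factors"] = [Factor(**f) if isinstance(f, dict) else f for f in d["factors"]]
        if "mesh" in d and isinstance(d["mesh"], dict):
            d["mesh"] = MeshOptions(**d["mesh"])
        if "solver" in d and isinstance(d["solver"], dict):
            sd = dict(d["solver"])
            if "penalty_continuation" in sd:
                sd["penalty_continuation"] = tuple(sd["penalty_continuation"])
            d["solver"] = SolverSettings(**sd)
        if "media_levels" in d:
            d["media_levels"] = tuple(d["media_levels"])
        if "station_range" in d and d["station_range"] is not None:
            d["station_range"] = tuple(d["station_range"])
        return cls(**d)

    @classmethod
    def from_file(cls, path) -> "CampaignConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def compact_config(seed: int = 0, **overrides) -> CampaignConfig:
    """Desk-scale campaign configuration.

    Same phantom, factors, pressure and physics as the default, but with a
    coarser 32-sector mesh and the evaluation window narrowed to the
    plaque-dip neighbourhood (z in [1.6, 2.4] mm), where all axial variation
    of the phantom lives; the axially uniform remainder of the segment adds
    identical sections only.  This is the problem size used by the
    reproduction script and the heavier tests.
    """
    base = dict(
        mesh=MeshOptions(n_theta=32, n_cap=2, n_lc=2, n_ft_outer=2, n_wall_layer=2),
        station_range=(1.6, 2.4),
        solver=SolverSettings(max_iterations=25),
        seed=seed,
    )
    base.update(overrides)
    return CampaignConfig(**base)


def material_table(
    lc_c10: float, ft_c10: float, media_behaviour: str
) -> dict[str, ConstitutiveModel]:
    """Region -> constitutive model for one design point."""
    ft = mat.fibrous_tissue(ft_c10)
    return {
        "ft": ft,
        "ft_wall": ft,
        "lc": mat.lipid_core(lc_c10),
        "media": mat.media(media_behaviour),
        "adventitia": mat.ADVENTITIA,
    }


class GeometryCache:
    """Meshes and frames keyed by (slice thickness, wall thickness).

    Geometry depends on the design point only through ST and WT, and a
    face-centred design visits just three levels of each, so meshing is
    shared across runs.
    """

    def __init__(self, master: ContourStack, config: CampaignConfig):
        self.master = master
        self.config = config
        self._stacks: dict[float, ContourStack] = {}
        self._sections: dict[tuple[float, float], list] = {}
        z = master.z
        if config.station_range is not None:
            lo, hi = config.station_range
        else:
            lo, hi = z[0] + config.exclusion, z[-1] - config.exclusion
        self.station_ids = [k for k in range(len(z)) if lo - 1e-9 <= z[k] <= hi + 1e-9]
        if not self.station_ids:
            raise CampaignError("exclusion removed every evaluation station")

    def stack(self, st: float) -> ContourStack:
        key = round(float(st), 6)
        if key not in self._stacks:
            self._stacks[key] = resample_slices(self.master, st)
        return self._stacks[key]

    def sections(self, st: float, wt: float):
        """[(mesh, frames)] for the evaluation stations."""
        key = (round(float(st), 6), round(float(wt), 6))
        if key not in self._sections:
            stack = self.stack(st)
            part = partition_wall(stack, wt)
            centerline = section_centerline(stack)
            out = []
            for k in self.station_ids:
                mesh = mesh_section(stack, k, part, self.config.mesh)
                frames = element_basis(mesh, centerline)
                out.append((mesh, frames))
            self._sections[key] = out
        return self._sections[key]


def solve_design_point(
    cache: GeometryCache,
    wt: float,
    st: float,
    lc_c10: float,
    ft_c10: float,
    media_behaviour: str,
) -> StressSummary:
    """Solve all evaluation stations of one design point and extract peaks."""
    cfg = cache.config
    import dataclasses

    mats = material_table(lc_c10, ft_c10, media_behaviour)
    penalty = cfg.solver.bulk_penalty
    fields = []
    solved: dict[bytes, object] = {}  # geometry digest -> recovered field
    u_prev = None  # warm start from the neighbouring station
    for mesh, frames in cache.sections(st, wt):
        # identical cross-sections (the phantom is axially uniform away from
        # the cap dip) are solved once and reused
        key = hashlib.sha1(np.round(mesh.nodes, 12).tobytes()).digest()
        if key in solved:
            fields.append(dataclasses.replace(solved[key], station_z=mesh.station_z))
            continue
        model = PlaneStrainModel(mesh, mats, frames, penalty, cfg.solver.stabilization)
        sol = model.solve(LoadCase(pressure=cfg.pressure), cfg.solver, u0=u_prev)
        u_prev = sol.u
        fld = recover_stresses(model, sol, frames)
        solved[key] = fld
        fields.append(fld)
    # stations were pre-filtered to the evaluation window
    return peak_stresses(fields, exclusion=0.0, include_lc=cfg.include_lc_in_pps)


def solve_one(
    wt: float,
    st: float,
    lc_c10: float,
    ft_c10: float,
    media_behaviour: str = "anisotropic",
    config: CampaignConfig | None = None,
) -> StressSummary:
    """Convenience wrapper: one design point on the default phantom."""
    cfg = config or CampaignConfig()
    master = build_phantom(replace(cfg.phantom, seed=cfg.seed))
    cache = GeometryCache(master, cfg)
    return solve_design_point(cache, wt, st, lc_c10, ft_c10, media_behaviour)


@dataclass
class CampaignReport:
    """Run table, fitted surfaces, media comparison and provenance."""

    runs: pd.DataFrame
    surfaces: dict[tuple[str, str, str], ResponseSurface]  # (geometry, response, kind)
    media_tests: dict[tuple[str, str], TTestResult]  # (geometry, response)
    failed_runs: list[int]
    provenance: dict

    def save(self, directory) -> None:
        import pathlib

        d = pathlib.Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.runs.to_csv(d / "runs.csv", index=False)
        summary = {"provenance": self.provenance, "failed_runs": self.failed_runs,
                   "media_tests": {}, "surfaces": {}}
        for (geom, resp, kind), rs in self.surfaces.items():
            tag = f"{geom}_{resp}_{kind}"
            rs.anova.to_csv(d / f"anova_{tag}.csv", index=False)
            summary["surfaces"][tag] = {
                "r_squared": rs.r_squared,
                "normality_p": rs.normality_p,
                "terms": {row.term: row.p_value for row in rs.anova.itertuples()},
            }
        for (geom, resp), tt in self.media_tests.items():
            summary["media_tests"][f"{geom}_{resp}"] = {
                "mean_difference_kpa": tt.mean_difference,
                "p_value": tt.p_value,
                "n": tt.n,
                "degenerate": tt.degenerate,
            }
        (d / "report.json").write_text(json.dumps(summary, indent=1, default=float))


def run_campaign(config: CampaignConfig) -> CampaignReport:
    """Execute the full screening campaign described by `config`."""
    design = face_centred_ccd(config.factors)
    geometries = tuple(f"geometry{g+1}" for g in range(config.n_geometries))
    runs = cross_with_categorical(design, config.media_levels, geometries)
    log.info("campaign: %d runs (%d design points x %d media x %d geometries)",
             len(runs), len(design), len(config.media_levels), config.n_geometries)

    caches = {}
    for g, geom in enumerate(geometries):
        spec = replace(config.phantom, seed=config.seed + g)
        caches[geom] = GeometryCache(build_phantom(spec), config)

    pps = np.full(len(runs), np.nan)
    pcs = np.full(len(runs), np.nan)
    n_iter = np.zeros(len(runs), dtype=int)
    wall_t = np.zeros(len(runs))
    failed: list[int] = []
    for i, row in runs.iterrows():
        t0 = time.perf_counter()
        try:
            summary = solve_design_point(
                caches[row.geometry], row.WT, row.ST, row.LC, row.FT, row.media_behaviour
            )
            pps[i], pcs[i] = summary.pps, summary.pcs
        except NonConvergenceError as exc:
            failed.append(int(row.run))
            log.warning("run %d failed to converge: %s", row.run, exc)
        wall_t[i] = time.perf_counter() - t0
        log.info("run %3d/%d (WT=%.3g ST=%.3g LC=%.4g FT=%.4g %s): "
                 "PPS=%.1f PCS=%.1f kPa [%.1fs]",
                 i + 1, len(runs), row.WT, row.ST, row.LC, row.FT,
                 row.media_behaviour, pps[i], pcs[i], wall_t[i])
    if len(failed) > 0.1 * len(runs):
        raise CampaignError(
            f"{len(failed)}/{len(runs)} runs failed to converge: {failed}"
        )

    runs = runs.copy()
    runs["PPS"] = pps
    runs["PCS"] = pcs
    runs["solve_seconds"] = wall_t
    ok = runs.dropna(subset=["PPS", "PCS"])

    surfaces: dict[tuple[str, str, str], ResponseSurface] = {}
    media_tests: dict[tuple[str, str], TTestResult] = {}
    factor_names = [f.name for f in config.factors]
    for geom in geometries:
        for resp in ("PPS", "PCS"):
            for mb in config.media_levels:
                sub = ok[(ok.geometry == geom) & (ok.media_behaviour == mb)]
                key_kind = mb
                surfaces[(geom, resp, f"full_{key_kind}")] = fit_response_surface(
                    sub, resp, factor_names
                )
                surfaces[(geom, resp, f"reduced_{key_kind}")] = fit_response_surface(
                    sub, resp, factor_names, reduce=True
                )
            if len(config.media_levels) == 2:
                a, b = config.media_levels
                sa = ok[(ok.geometry == geom) & (ok.media_behaviour == a)]
                sb = ok[(ok.geometry == geom) & (ok.media_behaviour == b)]
                merged = sa.merge(sb, on="block_run", suffixes=("_a", "_b"))
                if len(merged) >= 2:
                    media_tests[(geom, resp)] = paired_t_test(
                        merged[f"{resp}_a"], merged[f"{resp}_b"]
                    )

    report = CampaignReport(
        runs=runs,
        surfaces=surfaces,
        media_tests=media_tests,
        failed_runs=failed,
        provenance={
            "config_hash": config.hash(),
            "seed": config.seed,
            "version": __version__,
            "n_runs": len(runs),
            "config": config.to_dict(),
        },
    )
    if config.output_dir:
        report.save(config.output_dir)
    return report


def refit_from_runs(runs: pd.DataFrame, response: str, reduce: bool = False) -> ResponseSurface:
    """Re-fit a response surface from a stored run table (bit-identical)."""
    return fit_response_surface(runs.dropna(subset=[response]), response, reduce=reduce)
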