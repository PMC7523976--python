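"""Plane-strain nonlinear finite elements for pressurized plaque sections.

Total-Lagrangian, nearly incompressible hyperelasticity on the structured
quad meshes of :mod:`plaquestress.phantom`, with a follower pressure load on
the deforming lumen boundary and Newton iteration with adaptive load
stepping.  Each axial station of the phantom is solved as an independent
plane-strain section: the segment ends are fully constrained far from the
evaluation zone in the 3D picture, and near-boundary results are excluded
from the responses anyway, which makes the 2D surrogate the deliberate
desk-scale reduction of the full 3D model.

Element technology: 4-node quadrilaterals with an F-bar-type strain
projection defined at the energy level: at every 2x2 Gauss point the
in-plane right Cauchy-Green tensor is rescaled to the element-centroid
dilatation, Cbar = (J0/J) C with J0 = det F at the centroid, before the
isochoric strain energy is evaluated, and the volumetric penalty
U(J0) = K/2 (J0 - 1)^2 acts on the centroid dilatation only.  This removes
the volumetric locking a pure displacement low-order element shows near
incompressibility; the hourglass-type dilatational modes the projection
leaves unconstrained are controlled by a small fluctuation penalty
eps K/2 sum_g w_g (J_g - J0)^2 (eps << 1, configurable).  Residual and
tangent are exact derivatives of this element energy, so the tangent is
consistent (the follower-load stiffness is the only non-symmetric
contribution), and Newton is globalized by an Armijo backtracking line
search on the total potential (the follower pressure on the closed lumen
derives from the potential -p * enclosed-area change).

Rigid-body modes of the self-equilibrated pressurized section are removed by
three scalar constraints on two outer-boundary nodes: one node pinned, the
diametrically opposite one fixed only perpendicular to the joining line, so
the constraints carry (essentially) zero reaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sps
import scipy.sparse.linalg as spla

from . import _symdiff
from .constitutive import ConstitutiveModel, MediaAnisoParams, default_bulk_penalty
from .fiber_frames import LocalFrame
from .phantom import SectionMesh


class AssemblyError(RuntimeError):
    pass


class NonConvergenceError(RuntimeError):
    def __init__(self, message, log=None):
        super().__init__(message)
        self.log = log or []


class ConstraintError(RuntimeError):
    pass


@dataclass(frozen=True)
class LoadCase:
    """Luminal pressure [kPa] and rigid-body constraint specification."""

    pressure: float = 13.0
    pin_nodes: tuple[int, int] | None = None  # (A fully pinned, B tangentially)

    def __post_init__(self):
        if self.pressure < 0:
            raise ValueError("pressure must be non-negative")


@dataclass(frozen=True)
class SolverSettings:
    tolerance: float = 1e-8  # relative residual
    max_iterations: int = 40
    n_load_steps: int = 5
    bulk_penalty: float | None = None  # default: 1e4 x stiffest material
    min_step_fraction: float = 1 / 64  # load-step bisection floor
    stabilization: float = 0.002  # dilatational-fluctuation penalty fraction
    # penalty continuation: pressure is stepped at the softest factor, then
    # the penalty is ramped to 1 with warm restarts (robust for fine meshes
    # of very soft tissue, where full-penalty Newton from zero stalls)
    penalty_continuation: tuple[float, ...] = (0.01, 0.1, 1.0)

    def __post_init__(self):
        if not 0 < self.tolerance <= 1e-2:
            raise ValueError("tolerance must lie in (0, 1e-2]")
        if self.n_load_steps < 1:
            raise ValueError("need at least one load step")


@dataclass
class Solution:
    u: np.ndarray  # (n_nodes, 2) displacements [mm]
    deformed: np.ndarray  # (n_nodes, 2)
    log: list[dict] = field(default_factory=list)
    converged: bool = True
    pressure: float = 0.0
    residual: float = 0.0


def replace_settings_max_iter(settings: SolverSettings, n: int) -> SolverSettings:
    from dataclasses import replace

    return replace(settings, max_iterations=min(settings.max_iterations, n))


_GP = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]]) / np.sqrt(3.0)


def _shape_grad(xi, eta):
    """dN_a/d(xi, eta) for the 4-node quad, (4, 2)."""
    return 0.25 * np.array(
        [
            [-(1 - eta), -(1 - xi)],
            [(1 - eta), -(1 + xi)],
            [(1 + eta), (1 + xi)],
            [-(1 + eta), (1 - xi)],
        ]
    )


class PlaneStrainModel:
    """Precomputed FE operator for one section mesh + material assignment.

    `materials` maps region names ('ft', 'lc', 'ft_wall', 'media',
    'adventitia') to constitutive models; `frames` supplies per-element fiber
    angles for anisotropic regions.
    """

    def __init__(
        self,
        mesh: SectionMesh,
        materials: dict[str, ConstitutiveModel],
        frames: LocalFrame | None = None,
        bulk_penalty: float | None = None,
        stabilization: float = 0.002,
    ):
        self.mesh = mesh
        self.stabilization = float(stabilization)
        self.materials = materials
        names = mesh.region_names()
        used = {n for n in names}
        missing = used - set(materials)
        if missing:
            raise ValueError(f"no material assigned for regions {sorted(missing)}")
        # volumetric penalty: uniform, 1e4 x the stiffest material present,
        # so |J - 1| ~ stress / K stays small even inside the soft lipid
        # core; the fluctuation stabilization is scaled to the LOCAL material
        # stiffness instead, since a soft tissue stabilized at the wall's
        # penalty scale locks
        stiff_e = np.empty(mesh.n_elems)
        for region, model in materials.items():
            stiff_e[names == region] = model.stiffness_scale
        if bulk_penalty is not None:
            K = float(bulk_penalty)
        else:
            K = default_bulk_penalty([materials[n] for n in used])
        self.K_bulk = np.full(mesh.n_elems, K)
        self.K_stab = self.stabilization * 1e4 * stiff_e

        X = mesh.nodes[mesh.quads]  # (m, 4, 2)
        m = mesh.n_elems
        self.gradN = np.empty((m, 4, 4, 2))  # (elem, gp, node, dim)
        self.wdet = np.empty((m, 4))
        for g, (xi, eta) in enumerate(_GP):
            dN = _shape_grad(xi, eta)  # (4, 2)
            Jmap = np.einsum("maI,aj->mjI", X, dN)  # dX_I/dxi_j
            det = Jmap[:, 0, 0] * Jmap[:, 1, 1] - Jmap[:, 0, 1] * Jmap[:, 1, 0]
            if np.any(det <= 0):
                bad = int(np.flatnonzero(det <= 0)[0])
                raise AssemblyError(f"degenerate element {bad} in reference mesh")
            inv = np.empty_like(Jmap)
            inv[:, 0, 0] = Jmap[:, 1, 1]
            inv[:, 1, 1] = Jmap[:, 0, 0]
            inv[:, 0, 1] = -Jmap[:, 0, 1]
            inv[:, 1, 0] = -Jmap[:, 1, 0]
            inv /= det[:, None, None]
            # dN_a/dX_I = dN_a/dxi_j * dxi_j/dX_I; inv indices are [I, j]
            self.gradN[:, g] = np.einsum("aj,mIj->maI", dN, inv)
            self.wdet[:, g] = det
        self.volume = self.wdet.sum(axis=1)
        # centroid gradients for stress recovery
        dN0 = _shape_grad(0.0, 0.0)
        Jmap0 = np.einsum("maI,aj->mjI", X, dN0)
        det0 = Jmap0[:, 0, 0] * Jmap0[:, 1, 1] - Jmap0[:, 0, 1] * Jmap0[:, 1, 0]
        inv0 = np.empty_like(Jmap0)
        inv0[:, 0, 0] = Jmap0[:, 1, 1]
        inv0[:, 1, 1] = Jmap0[:, 0, 0]
        inv0[:, 0, 1] = -Jmap0[:, 0, 1]
        inv0[:, 1, 0] = -Jmap0[:, 1, 0]
        inv0 /= det0[:, None, None]
        self.gradN0 = np.einsum("aj,mIj->maI", dN0, inv0)

        # dof bookkeeping
        self.ndof = 2 * len(mesh.nodes)
        edof = np.empty((m, 8), dtype=np.int64)
        edof[:, 0::2] = 2 * mesh.quads
        edof[:, 1::2] = 2 * mesh.quads + 1
        self.edof = edof
        self._rows = np.repeat(edof, 8, axis=1).ravel()
        self._cols = np.tile(edof, (1, 8)).ravel()

        # material batches; regions sharing a Yeoh parameter set are merged
        angles = np.zeros(m)
        if frames is not None:
            angles[frames.element_ids] = frames.inplane_angles()
        yeoh_groups: dict[tuple, list[np.ndarray]] = {}
        self.batches = []
        for region, model in materials.items():
            sel = np.flatnonzero(names == region)
            if len(sel) == 0:
                continue
            if isinstance(model, MediaAnisoParams):
                params = (model.mu, model.k1, model.k2, model.rho, model.phi_rad,
                          angles[sel][:, None])
                self.batches.append(("media", sel, params))
            else:
                yeoh_groups.setdefault(model.constants, []).append(sel)
        for constants, sels in yeoh_groups.items():
            self.batches.append(("yeoh", np.sort(np.concatenate(sels)), constants))

        # lumen boundary edges, CCW
        loop = mesh.lumen_loop
        self.lumen_edges = np.column_stack([loop, np.roll(loop, -1)])

    # -- constraints ------------------------------------------------------

    def default_pins(self) -> tuple[int, int]:
        """Outer-boundary nodes at 1/4 and 3/4 of the angular range."""
        nr1 = self.mesh.n_radial + 1
        n_t = self.mesh.n_theta
        outer = np.arange(n_t) * nr1 + self.mesh.n_radial
        return int(outer[n_t // 4]), int(outer[3 * n_t // 4])

    def constraint_basis(self, load: LoadCase) -> sps.csr_matrix:
        a, b = load.pin_nodes if load.pin_nodes is not None else self.default_pins()
        d = self.mesh.nodes[b] - self.mesh.nodes[a]
        ln = np.linalg.norm(d)
        if ln < 1e-12:
            raise ConstraintError("pin nodes coincide")
        d /= ln
        fixed = {2 * a, 2 * a + 1}
        free = [i for i in range(self.ndof) if i not in fixed and i not in (2 * b, 2 * b + 1)]
        rows = list(free)
        cols = list(range(len(free)))
        vals = [1.0] * len(free)
        # node b: free along d (the AB line), fixed perpendicular to it
        rows += [2 * b, 2 * b + 1]
        cols += [len(free), len(free)]
        vals += [d[0], d[1]]
        return sps.csr_matrix((vals, (rows, cols)), shape=(self.ndof, len(free) + 1))

    # -- assembly ---------------------------------------------------------

    @staticmethod
    def _det2(F):
        return F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]

    @staticmethod
    def _inv2(F, J):
        Finv = np.empty_like(F)
        Finv[..., 0, 0] = F[..., 1, 1]
        Finv[..., 1, 1] = F[..., 0, 0]
        Finv[..., 0, 1] = -F[..., 0, 1]
        Finv[..., 1, 0] = -F[..., 1, 0]
        Finv /= J[..., None, None]
        return Finv

    def kinematics(self, u: np.ndarray):
        """Gauss-point and centroid deformation gradients and Jacobians."""
        ue = u[self.mesh.quads]  # (m, 4, 2)
        F = np.einsum("mai,mgaJ->mgiJ", ue, self.gradN)
        F[..., 0, 0] += 1.0
        F[..., 1, 1] += 1.0
        F0 = np.einsum("mai,maJ->miJ", ue, self.gradN0)
        F0[..., 0, 0] += 1.0
        F0[..., 1, 1] += 1.0
        return ue, F, self._det2(F), F0, self._det2(F0)

    def assemble(self, u: np.ndarray, pressure: float, tangent: bool = True,
                 pf: float = 1.0):
        """Residual r = f_int - f_ext and (optionally) consistent tangent.

        `pf` scales the volumetric and stabilization penalties (continuation).
        """
        mesh = self.mesh
        ue, F, J, F0, J0 = self.kinematics(u)
        if np.any(J <= 0) or np.any(J0 <= 0):
            bad = int(np.flatnonzero(np.any(J <= 0, axis=1) | (J0 <= 0))[0])
            raise AssemblyError(f"inverted element {bad} (det F <= 0)")
        C = np.einsum("mgkI,mgkJ->mgIJ", F, F)
        s = (J0[:, None] / J)  # F-bar dilatation rescale
        Cb = s[..., None, None] * C

        m = mesh.n_elems
        Sb = np.empty((m, 4, 2, 2))
        CCb = np.empty((m, 4, 2, 2, 2, 2)) if tangent else None
        for kind, sel, params in self.batches:
            Ss, CCs = _symdiff.eval2d(kind, Cb[sel], params)
            Sb[sel] = Ss
            if tangent:
                CCb[sel] = CCs

        w = self.wdet
        Finv = self._inv2(F, J)
        F0inv = self._inv2(F0, J0)
        # A[a, i] = gradN_a . Finv (per gauss point); A0 at the centroid
        A = np.einsum("mgaJ,mgJi->mgai", self.gradN, Finv)
        A0 = np.einsum("maJ,mJi->mai", self.gradN0, F0inv)
        q = 0.5 * np.einsum("mgIJ,mgIJ->mg", Sb, Cb)  # pressure-like term

        # residual: sum_g w [ s (F Sb) . B_a - q A[a] ] + Lambda A0[a]
        P = np.einsum("mgiM,mgMJ->mgiJ", F, Sb)
        f_el = np.einsum("mg,mg,mgiJ,mgaJ->mai", w, s, P, self.gradN)
        f_el -= np.einsum("mg,mg,mgai->mai", w, q, A)
        Kb = pf * self.K_bulk
        Up = Kb * (J0 - 1.0)
        Lam = (w * q).sum(axis=1) + self.volume * Up * J0
        f_el += Lam[:, None, None] * A0

        # dilatational-fluctuation stabilization: eps K/2 sum w (J - J0)^2
        epsK = pf * self.K_stab
        dJ = J - J0[:, None]
        GA = J[..., None, None] * A  # d J / du at gauss points
        GA0 = J0[:, None, None] * A0  # d J0 / du
        dvec = GA - GA0[:, None]  # (m, g, a, i): d(J - J0)/du
        f_el += epsK[:, None, None] * np.einsum("mg,mg,mgai->mai", w, dJ, dvec)

        r = np.zeros(self.ndof)
        np.add.at(r, self.edof.ravel(), f_el.reshape(m, 8).ravel())

        # follower pressure on the deformed lumen
        x = mesh.nodes + u
        ea, eb = self.lumen_edges[:, 0], self.lumen_edges[:, 1]
        t = x[eb] - x[ea]
        fe = 0.5 * pressure * np.column_stack([t[:, 1], -t[:, 0]])
        np.add.at(r, 2 * ea, -fe[:, 0])
        np.add.at(r, 2 * ea + 1, -fe[:, 1])
        np.add.at(r, 2 * eb, -fe[:, 0])
        np.add.at(r, 2 * eb + 1, -fe[:, 1])

        if not tangent:
            return r, None

        # exact Hessian of the F-bar element energy ------------------------
        # dA0mA[b,k] = A0[b,k] - A[b,k] drives the dilatation-rescale terms
        dA0mA = A0[:, None] - A  # (m, g, b, k)
        FSbB = np.einsum("mgiJ,mgaJ->mgai", P, self.gradN)  # (F Sb) . B_a
        E = np.einsum("mgiM,mgaJ->mgaiMJ", F, self.gradN)
        W = np.einsum("mgMJPQ,mgPQ->mgMJ", CCb, C)  # CCb : C
        EW = np.einsum("mgaiMJ,mgMJ->mgai", E, W)
        M = Sb + 0.5 * s[..., None, None] * W
        FMB = np.einsum("mgiM,mgMJ,mgaJ->mgai", F, M, self.gradN)
        MC = np.einsum("mgIJ,mgIJ->mg", M, C)

        # d1a: ds (F Sb B_a)
        Km = np.einsum("mg,mg,mgai,mgbk->maibk", w, s, FSbB, dA0mA)
        # d1b: s dF Sb B: delta_ik (B_a Sb B_b)
        sBSB = np.einsum("mg,mg,mgaJ,mgJL,mgbL->mab", w, s, self.gradN, Sb, self.gradN)
        Km += sBSB[:, :, None, :, None] * np.eye(2)[None, None, :, None, :]
        # d1c: s F dSb B
        T1 = np.einsum("mgaiMJ,mgMJPQ->mgaiPQ", E, CCb)
        Km += np.einsum("mg,mg,mgaiPQ,mgbkPQ->maibk", w, s**2, T1, E)
        Km += 0.5 * np.einsum("mg,mg,mgai,mgbk->maibk", w, s**2, EW, dA0mA)
        # d2a: -dq A[a]
        dq_b = np.einsum("mg,mgbk->mgbk", s, FMB) + 0.5 * (s * MC)[..., None, None] * dA0mA
        Km -= np.einsum("mg,mgai,mgbk->maibk", w, A, dq_b)
        # d2b: +q A[a,k] A[b,i]
        Km += np.einsum("mg,mg,mgak,mgbi->maibk", w, q, A, A)
        # d3a: dLambda A0[a]
        dLam = np.einsum("mg,mgbk->mbk", w, dq_b)
        dLam += (self.volume * (Kb * J0 + Up) * J0)[:, None, None] * A0
        Km += np.einsum("mai,mbk->maibk", A0, dLam)
        # d3b: -Lambda A0[a,k] A0[b,i]
        Km -= Lam[:, None, None, None, None] * np.einsum("mak,mbi->maibk", A0, A0)
        # stabilization tangent
        eK = epsK[:, None, None, None, None]
        Km += eK * np.einsum("mg,mgai,mgbk->maibk", w, dvec, dvec)
        Km += eK * np.einsum("mg,mg,mg,mgai,mgbk->maibk", w, dJ, J, A, A)
        Km -= eK * np.einsum("mg,mg,mg,mgak,mgbi->maibk", w, dJ, J, A, A)
        wdJ = (w * dJ).sum(axis=1)
        Km -= (epsK * wdJ * J0)[:, None, None, None, None] * np.einsum("mai,mbk->maibk", A0, A0)
        Km += (epsK * wdJ * J0)[:, None, None, None, None] * np.einsum("mak,mbi->maibk", A0, A0)

        Kdata = Km.reshape(m, 8, 8)
        Kmat = sps.coo_matrix(
            (Kdata.ravel(), (self._rows, self._cols)), shape=(self.ndof, self.ndof)
        ).tocsr()

        # follower-load stiffness: f depends linearly on edge node positions
        if pressure == 0.0:
            return r, Kmat
        R = 0.5 * pressure * np.array([[0.0, 1.0], [-1.0, 0.0]])
        rows, cols, vals = [], [], []
        for sign_node in (ea, eb):  # force carried by node a and node b alike
            for i in range(2):
                for j in range(2):
                    if R[i, j] == 0.0:
                        continue
                    rows += [2 * sign_node + i, 2 * sign_node + i]
                    cols += [2 * eb + j, 2 * ea + j]
                    vals += [np.full(len(ea), -R[i, j]), np.full(len(ea), R[i, j])]
        Kext = sps.coo_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.ndof, self.ndof),
        ).tocsr()
        return r, Kmat + Kext

    def potential(self, u: np.ndarray, pressure: float, pf: float = 1.0) -> float:
        """Total potential energy (elastic + penalties - pressure work)."""
        ue, F, J, F0, J0 = self.kinematics(u)
        if np.any(J <= 0) or np.any(J0 <= 0):
            return np.inf
        C = np.einsum("mgkI,mgkJ->mgIJ", F, F)
        Cb = (J0[:, None] / J)[..., None, None] * C
        psi = np.empty_like(J)
        for kind, sel, params in self.batches:
            psi[sel] = _symdiff.eval2d(kind, Cb[sel], params, out_psi=True)[0]
        E = float((self.wdet * psi).sum())
        E += float((self.volume * pf * self.K_bulk / 2 * (J0 - 1.0) ** 2).sum())
        E += float((self.wdet * pf * self.K_stab[:, None] / 2 * (J - J0[:, None]) ** 2).sum())
        # follower pressure potential: -p x enclosed lumen-area change
        for pts in (self.mesh.nodes + u, self.mesh.nodes):
            loop = pts[self.mesh.lumen_loop]
            area = 0.5 * np.sum(
                loop[:, 0] * np.roll(loop[:, 1], -1) - np.roll(loop[:, 0], -1) * loop[:, 1]
            )
            if pts is self.mesh.nodes:
                E += pressure * area
            else:
                E -= pressure * area
        return E

    # -- Newton solve -----------------------------------------------------

    def reference_force(self, pressure: float) -> float:
        x = self.mesh.nodes
        t = x[self.lumen_edges[:, 1]] - x[self.lumen_edges[:, 0]]
        perimeter = np.linalg.norm(t, axis=1).sum()
        return max(abs(pressure) * perimeter, 1e-9)

    def solve(
        self,
        load: LoadCase,
        settings: SolverSettings = SolverSettings(),
        u0: np.ndarray | None = None,
    ) -> Solution:
        """Solve to the target pressure.

        A warm start `u0` (e.g. the converged neighbouring station) is tried
        with a single Newton solve at full pressure first; on failure the
        incremental load-stepping path from the reference state is used.
        """
        Z = self.constraint_basis(load)
        ZT = Z.T.tocsr()
        u = np.zeros((len(self.mesh.nodes), 2))
        log: list[dict] = []
        p_target = load.pressure
        if p_target == 0.0:
            r, _ = self.assemble(u, 0.0, tangent=False)
            return Solution(u=u, deformed=self.mesh.nodes.copy(), log=log, pressure=0.0,
                            residual=float(np.linalg.norm(ZT @ r)))

        ref = self.reference_force(p_target)
        if u0 is not None and u0.shape == u.shape:
            warm = replace_settings_max_iter(settings, 8)
            ok, u_w, warm_log = self._newton(u0, p_target, ref, warm, Z, ZT)
            log.extend(warm_log)
            if not ok:
                # retry the warm start through a short penalty ramp
                u_r, ramp_ok = u0, True
                for pf in (0.1, 1.0):
                    ok_r, u_r, ramp_log = self._newton(u_r, p_target, ref, warm, Z, ZT, pf)
                    log.extend(ramp_log)
                    if not ok_r:
                        ramp_ok = False
                        break
                if ramp_ok:
                    ok, u_w = True, u_r
            if ok:
                return Solution(u=u_w, deformed=self.mesh.nodes + u_w, log=log,
                                pressure=p_target, residual=log[-1]["residual"])
        pfs = tuple(settings.penalty_continuation) or (1.0,)
        pf0 = pfs[0]
        p_done = 0.0
        dp = p_target / settings.n_load_steps
        min_dp = p_target * settings.min_step_fraction

        # phase 1: pressure stepping at the softest penalty factor
        u_hist: list[tuple[float, np.ndarray]] = [(0.0, u.copy())]
        while p_done < p_target - 1e-12:
            p_try = min(p_done + dp, p_target)
            # secant predictor from the two previous converged states
            u_start = u
            if len(u_hist) >= 2:
                (p1, u1), (p2, u2) = u_hist[-2], u_hist[-1]
                if p2 > p1:
                    u_pred = u2 + (u2 - u1) * ((p_try - p2) / (p2 - p1))
                    _, _, Jp, _, J0p = self.kinematics(u_pred)
                    if Jp.min() > 0.05 and J0p.min() > 0.05:
                        u_start = u_pred
            ok, u_new, step_log = self._newton(u_start, p_try, ref, settings, Z, ZT, pf0)
            if not ok and u_start is not u:
                ok, u_new, retry_log = self._newton(u, p_try, ref, settings, Z, ZT, pf0)
                step_log.extend(retry_log)
            log.extend(step_log)
            if ok:
                u = u_new
                u_hist.append((p_try, u.copy()))
                p_done = p_try
                continue
            dp /= 2.0
            if dp < min_dp:
                raise NonConvergenceError(
                    f"load step below {min_dp:.3g} kPa at p = {p_done:.3g} kPa", log
                )

        # phase 2: ramp the penalty to full strength at constant pressure
        todo = list(pfs[1:])
        pf_prev = pf0
        while todo:
            pf = todo[0]
            ok, u_new, step_log = self._newton(u, p_target, ref, settings, Z, ZT, pf)
            log.extend(step_log)
            if ok:
                u = u_new
                pf_prev = pf
                todo.pop(0)
                continue
            pf_mid = float(np.sqrt(pf_prev * pf))
            if pf_mid / pf_prev < 1.05:
                raise NonConvergenceError(
                    f"penalty continuation stalled at factor {pf_prev:.3g}", log
                )
            todo.insert(0, pf_mid)
        final = log[-1]["residual"] if log else 0.0
        return Solution(
            u=u, deformed=self.mesh.nodes + u, log=log, pressure=p_target, residual=final
        )

    def _newton(self, u0, pressure, ref, settings, Z, ZT, pf: float = 1.0):
        u = u0.copy()
        step_log = []
        for it in range(settings.max_iterations):
            try:
                r, Kt = self.assemble(u, pressure, pf=pf)
            except AssemblyError:
                return False, u0, step_log
            rr = ZT @ r
            if not np.all(np.isfinite(rr)):
                return False, u0, step_log
            res = float(np.linalg.norm(rr)) / ref
            step_log.append({"pressure": pressure, "penalty_factor": pf,
                             "iteration": it, "residual": res})
            if res <= settings.tolerance:
                return True, u, step_log
            Kr = (ZT @ Kt @ Z).tocsc()
            try:
                du = spla.spsolve(Kr, -rr)
            except RuntimeError:
                return False, u0, step_log
            if not np.all(np.isfinite(du)):
                return False, u0, step_log
            # Armijo backtracking on the total potential
            slope = float(rr @ du)
            if slope >= 0:  # not a descent direction; fall back to -gradient
                du = -rr / max(np.abs(Kr.diagonal()).mean(), 1.0)
                slope = float(rr @ du)
            pi0 = self.potential(u, pressure, pf)
            step = (Z @ du).reshape(-1, 2)
            scale = 1.0
            for _ in range(25):
                u_trial = u + scale * step
                pi_t = self.potential(u_trial, pressure, pf)
                if pi_t <= pi0 + 1e-4 * scale * slope:
                    break
                scale *= 0.5
            else:
                return False, u0, step_log
            u = u_trial
        return False, u0, step_log



def assemble(
    mesh: SectionMesh,
    materials: dict[str, ConstitutiveModel],
    frames: LocalFrame | None,
    u: np.ndarray,
    pressure: float = 0.0,
    bulk_penalty: float | None = None,
):
    """Residual and consistent tangent at displacement state u."""
    model = PlaneStrainModel(mesh, materials, frames, bulk_penalty)
    return model.assemble(np.asarray(u, dtype=float), pressure)


def newton_solve(
    mesh: SectionMesh,
    materials: dict[str, ConstitutiveModel],
    frames: LocalFrame | None,
    load: LoadCase,
    settings: SolverSettings = SolverSettings(),
) -> Solution:
    """Solve one pressurized section; raises NonConvergenceError with log."""
    model = PlaneStrainModel(
        mesh, materials, frames, settings.bulk_penalty, settings.stabilization
    )
    return model.solve(load, settings)


# --------------------------------------------------------------------------
# semi-analytical verification oracle


def tube_inflation_reference(
    inner_radius: float,
    layer_radii: list[float],
    layer_models: list[ConstitutiveModel],
    pressure: float,
    n_profile: int = 200,
):
    """Incompressible plane-strain inflation of a concentric layered tube.

    Classic quadrature oracle: with lambda_z = 1 and incompressibility the
    deformed radius satisfies r^2 - ri^2 = R^2 - Ri^2, and equilibrium gives
    p = integral (sigma_theta - sigma_r) dr / r across the wall.  The inner
    deformed radius is found by root bracketing, stress profiles follow by
    cumulative quadrature.  Only isotropic (Yeoh) layers are supported.

    Returns dict with deformed radii and radial profiles of sigma_r and
    sigma_theta (kPa) on `n_profile` reference-radius sample points.
    """
    from scipy.integrate import quad
    from scipy.optimize import brentq

    from .constitutive import YeohParams

    if any(not isinstance(mdl, YeohParams) for mdl in layer_models):
        raise ValueError("tube oracle supports isotropic Yeoh layers only")
    Ri = float(inner_radius)
    Ro = float(layer_radii[-1])
    if len(layer_radii) != len(layer_models):
        raise ValueError("one outer radius per layer required")

    def model_at(R):
        for Rb, mdl in zip(layer_radii, layer_models):
            if R <= Rb + 1e-12:
                return mdl
        return layer_models[-1]

    def dpsi(mdl, I1):
        x = I1 - 3.0
        return mdl.c10 + 2 * mdl.c20 * x + 3 * mdl.c30 * x**2

    def sig_diff(R, ri):
        """(sigma_theta - sigma_r) at reference radius R."""
        r2 = R * R - Ri * Ri + ri * ri
        lam2 = r2 / (R * R)
        I1 = lam2 + 1.0 / lam2 + 1.0
        return 2.0 * (lam2 - 1.0 / lam2) * dpsi(model_at(R), I1)

    def p_of(ri):
        # dr/r = R dR / r^2
        total = 0.0
        bounds = [Ri] + list(layer_radii)
        for Ra, Rb in zip(bounds[:-1], bounds[1:]):
            val, _ = quad(lambda R: sig_diff(R, ri) * R / (R * R - Ri * Ri + ri * ri), Ra, Rb,
                          limit=200)
            total += val
        return total

    if pressure == 0.0:
        ri = Ri
    else:
        lo, hi = Ri * (1 + 1e-12), Ri * 4.0
        ri = brentq(lambda x: p_of(x) - pressure, lo, hi, xtol=1e-12, rtol=1e-14)

    Rs = np.linspace(Ri, Ro, n_profile)
    sig_r = np.empty_like(Rs)
    for i, R in enumerate(Rs):
        val, _ = quad(lambda Rq: sig_diff(Rq, ri) * Rq / (Rq * Rq - Ri * Ri + ri * ri), Ri, R,
                      limit=200)
        sig_r[i] = -pressure + val
    sig_t = sig_r + np.array([sig_diff(R, ri) for R in Rs])
    r_def = np.sqrt(Rs**2 - Ri**2 + ri**2)
    return {
        "R": Rs,
        "r": r_def,
        "sigma_r": sig_r,
        "sigma_theta": sig_t,
        "inner_radius_deformed": ri,
        "layer_radii_deformed": [float(np.sqrt(Rb**2 - Ri**2 + ri**2)) for Rb in layer_radii],
    }
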