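"""Hyperelastic constitutive models for arterial wall layers and plaque tissue.

Implements the two strain-energy density functions (SEDF) used throughout the
package, with units fixed repo-wide to kPa and mm:

* Yeoh polynomial (isotropic, order 1-3):
      Psi = sum_i c_i0 (I1 - 3)^i
  1st order is neo-Hookean (lipid core), 2nd order covers fibrous tissue,
  3rd order the isotropic wall-layer fits.

* Fiber-reinforced anisotropic media model with two symmetric fiber families
  at +/-phi from the circumferential direction and a "degree of anisotropy"
  weight rho in [0, 1]:
      Psi = mu/2 (I1-3) + k1/(2 k2) (exp[k2((1-rho)(I1-3)^2
                                            + rho(I4-1)^2)] - 1)
  with I1 = lr^2 + lt^2 + lz^2 and I4 = lt^2 cos^2 phi + lz^2 sin^2 phi.

Closed-form homogeneous responses (principal Cauchy stresses under declared
zero-traction axes) support parameter fitting and solver verification; the
full tensorial S = 2 dPsi/dC and tangent CC = 4 d2Psi/dC2 (nearly
incompressible, isochoric split + volumetric penalty) feed the FE solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

from . import _symdiff

_EXP_ARG_MAX = 500.0  # exp overflow guard for the media energy


class InvalidStateError(ValueError):
    """Deformation state violates positivity / incompressibility."""


class RangeError(FloatingPointError):
    """Energy evaluation left the numerically representable range."""


class FitError(ValueError):
    """Degenerate data passed to a material fit."""


# --------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class YeohParams:
    """Yeoh SEDF constants in kPa; constants above `order` must be zero."""

    c10: float
    c20: float = 0.0
    c30: float = 0.0
    order: int = 3

    def __post_init__(self):
        if not 1 <= self.order <= 3:
            raise ValueError("Yeoh order must be 1, 2 or 3")
        if self.c10 <= 0:
            raise ValueError("c10 must be positive")
        cs = (self.c10, self.c20, self.c30)
        for i in range(self.order, 3):
            if cs[i] != 0.0:
                raise ValueError(f"c{i+1}0 must be exactly 0 for order {self.order}")

    @property
    def constants(self) -> tuple[float, float, float]:
        return (self.c10, self.c20, self.c30)

    @property
    def kind(self) -> str:
        return "yeoh"

    @property
    def stiffness_scale(self) -> float:
        return self.c10


@dataclass(frozen=True)
class MediaAnisoParams:
    """Anisotropic media constants: mu, k1 [kPa]; k2, rho [-]; phi [deg]."""

    mu: float
    k1: float
    k2: float
    phi_deg: float
    rho: float

    def __post_init__(self):
        if min(self.mu, self.k1, self.k2) <= 0:
            raise ValueError("mu, k1, k2 must be positive")
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if not 0.0 <= self.phi_deg <= 90.0:
            raise ValueError("phi must lie in [0, 90] degrees")

    @property
    def phi_rad(self) -> float:
        return np.deg2rad(self.phi_deg)

    @property
    def kind(self) -> str:
        return "media"

    @property
    def stiffness_scale(self) -> float:
        return self.mu


ConstitutiveModel = YeohParams | MediaAnisoParams


def default_bulk_penalty(models: Sequence[ConstitutiveModel], factor: float = 1e4) -> float:
    """Volumetric penalty K = factor x largest c10/mu among the given models."""
    return factor * max(m.stiffness_scale for m in models)


# --------------------------------------------------------------------------
# deformation state


@dataclass(frozen=True)
class DeformationState:
    """Principal stretches in the local (r, theta, z) frame, or a full C."""

    stretches: tuple[float, float, float] | None = None
    C: np.ndarray | None = None
    mode: Literal["principal", "full-tensor"] = "principal"

    @classmethod
    def from_principal(cls, lr: float, lt: float, lz: float) -> "DeformationState":
        if min(lr, lt, lz) <= 0:
            raise InvalidStateError("principal stretches must be positive")
        return cls(stretches=(float(lr), float(lt), float(lz)), mode="principal")

    @classmethod
    def from_C(cls, C: np.ndarray) -> "DeformationState":
        C = np.asarray(C, dtype=float)
        if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-12):
            raise InvalidStateError("C must be a symmetric 3x3 tensor")
        if np.linalg.eigvalsh(C).min() <= 0:
            raise InvalidStateError("C must be positive definite")
        return cls(C=C, mode="full-tensor")

    @property
    def principal(self) -> tuple[float, float, float]:
        if self.mode == "principal":
            return self.stretches  # type: ignore[return-value]
        lam2 = np.linalg.eigvalsh(self.C)
        # eigvalsh sorts ascending; keep that order (no frame attached)
        return tuple(np.sqrt(lam2))  # type: ignore[return-value]

    @property
    def J(self) -> float:
        if self.mode == "principal":
            return float(np.prod(self.stretches))
        return float(np.sqrt(np.linalg.det(self.C)))

    def require_incompressible(self, tol: float = 1e-9) -> None:
        if abs(self.J - 1.0) > tol:
            raise InvalidStateError(f"state is not incompressible: J = {self.J!r}")

    def as_C(self) -> np.ndarray:
        if self.mode == "full-tensor":
            return self.C  # type: ignore[return-value]
        lr, lt, lz = self.stretches  # type: ignore[misc]
        return np.diag([lr**2, lt**2, lz**2])


def invariants(state: DeformationState, phi_deg: float) -> tuple[float, float]:
    """I1 = tr C and the fiber pseudo-invariant I4 for family angle phi.

    I4 is the (identical) squared stretch of the two symmetric +/-phi fiber
    families, I4 = lt^2 cos^2 phi + lz^2 sin^2 phi, evaluated in the local
    (r, theta, z) frame via the generalized structure tensor
    H = cos^2 phi e_t (x) e_t + sin^2 phi e_z (x) e_z (cross terms of the two
    families cancel).
    """
    C = state.as_C()
    if np.linalg.eigvalsh(C).min() <= 0:
        raise InvalidStateError("non-positive stretch in deformation state")
    phi = np.deg2rad(phi_deg)
    I1 = float(np.trace(C))
    I4 = float(np.cos(phi) ** 2 * C[1, 1] + np.sin(phi) ** 2 * C[2, 2])
    return I1, I4


def strain_energy(model: ConstitutiveModel, state: DeformationState) -> float:
    """Incompressible strain energy Psi [kPa] at the given state."""
    phi = model.phi_deg if isinstance(model, MediaAnisoParams) else 0.0
    I1, I4 = invariants(state, phi)
    if isinstance(model, YeohParams):
        x = I1 - 3.0
        return float(model.c10 * x + model.c20 * x**2 + model.c30 * x**3)
    q = model.k2 * ((1 - model.rho) * (I1 - 3) ** 2 + model.rho * (I4 - 1) ** 2)
    if q > _EXP_ARG_MAX:
        raise RangeError(f"media energy overflow: exp argument {q:.3g} at I1={I1:.6g}, I4={I4:.6g}")
    return float(model.mu / 2 * (I1 - 3) + model.k1 / (2 * model.k2) * (np.exp(q) - 1))


def _dpsi_dinvariants(model: ConstitutiveModel, I1: float, I4: float) -> tuple[float, float]:
    if isinstance(model, YeohParams):
        x = I1 - 3.0
        return model.c10 + 2 * model.c20 * x + 3 * model.c30 * x**2, 0.0
    q = model.k2 * ((1 - model.rho) * (I1 - 3) ** 2 + model.rho * (I4 - 1) ** 2)
    if q > _EXP_ARG_MAX:
        raise RangeError(f"media energy overflow: exp argument {q:.3g} at I1={I1:.6g}, I4={I4:.6g}")
    e = np.exp(q)
    dI1 = model.mu / 2 + model.k1 * (1 - model.rho) * (I1 - 3) * e
    dI4 = model.k1 * model.rho * (I4 - 1) * e
    return float(dI1), float(dI4)


_AXES = {"r": 0, "theta": 1, "z": 2}


def cauchy_stress_principal(
    model: ConstitutiveModel,
    state: DeformationState,
    zero_stress_axis: str = "r",
) -> np.ndarray:
    """Principal Cauchy stresses (sigma_r, sigma_t, sigma_z) [kPa].

    Incompressible homogeneous state: sigma_i = lambda_i dPsi/dlambda_i - p,
    with the hydrostatic pressure p fixed so the declared axis carries zero
    traction (radial for (equi)biaxial states; for uniaxial loading along
    theta or z either lateral axis may be declared, they are equivalent for
    isotropic models).
    """
    state.require_incompressible()
    if zero_stress_axis not in _AXES:
        raise ValueError(f"unknown axis {zero_stress_axis!r}; expected r, theta or z")
    lr, lt, lz = state.principal
    phi = model.phi_deg if isinstance(model, MediaAnisoParams) else 0.0
    I1, I4 = invariants(state, phi)
    dI1, dI4 = _dpsi_dinvariants(model, I1, I4)
    phi_r = np.deg2rad(phi)
    # lambda_i dPsi/dlambda_i for (r, theta, z)
    t = np.array(
        [
            2 * lr**2 * dI1,
            2 * lt**2 * dI1 + 2 * lt**2 * np.cos(phi_r) ** 2 * dI4,
            2 * lz**2 * dI1 + 2 * lz**2 * np.sin(phi_r) ** 2 * dI4,
        ]
    )
    return t - t[_AXES[zero_stress_axis]]


def pk2_stress_and_tangent(
    model: ConstitutiveModel,
    C: np.ndarray,
    fiber_frame: np.ndarray | None = None,
    bulk_penalty: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Second Piola-Kirchhoff stress S and material tangent CC at C.

    Nearly incompressible: isochoric split of the SEDF plus the volumetric
    penalty U(J) = K/2 (J-1)^2; K defaults to 1e4 x the model's stiffness
    scale.  For the media model, `fiber_frame` is the 3x3 matrix whose
    columns are (e_r, e_theta, e_z); C is rotated into that frame, evaluated
    against the constant structure tensor, and S, CC are rotated back.

    Returns S (3x3, kPa) and CC (3x3x3x3, kPa) with
    S = 2 dPsi/dC and CC = 4 d2Psi/dCdC.
    """
    C = np.asarray(C, dtype=float)
    if C.shape != (3, 3) or not np.allclose(C, C.T, atol=1e-10):
        raise InvalidStateError("C must be a symmetric 3x3 tensor")
    try:
        np.linalg.cholesky(C)
    except np.linalg.LinAlgError as exc:
        raise InvalidStateError("C must be positive definite") from exc
    K = default_bulk_penalty([model]) if bulk_penalty is None else float(bulk_penalty)
    if isinstance(model, MediaAnisoParams):
        Q = np.eye(3) if fiber_frame is None else np.asarray(fiber_frame, dtype=float)
        Cl = Q.T @ C @ Q
        params = (model.mu, model.k1, model.k2, model.rho, model.phi_rad)
        _, S, CC = _symdiff.eval3d("media", Cl, params, K)
        if not (np.all(np.isfinite(S)) and np.all(np.isfinite(CC))):
            I1, I4 = invariants(DeformationState.from_C(C), model.phi_deg)
            raise RangeError(f"media energy overflow at I1={I1:.6g}, I4={I4:.6g}")
        S = Q @ S @ Q.T
        CC = np.einsum("iI,jJ,kK,lL,IJKL->ijkl", Q, Q, Q, Q, CC)
        return S, CC
    _, S, CC = _symdiff.eval3d("yeoh", C, model.constants, K)
    return S, CC


# --------------------------------------------------------------------------
# uniaxial response and initial-stiffness fitting


def yeoh_uniaxial_stress(stretch: np.ndarray, c10: float, c20: float = 0.0, c30: float = 0.0) -> np.ndarray:
    """Incompressible uniaxial Cauchy stress of a Yeoh solid at stretch lambda."""
    lam = np.asarray(stretch, dtype=float)
    I1 = lam**2 + 2.0 / lam
    x = I1 - 3.0
    dpsi = c10 + 2 * c20 * x + 3 * c30 * x**2
    return 2.0 * (lam**2 - 1.0 / lam) * dpsi


@dataclass(frozen=True)
class FitResult:
    """Initial-stiffness fit of the 2nd-order Yeoh uniaxial response."""

    c10: float
    c20: float
    r_squared: float
    residuals: np.ndarray = field(repr=False)


def fit_initial_stiffness(data: np.ndarray, fixed_c20: float = 20.0) -> FitResult:
    """Fit only c10 (initial stiffness) of a 2nd-order Yeoh model.

    `data`: (n, 2) array of (stretch, Cauchy stress kPa) pairs from uniaxial
    tension; c20 (strain stiffening) is held fixed.  The model is linear in
    c10, so the least-squares solution is closed form.  Reports R^2 against
    the measured stresses.
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 3:
        raise FitError("need at least 3 (stretch, stress) pairs")
    lam, sigma = data[:, 0], data[:, 1]
    if np.any(lam <= 1.0):
        raise FitError("uniaxial fit expects stretches > 1")
    if np.allclose(sigma, 0.0):
        raise FitError("degenerate data: all stresses are zero")
    I1 = lam**2 + 2.0 / lam
    x = I1 - 3.0
    basis = 2.0 * (lam**2 - 1.0 / lam)  # coefficient of c10
    offset = basis * 2.0 * fixed_c20 * x  # fixed c20 contribution
    y = sigma - offset
    c10 = float(y @ basis / (basis @ basis))
    if c10 <= 0:
        raise FitError(f"fitted c10 = {c10:.4g} is not positive")
    pred = yeoh_uniaxial_stress(lam, c10, fixed_c20)
    resid = sigma - pred
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((sigma - sigma.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return FitResult(c10=c10, c20=fixed_c20, r_squared=r2, residuals=resid)


def read_stress_stretch(path) -> np.ndarray:
    """Read 2-column delimited (stretch, Cauchy stress kPa) text data.

    Comma or whitespace delimited; an optional non-numeric header line is
    skipped.
    """
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            try:
                rows.append([float(parts[0]), float(parts[1])])
            except (ValueError, IndexError):
                if not rows:
                    continue  # header
                raise
    return np.asarray(rows, dtype=float)
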