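"""Symbolically generated strain-energy derivatives.

The strain-energy densities (Yeoh polynomial and the rho-weighted exponential
fiber-reinforced media model) are differentiated exactly with sympy and
lambdified into vectorized numpy callables, once per model family.  This gives
machine-precision second Piola-Kirchhoff stresses S = 2 dPsi/dC and material
tangents CC = 4 d2Psi/dC2 without hand-derived tensor calculus, and keeps the
analytic route independent of the finite-difference oracles used in tests.

Conventions
-----------
* Voigt ordering 3D: (11, 22, 33, 12, 13, 23); 2D plane strain: (11, 22, 12).
* Off-diagonal components of C enter the symbolic energy once (the matrix is
  built symmetrically), so for a scalar variable c12 representing both C12 and
  C21: dPsi/dc12 = 2 dPsi/dC12.  The factor bookkeeping below converts plain
  partials to tensor components:
    S_II = 2 dpsi/dc_II,  S_IJ = dpsi/dc_IJ (I != J)
    CC_ab = f_a * f_b * d2psi/dc_a dc_b   with f = 2 (diagonal), 1 (off-diag).
* The isochoric split is applied to both invariants: Ibar = (det C)^(-1/3) I,
  and the volumetric part is U(J) = K/2 (J-1)^2 with J = sqrt(det C).
* Media structure tensor in the local (r, theta, z) frame:
  H = diag(0, cos^2 phi, sin^2 phi); I4 = H : C is the shared squared stretch
  of the two symmetric +/-phi fiber families.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import sympy as sp

VOIGT3D = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
_FAC3D = np.array([2.0, 2.0, 2.0, 1.0, 1.0, 1.0])
_FAC2D = np.array([2.0, 2.0, 1.0])


def _yeoh_psi(i1bar, c10, c20, c30):
    x = i1bar - 3
    return c10 * x + c20 * x**2 + c30 * x**3


def _media_psi(i1bar, i4bar, mu, k1, k2, rho):
    q = k2 * ((1 - rho) * (i1bar - 3) ** 2 + rho * (i4bar - 1) ** 2)
    return mu / 2 * (i1bar - 3) + k1 / (2 * k2) * (sp.exp(q) - 1)


def _lambdify(args, exprs):
    return sp.lambdify(args, exprs, modules="numpy", cse=True)


@lru_cache(maxsize=None)
def model3d(kind: str):
    """Build (psi, S_voigt6, CC_voigt66) callables for a 3D symmetric C.

    Signature of the returned callable:
        f(c11, c22, c33, c12, c13, c23, *params, K) -> list of 1+6+36 arrays
    params: yeoh -> (c10, c20, c30); media -> (mu, k1, k2, rho, phi_rad).
    The media energy expects C expressed in the local (r, theta, z) frame.
    """
    c = sp.symbols("c11 c22 c33 c12 c13 c23", real=True)
    C = sp.Matrix([[c[0], c[3], c[4]], [c[3], c[1], c[5]], [c[4], c[5], c[2]]])
    detC = C.det()
    J = sp.sqrt(detC)
    i1bar = detC ** sp.Rational(-1, 3) * sp.trace(C)
    if kind == "yeoh":
        params = sp.symbols("p_c10 p_c20 p_c30", positive=False)
        psi_iso = _yeoh_psi(i1bar, *params)
    elif kind == "media":
        mu, k1, k2, rho = sp.symbols("p_mu p_k1 p_k2 p_rho")
        phi = sp.Symbol("p_phi")
        H = sp.diag(0, sp.cos(phi) ** 2, sp.sin(phi) ** 2)
        i4bar = detC ** sp.Rational(-1, 3) * sp.trace(H * C)
        psi_iso = _media_psi(i1bar, i4bar, mu, k1, k2, rho)
        params = (mu, k1, k2, rho, phi)
    else:  # pragma: no cover
        raise ValueError(f"unknown model kind {kind!r}")
    K = sp.Symbol("p_K")
    psi = psi_iso + K / 2 * (J - 1) ** 2

    grad = [sp.diff(psi, ci) for ci in c]
    hess = [[sp.diff(g, cj) for cj in c] for g in grad]
    exprs = [psi] + grad + [h for row in hess for h in row]
    return _lambdify(tuple(c) + tuple(params) + (K,), exprs)


def eval3d(kind: str, C: np.ndarray, params: tuple[float, ...], K: float):
    """Evaluate (psi, S 3x3, CC 3x3x3x3) at one or many 3x3 C tensors."""
    f = model3d(kind)
    C = np.asarray(C, dtype=float)
    single = C.ndim == 2
    Cb = C[None] if single else C
    args = [Cb[..., i, j] for (i, j) in VOIGT3D]
    with np.errstate(over="ignore", invalid="ignore"):
        out = f(*args, *params, K)
    n = Cb.shape[0]
    psi = np.broadcast_to(np.asarray(out[0], dtype=float), (n,)).copy()
    g = np.stack([np.broadcast_to(o, (n,)) for o in out[1:7]], axis=-1)
    h = np.stack([np.broadcast_to(o, (n,)) for o in out[7:]], axis=-1)
    h = h.reshape(n, 6, 6)
    S6 = g * _FAC3D
    CC66 = h * _FAC3D[:, None] * _FAC3D[None, :]
    S = np.zeros((n, 3, 3))
    CC = np.zeros((n, 3, 3, 3, 3))
    for a, (i, j) in enumerate(VOIGT3D):
        S[:, i, j] = S6[:, a]
        S[:, j, i] = S6[:, a]
        for b, (k, l) in enumerate(VOIGT3D):
            CC[:, i, j, k, l] = CC66[:, a, b]
            CC[:, j, i, k, l] = CC66[:, a, b]
            CC[:, i, j, l, k] = CC66[:, a, b]
            CC[:, j, i, l, k] = CC66[:, a, b]
    if single:
        return psi[0], S[0], CC[0]
    return psi, S, CC


@lru_cache(maxsize=None)
def model2d(kind: str):
    """Plane-strain isochoric energy derivatives (volumetric part excluded).

    Variables (c11, c22, c12) with C33 = 1, C13 = C23 = 0.  For the media
    model the in-plane circumferential direction is m = (cos a, sin a) with a
    the element fiber-frame angle, and the out-of-plane (axial) fiber
    contribution enters through C33 = 1:
        I4 = cos^2 phi (m.C2.m) + sin^2 phi.
    Returns a callable
        f(c11, c22, c12, *params) -> [psi, g1, g2, g3, h11..h33]
    params: yeoh -> (c10, c20, c30); media -> (mu, k1, k2, rho, phi, alpha).
    """
    c11, c22, c12 = sp.symbols("c11 c22 c12", real=True)
    C2 = sp.Matrix([[c11, c12], [c12, c22]])
    detC = C2.det()  # det of full C with C33 = 1
    i1 = c11 + c22 + 1
    i1bar = detC ** sp.Rational(-1, 3) * i1
    if kind == "yeoh":
        params = sp.symbols("p_c10 p_c20 p_c30")
        psi = _yeoh_psi(i1bar, *params)
    elif kind == "media":
        mu, k1, k2, rho, phi, alpha = sp.symbols("p_mu p_k1 p_k2 p_rho p_phi p_alpha")
        m = sp.Matrix([sp.cos(alpha), sp.sin(alpha)])
        i4 = sp.cos(phi) ** 2 * (m.T * C2 * m)[0, 0] + sp.sin(phi) ** 2 * 1
        i4bar = detC ** sp.Rational(-1, 3) * i4
        psi = _media_psi(i1bar, i4bar, mu, k1, k2, rho)
        params = (mu, k1, k2, rho, phi, alpha)
    else:  # pragma: no cover
        raise ValueError(f"unknown model kind {kind!r}")
    cvars = (c11, c22, c12)
    grad = [sp.diff(psi, ci) for ci in cvars]
    hess = [sp.diff(g, cj) for g in grad for cj in cvars]
    return _lambdify(cvars + tuple(params), [psi] + grad + hess)


VOIGT2D = ((0, 0), (1, 1), (0, 1))


def eval2d(kind: str, C2: np.ndarray, params: tuple, out_psi: bool = False):
    """Evaluate isochoric (S 2x2, CC 2x2x2x2) at a batch of in-plane C.

    C2: (..., 2, 2).  params as in :func:`model2d`; array-valued parameters
    (e.g. per-element fiber angle) broadcast against the batch.
    """
    f = model2d(kind)
    C2 = np.asarray(C2, dtype=float)
    shp = C2.shape[:-2]
    args = [C2[..., i, j] for (i, j) in VOIGT2D]
    with np.errstate(over="ignore", invalid="ignore"):
        out = f(*args, *params)
    psi = np.broadcast_to(np.asarray(out[0], dtype=float), shp)
    g = np.stack([np.broadcast_to(o, shp) for o in out[1:4]], axis=-1)
    h = np.stack([np.broadcast_to(o, shp) for o in out[4:]], axis=-1).reshape(shp + (3, 3))
    S3 = g * _FAC2D
    CC33 = h * _FAC2D[:, None] * _FAC2D[None, :]
    S = np.zeros(shp + (2, 2))
    CC = np.zeros(shp + (2, 2, 2, 2))
    for a, (i, j) in enumerate(VOIGT2D):
        S[..., i, j] = S3[..., a]
        S[..., j, i] = S3[..., a]
        for b, (k, l) in enumerate(VOIGT2D):
            CC[..., i, j, k, l] = CC33[..., a, b]
            CC[..., j, i, k, l] = CC33[..., a, b]
            CC[..., i, j, l, k] = CC33[..., a, b]
            CC[..., j, i, l, k] = CC33[..., a, b]
    if out_psi:
        return psi, S, CC
    return S, CC
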