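"""Rigorous Debye-Wolf focal fields and modal coefficients (the oracle path).

The focal field of an aplanatic objective illuminated by an x-polarised,
Gaussian-apodised beam is a vectorial diffraction integral over the exit
pupil.  After carrying out the azimuthal pupil integral analytically the
field reduces to a single integral over the polar aperture angle theta with
Bessel-function kernels::

    E(rho, psi, z; k) = -i f k  Int_0^{arcsin(NA/eta)}  cos(th) sin(th)
        exp(-(kW)^2 sin^2 th + i eta k z cos th)
        [ (1+cos th) J0(x) + (cos th - 1) cos(2 psi) J2(x) ]   (Ex)
        [ (cos th - 1) sin(2 psi) J2(x) ]                       (Ey)
        [ 2 sin th cos(psi) J1(x) ]                             (Ez)
        dth,        x = eta k rho sin th

evaluated here with fixed-order Gauss-Legendre quadrature.  This module is
the ground truth that every fast approximation in the package is tested
against; it is deliberately free of Taylor/regression machinery.

Detection only uses the x component: the sample modal coefficient is
``alpha_scat(k) = sum_s rho_s Ex(P_s; k)^2`` and the reference (mirror)
coefficient is the analogous Riemann sum over a grid on the mirror plane.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import j0, j1

from .optics_core import CylindricalPoint, OpticalSystem, ScattererSet

__all__ = [
    "EFieldVector",
    "QuadratureError",
    "focal_field_rigorous",
    "focal_field_aperture",
    "ex_incident",
    "h_components",
    "mirror_modal_coefficient",
    "scat_modal_coefficient_rigorous",
]

DEFAULT_NODES = 200

# The azimuthal reduction leaves it ambiguous whether the longitudinal (Ez)
# kernel carries the common cos(theta) factor of the transverse rows.  Ez does
# not enter detection (only Ex does), so the choice is isolated here; set
# False to drop the cos(theta) factor from the Ez kernel.
EZ_INCLUDES_COS_THETA = True


class QuadratureError(RuntimeError):
    """Gauss-Legendre node doubling failed to converge to tolerance."""


def _j2(x: np.ndarray, j0x: np.ndarray | None = None) -> np.ndarray:
    """J2 via the recurrence 2 J1(x)/x - J0(x) (pass j0x to reuse it).

    Much faster than the generic-order routine; the small-x series branch
    avoids the 0/0 and keeps the error absolute (~1e-16), negligible against
    the O(1) J0 kernel terms these integrands mix with.
    """
    if j0x is None:
        j0x = j0(x)
    small = np.abs(x) < 1e-4
    xs = np.where(small, 1.0, x)
    out = 2.0 * j1(xs) / xs - j0x
    x2 = x * x
    return np.where(small, x2 / 8.0 * (1.0 - x2 / 12.0), out)


@dataclass(frozen=True)
class EFieldVector:
    """Complex field components at one point for one (or a grid of) k."""

    ex: complex | np.ndarray
    ey: complex | np.ndarray
    ez: complex | np.ndarray


@lru_cache(maxsize=32)
def _gl_nodes(n_nodes: int, theta_max: float):
    """Gauss-Legendre nodes/weights mapped to [0, theta_max]."""
    x, w = np.polynomial.legendre.leggauss(n_nodes)
    theta = 0.5 * theta_max * (x + 1.0)
    weights = 0.5 * theta_max * w
    return theta, weights


def _prefactors(sys: OpticalSystem, k: np.ndarray, n_nodes: int):
    theta, w = _gl_nodes(n_nodes, sys.theta_max)
    st, ct = np.sin(theta), np.cos(theta)
    k = np.atleast_1d(np.asarray(k, float))
    apod = np.exp(-((k[:, None] * sys.w_um) ** 2) * st**2)  # (K, Q)
    return theta, w, st, ct, k, apod


def h_components(rho, z, k, sys: OpticalSystem, n_nodes: int = DEFAULT_NODES):
    """Slowly varying radial integrals ``h0`` and ``h2`` of the x field.

    With the fast axial phase ``exp(i eta k z cos th)`` split as
    ``exp(i eta k z) * exp(i eta k z (cos th - 1))`` the x component factors
    as ``Ex = -i f k exp(i eta k z) (h0 + cos(2 psi) h2)`` where::

        h_c(rho, z; k) = Int g_c(th) exp(-(kW)^2 sin^2 th)
                             exp(i eta k z (cos th - 1)) J_c(eta k rho sin th) dth
        g_0 = cos th sin th (1 + cos th),   g_2 = cos th sin th (cos th - 1)

    Parameters are broadcast: ``rho`` and ``z`` must have equal shape (P,),
    ``k`` has shape (K,).  Returns two arrays of shape (P, K).
    """
    theta, w, st, ct, k, apod = _prefactors(sys, k, n_nodes)
    rho = np.atleast_1d(np.asarray(rho, float))
    z = np.broadcast_to(np.atleast_1d(np.asarray(z, float)), rho.shape)
    g0 = ct * st * (1.0 + ct)
    g2 = ct * st * (ct - 1.0)
    eta = sys.eta

    out0 = np.empty((rho.size, k.size), complex)
    out2 = np.empty_like(out0)
    z_const = rho.size > 1 and np.all(z == z.flat[0])
    if z_const:
        # axial phase independent of the point: fold it into the weights once
        ax0 = np.exp(1j * eta * k[:, None] * z.flat[0] * (ct - 1.0))
        common0 = (apod * ax0)[None, :, :] * w
    chunk = max(1, int(4e7 // (k.size * theta.size)) or 1)
    for i0 in range(0, rho.size, chunk):
        sl = slice(i0, i0 + chunk)
        x = eta * k[None, :, None] * rho[sl, None, None] * st  # (P, K, Q)
        j0x = j0(x)
        j2x = _j2(x, j0x)
        if z_const:
            out0[sl] = np.einsum("kq,q,pkq->pk", common0[0], g0, j0x)
            out2[sl] = np.einsum("kq,q,pkq->pk", common0[0], g2, j2x)
        else:
            ax = np.exp(1j * eta * k[None, :, None] * z[sl, None, None] * (ct - 1.0))
            common = apod[None, :, :] * ax * w
            out0[sl] = np.einsum("pkq,q,pkq->pk", common, g0, j0x)
            out2[sl] = np.einsum("pkq,q,pkq->pk", common, g2, j2x)
    return out0, out2


def ex_incident(rho, psi, z, k, sys: OpticalSystem,
                n_nodes: int = DEFAULT_NODES) -> np.ndarray:
    """Rigorous x component of the incident focal field.

    ``rho``, ``psi``, ``z`` are beam-frame cylindrical coordinates of shape
    (P,) (z relative to focus); ``k`` has shape (K,).  Returns (P, K).
    """
    h0, h2 = h_components(rho, z, k, sys, n_nodes)
    k = np.atleast_1d(np.asarray(k, float))
    z = np.broadcast_to(np.atleast_1d(np.asarray(z, float)),
                        np.atleast_1d(rho).shape)
    psi = np.broadcast_to(np.atleast_1d(np.asarray(psi, float)),
                          np.atleast_1d(rho).shape)
    phase = np.exp(1j * sys.eta * k[None, :] * z[:, None])
    pref = -1j * sys.f_um * k[None, :]
    return pref * phase * (h0 + np.cos(2.0 * psi)[:, None] * h2)


def focal_field_rigorous(p: CylindricalPoint, k, sys: OpticalSystem,
                         n_nodes: int = DEFAULT_NODES,
                         ez_includes_cos_theta: bool | None = None,
                         check_convergence: bool = False,
                         conv_tol: float = 1e-9) -> EFieldVector:
    """All three components of the Bessel-reduced focal field at one point.

    With ``check_convergence=True`` the quadrature is repeated at doubled
    node count and a :class:`QuadratureError` carrying both estimates is
    raised if the relative change exceeds ``conv_tol``.
    """
    if ez_includes_cos_theta is None:
        ez_includes_cos_theta = EZ_INCLUDES_COS_THETA

    def evaluate(nn: int) -> EFieldVector:
        theta, w, st, ct, kk, apod = _prefactors(sys, k, nn)
        x = sys.eta * kk[:, None] * p.rho * st  # (K, Q)
        axial = np.exp(1j * sys.eta * kk[:, None] * p.z * ct)
        common = apod * axial * w
        base = ct * st
        ex_kern = base * ((1.0 + ct) * j0(x)
                          + (ct - 1.0) * np.cos(2.0 * p.psi) * _j2(x))
        ey_kern = base * (ct - 1.0) * np.sin(2.0 * p.psi) * _j2(x)
        ez_base = base if ez_includes_cos_theta else st
        ez_kern = ez_base * 2.0 * st * np.cos(p.psi) * j1(x)
        pref = -1j * sys.f_um * kk
        ex = pref * np.sum(common * ex_kern, axis=-1)
        ey = pref * np.sum(common * ey_kern, axis=-1)
        ez = pref * np.sum(common * ez_kern, axis=-1)
        if np.isscalar(k) or np.ndim(k) == 0:
            return EFieldVector(ex[0], ey[0], ez[0])
        return EFieldVector(ex, ey, ez)

    result = evaluate(n_nodes)
    if check_convergence:
        refined = evaluate(2 * n_nodes)
        a = np.array([result.ex, result.ey, result.ez], dtype=complex)
        b = np.array([refined.ex, refined.ey, refined.ez], dtype=complex)
        scale = max(float(np.max(np.abs(b))), 1e-300)
        change = float(np.max(np.abs(a - b))) / scale
        if change > conv_tol:
            raise QuadratureError(
                f"node doubling changed the field by {change:.3e} (> {conv_tol:g}); "
                f"estimates at n={n_nodes}: {a.tolist()}, at n={2*n_nodes}: {b.tolist()}"
            )
    return result


def focal_field_aperture(p: CylindricalPoint, k: float, sys: OpticalSystem,
                         n_theta: int = 160, n_phi: int = 256,
                         ez_includes_cos_theta: bool | None = None) -> EFieldVector:
    """Direct 2-D aperture-integral evaluation of the focal field.

    Independent numerical route used to validate the Bessel reduction: the
    vectorial pupil integral is evaluated as a tensor-product quadrature over
    the aperture (Gauss-Legendre in theta, periodic trapezoid in phi) with the
    refraction vector written out explicitly -- no Bessel functions involved.
    """
    if ez_includes_cos_theta is None:
        ez_includes_cos_theta = EZ_INCLUDES_COS_THETA
    theta, wt = _gl_nodes(n_theta, sys.theta_max)
    phi = np.arange(n_phi) * (2.0 * np.pi / n_phi)
    wphi = 2.0 * np.pi / n_phi
    st, ct = np.sin(theta)[:, None], np.cos(theta)[:, None]
    cphi, c2phi, s2phi = np.cos(phi)[None, :], np.cos(2 * phi)[None, :], np.sin(2 * phi)[None, :]

    # Refraction (vectorial pupil) factors consistent with an x-polarised input.
    vx = ct * ((1.0 + ct) + (1.0 - ct) * c2phi)
    vy = ct * (1.0 - ct) * s2phi
    vz = (ct if ez_includes_cos_theta else 1.0) * (-2j) * st * cphi

    phase = np.exp(
        -((k * sys.w_um) ** 2) * st**2
        + 1j * sys.eta * k * (p.rho * st * np.cos(phi[None, :] - p.psi) + p.z * ct)
    )
    meas = st * wt[:, None] * wphi / (2.0 * np.pi)
    pref = -1j * sys.f_um * k
    ex = pref * np.sum(meas * vx * phase)
    ey = pref * np.sum(meas * vy * phase)
    ez = pref * np.sum(meas * vz * phase)
    return EFieldVector(ex, ey, ez)


def scat_modal_coefficient_rigorous(scat: ScattererSet, k, sys: OpticalSystem,
                                    x_beam: float = 0.0, y_beam: float = 0.0,
                                    rho_max_um: float | None = None,
                                    n_nodes: int = DEFAULT_NODES) -> np.ndarray:
    """Sample-arm modal coefficient: ``sum_s rho_s Ex(P_s; k)^2`` over k.

    Scatterer coordinates are translated into the beam frame of
    ``(x_beam, y_beam)`` with depth taken relative to the focal plane.
    Returns an array of shape (K,).
    """
    k = np.atleast_1d(np.asarray(k, float))
    rho, psi, z, w = scat.beam_frame(x_beam, y_beam, sys.zf_um, rho_max_um)
    if rho.size == 0:
        return np.zeros(k.size, complex)
    ex = ex_incident(rho, psi, z, k, sys, n_nodes)
    return np.einsum("p,pk->k", w, ex * ex)


def mirror_modal_coefficient(k, sys: OpticalSystem,
                             n_nodes: int = DEFAULT_NODES,
                             truncation_check: bool = False,
                             truncation_tol: float = 1e-4) -> np.ndarray:
    """Reference-arm modal coefficient from the mirror-plane Riemann sum.

    ``alpha_mirr(k) = Delta_N * sum_t rho_mirr * Ex(x_t, y_t, z_mirr; k)^2``
    over a uniform square grid covering the beam footprint on the mirror.
    Grid points sharing a radius are grouped so the field quadrature runs
    only over unique radii (the sum itself is unchanged).

    With ``truncation_check=True`` the grid extent is enlarged by 25% (same
    step) and a warning is emitted if |alpha_mirr| changes by more than
    ``truncation_tol`` relative.
    """
    import warnings

    k = np.atleast_1d(np.asarray(k, float))
    m = sys.resolved_mirror()
    if m.reflectivity == 0.0:
        return np.zeros(k.size, complex)

    def riemann(half_width: float, n_pts: int) -> np.ndarray:
        coords = np.linspace(-half_width, half_width, n_pts)
        step = coords[1] - coords[0]
        xx, yy = np.meshgrid(coords, coords, indexing="ij")
        rho = np.hypot(xx, yy).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            cos2psi = np.where(rho > 0, (xx**2 - yy**2).ravel() / np.where(rho > 0, rho, 1.0) ** 2, 1.0)
        z_dwi = m.z_um - sys.zf_um
        rho_u, inv = np.unique(rho, return_inverse=True)
        h0, h2 = h_components(rho_u, np.full_like(rho_u, z_dwi), k, sys, n_nodes)
        pref = -1j * sys.f_um * k * np.exp(1j * sys.eta * k * z_dwi)  # (K,)
        ex = pref[None, :] * (h0[inv] + cos2psi[:, None] * h2[inv])
        return (step * step) * m.reflectivity * np.einsum("pk,pk->k", ex, ex)

    hw = m.half_width_um
    alpha = riemann(hw, m.n_points)
    if truncation_check:
        step = 2.0 * hw / (m.n_points - 1)
        n_big = int(np.ceil(1.25 * hw / step)) * 2 + 1
        hw_big = 0.5 * step * (n_big - 1)
        alpha_big = riemann(hw_big, n_big)
        rel = np.max(np.abs(np.abs(alpha_big) - np.abs(alpha))
                     / np.maximum(np.abs(alpha_big), 1e-300))
        if rel > truncation_tol:
            warnings.warn(
                f"mirror grid truncation: enlarging the grid by 25% changes "
                f"|alpha_mirr| by {rel:.2e} relative (> {truncation_tol:g}); "
                "increase mirror half-width or n_points", stacklevel=2)
    return alpha
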