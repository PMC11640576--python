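"""Fast focal-field evaluation by Taylor expansion about sparse source points.

The slowly varying radial integrals ``h0`` and ``h2`` (see
:mod:`octsim.dwi_reference`) are analytic in both ``rho`` and ``z``, and --
crucially -- after factoring out the rapid axial phase ``exp(i eta k z)``
their residual axial oscillation rate is only ``eta k (1 - cos theta_max)``,
two orders of magnitude slower at low NA.  This makes them excellent targets
for polynomial approximation: we evaluate ``h_c`` and its mixed derivatives

    S(c, m, n, j, l; k) = d^(m+n) h_c / d rho^m d z^n  at  (rho_j, z_l)

once, by analytic differentiation under the integral sign, on a sparse grid
of *source points* ``(rho_j, z_l)``, and reconstruct the field anywhere via
the truncated Taylor series about the nearest source point.

Derivatives under the integral:

* each axial derivative multiplies the integrand by ``i eta k (cos th - 1)``;
* each radial derivative multiplies by ``eta k sin th`` and raises the Bessel
  derivative order, expanded with
  ``J_c^(m)(x) = 2^-m sum_i (-1)^i C(m,i) J_{c-m+2i}(x)``
  (negative orders via ``J_-n = (-1)^n J_n``).

A second, short Taylor series in the *axial displacement* delta reuses the
same array S to re-evaluate the field of axially displaced scatterers at
negligible cost, which is what makes simulated elastography load series
cheap: ``h(rho0, z0 + delta) ~= sum_n0 delta^n0/n0! * d^n0 h / d z^n0`` where
each derivative is itself Taylor-reconstructed from S (requiring ``D_z0``
extra stored axial orders to keep all reconstructed derivatives at full
polynomial degree).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from math import comb

import numpy as np
from scipy.special import jn

from .optics_core import OpticalSystem

__all__ = [
    "SourceGrid",
    "DerivativeArray",
    "build_source_grid",
    "compute_derivative_array",
    "h_derivative_direct",
    "taylor_h",
    "axial_derivative_fast",
    "displaced_h",
    "field_x_fast",
    "choose_Dz0",
]


class DomainError(ValueError):
    """Requested point lies outside the region covered by the source grid."""


@dataclass(frozen=True)
class SourceGrid:
    """Sparse grid of source points covering [0, rho_max] x [z_min, z_max].

    Source points sit at cell centres: ``rho_j = (j + 1/2) s_rho`` and
    ``z_l = z_min + (l + 1/2) s_z``, so no point of the covered domain is
    farther than half a spacing from its nearest source coordinate.
    ``d_rho``/``d_z`` are the highest stored radial/axial Taylor orders and
    ``d_z0`` the additional axial orders reserved for the displacement series.
    """

    rho_sources: np.ndarray
    z_sources: np.ndarray
    s_rho: float
    s_z: float
    d_rho: int
    d_z: int
    d_z0: int = 0

    @property
    def n_rho(self) -> int:
        return self.rho_sources.size

    @property
    def n_z(self) -> int:
        return self.z_sources.size

    @property
    def n_axial_orders(self) -> int:
        """Stored axial orders: 0 .. d_z + d_z0."""
        return self.d_z + self.d_z0 + 1

    def n_total(self, nk: int) -> int:
        """Number of stored quadratures per field component,
        (D_rho+1)(D_z+1) N_rho N_z N_k (displacement orders excluded)."""
        return (self.d_rho + 1) * (self.d_z + 1) * self.n_rho * self.n_z * nk

    def nearest(self, rho, z):
        """Indices of the nearest source point (ties toward the lower index)."""
        rho = np.asarray(rho, float)
        z = np.asarray(z, float)
        # nearest by absolute distance; np.argmin returns the first (lower)
        # index on exact ties, which is the documented tie-break
        j0 = np.argmin(np.abs(rho[..., None] - self.rho_sources), axis=-1)
        l0 = np.argmin(np.abs(z[..., None] - self.z_sources), axis=-1)
        return j0, l0

    def covers(self, rho, z, slack: float = 1e-9) -> np.ndarray:
        lo_r, hi_r = 0.0, self.rho_sources[-1] + 0.5 * self.s_rho
        lo_z = self.z_sources[0] - 0.5 * self.s_z
        hi_z = self.z_sources[-1] + 0.5 * self.s_z
        return ((np.asarray(rho) >= lo_r - slack) & (np.asarray(rho) <= hi_r + slack)
                & (np.asarray(z) >= lo_z - slack) & (np.asarray(z) <= hi_z + slack))


def build_source_grid(rho_max: float, z_max: float, s_rho: float, s_z: float,
                      d_rho: int = 20, d_z: int = 8, d_z0: int = 0,
                      z_min: float = 0.0) -> SourceGrid:
    """Construct the minimal cell-centred source grid covering the domain.

    ``N_rho = ceil(rho_max / s_rho)`` and ``N_z = ceil((z_max - z_min) / s_z)``
    source coordinates are placed at cell centres so that the maximum offset
    from any covered point to its nearest source is half a spacing per axis.
    """
    if rho_max <= 0 or z_max <= z_min:
        raise ValueError("extents must be positive")
    if s_rho <= 0 or s_z <= 0:
        raise ValueError("spacings must be positive")
    n_rho = int(np.ceil(rho_max / s_rho - 1e-12))
    n_z = int(np.ceil((z_max - z_min) / s_z - 1e-12))
    rho_sources = (np.arange(n_rho) + 0.5) * s_rho
    z_sources = z_min + (np.arange(n_z) + 0.5) * s_z
    return SourceGrid(rho_sources, z_sources, s_rho, s_z, d_rho, d_z, d_z0)


@dataclass
class DerivativeArray:
    """Mixed derivatives of (h0, h2) at the source points.

    ``S`` has shape ``(2, d_rho+1, d_z+d_z0+1, N_rho, N_z, K)`` with the
    leading axis indexing the J0- and J2-kernel components of the x field.
    """

    S: np.ndarray
    grid: SourceGrid
    k_list: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.S.view(float))):
            raise FloatingPointError("derivative array contains non-finite entries")

    # -- persistence -------------------------------------------------------
    def save(self, path, config_meta: dict | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            d = f.create_dataset("S", data=self.S)
            d.attrs["axes"] = "component(J0,J2), d/drho order, d/dz order, rho_source, z_source, k"
            f.create_dataset("rho_sources", data=self.grid.rho_sources)
            f.create_dataset("z_sources", data=self.grid.z_sources)
            f.create_dataset("k_list", data=self.k_list)
            f.attrs["s_rho"] = self.grid.s_rho
            f.attrs["s_z"] = self.grid.s_z
            f.attrs["d_rho"] = self.grid.d_rho
            f.attrs["d_z"] = self.grid.d_z
            f.attrs["d_z0"] = self.grid.d_z0
            if config_meta:
                f.attrs["config"] = json.dumps(config_meta, sort_keys=True)

    @classmethod
    def load(cls, path) -> "DerivativeArray":
        import h5py

        with h5py.File(path, "r") as f:
            grid = SourceGrid(
                f["rho_sources"][:], f["z_sources"][:],
                float(f.attrs["s_rho"]), float(f.attrs["s_z"]),
                int(f.attrs["d_rho"]), int(f.attrs["d_z"]), int(f.attrs["d_z0"]),
            )
            return cls(f["S"][:], grid, f["k_list"][:])


def _bessel_derivative_weights(c: int, m: int):
    """Orders and signed weights of J_c^(m) = 2^-m sum_i (-1)^i C(m,i) J_{c-m+2i},
    folded to nonnegative orders via J_{-n} = (-1)^n J_n."""
    out: dict[int, float] = {}
    for i in range(m + 1):
        order = c - m + 2 * i
        wgt = (0.5**m) * ((-1) ** i) * comb(m, i)
        if order < 0:
            wgt *= (-1) ** (-order)
            order = -order
        out[order] = out.get(order, 0.0) + wgt
    return out


def compute_derivative_array(grid: SourceGrid, sys: OpticalSystem, k_list,
                             n_nodes: int = 200) -> DerivativeArray:
    """Evaluate S(c, m, n, j, l; k) by quadrature of the differentiated kernel.

    ``k_list`` is either the full wavenumber grid or the anchor subset used
    by the multi-spectral regression.  Factorials are *not* folded into S;
    they are applied as scaled offset powers at evaluation time, which keeps
    every stored quadrature finite at high order.
    """
    k = np.atleast_1d(np.asarray(k_list, float))
    x_leg, w_leg = np.polynomial.legendre.leggauss(n_nodes)
    theta = 0.5 * sys.theta_max * (x_leg + 1.0)
    w = 0.5 * sys.theta_max * w_leg
    st, ct = np.sin(theta), np.cos(theta)
    eta = sys.eta

    apod = np.exp(-((k[:, None] * sys.w_um) ** 2) * st**2)           # (K, Q)
    g = {0: ct * st * (1.0 + ct), 2: ct * st * (ct - 1.0)}            # (Q,)

    # axial phase and derivative factors at every source z:   (n, l, K, Q)
    base_ax = 1j * eta * k[:, None] * (ct - 1.0)                      # (K, Q)
    phase_ax = np.exp(base_ax[None, :, :] * grid.z_sources[:, None, None])  # (l, K, Q)
    n_orders = grid.n_axial_orders
    axial = np.empty((n_orders, grid.n_z, k.size, theta.size), complex)
    axial[0] = phase_ax
    for n in range(1, n_orders):
        axial[n] = axial[n - 1] * base_ax[None]

    # Bessel table J_p(eta k rho_j sin th) for p = 0 .. d_rho + 2   (p, j, K, Q)
    arg = eta * k[None, :, None] * grid.rho_sources[:, None, None] * st  # (j, K, Q)
    p_max = grid.d_rho + 2
    jtab = np.empty((p_max + 1, grid.n_rho, k.size, theta.size))
    for p in range(p_max + 1):
        jtab[p] = jn(p, arg)

    radial_scale = eta * k[None, :, None] * st                        # (1, K, Q) broadcast

    S = np.empty((2, grid.d_rho + 1, n_orders, grid.n_rho, grid.n_z, k.size),
                 complex)
    for ci, c in enumerate((0, 2)):
        for m in range(grid.d_rho + 1):
            jm = np.zeros_like(jtab[0])
            for order, wgt in _bessel_derivative_weights(c, m).items():
                jm += wgt * jtab[order]
            # radial part of the differentiated kernel, weights folded in (j,K,Q)
            rad = (radial_scale**m) * jm * apod[None] * (w * g[c])[None, None, :]
            S[ci, m] = np.einsum("jkq,nlkq->njlk", rad, axial)
    arr = DerivativeArray(S, grid, k)
    return arr


def h_derivative_direct(rho: float, z: float, k, sys: OpticalSystem,
                        m: int = 0, n: int = 0, n_nodes: int = 200):
    """Direct quadrature of d^(m+n) h_c / d rho^m d z^n at an arbitrary point.

    Returns ``(h0_deriv, h2_deriv)`` arrays over k.  Shares the analytic
    differentiation rules with :func:`compute_derivative_array` but evaluates
    at a single free point; used for source-free spot checks.
    """
    k = np.atleast_1d(np.asarray(k, float))
    x_leg, w_leg = np.polynomial.legendre.leggauss(n_nodes)
    theta = 0.5 * sys.theta_max * (x_leg + 1.0)
    w = 0.5 * sys.theta_max * w_leg
    st, ct = np.sin(theta), np.cos(theta)
    eta = sys.eta
    apod = np.exp(-((k[:, None] * sys.w_um) ** 2) * st**2)
    base_ax = 1j * eta * k[:, None] * (ct - 1.0)
    axial = np.exp(base_ax * z) * base_ax**n
    arg = eta * k[:, None] * rho * st
    scale = (eta * k[:, None] * st) ** m
    out = []
    for c in (0, 2):
        gc = ct * st * ((1.0 + ct) if c == 0 else (ct - 1.0))
        jm = np.zeros_like(arg)
        for order, wgt in _bessel_derivative_weights(c, m).items():
            jm += wgt * jn(order, arg)
        out.append(np.sum(w * gc * apod * axial * scale * jm, axis=-1))
    return out[0], out[1]


def _offsets(arr: DerivativeArray, rho, z):
    rho = np.atleast_1d(np.asarray(rho, float))
    z = np.atleast_1d(np.asarray(z, float))
    grid = arr.grid
    ok = grid.covers(rho, z)
    if not np.all(ok):
        bad = np.argwhere(~ok)[0]
        raise DomainError(
            f"point (rho={rho[tuple(bad)]:.3f}, z={z[tuple(bad)]:.3f}) µm lies "
            "outside the source-grid domain; rebuild the grid to cover it "
            "(no silent extrapolation)")
    j0, l0 = grid.nearest(rho, z)
    drho = rho - grid.rho_sources[j0]
    dz = z - grid.z_sources[l0]
    return j0, l0, drho, dz


def _horner_eval(S_cell: np.ndarray, drho, dz, d_rho: int, d_z: int,
                 n_shift: int = 0):
    """Factorial-scaled Horner evaluation of the double Taylor sum.

    ``S_cell`` has shape (2, d_rho+1, n_orders, K); ``drho``/``dz`` shape (P,).
    Returns (2, P, K).  Evaluates
    sum_m drho^m/m! sum_n dz^n/n! S[:, m, n + n_shift] with Horner recursion
    in n inside m (the spec of the stored array keeps factorials out of S).
    """
    drho = drho[None, :, None]
    dz = dz[None, :, None]
    P = dz.shape[1]
    K = S_cell.shape[-1]
    outer = np.zeros((2, P, K), complex)
    for m in range(d_rho, -1, -1):
        inner = np.broadcast_to(S_cell[:, m, d_z + n_shift][:, None, :],
                                (2, P, K)).copy()
        for n in range(d_z - 1, -1, -1):
            inner *= dz / (n + 1.0)
            inner += S_cell[:, m, n + n_shift][:, None, :]
        if m == d_rho:
            outer = inner
        else:
            outer *= drho / (m + 1.0)
            outer += inner
    return outer


def taylor_h(rho, z, arr: DerivativeArray):
    """Taylor-reconstructed (h0, h2) at points (rho, z) for every stored k.

    Expansion about the nearest source point, radial order d_rho, axial order
    d_z (the extra d_z0 orders are reserved for the displacement series and
    not consumed here).  Returns two (P, K) arrays.
    """
    return axial_derivative_fast(rho, z, 0, arr)


def axial_derivative_fast(rho, z, n0: int, arr: DerivativeArray):
    """n0-th axial derivative of the Taylor-reconstructed h, via index shift.

    Differentiating the Taylor polynomial in z simply shifts the axial index
    of S: the reconstruction uses S[:, m, n + n0] with the same scaled offset
    powers.  Requires ``n0 <= d_z0`` so that all consumed orders are stored.
    """
    grid = arr.grid
    if n0 < 0:
        raise ValueError("derivative order must be >= 0")
    if grid.d_z + n0 > grid.d_z + grid.d_z0:
        raise ValueError(
            f"axial derivative order {n0} exceeds the stored displacement "
            f"orders d_z0={grid.d_z0}; rebuild the derivative array")
    rho1 = np.atleast_1d(np.asarray(rho, float))
    z1 = np.atleast_1d(np.asarray(z, float))
    j0, l0, drho, dz = _offsets(arr, rho1, z1)
    K = arr.S.shape[-1]
    out0 = np.empty((rho1.size, K), complex)
    out2 = np.empty_like(out0)
    cell_id = j0 * grid.n_z + l0
    for cid in np.unique(cell_id):
        sel = cell_id == cid
        jj, ll = divmod(int(cid), grid.n_z)
        vals = _horner_eval(arr.S[:, :, :, jj, ll, :], drho[sel], dz[sel],
                            grid.d_rho, grid.d_z, n_shift=n0)
        out0[sel] = vals[0]
        out2[sel] = vals[1]
    return out0, out2


def displaced_h(rho, z, delta, arr: DerivativeArray, d_z0: int | None = None):
    """(h0, h2) at the axially displaced points (rho, z + delta).

    Second Taylor expansion, centred on each undisplaced point, of order
    ``d_z0`` (default: all stored displacement orders); each axial derivative
    is itself reconstructed from S via :func:`axial_derivative_fast`.  Note
    the *field* at the displaced position also needs the factored phase at
    ``z + delta`` -- see :func:`field_x_fast`.
    """
    grid = arr.grid
    if d_z0 is None:
        d_z0 = grid.d_z0
    if d_z0 > grid.d_z0:
        raise ValueError(f"d_z0={d_z0} exceeds stored displacement orders {grid.d_z0}")
    rho1 = np.atleast_1d(np.asarray(rho, float))
    delta1 = np.broadcast_to(np.atleast_1d(np.asarray(delta, float)), rho1.shape)
    out0, out2 = taylor_h(rho1, z, arr)
    fact = 1.0
    pow_d = np.ones_like(delta1)
    for n0 in range(1, d_z0 + 1):
        pow_d = pow_d * delta1
        fact *= n0
        d0, d2 = axial_derivative_fast(rho1, z, n0, arr)
        out0 += (pow_d / fact)[:, None] * d0
        out2 += (pow_d / fact)[:, None] * d2
    return out0, out2


def field_x_fast(rho, psi, z, arr: DerivativeArray, sys: OpticalSystem,
                 delta=None, d_z0: int | None = None) -> np.ndarray:
    """Fast x component of the focal field at (rho, psi, z [+ delta]).

    ``Ex = -i f k exp(i eta k (z + delta)) (h0 + cos(2 psi) h2)`` with the h
    pair Taylor-reconstructed (and displacement-expanded when ``delta`` is
    given).  The psi dependence lives entirely outside the Taylor machinery.
    Returns (P, K) over the k list the derivative array was built with.
    """
    rho1 = np.atleast_1d(np.asarray(rho, float))
    psi1 = np.broadcast_to(np.atleast_1d(np.asarray(psi, float)), rho1.shape)
    z1 = np.broadcast_to(np.atleast_1d(np.asarray(z, float)), rho1.shape)
    if delta is None:
        h0, h2 = taylor_h(rho1, z1, arr)
        z_eff = z1
    else:
        delta1 = np.broadcast_to(np.atleast_1d(np.asarray(delta, float)), rho1.shape)
        h0, h2 = displaced_h(rho1, z1, delta1, arr, d_z0)
        z_eff = z1 + delta1
    k = arr.k_list
    phase = np.exp(1j * sys.eta * k[None, :] * z_eff[:, None])
    pref = -1j * sys.f_um * k[None, :]
    return pref * phase * (h0 + np.cos(2.0 * psi1)[:, None] * h2)


def choose_Dz0(max_displacement_um: float) -> int:
    """Displacement-series order for a declared maximum axial displacement.

    ``D_z0 = ceil(0.15 * Ms)`` with Ms in µm keeps the displacement-series
    truncation below the package's integral-error budget; 0 for Ms = 0.
    """
    if max_displacement_um < 0:
        raise ValueError("maximum displacement must be >= 0")
    return int(np.ceil(0.15 * max_displacement_um))
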