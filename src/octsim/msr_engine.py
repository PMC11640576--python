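"""Multi-spectral regression: full-spectrum fields from a few anchor k's.

Every pupil integrand the simulator encounters has the parametric form
``d(s) exp(-a(s)^2 k^2) exp(i b(s) k)`` with ``a``/``b`` geometry-dependent
but k-independent.  If coefficient functions ``C_j(k)`` can be found with

    exp(-alpha^2 k^2) exp(i beta k)
        ~= sum_j C_j(k) exp(-alpha^2 k_j^2) exp(i beta k_j)

for all alpha in the pupil's apodization range and all |beta| <= B, then the
same combination reconstructs the *field* at any k from the fields at the L
anchor wavenumbers -- the k-dependence of the simulation collapses from Nk
direct quadratures to L.  The admissible phase-argument bound B follows from
the scan geometry:

    B = rho_max * NA + z_max * NA^2 / eta + eta * D / 2

(lateral phase + defocus phase + half a depth band, all in µm).  Substituting
the anchor reconstruction into the sample modal coefficient and grouping
scatterers into depth bands of thickness D (band centre z_h, per-scatterer
shift Delta = z_h - z_s) turns alpha_scat(k) into a band sum over *cross-modal
coefficients*, second moments of the anchor fields per band:

    alpha_scat(k) ~= sum_h exp(2 i eta k z_h) sum_{j1 j2}
        (k^2/(k_j1 k_j2)) C_j1(k) C_j2(k) exp(-i eta (k_j1+k_j2) z_h)
        alpha_cross(j1, j2, h)

    alpha_cross(j1, j2, h) = sum_{s in band h} rho_s Ex(P_s;k_j1) Ex(P_s;k_j2)

whose cost is independent of Nk and, per band, quadratic only in L.

The coefficient fit is a linear least-squares problem: the residual of the
training identity is linear in C_j(k), so each k decouples into an ordinary
complex least-squares solve over a training grid in (alpha, beta) -- solved
here by SVD-based ``lstsq`` (deterministic; one factorization covers all k
because only the right-hand side depends on k).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .optics_core import OpticalSystem, ScattererSet

__all__ = [
    "MSRModel",
    "compute_bound_B",
    "fit_msr",
    "reconstruct_field",
    "assign_bands",
    "band_centers_for",
    "cross_modal_table",
    "assemble_alpha_scat",
]


def compute_bound_B(rho_max: float, z_max: float, na: float, eta: float,
                    d_band: float, defocus_half: bool = False) -> float:
    """Phase-argument bound B (µm) for the coefficient fit.

    ``B = rho_max*NA + z_max*NA^2/eta + eta*D/2``.  With
    ``defocus_half=True`` the defocus term is halved (the small-angle
    expansion of ``z(1 - cos theta_max)`` suggests an extra factor 1/2); the
    default keeps the more conservative full term.
    """
    defocus = z_max * na * na / eta
    if defocus_half:
        defocus *= 0.5
    return rho_max * na + defocus + eta * d_band / 2.0


@dataclass
class MSRModel:
    """Fitted multi-spectral regression model.

    Attributes
    ----------
    k_anchors : the L anchor wavenumbers (rad/µm), uniform incl. endpoints.
    k_grid : the Nk reconstruction wavenumbers.
    C : complex coefficient table of shape (L, Nk).
    B : phase-argument bound used in training (µm).
    d_band : depth-band thickness D (µm).
    training_report : held-out residual statistics of the fit.
    """

    k_anchors: np.ndarray
    k_grid: np.ndarray
    C: np.ndarray
    B: float
    d_band: float
    alpha_max: float
    training_report: dict = field(default_factory=dict)

    @property
    def L(self) -> int:
        return self.k_anchors.size

    def save(self, path, config_meta: dict | None = None) -> None:
        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("k_anchors", data=self.k_anchors)
            f.create_dataset("k_grid", data=self.k_grid)
            f.create_dataset("C", data=self.C)
            f.attrs["B"] = self.B
            f.attrs["d_band"] = self.d_band
            f.attrs["alpha_max"] = self.alpha_max
            f.attrs["training_report"] = json.dumps(self.training_report)
            if config_meta:
                f.attrs["config"] = json.dumps(config_meta, sort_keys=True)

    @classmethod
    def load(cls, path) -> "MSRModel":
        import h5py

        with h5py.File(path, "r") as f:
            return cls(
                f["k_anchors"][:], f["k_grid"][:], f["C"][:],
                float(f.attrs["B"]), float(f.attrs["d_band"]),
                float(f.attrs["alpha_max"]),
                json.loads(f.attrs["training_report"]),
            )


def _design_matrix(k_anchors, alphas, betas):
    """Rows: training points (alpha, beta); columns: anchors."""
    ea = np.exp(-np.square(alphas)[:, None] * np.square(k_anchors)[None, :])
    eb = np.exp(1j * betas[:, None] * k_anchors[None, :])
    return (ea[:, None, :] * eb[None, :, :]).reshape(-1, k_anchors.size)


def _targets(k_grid, alphas, betas):
    ea = np.exp(-np.square(alphas)[:, None] * np.square(k_grid)[None, :])
    eb = np.exp(1j * betas[:, None] * k_grid[None, :])
    return (ea[:, None, :] * eb[None, :, :]).reshape(-1, k_grid.size)


def fit_msr(sys: OpticalSystem, L: int, B: float, d_band: float,
            alpha_max: float | None = None,
            n_alpha: int = 32, n_beta: int = 129,
            residual_warn: float = 1e-3) -> MSRModel:
    """Fit the coefficient functions C_j(k) by per-k linear least squares.

    Anchors are L wavenumbers uniform over the spectrum including both
    endpoints.  The training grid samples alpha on ``n_alpha`` points in
    [0, alpha_max] (default alpha_max = W*NA/eta, the physical apodization
    range of the pupil) and beta on ``n_beta`` uniform points in [-B, B];
    the target is evaluated on the full k grid.  A denser held-out grid
    provides max/mean residuals in ``training_report``; residuals above
    ``residual_warn`` emit a warning but the model is still returned.
    """
    import warnings

    if L < 2:
        raise ValueError("L must be >= 2")
    if B <= 0:
        raise ValueError("B must be positive")
    k_grid = sys.k_grid
    k_anchors = np.linspace(sys.k_min, sys.k_max, L)
    if alpha_max is None:
        alpha_max = sys.w_um * sys.na / sys.eta

    alphas = np.linspace(0.0, alpha_max, n_alpha)
    betas = np.linspace(-B, B, n_beta)
    M = _design_matrix(k_anchors, alphas, betas)
    T = _targets(k_grid, alphas, betas)
    C, *_ = scipy.linalg.lstsq(M, T, lapack_driver="gelsd")

    # held-out residuals on a denser grid
    a_h = np.linspace(0.0, alpha_max, 2 * n_alpha + 1)
    b_h = np.linspace(-B, B, 2 * n_beta + 1)
    Mh = _design_matrix(k_anchors, a_h, b_h)
    Th = _targets(k_grid, a_h, b_h)
    R = Mh @ C - Th
    resid_max = float(np.max(np.abs(R)))
    resid_mean = float(np.mean(np.abs(R)))
    report = {
        "heldout_max_residual": resid_max,
        "heldout_mean_residual": resid_mean,
        "train_points": int(M.shape[0]),
        "heldout_points": int(Mh.shape[0]),
        "n_alpha": n_alpha, "n_beta": n_beta,
    }
    if resid_max > residual_warn:
        warnings.warn(
            f"MSR held-out max residual {resid_max:.2e} exceeds {residual_warn:g}; "
            "consider increasing L or reducing B", stacklevel=2)
    return MSRModel(k_anchors, k_grid, C, float(B), float(d_band),
                    float(alpha_max), report)


def reconstruct_field(e_at_anchors: np.ndarray, k, z, delta,
                      model: MSRModel, sys: OpticalSystem) -> np.ndarray:
    """Monochromatic field at arbitrary k from its values at the L anchors.

    ``E(r,z;k) ~= sum_j (k/k_j) C_j(k) exp(i eta (k-k_j)(z+Delta)) E(r,z;k_j)``
    where ``z`` is the focus-relative axial coordinate of the point and
    ``Delta`` any shift keeping the residual pupil phase within [-B, B]
    (the result is approximately Delta-independent in that range).

    ``e_at_anchors`` has shape (..., L); ``k`` scalar or (K,).  Returns
    shape (..., K).
    """
    k = np.atleast_1d(np.asarray(k, float))
    if np.any(k < model.k_grid[0] - 1e-9) or np.any(k > model.k_grid[-1] + 1e-9):
        raise ValueError("k outside the fitted spectrum")
    Ck = _coeffs_at(model, k)  # (L, K)
    kj = model.k_anchors
    phase = np.exp(1j * sys.eta * (k[None, :] - kj[:, None]) * (z + delta))  # (L, K)
    weights = (k[None, :] / kj[:, None]) * Ck * phase
    return np.tensordot(e_at_anchors, weights, axes=([-1], [0]))


def _coeffs_at(model: MSRModel, k: np.ndarray) -> np.ndarray:
    """C_j(k) at arbitrary k: stored table on the fitted grid, fresh
    least-squares solve (same training grid) for wavenumbers off it."""
    kg = model.k_grid
    if k.size == kg.size and np.allclose(k, kg, rtol=0, atol=1e-12):
        return model.C
    on_grid = np.isclose(k[:, None], kg[None, :], rtol=0, atol=1e-12)
    out = np.empty((model.L, k.size), complex)
    hits = on_grid.any(axis=1)
    if np.any(hits):
        out[:, hits] = model.C[:, np.argmax(on_grid[hits], axis=1)]
    if np.any(~hits):
        rep = model.training_report
        alphas = np.linspace(0.0, model.alpha_max, int(rep.get("n_alpha", 32)))
        betas = np.linspace(-model.B, model.B, int(rep.get("n_beta", 129)))
        M = _design_matrix(model.k_anchors, alphas, betas)
        T = _targets(k[~hits], alphas, betas)
        C_off, *_ = scipy.linalg.lstsq(M, T, lapack_driver="gelsd")
        out[:, ~hits] = C_off
    return out


# ---------------------------------------------------------------------------
# Depth banding and cross-modal assembly
# ---------------------------------------------------------------------------

def band_centers_for(z_min: float, z_max: float, d_band: float) -> np.ndarray:
    """Band centres z_h = z_min + (h - 1/2) D covering [z_min, z_max]."""
    n_bands = max(1, int(np.ceil((z_max - z_min) / d_band - 1e-12)))
    return z_min + (np.arange(n_bands) + 0.5) * d_band


def assign_bands(z: np.ndarray, centers: np.ndarray, d_band: float) -> np.ndarray:
    """Band index per depth; |z - z_h| <= D/2, boundaries to the lower band."""
    z = np.asarray(z, float)
    z_min = centers[0] - 0.5 * d_band
    # ceil((z - z_min)/D) - 1 assigns exact boundaries to the lower band
    idx = np.ceil((z - z_min) / d_band - 1e-12).astype(int) - 1
    idx = np.clip(idx, 0, centers.size - 1)
    out_of = (z < z_min - 1e-9) | (z > centers[-1] + 0.5 * d_band + 1e-9)
    if np.any(out_of):
        raise ValueError(
            f"{int(np.sum(out_of))} scatterer depth(s) fall outside every "
            "depth band; extend the banding range")
    return idx


def cross_modal_table(e_anchors: np.ndarray, rho_s: np.ndarray,
                      band_idx: np.ndarray, n_bands: int) -> np.ndarray:
    """alpha_cross(j1, j2, h) = sum_{s in band h} rho_s E_s(k_j1) E_s(k_j2).

    ``e_anchors`` has shape (Ns, L).  Returns (L, L, n_bands), exactly
    symmetric in (j1, j2); empty bands are zero.
    """
    ns, L = e_anchors.shape
    out = np.zeros((L, L, n_bands), complex)
    for h in range(n_bands):
        sel = band_idx == h
        if not np.any(sel):
            continue
        e = e_anchors[sel]
        t = np.einsum("s,sj,sl->jl", rho_s[sel], e, e)
        # enforce exact (bitwise) symmetry against summation-order rounding
        out[:, :, h] = np.triu(t) + np.triu(t, 1).T
    return out


def assemble_alpha_scat(alpha_cross: np.ndarray, centers_dwi: np.ndarray,
                        model: MSRModel, sys: OpticalSystem,
                        k=None) -> np.ndarray:
    """Full-spectrum sample modal coefficient from the cross-modal table.

    ``centers_dwi`` are the band centres in the same (focus-relative) axial
    coordinate the anchor fields were evaluated in.  Returns alpha_scat on
    ``k`` (default: the model's full k grid).
    """
    if k is None:
        k = model.k_grid
    k = np.atleast_1d(np.asarray(k, float))
    Ck = _coeffs_at(model, k)                      # (L, K)
    kj = model.k_anchors
    eta = sys.eta
    W = (k[None, :] / kj[:, None]) * Ck            # (L, K)
    out = np.zeros(k.size, complex)
    for h, zh in enumerate(centers_dwi):
        P = alpha_cross[:, :, h]
        if not np.any(P):
            continue
        # e^{2 i eta k zh} (W e^{-i eta kj zh})^T P (W e^{-i eta kj zh})
        ph = np.exp(-1j * eta * kj[:, None] * zh) * W          # (L, K)
        out += np.exp(2j * eta * k * zh) * np.einsum("jk,jl,lk->k", ph, P, ph)
    return out
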