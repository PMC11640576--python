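"""Interferogram formation and A-/B-/C-scan assembly over field backends.

The spectral-domain detector records, per wavenumber,

    I(k) = | alpha_scat(k) + alpha_mirr(k) |^2

and the depth profile is the inverse Fourier transform of the spectrum over
k evaluated at the round-trip argument 2z.  On the uniform k grid this is a
plain inverse FFT with depth pixel ``dz = pi / (eta * dk * N_fft)``: a
scatterer at geometric depth z (optical path difference 2 eta (z - z_mirr))
lands at the bin nearest z - z_mirr.  By default the self-beat backgrounds
|alpha_scat|^2 and |alpha_mirr|^2 are removed before the transform, keeping
the depth-encoding cross term; ``background="complex"`` instead transforms
``alpha_scat * conj(alpha_mirr)`` directly, giving the one-sided complex
(phase-sensitive) A-scan, and ``background="raw"`` transforms I(k) untouched.

Three interchangeable field backends feed the same detection path:

* ``RigorousBackend``   -- direct Debye-Wolf quadrature per scatterer and k;
* ``TaylorBackend``     -- Taylor source-grid reconstruction at every k;
* ``TaylorMSRBackend``  -- Taylor reconstruction at L anchor wavenumbers plus
  multi-spectral regression band assembly (the recommended fast path, cost
  essentially independent of Nk), with optional displacement series for
  cheap elastography load sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import dwi_reference, msr_engine, taylor_engine
from .optics_core import (ApproximationParams, OpticalSystem, ScanGeometry,
                          ScattererSet)

__all__ = [
    "Interferogram",
    "AScan",
    "CScan",
    "make_interferogram",
    "make_ascan",
    "RigorousBackend",
    "TaylorBackend",
    "TaylorMSRBackend",
    "make_backend",
    "simulate_ascan",
    "simulate_cscan",
    "simulate_loaded_series",
]


@dataclass
class Interferogram:
    """Detected spectrum on the uniform k grid, with optional components."""

    k_grid: np.ndarray
    intensity: np.ndarray
    alpha_scat: np.ndarray | None = None
    alpha_mirr: np.ndarray | None = None


@dataclass
class AScan:
    """Depth-resolved complex amplitude at one lateral position."""

    z_axis: np.ndarray
    amplitude: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class CScan:
    """Volume of A-scans over the lateral scan grid, shape (nx, ny, nz)."""

    x_um: np.ndarray
    y_um: np.ndarray
    z_axis: np.ndarray
    data: np.ndarray
    meta: dict = field(default_factory=dict)

    def magnitude_normalized(self) -> np.ndarray:
        mag = np.abs(self.data)
        peak = mag.max()
        return mag / peak if peak > 0 else mag

    def save(self, path) -> None:
        import json

        import h5py

        with h5py.File(path, "w") as f:
            f.create_dataset("ascans", data=self.data)
            f.create_dataset("x_um", data=self.x_um)
            f.create_dataset("y_um", data=self.y_um)
            f.create_dataset("z_axis_um", data=self.z_axis)
            f.attrs["config"] = json.dumps(
                {k: v for k, v in self.meta.items() if isinstance(v, (int, float, str))},
                sort_keys=True)

    @classmethod
    def load(cls, path) -> "CScan":
        import json

        import h5py

        with h5py.File(path, "r") as f:
            meta = json.loads(f.attrs.get("config", "{}"))
            return cls(f["x_um"][:], f["y_um"][:], f["z_axis_um"][:],
                       f["ascans"][:], meta)


def make_interferogram(alpha_scat: np.ndarray, alpha_mirr: np.ndarray,
                       k_grid: np.ndarray) -> Interferogram:
    """Pointwise detected intensity |alpha_scat + alpha_mirr|^2."""
    alpha_scat = np.asarray(alpha_scat)
    alpha_mirr = np.asarray(alpha_mirr)
    if alpha_scat.shape != alpha_mirr.shape or alpha_scat.shape != np.shape(k_grid):
        raise ValueError("alpha_scat, alpha_mirr and k_grid must share one shape")
    intensity = np.abs(alpha_scat + alpha_mirr) ** 2
    return Interferogram(np.asarray(k_grid, float), intensity,
                         alpha_scat, alpha_mirr)


def make_ascan(ig: Interferogram, eta: float = 1.0,
               background: str = "subtract", window: str = "rect",
               pad_factor: int = 1) -> AScan:
    """Inverse-FFT depth profile of an interferogram.

    background:
      ``"subtract"`` (default) removes |alpha_scat|^2 + |alpha_mirr|^2,
      keeping the real cross term 2 Re(alpha_scat conj(alpha_mirr));
      ``"complex"`` transforms alpha_scat * conj(alpha_mirr) (one-sided
      phase-sensitive A-scan); ``"raw"`` transforms I(k) as detected.
    window: ``"rect"`` (none) or ``"hann"``.
    """
    k = ig.k_grid
    dk = np.diff(k)
    if k.size < 2 or not np.allclose(dk, dk[0], rtol=1e-9, atol=0):
        raise ValueError("A-scan reconstruction requires a uniform k grid")
    if background == "raw":
        spec = ig.intensity.astype(complex)
    elif background in ("subtract", "complex"):
        if ig.alpha_scat is None or ig.alpha_mirr is None:
            raise ValueError(f"background={background!r} needs stored components")
        cross = ig.alpha_scat * np.conj(ig.alpha_mirr)
        spec = 2.0 * cross.real if background == "subtract" else cross
        spec = spec.astype(complex)
    else:
        raise ValueError(f"unknown background mode {background!r}")
    if window == "hann":
        spec = spec * np.hanning(spec.size)
    elif window != "rect":
        raise ValueError(f"unknown window {window!r}")
    n_fft = int(pad_factor) * spec.size
    # sign convention: the cross term carries exp(+2i eta k (z_s - z_mirr)),
    # so the exp(-2 pi i p i / N) kernel maps positive depth to ascending bins
    amp = np.fft.fft(spec, n=n_fft) / n_fft
    dz = np.pi / (eta * dk[0] * n_fft)
    z_axis = np.arange(n_fft) * dz
    return AScan(z_axis, amp, {
        "depth_pixel_um": dz, "pad_factor": int(pad_factor),
        "background": background, "window": window, "nk": spec.size // int(pad_factor),
        "depth_origin": "mirror plane (zero optical path difference)",
    })


# ---------------------------------------------------------------------------
# Field backends
# ---------------------------------------------------------------------------

class BackendNotPrepared(RuntimeError):
    pass


class RigorousBackend:
    """Direct Debye-Wolf quadrature for every scatterer and wavenumber."""

    name = "rigorous"

    def __init__(self, sys: OpticalSystem, scan: ScanGeometry,
                 n_nodes: int = dwi_reference.DEFAULT_NODES):
        self.sys = sys
        self.scan = scan
        self.n_nodes = n_nodes

    def alpha_scat(self, sample: ScattererSet, x_beam: float, y_beam: float,
                   delta=None) -> np.ndarray:
        sample_eff = sample if delta is None else sample.with_z(sample.z + delta)
        return dwi_reference.scat_modal_coefficient_rigorous(
            sample_eff, self.sys.k_grid, self.sys, x_beam, y_beam,
            self.scan.rho_max_um, self.n_nodes)


class _TaylorBase:
    def __init__(self, sys: OpticalSystem, scan: ScanGeometry, z_max_um: float,
                 approx: ApproximationParams, n_nodes: int = 200,
                 z_margin_um: float = 0.0):
        self.sys = sys
        self.scan = scan
        self.z_max_um = float(z_max_um)
        self.approx = approx
        self.n_nodes = n_nodes
        # source grid in focus-relative axial coordinates
        self.grid = taylor_engine.build_source_grid(
            scan.rho_max_um,
            z_max_um - sys.zf_um + z_margin_um,
            approx.s_rho_um, approx.s_z_um,
            d_rho=approx.d_rho, d_z=approx.d_z, d_z0=approx.d_z0,
            z_min=-sys.zf_um - z_margin_um,
        )
        self.deriv: taylor_engine.DerivativeArray | None = None

    def _require(self):
        if self.deriv is None:
            raise BackendNotPrepared(
                "derivative array not built; call prepare() (CLI: run the "
                "`fit-grid` step, or `simulate` which prepares on demand)")


class TaylorBackend(_TaylorBase):
    """Taylor source-grid reconstruction of the field at every wavenumber."""

    name = "taylor"

    def prepare(self) -> "TaylorBackend":
        self.deriv = taylor_engine.compute_derivative_array(
            self.grid, self.sys, self.sys.k_grid, self.n_nodes)
        return self

    def alpha_scat(self, sample: ScattererSet, x_beam: float, y_beam: float,
                   delta=None) -> np.ndarray:
        self._require()
        rho, psi, z, w = sample.beam_frame(x_beam, y_beam, self.sys.zf_um,
                                           self.scan.rho_max_um)
        if rho.size == 0:
            return np.zeros(self.sys.nk, complex)
        d = None if delta is None else _mask_like(delta, sample, x_beam, y_beam,
                                                  self.sys, self.scan)
        ex = taylor_engine.field_x_fast(rho, psi, z, self.deriv, self.sys, d)
        return np.einsum("p,pk->k", w, ex * ex)


class TaylorMSRBackend(_TaylorBase):
    """Taylor anchors + multi-spectral regression band assembly (fast path)."""

    name = "taylor+msr"

    def __init__(self, sys: OpticalSystem, scan: ScanGeometry, z_max_um: float,
                 approx: ApproximationParams, n_nodes: int = 200,
                 z_margin_um: float = 0.0, msr_model: msr_engine.MSRModel | None = None):
        super().__init__(sys, scan, z_max_um, approx, n_nodes, z_margin_um)
        self.msr = msr_model

    def prepare(self) -> "TaylorMSRBackend":
        if self.msr is None:
            B = msr_engine.compute_bound_B(
                self.scan.rho_max_um, self.z_max_um, self.sys.na, self.sys.eta,
                self.approx.msr_d_um)
            self.msr = msr_engine.fit_msr(self.sys, self.approx.msr_l, B,
                                          self.approx.msr_d_um)
        self.deriv = taylor_engine.compute_derivative_array(
            self.grid, self.sys, self.msr.k_anchors, self.n_nodes)
        return self

    def alpha_scat(self, sample: ScattererSet, x_beam: float, y_beam: float,
                   delta=None) -> np.ndarray:
        self._require()
        if self.msr is None:
            raise BackendNotPrepared("MSR model missing; call prepare() "
                                     "(CLI: the `fit-msr` step)")
        rho, psi, z, w = sample.beam_frame(x_beam, y_beam, self.sys.zf_um,
                                           self.scan.rho_max_um)
        if rho.size == 0:
            return np.zeros(self.sys.nk, complex)
        d = None if delta is None else _mask_like(delta, sample, x_beam, y_beam,
                                                  self.sys, self.scan)
        e_anchors = taylor_engine.field_x_fast(rho, psi, z, self.deriv,
                                               self.sys, d)          # (P, L)
        z_disp = z + (0.0 if d is None else d)                        # focus-relative
        centers = msr_engine.band_centers_for(-self.sys.zf_um,
                                              self.z_max_um - self.sys.zf_um,
                                              self.msr.d_band)
        band_idx = msr_engine.assign_bands(z_disp, centers, self.msr.d_band)
        table = msr_engine.cross_modal_table(e_anchors, w, band_idx, centers.size)
        return msr_engine.assemble_alpha_scat(table, centers, self.msr, self.sys)


def _mask_like(delta, sample: ScattererSet, x_beam, y_beam, sys, scan):
    """Restrict a per-scatterer displacement vector to the beam-frame subset."""
    delta = np.asarray(delta, float)
    if delta.ndim == 0:
        return float(delta)
    rho = np.hypot(sample.x - x_beam, sample.y - y_beam)
    return delta[rho <= scan.rho_max_um]


def make_backend(name: str, sys: OpticalSystem, scan: ScanGeometry,
                 z_max_um: float, approx: ApproximationParams | None = None,
                 prepare: bool = True, **kw):
    """Factory: ``rigorous``, ``taylor`` or ``taylor+msr``."""
    if name == "rigorous":
        return RigorousBackend(sys, scan, **kw)
    approx = approx or ApproximationParams()
    cls = {"taylor": TaylorBackend, "taylor+msr": TaylorMSRBackend}.get(name)
    if cls is None:
        raise ValueError(f"unknown backend {name!r}")
    backend = cls(sys, scan, z_max_um, approx, **kw)
    return backend.prepare() if prepare else backend


# ---------------------------------------------------------------------------
# Scan drivers
# ---------------------------------------------------------------------------

def simulate_ascan(sample: ScattererSet, sys: OpticalSystem, backend,
                   x_beam: float = 0.0, y_beam: float = 0.0,
                   alpha_mirr: np.ndarray | None = None, delta=None,
                   background: str = "subtract", window: str = "rect",
                   pad_factor: int = 1) -> AScan:
    """One A-scan at a given beam position using the chosen backend."""
    if alpha_mirr is None:
        alpha_mirr = dwi_reference.mirror_modal_coefficient(sys.k_grid, sys)
    a_scat = backend.alpha_scat(sample, x_beam, y_beam, delta)
    ig = make_interferogram(a_scat, alpha_mirr, sys.k_grid)
    scan = make_ascan(ig, sys.eta, background, window, pad_factor)
    scan.meta.update({"x_um": x_beam, "y_um": y_beam, "backend": backend.name})
    return scan


def simulate_cscan(sample: ScattererSet, scan: ScanGeometry, sys: OpticalSystem,
                   backend, delta=None, background: str = "subtract",
                   window: str = "rect", pad_factor: int = 1,
                   mirror_nodes: int | None = None) -> CScan:
    """C-scan over the lateral grid; the mirror coefficient is shared.

    For each lateral position scatterers are translated into the beam frame,
    those beyond the radial cutoff dropped, alpha_scat computed with the
    selected backend and the A-scan reconstructed.
    """
    alpha_mirr = dwi_reference.mirror_modal_coefficient(
        sys.k_grid, sys, mirror_nodes or dwi_reference.DEFAULT_NODES)
    nx, ny = scan.x_um.size, scan.y_um.size
    data = None
    z_axis = None
    for ix, xb in enumerate(scan.x_um):
        for iy, yb in enumerate(scan.y_um):
            a = simulate_ascan(sample, sys, backend, xb, yb, alpha_mirr,
                               delta, background, window, pad_factor)
            if data is None:
                z_axis = a.z_axis
                data = np.empty((nx, ny, z_axis.size), complex)
            data[ix, iy] = a.amplitude
    return CScan(scan.x_um.copy(), scan.y_um.copy(), z_axis, data, {
        "backend": backend.name, "background": background, "window": window,
        "pad_factor": int(pad_factor), "nk": int(sys.nk),
    })


def simulate_loaded_series(sample: ScattererSet, displacements,
                           scan: ScanGeometry, sys: OpticalSystem, backend,
                           max_displacement_um: float | None = None,
                           **ascan_kw) -> list[CScan]:
    """Series of C-scans of one sample under per-step axial displacements.

    ``displacements`` is an iterable of per-scatterer axial displacement
    vectors (µm), one per load step; step 0 (the unloaded state) is always
    simulated first.  Every |displacement| must stay within the declared
    ``max_displacement_um`` the backend's displacement series was sized for
    (``choose_Dz0``); violating the contract raises.
    """
    displacements = [np.zeros(sample.n)] + [np.asarray(d, float) for d in displacements]
    if max_displacement_um is None:
        grid = getattr(backend, "grid", None)
        if grid is not None:
            max_displacement_um = grid.d_z0 / 0.15 if grid.d_z0 else 0.0
    for d in displacements[1:]:
        if d.shape != (sample.n,):
            raise ValueError("each displacement field must have one entry per scatterer")
        if max_displacement_um is not None and np.any(np.abs(d) > max_displacement_um + 1e-9):
            raise ValueError(
                f"displacement exceeds the declared maximum {max_displacement_um} µm "
                "the displacement series was built for")
    out = []
    for step, d in enumerate(displacements):
        delta = None if step == 0 else d
        c = simulate_cscan(sample, scan, sys, backend, delta=delta, **ascan_kw)
        c.meta["load_step"] = step
        out.append(c)
    return out
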