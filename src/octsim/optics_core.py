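"""Domain types, units and configuration validation for the OCT simulator.

Conventions used throughout the package
---------------------------------------
* Lengths are micrometres (µm) internally; wavenumbers are rad/µm.
  Config files carry explicit unit suffixes in the key names
  (``lambda_min_nm``, ``z_max_um``, ``z_max_mm`` ...).
* Coordinates are right handed; ``z`` increases into the sample, ``z = 0``
  is the sample surface.  The focal field is always evaluated at the
  focus-relative depth ``z - zf`` (the focus is set by translating the
  axial coordinate handed to the Debye-Wolf integral).
* Lateral scanning is implemented by translating scatterer ``(x, y)``
  coordinates into the beam frame, which is equivalent to translating
  the beam.
* The spectrum is sampled uniformly in wavenumber ``k`` (not wavelength),
  because the A-scan is the inverse Fourier transform of the
  interferogram over ``k``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "MirrorSpec",
    "OpticalSystem",
    "ScanGeometry",
    "ScattererSet",
    "CylindricalPoint",
    "ApproximationParams",
    "nyquist_min_nk",
    "validate_config",
    "ConfigError",
    "read_config",
    "write_config",
    "config_to_dict",
    "config_from_dict",
]

TWO_PI = 2.0 * np.pi


class ConfigError(ValueError):
    """Raised when a configuration violates a physical or sampling invariant."""


@dataclass(frozen=True)
class MirrorSpec:
    """Reference-arm mirror: an ideal plane reflector sampled on a uniform grid.

    The reference modal coefficient is a Riemann sum of the squared incident
    field over an ``n_points`` x ``n_points`` grid at the plane ``z = z_um``
    with per-cell area ``delta_n_um2``.  When ``half_width_um`` is None a
    default of four beam waist radii at the mirror plane is used, which makes
    the grid-truncation error of the sum negligible at low NA.
    """

    z_um: float = 0.0
    reflectivity: float = 1.0
    n_points: int = 129
    half_width_um: float | None = None

    @property
    def delta_n_um2(self) -> float:
        if self.half_width_um is None:
            raise ValueError("half_width_um not resolved; use resolved_mirror()")
        step = 2.0 * self.half_width_um / (self.n_points - 1)
        return step * step


@dataclass(frozen=True)
class OpticalSystem:
    """Interferometer description: objective, spectrum, focus and mirror.

    Parameters
    ----------
    na : numerical aperture of the objective (dimensionless, < eta).
    eta : refractive index of the focal region.
    f_um : focal length of the objective (µm).  It scales the field
        amplitude linearly and cancels from every normalized output.
    w_um : Gaussian apodization length W (µm); the pupil profile is
        ``exp(-(k W)^2 sin^2 theta)`` and the focal amplitude falls off as
        ``exp(-eta^2 rho^2 / 4 W^2)``.  The default 5.5 µm reproduces the
        ~13 µm FWHM lateral resolution of the 1300 nm spectral-domain
        instrument class this simulator's default spectrum models.
    lambda_min_nm, lambda_max_nm : spectral edges (nm, vacuum).
    nk : number of wavenumber samples, uniform in k.
    zf_um : focal-plane depth below the sample surface (µm).
    mirror : reference-arm mirror specification.
    """

    na: float
    lambda_min_nm: float
    lambda_max_nm: float
    nk: int
    eta: float = 1.0
    f_um: float = 1.0e4
    w_um: float = 5.5
    zf_um: float = 0.0
    mirror: MirrorSpec = field(default_factory=MirrorSpec)

    def __post_init__(self) -> None:
        if not (0.0 < self.na < self.eta):
            raise ConfigError(
                f"numerical aperture must satisfy 0 < NA < eta; got "
                f"NA={self.na}, eta={self.eta} (NA >= eta would require "
                "evanescent aperture components)"
            )
        if not (self.lambda_min_nm < self.lambda_max_nm):
            raise ConfigError("lambda_min_nm must be < lambda_max_nm")
        if self.nk < 2:
            raise ConfigError("nk must be >= 2 to form a spectrum")
        if self.w_um <= 0:
            raise ConfigError("w_um must be positive")
        if self.f_um <= 0:
            raise ConfigError("f_um must be positive")

    # -- spectral grid ----------------------------------------------------
    @property
    def k_min(self) -> float:
        """Smallest wavenumber, 2*pi/lambda_max (rad/µm)."""
        return TWO_PI / (self.lambda_max_nm * 1e-3)

    @property
    def k_max(self) -> float:
        return TWO_PI / (self.lambda_min_nm * 1e-3)

    @property
    def k_center(self) -> float:
        return 0.5 * (self.k_min + self.k_max)

    @property
    def k_grid(self) -> np.ndarray:
        """Uniform wavenumber grid between 2*pi/lambda_max and 2*pi/lambda_min."""
        return np.linspace(self.k_min, self.k_max, self.nk)

    @property
    def theta_max(self) -> float:
        """Aperture half-angle arcsin(NA/eta) (rad)."""
        return float(np.arcsin(self.na / self.eta))

    def beam_waist_um(self) -> float:
        """Gaussian-estimate beam waist radius at focus (µm), used only to
        size default evaluation grids (mirror extent); not an accuracy surface."""
        lam_c = 2.0 * TWO_PI / (self.k_min + self.k_max)  # 2pi/k_center
        return max(lam_c / (np.pi * self.na), 2.0 * self.w_um / self.eta)

    def resolved_mirror(self) -> MirrorSpec:
        """Mirror spec with the default half-width filled in (4 beam waists
        at the mirror plane, accounting for defocus)."""
        m = self.mirror
        if m.half_width_um is not None:
            return m
        w0 = self.beam_waist_um()
        lam_c = 2.0 * TWO_PI / (self.k_min + self.k_max)
        z_r = np.pi * w0 * w0 * self.eta / lam_c
        dz = m.z_um - self.zf_um
        w_at = w0 * np.sqrt(1.0 + (dz / z_r) ** 2)
        return replace(m, half_width_um=4.0 * float(w_at))


@dataclass(frozen=True)
class ScanGeometry:
    """Lateral beam positions and the radial cutoff for scatterer inclusion.

    Scatterers farther than ``rho_max_um`` from the beam axis contribute
    negligibly to the focal field at low NA and are excluded from each A-scan.
    """

    x_um: np.ndarray
    y_um: np.ndarray
    rho_max_um: float = 70.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "x_um", np.atleast_1d(np.asarray(self.x_um, float)))
        object.__setattr__(self, "y_um", np.atleast_1d(np.asarray(self.y_um, float)))
        if self.rho_max_um <= 0:
            raise ConfigError("rho_max_um must be positive")
        if not (np.all(np.isfinite(self.x_um)) and np.all(np.isfinite(self.y_um))):
            raise ConfigError("scan positions must be finite")

    @property
    def n_ascans(self) -> int:
        return self.x_um.size * self.y_um.size


@dataclass(frozen=True)
class CylindricalPoint:
    """A point in beam-centred cylindrical coordinates (z relative to focus)."""

    rho: float
    psi: float
    z: float

    def __post_init__(self) -> None:
        if self.rho < 0:
            raise ValueError("rho must be >= 0")


class ScattererSet:
    """Positions and cross-sections of discrete dipole scatterers.

    Each scatterer radiates as a harmonically oscillating dipole driven by
    the incident field (first-order Born approximation) with a nonnegative
    cross-section weight ``rho_s``.
    """

    __slots__ = ("x", "y", "z", "rho_s")

    def __init__(self, x, y, z, rho_s=None):
        self.x = np.atleast_1d(np.asarray(x, float))
        self.y = np.atleast_1d(np.asarray(y, float))
        self.z = np.atleast_1d(np.asarray(z, float))
        if rho_s is None:
            rho_s = np.ones_like(self.x)
        self.rho_s = np.atleast_1d(np.asarray(rho_s, float))
        n = self.x.size
        if not (self.y.size == n and self.z.size == n and self.rho_s.size == n):
            raise ValueError("x, y, z, rho_s must have equal length")
        if np.any(self.rho_s < 0):
            raise ValueError("all scattering cross-sections rho_s must be >= 0")

    @property
    def n(self) -> int:
        return self.x.size

    def __len__(self) -> int:
        return self.n

    def translated(self, dx: float = 0.0, dy: float = 0.0, dz: float = 0.0) -> "ScattererSet":
        return ScattererSet(self.x + dx, self.y + dy, self.z + dz, self.rho_s)

    def with_z(self, z: np.ndarray) -> "ScattererSet":
        return ScattererSet(self.x, self.y, np.asarray(z, float), self.rho_s)

    def subset(self, mask) -> "ScattererSet":
        return ScattererSet(self.x[mask], self.y[mask], self.z[mask], self.rho_s[mask])

    # -- beam-frame view ---------------------------------------------------
    def beam_frame(self, x_beam: float, y_beam: float, zf_um: float,
                   rho_max_um: float | None = None):
        """Cylindrical coordinates relative to a beam axis and focus.

        Returns ``(rho, psi, z_dwi, rho_s)`` arrays, optionally restricted to
        ``rho <= rho_max_um``.
        """
        dx = self.x - x_beam
        dy = self.y - y_beam
        rho = np.hypot(dx, dy)
        psi = np.arctan2(dy, dx)
        z_dwi = self.z - zf_um
        w = self.rho_s
        if rho_max_um is not None:
            m = rho <= rho_max_um
            return rho[m], psi[m], z_dwi[m], w[m]
        return rho, psi, z_dwi, w

    # -- I/O ----------------------------------------------------------------
    COLUMNS = ("x_um", "y_um", "z_um", "rho_s")

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"x_um": self.x, "y_um": self.y, "z_um": self.z, "rho_s": self.rho_s}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ScattererSet":
        df = pd.read_csv(path)
        missing = [c for c in cls.COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"scatterer table missing required columns: {missing}")
        return cls(df["x_um"].values, df["y_um"].values, df["z_um"].values,
                   df["rho_s"].values)

    def __eq__(self, other) -> bool:
        if not isinstance(other, ScattererSet):
            return NotImplemented
        return (np.array_equal(self.x, other.x) and np.array_equal(self.y, other.y)
                and np.array_equal(self.z, other.z)
                and np.array_equal(self.rho_s, other.rho_s))


@dataclass(frozen=True)
class ApproximationParams:
    """Orders and spacings of the fast-evaluation machinery.

    ``d_rho``/``d_z`` are the highest radial/axial Taylor orders retained,
    ``s_rho_um``/``s_z_um`` the source-grid spacings, ``d_z0`` the extra
    axial orders reserved for the displacement series, ``msr_l`` the number
    of anchor wavenumbers and ``msr_d_um`` the depth-band thickness of the
    multi-spectral regression.  The defaults are the recommended operating
    point (error below the 3e-4 integral-error budget for the reference
    low-NA configuration).
    """

    d_rho: int = 20
    d_z: int = 8
    s_rho_um: float = 28.0
    s_z_um: float = 190.0
    d_z0: int = 0
    msr_l: int = 35
    msr_d_um: float = 15.0

    def __post_init__(self) -> None:
        if min(self.d_rho, self.d_z, self.d_z0) < 0:
            raise ConfigError("Taylor orders must be >= 0")
        if self.s_rho_um <= 0 or self.s_z_um <= 0:
            raise ConfigError("source-grid spacings must be positive")
        if self.msr_l < 2:
            raise ConfigError("msr_l must be >= 2")
        if self.msr_d_um <= 0:
            raise ConfigError("msr_d_um must be positive")


def nyquist_min_nk(z_max_um: float, sys: OpticalSystem) -> int:
    """Minimum number of wavenumber samples resolving depth ``z_max_um``.

    The interferometric fringe of the deepest scatterer oscillates as
    ``exp(2i eta k z_max)``; sampling it at >= 2 samples per period over the
    spectral span requires ``Nk >= 2 eta z_max (k_max - k_min) / pi``.
    """
    return int(np.ceil(2.0 * sys.eta * z_max_um * (sys.k_max - sys.k_min) / np.pi))


def validate_config(sys: OpticalSystem, scan: ScanGeometry, z_max_um: float,
                    approx: ApproximationParams | None = None,
                    allow_sub_nyquist: bool = False):
    """Cross-field validation of a full simulation configuration.

    Raises :class:`ConfigError` on violation; returns the inputs unchanged
    (dataclass ``__post_init__`` already guarantees per-object invariants).
    """
    if z_max_um <= 0:
        raise ConfigError("z_max_um must be positive")
    n_min = nyquist_min_nk(z_max_um, sys)
    if sys.nk < n_min and not allow_sub_nyquist:
        raise ConfigError(
            f"nk={sys.nk} is below the Nyquist bound for z_max={z_max_um} µm: "
            f"at least nk={n_min} wavenumber samples are required to avoid "
            "depth aliasing (pass allow_sub_nyquist=True to override)"
        )
    return sys, scan, z_max_um, approx


# ---------------------------------------------------------------------------
# Flat key-value configuration files
# ---------------------------------------------------------------------------

_MM = 1.0e3  # mm -> µm


def config_to_dict(sys: OpticalSystem, scan: ScanGeometry, z_max_um: float,
                   approx: ApproximationParams | None = None) -> dict:
    """Flatten a configuration to documented key-value pairs (units in keys)."""
    m = sys.mirror
    d = {
        "na": sys.na,
        "eta": sys.eta,
        "f_um": sys.f_um,
        "w_um": sys.w_um,
        "lambda_min_nm": sys.lambda_min_nm,
        "lambda_max_nm": sys.lambda_max_nm,
        "nk": sys.nk,
        "zf_um": sys.zf_um,
        "z_max_um": z_max_um,
        "rho_max_um": scan.rho_max_um,
        "x_scan_um": ",".join(repr(float(v)) for v in scan.x_um),
        "y_scan_um": ",".join(repr(float(v)) for v in scan.y_um),
        "mirror_z_um": m.z_um,
        "mirror_reflectivity": m.reflectivity,
        "mirror_n_points": m.n_points,
    }
    if m.half_width_um is not None:
        d["mirror_half_width_um"] = m.half_width_um
    if approx is not None:
        d.update({
            "d_rho": approx.d_rho, "d_z": approx.d_z, "d_z0": approx.d_z0,
            "s_rho_um": approx.s_rho_um, "s_z_um": approx.s_z_um,
            "msr_l": approx.msr_l, "msr_d_um": approx.msr_d_um,
        })
    return d


def config_from_dict(d: Mapping) -> tuple[OpticalSystem, ScanGeometry, float,
                                          ApproximationParams | None]:
    d = dict(d)

    def length(base: str, default=None):
        # accept <base>_um or <base>_mm
        if f"{base}_um" in d:
            return float(d[f"{base}_um"])
        if f"{base}_mm" in d:
            return float(d[f"{base}_mm"]) * _MM
        if default is not None:
            return default
        raise ConfigError(f"missing required key {base}_um (or {base}_mm)")

    def floats(key):
        v = d[key]
        if isinstance(v, str):
            return np.array([float(t) for t in v.split(",") if t.strip()])
        return np.atleast_1d(np.asarray(v, float))

    mirror = MirrorSpec(
        z_um=length("mirror_z", 0.0),
        reflectivity=float(d.get("mirror_reflectivity", 1.0)),
        n_points=int(d.get("mirror_n_points", 129)),
        half_width_um=(float(d["mirror_half_width_um"])
                       if "mirror_half_width_um" in d else None),
    )
    sys = OpticalSystem(
        na=float(d["na"]),
        eta=float(d.get("eta", 1.0)),
        f_um=length("f", 1.0e4),
        w_um=length("w", 5.5),
        lambda_min_nm=float(d["lambda_min_nm"]),
        lambda_max_nm=float(d["lambda_max_nm"]),
        nk=int(d["nk"]),
        zf_um=length("zf", 0.0),
        mirror=mirror,
    )
    scan = ScanGeometry(
        x_um=floats("x_scan_um") if "x_scan_um" in d else np.array([0.0]),
        y_um=floats("y_scan_um") if "y_scan_um" in d else np.array([0.0]),
        rho_max_um=length("rho_max", 70.0),
    )
    z_max_um = length("z_max")
    approx = None
    if "d_rho" in d:
        approx = ApproximationParams(
            d_rho=int(d["d_rho"]), d_z=int(d["d_z"]), d_z0=int(d.get("d_z0", 0)),
            s_rho_um=length("s_rho", 28.0), s_z_um=length("s_z", 190.0),
            msr_l=int(d.get("msr_l", 35)), msr_d_um=length("msr_d", 15.0),
        )
    return sys, scan, z_max_um, approx


def write_config(path, sys: OpticalSystem, scan: ScanGeometry, z_max_um: float,
                 approx: ApproximationParams | None = None) -> None:
    lines = [f"{k} = {v}" for k, v in config_to_dict(sys, scan, z_max_um, approx).items()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_config(path):
    """Parse a flat ``key = value`` configuration file and validate it."""
    raw: dict[str, str] = {}
    for ln in Path(path).read_text().splitlines():
        ln = ln.split("#", 1)[0].strip()
        if not ln:
            continue
        if "=" not in ln:
            raise ConfigError(f"malformed config line: {ln!r}")
        key, val = (t.strip() for t in ln.split("=", 1))
        raw[key] = val
    return config_from_dict(raw)
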