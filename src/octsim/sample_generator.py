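"""Synthetic scatterer phantoms and axial displacement fields.

Generates the standard test objects for the simulator: uniform random
scatterer clouds at a speckle-forming density, heterogeneous-reflectivity
regions (e.g. a marked block with boosted cross-section), uniform axial
strain, and a stiff elliptic-cylinder inclusion with piecewise-constant
strain.  Sign convention: negative strain is compression and displaces
scatterers toward the surface (z = 0); a uniform strain ``eps`` maps
``z -> z (1 + eps)``, and a depth-varying strain field is integrated from
the surface downward, ``dz(z) = int_0^z eps(x, y, zeta) d zeta``, which
keeps the displacement continuous across internal boundaries along each
A-line and reduces exactly to the uniform map when the field is constant.
Displacements are axial only; laterally consistent 3-D deformation belongs
to an external mechanical model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .optics_core import ScattererSet

__all__ = [
    "DEFAULT_DENSITY_UM3",
    "PhantomSpec",
    "EllipticInclusion",
    "generate_uniform_phantom",
    "apply_uniform_strain",
    "apply_inclusion_strain",
    "inclusion_displacement",
    "max_axial_displacement",
    "strain_series_steps",
]

# Reference speckle density: 312500 scatterers in a 200 x 200 x 1000 µm^3
# volume, enough for fully developed speckle at the reference resolution.
DEFAULT_DENSITY_UM3 = 312500 / (200.0 * 200.0 * 1000.0)

MAX_STRAIN = 0.05  # |strain| bound; the small-displacement model breaks above


@dataclass(frozen=True)
class EllipticInclusion:
    """Elliptic-cylinder inclusion, axis along y, with its own strain.

    The cross-section in the (x, z) plane is the ellipse centred at
    ``(x0_um, z0_um)`` with semi-axes ``ax_um`` (x) and ``az_um`` (z); it
    extends through the full y range.  ``strain_in`` applies inside,
    ``strain_out`` outside (dimensionless; -1e-3 is -1 millistrain).
    """

    x0_um: float
    z0_um: float
    ax_um: float
    az_um: float
    strain_in: float
    strain_out: float

    def __post_init__(self):
        if self.ax_um <= 0 or self.az_um <= 0:
            raise ValueError("inclusion semi-axes must be positive")
        for s in (self.strain_in, self.strain_out):
            if abs(s) > MAX_STRAIN:
                raise ValueError(f"|strain| must be <= {MAX_STRAIN}")

    def inside(self, x, z):
        return (((np.asarray(x) - self.x0_um) / self.ax_um) ** 2
                + ((np.asarray(z) - self.z0_um) / self.az_um) ** 2) <= 1.0

    # z interval cut by the cylinder on the vertical line through x
    def z_span(self, x):
        x = np.asarray(x, float)
        t = 1.0 - ((x - self.x0_um) / self.ax_um) ** 2
        half = self.az_um * np.sqrt(np.clip(t, 0.0, None))
        return self.z0_um - half, self.z0_um + half, t > 0


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of a uniform random phantom.

    Either ``n_scatterers`` or ``density_um3`` fixes the count (count wins
    if both are given).  ``rho_s_profile`` may be a constant, a callable
    ``f(z) -> weight`` emulating depth attenuation, or None (constant 1).
    """

    x_extent_um: float
    y_extent_um: float
    z_extent_um: float
    n_scatterers: int | None = None
    density_um3: float | None = None
    seed: int = 0
    rho_s_profile: object = None

    def count(self) -> int:
        if self.n_scatterers is not None:
            return int(self.n_scatterers)
        dens = DEFAULT_DENSITY_UM3 if self.density_um3 is None else self.density_um3
        return int(round(dens * self.x_extent_um * self.y_extent_um * self.z_extent_um))


def generate_uniform_phantom(spec: PhantomSpec) -> ScattererSet:
    """I.i.d. uniform scatterer cloud in the box, deterministic per seed.

    x and y are centred on the optical axis (range ±extent/2); z spans
    [0, z_extent].
    """
    if min(spec.x_extent_um, spec.y_extent_um, spec.z_extent_um) <= 0:
        raise ValueError("phantom volume extents must be positive")
    n = spec.count()
    rng = np.random.default_rng(spec.seed)
    x = rng.uniform(-spec.x_extent_um / 2, spec.x_extent_um / 2, n)
    y = rng.uniform(-spec.y_extent_um / 2, spec.y_extent_um / 2, n)
    z = rng.uniform(0.0, spec.z_extent_um, n)
    prof = spec.rho_s_profile
    if prof is None:
        w = np.ones(n)
    elif callable(prof):
        w = np.asarray(prof(z), float) * np.ones(n)
    else:
        w = float(prof) * np.ones(n)
    return ScattererSet(x, y, z, w)


def apply_uniform_strain(scat: ScattererSet, strain: float) -> ScattererSet:
    """Uniform axial strain: z -> z (1 + strain); x, y, rho_s unchanged."""
    if abs(strain) > MAX_STRAIN:
        raise ValueError(f"|strain| must be <= {MAX_STRAIN}")
    return scat.with_z(scat.z * (1.0 + strain))


def inclusion_displacement(x, z, inc: EllipticInclusion) -> np.ndarray:
    """Axial displacement of the piecewise-constant inclusion strain field.

    Integrates the strain from the surface down along each A-line:
    slope ``strain_out`` above and below the inclusion, ``strain_in``
    across it, continuous at the boundaries.
    """
    x = np.asarray(x, float)
    z = np.asarray(z, float)
    z_lo, z_hi, cut = inc.z_span(x)
    # path lengths through each strain region from the surface to depth z
    in_len = np.clip(np.minimum(z, z_hi) - z_lo, 0.0, None) * cut
    out_len = z - in_len
    return inc.strain_out * out_len + inc.strain_in * in_len


def apply_inclusion_strain(scat: ScattererSet, inc: EllipticInclusion) -> ScattererSet:
    """Displace scatterers by the inclusion strain field (axial only)."""
    dz = inclusion_displacement(scat.x, scat.z, inc)
    return scat.with_z(scat.z + dz)


def max_axial_displacement(*states: ScattererSet) -> float:
    """Maximum per-scatterer axial excursion across sample states (µm).

    For each scatterer the spread max_d z - min_d z over all supplied
    states; the maximum over scatterers sizes the displacement series.
    """
    if len(states) < 2:
        return 0.0
    zs = np.stack([s.z for s in states])
    return float(np.max(zs.max(axis=0) - zs.min(axis=0)))


def strain_series_steps(max_millistrain: float, step_millistrain: float) -> np.ndarray:
    """Uniform strain schedule (in strain units) from one step up to the max."""
    n = int(round(max_millistrain / step_millistrain))
    return (np.arange(1, n + 1) * step_millistrain) * 1e-3
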