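"""Analytic electromagnetic model of an MRI bore as a circular waveguide.

The bore is treated as an air-filled circular waveguide with perfectly
conducting walls and partially reflective end planes.  A point-dipole tone
source excites a truncated set of TE/TM modes; each mode propagates (or
decays evanescently) away from the source plane and reflects at both ends,
so above the dominant-mode cutoff the model produces the standing-wave
patterns that make microwave-frequency pilot tones motion sensitive, while
below cutoff the field decays monotonically with axial distance from the
transmitter.

Coordinates are cylindrical (rho, phi, z) with z along the bore axis and
the origin at the axial center; SI units throughout (meters, Hz, radians).
Field vectors are returned in Cartesian components (Hx, Hy, Hz) so they dot
directly with coil normals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
from scipy import special
from scipy.constants import c as C_LIGHT, epsilon_0

__all__ = [
    "ModeFamily",
    "WaveguideMode",
    "BoreModel",
    "SourceSpec",
    "CoilSurface",
    "FieldSample",
    "FluxSeries",
    "mode_cutoff",
    "propagation_constant",
    "field_at_points",
    "coil_flux",
    "surface_flux",
    "sweep_coil_positions",
    "isotropic_power_density",
]


class ModeFamily(str, Enum):
    TE = "TE"
    TM = "TM"


def _bessel_root(family: ModeFamily, n: int, m: int) -> float:
    """m-th positive root of J_n' (TE) or J_n (TM)."""
    if not (isinstance(n, (int, np.integer)) and isinstance(m, (int, np.integer))):
        raise ValueError("mode indices must be integers")
    if n < 0:
        raise ValueError(f"azimuthal index must be >= 0, got {n}")
    if m < 1:
        raise ValueError(f"radial index must be >= 1, got {m}")
    if family == ModeFamily.TE:
        return float(special.jnp_zeros(n, m)[m - 1])
    return float(special.jn_zeros(n, m)[m - 1])


def mode_cutoff(family: ModeFamily | str, azimuthal_index: int, radial_index: int,
                radius: float) -> float:
    """Cutoff frequency (Hz) of a circular-waveguide mode.

    ``p * c / (2 pi radius)`` where ``p`` is the radial_index-th positive
    root of J_n' for TE modes or of J_n for TM modes.  The dominant TE11
    mode of a 0.35 m radius bore cuts off near 251 MHz, which is why a
    127.8 MHz pilot tone decays evanescently while a 2.4 GHz tone fills the
    bore with standing waves.
    """
    family = ModeFamily(family)
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    p = _bessel_root(family, azimuthal_index, radial_index)
    return p * C_LIGHT / (2.0 * math.pi * radius)


@dataclass(frozen=True)
class WaveguideMode:
    """One TE/TM mode of a circular waveguide of a given radius."""

    family: ModeFamily
    azimuthal_index: int
    radial_index: int
    radius: float
    root: float = field(init=False)
    cutoff_frequency: float = field(init=False)

    def __post_init__(self) -> None:
        fam = ModeFamily(self.family)
        object.__setattr__(self, "family", fam)
        p = _bessel_root(fam, self.azimuthal_index, self.radial_index)
        object.__setattr__(self, "root", p)
        object.__setattr__(
            self, "cutoff_frequency", p * C_LIGHT / (2.0 * math.pi * self.radius)
        )

    @property
    def kc(self) -> float:
        """Cutoff (transverse) wavenumber, rad/m."""
        return self.root / self.radius

    @property
    def label(self) -> str:
        return f"{self.family.value}{self.azimuthal_index}{self.radial_index}"


def propagation_constant(mode: WaveguideMode, frequency: float) -> complex:
    """Axial wavenumber ``kz`` such that a forward wave goes as ``exp(-j kz z)``.

    Purely real (propagating) above cutoff, purely imaginary below it with
    decay rate ``alpha = (2 pi / c) sqrt(fc^2 - f^2)`` Np/m, and zero at the
    band edge.
    """
    if frequency <= 0:
        raise ValueError(f"frequency must be positive, got {frequency}")
    k = 2.0 * math.pi * frequency / C_LIGHT
    kc = mode.kc
    if k >= kc:
        return complex(math.sqrt(k * k - kc * kc), 0.0)
    return complex(0.0, -math.sqrt(kc * kc - k * k))


@dataclass
class BoreModel:
    """Bore geometry: radius, length, and complex end-plane reflection.

    Default ``end_reflection = 1`` (fully reflective end planes) guarantees
    standing waves above cutoff.  The walls are assumed perfectly
    conducting (implicit in the modal expansion).
    """

    radius: float = 0.35
    length: float = 1.35
    end_reflection: complex = 1.0 + 0.0j

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError(f"bore radius must be positive, got {self.radius}")
        if self.length <= 0:
            raise ValueError(f"bore length must be positive, got {self.length}")
        if abs(self.end_reflection) > 1.0 + 1e-12:
            raise ValueError("end reflection magnitude must be <= 1")

    def mode_catalog(self, frequency: float, *, factor: float = 1.5,
                     max_modes: int = 50, min_modes: int = 6,
                     max_azimuthal: int = 12,
                     max_radial: int = 12) -> list[WaveguideMode]:
        """Modes with cutoff below ``factor * frequency``, capped at ``max_modes``.

        At least ``min_modes`` lowest-cutoff modes are always returned so
        that sub-cutoff operation still produces an (evanescent) field.
        """
        candidates: list[WaveguideMode] = []
        for fam in (ModeFamily.TE, ModeFamily.TM):
            for n in range(max_azimuthal + 1):
                for m in range(1, max_radial + 1):
                    candidates.append(WaveguideMode(fam, n, m, self.radius))
        candidates.sort(key=lambda md: md.cutoff_frequency)
        kept = [md for md in candidates if md.cutoff_frequency < factor * frequency]
        if len(kept) < min_modes:
            kept = candidates[:min_modes]
        return kept[:max_modes]

    def contains(self, rho: np.ndarray, z: np.ndarray, *, tol: float = 1e-9) -> np.ndarray:
        return (rho <= self.radius + tol) & (np.abs(z) <= self.length / 2 + tol)


@dataclass
class SourceSpec:
    """Point-dipole tone source inside the bore.

    ``position`` is (rho, phi, z); ``orientation`` is a Cartesian unit
    vector the magnetic dipole points along.  ``amplitude`` is in arbitrary
    linear field units; ``power_dbm`` is bookkeeping only.
    """

    position: tuple[float, float, float]
    orientation: tuple[float, float, float] = (1.0, 0.0, 0.0)
    frequency: float = 127.8e6
    amplitude: complex = 1.0 + 0.0j
    power_dbm: float | None = None
    external: bool = False

    def __post_init__(self) -> None:
        if self.frequency <= 0:
            raise ValueError("source frequency must be positive")
        o = np.asarray(self.orientation, dtype=float)
        norm = np.linalg.norm(o)
        if norm == 0:
            raise ValueError("source orientation must be a nonzero vector")
        self.orientation = tuple(o / norm)


@dataclass
class CoilSurface:
    """Rectangular receive-coil surface (default 10 x 14 cm^2, posterior-coil sized)."""

    center: tuple[float, float, float]
    normal: tuple[float, float, float]
    width: float = 0.10
    height: float = 0.14
    coil_id: str = "coil"
    quadrature_points: int = 8

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("coil dimensions must be positive")
        nrm = np.asarray(self.normal, dtype=float)
        norm = np.linalg.norm(nrm)
        if norm == 0:
            raise ValueError("coil normal must be a nonzero vector")
        self.normal = tuple(nrm / norm)

    @property
    def area(self) -> float:
        return self.width * self.height

    def shifted(self, dz: float) -> "CoilSurface":
        rho, phi, z = self.center
        return CoilSurface((rho, phi, z + dz), self.normal, self.width,
                           self.height, self.coil_id, self.quadrature_points)

    def grid(self, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Gauss-Legendre tensor grid on the rectangle -> (points_xyz [N,3], weights [N])."""
        nodes, wts = np.polynomial.legendre.leggauss(n)
        nhat = np.asarray(self.normal)
        ref = np.array([0.0, 0.0, 1.0])
        if abs(np.dot(ref, nhat)) > 1.0 - 1e-9:
            ref = np.array([1.0, 0.0, 0.0])
        u = np.cross(ref, nhat)
        u /= np.linalg.norm(u)
        v = np.cross(nhat, u)
        rho, phi, z = self.center
        c_xyz = np.array([rho * math.cos(phi), rho * math.sin(phi), z])
        uu, vv = np.meshgrid(nodes * self.width / 2, nodes * self.height / 2,
                             indexing="ij")
        pts = (c_xyz[None, :]
               + uu.reshape(-1, 1) * u[None, :]
               + vv.reshape(-1, 1) * v[None, :])
        w2d = np.outer(wts, wts).reshape(-1) * (self.width / 2) * (self.height / 2)
        return pts, w2d


@dataclass
class FieldSample:
    """Complex magnetic field at a set of Cartesian points."""

    points: np.ndarray  # [N, 3] Cartesian
    H: np.ndarray       # [N, 3] complex (Hx, Hy, Hz)


@dataclass
class FluxSeries:
    """Complex coil flux along an ordered axis (positions or times) at one tone."""

    coil_id: str
    frequency: float
    axis: np.ndarray
    flux: np.ndarray
    axis_name: str = "offset_m"

    def __post_init__(self) -> None:
        self.axis = np.asarray(self.axis, dtype=float)
        self.flux = np.asarray(self.flux, dtype=complex)
        if self.axis.shape != self.flux.shape:
            raise ValueError("axis and flux must have equal length")


def _mode_H(mode: WaveguideMode, frequency: float, rho: np.ndarray,
            phi: np.ndarray, direction: int) -> np.ndarray:
    """Cylindrical H components (H_rho, H_phi, H_z) of a traveling mode.

    ``direction`` is +1 (toward +z) or -1; the beta-proportional transverse
    TE components flip sign with direction, which is what makes counter-
    propagating waves interfere into standing patterns.
    """
    kc = mode.kc
    kz = propagation_constant(mode, frequency)
    n = mode.azimuthal_index
    x = kc * rho
    # two Bessel evaluations serve jn, jn' and jn/rho via the standard
    # recurrences: J_n' = J_{n-1} - (n/x) J_n  (n >= 1), J_0' = -J_1
    if n == 0:
        jn = special.jv(0, x)
        jnp = -special.jv(1, x)
    else:
        jnm1 = special.jv(n - 1, x)
        jn = special.jv(n, x)
        with np.errstate(divide="ignore", invalid="ignore"):
            jnp = np.where(x > 0, jnm1 - n * jn / np.where(x > 0, x, 1.0),
                           0.5 if n == 1 else 0.0)
    s = float(direction)
    if n == 0:
        jn_over_rho = np.zeros_like(rho)
    else:
        small = rho < 1e-12
        jn_over_rho = np.where(small, kc / 2.0 if n == 1 else 0.0,
                               jn / np.where(small, 1.0, rho))
    if mode.family == ModeFamily.TE:
        Hz = jn * np.cos(n * phi)
        Hrho = -1j * s * (kz / kc) * jnp * np.cos(n * phi)
        Hphi = 1j * s * (kz * n / kc**2) * jn_over_rho * np.sin(n * phi)
    else:
        omega_eps = 2.0 * math.pi * frequency * epsilon_0
        Hz = np.zeros_like(rho, dtype=complex)
        Hrho = 1j * (omega_eps * n / kc**2) * jn_over_rho * np.sin(n * phi)
        Hphi = -1j * (omega_eps / kc) * jnp * np.cos(n * phi)
    return np.stack([Hrho, Hphi, Hz], axis=-1)


def _cavity_amplitudes(bore: BoreModel, kz: complex,
                       z_src: float) -> tuple[complex, complex, float]:
    """Right/left-going amplitudes at the source plane for a two-ended cavity.

    Solves the multiple-reflection sum in closed form: with ``a = exp(-2j kz
    z0)`` and ``b = exp(-2j kz (L - z0))`` (z0 measured from the -z end),
    ``R0 = (1 + G a)/(1 - G^2 a b)`` and symmetrically for ``L0``.
    """
    L = bore.length
    z0 = z_src + L / 2.0
    G = bore.end_reflection
    a = np.exp(-2j * kz * z0)
    b = np.exp(-2j * kz * (L - z0))
    denom = 1.0 - G * G * a * b
    if abs(denom) < 1e-12:
        # exactly on a lossless cavity resonance; nudge off it numerically
        denom = 1e-12
    R0 = (1.0 + G * a) / denom
    L0 = (1.0 + G * b) / denom
    return complex(R0), complex(L0), z0


def _coupling_coefficients(modes: Sequence[WaveguideMode], source: SourceSpec) -> np.ndarray:
    """Per-mode excitation: mode field at the source projected on its orientation.

    Point-dipole approximation, normalized so the coefficient vector has
    unit norm (total excited power 1 at unit amplitude).  Each n >= 1 mode's
    azimuthal pattern is rotated to the polarization maximally coupled to
    the source azimuth.
    """
    rho_s, phi_s, _ = source.position
    o = np.asarray(source.orientation)
    coeffs = np.empty(len(modes), dtype=complex)
    for i, mode in enumerate(modes):
        # evaluate the +z-traveling pattern at the source point, phi'=0 plane
        Hcyl = _mode_H(mode, source.frequency, np.array([rho_s]),
                       np.array([0.0]), +1)[0]
        cphi, sphi = math.cos(phi_s), math.sin(phi_s)
        Hxyz = np.array([
            Hcyl[0] * cphi - Hcyl[1] * sphi,
            Hcyl[0] * sphi + Hcyl[1] * cphi,
            Hcyl[2],
        ])
        coeffs[i] = np.conj(np.dot(Hxyz, o))
    norm = np.linalg.norm(coeffs)
    if norm > 0:
        coeffs = coeffs / norm
    return coeffs


def field_at_points(bore: BoreModel, source: SourceSpec,
                    mode_set: Sequence[WaveguideMode],
                    points: np.ndarray, *, check_inside: bool = True) -> FieldSample:
    """Truncated modal H field at Cartesian ``points`` [N, 3].

    Each mode propagates from the source plane in both z directions,
    reflects at both end planes with ``bore.end_reflection``, and decays
    evanescently below its cutoff.  Linear in ``source.amplitude``.
    """
    if len(mode_set) == 0:
        raise ValueError("mode_set must be non-empty")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    x, y, z = pts[:, 0], pts[:, 1], pts[:, 2]
    rho = np.hypot(x, y)
    if check_inside and not np.all(bore.contains(rho, z)):
        raise ValueError("field requested at points outside the bore")
    rho_s, phi_s, z_s = source.position
    if not source.external and rho_s > bore.radius + 1e-9:
        raise ValueError("source outside the bore (set external=True to allow)")
    phi = np.arctan2(y, x) - phi_s  # azimuth relative to source polarization
    coeffs = _coupling_coefficients(mode_set, source)

    H_cyl = np.zeros((pts.shape[0], 3), dtype=complex)
    right = z >= z_s
    for mode, cm in zip(mode_set, coeffs):
        if cm == 0:
            continue
        kz = propagation_constant(mode, source.frequency)
        R0, L0, z0 = _cavity_amplitudes(bore, kz, z_s)
        G = bore.end_reflection
        L = bore.length
        zz = z + L / 2.0  # shift to [0, L]
        amp_f = np.zeros(pts.shape[0], dtype=complex)  # +z-going
        amp_b = np.zeros(pts.shape[0], dtype=complex)  # -z-going
        # region z >= z0: direct right-going wave plus its far-end reflection
        amp_f[right] = R0 * np.exp(-1j * kz * (zz[right] - z0))
        amp_b[right] = G * R0 * np.exp(-1j * kz * (2 * L - z0 - zz[right]))
        # region z < z0: direct left-going wave plus its near-end reflection
        amp_b[~right] = L0 * np.exp(-1j * kz * (z0 - zz[~right]))
        amp_f[~right] = G * L0 * np.exp(-1j * kz * (z0 + zz[~right]))
        # direction-independent and direction-flipping parts share one
        # Bessel evaluation: H(+z) = even + odd, H(-z) = even - odd
        Hf = _mode_H(mode, source.frequency, rho, phi, +1)
        if mode.family == ModeFamily.TE:
            even = np.zeros_like(Hf)
            even[:, 2] = Hf[:, 2]          # Hz does not flip
            odd = Hf - even                # transverse TE terms flip sign
        else:
            even, odd = Hf, np.zeros_like(Hf)  # TM H has no direction flip
        H_cyl += cm * ((amp_f + amp_b)[:, None] * even
                       + (amp_f - amp_b)[:, None] * odd)

    # rotate cylindrical components (in the phi'=phi-phi_s frame) to Cartesian
    phi_abs = np.arctan2(y, x)
    cph, sph = np.cos(phi_abs), np.sin(phi_abs)
    Hx = H_cyl[:, 0] * cph - H_cyl[:, 1] * sph
    Hy = H_cyl[:, 0] * sph + H_cyl[:, 1] * cph
    H = np.stack([Hx, Hy, H_cyl[:, 2]], axis=-1) * source.amplitude
    return FieldSample(points=pts, H=H)


def surface_flux(field_fn, coil: CoilSurface, *, rtol: float = 1e-6,
                 max_order: int = 128) -> complex:
    """Flux of a vector field through the coil by adaptive Gauss-Legendre quadrature.

    ``field_fn(points [N, 3]) -> H [N, 3]``.  Starts at the coil's
    ``quadrature_points`` per axis (>= 8) and doubles until successive
    estimates agree to ``rtol`` relative, hard cap ``max_order`` per axis.
    """
    nhat = np.asarray(coil.normal)
    order = max(8, coil.quadrature_points)
    prev = None
    while True:
        pts, wts = coil.grid(order)
        H = np.asarray(field_fn(pts))
        flux = complex(np.sum((H @ nhat) * wts))
        if prev is not None:
            scale = max(abs(flux), abs(prev), 1e-300)
            if abs(flux - prev) <= rtol * scale:
                return flux
        if order >= max_order:
            return flux
        prev = flux
        order = min(order * 2, max_order)


def coil_flux(bore: BoreModel, source: SourceSpec,
              mode_set: Sequence[WaveguideMode], coil: CoilSurface, *,
              rtol: float = 1e-6, max_order: int = 128) -> complex:
    """Flux of the modal bore field through a coil surface.

    Validates the coil geometry against the bore, then integrates with
    :func:`surface_flux`.
    """
    rho_c, _, z_c = coil.center
    half_diag = math.hypot(coil.width, coil.height) / 2.0
    if rho_c > bore.radius + 1e-9 or abs(z_c) + half_diag > bore.length / 2 + 1e-9:
        raise ValueError("coil does not fit inside the bore")

    def field_fn(pts):
        return field_at_points(bore, source, mode_set, pts).H

    return surface_flux(field_fn, coil, rtol=rtol, max_order=max_order)


def _flux_over_offsets(bore: BoreModel, source: SourceSpec,
                       mode_set: Sequence[WaveguideMode], coil: CoilSurface,
                       offsets: np.ndarray, *, rtol: float = 1e-6,
                       max_order: int = 128) -> np.ndarray:
    """Flux for every z-offset of one coil, sharing a single field evaluation.

    All shifted copies of the coil have the same transverse quadrature
    grid, so the field is evaluated once on the stacked point set per
    quadrature order; the order doubles until every offset's flux is
    converged to ``rtol``.
    """
    if offsets.size == 0:
        return np.array([], dtype=complex)
    for dz in (offsets.min(), offsets.max()):
        shifted = coil.shifted(float(dz))
        rho_c, _, z_c = shifted.center
        half_diag = math.hypot(coil.width, coil.height) / 2.0
        if rho_c > bore.radius + 1e-9 or abs(z_c) + half_diag > bore.length / 2 + 1e-9:
            raise ValueError(f"coil offset {dz:g} m puts the coil outside the bore")
    nhat = np.asarray(coil.normal)
    rho_s, phi_s, z_s = source.position
    coeffs = _coupling_coefficients(mode_set, source)
    order = max(8, coil.quadrature_points)
    prev = None
    while True:
        pts, wts = coil.grid(order)
        x, y, z_base = pts[:, 0], pts[:, 1], pts[:, 2]
        rho = np.hypot(x, y)
        phi = np.arctan2(y, x) - phi_s
        phi_abs = np.arctan2(y, x)
        cph, sph = np.cos(phi_abs), np.sin(phi_abs)
        z = z_base[None, :] + offsets[:, None]  # [offsets, N]
        right = z >= z_s
        one_sided = bool(np.all(right)) or bool(np.all(~right))
        flux = np.zeros(offsets.size, dtype=complex)
        G = bore.end_reflection
        L = bore.length
        zz = z + L / 2.0
        zzb = z_base + L / 2.0
        for mode, cm in zip(mode_set, coeffs):
            if cm == 0:
                continue
            kz = propagation_constant(mode, source.frequency)
            R0, L0, z0 = _cavity_amplitudes(bore, kz, z_s)
            # transverse pattern is offset-independent: evaluate Bessel terms
            # once, project on the coil normal, and reuse for every offset
            Hf = _mode_H(mode, source.frequency, rho, phi, +1)
            if mode.family == ModeFamily.TE:
                even = np.zeros_like(Hf)
                even[:, 2] = Hf[:, 2]
                odd = Hf - even
            else:
                even, odd = Hf, np.zeros_like(Hf)

            def _dot_n(Hc):
                Hx = Hc[:, 0] * cph - Hc[:, 1] * sph
                Hy = Hc[:, 0] * sph + Hc[:, 1] * cph
                return Hx * nhat[0] + Hy * nhat[1] + Hc[:, 2] * nhat[2]

            pe, po = _dot_n(even), _dot_n(odd)
            if one_sided:
                # whole coil on one side of the source plane for every
                # offset: the axial phase factors into (base) x (offset)
                # outer products, so the quadrature sum is done once
                ef = np.exp(-1j * kz * zzb)         # forward base phase
                eb = np.conj(ef) if kz.imag == 0 else np.exp(1j * kz * zzb)
                Af = np.dot(wts, ef * (pe + po))
                Ab = np.dot(wts, eb * (pe - po))
                df = np.exp(-1j * kz * offsets)
                db = np.exp(1j * kz * offsets)
                if np.all(right):
                    cf = R0 * np.exp(1j * kz * z0)
                    cb = G * R0 * np.exp(-1j * kz * (2 * L - z0))
                else:
                    cf = G * L0 * np.exp(-1j * kz * z0)
                    cb = L0 * np.exp(-1j * kz * z0)
                flux += cm * (cf * Af * df + cb * Ab * db)
            else:
                amp_f = np.where(right,
                                 R0 * np.exp(-1j * kz * (zz - z0)),
                                 G * L0 * np.exp(-1j * kz * (z0 + zz)))
                amp_b = np.where(right,
                                 G * R0 * np.exp(-1j * kz * (2 * L - z0 - zz)),
                                 L0 * np.exp(-1j * kz * (z0 - zz)))
                flux += cm * (((amp_f + amp_b) * pe[None, :]) @ wts
                              + ((amp_f - amp_b) * po[None, :]) @ wts)
        flux = flux * source.amplitude
        if prev is not None:
            # relative to the flux scale of the whole series: interference
            # nulls (and symmetry-null modes) otherwise stall convergence
            scale = np.max(np.abs(flux)) + 1e-300
            if np.max(np.abs(flux - prev)) <= rtol * scale:
                return flux
        if order >= max_order:
            return flux
        prev = flux
        order = min(order * 2, max_order)


def sweep_coil_positions(bore: BoreModel, sources: SourceSpec | Iterable[SourceSpec],
                         coils: Sequence[CoilSurface],
                         z_offsets: Sequence[float], *,
                         mode_kwargs: dict | None = None) -> list[FluxSeries]:
    """Translate coils along z and record the complex flux per coil per tone.

    Emulates a posterior-array translation sweep: every coil is rigidly
    shifted by each offset and the flux from every source frequency is
    recorded.  Deterministic; returns one FluxSeries per (coil, source).
    """
    if isinstance(sources, SourceSpec):
        sources = [sources]
    sources = list(sources)
    offsets = np.asarray(list(z_offsets), dtype=float)
    out: list[FluxSeries] = []
    for src in sources:
        modes = bore.mode_catalog(src.frequency, **(mode_kwargs or {}))
        for coil in coils:
            flux = _flux_over_offsets(bore, src, modes, coil, offsets)
            out.append(FluxSeries(coil.coil_id, src.frequency, offsets, flux))
    return out


def isotropic_power_density(power_mw: float, distance_cm: float) -> float:
    """Worst-case power density (mW/cm^2) of an isotropic radiator.

    ``P / (4 pi r^2)`` — e.g. 100 mW at 10 cm gives 0.08 mW/cm^2, far below
    the 5 mW/cm^2 FCC exposure limit.
    """
    if power_mw < 0:
        raise ValueError("power must be non-negative")
    if distance_cm <= 0:
        raise ValueError("distance must be positive")
    return power_mw / (4.0 * math.pi * distance_cm**2)
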