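"""Forward optical model of a Kretschmann-configuration SPR sensor.

A prism-coupled layered stack (prism | metal | adlayers | buffer) is
described by :class:`OpticalStack`; p-polarised intensity reflectance is
computed with the Abeles characteristic (transfer) matrix method, and
independently with a recursive Parratt scheme used as a cross-check.
Derived instrument constants — the bulk sensitivity factor S (deg/RIU) and
the evanescent decay length delta (nm) — are computed from the same stack,
and SPR dip positions are localised with the weighted-centroid estimator.

Angles are internal incidence angles inside the prism, in degrees;
wavelengths in nm; thicknesses in nm. Only p polarisation is modelled,
since surface plasmons couple only to p-polarised light.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "OpticalLayer",
    "OpticalStack",
    "AngularSpectrum",
    "InstrumentModel",
    "ConfigurationError",
    "DipBoundaryError",
    "PlasmonModelError",
    "GOLD_NK",
    "gold_index",
    "gold_layer",
    "water_layer",
    "prism_layer",
    "reflectance",
    "reflectance_tmm",
    "reflectance_parratt",
    "angular_spectrum",
    "weighted_centroid_dip",
    "sensitivity_factor",
    "decay_length",
]


class ConfigurationError(ValueError):
    """A layer or stack is not usable at the requested wavelength."""


class DipBoundaryError(ValueError):
    """The SPR dip is absent or not fully contained in the scan window."""


class PlasmonModelError(ValueError):
    """The metal/ambient pair supports no bound surface-plasmon mode."""


# Literature gold n + ik (Johnson & Christy-style tabulation), 600-800 nm.
# Linearly interpolated; override via OpticalLayer.refractive_index.
GOLD_NK: dict[float, complex] = {
    600.0: 0.249 + 2.990j,
    620.0: 0.208 + 3.120j,
    640.0: 0.181 + 3.258j,
    660.0: 0.161 + 3.398j,
    680.0: 0.148 + 3.536j,
    700.0: 0.140 + 3.670j,
    720.0: 0.135 + 3.800j,
    740.0: 0.132 + 3.928j,
    760.0: 0.131 + 4.055j,
    780.0: 0.131 + 4.180j,
    800.0: 0.132 + 4.305j,
}


def gold_index(wavelength: float) -> complex:
    """Gold refractive index n + ik by linear interpolation of the table."""
    wl = np.array(sorted(GOLD_NK))
    if not (wl[0] <= wavelength <= wl[-1]):
        raise ConfigurationError(
            f"gold dispersion table covers {wl[0]:g}-{wl[-1]:g} nm, "
            f"got {wavelength:g} nm"
        )
    vals = np.array([GOLD_NK[w] for w in wl])
    n = np.interp(wavelength, wl, vals.real)
    k = np.interp(wavelength, wl, vals.imag)
    return complex(n, k)


@dataclass(frozen=True)
class OpticalLayer:
    """One homogeneous, isotropic optical layer.

    ``thickness`` is in nm; ``None`` marks a semi-infinite medium (prism or
    ambient buffer). ``refractive_index`` maps wavelength (nm) to the complex
    index n + ik, or is a callable wavelength -> complex.
    """

    name: str
    thickness: float | None
    refractive_index: Mapping[float, complex] | Callable[[float], complex]

    def __post_init__(self) -> None:
        if self.thickness is not None:
            if not np.isfinite(self.thickness) or self.thickness < 0:
                raise ValueError(
                    f"layer {self.name!r}: finite thickness must be >= 0 nm"
                )

    @property
    def semi_infinite(self) -> bool:
        return self.thickness is None

    def index_at(self, wavelength: float) -> complex:
        if callable(self.refractive_index):
            n = complex(self.refractive_index(wavelength))
        else:
            try:
                n = complex(self.refractive_index[wavelength])
            except KeyError:
                raise ConfigurationError(
                    f"layer {self.name!r} has no refractive index at "
                    f"{wavelength:g} nm"
                ) from None
        if n.imag < 0:
            raise ConfigurationError(
                f"layer {self.name!r}: extinction k must be >= 0 "
                f"(gain media not modelled)"
            )
        return n


def prism_layer(n: float = 1.515, name: str = "prism") -> OpticalLayer:
    return OpticalLayer(name, None, lambda wl: complex(n))


def water_layer(n: float = 1.333, name: str = "buffer") -> OpticalLayer:
    return OpticalLayer(name, None, lambda wl: complex(n))


def gold_layer(thickness: float = 50.0, name: str = "gold") -> OpticalLayer:
    return OpticalLayer(name, thickness, gold_index)


@dataclass(frozen=True)
class OpticalStack:
    """Ordered layers: incident prism first, ambient buffer last.

    Exactly the first and last layers are semi-infinite; inner layers have
    finite thickness (zero thickness is allowed and is optically inert).
    """

    layers: tuple[OpticalLayer, ...]

    def __init__(self, layers: Sequence[OpticalLayer]):
        object.__setattr__(self, "layers", tuple(layers))
        if len(self.layers) < 2:
            raise ValueError("stack needs at least prism and ambient")
        if not self.layers[0].semi_infinite or not self.layers[-1].semi_infinite:
            raise ValueError("first and last layers must be semi-infinite")
        for lay in self.layers[1:-1]:
            if lay.semi_infinite:
                raise ValueError(
                    f"inner layer {lay.name!r} must have finite thickness"
                )

    def indices(self, wavelength: float) -> np.ndarray:
        return np.array([l.index_at(wavelength) for l in self.layers])

    def thicknesses(self) -> np.ndarray:
        return np.array([l.thickness or 0.0 for l in self.layers[1:-1]])

    def replace_layer(self, index: int, layer: OpticalLayer) -> "OpticalStack":
        lst = list(self.layers)
        lst[index] = layer
        return OpticalStack(lst)

    def insert_layer(self, index: int, layer: OpticalLayer) -> "OpticalStack":
        lst = list(self.layers)
        lst.insert(index, layer)
        return OpticalStack(lst)

    def with_ambient_index(
        self, shift: float, wavelength: float | None = None
    ) -> "OpticalStack":
        """Return a stack whose ambient index is raised by ``shift`` RIU."""
        old = self.layers[-1]
        base = old.refractive_index

        def shifted(wl: float) -> complex:
            n = base(wl) if callable(base) else complex(base[wl])
            if wavelength is None or wl == wavelength:
                return n + shift
            return n

        return self.replace_layer(
            len(self.layers) - 1, OpticalLayer(old.name, None, shifted)
        )


def kretschmann_stack(
    prism_n: float = 1.515,
    gold_thickness: float = 50.0,
    ambient_n: float = 1.333,
) -> OpticalStack:
    """Bare gold sensor: prism | Au | buffer."""
    return OpticalStack(
        [prism_layer(prism_n), gold_layer(gold_thickness), water_layer(ambient_n)]
    )


@dataclass(frozen=True)
class AngularSpectrum:
    """Reflectance vs internal angle at one wavelength (one scan frame)."""

    wavelength: float
    angles: np.ndarray  # degrees, strictly increasing
    reflectance: np.ndarray  # unitless, in [0, 1]

    def __post_init__(self) -> None:
        a = np.asarray(self.angles, dtype=float)
        r = np.asarray(self.reflectance, dtype=float)
        if a.ndim != 1 or a.shape != r.shape:
            raise ValueError("angles and reflectance must be matching 1-D arrays")
        if not np.all(np.diff(a) > 0):
            raise ValueError("angles must be strictly increasing")
        object.__setattr__(self, "angles", a)
        object.__setattr__(self, "reflectance", r)


@dataclass(frozen=True)
class InstrumentModel:
    """Angular-scan SPR instrument: wavelengths, scan window, noise, timing."""

    wavelengths: tuple[float, ...] = (670.0, 785.0)
    angle_min: float = 58.0
    angle_max: float = 77.0
    angle_step: float = 0.01
    reflectance_noise_sd: float = 0.0
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        if len(self.wavelengths) < 1:
            raise ValueError("at least one wavelength required")
        if self.angle_step <= 0:
            raise ValueError("angle step must be > 0")
        if self.reflectance_noise_sd < 0:
            raise ValueError("noise sd must be >= 0")
        if self.angle_max <= self.angle_min:
            raise ValueError("empty angular window")

    def angle_grid(self) -> np.ndarray:
        n = int(round((self.angle_max - self.angle_min) / self.angle_step)) + 1
        return np.linspace(self.angle_min, self.angle_max, n)


def _kz(n: np.ndarray, k0: float, kx: complex) -> np.ndarray:
    """Normal wavevector component per layer; decaying branch Im(kz) >= 0."""
    kz = np.sqrt((n**2) * k0**2 - kx**2 + 0j)
    return np.where(kz.imag < 0, -kz, kz)


def reflectance_tmm(
    stack: OpticalStack, wavelength: float, angles_deg: np.ndarray | float
) -> np.ndarray | float:
    """p-polarised intensity reflectance via the characteristic-matrix method.

    Vectorised over ``angles_deg`` (internal incidence, degrees).
    """
    scalar = np.isscalar(angles_deg)
    theta = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    if np.any(theta <= 0) or np.any(theta >= 90):
        raise ValueError("angle must lie in (0, 90) degrees")
    n = stack.indices(wavelength)
    d = stack.thicknesses()
    k0 = 2 * np.pi / wavelength
    kx = n[0].real * k0 * np.sin(np.radians(theta))  # real: prism lossless

    # p-polarisation admittance q_j = kz_j / (k0 n_j^2)
    kz = np.array([_kz(nj, k0, kx) for nj in n])  # (layers, angles)
    q = kz / (k0 * n[:, None] ** 2)

    m00 = np.ones_like(kx, dtype=complex)
    m01 = np.zeros_like(m00)
    m10 = np.zeros_like(m00)
    m11 = np.ones_like(m00)
    for j in range(1, len(n) - 1):
        beta = kz[j] * d[j - 1]
        c, s = np.cos(beta), np.sin(beta)
        a00, a01 = c, -1j * s / q[j]
        a10, a11 = -1j * q[j] * s, c
        m00, m01, m10, m11 = (
            m00 * a00 + m01 * a10,
            m00 * a01 + m01 * a11,
            m10 * a00 + m11 * a10,
            m10 * a01 + m11 * a11,
        )
    qN = q[-1]
    num = (m00 + m01 * qN) * q[0] - (m10 + m11 * qN)
    den = (m00 + m01 * qN) * q[0] + (m10 + m11 * qN)
    r = num / den
    R = np.abs(r) ** 2
    R = np.clip(R, 0.0, 1.0)  # passive media; clip sub-eps rounding excursions
    return float(R[0]) if scalar else R


def reflectance(
    stack: OpticalStack, wavelength: float, angle_deg: float
) -> float:
    """p-polarised intensity reflectance at one internal angle (degrees)."""
    return float(reflectance_tmm(stack, wavelength, angle_deg))


def reflectance_parratt(
    stack: OpticalStack, wavelength: float, angles_deg: np.ndarray | float
) -> np.ndarray | float:
    """Recursive single-interface (Parratt) reflectance; independent of the
    matrix route and used to cross-check it."""
    scalar = np.isscalar(angles_deg)
    theta = np.atleast_1d(np.asarray(angles_deg, dtype=float))
    n = stack.indices(wavelength)
    d = stack.thicknesses()
    k0 = 2 * np.pi / wavelength
    kx = n[0].real * k0 * np.sin(np.radians(theta))
    kz = np.array([_kz(nj, k0, kx) for nj in n])

    def r_pp(j: int) -> np.ndarray:
        # p-pol Fresnel coefficient for interface j | j+1
        a = n[j + 1] ** 2 * kz[j]
        b = n[j] ** 2 * kz[j + 1]
        return (a - b) / (a + b)

    r = r_pp(len(n) - 2)
    for j in range(len(n) - 3, -1, -1):
        phase = np.exp(2j * kz[j + 1] * d[j])
        rj = r_pp(j)
        r = (rj + r * phase) / (1 + rj * r * phase)
    R = np.clip(np.abs(r) ** 2, 0.0, 1.0)
    return float(R[0]) if scalar else R


def angular_spectrum(
    stack: OpticalStack, wavelength: float, instrument: InstrumentModel
) -> AngularSpectrum:
    """Sweep reflectance over the instrument's angular window (noise-free)."""
    grid = instrument.angle_grid()
    return AngularSpectrum(wavelength, grid, reflectance_tmm(stack, wavelength, grid))


def weighted_centroid_dip(
    spectrum: AngularSpectrum, threshold_fraction: float = 0.5
) -> float:
    """Weighted-centroid SPR dip angle (degrees).

    Points below the threshold T = R_min + f (R_edge - R_min), with R_edge
    the lower of the two window-edge reflectances, contribute weight
    w = T - R; the dip is the weight-averaged angle. Raises
    :class:`DipBoundaryError` when the dip touches a window edge.
    """
    if not (0 < threshold_fraction < 1):
        raise ValueError("threshold_fraction must be in (0, 1)")
    R = spectrum.reflectance
    theta = spectrum.angles
    i_min = int(np.argmin(R))
    if i_min in (0, len(R) - 1):
        raise DipBoundaryError("reflectance minimum lies on a window edge")
    r_min = R[i_min]
    r_edge = min(R[0], R[-1])
    if r_edge <= r_min:
        raise DipBoundaryError("no dip: edge reflectance not above minimum")
    T = r_min + threshold_fraction * (r_edge - r_min)
    w = np.maximum(0.0, T - R)
    if w[0] > 0 or w[-1] > 0:
        raise DipBoundaryError("dip not fully contained in the scan window")
    return float(np.sum(w * theta) / np.sum(w))


def sensitivity_factor(
    stack: OpticalStack,
    wavelength: float,
    ri_step: float = 1e-3,
    instrument: InstrumentModel | None = None,
    threshold_fraction: float = 0.5,
) -> float:
    """Bulk sensitivity S = d(dip angle)/d(ambient index), deg/RIU.

    Forward finite difference of the weighted-centroid dip under a small
    ambient refractive-index step.
    """
    if not (0 < ri_step <= 5e-3):
        raise ValueError("ri_step must be in (0, 5e-3]")
    instrument = instrument or InstrumentModel()
    dip0 = weighted_centroid_dip(
        angular_spectrum(stack, wavelength, instrument), threshold_fraction
    )
    bumped = stack.with_ambient_index(ri_step)
    dip1 = weighted_centroid_dip(
        angular_spectrum(bumped, wavelength, instrument), threshold_fraction
    )
    return (dip1 - dip0) / ri_step


def _find_metal(stack: OpticalStack, wavelength: float) -> complex:
    inner = stack.layers[1:-1]
    if not inner:
        raise PlasmonModelError("stack has no metal layer")
    idx = max(inner, key=lambda l: l.index_at(wavelength).imag)
    n_m = idx.index_at(wavelength)
    if n_m.imag <= 0:
        raise PlasmonModelError("no absorbing metal layer in the stack")
    return n_m


def decay_length(
    stack: OpticalStack, wavelength: float, convention: str = "amplitude"
) -> float:
    """Evanescent decay length delta of the surface-plasmon field (nm).

    Evaluated from the bound-mode dispersion relation of the metal/ambient
    pair: k_sp = (2 pi / lambda) sqrt(eps_m n_a^2 / (eps_m + n_a^2)), with
    delta = 1 / Im(k_z,ambient) at that propagation constant.

    ``convention`` selects the field-amplitude decay length (``"amplitude"``,
    default: E ~ e^(-z/delta)) or the intensity decay length
    (``"intensity"``: |E|^2 ~ e^(-z/delta), i.e. half the amplitude length).
    The intensity convention is the one entering the dual-wavelength
    thickness equation, since the adlayer response weights the refractive
    index profile by the local field intensity.
    """
    if convention not in ("amplitude", "intensity"):
        raise ValueError("convention must be 'amplitude' or 'intensity'")
    n_m = _find_metal(stack, wavelength)
    eps_m = n_m**2
    n_a = stack.layers[-1].index_at(wavelength)
    if abs(n_a.imag) > 1e-9:
        raise PlasmonModelError("ambient must be a lossless dielectric")
    eps_a = (n_a.real) ** 2
    if eps_m.real + eps_a >= 0:
        raise PlasmonModelError(
            "Re(eps_metal) + n_ambient^2 >= 0: no bound plasmon mode"
        )
    k0 = 2 * np.pi / wavelength
    ksp2 = k0**2 * eps_m * eps_a / (eps_m + eps_a)
    kz_a = np.sqrt(eps_a * k0**2 - ksp2 + 0j)
    if kz_a.imag < 0:
        kz_a = -kz_a
    delta = 1.0 / kz_a.imag
    if convention == "intensity":
        delta /= 2.0
    return float(delta)
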