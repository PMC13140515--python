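"""Stepwise two-wavelength fitting of adsorbed optical layers.

One layer at a time is fitted by matching modelled full SPR spectra to
measured spectra at both laser wavelengths simultaneously: the layer
thickness d is a single global parameter shared by both wavelengths,
while the refractive indices n(lambda1), n(lambda2) are independent.
Fitted layers are frozen into the stack before the next layer is solved
(capture layer first, corona on top), so a later stage never re-fits an
earlier one.

Thin layers carry a d*(n - n_ambient) degeneracy: within a narrow box the
product is far better determined than its factors. Fits whose residual is
flat along that ridge are flagged rather than silently accepted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .optics import AngularSpectrum, OpticalLayer, OpticalStack, reflectance_tmm

__all__ = [
    "LayerFitSpec",
    "LayerFitResult",
    "StageOrderError",
    "fit_layer",
    "fit_stack_sequential",
]

# published search boxes for the two stages
EV_LAYER_BOX = {"d_bounds": (80.0, 120.0), "n_bounds": (1.334, 1.335)}
CORONA_LAYER_BOX = {"d_bounds": (1.0, 10.0), "n_bounds": (1.36, 1.37)}


class StageOrderError(ValueError):
    """A sequential-fit stage produced an implausibly poor fit."""


@dataclass(frozen=True)
class LayerFitSpec:
    """Search box and options for one free layer.

    ``layer_index`` points at the free layer within the stack handed to
    :func:`fit_layer`; :func:`fit_stack_sequential` fills it in as layers
    are inserted. ``n_bounds`` may be one (lo, hi) pair applied to every
    wavelength or a mapping wavelength -> (lo, hi).
    """

    d_bounds: tuple[float, float]
    n_bounds: tuple[float, float] | dict[float, tuple[float, float]]
    layer_index: int | None = None
    name: str = "layer"
    angle_window: tuple[float, float] | None = None
    wavelength_weights: dict[float, float] | None = None  # equal if None
    normalize_spectra: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.d_bounds
        if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
            raise ValueError("d_bounds must be finite with lo < hi")
        bounds = (
            self.n_bounds.values()
            if isinstance(self.n_bounds, dict)
            else [self.n_bounds]
        )
        for b in bounds:
            if not (np.isfinite(b[0]) and np.isfinite(b[1]) and b[0] < b[1]):
                raise ValueError("n_bounds must be finite with lo < hi")

    def _n_bounds_map(self, wavelengths) -> dict[float, tuple[float, float]]:
        if isinstance(self.n_bounds, dict):
            return {wl: self.n_bounds[wl] for wl in wavelengths}
        return {wl: tuple(self.n_bounds) for wl in wavelengths}


@dataclass(frozen=True)
class LayerFitResult:
    """Fitted thickness (nm), per-wavelength indices, and diagnostics."""

    name: str
    d: float
    n: dict[float, float]
    rss: dict[float, float]  # residual sum of squares per wavelength
    converged: bool
    at_bounds: bool = False
    degenerate: bool = False
    poor_fit: bool = False

    @property
    def rss_total(self) -> float:
        return float(sum(self.rss.values()))


def _model_spectra(
    stack: OpticalStack,
    spec: LayerFitSpec,
    wavelengths: list[float],
    angle_grids: dict[float, np.ndarray],
    d: float,
    n_by_wl: dict[float, float],
) -> dict[float, np.ndarray]:
    layer = OpticalLayer(spec.name, d, {wl: complex(n) for wl, n in n_by_wl.items()})
    trial = stack.replace_layer(spec.layer_index, layer)
    return {wl: reflectance_tmm(trial, wl, angle_grids[wl]) for wl in wavelengths}


def fit_layer(
    measured: dict[float, AngularSpectrum],
    base_stack: OpticalStack,
    spec: LayerFitSpec,
    poor_fit_threshold: float = 1e-7,
) -> LayerFitResult:
    """Fit one layer's (d, n(lambda1), n(lambda2)) to measured spectra.

    Bounded trust-region least squares on the concatenated reflectance
    residuals of both wavelengths, started from the best points of a fixed
    3x3x3 grid over the search box (deterministic ordering). Non-convergence
    is reported through the ``converged`` flag, never as an exception.

    ``poor_fit_threshold`` is the mean squared residual per point above
    which the fit is flagged implausible; the 1e-7 default suits
    reflectance noise up to ~1e-4 and should be raised for noisier data.
    """
    if spec.layer_index is None:
        raise ValueError("spec.layer_index must identify the free layer")
    wavelengths = sorted(measured)
    if len(wavelengths) < 1:
        raise ValueError("at least one measured spectrum required")
    n_bounds = spec._n_bounds_map(wavelengths)

    grids: dict[float, np.ndarray] = {}
    targets: dict[float, np.ndarray] = {}
    weights = spec.wavelength_weights or {wl: 1.0 for wl in wavelengths}
    for wl in wavelengths:
        sp = measured[wl]
        mask = np.ones(sp.angles.size, dtype=bool)
        if spec.angle_window is not None:
            a, b = spec.angle_window
            mask = (sp.angles >= a) & (sp.angles <= b)
        grids[wl] = sp.angles[mask]
        y = sp.reflectance[mask]
        if spec.normalize_spectra:
            y = y / np.max(y)
        targets[wl] = y

    def residuals(x: np.ndarray) -> np.ndarray:
        d = x[0]
        n_by_wl = {wl: x[1 + i] for i, wl in enumerate(wavelengths)}
        model = _model_spectra(base_stack, spec, wavelengths, grids, d, n_by_wl)
        parts = []
        for wl in wavelengths:
            m = model[wl]
            if spec.normalize_spectra:
                m = m / np.max(m)
            parts.append(np.sqrt(weights[wl]) * (m - targets[wl]))
        return np.concatenate(parts)

    lo = np.array([spec.d_bounds[0]] + [n_bounds[wl][0] for wl in wavelengths])
    hi = np.array([spec.d_bounds[1]] + [n_bounds[wl][1] for wl in wavelengths])

    # fixed 3x3x3 multi-start grid over the box, best starts refined
    fracs = np.array([0.25, 0.5, 0.75])
    axes = [lo[i] + fracs * (hi[i] - lo[i]) for i in range(len(lo))]
    mesh = np.stack(
        [g.ravel() for g in np.meshgrid(*axes, indexing="ij")], axis=1
    )
    start_rss = np.array([float(np.sum(residuals(x) ** 2)) for x in mesh])
    order = np.argsort(start_rss, kind="stable")

    best = None
    for idx in order[:3]:
        sol = least_squares(
            residuals, mesh[idx], bounds=(lo, hi), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=400,
        )
        if best is None or sol.cost < best.cost:
            best = sol
    x = best.x
    d_fit = float(x[0])
    n_fit = {wl: float(x[1 + i]) for i, wl in enumerate(wavelengths)}

    model = _model_spectra(base_stack, spec, wavelengths, grids, d_fit, n_fit)
    rss = {}
    npts = 0
    for wl in wavelengths:
        m = model[wl]
        y = targets[wl]
        if spec.normalize_spectra:
            m = m / np.max(m)
        rss[wl] = float(np.sum((m - y) ** 2))
        npts += y.size
    rss_total = sum(rss.values())

    tol = 1e-9
    at_bounds = bool(np.any(x - lo < tol * (hi - lo)) or np.any(hi - x < tol * (hi - lo)))

    # probe the d*(n - n_ambient) compensation ridge: move d by +-10%
    # (clipped to the box) while rescaling each wavelength's index so the
    # optical increment d*(n - n_amb) is preserved; a flat residual along
    # this ridge means the box-constrained optimum is not unique
    degenerate = False
    n_amb = {wl: base_stack.layers[-1].index_at(wl).real for wl in wavelengths}
    for factor in (0.9, 1.1):
        d_alt = min(max(d_fit * factor, spec.d_bounds[0]), spec.d_bounds[1])
        if abs(d_alt - d_fit) < 1e-12:
            continue
        scale = d_fit / d_alt
        n_probe = {}
        inside = True
        for wl in wavelengths:
            n_probe[wl] = n_amb[wl] + (n_fit[wl] - n_amb[wl]) * scale
            b = n_bounds[wl]
            if not (b[0] - 1e-12 <= n_probe[wl] <= b[1] + 1e-12):
                inside = False
        if not inside:
            continue
        alt = _model_spectra(base_stack, spec, wavelengths, grids, d_alt, n_probe)
        alt_rss = 0.0
        for wl in wavelengths:
            m = alt[wl]
            if spec.normalize_spectra:
                m = m / np.max(m)
            alt_rss += float(np.sum((m - targets[wl]) ** 2))
        if abs(alt_rss - rss_total) < 1e-12:
            degenerate = True
            break

    poor_fit = rss_total / npts > poor_fit_threshold
    result = LayerFitResult(
        name=spec.name,
        d=d_fit,
        n=n_fit,
        rss=rss,
        converged=bool(best.success),
        at_bounds=at_bounds,
        degenerate=degenerate,
        poor_fit=poor_fit,
    )
    if at_bounds:
        warnings.warn(
            f"layer {spec.name!r}: solution pinned at a search-box bound",
            stacklevel=2,
        )
    return result


def fit_stack_sequential(
    timeline: list[tuple[str, dict[float, AngularSpectrum]]],
    base_stack: OpticalStack,
    specs: list[LayerFitSpec],
    strict: bool = True,
    poor_fit_threshold: float = 1e-7,
) -> list[LayerFitResult]:
    """Solve layers one at a time along a staged experiment.

    For stage k, a new free layer is inserted just below the ambient medium
    (on top of all previously fitted layers), fitted to that stage's spectra,
    then frozen at its fitted values before stage k+1. With ``strict`` (the
    default) a stage whose residual explodes — the signature of stage/spec
    mismatch, e.g. permuted search boxes — raises :class:`StageOrderError`.
    """
    if len(timeline) != len(specs):
        raise ValueError("one LayerFitSpec required per stage")
    stack = base_stack
    results: list[LayerFitResult] = []
    for (label, spectra), spec0 in zip(timeline, specs):
        insert_at = len(stack.layers) - 1
        placeholder = OpticalLayer(
            spec0.name or label,
            0.5 * sum(spec0.d_bounds),
            {wl: complex(stack.layers[-1].index_at(wl).real) for wl in spectra},
        )
        stack = stack.insert_layer(insert_at, placeholder)
        spec = replace(spec0, layer_index=insert_at, name=spec0.name or label)
        res = fit_layer(spectra, stack, spec, poor_fit_threshold)
        if strict and res.poor_fit:
            raise StageOrderError(
                f"stage {label!r}: residual {res.rss_total:.3g} is far above "
                "the noise floor; check stage order and search boxes"
            )
        results.append(res)
        fitted = OpticalLayer(
            spec.name, res.d, {wl: complex(res.n[wl]) for wl in res.n}
        )
        stack = stack.replace_layer(insert_at, fitted)
    return results
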