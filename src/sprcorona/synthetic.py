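"""Synthetic experiments with known ground truth.

Two generators feed the pipeline:

* :func:`simulate_spr_experiment` renders a staged capture experiment
  (baseline -> vesicle injection -> wash -> plasma injection -> wash) as
  per-frame angular reflectance scans at both laser wavelengths and two
  flow channels. Adsorbed layers grow smoothly to their stage truth;
  the plasma stage adds a bulk refractive-index jump that the wash
  removes, leaving only the corona layer. The control channel sees bulk
  effects but no binding, so reference subtraction can cancel them.

* :func:`simulate_proteomics` draws a TMT-like protein x sample intensity
  matrix with group effects and intensity-dependent (missing-not-at-
  random) dropout — the structure the downshifted-normal imputation
  assumes.

Every artefact embeds its scenario and seed; regeneration is
bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .optics import (
    AngularSpectrum,
    InstrumentModel,
    OpticalLayer,
    OpticalStack,
    kretschmann_stack,
    reflectance_tmm,
)
from .proteomics import IntensityMatrix
from .sensorgram import SpectralFrames

__all__ = [
    "LayerTruth",
    "StageTimes",
    "SprScenario",
    "SprExperiment",
    "ProteomicsScenario",
    "simulate_spr_experiment",
    "simulate_proteomics",
    "expected_missing_fraction",
]


@dataclass(frozen=True)
class LayerTruth:
    """Ground-truth optical slab: thickness (nm) and index per wavelength."""

    thickness: float
    n: dict[float, float]

    def __post_init__(self) -> None:
        if self.thickness < 0:
            raise ValueError("layer thickness must be >= 0")


@dataclass(frozen=True)
class StageTimes:
    """Stage boundaries (s): baseline, capture, wash, plasma, final wash."""

    baseline_end: float = 120.0
    capture_end: float = 720.0  # 10 min vesicle injection
    wash1_end: float = 1320.0  # 10 min buffer flush
    plasma_end: float = 2220.0  # 15 min plasma injection
    wash2_end: float = 3120.0  # 15 min final flush

    def __post_init__(self) -> None:
        seq = (
            0.0,
            self.baseline_end,
            self.capture_end,
            self.wash1_end,
            self.plasma_end,
            self.wash2_end,
        )
        if not all(a < b for a, b in zip(seq, seq[1:])):
            raise ValueError("stage boundaries must be strictly increasing")


@dataclass(frozen=True)
class SprScenario:
    """Staged capture/corona experiment with known truth.

    Defaults sit at the mid-points of the printed search boxes: a 100 nm
    vesicle film of index 1.3345 and a 5.5 nm corona of index 1.365, with
    a 5e-3 RIU bulk jump during the plasma stage (a few hundred mdeg at
    typical gold-sensor sensitivity, as diluted plasma produces).
    """

    stack: OpticalStack = field(default_factory=kretschmann_stack)
    ev_layer: LayerTruth = field(
        default_factory=lambda: LayerTruth(100.0, {670.0: 1.3345, 785.0: 1.3345})
    )
    corona_layer: LayerTruth = field(
        default_factory=lambda: LayerTruth(5.5, {670.0: 1.365, 785.0: 1.365})
    )
    bulk_jump_riu: float = 5e-3
    stages: StageTimes = field(default_factory=StageTimes)
    instrument: InstrumentModel = field(default_factory=InstrumentModel)
    growth_tau: float = 120.0  # saturation time constant of layer growth, s
    seed: int = 0
    sample_channel: str = "ch1"
    control_channel: str = "ch2"

    def __post_init__(self) -> None:
        for wl in self.instrument.wavelengths:
            if wl not in self.ev_layer.n or wl not in self.corona_layer.n:
                raise ValueError(f"layer truth missing index at {wl:g} nm")
        if self.growth_tau <= 0:
            raise ValueError("growth_tau must be > 0")
        if self.bulk_jump_riu < 0:
            raise ValueError("bulk_jump_riu must be >= 0")


@dataclass(frozen=True)
class SprExperiment:
    """Rendered frames plus the per-frame ground truth and scenario."""

    frames: SpectralFrames
    scenario: SprScenario
    truth: pd.DataFrame  # per frame: time, d_ev, d_corona, bulk_riu


def _growth(t: np.ndarray, t0: float, t1: float, target: float, tau: float) -> np.ndarray:
    """Saturating growth from 0 at t0 to exactly ``target`` at t1, held after."""
    x = np.clip(t - t0, 0.0, t1 - t0)
    return target * (-np.expm1(-x / tau)) / (-np.expm1(-(t1 - t0) / tau))


def _bulk_profile(t: np.ndarray, stages: StageTimes, jump: float) -> np.ndarray:
    return np.where((t >= stages.wash1_end) & (t < stages.plasma_end), jump, 0.0)


def simulate_spr_experiment(sc: SprScenario) -> SprExperiment:
    """Render the staged experiment to per-frame angular scans.

    Gaussian reflectance noise (instrument ``reflectance_noise_sd``) is
    applied per point; draws outside [0, 1] are rejected and resampled so
    the passive-medium bound is respected without clipping bias.
    """
    inst = sc.instrument
    st = sc.stages
    rng = np.random.default_rng(sc.seed)
    times = np.arange(0.0, st.wash2_end + inst.frame_interval / 2, inst.frame_interval)
    grid = inst.angle_grid()

    d_ev = _growth(times, st.baseline_end, st.capture_end, sc.ev_layer.thickness, sc.growth_tau)
    d_cor = _growth(
        times, st.wash1_end, st.plasma_end, sc.corona_layer.thickness, sc.growth_tau
    )
    bulk = _bulk_profile(times, st, sc.bulk_jump_riu)

    frames: dict[tuple[str, float], list[AngularSpectrum]] = {}
    for channel in (sc.sample_channel, sc.control_channel):
        binding = channel == sc.sample_channel
        for wl in inst.wavelengths:
            series: list[AngularSpectrum] = []
            cache: dict[tuple[float, float, float], np.ndarray] = {}
            for i, t in enumerate(times):
                key = (d_ev[i] if binding else 0.0, d_cor[i] if binding else 0.0, bulk[i])
                R = cache.get(key)
                if R is None:
                    stack = sc.stack
                    insert_at = len(stack.layers) - 1
                    if binding and key[0] > 0:
                        stack = stack.insert_layer(
                            insert_at,
                            OpticalLayer("ev", key[0], {wl: complex(sc.ev_layer.n[wl])}),
                        )
                        insert_at += 1
                    if binding and key[1] > 0:
                        stack = stack.insert_layer(
                            insert_at,
                            OpticalLayer(
                                "corona", key[1], {wl: complex(sc.corona_layer.n[wl])}
                            ),
                        )
                    if key[2] > 0:
                        stack = stack.with_ambient_index(key[2])
                    R = reflectance_tmm(stack, wl, grid)
                    cache[key] = R
                noisy = R
                if inst.reflectance_noise_sd > 0:
                    noisy = R + rng.normal(0.0, inst.reflectance_noise_sd, R.shape)
                    bad = (noisy < 0) | (noisy > 1)
                    while np.any(bad):  # rejection keeps R in [0, 1] unbiased
                        noisy[bad] = R[bad] + rng.normal(
                            0.0, inst.reflectance_noise_sd, int(bad.sum())
                        )
                        bad = (noisy < 0) | (noisy > 1)
                series.append(AngularSpectrum(wl, grid, noisy))
            frames[(channel, wl)] = series

    truth = pd.DataFrame(
        {"time_s": times, "d_ev_nm": d_ev, "d_corona_nm": d_cor, "bulk_riu": bulk}
    )
    return SprExperiment(SpectralFrames(times, frames), sc, truth)


@dataclass(frozen=True)
class ProteomicsScenario:
    """TMT-like intensity matrix generator settings.

    Log2 intensities are normal with ``log2_mean``/``log2_sd``; a fraction
    of proteins is shifted by ``effect`` log2 units (random sign) in the
    first group. Dropout is Bernoulli with probability
    sigmoid(intercept - slope * log2-intensity), so low-abundance values
    go missing preferentially. Defaults mirror a two-condition,
    three-replicate reporter-ion experiment.
    """

    n_proteins: int = 1000
    replicates: dict[str, int] = field(default_factory=lambda: {"A": 3, "B": 3})
    frac_shifted: float = 0.1
    effect: float = 1.0
    within_sd: float = 0.25
    log2_mean: float = 20.0
    log2_sd: float = 2.0
    missing_intercept: float = 15.5
    missing_slope: float = 1.0
    contaminant_fraction: float = 0.05
    seed: int = 0
    # +effect in the first group by default; random per-protein sign optional
    random_sign: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.frac_shifted <= 1 and 0 <= self.contaminant_fraction <= 1):
            raise ValueError("fractions must be in [0, 1]")
        if any(r < 2 for r in self.replicates.values()):
            raise ValueError("every group needs >= 2 replicates")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def expected_missing_fraction(sc: ProteomicsScenario, n_grid: int = 20001) -> float:
    """Analytic expectation of the dropout fraction under the scenario.

    E[sigmoid(intercept - slope x)] for x ~ Normal(log2_mean, log2_sd^2),
    evaluated by Gauss-grid quadrature (no sampling involved).
    """
    x = np.linspace(
        sc.log2_mean - 10 * sc.log2_sd, sc.log2_mean + 10 * sc.log2_sd, n_grid
    )
    pdf = np.exp(-0.5 * ((x - sc.log2_mean) / sc.log2_sd) ** 2) / (
        sc.log2_sd * np.sqrt(2 * np.pi)
    )
    p = _sigmoid(sc.missing_intercept - sc.missing_slope * x)
    return float(np.trapezoid(p * pdf, x))


def simulate_proteomics(sc: ProteomicsScenario) -> tuple[IntensityMatrix, pd.DataFrame]:
    """Draw an intensity matrix (raw scale, NaN dropout) plus truth labels.

    Returns the matrix and a per-protein truth table with columns
    ``shifted`` (bool), ``effect_log2`` (signed shift applied in the first
    group) and ``contaminant``.
    """
    rng = np.random.default_rng(sc.seed)
    groups = list(sc.replicates)
    samples = [f"{g}{i + 1}" for g in groups for i in range(sc.replicates[g])]
    group_of = pd.Series(
        [g for g in groups for _ in range(sc.replicates[g])], index=samples
    )
    accession = [f"P{i:05d}" for i in range(sc.n_proteins)]

    base = rng.normal(sc.log2_mean, sc.log2_sd, sc.n_proteins)
    shifted = rng.random(sc.n_proteins) < sc.frac_shifted
    signs = rng.choice([-1.0, 1.0], sc.n_proteins) if sc.random_sign else np.ones(sc.n_proteins)
    effect = np.where(shifted, sc.effect * signs, 0.0)
    contaminant = rng.random(sc.n_proteins) < sc.contaminant_fraction

    log2 = np.empty((sc.n_proteins, len(samples)))
    for j, s in enumerate(samples):
        mean = base + (effect if group_of[s] == groups[0] else 0.0)
        log2[:, j] = rng.normal(mean, sc.within_sd)

    p_missing = _sigmoid(sc.missing_intercept - sc.missing_slope * log2)
    dropped = rng.random(log2.shape) < p_missing
    values = np.power(2.0, log2)
    values[dropped] = np.nan

    frame = pd.DataFrame(values, index=accession, columns=samples)
    frame.index.name = "accession"
    matrix = IntensityMatrix(
        values=frame,
        groups=group_of,
        gene=pd.Series([f"GENE{i}" for i in range(sc.n_proteins)], index=accession),
        contaminant=pd.Series(contaminant, index=accession),
    )
    truth = pd.DataFrame(
        {"shifted": shifted, "effect_log2": effect, "contaminant": contaminant},
        index=accession,
    )
    expected = expected_missing_fraction(sc)
    if expected > 0.9:
        import warnings

        warnings.warn(
            f"expected missingness {expected:.2f} > 0.9: pipeline untestable",
            stacklevel=2,
        )
    return matrix, truth
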