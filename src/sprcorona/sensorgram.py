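"""Kinetic processing of SPR scans: dip tracking, zeroing, referencing.

Frame-wise angular scans are reduced to sensorgrams (dip angle vs time,
in millidegrees), the injection time is taken as the zero point for both
time and response, and bulk/nonspecific effects are removed by
subtracting the buffer control channel from the sample channel.
All interpolation is linear; no smoothing is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .optics import AngularSpectrum, DipBoundaryError, weighted_centroid_dip

__all__ = [
    "SpectralFrames",
    "Sensorgram",
    "ProcessedResponse",
    "AlignmentError",
    "extract_kinetics",
    "zero_at_injection",
    "subtract_reference",
    "steady_state_response",
]


class AlignmentError(ValueError):
    """Sample and control series do not overlap in time."""


@dataclass(frozen=True)
class SpectralFrames:
    """Time-ordered angular scans, keyed by (channel, wavelength)."""

    times: np.ndarray  # seconds, strictly increasing, shared by all keys
    frames: Mapping[tuple[str, float], Sequence[AngularSpectrum]]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("frame times must be strictly increasing")
        object.__setattr__(self, "times", t)
        for key, seq in self.frames.items():
            if len(seq) != len(t):
                raise ValueError(f"series {key}: frame count != time count")

    @property
    def channels(self) -> list[str]:
        return sorted({ch for ch, _ in self.frames})

    @property
    def wavelengths(self) -> list[float]:
        return sorted({wl for _, wl in self.frames})


@dataclass(frozen=True)
class Sensorgram:
    """Dip angle (mdeg) vs time (s) per (channel, wavelength)."""

    times: np.ndarray
    angles_mdeg: Mapping[tuple[str, float], np.ndarray]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(
            self,
            "angles_mdeg",
            {k: np.asarray(v, dtype=float) for k, v in self.angles_mdeg.items()},
        )
        for key, v in self.angles_mdeg.items():
            if v.shape != t.shape:
                raise ValueError(f"series {key}: length mismatch with time axis")

    @property
    def channels(self) -> list[str]:
        return sorted({ch for ch, _ in self.angles_mdeg})

    def wavelengths(self, channel: str) -> list[float]:
        return sorted(wl for ch, wl in self.angles_mdeg if ch == channel)


@dataclass(frozen=True)
class ProcessedResponse:
    """Response (mdeg) per wavelength, re-origined at the injection time."""

    times: np.ndarray  # seconds relative to injection
    response_mdeg: Mapping[float, np.ndarray]
    channel: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(
            self,
            "response_mdeg",
            {k: np.asarray(v, dtype=float) for k, v in self.response_mdeg.items()},
        )

    @property
    def wavelengths(self) -> list[float]:
        return sorted(self.response_mdeg)


def extract_kinetics(
    frames: SpectralFrames, threshold_fraction: float = 0.5
) -> Sensorgram:
    """Localise the SPR dip in every frame; angles returned in mdeg.

    Dip-boundary failures are re-raised with the offending frame index.
    """
    out: dict[tuple[str, float], np.ndarray] = {}
    for key, seq in frames.frames.items():
        angles = np.empty(len(seq))
        for i, spec in enumerate(seq):
            try:
                angles[i] = weighted_centroid_dip(spec, threshold_fraction)
            except DipBoundaryError as exc:
                raise DipBoundaryError(
                    f"series {key}, frame {i} (t={frames.times[i]:g} s): {exc}"
                ) from exc
        out[key] = angles * 1000.0  # deg -> mdeg
    return Sensorgram(frames.times, out)


def zero_at_injection(
    sg: Sensorgram, t_inj: float, channel: str | None = None
) -> ProcessedResponse:
    """Re-origin time and response at the sample-injection instant.

    The response at ``t_inj`` is linearly interpolated between the
    neighbouring frames and subtracted, so response(0) == 0 exactly.
    """
    if channel is None:
        chans = sg.channels
        if len(chans) != 1:
            raise ValueError("channel must be given for a multi-channel sensorgram")
        channel = chans[0]
    t = sg.times
    if not (t[0] <= t_inj <= t[-1]):
        raise ValueError(f"t_inj={t_inj:g} s outside recorded span [{t[0]:g}, {t[-1]:g}]")
    resp = {}
    for (ch, wl), y in sg.angles_mdeg.items():
        if ch != channel:
            continue
        y0 = float(np.interp(t_inj, t, y))
        resp[wl] = y - y0
    if not resp:
        raise ValueError(f"no series recorded for channel {channel!r}")
    return ProcessedResponse(t - t_inj, resp, channel)


def subtract_reference(
    sample: ProcessedResponse, control: ProcessedResponse
) -> ProcessedResponse:
    """Subtract the buffer control channel to remove bulk/nonspecific signal.

    The control is linearly interpolated onto the sample time base; the
    result is restricted to the overlapping time range.
    """
    if set(sample.wavelengths) != set(control.wavelengths):
        raise ValueError("sample and control must share the wavelength set")
    lo = max(sample.times[0], control.times[0])
    hi = min(sample.times[-1], control.times[-1])
    if lo > hi:
        raise AlignmentError("sample and control time ranges are disjoint")
    mask = (sample.times >= lo) & (sample.times <= hi)
    t = sample.times[mask]
    corrected = {}
    for wl in sample.wavelengths:
        ctrl = np.interp(t, control.times, control.response_mdeg[wl])
        corrected[wl] = sample.response_mdeg[wl][mask] - ctrl
    return ProcessedResponse(t, corrected, sample.channel)


def steady_state_response(
    pr: ProcessedResponse, window: tuple[float, float]
) -> dict[float, tuple[float, float]]:
    """Mean and sd (mdeg) of the response in a plateau window, per wavelength.

    The window ``[t_a, t_b]`` selects samples by time; the sd is the
    population standard deviation of the selected points (0 for one point).
    """
    t_a, t_b = window
    if t_b < t_a:
        raise ValueError("window must satisfy t_a <= t_b")
    if t_a < pr.times[0] or t_b > pr.times[-1]:
        raise ValueError("window outside recorded span")
    mask = (pr.times >= t_a) & (pr.times <= t_b)
    if not np.any(mask):
        raise ValueError("window contains no samples")
    return {
        wl: (float(np.mean(y[mask])), float(np.std(y[mask])))
        for wl, y in pr.response_mdeg.items()
    }
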