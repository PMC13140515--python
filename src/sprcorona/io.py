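"""TSV/TOML interchange and shipped reference data.

Documented dialects (all tab-separated, ``#`` comment lines allowed):

* spectra (long format): ``time_s  channel  wavelength_nm  angle_deg
  reflectance``
* sensorgram: ``time_s  channel  wavelength_nm  dip_angle_mdeg``
* intensity table (MaxQuant proteinGroups-like): ``accession  gene
  contaminant`` then one intensity column per sample; contaminants are
  marked ``+``; empty/zero intensities are missing
* group map: ``sample  group``

Stacks and instruments can also be described in a TOML config with
``[stack]``, ``[instrument]`` and ``[gold_dispersion]`` sections.
"""

from __future__ import annotations

import importlib.resources
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .optics import (
    GOLD_NK,
    AngularSpectrum,
    InstrumentModel,
    OpticalLayer,
    OpticalStack,
)
from .proteomics import IntensityMatrix
from .sensorgram import Sensorgram, SpectralFrames

__all__ = [
    "write_spectra_tsv",
    "read_spectra_tsv",
    "write_sensorgram_tsv",
    "read_sensorgram_tsv",
    "read_intensity_tsv",
    "write_differential_tsv",
    "write_overlap_json",
    "load_table2",
    "table2_significance_counts",
    "load_config",
]


def write_spectra_tsv(path: str | Path, frames: SpectralFrames) -> None:
    rows = []
    for (channel, wl), series in frames.frames.items():
        for t, spec in zip(frames.times, series):
            rows.append(
                pd.DataFrame(
                    {
                        "time_s": t,
                        "channel": channel,
                        "wavelength_nm": wl,
                        "angle_deg": spec.angles,
                        "reflectance": spec.reflectance,
                    }
                )
            )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_spectra_tsv(path: str | Path) -> SpectralFrames:
    df = pd.read_csv(path, sep="\t", comment="#")
    frames: dict[tuple[str, float], list[AngularSpectrum]] = {}
    times = np.array(sorted(df["time_s"].unique()))
    for (channel, wl), sub in df.groupby(["channel", "wavelength_nm"]):
        series = []
        for t in times:
            at = sub[sub["time_s"] == t].sort_values("angle_deg")
            series.append(
                AngularSpectrum(
                    float(wl),
                    at["angle_deg"].to_numpy(),
                    at["reflectance"].to_numpy(),
                )
            )
        frames[(str(channel), float(wl))] = series
    return SpectralFrames(times, frames)


def write_sensorgram_tsv(path: str | Path, sg: Sensorgram) -> None:
    rows = []
    for (channel, wl), y in sg.angles_mdeg.items():
        rows.append(
            pd.DataFrame(
                {
                    "time_s": sg.times,
                    "channel": channel,
                    "wavelength_nm": wl,
                    "dip_angle_mdeg": y,
                }
            )
        )
    pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_sensorgram_tsv(path: str | Path) -> Sensorgram:
    df = pd.read_csv(path, sep="\t", comment="#")
    times = np.array(sorted(df["time_s"].unique()))
    series = {}
    for (channel, wl), sub in df.groupby(["channel", "wavelength_nm"]):
        sub = sub.sort_values("time_s")
        series[(str(channel), float(wl))] = sub["dip_angle_mdeg"].to_numpy()
    return Sensorgram(times, series)


def read_intensity_tsv(
    matrix_path: str | Path, groups_path: str | Path
) -> IntensityMatrix:
    """Read a proteinGroups-like intensity table plus its sample->group map."""
    df = pd.read_csv(matrix_path, sep="\t", comment="#")
    meta_cols = {"accession", "gene", "contaminant"}
    sample_cols = [c for c in df.columns if c not in meta_cols]
    df = df.set_index("accession")
    groups = (
        pd.read_csv(groups_path, sep="\t", comment="#")
        .set_index("sample")["group"]
    )
    values = df[sample_cols].apply(pd.to_numeric, errors="coerce")
    values = values.where(values > 0)  # zero intensity == not quantified
    contaminant = (
        df["contaminant"].fillna("").astype(str).str.strip() == "+"
        if "contaminant" in df
        else pd.Series(False, index=df.index)
    )
    gene = df["gene"] if "gene" in df else None
    return IntensityMatrix(
        values=values, groups=groups, gene=gene, contaminant=contaminant
    )


def write_differential_tsv(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="accession")


def write_overlap_json(path: str | Path, comparison) -> None:
    payload = {
        "sets": {k: sorted(v) for k, v in comparison.sets.items()},
        "shared": {f"{a}|{b}": n for (a, b), n in comparison.shared.items()},
        "unique": {f"{a}|{b}": n for (a, b), n in comparison.unique.items()},
        "common": sorted(comparison.common),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_table2() -> pd.DataFrame:
    """The shipped transcription of the published differential-enrichment
    table (42 proteins, HA-decorated vs control plasma-exposed vesicles).

    ``adj_p_value`` holds the printed values, which are consistent with
    -log10-transformed BH-adjusted p values; ``not_in_nascent`` marks the
    rows printed in bold (protein absent from all nascent-vesicle sets).
    """
    ref = importlib.resources.files("sprcorona") / "data" / "table2.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("ev_previous", "ev_this_study", "not_in_nascent"):
        df[col] = df[col].fillna("").astype(str).str.strip() != ""
    return df


def table2_significance_counts(
    table: pd.DataFrame | None = None, threshold_neglog10: float = 1.30
) -> dict[str, int]:
    """Sign/threshold bookkeeping of the shipped table.

    Reads the printed adjusted p values on the -log10 scale and counts
    proteins at or above the published significance line, split by fold-
    change sign, plus the bolded not-in-nascent rows.
    """
    t = load_table2() if table is None else table
    sig = t[t["adj_p_value"] >= threshold_neglog10]
    return {
        "significant_total": int(len(sig)),
        "reduced_abundance": int((sig["log2fc"] < 0).sum()),
        "increased_abundance": int((sig["log2fc"] > 0).sum()),
        "not_in_nascent": int(sig["not_in_nascent"].sum()),
    }


def _layer_from_config(entry: Mapping) -> OpticalLayer:
    name = entry.get("name", "layer")
    thickness = entry.get("thickness_nm")
    if "material" in entry and entry["material"] == "gold":
        from .optics import gold_index

        return OpticalLayer(name, thickness, gold_index)
    idx = entry["refractive_index"]
    if isinstance(idx, Mapping):
        table = {
            float(wl): complex(float(v[0]), float(v[1]))
            if isinstance(v, (list, tuple))
            else complex(v)
            for wl, v in idx.items()
        }
        return OpticalLayer(name, thickness, table)
    n = complex(float(idx))
    return OpticalLayer(name, thickness, lambda wl, _n=n: _n)


def load_config(path: str | Path) -> tuple[OpticalStack, InstrumentModel]:
    """Build a stack and instrument from a TOML config.

    Sections: ``[[stack.layers]]`` (ordered; omit ``thickness_nm`` for the
    semi-infinite prism/ambient, set ``material = "gold"`` for the shipped
    gold dispersion), ``[instrument]`` (keys mirroring
    :class:`InstrumentModel`) and optional ``[gold_dispersion]`` overrides
    ``{wavelength = [n, k]}`` applied to the built-in table.
    """
    import tomllib

    with open(path, "rb") as fh:
        cfg = tomllib.load(fh)
    for wl, nk in cfg.get("gold_dispersion", {}).items():
        GOLD_NK[float(wl)] = complex(float(nk[0]), float(nk[1]))
    layers = [_layer_from_config(e) for e in cfg["stack"]["layers"]]
    inst_cfg = cfg.get("instrument", {})
    if "wavelengths" in inst_cfg:
        inst_cfg["wavelengths"] = tuple(float(w) for w in inst_cfg["wavelengths"])
    return OpticalStack(layers), InstrumentModel(**inst_cfg)
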