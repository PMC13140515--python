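"""Perseus-style post-quantification proteomics statistics.

Reporter-ion protein intensities (a MaxQuant ``proteinGroups``-like table)
are filtered for contaminants and minimum valid values per group, scaled
so every sample's summed intensity matches the largest sample sum,
log2-transformed, and missing values are imputed from a downshifted,
narrowed normal (width * sigma, mean - downshift * sigma) that mimics the
abundance region where values drop below the detection limit. Group
differences are then tested protein-wise with two-sample t tests and
Benjamini-Hochberg adjusted; a protein is called significantly
differentially enriched when its adjusted (-log10) p value is >= 1.30,
i.e. p_adj <= 10^(-1.30).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "IntensityMatrix",
    "SetComparison",
    "SIGNIFICANCE_NEGLOG10_P",
    "filter_proteins",
    "normalize",
    "log2_transform",
    "impute",
    "differential",
    "set_overlap",
    "top_enriched",
]

# Figure-style significance line: adjusted (-log10) p of 1.30 exactly,
# i.e. p_adj <= 10**-1.30 (~0.0501), not a rounded 0.05.
SIGNIFICANCE_NEGLOG10_P = 1.30


@dataclass(frozen=True)
class IntensityMatrix:
    """Protein x sample intensities with group labels.

    ``values``: DataFrame indexed by protein accession, one column per
    sample; NaN marks a missing value. ``groups`` maps sample -> group
    label. ``gene`` maps accession -> gene name; ``contaminant`` flags
    potential contaminant proteins. ``log_space`` records whether values
    are log2 intensities.
    """

    values: pd.DataFrame
    groups: pd.Series
    gene: pd.Series | None = None
    contaminant: pd.Series | None = None
    log_space: bool = False

    def __post_init__(self) -> None:
        v = self.values
        missing = set(v.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        counts = self.groups.loc[list(v.columns)].value_counts()
        if len(counts) < 1 or counts.max() < 2:
            raise ValueError("need at least one group with >= 2 samples")
        if not self.log_space and bool((v < 0).any().any()):
            raise ValueError("raw intensities must be >= 0")
        gene = self.gene if self.gene is not None else pd.Series(
            v.index, index=v.index
        )
        contaminant = (
            self.contaminant
            if self.contaminant is not None
            else pd.Series(False, index=v.index)
        )
        object.__setattr__(self, "gene", gene.reindex(v.index))
        object.__setattr__(
            self, "contaminant", contaminant.reindex(v.index).fillna(False)
        )

    def group_columns(self, group: str) -> list[str]:
        cols = [c for c in self.values.columns if self.groups[c] == group]
        if not cols:
            raise KeyError(f"no samples in group {group!r}")
        return cols

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for c in self.values.columns:
            g = self.groups[c]
            if g not in seen:
                seen.append(g)
        return seen


def filter_proteins(
    m: IntensityMatrix, min_valid: int = 3, require_all_groups: bool = False
) -> IntensityMatrix:
    """Remove contaminants and proteins with too few valid values.

    Default reading: a protein is kept when at least one sample group has
    >= ``min_valid`` present values. ``require_all_groups=True`` applies
    the stricter reading (every group must reach ``min_valid``).
    """
    if min_valid < 1:
        raise ValueError("min_valid must be >= 1")
    keep = ~m.contaminant.to_numpy(dtype=bool)
    per_group = []
    for g in m.group_names:
        cols = m.group_columns(g)
        per_group.append(m.values[cols].notna().sum(axis=1) >= min_valid)
    counts = pd.concat(per_group, axis=1)
    keep &= counts.all(axis=1) if require_all_groups else counts.any(axis=1)
    return replace(m, values=m.values.loc[keep])


def normalize(m: IntensityMatrix, per: str = "sample") -> IntensityMatrix:
    """Equalise summed intensities across samples.

    Each sample column is divided by its own summed intensity and
    multiplied by the maximum summed intensity across all samples, so all
    column sums end up equal to that maximum. ``per="group"`` applies the
    alternative reading: one factor per sample group, computed from group
    total intensities.
    """
    if m.log_space:
        raise ValueError("normalize operates on raw intensities, not log space")
    v = m.values
    col_sums = v.sum(axis=0, skipna=True)
    if (col_sums <= 0).any():
        bad = col_sums.index[col_sums <= 0].tolist()
        raise ValueError(f"zero or negative summed intensity in samples: {bad}")
    if per == "sample":
        factors = col_sums.max() / col_sums
    elif per == "group":
        group_of = m.groups.loc[list(v.columns)]
        group_sums = col_sums.groupby(group_of).sum()
        scale = group_sums.max() / group_sums
        factors = pd.Series(
            [scale[group_of[c]] for c in v.columns], index=v.columns
        )
    else:
        raise ValueError("per must be 'sample' or 'group'")
    return replace(m, values=v * factors)


def log2_transform(m: IntensityMatrix) -> IntensityMatrix:
    """Log2-transform intensities; zeros become missing values."""
    if m.log_space:
        return m
    v = m.values.where(m.values > 0)
    return replace(m, values=np.log2(v), log_space=True)


def impute(
    m: IntensityMatrix,
    width: float = 0.3,
    downshift: float = 1.8,
    seed: int | np.random.Generator = 0,
    reference: str = "sample",
) -> IntensityMatrix:
    """Replace missing log2 intensities by downshifted-normal draws.

    For reference column c with present-value mean mu_c and sd sigma_c,
    each missing cell receives a draw from
    Normal(mu_c - downshift * sigma_c, (width * sigma_c)^2) — the typical
    abundance region of values below the detection limit. ``reference``
    selects the distribution scope: per sample column (default, the
    standard Perseus behaviour) or per protein row (``"protein"``).
    Present values are never touched; results are reproducible by seed.
    """
    if not m.log_space:
        raise ValueError("impute expects log2-transformed intensities")
    rng = (
        seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    )
    v = m.values.copy()
    axis_items = (
        [(c, v[c]) for c in v.columns]
        if reference == "sample"
        else [(i, v.loc[i]) for i in v.index]
    )
    if reference not in ("sample", "protein"):
        raise ValueError("reference must be 'sample' or 'protein'")
    for name, series in axis_items:
        missing = series.isna()
        if not missing.any():
            continue
        present = series.dropna()
        if present.size < 2:
            raise ValueError(
                f"cannot estimate imputation sd: reference {name!r} has "
                f"{present.size} present value(s)"
            )
        mu, sigma = float(present.mean()), float(present.std(ddof=1))
        draws = rng.normal(mu - downshift * sigma, width * sigma, int(missing.sum()))
        if reference == "sample":
            v.loc[missing, name] = draws
        else:
            v.loc[name, missing[missing].index] = draws
    return replace(m, values=v)


def differential(
    m: IntensityMatrix,
    group_a: str,
    group_b: str,
    test: str = "student",
    alpha_neglog10: float = SIGNIFICANCE_NEGLOG10_P,
) -> pd.DataFrame:
    """Protein-wise differential enrichment of group A versus group B.

    Two-sample t tests on log2 intensities (pooled-variance Student by
    default, Welch via ``test="welch"``), Benjamini-Hochberg adjusted
    across all testable proteins. log2 fold change is mean(A) - mean(B).
    Proteins with zero variance in both groups (t undefined) are flagged
    ``tested=False`` and excluded from the BH family.
    """
    if not m.log_space:
        raise ValueError("differential expects log2-transformed intensities")
    a = m.values[m.group_columns(group_a)].to_numpy()
    b = m.values[m.group_columns(group_b)].to_numpy()
    if a.shape[1] < 2 or b.shape[1] < 2:
        raise ValueError("both groups need >= 2 samples")
    if np.isnan(a).any() or np.isnan(b).any():
        raise ValueError("matrix contains missing values; impute first")
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=(test == "student"))
    degenerate = (a.var(axis=1) == 0) & (b.var(axis=1) == 0)
    p = np.where(degenerate, np.nan, p)
    tested = np.isfinite(p)
    p_adj = np.full_like(log2fc, np.nan)
    if tested.any():
        p_adj[tested] = multipletests(p[tested], method="fdr_bh")[1]
    significant = np.where(
        tested, p_adj <= 10.0 ** (-alpha_neglog10), False
    )
    return pd.DataFrame(
        {
            "gene": m.gene.reindex(m.values.index).to_numpy(),
            "log2fc": log2fc,
            "p": p,
            "p_adj": p_adj,
            "neg_log10_p_adj": -np.log10(p_adj),
            "significant": significant,
            "tested": tested,
        },
        index=m.values.index,
    )


@dataclass(frozen=True)
class SetComparison:
    """Pairwise and n-way overlap bookkeeping of detected-protein sets."""

    sets: dict[str, frozenset]
    shared: dict[tuple[str, str], int]
    unique: dict[tuple[str, str], int]  # count in first set only, vs second
    common: frozenset  # n-way intersection

    def union_size(self, a: str, b: str) -> int:
        return len(self.sets[a] | self.sets[b])


def set_overlap(detections: dict[str, "set[str] | list[str]"]) -> SetComparison:
    """Exact shared/unique counts for all pairs plus the n-way intersection.

    Duplicate identifiers within one input set are deduplicated with a
    warning.
    """
    clean: dict[str, frozenset] = {}
    for name, ids in detections.items():
        ids = list(ids)
        fs = frozenset(ids)
        if len(fs) != len(ids):
            warnings.warn(
                f"set {name!r}: {len(ids) - len(fs)} duplicate identifier(s) "
                "removed",
                stacklevel=2,
            )
        clean[name] = fs
    names = list(clean)
    shared, unique = {}, {}
    for a in names:
        for b in names:
            if a == b:
                continue
            shared[(a, b)] = len(clean[a] & clean[b])
            unique[(a, b)] = len(clean[a] - clean[b])
    common = frozenset.intersection(*clean.values()) if clean else frozenset()
    return SetComparison(clean, shared, unique, common)


def top_enriched(
    m: IntensityMatrix, k: int = 20, group: str | None = None
) -> pd.DataFrame:
    """Proteins ranked by mean intensity across a condition's replicates.

    Ties are broken by accession in lexicographic order. When ``k`` exceeds
    the protein count, all proteins are returned (with a warning note).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    cols = m.group_columns(group) if group is not None else list(m.values.columns)
    means = m.values[cols].mean(axis=1, skipna=True)
    idx_name = m.values.index.name or "accession"
    order = (
        pd.DataFrame(
            {
                idx_name: means.index,
                "gene": m.gene.reindex(means.index).to_numpy(),
                "mean_intensity": means.to_numpy(),
            }
        )
        .sort_values(
            ["mean_intensity", idx_name], ascending=[False, True], kind="stable"
        )
        .set_index(idx_name)
    )
    if k > len(order):
        warnings.warn(
            f"k={k} exceeds protein count {len(order)}; returning all",
            stacklevel=2,
        )
    return order.head(k)
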