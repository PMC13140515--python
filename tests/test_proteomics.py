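"""Filtering, normalization, imputation, differential testing, overlaps."""

import numpy as np
import pandas as pd
import pytest

from sprcorona.io import load_table2, table2_significance_counts
from sprcorona.proteomics import (
    IntensityMatrix,
    differential,
    filter_proteins,
    impute,
    log2_transform,
    normalize,
    set_overlap,
    top_enriched,
)


def make_matrix(values, samples=None, groups=None, contaminant=None, log_space=False):
    values = np.asarray(values, dtype=float)
    n_prot, n_samp = values.shape
    samples = samples or [f"s{j}" for j in range(n_samp)]
    if groups is None:
        half = n_samp // 2
        groups = ["A"] * half + ["B"] * (n_samp - half)
    acc = [f"P{i:03d}" for i in range(n_prot)]
    df = pd.DataFrame(values, index=acc, columns=samples)
    df.index.name = "accession"
    return IntensityMatrix(
        values=df,
        groups=pd.Series(groups, index=samples),
        contaminant=pd.Series(
            contaminant if contaminant is not None else [False] * n_prot, index=acc
        ),
        log_space=log_space,
    )


class TestFilter:
    def test_one_full_group_keeps_protein(self):
        m = make_matrix([[1, 2, 3, np.nan, np.nan, np.nan]])
        assert len(filter_proteins(m).values) == 1

    def test_no_group_reaching_three_removes(self):
        m = make_matrix([[1, 2, np.nan, 4, 5, np.nan]])
        assert len(filter_proteins(m).values) == 0

    def test_contaminant_removed_despite_full_data(self):
        m = make_matrix([[1, 2, 3, 4, 5, 6]], contaminant=[True])
        assert len(filter_proteins(m).values) == 0

    def test_strict_reading_requires_every_group(self):
        m = make_matrix([[1, 2, 3, np.nan, np.nan, np.nan]])
        assert len(filter_proteins(m, require_all_groups=True).values) == 0


class TestNormalize:
    def test_column_sums_equalised_by_formula(self):
        m = make_matrix([[4.0, 8.0], [6.0, 12.0]], groups=["A", "A"])
        out = normalize(m)
        # sums 10 and 20 -> factors 2 and 1
        assert np.allclose(out.values.sum(axis=0), 20.0)
        assert np.allclose(out.values["s0"], [8.0, 12.0])

    def test_equal_sums_identity(self):
        m = make_matrix([[1.0, 2.0], [3.0, 2.0]], groups=["A", "A"])
        out = normalize(m)
        assert np.allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_random_matrix_property_and_idempotence(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.lognormal(3, 1, (50, 6)))
        out = normalize(m)
        sums = out.values.sum(axis=0).to_numpy()
        assert np.max(np.abs(sums / sums[0] - 1)) < 1e-9
        twice = normalize(out)
        assert np.allclose(twice.values.to_numpy(), out.values.to_numpy(), rtol=1e-12)

    def test_zero_sum_column_rejected(self):
        m = make_matrix([[0.0, 1.0], [0.0, 2.0]], groups=["A", "A"])
        with pytest.raises(ValueError):
            normalize(m)


class TestImpute:
    def test_no_missing_returned_unchanged(self):
        m = make_matrix(np.arange(12.0).reshape(2, 6) + 1, log_space=True)
        out = impute(m, seed=1)
        assert np.array_equal(out.values.to_numpy(), m.values.to_numpy())

    def test_seed_determinism_and_present_untouched(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(20, 1, (30, 4))
        vals[rng.random((30, 4)) < 0.2] = np.nan
        m = make_matrix(vals, groups=["A", "A", "B", "B"], log_space=True)
        a = impute(m, seed=42)
        b = impute(m, seed=42)
        assert np.array_equal(a.values.to_numpy(), b.values.to_numpy())
        present = ~np.isnan(vals)
        assert np.array_equal(a.values.to_numpy()[present], vals[present])
        assert not np.isnan(a.values.to_numpy()).any()

    def test_draw_moments_match_downshifted_normal(self):
        # large column: mu ~ 20, sigma ~ 1 -> draws ~ N(18.2, 0.3^2)
        rng = np.random.default_rng(8)
        n = 2 * 10**5
        col = rng.normal(20.0, 1.0, n)
        present_mask = np.ones(n, dtype=bool)
        present_mask[: n // 2] = False  # half the cells missing
        vals = np.where(present_mask, col, np.nan).reshape(-1, 1)
        vals = np.hstack([vals, np.full((n, 1), 20.0)])
        m = make_matrix(vals, groups=["A", "A"], log_space=True)
        out = impute(m, seed=9)
        drawn = out.values.to_numpy()[~present_mask, 0]
        mu = np.mean(col[present_mask])
        sigma = np.std(col[present_mask], ddof=1)
        n_draw = drawn.size
        assert abs(np.mean(drawn) - (mu - 1.8 * sigma)) < 3 * 0.3 * sigma / np.sqrt(n_draw)
        assert np.std(drawn) == pytest.approx(0.3 * sigma, rel=0.01)

    def test_underdetermined_column_named_in_error(self):
        vals = np.array([[np.nan, 1.0], [np.nan, 2.0], [3.0, 3.0]])
        m = make_matrix(vals, groups=["A", "A"], log_space=True)
        with pytest.raises(ValueError, match="s0"):
            impute(m, seed=0)


class TestDifferential:
    def test_identical_groups_zero_log2fc(self):
        rng = np.random.default_rng(2)
        half = rng.normal(20, 1, (20, 3))
        m = make_matrix(np.hstack([half, half]), log_space=True)
        table = differential(m, "A", "B")
        assert np.allclose(table["log2fc"], 0.0)

    def test_bh_hand_example(self):
        # engineer 4 proteins whose raw p values are known, then compare
        # the BH column against the hand-computed step-up minimum
        rng = np.random.default_rng(0)
        m = make_matrix(rng.normal(20, 1, (4, 6)), log_space=True)
        table = differential(m, "A", "B")
        p = table["p"].to_numpy()
        mtests = len(p)
        order = np.argsort(p)
        stepped = p[order] * mtests / (np.arange(mtests) + 1)
        expected_sorted = np.minimum.accumulate(stepped[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(expected_sorted, 1.0)
        assert np.allclose(table["p_adj"].to_numpy(), expected)

    def test_zero_variance_both_groups_flagged(self):
        vals = np.array([[1.0, 1.0, 1.0, 2.0, 2.0, 2.0], [1, 2, 3, 4, 5, 6.0]])
        m = make_matrix(vals, log_space=True)
        table = differential(m, "A", "B")
        assert not table["tested"].iloc[0]
        assert table["tested"].iloc[1]
        # BH family excludes the untested protein
        assert table["p_adj"].iloc[1] == pytest.approx(table["p"].iloc[1])

    def test_welch_option_differs_with_unequal_variance(self):
        rng = np.random.default_rng(5)
        a = rng.normal(20, 0.1, (50, 3))
        b = rng.normal(20, 3.0, (50, 4))
        m = make_matrix(
            np.hstack([a, b]), groups=["A"] * 3 + ["B"] * 4, log_space=True
        )
        student = differential(m, "A", "B")["p"].to_numpy()
        welch = differential(m, "A", "B", test="welch")["p"].to_numpy()
        assert not np.allclose(student, welch)

    def test_significance_threshold_is_neglog10_1p30(self):
        # the cutoff must be 10^-1.30 (~0.0501), not 0.05
        rng = np.random.default_rng(1)
        m = make_matrix(rng.normal(20, 1, (5, 6)), log_space=True)
        table = differential(m, "A", "B")
        cutoff = 10.0 ** -1.30
        assert np.array_equal(
            table["significant"].to_numpy(), table["p_adj"].to_numpy() <= cutoff
        )
        assert cutoff > 0.05  # the two conventions genuinely differ


class TestSetOverlap:
    def test_small_example(self):
        cmp = set_overlap({"x": {"A", "B", "C"}, "y": {"B", "C", "D"}})
        assert cmp.shared[("x", "y")] == 2
        assert cmp.unique[("x", "y")] == 1
        assert cmp.unique[("y", "x")] == 1
        assert cmp.union_size("x", "y") == 4

    def test_identical_sets(self):
        cmp = set_overlap({"x": {"A", "B"}, "y": {"A", "B"}})
        assert cmp.unique[("x", "y")] == 0 and cmp.shared[("x", "y")] == 2

    def test_duplicates_warn_and_dedupe(self):
        with pytest.warns(UserWarning, match="duplicate"):
            cmp = set_overlap({"x": ["A", "A", "B"], "y": ["B"]})
        assert len(cmp.sets["x"]) == 2

    def test_three_sets_match_brute_force(self):
        rng = np.random.default_rng(17)
        alphabet = [f"ID{i}" for i in range(300)]
        sets = {
            name: set(rng.choice(alphabet, 100, replace=False)) for name in "pqr"
        }
        cmp = set_overlap(sets)
        for a in "pqr":
            for b in "pqr":
                if a == b:
                    continue
                shared_bf = sum(1 for x in sets[a] if x in sets[b])
                assert cmp.shared[(a, b)] == shared_bf
                assert cmp.unique[(a, b)] == len(sets[a]) - shared_bf
        assert cmp.common == sets["p"] & sets["q"] & sets["r"]


class TestTopEnriched:
    def test_unique_maximum(self):
        m = make_matrix([[1.0, 1.0], [5.0, 5.0], [3.0, 3.0]], groups=["A", "A"])
        top = top_enriched(m, k=1, group="A")
        assert list(top.index) == ["P001"]

    def test_column_permutation_invariance(self):
        rng = np.random.default_rng(4)
        vals = rng.lognormal(3, 1, (20, 4))
        m = make_matrix(vals, groups=["A"] * 4)
        perm = make_matrix(vals[:, [2, 0, 3, 1]], groups=["A"] * 4)
        assert list(top_enriched(m, 5, "A").index) == list(
            top_enriched(perm, 5, "A").index
        )

    def test_matches_brute_force_sort(self):
        rng = np.random.default_rng(12)
        vals = rng.lognormal(3, 1, (50, 3))
        m = make_matrix(vals, groups=["A"] * 3)
        top = top_enriched(m, 50, "A")
        means = m.values.mean(axis=1)
        oracle = sorted(means.index, key=lambda a: (-means[a], a))
        assert list(top.index) == oracle

    def test_k_beyond_count_returns_all_with_note(self):
        m = make_matrix([[1.0, 2.0]], groups=["A", "A"])
        with pytest.warns(UserWarning, match="exceeds"):
            top = top_enriched(m, k=5)
        assert len(top) == 1


class TestTable2Fixture:
    def test_shape_and_columns(self):
        t = load_table2()
        assert len(t) == 42
        assert {"gene", "accession", "log2fc", "adj_p_value"} <= set(t.columns)
        assert t["accession"].is_unique

    def test_sign_threshold_bookkeeping(self):
        counts = table2_significance_counts()
        assert counts["significant_total"] == 42
        assert counts["reduced_abundance"] == 14
        assert counts["increased_abundance"] == 28
        assert counts["not_in_nascent"] == 12

    def test_named_entries_transcribed(self):
        t = load_table2().set_index("gene")
        assert t.loc["TF", "log2fc"] == pytest.approx(2.147)
        assert t.loc["TF", "accession"] == "P02787"
        assert t.loc["TMEM209", "log2fc"] == pytest.approx(-2.977)
        assert bool(t.loc["SERPINA1", "not_in_nascent"])
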