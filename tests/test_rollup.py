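"""Protein rollup, contaminant removal, Welch/BH statistics and the
enrichment call."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxidia.containers import DesignTable
from proxidia.rollup import (
    ThresholdParams,
    benjamini_hochberg,
    differential_test,
    enrichment_call,
    remove_nontarget,
    rollup_proteins,
    welch_ttest,
)

from conftest import build_matrix


def welch_oracle(a, b):
    """Independent closed-form Welch-Satterthwaite computation."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1) / na, b.var(ddof=1) / nb
    t = (a.mean() - b.mean()) / np.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (na - 1) + vb**2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, df, p


def bh_oracle(pvals):
    """Brute-force step-up: q_(i) = min_{k >= i} m p_(k) / k, capped at 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sp = p[order]
    q_sorted = np.empty(m)
    for i in range(m):
        q_sorted[i] = min(min(m * sp[j] / (j + 1) for j in range(i, m)), 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestRollup:
    def test_peptides_summed_per_protein(self):
        m = build_matrix(
            [[1e6, 5.0], [2e6, 6.0], [7.0, 8.0]],
            samples=["s1", "s2"],
            proteins=["P1", "P1", "P2"],
        )
        table = rollup_proteins(m)
        assert table.n_proteins == 2
        assert table.intensities.iloc[0].tolist() == [3e6, 11.0]
        assert table.meta.loc[0, "n_peptides"] == 2

    def test_single_peptide_protein_is_identity(self):
        m = build_matrix([[4.0, 5.0]], samples=["s1", "s2"], proteins=["P9"])
        table = rollup_proteins(m)
        assert table.intensities.iloc[0].tolist() == [4.0, 5.0]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.uniform(1, 10, size=(12, 3))
        proteins = [f"P{i % 4}" for i in range(12)]
        m = build_matrix(values, samples=["a", "b", "c"], proteins=proteins)
        perm = rng.permutation(12)
        m2 = m.subset(m.intensities.index[perm])
        t1 = rollup_proteins(m).intensities.set_index(
            rollup_proteins(m).meta["protein"]
        )
        t2 = rollup_proteins(m2).intensities.set_index(
            rollup_proteins(m2).meta["protein"]
        )
        pd.testing.assert_frame_equal(t1.sort_index(), t2.sort_index())

    def test_biotinylated_evidence_aggregated(self):
        m = build_matrix(
            [[1.0], [2.0]],
            samples=["s1"],
            proteins=["P1", "P1"],
            biotinylated=[False, True],
        )
        assert bool(rollup_proteins(m).meta.loc[0, "biotinylated_evidence"])


class TestRemoveNontarget:
    def test_contaminant_and_species_flags_dropped(self):
        m = build_matrix(
            [[1.0], [2.0], [3.0]],
            samples=["s1"],
            proteins=["KRT1", "XEN1", "P1"],
            contaminant=[True, False, False],
            nontarget_species=[False, True, False],
        )
        table, removed = remove_nontarget(rollup_proteins(m))
        assert list(table.meta["protein"]) == ["P1"]
        assert set(removed) == {"KRT1", "XEN1"}

    def test_no_flags_is_identity(self):
        m = build_matrix([[1.0], [2.0]], samples=["s1"], proteins=["P1", "P2"])
        table, removed = remove_nontarget(rollup_proteins(m))
        assert table.n_proteins == 2 and removed == []

    def test_external_annotation_merged(self):
        m = build_matrix([[1.0], [2.0]], samples=["s1"], proteins=["P1", "P2"])
        ann = pd.DataFrame({"protein": ["P2"], "contaminant": [True]})
        table, removed = remove_nontarget(rollup_proteins(m), ann)
        assert removed == ["P2"]


class TestWelch:
    def test_spec_example_values(self):
        t, df, p = welch_ttest([1, 2, 3], [2, 3, 4])
        assert t == pytest.approx(-1.2247, abs=1e-4)
        assert df == pytest.approx(4.0)
        assert p == pytest.approx(0.2878, abs=1e-4)

    def test_matches_closed_form_oracle_on_random_samples(self):
        rng = np.random.default_rng(123)
        for _ in range(1000):
            na, nb = rng.integers(3, 9, size=2)
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), na)
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), nb)
            t, df, p = welch_ttest(a, b)
            t0, df0, p0 = welch_oracle(a, b)
            assert abs(t - t0) < 1e-10
            assert abs(df - df0) < 1e-10
            assert abs(p - p0) < 1e-10

    def test_summary_statistic_identity(self):
        # p recomputed from (mean, SEM, n) equals p from raw values
        rng = np.random.default_rng(7)
        a, b = rng.normal(0, 1, 5), rng.normal(1, 2, 4)
        _, _, p_raw = welch_ttest(a, b)
        sa2, sb2 = a.var(ddof=1) / 5, b.var(ddof=1) / 4
        t = (a.mean() - b.mean()) / np.sqrt(sa2 + sb2)
        df = (sa2 + sb2) ** 2 / (sa2**2 / 4 + sb2**2 / 3)
        assert abs(p_raw - 2 * stats.t.sf(abs(t), df)) < 1e-10

    def test_zero_variance_conventions(self):
        assert welch_ttest([1, 1, 1], [1, 1, 1])[2] == 1.0
        assert welch_ttest([2, 2, 2], [1, 1, 1])[2] == 0.0


class TestBenjaminiHochberg:
    def test_spec_example_all_adjust_to_004(self):
        q = benjamini_hochberg([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_matches_brute_force_on_grid_vectors(self):
        rng = np.random.default_rng(99)
        grid = np.round(np.arange(0.01, 1.0, 0.01), 2)
        for length in range(1, 9):
            for _ in range(40):
                p = rng.choice(grid, size=length)
                assert np.allclose(
                    benjamini_hochberg(p), bh_oracle(p), atol=1e-12
                )

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=50)
        q = benjamini_hochberg(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()


class TestDifferentialTest:
    def make_proteins(self, ca, dn, proteins=None):
        arr = np.column_stack([np.asarray(ca), np.asarray(dn)])
        values = arr.reshape(len(arr), -1)
        m = build_matrix(values, proteins=proteins)
        return rollup_proteins(m)

    def test_enrichment_call_boundaries_strict(self):
        thr = ThresholdParams()
        assert not enrichment_call(1.5, 0.01, thr)   # FC exactly at threshold
        assert not enrichment_call(2.0, 0.05, thr)   # q exactly at threshold
        assert enrichment_call(1.51, 0.049, thr)
        assert not enrichment_call(np.nan, 0.01, thr)

    def test_mink1_style_protein_called_enriched(self, design_3v3):
        # FC 2.15 with tiny replicate noise: q < 0.001 and the call is made
        rng = np.random.default_rng(0)
        values = np.vstack(
            [
                np.concatenate([2.15e6 * (1 + rng.normal(0, 1e-3, 3)),
                                1e6 * (1 + rng.normal(0, 1e-3, 3))]),
                np.concatenate([1.0e6 * (1 + rng.normal(0, 1e-3, 3)),
                                1e6 * (1 + rng.normal(0, 1e-3, 3))]),
            ]
        )
        m = build_matrix(values, proteins=["Mink1", "Ctrl"])
        res = differential_test(rollup_proteins(m), design_3v3)
        row = res.set_index("protein").loc["Mink1"]
        assert row["fc"] == pytest.approx(2.15, rel=2e-3)
        assert row["q"] < 0.001
        assert bool(row["enriched"])

    def test_group_label_swap_inverts_fc_keeps_p(self, design_3v3):
        rng = np.random.default_rng(11)
        values = rng.lognormal(13, 1, size=(20, 6))
        m = build_matrix(values)
        res = differential_test(rollup_proteins(m), design_3v3)
        swapped = DesignTable(design_3v3.table, "DN", "CA")
        res_sw = differential_test(rollup_proteins(m), swapped)
        assert np.allclose(res["fc"], 1.0 / res_sw["fc"])
        assert np.allclose(res["p"], res_sw["p"], atol=1e-12)

    def test_zero_group_mean_flagged_untestable(self, design_3v3):
        values = np.array(
            [[0.0, 0.0, 0.0, 1.0, 2.0, 3.0], [5.0, 6.0, 7.0, 5.0, 6.0, 7.0]]
        )
        m = build_matrix(values)
        res = differential_test(rollup_proteins(m), design_3v3)
        assert bool(res.loc[0, "untestable"])
        assert np.isnan(res.loc[0, "fc"])
        assert not bool(res.loc[0, "enriched"])

    def test_fc_modes(self, design_3v3):
        values = np.array([[4.0, 8.0, 16.0, 1.0, 2.0, 4.0]])
        m = build_matrix(values)
        linear = differential_test(rollup_proteins(m), design_3v3,
                                   fc_mode="linear_means")
        logm = differential_test(rollup_proteins(m), design_3v3,
                                 fc_mode="log_means")
        assert linear.loc[0, "fc"] == pytest.approx(28.0 / 7.0)
        assert logm.loc[0, "fc"] == pytest.approx(4.0)
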