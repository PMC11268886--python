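"""Charge-state collapse, the three imputation rules, occurrence filter."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from proxidia.containers import AmbiguityError, PeptideMatrix, ValidationError
from proxidia.preprocess import (
    ImputationParams,
    collapse_charge_states,
    impute_missing,
    occurrence_filter,
)

from conftest import build_matrix

NA = np.nan


def precursor_matrix(rows, samples):
    """rows: (sequence, charge, protein, values...)"""
    ann = pd.DataFrame(
        [r[:3] for r in rows], columns=["sequence", "charge", "protein"]
    )
    X = pd.DataFrame([r[3:] for r in rows], columns=samples, dtype=float)
    return PeptideMatrix(ann, X)


class TestCollapse:
    def test_charge_states_summed_per_sequence(self):
        m = precursor_matrix(
            [
                ("PEPK", 2, "P1", 1e6, 2e6),
                ("PEPK", 3, "P1", 2e6, NA),
                ("OTHR", 2, "P2", 5.0, 6.0),
            ],
            ["s1", "s2"],
        )
        out = collapse_charge_states(m)
        assert out.n_peptides == 2
        assert out.intensities.iloc[0].tolist() == [3e6, 2e6]

    def test_cell_missing_only_when_all_charges_missing(self):
        m = precursor_matrix(
            [("PEPK", 2, "P1", NA, 1e6), ("PEPK", 3, "P1", NA, NA)],
            ["s1", "s2"],
        )
        out = collapse_charge_states(m)
        assert np.isnan(out.intensities.loc[0, "s1"])
        assert out.intensities.loc[0, "s2"] == 1e6

    def test_flags_or_combined(self):
        ann = pd.DataFrame(
            {
                "sequence": ["PEPK", "PEPK"],
                "charge": [2, 3],
                "protein": ["P1", "P1"],
                "biotinylated": [True, False],
                "phospho": [False, True],
            }
        )
        X = pd.DataFrame({"s1": [1.0, 2.0]})
        out = collapse_charge_states(PeptideMatrix(ann, X))
        assert bool(out.annotations.loc[0, "biotinylated"])
        assert bool(out.annotations.loc[0, "phospho"])

    def test_conflicting_protein_mapping_is_ambiguity_error(self):
        m = precursor_matrix(
            [("PEPK", 2, "P1", 1.0), ("PEPK", 3, "P2", 2.0)], ["s1"]
        )
        with pytest.raises(AmbiguityError, match="PEPK"):
            collapse_charge_states(m)


class TestImputationRules:
    def test_rule2_sets_zero_when_mostly_missing_and_intense(self, design_3v3):
        # filler rows keep the global intensity range well defined
        values = [[6e6, NA, NA, 6e6, 6.1e6, 5.9e6]] + [
            [1e4, 1.1e4, 0.9e4, 1e4, 1.2e4, 0.8e4]
        ] * 10
        m = build_matrix(values)
        out, mask, counts = impute_missing(m, design_3v3, ImputationParams(seed=1))
        assert out.intensities.loc[0, "CA_2"] == 0.0
        assert out.intensities.loc[0, "CA_3"] == 0.0
        assert counts["rule2"] == 2

    def test_rule2_requires_strictly_more_than_half_missing(self, design_2v2):
        # 1 of 2 missing is exactly half: falls through to the low-tail pool
        values = [[6e6, NA, 6e6, 6.1e6]] + [
            [1e4, 1.1e4, 1.05e4, 0.95e4]
        ] * 10
        m = build_matrix(values, samples=["CA_1", "CA_2", "DN_1", "DN_2"])
        out, mask, counts = impute_missing(m, design_2v2, ImputationParams(seed=1))
        assert counts["rule2"] == 0
        assert counts["rule3"] == 1
        assert out.intensities.loc[0, "CA_2"] > 0

    def test_rule3_draws_come_from_lowest_tail_pool(self, design_3v3):
        rng = np.random.default_rng(0)
        filler = rng.uniform(1e5, 1e6, size=(200, 6))
        values = np.vstack([[1e4, NA, NA, 1e4, 1.1e4, 0.9e4], filler])
        m = build_matrix(values)
        params = ImputationParams(seed=2)
        out, mask, counts = impute_missing(m, design_3v3, params)
        measured = values[~np.isnan(values)]
        k = max(1, int(np.floor(measured.size * params.low_tail_fraction)))
        pool = set(np.sort(measured)[:k])
        assert counts["rule3"] == 2
        assert out.intensities.loc[0, "CA_2"] in pool
        assert out.intensities.loc[0, "CA_3"] in pool

    def test_rule1_draws_match_bin_normal_distribution(self, design_3v3):
        # 10,000 target peptides, each missing one cell in a 3-sample group;
        # anchors at 1e3/1e9 pin the global bin grid so the 1e6-cloud sits in
        # one bin, whose empirical moments are computed independently here
        n = 10_000
        lo, hi = 10**6.05, 10**6.15
        targets = np.tile([lo, hi, NA, lo, hi, lo], (n, 1))
        anchors = np.array(
            [[1e3, 1e3, 1e3, 1e3, 1e3, 1e3], [1e9, 1e9, 1e9, 1e9, 1e9, 1e9]]
        )
        values = np.vstack([targets, anchors])
        m = build_matrix(values)
        params = ImputationParams(seed=3)
        out, mask, counts = impute_missing(m, design_3v3, params)
        assert counts["rule1"] == n

        measured = values[~np.isnan(values)]
        edges = np.linspace(3.0, 9.0, params.n_bins + 1)
        cloud_bin = np.digitize(6.1, edges) - 1
        logm = np.log10(measured)
        in_bin = measured[
            (logm >= edges[cloud_bin]) & (logm < edges[cloud_bin + 1])
        ]
        draws = out.intensities.iloc[:n]["CA_3"].to_numpy()
        ks = stats.kstest(
            draws, "norm", args=(in_bin.mean(), in_bin.std(ddof=1))
        )
        assert ks.pvalue > 0.01

    def test_measured_cells_bit_identical_and_no_missing_left(self, design_3v3):
        rng = np.random.default_rng(5)
        values = rng.uniform(1e4, 1e7, size=(50, 6))
        drop = rng.random(values.shape) < 0.2
        values[drop] = NA
        m = build_matrix(values)
        out, mask, _ = impute_missing(m, design_3v3, ImputationParams(seed=7))
        assert out.intensities.notna().all().all()
        before = m.intensities.to_numpy()
        after = out.intensities.to_numpy()
        keep = mask.to_numpy()
        assert np.array_equal(before[keep], after[keep])

    def test_identity_when_no_cells_missing(self, design_3v3):
        values = np.random.default_rng(1).uniform(1e4, 1e6, size=(20, 6))
        m = build_matrix(values)
        out, mask, counts = impute_missing(m, design_3v3, ImputationParams())
        assert out.intensities.equals(m.intensities)
        assert sum(counts.values()) == 0

    def test_same_seed_reproducible_draws(self, design_3v3):
        rng = np.random.default_rng(9)
        values = rng.uniform(1e4, 1e7, size=(40, 6))
        values[rng.random(values.shape) < 0.3] = NA
        m = build_matrix(values)
        a, _, _ = impute_missing(m, design_3v3, ImputationParams(seed=42))
        b, _, _ = impute_missing(m, design_3v3, ImputationParams(seed=42))
        assert a.intensities.equals(b.intensities)

    def test_all_missing_matrix_rejected(self, design_3v3):
        m = build_matrix(np.full((3, 6), NA))
        with pytest.raises(ValidationError):
            impute_missing(m, design_3v3, ImputationParams())


class TestOccurrenceFilter:
    @pytest.mark.parametrize(
        "detected, kept",
        [
            # detected only in CA_1: 1 total -> removed
            ([1, 0, 0, 0, 0, 0], False),
            # CA_1 and DN_1: 2 total but 1/3 per group -> removed
            ([1, 0, 0, 1, 0, 0], False),
            # CA_1, CA_2: 2 total and 2/3 in CA -> kept
            ([1, 1, 0, 0, 0, 0], True),
            # everywhere -> kept
            ([1, 1, 1, 1, 1, 1], True),
        ],
    )
    def test_stated_examples(self, design_3v3, detected, kept):
        values = np.where(np.array([detected], dtype=bool), 5e5, NA)
        values = np.vstack([values, np.full((1, 6), 4e5)])  # companion row
        m = build_matrix(values)
        mask = m.detection_mask
        imputed, _, _ = impute_missing(m, design_3v3, ImputationParams(seed=0))
        out = occurrence_filter(imputed, mask, design_3v3)
        assert (m.annotations.loc[0, "sequence"] in
                set(out.annotations["sequence"])) == kept

    def test_idempotent_and_order_independent(self, design_3v3):
        rng = np.random.default_rng(3)
        values = rng.uniform(1e4, 1e6, size=(30, 6))
        values[rng.random(values.shape) < 0.5] = NA
        m = build_matrix(values)
        mask = m.detection_mask
        imputed, _, _ = impute_missing(m, design_3v3, ImputationParams(seed=0))
        once = occurrence_filter(imputed, mask, design_3v3)
        twice = occurrence_filter(
            once, mask.loc[once.intensities.index], design_3v3
        )
        assert once.annotations.equals(twice.annotations)

        perm = rng.permutation(len(values))
        m2 = imputed.subset(imputed.intensities.index[perm])
        out2 = occurrence_filter(m2, mask.iloc[perm], design_3v3)
        assert set(out2.annotations["sequence"]) == set(
            once.annotations["sequence"]
        )
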