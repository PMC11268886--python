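"""Protein rollup, contaminant removal and the differential enrichment test.

The enrichment statistic is the published recipe: per protein, the fold
change is the ratio of the experimental-group mean intensity to the
control-group mean on the linear scale, significance comes from a
two-tailed heteroscedastic (Welch) t-test on log2-transformed protein
intensities with Benjamini-Hochberg adjustment across proteins, and a
protein is called enriched when FC > 1.5 (strict) and the adjusted
p-value is below 0.05 (strict).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .containers import DesignTable, PeptideMatrix, ProteinTable, ValidationError

_FC_MODES = ("linear_means", "log_means")


@dataclass
class ThresholdParams:
    """Enrichment-call thresholds (both comparisons strict)."""

    fc_threshold: float = 1.5
    q_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValidationError("fc_threshold must be > 0")
        if not 0.0 < self.q_threshold < 1.0:
            raise ValidationError("q_threshold must be in (0, 1)")


def enrichment_call(fc: float, q: float, thresholds: ThresholdParams) -> bool:
    """FC strictly above the FC threshold and q strictly below the q threshold."""
    if np.isnan(fc) or np.isnan(q):
        return False
    return (fc > thresholds.fc_threshold) and (q < thresholds.q_threshold)


def rollup_proteins(matrix: PeptideMatrix) -> ProteinTable:
    """Sum all peptide values of a protein into one intensity per sample."""
    if matrix.n_missing:
        raise ValidationError("rollup requires a matrix with no missing cells")
    ann = matrix.annotations
    keys = ann["protein"]
    X = matrix.intensities.groupby(keys.values, sort=False).sum()
    meta = ann.groupby(keys.values, sort=False).agg(
        gene=("gene", "first"),
        n_peptides=("sequence", "size"),
        biotinylated_evidence=("biotinylated", "any"),
        phospho_evidence=("phospho", "any"),
        contaminant=("contaminant", "any"),
        nontarget_species=("nontarget_species", "any"),
    )
    meta.insert(0, "protein", meta.index)
    meta = meta.reset_index(drop=True)
    X = X.reset_index(drop=True)
    return ProteinTable(meta, X)


def remove_nontarget(
    proteins: ProteinTable, annotation: pd.DataFrame | None = None
) -> tuple[ProteinTable, list[str]]:
    """Drop contaminant and non-target-species proteins (keratins, avidins...).

    ``annotation`` may supply extra per-protein flags (columns ``protein``
    plus any of ``contaminant``/``nontarget_species``) to merge with the
    flags carried on the peptide report.  Returns the filtered table and
    the list of removed protein ids.
    """
    flagged = proteins.meta["contaminant"] | proteins.meta["nontarget_species"]
    if annotation is not None:
        ann = annotation.set_index("protein")
        for col in ("contaminant", "nontarget_species"):
            if col in ann.columns:
                extra = proteins.meta["protein"].map(ann[col]).eq(True)
                flagged |= extra.to_numpy()
    removed = list(proteins.meta.loc[flagged.to_numpy(), "protein"])
    return proteins.subset(~flagged.to_numpy()), removed


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-tailed Welch t-test; returns (t, Welch-Satterthwaite df, p).

    Degenerate variance handling: if both groups have zero variance the
    p-value is 1 for equal means (no evidence) and 0 otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0.0 and vb == 0.0:
        if a.mean() == b.mean():
            return 0.0, float(len(a) + len(b) - 2), 1.0
        return np.inf if a.mean() > b.mean() else -np.inf, float(
            len(a) + len(b) - 2
        ), 0.0
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / len(a), vb / len(b)
    df = (sa + sb) ** 2 / (
        sa**2 / (len(a) - 1) + sb**2 / (len(b) - 1)
    )
    return float(res.statistic), float(df), float(res.pvalue)


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """Step-up FDR adjustment across all tested hypotheses."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def _differential_core(
    X: pd.DataFrame,
    design: DesignTable,
    thresholds: ThresholdParams,
    fc_mode: str,
    log2_zero_replacement: float | None = None,
) -> pd.DataFrame:
    design.require_replicates(2)
    expt_cols = design.samples_in(design.experimental)
    ctrl_cols = design.samples_in(design.control)
    A = X[expt_cols].to_numpy(dtype=float)
    B = X[ctrl_cols].to_numpy(dtype=float)
    mean_a = A.mean(axis=1)
    mean_b = B.mean(axis=1)

    # zeros are legal assigned intensities but cannot enter log2; replace
    # with half the smallest positive value in the matrix
    if log2_zero_replacement is None:
        positive = X.to_numpy()[X.to_numpy() > 0]
        log2_zero_replacement = (
            positive.min() / 2.0 if positive.size else np.nan
        )
    logA = np.log2(np.where(A > 0, A, log2_zero_replacement))
    logB = np.log2(np.where(B > 0, B, log2_zero_replacement))

    n = len(X)
    t_stat = np.full(n, np.nan)
    dof = np.full(n, np.nan)
    p = np.full(n, np.nan)
    for i in range(n):
        t_stat[i], dof[i], p[i] = welch_ttest(logA[i], logB[i])

    untestable = (mean_a <= 0) | (mean_b <= 0)
    if fc_mode == "linear_means":
        with np.errstate(divide="ignore", invalid="ignore"):
            fc = np.where(untestable, np.nan, mean_a / mean_b)
    else:
        fc = np.where(
            untestable, np.nan, 2.0 ** (logA.mean(axis=1) - logB.mean(axis=1))
        )
    p = np.where(untestable, np.nan, p)

    q = np.full(n, np.nan)
    testable = ~np.isnan(p)
    q[testable] = benjamini_hochberg(p[testable])
    enriched = np.array(
        [enrichment_call(f, qq, thresholds) for f, qq in zip(fc, q)]
    )
    return pd.DataFrame(
        {
            "mean_experimental": mean_a,
            "mean_control": mean_b,
            "fc": fc,
            "log2_fc": np.log2(fc),
            "t": t_stat,
            "df": dof,
            "p": p,
            "q": q,
            "enriched": enriched,
            "untestable": untestable,
        },
        index=X.index,
    )


def differential_test(
    proteins: ProteinTable,
    design: DesignTable,
    thresholds: ThresholdParams | None = None,
    fc_mode: str = "linear_means",
) -> pd.DataFrame:
    """Per-protein fold change, Welch test on log2 intensities, BH FDR, call.

    Parameters
    ----------
    proteins : ProteinTable
        Rolled-up, contaminant-free protein intensities.
    design : DesignTable
        Two-group design with >= 2 samples per group.
    thresholds : ThresholdParams
        FC and FDR-adjusted p cutoffs for the enrichment call.
    fc_mode : {"linear_means", "log_means"}
        Fold change as the ratio of linear-scale group means (default) or
        back-transformed from the mean log2 difference.
    """
    thresholds = thresholds or ThresholdParams()
    if fc_mode not in _FC_MODES:
        raise ValidationError(f"fc_mode must be one of {_FC_MODES}")
    stats_frame = _differential_core(
        proteins.intensities, design, thresholds, fc_mode
    )
    out = pd.concat(
        [
            proteins.meta[
                ["protein", "gene", "n_peptides", "biotinylated_evidence"]
            ].reset_index(drop=True),
            stats_frame.reset_index(drop=True),
        ],
        axis=1,
    )
    return out


def differential_test_peptides(
    matrix: PeptideMatrix,
    design: DesignTable,
    thresholds: ThresholdParams | None = None,
    fc_mode: str = "linear_means",
) -> pd.DataFrame:
    """The same differential statistic applied per peptide row.

    Used for phosphopeptides, which are quantified and gated at the
    peptide level before being mapped back to proteins.
    """
    thresholds = thresholds or ThresholdParams()
    if fc_mode not in _FC_MODES:
        raise ValidationError(f"fc_mode must be one of {_FC_MODES}")
    if matrix.n_missing:
        raise ValidationError("peptide-level test requires a complete matrix")
    stats_frame = _differential_core(
        matrix.intensities, design, thresholds, fc_mode
    )
    out = pd.concat(
        [
            matrix.annotations[
                ["sequence", "protein", "gene", "biotinylated", "phospho"]
            ].reset_index(drop=True),
            stats_frame.reset_index(drop=True),
        ],
        axis=1,
    )
    return out
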