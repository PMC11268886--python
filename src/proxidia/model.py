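"""Model/Results interface tying the enrichment pipeline together.

:class:`ProximityEnrichmentModel` holds the inputs (a precursor-level
peptide report and a two-group sample design) and the analysis
parameters; :meth:`~ProximityEnrichmentModel.fit` executes the stage
order

    collapse charge states -> impute missing values -> occurrence filter
    -> total-intensity normalization -> trimmed-mean normalization
    -> protein rollup -> contaminant removal -> differential test

and returns a :class:`ProximityEnrichmentResults` carrying the
per-protein estimates (fold changes, Welch statistics, FDR-adjusted
p-values, enrichment calls), normalization diagnostics and stage
counts.  Network assembly, phosphopeptide filtering and volcano plotting
hang off the results object.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .containers import DesignTable, PeptideMatrix
from .network import (
    KinasePSSM,
    build_network,
    kinase_percentile_gate,
    phospho_filter_chain,
)
from .normalize import total_intensity_normalize, trimmed_mean_normalize
from .preprocess import (
    ImputationParams,
    collapse_charge_states,
    impute_missing,
    occurrence_filter,
)
from .rollup import (
    ThresholdParams,
    differential_test,
    differential_test_peptides,
    remove_nontarget,
    rollup_proteins,
)


class ProximityEnrichmentModel:
    """Differential enrichment model for a proximity-labeling DIA experiment.

    Parameters
    ----------
    peptides : PeptideMatrix
        Precursor-level intensity report (pre-collapse).
    design : DesignTable
        Two-group sample design; the experimental group is the fold
        change numerator.
    imputation : ImputationParams, optional
        Missing-value imputation settings (procedure defaults).
    thresholds : ThresholdParams, optional
        FC/FDR gates for the enrichment call (FC > 1.5, q < 0.05).
    trim_fraction : float
        Two-sided trim for trimmed-mean normalization.
    annotation : DataFrame, optional
        Extra per-protein contaminant/non-target flags.
    fc_mode : {"linear_means", "log_means"}
        Fold change convention.
    """

    def __init__(
        self,
        peptides: PeptideMatrix,
        design: DesignTable,
        imputation: ImputationParams | None = None,
        thresholds: ThresholdParams | None = None,
        trim_fraction: float = 0.10,
        annotation: pd.DataFrame | None = None,
        fc_mode: str = "linear_means",
    ) -> None:
        design.validate_matrix(peptides)
        self.peptides = peptides
        self.design = design
        self.imputation = imputation or ImputationParams()
        self.thresholds = thresholds or ThresholdParams()
        self.trim_fraction = trim_fraction
        self.annotation = annotation
        self.fc_mode = fc_mode

    # -- constructors --------------------------------------------------------

    @classmethod
    def from_files(
        cls,
        report_path,
        design_path,
        columns=None,
        experimental=None,
        control=None,
        **kwargs,
    ) -> "ProximityEnrichmentModel":
        """Build from a delimited peptide report and a design table."""
        matrix = pio.read_peptide_report(report_path, columns=columns)
        design = pio.read_design(design_path, experimental, control)
        return cls(matrix, design, **kwargs)

    @classmethod
    def from_simulation(cls, config, **kwargs):
        """Simulate a report and return ``(model, truth_table)``."""
        from .simulate import design_for, simulate_peptide_report

        matrix, truth = simulate_peptide_report(config)
        model = cls(matrix, design_for(config), **kwargs)
        return model, truth

    # -- estimation ----------------------------------------------------------

    def fit(self) -> "ProximityEnrichmentResults":
        log: list[str] = []
        stage_counts: dict[str, int] = {}
        stage_counts["precursors"] = self.peptides.n_peptides

        collapsed = collapse_charge_states(self.peptides)
        stage_counts["peptides_collapsed"] = collapsed.n_peptides
        log.append(
            f"collapsed {stage_counts['precursors']} precursors into "
            f"{collapsed.n_peptides} peptides"
        )

        imputed, mask, imp_counts = impute_missing(
            collapsed, self.design, self.imputation
        )
        log.append(
            "imputed cells by rule: "
            + ", ".join(f"{k}={v}" for k, v in imp_counts.items())
            + f" (seed={self.imputation.seed})"
        )

        filtered = occurrence_filter(imputed, mask, self.design)
        mask = mask.loc[filtered.intensities.index]
        stage_counts["peptides_after_filter"] = filtered.n_peptides
        log.append(
            f"occurrence filter removed "
            f"{collapsed.n_peptides - filtered.n_peptides} peptides"
        )

        normalized, report_total = total_intensity_normalize(filtered)
        normalized, report_trim = trimmed_mean_normalize(
            normalized, self.trim_fraction
        )
        norm_report = report_total.merge(report_trim, on="sample")

        proteins = rollup_proteins(normalized)
        stage_counts["proteins"] = proteins.n_proteins
        proteins, removed = remove_nontarget(proteins, self.annotation)
        stage_counts["proteins_after_contaminant_removal"] = proteins.n_proteins
        if removed:
            log.append(f"removed {len(removed)} contaminant/non-target proteins")

        results = differential_test(
            proteins, self.design, self.thresholds, self.fc_mode
        )
        stage_counts["proteins_tested"] = int((~results["untestable"]).sum())
        stage_counts["proteins_enriched"] = int(results["enriched"].sum())
        log.append(
            f"{stage_counts['proteins_enriched']} proteins enriched at "
            f"FC > {self.thresholds.fc_threshold}, "
            f"q < {self.thresholds.q_threshold}"
        )
        return ProximityEnrichmentResults(
            model=self,
            proteins=results,
            protein_table=proteins,
            peptides=normalized,
            detection_mask=mask,
            normalization=norm_report,
            imputation_counts=imp_counts,
            stage_counts=stage_counts,
            log=log,
        )


class ProximityEnrichmentResults:
    """Fitted enrichment results.

    Attributes
    ----------
    proteins : DataFrame
        One row per protein: group means, ``fc``, ``log2_fc``, ``t``,
        ``df``, ``p``, ``q``, ``enriched``, ``untestable``, peptide
        counts and biotinylated-peptide evidence.
    peptides : PeptideMatrix
        The normalized, complete peptide matrix the rollup used.
    normalization : DataFrame
        Per-sample scale factors from both normalization stages.
    stage_counts : dict
        Row counts through the pipeline stages.
    """

    def __init__(
        self,
        model,
        proteins,
        protein_table,
        peptides,
        detection_mask,
        normalization,
        imputation_counts,
        stage_counts,
        log,
    ) -> None:
        self.model = model
        self.proteins = proteins
        self.protein_table = protein_table
        self.peptides = peptides
        self.detection_mask = detection_mask
        self.normalization = normalization
        self.imputation_counts = imputation_counts
        self.stage_counts = stage_counts
        self.log = log

    # -- summaries -----------------------------------------------------------

    @property
    def enriched(self) -> pd.DataFrame:
        return self.proteins.loc[self.proteins["enriched"]]

    def summary(self, top: int = 10) -> str:
        """Human-readable fit summary (counts, thresholds, top proteins)."""
        thr = self.model.thresholds
        design = self.model.design
        lines = [
            "Proximity enrichment results",
            "=" * 60,
            f"groups:            {design.experimental} (experimental) vs "
            f"{design.control} (control)",
            f"samples:           {design.n_in(design.experimental)} + "
            f"{design.n_in(design.control)}",
            f"precursors:        {self.stage_counts['precursors']}",
            f"peptides kept:     {self.stage_counts['peptides_after_filter']}",
            f"proteins tested:   {self.stage_counts['proteins_tested']}",
            f"enriched:          {self.stage_counts['proteins_enriched']} "
            f"(FC > {thr.fc_threshold}, q < {thr.q_threshold})",
            "-" * 60,
            f"{'gene':<14}{'FC':>8}{'log2FC':>9}{'p':>11}{'q':>11}",
        ]
        head = self.enriched.sort_values("q").head(top)
        for rec in head.itertuples(index=False):
            lines.append(
                f"{rec.gene:<14}{rec.fc:>8.3f}{rec.log2_fc:>9.3f}"
                f"{rec.p:>11.3g}{rec.q:>11.3g}"
            )
        lines.append("=" * 60)
        return "\n".join(lines)

    def volcano_data(self) -> pd.DataFrame:
        """Volcano export: log2 FC, -log10 raw p and the enrichment flag."""
        out = self.proteins.loc[
            ~self.proteins["untestable"],
            ["protein", "gene", "log2_fc", "p", "q", "enriched"],
        ].copy()
        out["neg_log10_p"] = -np.log10(out["p"].clip(lower=1e-300))
        return out.reset_index(drop=True)

    def plot_volcano(self, ax=None):
        """Volcano plot with dashed guides at FC = +/-1.5 and p = 0.05."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 4))
        data = self.volcano_data()
        colors = np.where(data["enriched"], "crimson", "grey")
        ax.scatter(data["log2_fc"], data["neg_log10_p"], s=8, c=colors,
                   alpha=0.7, linewidths=0)
        fc = self.model.thresholds.fc_threshold
        ax.axvline(np.log2(fc), ls="--", c="k", lw=0.8)
        ax.axvline(-np.log2(fc), ls="--", c="k", lw=0.8)
        ax.axhline(-np.log10(0.05), ls="--", c="k", lw=0.8)
        ax.set_xlabel("log2 fold change")
        ax.set_ylabel("-log10 p")
        return ax

    # -- downstream analyses -------------------------------------------------

    def build_network(
        self,
        external_edges: pd.DataFrame | None = None,
        score_cutoff: float = 0.7,
        bait: str = "Rac1",
        include_bait_edges: bool = True,
    ):
        return build_network(
            self.proteins, external_edges, score_cutoff, bait,
            include_bait_edges,
        )

    def phospho_peptide_results(self) -> pd.DataFrame:
        """Peptide-level differential statistics for phospho-flagged rows."""
        ann = self.peptides.annotations
        phospho = self.peptides.subset(ann["phospho"].to_numpy())
        if phospho.n_peptides == 0:
            return pd.DataFrame(
                columns=["sequence", "protein", "gene", "fc", "q", "enriched"]
            )
        return differential_test_peptides(
            phospho, self.model.design, self.model.thresholds,
            self.model.fc_mode,
        )

    def phospho_chain(self, phospho: pd.DataFrame | None = None):
        """Run the three-stage phosphopeptide filter against these results."""
        if phospho is None:
            phospho = self.phospho_peptide_results()
        return phospho_filter_chain(phospho, self.proteins,
                                    self.model.thresholds)

    def kinase_pairs(
        self,
        sites: pd.DataFrame,
        pssms,
        background=None,
        percentile_cutoff: float = 90.0,
    ) -> pd.DataFrame:
        """Gate candidate sites against kinase PSSMs (percentile > cutoff)."""
        objs = []
        for name, mat in (pssms.items() if isinstance(pssms, dict) else pssms):
            objs.append(KinasePSSM(name, mat, background or []))
        return kinase_percentile_gate(sites, objs, percentile_cutoff)

    # -- persistence ---------------------------------------------------------

    def to_directory(self, path) -> Path:
        """Write the results tables to a directory (TSV + JSON)."""
        out = Path(path)
        out.mkdir(parents=True, exist_ok=True)
        pio.write_results(self.proteins, out / "protein_results.tsv")
        pio.write_results(self.normalization, out / "normalization_report.tsv")
        pio.write_results(self.volcano_data(), out / "volcano.tsv")
        with open(out / "stage_counts.json", "w") as fh:
            json.dump(self.stage_counts, fh, indent=1, sort_keys=True)
        with open(out / "run.log", "w") as fh:
            fh.write("\n".join(self.log) + "\n")
        return out
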