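"""Core tabular containers for peptide-level DIA proteomics data.

The in-memory model mirrors a search-engine peptide export: one row per
precursor (peptide sequence x charge) with a protein/gene mapping and
modification flags, and one column per sample.  Missing cells (peak
detection criteria not met) are ``NaN`` and are distinct from an observed
intensity of ``0``, which the imputation rules themselves can assign.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

#: modification / provenance flags carried on every precursor row
FLAG_COLUMNS = ("biotinylated", "phospho", "contaminant", "nontarget_species")


class ValidationError(ValueError):
    """An input table violates the format contract."""


class AmbiguityError(ValidationError):
    """A peptide sequence maps to more than one protein."""


@dataclass
class PeptideMatrix:
    """Peptide (precursor) x sample intensity table.

    Parameters
    ----------
    annotations : pandas.DataFrame
        Row metadata.  Required columns: ``sequence``, ``protein``.
        Optional: ``charge`` (present before charge-state collapse),
        ``gene`` and the boolean flags in :data:`FLAG_COLUMNS` (created
        with defaults when absent).
    intensities : pandas.DataFrame
        Float intensities, same index as ``annotations``; ``NaN`` marks a
        missing (undetected) cell, values must be non-negative.
    """

    annotations: pd.DataFrame
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        ann = self.annotations.copy()
        X = self.intensities.copy()
        if not ann.index.equals(X.index):
            raise ValidationError(
                "annotation and intensity tables have different indices"
            )
        for col in ("sequence", "protein"):
            if col not in ann.columns:
                raise ValidationError(f"annotation table lacks column {col!r}")
        if "gene" not in ann.columns:
            ann["gene"] = ann["protein"]
        for col in FLAG_COLUMNS:
            ann[col] = ann[col].astype(bool) if col in ann.columns else False
        try:
            X = X.astype(float)
        except (TypeError, ValueError) as exc:
            raise ValidationError(f"non-numeric intensity value: {exc}") from exc
        with np.errstate(invalid="ignore"):
            neg = X.lt(0)
        if neg.to_numpy().any():
            row, col = np.argwhere(neg.to_numpy())[0]
            raise ValidationError(
                f"negative intensity for sequence "
                f"{ann['sequence'].iloc[row]!r}, sample {X.columns[col]!r}"
            )
        key = ["sequence", "charge"] if "charge" in ann.columns else ["sequence"]
        dup = ann.duplicated(subset=key)
        if dup.any():
            raise ValidationError(
                f"duplicate precursor keys: "
                f"{ann.loc[dup, key].to_records(index=False)[:5]!r}"
            )
        self.annotations = ann
        self.intensities = X

    # -- basic introspection -------------------------------------------------

    @property
    def samples(self) -> list[str]:
        return list(self.intensities.columns)

    @property
    def n_peptides(self) -> int:
        return len(self.annotations)

    @property
    def is_collapsed(self) -> bool:
        """True once charge states have been summed into peptide rows."""
        return "charge" not in self.annotations.columns

    @property
    def detection_mask(self) -> pd.DataFrame:
        """Boolean mask of originally measured cells (True = measured)."""
        return self.intensities.notna()

    @property
    def n_missing(self) -> int:
        return int(self.intensities.isna().to_numpy().sum())

    # -- manipulation --------------------------------------------------------

    def copy(self) -> "PeptideMatrix":
        return PeptideMatrix(self.annotations.copy(), self.intensities.copy())

    def subset(self, keep) -> "PeptideMatrix":
        """Row subset by boolean mask or index labels."""
        return PeptideMatrix(
            self.annotations.loc[keep].copy(), self.intensities.loc[keep].copy()
        )

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<PeptideMatrix {self.n_peptides} rows x {len(self.samples)} "
            f"samples, {self.n_missing} missing>"
        )


@dataclass
class DesignTable:
    """Sample -> biological group assignment for a two-group comparison.

    ``experimental`` / ``control`` name the numerator and denominator of
    the fold change (constitutively-active vs dominant-negative bait in
    the assay this package models, but any two labels work).
    """

    table: pd.DataFrame  # columns: sample, group, replicate
    experimental: str
    control: str

    def __post_init__(self) -> None:
        t = self.table
        for col in ("sample", "group"):
            if col not in t.columns:
                raise ValidationError(f"design table lacks column {col!r}")
        if "replicate" not in t.columns:
            t = t.copy()
            t["replicate"] = t.groupby("group", sort=False).cumcount() + 1
        if t["sample"].duplicated().any():
            raise ValidationError("duplicate sample ids in design table")
        groups = list(dict.fromkeys(t["group"]))
        if len(groups) != 2:
            raise ValidationError(
                f"exactly two groups required, found {groups!r}"
            )
        if {self.experimental, self.control} != set(groups):
            raise ValidationError(
                f"groups {groups!r} do not match experimental="
                f"{self.experimental!r} / control={self.control!r}"
            )
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        experimental: str | None = None,
        control: str | None = None,
    ) -> "DesignTable":
        """Build from a (sample, group[, replicate]) frame.

        When the groups are the conventional ``CA``/``DN`` labels the
        experimental group is inferred; otherwise the first group in file
        order is taken as experimental unless stated explicitly.
        """
        groups = list(dict.fromkeys(frame["group"]))
        if experimental is None:
            if set(groups) == {"CA", "DN"}:
                experimental, control = "CA", "DN"
            else:
                experimental = groups[0]
        if control is None:
            others = [g for g in groups if g != experimental]
            control = others[0] if others else None
        return cls(frame, experimental, control)

    @property
    def groups(self) -> tuple[str, str]:
        return (self.experimental, self.control)

    def samples_in(self, group: str) -> list[str]:
        t = self.table
        return list(t.loc[t["group"] == group, "sample"])

    def n_in(self, group: str) -> int:
        return len(self.samples_in(group))

    def validate_matrix(self, matrix: PeptideMatrix) -> None:
        """Every matrix column must appear exactly once in the design."""
        design_samples = list(self.table["sample"])
        missing = [s for s in matrix.samples if s not in design_samples]
        extra = [s for s in design_samples if s not in matrix.samples]
        if missing:
            raise ValidationError(f"samples absent from design: {missing!r}")
        if extra:
            raise ValidationError(f"design samples absent from matrix: {extra!r}")

    def require_replicates(self, n_min: int = 2) -> None:
        for g in self.groups:
            if self.n_in(g) < n_min:
                raise ValidationError(
                    f"group {g!r} has fewer than {n_min} samples"
                )


@dataclass
class ProteinTable:
    """Protein x sample intensities after peptide rollup."""

    meta: pd.DataFrame  # protein, gene, n_peptides, flag aggregates
    intensities: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.intensities.index):
            raise ValidationError("protein meta/intensity index mismatch")

    @property
    def n_proteins(self) -> int:
        return len(self.meta)

    def subset(self, keep) -> "ProteinTable":
        return ProteinTable(
            self.meta.loc[keep].copy(), self.intensities.loc[keep].copy()
        )
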