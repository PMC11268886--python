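"""Precursor collapse, missing-value imputation and occurrence filtering.

The imputation scheme models the two regimes of DIA dropout: values
missing within a mostly-observed group are treated as stochastic
(drawn from the intensity neighbourhood of the peptide), while peptides
missing in most of a group are treated as left-censored -- set to zero
when the peptide is otherwise intense (true absence in that group), or
drawn from the low tail of the observed intensity distribution.

Rule order per peptide x group:

1. missing fraction < ``group_missing_threshold``: each missing cell is
   drawn from a Normal whose mean/SD come from all measured values in the
   same intensity bin (``n_bins`` equal-width bins on log10 intensity over
   all measured values; the peptide's bin is chosen from its within-group
   measured mean).  Negative draws are redrawn.
2. missing fraction strictly > the threshold and the peptide's reference
   intensity > ``high_intensity_cutoff``: the group's missing cells are
   set to 0 (an intense peptide absent from most of a group is treated as
   genuinely absent there).
3. any still-missing cell is drawn uniformly from the pool of measured
   values below the ``low_tail_fraction`` quantile.

The boolean detection mask of originally measured cells is preserved
unchanged so that downstream filtering can refer to real detections.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd

from .containers import (
    AmbiguityError,
    DesignTable,
    PeptideMatrix,
    ValidationError,
)

_REFERENCE_STATS = ("group_mean", "global_mean", "group_max")
_BIN_SCALES = ("log10", "linear")


@dataclass
class ImputationParams:
    """Tunable parameters of the imputation rules.

    Defaults are the published procedure: 20 intensity bins, a 50%
    within-group missingness threshold, a 5e6 intensity cutoff for the
    set-to-zero rule, and a lowest-2% pool for left-censored draws.
    """

    n_bins: int = 20
    group_missing_threshold: float = 0.5
    high_intensity_cutoff: float = 5e6
    low_tail_fraction: float = 0.02
    bin_scale: str = "log10"
    reference_stat: str = "group_mean"
    min_bin_count: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 2:
            raise ValidationError("n_bins must be >= 2")
        for name in ("group_missing_threshold", "low_tail_fraction"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0, 1), got {v}")
        if self.bin_scale not in _BIN_SCALES:
            raise ValidationError(f"bin_scale must be one of {_BIN_SCALES}")
        if self.reference_stat not in _REFERENCE_STATS:
            raise ValidationError(
                f"reference_stat must be one of {_REFERENCE_STATS}"
            )


class ImputationResult(NamedTuple):
    matrix: PeptideMatrix
    mask: pd.DataFrame
    counts: dict


def collapse_charge_states(matrix: PeptideMatrix) -> PeptideMatrix:
    """Sum precursor charge states into a single value per peptide sequence.

    A cell is the sum over the measured charge states; it stays missing
    only when every charge state is missing.  Flags are OR-combined.  A
    sequence mapped to more than one protein is an error.
    """
    if matrix.is_collapsed:
        return matrix.copy()
    ann = matrix.annotations
    nprot = ann.groupby("sequence", sort=False)["protein"].nunique()
    ambiguous = nprot[nprot > 1]
    if len(ambiguous):
        raise AmbiguityError(
            f"sequences mapped to multiple proteins: {list(ambiguous.index[:5])!r}"
        )
    keys = ann["sequence"]
    X = matrix.intensities.groupby(keys.values, sort=False).sum(min_count=1)
    agg = {
        "protein": ("protein", "first"),
        "gene": ("gene", "first"),
        "biotinylated": ("biotinylated", "any"),
        "phospho": ("phospho", "any"),
        "contaminant": ("contaminant", "any"),
        "nontarget_species": ("nontarget_species", "any"),
    }
    meta = ann.groupby(keys.values, sort=False).agg(**agg)
    meta.insert(0, "sequence", meta.index)
    meta = meta.reset_index(drop=True)
    X = X.reset_index(drop=True)
    return PeptideMatrix(meta, X)


def _bin_statistics(measured: np.ndarray, params: ImputationParams):
    """Equal-width intensity bins over all measured values with pooled stats.

    Returns (edges, means, sds) on the linear intensity scale; bins with
    fewer than ``min_bin_count`` values are pooled with their nearest
    neighbouring bins until the count is reached.
    """
    if params.bin_scale == "log10":
        positive = measured[measured > 0]
        if positive.size == 0:
            raise ValidationError("no positive measured values to bin")
        coords = np.log10(positive)
        values = positive
    else:
        coords = measured
        values = measured
    lo, hi = coords.min(), coords.max()
    if hi == lo:
        hi = lo + 1e-9
    edges = np.linspace(lo, hi, params.n_bins + 1)
    idx = np.clip(np.digitize(coords, edges) - 1, 0, params.n_bins - 1)
    means = np.empty(params.n_bins)
    sds = np.empty(params.n_bins)
    for b in range(params.n_bins):
        pooled = values[idx == b]
        radius = 1
        while pooled.size < params.min_bin_count and radius < params.n_bins:
            sel = np.abs(idx - b) <= radius
            pooled = values[sel]
            radius += 1
        if pooled.size == 0:
            pooled = values
        means[b] = pooled.mean()
        sds[b] = pooled.std(ddof=1) if pooled.size > 1 else 0.0
    return edges, means, sds


def _low_tail_pool(measured: np.ndarray, fraction: float) -> np.ndarray:
    k = max(1, int(np.floor(measured.size * fraction)))
    return np.sort(measured)[:k]


def impute_missing(
    matrix: PeptideMatrix,
    design: DesignTable,
    params: ImputationParams | None = None,
) -> ImputationResult:
    """Fill every missing cell according to the three imputation rules.

    Returns the imputed matrix, the original detection mask (unchanged),
    and per-rule cell counts.  Draws come from a generator seeded with
    ``params.seed`` and are reproducible.
    """
    params = params or ImputationParams()
    design.validate_matrix(matrix)
    rng = np.random.default_rng(params.seed)
    mask = matrix.detection_mask
    X = matrix.intensities.to_numpy(copy=True)
    M = mask.to_numpy()
    measured = X[M]
    if measured.size == 0:
        raise ValidationError("matrix has no measured values at all")
    counts = {"rule1": 0, "rule2": 0, "rule3": 0}
    if not M.all():
        edges, bin_means, bin_sds = _bin_statistics(measured, params)
        columns = list(matrix.intensities.columns)
        global_row_mean = np.where(
            M.any(axis=1),
            np.nansum(np.where(M, X, np.nan), axis=1) / np.maximum(M.sum(axis=1), 1),
            np.nan,
        )
        for group in design.groups:
            cols = [columns.index(s) for s in design.samples_in(group)]
            sub = X[:, cols]
            subm = M[:, cols]
            n = len(cols)
            n_missing = (~subm).sum(axis=1)
            frac = n_missing / n
            with np.errstate(invalid="ignore"):
                group_mean = np.where(
                    subm.any(axis=1),
                    np.nansum(np.where(subm, sub, np.nan), axis=1)
                    / np.maximum(subm.sum(axis=1), 1),
                    np.nan,
                )
                group_max = np.where(
                    subm.any(axis=1),
                    np.max(np.where(subm, sub, -np.inf), axis=1),
                    np.nan,
                )
            if params.reference_stat == "group_mean":
                reference = group_mean
            elif params.reference_stat == "group_max":
                reference = group_max
            else:
                reference = global_row_mean
            reference = np.where(np.isnan(reference), global_row_mean, reference)

            # rule 1: sporadic within-group dropout
            rule1_rows = np.flatnonzero(
                (n_missing > 0)
                & (frac < params.group_missing_threshold)
                & (group_mean > 0)
            )
            if rule1_rows.size:
                if params.bin_scale == "log10":
                    coord = np.log10(group_mean[rule1_rows])
                else:
                    coord = group_mean[rule1_rows]
                bins = np.clip(
                    np.digitize(coord, edges) - 1, 0, params.n_bins - 1
                )
                for row, b in zip(rule1_rows, bins):
                    miss = np.flatnonzero(~subm[row])
                    draws = rng.normal(bin_means[b], bin_sds[b], size=miss.size)
                    for _ in range(1000):
                        bad = draws < 0
                        if not bad.any():
                            break
                        draws[bad] = rng.normal(
                            bin_means[b], bin_sds[b], size=bad.sum()
                        )
                    np.clip(draws, 0.0, None, out=draws)
                    X[row, np.array(cols)[miss]] = draws
                    counts["rule1"] += miss.size

            # rule 2: mostly-missing and intense -> genuinely absent
            rule2_rows = np.flatnonzero(
                (n_missing > 0)
                & (frac > params.group_missing_threshold)
                & (reference > params.high_intensity_cutoff)
            )
            for row in rule2_rows:
                miss = np.flatnonzero(~subm[row])
                X[row, np.array(cols)[miss]] = 0.0
                counts["rule2"] += miss.size

        # rule 3: everything still missing comes from the low-intensity pool
        still = np.isnan(X)
        if still.any():
            pool = _low_tail_pool(measured, params.low_tail_fraction)
            X[still] = rng.choice(pool, size=int(still.sum()), replace=True)
            counts["rule3"] = int(still.sum())

    out = PeptideMatrix(
        matrix.annotations.copy(),
        pd.DataFrame(X, index=mask.index, columns=mask.columns),
    )
    return ImputationResult(out, mask, counts)


def occurrence_filter(
    matrix: PeptideMatrix,
    mask: pd.DataFrame,
    design: DesignTable,
    min_total_detections: int = 2,
    min_group_fraction: float = 0.5,
) -> PeptideMatrix:
    """Drop peptides too sparsely detected to quantify.

    A peptide is kept when it was measured at least
    ``min_total_detections`` times across all samples *and* in at least
    ``min_group_fraction`` of the replicates of at least one group.
    Detections refer to the pre-imputation mask, never to imputed cells.
    """
    if not mask.index.equals(matrix.intensities.index):
        raise ValidationError("detection mask does not align with matrix")
    design.validate_matrix(matrix)
    total_ok = mask.sum(axis=1) >= min_total_detections
    group_ok = pd.Series(False, index=mask.index)
    for group in design.groups:
        cols = design.samples_in(group)
        group_ok |= mask[cols].sum(axis=1) >= min_group_fraction * len(cols)
    keep = total_ok & group_ok
    return matrix.subset(keep)
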