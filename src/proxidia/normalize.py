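"""Between-sample normalization: total-intensity then trimmed-mean scaling.

Both operations rescale each sample by a single positive factor so a
per-sample statistic (the column total, then the 10% two-sided trimmed
mean) equals the grand mean of that statistic across samples.  Each is
exactly idempotent and equivariant to per-sample rescaling of the input.
Zeros assigned by the imputation rules participate as the value 0.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .containers import PeptideMatrix, ValidationError


def _require_complete(matrix: PeptideMatrix, op: str) -> None:
    if matrix.n_missing:
        raise ValidationError(f"{op} requires a matrix with no missing cells")


def total_intensity_normalize(
    matrix: PeptideMatrix,
) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Scale each sample so all per-sample totals equal their grand mean."""
    _require_complete(matrix, "total_intensity_normalize")
    totals = matrix.intensities.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValidationError(
            f"samples with zero total intensity: {list(zero.index)!r}"
        )
    target = totals.mean()
    factors = target / totals
    X = matrix.intensities * factors
    report = pd.DataFrame(
        {
            "sample": totals.index,
            "raw_total": totals.to_numpy(),
            "total_scale_factor": factors.to_numpy(),
        }
    ).reset_index(drop=True)
    return PeptideMatrix(matrix.annotations.copy(), X), report


def trimmed_mean(values: np.ndarray, trim: float) -> float:
    """Mean after discarding ``floor(n * trim)`` values at each tail (by value)."""
    v = np.sort(np.asarray(values, dtype=float))
    k = int(np.floor(v.size * trim))
    kept = v[k : v.size - k]
    if kept.size == 0:
        raise ValidationError("trimmed set is empty; too few peptides")
    return float(kept.mean())


def trimmed_mean_normalize(
    matrix: PeptideMatrix, trim: float = 0.10
) -> tuple[PeptideMatrix, pd.DataFrame]:
    """Scale each sample so its two-sided trimmed mean equals the grand mean.

    The trim is per sample: the top and bottom ``trim`` fraction of that
    sample's values are excluded and the mean of the rest is the sample's
    scale statistic.
    """
    _require_complete(matrix, "trimmed_mean_normalize")
    if not 0.0 <= trim < 0.5:
        raise ValidationError(f"trim fraction must be in [0, 0.5), got {trim}")
    tms = matrix.intensities.apply(lambda col: trimmed_mean(col.to_numpy(), trim))
    zero = tms[tms == 0]
    if len(zero):
        raise ValidationError(
            f"samples with zero trimmed mean: {list(zero.index)!r}"
        )
    target = tms.mean()
    factors = target / tms
    X = matrix.intensities * factors
    report = pd.DataFrame(
        {
            "sample": tms.index,
            "trimmed_mean": tms.to_numpy(),
            "trimmed_mean_scale_factor": factors.to_numpy(),
            "trim_fraction": trim,
        }
    ).reset_index(drop=True)
    return PeptideMatrix(matrix.annotations.copy(), X), report
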