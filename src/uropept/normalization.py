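"""Reference-peptide scaling and healthy-control fold changes.

CE-MS peptide intensities are made comparable across runs by scaling each
sample so that the summed intensity of a panel of stable internal-standard
peptides (in the original platform: 29 collagen fragments unaffected by
disease) hits a common target.  The resulting unitless values are the
*relative peptide abundances* the rest of the pipeline consumes.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd

from .core import AbundanceMatrix

logger = logging.getLogger(__name__)

MISSING_POLICIES = ("zero-fill", "observed-only")


def normalize_to_reference(
    matrix: AbundanceMatrix,
    reference_ids: list[str],
    target: float | str = "cohort-median",
) -> AbundanceMatrix:
    """Scale each sample so its summed reference abundance equals ``target``.

    ``target`` is a positive number or ``"cohort-median"`` (the median of
    the per-sample reference sums, which makes the operation idempotent and
    keeps the cohort on its native intensity scale).  Samples with no
    detected reference peptide cannot be scaled and are excluded with a
    logged id.  The missingness pattern is unchanged.
    """
    missing_refs = set(reference_ids) - set(matrix.peptide_ids)
    if missing_refs:
        raise KeyError(f"reference ids absent from matrix: {sorted(missing_refs)}")
    ref_sums = matrix.values[reference_ids].sum(axis=1, min_count=1)
    no_ref = ref_sums.isna() | (ref_sums <= 0)
    if no_ref.any():
        excluded = list(matrix.values.index[no_ref])
        logger.info("excluded %d samples with no detected reference: %s",
                    len(excluded), excluded)
    kept = matrix.values.loc[~no_ref]
    ref_sums = ref_sums[~no_ref]
    if isinstance(target, str):
        if target != "cohort-median":
            raise ValueError("target must be a positive number or 'cohort-median'")
        target_value = float(ref_sums.median())
    else:
        if target <= 0:
            raise ValueError("target must be > 0")
        target_value = float(target)
    factors = target_value / ref_sums
    return AbundanceMatrix(kept.mul(factors, axis=0))


def _condition_means(
    values: pd.DataFrame, conditions: pd.Series, missing_policy: str, center: str
) -> pd.DataFrame:
    """Per-condition center (mean/median) of each peptide column.

    ``zero-fill`` counts non-detections as 0 (every subject of the condition
    contributes); ``observed-only`` averages over detected values only.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    data = values.fillna(0.0) if missing_policy == "zero-fill" else values
    grouped = data.groupby(conditions.loc[values.index].to_numpy())
    out = grouped.mean() if center == "mean" else grouped.median()
    out.index.name = "condition"
    return out


def fold_change_vs_controls(
    matrix: AbundanceMatrix,
    conditions: pd.Series,
    control_label: str = "HC",
    missing_policy: str = "zero-fill",
    center: str = "mean",
) -> pd.DataFrame:
    """Peptide x condition fold changes relative to healthy controls.

    Cell (p, c) = center abundance of peptide p in condition c divided by
    its center abundance in the control group; the control column is
    identically 1.  ``center`` selects mean (default) or median
    normalization.  Conditions with zero control center are reported
    missing with a warning.
    """
    aligned = conditions.reindex(matrix.values.index)
    if aligned.isna().any():
        missing = list(matrix.values.index[aligned.isna()])
        raise KeyError(f"samples without condition labels: {missing}")
    if control_label not in set(aligned):
        raise ValueError(f"control label {control_label!r} absent from conditions")
    means = _condition_means(matrix.values, aligned, missing_policy, center)
    control = means.loc[control_label]
    zero_control = control <= 0
    if zero_control.any():
        warnings.warn(
            f"zero control {center} for peptide(s) "
            f"{list(control.index[zero_control])}; fold changes undefined",
            stacklevel=2,
        )
    ratios = means.div(control.where(~zero_control, np.nan), axis=1)
    return ratios.T  # peptides as rows, conditions as columns
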