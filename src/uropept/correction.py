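"""Proteinuria correction of urinary peptide abundances.

Urinary abundance of a filtered peptide has two sources: glomerular
filtration of the circulating fragment, and unspecific protein leakage
(proteinuria).  To remove the leakage share, the per-protein *combined
abundance* (the sum over that protein's mutually exclusive fragments) is
regressed on proteinuria on the log-log scale,

    log10(combined abundance) = a + b * log10(proteinuria),

and the fitted slope b — the leakage elasticity of that protein's fragments
— is then subtracted from every individual peptide:

    log10(abundance corrected) = log10(abundance observed) - b * log10(proteinuria).

Fitting the slope on the combined variable rather than per peptide avoids
overfitting 23 separate slopes; by construction, re-regressing the corrected
combined abundance on log proteinuria over the same samples gives a slope of
exactly zero (OLS residualization).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import AbundanceMatrix

#: Proteinuria floor (g/g creatinine) applied before taking log10.  Measured
#: zeros are below the assay resolution, not true zeros: they are excluded
#: from slope *fitting* (a sentinel would bias b) but still *corrected*
#: using the floored value.
PROTEINURIA_FLOOR = 0.01


class InsufficientDataError(ValueError):
    """Fewer usable points than the fit requires."""


class DegenerateFitError(ValueError):
    """No variance in the regressor; the slope is undefined."""


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of log10(combined abundance) on log10(proteinuria)."""

    protein_id: str
    intercept_a: float
    slope_b: float
    n_used: int
    r: float
    stderr_b: float

    def __post_init__(self) -> None:
        if self.n_used < 3:
            raise InsufficientDataError(
                f"{self.protein_id}: fit reported with n_used={self.n_used} < 3"
            )
        if not np.isfinite(self.r) or abs(self.r) > 1 + 1e-12:
            raise ValueError(f"{self.protein_id}: invalid correlation r={self.r}")


def combined_abundance(
    matrix: AbundanceMatrix,
    peptide_map: Mapping[str, str],
    level: str = "protein",
) -> pd.DataFrame:
    """Sum member peptide abundances per protein (or per exclusivity group).

    ``peptide_map`` maps every peptide column to its protein id (or group
    label when ``level="group"``).  Within the sum a non-detected member
    contributes 0; the combined cell itself is missing only when *all*
    members are missing for that sample.
    """
    if level not in ("protein", "group"):
        raise ValueError("level must be 'protein' or 'group'")
    unmapped = [p for p in matrix.peptide_ids if p not in peptide_map]
    if unmapped:
        raise KeyError(f"unmapped peptide(s): {unmapped}")
    keys = [peptide_map[p] for p in matrix.peptide_ids]
    grouped = matrix.values.T.groupby(np.asarray(keys))
    combined = grouped.sum(min_count=1).T  # NaN only when every member missing
    combined.columns.name = level
    return combined


def estimate_proteinuria_slope(
    combined: pd.Series,
    proteinuria: pd.Series,
    protein_id: str = "",
    floor: float = PROTEINURIA_FLOOR,
) -> RegressionFit:
    """OLS of log10(combined) on log10(proteinuria) over the fitting subset.

    The fitting subset takes samples where the combined abundance is present
    and positive and proteinuria is present and above ``floor``.  Returns
    intercept a, slope b, the sample count, the Pearson r of the fitted
    points and the closed-form standard error of b.
    """
    proteinuria = proteinuria.reindex(combined.index)
    usable = (
        combined.notna()
        & (combined > 0)
        & proteinuria.notna()
        & (proteinuria > floor)
    )
    x = np.log10(proteinuria[usable].to_numpy(float))
    y = np.log10(combined[usable].to_numpy(float))
    if len(x) < 3:
        raise InsufficientDataError(
            f"{protein_id or 'fit'}: only {len(x)} usable points (need >= 3)"
        )
    if np.ptp(x) == 0:
        raise DegenerateFitError(
            f"{protein_id or 'fit'}: proteinuria constant on the fitting subset"
        )
    res = stats.linregress(x, y)
    return RegressionFit(
        protein_id=protein_id,
        intercept_a=float(res.intercept),
        slope_b=float(res.slope),
        n_used=len(x),
        r=float(res.rvalue),
        stderr_b=float(res.stderr),
    )


def fit_all_slopes(
    combined: pd.DataFrame,
    proteinuria: pd.Series,
    floor: float = PROTEINURIA_FLOOR,
) -> dict[str, RegressionFit]:
    """One slope fit per combined-abundance column."""
    return {
        str(col): estimate_proteinuria_slope(
            combined[col], proteinuria, protein_id=str(col), floor=floor
        )
        for col in combined.columns
    }


def correct_for_proteinuria(
    matrix: AbundanceMatrix,
    fits: Mapping[str, RegressionFit],
    peptide_map: Mapping[str, str],
    proteinuria: pd.Series,
    floor: float = PROTEINURIA_FLOOR,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-peptide proteinuria-corrected log10 abundances.

    Each peptide inherits the slope b fitted for its parent protein (or
    group).  The correction applies only where the peptide is detected
    (> 0) and proteinuria is present; other entries stay missing.  Returns
    the corrected log10 matrix plus a report counting skipped entries.
    No pseudo-abundance is imputed for non-detections.
    """
    missing_fits = {
        peptide_map[p]
        for p in matrix.peptide_ids
        if p not in peptide_map or peptide_map[p] not in fits
    }
    unmapped = [p for p in matrix.peptide_ids if p not in peptide_map]
    if unmapped:
        raise KeyError(f"unmapped peptide(s): {unmapped}")
    if missing_fits:
        raise KeyError(f"no slope fit for: {sorted(missing_fits)}")

    values = matrix.values
    pu = proteinuria.reindex(values.index).to_numpy(float)
    log_pu = np.log10(np.maximum(pu, floor))
    slopes = np.array([fits[peptide_map[p]].slope_b for p in matrix.peptide_ids])

    arr = values.to_numpy(float)
    detected = np.isfinite(arr) & (arr > 0)
    pu_known = np.isfinite(pu)[:, None]
    applicable = detected & pu_known
    with np.errstate(divide="ignore", invalid="ignore"):
        corrected = np.where(
            applicable, np.log10(np.where(detected, arr, 1.0)) - log_pu[:, None] * slopes, np.nan
        )
    report = {
        "n_corrected": int(applicable.sum()),
        "n_not_detected": int((~detected).sum()),
        "n_missing_proteinuria": int((detected & ~pu_known).sum()),
        "n_floored_proteinuria": int(
            ((np.isfinite(pu) & (pu <= floor))[:, None] & detected).sum()
        ),
    }
    out = pd.DataFrame(corrected, index=values.index, columns=values.columns)
    return out, report


def correct_combined(
    combined: pd.DataFrame,
    fits: Mapping[str, RegressionFit],
    proteinuria: pd.Series,
    floor: float = PROTEINURIA_FLOOR,
) -> pd.DataFrame:
    """Proteinuria-corrected log10 *combined* abundances (identity mapping)."""
    matrix = AbundanceMatrix(combined)
    identity = {c: c for c in combined.columns}
    corrected, _ = correct_for_proteinuria(matrix, fits, identity, proteinuria, floor)
    return corrected


def fits_frame(fits: Mapping[str, RegressionFit]) -> pd.DataFrame:
    """Fits as a tidy frame (protein_id, a, b, n_used, r, stderr_b)."""
    frame = pd.DataFrame(
        {
            "protein_id": [f.protein_id for f in fits.values()],
            "intercept_a": [f.intercept_a for f in fits.values()],
            "slope_b": [f.slope_b for f in fits.values()],
            "n_used": [f.n_used for f in fits.values()],
            "r": [f.r for f in fits.values()],
            "stderr_b": [f.stderr_b for f in fits.values()],
        }
    ).set_index("protein_id")
    return frame
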