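"""Rank correlations with clinical covariates and per-condition summaries.

Association of each peptide with eGFR and proteinuria uses Spearman's rank
correlation (midranks for ties) with a two-sided p-value from the
t-approximation t = rho * sqrt((n - 2) / (1 - rho^2)) on n - 2 degrees of
freedom; for tiny samples an exact permutation p-value is available.
Spearman is invariant under monotone transforms, so log-transforming the
inputs changes nothing about the result — the option exists to make that
equivalence explicit.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass


import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import AbundanceMatrix
from .normalization import _condition_means

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer than 3 complete pairs."""


class UndefinedCorrelationError(ValueError):
    """One input has zero rank variance; rho is undefined."""


@dataclass(frozen=True)
class AssociationResult:
    peptide_id: str
    covariate: str
    rho: float
    p_value: float
    n: int

    def __post_init__(self) -> None:
        if abs(self.rho) > 1 + 1e-12:
            raise ValueError(f"|rho| > 1 for {self.peptide_id}")
        if self.n < 3:
            raise InsufficientDataError(f"{self.peptide_id}: n={self.n} < 3")


def spearman(
    x: np.ndarray, y: np.ndarray, method: str = "t-approx"
) -> tuple[float, float]:
    """Spearman rho and two-sided p on pairwise-complete observations.

    ``method="t-approx"`` (default) uses the t-distribution approximation;
    ``method="exact"`` enumerates all permutations of one margin (n <= 10
    only) and is valid with ties.  |rho| = 1 reports the distribution's
    limiting p-value.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    complete = np.isfinite(x) & np.isfinite(y)
    x, y = x[complete], y[complete]
    n = len(x)
    if n < 3:
        raise InsufficientDataError(f"only {n} complete pairs (need >= 3)")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero rank variance in one input")
    if method == "t-approx":
        res = stats.spearmanr(x, y)
        return float(res.statistic), float(res.pvalue)
    if method == "exact":
        return _spearman_exact(x, y)
    raise ValueError("method must be 't-approx' or 'exact'")


def _spearman_exact(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Permutation p-value: share of rank permutations with |rho| >= |observed|."""
    n = len(x)
    if n > 10:
        raise ValueError("exact permutation p-value limited to n <= 10")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx_c = rx - rx.mean()
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum() * (ry_c**2).sum())
    rho_obs = float((rx_c * ry_c).sum() / denom)
    perms = np.array(list(itertools.permutations(range(n))))
    rhos = (rx_c[perms] * ry_c).sum(axis=1) / denom
    p = float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))
    return rho_obs, p


def associate_peptides(
    matrix: AbundanceMatrix,
    covariate: pd.Series,
    covariate_name: str = "covariate",
    log_transform: bool = False,
    method: str = "t-approx",
) -> list[AssociationResult]:
    """Spearman association of every peptide with one clinical covariate.

    Samples missing either the abundance or the covariate are dropped
    pairwise.  With ``log_transform`` both sides are log10-transformed
    before ranking — a no-op for the ranks, retained for parity with how
    the underlying measurements are conventionally analysed.  Peptides with
    fewer than 3 usable pairs are omitted with a logged reason.
    """
    cov = covariate.reindex(matrix.values.index).to_numpy(float)
    if log_transform:
        with np.errstate(divide="ignore"):
            cov = np.log10(cov)
        cov[np.isneginf(cov)] = np.nan  # zero covariate -> unusable after log
    results: list[AssociationResult] = []
    for peptide_id in matrix.peptide_ids:
        values = matrix.values[peptide_id].to_numpy(float)
        if log_transform:
            with np.errstate(divide="ignore"):
                values = np.log10(values)
            values[np.isneginf(values)] = np.nan
        try:
            rho, p = spearman(values, cov, method=method)
        except InsufficientDataError:
            logger.info(
                "peptide %s omitted: fewer than 3 samples with both "
                "abundance and %s", peptide_id, covariate_name,
            )
            continue
        except UndefinedCorrelationError:
            logger.info("peptide %s omitted: zero rank variance", peptide_id)
            continue
        n = int(np.sum(np.isfinite(values) & np.isfinite(cov)))
        results.append(AssociationResult(peptide_id, covariate_name, rho, p, n))
    return results


def association_frame(
    results: list[AssociationResult], bh_adjust: bool = True
) -> pd.DataFrame:
    """Results as a tidy frame, one row per (peptide, covariate).

    The Benjamini-Hochberg column (``p_bh``, per covariate) is an extension
    beyond the raw two-sided p-values and is labelled as such.
    """
    frame = pd.DataFrame(
        {
            "peptide_id": [r.peptide_id for r in results],
            "covariate": [r.covariate for r in results],
            "rho": [r.rho for r in results],
            "p_value": [r.p_value for r in results],
            "n": [r.n for r in results],
        }
    )
    if bh_adjust and len(frame):
        frame["p_bh"] = np.nan
        for cov, idx in frame.groupby("covariate").groups.items():
            frame.loc[idx, "p_bh"] = multipletests(
                frame.loc[idx, "p_value"], method="fdr_bh"
            )[1]
    return frame


def condition_summary(
    values: pd.DataFrame,
    conditions: pd.Series,
    control_label: str = "HC",
    is_log10: bool = False,
    missing_policy: str | None = None,
    center: str = "mean",
) -> pd.DataFrame:
    """Per-condition summary normalized to healthy controls.

    ``values`` is either a raw (linear-scale) abundance/combined matrix, or
    a proteinuria-corrected matrix on the log10 scale (``is_log10=True``);
    corrected values are mapped back through 10**x before averaging so the
    adjusted and unadjusted summaries share units.  Missing policy defaults
    to zero-fill on the linear scale and observed-only for corrected values
    (which are undefined at non-detection).  Rows = peptides/proteins,
    columns = conditions; the control column is identically 1.
    """
    if missing_policy is None:
        missing_policy = "observed-only" if is_log10 else "zero-fill"
    data = 10.0**values if is_log10 else values
    aligned = conditions.reindex(data.index)
    if aligned.isna().any():
        raise KeyError(
            f"samples without condition labels: {list(data.index[aligned.isna()])}"
        )
    if control_label not in set(aligned):
        raise ValueError(f"control label {control_label!r} absent")
    means = _condition_means(data, aligned, missing_policy, center)
    control = means.loc[control_label]
    zero = ~(control > 0)
    if zero.any():
        warnings.warn(
            f"zero control {center} for {list(control.index[zero])}", stacklevel=2
        )
    return means.div(control.where(~zero, np.nan), axis=1).T


def figure_order(peptides, protein_order: tuple[str, ...] = ("CFB", "C4B", "C4A", "C3")):
    """Peptide ids ordered by protein (CFB, C4B, C4A, C3) then start position."""
    rank = {p: i for i, p in enumerate(protein_order)}
    ordered = sorted(
        peptides, key=lambda p: (rank.get(p.protein_id, len(rank)), p.start, p.stop)
    )
    return [p.peptide_id for p in ordered]
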