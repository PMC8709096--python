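"""Domain types and delimited-text / FASTA readers and writers.

The pipeline's tabular interchange formats are plain TSV/CSV (UTF-8):

* peptide annotation table — one row per peptide with its parent protein and
  1-based inclusive residue coordinates;
* clinical table — one row per subject (condition, serum creatinine, age,
  sex, proteinuria, optionally eGFR);
* abundance matrix — wide sample x peptide table of nonnegative relative
  abundances where an empty cell means "not detected" (missing, not zero);
* cohort table — per-condition subject counts.

Protein sequences come in as FASTA via Biopython.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

AMINO_ACIDS = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: Condition vocabulary seeded from the study's cohort table (long label ->
#: figure abbreviation).  The vocabulary is open: unknown labels warn and
#: pass through, so the pipeline generalizes past these 22 categories.
CONDITION_ABBREVIATIONS: dict[str, str] = {
    "Acute kidney injury": "AKI",
    "ADPKD": "ADPKD",
    "Amyloidosis": "Amyl",
    "Atypical hemolytic uremic syndrome": "AHUS",
    "C3 glomerulopathy": "C3G",
    "CAKUT": "CAKUT",
    "Diabetes Mellitus": "DM",
    "Diabetic kidney disease": "DKD",
    "Fanconi syndrom": "FS",
    "FSGS": "FSGS",
    "IgAN": "IgAN",
    "MCD": "MCD",
    "MGN": "MGN",
    "Morbus Fabry": "MF",
    "MPGN": "MPGN",
    "Hypertensive nephrosclerosis": "HN",
    "Nephrotic syndrom": "NS",
    "Kidney transplantation": "NTx",
    "SLE": "SLE",
    "LN": "LN",
    "Vasculitis": "Vas",
    "Healthy control": "HC",
}

KNOWN_CONDITIONS = frozenset(CONDITION_ABBREVIATIONS) | frozenset(
    CONDITION_ABBREVIATIONS.values()
)


class FormatError(ValueError):
    """Structural problem in an input file (missing column, duplicate key)."""


class ValidationError(ValueError):
    """A value violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class PeptideRecord:
    """One detected peptide located on its parent protein.

    Coordinates are 1-based and inclusive on both ends, so a record with
    ``start == stop`` covers a single residue and a consistent record has
    ``stop - start + 1 == len(sequence)``.
    """

    peptide_id: str
    sequence: str
    protein_id: str
    start: int
    stop: int
    avg_rel_abundance: float | None = None

    @property
    def span(self) -> int:
        """Number of residues covered by the printed coordinates."""
        return self.stop - self.start + 1

    def validation_issues(self) -> list[str]:
        """Return human-readable invariant violations (empty if consistent)."""
        issues: list[str] = []
        if self.stop < self.start:
            issues.append(
                f"peptide {self.peptide_id}: stop {self.stop} < start {self.start}"
            )
        bad = set(self.sequence) - AMINO_ACIDS
        if bad:
            issues.append(
                f"peptide {self.peptide_id}: non-standard residues {sorted(bad)}"
            )
        if self.sequence and self.stop >= self.start and self.span != len(self.sequence):
            issues.append(
                f"peptide {self.peptide_id}: coordinate span {self.span} "
                f"!= sequence length {len(self.sequence)}"
            )
        if self.avg_rel_abundance is not None and self.avg_rel_abundance < 0:
            issues.append(f"peptide {self.peptide_id}: negative abundance")
        return issues


@dataclass
class SampleRecord:
    """One subject's clinical covariates.

    Units: serum creatinine mg/dL, age years, proteinuria g per g urinary
    creatinine, eGFR mL/min/1.73 m^2.  Any covariate may be absent (``None``).
    """

    sample_id: str
    condition: str
    serum_creatinine: float | None = None
    age: float | None = None
    sex: str | None = None
    proteinuria: float | None = None
    egfr: float | None = None

    def __post_init__(self) -> None:
        if self.serum_creatinine is not None and self.serum_creatinine <= 0:
            raise ValidationError(
                f"sample {self.sample_id}: serum creatinine must be > 0"
            )
        if self.proteinuria is not None and self.proteinuria < 0:
            raise ValidationError(f"sample {self.sample_id}: proteinuria must be >= 0")
        if self.age is not None and not (0 < self.age < 130):
            raise ValidationError(f"sample {self.sample_id}: age out of range")
        if self.egfr is not None and self.egfr <= 0:
            raise ValidationError(f"sample {self.sample_id}: eGFR must be > 0")
        if self.sex is not None and self.sex not in ("female", "male"):
            raise ValidationError(
                f"sample {self.sample_id}: sex must be 'female' or 'male'"
            )


@dataclass
class AbundanceMatrix:
    """Sample x peptide relative abundances with explicit missingness.

    Wraps a pandas DataFrame (rows = samples, columns = peptides); NaN means
    the peptide was not detected in that sample.  Non-detection is *missing*,
    never zero, at this layer — downstream operations choose their own
    zero-vs-missing semantics explicitly.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        v = self.values
        if v.index.has_duplicates:
            raise FormatError("duplicate sample_id in abundance matrix")
        if v.columns.has_duplicates:
            raise FormatError("duplicate peptide_id in abundance matrix")
        arr = v.to_numpy(dtype=float)
        if np.nanmin(arr, initial=0.0) < 0:
            raise ValidationError("abundance values must be nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def peptide_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def drop_empty_samples(self) -> tuple["AbundanceMatrix", int]:
        """Drop samples with zero detected peptides; return (matrix, n_dropped).

        Mirrors the study inclusion rule: a dataset enters the analysis only
        if at least one peptide of interest was detected.
        """
        keep = self.values.notna().any(axis=1)
        n_dropped = int((~keep).sum())
        if n_dropped:
            logger.info("dropped %d samples with no detected peptide", n_dropped)
        return AbundanceMatrix(self.values.loc[keep]), n_dropped


@dataclass
class CohortTable:
    """Per-condition subject counts."""

    rows: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [c for c, _ in self.rows]
        if len(labels) != len(set(labels)):
            raise FormatError("duplicate condition labels in cohort table")
        if any(n < 0 for _, n in self.rows):
            raise ValidationError("n_subjects must be >= 0")

    @property
    def conditions(self) -> list[str]:
        return [c for c, _ in self.rows]

    @property
    def total(self) -> int:
        return sum(n for _, n in self.rows)

    def fractions(self) -> dict[str, float]:
        tot = self.total
        return {c: n / tot for c, n in self.rows}


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _sniff_delimiter(header_line: str) -> str:
    # tab wins if present; both dialects are common in proteomics exports
    return "\t" if "\t" in header_line else ","


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    sep = _sniff_delimiter(header)
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


_PEPTIDE_COLUMNS = {
    "peptide_id": ("peptide_id", "Peptide ID", "ID", "id"),
    "sequence": ("sequence", "Sequence"),
    "protein_id": ("protein_id", "Complement", "protein", "Protein"),
    "start": ("start", "Start AA", "Start"),
    "stop": ("stop", "Stop AA", "Stop"),
    "avg_rel_abundance": ("avg_rel_abundance", "Avg. rel. abund.", "avg_abundance"),
}


def _resolve_columns(
    frame: pd.DataFrame, wanted: Mapping[str, tuple[str, ...]], required: Iterable[str]
) -> dict[str, str]:
    resolved: dict[str, str] = {}
    for canonical, aliases in wanted.items():
        for alias in aliases:
            if alias in frame.columns:
                resolved[canonical] = alias
                break
    missing = [c for c in required if c not in resolved]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    return resolved


def read_peptide_table(
    path: str | Path, on_invalid: str = "warn"
) -> list[PeptideRecord]:
    """Read a peptide annotation table into records.

    Parameters
    ----------
    path
        TSV/CSV file with columns peptide_id, sequence, protein_id, start,
        stop and optionally avg_rel_abundance (published column aliases such
        as "Peptide ID" / "Start AA" are accepted).
    on_invalid
        ``"warn"`` (default) keeps rows that violate the coordinate/length
        invariant and reports each violation with its row number — printed
        tables occasionally carry internally inconsistent coordinates and the
        reader must not silently repair them.  ``"raise"`` turns violations
        into :class:`ValidationError`.
    """
    if on_invalid not in ("warn", "raise"):
        raise ValueError("on_invalid must be 'warn' or 'raise'")
    frame = _read_frame(path)
    cols = _resolve_columns(
        frame, _PEPTIDE_COLUMNS, ["peptide_id", "sequence", "protein_id", "start", "stop"]
    )
    records: list[PeptideRecord] = []
    for i, row in enumerate(frame.itertuples(index=False), start=2):  # header = line 1
        row_d = dict(zip(frame.columns, row))
        abund_col = cols.get("avg_rel_abundance")
        abund_raw = row_d.get(abund_col, "") if abund_col else ""
        rec = PeptideRecord(
            peptide_id=row_d[cols["peptide_id"]].strip(),
            sequence=row_d[cols["sequence"]].strip().upper(),
            protein_id=row_d[cols["protein_id"]].strip(),
            start=int(row_d[cols["start"]]),
            stop=int(row_d[cols["stop"]]),
            avg_rel_abundance=float(abund_raw) if str(abund_raw).strip() else None,
        )
        issues = rec.validation_issues()
        for issue in issues:
            msg = f"line {i}: {issue}"
            if on_invalid == "raise":
                raise ValidationError(msg)
            warnings.warn(msg, stacklevel=2)
        records.append(rec)
    return records


def read_abundance_matrix(
    path: str | Path, missing_sentinels: Sequence[str] = ("", "NA", "NaN", "nan")
) -> AbundanceMatrix:
    """Read a wide sample x peptide matrix; empty cells are non-detections.

    Samples in which no peptide at all was detected are dropped (with a
    logged count), mirroring the study's inclusion rule.
    """
    frame = _read_frame(path)
    if frame.columns[0] in frame.columns[1:]:
        raise FormatError("first column (sample_id) repeated among peptide columns")
    sample_col = frame.columns[0]
    if frame[sample_col].duplicated().any():
        dupes = frame[sample_col][frame[sample_col].duplicated()].tolist()
        raise FormatError(f"duplicate sample_id(s): {dupes}")
    frame = frame.set_index(sample_col)
    frame = frame.mask(frame.isin(list(missing_sentinels)))
    try:
        frame = frame.astype(float)
    except ValueError as exc:
        raise FormatError(f"non-numeric abundance value: {exc}") from exc
    if (frame < 0).any().any():
        bad = frame.columns[(frame < 0).any()].tolist()
        raise ValidationError(f"negative abundance in column(s): {bad}")
    matrix, _ = AbundanceMatrix(frame).drop_empty_samples()
    return matrix


def _parse_optional_float(raw: str) -> float | None:
    raw = raw.strip()
    return float(raw) if raw else None


def read_clinical_table(path: str | Path) -> list[SampleRecord]:
    """Read a per-sample clinical covariate table.

    Unknown condition labels trigger a warning and pass through unchanged —
    the vocabulary is an open set seeded with the study's 22 categories.
    """
    frame = _read_frame(path)
    required = ["sample_id", "condition"]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise FormatError(f"missing required column(s): {missing}")
    records: list[SampleRecord] = []
    unknown: set[str] = set()
    for row in frame.to_dict("records"):
        condition = row["condition"].strip()
        if condition and condition not in KNOWN_CONDITIONS:
            unknown.add(condition)
        records.append(
            SampleRecord(
                sample_id=row["sample_id"].strip(),
                condition=condition,
                serum_creatinine=_parse_optional_float(row.get("serum_creatinine", "")),
                age=_parse_optional_float(row.get("age", "")),
                sex=(row.get("sex", "").strip() or None),
                proteinuria=_parse_optional_float(row.get("proteinuria", "")),
                egfr=_parse_optional_float(row.get("egfr", "")),
            )
        )
    if unknown:
        warnings.warn(
            f"unknown condition label(s) passed through: {sorted(unknown)}",
            stacklevel=2,
        )
    return records


def clinical_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Clinical records as a DataFrame indexed by sample_id."""
    frame = pd.DataFrame(
        {
            "condition": [r.condition for r in records],
            "serum_creatinine": [r.serum_creatinine for r in records],
            "age": [r.age for r in records],
            "sex": [r.sex for r in records],
            "proteinuria": [r.proteinuria for r in records],
            "egfr": [r.egfr for r in records],
        },
        index=pd.Index([r.sample_id for r in records], name="sample_id"),
    )
    for col in ("serum_creatinine", "age", "proteinuria", "egfr"):
        frame[col] = frame[col].astype(float)
    return frame


def read_cohort_table(path: str | Path, total_label: str = "Total") -> CohortTable:
    """Read (condition, N) rows; a trailing ``Total`` row is excluded."""
    frame = _read_frame(path)
    if frame.shape[1] < 2:
        raise FormatError("cohort table needs at least two columns (condition, N)")
    cond_col, n_col = frame.columns[0], frame.columns[1]
    rows: list[tuple[str, int]] = []
    for row in frame.to_dict("records"):
        label = row[cond_col].strip()
        if label == total_label:
            continue
        rows.append((label, int(str(row[n_col]).replace(",", ""))))
    return CohortTable(rows)


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read protein sequences keyed by the first whitespace token of the header."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        key = record.id.split()[0]
        if key in sequences:
            raise FormatError(f"duplicate FASTA id: {key}")
        sequences[key] = str(record.seq).upper()
    return sequences


def write_table(frame: pd.DataFrame, path: str | Path, sep: str = "\t") -> None:
    """Write a DataFrame as delimited text (UTF-8), index included if named."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, sep=sep, index=frame.index.name is not None)


def write_abundance_matrix(matrix: AbundanceMatrix, path: str | Path) -> None:
    """Write a matrix in the wide input layout; NaN becomes an empty cell."""
    out = matrix.values.copy()
    out.index.name = out.index.name or "sample_id"
    out.to_csv(path, sep="\t", na_rep="")
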