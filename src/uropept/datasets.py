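"""Packaged fixture loaders.

Ships the published annotation of the 23 urinary complement fragments, the
per-condition cohort counts, and a *synthetic* protein FASTA: the parent
protein sequences are constructed stand-ins (seeded random filler with the
real fragment regions embedded at the printed coordinates), adequate for
coordinate arithmetic and tests but not biological reference sequences.
"""

from __future__ import annotations

import warnings
from importlib import resources

from .core import CohortTable, PeptideRecord, read_cohort_table, read_fasta, read_peptide_table


def _data_path(name: str):
    return resources.files("uropept.data").joinpath(name)


def load_peptide_annotation() -> list[PeptideRecord]:
    """The 23 published complement-fragment records (printed values kept as-is).

    One printed row carries internally inconsistent coordinates; the reader
    reports it and preserves the printed values, so the warning is expected
    and suppressed here.
    """
    with resources.as_file(_data_path("table1_peptides.tsv")) as path:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return read_peptide_table(path, on_invalid="warn")


def load_cohort_table() -> CohortTable:
    """Per-condition subject counts of the study cohort (Total row excluded)."""
    with resources.as_file(_data_path("table2_cohort.tsv")) as path:
        return read_cohort_table(path)


def load_protein_sequences() -> dict[str, str]:
    """Synthetic stand-in sequences for C3, C4A, C4B and CFB."""
    with resources.as_file(_data_path("complement_proteins_synthetic.fasta")) as path:
        return read_fasta(path)
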