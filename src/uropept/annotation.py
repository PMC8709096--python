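"""Peptide-to-protein mapping and mutually-exclusive overlap groups.

Overlapping fragments from one protein region are *mutually exclusive*: a
single parent molecule can yield at most one of them, because they share
residues.  Grouping peptides into connected components of the interval
overlap graph therefore identifies sets whose abundances can meaningfully be
summed into one combined variable per protein (or per region).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core import PeptideRecord


class PeptideNotFoundError(LookupError):
    """Peptide sequence has no exact match in the protein sequence."""


class CoordinateError(ValueError):
    """Peptide coordinates fall outside the protein."""


@dataclass(frozen=True)
class ExclusivityGroup:
    """A maximal set of peptides whose intervals form one overlap component.

    ``region_start``/``region_stop`` are the 1-based inclusive envelope of
    all member intervals.
    """

    protein_id: str
    member_peptide_ids: frozenset[str]
    region_start: int
    region_stop: int

    @property
    def label(self) -> str:
        return f"{self.protein_id}:{self.region_start}-{self.region_stop}"


def locate_peptide(
    sequence: str, protein_sequence: str, peptide_id: str | None = None
) -> tuple[int, int]:
    """Locate a peptide in a protein; returns 1-based inclusive (start, stop).

    On repetitive proteins a peptide can match more than once; the leftmost
    match is returned deterministically and a warning lists every match
    start so the ambiguity is visible.
    """
    if not sequence or not protein_sequence:
        raise ValueError("sequences must be non-empty")
    name = peptide_id or sequence
    starts: list[int] = []
    pos = protein_sequence.find(sequence)
    while pos != -1:
        starts.append(pos + 1)
        pos = protein_sequence.find(sequence, pos + 1)
    if not starts:
        raise PeptideNotFoundError(f"peptide {name} not found in protein sequence")
    if len(starts) > 1:
        warnings.warn(
            f"peptide {name} matches at {len(starts)} positions "
            f"(starts {starts}); using the leftmost",
            stacklevel=2,
        )
    start = starts[0]
    return start, start + len(sequence) - 1


def build_exclusivity_groups(
    peptides: Sequence[PeptideRecord],
) -> list[ExclusivityGroup]:
    """Connected components of the per-protein interval-overlap graph.

    Two peptides overlap iff their closed intervals share at least one
    residue; adjacency without sharing (stop + 1 == next start) does not
    merge groups, since exclusivity derives from shared residues.  Output is
    deterministic, ordered by (protein_id, region_start).
    """
    by_protein: dict[str, list[PeptideRecord]] = {}
    for p in peptides:
        by_protein.setdefault(p.protein_id, []).append(p)

    groups: list[ExclusivityGroup] = []
    for protein_id in sorted(by_protein):
        # sweep intervals sorted by start; a new component opens when the
        # next start lies strictly beyond the running max stop
        members = sorted(by_protein[protein_id], key=lambda p: (p.start, p.stop))
        current: list[PeptideRecord] = []
        reach = -1
        for p in members:
            if current and p.start > reach:
                groups.append(_make_group(protein_id, current))
                current = []
            current.append(p)
            reach = max(reach, p.stop)
        if current:
            groups.append(_make_group(protein_id, current))
    groups.sort(key=lambda g: (g.protein_id, g.region_start))
    return groups


def _make_group(protein_id: str, members: Sequence[PeptideRecord]) -> ExclusivityGroup:
    return ExclusivityGroup(
        protein_id=protein_id,
        member_peptide_ids=frozenset(p.peptide_id for p in members),
        region_start=min(p.start for p in members),
        region_stop=max(p.stop for p in members),
    )


def peptide_to_protein(peptides: Iterable[PeptideRecord]) -> dict[str, str]:
    """Mapping peptide_id -> protein_id."""
    return {p.peptide_id: p.protein_id for p in peptides}


def peptide_to_group(peptides: Sequence[PeptideRecord]) -> dict[str, str]:
    """Mapping peptide_id -> exclusivity-group label."""
    mapping: dict[str, str] = {}
    for group in build_exclusivity_groups(peptides):
        for pid in group.member_peptide_ids:
            mapping[pid] = group.label
    return mapping


def coverage_map(
    peptides: Sequence[PeptideRecord], protein_length: int
) -> np.ndarray:
    """Per-residue coverage counts over a protein of the given length.

    Element ``i`` (0-based) counts the peptides whose interval contains
    residue ``i + 1``; the vector sums to the total covered residue count
    Σ(stop − start + 1).
    """
    for p in peptides:
        if p.stop > protein_length:
            raise CoordinateError(
                f"peptide {p.peptide_id} stop {p.stop} exceeds "
                f"protein length {protein_length}"
            )
        if p.start < 1:
            raise CoordinateError(f"peptide {p.peptide_id} start {p.start} < 1")
    cover = np.zeros(protein_length, dtype=int)
    for p in peptides:
        cover[p.start - 1 : p.stop] += 1
    return cover


def groups_to_bed(groups: Sequence[ExclusivityGroup]) -> pd.DataFrame:
    """BED-like frame (0-based half-open) for region visualization tools."""
    return pd.DataFrame(
        {
            "chrom": [g.protein_id for g in groups],
            "start": [g.region_start - 1 for g in groups],
            "end": [g.region_stop for g in groups],
            "name": [g.label for g in groups],
        }
    )


def write_bed(groups: Sequence[ExclusivityGroup], path: str | Path) -> None:
    groups_to_bed(groups).to_csv(path, sep="\t", header=False, index=False)
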