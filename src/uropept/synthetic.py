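"""Synthetic cohort generator.

Emulates the statistical structure the analysis assumes, so the whole
pipeline is testable without any data download:

* per-condition eGFR distributions (truncated normals on [5, 120] mL/min);
* log10 proteinuria inversely linked to eGFR with lognormal scatter;
* per-protein combined log10 abundance driven by a proteinuria-leakage
  slope ``b_true``, an optional direct eGFR effect ``gamma``, optional
  per-condition disease effects ``delta``, and multiplicative noise;
* mutually exclusive allocation of each protein's combined abundance to
  its overlapping fragments (Dirichlet shares over groups and members,
  drawn once per cohort and held fixed);
* detection-limit censoring (values below the platform floor are missing);
* condition-independent internal-standard reference peptides.

Default parameters encode the study's direction-only sign pattern: C3
fragments positively coupled to proteinuria (b = +0.8), C4A/C4B weakly
positive (+0.3), CFB weakly negative (-0.1).  Direct condition and eGFR
effects default to zero so that, out of the box, all abundance variation
flows through the filtration/leakage mechanism the correction targets;
disease effects are opt-in via ``condition_spec``.

A ``truth`` record stores every drawn parameter for recovery tests; a fixed
seed gives bit-identical output.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import datasets
from .annotation import build_exclusivity_groups
from .clinical import invert_ckd_epi
from .core import AbundanceMatrix, PeptideRecord, SampleRecord, clinical_frame
from .correction import PROTEINURIA_FLOOR


class ConfigError(ValueError):
    """Invalid generator configuration."""


@dataclass(frozen=True)
class ConditionSpec:
    """One condition's cohort fraction, eGFR distribution and disease effects.

    ``effects`` maps protein_id -> additive log10-abundance shift delta.
    """

    fraction: float
    egfr_mean: float
    egfr_sd: float
    effects: Mapping[str, float] = field(default_factory=dict)


#: Plausible per-condition eGFR means/SDs (mL/min/1.73 m^2): healthy and
#: purely metabolic groups near-normal, acute injury / transplant /
#: glomerulopathies reduced.
_EGFR_BY_CONDITION: dict[str, tuple[float, float]] = {
    "AKI": (35, 20), "ADPKD": (70, 25), "Amyl": (55, 25), "AHUS": (45, 25),
    "C3G": (60, 25), "CAKUT": (75, 25), "DM": (85, 16), "DKD": (48, 22),
    "FS": (80, 20), "FSGS": (55, 25), "IgAN": (65, 25), "MCD": (85, 20),
    "MGN": (70, 25), "MF": (80, 20), "MPGN": (50, 25), "HN": (55, 20),
    "NS": (70, 25), "NTx": (50, 18), "SLE": (95, 15), "LN": (75, 25),
    "Vas": (45, 25), "HC": (100, 13),
}

DEFAULT_B_TRUE: dict[str, float] = {"C3": 0.8, "C4A": 0.3, "C4B": 0.3, "CFB": -0.1}

#: Baseline log10 combined abundance per protein at floor proteinuria,
#: roughly matching the published per-protein abundance ordering
#: (C3 >> CFB >> C4B ~ C4A).
DEFAULT_BASELINE_LOG10: dict[str, float] = {
    "C3": 3.5, "CFB": 3.2, "C4A": 2.3, "C4B": 2.4,
}


def default_condition_spec() -> dict[str, ConditionSpec]:
    """Condition fractions from the packaged cohort table, zero disease effects."""
    cohort = datasets.load_cohort_table()
    from .core import CONDITION_ABBREVIATIONS

    fractions = cohort.fractions()
    spec: dict[str, ConditionSpec] = {}
    for label, frac in fractions.items():
        abbrev = CONDITION_ABBREVIATIONS.get(label, label)
        mean, sd = _EGFR_BY_CONDITION[abbrev]
        spec[abbrev] = ConditionSpec(fraction=frac, egfr_mean=mean, egfr_sd=sd)
    return spec


def example_disease_effects() -> dict[str, ConditionSpec]:
    """Condition spec with planted disease effects, for effect-recovery tests.

    Plants a 3-fold C3 elevation in minimal change disease (delta =
    log10 3) and a 2.5-fold CFB elevation in acute kidney injury, on top of
    the default fractions and eGFR distributions.
    """
    spec = default_condition_spec()
    planted = {
        "MCD": {"C3": float(np.log10(3.0))},
        "AKI": {"CFB": float(np.log10(2.5))},
    }
    for cond, effects in planted.items():
        base = spec[cond]
        spec[cond] = ConditionSpec(base.fraction, base.egfr_mean, base.egfr_sd, effects)
    return spec


@dataclass
class GeneratorConfig:
    """All dials of the synthetic cohort; defaults are the study conditions."""

    n_subjects: int = 2000
    condition_spec: Mapping[str, ConditionSpec] = field(
        default_factory=default_condition_spec
    )
    b_true: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_B_TRUE))
    baseline_log10: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_LOG10)
    )
    egfr_effect_gamma: Mapping[str, float] = field(default_factory=dict)
    proteinuria_c0: float = 0.5
    proteinuria_c1: float = -0.015  # log10(g/g) per eGFR unit
    proteinuria_sigma: float = 0.35
    noise_sigma: float = 0.25  # log10 units
    detection_limit: float = 0.05
    allocation_alpha: float = 2.0
    n_reference_peptides: int = 29
    reference_level: float = 1000.0
    reference_sigma: float = 0.05
    egfr_bounds: tuple[float, float] = (5.0, 120.0)
    seed: int = 0

    def validate(self) -> None:
        total = sum(c.fraction for c in self.condition_spec.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"condition fractions sum to {total}, not 1")
        if any(c.fraction < 0 for c in self.condition_spec.values()):
            raise ConfigError("condition fractions must be >= 0")
        for name in ("proteinuria_sigma", "noise_sigma", "reference_sigma"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.detection_limit < 0:
            raise ConfigError("detection_limit must be >= 0")
        if self.allocation_alpha <= 0:
            raise ConfigError("allocation_alpha must be > 0")
        if self.n_subjects <= 0:
            raise ConfigError("n_subjects must be > 0")


def _truncated_normal(
    rng: np.random.Generator,
    mean: np.ndarray,
    sd: np.ndarray,
    low: float,
    high: float,
) -> np.ndarray:
    a = (low - mean) / sd
    b = (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, random_state=rng)


def generate_cohort(
    config: GeneratorConfig, peptides: Sequence[PeptideRecord]
) -> tuple[list[SampleRecord], AbundanceMatrix, dict]:
    """Draw one synthetic cohort.

    Returns clinical records, the abundance matrix (complement peptides
    followed by reference peptides), and a truth record holding every
    parameter actually used, including the per-peptide allocation shares.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects

    proteins = sorted({p.protein_id for p in peptides})
    for prot in proteins:
        if prot not in config.b_true or prot not in config.baseline_log10:
            raise ConfigError(f"no b_true/baseline for protein {prot}")

    labels = sorted(config.condition_spec)
    fractions = np.array([config.condition_spec[c].fraction for c in labels])
    conditions = rng.choice(labels, size=n, p=fractions / fractions.sum())

    egfr_mean = np.array([config.condition_spec[c].egfr_mean for c in conditions])
    egfr_sd = np.array([config.condition_spec[c].egfr_sd for c in conditions])
    low, high = config.egfr_bounds
    egfr = _truncated_normal(rng, egfr_mean, egfr_sd, low, high)

    age = np.clip(rng.normal(55.0, 15.0, size=n), 20.0, 90.0)
    sex = np.where(rng.random(n) < 0.5, "female", "male")
    scr = invert_ckd_epi(egfr, age, sex)

    log_pu_true = (
        config.proteinuria_c0
        + config.proteinuria_c1 * egfr
        + rng.normal(0.0, config.proteinuria_sigma, size=n)
    )
    pu_true = 10.0**log_pu_true
    pu_measured = np.round(pu_true, 2)  # assay resolution; small values hit 0

    # fixed per-cohort allocation: Dirichlet over a protein's groups, then
    # Dirichlet over each group's members
    groups = build_exclusivity_groups(peptides)
    share: dict[str, float] = {}
    group_shares_truth: dict[str, dict[str, float]] = {}
    for prot in proteins:
        prot_groups = [g for g in groups if g.protein_id == prot]
        gs = rng.dirichlet(np.full(len(prot_groups), config.allocation_alpha))
        group_shares_truth[prot] = {}
        for g, g_share in zip(prot_groups, gs):
            members = sorted(g.member_peptide_ids)
            ms = rng.dirichlet(np.full(len(members), config.allocation_alpha))
            group_shares_truth[prot][g.label] = float(g_share)
            for pid, m_share in zip(members, ms):
                share[pid] = float(g_share * m_share)

    cond_index = {c: i for i, c in enumerate(labels)}
    delta = np.zeros((len(labels), len(proteins)))
    for ci, cond in enumerate(labels):
        for pi, prot in enumerate(proteins):
            delta[ci, pi] = config.condition_spec[cond].effects.get(prot, 0.0)
    gamma = np.array([config.egfr_effect_gamma.get(p, 0.0) for p in proteins])
    mu = np.array([config.baseline_log10[p] for p in proteins])
    b = np.array([config.b_true[p] for p in proteins])

    cond_rows = np.array([cond_index[c] for c in conditions])
    log_pu_floored = np.log10(np.maximum(pu_true, PROTEINURIA_FLOOR))
    latent = (
        mu[None, :]
        + delta[cond_rows]
        + gamma[None, :] * (egfr[:, None] - 90.0)
        + b[None, :] * log_pu_floored[:, None]
        + rng.normal(0.0, config.noise_sigma, size=(n, len(proteins)))
    )

    peptide_ids = [p.peptide_id for p in peptides]
    prot_index = {p: i for i, p in enumerate(proteins)}
    cols = np.array([prot_index[p.protein_id] for p in peptides])
    shares = np.array([share[pid] for pid in peptide_ids])
    abundance = 10.0 ** latent[:, cols] * shares[None, :]
    abundance = np.where(abundance >= config.detection_limit, abundance, np.nan)

    ref_ids = [f"REF{i + 1:03d}" for i in range(config.n_reference_peptides)]
    ref = config.reference_level * 10.0 ** rng.normal(
        0.0, config.reference_sigma, size=(n, len(ref_ids))
    )
    ref = np.where(ref >= config.detection_limit, ref, np.nan)

    sample_ids = [f"S{i + 1:05d}" for i in range(n)]
    values = pd.DataFrame(
        np.hstack([abundance, ref]),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=peptide_ids + ref_ids,
    )
    matrix = AbundanceMatrix(values)

    records = [
        SampleRecord(
            sample_id=sid,
            condition=str(cond),
            serum_creatinine=round(float(s), 3),
            age=round(float(a), 1),
            sex=str(sx),
            proteinuria=float(p),
            egfr=None,
        )
        for sid, cond, s, a, sx, p in zip(
            sample_ids, conditions, scr, age, sex, pu_measured
        )
    ]

    truth = {
        "seed": config.seed,
        "n_subjects": n,
        "b_true": {p: float(config.b_true[p]) for p in proteins},
        "baseline_log10": {p: float(config.baseline_log10[p]) for p in proteins},
        "egfr_effect_gamma": {p: float(gamma[i]) for p, i in prot_index.items()},
        "proteinuria_link": {
            "c0": config.proteinuria_c0,
            "c1": config.proteinuria_c1,
            "sigma": config.proteinuria_sigma,
        },
        "noise_sigma": config.noise_sigma,
        "detection_limit": config.detection_limit,
        "allocation_alpha": config.allocation_alpha,
        "condition_effects": {
            c: dict(config.condition_spec[c].effects)
            for c in labels
            if config.condition_spec[c].effects
        },
        "peptide_shares": share,
        "group_shares": group_shares_truth,
        "reference_ids": ref_ids,
        "condition_counts": {
            c: int((conditions == c).sum()) for c in labels
        },
    }
    return records, matrix, truth


def make_fixture_suite(output_dir: str | Path, seed: int = 7, n_subjects: int = 200) -> dict[str, Path]:
    """Write a small deterministic cohort plus the packaged tables to a directory.

    Emits the pipeline's own input formats: clinical TSV, wide abundance
    TSV, peptide annotation TSV, cohort TSV and a truth JSON sidecar.
    """
    from .core import write_abundance_matrix, write_table

    output_dir = Path(output_dir)
    output_dir.mkdir(parents=True, exist_ok=True)
    peptides = datasets.load_peptide_annotation()
    config = GeneratorConfig(n_subjects=n_subjects, seed=seed)
    records, matrix, truth = generate_cohort(config, peptides)

    paths = {
        "clinical": output_dir / "clinical.tsv",
        "abundance": output_dir / "abundance.tsv",
        "peptides": output_dir / "peptides.tsv",
        "cohort": output_dir / "cohort.tsv",
        "truth": output_dir / "truth.json",
    }
    frame = clinical_frame(records).reset_index()
    frame.to_csv(paths["clinical"], sep="\t", index=False)
    write_abundance_matrix(matrix, paths["abundance"])
    pep_frame = pd.DataFrame(
        {
            "peptide_id": [p.peptide_id for p in peptides],
            "sequence": [p.sequence for p in peptides],
            "protein_id": [p.protein_id for p in peptides],
            "start": [p.start for p in peptides],
            "stop": [p.stop for p in peptides],
            "avg_rel_abundance": [p.avg_rel_abundance for p in peptides],
        }
    )
    pep_frame.to_csv(paths["peptides"], sep="\t", index=False)
    cohort = datasets.load_cohort_table()
    pd.DataFrame(cohort.rows, columns=["condition", "n_subjects"]).to_csv(
        paths["cohort"], sep="\t", index=False
    )
    with open(paths["truth"], "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
    return paths


def cohort_digest(records: Sequence[SampleRecord], matrix: AbundanceMatrix) -> str:
    """SHA-256 over the serialized cohort, for determinism checks."""
    clin = clinical_frame(records).to_csv()
    abund = matrix.values.to_csv()
    return hashlib.sha256((clin + abund).encode()).hexdigest()
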