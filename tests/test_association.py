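"""Spearman correlation, per-peptide associations and condition summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from uropept.association import (
    InsufficientDataError,
    UndefinedCorrelationError,
    associate_peptides,
    association_frame,
    condition_summary,
    figure_order,
    spearman,
)
from uropept.core import AbundanceMatrix


def _midrank(values):
    """Oracle midranks: 1 + (#smaller) + (#equal - 1) / 2, by counting."""
    values = np.asarray(values, dtype=float)
    return np.array(
        [1 + np.sum(values < v) + (np.sum(values == v) - 1) / 2 for v in values]
    )


def _oracle_spearman(x, y):
    """Brute-force midrank Pearson with two-sided t-approximation p-value."""
    rx, ry = _midrank(x), _midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    rho = float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))
    n = len(rx)
    if abs(rho) >= 1.0:
        return rho, 0.0
    t = rho * np.sqrt((n - 2) / (1 - rho**2))
    return rho, float(2 * stats.t.sf(abs(t), n - 2))


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman(np.array([1, 2, 3]), np.array([10, 20, 30]))
        assert rho == pytest.approx(1.0)
        rho, _ = spearman(np.array([1, 2, 3]), np.array([3, 2, 1]))
        assert rho == pytest.approx(-1.0)

    def test_random_vectors_with_ties_match_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(200):
            x = rng.integers(0, 4, 8).astype(float)
            y = rng.integers(0, 4, 8).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho, p = spearman(x, y)
            rho_o, p_o = _oracle_spearman(x, y)
            assert rho == pytest.approx(rho_o, abs=1e-12)
            assert p == pytest.approx(p_o, abs=1e-10)

    def test_pairwise_completion(self):
        x = np.array([1.0, np.nan, 2.0, 3.0, 4.0])
        y = np.array([2.0, 5.0, np.nan, 6.0, 8.0])
        rho, _ = spearman(x, y)
        assert rho == pytest.approx(1.0)

    def test_insufficient_and_degenerate_inputs(self):
        with pytest.raises(InsufficientDataError):
            spearman(np.array([1.0, 2.0]), np.array([1.0, 2.0]))
        with pytest.raises(UndefinedCorrelationError):
            spearman(np.array([1.0, 1.0, 1.0]), np.array([1.0, 2.0, 3.0]))

    def test_exact_permutation_p_is_calibrated(self):
        # for n=4 distinct values the exact two-sided p of rho=1 is 2/4! = 1/12
        x = np.array([1.0, 2.0, 3.0, 4.0])
        rho, p = spearman(x, x, method="exact")
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(2 / 24)

    def test_exact_agrees_with_full_enumeration_under_ties(self):
        x = np.array([1.0, 1.0, 2.0, 3.0])
        y = np.array([2.0, 3.0, 3.0, 5.0])
        rho, p = spearman(x, y, method="exact")
        rho_o, _ = _oracle_spearman(x, y)
        count = 0
        denom = 0
        for perm in itertools.permutations(range(4)):
            r, _ = _oracle_spearman(x[list(perm)], y)
            denom += 1
            if abs(r) >= abs(rho_o) - 1e-12:
                count += 1
        assert rho == pytest.approx(rho_o)
        assert p == pytest.approx(count / denom)


class TestAssociatePeptides:
    def _matrix(self):
        rng = np.random.default_rng(4)
        pu = pd.Series(10 ** rng.uniform(-1, 1, 60))
        frame = pd.DataFrame(
            {
                "coupled": 10 ** (2 + 0.9 * np.log10(pu) + rng.normal(0, 0.2, 60)),
                "flat": 10 ** rng.normal(1, 0.3, 60),
                "sparse": np.where(np.arange(60) < 2, 5.0, np.nan),
            }
        )
        frame.index = pu.index = pd.Index([f"s{i}" for i in range(60)], name="sample_id")
        return AbundanceMatrix(frame), pu

    def test_planted_dependence_recovered_and_sparse_omitted(self):
        matrix, pu = self._matrix()
        results = {r.peptide_id: r for r in associate_peptides(matrix, pu, "proteinuria")}
        assert "sparse" not in results  # < 3 usable pairs, logged and omitted
        assert results["coupled"].rho > 0.6
        assert abs(results["flat"].rho) < 0.3

    def test_log_transform_does_not_change_ranks(self):
        matrix, pu = self._matrix()
        plain = associate_peptides(matrix, pu, "pu", log_transform=False)
        logged = associate_peptides(matrix, pu, "pu", log_transform=True)
        for a, b in zip(plain, logged):
            assert a.rho == pytest.approx(b.rho, abs=1e-12)
            assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_invariant_to_sample_ordering(self):
        matrix, pu = self._matrix()
        base = associate_peptides(matrix, pu, "pu")
        shuffled = AbundanceMatrix(matrix.values.iloc[::-1])
        again = associate_peptides(shuffled, pu, "pu")
        for a, b in zip(base, again):
            assert a.rho == pytest.approx(b.rho, abs=1e-12)

    def test_bh_column_is_monotone_in_p(self):
        matrix, pu = self._matrix()
        frame = association_frame(associate_peptides(matrix, pu, "pu"))
        assert "p_bh" in frame.columns
        ordered = frame.sort_values("p_value")
        assert (np.diff(ordered["p_bh"]) >= -1e-12).all()
        assert (frame["p_bh"] >= frame["p_value"] - 1e-12).all()


class TestConditionSummary:
    def _toy(self):
        frame = pd.DataFrame(
            {"C3": [10.0, 20.0, 60.0, 30.0], "CFB": [5.0, 5.0, 5.0, np.nan]},
            index=pd.Index(["h1", "h2", "d1", "d2"], name="sample_id"),
        )
        cond = pd.Series(["HC", "HC", "D", "D"], index=frame.index)
        return frame, cond

    def test_control_column_of_ones_and_hand_ratios(self):
        frame, cond = self._toy()
        summary = condition_summary(frame, cond)
        np.testing.assert_allclose(summary["HC"], 1.0)
        # zero-fill: C3 HC mean 15, D mean 45; CFB HC mean 5, D mean 2.5
        assert summary.loc["C3", "D"] == pytest.approx(3.0)
        assert summary.loc["CFB", "D"] == pytest.approx(0.5)

    def test_log10_input_mapped_back_before_averaging(self):
        frame, cond = self._toy()
        logged = np.log10(frame)
        summary = condition_summary(logged, cond, is_log10=True)
        # observed-only on the linear scale: CFB D mean is 5 (one value)
        assert summary.loc["CFB", "D"] == pytest.approx(1.0)
        assert summary.loc["C3", "D"] == pytest.approx(3.0)

    def test_planted_threefold_elevation_recovered(self, table1_peptides):
        from uropept.correction import combined_abundance
        from uropept.annotation import peptide_to_protein
        from uropept.core import clinical_frame
        from uropept.synthetic import (
            GeneratorConfig, example_disease_effects, generate_cohort,
        )

        config = GeneratorConfig(
            n_subjects=4000, seed=9, condition_spec=example_disease_effects(),
            b_true={"C3": 0.0, "C4A": 0.0, "C4B": 0.0, "CFB": 0.0},
            noise_sigma=0.1,
        )
        records, matrix, truth = generate_cohort(config, table1_peptides)
        clin = clinical_frame(records)
        complement = AbundanceMatrix(
            matrix.values[[p.peptide_id for p in table1_peptides]]
        )
        combined = combined_abundance(complement, peptide_to_protein(table1_peptides))
        summary = condition_summary(combined, clin["condition"])
        # geometric-mean bias of the lognormal noise cancels in the ratio
        assert summary.loc["C3", "MCD"] == pytest.approx(3.0, rel=0.15)
        assert summary.loc["CFB", "AKI"] == pytest.approx(2.5, rel=0.15)
        assert summary.loc["C3", "HC"] == 1.0


def test_figure_order_sorts_cfb_c4b_c4a_c3_then_start(table1_peptides):
    order = figure_order(table1_peptides)
    assert order[0] == "e13403"  # CFB region start 234
    assert order[-1] == "e08849"  # last C3 peptide by start
    proteins = [
        {p.peptide_id: p for p in table1_peptides}[pid].protein_id for pid in order
    ]
    boundaries = [proteins.index(x) for x in ("CFB", "C4B", "C4A", "C3")]
    assert boundaries == sorted(boundaries)
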