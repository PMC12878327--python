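"""Error metrics, improvements, quantile cohorts and compound classes."""

import numpy as np
import pytest
from rdkit import Chem

from p31shift import (
    MoleculeRecord,
    ShiftPrediction,
    classify_p_class,
    compute_error_metrics,
    improvement_percent,
    quantile_split,
    relative_mae,
    round_half_up,
    stratified_report,
)


class TestErrorMetrics:
    def test_perfect_predictions_give_zero_errors(self):
        m = compute_error_metrics([(5.0, 5.0), (-3.0, -3.0)])
        assert m.rmse == m.mae == m.mse == 0.0

    def test_hand_arithmetic_case(self):
        m = compute_error_metrics([(0.0, 1.0), (0.0, -1.0)])
        assert m.rmse == pytest.approx(1.0)
        assert m.mae == pytest.approx(1.0)
        assert m.mse == pytest.approx(0.0)

    def test_signed_error_is_exp_minus_calc(self):
        m = compute_error_metrics([(10.0, 12.0)])
        assert m.mse == pytest.approx(-2.0)  # overestimated shift → negative

    def test_rmse_dominates_mae(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 50))
            pairs = rng.normal(scale=20.0, size=(n, 2))
            m = compute_error_metrics(pairs)
            assert m.rmse >= m.mae >= 0.0
            assert abs(m.mse) <= m.mae

    def test_relative_mae_reproduces_printed_values(self):
        assert round_half_up(relative_mae(18.22, 698.0), 1) == 2.6
        assert round_half_up(relative_mae(15.27, 698.0), 1) == 2.2

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            compute_error_metrics([])

    def test_pooled_mse_is_weighted_mean_of_cohort_mse(self, rng):
        pairs = rng.normal(scale=15.0, size=(60, 2))
        split = [pairs[:17], pairs[17:40], pairs[40:]]
        pooled = compute_error_metrics(pairs).mse
        weighted = sum(len(s) * compute_error_metrics(s).mse for s in split) / len(pairs)
        assert weighted == pytest.approx(pooled, abs=1e-9)


class TestImprovement:
    @pytest.mark.parametrize(
        "ref,alt,expected",
        [
            (30.82, 29.37, 4.7),
            (26.92, 26.47, 1.7),
            (25.33, 23.03, 9.1),
            (39.86, 40.79, -2.3),
        ],
    )
    def test_reproduces_printed_improvements(self, ref, alt, expected):
        assert round_half_up(improvement_percent(ref, alt), 1) == expected

    def test_identical_rmse_gives_zero(self):
        assert improvement_percent(17.3, 17.3) == 0.0

    def test_sign_antisymmetry(self, rng):
        for _ in range(20):
            a, b = rng.uniform(1.0, 50.0, size=2)
            assert np.sign(improvement_percent(a, b)) == -np.sign(improvement_percent(b, a))

    def test_nonpositive_reference_rejected(self):
        with pytest.raises(ValueError):
            improvement_percent(0.0, 1.0)


def _records_with_sizes(sizes):
    return [
        MoleculeRecord(f"m{i:05d}", "CP(C)C", delta_exp=0.0, n_atoms=int(s))
        for i, s in enumerate(sizes)
    ]


class TestQuantileSplit:
    def test_large_dataset_group_sizes(self):
        """10,007 records into five quantiles: 2002/2002/2001/2001/2001."""
        records = _records_with_sizes(np.arange(10007) % 78 + 3)
        cohorts = quantile_split(records, "n_atoms", 5)
        assert [len(c.member_ids) for c in cohorts] == [2002, 2002, 2001, 2001, 2001]

    @pytest.mark.parametrize(
        "n,k,expected",
        [(5, 5, [1, 1, 1, 1, 1]), (7, 5, [2, 2, 1, 1, 1]), (10, 3, [4, 3, 3])],
    )
    def test_small_splits(self, n, k, expected):
        cohorts = quantile_split(_records_with_sizes(range(3, 3 + n)), "n_atoms", k)
        assert [len(c.member_ids) for c in cohorts] == expected

    def test_cohorts_partition_the_input(self, rng):
        records = _records_with_sizes(rng.integers(3, 80, size=83))
        cohorts = quantile_split(records, "n_atoms", 5)
        ids = [m for c in cohorts for m in c.member_ids]
        assert len(ids) == len(set(ids)) == len(records)
        # contiguous in the sort key: each cohort's max <= next cohort's min
        maxima = [max(r.n_atoms for r in records if r.mol_id in set(c.member_ids))
                  for c in cohorts]
        minima = [min(r.n_atoms for r in records if r.mol_id in set(c.member_ids))
                  for c in cohorts]
        assert all(maxima[i] <= minima[i + 1] for i in range(len(cohorts) - 1))

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            quantile_split(_records_with_sizes([5, 6]), "n_atoms", 5)


class TestClassification:
    @pytest.mark.parametrize(
        "smiles,expected",
        [
            ("CCP(=O)(OCC)OCC", "phosphonate"),
            ("CCP(OCC)OCC", "phosphonite"),
            ("CC[PH](=O)OCC", "monoalkyl_phosphinate"),
            ("CCP(=O)(CC)OCC", "dialkyl_phosphinate"),
            ("CP(C)C", "other"),  # trimethylphosphine matches no class
            ("CCOP(OCC)OCC", "other"),  # phosphite: no P-C bond
        ],
    )
    def test_class_assignment(self, smiles, expected):
        assert classify_p_class(smiles) == expected

    def test_invariant_under_canonicalization(self):
        for smiles in ["CCP(=O)(OCC)OCC", "CC[PH](=O)OCC", "CCP(OCC)OCC"]:
            canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
            assert classify_p_class(smiles) == classify_p_class(canonical)

    def test_unparsable_smiles_rejected(self):
        with pytest.raises(ValueError):
            classify_p_class("not_a_smiles")


def _toy_dataset():
    records = [
        MoleculeRecord("a", "CCP(=O)(OCC)OCC", delta_exp=30.0, solvent="CHCl3",
                       n_atoms=25, n_rotatable_bonds=6),
        MoleculeRecord("b", "CCP(OCC)OCC", delta_exp=160.0, solvent="CHCl3",
                       n_atoms=24, n_rotatable_bonds=6),
        MoleculeRecord("c", "CP(C)C", delta_exp=-62.0, solvent="H2O",
                       n_atoms=13, n_rotatable_bonds=0),
        MoleculeRecord("d", "CC[PH](=O)OCC", delta_exp=25.0, solvent="unknown",
                       n_atoms=19, n_rotatable_bonds=3),
        MoleculeRecord("e", "CCP(=O)(CC)OCC", delta_exp=40.0, n_atoms=24,
                       n_rotatable_bonds=5),
    ]
    return records


class TestStratifiedReport:
    def test_perfect_predictions_give_zero_everywhere(self):
        records = _toy_dataset()
        predictions = [
            ShiftPrediction(r.mol_id, delta_vac=r.delta_exp, delta_boltzmann=r.delta_exp)
            for r in records
        ]
        report = stratified_report(records, predictions, [("vac", "boltzmann")])
        assert report.cohorts and all(c.metrics.rmse == 0.0 for c in report.cohorts)
        assert report.improvements and all(r.improvement == 0.0 for r in report.improvements)

    def test_identical_conditions_give_zero_improvement(self):
        records = _toy_dataset()
        predictions = [
            ShiftPrediction(r.mol_id, delta_vac=r.delta_exp + 3.0,
                            delta_boltzmann=r.delta_exp + 3.0)
            for r in records
        ]
        report = stratified_report(records, predictions, [("vac", "boltzmann")])
        assert all(r.improvement == 0.0 for r in report.improvements)

    def test_records_without_shift_are_excluded(self):
        records = _toy_dataset()
        records.append(MoleculeRecord("f", "CP(C)C", n_atoms=13))
        predictions = [ShiftPrediction(r.mol_id, delta_vac=r.delta_exp or 0.0)
                       for r in records]
        report = stratified_report(records, predictions, [("vac", "vac")])
        assert report.n_excluded == 1

    def test_unknown_solvent_forms_own_cohort_only(self):
        records = _toy_dataset()
        predictions = [ShiftPrediction(r.mol_id, delta_vac=r.delta_exp)
                       for r in records]
        report = stratified_report(records, predictions, [("vac", "vac")])
        solvent_cohorts = {c.key for c in report.cohorts if c.kind == "solvent"}
        assert "unknown" in solvent_cohorts
        known = {c.key: c.metrics.n for c in report.cohorts
                 if c.kind == "solvent" and c.key != "unknown"}
        assert sum(known.values()) == 3  # the unknown records sit outside

    def test_class_cohorts_report_mean_shifts(self):
        records = _toy_dataset()
        predictions = [ShiftPrediction(r.mol_id, delta_vac=r.delta_exp + 1.0)
                       for r in records]
        report = stratified_report(records, predictions, [("vac", "vac")])
        phosphonate = [c for c in report.cohorts
                       if c.kind == "class" and c.key == "phosphonate"]
        assert len(phosphonate) == 1
        assert phosphonate[0].mean_exp == pytest.approx(30.0)
        assert phosphonate[0].mean_calc == pytest.approx(31.0)

    def test_pooled_vs_cohort_mse_consistency(self, rng):
        records = _toy_dataset() * 1  # five records, distinct solvents incl. unknown
        predictions = [
            ShiftPrediction(r.mol_id, delta_vac=r.delta_exp + float(rng.normal(0, 4)))
            for r in records
        ]
        report = stratified_report(records, predictions, [("vac", "vac")])
        overall = next(c for c in report.cohorts if c.kind == "all")
        size_rows = [c for c in report.cohorts if c.kind == "size_quantile"
                     and c.condition == "vac"]
        weighted = sum(c.metrics.n * c.metrics.mse for c in size_rows)
        weighted /= sum(c.metrics.n for c in size_rows)
        assert weighted == pytest.approx(overall.metrics.mse, abs=1e-9)


def test_round_half_up_at_table_precision():
    assert round_half_up(2.45, 1) == 2.5
    assert round_half_up(2.449, 1) == 2.4
    assert round_half_up(-2.333, 1) == -2.3
    assert round_half_up(16.805, 2) == 16.81
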