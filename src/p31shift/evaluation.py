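"""Error metrics and cohort-stratified comparison of predicted versus
experimental ³¹P shifts.

Errors are always experimental minus calculated: RMSE and MAE in ppm, the
mean signed error (MSE, negative when shifts are overestimated), and the
relative MAE = 100·MAE/Δδ where Δδ is the shift range spanned by the
dataset (698 ppm by default). Cohorts stratify by experimental solvent,
molecule-size or rotatable-bond quantiles, and phosphorus compound class;
pairs of prediction conditions are compared through the relative RMSE
improvement 100·(RMSE_ref − RMSE_alt)/RMSE_ref.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd
from rdkit import Chem

from .datamodel import (
    CANONICAL_SOLVENTS,
    MoleculeRecord,
    ShiftPrediction,
    UNKNOWN_SOLVENT,
)

log = logging.getLogger(__name__)

#: Default Δδ normalization for the relative MAE, in ppm.
SHIFT_RANGE_PPM = 698.0


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round half away from zero at ``ndigits`` decimals (table precision)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ErrorMetrics:
    """Summary errors for one cohort under one prediction condition."""

    n: int
    rmse: float
    mae: float
    mse: float
    rel_mae: float


def relative_mae(mae: float, shift_range: float = SHIFT_RANGE_PPM) -> float:
    """Relative MAE in percent: 100·MAE/Δδ (full precision)."""
    if shift_range <= 0:
        raise ValueError("shift_range must be positive")
    return 100.0 * mae / shift_range


def compute_error_metrics(pairs, shift_range: float = SHIFT_RANGE_PPM) -> ErrorMetrics:
    """RMSE, MAE, MSE and relative MAE for (δ_exp, δ_calc) pairs in ppm."""
    arr = np.asarray(list(pairs), dtype=float)
    if arr.size == 0:
        raise ValueError("empty pair list")
    err = arr[:, 0] - arr[:, 1]
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    metrics = ErrorMetrics(
        n=len(err),
        rmse=rmse,
        mae=mae,
        mse=float(np.mean(err)),
        rel_mae=relative_mae(mae, shift_range),
    )
    # Cauchy-Schwarz: quadratic mean dominates arithmetic mean of |err|
    assert metrics.rmse >= metrics.mae - 1e-12 and metrics.mae >= 0
    return metrics


def improvement_percent(rmse_reference: float, rmse_alternative: float) -> float:
    """Relative RMSE improvement in percent, full precision.

    Positive when the alternative condition is more accurate; round to
    one decimal with :func:`round_half_up` for reporting.
    """
    if rmse_reference <= 0:
        raise ValueError("reference RMSE must be positive")
    return 100.0 * (rmse_reference - rmse_alternative) / rmse_reference


@dataclass
class CohortSpec:
    """A named subset of molecules used for stratified evaluation."""

    kind: str  # all | solvent | size_quantile | rotatable_quantile | class
    key: str
    member_ids: list[str]


def quantile_split(records, key: str = "n_atoms", k: int = 5) -> list[CohortSpec]:
    """Split records into k contiguous quantile cohorts by an integer key.

    Records are sorted ascending by (key value, mol_id); group sizes
    differ by at most one with the larger groups first. Cohorts are
    labeled ``Q1``..``Qk``; the key-value range of each is appended to
    its label key as ``Qi[lo-hi]``.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(records) < k:
        raise ValueError(f"cannot split {len(records)} records into {k} quantiles")
    kind = "size_quantile" if key == "n_atoms" else "rotatable_quantile"
    ordered = sorted(records, key=lambda r: (getattr(r, key), r.mol_id))
    n = len(ordered)
    base, rem = divmod(n, k)
    cohorts = []
    start = 0
    for i in range(k):
        size = base + (1 if i < rem else 0)
        group = ordered[start : start + size]
        start += size
        lo = getattr(group[0], key)
        hi = getattr(group[-1], key)
        cohorts.append(
            CohortSpec(kind=kind, key=f"Q{i + 1}[{lo}-{hi}]", member_ids=[r.mol_id for r in group])
        )
    return cohorts


# Substructure patterns for the four phosphorus compound classes, matched
# in a fixed priority order (first match wins); R groups are carbon.
_CLASS_PATTERNS = [
    ("phosphonate", "[PX4;H0](=O)([OX2][#6])([OX2][#6])[#6]"),  # RCH2P(=O)(OR)2
    ("dialkyl_phosphinate", "[PX4;H0](=O)([OX2][#6])([#6])[#6]"),  # (RCH2)2P(=O)OR
    ("monoalkyl_phosphinate", "[PX4;H1](=O)([OX2][#6])[#6]"),  # RCH2P(=O)(H)OR
    ("phosphonite", "[PX3;H0]([OX2][#6])([OX2][#6])[#6]"),  # RCH2P(OR)2
]
_COMPILED_PATTERNS = [(name, Chem.MolFromSmarts(smarts)) for name, smarts in _CLASS_PATTERNS]


def classify_p_class(smiles: str) -> str:
    """Assign a phosphorus compound class by substructure matching.

    Returns the first matching class in the priority order phosphonate →
    dialkyl_phosphinate → monoalkyl_phosphinate → phosphonite, else
    ``"other"``. Deterministic and invariant under SMILES
    canonicalization.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    if not any(a.GetAtomicNum() == 15 for a in mol.GetAtoms()):
        raise ValueError(f"no phosphorus atom in {smiles!r}")
    for name, pattern in _COMPILED_PATTERNS:
        if mol.HasSubstructMatch(pattern):
            return name
    return "other"


@dataclass
class CohortResult:
    """Per-cohort, per-condition error metrics row."""

    kind: str
    key: str
    condition: str
    metrics: ErrorMetrics
    mean_exp: float
    mean_calc: float


@dataclass
class ImprovementResult:
    """Relative RMSE improvement of one condition pair in one cohort."""

    kind: str
    key: str
    reference: str
    alternative: str
    n: int
    improvement: float


@dataclass
class EvaluationReport:
    """Stratified evaluation output: metric rows plus improvements."""

    cohorts: list[CohortResult] = field(default_factory=list)
    improvements: list[ImprovementResult] = field(default_factory=list)
    n_excluded: int = 0
    warnings: list[str] = field(default_factory=list)

    def cohorts_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": c.kind,
                "cohort": c.key,
                "condition": c.condition,
                "n": c.metrics.n,
                "rmse_ppm": round_half_up(c.metrics.rmse, 2),
                "mae_ppm": round_half_up(c.metrics.mae, 2),
                "mse_ppm": round_half_up(c.metrics.mse, 2),
                "rel_mae_pct": round_half_up(c.metrics.rel_mae, 1),
                "mean_exp_ppm": round_half_up(c.mean_exp, 2),
                "mean_calc_ppm": round_half_up(c.mean_calc, 2),
            }
            for c in self.cohorts
        ]
        return pd.DataFrame(rows)

    def improvements_frame(self) -> pd.DataFrame:
        rows = [
            {
                "kind": r.kind,
                "cohort": r.key,
                "reference": r.reference,
                "alternative": r.alternative,
                "n": r.n,
                "improvement_pct": round_half_up(r.improvement, 1),
            }
            for r in self.improvements
        ]
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        parts = ["Cohort metrics", self.cohorts_frame().to_string(index=False)]
        if self.improvements:
            parts += ["", "Improvements", self.improvements_frame().to_string(index=False)]
        return "\n".join(parts)


def prediction_value(pred: ShiftPrediction, label: str, record: MoleculeRecord):
    """Resolve a condition label to a predicted shift for one molecule.

    ``"vac"`` and ``"boltzmann"`` address the vacuum single-point and
    Boltzmann ensemble shifts; ``"solvent"`` addresses the prediction
    under the molecule's *own* experimental solvent (None for unknown
    solvent); any other label addresses that implicit-solvent condition
    directly.
    """
    if label == "vac":
        return pred.delta_vac
    if label == "boltzmann":
        return pred.delta_boltzmann
    if label == "solvent":
        if record.solvent in CANONICAL_SOLVENTS:
            return pred.delta_solvent.get(record.solvent)
        return None
    return pred.delta_solvent.get(label)


def _build_cohorts(records, quantiles: int) -> list[CohortSpec]:
    cohorts = [CohortSpec("all", "all", [r.mol_id for r in records])]
    for solvent in CANONICAL_SOLVENTS + (UNKNOWN_SOLVENT,):
        ids = [r.mol_id for r in records if r.solvent == solvent]
        if ids:
            cohorts.append(CohortSpec("solvent", solvent, ids))
    if len(records) >= quantiles:
        cohorts.extend(quantile_split(records, "n_atoms", quantiles))
        cohorts.extend(quantile_split(records, "n_rotatable_bonds", quantiles))
    by_class: dict[str, list[str]] = {}
    for r in records:
        label = r.class_label
        if label in ("unassigned", ""):
            label = classify_p_class(r.smiles)
        by_class.setdefault(label, []).append(r.mol_id)
    for label in sorted(by_class):
        cohorts.append(CohortSpec("class", label, by_class[label]))
    return cohorts


def stratified_report(
    records,
    predictions,
    condition_pairs,
    shift_range: float = SHIFT_RANGE_PPM,
    quantiles: int = 5,
) -> EvaluationReport:
    """Cohort-stratified error metrics and condition-pair improvements.

    ``condition_pairs`` is a list of (reference, alternative) condition
    labels (see :func:`prediction_value`). Records lacking an
    experimental shift or a prediction are excluded with a logged count;
    cohorts empty after exclusion are dropped with a warning.
    Improvements are computed on the members for which *both* conditions
    of a pair are available, so the comparison is paired.
    """
    preds = {p.mol_id: p for p in predictions}
    usable = [r for r in records if r.delta_exp is not None and r.mol_id in preds]
    report = EvaluationReport(n_excluded=len(records) - len(usable))
    if report.n_excluded:
        log.info("stratified_report: excluded %d records without shift/prediction",
                 report.n_excluded)
    if not usable:
        report.warnings.append("no usable records")
        return report

    labels: list[str] = []
    for ref, alt in condition_pairs:
        for lab in (ref, alt):
            if lab not in labels:
                labels.append(lab)

    by_id = {r.mol_id: r for r in usable}
    for cohort in _build_cohorts(usable, quantiles):
        members = [by_id[m] for m in cohort.member_ids if m in by_id]
        values = {
            lab: {
                r.mol_id: v
                for r in members
                if (v := prediction_value(preds[r.mol_id], lab, r)) is not None
            }
            for lab in labels
        }
        for lab in labels:
            avail = values[lab]
            if not avail:
                report.warnings.append(f"{cohort.kind}/{cohort.key}: no predictions for {lab}")
                continue
            pairs = [(by_id[m].delta_exp, v) for m, v in avail.items()]
            metrics = compute_error_metrics(pairs, shift_range)
            report.cohorts.append(
                CohortResult(
                    kind=cohort.kind,
                    key=cohort.key,
                    condition=lab,
                    metrics=metrics,
                    mean_exp=float(np.mean([p[0] for p in pairs])),
                    mean_calc=float(np.mean([p[1] for p in pairs])),
                )
            )
        for ref, alt in condition_pairs:
            both = sorted(set(values[ref]) & set(values[alt]))
            if not both:
                continue
            rmse_ref = compute_error_metrics(
                [(by_id[m].delta_exp, values[ref][m]) for m in both], shift_range
            ).rmse
            rmse_alt = compute_error_metrics(
                [(by_id[m].delta_exp, values[alt][m]) for m in both], shift_range
            ).rmse
            if rmse_ref <= 0:
                # both conditions perfect: improvement is 0 by convention;
                # a perfect reference beaten by an imperfect alternative
                # has no defined relative improvement
                if rmse_alt > 0:
                    report.warnings.append(
                        f"{cohort.kind}/{cohort.key}: reference RMSE 0 for ({ref}, {alt})"
                    )
                    continue
                improvement = 0.0
            else:
                improvement = improvement_percent(rmse_ref, rmse_alt)
            report.improvements.append(
                ImprovementResult(
                    kind=cohort.kind,
                    key=cohort.key,
                    reference=ref,
                    alternative=alt,
                    n=len(both),
                    improvement=improvement,
                )
            )
    return report
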