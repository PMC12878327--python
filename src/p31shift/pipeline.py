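"""End-to-end orchestration: load or generate molecules and ensembles,
filter and prune conformers, attach shieldings from a backend, Boltzmann-
average, reference to the experimental scale, evaluate per cohort, and
write SDF/CSV reports.

One bad molecule never aborts a run: per-molecule failures are logged,
counted in the manifest and skipped.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .datamodel import (
    CANONICAL_SOLVENTS,
    ConformerEnsemble,
    MoleculeRecord,
    ReferenceScheme,
    ShiftPrediction,
)
from .evaluation import EvaluationReport, stratified_report, SHIFT_RANGE_PPM
from .geometry import PruneConfig, filter_energy_window, prune_ensemble
from .io import (
    read_conformer_xyz,
    read_molecule_table,
    write_nmredata_sdf,
)
from .shifts import predict_molecule
from .synthetic import GroundTruth, SyntheticConfig, generate_dataset, surrogate_shielding

log = logging.getLogger(__name__)

DEFAULT_CONDITIONS = ("vac",) + CANONICAL_SOLVENTS
DEFAULT_CONDITION_PAIRS = (("vac", "boltzmann"), ("vac", "solvent"))


class ConfigError(ValueError):
    """Invalid pipeline configuration (detected before any processing)."""


@dataclass
class PipelineConfig:
    """Inputs, backend and thresholds for one pipeline run.

    Exactly one input source must be set: either ``synthetic`` or the
    (``molecule_csv``, ``ensemble_dir``) pair. The ``surrogate`` backend
    requires the synthetic source (it needs the latent ground truth);
    the ``precomputed`` backend reads per-conformer shieldings from
    ``shielding_csv`` (columns mol_id, conf_id, condition, sigma_ppm)
    and requires an explicit ``scheme``.
    """

    synthetic: SyntheticConfig | None = None
    molecule_csv: str | None = None
    ensemble_dir: str | None = None
    backend: str = "surrogate"
    shielding_csv: str | None = None
    scheme: ReferenceScheme | None = None
    prune: PruneConfig = field(default_factory=PruneConfig)
    temperature: float = 298.15
    conditions: tuple = DEFAULT_CONDITIONS
    condition_pairs: tuple = DEFAULT_CONDITION_PAIRS
    shift_range: float = SHIFT_RANGE_PPM
    out_dir: str | None = None

    def validate(self) -> None:
        has_synthetic = self.synthetic is not None
        has_files = self.molecule_csv is not None or self.ensemble_dir is not None
        if has_synthetic == has_files:
            raise ConfigError("exactly one input source required: synthetic or CSV+XYZ")
        if has_files and (self.molecule_csv is None or self.ensemble_dir is None):
            raise ConfigError("file input needs both molecule_csv and ensemble_dir")
        if not self.conditions:
            raise ConfigError("at least one condition required")
        if self.backend not in ("surrogate", "precomputed"):
            raise ConfigError(f"unknown backend {self.backend!r}")
        if self.backend == "surrogate" and not has_synthetic:
            raise ConfigError("surrogate backend requires the synthetic input source")
        if self.backend == "precomputed":
            if self.shielding_csv is None:
                raise ConfigError("precomputed backend requires shielding_csv")
            if self.scheme is None:
                raise ConfigError("precomputed backend requires an explicit ReferenceScheme")


@dataclass
class PipelineResult:
    records: list[MoleculeRecord]
    predictions: list[ShiftPrediction]
    report: EvaluationReport
    manifest: dict
    output_files: dict = field(default_factory=dict)


def _precomputed_backend(shielding_csv):
    table = pd.read_csv(shielding_csv, dtype={"mol_id": str, "conf_id": str, "condition": str})
    lookup: dict[tuple[str, str], dict[str, float]] = {}
    for row in table.itertuples(index=False):
        lookup.setdefault((row.mol_id, row.condition), {})[row.conf_id] = float(row.sigma_ppm)

    def backend(ensemble: ConformerEnsemble, condition: str):
        sigmas = lookup.get((ensemble.mol_id, condition), {})
        missing = [c.conf_id for c in ensemble if c.conf_id not in sigmas]
        if missing:
            raise ValueError(
                f"{ensemble.mol_id}/{condition}: missing shieldings for conformers {missing}"
            )
        return [sigmas[c.conf_id] for c in ensemble]

    return backend


def _surrogate_backend(truth: GroundTruth):
    def backend(ensemble: ConformerEnsemble, condition: str):
        return surrogate_shielding(ensemble, condition, truth)

    return backend


def _load_inputs(config: PipelineConfig):
    if config.synthetic is not None:
        records, ensembles, truth = generate_dataset(config.synthetic)
        return records, ensembles, truth, []
    table = read_molecule_table(config.molecule_csv)
    ensembles = {}
    for rec in table.records:
        xyz = Path(config.ensemble_dir) / f"{rec.mol_id}.xyz"
        if xyz.exists():
            ensembles[rec.mol_id] = read_conformer_xyz(xyz, temperature=config.temperature)
    return table.records, ensembles, None, table.warnings


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the full workflow and optionally write its output files.

    Per molecule: energy-window filter → greedy RMSD pruning → backend
    shieldings per condition → Boltzmann averaging → referencing.
    Evaluation stratifies by solvent, size/rotatable-bond quantile and
    compound class over the configured condition pairs.
    """
    config.validate()
    records, ensembles, truth, input_warnings = _load_inputs(config)
    if config.backend == "surrogate":
        backend = _surrogate_backend(truth)
        scheme = config.scheme or truth.reference_scheme()
    else:
        backend = _precomputed_backend(config.shielding_csv)
        scheme = config.scheme

    predictions: list[ShiftPrediction] = []
    failures: list[str] = []
    processed_records: list[MoleculeRecord] = []
    for i, rec in enumerate(records):
        try:
            ensemble = ensembles[rec.mol_id]
        except KeyError:
            failures.append(f"{rec.mol_id}: no conformer ensemble")
            continue
        try:
            pruned = prune_ensemble(
                filter_energy_window(ensemble, config.prune.energy_window), config.prune
            )
            pred = ShiftPrediction(mol_id=rec.mol_id, n_conformers_used=len(pruned))
            for condition in config.conditions:
                cond_pred = predict_molecule(
                    rec, pruned.with_shieldings(backend(pruned, condition)), scheme, condition
                )
                if condition == "vac":
                    pred.delta_vac = cond_pred.delta_vac
                else:
                    pred.delta_solvent[condition] = cond_pred.delta_solvent[condition]
                if condition == "vac" or pred.delta_boltzmann is None:
                    pred.delta_boltzmann = cond_pred.delta_boltzmann
                    pred.delta_lowest_shielding = cond_pred.delta_lowest_shielding
                    pred.delta_highest_shielding = cond_pred.delta_highest_shielding
        except (ValueError, KeyError) as exc:
            failures.append(f"{rec.mol_id}: {exc}")
            continue
        predictions.append(pred)
        processed_records.append(rec)
        if (i + 1) % 100 == 0:
            log.info("processed %d/%d molecules", i + 1, len(records))

    if records and not predictions:
        raise ValueError(f"all {len(records)} molecules failed; first: {failures[0]}")

    report = stratified_report(
        processed_records, predictions, config.condition_pairs, config.shift_range
    )
    manifest = {
        "package_version": __version__,
        "n_input": len(records),
        "n_processed": len(predictions),
        "n_skipped": len(failures),
        "failures": failures,
        "input_warnings": input_warnings,
        "backend": config.backend,
        "conditions": list(config.conditions),
        "condition_pairs": [list(p) for p in config.condition_pairs],
        "temperature_K": config.temperature,
        "prune": asdict(config.prune),
        "scheme": asdict(scheme),
        "synthetic": asdict(config.synthetic) if config.synthetic else None,
        "seed": config.synthetic.seed if config.synthetic else None,
    }

    result = PipelineResult(processed_records, predictions, report, manifest)
    if config.out_dir is not None:
        result.output_files = write_outputs(result, config.out_dir)
    return result


def predictions_frame(records, predictions) -> pd.DataFrame:
    """Flat per-molecule table of metadata and predicted shifts."""
    by_id = {r.mol_id: r for r in records}
    rows = []
    for pred in predictions:
        rec = by_id[pred.mol_id]
        row = {
            "mol_id": rec.mol_id,
            "smiles": rec.smiles,
            "delta_exp_ppm": rec.delta_exp,
            "solvent": rec.solvent,
            "n_atoms": rec.n_atoms,
            "n_rotatable_bonds": rec.n_rotatable_bonds,
            "class_label": rec.class_label,
            "n_conformers_used": pred.n_conformers_used,
            "delta_vac_ppm": pred.delta_vac,
            "delta_boltzmann_ppm": pred.delta_boltzmann,
            "delta_lowest_shielding_ppm": pred.delta_lowest_shielding,
            "delta_highest_shielding_ppm": pred.delta_highest_shielding,
        }
        for solvent in CANONICAL_SOLVENTS:
            row[f"delta_{solvent}_ppm"] = pred.delta_solvent.get(solvent)
        rows.append(row)
    return pd.DataFrame(rows)


def write_outputs(result: PipelineResult, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    files = {
        "predictions": out / "predictions.csv",
        "cohorts": out / "report_cohorts.csv",
        "improvements": out / "report_improvements.csv",
        "sdf": out / "nmredata.sdf",
        "manifest": out / "manifest.json",
    }
    # %.17g round-trips doubles exactly, so re-evaluating the CSV
    # reproduces the in-run report bit for bit
    predictions_frame(result.records, result.predictions).to_csv(
        files["predictions"], index=False, float_format="%.17g"
    )
    result.report.cohorts_frame().to_csv(files["cohorts"], index=False)
    result.report.improvements_frame().to_csv(files["improvements"], index=False)
    write_nmredata_sdf(result.records, result.predictions, files["sdf"])
    files["manifest"].write_text(json.dumps(result.manifest, indent=2, sort_keys=True) + "\n")
    return {k: str(v) for k, v in files.items()}


def evaluate_predictions_csv(
    path,
    condition_pairs=DEFAULT_CONDITION_PAIRS,
    shift_range: float = SHIFT_RANGE_PPM,
) -> EvaluationReport:
    """Re-evaluate a written predictions CSV; reproduces the in-run report."""
    df = pd.read_csv(path, dtype={"mol_id": str}, float_precision="round_trip")
    records, predictions = [], []
    for row in df.itertuples(index=False):
        records.append(
            MoleculeRecord(
                mol_id=row.mol_id,
                smiles=row.smiles,
                delta_exp=None if pd.isna(row.delta_exp_ppm) else float(row.delta_exp_ppm),
                solvent=row.solvent,
                n_atoms=int(row.n_atoms),
                n_rotatable_bonds=int(row.n_rotatable_bonds),
                class_label=row.class_label,
            )
        )
        pred = ShiftPrediction(
            mol_id=row.mol_id,
            n_conformers_used=int(row.n_conformers_used),
        )
        for attr, col in (
            ("delta_vac", "delta_vac_ppm"),
            ("delta_boltzmann", "delta_boltzmann_ppm"),
            ("delta_lowest_shielding", "delta_lowest_shielding_ppm"),
            ("delta_highest_shielding", "delta_highest_shielding_ppm"),
        ):
            value = getattr(row, col)
            if pd.notna(value):
                setattr(pred, attr, float(value))
        for solvent in CANONICAL_SOLVENTS:
            value = getattr(row, f"delta_{solvent}_ppm")
            if pd.notna(value):
                pred.delta_solvent[solvent] = float(value)
        predictions.append(pred)
    return stratified_report(records, predictions, condition_pairs, shift_range)
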