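"""Readers and writers: molecule CSV tables, multi-conformer XYZ, and SDF
files carrying NMReData-style ³¹P shift tags."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdMolDescriptors
from rdkit import RDLogger

from .datamodel import (
    CANONICAL_SOLVENTS,
    Conformer,
    ConformerEnsemble,
    MoleculeRecord,
    ShiftPrediction,
    UNKNOWN_SOLVENT,
    normalize_solvent,
)

log = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

# NMReData-style data-field names. The initiative's standard tag set has no
# slot for per-solvent computed shifts, so the computed values use explicit
# local tags alongside the version tag.
TAG_VERSION = "NMREDATA_VERSION"
TAG_VAC = "P31_SHIFT_VAC_PPM"
TAG_BOLTZMANN = "P31_SHIFT_BOLTZMANN_PPM"
TAG_EXP = "P31_SHIFT_EXP_PPM"
TAG_SOLVENT_EXP = "P31_SOLVENT_EXP"
SOLVENT_TAGS = {
    "CHCl3": "P31_SHIFT_CPCM_CHCL3_PPM",
    "DMSO": "P31_SHIFT_CPCM_DMSO_PPM",
    "toluene": "P31_SHIFT_CPCM_TOLUENE_PPM",
    "H2O": "P31_SHIFT_CPCM_H2O_PPM",
    "CH3CN": "P31_SHIFT_CPCM_CH3CN_PPM",
}
_KNOWN_TAGS = {TAG_VERSION, TAG_VAC, TAG_BOLTZMANN, TAG_EXP, TAG_SOLVENT_EXP} | set(
    SOLVENT_TAGS.values()
)


def molecule_properties(smiles: str) -> tuple[str, int, int, int]:
    """Canonical SMILES, atom count (with H), rotatable bonds (strict), P count.

    Raises ``ValueError`` if the SMILES does not parse.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparsable SMILES: {smiles!r}")
    n_atoms = Chem.AddHs(mol).GetNumAtoms()
    n_rot = rdMolDescriptors.CalcNumRotatableBonds(
        mol, rdMolDescriptors.NumRotatableBondsOptions.Strict
    )
    n_p = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 15)
    return Chem.MolToSmiles(mol), n_atoms, n_rot, n_p


@dataclass
class MoleculeTable:
    """Result of :func:`read_molecule_table`: parsed records plus the
    row-level warnings collected while skipping bad rows."""

    records: list[MoleculeRecord]
    warnings: list[str]

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)


def read_molecule_table(path) -> MoleculeTable:
    """Read a molecule CSV (columns mol_id, smiles[, delta_exp_ppm, solvent]).

    Rows whose SMILES does not parse, or parses to a phosphorus-free
    molecule, are skipped and reported as warnings. Duplicate mol_id is a
    hard error. Extra columns are ignored with a log note.
    """
    df = pd.read_csv(path, dtype={"mol_id": str, "smiles": str})
    for col in ("mol_id", "smiles"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    extra = set(df.columns) - {"mol_id", "smiles", "delta_exp_ppm", "solvent"}
    if extra:
        log.info("%s: ignoring extra columns %s", path, sorted(extra))
    dupes = df["mol_id"][df["mol_id"].duplicated()]
    if not dupes.empty:
        raise ValueError(f"{path}: duplicate mol_id values: {sorted(set(dupes))}")

    records: list[MoleculeRecord] = []
    warnings: list[str] = []
    for row in df.itertuples(index=False):
        mol_id = str(row.mol_id)
        try:
            smiles, n_atoms, n_rot, n_p = molecule_properties(str(row.smiles))
            if n_p == 0:
                raise ValueError(f"no phosphorus atom in {row.smiles!r}")
        except ValueError as exc:
            warnings.append(f"{mol_id}: {exc}")
            continue
        delta_exp = getattr(row, "delta_exp_ppm", None)
        delta_exp = float(delta_exp) if delta_exp is not None and pd.notna(delta_exp) else None
        solvent = normalize_solvent(getattr(row, "solvent", None))
        records.append(
            MoleculeRecord(
                mol_id=mol_id,
                smiles=smiles,
                delta_exp=delta_exp,
                solvent=solvent,
                n_atoms=n_atoms,
                n_rotatable_bonds=n_rot,
            )
        )
    return MoleculeTable(records, warnings)


def write_molecule_table(records, path) -> None:
    """Write records back out in the canonical CSV schema."""
    pd.DataFrame(
        {
            "mol_id": [r.mol_id for r in records],
            "smiles": [r.smiles for r in records],
            "delta_exp_ppm": [r.delta_exp for r in records],
            "solvent": [r.solvent for r in records],
        }
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# multi-conformer XYZ

def read_conformer_xyz(path, temperature: float = 298.15) -> ConformerEnsemble:
    """Read concatenated XYZ blocks with ``conf=<id> dG=<float>`` comments.

    Relative Gibbs energies (kcal/mol) are shifted so their minimum is
    exactly 0; block order is preserved. Inconsistent atom counts or a
    missing dG token are hard errors.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    blocks: list[tuple[str, float, np.ndarray]] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            natoms = int(lines[i].strip())
        except ValueError as exc:
            raise ValueError(f"{path}: expected atom count at line {i + 1}") from exc
        comment = lines[i + 1] if i + 1 < len(lines) else ""
        tokens = dict(
            t.split("=", 1) for t in comment.split() if "=" in t
        )
        if "dG" not in tokens:
            raise ValueError(f"{path}: missing dG token in comment line {i + 2}")
        conf_id = tokens.get("conf", f"c{len(blocks):03d}")
        dg = float(tokens["dG"])
        coord_lines = lines[i + 2 : i + 2 + natoms]
        if len(coord_lines) < natoms:
            raise ValueError(f"{path}: truncated XYZ block at line {i + 1}")
        coords = np.array(
            [[float(x) for x in ln.split()[1:4]] for ln in coord_lines], dtype=float
        )
        blocks.append((conf_id, dg, coords))
        i += 2 + natoms

    if not blocks:
        raise ValueError(f"{path}: no XYZ blocks found")
    counts = {c.shape[0] for _, _, c in blocks}
    if len(counts) != 1:
        raise ValueError(f"{path}: inconsistent atom counts across blocks: {sorted(counts)}")
    dg_min = min(dg for _, dg, _ in blocks)
    confs = [Conformer(cid, coords, dg - dg_min) for cid, dg, coords in blocks]
    return ConformerEnsemble(path.stem, confs, temperature=temperature)


def write_conformer_xyz(ensemble: ConformerEnsemble, path, symbols=None) -> None:
    """Write an ensemble as concatenated XYZ blocks (dG in kcal/mol)."""
    symbols = symbols or ["X"] * ensemble.n_atoms
    out = []
    for conf in ensemble:
        out.append(str(conf.n_atoms))
        out.append(f"conf={conf.conf_id} dG={conf.delta_G:.6f}")
        for sym, (x, y, z) in zip(symbols, conf.coords):
            out.append(f"{sym} {x:.6f} {y:.6f} {z:.6f}")
    Path(path).write_text("\n".join(out) + "\n")


# ---------------------------------------------------------------------------
# NMReData-style SDF

def _fmt(value: float) -> str:
    return f"{value:.2f}"


def write_nmredata_sdf(records, predictions, path) -> None:
    """Write a V2000 SDF with NMReData-style shift data fields.

    One entry per record; ppm values are serialized at 2 decimals. Tags
    for absent prediction entries are omitted. A prediction whose mol_id
    has no matching record is a hard error.
    """
    by_id = {r.mol_id: r for r in records}
    preds = {p.mol_id: p for p in (predictions or [])}
    missing = set(preds) - set(by_id)
    if missing:
        raise ValueError(f"predictions without matching record: {sorted(missing)}")

    writer = Chem.SDWriter(str(path))
    try:
        for rec in records:
            mol = Chem.MolFromSmiles(rec.smiles)
            if mol is None:
                raise ValueError(f"{rec.mol_id}: unparsable SMILES {rec.smiles!r}")
            mol.SetProp("_Name", rec.mol_id)
            mol.SetProp(TAG_VERSION, "1.1")
            if rec.delta_exp is not None:
                mol.SetProp(TAG_EXP, _fmt(rec.delta_exp))
            mol.SetProp(TAG_SOLVENT_EXP, rec.solvent)
            pred = preds.get(rec.mol_id)
            if pred is not None:
                if pred.delta_vac is not None:
                    mol.SetProp(TAG_VAC, _fmt(pred.delta_vac))
                if pred.delta_boltzmann is not None:
                    mol.SetProp(TAG_BOLTZMANN, _fmt(pred.delta_boltzmann))
                for solvent, tag in SOLVENT_TAGS.items():
                    if solvent in pred.delta_solvent:
                        mol.SetProp(tag, _fmt(pred.delta_solvent[solvent]))
                for tag, value in pred.extra_tags.items():
                    mol.SetProp(tag, str(value))
            writer.write(mol)
    finally:
        writer.close()


def read_nmredata_sdf(path) -> tuple[list[MoleculeRecord], list[ShiftPrediction]]:
    """Read an SDF written by :func:`write_nmredata_sdf`.

    Inverse of the writer on its own output (2-decimal ppm precision);
    unrecognized data tags are kept in each prediction's pass-through
    ``extra_tags`` map. Malformed molecule blocks are skipped with a
    logged warning.
    """
    records: list[MoleculeRecord] = []
    predictions: list[ShiftPrediction] = []
    supplier = Chem.SDMolSupplier(str(path), sanitize=True, removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            log.warning("%s: skipping malformed molecule block %d", path, i)
            continue
        mol_id = mol.GetProp("_Name") if mol.HasProp("_Name") else f"mol{i:05d}"
        smiles, n_atoms, n_rot, _ = molecule_properties(Chem.MolToSmiles(mol))
        props = mol.GetPropsAsDict()
        delta_exp = float(props[TAG_EXP]) if TAG_EXP in props else None
        solvent = str(props.get(TAG_SOLVENT_EXP, UNKNOWN_SOLVENT))
        if solvent not in CANONICAL_SOLVENTS + (UNKNOWN_SOLVENT,):
            solvent = normalize_solvent(solvent)
        records.append(
            MoleculeRecord(
                mol_id=mol_id,
                smiles=smiles,
                delta_exp=delta_exp,
                solvent=solvent,
                n_atoms=n_atoms,
                n_rotatable_bonds=n_rot,
            )
        )
        pred = ShiftPrediction(mol_id=mol_id)
        if TAG_VAC in props:
            pred.delta_vac = float(props[TAG_VAC])
        if TAG_BOLTZMANN in props:
            pred.delta_boltzmann = float(props[TAG_BOLTZMANN])
        for solvent_name, tag in SOLVENT_TAGS.items():
            if tag in props:
                pred.delta_solvent[solvent_name] = float(props[tag])
        for tag, value in props.items():
            if tag not in _KNOWN_TAGS and not tag.startswith("_"):
                pred.extra_tags[tag] = value
        predictions.append(pred)
    return records, predictions
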