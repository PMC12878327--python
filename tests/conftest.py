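import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from p31shift import (
    Conformer,
    ConformerEnsemble,
    MoleculeRecord,
    PipelineConfig,
    ShiftPrediction,
    SyntheticConfig,
    run_pipeline,
)


def random_rigid_transform(coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Apply a random proper rotation plus translation."""
    rot = Rotation.random(random_state=int(rng.integers(2**31 - 1)))
    shift = rng.normal(scale=5.0, size=3)
    return coords @ rot.as_matrix().T + shift


def oracle_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """Independent minimal RMSD via scipy's rotation estimation."""
    a = coords_a - coords_a.mean(axis=0)
    b = coords_b - coords_b.mean(axis=0)
    _, rssd = Rotation.align_vectors(a, b)
    return float(rssd / np.sqrt(len(a)))


def make_ensemble(
    rng: np.random.Generator,
    n_conformers: int,
    n_atoms: int = 8,
    mol_id: str = "m",
    spread: float = 1.0,
    sigmas=None,
    temperature: float = 298.15,
) -> ConformerEnsemble:
    """Random ensemble: jittered copies of one base geometry, sorted ΔG."""
    base = rng.normal(scale=2.0, size=(n_atoms, 3))
    dgs = np.concatenate([[0.0], np.sort(rng.uniform(0.0, 5.9, size=n_conformers - 1))])
    confs = []
    for i, dg in enumerate(dgs):
        coords = base + rng.normal(scale=spread, size=(n_atoms, 3))
        sigma = None if sigmas is None else sigmas[i]
        confs.append(Conformer(f"c{i:03d}", coords, float(dg), sigma_P=sigma))
    return ConformerEnsemble(mol_id, confs, temperature=temperature)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


@pytest.fixture
def sample_records() -> list[MoleculeRecord]:
    return [
        MoleculeRecord("m1", "CP(C)C", delta_exp=-62.0, solvent="CHCl3",
                       n_atoms=13, n_rotatable_bonds=0),
        MoleculeRecord("m2", "CCP(=O)(OCC)OCC", delta_exp=32.5, solvent="H2O",
                       n_atoms=25, n_rotatable_bonds=6),
        MoleculeRecord("m3", "CCP(OCC)OCC", delta_exp=165.0, solvent="unknown",
                       n_atoms=24, n_rotatable_bonds=6),
    ]


@pytest.fixture
def sample_predictions() -> list[ShiftPrediction]:
    return [
        ShiftPrediction("m1", delta_vac=-60.12, delta_boltzmann=-61.57,
                        delta_solvent={"CHCl3": -60.94}),
        ShiftPrediction("m2", delta_vac=30.0, delta_boltzmann=31.25,
                        delta_solvent={"H2O": 31.99, "DMSO": 30.51}),
        ShiftPrediction("m3", delta_vac=170.02),
    ]


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One small surrogate-backend pipeline run with written outputs."""
    out = tmp_path_factory.mktemp("run")
    config = PipelineConfig(
        synthetic=SyntheticConfig(n_molecules=60, seed=5,
                                  solvent_offsets={"CHCl3": 3.0, "H2O": -5.0}),
        out_dir=str(out),
    )
    return run_pipeline(config)
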