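"""Core domain types for conformer-ensemble ³¹P NMR shift prediction.

A *shielding* (σ, ppm) is the quantum-chemical observable computed per
conformer; a *chemical shift* (δ, ppm) is the experimental-scale quantity
obtained by referencing σ against a secondary standard (trimethylphosphine,
δ_exp = −62.0 ppm vs 85% H₃PO₄). These types carry molecules, conformer
ensembles with relative Gibbs energies, the referencing scheme, and
per-molecule predictions through the pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical implicit-solvent labels understood throughout the package.
CANONICAL_SOLVENTS = ("CHCl3", "DMSO", "toluene", "H2O", "CH3CN")

UNKNOWN_SOLVENT = "unknown"

#: Phosphorus compound classes distinguished by the evaluation module.
P_CLASSES = (
    "monoalkyl_phosphinate",
    "phosphonite",
    "phosphonate",
    "dialkyl_phosphinate",
    "other",
)

UNASSIGNED_CLASS = "unassigned"

# Deuterated spellings map to the nondeuterated canonical label: the
# dielectric continuum uses the nondeuterated solvent's constant.
_SOLVENT_ALIASES = {
    "chcl3": "CHCl3",
    "cdcl3": "CHCl3",
    "chloroform": "CHCl3",
    "dmso": "DMSO",
    "dmso-d6": "DMSO",
    "dmso_d6": "DMSO",
    "toluene": "toluene",
    "toluol": "toluene",
    "toluene-d8": "toluene",
    "h2o": "H2O",
    "d2o": "H2O",
    "water": "H2O",
    "ch3cn": "CH3CN",
    "cd3cn": "CH3CN",
    "acetonitrile": "CH3CN",
    "mecn": "CH3CN",
}


def normalize_solvent(label: object) -> str:
    """Map a free-form solvent label to one of the canonical names.

    Case-insensitive; deuterated spellings (CDCl3, DMSO-d6, D2O, CD3CN)
    collapse onto their nondeuterated canonical labels. Anything
    unrecognized (including missing values) becomes ``"unknown"``.
    """
    if label is None:
        return UNKNOWN_SOLVENT
    text = str(label).strip()
    if not text or text.lower() in ("nan", "none", "na", "unknown", "-"):
        return UNKNOWN_SOLVENT
    return _SOLVENT_ALIASES.get(text.lower(), UNKNOWN_SOLVENT)


@dataclass
class MoleculeRecord:
    """One compound: identity, experimental shift and cohort metadata.

    Parameters
    ----------
    mol_id : str
        Unique identifier within a dataset.
    smiles : str
        Canonical SMILES; must contain at least one phosphorus atom.
    delta_exp : float or None
        Experimental ³¹P shift in ppm, if measured.
    solvent : str
        One of :data:`CANONICAL_SOLVENTS` or ``"unknown"``.
    n_atoms : int
        Atom count including hydrogens.
    n_rotatable_bonds : int
        Rotatable-bond count (strict definition: amide and terminal
        methyl torsions excluded).
    class_label : str
        One of :data:`P_CLASSES` or ``"unassigned"``.
    """

    mol_id: str
    smiles: str
    delta_exp: float | None = None
    solvent: str = UNKNOWN_SOLVENT
    n_atoms: int = 0
    n_rotatable_bonds: int = 0
    class_label: str = UNASSIGNED_CLASS

    def __post_init__(self) -> None:
        if self.n_atoms and self.n_atoms < 2:
            raise ValueError(f"{self.mol_id}: n_atoms must be >= 2, got {self.n_atoms}")
        if self.solvent not in CANONICAL_SOLVENTS + (UNKNOWN_SOLVENT,):
            self.solvent = normalize_solvent(self.solvent)


@dataclass
class Conformer:
    """A single 3D geometry with its relative Gibbs energy.

    ``sigma_P`` holds the isotropic shielding(s) at phosphorus in ppm —
    a scalar for single-P molecules, a sequence for molecules with
    several symmetry-equivalent P atoms — or ``None`` when no shielding
    has been attached yet.
    """

    conf_id: str
    coords: np.ndarray
    delta_G: float
    sigma_P: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError(f"conformer {self.conf_id}: coords must be N x 3")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"conformer {self.conf_id}: non-finite coordinates")
        self.delta_G = float(self.delta_G)

    @property
    def n_atoms(self) -> int:
        return int(self.coords.shape[0])


@dataclass
class ConformerEnsemble:
    """An ordered set of conformers of one molecule.

    Relative Gibbs energies are in kcal/mol with the lowest conformer at
    exactly 0; all conformers share one atom ordering. ``temperature``
    (K) is the temperature used for Boltzmann weighting.
    """

    mol_id: str
    conformers: list[Conformer]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not self.conformers:
            raise ValueError(f"{self.mol_id}: ensemble must contain >= 1 conformer")
        counts = {c.n_atoms for c in self.conformers}
        if len(counts) != 1:
            raise ValueError(
                f"{self.mol_id}: inconsistent atom counts across conformers: {sorted(counts)}"
            )
        dg = self.delta_g
        if dg.min() < -1e-9 or dg.min() > 1e-6:
            raise ValueError(
                f"{self.mol_id}: relative Gibbs energies must have min exactly 0 "
                f"(got min {dg.min():g}); normalize on read"
            )
        if self.temperature <= 0:
            raise ValueError(f"{self.mol_id}: temperature must be positive")

    @property
    def delta_g(self) -> np.ndarray:
        return np.array([c.delta_G for c in self.conformers], dtype=float)

    @property
    def n_atoms(self) -> int:
        return self.conformers[0].n_atoms

    def __len__(self) -> int:
        return len(self.conformers)

    def __iter__(self):
        return iter(self.conformers)

    def lowest(self) -> Conformer:
        """The (first) conformer with ΔG = 0."""
        return min(self.conformers, key=lambda c: (c.delta_G, c.conf_id))

    def subset(self, indices) -> "ConformerEnsemble":
        return ConformerEnsemble(
            mol_id=self.mol_id,
            conformers=[self.conformers[i] for i in indices],
            temperature=self.temperature,
        )

    def with_shieldings(self, sigmas) -> "ConformerEnsemble":
        """Return a copy with per-conformer shieldings attached (ppm)."""
        if len(sigmas) != len(self.conformers):
            raise ValueError(
                f"{self.mol_id}: {len(sigmas)} shieldings for {len(self.conformers)} conformers"
            )
        confs = [
            Conformer(c.conf_id, c.coords, c.delta_G, sigma_P=s)
            for c, s in zip(self.conformers, sigmas)
        ]
        return ConformerEnsemble(self.mol_id, confs, self.temperature)


@dataclass
class ReferenceScheme:
    """Shielding → shift referencing via trimethylphosphine.

    ``sigma_ref`` is the computed shielding of PMe₃ under the same
    backend settings as the molecule shieldings; ``delta_ref_exp`` its
    experimental shift versus 85% phosphoric acid (−62.0 ppm). Under the
    default ``"physical"`` convention δ = (σ_ref − σ) + δ_ref_exp, so the
    reference compound maps to its own experimental shift. The
    ``"as_printed"`` convention δ = σ_ref − σ − δ_ref_exp keeps the
    opposite sign on the experimental correction.
    """

    sigma_ref: float
    delta_ref_exp: float = -62.0
    convention: str = "physical"

    def __post_init__(self) -> None:
        if self.convention not in ("physical", "as_printed"):
            raise ValueError(f"unknown referencing convention: {self.convention!r}")


@dataclass
class ShiftPrediction:
    """Predicted ³¹P shifts for one molecule under the run's conditions.

    ``delta_vac`` is the single-point (lowest-energy conformer) vacuum
    shift; ``delta_solvent`` maps solvent labels to single-point shifts
    under the matching implicit-solvent condition; the Boltzmann /
    lowest-shielding / highest-shielding entries summarize the conformer
    ensemble. Note the shift from the *highest* shielding is the lowest
    shift (δ decreases as σ increases).
    """

    mol_id: str
    delta_vac: float | None = None
    delta_solvent: dict = field(default_factory=dict)
    delta_boltzmann: float | None = None
    delta_lowest_shielding: float | None = None
    delta_highest_shielding: float | None = None
    n_conformers_used: int = 0
    extra_tags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if (
            self.delta_lowest_shielding is not None
            and self.delta_highest_shielding is not None
            and self.delta_highest_shielding > self.delta_lowest_shielding + 1e-9
        ):
            raise ValueError(
                f"{self.mol_id}: shift from highest shielding must not exceed "
                "shift from lowest shielding"
            )
        if self.n_conformers_used and not (1 <= self.n_conformers_used <= 20):
            raise ValueError(
                f"{self.mol_id}: n_conformers_used must lie in [1, 20], "
                f"got {self.n_conformers_used}"
            )
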