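"""Conformer-ensemble geometry operations.

Energy-window filtering of thermally accessible conformers, optimal-
superposition (Kabsch) RMSD between geometries, and the greedy RMSD-based
pruning that caps an ensemble at 20 members: candidates are visited in
ascending relative Gibbs energy and accepted only when their minimum RMSD
to every already-selected conformer exceeds 0.5 Å, so near-duplicate
geometries collapse onto their lowest-energy representative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import ConformerEnsemble


@dataclass
class PruneConfig:
    """Thresholds for conformer selection.

    rmsd_threshold : Å, minimum separation between selected conformers.
    max_conformers : cap on the pruned ensemble size.
    energy_window : kcal/mol, maximum relative Gibbs energy considered
    thermally accessible at the working temperature.
    """

    rmsd_threshold: float = 0.5
    max_conformers: int = 20
    energy_window: float = 6.0

    def __post_init__(self) -> None:
        if self.rmsd_threshold <= 0:
            raise ValueError("rmsd_threshold must be positive")
        if self.max_conformers < 1:
            raise ValueError("max_conformers must be >= 1")
        if self.energy_window <= 0:
            raise ValueError("energy_window must be positive")


def kabsch_rmsd(coords_a: np.ndarray, coords_b: np.ndarray) -> float:
    """RMSD (Å) after optimal rigid superposition of two geometries.

    Both coordinate sets are translated to their centroids and the
    rotation minimizing the squared deviation is found from the SVD of
    the covariance matrix; improper (mirror) rotations are excluded by
    forcing the rotation determinant to +1. Identical atom ordering is
    assumed — no atom reassignment or symmetry permutation is attempted.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("coordinates must be N x 3 arrays")
    n = a.shape[0]
    if n < 3:
        raise ValueError("RMSD superposition needs >= 3 atoms (rotation under-determined)")

    ac = a - a.mean(axis=0)
    bc = b - b.mean(axis=0)
    u, _, vt = np.linalg.svd(ac.T @ bc)
    # flip the weakest direction rather than allow an improper rotation
    d = np.sign(np.linalg.det(u @ vt)) or 1.0
    rotation = (u * np.array([1.0, 1.0, d])) @ vt
    residual = ac @ rotation - bc
    return float(np.sqrt(np.mean(np.sum(residual * residual, axis=1))))


def filter_energy_window(ensemble: ConformerEnsemble, window: float = 6.0) -> ConformerEnsemble:
    """Keep conformers with ΔG ≤ window (kcal/mol, inclusive boundary).

    The ΔG = 0 conformer is always retained, so the result is never
    empty; input order is preserved.
    """
    if window <= 0:
        raise ValueError("energy window must be positive")
    keep = [i for i, c in enumerate(ensemble.conformers) if c.delta_G <= window]
    if len(keep) == len(ensemble):
        return ensemble
    return ensemble.subset(keep)


def prune_ensemble(ensemble: ConformerEnsemble, config: PruneConfig | None = None) -> ConformerEnsemble:
    """Greedy RMSD pruning of an energy-window-filtered ensemble.

    Ensembles no larger than ``max_conformers`` are returned unchanged.
    Otherwise candidates are visited in ascending (ΔG, conf_id) order
    starting from the lowest-energy conformer, which is always selected
    first; a candidate joins the selection iff its minimum RMSD to all
    already-selected conformers is strictly greater than
    ``rmsd_threshold``. Selection stops when ``max_conformers`` members
    are chosen or candidates run out (no threshold relaxation). The
    output is sorted by ΔG.
    """
    config = config or PruneConfig()
    if len(ensemble) <= config.max_conformers:
        return ensemble

    order = sorted(
        range(len(ensemble)),
        key=lambda i: (ensemble.conformers[i].delta_G, ensemble.conformers[i].conf_id),
    )
    selected = [order[0]]
    for idx in order[1:]:
        if len(selected) >= config.max_conformers:
            break
        min_rmsd = min(
            kabsch_rmsd(ensemble.conformers[idx].coords, ensemble.conformers[j].coords)
            for j in selected
        )
        if min_rmsd > config.rmsd_threshold:
            selected.append(idx)
    return ensemble.subset(selected)
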