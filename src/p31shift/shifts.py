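"""Boltzmann statistics over conformer shieldings and shielding → shift
referencing.

The ensemble-averaged shielding at temperature T is

    σ_bol = Σ_i σ_i · exp(−ΔG_i / RT) / Σ_i exp(−ΔG_i / RT)

with ΔG_i the relative Gibbs energy of conformer i in kcal/mol and
R = 1.987204259×10⁻³ kcal mol⁻¹ K⁻¹. Shieldings are converted to shifts
against the computed shielding of trimethylphosphine and corrected by its
experimental shift (−62.0 ppm) to land on the 85% H₃PO₄ scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import (
    Conformer,
    ConformerEnsemble,
    MoleculeRecord,
    ReferenceScheme,
    ShiftPrediction,
)

#: Gas constant in kcal mol^-1 K^-1.
GAS_CONSTANT_KCAL = 1.987204259e-3


def boltzmann_weights(delta_g, temperature: float = 298.15) -> np.ndarray:
    """Normalized Boltzmann populations w_i ∝ exp(−ΔG_i/RT).

    ``delta_g`` are relative Gibbs energies in kcal/mol (all ≥ 0, the
    reference conformer at 0); ``temperature`` in K.
    """
    dg = np.asarray(delta_g, dtype=float)
    if dg.size == 0:
        raise ValueError("empty energy list")
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    if not np.all(np.isfinite(dg)) or np.any(dg < 0):
        raise ValueError("relative Gibbs energies must be finite and >= 0")
    # subtract the minimum so the largest exponent is 0 (no overflow)
    w = np.exp(-(dg - dg.min()) / (GAS_CONSTANT_KCAL * temperature))
    return w / w.sum()


@dataclass
class BoltzmannResult:
    """Ensemble shielding summary: Boltzmann average, extremes, weights."""

    sigma_bol: float
    sigma_lowest: float
    sigma_highest: float
    weights: np.ndarray


def _conformer_sigma(conformer: Conformer) -> float:
    """Per-conformer isotropic shielding; symmetry-equivalent P atoms of a
    multi-phosphorus molecule are averaged before Boltzmann weighting."""
    if conformer.sigma_P is None:
        raise ValueError(f"conformer {conformer.conf_id} carries no shielding")
    return float(np.mean(np.atleast_1d(np.asarray(conformer.sigma_P, dtype=float))))


def boltzmann_shielding(ensemble: ConformerEnsemble) -> BoltzmannResult:
    """Boltzmann-averaged, lowest and highest shielding of an ensemble."""
    sigmas = np.array([_conformer_sigma(c) for c in ensemble], dtype=float)
    weights = boltzmann_weights(ensemble.delta_g, ensemble.temperature)
    return BoltzmannResult(
        sigma_bol=float(np.dot(weights, sigmas)),
        sigma_lowest=float(sigmas.min()),
        sigma_highest=float(sigmas.max()),
        weights=weights,
    )


def shielding_to_shift(sigma, scheme: ReferenceScheme):
    """Convert isotropic shielding(s) to referenced chemical shift(s).

    ``physical`` convention: δ = (σ_ref − σ) + δ_ref_exp, so the
    reference compound reproduces its own experimental shift.
    ``as_printed``: δ = σ_ref − σ − δ_ref_exp (opposite sign on the
    experimental correction). Both are strictly decreasing in σ.
    """
    sigma = np.asarray(sigma, dtype=float)
    if scheme.convention == "physical":
        delta = (scheme.sigma_ref - sigma) + scheme.delta_ref_exp
    else:
        delta = scheme.sigma_ref - sigma - scheme.delta_ref_exp
    return float(delta) if delta.ndim == 0 else delta


def predict_molecule(
    record: MoleculeRecord,
    ensemble: ConformerEnsemble,
    scheme: ReferenceScheme,
    condition_label: str = "vac",
) -> ShiftPrediction:
    """Single-point and ensemble shift prediction for one molecule.

    The ensemble must already be energy-window filtered and pruned, with
    shieldings for ``condition_label`` attached to every conformer. The
    single-point shift (stored under ``delta_vac`` for condition "vac",
    under ``delta_solvent[label]`` otherwise) comes from the
    lowest-energy conformer; the Boltzmann / extreme-shielding shifts
    summarize the whole ensemble.
    """
    result = boltzmann_shielding(ensemble)
    single = shielding_to_shift(_conformer_sigma(ensemble.lowest()), scheme)
    pred = ShiftPrediction(
        mol_id=record.mol_id,
        delta_boltzmann=shielding_to_shift(result.sigma_bol, scheme),
        # highest shift comes from the lowest shielding and vice versa
        delta_lowest_shielding=shielding_to_shift(result.sigma_lowest, scheme),
        delta_highest_shielding=shielding_to_shift(result.sigma_highest, scheme),
        n_conformers_used=len(ensemble),
    )
    if condition_label == "vac":
        pred.delta_vac = single
    else:
        pred.delta_solvent[condition_label] = single
    return pred
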