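# Methods

## Problem setting

The package post-processes conformer-resolved isotropic ³¹P shieldings into
experimental-scale chemical shifts and quantifies, on cohort level, how
much conformer averaging and implicit-solvent modelling improve agreement
with measured shifts. It deliberately does not compute shieldings or search
conformers: those arrive from a backend (a CSV of precomputed values, or
the synthetic surrogate) so the statistical pipeline can be exercised and
validated independently of any electronic-structure code.

## Conformer selection

Conformers carry relative Gibbs energies ΔG (kcal/mol) with the minimum
pinned to exactly 0; readers shift raw energies accordingly. Selection has
two stages.

**Energy window.** Conformers with ΔG ≤ 6 kcal/mol (inclusive boundary;
chosen for determinism at the edge) are thermally accessible at 298.15 K.
The ΔG = 0 conformer is always retained, so the filter never empties an
ensemble.

**Greedy RMSD pruning.** Ensembles of at most 20 members pass through
unchanged. Larger ensembles are traversed in ascending (ΔG, conf_id) order
— the id tie-break makes the traversal reproducible — starting from the
lowest-energy conformer, which is always selected. A candidate is accepted
iff its minimum RMSD to every already-selected conformer is strictly
greater than 0.5 Å; traversal stops at 20 selections or when candidates
are exhausted (no threshold relaxation in the latter case). Consequences
asserted in tests: every pair of surviving conformers is separated by
> 0.5 Å, the ΔG = 0 conformer always survives, and the procedure is
idempotent.

RMSD is the all-atom Kabsch superposition RMSD: both geometries are
centered, the optimal rotation comes from the SVD of the 3×3 covariance
matrix, and improper (mirror) rotations are excluded by forcing the
rotation determinant to +1. The residual is computed explicitly from the
rotated coordinates rather than from the singular-value trace identity —
the identity cancels catastrophically near zero RMSD (≈10⁻⁸ Å of spurious
deviation for identical inputs), while the explicit residual is exact
there. No symmetry-equivalent atom permutation is attempted; identical
atom ordering across conformers is a validated precondition. Fewer than
three atoms is an error (the rotation is under-determined).

## Boltzmann averaging and referencing

Populations are w_i ∝ exp(−ΔG_i/RT) with R = 1.987204259×10⁻³
kcal mol⁻¹ K⁻¹ and T the ensemble temperature (default 298.15 K). The
maximum exponent is shifted to zero before exponentiation, so arbitrarily
cold temperatures underflow gracefully to a point mass on the ground
state. σ_bol = Σ w_i σ_i together with the ensemble's extreme shieldings
summarize the ensemble; for molecules with several symmetry-equivalent
phosphorus atoms the per-atom shieldings are averaged per conformer before
weighting.

Referencing uses trimethylphosphine as secondary standard. The default
`physical` convention, δ = (σ_ref − σ) + δ_ref_exp with
δ_ref_exp = −62.0 ppm, maps the reference compound onto its own
experimental shift and is what referencing to 85 % H₃PO₄ requires. An
`as_printed` convention with the opposite sign on the experimental
correction (δ = σ_ref − σ − δ_ref_exp) is kept selectable because that
variant of the equation also circulates; under it PMe₃ maps to +62.0 ppm.
The two conventions differ by exactly 124.0 ppm for any input, and both
are strictly decreasing in σ. σ_ref is a configuration input, not a
constant: it must come from the same backend settings as the molecule
shieldings, so every backend (including the surrogate) supplies its own.

The single-point ("vacuum" or per-solvent) prediction uses the ΔG = 0
conformer's shielding; the ensemble prediction uses σ_bol.

## Error metrics and stratification

All errors are experimental minus calculated, so a negative mean signed
error means overestimated shifts. RMSE and MAE are standard; the relative
MAE divides the MAE by the shift range Δδ covered by the dataset (default
698 ppm, configurable via `--range`). Condition pairs are compared through
the relative RMSE improvement 100·(RMSE_ref − RMSE_alt)/RMSE_ref, computed
on the paired subset of molecules for which both conditions exist. When
both RMSEs are exactly zero the improvement is reported as 0; a perfect
reference beaten by an imperfect alternative has no defined relative
improvement and is dropped with a warning. Reporting rounds half away from
zero to the customary table precisions (metrics 2 decimals, improvements
and relative MAE 1 decimal); internal computation is full precision.

Cohorts: the full dataset; per experimental solvent, with unknown-solvent
records forming their own cohort and otherwise appearing only in "all";
five contiguous quantiles by atom count and by rotatable-bond count
(records sorted by (key, mol_id) — the id as stable tie-break, since many
molecules share an atom count — group sizes differing by at most one,
larger groups first); and phosphorus compound class. Classes are assigned
by SMARTS substructure matching in a fixed priority order (phosphonate →
dialkyl phosphinate → monoalkyl phosphinate → phosphonite → other) with R
groups restricted to carbon; the priority order resolves the rare
multi-match deterministically.

## Synthetic data and the surrogate backend

The generator emulates the statistical structure the evaluation assumes,
not shielding physics. Per molecule, drawn from an independent
counter-based random stream (`SeedSequence(seed, spawn_key=(i,))`) so any
subset is reproducible regardless of iteration order:

- **Scaffold.** Classes cycle deterministically through monoalkyl
  phosphinate, phosphonite, phosphonate, dialkyl phosphinate and "other"
  (phosphines, phosphites, phosphine oxides), with random C₁–C₈ alkyl
  substituents. This guarantees class coverage from five molecules up and
  exercises the classifier; it is not a claim about real dataset
  composition.
- **True shift.** δ_true ~ class mean + N(0, 20 ppm), class means set to
  typical experimental values per class (e.g. phosphonites far downfield
  near 115 ppm).
- **Solvent.** Assigned with probabilities proportional to the cohort
  sizes of a large heterogeneous collection (CHCl₃ ≫ H₂O > DMSO > toluene
  > CH₃CN) and revealed with probability 0.32 — the known-solvent fraction
  of such collections; hidden labels read "unknown".
- **Experimental shift.** δ_exp = δ_true + offset(solvent) +
  offset(class) + N(0, noise_sd) with noise_sd defaulting to 5 ppm;
  offsets default to zero and are the knobs parameter-recovery tests turn.
- **Conformers.** Count ~ Poisson(a·n_atoms^b) with a = 0.0315, b = 2.515
  — fit to per-size-quantile mean counts of ≈24 at 14 atoms and ≈933 at
  60 atoms — clamped to [1, 25]. The default cap of 25 keeps generation
  desk-scale while still exceeding the 20-conformer pruning threshold for
  most molecules, so the pruning path runs routinely; raise
  `max_conformer_count` to study the count law itself. ΔG values follow
  an exponential law (scale 2 kcal/mol) truncated to the 6 kcal/mol
  window, minimum forced to 0. Geometries are a seeded ETKDG embedding of
  the SMILES (cached per SMILES; embed seed derived from a CRC of the
  SMILES so it is stable across runs) plus per-conformer Gaussian jitter
  of 0.4 Å.

The surrogate backend inverts the referencing equation exactly:
σ_i = σ_ref − (δ_true − δ_ref_exp) + g(conformer) + s(condition), with
σ_ref = 300 ppm by default. g is a deterministic perturbation uniform in
[−A, +A] keyed on a SHA-256 hash of the conformer geometry (A = 1 ppm by
default), standing in for the conformation dependence of the shielding;
s equals the negated solvent offset when the condition matches the
molecule's assigned solvent, so modelling the right solvent removes
exactly that solvent's bias. Under the physical scheme the vacuum
single-point prediction error is noise + g(ground-state conformer),
giving the analytic noise floor sqrt(noise_sd² + A²/3) that the
recovery tests check (5.03 ppm at the defaults).

What passing tests on this generator do **not** show: agreement with real
quantum-chemical shieldings, real conformational energetics, or real
dataset composition. They show that the selection, averaging, referencing
and evaluation algebra is correct, that injected systematic effects are
recovered where and only where they were injected, and that the pipeline
is deterministic.

## Pipeline and numerical choices

`run_pipeline` validates its configuration before touching any molecule
(exactly one input source; surrogate backend only with the synthetic
source, since it needs the latent ground truth). Molecules are processed
independently; a failure (missing ensemble, missing shielding) is logged,
counted in the manifest and skipped, and the run aborts only if every
molecule fails. Predictions are written with `%.17g` formatting and read
back with round-trip float parsing, so re-evaluating the written CSV
reproduces the in-run report bit for bit; repeated runs with the same
configuration produce byte-identical outputs (no timestamps are written).
SDF shift tags are serialized at 2 decimal places, the precision of the
tabulated statistics; unknown tags pass through reads untouched.

Problem sizes in the test-suite and acceptance script — 200 random
ensembles for the pruning oracle, n = 1000 for parameter recovery,
n = 2000 for the noise-floor convergence check, 20 seeds for the
ensemble-vs-single-point expectation — were chosen as the smallest sizes
at which the statistical assertions have comfortable margins under the
generator's defaults.

## Known limitations

- Pruning RMSD uses all atoms with fixed ordering; symmetry-equivalent
  permutations (e.g. rotated methyl groups) count as geometric difference.
- The classifier's patterns demand the exact generic-formula connectivity
  with carbon R groups; exotic substitution falls into "other".
- The surrogate's conformer perturbation is independent across conformers,
  which flatters Boltzmann averaging relative to correlated real-world
  conformer shieldings.
- Quantile boundaries depend on the mol_id tie-break; only cohort sizes,
  not exact memberships, are comparable across datasets with many tied
  atom counts.
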