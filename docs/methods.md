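# Methods

## Scope and data flow

`shiftjudge` is the statistics-and-diagnostics half of a computational
NMR structure-verification workflow. Everything upstream — conformational
search, geometry optimization, GIAO shielding computation, solvation —
is external; the package consumes their numeric products: per-conformer
isotropic shieldings (ppm) and relative Gibbs free energies, plus
experimental ¹H/¹³C assignment tables. It deliberately handles no 3D
structure formats and no quantum-chemistry engines.

The pipeline is: energy window → Boltzmann weights → per-nucleus
ensemble averaging → per-element linear scaling → CMAE/RMSD/Pearson →
ranking and diagnostics.

## Ensemble averaging

Weights are `w_n = exp(−E_n/RT)/Σ exp(−E_m/RT)` with
`R = 8.31446 J K⁻¹ mol⁻¹` and `T = 298 K` by default. Energies are
internal J·mol⁻¹; input files declare their unit per row
(1 kcal = 4184 J, 1 hartree = 2 625 499.6 J/mol) so the ambiguity of
"which unit are these energies in" never reaches the math. Because
weights depend only on energy differences, absolute energies are
accepted and re-zeroed to the ensemble minimum.

Numerical choices: the minimum energy is subtracted before
exponentiation (an identity that prevents overflow for any finite
input); degenerate minima share weight exactly with no tie-breaking; the
energy window (default 10 kcal/mol, the span a conformational search
typically covers) is applied to the re-zeroed energies *before*
weighting, and a window of 0 keeps exactly the minimum-energy
conformer(s). The "significant conformers" entering the average are thus
defined as those inside the window; no additional weight cutoff is
applied.

## Scaling and scoring

The regression is σ on δ_exp (`σ = a·δ_exp + b`), inverted to
`δ_calc = (σ − b)/a` — this orientation is what the corrected MAE
definition `|δ_exp − (σ − b)/a|` requires, and it makes every statistic
invariant under affine transforms of the shieldings (the correction is
scale- and offset-free by construction; the test suite asserts this to
1e−10 ppm). Fits are unweighted least squares, always per element: ¹H
and ¹³C ranges differ by an order of magnitude and a joint fit would be
meaningless. A positive fitted slope is physically suspect (shielding
falls as shift rises) and raises a warning, not an error.

Two fit scopes are first-class: `per_candidate` (each structural
hypothesis judged under its own best linear map — also the choice for
rival candidates of one compound, so each is given its best case) and
`pooled` (one fit per element across a compound series; the natural
scope for series-wide summary statistics). Pooled "overall" statistics
pool compounds, never elements. The pooled report carries no per-nucleus
residual map because locant labels repeat across compounds; the
per-candidate reports computed under the pooled fit carry them.

Equivalence groups (e.g. N-CH₃ protons) are scored once per group: the
single observed shift against the arithmetic mean of the members'
Boltzmann-averaged shieldings — the conventional treatment of
rotationally averaged nuclei. Missing (unassigned) experimental entries
are excluded from fitting and scoring but retained for prediction.
Elements with fewer than two matched nuclei produce a null report
(statistics `None`, note `"insufficient data"`) rather than an error, so
batch runs over many compounds complete.

## Ranking, outliers, swaps, predictions

**Ranking.** The combined score is `Σ_e CMAE_e / range_e` over elements
with a valid report, where `range_e` is the spread of that element's
assigned experimental shifts. Normalizing by the range expresses each
element's error as a fraction of its own scale (a 1.5 ppm carbon error
and a 0.15 ppm proton error are comparable burdens), so neither nucleus
dominates. Ties break by RMSD sum, then lexically by candidate id.

**Outliers.** `z = residual / RMSD` of the candidate's own report;
`|z| > k` flags the nucleus (default k = 2, configurable — "significant
outlier" has no universal definition). A report with RMSD exactly 0
yields no flags.

**Swap suggestions.** Assignment errors in practice are pairwise
exchanges, so the search space is transpositions: every same-element
pair of assigned values is trial-swapped, the scaling refit, and the
CMAE recomputed — O(n²) trials and exact at that scope. Swaps improving
CMAE by more than `min_improvement` (defaults 0.02 ppm ¹H / 0.10 ppm
¹³C, chosen at the noise floor of each element's typical CMAE to
suppress noise-level churn) are reported best first; a greedy
non-overlapping subset is marked `accepted`. Deltas are evaluated
against the unswapped baseline rather than recomputed after each
acceptance — exact for disjoint transpositions, and validated against a
brute-force search over all ≤2-transposition compositions in the tests.
Trial fits on scrambled assignments may be degenerate; their
positive-slope warnings are suppressed inside the search.

**Missing-shift prediction.** Each unassigned nucleus with a computed
shielding gets `δ = (σ − b)/a` from the fit over the assigned nuclei of
the same element. With Gaussian noise of sd s the predictions are
unbiased with MAE ≈ s·√(2/π); the tests assert MAE ≤ 2s.

## Synthetic study conditions

The generator emulates what the pipeline assumes about real data, with
defaults fixed once as the study conditions:

| parameter | default | rationale |
|---|---|---|
| nuclei per compound | 14 ¹H, 20 ¹³C | 13 compounds give ≈182 ¹H / 260 ¹³C, the pool size of a full alkaloid-series study |
| true slopes / intercepts | a = −1.05; b = 31 (¹H), 185 (¹³C) ppm | typical GIAO-DFT correlation parameters |
| shift ranges | 2.5–9.5 ppm ¹H, 20–170 ppm ¹³C | aromatic-alkaloid spectral windows |
| conformer energies | Exp(2.5 kcal/mol) truncated at 10 | low-energy-dominated ensemble inside the search window (inverse-CDF sampling, min re-zeroed) |
| conformer σ spread | 0.3 ppm | per-conformer, per-nucleus shielding variation |
| per-nucleus noise | 0.15 ppm ¹H, 2.0 ppm ¹³C | reproduces residual scatter at the ~0.2 / ~2 ppm RMSD level typical of scaled DFT shifts |
| n_conformers | 5 | "several" low-energy conformers |

Noise is specified on the chemical-shift scale (the scale residuals are
quoted in) and enters the shielding through |a|; it is per nucleus and
shared across conformers (method error), while the conformer spread is
drawn per conformer. Decoys displace k randomly chosen nuclei by
±magnitude·|a| in every conformer — a localized, structure-like error,
not broadband noise. All randomness flows through one seeded NumPy
PCG64 generator; identical seeds give bit-identical datasets.

What the generator does **not** emulate: heavy-tailed or correlated
residuals (e.g. electron-correlation pathologies of N-oxide-type
moieties), ring-current or solvent-specific effects, exchange-broadened
or overlapping resonances, and label ambiguity. Passing tests therefore
demonstrate the statistical machinery — calibration, discrimination
power, recovery — under the stated noise model, not the accuracy of any
quantum-chemistry protocol on real molecules.

## Problem sizes in the tests and acceptance script

Property checks use the sizes their statements name (noise calibration
at n = 10⁴; 1000 random residual sets; prediction-bias check at
n = 10³). The Monte-Carlo discrimination protocols (decoy ranking,
swap recovery, outlier detection) use 100 seeds each at 20 carbons per
compound, and the acceptance script's series statistics use the
13-compound defaults above — sizes at which the whole suite and the
script each complete in well under a minute on one CPU.

## Known limitations

- The scaling is strictly linear; systematic curvature (heavy-atom or
  anisotropy effects) is absorbed into the residuals.
- Swap search is limited to transpositions, greedily composed; a full
  assignment optimization (Hungarian-style) is out of scope since
  documented real reassignments are pairwise.
- No probabilistic structure scores (DP4/CP3-style posteriors) and no
  bootstrap confidence intervals on CMAE — the descriptors are the
  classical CMAE/RMSD/r triple.
- Matching between computed and experimental nuclei is exact
  case-insensitive label equality; no fuzzy locant reconciliation.
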