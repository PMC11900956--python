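# shiftjudge

Verification and ranking of candidate molecular structures against
experimental NMR chemical shifts, using Boltzmann-averaged, empirically
scaled isotropic shieldings.

## The problem

When a natural product is isolated, its structure is usually assigned from
1D/2D NMR data — and sometimes assigned wrongly, with the error surfacing
only years later. Quantum chemistry offers an independent check: compute
isotropic shielding constants σ for each plausible structure, convert them
to chemical shifts, and ask which structural hypothesis agrees best with
the observed spectrum. `shiftjudge` implements the statistical half of
that workflow. It consumes the numeric output of external
conformer-search/DFT runs (per-conformer shieldings and relative Gibbs
free energies) together with experimental ¹H/¹³C assignment tables, and it
answers: *how well does each candidate fit, which candidate wins, which
resonances are suspicious, which assignments were probably swapped, and
what values should the unassigned shifts have?*

## The model

1. **Boltzmann averaging.** Within a relative-Gibbs-energy window
   (default 0–10 kcal/mol), conformer populations are
   `w_n = exp(−E_n/RT) / Σ_m exp(−E_m/RT)` with `R = 8.31446 J K⁻¹ mol⁻¹`,
   `T = 298 K`, and the ensemble shielding of nucleus *i* is
   `σ_i = Σ_n w_n σ_{n,i}`.
2. **Empirical scaling.** Systematic method error is removed by ordinary
   least squares of σ on the experimental shift, `σ = a·δ_exp + b`
   (per element — ¹H and ¹³C are never pooled; slope `a` ≈ −1), and
   inversion `δ_calc = (σ − b)/a`. The fit scope is either per candidate
   or pooled across a whole compound series.
3. **Scoring.** Corrected mean absolute error
   `CMAE = (1/n) Σ |δ_exp − (σ_i − b)/a|`, root-mean-square deviation
   `RMSD = sqrt((1/n) Σ (δ_exp − δ_calc)²)`, and the Pearson r between
   δ_exp and δ_calc.
4. **Discrimination & diagnostics.** Rival candidates are ranked by the
   element-balanced score `CMAE_H/range_H + CMAE_C/range_C`; nuclei with
   `|residual| > k·RMSD` (default k = 2) are flagged as outliers;
   all pairwise swaps of same-element experimental assignments are
   trial-evaluated (with refitting) and CMAE-lowering swaps suggested;
   and shifts of unassigned nuclei are predicted through the fitted line.

A synthetic-data generator with known ground truth (true linear law,
conformer ensembles, per-nucleus noise, decoy perturbations, masking,
injected swaps) makes every stage testable without any quantum-chemistry
run.

## Worked example

Generate a 20-carbon/14-proton compound at the default study conditions,
build a decoy in which three carbons are displaced by ±8 ppm (the
signature of a locally wrong structural hypothesis), and rank the rivals:

```python
from shiftjudge import (PipelineConfig, generate_dataset, make_decoy,
                        rank_candidates, flag_outliers)
from shiftjudge.synthetic import SyntheticSpec

spec = SyntheticSpec(noise_sd_C=1.5, seed=11)
candidate, table, truth = generate_dataset(spec)
decoy = make_decoy(candidate, truth, k_nuclei=3, magnitude=8.0, seed=12)
config = PipelineConfig()
ranking = rank_candidates([decoy, candidate], table, config)
for entry in ranking.ranked:
    c, h = entry.reports["C"], entry.reports["H"]
    print(f"{entry.candidate_id:10s} combined={entry.combined_score:.4f} "
          f"CMAE(13C)={c.cmae:.2f} ppm  CMAE(1H)={h.cmae:.3f} ppm")
```

prints

```
syn        combined=0.0370 CMAE(13C)=1.11 ppm  CMAE(1H)=0.185 ppm
syn_decoy  combined=0.0475 CMAE(13C)=2.53 ppm  CMAE(1H)=0.185 ppm
```

The true structure wins: its ¹³C CMAE (1.11 ppm, at the noise level) is
less than half the decoy's (2.53 ppm), while ¹H — untouched by the decoy
— is identical. Outlier flagging on the decoy's carbon report
(`flag_outliers(ranking.ranked[-1].reports["C"], config.outlier_k)`)
flags `C-9` (z = −2.8) and `C-13` (z = −2.3) — two of the three
perturbed carbons — exactly the "localized large residuals" that should
prompt a second look at a proposed structure.

The same pipeline is scriptable from the shell:

```bash
shiftjudge simulate --out-dir demo --seed 11
shiftjudge score --shieldings demo/shieldings.tsv --energies demo/energies.tsv \
                 --experimental demo/experimental.tsv --mapping demo/mapping.tsv
# candidate_id=syn  element=H  n=14  cmae=0.18  rmsd=0.23  pearson_r=0.994
# candidate_id=syn  element=C  n=20  cmae=1.5   rmsd=1.8   pearson_r=0.9991
```

`shiftjudge rank|suggest|predict` expose ranking, swap/outlier
diagnostics and missing-shift prediction on the same interchange files;
`--fit-scope pooled` switches to one scaling fit per element across the
whole series.

## Interchange formats

Plain TSV/CSV with declared headers (see `shiftjudge.io`): per-conformer
shieldings, per-conformer energies with an explicit unit column
(kJ/mol, kcal/mol, hartree, J/mol — converted to J·mol⁻¹ and re-zeroed
per candidate), experimental tables with empty cells for unassigned
shifts and an optional equivalence-group column, and a
candidate→compound mapping. `shiftjudge.io.parse_qc_log` extracts
¹H/¹³C isotropic shieldings directly from quantum-chemistry output text.
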