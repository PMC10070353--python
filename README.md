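# psmkit

Reusable building blocks for interpreting multiplexed (TMT) proteomics and
HLA immunopeptidomics data at the peptide-spectrum-match (PSM) level: the
data-interpretation layer that sits between a database search engine's PSM
export and biological analysis.

The package is for computational proteomics researchers who need the
filtering and quantitation machinery of a search-engine pipeline as a
tested, scriptable Python library:

- **Target-decoy FDR autovalidation** — per-run/per-charge optimization of
  `(score, delta-rank-score)` thresholds to maximize accepted PSMs subject
  to FDR budgets (0.8% per run for precursor charges 2–4, 0.4% per plex
  for charges 5–6, 1% pooled for immunopeptidomes). The FDR estimate is
  the concatenated target-decoy ratio `FDR = D/T`; during optimization a
  next-decoy correction `(D + k)/T ≤ α` (default `k = 2`, one per
  threshold dimension) keeps the *realized* false-discovery proportion
  calibrated to the budget.
- **Subset-specific FDR** for rarely observed peptide classes (novel ORF
  categories, sequence variants): fixed record-level thresholds followed
  by a BCS × score grid search that tightens each class below a 1%
  class-conditional FDR.
- **PTM site tables** — localization confidence (score gap > 1.1), merging
  of non-conflicting site observations across charge states and plexes,
  representative selection, cross-plex site polishing (score ≥ 8 or both
  plexes), and the C-terminal modified-lysine `[^K][^K]k` artifact rule.
- **Protein grouping** — group closure over shared peptides (> 8
  residues), subgroup expansion with "top uses shared" allocation, protein
  scores as sums of distinct-peptide scores, and the two protein-polishing
  passes (within-plex all-false-score threshold; cross-plex score ≥ 25 or
  both plexes).
- **TMT quantitation** — reporter isotope-impurity correction by Cramer's
  rule from certificate-of-analysis factors, PSM quant filters (TMT label,
  precursor purity ≥ 50%, non-negative delta forward-reverse score), log2
  ratios (per-PSM-median or reference-channel denominator), median
  aggregation to proteins/sites, median/MAD channel normalization,
  reporting filters, and variant-peptide patient-consistency checks.
- **HLA immunopeptidome filtering** — spectral quality, class-specific
  charge/length/BCS thresholds, pooled FDR, contaminant removal,
  modified-peptide quality, 8–11mer restriction — with a stage-attributed
  audit log — plus length distributions, binding-motif position-frequency
  matrices, and HLA-II nested-set grouping.
- **Synthetic data** — seeded generators for PSM tables, reporter-level
  quant data and HLA peptide sets with known ground truth, so every stage
  can be validated against labels no real export provides.

## Worked example

`examples/01_fdr_autovalidation.py` generates 20,000 synthetic PSMs with
known correct/incorrect labels and runs autovalidation at the default
budgets:

```
input PSMs:    20000
accepted PSMs: 16283  (targets and decoys)

scope                        min_score  min_delta  est.FDR%  n_target
run=run0/charge=2                7.64      0.04    0.672      2083
run=run1/charge=2                7.32      0.28    0.659      1974
run=run2/charge=2                8.11      0.02    0.682      2053
...

pooled FDR estimate:  0.550%
realized FDP (truth): 0.692%
```

Each scope (one LC-MS/MS run × one charge state) gets its own thresholds;
the decoy-based estimate and the truth-label false-discovery proportion
both sit below the 0.8% budget. The remaining examples walk through
subset FDR, site tables, protein grouping, the quantitation stack and the
immunopeptidome chain the same way — each prints the numbers it computes
and a line on what they mean.

## File formats

PSM tables are tab-delimited with a documented header (see
`psmkit.io.PSM_COLUMNS`); unknown columns pass through untouched. Protein
sequences are FASTA; contaminant lists are plain text, one peptide per
line; quant matrices are written as GCT 1.3 with ratio-count row metadata.
Modified lysines are rendered lowercase `k`; all coordinates are 1-based.

## Layout

```
src/psmkit/      types, io, mapping, profiles, fdr, sites, grouping,
                 quant, hla, simulate
examples/        one narrative script per capability
tests/           unit + property + end-to-end acceptance tests
docs/methods.md  models, parameters, numerical choices, limitations
```
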