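# Methods

This note documents the statistical procedures psmkit implements, the
parameters that matter, the numerical and design choices made where the
conventions of search-engine pipelines are underspecified, and what the
synthetic-data validation does and does not demonstrate.

## Target-decoy FDR estimation and autovalidation

**Model.** Every PSM is either a correct or an incorrect assignment.
Decoy PSMs (from a reversed/shuffled database search) are assumed
exchangeable with incorrect target PSMs: at any score threshold the
expected number of accepted decoys equals the expected number of accepted
incorrect targets. The FDR estimate for an accepted set is the plain
concatenated ratio `FDR = n_decoy / n_target`, implemented in one
function (`estimate_fdr`) so alternative conventions such as `(D+1)/T` or
`2D/(T+D)` are one-line swaps. Degenerate inputs: an empty set is an
error; no decoys gives 0; decoys without targets is undefined (error).

**Autovalidation.** Within each scope — one LC-MS/MS run per precursor
charge state for charges 2–4 (budget 0.8%), one TMT plex for pooled
charges 5–6 (budget 0.4%, reflecting their sparser statistics), or one
pooled immunopeptidome across fractions (budget 1%) — the optimizer
searches every pair of observed `(score, delta_rank_score)` values and
returns the pair maximizing accepted targets subject to the budget.
Ties are broken by fewer accepted decoys, then lower score threshold,
then lower delta threshold; the result is therefore a deterministic
function of the input set, invariant to row order. Scopes with no
targets, or where no pair meets the budget, accept nothing and are
flagged — never silently relaxed.

**Selection-bias correction.** Maximizing acceptance under `D/T ≤ α`
stops just short of the next decoy event along each threshold axis, so
the decoy count at the selected pair systematically underestimates the
incorrect-match rate there; measured on synthetic data the realized
false-discovery proportion then overshoots the budget by roughly one
decoy event per threshold axis per scope (≈ 0.1–0.2 percentage points at
these scope sizes). The optimizer therefore tests candidates with a
next-decoy-corrected count `(D + k)/T ≤ α`, `k = 2` by default — the
two-dimensional analogue of the classical "+1 decoy" convention, one
event per optimized threshold dimension. Reported estimates remain plain
`D/T`; `decoy_correction=0` restores the uncorrected rule. A side effect
is a minimum useful scope depth of `k/α` targets (250 at 0.8%): scopes
shallower than that cannot demonstrate the budget and accept nothing.

**Subset-specific FDR.** Rarely observed classes (novel-ORF categories,
variant peptides) are noisier than the aggregate, so dataset-wide control
leaves them above 1%. Each class first passes fixed record-level
thresholds — score ≥ 7, scored peak intensity ≥ 50%, |mass error| < 5 ppm
(strict, the one strict bound among the record filters), plus per-'ome
BCS and length windows (HLA: BCS ≥ 5, lengths 8–12 class I / 9–50
class II; PTM: BCS ≥ 4, lengths 7–50) — then a BCS × score grid search
returns the pair of grid values maximizing retained targets subject to a
strict class-conditional `D/T < 1%`, ties broken by smaller BCS then
smaller score ("the lowest values that improve FDR", made a total order).
The grid search keeps the uncorrected estimator: subset classes are often
only a few hundred PSMs, where a `+k` rule would be categorically
infeasible, and the strict `<` bound is already the conservative reading.
Default grids start at the profile's fixed minima (11 BCS steps of 1,
17 score steps of 0.5); both are configurable since no standard endpoints
exist.

## PTM site localization and the VM site table

A site's localization score is the identification-score gap between the
two best placements; a gap strictly greater than 1.1 marks the site
confidently localized. A single-candidate placement is confident by
convention (there is no competitor). The upstream neutral-loss ion-type
score constant (0.5 for b/y − H3PO4 and b/y − H2O) is recorded as
provenance metadata only; spectra are never rescored here.

Observations merge into one site row when they agree on protein, mod
type and modification count, and their position sets are compatible:
identical confident positions, or an ambiguous candidate set containing a
confident set. An ambiguous observation's candidate set is defined as all
acceptor residues (S/T/Y for phospho, K for acetyl/diGly) covered by its
peptide — the most permissive set consistent with the peptide. Two
ambiguous observations merge only when their candidate sets are equal;
when an ambiguous set contains several confident rows it joins the
highest-scoring one (positions break ties). Representative selection is
lexicographic — confident first, then higher score, longer peptide,
smaller spectrum id — hence order-invariant. The build is a pure
function of its input and idempotent under rebuild.

Cross-plex polishing keeps a site iff best score ≥ 8.0 (inclusive) or it
was seen in ≥ 2 plexes. The C-terminal rule removes peptides whose last
three residues match `[^K][^K]k` (modified lysine rendered lowercase):
trypsin/Lys-C cannot cleave after a modified lysine, so such peptides
are artifacts unless an unmodified K in the two preceding positions
allows a missed-cleavage explanation; peptides shorter than three
residues are kept.

## Protein grouping and polishing

Proteins sharing a peptide longer than 8 residues join one group
(connected components); shorter peptides count as evidence but never
create edges. Within a group, proteins with identical peptide-evidence
sets coalesce, and a protein whose evidence is a strict subset of
another's folds into the largest such superset (accession order breaks
ties) — so subgroups are exactly the units with uniquely representing
peptides. A distinct peptide is the single best-scoring instance of a
sequence (ties to the smaller spectrum id); subgroup base scores sum
unique-peptide scores; each shared peptide is then allocated once, to
the highest-base-score subgroup containing it, with the ranking computed
once (no iterative re-allocation — "top uses shared" is a single pass).
"Unexpand" mode reports the whole group once, labeled by its top
subgroup, with every distinct peptide counted once — the reporting mode
used for PTM site tables.

Within-plex polishing removes a PSM iff it contributed to any subgroup
scoring strictly below the maximum score among subgroups consisting
entirely of presumed-false peptides (best PSM has negative delta
forward-reverse score); a subgroup exactly at the threshold survives,
and with no all-false subgroup nothing is removed. Removal is evaluated
per contribution, so a peptide spanning two groups via short evidence is
removed if either of its groups fails. Cross-plex polishing keeps
subgroups with score ≥ 25 (inclusive) or presence in ≥ 2 plexes.

## TMT quantitation

The impurity matrix is built from certificate-of-analysis −2/−1/+1/+2
percentages: column *j* carries `1 − Σimpurities/100` on the diagonal
and the stated fractions at the neighboring channels in reagent-series
order; spill beyond the plex is lost mass, so those columns sum to < 1.
Validity requires non-negative entries, column sums ≤ 1, diagonal
dominance per column, and non-singularity. Correction solves
`M·x = observed` by Cramer's rule (ratios of determinants via
`numpy.linalg.det`), refusing matrices with condition number above 1e8;
negative components — possible with noisy data — are clamped to zero and
flagged, since intensities are physical quantities.

PSMs enter quantitation only when TMT-labeled, with precursor isolation
purity ≥ 50% and non-negative delta forward-reverse score. Log2 ratios
use a configurable denominator: the per-PSM median of positive channel
intensities (default, for designs without a common reference) or a
designated reference channel. Zero intensities yield missing values,
never −∞; an all-zero vector is flagged. Feature-level values are
per-channel medians over contributing PSM ratios, with ratio counts
recorded; the protein reporting filter requires ≥ 2 fully quantified
unique peptides with ratio count ≥ 2 and protein-level ratio counts ≥ 2.

Median/MAD normalization shifts each channel to zero median and scales
channels so every MAD equals the pre-normalization median of per-channel
MADs. MAD is the raw median absolute deviation — no 1.4826 Gaussian
consistency factor, since only relative channel scaling matters. The
operation is idempotent; channels with fewer than 3 values or zero MAD
are centered only and flagged. Variant (SAAV) consistency keeps a
feature iff its robust z-score (row median/MAD) is ≥ 2 for every carrier
channel and < 2 for every non-carrier; a carrier with missing
quantitation fails, missing non-carriers are ignored.

Two estimator properties worth knowing, both measured on synthetic data:
the per-PSM-median denominator compresses fold changes by a few percent
when half the channels of a feature are regulated (the denominator mixes
the two groups), and MAD equalization shrinks channels whose spread is
inflated by one-sided regulation. Neither is an implementation artifact;
they are costs of those conventions. The package's fold-change recovery
validation therefore uses the setting in which the stack is actually
unbiased — a pooled-reference design (reference channel at baseline,
reference-channel ratio policy) with the symmetric ±FC/2 two-group
profile that keeps per-channel spreads equal — and with co-isolation
contamination disabled, since contamination destroys ratio information
by construction (its effect is validated separately as monotone ratio
compression toward zero). Null features are always simulated alongside
signal features so channel normalization is anchored by an unregulated
background, as in real cohorts.

## HLA immunopeptidome chain

Stage order is fixed: spectral quality (sequence tag length > 1,
precursor MH+ 600–4000 for immunopeptidomes; tag > 0, 800–6000 for
tryptic 'omes; records with unknown tag length pass), class PSM filters
(length ≥ 7, BCS ≥ 5, charges 1–4 class I / 2–6 class II), pooled 1%
FDR, contaminant removal (exact sequence match against blank-bead and
tryptic lists, plus species-annotation removal of non-human entries),
modified-peptide quality (score > 6 and SPI > 60%, both strict;
unmodified peptides unaffected), and for class I a final 8–11mer
restriction. Each removal is attributed to exactly one stage in the
audit, so stage counts sum to input minus output, and the chain is
idempotent. The sequence tag length travels as an optional PSM field
(`tag_length`); it is the one record attribute beyond the core schema the
spectral filter needs.

Summaries: length histograms; position-frequency matrices (20 × L,
column-normalized, single length enforced); PTM position distributions;
and HLA-II nested sets as connected components where peptides link by
substring containment or a shared core of ≥ 9 residues (the typical
class-II binding-core length; configurable, since "nested set" has no
universal formal definition). Core sharing is detected by exact k-mer
intersection, which is equivalent to sharing a common substring of the
core length.

## Synthetic data: what it emulates, and what it does not

The generators reproduce the statistical structure the filters assume:
correct-match scores from a shifted normal (location 13, scale 2.2),
incorrect matches and decoys from one shared Gumbel (location 4.5, scale
1.3) — standard search-score phenomenology; scores reported at 2
decimals like real engine exports; BCS/SPI/mass error/tag length
correlated with correctness; class-dependent correct priors (canonical
0.92; novel-ORF classes 0.60–0.65; variants 0.80) creating the
subset-FDR problem; "matched" decoy generation splitting incorrect
matches 50/50 target/decoy so decoy counts mirror incorrect-target
counts (an explicit decoy fraction is also available); localization gaps
below/above 1.1 at a configurable ambiguity rate; reporter intensities
as true abundances through a plausible CoA impurity matrix with
lognormal noise (σ in log2 units) and co-isolation contamination
proportional to 1 − purity (purity ~ 100·Beta(6, 1.5)); class-I lengths
with mode 9 and anchor residues at P2/PΩ; class-II nested sets grown
from seeded 9-mer cores with ragged flanks.

What passing these validations shows: the procedures are implemented
exactly (oracle equivalence, brute-force agreement, exact round trips)
and behave as advertised when their assumptions hold (calibration,
recovery). What they do not show: robustness to real-data violations of
those assumptions — score distributions that drift across runs,
decoy/incorrect inexchangeability, correlated co-isolation, shared-
peptide ambiguity from homologous protein families at database scale, or
contaminant lists' actual content. Sequence content is random except
where filters read sequences (tryptic termini, lysine rendering, nested
cores), so motif realism is limited to what is seeded.

## Problem sizes and tolerances used in validation

Calibration uses 20 seeded datasets of 20,000 PSMs (4 runs, 2 plexes)
per configuration, with the bound target + 3·binomial SE per charge
bucket. Oracle checks use 10 instances of up to 5,000 PSMs on empirical
grids of ≤ 50 × 50 values, and 200 random grouping instances of ≤ 10
proteins × ≤ 30 peptides. Round trips assert < 1e−10 relative error
(noiseless impurity inversion) and 1e−9 agreement between Cramer and LU
solutions on 10×10 and 16×16 systems; normalization post-conditions are
checked to 1e−12. Fold-change recovery uses 200 signal features (|log2
FC| = 1, σ = 0.3, 50 PSMs/feature) among 300 nulls, requiring |bias| <
0.05 and RMSE < 0.15. These sizes keep the full validation suite around
a minute on one CPU while leaving the binomial bounds meaningful.

## Known limitations

- FDR control is at the PSM level plus the described site/protein
  polishing passes; there is no peptide-level q-value machinery or
  mixture-model posterior error probability.
- The "automatic variable range precursor mass filtering" of upstream
  engines is reduced to the configurable MH+ range filter; the automatic
  variant is unspecified upstream behavior.
- Site rows are keyed to one protein accession (the lexicographically
  smallest mappable candidate); cross-protein site reporting is the
  grouping module's unexpand mode, not the site table's concern.
- The pipeline starts at PSM tables: no spectra, no mzML, no retention
  time, no binding prediction.
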