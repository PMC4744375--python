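# Methods

This note documents the statistical procedures, the pinned file dialects,
the synthetic-cohort generative model, and the numerical and design choices
behind `oncoprofiler`.

## Inputs and identity

All four data types are joined on the HUGO gene symbol; numeric gene ids
travel along as metadata only. Samples are identified by TCGA barcodes.
After parsing, a sample's key is the participant id plus the two-digit
sample-type code (`TCGA-XX-YYYY-01`), so replicate aliquots of one sample
collapse onto a single key everywhere. Sample types 01–09 are tumors,
10–19 normals; the parser accepts codes 01–29 and rejects everything else.

Because Firehose files drift between snapshots, one concrete dialect per
data type is pinned (MAF-style TSV with `Hugo_Symbol` /
`Variant_Classification` / `Tumor_Sample_Barcode`; GISTIC
`all_thresholded.by_genes` with three leading annotation columns; RSEM
matrices with `SYMBOL|NUMID` gene ids and an optional second header line of
measure names; 450k tables in a probe-level long dialect or a gene/region
wide dialect, detected by the presence of a `Probe` column). Exact
round-trip tests against the simulator need this frozen grammar.

Missing cells are rejected in expression and copy-number inputs — those
matrices have no legitimate holes — but allowed in methylation, where
masked probes are routine; missing betas propagate as missing and are never
imputed or zero-filled.

## Mutation profiles

The frequency denominator is the full assayed cohort, not the mutated
subset. MAFs list only mutated samples, so by default the cohort is every
distinct tumor barcode in the entity's MAF; when a sample manifest exists
it should be passed as an explicit roster (`--roster`), which is the only
way a truly unmutated sample can enter the denominator. All variant
classes, including Silent, qualify by default (`--exclude-classes`
restricts them). Frame-shift insertions and deletions stay separate in
tables even where a figure groups them.

## Relative expression

The reference for each (gene, tumor sample) is strictly the remaining
tumor samples of the same entity (leave-one-out); normals are excluded
from both sides. The z-score uses the n−1-denominator sd; a zero-spread
reference yields a degenerate flag rather than ±∞, and degenerate records
are excluded from calls (RSEM rows can be all-zero). Fold-change
thresholding is symmetric on the ratio scale: over at ≥ t, under at ≤ 1/t.
Scores are computed on the RSEM normalized scale by default; `--log2`
applies log2(x+1) first. Quartiles in the box-plot summaries use linear
interpolation and whiskers reach the most extreme points within 1.5 IQR,
so summaries are bit-reproducible.

The vectorized leave-one-out z-score uses a running-sum identity after
centering each gene row. That form cancels catastrophically when the
reference spread is tiny relative to the row scale, so rows whose
reference variance falls below 1e−6 of the mean centered square are
recomputed directly from the uncentered values, and a spread below 1e−24
of the reference's mean square — beneath float rounding — is treated as
exactly zero. A property test checks the fast path against physically
deleting the focal column.

## Differential methylation

Probe-level betas are aggregated to (gene, region) by the mean over
probes, ignoring missing values; composite region annotations
(`Body;3'UTR`) contribute the probe to each named region. The region
vocabulary is the six Illumina gene-group tokens (TSS1500, TSS200, 5'UTR,
1stExon, Body, 3'UTR).

Pairing matches tumor and normal samples of one participant; with multiple
aliquots the lexicographically smallest sample key wins, making the
pairing deterministic. Paired mode tests the per-pair beta differences
with the Wilcoxon signed-rank test (zero differences dropped; all-zero
rows are degenerate with p = 1; fewer than 5 informative pairs flags the
row underpowered). Unpaired mode contrasts all tumors against all normals
of the entity with the rank-sum test — the only contrast consistent with
"compared to normal controls".

Exact null distributions are used where cheap and valid: paired when
n ≤ 25 informative differences without ties in |d|, unpaired when
m + n ≤ 20 without ties; otherwise the normal approximation with
continuity and tie corrections. The wrappers delegate to
`scipy.stats.wilcoxon` / `mannwhitneyu`; the test suite verifies the exact
branches against independent sign-flip and assignment enumeration, and the
Benjamini–Hochberg adjustment (statsmodels `fdr_bh` behind `bh_adjust`)
against a hand-coded step-up oracle.

The BH family is every (gene, region) test of one invocation (one entity,
one mode). Rows with insufficient data are reported with missing p and
excluded from the family. This per-invocation family is reproducible and
conservative relative to per-gene adjustment; where the family convention
matters, restrict the invocation's gene list. Direction (hyper/hypo) comes
solely from the sign of delta-beta — p-values carry no direction — and the
per-pair difference histograms use bin width 0.05 on [−1, 1].

## Copy number

Only tumor samples are tallied (GISTIC matrices occasionally carry
normals). The subset semantics are "sample counted if its category is in
the subset"; category 0 is never an alteration and is rejected in subsets.
No re-thresholding of continuous segment means is attempted — inputs must
already be GISTIC2.0 thresholded output.

## Synthetic cohorts

The simulator emulates a Firehose per-entity download with one coherent
barcode roster across all four files plus a truth sidecar. Per gene:

* mutations are Bernoulli per tumor sample at the planted rate, with the
  variant class drawn from the planted weight table; the MAF lists only
  mutated samples, mirroring the real-world denominator ambiguity (the
  roster file carries the full cohort);
* copy-number categories are drawn from the planted 5-simplex; normal
  samples sit at category 0;
* expression is log-normal — exp(μ + σz) — matching RSEM's non-negative,
  right-skewed values; outliers are additive offsets on the z (log) scale,
  which is why recovery tests score with `--log2`;
* methylation probe betas are Beta-distributed with the planted mean
  (tumor mean = baseline + delta, clipped into the open unit interval;
  clip events are recorded in the sidecar so recovery tests can account
  for attenuation) and a common concentration (default 50, i.e. per-probe
  sd ≈ 0.06 at β = 0.3).

One RNG stream per data type is derived from the master seed, so adding a
data type never perturbs the others; identical spec and seed give
byte-identical files (floats are written as their shortest round-tripping
decimal). Defaults: 50% of participants have a matched normal, 2 probes
per gene region, no missing betas.

What the simulator does **not** emulate: mutational signatures and
hotspot structure, segment geometry behind the GISTIC categories,
gene–gene correlation, Infinium I/II probe chemistry, batch effects.
Passing recovery tests therefore demonstrates the estimators' correctness
under the stated sampling models, not robustness to those real-data
complications.

## Problem sizes and runtime choices

The bundled checks use sizes chosen to exercise every code path while
staying desk-scale: oracle equivalence on 1,000 random p-vectors and full
enumeration up to n = 8 (paired) and 5×5 (unpaired); recovery on cohorts
of 120–600 participants; methylation power at 200 replicates of 30 pairs;
round-trip integrity over 50 random specs; and a runtime budget of 30 s
per analysis subcommand on a 1,000-gene × 500-participant entity, the
batch analogue of an interactive tool's responsiveness. Detail panels
(pies, per-gene bars, histograms) render for at most `--max-detail-genes`
genes (default 12) — hundreds of per-gene panels are unreadable — while
global grids and all tables always cover every requested gene.

## Known limitations

* The readers accept exactly the pinned dialects; snapshot variants with
  renamed columns need upstream renaming.
* Expression fold change with `--log2` is a ratio of log-scale values;
  the two switches are composable but the combination is rarely what one
  wants.
* Unpaired methylation requires the entity to have normals; there is no
  pan-cancer normal pool.
* p-values from the approximate Wilcoxon branch are continuous
  approximations to a discrete null; at very small n the exact branch
  applies automatically.
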