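# Methods

## Graph model and SEPEP identification

Identified peptides, proteins and genes are the three vertex layers of
an undirected tripartite graph. Peptide→protein edges are established by
*exhaustive re-mapping*: every evidence peptide is matched as a
contiguous substring against every sequence in the (decoy-augmented)
database, regardless of any mapped-protein annotation delivered by the
upstream search tool, because parsimony-oriented tools may under-report
mappings and structural equivalence is only correct when neighborhoods
are complete. Matching uses a seed-and-verify index: each 4-mer maps to
the accessions containing it; a query fetches the candidates for its
first 4-mer and verifies containment (queries shorter than the seed
fall back to a full scan). An optional mode collapses I and L, which
are isobaric and indistinguishable by standard MS/MS, on both sides.
Protein→gene edges come from an explicit accession→gene table, so any
annotation source works.

Peptides with identical protein neighborhoods form one SEPEP; the
SEPEPs partition the mapped peptide set by construction. Peptides with
zero database hits (e.g., evidence searched against a different
database release) are dropped, counted and logged, not raised.

## Target–decoy FDR at the SEPEP level

Decoys are whole-sequence reversals with accession and gene prefixed by
`rev_` (configurable). A SEPEP is a decoy hit iff every protein in its
neighborhood is a decoy; mixed neighborhoods are targets (logged), and
their class and name are derived from the target members only. The
ranking statistic is the maximum member-peptide identification score —
a best-evidence rollup; sum-of-scores or member count would also be
monotone and the choice only matters near the threshold. At rank r,
FDR(r) = #decoys / max(1, #targets) among the top r (ties: decoys
before targets, then lexicographically smallest member peptide — the
conservative and deterministic order), clamped to 1; q-values are the
running minimum from the bottom of the list, hence monotone and
invariant to input order. The default threshold excludes SEPEPs with
q > 0.01. FDR is estimated globally per study, not per multiplex batch.

## Classification and naming

With g the host genes of a SEPEP's neighborhood, n the isoform count of
the single host gene and k the neighborhood size: C5 if |g| > 1; C1 if
n = 1; C2 if k = 1 < n; C4 if k = n > 1; C3 otherwise. The same truth
table classifies individual peptides in the proteome-wide assessment.

Single-gene SEPEPs are numbered within their gene, multi-gene SEPEPs
study-wide (ordered by their sorted gene key); within a scope the order
is descending member count, ties by smallest member peptide, making
names reproducible byte-for-byte across runs. Names are *not* stable
across studies — the cross-study join key is the alphabetically sorted,
semicolon-joined protein accession key in the mapping table, which
depends only on the neighborhood.

## Quantification

Label-free: SEPEP × sample value = sum of member PSM counts; a zero
total means nothing was observed and is stored as missing, which makes
the missingness filter meaningful for spectral counts (a config choice;
zeros can be kept as observed). Isobaric: value = median of member
log2 ratios over observed members. Gene level applies the same rules to
peptides whose host-gene set is exactly one gene; multi-gene peptides
contribute to no gene. Ratio matrices are normalized by subtracting
per-sample factors equal to the median observed *gene-level* value
(median centering anchored at the gene level so SEPEP and gene matrices
share one normalization); label-free PSM sums are not normalized.
Features missing in strictly more than 50% of samples are dropped
("more than 50%" read strictly: exactly half missing is retained).
Ratios are handled on the log2 scale throughout.

## Downstream statistics

Two-group comparisons use a two-sided t test per feature on pairwise
complete observations — Welch by default (no variance-equality
assumption), classic paired t when pairing is declared; features with
fewer than two observations per group (two non-degenerate pairs if
paired) are reported untested rather than dropped. Covariate analyses
use Pearson r with its two-sided p, requiring three complete pairs and
non-zero variance. Benjamini–Hochberg adjustment runs across all tested
features of a result set. The discordance report compares each
single-gene SEPEP with its host gene at alpha = 0.05 on adjusted p (the
conventional reading; configurable): `sepep_only` when the SEPEP is
significant and the gene is not, `opposite_sign` when both are
significant with opposite effect directions, `concordant` otherwise.
The three categories partition the tested SEPEPs.

## Synthetic studies

The generator emulates the structure the method exploits, behind one
seeded `numpy` generator (byte-identical outputs per seed).

**Proteome.** Each gene's base sequence is a chain of 8–14 tryptic
segments (8–18 residues, K/R terminal, no P after a cleavage site, so
segment boundaries are true tryptic sites). Isoform counts follow
{1: 0.25, 2: 0.35, 3: 0.25, 4: 0.15} (most genes multi-isoform, as in
mammalian annotation). Additional isoforms derive from the base by an
exon-skip-like internal deletion with off-boundary ends (40%, creating
a junction peptide specific to the short form and leaving the deleted
span specific to the long form), a mutually-exclusive-exon-like span
exchange (30%, junction plus novel-exon peptides on the variant), or an
alternative N-terminal exon (30%, a novel first segment). A pure
N-terminal truncation is deliberately *not* used: a truncated sequence
is a substring of the base and can never carry a discriminative
peptide, so such isoforms are invisible to any peptide-level method.
Every generated isoform is validated to retain shared peptides and at
least one isoform-specific length-filtered tryptic peptide. With
probability 0.1 a gene is a paralog sharing a run of segments with its
predecessor, producing multi-gene peptides and hence C5 SEPEPs.

**Abundances and evidence.** Ratio-scale isoform abundances put the
first isoform at linear weight 1 and minors at 0.1 (alternative
isoforms are typically the minor species; this is also what keeps the
planted effects invisible at the gene level). Gene-wise biological
sample variation is N(0, 0.2²) on the log2 scale, shared across the
gene's isoforms. Planted effects add ±1.0 log2 units to one minor
isoform of each of 20 regulated multi-isoform genes — a group shift in
the two-group design, a linear trend spanning the effect across the
time course. A peptide's expected value mixes its source isoforms
additively on the linear scale, `log2(Σᵢ 2^aᵢ)` — the physical model
for shared peptides and the reason parsimony rollup distorts isoform
quantification. Observed ratios add N(0, 0.3²) measurement noise with
10% per-sample dropout; PSM counts are Poisson with mean 8 × linear
abundance (zeros count as unobserved). Evidence is digested at zero
missed cleavages (identified peptides are overwhelmingly fully cleaved)
with the standard 7–50 length window. Each digestible peptide enters
the study with probability 0.9, emulating the deep coverage of
fractionated isobaric experiments over detectable fully tryptic
peptides. Identification scores are Beta(8,2) for genuine peptides and
Beta(2,8) for the 5% of reported peptides drawn from decoy-only
sequences (posterior-probability-like scores for evidence that already
passed upstream peptide-level FDR control).

**What the simulation does not model.** Spectrum-level effects (m/z,
retention time, co-isolation), missed-cleavage kinetics, realistic
score–abundance coupling, and intensity-dependent missingness. Score
separation between genuine and false identifications is stronger than
in raw search output, so the simulated 1% FDR filter rejects fewer
target SEPEPs than a typical real study; the estimator itself is
exercised on overlapping score mixtures in the unit tests. Passing
tests therefore demonstrate the correctness of graph construction,
grouping, error control, rollup and the discordance logic under a
controlled generative model — not the end-to-end error rates of any
particular instrument or search engine.

## Numerical and edge-case choices

Medians over even counts are the mean of the central pair; all-missing
cells stay missing through every transformation. Normalization requires
every sample to have at least one observed gene value. The FDR
threshold must lie in (0, 1]; q-values of an all-decoy input clamp
to 1. Digestion spans are deduplicated by position, and missed-cleavage
counts are recomputed per emitted span (a semi-tryptic fragment's count
reflects the sites strictly inside it). Non-standard residues pass
through untouched and match literally. Evidence rows collapsing to the
same stripped sequence combine as PSM sum / ratio mean / score max.

## Problem sizes

Default verification runs use 200-gene studies (~500 isoforms, ~7,000
unique tryptic peptides, ~750 quantifiable SEPEPs) over 10 seeds,
200 random graphs for the grouping oracle and 100 random sequences per
digestion setting — sizes at which every documented property is
measured in well under a minute each while leaving the estimators'
behaviour clearly resolved.
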