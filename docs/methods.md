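# Methods

## Scoring model

`prionscan` scores aggregation propensity by composition: the per-residue
prion propensities were measured by mutagenizing the Sup35 prion domain and
assaying prion formation, so a window's score is simply the mean propensity
of its residues. The packaged table (`data/propensities.tsv`) carries the 20
values released with the original PAPA implementation; its SHA-256-derived
checksum is printed by `prionscan --version` and recorded in every run
manifest. Users may substitute their own two-column table.

With window size w = 41 (default; must be odd), only full 41-mers act as
component windows. The score anchored at 1-based position k averages the
window means W(j) for j in [max(1, k−w+1), min(k, L−w+1)]: interior
positions average exactly 41 windows — an effective 81-residue span — while
positions within 40 residues of either terminus average over however many
full windows exist (at least one). Anchoring at the last residue of the
first window of each run, rather than at the run start, keeps scores aligned
with residue positions at the termini, which matters when variant and PTM
coordinates must be tested for PrLD membership. This full-windows-only
truncation rule was fixed by requiring the scanner to reproduce the known
hnRNPA1 isoform scores (0.093 / 0.042) — the alternative reading, in which
C-terminally truncated windows also contribute, yields 0.074 for the short
isoform and was rejected.

### Disorder gating

Prion-like aggregation requires intrinsic disorder, so a position receives a
score only when FoldIndex over its governing span is negative:

    FI = 2.785 * <H> − |<R>| − 1.151

where `<H>` is mean Kyte–Doolittle hydrophobicity rescaled to [0, 1] and
`<R>` mean unit net charge (D/E = −1, K/R = +1, H = 0). The constants live
in `ScoringConfig`, not in code paths. By default one FoldIndex is computed
over the union span of the governing windows (up to 81 residues, truncated
at termini); `foldindex_per_window=True` instead averages per-41-mer
FoldIndex values over the governing windows, for comparison with the older
gating behaviour. Proteins with no gated position take the arbitrary
sentinel score −1.0. Note the sentinel is a marker, not an ordering bound:
strongly charged windows can score below it (a poly-K window scores −1.577,
the table minimum), so all interfaces recognise it by exact equality
(`score == −1.0`), never by comparison.

### PrLD calls

Gated positions scoring strictly above a threshold contribute their
governing spans; overlapping spans are merged into maximal intervals, each
carrying the peak contributing score. Thresholds: 0.0 ("relaxed") defines
candidate PrLDs used by the variant and PTM analyses; 0.05 ("classical")
marks aggregation-prone domains. Comparisons are strict (> not ≥). Because a
domain at a higher threshold is built from a subset of the gated positions
at a lower one, calls at 0.05 are always interval-subsets of calls at 0.0.

### Coordinates, precision, residues

All interfaces are 1-based inclusive. Arithmetic is double precision; file
outputs are rounded to 6 decimals; unique-score counting rounds to 9
decimals to collapse float dust. Sequences must use the 20 canonical
residues: strict mode rejects anything else naming accession and position;
lenient mode (default for proteome scans) skips offending proteins with a
logged warning, since the propensity table is undefined off-alphabet.
Trailing `*` stop characters in FASTA records are stripped.

## Variant combinations

For each protein whose reference score exceeds 0.0, variants are filtered to
those matching the reference residue (mismatches are logged and skipped —
public tables mix isoform coordinate frames) and falling inside a PrLD
called on the reference at the relaxed threshold; domain boundaries are not
recomputed per variant. Enumeration yields the reference, every singleton
and every unordered pair at distinct positions (1 + k + C(k,2) − shared-
position pairs); singletons are included because reference-vs-variant
comparisons require them, and a pairs-only flag recovers the stricter
convention. Enumeration is lazy with an optional per-protein cap. Summaries
whose theoretical minimum hits the −1.0 sentinel (a variant can close the
disorder gate everywhere) are flagged and excluded from aggregate outputs.

## Isoform comparison

Isoforms are grouped by an explicit accession→gene TSV (with a
`gene=<symbol>` FASTA-header fallback); unmapped records are reported as
orphans, never silently dropped. Each isoform is compared with its gene's
maximum score: ties all classify as `max_isoform`; `crossing` requires the
isoform at or below the classical threshold with the gene max above it;
`high_with_higher` marks above-threshold isoforms with a higher-scoring
sibling; genes whose isoforms all stay at or below threshold are
`below_both` and excluded from crossing reports.

## Clinical mutations

`p.` notation is parsed in one- and three-letter forms; stop gains,
frameshifts, indels/duplications and synonymous records are excluded with a
reason (never an exception — malformed text is excluded as `unparseable`).
Positions are interpreted on the isoform named by an optional
`isoform_accession` column, because public variant tables frequently mix
frames between canonical and alternative isoforms; reference mismatches go
to a rejects file with a logged warning. Categories are a total function of
(wild-type, mutant) score against 0.05, evaluated in the order decreasing →
high-increasing → threshold-crossing → other; score-decreasing variants are
retained in all outputs.

## PTM enrichment

PrLDs are called at the relaxed 0.0 threshold. Because PrLD composition is
biased, raw counts would confound availability with modification: instead,
for each PTM type the analysis counts modifiable residues (the type's target
residues, packaged in `data/ptm_residues.tsv`: S/T/Y phosphorylation, K
acetylation/methylation/ubiquitination/sumoylation, R methylation;
user-overridable) inside and outside PrLDs, split by observed modification.
A residue modified by type A counts as unmodified for type B. The odds ratio

    OR = (f_in / (1 − f_in)) / (f_out / (1 − f_out)),  E = ln OR

is reported with the Wald standard error sqrt(1/a + 1/b + 1/c + 1/d), a
two-sided Fisher exact p, and Benjamini–Hochberg q across types at FDR 0.05.
Types with fewer than 100 proteome-wide sites are excluded before
correction. Zero cells leave OR/SE undefined and flagged; an optional
Haldane–Anscombe +0.5 correction estimates them anyway (the Fisher p always
uses raw counts). Duplicate (accession, position, type) records are
de-duplicated; sites beyond protein length, mismatching the sequence, or on
non-modifiable residues are rejected with logs.

## Synthetic fixtures

The generator emulates the structural features the analyses depend on, not
a realistic proteome. Proteins are block concatenations whose alphabets
(packaged data) make FoldIndex signs analytically predictable: Q/N-rich
blocks (Q 26%, N 26%, S 12%, G 10%, Y 14%, T 5%, K 3%, R 4%) are disordered
with positive mean propensity ≈ 0.09, charged blocks are disordered but
strongly prion-inhibiting, hydrophobic blocks are ordered. The default
architecture (ordered 60–100 / charged 50–80 / Q/N 90–140 / charged 50–80 /
ordered 60–100) plants one central PrLD per 80-protein proteome record; 30%
of genes get a second isoform with the Q/N block spliced out. Variants are
planted inside PrLDs alternating score-raising (→Y/W) and score-lowering
(→K/D) substitutions, with direction labels derived by rescoring. PTM sites
are planted per type (defaults: 550 sites each, scaled with proteome size;
arginine methylation at odds ratio 3, the others neutral) by solving for the
outside-odds that hits the target site count, Bernoulli sampling, and
rejection-resampling until the realized odds ratio is within 5% of plan —
so downstream estimates are checked against realized, not asymptotic,
truth. All stages stream from a single seeded generator; identical specs
give byte-identical bundles.

What fixtures do **not** emulate: real residue-order correlations, realistic
length and composition distributions, overlapping/nested PrLDs, isoform
frames that shift variant coordinates, or biological PTM clustering.
Passing fixture tests therefore demonstrates algorithmic correctness and
statistical calibration, not performance on any real proteome release.

## Problem sizes and numerical choices

The test and acceptance runs use 20–80-protein synthetic proteomes, 200
random proteins (41–500 aa) for oracle-equivalence sweeps, and 100 seeded
replicates for planted-odds-ratio recovery; these sizes give stable
statistics (≥ 500 sites per PTM type at the default proteome size) while
keeping runs in seconds. Score comparisons in tests use 1e−9 absolute
tolerance; the vectorised engine agrees with the naive oracle to ~1e−14.
Fisher p-values come from `scipy.stats.fisher_exact` and are oracle-checked
against exhaustive hypergeometric tail summation on small-margin tables; BH
correction uses `statsmodels` and is oracle-checked against the textbook
step-up recursion.

## Known limitations

- The propensity table is Sup35-derived; scores extrapolate to other
  proteins by composition only.
- FoldIndex is the only disorder gate; no other predictors are consulted.
- Combination enumeration is quadratic in the per-protein variant count; use
  the cap for pathological inputs.
- PLAAC-style composition-likelihood calls are out of scope; isoform outputs
  reserve a pass-through column for externally computed PLAAC annotations.
- N-terminal modifications have no modifiable-residue semantics here and are
  not analysed.
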