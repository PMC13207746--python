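# Methods

## Data model

A corpus is a set of condition-level datasets from published studies. Each
dataset is one biological/experimental condition and is either *profiling*
(a qualitative list of identified phosphosites, each carrying a localization
probability and/or A-score) or *differential* (a quantitative test-vs-control
comparison giving fold change and p-value per site). A study (PMID) may
contribute many datasets; the (PMID, condition-code) pair is the unit of the
replication filters. Phosphosites are identified by HGNC gene symbol,
accession, residue letter (S/T/Y) and 1-based position, written
`GENE_R<pos>` (e.g. `CAV1_Y14`). Integration happens at the level of
reported site identifications and calls; raw mass-spectrometry data are
never touched.

## Filters and calls

* **Class-I localization** — a profiling record is kept iff localization
  probability ≥ 0.75 (inclusive) or A-score > 13 (strict). The A-score
  boundary is deliberately exclusive; both thresholds are configurable
  (`FilterConfig.loc_prob_min`, `ascore_min`).
* **Differential call** — `U` iff fold change ≥ 1.3 and p < 0.05, `D` iff
  fold change ≤ 0.76 and p < 0.05, `none` otherwise. Fold changes are
  treatment/control ratios; the up/down thresholds are asymmetric on
  purpose (0.76 ≈ 1/1.3).
* **Duplicates** — multiple rows for one (site, dataset) collapse to one
  record: profiling keeps the maximum localization confidence; differential
  keeps the row with the most extreme fold change, except when duplicates
  imply both a U and a D call (distinct multiply-phosphorylated peptides),
  where the call with the smaller p-value wins and an exact tie drops the
  group as a conflict. Rationale: all downstream frequencies are counted
  per dataset, not per peptide.
* **Harmonization** — gene aliases are re-keyed through an alias→symbol
  table (a gene already canonical passes through); symbols are assigned
  accessions through a symbol→accession table; records failing either step
  are dropped and counted in a report. Sites detected in a study but failing
  the Class-I criterion are excluded from all frequency counts.

## Predominance

Per site of the target protein: the number of profiling datasets detecting
it, the number of differential datasets calling it (split U/D), and the
number of distinct PMIDs across both. Sites are ranked by profiling +
differential total (ties: differential count, then position). A site is
*predominant* iff detected in both dataset types and replicated in ≥ 3
studies (`min_pmids`). The combined rank key reflects the requirement that
predominant sites be consistently detected in both qualitative and
quantitative data. Differential-only sites are listed in the frequency
table (differential records carry no localization columns and are assumed
Class-I-curated upstream); they simply cannot be predominant.

## Intra-protein co-occurrence

For a site pair, the patterns UU/DD/UD/DU are tallied over differential
datasets where **both** sites are called; conditions where either site is
undetected or sub-threshold are ignored here (they enter only the
cross-protein contingency below). The positive co-regulation ratio is
(n_UU + n_DD)/(n_UD + n_DU); the negative ratio is its reciprocal. A zero
denominator with nonzero numerator yields `inf` ("infinite concordance");
0/0 yields NaN ("no data"). These sentinels are a package choice — exports
print `inf` and an empty cell. Under the generator, the conditional
concordance of a pure planted pair is ρ, so the positive ratio estimates
ρ/(1 − ρ).

## PsOP screen

For a predominant site versus a site on a different protein, every
differential dataset of the corpus falls in exactly one cell: *a* neither
called, *b* exactly one called (symmetric in which one), *c* both called
discordantly, *d* both called concordantly; a + b + c + d equals the number
of differential datasets. Only U/D calls count as "detected" in this table.

Significance is a one-sided Fisher's exact test on the 2×2
[[a, b], [c, d]], conditioning on its row margins (a+b, c+d) and column
margins (a+c, b+d). The hypergeometric family is indexed by the *d* cell:
the UUDD (positive) screen sums tables at least as extreme toward large *d*,
the UDDU (negative) screen toward large *c*. This cell-wise definition of
extremeness is what makes the two one-sided screens distinct; it coincides
with the usual odds-ratio-greater/less one-sided tests on the same 2×2
(at fixed margins *a* grows with *d*), which the test suite exploits as an
independent cross-check against `scipy.stats.fisher_exact`. The p-value is
computed with exact integer arithmetic (a single big-integer tail sum
divided by one binomial coefficient), and the test suite verifies it against
brute-force enumeration of all fixed-margin tables for every 2×2 with
n ≤ 50 at 1e-12.

A (site, category) row is emitted whenever its co-regulation frequency
(*d* for UUDD, *c* for UDDU) is nonzero, and **passes** iff

1. raw FET p < 0.05 (`fet_alpha`);
2. frequency ratio ≥ 0.10: co-regulation frequency divided by the
   predominant site's total differential frequency (`freq_ratio_min`);
3. ≥ 3 distinct PMIDs among the datasets contributing to the row's own
   category (`min_pmids`);
4. ≥ 3 distinct condition codes likewise (`min_codes`).

No multiple-testing correction enters the filters — the replication
criteria play that role — but a Benjamini–Hochberg column (`fet_bh`,
via statsmodels) is emitted for reference.

## Cross-referencing

A kinase is reported for a target site iff it annotates that site in the
kinase–substrate table AND at least one of the kinase's own phosphosites
passes the PsOP screen; evidence (validated/predicted) and sources are
carried through. Interaction partners require support from ≥ 2 distinct
source databases by default (`min_db_support`, configurable) — a reading of
"corroborated by cross-database support". Process grouping is descriptive
annotation, not enrichment; unannotated passing sites land in an
`unannotated` bucket. All outputs are deterministic with stable row order,
and every reported gene appears in the corresponding input table.

## Synthetic corpora

The generator defines the study conditions under which the pipeline is
validated. Structure: `n_studies` studies, each contributing a fixed or
ranged number of conditions; every condition yields one profiling and one
differential dataset (enrichment STY). An automatic roster of proteins
(`P0001`…) carries deterministically laid-out sites (residues cycling
S/T/Y, positions stepping by 10) at a background detection probability;
additional sites may be declared with their own detection probabilities.

Per condition, each site is detected independently with its detection
probability and given a tentative sign (U/D equiprobable). A **planted
pair** (anchor, partner, ρ, co_detect) then adds structure: whenever the
anchor is detected, the partner is forced detected with probability
`co_detect` and its sign set concordant with the anchor's with probability ρ
(discordant otherwise). Making co-detection conditional on the anchor lets
one predominant site anchor many pairs without its own detection saturating
— with a symmetric "both forced" event, twenty pairs at co-detection 0.6
would leave the anchor detected in essentially every condition, emptying the
*a* cell and destroying the contingency's power by construction rather than
by biology.

Fold changes are drawn log-normally around the effect sizes (defaults 1.8
up, 0.55 down, σ = 0.2 on the log scale) and truncated to stay beyond the
call thresholds, so a record's call is decided by its p-value: members of
planted pairs and declared predominant sites draw p ~ U(0, 0.05) (their
calls always survive), null sites draw p ~ U(0, 1) (≈ 5 % of their
detections are called), emulating background regulation. Profiling records
mirror detection with localization probabilities uniform on [0.75, 1] (all
Class I). Randomness is one `numpy` SeedSequence seeded once, with a child
stream per condition, so corpora are bit-reproducible and stable under
per-condition parallelism.

The **canonical study corpus** (`default_study_config`) has 5 studies × 12
conditions, a CAV1-like target with two predominant sites (detection 0.5
and 0.6 — the range in which frequently observed phosphosites of a single
protein are reported across public corpora), an intra-protein pair at
ρ = 0.75, twenty partner sites on distinct proteins planted at ρ = 0.95
with co-detection 0.6, and 200 null sites at background detection 0.2.
The detection levels were fixed once, by a pilot across many generator
seeds of the enumeration-verified pipeline, inside that realistic range;
with them the screen recovers 19–20 of the 20 planted pairs and flags no
null site on every pilot seed.

What the generator does **not** emulate: peptide-level effects (missed
cleavages, enrichment-chemistry bias, variable ionization), protein-
abundance confounding of site-level co-regulation, correlated study-level
batch structure, and non-uniform p-value behavior under misspecified
models. Passing tests therefore demonstrate the correctness and statistical
behavior of the pipeline under its stated model, not robustness to every
artefact of real mass-spectrometry corpora; on real data the replication
filters (PMIDs, condition codes) are the main defense against such
artefacts.

## Numerical and degenerate-input choices

* Fisher p-values use exact integer arithmetic; `p = 1` for an empty table
  or when the observed table is the least extreme attainable (e.g.
  c = d = 0).
* Ratio sentinels as above (`inf` / NaN), never exceptions.
* Ties in predominance ranking break by differential count, then position
  ascending (stable mergesort).
* An absent protein yields an empty table with a warning; an uncalled
  predominant site yields an empty screen with a warning; fewer than two
  called sites yield an empty co-occurrence table with a warning.
* Written corpora use shortest round-trip float formatting and re-read
  exactly (reading uses numpy's float parser, which is round-trip exact).

## Problem sizes used in validation

The test suite and acceptance script verify the Fisher test on all 316,251
tables with n ≤ 50 (both directions), check the algebraic invariants on
1,000 randomized mini-corpora, run the planted-recovery/null-control screen
on the canonical 60-condition corpus, and calibrate concordance ratios on
600-condition pure-pair corpora (within three delta-method standard errors
of ρ/(1 − ρ): Var ≈ ρ / (n(1 − ρ)³)). These sizes give stable statistics
while keeping the whole validation under a minute.
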