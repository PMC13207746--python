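# phoscoreg

Site-centric co-regulation analysis of protein phosphorylation across
multi-study phosphoproteomic corpora.

Published phosphoproteomic studies report, per experimental condition,
either qualitative *profiling* lists of identified phosphosites or
quantitative *differential* comparisons (fold change + p-value per site).
Integrating hundreds of such condition-level datasets makes it possible to
ask questions no single study can answer about a protein of interest — the
package's demo target is Caveolin-1 (CAV1), whose tyrosine 14 and serine 37
are its best-known phosphosites:

1. **Which phosphosites of the target protein are predominant?** Sites are
   ranked by detection frequency — the number of datasets identifying the
   site — and sites detected in both dataset types across ≥ 3 independent
   studies are designated predominant.
2. **Do sites within the protein move together?** For each site pair, the
   four joint regulation patterns UU, DD, UD, DU are tallied over conditions
   where both sites are called; the positive co-regulation ratio is
   (n_UU + n_DD) / (n_UD + n_DU) and the negative ratio its reciprocal.
3. **Which phosphosites of other proteins (PsOPs) co-regulate with a
   predominant site?** Each experimental condition is classified into a 2×2
   contingency — *a*: neither site called, *b*: exactly one called, *c*:
   both called discordantly, *d*: both called concordantly — and a one-sided
   Fisher's exact test on [[a, b], [c, d]] scores concordance (extremeness
   toward large *d*; UUDD category) or discordance (toward large *c*; UDDU).
   High-confidence PsOPs must pass four filters: raw p < 0.05, co-regulation
   frequency ≥ 10 % of the predominant site's differential frequency, and
   support from ≥ 3 distinct publications (PMIDs) and ≥ 3 distinct
   experimental-condition codes.
4. **What do the hits mean?** Passing PsOPs are cross-referenced against
   curated kinase–substrate, protein–protein-interaction and
   biological-process tables.

Upstream of all of this, records are harmonized to canonical gene symbols
and accessions, restricted to Class-I phosphosites (localization
probability ≥ 0.75 or A-score > 13), and calls are derived as **U** (fold
change ≥ 1.3, p < 0.05) or **D** (fold change ≤ 0.76, p < 0.05).

Because public corpora of this kind are assembled by manual curation, the
package ships a synthetic-corpus generator with planted ground truth
(predominant sites, concordant site pairs with tunable concordance ρ and
co-detection probability, and null sites), so every stage of the pipeline is
verifiable end to end without downloads. See `docs/methods.md` for the
generative model and all design decisions.

## Worked example

The packaged demo simulates the canonical study corpus (5 studies × 12
conditions; CAV1_Y14 and CAV1_S37 planted as predominant sites; 20 partner
sites planted at concordance 0.95 with co-detection 0.6; 200 null sites) and
runs every stage:

```bash
phoscoreg run --config examples/run.cfg
```

The JSON summary printed at the end includes

```
"predominant_sites": ["CAV1_S37", "CAV1_Y14"],
"psop_passing": {
  "CAV1_S37": {"UDDU": 0, "UUDD": 0},
  "CAV1_Y14": {"UDDU": 0, "UUDD": 20}
}
```

Both planted predominant sites are recovered (`demo_out/predominant.tsv`
shows S37 ranked first with 37 profiling + 37 differential detections over
5 studies, Y14 second with 29 + 29), and exactly the 20 planted partner
sites pass all four high-confidence filters for CAV1_Y14 — the top row of
`demo_out/psop_CAV1_Y14.tsv` reads contingency (a, b, c, d) = (23, 11, 2, 24)
with one-sided FET p ≈ 2×10⁻⁶ and frequency ratio 0.83. The crossref stage
then reports the two synthetic kinases whose own phosphosites pass the
screen (`kinases_CAV1_Y14.tsv`) and the one interaction partner with
two-database support (`interactors_CAV1_Y14.tsv`).

Each stage is also available separately:

```bash
phoscoreg simulate    --config examples/sim.cfg --out corpus/
phoscoreg predominant --corpus corpus/ --protein CAV1 --out freqs.tsv
phoscoreg cooccur     --corpus corpus/ --protein CAV1 --out cooccurrence.tsv
phoscoreg psop        --corpus corpus/ --site CAV1_Y14 --out psop_y14.tsv
phoscoreg crossref    --psop psop_y14.tsv --site CAV1_Y14 \
    --kinases examples/synthetic_kinases.tsv --ppi examples/synthetic_ppi.tsv --out xref/
```

Real corpora are read from three TSV files (`datasets.tsv`,
`profiling.tsv`, `differential.tsv`; column schemas in
`src/phoscoreg/io.py`), with optional `gene_map.tsv` / `accession_map.tsv`
for identifier harmonization.

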