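# exofam

Family-exome variant prioritization for Mendelian disease, plus the
downstream analyses that typically accompany a candidate-gene study:

- **Filter cascade** — QC-flag exclusion, homopolymer/tandem-repeat-adjacent
  indel exclusion, population allele-frequency filtering (strict >1%
  monogenic / >10% polygenic, with database absence treated as evidence of
  rarity), and effect-class retention, with a per-stage funnel report.
- **Segregation** — pedigree-aware inheritance-model predicates: de novo
  (with a <5x low-coverage confidence flag), homozygous autosomal recessive,
  and X-linked recessive (hemizygous genotype handling on chrX).
- **Prioritization** — ensemble deleteriousness majority vote over ten
  prediction tools (deleterious = 1, ambiguous = 0.5, strict >half rule),
  additive gene-evidence scoring (disease association, tissue expression,
  RVIS intolerance), and deterministic lexicographic ranking.
- **Network** — induced PPI module computation over seed proteins (bounded
  seed-to-seed path induction, default <=3 edges) and hypergeometric
  gene-set over-representation with Benjamini-Hochberg correction.
- **Assay statistics** — comparative-Ct (2^-ddCt) qPCR quantification,
  Renilla-normalised dual-luciferase activation, calcium standard-curve
  calibration, and Welch two-group comparisons with mean +/- SEM.
- **Synthetic data** — cohort, network, sequence-context and assay-table
  generators with planted ground truth, so every stage is testable without
  any external download.

## Test

```bash
python -m pytest -q tests/
```

The suite includes property-based tests (hypothesis) and brute-force oracle
comparisons for the segregation predicates, the ensemble vote, the network
induction, and the hypergeometric test.

## CLI

```bash
# generate a synthetic cohort with a planted X-linked recessive variant
exofam simulate --out sim/ --seed 1 --n-background 1000

# run the full cascade on it (filters -> segregation -> vote -> rank)
exofam prioritize \
    --vcf sim/cohort.vcf --ped sim/cohort.ped \
    --annotations sim/annotations.tsv --contexts sim/contexts.tsv \
    --truth sim/truth.json --out run/

# induced network module over a PPI edge list
exofam simulate-network --out net/
exofam network --edges net/edges.tsv --seeds net/seeds.txt --out module/

# assay quantification
exofam simulate-assay --assay qpcr --out assay.csv \
    --group control=1.0 --group treated=0.55
exofam assay --table assay.csv --assay qpcr \
    --control-group control --out qpcr_out/

# simulate + prioritize in one step
exofam full --out run/ --seed 1
```

`prioritize` writes `report.json` (funnel, ranked candidates,
planted-truth recovery), `funnel.tsv`, `candidates.tsv`, and a
`manifest.json` recording the config hash, seed, and input digests.
Validation failures exit with code 2.

## Layout

```
src/exofam/io_formats/   PED / VCF / annotation TSV / GMT / edge-list /
                         assay-CSV readers and writers, domain types
src/exofam/synthetic.py  cohort, context, network and assay generators
src/exofam/filtering.py  filter cascade + funnel report
src/exofam/segregation.py inheritance-model predicates
src/exofam/prioritization.py  vote, gene evidence, ranking, report
src/exofam/network.py    induced modules + enrichment
src/exofam/assays.py     qPCR / luciferase / calcium / group comparisons
src/exofam/cli.py        click-based CLI (exofam ...)
src/exofam/examples.py   hard-coded worked-example fixtures
```
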