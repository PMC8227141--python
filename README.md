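# circmeth

Integrative circRNA / DNA-methylation differential analysis on paired
tumor/normal multi-omics data, exercised end to end on synthetic bundles
with planted, manifest-recorded ground truth.

The pipeline:

1. **simulate** — paired tumor/normal bundle: gene annotation, circRNA
   catalog (exonic/intronic/intergenic), negative-binomial gene/circRNA
   (back-splice junction)/miRNA count matrices with planted log2 fold
   changes, 450K-style beta-value probe table with planted M-shifts inside
   circRNA regions, and Gaussian-copula coupling between selected circRNA/
   probe pairs. Every planted effect is recorded in a ground-truth manifest.
2. **de** — median-of-ratios size factors, moment/trend-shrunk NB
   dispersion, per-feature NB GLM Wald test, BH adjustment. Calling rules:
   genes/miRNAs need adjusted p < 0.05 and |log2FC| > 1; circRNAs need
   adjusted p < 0.05 plus junction support (BSJ count >= 2 in >= 2 samples,
   no fold-change cutoff).
3. **dm** — beta -> M logit transform, empirical-Bayes moderated t with a
   moment-matched variance prior; hyper/hypo calls at adjusted p < 0.05 and
   |dM| > 0.5.
4. **regions** — strand-aware Pre2000 / Interior / After2000 intervals per
   circRNA (2 kb flanks around the back-splice span), promoter/gene-body per
   gene, and exact probe-to-region assignment.
5. **integrate** — DE circRNAs harboring DM sites; the decoupling filter
   (circ DE + DM site, parental gene not DE); Spearman methylation-
   expression correlation (exact permutation p for small n); opposite-
   pattern circ/gene pairs; region-level DM summaries; chromosome density;
   Fisher overlap test; hypergeometric over-representation.
6. **cerna** — miRNA seed matching (8mer/7mer-m8/7mer-A1/6mer), a simplified
   duplex score with the score > 140 / energy < -20 retention rule, a
   validated miRNA-target filter, and assembly of the direction-constrained
   tripartite circRNA-miRNA-mRNA network.
7. **classify** — stratified 10-fold cross-validated ROC/AUC of tumor/normal
   classification from DE-circRNA expression features (rank-based AUC;
   nearest-centroid and k-NN reference classifiers, pluggable interface).

## CLI

```bash
# generate a synthetic bundle (plain-text TSV/BED6/FASTA + manifest.json)
circmeth simulate --out bundle/ --seed 1

# validate, then run individual stages
circmeth validate --bundle bundle/
circmeth de --bundle bundle/ --layer circ --out de_circ.tsv
circmeth dm --bundle bundle/ --out dm.tsv
circmeth regions --bundle bundle/ --out assignments.tsv

# or everything at once (simulates when --bundle is omitted)
circmeth all --out results_run/ --seed 1
```

`circmeth all` writes per-layer DE tables, the DM table, probe/region
assignments, the decoupled-circRNA correlation table, region-level DM
summaries, the ceRNA edge list + GraphML, and `report.json` with the
headline counts (n DE per layer, n DM, n DE circ with DM, n decoupled,
n correlated, network size, CV AUC).

Flags of note: `--flank-convention genomic-left` (strand-naive flanks),
`--paired` (pair covariates in the NB GLM), `--dm-cutoff`, `--p-adj-cutoff`.

## Layout

```
src/circmeth/
  simulate.py    synthetic multi-omics generation + ground-truth manifest
  bundle.py      bundle container, plain-text round-trip I/O
  diffexpr.py    NB differential expression (size factors, dispersion, Wald, BH)
  diffmeth.py    beta->M, moderated t, hyper/hypo calls
  regions.py     circRNA/gene region construction, probe mapping
  integrate.py   decoupling filter, Spearman correlation, summaries, Fisher/ORA
  cerna.py       seed match, duplex score, ceRNA network
  evaluate.py    stratified k-fold, rank AUC, CV harness
  pipeline.py    orchestration + run report
  cli.py         click CLI
tests/           unit + property tests; test_acceptance.py holds the
                 acceptance criteria, one test per criterion
```
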