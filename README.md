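# clonecensus

Clonal population-size estimation for gene-therapy clone tracking, TCR-beta
repertoire analysis, and microbial community ecology — with a synthetic-data
simulator that makes every estimator testable by parameter recovery.

## The problem

After hematopoietic gene therapy (e.g. for X-linked severe combined
immunodeficiency), each corrected progenitor cell carries the vector
integrated at a unique genomic position, so a unique integration site marks
one progenitor clone. Each mature T cell additionally carries a rearranged
TCR-beta CDR3 whose nucleotide sequence marks one T cell clonotype.
Sequencing samples only a small fraction of either population, so raw unique
counts understate the true clone numbers. `clonecensus` reconstructs minimum
population sizes from replicate sampling, and combines the two estimates
into a minimum bound on the number of cell divisions between progenitors and
peripheral T cells.

## Core statistics

**Chao1** (abundance-based, used for integration sites), with singleton and
doubleton counts f1, f2 over S_obs observed species:

    Chao1 = S_obs + f1^2 / (2 f2)

**Chao2** (incidence-based across m sequencing replicates, used for TCR-beta
clonotypes), with Q1/Q2 the species seen in exactly one/two replicates:

    Chao2 = S_obs + ((m-1)/m) * Q1^2 / (2 Q2)

Both fall back to the bias-corrected form `r1 (r1-1) / (2 (r2+1))` when the
doubleton class is empty, and both are lower-bound estimators. Confidence
intervals use the standard log-transform of the estimated excess.

**Division bound.** With TCRs and IntSites the two reconstructed population
sizes,

    CellDivisions = log2(TCRs - IntSites)

is the smallest number of divisions consistent with the data (cell death
only raises the true number). A per-progenitor variant
`log2(TCRs / IntSites)` is provided as a labeled alternative.

**Sonic abundance.** The number of cells in one clone is inferred from the
number k of distinct sheared-fragment lengths at its integration site by
inverting the occupancy curve `E[distinct] = sum_l (1 - (1 - theta_l)^n)`.

Also included: productive/frameshift/stop CDR3 classification, richness and
Pielou evenness, V/J usage with chi-squared comparison against a reference
cohort, Bray-Curtis dissimilarity with t-SNE embedding, contaminant
filtering, PERMANOVA, healthy-reference richness bands, Wilcoxon rank-sum
group comparisons, and RPKM quantification of marker-gene hits.

## Worked example

```python
from clonecensus import CloneCensus
from clonecensus.synthetic import SimulationConfig, simulate_dataset

cfg = SimulationConfig(n_progenitors=25, divisions=10, rearrangement_depth=3,
                       reads_per_replicate=2000, seed=7)
truth, intsites, clonotypes = simulate_dataset(cfg)
results = CloneCensus(intsites, clonotypes).fit()
print(results.summary())
```

prints

```
Clone census
============================================================
Population estimates (Chao lower bounds):
subject_id  timepoint_months     kind  observed_richness  estimate  ci_low  ci_high estimator
        S1              12.0 intsites                 25      25.0    25.0     25.0  chao1_bc
        S1              12.0      tcr                154     154.0   154.0    154.0  chao2_bc

Minimum cell divisions, log2(TCRs - IntSites):
subject_id  timepoint_months  tcr_estimate  intsite_estimate  divisions  divisions_ceil
        S1             12.00        154.00             25.00       7.01               8
Cohort: median 7.0, min 7.0, max 7.0 (1 defined, 0 undefined)
```

The simulation marked 25 progenitors and let each lineage rearrange its TCR
three divisions in, producing 194 distinct clonotypes of which 154
productive ones were recovered at this depth. Deep quadruplicate sampling
sees every site and clonotype, so the Chao estimates equal the observed
richness with degenerate intervals. The division bound, log2(154 - 25) =
7.01, is below the true 10 divisions, as a minimum bound must be.

The same analyses are scriptable from the shell:

```sh
clonecensus simulate --config sim.yaml --out-dir fixtures/
clonecensus chao --kind intsites --input fixtures/intsites.tsv --out estimates.tsv
clonecensus run --config run.yaml
```

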