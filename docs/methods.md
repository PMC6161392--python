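# Methods

## Scope and model

`clonecensus` treats a gene-therapy cohort as a collection of clone-marked
cell populations observed through replicate sequencing. Two marker systems
are modelled jointly:

- **Integration sites.** A vector-host junction is identified by the exact
  1-based triple (chromosome, position, strand). Because the genome is
  large relative to the number of transduced cells, a unique site is taken
  to mark a unique progenitor. An optional merge window (0-5 bp, default
  0, merging to the minimum position) absorbs off-by-a-few artifacts of
  shearing-based protocols; it is off by default because no merge rule can
  be assumed in general.
- **TCR-beta clonotypes.** A clonotype is the CDR3 nucleotide sequence.
  Frame status is always recomputed from the sequence (frame anchored at
  position 1; length not divisible by 3 is a frameshift, an in-frame stop
  codon is `stop`, otherwise `in_frame`); file labels are advisory only,
  so downstream richness has a single source of truth. All repertoire
  statistics use productive rearrangements unless asked otherwise, since
  nonproductive sequences do not mark functional clones. Amino-acid
  collapsing is available behind a flag.

## Population-size estimation

Chao1 is applied to integration sites using per-site abundances, where one
"individual" is a distinct (replicate, fragment length) capture of the site
— reads identical in site, replicate and length are PCR duplicates. Chao2
is applied to clonotypes as presence/absence per replicate; it requires at
least two replicates, and fitted groups with fewer are reported as
unestimable rather than silently dropped. The classic estimators are the
default, with the bias-corrected form used automatically when the
doubleton class is empty and available everywhere via a flag; Chao2
includes the small-sample factor (m-1)/m by default (toggleable) because
typical designs use only four replicates.

Variances use the standard Chao formulas (classic when the doubleton class
is nonzero, the bias-corrected variant otherwise) and intervals use the
log-transform of T = estimate - S_obs, which keeps the lower limit at or
above the observed richness. Two known properties matter in practice:
the interval degenerates to the point estimate when there are no
singletons, and near saturation (essentially all species observed but a
few singletons remaining) the interval sits strictly above the truth, so
coverage claims are only meaningful in the extrapolation regime (roughly
2-5 reads per species in the test suite, where empirical coverage of a
95% interval is 92-96%).

## Sonic abundance

Clone sizes within a sample are estimated from fragment-length diversity:
n cells sheared independently produce distinct junction-to-break lengths,
and the expected number of distinct lengths among n draws from length
distribution theta is `sum_l (1 - (1 - theta_l)^n)`. The estimator inverts
this monotone curve at the observed distinct-length count k by bisection
(tolerance 1e-6, cap 1e9 cells); k equal to the full support is reported
as saturated rather than extrapolated. The default theta is the pooled
empirical length distribution over all sites, which is exact for the
simulator's uniform shear model; an optional EM-style refinement
alternates theta (re-weighted by estimated clone sizes spread over each
clone's observed lengths) with re-inversion until estimates move less than
1e-6, capped at 200 iterations.

## Ontogeny bound

The minimum number of divisions between marked progenitors and the
observed T cell pool is `log2(TCRs - IntSites)` on the two population
estimates, computed only within a (subject, timepoint, cell fraction)
pairing. The difference form is the primary definition; the
per-progenitor reading `log2(TCRs / IntSites)` is shipped as a clearly
labeled alternative because the two coincide only when the progenitor
count is negligible next to the clonotype count. Pairs where the TCR
estimate does not exceed the site estimate are undefined and propagate as
flagged rows with a reason code, never as silent omissions. PBMC-derived
pairs can be flagged through the optional `cell_fraction` column.

Because both inputs are lower-bound estimators and rearrangement happens
after some initial divisions, the bound is itself a minimum: on simulated
ontogeny it must not exceed the true division count (plus sampling
tolerance). This holds only when the simulated pool satisfies
`log2(P * (q * 2^r - 1)) <= d` for P progenitors, rearrangement depth r,
productive fraction q and true divisions d — the acceptance suite uses
P = 25, r = 3, q = 0.8 against d in {8, 10, 12}.

## Synthetic data

The simulator emulates the study design, not patient biology:

- Progenitors are marked by sites drawn uniformly over a configurable
  genome (both strands) without collision.
- Expansion is a synchronous Galton-Watson doubling: each daughter cell
  survives each round independently with probability 1 - per_division_loss
  (default 0, making clone sizes exactly 2^divisions and oracles exact).
- Each surviving lineage branch at `rearrangement_depth` (default 0)
  receives its own VDJ clonotype: toy V segment + non-templated insertion
  + toy J segment, with the insertion length padded or the sequence
  resampled so the realized productive fraction matches
  `productive_fraction` (default 0.8) in expectation.
- Replicate sampling draws `reads_per_replicate` cells with replacement
  proportionally to clone size (default 4 replicates of 10 000 reads,
  mirroring quadruplicate reactions used to suppress PCR jackpotting);
  each sampled cell yields one site observation with a fresh shear length
  (default uniform 50-250 bp) and one template toward its clonotype's
  per-replicate count. Jackpotting itself can be emulated with a
  per-branch, per-replicate lognormal capture bias (sigma, default 0 so
  conservation oracles stay exact).
- Community tables are Poisson draws around log-normal taxon intensities
  with a group mean shift (natural-log units) on a random half of taxa;
  group_effect = 0 yields an exchangeable null used for calibration.

What the simulator does **not** model: realistic human germline V/J sets,
clone-size distributions of real patients, PCR chimeras, sequence errors,
or repeated-measures correlation in community data. Passing recovery tests
therefore demonstrates estimator correctness under the stated sampling
model, not robustness to those real-data features.

## Community ecology

Contaminant filtering matches blocklist entries against feature ids by
exact or lineage-prefix match; the shipped default list contains taxa
whose reads recur as reagent or cross-annotation artifacts (Apicomplexa;
common kit phages; herpesviruses 6/7; Shamonda virus) and is user-editable
YAML. Richness bands count nonzero features on raw counts (no
rarefaction) and use a t-interval across reference samples per body site.
Bray-Curtis is `sum|x-y| / sum(x+y)` on the vectors as given — normalize
to proportions first (the pipeline does) when comparing samples of
unequal depth. PERMANOVA uses the standard one-way sum-of-squares
partition on squared distances with freely permuted labels and the
Monte-Carlo +1 p-value correction (default 999 permutations); strata for
repeated measures are not modelled, so longitudinal designs should read
its p-values as descriptive. Rank-sum comparisons use exact enumeration
for tie-free groups of at most 8, the tie-corrected normal approximation
otherwise. RPKM is `count / ((length/1000) * (total/1e6))`, with
class-level aggregation by summation.

Chi-squared usage comparisons align the observed and reference segment
universes, pool expected counts below 5 (Cochran's rule) into an "other"
category — folding that category into the smallest kept one if it still
falls short — and report a degenerate (0, 0 df, p=1) result when pooling
leaves a single category. No multiple-testing correction is applied by
default; a Benjamini-Hochberg helper is deliberately out of scope of the
defaults since single-comparison p-values are the primary output.

## Determinism and problem sizes

Every stochastic component takes a NumPy `default_rng` seed explicitly;
the pipeline records the config hash and library versions in a manifest
sufficient to reproduce outputs byte-for-byte. The test suite's
simulation sizes (pools of 100-1000 species, 100 seeds per condition for
recovery and lower-bound suites, 1000 null seeds for PERMANOVA
calibration at 30 taxa x 12 samples) were chosen as the smallest designs
in which the targeted statistical properties are distinguishable from
noise at the asserted tolerances.
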